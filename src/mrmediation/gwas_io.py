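"""Reading, validating, filtering and LD-clumping GWAS summary statistics.

All file input for trait data flows through this module. Tables are plain
TSV with a header; column names are remapped through a ``column_map`` so
consortium files with arbitrary headers can be loaded without editing.
Effect sizes for binary traits are log-odds; a file that reports odds
ratios instead of betas can be log-transformed at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrmediation")

VALID_ALLELES = frozenset("ACGT")

#: default header names expected in input TSVs, keyed by canonical field
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}

#: canonical fields that must be present in every table
MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


class TraitType(str, Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"


class ConfigurationError(ValueError):
    """A column mapping, threshold or config value is unusable."""


class InputDataError(ValueError):
    """Input data violate the contract (empty tables, missing variants...)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP-trait association.

    ``beta`` is the per-effect-allele effect: log-odds for binary traits,
    trait units or SD for continuous traits. ``eaf`` and ``n`` are optional
    (NaN / None when absent).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def is_valid(self) -> bool:
        ok = (
            self.effect_allele in VALID_ALLELES
            and self.other_allele in VALID_ALLELES
            and self.effect_allele != self.other_allele
            and np.isfinite(self.beta)
            and self.se > 0
            and 0 < self.pval <= 1
        )
        if ok and self.eaf is not None and not np.isnan(self.eaf):
            ok = 0 < self.eaf < 1
        return bool(ok)

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"G", "C"})


_COLUMNS = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]


@dataclass
class SummaryStatTable:
    """A validated GWAS summary-statistics table for one trait.

    Backed by a pandas DataFrame with canonical columns; records are unique
    by ``variant_id`` and keep their input order.
    """

    trait_label: str
    trait_type: TraitType
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.trait_type = TraitType(self.trait_type)
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"table missing canonical columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].tolist()
            raise InputDataError(f"duplicate variant ids: {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def records(self) -> list[SummaryStatRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            n = None if pd.isna(row.n) else int(row.n)
            out.append(
                SummaryStatRecord(
                    row.variant_id, row.effect_allele, row.other_allele,
                    float(row.beta), float(row.se), float(row.pval), eaf, n,
                )
            )
        return out

    @classmethod
    def from_records(
        cls, trait_label: str, trait_type: TraitType | str,
        records: Sequence[SummaryStatRecord],
    ) -> "SummaryStatTable":
        df = pd.DataFrame(
            [
                (r.variant_id, r.effect_allele, r.other_allele,
                 np.nan if r.eaf is None else r.eaf,
                 r.beta, r.se, r.pval,
                 np.nan if r.n is None else r.n)
                for r in records
            ],
            columns=_COLUMNS,
        )
        return cls(trait_label, TraitType(trait_type), df)

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatTable":
        """Rows for the given variants, preserving this table's order."""
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))].copy()
        return SummaryStatTable(self.trait_label, self.trait_type, keep)


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered variant list."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError(f"LD matrix shape {self.r2.shape} != ({k},{k})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise InputDataError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise InputDataError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise InputDataError("LD r2 entries outside [0,1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, v1: str, v2: str) -> float:
        try:
            return float(self.r2[self._index[v1], self._index[v2]])
        except KeyError as exc:
            raise ConfigurationError(f"variant {exc.args[0]!r} absent from LD matrix") from exc

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_summary_table(
    path: str | Path,
    trait_label: str | None = None,
    trait_type: TraitType | str = TraitType.CONTINUOUS,
    column_map: Mapping[str, str] | None = None,
    effect_is_or: bool = False,
) -> SummaryStatTable:
    """Read a TSV of GWAS summary statistics into a validated table.

    ``column_map`` maps canonical field names (variant_id, effect_allele,
    other_allele, eaf, beta, se, pval, n) to the file's header names;
    unmapped optional fields default to :data:`DEFAULT_COLUMN_MAP`. With
    ``effect_is_or`` the effect column is interpreted as an odds ratio and
    log-transformed to a beta. Rows violating the per-record invariants
    (invalid alleles, se ≤ 0, p outside (0,1], eaf outside (0,1)) are
    dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"summary-statistics file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep="\t", dtype={cmap["variant_id"]: str}, na_values=["NA"])
    missing = [cmap[f] for f in MANDATORY_FIELDS if cmap[f] not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")

    df = pd.DataFrame({"variant_id": raw[cmap["variant_id"]].astype(str)})
    for f in ("effect_allele", "other_allele"):
        df[f] = raw[cmap[f]].astype(str).str.upper().str.strip()
    for f in ("beta", "se", "pval"):
        df[f] = pd.to_numeric(raw[cmap[f]], errors="coerce")
    for f in ("eaf", "n"):
        col = cmap.get(f)
        df[f] = pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan

    if effect_is_or:
        bad_or = ~(df["beta"] > 0)
        if bad_or.any():
            logger.warning("%s: %d rows with non-positive OR dropped", path.name, int(bad_or.sum()))
            df = df[~bad_or]
        df = df.assign(beta=np.log(df["beta"]))

    valid = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows of %d", path.name, n_dropped, len(df))
    df = df[valid]
    if df.empty:
        raise InputDataError(f"{path}: no valid rows after validation")
    label = trait_label if trait_label is not None else path.stem
    df = df[_COLUMNS].reset_index(drop=True)
    return SummaryStatTable(label, TraitType(trait_type), df)


def write_summary_table(table: SummaryStatTable, path: str | Path) -> None:
    """Write a table back to the canonical TSV dialect (missing values as NA)."""
    out = table.df[_COLUMNS].copy()
    out.columns = [DEFAULT_COLUMN_MAP[c] for c in _COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_matrix(path: str | Path, variant_ids: Sequence[str] | None = None) -> LDMatrix:
    """Read an LD r² table: either long form (id1, id2, r2) or a square matrix.

    Long form assumes unlisted pairs have r² = 0; the diagonal is implied.
    Square form needs the variant ids as both header and first column.
    """
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=1)
    if list(head.columns[:3]) == ["id1", "id2", "r2"]:
        long = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
        if variant_ids is None:
            variant_ids = sorted(set(long["id1"]) | set(long["id2"]))
        ids = list(variant_ids)
        idx = {v: i for i, v in enumerate(ids)}
        r2 = np.eye(len(ids))
        for row in long.itertuples(index=False):
            if row.id1 in idx and row.id2 in idx:
                i, j = idx[row.id1], idx[row.id2]
                r2[i, j] = r2[j, i] = row.r2
        return LDMatrix(ids, r2)
    mat = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix([str(c) for c in mat.columns], mat.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# instrument selection and clumping
# ---------------------------------------------------------------------------

def select_instruments(
    table: SummaryStatTable, p_threshold: float = 5e-8
) -> SummaryStatTable:
    """Retain rows with association p-value strictly below ``p_threshold``.

    The genome-wide significance convention is strict: p < 5×10⁻⁸. Row
    order is preserved. An empty result is returned with a warning rather
    than raised, so the caller decides whether it is fatal.
    """
    if not (0 < p_threshold <= 1):
        raise ConfigurationError(f"p_threshold must be in (0,1], got {p_threshold}")
    keep = table.df[table.df["pval"] < p_threshold].copy()
    if keep.empty:
        logger.warning(
            "%s: no instruments at p < %g", table.trait_label, p_threshold
        )
    return SummaryStatTable(table.trait_label, table.trait_type, keep)


def ld_clump(
    table: SummaryStatTable, ld: LDMatrix, r2_threshold: float = 0.001
) -> SummaryStatTable:
    """Greedy LD clumping: keep the most significant SNP, discard its LD partners.

    Candidates are ordered by p-value ascending (ties broken by variant id
    for determinism). Each round keeps the best remaining SNP and removes
    every remaining SNP with r² ≥ ``r2_threshold`` to it, so all pairwise
    r² among kept SNPs are below the threshold.
    """
    if not (0 < r2_threshold < 1):
        raise ConfigurationError(f"r2_threshold must be in (0,1), got {r2_threshold}")
    missing = [v for v in table.variant_ids if v not in ld._index]
    if missing:
        raise ConfigurationError(f"variants absent from LD matrix: {missing[:5]}")

    order = table.df.sort_values(
        ["pval", "variant_id"], kind="mergesort"
    )["variant_id"].tolist()
    idx = [ld._index[v] for v in order]
    sub = ld.r2[np.ix_(idx, idx)]

    kept: list[int] = []
    alive = np.ones(len(order), dtype=bool)
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept.append(i)
        alive &= sub[i] < r2_threshold
        alive[i] = False
    kept_ids = {order[i] for i in kept}
    n_removed = len(order) - len(kept_ids)
    if n_removed:
        logger.info("%s: clumping removed %d of %d SNPs", table.trait_label, n_removed, len(order))
    return table.subset(kept_ids)
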