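"""Allele harmonization of two (or three) summary-statistics tables.

Two-sample MR needs the variant-exposure and variant-outcome effects
expressed for the same effect allele at every shared SNP. The exposure
table is the allele reference: an outcome record whose alleles are swapped
relative to the exposure has its beta sign flipped (and eaf complemented);
a record whose alleles cannot be reconciled is dropped. Palindromic SNPs
(A/T or G/C) are ambiguous from alleles alone and are resolved by effect-
allele frequency, or dropped when frequency is missing or uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import InputDataError, SummaryStatTable

logger = logging.getLogger("mrmediation")

_PALINDROMES = ({"A", "T"}, {"G", "C"})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PalindromePolicy(str, Enum):
    DROP = "drop"
    INFER_BY_EAF = "infer_by_eaf"


@dataclass
class HarmonizedPair:
    """Per-SNP exposure/outcome effect arrays on a common effect allele.

    ``bx``/``se_x`` hold the variant-exposure effects and SEs, ``by``/``se_y``
    the variant-outcome (or variant-mediator) ones.
    """

    variant_ids: list[str]
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    n_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k = len(self.variant_ids)
        if not (self.bx.shape == self.se_x.shape == self.by.shape == self.se_y.shape == (k,)):
            raise InputDataError("harmonized arrays must share length with variant_ids")
        if k == 0:
            raise InputDataError("harmonized set is empty")
        if (self.se_x <= 0).any() or (self.se_y <= 0).any():
            raise InputDataError("harmonized SEs must be strictly positive")
        if len(set(self.variant_ids)) != k:
            raise InputDataError("duplicate variant ids in harmonized set")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def drop(self, variant_id: str) -> "HarmonizedPair":
        """A copy without one SNP (leave-one-out support)."""
        keep = [i for i, v in enumerate(self.variant_ids) if v != variant_id]
        if len(keep) == len(self.variant_ids):
            raise KeyError(variant_id)
        return HarmonizedPair(
            [self.variant_ids[i] for i in keep],
            self.bx[keep], self.se_x[keep], self.by[keep], self.se_y[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant_id": self.variant_ids, "bx": self.bx, "se_x": self.se_x,
             "by": self.by, "se_y": self.se_y}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedTriple:
    """Exposure/mediator/outcome effects aligned on a common effect allele."""

    variant_ids: list[str]
    bx: np.ndarray
    se_x: np.ndarray
    bm: np.ndarray
    se_m: np.ndarray
    by: np.ndarray
    se_y: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.bx, self.se_x, self.bm, self.se_m, self.by, self.se_y]
        for i, a in enumerate(arrays):
            arrays[i] = np.asarray(a, dtype=float)
        self.bx, self.se_x, self.bm, self.se_m, self.by, self.se_y = arrays
        k = len(self.variant_ids)
        if any(a.shape != (k,) for a in arrays):
            raise InputDataError("triple arrays must share length with variant_ids")
        if k == 0:
            raise InputDataError("harmonized triple is empty")
        if (self.se_x <= 0).any() or (self.se_m <= 0).any() or (self.se_y <= 0).any():
            raise InputDataError("harmonized SEs must be strictly positive")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def exposure_outcome(self) -> HarmonizedPair:
        return HarmonizedPair(list(self.variant_ids), self.bx, self.se_x, self.by, self.se_y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant_id": self.variant_ids, "bx": self.bx, "se_x": self.se_x,
             "bm": self.bm, "se_m": self.se_m, "by": self.by, "se_y": self.se_y}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMES


def _align_row(exp, out, policy: PalindromePolicy, eaf_window: float):
    """Classify one shared SNP: ('same'|'flip'|'drop_palindromic'|'drop_mismatch', sign).

    ``exp``/``out`` are namedtuples with effect_allele, other_allele, eaf.
    Alleles are matched directly or on the complementary strand; for
    palindromic SNPs strand and swap are indistinguishable, so allele
    frequency decides (both eafs on the same side of 0.5 → same allele).
    """
    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    if _is_palindromic(ea_e, oa_e):
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return "drop_mismatch", 0
        if policy is PalindromePolicy.DROP:
            return "drop_palindromic", 0
        eaf_e, eaf_o = exp.eaf, out.eaf
        if pd.isna(eaf_e) or pd.isna(eaf_o):
            return "drop_palindromic", 0
        # textual alignment first; complementing both alleles of a palindrome
        # equals swapping them, so strand is decided by frequency alone
        s1 = 1 if ea_o == ea_e else -1
        eaf_aligned = eaf_o if s1 == 1 else 1.0 - eaf_o
        if abs(eaf_e - 0.5) < eaf_window or abs(eaf_aligned - 0.5) < eaf_window:
            return "drop_palindromic", 0
        s2 = 1 if (eaf_e - 0.5) * (eaf_aligned - 0.5) > 0 else -1
        sign = s1 * s2
        return ("same", 1) if sign == 1 else ("flip", -1)

    if (ea_o, oa_o) == (ea_e, oa_e):
        return "same", 1
    if (ea_o, oa_o) == (oa_e, ea_e):
        return "flip", -1
    # try complementary strand
    ea_c, oa_c = _COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?")
    if (ea_c, oa_c) == (ea_e, oa_e):
        return "same", 1
    if (ea_c, oa_c) == (oa_e, ea_e):
        return "flip", -1
    return "drop_mismatch", 0


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    palindrome_policy: PalindromePolicy | str = PalindromePolicy.INFER_BY_EAF,
    eaf_window: float = 0.08,
) -> HarmonizedPair:
    """Align outcome effects onto the exposure table's effect alleles.

    Returns the intersection of variants ordered as in the exposure table.
    ``eaf_window`` is the half-width around 0.5 inside which a palindromic
    SNP's frequency is considered uninformative (default 0.08, i.e. drop
    when either eaf lies in (0.42, 0.58)).
    """
    policy = PalindromePolicy(palindrome_policy)
    out_rows = {r.variant_id: r for r in outcome.df.itertuples(index=False)}
    shared = [v for v in exposure.variant_ids if v in out_rows]
    if not shared:
        raise InputDataError(
            f"no shared variants between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )
    exp_rows = {r.variant_id: r for r in exposure.df.itertuples(index=False)}

    ids: list[str] = []
    bx, se_x, by, se_y = [], [], [], []
    n_flipped = n_pal = n_mis = 0
    for v in shared:
        action, sign = _align_row(exp_rows[v], out_rows[v], policy, eaf_window)
        if action == "drop_palindromic":
            n_pal += 1
            continue
        if action == "drop_mismatch":
            logger.warning("harmonize: allele mismatch at %s, dropped", v)
            n_mis += 1
            continue
        if action == "flip":
            n_flipped += 1
        ids.append(v)
        bx.append(exp_rows[v].beta)
        se_x.append(exp_rows[v].se)
        by.append(sign * out_rows[v].beta)
        se_y.append(out_rows[v].se)
    if not ids:
        raise InputDataError("harmonization dropped every shared variant")
    if n_pal:
        logger.info("harmonize: dropped %d palindromic SNPs", n_pal)
    return HarmonizedPair(
        ids, np.array(bx), np.array(se_x), np.array(by), np.array(se_y),
        n_flipped=n_flipped, n_dropped_palindromic=n_pal, n_dropped_mismatch=n_mis,
    )


def harmonize_triple(
    exposure: SummaryStatTable,
    mediator: SummaryStatTable,
    outcome: SummaryStatTable,
    variant_ids: list[str] | None = None,
    palindrome_policy: PalindromePolicy | str = PalindromePolicy.INFER_BY_EAF,
    eaf_window: float = 0.08,
) -> HarmonizedTriple:
    """Align mediator and outcome onto the exposure's effect alleles.

    The pairwise rules are applied twice with the exposure as the shared
    allele reference; only SNPs surviving both pairwise harmonizations are
    kept. ``variant_ids`` restricts the instrument set (e.g. the union of
    exposure- and mediator-significant clumped instruments); by default all
    three-way-shared variants are used.
    """
    if variant_ids is not None:
        exposure = exposure.subset(variant_ids)
    hm = harmonize(exposure, mediator, palindrome_policy, eaf_window)
    hy = harmonize(exposure, outcome, palindrome_policy, eaf_window)
    shared = [v for v in hm.variant_ids if v in set(hy.variant_ids)]
    if not shared:
        raise InputDataError("no variants survive three-way harmonization")
    im = {v: i for i, v in enumerate(hm.variant_ids)}
    iy = {v: i for i, v in enumerate(hy.variant_ids)}
    m_idx = [im[v] for v in shared]
    y_idx = [iy[v] for v in shared]
    return HarmonizedTriple(
        shared,
        hm.bx[m_idx], hm.se_x[m_idx],
        hm.by[m_idx], hm.se_y[m_idx],
        hy.by[y_idx], hy.se_y[y_idx],
    )
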