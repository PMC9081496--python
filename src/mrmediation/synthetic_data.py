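r"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the structure of consortium summary data used in
two-sample MR: per-SNP effect/SE pairs whose sampling noise scales with
the GWAS sample size, genome-wide-significant instruments, optional
directly pleiotropic SNPs, and mediator traits causally downstream of the
exposure. Traits are drawn with independent noise (non-overlapping
samples, the two-sample regime), SEs follow the standardized-trait
convention SE = (2·maf·(1−maf)·n)^(−1/2).

The causal diagram is

    SNP_k --gamma_k--> exposure --a_i--> mediator_i --b_i--> outcome
                   \----------------direct (d)------------------^
    SNP_k --alpha_k (pleiotropy)--------------------------------^
    SNP_m --delta_m--> mediator_i --b_i--> outcome

so the true total exposure->outcome effect is d + sum_i a_i*b_i. Each
mediator also has its own specific instruments (the SNP_m above) — without
them the variant-exposure and variant-mediator effects would be collinear
and the multivariable step unidentifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import (
    LDMatrix,
    SummaryStatTable,
    TraitType,
    ConfigurationError,
    write_ld_matrix,
    write_summary_table,
)

# ordered non-palindromic allele pairs; generated tables share one strand
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic two-sample MR study.

    Defaults mirror the emulated consortium setting at desk scale: a
    182,416-sample exposure GWAS, a 184,305-sample (cases+controls) outcome
    GWAS, UK-Biobank-scale mediator GWAS, 50 candidate exposure
    instruments with per-allele effects of 0.04–0.12 trait units (the
    magnitude range of top GWAS hits for a standardized trait), and no
    pleiotropy unless requested.
    """

    seed: int = 0
    n_snp: int = 50                      # candidate exposure instruments
    n_snp_mediator: int = 60             # mediator-specific instruments per mediator
    n_exposure: int = 182_416
    n_outcome: int = 184_305
    n_mediator: int = 337_000
    #: ("uniform_magnitude", lo, hi) — |effect| ~ U(lo,hi), random sign —
    #: or ("normal", mean, sd); used for both gamma_k and delta_m draws
    gamma_dist: tuple[str, float, float] = ("uniform_magnitude", 0.04, 0.12)
    beta_total_direct: float = -0.1      # direct exposure->outcome path d
    mediator_paths: list[tuple[float, float]] = field(default_factory=list)
    pleiotropy: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (fraction, mean, sd)
    maf_dist: tuple[float, float] = (0.05, 0.5)
    ld_block: tuple[int, float] = (1, 0.0)  # (block size, within-block r²)

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        for label, n in (("n_exposure", self.n_exposure),
                         ("n_outcome", self.n_outcome),
                         ("n_mediator", self.n_mediator)):
            if n < 100:
                raise ConfigurationError(f"{label} must be >= 100, got {n}")
        frac = self.pleiotropy[0]
        if not (0 <= frac <= 1):
            raise ConfigurationError(f"pleiotropy fraction must be in [0,1], got {frac}")
        lo, hi = self.maf_dist
        if not (0 < lo <= hi < 1):
            raise ConfigurationError(f"maf_dist bounds must satisfy 0 < lo <= hi < 1")
        kind = self.gamma_dist[0]
        if kind not in ("uniform_magnitude", "normal"):
            raise ConfigurationError(f"unknown gamma_dist kind {kind!r}")
        bs, r2 = self.ld_block
        if bs < 1 or not (0 <= r2 < 1):
            raise ConfigurationError("ld_block must be (size >= 1, r2 in [0,1))")
        if self.mediator_paths and self.n_snp_mediator < 1:
            raise ConfigurationError("n_snp_mediator must be >= 1 when mediators exist")

    @property
    def true_total_effect(self) -> float:
        return self.beta_total_direct + sum(a * b for a, b in self.mediator_paths)


@dataclass
class SimulatedStudy:
    """Generated tables plus the generative truth for recovery checks."""

    tables: dict[str, SummaryStatTable]
    ld: LDMatrix
    truth: dict

    @property
    def exposure(self) -> SummaryStatTable:
        return self.tables["exposure"]

    @property
    def outcome(self) -> SummaryStatTable:
        return self.tables["outcome"]

    def mediator(self, i: int) -> SummaryStatTable:
        return self.tables[f"mediator_{i + 1}"]

    @property
    def mediator_labels(self) -> list[str]:
        return [k for k in self.tables if k.startswith("mediator_")]

    def write(self, outdir: str | Path) -> None:
        """Emit the study in the TSV dialect gwas_io reads, plus truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            write_summary_table(table, outdir / f"{name}.tsv")
        write_ld_matrix(self.ld, outdir / "ld.tsv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _draw_effects(rng: np.random.Generator, dist, size: int) -> np.ndarray:
    kind, p1, p2 = dist
    if kind == "uniform_magnitude":
        mag = rng.uniform(p1, p2, size)
        sign = rng.choice([-1.0, 1.0], size)
        return mag * sign
    return rng.normal(p1, p2, size)


def _observed(rng, true_beta, maf, n):
    """Observed (beta, se, p) given true effects under the standardized-trait
    SE convention; p-values clamped away from exact 0 to keep them valid."""
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + rng.normal(0.0, se)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p


def _table(label, trait_type, ids, alleles, maf, beta, se, pval, n) -> SummaryStatTable:
    df = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": maf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": float(n),
    })
    return SummaryStatTable(label, trait_type, df)


def _block_ld(ids: list[str], block_size: int, r2: float) -> LDMatrix:
    k = len(ids)
    mat = np.eye(k)
    if block_size > 1 and r2 > 0:
        for start in range(0, k, block_size):
            end = min(start + block_size, k)
            mat[start:end, start:end] = r2
            np.fill_diagonal(mat[start:end, start:end], 1.0)
    return LDMatrix(ids, mat)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate one synthetic two-sample study under ``cfg``.

    Deterministic given ``cfg.seed``: structural quantities (MAFs, alleles,
    true effects, pleiotropy assignment) and each trait's sampling noise
    use separate derived streams, so adding a mediator never perturbs the
    exposure or outcome draws.
    """
    cfg.validate()
    n_med = len(cfg.mediator_paths)
    k_exp = cfg.n_snp
    k_per_med = cfg.n_snp_mediator if n_med else 0
    k_total = k_exp + n_med * k_per_med

    # derived, order-stable substreams
    rng_struct = np.random.default_rng([cfg.seed, 0])
    rng_exp = np.random.default_rng([cfg.seed, 1])
    rng_out = np.random.default_rng([cfg.seed, 2])
    rng_med = [np.random.default_rng([cfg.seed, 10 + i]) for i in range(n_med)]

    ids = [f"rs{i + 1:06d}" for i in range(k_total)]

    # structural draws go block by block (exposure instruments first, then
    # each mediator's own instruments) so adding a mediator appends draws
    # instead of shifting the stream under existing SNPs
    maf = np.empty(k_total)
    allele_idx = np.empty(k_total, dtype=int)
    maf[:k_exp] = rng_struct.uniform(*cfg.maf_dist, k_exp)
    allele_idx[:k_exp] = rng_struct.integers(0, len(_ALLELE_PAIRS), k_exp)

    gamma = np.zeros(k_total)
    gamma[:k_exp] = _draw_effects(rng_struct, cfg.gamma_dist, k_exp)

    # pleiotropic SNP->outcome effects, planted relative to the
    # exposure-increasing allele so a nonzero mean is directional in the
    # Egger sense (allele coding signs are arbitrary otherwise)
    frac, pl_mean, pl_sd = cfg.pleiotropy
    alpha = np.zeros(k_total)
    if frac > 0:
        n_pleio = int(round(frac * k_exp))
        which = rng_struct.choice(k_exp, size=n_pleio, replace=False)
        orient = np.where(gamma[which] >= 0, 1.0, -1.0)
        alpha[which] = rng_struct.normal(pl_mean, pl_sd, n_pleio) * orient

    # mediator-specific true effects delta_m, one block per mediator
    delta = np.zeros((n_med, k_total))
    for i in range(n_med):
        start = k_exp + i * k_per_med
        maf[start:start + k_per_med] = rng_struct.uniform(*cfg.maf_dist, k_per_med)
        allele_idx[start:start + k_per_med] = rng_struct.integers(
            0, len(_ALLELE_PAIRS), k_per_med
        )
        delta[i, start:start + k_per_med] = _draw_effects(
            rng_struct, cfg.gamma_dist, k_per_med
        )
    alleles = [_ALLELE_PAIRS[j] for j in allele_idx]

    # true per-SNP effects on each trait
    true_exp = gamma
    true_med = np.array(
        [cfg.mediator_paths[i][0] * gamma + delta[i] for i in range(n_med)]
    ).reshape(n_med, k_total)
    true_out = cfg.beta_total_direct * gamma + alpha
    for i, (_, b_i) in enumerate(cfg.mediator_paths):
        true_out = true_out + b_i * true_med[i]

    tables: dict[str, SummaryStatTable] = {}
    beta, se, pval = _observed(rng_exp, true_exp, maf, cfg.n_exposure)
    tables["exposure"] = _table("exposure", TraitType.CONTINUOUS,
                                ids, alleles, maf, beta, se, pval, cfg.n_exposure)
    beta, se, pval = _observed(rng_out, true_out, maf, cfg.n_outcome)
    tables["outcome"] = _table("outcome", TraitType.BINARY,
                               ids, alleles, maf, beta, se, pval, cfg.n_outcome)
    for i in range(n_med):
        beta, se, pval = _observed(rng_med[i], true_med[i], maf, cfg.n_mediator)
        tables[f"mediator_{i + 1}"] = _table(
            f"mediator_{i + 1}", TraitType.CONTINUOUS,
            ids, alleles, maf, beta, se, pval, cfg.n_mediator,
        )

    ld = _block_ld(ids, *cfg.ld_block)

    total = cfg.true_total_effect
    truth = {
        "config": {**asdict(cfg)},
        "true_total_effect": total,
        "true_direct_effect": cfg.beta_total_direct,
        "mediator_paths": [list(p) for p in cfg.mediator_paths],
        "true_indirect_effects": [a * b for a, b in cfg.mediator_paths],
        "true_proportions_pct": [
            100.0 * a * b / total for a, b in cfg.mediator_paths
        ] if total != 0 else [],
        "gamma": gamma[:k_exp].tolist(),
        "pleiotropy_alpha": alpha[:k_exp].tolist(),
    }
    return SimulatedStudy(tables, ld, truth)


def mediation_benchmark_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The benchmark study: four mediators with true mediation proportions
    (14, 12, 10, 9)% of a −0.1 total effect.

    Paths are a = (−0.14, −0.12, −0.10, −0.09), b = 0.1 each, direct
    effect −0.055, so indirect effects are (−0.014, −0.012, −0.010,
    −0.009) and the true total is −0.1 with a combined proportion of 45%.
    """
    cfg = SimulationConfig(
        seed=seed,
        beta_total_direct=-0.055,
        mediator_paths=[(-0.14, 0.1), (-0.12, 0.1), (-0.10, 0.1), (-0.09, 0.1)],
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown SimulationConfig field {key!r}")
        setattr(cfg, key, val)
    return cfg


def simulate_mediation_benchmark(seed: int = 0, **overrides) -> SimulatedStudy:
    """Generate the four-mediator benchmark study (see
    :func:`mediation_benchmark_config`)."""
    return simulate_study(mediation_benchmark_config(seed, **overrides))
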