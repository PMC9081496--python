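"""End-to-end orchestration of the two-step MR mediation workflow.

The in-memory entry points (:func:`total_effect_analysis`,
:func:`two_step_mediation`) run on already-loaded tables so simulations
and tests can drive them directly; :func:`run_total_effect` and
:func:`run_two_step` wrap them with file IO from an :class:`AnalysisConfig`.

Workflow: select genome-wide-significant instruments (p < 5×10⁻⁸), LD-clump
(r² < 0.001), harmonize, estimate the total effect (IVW plus the enabled
sensitivity battery); then per mediator, step 1 (exposure→mediator IVW over
the exposure's instruments), the p-value screen, step 2 (mediator→outcome
adjusted for the exposure by multivariable MR over the union of instrument
sets), and the product-of-coefficients decomposition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import gwas_io, harmonization, mediation, mr_core
from .gwas_io import (
    ConfigurationError,
    InputDataError,
    LDMatrix,
    SummaryStatTable,
    ld_clump,
    select_instruments,
)
from .harmonization import HarmonizedPair, harmonize, harmonize_triple
from .mediation import (
    MediationDecomposition,
    MediatorResult,
    indirect_effect,
    mvmr_adjusted_effect,
    proportion_mediated,
    screen_mediators,
)
from .mr_core import MREstimate, MRMethod, estimates_to_frame

logger = logging.getLogger("mrmediation")

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_NUMERICAL_ERROR = 4

DEFAULT_METHODS = (
    "ivw", "egger", "simple_median", "weighted_median",
    "raps", "presso", "single_snp", "leave_one_out",
)


class PipelineError(InputDataError):
    """A pipeline stage could not proceed (e.g. no instruments survive)."""


@dataclass
class TraitInput:
    path: str
    trait_type: str = "continuous"
    label: str | None = None
    effect_is_or: bool = False
    column_map: dict[str, str] | None = None

    def load(self) -> SummaryStatTable:
        return gwas_io.read_summary_table(
            self.path, trait_label=self.label,
            trait_type=self.trait_type, column_map=self.column_map,
            effect_is_or=self.effect_is_or,
        )


@dataclass
class AnalysisConfig:
    """Run configuration; thresholds default to the published workflow
    (p < 5×10⁻⁸ instruments, r² < 0.001 clumping, p < 0.05 screens)."""

    exposure: TraitInput
    outcome: TraitInput
    mediators: list[TraitInput] = field(default_factory=list)
    ld_path: str | None = None
    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    p_gate: float = 0.05
    min_proportion: float = 0.0
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_boot: int = 1000
    n_sim_presso: int = 1000
    seed: int | None = None
    palindrome_policy: str = "infer_by_eaf"
    eaf_window: float = 0.08
    output_dir: str = "mr_output"

    def __post_init__(self) -> None:
        stochastic = {"simple_median", "weighted_median", "presso"}
        if self.seed is None and stochastic & set(self.methods):
            raise ConfigurationError(
                "seed is mandatory when stochastic methods are enabled"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update(overrides)
        for key in ("exposure", "outcome"):
            if key not in raw:
                raise ConfigurationError(f"config missing required section {key!r}")
            raw[key] = TraitInput(**raw[key]) if isinstance(raw[key], dict) else raw[key]
        raw["mediators"] = [
            TraitInput(**m) if isinstance(m, dict) else m
            for m in raw.get("mediators", [])
        ]
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _audit(stage: str, n_in: int, n_out: int) -> dict:
    logger.info("[stage:%s] %d -> %d SNPs", stage, n_in, n_out)
    return {"stage": stage, "n_in": n_in, "n_out": n_out}


def prepare_instruments(
    table: SummaryStatTable, ld: LDMatrix | None,
    p_instrument: float, r2_clump: float, audit: list | None = None,
) -> SummaryStatTable:
    """Significance filter then LD clump; records stage counts."""
    sig = select_instruments(table, p_instrument)
    if audit is not None:
        audit.append(_audit(f"select[{table.trait_label}]", len(table), len(sig)))
    if len(sig) == 0:
        raise PipelineError(
            f"no instruments for {table.trait_label!r} at p < {p_instrument:g}"
        )
    if ld is None:
        return sig
    clumped = ld_clump(sig, ld, r2_clump)
    if audit is not None:
        audit.append(_audit(f"clump[{table.trait_label}]", len(sig), len(clumped)))
    return clumped


def total_effect_analysis(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    ld: LDMatrix | None = None,
    p_instrument: float = 5e-8,
    r2_clump: float = 0.001,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    seed: int = 0,
    n_boot: int = 1000,
    n_sim_presso: int = 1000,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
) -> dict:
    """Total-effect MR with the sensitivity battery, on in-memory tables.

    Returns a dict with the harmonized pair, the pooled estimates (one per
    enabled method), per-SNP batteries, the MR-PRESSO result, and a stage
    audit trail.
    """
    audit: list[dict] = []
    instruments = prepare_instruments(exposure, ld, p_instrument, r2_clump, audit)
    h = harmonize(instruments, outcome, palindrome_policy, eaf_window)
    audit.append(_audit("harmonize", len(instruments), h.n_snp))

    estimates: list[MREstimate] = []
    presso = None
    loo: list[MREstimate] = []
    per_snp: list[MREstimate] = []
    for m in methods:
        if m == "ivw":
            estimates.append(mr_core.ivw_fixed(h))
        elif m == "ivw_random":
            estimates.append(mr_core.ivw_fixed(h, random_effects=True))
        elif m == "egger":
            slope, intercept = mr_core.mr_egger(h)
            estimates += [slope, intercept]
        elif m == "simple_median":
            estimates.append(mr_core.simple_median(h, n_boot=n_boot, seed=seed))
        elif m == "weighted_median":
            estimates.append(mr_core.weighted_median(h, n_boot=n_boot, seed=seed))
        elif m == "raps":
            estimates.append(mr_core.mr_raps(h))
        elif m == "presso":
            presso = mr_core.mr_presso(h, n_sim=n_sim_presso, seed=seed)
            if presso.corrected is not None:
                estimates.append(presso.corrected)
        elif m == "leave_one_out":
            loo = mr_core.leave_one_out(h)
        elif m == "single_snp":
            per_snp = mr_core.single_snp(h)
        else:
            raise ConfigurationError(f"unknown method {m!r}")
    return {
        "harmonized": h,
        "estimates": estimates,
        "presso": presso,
        "leave_one_out": loo,
        "single_snp": per_snp,
        "audit": audit,
    }


def two_step_mediation(
    exposure: SummaryStatTable,
    mediators: dict[str, SummaryStatTable],
    outcome: SummaryStatTable,
    ld: LDMatrix | None = None,
    p_instrument: float = 5e-8,
    r2_clump: float = 0.001,
    p_gate: float = 0.05,
    min_proportion: float = 0.0,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
) -> MediationDecomposition:
    """The two-step mediation analysis on in-memory tables.

    Step 1 regresses each mediator on the exposure's instruments (IVW);
    step 2 estimates each mediator's outcome effect adjusted for the
    exposure by two-exposure multivariable MR over the union of the
    exposure's and that mediator's clumped instruments. Mediators failing
    either p-gate (or the optional proportion floor) are excluded from the
    combined proportion but reported with their exclusion reason.
    """
    audit: list[dict] = []
    instruments_x = prepare_instruments(exposure, ld, p_instrument, r2_clump, audit)
    h_total = harmonize(instruments_x, outcome, palindrome_policy, eaf_window)
    total = mr_core.ivw_fixed(h_total, label="total_effect")

    results: list[MediatorResult] = []
    for label, med_table in mediators.items():
        h1 = harmonize(instruments_x, med_table, palindrome_policy, eaf_window)
        step1 = dataclasses.replace(mr_core.ivw_fixed(h1), label=f"{label}:step1")

        # union of exposure- and mediator-significant clumped instruments
        try:
            instruments_m = prepare_instruments(
                med_table, ld, p_instrument, r2_clump, audit
            )
            union_ids = list(dict.fromkeys(
                instruments_x.variant_ids + instruments_m.variant_ids
            ))
        except PipelineError:
            logger.warning("mediator %s has no own instruments; using exposure's", label)
            union_ids = list(instruments_x.variant_ids)
        if ld is not None and len(union_ids) > len(instruments_x.variant_ids):
            union_ids = ld_clump(exposure.subset(union_ids), ld, r2_clump).variant_ids

        triple = harmonize_triple(
            exposure, med_table, outcome, variant_ids=union_ids,
            palindrome_policy=palindrome_policy, eaf_window=eaf_window,
        )
        _, step2 = mvmr_adjusted_effect(triple)
        step2 = dataclasses.replace(step2, label=f"{label}:step2")

        ind = indirect_effect(step1.beta, step2.beta)
        prop = proportion_mediated(ind, total.beta)
        results.append(MediatorResult(label, step1, step2, ind, prop, included=True))

    results = screen_mediators(results, p_gate=p_gate, min_proportion=min_proportion)
    if not any(m.included for m in results):
        logger.warning("no mediators pass the screen; decomposition is empty")
    return MediationDecomposition(total_effect=total, mediators=results)


# ---------------------------------------------------------------------------
# file-level runners
# ---------------------------------------------------------------------------

def _load_ld(cfg: AnalysisConfig, variant_ids) -> LDMatrix | None:
    if cfg.ld_path is None:
        return None
    return gwas_io.read_ld_matrix(cfg.ld_path, variant_ids)


def run_total_effect(cfg: AnalysisConfig) -> dict:
    """Load inputs per ``cfg``, run the total-effect battery, write reports."""
    exposure = cfg.exposure.load()
    outcome = cfg.outcome.load()
    ld = _load_ld(cfg, exposure.variant_ids)
    res = total_effect_analysis(
        exposure, outcome, ld,
        p_instrument=cfg.p_instrument, r2_clump=cfg.r2_clump,
        methods=cfg.methods, seed=cfg.seed or 0,
        n_boot=cfg.n_boot, n_sim_presso=cfg.n_sim_presso,
        palindrome_policy=cfg.palindrome_policy, eaf_window=cfg.eaf_window,
    )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    estimates_to_frame(res["estimates"]).to_csv(
        outdir / "estimates.tsv", sep="\t", index=False
    )
    res["harmonized"].to_tsv(outdir / "harmonized.tsv")
    if res["leave_one_out"]:
        estimates_to_frame(res["leave_one_out"]).to_csv(
            outdir / "leave_one_out.tsv", sep="\t", index=False
        )
    if res["single_snp"]:
        estimates_to_frame(res["single_snp"]).to_csv(
            outdir / "single_snp.tsv", sep="\t", index=False
        )
    payload = {
        "estimates": [e.to_dict() for e in res["estimates"]],
        "audit": res["audit"],
    }
    if res["presso"] is not None:
        payload["presso"] = {
            "global_rss": res["presso"].global_rss,
            "global_pval": res["presso"].global_pval,
            "outliers": [
                v for v, f in zip(res["presso"].variant_ids, res["presso"].outlier_flags) if f
            ],
        }
    (outdir / "estimates.json").write_text(json.dumps(payload, indent=2))
    return res


def run_two_step(cfg: AnalysisConfig) -> MediationDecomposition:
    """Load inputs per ``cfg``, run the two-step mediation, write the report."""
    if not cfg.mediators:
        raise ConfigurationError("two-step analysis requires at least one mediator")
    exposure = cfg.exposure.load()
    outcome = cfg.outcome.load()
    meds = {}
    for i, m in enumerate(cfg.mediators):
        t = m.load()
        meds[t.trait_label or f"mediator_{i + 1}"] = t
    ld = _load_ld(cfg, exposure.variant_ids)
    decomp = two_step_mediation(
        exposure, meds, outcome, ld,
        p_instrument=cfg.p_instrument, r2_clump=cfg.r2_clump,
        p_gate=cfg.p_gate, min_proportion=cfg.min_proportion,
        palindrome_policy=cfg.palindrome_policy, eaf_window=cfg.eaf_window,
    )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    decomp.report_frame().to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    decomp.to_json(outdir / "mediation.json")
    return decomp
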