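"""End-to-end screening workflow.

Mirrors the usual two-step mediation MR study design: a forward screen of
many candidate exposures against one outcome, a reverse-MR check with the
roles swapped, mediator linking (leg a: exposure -> mediator; leg b:
mediator -> outcome), mediation quantification for pairs where both legs
are significant, and optional replication against alternative outcome
datasets.

Significance gating uses raw p < ``mr_alpha`` with no multiple-testing
correction by default, matching the screening practice the workflow
emulates; Benjamini-Hochberg gating is available via ``fdr=True`` and the
report records which mode ran.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import (
    InsufficientInstrumentsError,
    IrreduciblePleiotropyError,
    UndefinedProportionError,
    ValidationError,
)
from .estimators import MREstimate, run_methods
from .instruments import clump, filter_by_f, harmonize, select_instruments
from .io_gwas import LDMatrix, SummaryStatsTable
from .mediation import MediationResult, mediate
from .presso import MIN_SNPS, presso_recursive_filter

logger = logging.getLogger("medmr")

DEFAULT_METHODS = ("ivw", "egger", "wmedian", "wmode", "bwmr")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and knobs for one screening run."""

    p_instrument_exposure: float = 1e-5
    p_instrument_outcome: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    min_f: float = 10.0
    presso_alpha: float = 0.05
    presso_k_sim: int = 1000
    mr_alpha: float = 0.05
    methods: tuple = DEFAULT_METHODS
    fdr: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_instrument_exposure",
            "p_instrument_outcome",
            "clump_r2",
            "presso_alpha",
            "mr_alpha",
        ):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ValidationError("clump_window_kb must be > 0")
        unknown = set(self.methods) - {"ivw", "egger", "wmedian", "wmode", "bwmr"}
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}")


@dataclass
class PairResult:
    """One exposure-outcome analysis with full provenance."""

    exposure_id: str
    outcome_id: str
    status: str  # ok | skipped | irreducible_pleiotropy
    reason: str = ""
    instrument_ids: list = field(default_factory=list)
    estimates: dict = field(default_factory=dict)  # method -> MREstimate
    presso: object = None  # PressoReport | None

    @property
    def primary(self) -> MREstimate | None:
        """The headline estimate: IVW, or the Wald ratio for one instrument."""
        return self.estimates.get("ivw") or self.estimates.get("wald")


@dataclass
class ScreenReport:
    """Everything one screening run produced, exportable as TSV tables."""

    config: ScreenConfig
    forward: dict = field(default_factory=dict)  # exposure_id -> PairResult
    reverse: dict = field(default_factory=dict)  # exposure_id -> PairResult
    associated: list = field(default_factory=list)
    mediation: pd.DataFrame = None
    pair_log: list = field(default_factory=list)

    def estimates_table(self) -> pd.DataFrame:
        rows = []
        tagged = [("forward", pr) for pr in self.forward.values()]
        tagged += [("reverse", pr) for pr in self.reverse.values()]
        for direction, pr in tagged:
            if pr.status != "ok":
                rows.append(
                    {
                        "direction": direction,
                        "exposure": pr.exposure_id,
                        "outcome": pr.outcome_id,
                        "method": "",
                        "status": pr.status,
                        "reason": pr.reason,
                    }
                )
                continue
            for name, est in pr.estimates.items():
                lo, hi = est.or_ci()
                rows.append(
                    {
                        "direction": direction,
                        "exposure": pr.exposure_id,
                        "outcome": pr.outcome_id,
                        "method": name,
                        "status": "ok",
                        "reason": "",
                        "beta": est.beta,
                        "se": est.se,
                        "pval": est.pval,
                        "odds_ratio": est.odds_ratio,
                        "or_ci_low": lo,
                        "or_ci_high": hi,
                        "n_snp": est.n_snp,
                        "instruments": ",".join(pr.instrument_ids),
                    }
                )
        return pd.DataFrame(rows)

    def presso_table(self) -> pd.DataFrame:
        rows = []
        for pr in self.forward.values():
            if pr.presso is None:
                continue
            rows.append(
                {
                    "exposure": pr.exposure_id,
                    "outcome": pr.outcome_id,
                    "rss_obs": pr.presso.rss_obs,
                    "global_p": pr.presso.global_p,
                    "final_global_p": pr.presso.final_global_p,
                    "removed": ",".join(pr.presso.removed_ids),
                    "k_sim": pr.presso.k_sim,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.estimates_table().to_csv(
            outdir / "estimates.tsv", sep="\t", index=False, float_format="%.10g"
        )
        self.presso_table().to_csv(
            outdir / "presso.tsv", sep="\t", index=False, float_format="%.10g"
        )
        med = self.mediation if self.mediation is not None else pd.DataFrame()
        med.to_csv(outdir / "mediation.tsv", sep="\t", index=False, float_format="%.10g")
        with open(outdir / "run_metadata.txt", "w") as fh:
            fh.write(f"medmr version: {__version__}\n")
            fh.write("multiple-testing mode: "
                     + ("benjamini-hochberg" if self.config.fdr else "raw p-values")
                     + "\n")
            for key, val in asdict(self.config).items():
                fh.write(f"{key} = {val}\n")


def _stage_seed(seed: int, *tokens) -> int:
    # crc32 rather than hash(): string hashing is salted per process and
    # would break run-to-run reproducibility.
    entropy = [seed] + [zlib.crc32(str(t).encode()) for t in tokens]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def analyze_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    cfg: ScreenConfig,
    p_threshold: float | None = None,
) -> PairResult:
    """Run the full QC + estimation chain for one exposure-outcome pair.

    select -> clump -> F-filter -> harmonize -> MR-PRESSO recursive filter
    -> all configured estimators.  Any stage that leaves no instruments
    marks the pair skipped (with the reason) instead of raising.
    """
    cfg.validate()
    p_thr = cfg.p_instrument_exposure if p_threshold is None else p_threshold
    pr = PairResult(exposure.trait_id, outcome.trait_id, status="skipped")

    ids = select_instruments(exposure, p_thr)
    if not ids:
        pr.reason = f"no instruments at p<{p_thr:g}"
        return pr
    ids = clump(exposure, ids, ld, cfg.clump_r2, cfg.clump_window_kb)
    ids = filter_by_f(exposure, ids, cfg.min_f)
    if not ids:
        pr.reason = f"no instruments with F>{cfg.min_f:g}"
        return pr
    try:
        hs = harmonize(exposure, outcome, ids)
    except ValidationError as exc:
        pr.reason = str(exc)
        return pr

    if len(hs) >= MIN_SNPS:
        try:
            pr.presso = presso_recursive_filter(
                hs,
                alpha=cfg.presso_alpha,
                k_sim=cfg.presso_k_sim,
                seed=_stage_seed(cfg.seed, "presso", exposure.trait_id, outcome.trait_id),
            )
            hs = pr.presso.retained
        except IrreduciblePleiotropyError as exc:
            pr.status = "irreducible_pleiotropy"
            pr.reason = str(exc)
            pr.presso = exc.partial_report
            return pr
    else:
        logger.info(
            "%s vs %s: %d instruments, too few for MR-PRESSO",
            exposure.trait_id,
            outcome.trait_id,
            len(hs),
        )

    pr.instrument_ids = hs.snp_ids
    pr.estimates = run_methods(
        hs, cfg.methods, seed=_stage_seed(cfg.seed, "mr", exposure.trait_id, outcome.trait_id)
    )
    pr.status = "ok" if pr.estimates else "skipped"
    if not pr.estimates:
        pr.reason = "no estimator applicable"
    return pr


def _gate(pvals: dict[str, float], alpha: float, fdr: bool) -> set[str]:
    """Ids passing the significance gate, raw or Benjamini-Hochberg."""
    if not pvals:
        return set()
    if not fdr:
        return {k for k, p in pvals.items() if p < alpha}
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    passing: set[str] = set()
    max_k = 0
    for k, (_, p) in enumerate(items, start=1):
        if p <= alpha * k / m:
            max_k = k
    return {items[i][0] for i in range(max_k)}


def run_forward_screen(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    cfg: ScreenConfig,
) -> ScreenReport:
    """Screen each exposure against the outcome; flag associated ones.

    An exposure is flagged associated when its primary (IVW) p passes the
    gate.  BWMR, when configured, serves as a confirmation method: the
    report records whether it agrees (same sign and significant).
    """
    cfg.validate()
    report = ScreenReport(config=cfg)
    pvals: dict[str, float] = {}
    for exposure in exposures:
        pr = analyze_pair(exposure, outcome, ld, cfg)
        report.forward[exposure.trait_id] = pr
        if pr.status == "ok" and pr.primary is not None:
            pvals[exposure.trait_id] = pr.primary.pval
    passing = _gate(pvals, cfg.mr_alpha, cfg.fdr)
    for tid, pr in report.forward.items():
        if tid in passing:
            report.associated.append(tid)
            bw = pr.estimates.get("bwmr")
            if bw is not None and pr.primary is not None:
                pr.estimates["bwmr"].aux["agrees_with_ivw"] = bool(
                    np.sign(bw.beta) == np.sign(pr.primary.beta)
                    and bw.pval < cfg.mr_alpha
                )
    logger.info(
        "forward screen: %d/%d exposures associated at alpha=%g",
        len(report.associated),
        len(exposures),
        cfg.mr_alpha,
    )
    return report


def run_reverse_mr(
    outcome_as_exposure: SummaryStatsTable,
    exposure_as_outcome: SummaryStatsTable,
    ld: LDMatrix,
    cfg: ScreenConfig,
) -> PairResult:
    """Reverse-direction MR: outcome instruments against the exposure trait.

    Instruments are selected at the (stricter) outcome threshold.  "No
    reverse effect" corresponds to a primary p >= ``mr_alpha``.
    """
    return analyze_pair(
        outcome_as_exposure,
        exposure_as_outcome,
        ld,
        cfg,
        p_threshold=cfg.p_instrument_outcome,
    )


def run_mediation_screen(
    exposures: list[SummaryStatsTable],
    mediators: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    cfg: ScreenConfig,
    forward: ScreenReport | None = None,
) -> ScreenReport:
    """Forward screen, reverse check, mediator legs and mediation table.

    For every associated exposure that shows no reverse effect, each
    mediator is tested on both legs (exposure -> mediator and mediator ->
    outcome, instruments at the exposure threshold).  Pairs with both legs
    significant get a full mediation decomposition using the IVW betas;
    the same-direction rule decides whether the proportion is reportable.
    """
    report = forward if forward is not None else run_forward_screen(
        exposures, outcome, ld, cfg
    )
    exp_by_id = {t.trait_id: t for t in exposures}
    rows = []
    for exp_id in report.associated:
        pr_fwd = report.forward[exp_id]
        exposure = exp_by_id[exp_id]

        rev = run_reverse_mr(outcome, exposure, ld, cfg)
        report.reverse[exp_id] = rev
        if rev.status == "ok" and rev.primary is not None and rev.primary.pval < cfg.mr_alpha:
            report.pair_log.append((exp_id, "*", "reverse effect detected; excluded"))
            continue

        beta_c_est = pr_fwd.primary
        for mediator in mediators:
            leg_a = analyze_pair(exposure, mediator, ld, cfg)
            if leg_a.status != "ok" or leg_a.primary is None:
                report.pair_log.append((exp_id, mediator.trait_id, f"leg a: {leg_a.reason}"))
                continue
            if leg_a.primary.pval >= cfg.mr_alpha:
                report.pair_log.append((exp_id, mediator.trait_id, "leg a not significant"))
                continue
            leg_b = analyze_pair(mediator, outcome, ld, cfg)
            if leg_b.status != "ok" or leg_b.primary is None:
                report.pair_log.append((exp_id, mediator.trait_id, f"leg b: {leg_b.reason}"))
                continue
            if leg_b.primary.pval >= cfg.mr_alpha:
                report.pair_log.append((exp_id, mediator.trait_id, "leg b not significant"))
                continue
            try:
                med = mediate(
                    leg_a.primary.beta,
                    leg_a.primary.se,
                    leg_b.primary.beta,
                    leg_b.primary.se,
                    beta_c_est.beta,
                    beta_c_est.se,
                    alpha=cfg.mr_alpha,
                )
            except UndefinedProportionError:
                report.pair_log.append((exp_id, mediator.trait_id, "total effect ~ 0"))
                continue
            rows.append(_mediation_row(exp_id, mediator.trait_id, med, leg_a, leg_b))
    report.mediation = pd.DataFrame(rows)
    logger.info("mediation screen: %d pairs reported", len(rows))
    return report


def _mediation_row(exp_id, med_id, m: MediationResult, leg_a: PairResult, leg_b: PairResult):
    return {
        "exposure": exp_id,
        "mediator": med_id,
        "beta_a": m.beta_a,
        "se_a": m.se_a,
        "beta_b": m.beta_b,
        "se_b": m.se_b,
        "beta_c": m.beta_c,
        "se_c": m.se_c,
        "indirect": m.indirect,
        "se_indirect": m.se_indirect,
        "direct": m.direct,
        "se_direct": m.se_direct,
        "proportion": m.proportion,
        "proportion_ci_low": m.proportion_ci[0],
        "proportion_ci_high": m.proportion_ci[1],
        "proportion_pval": m.proportion_pval,
        "same_direction": m.same_direction,
        "proportion_reported": m.proportion_reported,
        "leg_a_instruments": ",".join(leg_a.instrument_ids),
        "leg_b_instruments": ",".join(leg_b.instrument_ids),
    }


def run_replication(
    exposure: SummaryStatsTable,
    validation_outcomes: list[SummaryStatsTable],
    ld: LDMatrix,
    cfg: ScreenConfig,
    primary_estimate: MREstimate,
) -> pd.DataFrame:
    """Re-run the exposure against alternative outcome datasets.

    Concordance means the replication estimate has the same sign as the
    primary one and p < ``mr_alpha``.
    """
    rows = []
    for outcome in validation_outcomes:
        pr = analyze_pair(exposure, outcome, ld, cfg)
        est = pr.primary if pr.status == "ok" else None
        rows.append(
            {
                "exposure": exposure.trait_id,
                "outcome": outcome.trait_id,
                "status": pr.status,
                "beta": est.beta if est else float("nan"),
                "pval": est.pval if est else float("nan"),
                "concordant": bool(
                    est is not None
                    and np.sign(est.beta) == np.sign(primary_estimate.beta)
                    and est.pval < cfg.mr_alpha
                ),
            }
        )
    return pd.DataFrame(rows)


def forest_table(estimates: dict[str, MREstimate]) -> str:
    """Plain-text forest-style rendering of a method -> estimate mapping."""
    lines = [
        f"{'method':<10}{'n_snp':>6}{'OR':>10}{'95% CI':>22}{'p':>12}",
    ]
    for name, est in estimates.items():
        lo, hi = est.or_ci()
        lines.append(
            f"{name:<10}{est.n_snp:>6}{est.odds_ratio:>10.3f}"
            f"{f'({lo:.3f}, {hi:.3f})':>22}{est.pval:>12.3g}"
        )
    return "\n".join(lines)
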