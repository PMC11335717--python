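"""MR-PRESSO: simulation-based pleiotropy detection and outlier removal.

The global test compares the observed residual sum of squares of the
leave-one-out IVW fit against its parametric-bootstrap null distribution;
the outlier test does the same per SNP.  The recursive filter removes the
worst outlier one at a time until the global test is no longer significant.

Discrepancies are variance-standardized (divided by ``sigma_y^2``) by
default so that heteroskedastic SNPs are calibrated on a common scale; the
unstandardized residual sum of squares is available via
``standardized=False``.  The distortion test is deliberately not
implemented: removal, not correction, is the supported remedy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientInstrumentsError,
    IrreduciblePleiotropyError,
    ValidationError,
)
from .instruments import HarmonizedSet

logger = logging.getLogger("medmr")

MIN_SNPS = 4


@dataclass
class PressoReport:
    """Result of the global test, outlier test and recursive removal loop."""

    rss_obs: float
    global_p: float
    k_sim: int
    outlier_p: pd.DataFrame  # snp_id, d_obs, raw_p, adj_p
    removed_ids: list = field(default_factory=list)
    final_global_p: float = None
    retained: HarmonizedSet = None
    seed: int = 0

    def __post_init__(self):
        floor = 1.0 / (self.k_sim + 1)
        if not (floor - 1e-12 <= self.global_p <= 1.0):
            raise ValidationError(
                f"global_p {self.global_p} outside [{floor}, 1]"
            )
        if self.final_global_p is None:
            self.final_global_p = self.global_p
        if self.retained is not None:
            overlap = set(self.removed_ids) & set(self.retained.snp_ids)
            if overlap:
                raise ValidationError(f"removed ids still retained: {sorted(overlap)}")


def _loo_slopes(g: np.ndarray, G: np.ndarray, sy2: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for each left-out SNP.

    Works on 1-D observed arrays or 2-D (replicate, SNP) simulated arrays.
    """
    t1 = g * G / sy2
    t2 = g * g / sy2
    s1 = t1.sum(axis=-1, keepdims=g.ndim == 2)
    s2 = t2.sum(axis=-1, keepdims=g.ndim == 2)
    return (s1 - t1) / (s2 - t2)


def _presso_core(hs: HarmonizedSet, k_sim: int, seed: int, standardized: bool):
    g, sx, G, sy = hs.arrays()
    n = len(g)
    sy2 = sy**2
    denom = sy2 if standardized else 1.0

    beta_loo = _loo_slopes(g, G, sy2)
    d_obs = (G - beta_loo * g) ** 2 / denom
    rss_obs = float(d_obs.sum())

    # One stream, filled replicate-major so draws are ordered (replicate, SNP).
    rng = np.random.default_rng(seed)
    G_star = beta_loo * g + sy * rng.standard_normal((k_sim, n))
    g_star = g + sx * rng.standard_normal((k_sim, n))
    beta_loo_star = _loo_slopes(g_star, G_star, sy2)
    d_star = (G_star - beta_loo_star * g_star) ** 2 / denom
    rss_star = d_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (k_sim + 1))
    raw_p = (1 + np.sum(d_star >= d_obs, axis=0)) / (k_sim + 1)
    outlier = pd.DataFrame(
        {
            "snp_id": hs.snp_ids,
            "d_obs": d_obs,
            "raw_p": raw_p,
            "adj_p": np.minimum(1.0, n * raw_p),
        }
    )
    return rss_obs, global_p, outlier


def _check_inputs(hs: HarmonizedSet, k_sim: int) -> None:
    if len(hs) < MIN_SNPS:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= {MIN_SNPS} instruments, got {len(hs)}"
        )
    if k_sim < 1:
        raise ValidationError("k_sim must be >= 1")


def presso_global(
    hs: HarmonizedSet, k_sim: int = 1000, seed: int = 0, standardized: bool = True
) -> PressoReport:
    """Global heterogeneity test: empirical p of the observed RSS.

    ``global_p = (1 + #{RSS* >= RSS_obs}) / (k_sim + 1)``, so the smallest
    attainable p is ``1/(k_sim+1)`` and the test can never return 0.
    """
    _check_inputs(hs, k_sim)
    rss_obs, global_p, outlier = _presso_core(hs, k_sim, seed, standardized)
    return PressoReport(
        rss_obs=rss_obs,
        global_p=global_p,
        k_sim=k_sim,
        outlier_p=outlier,
        retained=hs,
        seed=seed,
    )


def presso_outlier_test(
    hs: HarmonizedSet, k_sim: int = 1000, seed: int = 0, standardized: bool = True
) -> pd.DataFrame:
    """Per-SNP outlier test: raw and Bonferroni-adjusted empirical p-values."""
    _check_inputs(hs, k_sim)
    _, _, outlier = _presso_core(hs, k_sim, seed, standardized)
    return outlier


def _iteration_seed(seed: int, iteration: int) -> int:
    return int(np.random.SeedSequence([seed, iteration]).generate_state(1)[0] % (2**31))


def presso_recursive_filter(
    hs: HarmonizedSet,
    alpha: float = 0.05,
    k_sim: int = 1000,
    seed: int = 0,
    standardized: bool = True,
    mode: str = "retest",
) -> PressoReport:
    """Remove outliers until the global test is non-significant.

    While ``global_p <= alpha``, the SNP with the smallest raw outlier p is
    removed (p ties break on the smaller snp_id) and the global test is
    re-run on the survivors.  ``mode="retest"`` (default) recomputes
    outlier p-values on the current set before every removal — the stricter
    reading of sequential removal; ``mode="sort_once"`` fixes the removal
    order from the initial outlier test.  The loop refuses to shrink the
    set below four SNPs: if significance persists an
    :class:`IrreduciblePleiotropyError` carrying the partial report is
    raised.  Each iteration draws from a fresh seed derived from ``seed``
    and the iteration number, so the whole report is reproducible.
    """
    if mode not in ("retest", "sort_once"):
        raise ValidationError(f"unknown mode {mode!r}")
    _check_inputs(hs, k_sim)

    first = presso_global(hs, k_sim, _iteration_seed(seed, 0), standardized)
    report = PressoReport(
        rss_obs=first.rss_obs,
        global_p=first.global_p,
        k_sim=k_sim,
        outlier_p=first.outlier_p,
        retained=hs,
        final_global_p=first.global_p,
        seed=seed,
    )
    if first.global_p > alpha:
        return report

    fixed_order: list[str] = []
    if mode == "sort_once":
        ranked = first.outlier_p.sort_values(["raw_p", "snp_id"], kind="mergesort")
        fixed_order = ranked["snp_id"].tolist()

    current = hs
    removed: list[str] = []
    global_p = first.global_p
    iteration = 0
    while global_p <= alpha:
        if len(current) - 1 < MIN_SNPS:
            report.removed_ids = removed
            report.final_global_p = global_p
            report.retained = current
            raise IrreduciblePleiotropyError(
                f"global test still significant (p={global_p:.4g}) but only "
                f"{len(current)} instruments remain",
                partial_report=report,
            )
        iteration += 1
        if mode == "retest":
            ranked = presso_outlier_test(
                current, k_sim, _iteration_seed(seed, 2 * iteration - 1), standardized
            ).sort_values(["raw_p", "snp_id"], kind="mergesort")
            victim = ranked["snp_id"].iloc[0]
        else:
            victim = fixed_order[iteration - 1]
        removed.append(victim)
        current = current.drop_snps([victim])
        step = presso_global(
            current, k_sim, _iteration_seed(seed, 2 * iteration), standardized
        )
        global_p = step.global_p
        logger.info(
            "presso: removed %s (iteration %d), global_p now %.4g",
            victim,
            iteration,
            global_p,
        )

    report.removed_ids = removed
    report.final_global_p = global_p
    report.retained = current
    return report
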