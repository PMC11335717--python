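"""Causal-effect estimators for two-sample MR on a harmonized SNP set.

Implements the Wald ratio, inverse-variance-weighted (IVW) regression
through the origin, MR-Egger regression with its intercept-based pleiotropy
test, the weighted median and weighted mode estimators, Cochran's Q
heterogeneity statistic, and a Bayesian-weighted robust estimator (BWMR)
that probabilistically down-weights outlying instruments via a
two-component Gaussian scale mixture fitted by EM.

Notation: per SNP j the harmonized set carries the exposure association
``gamma_hat_j`` with SE ``sigma_x_j`` and the outcome association
``Gamma_hat_j`` with SE ``sigma_y_j``.  All estimators target the slope
beta in ``Gamma = beta * gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    ConvergenceError,
    DegenerateDesignError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ValidationError,
)
from .instruments import HarmonizedSet

_TINY_P = 5e-324


@dataclass
class MREstimate:
    """One method's causal estimate with its sensitivity auxiliaries."""

    method: str  # wald | ivw | egger | wmedian | wmode | bwmr
    beta: float
    se: float
    pval: float
    n_snp: int
    aux: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return self.beta - z * self.se, self.beta + z * self.se

    def or_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self.ci(alpha)
        return float(np.exp(lo)), float(np.exp(hi))


def _norm_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


def wald_ratio(gamma_hat: float, sigma_x: float, Gamma_hat: float, sigma_y: float) -> MREstimate:
    """Single-instrument ratio estimate Gamma/gamma.

    The first-order SE ``sigma_y/|gamma|`` ignores the exposure-side noise,
    the usual leading-term approximation for strong instruments.
    """
    if gamma_hat == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for gamma_hat = 0")
    beta = Gamma_hat / gamma_hat
    se = sigma_y / abs(gamma_hat)
    return MREstimate("wald", float(beta), float(se), _norm_p(beta / se), 1)


def _ratio_se(gamma, sigma_x, Gamma, sigma_y):
    """Delta-method SE of the per-SNP Wald ratio, including exposure noise."""
    return np.sqrt(sigma_y**2 / gamma**2 + Gamma**2 * sigma_x**2 / gamma**4)


def ivw(hs: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of Gamma on gamma through the origin with weights
    ``1/sigma_y^2``.  ``mode="fixed"`` uses the fixed-effect SE
    ``1/sqrt(sum gamma^2/sigma_y^2)``; the default multiplicative
    random-effects model inflates it by ``sqrt(Q/(J-1))``, floored at 1, to
    absorb balanced heterogeneity.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValidationError(f"unknown IVW mode {mode!r}")
    g, sx, G, sy = hs.arrays()
    if len(g) == 0:
        raise ValidationError("empty harmonized set")
    w = 1.0 / sy**2
    denom = float(np.sum(w * g**2))
    if denom == 0:
        raise DegenerateDesignError("all exposure effects are zero")
    beta = float(np.sum(w * g * G) / denom)
    se = float(np.sqrt(1.0 / denom))
    aux: dict = {}
    if len(g) >= 2:
        q, q_p = cochran_q(hs, beta)
        aux.update(cochran_q=q, q_pval=q_p)
        if mode == "multiplicative_random":
            se *= max(1.0, np.sqrt(q / (len(g) - 1)))
    return MREstimate("ivw", beta, se, _norm_p(beta / se), len(g), aux)


def cochran_q(hs: HarmonizedSet, beta_ivw: float) -> tuple[float, float]:
    """Heterogeneity of per-SNP ratios around the pooled IVW slope.

    ``Q = sum_j (gamma_j^2/sigma_y_j^2) (Gamma_j/gamma_j - beta_ivw)^2``,
    chi-square with J-1 df under homogeneity.
    """
    g, _, G, sy = hs.arrays()
    if len(g) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    # (gamma^2/sigma_y^2)(Gamma/gamma - beta)^2 == (Gamma - beta*gamma)^2/sigma_y^2,
    # the latter form staying defined for gamma_hat = 0.
    q = float(np.sum((G - beta_ivw * g) ** 2 / sy**2))
    return q, float(stats.chi2.sf(q, len(g) - 1))


def mr_egger(hs: HarmonizedSet) -> MREstimate:
    """MR-Egger weighted regression with an unconstrained intercept.

    Rows are first oriented so every exposure effect is non-negative
    (jointly negating gamma and Gamma where needed), which makes the fit
    invariant to arbitrary per-SNP allele re-coding.  The intercept
    estimates the average directional pleiotropic effect; its test
    (``egger_intercept_pval``) flags horizontal pleiotropy.  SEs use the
    multiplicative overdispersion model, floored at 1; inference is on
    t(J-2).
    """
    g, sx, G, sy = hs.arrays()
    n = len(g)
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    if np.any(g == 0):
        raise DegenerateInstrumentError(
            "instruments with gamma_hat = 0 cannot be oriented; remove them first"
        )
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    if np.allclose(g, g[0]):
        raise DegenerateDesignError("all |gamma_hat| equal: Egger design is collinear")

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = G - X @ coef
    dof = n - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))

    def t_p(est, se):
        return max(2.0 * stats.t.sf(abs(est / se), dof), _TINY_P)

    aux = {
        "egger_intercept": float(intercept),
        "egger_intercept_se": float(se_int),
        "egger_intercept_pval": t_p(intercept, se_int),
        "residual_sd": float(np.sqrt(sigma2)),
    }
    return MREstimate(
        "egger", float(slope), float(se_slope), t_p(slope, se_slope), n, aux
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at cumulative-midpoint positions."""
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    w = w / w.sum()
    mid = np.cumsum(w) - w / 2.0
    if 0.5 <= mid[0]:
        return float(v[0])
    if 0.5 >= mid[-1]:
        return float(v[-1])
    return float(np.interp(0.5, mid, v))


def weighted_median(
    hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Consistent when instruments contributing at least half the weight are
    valid.  SE comes from a seeded parametric bootstrap that redraws
    gamma_hat and Gamma_hat from their sampling distributions.
    """
    g, sx, G, sy = hs.arrays()
    n = len(g)
    if n < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    if np.any(g == 0):
        raise DegenerateInstrumentError("weighted median undefined with gamma_hat = 0")
    ratios = G / g
    weights = 1.0 / _ratio_se(g, sx, G, sy) ** 2
    beta = _weighted_median(ratios, weights)
    se = _bootstrap_se(_weighted_median, g, sx, G, sy, n_boot, seed)
    return MREstimate(
        "wmedian", beta, se, _norm_p(beta / se), n, {"n_boot": n_boot, "seed": seed}
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale=1.0)) / 0.6745
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return 0.0
    return phi * 0.9 * min(scales) * len(ratios) ** (-0.2)


_MODE_GRID = 512


def _weighted_mode(values, weights, phi: float = 1.0):
    h = _mode_bandwidth(values, phi)
    if h == 0.0:
        return float(values[0])
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, _MODE_GRID)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - values[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    hs: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Mode of the inverse-variance-weighted smoothed density of Wald ratios.

    Gaussian kernel with modified Silverman bandwidth
    ``h = phi * 0.9 * min(SD, MAD/0.6745) * J^(-1/5)``; the estimate is the
    argmax over a 512-point grid spanning [min-3h, max+3h].  Consistent when
    the largest group of instruments sharing a ratio is valid.  If every
    ratio is identical (h = 0) that common ratio is returned with the
    fixed-effect IVW standard error.
    """
    g, sx, G, sy = hs.arrays()
    n = len(g)
    if n < 3:
        raise InsufficientInstrumentsError("weighted mode needs >= 3 instruments")
    if np.any(g == 0):
        raise DegenerateInstrumentError("weighted mode undefined with gamma_hat = 0")
    ratios = G / g
    weights = 1.0 / _ratio_se(g, sx, G, sy) ** 2
    h = _mode_bandwidth(ratios, phi)
    if h == 0.0:
        se = float(1.0 / np.sqrt(np.sum(g**2 / sy**2)))
        beta = float(ratios[0])
        return MREstimate("wmode", beta, se, _norm_p(beta / se), n, {"bandwidth": 0.0})
    beta = _weighted_mode(ratios, weights, phi)
    se = _bootstrap_se(lambda v, w: _weighted_mode(v, w, phi), g, sx, G, sy, n_boot, seed)
    return MREstimate(
        "wmode",
        beta,
        se,
        _norm_p(beta / se),
        n,
        {"bandwidth": h, "n_boot": n_boot, "seed": seed},
    )


def _bootstrap_se(point_fn, g, sx, G, sy, n_boot: int, seed: int) -> float:
    """Parametric bootstrap SE: redraw (gamma*, Gamma*) and recompute."""
    rng = np.random.default_rng(seed)
    n = len(g)
    estimates = np.empty(n_boot)
    for i in range(n_boot):
        gb = g + rng.normal(size=n) * sx
        Gb = G + rng.normal(size=n) * sy
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        ratios = Gb / gb
        weights = 1.0 / _ratio_se(gb, sx, Gb, sy) ** 2
        estimates[i] = point_fn(ratios, weights)
    return float(np.std(estimates, ddof=1))


def bwmr(
    hs: HarmonizedSet,
    kappa: float = 100.0,
    max_iter: int = 200,
    tol: float = 1e-8,
    fix_null: bool = False,
) -> MREstimate:
    """Bayesian-weighted robust MR via a Gaussian scale-mixture EM.

    Marginal model: ``Gamma_j ~ N(beta*gamma_j, v_j)`` with
    ``v_j = beta^2*sigma_x_j^2 + sigma_y_j^2 + tau^2``, where tau^2 absorbs
    balanced pleiotropy.  Each SNP is a non-outlier with prior weight
    ``1-eta`` (variance ``v_j``) or an outlier with weight ``eta``
    (variance ``kappa*v_j``).  EM alternates computing per-SNP non-outlier
    responsibilities ``w_j`` (reported in ``aux["weights"]``) with
    maximizing the responsibility-weighted log-likelihood over
    ``(beta, tau^2, eta)``.  The SE comes from the observed information of
    that weighted likelihood in beta at convergence.

    ``fix_null=True`` pins ``eta = tau^2 = 0`` and drops the exposure-noise
    variance term, collapsing the model to fixed-effect IVW (used as an
    internal consistency check).
    """
    g, sx, G, sy = hs.arrays()
    n = len(g)
    if n < 3:
        raise InsufficientInstrumentsError("BWMR needs >= 3 instruments")

    ivw_fixed = ivw(hs, mode="fixed")
    beta = ivw_fixed.beta

    if fix_null:
        w_prec = g**2 / sy**2
        se = float(1.0 / np.sqrt(np.sum(w_prec)))
        return MREstimate(
            "bwmr",
            beta,
            se,
            _norm_p(beta / se),
            n,
            {"tau2": 0.0, "eta": 0.0, "weights": np.ones(n), "n_iter": 0},
        )

    # Method-of-moments (DerSimonian-Laird) start for tau^2 from Q.
    w0 = g**2 / sy**2
    q = float(np.sum(w0 * (G / g - beta) ** 2)) if n >= 2 else 0.0
    denom = np.sum(w0) - np.sum(w0**2) / np.sum(w0)
    tau2 = max(0.0, (q - (n - 1)) / denom) if denom > 0 else 0.0
    eta = 0.05

    def log_density(beta_, tau2_, scale):
        v = beta_**2 * sx**2 + sy**2 + tau2_
        vv = scale * v
        return -0.5 * ((G - beta_ * g) ** 2 / vv + np.log(2 * np.pi * vv))

    def weighted_nll(params, w):
        beta_, log_tau2 = params
        tau2_ = np.exp(log_tau2)
        return -float(
            np.sum(w * log_density(beta_, tau2_, 1.0))
            + np.sum((1 - w) * log_density(beta_, tau2_, kappa))
        )

    w = np.ones(n)
    for it in range(max_iter):
        # E-step: non-outlier responsibilities.
        l1 = log_density(beta, tau2, 1.0) + np.log(max(1 - eta, 1e-12))
        l2 = log_density(beta, tau2, kappa) + np.log(max(eta, 1e-12))
        m = np.maximum(l1, l2)
        w = np.exp(l1 - m) / (np.exp(l1 - m) + np.exp(l2 - m))
        # M-step.
        eta = float(np.mean(1 - w))
        res = optimize.minimize(
            weighted_nll,
            x0=[beta, np.log(max(tau2, 1e-10))],
            args=(w,),
            method="Nelder-Mead",
            options={"xatol": tol / 10, "fatol": 1e-12, "maxiter": 2000},
        )
        new_beta, new_log_tau2 = res.x
        converged = abs(new_beta - beta) < tol
        beta, tau2 = float(new_beta), float(np.exp(new_log_tau2))
        if converged:
            break
    else:
        raise ConvergenceError(
            f"BWMR did not converge in {max_iter} iterations",
            last_iterate={"beta": beta, "tau2": tau2, "eta": eta, "weights": w},
        )

    # Observed information in beta of the weighted log-likelihood.
    def nll_beta(b):
        return weighted_nll([b, np.log(max(tau2, 1e-300))], w)

    hstep = max(1e-5, 1e-5 * abs(beta))
    info = (nll_beta(beta + hstep) - 2 * nll_beta(beta) + nll_beta(beta - hstep)) / hstep**2
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    aux = {"tau2": tau2, "eta": eta, "weights": w, "n_iter": it + 1}
    return MREstimate("bwmr", beta, se, _norm_p(beta / se), n, aux)


_METHODS = {
    "ivw": ivw,
    "egger": mr_egger,
    "wmedian": weighted_median,
    "wmode": weighted_mode,
    "bwmr": bwmr,
}


def run_methods(hs: HarmonizedSet, methods, seed: int = 0) -> dict[str, MREstimate]:
    """Run a list of estimators on one harmonized set.

    Single-SNP sets fall back to the Wald ratio whatever was requested.
    Methods whose preconditions fail (too few instruments, degenerate
    design) are skipped with a log message rather than aborting the screen.
    """
    import logging

    log = logging.getLogger("medmr")
    out: dict[str, MREstimate] = {}
    if len(hs) == 1:
        row = hs.df.iloc[0]
        out["wald"] = wald_ratio(
            row["gamma_hat"], row["sigma_x"], row["Gamma_hat"], row["sigma_y"]
        )
        return out
    for name in methods:
        if name not in _METHODS:
            raise ValidationError(f"unknown MR method {name!r}")
        fn = _METHODS[name]
        try:
            if name in ("wmedian", "wmode"):
                out[name] = fn(hs, seed=seed)
            else:
                out[name] = fn(hs)
        except (InsufficientInstrumentsError, DegenerateDesignError) as exc:
            log.info("method %s skipped for %s: %s", name, hs.exposure_id, exc)
    return out
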