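"""Synthetic three-trait GWAS summary statistics under a known causal model.

The generator emulates the setting of a two-step mediation MR study: an
exposure X acts on an outcome Y partly through a mediator M,

    X --a--> M --b--> Y,      X --c'--> Y  (direct),

so the total exposure effect is ``c = a*b + c'``.  Per-SNP true marginal
effects follow the linear structural model:

* exposure instruments carry ``gamma_j`` on X, ``a*gamma_j`` on M and
  ``c*gamma_j + alpha_j`` on Y, where ``alpha_j`` is an optional direct
  (horizontally pleiotropic) effect;
* mediator instruments carry ``delta_j`` on M and ``b*delta_j`` on Y;
* outcome instruments carry ``eps_j`` on Y (and ``reverse_effect*eps_j``
  on X when a reverse causal path is requested);
* the remaining SNPs are null.

Observed effects are the true effects plus independent Gaussian noise with
standard error ``1/sqrt(2*maf*(1-maf)*n)``, the usual first-order expression
for a standardized trait.  The three GWAS are sampled with independent
noise, matching the non-overlapping-samples assumption of two-sample MR.
LD is block-diagonal AR(1); true effects are assigned to block
representatives only, so LD matters to clumping but does not correlate the
estimation noise.

Locus-level attributes (positions, alleles, allele frequencies) are drawn
from a separate ``locus_seed`` stream so that independent replicates share
a common variant panel and can be cross-combined into multi-trait screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io_gwas import LDMatrix, SummaryStatsTable

_TINY_P = 5e-324  # smallest positive subnormal; keeps pval in (0, 1]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("T", "C"), ("C", "T"), ("T", "G"), ("G", "T"),
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic three-trait study.

    Defaults mirror a desk-scale version of a microbiome-exposure /
    immune-mediator / disease-outcome design: 50 genuine exposure
    instruments among 200 variants, 50,000 samples per GWAS, and structural
    effects a=0.3, b=-0.2, c'=-0.05 (total effect -0.11, 54.5% mediated).
    """

    n_snps: int = 200
    n_instruments: int = 50
    n_mediator_instruments: int = 50
    n_outcome_instruments: int = 0
    n_x: int = 50_000
    n_m: int = 50_000
    n_y: int = 50_000
    a: float = 0.3
    b: float = -0.2
    c_prime: float = -0.05
    reverse_effect: float = 0.0
    sigma_gamma: float = 0.08
    sigma_delta: float = 0.08
    sigma_epsilon: float = 0.08
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.0
    prop_pleiotropic: float = 0.0
    outlier_ids_and_shifts: dict = field(default_factory=dict)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    maf_range: tuple = (0.1, 0.5)
    palindromic_frac: float = 0.1
    seed: int = 0
    locus_seed: int = 7

    @property
    def c_total(self) -> float:
        return self.a * self.b + self.c_prime

    def validate(self) -> None:
        if not (0 <= self.prop_pleiotropic <= 1):
            raise ValidationError("prop_pleiotropic must be in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_instruments > self.n_snps:
            raise ValidationError("n_instruments cannot exceed n_snps")
        if min(self.n_x, self.n_m, self.n_y) < 100:
            raise ValidationError("sample sizes must be >= 100")
        if not abs(self.ld_rho) < 1:
            raise ValidationError("|ld_rho| must be < 1")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")
        if not (0 <= self.palindromic_frac <= 1):
            raise ValidationError("palindromic_frac must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        n_blocks = math.ceil(self.n_snps / self.ld_block_size)
        needed = (
            self.n_instruments
            + self.n_mediator_instruments
            + self.n_outcome_instruments
        )
        if needed > n_blocks:
            raise ValidationError(
                f"{needed} instrument loci requested but only {n_blocks} LD blocks"
            )


@dataclass
class TruthRecord:
    """Ground-truth structural quantities behind one simulated study."""

    a: float
    b: float
    c_prime: float
    c_total: float
    gamma: pd.Series  # true per-SNP exposure effects
    alpha: pd.Series  # true per-SNP direct (pleiotropic) outcome effects
    delta: pd.Series  # true per-SNP mediator-instrument effects
    epsilon: pd.Series  # true per-SNP outcome-instrument effects
    instrument_ids: list
    mediator_instrument_ids: list
    outcome_instrument_ids: list
    outlier_ids: list
    snp_ids: list
    seed: int


def truth_consistency_check(truth: TruthRecord) -> bool:
    """True iff the effect decomposition is exact and outlier ids are known SNPs."""
    ids = set(truth.snp_ids)
    return truth.c_total == truth.a * truth.b + truth.c_prime and set(
        truth.outlier_ids
    ) <= ids


def _block_sizes(n_snps: int, block_size: int) -> list[int]:
    full, rem = divmod(n_snps, block_size)
    return [block_size] * full + ([rem] if rem else [])


def _draw_loci(cfg: SimConfig):
    """Variant panel: ids, positions, alleles, MAFs (locus_seed stream)."""
    rng = np.random.default_rng(cfg.locus_seed)
    n = cfg.n_snps
    snp_ids = [f"rs{i + 1}" for i in range(n)]

    sizes = _block_sizes(n, cfg.ld_block_size)
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    i = 0
    for block, size in enumerate(sizes):
        # Blocks sharing a chromosome sit 30 Mb apart, far outside any
        # realistic clumping window; SNPs within a block are 1 kb apart.
        start = 1_000_000 + (block // 22) * 30_000_000
        chrom[i : i + size] = str(block % 22 + 1)
        pos[i : i + size] = start + np.arange(size) * 1_000
        i += size

    maf = rng.uniform(*cfg.maf_range, size=n)
    is_pal = rng.random(n) < cfg.palindromic_frac
    pal_idx = rng.integers(0, 4, size=n)
    npal_idx = rng.integers(0, 8, size=n)
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for j in range(n):
        ea[j], oa[j] = (
            _PALINDROMIC_PAIRS[pal_idx[j]] if is_pal[j] else _NONPALINDROMIC_PAIRS[npal_idx[j]]
        )
    return snp_ids, chrom, pos, ea, oa, maf, sizes


def _ld_from_blocks(snp_ids, sizes, rho) -> LDMatrix:
    n = len(snp_ids)
    r = np.eye(n)
    i = 0
    for size in sizes:
        idx = np.arange(size)
        r[i : i + size, i : i + size] = rho ** np.abs(idx[:, None] - idx[None, :])
        i += size
    return LDMatrix(list(snp_ids), r)


def _sumstats_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), _TINY_P)


def simulate_three_trait_gwas(
    cfg: SimConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable, LDMatrix, TruthRecord]:
    """Generate (exposure, mediator, outcome) summary statistics plus truth.

    The three tables share snp ids, positions, alleles and allele
    frequencies; only effect estimates differ.  The same ``cfg`` (including
    seed) always returns bit-identical output.
    """
    cfg.validate()
    snp_ids, chrom, pos, ea, oa, maf, sizes = _draw_loci(cfg)
    n = cfg.n_snps

    # Block representatives (first SNP of each block) carry the true effects.
    rep_idx = np.cumsum([0] + sizes[:-1])
    nI, nM, nO = (
        cfg.n_instruments,
        cfg.n_mediator_instruments,
        cfg.n_outcome_instruments,
    )
    x_idx = rep_idx[:nI]
    m_idx = rep_idx[nI : nI + nM]
    y_idx = rep_idx[nI + nM : nI + nM + nO]

    rng = np.random.default_rng(cfg.seed)
    # Instrument effects are half-normal (one-signed): instruments are
    # reported oriented to the trait-increasing allele, the usual GWAS
    # convention.  This also makes "directional" pleiotropy directional
    # relative to the instruments' shared orientation.
    gamma = np.zeros(n)
    gamma[x_idx] = np.abs(rng.normal(0.0, cfg.sigma_gamma, size=nI))
    delta = np.zeros(n)
    delta[m_idx] = np.abs(rng.normal(0.0, cfg.sigma_delta, size=nM))
    eps = np.zeros(n)
    eps[y_idx] = np.abs(rng.normal(0.0, cfg.sigma_epsilon, size=nO))

    alpha = np.zeros(n)
    if cfg.pleiotropy_mode != "none" and cfg.prop_pleiotropic > 0 and nI > 0:
        k = int(round(cfg.prop_pleiotropic * nI))
        chosen = rng.choice(x_idx, size=k, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        alpha[chosen] = rng.normal(mean, cfg.pleiotropy_sd, size=k)

    c_total = cfg.c_total
    true_x = gamma + cfg.reverse_effect * eps
    true_m = cfg.a * gamma + delta
    true_y = c_total * gamma + alpha + cfg.b * delta + eps

    se_x = _sumstats_se(maf, cfg.n_x)
    se_m = _sumstats_se(maf, cfg.n_m)
    se_y = _sumstats_se(maf, cfg.n_y)
    beta_x = true_x + rng.normal(size=n) * se_x
    beta_m = true_m + rng.normal(size=n) * se_m
    beta_y = true_y + rng.normal(size=n) * se_y

    # Gross outliers: shifts are expressed in multiples of the outcome SE.
    id_pos = {s: i for i, s in enumerate(snp_ids)}
    for snp, shift in cfg.outlier_ids_and_shifts.items():
        if snp not in id_pos:
            raise ValidationError(f"outlier id {snp!r} is not a generated SNP")
        beta_y[id_pos[snp]] += shift * se_y[id_pos[snp]]

    def table(trait_id, trait_type, beta, se, n_samples):
        df = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": chrom,
                "pos_bp": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pval": _two_sided_p(beta, se),
                "n": n_samples,
            }
        )
        return SummaryStatsTable(trait_id, trait_type, df)

    x_tab = table("exposure", "quantitative", beta_x, se_x, cfg.n_x)
    m_tab = table("mediator", "quantitative", beta_m, se_m, cfg.n_m)
    y_tab = table("outcome", "binary", beta_y, se_y, cfg.n_y)
    ld = _ld_from_blocks(snp_ids, sizes, cfg.ld_rho)

    idx = pd.Index(snp_ids, name="snp_id")
    truth = TruthRecord(
        a=cfg.a,
        b=cfg.b,
        c_prime=cfg.c_prime,
        c_total=c_total,
        gamma=pd.Series(gamma, index=idx),
        alpha=pd.Series(alpha, index=idx),
        delta=pd.Series(delta, index=idx),
        epsilon=pd.Series(eps, index=idx),
        instrument_ids=[snp_ids[i] for i in x_idx],
        mediator_instrument_ids=[snp_ids[i] for i in m_idx],
        outcome_instrument_ids=[snp_ids[i] for i in y_idx],
        outlier_ids=list(cfg.outlier_ids_and_shifts),
        snp_ids=list(snp_ids),
        seed=cfg.seed,
    )
    return x_tab, m_tab, y_tab, ld, truth


def flipped_export(table: SummaryStatsTable) -> SummaryStatsTable:
    """Re-export a table with alleles swapped, beta negated and eaf mirrored.

    Emulates a GWAS export whose effect allele is the other strand
    orientation of the same association; harmonization against the original
    exposure must undo it exactly.
    """
    df = table.df.copy()
    df[["effect_allele", "other_allele"]] = df[["other_allele", "effect_allele"]].to_numpy()
    df["beta"] = -df["beta"]
    df["eaf"] = 1.0 - df["eaf"]
    return SummaryStatsTable(table.trait_id + "_flipped", table.trait_type, df)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Convenience: the same study design with a fresh noise seed."""
    return replace(cfg, seed=seed)
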