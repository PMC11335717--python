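"""Instrument selection, LD clumping, strength filtering and harmonization.

The quality-control pipeline for one exposure-outcome pair runs
select -> clump -> F-filter -> harmonize; the pleiotropy screen
(:mod:`medmr.presso`) operates on the harmonized set afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_gwas import LDMatrix, SummaryStatsTable

logger = logging.getLogger("medmr")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP effect pairs for one exposure-outcome analysis.

    ``df`` columns: snp_id, gamma_hat (exposure effect), sigma_x (its SE),
    Gamma_hat (outcome effect on the exposure's effect allele), sigma_y.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    dropped: list = None  # (snp_id, reason) pairs, populated by harmonize()

    def __post_init__(self):
        if self.dropped is None:
            self.dropped = []
        required = {"snp_id", "gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"HarmonizedSet missing columns {sorted(missing)}")
        if len(self.df) == 0:
            raise ValidationError("HarmonizedSet must contain at least one SNP")
        if self.df["snp_id"].duplicated().any():
            raise ValidationError("duplicate snp_id in HarmonizedSet")
        if not ((self.df["sigma_x"] > 0).all() and (self.df["sigma_y"] > 0).all()):
            raise ValidationError("sigma_x and sigma_y must be > 0")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def arrays(self):
        """(gamma_hat, sigma_x, Gamma_hat, sigma_y) as float arrays."""
        d = self.df
        return (
            d["gamma_hat"].to_numpy(float),
            d["sigma_x"].to_numpy(float),
            d["Gamma_hat"].to_numpy(float),
            d["sigma_y"].to_numpy(float),
        )

    def drop_snps(self, snp_ids) -> "HarmonizedSet":
        keep = ~self.df["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(self.exposure_id, self.outcome_id, self.df[keep])


def write_harmonized(hs: HarmonizedSet, path) -> None:
    """Write a harmonized set as TSV (trait ids carried as columns)."""
    df = hs.df.copy()
    df.insert(0, "exposure_id", hs.exposure_id)
    df.insert(1, "outcome_id", hs.outcome_id)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_harmonized(path) -> HarmonizedSet:
    df = pd.read_csv(path, sep="\t")
    exposure_id = str(df["exposure_id"].iloc[0]) if "exposure_id" in df else "exposure"
    outcome_id = str(df["outcome_id"].iloc[0]) if "outcome_id" in df else "outcome"
    cols = ["snp_id", "gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"]
    return HarmonizedSet(exposure_id, outcome_id, df[cols].copy())


def select_instruments(table: SummaryStatsTable, p_threshold: float) -> list[str]:
    """Ids of SNPs with association p strictly below ``p_threshold``.

    Returned in ascending p order (ties broken by snp_id so the result is
    deterministic).
    """
    if not (0 < p_threshold < 1):
        raise ValidationError("p_threshold must lie in (0, 1)")
    hits = table.df[table.df["pval"] < p_threshold]
    hits = hits.sort_values(["pval", "snp_id"], kind="mergesort")
    ids = hits["snp_id"].tolist()
    if not ids:
        logger.info("no instruments below p<%g for %s", p_threshold, table.trait_id)
    return ids


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument strength F = (beta/se)^2."""
    if se <= 0:
        raise ValidationError("se must be > 0")
    return (beta / se) ** 2


def filter_by_f(table: SummaryStatsTable, snp_ids, min_f: float = 10.0) -> list[str]:
    """Keep SNPs whose F-statistic strictly exceeds ``min_f``."""
    sub = table.subset(snp_ids).df
    f = (sub["beta"] / sub["se"]) ** 2
    kept = sub.loc[f > min_f, "snp_id"].tolist()
    logger.info("F>%g filter: %d of %d instruments kept", min_f, len(kept), len(sub))
    return kept


def mean_f_statistic(table: SummaryStatsTable, snp_ids) -> float:
    """Mean F across a set of instruments (reported for diagnostics)."""
    sub = table.subset(snp_ids).df
    return float(((sub["beta"] / sub["se"]) ** 2).mean())


def clump(
    table: SummaryStatsTable,
    candidate_ids,
    ld: LDMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000.0,
) -> list[str]:
    """Greedy LD clumping.

    Repeatedly keep the remaining candidate with the smallest p (the index
    SNP) and discard candidates on the same chromosome within
    ``window_kb`` kilobases whose squared correlation with the index is at
    or above ``r2_threshold``.  The result depends only on p-values,
    positions and LD — never on the input ordering; p ties break on snp_id.
    """
    missing = [s for s in candidate_ids if s not in ld]
    if missing:
        raise ValidationError(f"candidates absent from LD matrix: {missing}")
    if not candidate_ids:
        return []
    cand = table.subset(candidate_ids).df[["snp_id", "chrom", "pos_bp", "pval"]]
    cand = cand.sort_values(["pval", "snp_id"], kind="mergesort")

    kept: list[str] = []
    rows = list(cand.itertuples(index=False))
    window_bp = window_kb * 1_000.0
    while rows:
        index_snp = rows.pop(0)
        kept.append(index_snp.snp_id)
        survivors = []
        for row in rows:
            if (
                row.chrom == index_snp.chrom
                and abs(row.pos_bp - index_snp.pos_bp) <= window_bp
                and ld.r2(row.snp_id, index_snp.snp_id) >= r2_threshold
            ):
                continue
            survivors.append(row)
        rows = survivors
    logger.info("clumping: %d of %d candidates retained", len(kept), len(cand))
    return kept


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    instrument_ids,
    palindrome_eaf_tol: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Rules, applied per instrument present in both tables:

    * same allele pair, same orientation: keep as-is;
    * effect/other swapped: negate the outcome beta, mirror its eaf;
    * strand-complemented (with or without a swap): complement, then apply
      the same rules;
    * palindromic (A/T or G/C) SNPs carry no strand information, so they are
      oriented by allele frequency: both traits must have
      ``|eaf - 0.5| > palindrome_eaf_tol``, and the outcome is flipped when
      the two eafs fall on opposite sides of 0.5; otherwise the SNP is
      dropped as ambiguous;
    * irreconcilable allele pairs are dropped, never fatal.

    Instruments missing from the outcome table are dropped.  Every drop is
    logged with its reason and recorded on the returned set.
    """
    missing = set(instrument_ids) - set(exposure.snp_ids)
    if missing:
        raise ValidationError(f"instrument ids absent from exposure table: {sorted(missing)}")
    exp = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")

    rows = []
    dropped: list[tuple[str, str]] = []
    for snp in instrument_ids:
        if snp not in out.index:
            dropped.append((snp, "absent from outcome table"))
            continue
        e = exp.loc[snp]
        o = out.loc[snp]
        e_pair = (e["effect_allele"], e["other_allele"])
        o_pair = (o["effect_allele"], o["other_allele"])
        beta_y = float(o["beta"])

        if _is_palindromic(*e_pair):
            if set(o_pair) != set(e_pair):
                dropped.append((snp, "irreconcilable alleles"))
                continue
            eaf_e, eaf_o = float(e["eaf"]), float(o["eaf"])
            if o_pair != e_pair:  # labels swapped: express on exposure's allele
                beta_y = -beta_y
                eaf_o = 1.0 - eaf_o
            if (
                abs(eaf_e - 0.5) <= palindrome_eaf_tol
                or abs(eaf_o - 0.5) <= palindrome_eaf_tol
            ):
                dropped.append((snp, "palindromic with ambiguous eaf"))
                continue
            if (eaf_e - 0.5) * (eaf_o - 0.5) < 0:  # opposite strands
                beta_y = -beta_y
        else:
            comp = (_COMPLEMENT[o_pair[0]], _COMPLEMENT[o_pair[1]])
            if o_pair == e_pair or comp == e_pair:
                pass
            elif o_pair == e_pair[::-1] or comp == e_pair[::-1]:
                beta_y = -beta_y
            else:
                dropped.append((snp, "irreconcilable alleles"))
                continue

        rows.append(
            {
                "snp_id": snp,
                "gamma_hat": float(e["beta"]),
                "sigma_x": float(e["se"]),
                "Gamma_hat": beta_y,
                "sigma_y": float(o["se"]),
            }
        )

    for snp, reason in dropped:
        logger.info("harmonize: dropped %s (%s)", snp, reason)
    if not rows:
        raise ValidationError(
            f"no instruments survived harmonization of "
            f"{exposure.trait_id!r} vs {outcome.trait_id!r}"
        )
    hs = HarmonizedSet(exposure.trait_id, outcome.trait_id, pd.DataFrame(rows))
    hs.dropped = dropped
    logger.info(
        "harmonize %s vs %s: %d aligned, %d dropped",
        exposure.trait_id,
        outcome.trait_id,
        len(hs),
        len(dropped),
    )
    return hs
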