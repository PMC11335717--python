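"""Reading and writing GWAS summary-statistics tables and LD matrices.

The canonical on-disk dialect is tab-delimited text with the header
``snp_id, chrom, pos_bp, effect_allele, other_allele, eaf, beta, se, pval, n``.
Foreign headers are accommodated through a ``column_map``.  Effect sizes are
assumed to be on an additive per-effect-allele scale: log odds ratios for
binary traits and standard-deviation units for quantitative traits.
Positions are 1-based base pairs (GWAS-catalog convention) and are only used
for distance-based clumping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger("medmr")

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos_bp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP-level association statistic."""

    snp_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int


@dataclass
class SummaryStatsTable:
    """One GWAS dataset (exposure, mediator, or outcome trait).

    ``df`` holds the canonical columns; ``snp_id`` values are unique and the
    table is non-empty.
    """

    trait_id: str
    trait_type: str  # "binary" | "quantitative"
    df: pd.DataFrame

    def __post_init__(self):
        if self.trait_type not in ("binary", "quantitative"):
            raise ValidationError(
                f"trait_type must be binary or quantitative, got {self.trait_type!r}"
            )
        if len(self.df) == 0:
            raise ValidationError(f"table {self.trait_id!r} has no records")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"table {self.trait_id!r} missing columns: {missing}")
        dupes = self.df["snp_id"][self.df["snp_id"].duplicated()].tolist()
        if dupes:
            raise ValidationError(f"duplicate snp_id in {self.trait_id!r}: {sorted(set(dupes))}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    @property
    def records(self) -> list[SummaryStatRecord]:
        return [SummaryStatRecord(**row) for row in self.df[CANONICAL_COLUMNS].to_dict("records")]

    def subset(self, snp_ids) -> "SummaryStatsTable":
        """Rows restricted to ``snp_ids``, in the given order."""
        sub = self.df.set_index("snp_id", drop=False).loc[list(snp_ids)]
        return SummaryStatsTable(self.trait_id, self.trait_type, sub.reset_index(drop=True))


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r) for an ordered set of SNPs."""

    snp_ids: list[str]
    r: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValidationError(
                f"LD matrix shape {self.r.shape} does not match {k} snp ids"
            )
        if np.max(np.abs(self.r)) > 1 + 1e-8:
            raise ValidationError("LD correlations must lie in [-1, 1]")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric within 1e-8")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two SNPs."""
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Apply record-level invariants row by row.

    Returns the surviving frame and a list of (line_number, reason) for
    rejected rows.  Line numbers are 1-based counting the header as line 1.
    """
    reasons = pd.Series("", index=df.index)

    def flag(mask, reason):
        nonlocal reasons
        mask = mask & (reasons == "")
        reasons[mask] = reason

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=ea, other_allele=oa)

    flag(~ea.isin(_BASES) | ~oa.isin(_BASES), "allele not in A/C/G/T")
    flag(ea == oa, "effect_allele equals other_allele")
    flag(~(df["se"] > 0), "se must be > 0")
    flag(~df["eaf"].between(0, 1), "eaf outside [0, 1]")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0, 1]")
    flag(~(df["n"] > 0), "n must be positive")

    bad = reasons != ""
    rejected = [(int(i) + 2, reasons[i]) for i in df.index[bad]]
    return df[~bad], rejected


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"snp_id": "SNP", "pval": "P"}``.  Rows violating record invariants are
    rejected individually and logged with their line numbers; if more than
    half of the data rows fail, the whole read is treated as a format error.
    """
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise FormatError(f"{path}: empty or undelimited file") from None
    if len(df.columns) == 0 or len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[CANONICAL_COLUMNS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos_bp"] = pd.to_numeric(df["pos_bp"], errors="coerce").astype("Int64")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype("Int64")

    n_data = len(df)
    kept, rejected = _validate_rows(df)
    for line_no, reason in rejected:
        logger.warning("%s line %d rejected: %s", path, line_no, reason)
    if len(rejected) > n_data / 2:
        raise FormatError(
            f"{path}: {len(rejected)}/{n_data} rows failed validation; "
            "refusing to load a majority-invalid file"
        )
    if len(kept) == 0:
        raise FormatError(f"{path}: no valid rows after validation")

    dupes = kept["snp_id"][kept["snp_id"].duplicated()]
    if len(dupes) > 0:
        raise ValidationError(f"{path}: duplicate snp_id values {sorted(set(dupes))}")

    kept = kept.assign(pos_bp=kept["pos_bp"].astype(int), n=kept["n"].astype(int))
    tid = trait_id if trait_id is not None else str(path)
    table = SummaryStatsTable(tid, trait_type, kept.reset_index(drop=True))
    logger.info("read %s: %d rows loaded, %d rejected", path, len(table), len(rejected))
    return table


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write a table in the canonical tab-delimited dialect.

    Floats are rendered with 12 significant digits so that a write→read
    round trip is the identity to within float-rendering precision.
    """
    df = table.df[CANONICAL_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    logger.info("wrote %s: %d rows", path, len(df))


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD correlation matrix: first row snp ids, body a square matrix."""
    df = pd.read_csv(path, sep="\t")
    ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(
            f"{path}: LD matrix is {mat.shape[0]}x{mat.shape[1]}, expected square"
        )
    return LDMatrix(ids, mat)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, columns=ld.snp_ids).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_config(path) -> dict:
    """Parse a plain ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored.  Values are returned as
    int/float/bool where they parse as such, else strings.
    """
    out: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: expected 'key = value', got {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            out[key] = _coerce(val)
    return out


def _coerce(val: str):
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def setup_logging(level: int = logging.INFO, logfile=None) -> None:
    """Route package logs to stderr and optionally to a file."""
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        logger.addHandler(fh)
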