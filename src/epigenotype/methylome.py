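"""Per-cytosine methylation tables (allc format) and methylation-status calls.

The allc format is a 7-column TSV with one row per cytosine:

    chrom  pos  strand  context  mc  total  is_methylated

``pos`` is 1-based, ``mc`` is the methylated-read count, ``total`` the
total read count (methylated + unmethylated) and ``is_methylated`` a 0/1
call.  The weighted methylation level of a position or region is
mc / (mc + uC) = mc / total.  Methylation-status calls use a one-sided
binomial test against the bisulfite non-conversion rate, corrected with
Benjamini-Hochberg FDR; only positions with at least three mapped reads
are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "total", "is_methylated"]
VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH"})
VALID_STRANDS = frozenset({"+", "-"})

MIN_COVERAGE = 3  # minimum mapped reads for a position to be testable


class AllcFormatError(ValueError):
    """Raised when an allc file does not have the expected columns."""


class AllcValidationError(ValueError):
    """Raised when allc records violate table invariants (e.g. mc > total)."""


def _validate_frame(df: pd.DataFrame, where: str = "table") -> pd.DataFrame:
    if list(df.columns) != ALLC_COLUMNS:
        raise AllcFormatError(
            f"{where}: expected columns {ALLC_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) == 0:
        return df.reset_index(drop=True)
    bad_ctx = set(df["context"].unique()) - VALID_CONTEXTS
    if bad_ctx:
        raise AllcValidationError(f"{where}: invalid context values {sorted(bad_ctx)}")
    bad_strand = set(df["strand"].unique()) - VALID_STRANDS
    if bad_strand:
        raise AllcValidationError(f"{where}: invalid strand values {sorted(bad_strand)}")
    if (df["total"] <= 0).any():
        raise AllcValidationError(f"{where}: total read count must be positive")
    if (df["mc"] < 0).any():
        raise AllcValidationError(f"{where}: negative methylated-read count")
    if (df["mc"] > df["total"]).any():
        n = int((df["mc"] > df["total"]).sum())
        raise AllcValidationError(f"{where}: mc > total at {n} position(s)")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise AllcValidationError(
            f"{where}: duplicate positions (positions must be strictly "
            f"increasing within a chromosome)"
        )
    return df


@dataclass
class MethylomeTable:
    """Per-cytosine methylation counts and calls for one sample.

    ``df`` holds one row per cytosine with the allc columns; positions are
    1-based and strictly increasing within each chromosome.
    """

    sample_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df, where=f"sample {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def levels(self) -> pd.Series:
        """Weighted methylation level mc/total per position."""
        return self.df["mc"] / self.df["total"]

    def by_position(self) -> pd.DataFrame:
        """The table indexed by (chrom, pos) for positionwise joins."""
        return self.df.set_index(["chrom", "pos"])


@dataclass
class PanMethylome(MethylomeTable):
    """Positionwise sum of methylated and total reads across samples of a line."""

    n_samples: int = 0


def read_allc(path, sample_id: str | None = None) -> MethylomeTable:
    """Read an allc TSV (gzip-transparent; header row optional)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=ALLC_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
        comment="#",
    )
    if len(df) and isinstance(df.iloc[0]["pos"], str):
        # first row was a header line
        df = df.iloc[1:].reset_index(drop=True)
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            ALLC_COLUMNS, [str, int, str, str, int, int, int])})
    try:
        df["pos"] = df["pos"].astype(np.int64)
        df["mc"] = df["mc"].astype(np.int64)
        df["total"] = df["total"].astype(np.int64)
        df["is_methylated"] = df["is_methylated"].astype(np.int64).astype(bool)
    except (ValueError, TypeError) as exc:
        raise AllcFormatError(f"{path}: malformed numeric column: {exc}") from None
    if sample_id is None:
        sample_id = str(path)
    return MethylomeTable(sample_id=sample_id, df=df)


def write_allc(table: MethylomeTable, path) -> None:
    df = table.df.copy()
    df["is_methylated"] = df["is_methylated"].astype(int)
    df.to_csv(path, sep="\t", header=False, index=False)


def weighted_methylation(mc, total):
    """Weighted methylation level mc / (mC + uC) = mc / total.

    Accepts scalars or arrays; ``total`` must be positive everywhere
    (positions without coverage must be filtered by the caller).
    """
    mc = np.asarray(mc)
    total = np.asarray(total)
    if np.any(total <= 0):
        raise ValueError("weighted methylation undefined for total <= 0")
    out = mc / total
    return float(out) if out.ndim == 0 else out


def binomial_tail_p(mc, total, nonconversion: float):
    """One-sided binomial p-value P(X >= mc | n = total, p = nonconversion)."""
    mc = np.asarray(mc)
    total = np.asarray(total)
    return stats.binom.sf(mc - 1, total, nonconversion)


def call_methylation_status(
    table: MethylomeTable, nonconversion: float, alpha: float = 0.05
) -> MethylomeTable:
    """Call methylated positions by binomial test + Benjamini-Hochberg FDR.

    Positions with fewer than three mapped reads are excluded from testing
    and marked unmethylated.  The BH family is all tested positions of the
    sample, pooled across contexts.  Returns a new table; the input is not
    modified.
    """
    if not 0.0 <= nonconversion <= 1.0:
        raise ValueError(f"nonconversion rate must be in [0, 1], got {nonconversion}")
    df = table.df.copy()
    testable = (df["total"] >= MIN_COVERAGE).to_numpy()
    is_methylated = np.zeros(len(df), dtype=bool)
    if testable.any():
        p = binomial_tail_p(
            df.loc[testable, "mc"].to_numpy(),
            df.loc[testable, "total"].to_numpy(),
            nonconversion,
        )
        reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        is_methylated[testable] = reject
    df["is_methylated"] = is_methylated
    return MethylomeTable(sample_id=table.sample_id, df=df)


def combine_pan_methylome(tables: list[MethylomeTable], line_id: str = "pan") -> PanMethylome:
    """Sum methylated and total reads at each position across samples of a line.

    Positions present in only some samples are kept with the partial sums.
    Conflicting strand or context annotations at a shared position raise a
    validation error.
    """
    if not tables:
        raise ValueError("need at least one methylome table")
    frames = [t.df for t in tables]
    cat = pd.concat(frames, ignore_index=True)
    meta = cat.groupby(["chrom", "pos"])[["strand", "context"]].nunique()
    conflict = (meta > 1).any(axis=1)
    if conflict.any():
        where = meta.index[conflict][0]
        raise AllcValidationError(
            f"conflicting strand/context annotations at {where[0]}:{where[1]}"
        )
    agg = (
        cat.groupby(["chrom", "pos"], as_index=False)
        .agg(
            strand=("strand", "first"),
            context=("context", "first"),
            mc=("mc", "sum"),
            total=("total", "sum"),
        )
    )
    agg["is_methylated"] = False
    agg = agg[ALLC_COLUMNS]
    return PanMethylome(sample_id=line_id, df=agg, n_samples=len(tables))


def unmethylated_twin(pan: PanMethylome) -> PanMethylome:
    """The unmethylated counterpart: methylated reads set to zero, totals kept."""
    df = pan.df.copy()
    df["mc"] = 0
    df["is_methylated"] = False
    return PanMethylome(sample_id=f"{pan.sample_id}_unmethylated", df=df,
                        n_samples=pan.n_samples)
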