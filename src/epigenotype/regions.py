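"""Region-level filters, transgenerational epiallele calls and annotation.

Candidate differentially methylated regions (from any external DMR
caller) are filtered on length, covered-cytosine count and methylation
span, then tested for transgenerational change with a one-sided z-test
of a greater-than-25% level difference between adjacent generations
(Benjamini-Hochberg corrected per line).  A region with at least one
significant generation pair is an epilocus; several significant pairs
mark a hotspot of instability.  Companion helpers reproduce the
parent-parent DMR retention rule with sibling-specific elimination, the
methylated-region retention test, per-base-pair genomic feature
categorization and the gene-density definition of the centromere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .methylome import MIN_COVERAGE, MethylomeTable

# fixed centromere intervals (bp, 0-based half-open) for the A. thaliana
# TAIR10 assembly; chromosome 4 has two intervals flanking the
# heterochromatic knob
ARABIDOPSIS_CENTROMERES: dict[str, list[tuple[int, int]]] = {
    "Chr1": [(13_300_000, 16_300_000)],
    "Chr2": [(2_400_000, 5_400_000)],
    "Chr3": [(12_000_000, 15_000_000)],
    "Chr4": [(1_600_000, 1_900_000), (2_900_000, 5_000_000)],
    "Chr5": [(10_400_000, 13_400_000)],
}


@dataclass
class Region:
    """A genomic region with per-sample methylation counts.

    Coordinates are 0-based half-open.  ``samples`` maps sample (or
    generation) id to summed (mc, total) read counts over the region;
    ``n_cytosines_covered`` counts cytosines covered by at least three
    reads in every relevant sample.
    """

    chrom: str
    start: int
    end: int
    samples: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_cytosines_covered: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def level(self, sample: str) -> float:
        mc, total = self.samples[sample]
        if total <= 0:
            raise ValueError(f"no coverage for {sample} in {self.name or self.chrom}")
        return mc / total

    def levels(self) -> dict[str, float]:
        return {s: self.level(s) for s in self.samples}

    def span(self) -> float:
        """Difference between the highest and lowest sample level."""
        lv = list(self.levels().values())
        return max(lv) - min(lv)

    def overlaps(self, other: "Region") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and self.end > other.start)


def count_covered_cytosines(
    region: Region, tables: list[MethylomeTable], min_cov: int = MIN_COVERAGE
) -> int:
    """Cytosines inside the region covered >= min_cov in every table."""
    covered = None
    for t in tables:
        sub = t.df[(t.df["chrom"] == region.chrom)
                   & (t.df["pos"] > region.start)
                   & (t.df["pos"] <= region.end)]
        pos = set(sub.loc[sub["total"] >= min_cov, "pos"])
        covered = pos if covered is None else covered & pos
    return len(covered or ())


def filter_regions(
    candidates: list[Region],
    min_len: int = 40,
    min_cytosines: int = 10,
    min_cov: int = MIN_COVERAGE,
    min_span_diff: float = 0.20,
    tables: list[MethylomeTable] | None = None,
) -> list[Region]:
    """Retain candidate regions passing the length/coverage/span filters.

    A region survives when it is at least ``min_len`` bp long, has at
    least ``min_cytosines`` cytosines covered by ``min_cov`` reads in all
    samples, and the difference between its highest and lowest sample
    methylation level is at least ``min_span_diff``.  When ``tables`` is
    given, ``n_cytosines_covered`` is (re)computed from them.
    """
    out = []
    for r in candidates:
        if tables is not None:
            r.n_cytosines_covered = count_covered_cytosines(r, tables, min_cov)
        if r.length < min_len:
            continue
        if (r.n_cytosines_covered or 0) < min_cytosines:
            continue
        if r.span() < min_span_diff:
            continue
        out.append(r)
    return out


class ZTestResult(NamedTuple):
    z: float
    p: float


def ztest_level_difference(
    mc1: int, total1: int, mc2: int, total2: int, delta: float = 0.25
) -> ZTestResult:
    """One-sided z-test that two methylation levels differ by more than delta.

    Tests H1: |p1 - p2| > delta with the unpooled binomial standard error
    sqrt(p1(1-p1)/n1 + p2(1-p2)/n2); the p-value is the upper normal tail
    of z = (|p1 - p2| - delta) / SE.
    """
    if total1 <= 0 or total2 <= 0:
        raise ValueError("z-test undefined for zero total reads")
    p1, p2 = mc1 / total1, mc2 / total2
    se = np.sqrt(p1 * (1 - p1) / total1 + p2 * (1 - p2) / total2)
    diff = abs(p1 - p2)
    if se == 0.0:
        # both levels are exactly 0 or 1: the difference is known without error
        return ZTestResult(z=np.inf if diff > delta else -np.inf,
                           p=0.0 if diff > delta else 1.0)
    z = (diff - delta) / se
    return ZTestResult(z=float(z), p=float(stats.norm.sf(z)))


@dataclass
class EpialleleCall:
    """One adjacent-generation comparison at one region."""

    region: Region
    generation_pair: tuple[str, str]
    z: float
    p: float
    p_adjusted: float | None = None
    is_epiallele: bool = False


def call_epialleles(
    line_regions: list[Region],
    generations: list[str],
    delta: float = 0.25,
    alpha: float = 0.05,
) -> tuple[list[EpialleleCall], pd.DataFrame]:
    """Transgenerational epiallele calls for one line.

    For every region, each adjacent generation pair is z-tested for a
    greater-than-``delta`` methylation-level difference; p-values are BH
    corrected across all tests of the line and calls made at adjusted
    p <= ``alpha``.  The summary table marks epiloci (>= 1 epiallele) and
    hotspots (multiple changes between generations).
    """
    if len(generations) < 2:
        raise ValueError("need at least two generations")
    calls: list[EpialleleCall] = []
    for r in line_regions:
        for g1, g2 in zip(generations[:-1], generations[1:]):
            res = ztest_level_difference(*r.samples[g1], *r.samples[g2], delta=delta)
            calls.append(EpialleleCall(region=r, generation_pair=(g1, g2),
                                       z=res.z, p=res.p))
    if calls:
        _, adj, _, _ = multipletests([c.p for c in calls], alpha=alpha,
                                     method="fdr_bh")
        for c, a in zip(calls, adj):
            c.p_adjusted = float(a)
            c.is_epiallele = a <= alpha
    rows = []
    for r in line_regions:
        n = sum(c.is_epiallele for c in calls if c.region is r)
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end, "name": r.name,
            "n_epialleles": n, "is_epilocus": n >= 1, "is_hotspot": n >= 2,
            "n_tests": len(generations) - 1,
        })
    return calls, pd.DataFrame(rows)


def sibling_specific_dmrs(
    candidates: list[Region],
    focal: str,
    siblings: list[str],
    min_len: int = 40,
    min_diff: float = 0.25,
    delta: float = 0.25,
    alpha: float = 0.05,
) -> list[Region]:
    """DMRs that differ between a parent and its selfed sibling lines.

    Candidates are filtered to >= ``min_len`` bp with >= ``min_diff``
    absolute difference between the most and least methylated samples;
    the focal parent is z-tested against each sibling, p-values are BH
    corrected over all comparisons, and a region is sibling-specific when
    at least one comparison is significant at adjusted p <= ``alpha``.
    """
    kept = [r for r in candidates if r.length >= min_len and r.span() >= min_diff]
    tests: list[tuple[Region, float]] = []
    for r in kept:
        for sib in siblings:
            res = ztest_level_difference(*r.samples[focal], *r.samples[sib],
                                         delta=delta)
            tests.append((r, res.p))
    if not tests:
        return []
    _, adj, _, _ = multipletests([p for _, p in tests], alpha=alpha, method="fdr_bh")
    significant: set[int] = set()
    for (r, _), a in zip(tests, adj):
        if a <= alpha:
            significant.add(id(r))
    return [r for r in kept if id(r) in significant]


def parent_dmr_filter(
    parent_dmrs: list[Region],
    sibling_dmrs: list[Region],
    min_len: int = 40,
    min_diff: float = 0.25,
) -> list[Region]:
    """Retain parent-parent DMRs, eliminating sibling-variable regions.

    Parent DMRs shorter than ``min_len`` bp or with less than ``min_diff``
    absolute methylation difference are dropped; any remaining DMR that
    overlaps a sibling-specific DMR by at least one base is eliminated.
    """
    kept = [r for r in parent_dmrs if r.length >= min_len and r.span() >= min_diff]
    return [r for r in kept if not any(r.overlaps(s) for s in sibling_dmrs)]


def retain_methylated_regions(
    regions: list[Region],
    generations: list[str],
    alpha: float = 0.05,
    expected_level: float = 0.25,
    min_any_level: float = 0.10,
) -> list[Region]:
    """Retention test for methylated regions of a transgenerational line.

    Each region's most methylated generation is z-tested (one-sided)
    against the null level ``expected_level / n_generations`` — the level
    expected if 25% methylation occurred in a single generation and were
    diluted across the line.  P-values are BH corrected across regions;
    regions failing the test, or whose level is below ``min_any_level``
    in every generation, are removed.
    """
    if not regions:
        return []
    threshold = expected_level / len(generations)
    pvals = []
    for r in regions:
        best = max(generations, key=lambda g: r.level(g))
        mc, total = r.samples[best]
        se = np.sqrt(threshold * (1 - threshold) / total)
        z = (mc / total - threshold) / se
        pvals.append(stats.norm.sf(z))
    _, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    for r, a in zip(regions, adj):
        if a > alpha:
            continue
        if max(r.level(g) for g in generations) < min_any_level:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# genomic feature categorization
# ---------------------------------------------------------------------------

# priority high -> low; unassigned bases are intergenic
FEATURE_PRIORITY = ("ncRNA", "UTR", "intron", "CDS", "promoter", "TE")
INTERGENIC = "intergenic"

_NCRNA_TYPES = {"ncRNA", "tRNA", "rRNA", "snRNA", "snoRNA", "miRNA", "lncRNA",
                "ncRNA_gene", "antisense_RNA", "antisense_lncRNA"}
_TE_TYPES = {"transposable_element", "transposable_element_gene",
             "transposon_fragment"}
_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}

PROMOTER_BP = 1000  # promoter: 1 kb upstream of the transcription start site


class FeatureMap:
    """Priority-resolved genomic feature intervals.

    Holds typed intervals (0-based half-open) per chromosome; every base
    pair queried through :func:`assign_features` resolves to exactly one
    type, highest priority winning.
    """

    def __init__(self, intervals: list[tuple[str, int, int, str]]):
        self.by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, ftype in intervals:
            if ftype not in FEATURE_PRIORITY:
                raise ValueError(f"unknown feature type {ftype!r}")
            if end <= start:
                raise ValueError(f"malformed interval {chrom}:{start}-{end}")
            self.by_chrom.setdefault(chrom, []).append((int(start), int(end), ftype))

    @classmethod
    def from_gff3(cls, path) -> "FeatureMap":
        """Build a feature map from a GFF3 annotation.

        Promoters are 1 kb upstream of each protein-coding gene's TSS
        (strand aware); introns are mRNA spans minus their exons; UTRs,
        CDS, non-coding RNA and transposable-element records map directly.
        """
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
        intervals: list[tuple[str, int, int, str]] = []
        for f in db.all_features():
            s, e = f.start - 1, f.end  # GFF3 is 1-based inclusive
            if f.featuretype in _NCRNA_TYPES:
                intervals.append((f.seqid, s, e, "ncRNA"))
            elif f.featuretype in _UTR_TYPES:
                intervals.append((f.seqid, s, e, "UTR"))
            elif f.featuretype == "CDS":
                intervals.append((f.seqid, s, e, "CDS"))
            elif f.featuretype in _TE_TYPES:
                intervals.append((f.seqid, s, e, "TE"))
            elif f.featuretype == "gene":
                if f.strand == "-":
                    intervals.append((f.seqid, e, e + PROMOTER_BP, "promoter"))
                else:
                    intervals.append((f.seqid, max(0, s - PROMOTER_BP), s, "promoter"))
            elif f.featuretype == "mRNA":
                exons = sorted((c.start - 1, c.end)
                               for c in db.children(f, featuretype="exon"))
                prev = s
                for xs, xe in exons:
                    if xs > prev:
                        intervals.append((f.seqid, prev, xs, "intron"))
                    prev = max(prev, xe)
                if e > prev and exons:
                    intervals.append((f.seqid, prev, e, "intron"))
        return cls(intervals)


def assign_features(region: Region, fmap: FeatureMap) -> dict[str, float]:
    """Proportional feature content of a region, one type per base pair.

    Every base takes the highest-priority overlapping feature type
    (ncRNA > UTR > intron > CDS > promoter > TE); bases under no feature
    are intergenic.  Proportions sum to 1.
    """
    n = region.length
    # paint lowest priority first so higher priorities overwrite
    code = np.full(n, len(FEATURE_PRIORITY), dtype=np.int8)  # intergenic
    order = {t: i for i, t in enumerate(FEATURE_PRIORITY)}
    ivs = fmap.by_chrom.get(region.chrom, [])
    for prio in range(len(FEATURE_PRIORITY) - 1, -1, -1):
        ftype = FEATURE_PRIORITY[prio]
        for s, e, t in ivs:
            if t != ftype:
                continue
            lo, hi = max(s, region.start), min(e, region.end)
            if hi > lo:
                code[lo - region.start:hi - region.start] = order[t]
    counts = np.bincount(code, minlength=len(FEATURE_PRIORITY) + 1)
    out = {t: counts[i] / n for i, t in enumerate(FEATURE_PRIORITY)}
    out[INTERGENIC] = counts[len(FEATURE_PRIORITY)] / n
    return out


def define_centromere(
    gene_density: np.ndarray,
    bin_size: int = 100_000,
    half_width: int = 1_500_000,
    override: list[tuple[int, int]] | None = None,
    grid_step: int = 1000,
) -> list[tuple[int, int]] | None:
    """Locate the centromere from gene density along a chromosome.

    A smoothing spline is fitted to genic base pairs per ``bin_size`` bin;
    the spline minimum is the centromere center and the centromere spans
    ``half_width`` on either side.  A user-supplied ``override`` interval
    list (e.g. for a chromosome with a heterochromatic knob) is returned
    unchanged.  A flat density profile yields a warning and ``None``.
    """
    if override is not None:
        return override
    gene_density = np.asarray(gene_density, dtype=float)
    if len(gene_density) < 4 or np.ptp(gene_density) == 0:
        warnings.warn("gene density flat or too short; centromere undefined")
        return None
    centers = (np.arange(len(gene_density)) + 0.5) * bin_size
    spline = UnivariateSpline(centers, gene_density)
    fine = np.arange(centers[0], centers[-1], grid_step)
    center = float(fine[np.argmin(spline(fine))])
    start = max(0, int(round(center - half_width)))
    return [(start, int(round(center + half_width)))]
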