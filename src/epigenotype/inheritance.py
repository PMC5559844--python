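"""Categorize parental DMRs by their F2 inheritance pattern.

At each region that differs between the parents, F2 individuals are
grouped by their epigenotype (maternal / heterozygous / paternal, from
the epigenotype map) and the group means of the region's methylation
level are compared pairwise with a Games-Howell-style Welch statistic,

    t = |mean_a - mean_b| / sqrt(s_a^2/n_a + s_b^2/n_b).

Because group sizes are small and unbalanced, significance comes from a
permutation null: the observed epigenotype labels are reshuffled 2000
times, the statistic recomputed, and a comparison is significant when
the observed t reaches the 99th percentile of its null distribution.

Regions are then categorized:

* **expected** — all three comparisons significant: methylation follows
  the epigenotype additively;
* **parental_dominant** — mean F2 level within 10% of one parent and
  every F2 closer to that parent (trans-chromosomal (de)methylation);
* **no_association** — neither heterozygous comparison significant;
* **ambiguous** — only one heterozygous comparison significant, or the
  evidence is otherwise contradictory;
* **unassessable** — a t-value could not be obtained (a group smaller
  than two, or no variance), so the region is removed from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epigenotyping import FATHER, MOTHER, MPV, EpigenotypeMap
from .regions import Region

# pairwise comparisons: mother-father, het-father, het-mother
PAIRS: tuple[tuple[int, int], ...] = ((MOTHER, FATHER), (MPV, FATHER), (MPV, MOTHER))
PAIR_NAMES = {(MOTHER, FATHER): "M-P", (MPV, FATHER): "H-P", (MPV, MOTHER): "H-M"}

CATEGORIES = ("expected", "parental_dominant", "no_association", "ambiguous",
              "unassessable")


def games_howell_t(group_a, group_b, min_group: int = 2) -> float | None:
    """Welch-type pairwise statistic between two groups of levels.

    Returns ``None`` when either group has fewer than ``min_group``
    members or the pooled standard error is zero (no variance in both
    groups), in which case the region cannot be assessed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < min_group or len(b) < min_group:
        return None
    se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if se2 == 0.0:
        return None
    return float(abs(a.mean() - b.mean()) / np.sqrt(se2))


def _pair_t_matrix(label_matrix: np.ndarray, levels: np.ndarray,
                   min_group: int = 2) -> np.ndarray:
    """t statistics for all PAIRS over rows of permuted labels; NaN if invalid."""
    B = label_matrix.shape[0]
    cnt = np.empty((3, B))
    mean = np.empty((3, B))
    var = np.empty((3, B))
    for s in range(3):
        mask = label_matrix == s
        c = mask.sum(axis=1)
        tot = mask @ levels
        tot2 = mask @ (levels ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = tot / c
            v = (tot2 - c * m ** 2) / (c - 1)
        cnt[s], mean[s], var[s] = c, m, np.maximum(v, 0.0)
    out = np.empty((len(PAIRS), B))
    for k, (a, b) in enumerate(PAIRS):
        with np.errstate(invalid="ignore", divide="ignore"):
            se2 = var[a] / cnt[a] + var[b] / cnt[b]
            t = np.abs(mean[a] - mean[b]) / np.sqrt(se2)
        t[(cnt[a] < min_group) | (cnt[b] < min_group) | (se2 <= 0)] = np.nan
        out[k] = t
    return out


def bootstrap_null(
    levels,
    epigenotypes,
    n_boot: int = 2000,
    seed=0,
    with_replacement: bool = False,
    percentile: float = 99.0,
    min_group: int = 2,
) -> dict[tuple[int, int], float] | None:
    """Per-pair null thresholds from label-reshuffled t statistics.

    The observed epigenotype multiset is permuted ``n_boot`` times
    (optionally resampled with replacement), the pairwise statistic is
    recomputed per draw, and the threshold is the ``percentile`` of the
    valid null values for each pair.  Returns ``None`` when some pair
    never yields a statistic (degenerate labels), in which case the
    region is removed.
    """
    levels = np.asarray(levels, dtype=float)
    labels = np.asarray(epigenotypes, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(levels)
    if with_replacement:
        perm = labels[rng.integers(0, n, size=(n_boot, n))]
    else:
        perm = rng.permuted(np.tile(labels, (n_boot, 1)), axis=1)
    t_null = _pair_t_matrix(perm, levels, min_group=min_group)
    thresholds: dict[tuple[int, int], float] = {}
    for k, pair in enumerate(PAIRS):
        valid = t_null[k][~np.isnan(t_null[k])]
        if len(valid) == 0:
            return None
        thresholds[pair] = float(np.percentile(valid, percentile))
    return thresholds


def categorize(
    levels,
    epigenotypes,
    parent_levels: tuple[float, float],
    significant: dict[tuple[int, int], bool],
    tol: float = 0.10,
) -> str:
    """Apply the inheritance-category rules in order.

    1. all three comparisons significant -> ``expected``;
    2. mean F2 level within ``tol`` of one parent and every F2 closer to
       that parent -> ``parental_dominant``;
    3. neither heterozygous comparison significant -> ``no_association``;
    4. otherwise -> ``ambiguous`` (covers exactly one significant
       heterozygous comparison, and the contradictory case of both
       heterozygous comparisons significant without a parental one).
    """
    levels = np.asarray(levels, dtype=float)
    if all(significant[p] for p in PAIRS):
        return "expected"
    pm, pf = parent_levels
    mean = levels.mean()
    for parent, other in ((pm, pf), (pf, pm)):
        if abs(mean - parent) <= tol and np.all(
                np.abs(levels - parent) <= np.abs(levels - other)):
            return "parental_dominant"
    if not significant[(MPV, FATHER)] and not significant[(MPV, MOTHER)]:
        return "no_association"
    return "ambiguous"


@dataclass
class InheritanceRecord:
    """Categorization evidence for one region."""

    region: Region | None
    levels: np.ndarray
    epigenotypes: np.ndarray
    parent_levels: tuple[float, float]
    t_values: dict[tuple[int, int], float | None] = field(default_factory=dict)
    thresholds: dict[tuple[int, int], float] | None = None
    significant: dict[tuple[int, int], bool] = field(default_factory=dict)
    category: str = "unassessable"


def epigenotype_at(emap: EpigenotypeMap, sample: str, chrom: str, pos: int) -> int:
    """Final epigenotype state of the bin containing a position (0-based)."""
    for i, b in enumerate(emap.binset.bins[chrom]):
        if b.start <= pos < b.end:
            return int(emap.final_states[(sample, chrom)][i])
    raise KeyError(f"position {chrom}:{pos} not covered by any bin")


def assess_region(
    levels,
    epigenotypes,
    parent_levels: tuple[float, float],
    n_boot: int = 2000,
    seed=0,
    tol: float = 0.10,
    with_replacement: bool = False,
    region: Region | None = None,
) -> InheritanceRecord:
    """t-values, permutation thresholds and category for one region."""
    rec = InheritanceRecord(
        region=region,
        levels=np.asarray(levels, dtype=float),
        epigenotypes=np.asarray(epigenotypes, dtype=int),
        parent_levels=parent_levels,
    )
    groups = {s: rec.levels[rec.epigenotypes == s] for s in range(3)}
    for a, b in PAIRS:
        rec.t_values[(a, b)] = games_howell_t(groups[a], groups[b])
    if any(t is None for t in rec.t_values.values()):
        return rec  # unassessable: a t-value could not be obtained
    rec.thresholds = bootstrap_null(
        rec.levels, rec.epigenotypes, n_boot=n_boot, seed=seed,
        with_replacement=with_replacement,
    )
    if rec.thresholds is None:
        return rec
    rec.significant = {
        p: rec.t_values[p] >= rec.thresholds[p] for p in PAIRS
    }
    rec.category = categorize(rec.levels, rec.epigenotypes, parent_levels,
                              rec.significant, tol=tol)
    return rec


def categorize_regions(
    regions: list[Region],
    emap: EpigenotypeMap,
    f2_ids: list[str],
    mother_id: str,
    father_id: str,
    n_boot: int = 2000,
    seed: int = 0,
    tol: float = 0.10,
) -> tuple[list[InheritanceRecord], pd.DataFrame]:
    """Categorize every region of a cohort by inheritance pattern.

    F2 epigenotypes are looked up from the map at the region midpoint;
    each region gets its own RNG stream derived from ``seed`` so results
    are reproducible region by region.
    """
    records, rows = [], []
    for i, r in enumerate(regions):
        mid = (r.start + r.end) // 2
        labels = [epigenotype_at(emap, s, r.chrom, mid) for s in f2_ids]
        levels = [r.level(s) for s in f2_ids]
        rec = assess_region(
            levels, labels, (r.level(mother_id), r.level(father_id)),
            n_boot=n_boot, seed=[seed, i], tol=tol, region=r,
        )
        records.append(rec)
        row = {"chrom": r.chrom, "start": r.start, "end": r.end, "name": r.name,
               "category": rec.category}
        for p in PAIRS:
            row[f"t_{PAIR_NAMES[p]}"] = rec.t_values.get(p)
            row[f"thr_{PAIR_NAMES[p]}"] = (rec.thresholds or {}).get(p)
        rows.append(row)
    return records, pd.DataFrame(rows)
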