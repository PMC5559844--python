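"""Population statistics on epigenotype maps: crossovers and allele frequency.

Crossovers are counted where adjacent bins of a sample's final map carry
different states.  Per chromosome, a Poisson distribution is fitted to
the per-sample crossover counts (mean = sample mean) and the observed
category counts for 0..6 crossovers (with a pooled ">6" category) are
compared to the Poisson expectation with an exact multinomial
goodness-of-fit test; p-values are Benjamini-Hochberg corrected across
chromosomes.

In an F2 population each individual contributes two alleles per bin (a
heterozygote one of each), so allele frequency is expected 1:1.  A
chi-square goodness-of-fit test is run per bin and BH-corrected across
bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy
from statsmodels.stats.multitest import multipletests

from .epigenotyping import FATHER, MOTHER, MPV, EpigenotypeMap

MAX_CROSSOVER_CATEGORY = 6  # categories 0..6 plus a pooled ">6" remainder


def count_crossovers(emap: EpigenotypeMap) -> pd.DataFrame:
    """Per-sample, per-chromosome counts of adjacent-bin state changes."""
    rows = []
    for sample in emap.samples:
        for chrom in emap.chroms:
            states = emap.final_states[(sample, chrom)]
            valid = states >= 0
            s = states[valid]
            rows.append({
                "sample": sample,
                "chrom": chrom,
                "n_crossovers": int(np.sum(s[:-1] != s[1:])) if len(s) > 1 else 0,
            })
    return pd.DataFrame(rows)


@lru_cache(maxsize=8)
def _compositions(n: int, k: int) -> np.ndarray:
    """All ways to place n items into k ordered cells (stars and bars).

    Cached: repeated tests over the same (n, k) outcome space (e.g. one
    test per chromosome) reuse the enumeration.  Callers must not mutate
    the returned array.
    """
    bars = np.array(list(combinations(range(n + k - 1), k - 1)), dtype=np.int64)
    if k == 1:
        return np.full((1, 1), n, dtype=np.int64)
    padded = np.concatenate(
        [np.full((len(bars), 1), -1), bars,
         np.full((len(bars), 1), n + k - 1)], axis=1)
    return np.diff(padded, axis=1) - 1


def _multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    counts = np.atleast_2d(counts)
    n = counts.sum(axis=1)
    return (gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
            + xlogy(counts, probs).sum(axis=1))


def exact_multinomial_test(
    observed: np.ndarray,
    probs: np.ndarray,
    enumeration_limit: int = 1_000_000,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Exact multinomial goodness-of-fit p-value.

    The p-value is the total probability of outcomes no more likely than
    the observed one.  All outcomes are enumerated when the outcome space
    has at most ``enumeration_limit`` elements; otherwise the p-value is
    estimated from ``n_mc`` seeded Monte-Carlo draws (reported resolution
    ~ 1/sqrt(n_mc)).
    """
    observed = np.asarray(observed, dtype=np.int64)
    probs = np.asarray(probs, dtype=float)
    if observed.ndim != 1 or observed.shape != probs.shape:
        raise ValueError("observed counts and probabilities must align")
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError("category probabilities must sum to 1")
    n, k = int(observed.sum()), len(observed)
    if n == 0:
        return 1.0
    obs_logp = _multinomial_logpmf(observed, probs)[0]
    tol = 1e-9  # float slack so ties count as "no more likely"
    if comb(n + k - 1, k - 1) <= enumeration_limit:
        space = _compositions(n, k)
        logp = _multinomial_logpmf(space, probs)
        return float(np.exp(logp[logp <= obs_logp + tol]).sum())
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_mc)
    logp = _multinomial_logpmf(draws, probs)
    return float(np.mean(logp <= obs_logp + tol))


@dataclass
class CrossoverSummary:
    """Poisson fit and exact multinomial test for one chromosome."""

    chrom: str
    counts: np.ndarray            # per-sample crossover counts
    poisson_mean: float
    category_probs: np.ndarray    # P(X = 0..6) plus the ">6" remainder
    observed_categories: np.ndarray
    p_value: float
    p_adjusted: float | None = None


def crossover_test(
    counts: np.ndarray, chrom: str = "", max_k: int = MAX_CROSSOVER_CATEGORY,
    seed: int = 0,
) -> CrossoverSummary:
    """Fit a Poisson to per-sample crossover counts and test the fit.

    The Poisson mean is the sample mean; expected category probabilities
    are pmf(0..max_k) with the residual mass pooled into a terminal ">"
    category, compared to the observed counts with the exact multinomial
    test.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if len(counts) < 2:
        raise ValueError("need crossover counts for at least 2 samples")
    if (counts < 0).any():
        raise ValueError("crossover counts must be non-negative")
    lam = float(counts.mean())
    pmf = stats.poisson.pmf(np.arange(max_k + 1), lam)
    probs = np.append(pmf, max(0.0, 1.0 - pmf.sum()))
    observed = np.bincount(np.minimum(counts, max_k + 1), minlength=max_k + 2)
    p = exact_multinomial_test(observed, probs, seed=seed)
    return CrossoverSummary(
        chrom=chrom, counts=counts, poisson_mean=lam, category_probs=probs,
        observed_categories=observed, p_value=p,
    )


def crossover_summary(emap: EpigenotypeMap, seed: int = 0) -> pd.DataFrame:
    """Per-chromosome crossover test with BH correction across chromosomes."""
    cc = count_crossovers(emap)
    results = []
    for chrom, sub in cc.groupby("chrom", sort=True):
        results.append(crossover_test(sub["n_crossovers"].to_numpy(),
                                      chrom=str(chrom), seed=seed))
    pvals = [r.p_value for r in results]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    rows = []
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
        rows.append({
            "chrom": r.chrom, "n_samples": len(r.counts),
            "mean_crossovers": r.poisson_mean,
            "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        })
    return pd.DataFrame(rows)


def allele_frequency_test(emap: EpigenotypeMap, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square test of the expected 1:1 allele ratio at every bin.

    Each F2 contributes two alleles per bin: homozygous states contribute
    two of one parent, the heterozygous state one of each.  Bins where a
    sample's state is undefined drop that sample.  P-values are
    BH-corrected across all bins of all chromosomes.
    """
    if not emap.samples:
        raise ValueError("no samples in map")
    rows = []
    for chrom in emap.chroms:
        bins = emap.binset.bins[chrom]
        states = np.stack([emap.final_states[(s, chrom)] for s in emap.samples])
        for i, b in enumerate(bins):
            col = states[:, i]
            col = col[col >= 0]
            maternal = int(2 * np.sum(col == MOTHER) + np.sum(col == MPV))
            paternal = int(2 * np.sum(col == FATHER) + np.sum(col == MPV))
            total = maternal + paternal
            if total == 0:
                continue
            chi2, p = stats.chisquare([maternal, paternal])
            rows.append({
                "chrom": chrom, "start": b.start, "end": b.end,
                "maternal_alleles": maternal, "paternal_alleles": paternal,
                "chi2": float(chi2), "p_value": float(p),
            })
    df = pd.DataFrame(rows)
    if len(df):
        reject, adj, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
        df["p_adjusted"] = adj
        df["reject_1to1"] = reject
    return df
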