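"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from epigenotype.methylome import ALLC_COLUMNS, MethylomeTable


def make_table(sample_id, rows):
    """Build a MethylomeTable from (chrom, pos, strand, context, mc, total,
    is_methylated) tuples."""
    df = pd.DataFrame(rows, columns=ALLC_COLUMNS)
    df["is_methylated"] = df["is_methylated"].astype(bool)
    return MethylomeTable(sample_id=sample_id, df=df)


def brute_force_chain(emissions, T, init=None, mask=None):
    """Exhaustive 3^N enumeration oracle for posteriors and the best path.

    Returns (posteriors, best_path, best_path_probability), computed by
    summing/maximizing over every state path explicitly.
    """
    E = np.array(emissions, dtype=float)
    if mask is not None:
        E[np.asarray(mask, dtype=bool)] = 1.0
    T = np.asarray(T, dtype=float)
    N = E.shape[0]
    pi = np.full(3, 1.0 / 3.0) if init is None else np.asarray(init, dtype=float)
    post = np.zeros((N, 3))
    best_p, best_path = -np.inf, None
    for path in product(range(3), repeat=N):
        p = pi[path[0]] * E[0, path[0]]
        for i in range(1, N):
            p *= T[path[i - 1], path[i]] * E[i, path[i]]
        for i, s in enumerate(path):
            post[i, s] += p
        if p > best_p:
            best_p, best_path = p, np.array(path)
    post /= post.sum(axis=1, keepdims=True)
    return post, best_path, best_p


def path_probability(path, emissions, T, init=None, mask=None):
    """Probability of one explicit state path (for Viterbi score checks)."""
    E = np.array(emissions, dtype=float)
    if mask is not None:
        E[np.asarray(mask, dtype=bool)] = 1.0
    T = np.asarray(T, dtype=float)
    pi = np.full(3, 1.0 / 3.0) if init is None else np.asarray(init, dtype=float)
    p = pi[path[0]] * E[0, path[0]]
    for i in range(1, len(path)):
        p *= T[path[i - 1], path[i]] * E[i, path[i]]
    return p


@pytest.fixture(scope="session")
def small_parents():
    """Small synthetic parental methylomes (2 Mb, 600 informative positions)."""
    from epigenotype.simulate import synth_parents

    return synth_parents(n_positions=600, chrom_length=2_000_000, seed=11)
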