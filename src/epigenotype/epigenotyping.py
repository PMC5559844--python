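"""Epigenotype maps: bin classifier + HMM smoothing along each chromosome.

The procedure assigns every genomic bin of every offspring one of three
parent-of-origin states — MOTHER, MPV (mid-parent, i.e. heterozygous) or
FATHER — using only DNA methylation:

1. *Informative positions*: cytosines covered by at least three reads in
   both parents where exactly one parent is methylated (binomial call).
2. *Bins*: each chromosome is tiled with fixed-width bins; bins with
   fewer than three informative positions are merged with a neighbor.
3. *Classifier*: per bin, a one-vs-rest logistic-regression classifier is
   trained on the maternal, paternal and mid-parent feature vectors
   (methylation levels at the bin's positions), with classes weighted
   1:2:1 for an F2 population, and applied to every sample.
4. *Forward-backward*: the class probabilities become HMM emissions; the
   transition matrix is counted from the preliminary state sequences of
   all samples except the parents (pseudo-count 1) and posteriors are
   computed per chromosome.  Centromeric bins can be masked so that only
   transitions inform the posterior (emission 1.0 in every state).
5. *Viterbi*: a second transition matrix is counted from the
   forward-backward states and the Viterbi path over the posteriors is
   the final epigenotype.  Adjacent bins with different final states
   define crossovers.

Derived populations with different expected heterozygosity (e.g. F8
epiRILs, heterozygosity (1/2)^7) use adjusted class weights, and an
emission adjustment that moves mid-parent probability mass onto the
mutant parent before smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .methylome import MIN_COVERAGE, MethylomeTable

MOTHER, MPV, FATHER = 0, 1, 2
STATE_NAMES = ("mother", "mpv", "father")
_STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

F2_CLASS_WEIGHTS = (0.25, 0.5, 0.25)


def epiril_class_weights(n_generations: int = 8) -> tuple[float, float, float]:
    """Class weights from expected heterozygosity of a selfed generation.

    Heterozygosity halves each selfed generation: h = (1/2)^(g-1), so for
    an F8 population h = (1/2)^7 = 0.0078125 and each homozygous class
    gets (1 - h)/2 = 0.49609375 (the 127:2:127 ratio).
    """
    if n_generations < 2:
        raise ValueError("need generation >= 2")
    h = 0.5 ** (n_generations - 1)
    return ((1.0 - h) / 2.0, h, (1.0 - h) / 2.0)


# ---------------------------------------------------------------------------
# informative positions and bins
# ---------------------------------------------------------------------------

def find_informative_positions(
    mother: MethylomeTable, father: MethylomeTable, min_coverage: int = MIN_COVERAGE
) -> dict[str, np.ndarray]:
    """Differentially methylated positions usable as parent-of-origin markers.

    A position qualifies when both parents cover it with at least
    ``min_coverage`` reads and exactly one parent is methylated.  Returns
    sorted position arrays (1-based) keyed by chromosome.
    """
    m = mother.df.set_index(["chrom", "pos"])[["total", "is_methylated"]]
    f = father.df.set_index(["chrom", "pos"])[["total", "is_methylated"]]
    j = m.join(f, how="inner", lsuffix="_m", rsuffix="_f")
    ok = (
        (j["total_m"] >= min_coverage)
        & (j["total_f"] >= min_coverage)
        & (j["is_methylated_m"] != j["is_methylated_f"])
    )
    j = j[ok]
    out: dict[str, np.ndarray] = {}
    for chrom, sub in j.groupby(level="chrom", sort=True):
        out[str(chrom)] = np.sort(sub.index.get_level_values("pos").to_numpy())
    return out


@dataclass
class Bin:
    """A genomic bin: 0-based half-open interval with its informative positions."""

    start: int
    end: int
    positions: np.ndarray
    is_centromere: bool = False

    @property
    def n_positions(self) -> int:
        return len(self.positions)


@dataclass
class BinSet:
    """Per-chromosome bins tiling each chromosome without overlap."""

    bins: dict[str, list[Bin]]
    bin_size: int

    def n_bins(self, chrom: str) -> int:
        return len(self.bins[chrom])


def make_bins(
    chrom_length: int,
    bin_size: int,
    positions: np.ndarray,
    min_positions: int = 3,
) -> list[Bin]:
    """Tile a chromosome with fixed-width bins and merge sparse ones.

    Bins with fewer than ``min_positions`` informative positions are merged
    forward into the next bin (a single left-to-right pass); a sparse
    terminal bin merges backward into the last emitted bin.  Merging leaves
    at least one bin even if the whole chromosome has too few positions.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    positions = np.asarray(positions, dtype=np.int64)
    edges = list(range(0, int(chrom_length), int(bin_size))) + [int(chrom_length)]
    if len(edges) < 2:  # chrom shorter than one bin
        edges = [0, int(chrom_length)]
    out: list[Bin] = []
    carry_start: int | None = None
    carry_pos: list[np.ndarray] = []
    for s, e in zip(edges[:-1], edges[1:]):
        # positions are 1-based: p falls in [s, e) iff s < p <= e
        in_bin = positions[(positions > s) & (positions <= e)]
        start = s if carry_start is None else carry_start
        pos = np.concatenate(carry_pos + [in_bin]) if carry_pos else in_bin
        if len(pos) >= min_positions:
            out.append(Bin(start=start, end=e, positions=pos))
            carry_start, carry_pos = None, []
        else:
            carry_start, carry_pos = start, [pos]
    if carry_start is not None:
        pos = carry_pos[0]
        if out:
            last = out[-1]
            out[-1] = Bin(
                start=last.start,
                end=edges[-1],
                positions=np.concatenate([last.positions, pos]),
            )
        else:
            out.append(Bin(start=carry_start, end=edges[-1], positions=pos))
    return out


def flag_centromere_bins(
    bins: list[Bin], intervals: list[tuple[int, int]] | None
) -> None:
    """Mark bins overlapping any centromere interval (any-overlap, in place)."""
    if not intervals:
        return
    for b in bins:
        b.is_centromere = any(b.start < e and b.end > s for s, e in intervals)


# ---------------------------------------------------------------------------
# per-bin classifier
# ---------------------------------------------------------------------------

def midparent_vector(mother_levels: np.ndarray, father_levels: np.ndarray) -> np.ndarray:
    """Mid-parent value: elementwise mean of the parental methylation levels."""
    mother_levels = np.asarray(mother_levels, dtype=float)
    father_levels = np.asarray(father_levels, dtype=float)
    if mother_levels.shape != father_levels.shape:
        raise ValueError(
            f"parental vectors differ in shape: {mother_levels.shape} vs "
            f"{father_levels.shape}"
        )
    return (mother_levels + father_levels) / 2.0


def train_and_classify_bin(
    train_X: np.ndarray,
    train_y: np.ndarray,
    sample_X: np.ndarray,
    class_weights: tuple[float, float, float] = F2_CLASS_WEIGHTS,
    C: float = 100.0,
) -> tuple[np.ndarray, bool]:
    """One-vs-rest logistic regression for one bin.

    ``train_X`` holds the labeled parental/mid-parent feature vectors
    (replicates allowed), ``train_y`` their states, ``sample_X`` the
    vectors to classify.  Class weights enter as per-sample weights,
    rescaled to mean 1 so that only their ratio matters and the effective
    amount of L2 regularization stays at the solver default regardless of
    how the weights were normalized.  Fits one L2-regularized binary
    logistic regression (liblinear) per state and normalizes the three
    positive-class probabilities per sample.

    Returns ``(probs, informative)`` where ``probs`` is (n_samples, 3) and
    ``informative`` is False when the training vectors are all identical
    (mother equals father throughout the bin) — then the probabilities are
    uniform.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    sample_X = np.asarray(sample_X, dtype=float)
    n = sample_X.shape[0]
    if len({MOTHER, MPV, FATHER} - set(train_y)) > 0:
        raise ValueError("need at least one training vector per class")
    if np.all(np.ptp(train_X, axis=0) < 1e-12):
        return np.full((n, 3), 1.0 / 3.0), False
    w = np.asarray(class_weights, dtype=float)[train_y]
    w = w * (len(w) / w.sum())  # ratio-preserving rescale to mean weight 1
    scores = np.empty((n, 3))
    for k in range(3):
        yk = train_y == k
        clf = LogisticRegression(solver="liblinear", C=C)
        clf.fit(train_X, yk, sample_weight=w)
        pos_col = int(np.flatnonzero(clf.classes_)[0])
        scores[:, k] = clf.predict_proba(sample_X)[:, pos_col]
    scores /= scores.sum(axis=1, keepdims=True)
    return scores, True


# ---------------------------------------------------------------------------
# HMM: transitions, forward-backward, Viterbi
# ---------------------------------------------------------------------------

def estimate_transitions(
    state_sequences: list[np.ndarray], pseudo: float = 1.0
) -> np.ndarray:
    """Row-normalized 3x3 transition counts over adjacent bins.

    Counts transitions l -> k over all consecutive bin pairs of every
    sequence, adds ``pseudo`` to every cell and normalizes rows.  With no
    sequences (or none with two bins) every row is uniform.  Negative
    (undefined) states are skipped.
    """
    counts = np.full((3, 3), float(pseudo))
    for seq in state_sequences:
        seq = np.asarray(seq, dtype=int)
        for a, b in zip(seq[:-1], seq[1:]):
            if a >= 0 and b >= 0:
                counts[a, b] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _masked_emissions(emissions: np.ndarray, mask) -> np.ndarray:
    E = np.array(emissions, dtype=float)
    if E.ndim != 2 or E.shape[1] != 3:
        raise ValueError("emissions must be (n_bins, 3)")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        E[mask] = 1.0  # masked bins: only transitions inform the posterior
    return E


def forward_backward(
    emissions: np.ndarray,
    T: np.ndarray,
    centromere_mask=None,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward-backward posteriors over a 3-state chain.

    ``emissions`` are the per-bin class probabilities; masked bins use
    emission 1.0 in every state.  The initial distribution defaults to
    uniform.  Per-bin scaling keeps the recursion underflow-free for long
    chromosomes.  Returns ``(posteriors, states)`` with posteriors
    normalized per bin and states the per-bin argmax (ties resolved in
    state order MOTHER < MPV < FATHER).
    """
    E = _masked_emissions(emissions, centromere_mask)
    T = np.asarray(T, dtype=float)
    N = E.shape[0]
    pi = np.full(3, 1.0 / 3.0) if init is None else np.asarray(init, dtype=float)
    alpha = np.empty((N, 3))
    scale = np.empty(N)
    a = pi * E[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for i in range(1, N):
        a = (alpha[i - 1] @ T) * E[i]
        scale[i] = a.sum()
        alpha[i] = a / scale[i]
    beta = np.empty((N, 3))
    beta[-1] = 1.0
    for i in range(N - 2, -1, -1):
        beta[i] = (T @ (E[i + 1] * beta[i + 1])) / scale[i + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, post.argmax(axis=1)


def viterbi(
    emissions: np.ndarray,
    T: np.ndarray,
    centromere_mask=None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Maximum-likelihood state path (log-space Viterbi with traceback).

    Masked bins contribute emission 1.0 (log 0) so only transitions shape
    the path there.  Ties break toward the lower state index.
    """
    E = _masked_emissions(emissions, centromere_mask)
    T = np.asarray(T, dtype=float)
    N = E.shape[0]
    with np.errstate(divide="ignore"):
        logE = np.log(E)
        logT = np.log(T)
        logpi = np.log(np.full(3, 1.0 / 3.0) if init is None
                       else np.asarray(init, dtype=float))
    delta = np.empty((N, 3))
    back = np.zeros((N, 3), dtype=int)
    delta[0] = logpi + logE[0]
    for i in range(1, N):
        cand = delta[i - 1][:, None] + logT  # (from, to)
        back[i] = cand.argmax(axis=0)
        delta[i] = cand.max(axis=0) + logE[i]
    path = np.empty(N, dtype=int)
    path[-1] = int(delta[-1].argmax())
    for i in range(N - 2, -1, -1):
        path[i] = back[i + 1, path[i + 1]]
    return path


def epiril_adjust(probs: np.ndarray) -> np.ndarray:
    """Move mid-parent emission mass onto the (mutant) father state.

    In epiRIL populations the classifier splits the mutant parent's
    probability between the FATHER and MPV states; before smoothing, the
    MPV emission is added to FATHER and zeroed.
    """
    out = np.array(probs, dtype=float)
    out[..., FATHER] += out[..., MPV]
    out[..., MPV] = 0.0
    return out


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

@dataclass
class EpigenotypeMap:
    """Stage-wise epigenotype calls for a cohort.

    Per sample and chromosome the map stores the preliminary classifier
    states/probabilities (``lr``), the forward-backward posteriors
    (``fb``) and the final Viterbi states.  A state of -1 marks a
    chromosome with too few informative positions to genotype.
    """

    binset: BinSet
    samples: list[str]
    lr_probs: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    lr_states: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    fb_posteriors: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    fb_states: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    final_states: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    transitions: dict[str, np.ndarray] = field(default_factory=dict)
    transitions_fb: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.binset.bins)

    def final(self, sample: str, chrom: str) -> np.ndarray:
        return self.final_states[(sample, chrom)]

    def breakpoints(self) -> pd.DataFrame:
        """Crossover positions: the shared boundary of adjacent bins whose
        final states differ (the end of the left bin, 0-based)."""
        rows = []
        for sample in self.samples:
            for chrom in self.chroms:
                states = self.final_states[(sample, chrom)]
                bins = self.binset.bins[chrom]
                for i in range(len(states) - 1):
                    if states[i] != states[i + 1] and states[i] >= 0 and states[i + 1] >= 0:
                        rows.append((sample, chrom, bins[i].end,
                                     STATE_NAMES[states[i]], STATE_NAMES[states[i + 1]]))
        return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "left_state",
                                           "right_state"])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-sample per-bin table with all three stages."""
        rows = []
        for sample in self.samples:
            for chrom in self.chroms:
                bins = self.binset.bins[chrom]
                lrp = self.lr_probs[(sample, chrom)]
                fbp = self.fb_posteriors[(sample, chrom)]
                lrs = self.lr_states[(sample, chrom)]
                fbs = self.fb_states[(sample, chrom)]
                fin = self.final_states[(sample, chrom)]
                for i, b in enumerate(bins):
                    rows.append({
                        "chrom": chrom, "start": b.start, "end": b.end,
                        "sample": sample,
                        "n_positions": b.n_positions,
                        "is_centromere": b.is_centromere,
                        "lr_state": STATE_NAMES[lrs[i]] if lrs[i] >= 0 else "undefined",
                        "lr_p_mother": lrp[i, MOTHER],
                        "lr_p_mpv": lrp[i, MPV],
                        "lr_p_father": lrp[i, FATHER],
                        "fb_state": STATE_NAMES[fbs[i]] if fbs[i] >= 0 else "undefined",
                        "fb_p_mother": fbp[i, MOTHER],
                        "fb_p_mpv": fbp[i, MPV],
                        "fb_p_father": fbp[i, FATHER],
                        "final_state": STATE_NAMES[fin[i]] if fin[i] >= 0 else "undefined",
                    })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpigenotypeMap":
        """Rebuild a map (states and probabilities) from ``to_frame`` output."""
        samples = list(df["sample"].unique())
        bins: dict[str, list[Bin]] = {}
        obj = cls(binset=BinSet(bins=bins, bin_size=0), samples=samples)
        for chrom, cdf in df.groupby("chrom", sort=True):
            first = cdf[cdf["sample"] == samples[0]].sort_values("start")
            bins[str(chrom)] = [
                Bin(start=int(r.start), end=int(r.end), positions=np.empty(0, int),
                    is_centromere=bool(getattr(r, "is_centromere", False)))
                for r in first.itertuples()
            ]
            for sample, sdf in cdf.groupby("sample"):
                sdf = sdf.sort_values("start")
                key = (str(sample), str(chrom))
                obj.lr_states[key] = np.array(
                    [_STATE_INDEX.get(s, -1) for s in sdf["lr_state"]])
                obj.fb_states[key] = np.array(
                    [_STATE_INDEX.get(s, -1) for s in sdf["fb_state"]])
                obj.final_states[key] = np.array(
                    [_STATE_INDEX.get(s, -1) for s in sdf["final_state"]])
                obj.lr_probs[key] = sdf[["lr_p_mother", "lr_p_mpv",
                                         "lr_p_father"]].to_numpy()
                obj.fb_posteriors[key] = sdf[["fb_p_mother", "fb_p_mpv",
                                              "fb_p_father"]].to_numpy()
        return obj


def _levels_at(table: MethylomeTable, chrom: str, positions: np.ndarray):
    """(levels, covered) for one sample at given 1-based positions of a chrom."""
    sub = table.df[table.df["chrom"] == chrom]
    idx = pd.Index(sub["pos"])
    total = pd.Series(sub["total"].to_numpy(), index=idx).reindex(positions)
    mc = pd.Series(sub["mc"].to_numpy(), index=idx).reindex(positions)
    covered = (total >= MIN_COVERAGE).to_numpy(na_value=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = (mc / total).to_numpy()
    return levels, covered


def epigenotype_pipeline(
    mother: MethylomeTable,
    father: MethylomeTable,
    samples: list[MethylomeTable],
    replicates: list[tuple[MethylomeTable, MethylomeTable]] | None = None,
    bin_size: int = 50_000,
    chrom_lengths: dict[str, int] | None = None,
    centromeres: dict[str, list[tuple[int, int]]] | None = None,
    mask_centromere: bool = True,
    mode: str = "f2",
    position_whitelist: dict[str, np.ndarray] | None = None,
    transition_samples: str = "all",
    pseudo: float = 1.0,
) -> EpigenotypeMap:
    """Run the full epigenotyping procedure on a cohort.

    Parameters
    ----------
    mother, father
        Parental methylomes with methylation-status calls set.
    samples
        Offspring methylomes to genotype.
    replicates
        Optional parental replicate pairs (e.g. selfed sibling lines);
        each pair contributes extra maternal/paternal/mid-parent training
        vectors.
    bin_size
        Bin width in bp (default 50 kb).
    chrom_lengths
        Chromosome sizes; defaults to the maximum observed position.
    centromeres
        Per-chromosome masked intervals (0-based half-open).
    mode
        "f2" (1:2:1 class weights) or "epiril" (F8 heterozygosity weights
        plus the mid-parent emission adjustment).
    position_whitelist
        Optional per-chromosome positions to restrict the marker set
        (e.g. CG sites in gene-body-methylated genes for epiRILs).
    transition_samples
        "all": transition matrices count every classified non-parent
        sequence, including replicates and the mid-parent pseudo-sample;
        "offspring": offspring sequences only.

    Feature-space rule: informative positions additionally covered by at
    least three reads in every sample (parents, replicates, offspring)
    are kept; each chromosome is processed independently.
    """
    if mode not in ("f2", "epiril"):
        raise ValueError(f"unknown mode {mode!r}")
    if transition_samples not in ("all", "offspring"):
        raise ValueError(f"unknown transition_samples {transition_samples!r}")
    replicates = replicates or []
    class_weights = F2_CLASS_WEIGHTS if mode == "f2" else epiril_class_weights(8)

    informative = find_informative_positions(mother, father)
    if position_whitelist is not None:
        informative = {
            c: np.intersect1d(p, position_whitelist.get(c, np.empty(0, int)))
            for c, p in informative.items()
        }

    all_tables = [mother, father]
    for rm, rf in replicates:
        all_tables.extend([rm, rf])
    all_tables.extend(samples)
    sample_ids = [s.sample_id for s in samples]

    chroms = sorted(informative)
    if chrom_lengths is None:
        chrom_lengths = {}
        for t in all_tables:
            for chrom, sub in t.df.groupby("chrom"):
                chrom_lengths[str(chrom)] = max(
                    chrom_lengths.get(str(chrom), 0), int(sub["pos"].max())
                )

    binset = BinSet(bins={}, bin_size=bin_size)
    emap = EpigenotypeMap(binset=binset, samples=sample_ids)

    for chrom in chroms:
        positions = informative[chrom]
        # keep positions covered >= 3x in every sample
        levels_list, keep = [], np.ones(len(positions), dtype=bool)
        for t in all_tables:
            lv, cov = _levels_at(t, chrom, positions)
            levels_list.append(lv)
            keep &= cov
        positions = positions[keep]
        levels = {t.sample_id: lv[keep] for t, lv in zip(all_tables, levels_list)}

        if len(positions) < 3:
            warnings.warn(
                f"chromosome {chrom}: fewer than 3 usable informative positions; "
                f"map undefined"
            )
            bins = [Bin(start=0, end=chrom_lengths[chrom], positions=positions)]
            binset.bins[chrom] = bins
            undef = np.array([-1])
            uni = np.full((1, 3), 1.0 / 3.0)
            for sid in sample_ids:
                key = (sid, chrom)
                emap.lr_probs[key] = uni.copy()
                emap.fb_posteriors[key] = uni.copy()
                emap.lr_states[key] = undef.copy()
                emap.fb_states[key] = undef.copy()
                emap.final_states[key] = undef.copy()
            continue

        bins = make_bins(chrom_lengths[chrom], bin_size, positions)
        if mask_centromere and centromeres:
            flag_centromere_bins(bins, centromeres.get(chrom))
        binset.bins[chrom] = bins
        mask = np.array([b.is_centromere for b in bins])
        pos_index = pd.Index(positions)

        m_lv = levels[mother.sample_id]
        f_lv = levels[father.sample_id]

        # auxiliary sequences (replicates + mid-parent pseudo-samples) enter
        # the transition estimate in "all" mode
        aux_vectors: list[np.ndarray] = [midparent_vector(m_lv, f_lv)]
        for rm, rf in replicates:
            aux_vectors.append(levels[rm.sample_id])
            aux_vectors.append(levels[rf.sample_id])
            aux_vectors.append(
                midparent_vector(levels[rm.sample_id], levels[rf.sample_id]))

        n_bins = len(bins)
        n_samp = len(samples)
        n_aux = len(aux_vectors)
        lr = np.empty((n_bins, n_samp, 3))
        lr_aux = np.empty((n_bins, n_aux, 3))
        for i, b in enumerate(bins):
            sel = pos_index.get_indexer(b.positions)
            bm, bf = m_lv[sel], f_lv[sel]
            train_X = [bm, midparent_vector(bm, bf), bf]
            train_y = [MOTHER, MPV, FATHER]
            for rm, rf in replicates:
                brm = levels[rm.sample_id][sel]
                brf = levels[rf.sample_id][sel]
                train_X.extend([brm, midparent_vector(brm, brf), brf])
                train_y.extend([MOTHER, MPV, FATHER])
            query = np.vstack(
                [levels[sid][sel] for sid in sample_ids]
                + [v[sel] for v in aux_vectors]
            )
            probs, _ = train_and_classify_bin(
                np.vstack(train_X), np.array(train_y), query, class_weights
            )
            lr[i] = probs[:n_samp]
            lr_aux[i] = probs[n_samp:]

        if mode == "epiril":
            emissions = epiril_adjust(lr)
            emissions_aux = epiril_adjust(lr_aux)
        else:
            emissions = lr
            emissions_aux = lr_aux

        lr_states = lr.argmax(axis=2)          # (n_bins, n_samp)
        lr_aux_states = lr_aux.argmax(axis=2)
        seqs = [lr_states[:, j] for j in range(n_samp)]
        if transition_samples == "all":
            seqs += [lr_aux_states[:, j] for j in range(n_aux)]
        T = estimate_transitions(seqs, pseudo=pseudo)
        emap.transitions[chrom] = T

        fb_post = np.empty_like(emissions)
        fb_states = np.empty((n_bins, n_samp), dtype=int)
        fb_aux_states = np.empty((n_bins, n_aux), dtype=int)
        for j in range(n_samp):
            fb_post[:, j], fb_states[:, j] = forward_backward(
                emissions[:, j], T, mask)
        for j in range(n_aux):
            _, fb_aux_states[:, j] = forward_backward(emissions_aux[:, j], T, mask)

        seqs2 = [fb_states[:, j] for j in range(n_samp)]
        if transition_samples == "all":
            seqs2 += [fb_aux_states[:, j] for j in range(n_aux)]
        T2 = estimate_transitions(seqs2, pseudo=pseudo)
        emap.transitions_fb[chrom] = T2

        for j, sid in enumerate(sample_ids):
            key = (sid, chrom)
            emap.lr_probs[key] = lr[:, j]
            emap.lr_states[key] = lr_states[:, j]
            emap.fb_posteriors[key] = fb_post[:, j]
            emap.fb_states[key] = fb_states[:, j]
            emap.final_states[key] = viterbi(fb_post[:, j], T2, mask)

    return emap
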