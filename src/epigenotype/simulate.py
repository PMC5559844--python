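"""Validation simulator: offspring with known genotype blocks and bounded noise.

Two synthetic parental methylomes are generated whose informative
positions mirror parental differentially methylated positions (one parent
drawn high, Beta(8, 2); the other low, Beta(2, 8)).  Simulated offspring
carry 0..k equally spaced potential breakpoints; the genotype of each
inter-breakpoint region is drawn 1:2:1 (maternal:heterozygous:paternal),
and adjacent regions may share a genotype, so k potential breakpoints
yield 0..k actual crossovers.  The simulated methylation level at a
position is drawn uniformly within +/- y of the genotype-expected level
(maternal, mid-parent or paternal level), clamped to [0, 1].

Pipeline accuracy against the known blocks is the micro-averaged F1
score over bins, which for single-label multiclass prediction equals the
fraction of correctly labeled bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .epigenotyping import Bin, epigenotype_pipeline
from .methylome import ALLC_COLUMNS, MethylomeTable

_PARENT_TOTAL = 100   # reads per simulated parental position (levels exact at 1/100)
_OFFSPRING_TOTAL = 200  # mid-parent levels are multiples of 1/200, kept exact

GENOTYPE_PROBS = (0.25, 0.5, 0.25)  # maternal : heterozygous : paternal


@dataclass
class SimulationConfig:
    """Grid of simulation conditions.

    Defaults reproduce the validation design: 20 offspring whose potential
    breakpoint counts are 0..19 equally spaced along the chromosome, error
    levels y from 0 to 1 in 0.1 steps, bin sizes 10-500 kb, 25 iterations
    per condition, on a 20-Mb synthetic chromosome carrying 20,000
    informative positions.
    """

    n_samples: int = 20
    errors: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
    bin_sizes: tuple[int, ...] = (10_000, 20_000, 50_000, 100_000, 200_000, 500_000)
    iterations: int = 25
    seed: int = 0
    n_positions: int = 20_000
    chrom_length: int = 20_000_000

    def __post_init__(self) -> None:
        for y in self.errors:
            if not 0.0 <= y <= 1.0:
                raise ValueError(f"error level must be in [0, 1], got {y}")


@dataclass
class SimTruth:
    """Assigned genotype blocks of one simulated offspring.

    ``regions`` are (start, end, state) tuples in 0-based half-open
    coordinates tiling the chromosome; states follow the MOTHER/MPV/FATHER
    encoding of :mod:`epigenotype.epigenotyping`.
    """

    sample_id: str
    chrom: str
    chrom_length: int
    regions: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_crossovers(self) -> int:
        states = [s for _, _, s in self.regions]
        return int(sum(a != b for a, b in zip(states[:-1], states[1:])))

    def genotype_at(self, positions: np.ndarray) -> np.ndarray:
        """Genotype state at 1-based positions."""
        starts = np.array([s for s, _, _ in self.regions])
        states = np.array([g for _, _, g in self.regions])
        idx = np.searchsorted(starts, np.asarray(positions) - 1, side="right") - 1
        return states[np.clip(idx, 0, len(states) - 1)]

    def project_to_bins(self, bins: list[Bin]) -> np.ndarray:
        """Per-bin truth: majority genotype of the bin's informative positions.

        Bins that straddle a breakpoint take the genotype of most of their
        positions (ties resolved toward the lower state index); empty bins
        take the genotype at the bin midpoint.
        """
        out = np.empty(len(bins), dtype=int)
        for i, b in enumerate(bins):
            if b.n_positions:
                g = self.genotype_at(b.positions)
                out[i] = int(np.bincount(g, minlength=3).argmax())
            else:
                out[i] = int(self.genotype_at(np.array([(b.start + b.end) // 2 + 1]))[0])
        return out


def _table_from_levels(sample_id, chrom, positions, mc, total, methylated) -> MethylomeTable:
    n = len(positions)
    df = pd.DataFrame({
        "chrom": np.repeat(chrom, n),
        "pos": positions,
        "strand": np.repeat("+", n),
        "context": np.repeat("CG", n),
        "mc": mc,
        "total": np.repeat(total, n),
        "is_methylated": methylated,
    })[ALLC_COLUMNS]
    return MethylomeTable(sample_id=sample_id, df=df)


def synth_parents(
    n_positions: int = 20_000,
    chrom_length: int = 20_000_000,
    seed=0,
    chrom: str = "Chr1",
) -> tuple[MethylomeTable, MethylomeTable]:
    """Two synthetic parental methylomes of differentially methylated positions.

    Positions are scattered uniformly; at each one a randomly chosen parent
    is the methylated one with level ~ Beta(8, 2) while the other is
    unmethylated with level ~ Beta(2, 8).  Counts use a fixed total of 100
    reads with mc rounded to the drawn level, so stored levels are exact
    multiples of 0.01.  Methylation-status flags are set by construction,
    making every position informative.
    """
    rng = np.random.default_rng(seed)
    if n_positions == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            ALLC_COLUMNS, [str, int, str, str, int, int, bool])})
        return (MethylomeTable("sim_mother", empty.copy()),
                MethylomeTable("sim_father", empty.copy()))
    positions = np.sort(rng.choice(chrom_length, size=n_positions, replace=False)) + 1
    high = rng.beta(8.0, 2.0, size=n_positions)
    low = rng.beta(2.0, 8.0, size=n_positions)
    mother_is_high = rng.random(n_positions) < 0.5
    m_level = np.where(mother_is_high, high, low)
    f_level = np.where(mother_is_high, low, high)
    m_mc = np.rint(m_level * _PARENT_TOTAL).astype(np.int64)
    f_mc = np.rint(f_level * _PARENT_TOTAL).astype(np.int64)
    mother = _table_from_levels("sim_mother", chrom, positions, m_mc,
                                _PARENT_TOTAL, mother_is_high)
    father = _table_from_levels("sim_father", chrom, positions, f_mc,
                                _PARENT_TOTAL, ~mother_is_high)
    return mother, father


def simulate_offspring(
    mother: MethylomeTable,
    father: MethylomeTable,
    n_breakpoints: int,
    y: float,
    seed=0,
    sample_id: str = "sim_offspring",
) -> tuple[MethylomeTable, SimTruth]:
    """Simulate one offspring methylome with known genotype blocks.

    ``n_breakpoints`` potential breakpoints are equally spaced along the
    chromosome; each of the n_breakpoints + 1 regions draws its genotype
    with probabilities 1:2:1.  Per position the simulated level is drawn
    uniformly from [max(0, x - y), min(1, x + y)] where x is the level
    expected under the region's genotype.  With y = 0 the level equals x
    exactly.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"error level y must be in [0, 1], got {y}")
    rng = np.random.default_rng(seed)
    mdf, fdf = mother.df, father.df
    if not np.array_equal(mdf["pos"].to_numpy(), fdf["pos"].to_numpy()):
        raise ValueError("parents must share positions")
    chrom = str(mdf["chrom"].iloc[0])
    positions = mdf["pos"].to_numpy()
    chrom_length = int(positions.max())
    m_level = (mdf["mc"] / mdf["total"]).to_numpy()
    f_level = (fdf["mc"] / fdf["total"]).to_numpy()

    edges = np.linspace(0, chrom_length, n_breakpoints + 2)
    genotypes = rng.choice(3, size=n_breakpoints + 1, p=GENOTYPE_PROBS)
    regions = [(int(round(edges[i])), int(round(edges[i + 1])), int(genotypes[i]))
               for i in range(n_breakpoints + 1)]
    truth = SimTruth(sample_id=sample_id, chrom=chrom,
                     chrom_length=chrom_length, regions=regions)

    g = truth.genotype_at(positions)
    expected = np.select(
        [g == 0, g == 1, g == 2],
        [m_level, (m_level + f_level) / 2.0, f_level],
    )
    lo = np.maximum(0.0, expected - y)
    hi = np.minimum(1.0, expected + y)
    level = rng.uniform(lo, hi)
    mc = np.rint(level * _OFFSPRING_TOTAL).astype(np.int64)
    table = _table_from_levels(sample_id, chrom, positions, mc,
                               _OFFSPRING_TOTAL, mc > _OFFSPRING_TOTAL // 2)
    return table, truth


def accuracy_f1(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Micro-averaged F1 between per-bin predictions and projected truth.

    For single-label multiclass predictions this equals the fraction of
    correctly labeled bins.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"bin mismatch: {predicted.shape} vs {truth.shape}")
    return float(f1_score(truth, predicted, average="micro"))


def run_grid(
    config: SimulationConfig,
    parents: tuple[MethylomeTable, MethylomeTable] | None = None,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Run the validation grid and score pipeline accuracy.

    For each error level: ``iterations`` independent cohorts of
    ``n_samples`` offspring (sample j carries j potential breakpoints) are
    simulated, the epigenotyping pipeline is run at every bin size with no
    centromere mask, and per-sample micro-F1 against the assigned blocks
    is recorded.  Each (error, iteration, sample) triple has its own RNG
    stream derived from ``config.seed``, so results are reproducible and
    offspring are shared across bin sizes within an iteration.

    Returns a table of accuracies; with ``aggregate=True`` the mean over
    iterations per (error, bin_size, sample).
    """
    if parents is None:
        parents = synth_parents(config.n_positions, config.chrom_length,
                                seed=config.seed)
    mother, father = parents
    chrom = str(mother.df["chrom"].iloc[0])
    rows = []
    for y in config.errors:
        iy = int(round(float(y) * 10))
        for it in range(config.iterations):
            cohort, truths = [], []
            for j in range(config.n_samples):
                table, truth = simulate_offspring(
                    mother, father, n_breakpoints=j, y=float(y),
                    seed=[config.seed, iy, it, j], sample_id=f"sim_F2_{j:02d}",
                )
                cohort.append(table)
                truths.append(truth)
            for bin_size in config.bin_sizes:
                emap = epigenotype_pipeline(
                    mother, father, cohort, bin_size=bin_size,
                    mask_centromere=False,
                )
                bins = emap.binset.bins[chrom]
                for j, (table, truth) in enumerate(zip(cohort, truths)):
                    pred = emap.final(table.sample_id, chrom)
                    acc = accuracy_f1(pred, truth.project_to_bins(bins))
                    rows.append({
                        "error": float(y), "bin_size": bin_size,
                        "iteration": it, "sample": table.sample_id,
                        "n_breakpoints": j, "accuracy": acc,
                    })
    df = pd.DataFrame(rows)
    if aggregate:
        df = (
            df.groupby(["error", "bin_size", "sample", "n_breakpoints"],
                       as_index=False)["accuracy"].mean()
        )
    return df
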