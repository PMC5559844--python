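"""Plain-text I/O for region tables, chromosome sizes and centromere BEDs."""

from __future__ import annotations

import pandas as pd

from .regions import Region


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def read_centromere_bed(path) -> dict[str, list[tuple[int, int]]]:
    """BED (chrom, start, end) of centromere intervals, 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    out: dict[str, list[tuple[int, int]]] = {}
    for r in df.itertuples():
        out.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    return out


def read_regions_tsv(path) -> list[Region]:
    """BED-like region table with per-sample count columns.

    Expected columns: chrom, start, end, optional name and
    n_cytosines_covered, then paired ``mc_<sample>`` / ``total_<sample>``
    columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = [c[3:] for c in df.columns if c.startswith("mc_")]
    regions = []
    for r in df.itertuples():
        samples = {s: (int(getattr(r, f"mc_{s}")), int(getattr(r, f"total_{s}")))
                   for s in sample_ids}
        regions.append(Region(
            chrom=r.chrom, start=int(r.start), end=int(r.end), samples=samples,
            n_cytosines_covered=(int(r.n_cytosines_covered)
                                 if hasattr(r, "n_cytosines_covered") else None),
            name=str(getattr(r, "name", "")),
        ))
    return regions


def write_regions_tsv(regions: list[Region], path) -> None:
    rows = []
    for r in regions:
        row = {"chrom": r.chrom, "start": r.start, "end": r.end, "name": r.name,
               "n_cytosines_covered": r.n_cytosines_covered}
        for s, (mc, total) in r.samples.items():
            row[f"mc_{s}"] = mc
            row[f"total_{s}"] = total
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
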