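"""Plain-text genomic track and interval writers/readers.

bedGraph and BED outputs use 0-based half-open coordinates; every writer
emits a ``# generated-by`` provenance header. Floats are written with
``repr`` so that round-trips are lossless for exactly representable values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from senhic.bins import GenomeBins

HEADER = "# generated-by senhic\n"


def write_bedgraph(path, bins: GenomeBins, values: np.ndarray) -> None:
    """Per-bin track as bedGraph; NaN bins are skipped."""
    values = np.asarray(values, dtype=float)
    starts = bins.starts()
    ends = bins.ends()
    with open(path, "w") as fh:
        fh.write(HEADER)
        for i in range(bins.n_bins):
            if np.isfinite(values[i]):
                fh.write(f"{bins.chrom}\t{starts[i]}\t{ends[i]}\t{float(values[i])!r}\n")


def read_bedgraph(path, bins: GenomeBins) -> np.ndarray:
    """Read a per-bin bedGraph back onto a bin grid; missing bins are NaN."""
    values = np.full(bins.n_bins, np.nan)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, _end, value = line.split("\t")
            if chrom != bins.chrom:
                continue
            values[int(start) // bins.bin_size] = float(value)
    return values


def write_bed(path, bins: GenomeBins, intervals, score_fmt: str = "0") -> None:
    """Bin intervals as BED4/5: ``(start_bin, end_bin_inclusive, name)``."""
    with open(path, "w") as fh:
        fh.write(HEADER)
        for item in intervals:
            s, e, name = item[0], item[1], item[2]
            fh.write(f"{bins.chrom}\t{s * bins.bin_size}"
                     f"\t{(e + 1) * bins.bin_size}\t{name}\t{score_fmt}\n")


def write_tsv(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER)
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_gene_table(path) -> pd.DataFrame:
    """Gene table TSV with at least gene_id/chrom/start/end/strand columns."""
    df = read_tsv(path)
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    return df


def read_gene_set(path) -> list[str]:
    """One gene id per line; blank lines and # comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
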