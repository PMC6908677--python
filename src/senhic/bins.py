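"""Fixed-width genomic bin grids.

All coordinates in the package are 0-based, half-open. A :class:`GenomeBins`
describes the binning of a single chromosome into ``n_bins`` consecutive
windows of ``bin_size`` bp; bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GenomeBins:
    """Uniform binning of one chromosome.

    Parameters
    ----------
    chrom
        Chromosome name.
    bin_size
        Bin width in bp; must be positive.
    n_bins
        Number of bins; must be positive.
    """

    chrom: str
    bin_size: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if self.n_bins <= 0:
            raise ValueError(f"n_bins must be positive, got {self.n_bins}")

    @property
    def length(self) -> int:
        """Chromosome length in bp covered by the grid."""
        return self.bin_size * self.n_bins

    def starts(self) -> np.ndarray:
        """0-based start coordinate of every bin."""
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    def ends(self) -> np.ndarray:
        """Half-open end coordinate of every bin."""
        return (np.arange(self.n_bins, dtype=np.int64) + 1) * self.bin_size

    def bin_of(self, pos: int) -> int:
        """Index of the bin containing a 0-based position."""
        if not 0 <= pos < self.length:
            raise IndexError(f"position {pos} outside [0, {self.length})")
        return pos // self.bin_size

    def coarsened(self, factor: int) -> "GenomeBins":
        """Grid obtained by merging ``factor`` consecutive bins (ceil division)."""
        if factor < 1:
            raise ValueError(f"factor must be >= 1, got {factor}")
        n_coarse = -(-self.n_bins // factor)
        return GenomeBins(self.chrom, self.bin_size * factor, n_coarse)
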