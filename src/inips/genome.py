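"""Miniature genome model: fixed-size bins with GC content and N-masks.

The analysis operates on read counts in fixed-size genomic bins (20 kb by
default). For desk-scale simulation the hg19 chromosome lengths are scaled
down by a configurable divisor (default 500, ~310 bins of 20 kb genome
wide), which keeps every chromosome represented with its real relative
size while making whole-cohort simulations take seconds. Per-bin GC is
drawn from a Beta distribution whose mean is offset per chromosome, so GC
composition differs between chromosomes as it does in the real genome; a
configurable fraction of bins is flagged as containing N bases and is
excluded from simulation and analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HG19_CHROM_LENGTHS", "AUTOSOMES", "GenomeModel", "build_genome"]

# GRCh37/hg19 chromosome sizes (bp).
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class GenomeModel:
    """Binned genome with per-bin GC content and N-mask flags.

    Attributes
    ----------
    bins
        One row per bin: ``chrom``, ``start``, ``end`` (0-based half-open,
        in scaled coordinates), ``gc`` (fraction), ``n_mask`` (bool).
    chrom_lengths
        Scaled chromosome lengths (bp).
    bin_size
        Bin width in bp; the last bin of each chromosome may be shorter.
    seed
        Seed the model was built with (for provenance).
    """

    bins: pd.DataFrame
    chrom_lengths: dict[str, int]
    bin_size: int
    seed: int

    def __post_init__(self) -> None:
        self._chrom_arr = self.bins["chrom"].to_numpy()
        self._start_arr = self.bins["start"].to_numpy()
        self._offsets: dict[str, tuple[int, int]] = {}
        for chrom in self.chrom_lengths:
            idx = np.flatnonzero(self._chrom_arr == chrom)
            self._offsets[chrom] = (int(idx[0]), int(idx[-1]) + 1)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask over bins: autosomal bin?"""
        return np.isin(self._chrom_arr, AUTOSOMES)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self._chrom_arr == chrom

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._offsets[chrom]
        return slice(lo, hi)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` on ``chrom``."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_lengths[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        lo, _ = self._offsets[chrom]
        return lo + pos // self.bin_size

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bin_size": self.bin_size,
            "seed": self.seed,
            "chrom_lengths": self.chrom_lengths,
            "bins": self.bins.to_dict(orient="list"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, data: dict) -> "GenomeModel":
        return cls(
            bins=pd.DataFrame(data["bins"]),
            chrom_lengths={k: int(v) for k, v in data["chrom_lengths"].items()},
            bin_size=int(data["bin_size"]),
            seed=int(data["seed"]),
        )

    @classmethod
    def from_json(cls, path) -> "GenomeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_genome(
    bin_size: int = 20_000,
    scale: float = 500.0,
    n_mask_rate: float = 0.03,
    gc_mean: float = 0.41,
    gc_concentration: float = 300.0,
    gc_chrom_spread: float = 0.04,
    seed: int = 0,
) -> GenomeModel:
    """Build the scaled, binned genome model.

    Parameters
    ----------
    bin_size
        Bin width (bp), > 0.
    scale
        Divisor applied to hg19 chromosome lengths, > 0. ``scale=1`` gives
        a full-scale genome.
    n_mask_rate
        Probability that a bin is flagged as N-containing.
    gc_mean, gc_concentration, gc_chrom_spread
        Per-bin GC ~ Beta with mean ``gc_mean + offset(chrom)`` where the
        chromosome offset is uniform on +/- ``gc_chrom_spread``;
        ``gc_concentration`` sets the within-chromosome spread.
    seed
        RNG seed; the same seed yields an identical model.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if not (0 <= n_mask_rate <= 1):
        raise ValueError(f"n_mask_rate must be in [0,1], got {n_mask_rate}")

    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    chrom_lengths: dict[str, int] = {}
    for chrom, full_len in HG19_CHROM_LENGTHS.items():
        length = max(1, int(round(full_len / scale)))
        chrom_lengths[chrom] = length
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        mean_c = float(np.clip(gc_mean + rng.uniform(-gc_chrom_spread, gc_chrom_spread), 0.2, 0.7))
        a = mean_c * gc_concentration
        b = (1.0 - mean_c) * gc_concentration
        gc = rng.beta(a, b, size=len(starts))
        n_mask = rng.random(len(starts)) < n_mask_rate
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "gc": gc, "n_mask": n_mask}
            )
        )
    bins = pd.concat(rows, ignore_index=True)
    return GenomeModel(bins=bins, chrom_lengths=chrom_lengths, bin_size=bin_size, seed=seed)
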