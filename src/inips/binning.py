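"""Read filtering, 20-kb binning, bin masking, GC-LOESS correction and
chromosome percentages.

The counting convention follows standard shallow-WGS aneuploidy pipelines:
uniquely mapped, non-duplicate reads with MAPQ > 10 and length > 35 bp are
assigned to fixed 20-kb bins by start coordinate; bins containing N bases
or with zero reads are masked; counts are corrected for GC bias by LOESS
of count against bin GC (rounded to 0.1%) fitted on autosomal bins; each
chromosome's percentage is its corrected-count sum divided by the
corrected-count total over all autosomes (the same denominator is used for
%chrY, which feeds the chrY fetal-fraction formula).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import AUTOSOMES, GenomeModel
from .simulate import FragmentSet

__all__ = [
    "BinTable",
    "ChromProfile",
    "filter_fragments",
    "bin_counts",
    "filter_bins",
    "gc_correct",
    "chromosome_profile",
    "profile_sample",
]

MIN_MAPQ_EXCLUSIVE = 10
MIN_LEN_EXCLUSIVE = 35
GC_ROUNDING = 3  # decimals on the fraction scale == 0.1%


@dataclass
class BinTable:
    """Per-bin counts with GC and mask state.

    ``data`` columns: chrom, start, end, gc (rounded to 0.1%), n_mask,
    raw, masked, corrected (NaN until :func:`gc_correct` runs).
    """

    data: pd.DataFrame

    def unmasked(self) -> pd.DataFrame:
        return self.data.loc[~self.data["masked"]]

    @property
    def n_unmasked(self) -> int:
        return int((~self.data["masked"]).sum())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class ChromProfile:
    """Autosome-normalised per-chromosome read percentages.

    ``fractions[chrom]`` = corrected-count sum on ``chrom`` divided by the
    corrected-count total over all autosomes. The autosomal entries sum
    to 1; chrX/chrY use the same autosomal denominator.
    """

    fractions: dict[str, float]
    total_retained: float

    def fraction(self, chrom: str) -> float:
        return self.fractions[chrom]

    def percent(self, chrom: str) -> float:
        return 100.0 * self.fractions[chrom]

    @property
    def pct_chry(self) -> float:
        """%chrY (percent of the autosomal total)."""
        return self.percent("chrY")


def filter_fragments(
    sample: FragmentSet,
    min_mapq_exclusive: int = MIN_MAPQ_EXCLUSIVE,
    min_len_exclusive: int = MIN_LEN_EXCLUSIVE,
) -> FragmentSet:
    """Retain unique reads with MAPQ > 10 and length > 35 bp.

    Count mode passes through: its sampling rates already describe the
    retained reads (the removed classes are origin- and
    location-independent, so proportions are unchanged).
    """
    if sample.counts is not None:
        return sample
    df = sample.fragments
    length = (df["end"] - df["start"]).to_numpy()
    keep = (
        (df["mapq"].to_numpy() > min_mapq_exclusive)
        & (length > min_len_exclusive)
        & (~df["duplicate"].to_numpy())
    )
    return FragmentSet(
        sample_id=sample.sample_id,
        genome=sample.genome,
        length_model=sample.length_model,
        spec=sample.spec,
        provenance=sample.provenance,
        fragments=df.loc[keep].reset_index(drop=True),
    )


def bin_counts(sample: FragmentSet, genome: GenomeModel | None = None) -> BinTable:
    """Assign fragments to bins (by start coordinate) and attach GC.

    Count-mode samples already carry per-bin counts and are tabulated
    directly.
    """
    genome = genome or sample.genome
    bins = genome.bins

    if sample.counts is not None:
        raw = sample.counts.sum(axis=1)
    else:
        df = sample.fragments
        raw = np.zeros(genome.n_bins, dtype=np.int64)
        for chrom, grp in df.groupby("chrom", observed=True):
            if chrom not in genome.chrom_lengths:
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
            starts = grp["start"].to_numpy()
            if starts.min() < 0 or starts.max() >= genome.chrom_lengths[chrom]:
                raise ValueError(f"fragment start outside {chrom}")
            sl = genome.chrom_slice(chrom)
            idx = starts // genome.bin_size
            raw[sl] += np.bincount(idx, minlength=sl.stop - sl.start)

    data = pd.DataFrame(
        {
            "chrom": bins["chrom"],
            "start": bins["start"],
            "end": bins["end"],
            "gc": bins["gc"].round(GC_ROUNDING),
            "n_mask": bins["n_mask"],
            "raw": raw,
            "masked": False,
            "corrected": np.nan,
        }
    )
    return BinTable(data)


def filter_bins(table: BinTable) -> BinTable:
    """Mask zero-count bins and N-containing bins."""
    data = table.data.copy()
    data["masked"] = data["masked"] | data["n_mask"] | (data["raw"] == 0)
    if data["masked"].all():
        raise ValueError("all bins masked after filtering")
    return BinTable(data)


def gc_correct(table: BinTable, span: float = 0.3) -> BinTable:
    """LOESS GC correction of bin counts.

    A degree-1 LOESS of mean raw count against rounded GC is fitted on
    unmasked, full-width autosomal bins (aggregated per unique GC value)
    and evaluated at every unmasked bin's GC;
    ``corrected = raw * median(raw) / fitted`` with the median taken over
    the fitted bins. Bins with non-positive fitted values are masked. If
    the GC values are all identical the correction is the identity (with a
    warning).
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0,1], got {span}")
    data = table.data.copy()
    un = ~data["masked"].to_numpy()
    if un.sum() < 50:
        raise ValueError(f"need >= 50 unmasked bins for GC correction, have {int(un.sum())}")

    full_width = (data["end"] - data["start"]).to_numpy() == (data["end"] - data["start"]).max()
    fit_sel = un & full_width & data["chrom"].isin(AUTOSOMES).to_numpy()
    gc_fit = data.loc[fit_sel, "gc"].to_numpy()
    raw_fit = data.loc[fit_sel, "raw"].to_numpy().astype(float)

    if np.ptp(gc_fit) == 0:
        warnings.warn("degenerate GC (all identical); GC correction is the identity")
        data.loc[un, "corrected"] = data.loc[un, "raw"].astype(float)
        return BinTable(data)

    # aggregate to the rounded-GC grid, then local-linear smooth
    agg = pd.DataFrame({"gc": gc_fit, "raw": raw_fit}).groupby("gc")["raw"].mean()
    smoothed = lowess(agg.to_numpy(), agg.index.to_numpy(), frac=span, return_sorted=True)
    fitted_all = np.interp(data["gc"].to_numpy(), smoothed[:, 0], smoothed[:, 1])

    median_raw = float(np.median(raw_fit))
    bad = un & (fitted_all <= 0)
    data.loc[bad, "masked"] = True
    good = un & (fitted_all > 0)
    data.loc[good, "corrected"] = (
        data.loc[good, "raw"].to_numpy() * median_raw / fitted_all[good]
    )
    if data["masked"].all():
        raise ValueError("all bins masked after GC correction")
    return BinTable(data)


def chromosome_profile(table: BinTable) -> ChromProfile:
    """Per-chromosome percentages over the autosomal corrected total."""
    data = table.data
    un = data.loc[~data["masked"]]
    counts = un["corrected"]
    if counts.isna().any():
        raise ValueError("corrected counts missing; run gc_correct first")
    per_chrom = un.groupby("chrom", observed=True)["corrected"].sum()
    autosomal_total = float(per_chrom.reindex(AUTOSOMES, fill_value=0.0).sum())
    if autosomal_total <= 0:
        raise ValueError("zero autosomal corrected total")
    all_chroms = list(dict.fromkeys(data["chrom"]))
    fractions = {
        chrom: float(per_chrom.get(chrom, 0.0)) / autosomal_total for chrom in all_chroms
    }
    return ChromProfile(fractions=fractions, total_retained=float(counts.sum()))


def profile_sample(
    sample: FragmentSet,
    genome: GenomeModel | None = None,
    span: float = 0.3,
) -> ChromProfile:
    """Full per-sample pipeline: filter, bin, mask, GC-correct, profile."""
    filtered = filter_fragments(sample)
    table = bin_counts(filtered, genome)
    table = filter_bins(table)
    table = gc_correct(table, span=span)
    return chromosome_profile(table)
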