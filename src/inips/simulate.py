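"""Synthetic maternal-plasma cfDNA samples.

A sample is a mixture of maternal- and fetal-origin fragments. Fragment
origin is Bernoulli(FF); given the origin, the genomic location is drawn
over bins with probability proportional to

    bin length x copy weight(chromosome, origin) x g(GC),

where a fetal trisomy multiplies the target chromosome's fetal weight by
(1 + 0.5 m) for mosaicism degree m, a maternal CNV multiplies the
maternal weight by its copy ratio, and g(GC) = clamp(1 + beta (GC - 0.41),
0.2, 1.8) is a linear GC sampling bias that the GC-LOESS stage is meant
to remove. chrY is special-cased: male-fetal fragments hit chrY at a rate
calibrated so that a 100% male-DNA sample has expected %chrY = 0.170%
(the adult-male constant) and pure female DNA has %chrY = 0.002% (a
misalignment floor), both measured against the autosomal total on the
GC-corrected scale. Insert lengths are drawn per origin from the
LengthModel.

Two modes produce the same joint distribution over (bin, origin):

* ``fragment`` mode emits one record per fragment (with MAPQ and
  duplicate flags for the read-filtering stage) — BED6-serialisable;
* ``count`` mode draws per-(bin, origin) counts directly by
  binomial/multinomial sampling, which is what cohort-scale experiments
  use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import AUTOSOMES, GenomeModel
from .lengths import LengthModel, default_length_model

__all__ = [
    "SampleSpec",
    "MaternalCNV",
    "FragmentSet",
    "simulate_sample",
    "write_bed",
    "read_bed",
]

# Default nuisance rates for fragment-mode records. The read filters
# remove MAPQ <= 10 and duplicates, so in count mode these act as a
# uniform thinning and are folded away (proportions are unaffected).
MAPQ_HIGH_RATE = 0.90  # MAPQ == 60
MAPQ_MID_RATE = 0.05  # uniform 11..59
MAPQ_LOW_RATE = 0.05  # uniform 0..10
DUPLICATE_RATE = 0.02

GC_BIAS_REF = 0.41
GC_BIAS_CLAMP = (0.2, 1.8)
PCT_CHRY_ADULT_MALE = 0.170  # percent of autosomal reads
PCT_CHRY_FEMALE_FLOOR = 0.002  # percent; misalignment background

TARGET_CHROMS = ("chr13", "chr18", "chr21")


@dataclass(frozen=True)
class MaternalCNV:
    """Whole-chromosome maternal copy-number change (ratio 1.0 = normal)."""

    chrom: str
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError(f"copy_ratio must be positive, got {self.copy_ratio}")


@dataclass(frozen=True)
class SampleSpec:
    """Parameters of one simulated maternal-plasma sample.

    ``mosaicism`` is the fraction m of the fetal (placental) lineage
    carrying the trisomy: m = 1 is a full trisomy, m = 0.127 reproduces a
    12.7% confined placental mosaicism. Setting m > 0 requires an
    aneuploidy target.
    """

    fetal_fraction: float = 0.10
    fetal_sex: str = "male"
    aneuploidy: str | None = None  # None or one of chr13/chr18/chr21
    mosaicism: float = 1.0
    maternal_cnvs: tuple[MaternalCNV, ...] = ()
    n_fragments: int = 5_000_000
    seed: int = 0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fetal_fraction <= 1.0):
            raise ValueError(f"fetal_fraction must be in [0,1], got {self.fetal_fraction}")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError(f"fetal_sex must be 'male' or 'female', got {self.fetal_sex!r}")
        if self.aneuploidy is not None and self.aneuploidy not in TARGET_CHROMS:
            raise ValueError(f"aneuploidy must be one of {TARGET_CHROMS}, got {self.aneuploidy!r}")
        if not (0.0 <= self.mosaicism <= 1.0):
            raise ValueError(f"mosaicism must be in [0,1], got {self.mosaicism}")
        if self.aneuploidy is None and self.mosaicism not in (0.0, 1.0):
            raise ValueError("mosaicism degree set without an aneuploidy target")
        if self.n_fragments <= 0:
            raise ValueError(f"n_fragments must be positive, got {self.n_fragments}")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maternal_cnvs"] = [asdict(c) for c in self.maternal_cnvs]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, data: dict) -> "SampleSpec":
        data = dict(data)
        data["maternal_cnvs"] = tuple(
            MaternalCNV(**c) for c in data.get("maternal_cnvs", ())
        )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SampleSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class FragmentSet:
    """A simulated sample, in fragment or count representation.

    Fragment mode: ``fragments`` is a DataFrame with columns chrom, start,
    end, origin, mapq, duplicate (0-based half-open coordinates;
    end - start is the insert length in bp). Count mode: ``counts`` is an
    (n_bins, 2) array of per-bin counts, column 0 fetal / column 1
    maternal. The origin dimension is simulation ground truth; the
    analysis pipeline never reads it.
    """

    sample_id: str
    genome: GenomeModel
    length_model: LengthModel
    spec: SampleSpec | None = None
    provenance: str = "pre_selection"
    fragments: pd.DataFrame | None = None
    counts: np.ndarray | None = None
    # per-origin bin sampling probabilities of the underlying library,
    # shape (n_bins, 2); lets size selection redraw the selected library
    # at full depth instead of thinning the sequenced reads
    bin_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.fragments is None) == (self.counts is None):
            raise ValueError("exactly one of fragments/counts must be set")

    @property
    def mode(self) -> str:
        return "fragment" if self.fragments is not None else "count"

    @property
    def total(self) -> int:
        if self.fragments is not None:
            return len(self.fragments)
        return int(self.counts.sum())

    def origin_fraction(self) -> float:
        """Ground-truth fetal-origin fraction of the sample."""
        if self.total == 0:
            raise ValueError("empty sample has no origin fraction")
        if self.fragments is not None:
            return float((self.fragments["origin"].to_numpy() == "fetal").mean())
        return float(self.counts[:, 0].sum() / self.counts.sum())

    def bin_totals(self) -> np.ndarray:
        """Per-bin fragment counts summed over origins (count mode only)."""
        if self.counts is None:
            raise ValueError("bin_totals requires count mode")
        return self.counts.sum(axis=1)


def gc_weight(gc: np.ndarray, beta: float, ref: float = GC_BIAS_REF) -> np.ndarray:
    """Relative GC sampling weight g(GC), clamped to [0.2, 1.8]."""
    lo, hi = GC_BIAS_CLAMP
    return np.clip(1.0 + beta * (np.asarray(gc, dtype=float) - ref), lo, hi)


def _bin_probs(
    genome: GenomeModel,
    spec: SampleSpec,
    gc_bias_beta: float,
    pct_chry_male: float,
    pct_chry_floor: float,
) -> np.ndarray:
    """Per-origin bin sampling probabilities, shape (n_bins, 2).

    Column 0 fetal, column 1 maternal. N-masked bins get zero weight. The
    chrY weight is scaled so the expected GC-corrected chrY/autosome count
    ratio equals the calibrated %chrY per origin, independent of the GC
    bias realisation (the g factor cancels after LOESS correction).
    """
    bins = genome.bins
    chroms = bins["chrom"].to_numpy()
    length = (bins["end"] - bins["start"]).to_numpy().astype(float)
    length[bins["n_mask"].to_numpy()] = 0.0
    g = gc_weight(bins["gc"].to_numpy(), gc_bias_beta)

    copy = np.ones((genome.n_bins, 2))
    if spec.aneuploidy is not None:
        copy[chroms == spec.aneuploidy, 0] = 1.0 + 0.5 * spec.mosaicism
    for cnv in spec.maternal_cnvs:
        copy[chroms == cnv.chrom, 1] *= cnv.copy_ratio

    auto = np.isin(chroms, AUTOSOMES)
    is_y = chroms == "chrY"
    weights = length[:, None] * copy * g[:, None]

    y_len_total = length[is_y].sum()
    if y_len_total > 0:
        y_frac = np.array(
            [
                (pct_chry_male if spec.fetal_sex == "male" else pct_chry_floor) / 100.0,
                pct_chry_floor / 100.0,
            ]
        )
        auto_weight = (length[auto, None] * copy[auto]).sum(axis=0)
        scale = y_frac * auto_weight / y_len_total
        weights[is_y] = (length[is_y] * g[is_y])[:, None] * scale[None, :]

    totals = weights.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("degenerate genome: zero total sampling weight")
    return weights / totals


def simulate_sample(
    genome: GenomeModel,
    spec: SampleSpec,
    mode: str = "count",
    length_model: LengthModel | None = None,
    gc_bias_beta: float = 2.0,
    pct_chry_male: float = PCT_CHRY_ADULT_MALE,
    pct_chry_floor: float = PCT_CHRY_FEMALE_FLOOR,
    duplicate_rate: float = DUPLICATE_RATE,
) -> FragmentSet:
    """Simulate one maternal-plasma cfDNA sample.

    Parameters
    ----------
    mode
        ``"count"`` (fast, per-bin counts) or ``"fragment"`` (per-fragment
        records with MAPQ/duplicate annotations).
    gc_bias_beta
        Slope of the linear GC sampling bias; 0 disables it.

    Both modes are driven by ``spec.seed`` and are deterministic.
    """
    if mode not in ("fragment", "count"):
        raise ValueError(f"mode must be 'fragment' or 'count', got {mode!r}")
    model = length_model or default_length_model()
    rng = np.random.default_rng(spec.seed)
    probs = _bin_probs(genome, spec, gc_bias_beta, pct_chry_male, pct_chry_floor)
    n = spec.n_fragments
    n_fetal = int(rng.binomial(n, spec.fetal_fraction))

    if mode == "count":
        counts = np.zeros((genome.n_bins, 2), dtype=np.int64)
        counts[:, 0] = rng.multinomial(n_fetal, probs[:, 0])
        counts[:, 1] = rng.multinomial(n - n_fetal, probs[:, 1])
        return FragmentSet(
            sample_id=spec.sample_id,
            genome=genome,
            length_model=model,
            spec=spec,
            counts=counts,
            bin_probs=probs,
        )

    # fragment mode
    bins = genome.bins
    starts_arr = bins["start"].to_numpy()
    bin_len = (bins["end"] - bins["start"]).to_numpy()
    chrom_arr = bins["chrom"].to_numpy()
    grid = model.lengths

    origin_fetal = np.zeros(n, dtype=bool)
    origin_fetal[:n_fetal] = True
    rng.shuffle(origin_fetal)

    bin_idx = np.empty(n, dtype=np.int64)
    frag_len = np.empty(n, dtype=np.int64)
    for col, sel in ((0, origin_fetal), (1, ~origin_fetal)):
        k = int(sel.sum())
        if k == 0:
            continue
        bin_idx[sel] = rng.choice(genome.n_bins, size=k, p=probs[:, col])
        pmf = model.pmf("fetal" if col == 0 else "maternal")
        frag_len[sel] = rng.choice(grid, size=k, p=pmf)

    offset = rng.integers(0, np.maximum(bin_len[bin_idx], 1))
    start = starts_arr[bin_idx] + offset
    end = start + frag_len

    u = rng.random(n)
    mapq = np.full(n, 60, dtype=np.int64)
    mid = u >= MAPQ_HIGH_RATE
    low = u >= MAPQ_HIGH_RATE + MAPQ_MID_RATE
    mapq[mid] = rng.integers(11, 60, size=int(mid.sum()))
    mapq[low] = rng.integers(0, 11, size=int(low.sum()))
    duplicate = rng.random(n) < duplicate_rate

    fragments = pd.DataFrame(
        {
            "chrom": chrom_arr[bin_idx],
            "start": start,
            "end": end,
            "origin": np.where(origin_fetal, "fetal", "maternal"),
            "mapq": mapq,
            "duplicate": duplicate,
        }
    )
    return FragmentSet(
        sample_id=spec.sample_id,
        genome=genome,
        length_model=model,
        spec=spec,
        fragments=fragments,
    )


# -- BED6 round trip ----------------------------------------------------


def write_bed(sample: FragmentSet, path) -> None:
    """Write a fragment-mode sample as BED6.

    name = origin label (":dup" suffix for duplicates), score = MAPQ,
    strand = '+'.
    """
    if sample.fragments is None:
        raise ValueError("BED output requires fragment mode")
    df = sample.fragments
    name = df["origin"].astype(str) + np.where(df["duplicate"], ":dup", "")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": name,
            "score": df["mapq"],
            "strand": "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(
    path,
    genome: GenomeModel,
    length_model: LengthModel | None = None,
    sample_id: str = "sample",
) -> FragmentSet:
    """Read a BED6 fragment file written by :func:`write_bed`."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    name = df["name"].astype(str)
    fragments = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "origin": name.str.replace(":dup", "", regex=False),
            "mapq": df["score"].astype(np.int64),
            "duplicate": name.str.endswith(":dup"),
        }
    )
    return FragmentSet(
        sample_id=sample_id,
        genome=genome,
        length_model=length_model or default_length_model(),
        fragments=fragments,
    )
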