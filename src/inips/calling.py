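"""Aneuploidy calling: reference-cohort z-scores, three-way
classification, and trisomic-fraction / mosaicism arithmetic.

A sample's target-chromosome percentage p is standardised against a
euploid reference cohort, z = (p - mean_ref) / sd_ref, and classified

    affected    if z > 4.00
    unaffected  if z < 2.58
    no_call     if 2.58 <= z <= 4.00

(z = 2.58 is the two-sided 99% normal quantile, z = 4.00 the 99.99%
level; both boundary values fall in the no-call band). For a called
trisomy, the over-representation of the target chromosome converts to the
trisomic fetal DNA fraction, 2 (p / mean_ref - 1): a fully trisomic
pregnancy at fetal fraction FF elevates p by a factor 1 + FF/2. The
degree of confined placental mosaicism is the trisomic fraction divided
by the total fetal fraction (e.g. 5.6% / 44% = 12.7%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binning import ChromProfile

__all__ = [
    "Z_AFFECTED",
    "Z_UNAFFECTED",
    "ReferenceStats",
    "AneuploidyCall",
    "build_reference",
    "z_score",
    "classify",
    "call_sample",
    "trisomic_ff_from_ratio",
    "mosaicism_degree",
]

Z_AFFECTED = 4.00
Z_UNAFFECTED = 2.58
TARGET_CHROMS = ("chr13", "chr18", "chr21")
MIN_REFERENCE_SIZE = 20


@dataclass(frozen=True)
class ReferenceStats:
    """Euploid reference-cohort statistics per target chromosome.

    ``values[chrom]`` retains the raw percentage vector for the rank-based
    z variant; ``mean``/``sd`` (n-1 denominator) drive the standard
    z-score.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    values: dict[str, np.ndarray]
    n: int


@dataclass(frozen=True)
class AneuploidyCall:
    chrom: str
    z: float
    label: str  # affected / unaffected / no_call
    arm: str = "NIPS"  # NIPS (unselected) or iNIPS (size-selected)


def build_reference(
    profiles: list[ChromProfile], chroms: tuple[str, ...] = TARGET_CHROMS
) -> ReferenceStats:
    """Per-chromosome mean/sd of the autosome-normalised percentage.

    Profiles must come from euploid samples processed by the same
    pipeline arm as the samples that will be scored (selected references
    for the selected arm, unselected for the unselected arm).
    """
    if len(profiles) < MIN_REFERENCE_SIZE:
        raise ValueError(
            f"reference cohort needs >= {MIN_REFERENCE_SIZE} profiles, got {len(profiles)}"
        )
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    values: dict[str, np.ndarray] = {}
    for chrom in chroms:
        v = np.array([p.fraction(chrom) for p in profiles])
        s = float(v.std(ddof=1))
        if s == 0:
            raise ValueError(f"degenerate reference: zero variance on {chrom}")
        mean[chrom] = float(v.mean())
        sd[chrom] = s
        values[chrom] = v
    return ReferenceStats(mean=mean, sd=sd, values=values, n=len(profiles))


def z_score(
    profile: ChromProfile,
    ref: ReferenceStats,
    chrom: str,
    method: str = "zscore",
) -> float:
    """Standardised target-chromosome percentage.

    ``method="zscore"`` is the standard (p - mean)/sd. ``method="rank"``
    is a normal-approximated one-sample Mann-Whitney U of the sample
    value against the retained reference vector, provided for comparison
    with rank-based ("U test") formulations.
    """
    if chrom not in ref.mean:
        raise ValueError(f"{chrom!r} not in reference (has {sorted(ref.mean)})")
    p = profile.fraction(chrom)
    if method == "zscore":
        return (p - ref.mean[chrom]) / ref.sd[chrom]
    if method == "rank":
        v = ref.values[chrom]
        n = len(v)
        u = float((v < p).sum()) + 0.5 * float((v == p).sum())
        return (u - n / 2.0) / math.sqrt(n * (n + 2) / 12.0)
    raise ValueError(f"unknown method {method!r}")


def classify(z: float) -> str:
    """Three-way class from z: affected / unaffected / no_call."""
    if not math.isfinite(z):
        raise ValueError(f"non-finite z-score: {z}")
    if z > Z_AFFECTED:
        return "affected"
    if z < Z_UNAFFECTED:
        return "unaffected"
    return "no_call"


def call_sample(
    profile: ChromProfile,
    ref: ReferenceStats,
    chroms: tuple[str, ...] = TARGET_CHROMS,
    arm: str = "NIPS",
    method: str = "zscore",
) -> list[AneuploidyCall]:
    """Score and classify every target chromosome of one sample."""
    calls = []
    for chrom in chroms:
        z = z_score(profile, ref, chrom, method=method)
        calls.append(AneuploidyCall(chrom=chrom, z=z, label=classify(z), arm=arm))
    return calls


def trisomic_ff_from_ratio(p: float, mean_ref: float) -> float:
    """Trisomic fetal DNA fraction from chromosome over-representation.

    p / mean_ref = 1 + FF_trisomic / 2 for a trisomic target chromosome,
    hence FF_trisomic = 2 (p / mean_ref - 1), clamped below at 0.
    """
    if mean_ref <= 0:
        raise ValueError(f"mean_ref must be positive, got {mean_ref}")
    return max(0.0, 2.0 * (p / mean_ref - 1.0))


def mosaicism_degree(ff_trisomic: float, ff_total: float) -> float:
    """Fraction of the placental lineage carrying the trisomy."""
    if not (0 < ff_total <= 1):
        raise ValueError(f"ff_total must be in (0,1], got {ff_total}")
    if not (0 <= ff_trisomic <= ff_total):
        raise ValueError(
            f"ff_trisomic must be in [0, ff_total]: {ff_trisomic} vs {ff_total}"
        )
    return ff_trisomic / ff_total
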