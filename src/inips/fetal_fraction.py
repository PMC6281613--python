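"""Fetal-fraction estimation from chrY and pre/post-selection enrichment
metrics.

For a male-fetus pregnancy the fetal fraction follows from the chrY read
share:

    FF = (%chrY_MF - %chrY_FF) / (%chrY_AM - %chrY_FF)

where %chrY_MF is the sample's measured chrY percentage, %chrY_FF the
female-pregnancy background (misalignment floor) and %chrY_AM the
adult-male constant 0.170%. All three are percentages of the autosomal
read total. Female-fetus FF estimation (SeqFF-style regression) is out of
scope; synthetic studies fall back on ground-truth origin labels where
they need a sex-independent fetal fraction and say so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "PCT_CHRY_ADULT_MALE",
    "PCT_CHRY_FEMALE_BACKGROUND",
    "FFEstimate",
    "EnrichmentMetrics",
    "ff_from_chry",
    "enrichment_metrics",
]

PCT_CHRY_ADULT_MALE = 0.170  # % of autosomal reads in 100% male DNA
PCT_CHRY_FEMALE_BACKGROUND = 0.002  # % floor in pure female DNA


@dataclass(frozen=True)
class FFEstimate:
    """A fetal-fraction estimate with its inputs (all % of autosomes)."""

    value: float  # fraction in [0, 1]
    method: str
    pct_chry_mf: float
    pct_chry_ff: float
    pct_chry_am: float


@dataclass(frozen=True)
class EnrichmentMetrics:
    """Per-sample change in fetal/maternal fractions across selection."""

    ff_before: float
    ff_after: float

    @property
    def ff_fold(self) -> float:
        return self.ff_after / self.ff_before

    @property
    def maternal_decrease(self) -> float:
        return (1.0 - self.ff_before) / (1.0 - self.ff_after)


def ff_from_chry(
    pct_chry_mf: float,
    pct_chry_ff: float = PCT_CHRY_FEMALE_BACKGROUND,
    pct_chry_am: float = PCT_CHRY_ADULT_MALE,
) -> FFEstimate:
    """Chromosome-Y fetal-fraction estimate for a male-fetus sample.

    Raw values outside [0, 1] (sampling noise near FF = 0 or 1) are
    clamped with a warning.
    """
    if pct_chry_am <= pct_chry_ff:
        raise ValueError(
            f"adult-male %chrY ({pct_chry_am}) must exceed female background ({pct_chry_ff})"
        )
    raw = (pct_chry_mf - pct_chry_ff) / (pct_chry_am - pct_chry_ff)
    if raw < 0 or raw > 1:
        warnings.warn(f"chrY FF estimate {raw:.4f} outside [0,1]; clamping")
    return FFEstimate(
        value=min(1.0, max(0.0, raw)),
        method="chrY",
        pct_chry_mf=pct_chry_mf,
        pct_chry_ff=pct_chry_ff,
        pct_chry_am=pct_chry_am,
    )


def enrichment_metrics(ff_before: float, ff_after: float) -> EnrichmentMetrics:
    """Fold-change metrics between unselected and selected estimates."""
    if not (0 < ff_before < 1):
        raise ValueError(f"ff_before must be in (0,1), got {ff_before}")
    if not (0 < ff_after < 1):
        raise ValueError(f"ff_after must be in (0,1), got {ff_after}")
    return EnrichmentMetrics(ff_before=ff_before, ff_after=ff_after)
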