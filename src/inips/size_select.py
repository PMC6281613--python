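"""In-silico size selection of cfDNA fragments.

Mimics e-gel recovery of a fragment-length window: an inclusive insert
length filter, with library-size windows (insert + 90 bp of adapters)
convertible to insert windows. Because fetal fragments are shorter than
maternal ones, selecting a short window (default 125-135 bp) enriches the
fetal fraction; the closed-form predictor

    FF' = FF p_f / (FF p_f + (1 - FF) p_m)

(with p_f, p_m the per-origin window probabilities) is the analytic
oracle the simulated pipeline is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lengths import LengthModel
from .simulate import FragmentSet

__all__ = [
    "SizeWindow",
    "WindowProbabilities",
    "EmptySelectionError",
    "library_to_insert",
    "window_probability",
    "predict_enriched_ff",
    "apply_size_selection",
    "DEFAULT_ADAPTER_TOTAL",
]

# Total adapter contribution to library size: a 190-240 bp library window
# corresponds to 100-150 bp inserts.
DEFAULT_ADAPTER_TOTAL = 90


class EmptySelectionError(RuntimeError):
    """Raised when no fragment survives the size window."""


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-size window in insert or library frame."""

    low: int
    high: int
    frame: str = "insert"

    def __post_init__(self) -> None:
        if self.low <= 0 or self.high <= 0:
            raise ValueError(f"window bounds must be positive: {self}")
        if self.low > self.high:
            raise ValueError(f"window low > high: {self}")
        if self.frame not in ("insert", "library"):
            raise ValueError(f"frame must be 'insert' or 'library', got {self.frame!r}")


@dataclass(frozen=True)
class WindowProbabilities:
    """Per-origin window probabilities and their fetal/maternal ratio."""

    p_f: float
    p_m: float

    @property
    def r(self) -> float:
        if self.p_m == 0:
            return float("inf") if self.p_f > 0 else float("nan")
        return self.p_f / self.p_m


def library_to_insert(
    window: SizeWindow, adapter_total: int = DEFAULT_ADAPTER_TOTAL
) -> SizeWindow:
    """Convert a library-size window to the corresponding insert window."""
    if window.frame != "library":
        raise ValueError("library_to_insert requires a library-frame window")
    if window.low <= adapter_total:
        raise ValueError(
            f"library window low {window.low} must exceed adapter total {adapter_total}"
        )
    return SizeWindow(window.low - adapter_total, window.high - adapter_total, "insert")


def window_probability(model: LengthModel, window: SizeWindow) -> WindowProbabilities:
    """Per-origin probability that an insert length falls in the window."""
    if window.frame != "insert":
        raise ValueError("window_probability requires an insert-frame window")
    return WindowProbabilities(
        p_f=model.window_mass("fetal", window.low, window.high),
        p_m=model.window_mass("maternal", window.low, window.high),
    )


def predict_enriched_ff(ff: float, probs: WindowProbabilities) -> float:
    """Expected fetal fraction after selecting the window.

    Selection keeps a fetal fragment with probability p_f and a maternal
    one with p_m, so the surviving fetal share is
    ff p_f / (ff p_f + (1-ff) p_m).
    """
    if not (0.0 <= ff <= 1.0):
        raise ValueError(f"ff must be in [0,1], got {ff}")
    denom = ff * probs.p_f + (1.0 - ff) * probs.p_m
    if denom == 0:
        raise ValueError("window has zero probability for both origins")
    return ff * probs.p_f / denom


def apply_size_selection(
    sample: FragmentSet,
    window: SizeWindow,
    renormalize_depth: bool = True,
    seed: int | None = None,
) -> FragmentSet:
    """Select fragments whose insert length lies in the (inclusive) window.

    Fragment mode keeps the matching records (modelling selection applied
    to an already-sequenced read set; depth drops by the window mass).

    Count mode models the physical protocol, where the gel selects the
    library *before* sequencing: with ``renormalize_depth`` (the default)
    the selected library is sequenced at the original depth, i.e. the
    returned counts are a fresh full-depth draw from the post-selection
    distribution. Selection acts on fragment length only, so it leaves
    each origin's bin distribution unchanged and merely shifts the origin
    mix to the enriched fetal fraction ff p_f / (ff p_f + (1-ff) p_m).
    With ``renormalize_depth=False`` the realised counts are binomially
    thinned instead (selection after sequencing). Count-mode randomness
    is seeded from ``seed`` (defaults to the sample spec's seed + 1).
    """
    if window.frame != "insert":
        raise ValueError("apply_size_selection requires an insert-frame window")

    if sample.fragments is not None:
        length = (sample.fragments["end"] - sample.fragments["start"]).to_numpy()
        keep = (length >= window.low) & (length <= window.high)
        if not keep.any():
            raise EmptySelectionError(f"no fragment survives window {window}")
        return FragmentSet(
            sample_id=sample.sample_id,
            genome=sample.genome,
            length_model=sample.length_model,
            spec=sample.spec,
            provenance="post_selection",
            fragments=sample.fragments.loc[keep].reset_index(drop=True),
        )

    if seed is None:
        seed = (sample.spec.seed + 1) if sample.spec is not None else 0
    rng = np.random.default_rng(seed)
    probs = window_probability(sample.length_model, window)
    counts = sample.counts
    if probs.p_f == 0 and probs.p_m == 0:
        raise EmptySelectionError(f"window {window} has zero mass for both origins")

    if renormalize_depth and sample.bin_probs is not None:
        # redraw the selected library at full depth: the enriched origin
        # mix times the (unchanged) per-origin bin distributions
        ff = (
            sample.spec.fetal_fraction
            if sample.spec is not None
            else sample.origin_fraction()
        )
        ff_post = predict_enriched_ff(ff, probs)
        n = int(counts.sum())
        n_fetal = int(rng.binomial(n, ff_post))
        selected = np.zeros_like(counts)
        selected[:, 0] = rng.multinomial(n_fetal, sample.bin_probs[:, 0])
        selected[:, 1] = rng.multinomial(n - n_fetal, sample.bin_probs[:, 1])
        if selected.sum() == 0:
            raise EmptySelectionError(f"no fragment survives window {window}")
        return FragmentSet(
            sample_id=sample.sample_id,
            genome=sample.genome,
            length_model=sample.length_model,
            spec=sample.spec,
            provenance="post_selection",
            counts=selected.astype(np.int64),
            bin_probs=sample.bin_probs,
        )

    thinned = np.empty_like(counts)
    thinned[:, 0] = rng.binomial(counts[:, 0], probs.p_f)
    thinned[:, 1] = rng.binomial(counts[:, 1], probs.p_m)
    surviving = int(thinned.sum())
    if surviving == 0:
        raise EmptySelectionError(f"no fragment survives window {window}")
    if renormalize_depth:
        # no library model available: resample the thinned reads back to
        # the original depth (information stays capped at the window mass)
        flat = thinned.ravel().astype(float)
        resampled = rng.multinomial(int(counts.sum()), flat / flat.sum())
        thinned = resampled.reshape(thinned.shape)
    return FragmentSet(
        sample_id=sample.sample_id,
        genome=sample.genome,
        length_model=sample.length_model,
        spec=sample.spec,
        provenance="post_selection",
        counts=thinned.astype(np.int64),
    )
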