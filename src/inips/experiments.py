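"""Synthetic-cohort studies of size-selection NIPS.

Four desk-scale experiments mirror the validation studies of the
size-selection screening workflow, each fully reproducible from
(config, seed):

* window comparison — which insert window (115-125 / 125-135 / 135-145
  bp) maximises fetal-fraction enrichment on a small male-fetus cohort;
* fetal-fraction gradient — trisomy-21 detection sensitivity of the
  unselected (NIPS) and size-selected (iNIPS) arms at fetal fractions
  1-10%, 30 samples per fraction;
* enrichment cohort — per-sample fold-change in chrY-estimated fetal
  fraction (and fold-decrease of the maternal fraction) over a 50-sample
  male euploid cohort;
* maternal interference — how much a maternal whole-chromosome CNV's
  over-representation shrinks after selection, versus how much a fetal
  trisomy's grows.

Plus the confusion-matrix machinery (sensitivity/specificity with
Clopper-Pearson confidence intervals at 99%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import beta as beta_dist

from .binning import profile_sample
from .calling import ReferenceStats, build_reference, classify, z_score
from .fetal_fraction import enrichment_metrics, ff_from_chry
from .genome import GenomeModel, build_genome
from .lengths import LengthModel, default_length_model
from .simulate import MaternalCNV, SampleSpec, simulate_sample
from .size_select import SizeWindow, apply_size_selection, predict_enriched_ff, window_probability

__all__ = [
    "ExperimentConfig",
    "MetricsReport",
    "confusion_metrics",
    "clopper_pearson",
    "run_window_comparison",
    "run_gradient_experiment",
    "run_enrichment_cohort",
    "run_maternal_interference",
]

DEFAULT_WINDOW = (125, 135)
COMPARISON_WINDOWS = ((115, 125), (125, 135), (135, 145))


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared simulation settings for every experiment.

    Cohort fetal fractions are drawn log-normally (median ``ff_median``,
    log-sd ``ff_sigma``) unless an explicit ``ff_list`` is given; the
    printed study summaries report only medians and ranges, and the
    log-normal is the standard positive-skew choice for plasma FF.
    """

    name: str = "experiment"
    seed: int = 0
    n_samples: int = 50
    depth: int = 5_000_000
    mode: str = "count"
    gc_bias_beta: float = 2.0
    loess_span: float = 0.3
    genome_seed: int = 0
    genome_scale: float = 500.0
    bin_size: int = 20_000
    reference_size: int = 100
    window: tuple[int, int] = DEFAULT_WINDOW
    windows: tuple[tuple[int, int], ...] = COMPARISON_WINDOWS
    ff_median: float = 0.1458
    ff_sigma: float = 0.55
    ff_list: tuple[float, ...] | None = None
    fractions: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.10)
    n_per_fraction: int = 30
    trisomy: str = "chr21"
    maternal_cnvs: tuple[MaternalCNV, ...] = ()
    fixed_ff: float = 0.15
    confidence: float = 0.99

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["maternal_cnvs"] = [asdict(c) for c in self.maternal_cnvs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["maternal_cnvs"] = tuple(MaternalCNV(**c) for c in d.get("maternal_cnvs", ()))
        for key in ("window", "windows", "ff_list", "fractions"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in d[key]) \
                    if key == "windows" else tuple(d[key])
        return cls(**d)


@dataclass
class MetricsReport:
    """Result of one experiment: a summary dict and a per-sample table."""

    name: str
    summary: dict
    per_sample: pd.DataFrame

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "summary": self.summary}, fh, indent=2)

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


# -- shared plumbing ----------------------------------------------------


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0]) for c in ss.spawn(n)]


def _cohort_ffs(config: ExperimentConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.ff_list is not None:
        if len(config.ff_list) != n:
            raise ValueError("ff_list length does not match n_samples")
        return np.asarray(config.ff_list, dtype=float)
    ff = np.exp(rng.normal(np.log(config.ff_median), config.ff_sigma, size=n))
    return np.clip(ff, 0.005, 0.9)


def _genome(config: ExperimentConfig) -> GenomeModel:
    return build_genome(
        bin_size=config.bin_size, scale=config.genome_scale, seed=config.genome_seed
    )


def _profile(config, genome, spec, window=None, model=None):
    """Simulate one sample, optionally size-select, and profile it."""
    sample = simulate_sample(
        genome, spec, mode=config.mode, length_model=model,
        gc_bias_beta=config.gc_bias_beta,
    )
    if window is not None:
        sample = apply_size_selection(sample, SizeWindow(*window), renormalize_depth=True)
    return sample, profile_sample(sample, genome, span=config.loess_span)


def _reference(
    config: ExperimentConfig,
    genome: GenomeModel,
    window: tuple[int, int] | None,
    seed: int,
    model: LengthModel | None = None,
) -> ReferenceStats:
    """Arm-matched euploid reference cohort (male, typical FF spread)."""
    seeds = _child_seeds(seed, config.reference_size)
    rng = np.random.default_rng(seed)
    ffs = np.clip(np.exp(rng.normal(np.log(0.10), 0.5, size=config.reference_size)), 0.02, 0.4)
    profiles = []
    for i, s in enumerate(seeds):
        spec = SampleSpec(
            fetal_fraction=float(ffs[i]), fetal_sex="male", n_fragments=config.depth,
            seed=s, sample_id=f"ref{i}",
        )
        profiles.append(_profile(config, genome, spec, window=window, model=model)[1])
    return build_reference(profiles)


def clopper_pearson(k: int, n: int, confidence: float = 0.99) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def confusion_metrics(
    calls: Sequence[str],
    truths: Sequence[str],
    confidence: float = 0.99,
    no_call_policy: str = "miss",
) -> MetricsReport:
    """Sensitivity/specificity with Clopper-Pearson intervals.

    ``truths`` entries are "affected"/"unaffected"; ``calls`` may also be
    "no_call". With the default conservative policy a no-call counts as a
    non-detection (it stays in the denominator); ``no_call_policy=
    "exclude"`` drops no-calls from the denominators, as clinical reports
    do after resolving them.
    """
    if len(calls) == 0 or len(calls) != len(truths):
        raise ValueError("calls and truths must be equal-length and non-empty")
    if no_call_policy not in ("miss", "exclude"):
        raise ValueError(f"unknown no_call_policy {no_call_policy!r}")
    calls = np.asarray(calls)
    truths = np.asarray(truths)
    summary: dict = {"n": int(len(calls)), "no_call": int((calls == "no_call").sum())}
    for label, key in (("affected", "sensitivity"), ("unaffected", "specificity")):
        sel = truths == label
        if no_call_policy == "exclude":
            sel = sel & (calls != "no_call")
        n = int(sel.sum())
        k = int((calls[sel] == label).sum())
        if n == 0:
            summary[key] = None
            continue
        lo, hi = clopper_pearson(k, n, confidence)
        summary[key] = {"value": k / n, "k": k, "n": n, "ci": [lo, hi]}
    per_sample = pd.DataFrame({"call": calls, "truth": truths})
    return MetricsReport(name="confusion", summary=summary, per_sample=per_sample)


# -- experiments --------------------------------------------------------


def run_window_comparison(config: ExperimentConfig) -> MetricsReport:
    """Compare fetal-fraction enrichment across insert windows.

    For each sample the fetal fraction is chrY-estimated before and after
    selecting each window; the report holds per-window median fold
    changes and the argmax window.
    """
    if len(config.windows) < 2:
        raise ValueError("window comparison needs >= 2 windows")
    if config.n_samples <= 0:
        raise ValueError("empty cohort")
    genome = _genome(config)
    model = default_length_model()
    rng = np.random.default_rng(config.seed)
    ffs = _cohort_ffs(config, rng, config.n_samples)
    seeds = _child_seeds(config.seed + 1, config.n_samples)

    rows = []
    for i in range(config.n_samples):
        spec = SampleSpec(
            fetal_fraction=float(ffs[i]), fetal_sex="male",
            n_fragments=config.depth, seed=seeds[i], sample_id=f"s{i}",
        )
        sample, pre = _profile(config, genome, spec, model=model)
        ff_before = ff_from_chry(pre.pct_chry).value
        for widx, window in enumerate(config.windows):
            selected = apply_size_selection(
                sample, SizeWindow(*window), renormalize_depth=True,
                seed=seeds[i] + 7919 * (widx + 1),
            )
            post = profile_sample(selected, genome, span=config.loess_span)
            ff_after = ff_from_chry(post.pct_chry).value
            rows.append(
                {
                    "sample": spec.sample_id,
                    "ff_true": ffs[i],
                    "window": f"{window[0]}-{window[1]}",
                    "ff_before": ff_before,
                    "ff_after": ff_after,
                    "ff_fold": ff_after / ff_before if ff_before > 0 else np.nan,
                }
            )
    per_sample = pd.DataFrame(rows)
    medians = per_sample.groupby("window")["ff_fold"].median().to_dict()
    best = max(medians, key=medians.get)
    return MetricsReport(
        name=config.name or "window_comparison",
        summary={"median_ff_fold": medians, "best_window": best},
        per_sample=per_sample,
    )


def run_gradient_experiment(config: ExperimentConfig) -> MetricsReport:
    """Trisomy sensitivity across the low fetal-fraction gradient.

    Each fraction is simulated ``n_per_fraction`` times as a male-fetus
    full trisomy; both arms are scored against arm-matched euploid
    references. Fold metrics use ground-truth origin fractions (the chrY
    estimate is dominated by noise at FF = 1%).
    """
    if not config.fractions:
        raise ValueError("no fractions configured")
    if config.reference_size < 20:
        raise ValueError("reference cohort must have >= 20 samples")
    genome = _genome(config)
    model = default_length_model()
    ref_nips = _reference(config, genome, None, config.seed + 101, model)
    ref_inips = _reference(config, genome, config.window, config.seed + 202, model)

    rows = []
    seeds = _child_seeds(config.seed + 303, len(config.fractions) * config.n_per_fraction)
    it = iter(seeds)
    for ff in config.fractions:
        for i in range(config.n_per_fraction):
            s = next(it)
            spec = SampleSpec(
                fetal_fraction=float(ff), fetal_sex="male", aneuploidy=config.trisomy,
                mosaicism=1.0, n_fragments=config.depth, seed=s,
                sample_id=f"ff{ff:g}_{i}",
            )
            sample, pre = _profile(config, genome, spec, model=model)
            selected = apply_size_selection(
                sample, SizeWindow(*config.window), renormalize_depth=True
            )
            post = profile_sample(selected, genome, span=config.loess_span)
            z_n = z_score(pre, ref_nips, config.trisomy)
            z_i = z_score(post, ref_inips, config.trisomy)
            ff_pre = sample.origin_fraction()
            ff_post = selected.origin_fraction()
            rows.append(
                {
                    "sample": spec.sample_id,
                    "ff": ff,
                    "ff_true_pre": ff_pre,
                    "ff_true_post": ff_post,
                    "ff_fold": ff_post / ff_pre if ff_pre > 0 else np.nan,
                    "maternal_decrease": (1 - ff_pre) / (1 - ff_post),
                    "z_nips": z_n,
                    "z_inips": z_i,
                    "class_nips": classify(z_n),
                    "class_inips": classify(z_i),
                }
            )
    per_sample = pd.DataFrame(rows)

    sensitivity: dict = {"NIPS": {}, "iNIPS": {}}
    for ff in config.fractions:
        sub = per_sample.loc[per_sample["ff"] == ff]
        for arm, col in (("NIPS", "class_nips"), ("iNIPS", "class_inips")):
            k = int((sub[col] == "affected").sum())
            n = len(sub)
            lo, hi = clopper_pearson(k, n, config.confidence)
            sensitivity[arm][f"{ff:g}"] = {"value": k / n, "k": k, "n": n, "ci": [lo, hi]}
    summary = {
        "sensitivity": sensitivity,
        "median_ff_fold": float(per_sample["ff_fold"].median()),
        "median_maternal_decrease": float(per_sample["maternal_decrease"].median()),
    }
    return MetricsReport(name=config.name or "gradient", summary=summary, per_sample=per_sample)


def run_enrichment_cohort(config: ExperimentConfig) -> MetricsReport:
    """chrY-estimated enrichment metrics over a male euploid cohort."""
    if config.n_samples <= 0:
        raise ValueError("empty cohort")
    genome = _genome(config)
    model = default_length_model()
    rng = np.random.default_rng(config.seed)
    ffs = _cohort_ffs(config, rng, config.n_samples)
    seeds = _child_seeds(config.seed + 1, config.n_samples)

    rows = []
    for i in range(config.n_samples):
        spec = SampleSpec(
            fetal_fraction=float(ffs[i]), fetal_sex="male",
            n_fragments=config.depth, seed=seeds[i], sample_id=f"s{i}",
        )
        sample, pre = _profile(config, genome, spec, model=model)
        selected = apply_size_selection(
            sample, SizeWindow(*config.window), renormalize_depth=True
        )
        post = profile_sample(selected, genome, span=config.loess_span)
        ff_b = ff_from_chry(pre.pct_chry).value
        ff_a = ff_from_chry(post.pct_chry).value
        m = enrichment_metrics(ff_b, ff_a)
        rows.append(
            {
                "sample": spec.sample_id,
                "ff_true": ffs[i],
                "ff_before": ff_b,
                "ff_after": ff_a,
                "ff_fold": m.ff_fold,
                "maternal_decrease": m.maternal_decrease,
            }
        )
    per_sample = pd.DataFrame(rows)
    summary = {
        "median_ff_fold": float(per_sample["ff_fold"].median()),
        "median_maternal_decrease": float(per_sample["maternal_decrease"].median()),
        "ff_before_median": float(per_sample["ff_before"].median()),
        "ff_after_median": float(per_sample["ff_after"].median()),
    }
    return MetricsReport(name=config.name or "enrichment_cohort", summary=summary, per_sample=per_sample)


def run_maternal_interference(config: ExperimentConfig) -> MetricsReport:
    """Effect of selection on maternal-CNV versus fetal-trisomy signal.

    Simulates euploid-fetus pregnancies whose mother carries a
    whole-chromosome CNV, plus matched fetal-trisomy pregnancies, and
    reports the target chromosome's over-representation (p / mean_ref - 1)
    in each arm: the maternal excess shrinks by roughly the
    maternal-decrease factor after selection while the fetal excess grows
    by roughly the fetal-fraction fold.
    """
    if not config.maternal_cnvs:
        raise ValueError("no maternal CNV configured")
    genome = _genome(config)
    model = default_length_model()
    ref_nips = _reference(config, genome, None, config.seed + 101, model)
    ref_inips = _reference(config, genome, config.window, config.seed + 202, model)
    cnv = config.maternal_cnvs[0]
    target = cnv.chrom

    seeds = _child_seeds(config.seed + 303, 2 * config.n_samples)
    rows = []
    for kind in ("maternal_cnv", "fetal_trisomy"):
        for i in range(config.n_samples):
            s = seeds.pop()
            if kind == "maternal_cnv":
                spec = SampleSpec(
                    fetal_fraction=config.fixed_ff, fetal_sex="male",
                    maternal_cnvs=config.maternal_cnvs,
                    n_fragments=config.depth, seed=s, sample_id=f"{kind}_{i}",
                )
            else:
                spec = SampleSpec(
                    fetal_fraction=config.fixed_ff, fetal_sex="male",
                    aneuploidy=target, mosaicism=1.0,
                    n_fragments=config.depth, seed=s, sample_id=f"{kind}_{i}",
                )
            sample, pre = _profile(config, genome, spec, model=model)
            selected = apply_size_selection(
                sample, SizeWindow(*config.window), renormalize_depth=True
            )
            post = profile_sample(selected, genome, span=config.loess_span)
            rows.append(
                {
                    "sample": spec.sample_id,
                    "kind": kind,
                    "excess_nips": pre.fraction(target) / ref_nips.mean[target] - 1.0,
                    "excess_inips": post.fraction(target) / ref_inips.mean[target] - 1.0,
                }
            )
    per_sample = pd.DataFrame(rows)

    probs = window_probability(model, SizeWindow(*config.window))
    ff_after = predict_enriched_ff(config.fixed_ff, probs)
    summary = {"target": target, "copy_ratio": cnv.copy_ratio}
    for kind in ("maternal_cnv", "fetal_trisomy"):
        sub = per_sample.loc[per_sample["kind"] == kind]
        summary[kind] = {
            "mean_excess_nips": float(sub["excess_nips"].mean()),
            "mean_excess_inips": float(sub["excess_inips"].mean()),
        }
    summary["predicted_maternal_decrease"] = (1 - config.fixed_ff) / (1 - ff_after)
    summary["predicted_ff_fold"] = ff_after / config.fixed_ff
    return MetricsReport(name=config.name or "maternal_interference", summary=summary, per_sample=per_sample)
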