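"""Simulator contracts: origin mixing, chrY calibration, copy-number
weights, mode agreement, determinism and BED round-trip."""

import numpy as np
import pandas as pd
import pytest

from inips import (
    MaternalCNV,
    SampleSpec,
    SizeWindow,
    read_bed,
    simulate_sample,
    window_probability,
    write_bed,
)


def chrom_origin_counts(sample):
    """(chrom, origin) count table for either mode."""
    if sample.counts is not None:
        df = sample.genome.bins[["chrom"]].copy()
        df["fetal"] = sample.counts[:, 0]
        df["maternal"] = sample.counts[:, 1]
        return df.groupby("chrom")[["fetal", "maternal"]].sum()
    df = sample.fragments.pivot_table(
        index="chrom", columns="origin", aggfunc="size", fill_value=0
    )
    return df


def test_spec_validation():
    with pytest.raises(ValueError):
        SampleSpec(fetal_fraction=1.2)
    with pytest.raises(ValueError):
        SampleSpec(mosaicism=0.5)  # mosaicism without aneuploidy
    with pytest.raises(ValueError):
        SampleSpec(aneuploidy="chr2")
    with pytest.raises(ValueError):
        SampleSpec(n_fragments=0)
    # mosaic trisomy is fine
    SampleSpec(aneuploidy="chr21", mosaicism=0.127)


def test_spec_yaml_round_trip(tmp_path):
    spec = SampleSpec(
        fetal_fraction=0.02, aneuploidy="chr21", mosaicism=0.5,
        maternal_cnvs=(MaternalCNV("chr18", 1.1),), seed=9,
    )
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    assert SampleSpec.from_yaml(path) == spec


def test_ff_zero_has_no_fetal_fragments(genome):
    spec = SampleSpec(fetal_fraction=0.0, n_fragments=50_000, seed=1)
    assert simulate_sample(genome, spec, mode="count").counts[:, 0].sum() == 0
    frag = simulate_sample(genome, spec, mode="fragment")
    assert (frag.fragments["origin"] == "maternal").all()


def test_same_seed_is_bit_identical(genome):
    spec = SampleSpec(fetal_fraction=0.1, n_fragments=100_000, seed=11)
    a = simulate_sample(genome, spec, mode="count")
    b = simulate_sample(genome, spec, mode="count")
    assert np.array_equal(a.counts, b.counts)
    fa = simulate_sample(genome, spec, mode="fragment")
    fb = simulate_sample(genome, spec, mode="fragment")
    pd.testing.assert_frame_equal(fa.fragments, fb.fragments)


def test_origin_fraction_recovers_ff(genome):
    """Realised fetal share converges to the specified FF (binomial bound).

    Mirrors the paper's construction of low-FF samples by computational
    dilution from a high-FF source."""
    for ff in (0.02, 0.195):
        spec = SampleSpec(fetal_fraction=ff, n_fragments=1_000_000, seed=3)
        got = simulate_sample(genome, spec, mode="count").origin_fraction()
        assert abs(got - ff) < 3 * np.sqrt(ff * (1 - ff) / spec.n_fragments)


def test_trisomy_elevates_fetal_target_share(genome):
    """Full T21 multiplies the fetal chr21 share by 1.5; mosaic m=0.5 by 1.25."""
    base = SampleSpec(fetal_fraction=0.5, n_fragments=2_000_000, seed=5)
    eu = chrom_origin_counts(simulate_sample(genome, base, mode="count"))
    for m, factor in ((1.0, 1.5), (0.5, 1.25)):
        spec = SampleSpec(
            fetal_fraction=0.5, aneuploidy="chr21", mosaicism=m,
            n_fragments=2_000_000, seed=5,
        )
        tri = chrom_origin_counts(simulate_sample(genome, spec, mode="count"))
        share_eu = eu.loc["chr21", "fetal"] / eu["fetal"].sum()
        share_tri = tri.loc["chr21", "fetal"] / tri["fetal"].sum()
        # expected ratio factor/(1 + share_eu*(factor-1)); shares are small
        expected = factor / (1 + share_eu * (factor - 1))
        assert share_tri / share_eu == pytest.approx(expected, rel=0.05)


def test_maternal_cnv_scales_maternal_share_only(genome):
    spec = SampleSpec(
        fetal_fraction=0.2, maternal_cnvs=(MaternalCNV("chr21", 1.5),),
        n_fragments=2_000_000, seed=6,
    )
    counts = chrom_origin_counts(simulate_sample(genome, spec, mode="count"))
    base = chrom_origin_counts(
        simulate_sample(genome, SampleSpec(fetal_fraction=0.2, n_fragments=2_000_000, seed=6), mode="count")
    )
    mat_ratio = (counts.loc["chr21", "maternal"] / counts["maternal"].sum()) / (
        base.loc["chr21", "maternal"] / base["maternal"].sum()
    )
    fet_ratio = (counts.loc["chr21", "fetal"] / counts["fetal"].sum()) / (
        base.loc["chr21", "fetal"] / base["fetal"].sum()
    )
    assert mat_ratio == pytest.approx(1.5 / (1 + 0.0167 * 0.5), rel=0.05)
    assert fet_ratio == pytest.approx(1.0, abs=0.05)


@pytest.mark.parametrize("sex,ff,expected_pct", [
    ("male", 1.0, 0.170),
    ("male", 0.10, 0.10 * 0.170 + 0.90 * 0.002),
    ("female", 0.10, 0.002),
])
def test_chry_calibration(genome, sex, ff, expected_pct):
    """Expected %chrY = FF*0.170% + (1-FF)*0.002% for male fetuses (raw
    counts, no GC bias)."""
    spec = SampleSpec(fetal_fraction=ff, fetal_sex=sex, n_fragments=4_000_000, seed=8)
    sample = simulate_sample(genome, spec, mode="count", gc_bias_beta=0.0)
    counts = chrom_origin_counts(sample).sum(axis=1)
    autosomal = counts.drop(["chrX", "chrY"]).sum()
    pct = 100.0 * counts["chrY"] / autosomal
    sd = 100.0 * np.sqrt(expected_pct / 100.0 / autosomal)
    assert abs(pct - expected_pct) < 4 * sd + 1e-6


def test_fragment_and_count_mode_agree_in_distribution(genome, length_model):
    """Fragment-mode frequencies match count-mode probabilities within 4-sigma
    binomial bounds per (chromosome, origin) cell, plus the length-window
    cell against the analytic window mass."""
    spec = SampleSpec(fetal_fraction=0.3, fetal_sex="male", n_fragments=1_000_000, seed=13)
    frag = simulate_sample(genome, spec, mode="fragment")
    count = simulate_sample(genome, spec, mode="count")
    probs = count.bin_probs  # theoretical per-origin bin distribution

    bins = genome.bins
    for col, origin in ((0, "fetal"), (1, "maternal")):
        sub = frag.fragments.loc[frag.fragments["origin"] == origin]
        n = len(sub)
        got = sub.groupby("chrom").size().reindex(genome.chrom_lengths, fill_value=0) / n
        expected = pd.Series(probs[:, col], index=bins.index).groupby(bins["chrom"]).sum()
        for chrom in genome.chrom_lengths:
            p = expected[chrom]
            tol = 4 * np.sqrt(max(p * (1 - p), 1e-12) / n) + 1e-9
            assert abs(got[chrom] - p) < tol, chrom
        # length-window cell
        lengths = (sub["end"] - sub["start"]).to_numpy()
        p_win = length_model.window_mass(origin, 125, 135)
        freq = ((lengths >= 125) & (lengths <= 135)).mean()
        assert abs(freq - p_win) < 4 * np.sqrt(p_win * (1 - p_win) / n)


def test_fragment_records_well_formed(fragment_sample):
    df = fragment_sample.fragments
    assert (df["end"] > df["start"]).all()
    lengths = df["end"] - df["start"]
    assert lengths.between(60, 250).all()
    assert df["mapq"].between(0, 60).all()
    dup_rate = df["duplicate"].mean()
    assert abs(dup_rate - 0.02) < 4 * np.sqrt(0.02 * 0.98 / len(df))
    assert abs((df["mapq"] == 60).mean() - 0.90) < 0.01


def test_bed_round_trip(tmp_path, genome, fragment_sample):
    path = tmp_path / "frags.bed"
    write_bed(fragment_sample, path)
    back = read_bed(path, genome, fragment_sample.length_model)
    for col in ("chrom", "start", "end", "origin", "mapq", "duplicate"):
        assert (back.fragments[col] == fragment_sample.fragments[col]).all()
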