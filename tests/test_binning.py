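"""Read filtering, binning, bin masking, GC-LOESS correction and
chromosome percentages."""

import numpy as np
import pandas as pd
import pytest

from inips import (
    BinTable,
    FragmentSet,
    SampleSpec,
    bin_counts,
    build_genome,
    chromosome_profile,
    default_length_model,
    filter_bins,
    filter_fragments,
    gc_correct,
    profile_sample,
    simulate_sample,
)
from inips.genome import AUTOSOMES


def make_fragments(genome, rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq", "duplicate"])
    df["origin"] = "maternal"
    return FragmentSet(
        sample_id="hand", genome=genome, length_model=default_length_model(),
        fragments=df[["chrom", "start", "end", "origin", "mapq", "duplicate"]],
    )


class TestFilterFragments:
    def test_boundary_rules(self, genome):
        # MAPQ must exceed 10, length must exceed 35, duplicates removed
        rows = [
            ("chr1", 0, 100, 10, False),   # MAPQ == 10 -> removed
            ("chr1", 0, 100, 11, False),   # retained
            ("chr1", 0, 35, 60, False),    # length == 35 -> removed
            ("chr1", 0, 36, 60, False),    # retained
            ("chr1", 0, 100, 60, True),    # duplicate -> removed
        ]
        out = filter_fragments(make_fragments(genome, rows))
        kept = list(zip(out.fragments["end"] - out.fragments["start"], out.fragments["mapq"]))
        assert kept == [(100, 11), (36, 60)]

    def test_all_duplicates_yield_empty(self, genome):
        rows = [("chr1", 0, 100, 60, True)] * 3
        assert filter_fragments(make_fragments(genome, rows)).total == 0

    def test_count_mode_passthrough(self, male_sample):
        assert filter_fragments(male_sample) is male_sample


class TestBinCounts:
    def test_half_open_bin_assignment(self, genome):
        rows = [
            ("chr1", 19_999, 20_100, 60, False),  # bin 0
            ("chr1", 20_000, 20_100, 60, False),  # bin 1
        ]
        table = bin_counts(make_fragments(genome, rows), genome)
        assert table.data.loc[0, "raw"] == 1
        assert table.data.loc[1, "raw"] == 1

    def test_conservation(self, fragment_sample, genome):
        table = bin_counts(fragment_sample, genome)
        assert table.data["raw"].sum() == fragment_sample.total

    def test_gc_rounded_to_tenth_percent(self, fragment_sample, genome):
        table = bin_counts(fragment_sample, genome)
        gc = table.data["gc"].to_numpy()
        assert np.allclose(gc, np.round(gc, 3))

    def test_fragment_outside_genome_errors(self, genome):
        rows = [("chr1", genome.chrom_lengths["chr1"] + 5, genome.chrom_lengths["chr1"] + 105, 60, False)]
        with pytest.raises(ValueError):
            bin_counts(make_fragments(genome, rows), genome)
        with pytest.raises(ValueError):
            bin_counts(make_fragments(genome, [("chrZ", 0, 100, 60, False)]), genome)

    def test_uniform_counts_poisson_consistent(self, genome):
        """With no GC bias, per-bin counts on one chromosome are
        multinomial-uniform: the index of dispersion is ~1."""
        spec = SampleSpec(fetal_fraction=0.0, n_fragments=2_000_000, seed=17)
        sample = simulate_sample(genome, spec, mode="count", gc_bias_beta=0.0)
        table = bin_counts(sample, genome)
        sub = table.data[(table.data["chrom"] == "chr2") & ~table.data["n_mask"]]
        full = sub[(sub["end"] - sub["start"]) == genome.bin_size]["raw"].to_numpy()
        disp = full.var(ddof=1) / full.mean()
        # chi-square bound: dispersion within ~4 sd of 1 at k bins
        assert abs(disp - 1.0) < 4 * np.sqrt(2 / (len(full) - 1))


class TestFilterBins:
    def test_masks_zero_and_n_bins(self, genome, fragment_sample):
        table = bin_counts(fragment_sample, genome)
        table.data.loc[0, "raw"] = 0
        out = filter_bins(table)
        assert bool(out.data.loc[0, "masked"])
        assert out.data.loc[out.data["n_mask"], "masked"].all()
        # untouched bins stay unmasked
        live = (out.data["raw"] > 0) & ~out.data["n_mask"]
        assert not out.data.loc[live, "masked"].any()

    def test_all_masked_errors(self, genome):
        table = bin_counts(make_fragments(genome, []), genome)
        with pytest.raises(ValueError):
            filter_bins(table)


class TestGCCorrect:
    def _table(self, genome, beta, seed=23, depth=2_000_000):
        spec = SampleSpec(fetal_fraction=0.1, n_fragments=depth, seed=seed)
        sample = simulate_sample(genome, spec, mode="count", gc_bias_beta=beta)
        return filter_bins(bin_counts(sample, genome))

    @staticmethod
    def _gc_count_corr(table, column):
        data = table.data
        sel = (~data["masked"]) & data["chrom"].isin(AUTOSOMES) & (
            (data["end"] - data["start"]) == (data["end"] - data["start"]).max()
        )
        return np.corrcoef(data.loc[sel, "gc"], data.loc[sel, column])[0, 1]

    def test_no_bias_correction_is_nearly_identity(self, genome):
        table = gc_correct(self._table(genome, beta=0.0))
        un = table.unmasked()
        rel = (un["corrected"] - un["raw"]).abs() / un["raw"]
        assert rel.median() < 0.02

    def test_removes_linear_gc_bias(self, genome):
        table = self._table(genome, beta=2.0)
        assert abs(self._gc_count_corr(table, "raw")) > 0.3
        corrected = gc_correct(table)
        assert abs(self._gc_count_corr(corrected, "corrected")) < 0.05

    def test_total_count_preserved_within_contract(self, genome):
        table = gc_correct(self._table(genome, beta=2.0))
        un = table.unmasked()
        assert un["corrected"].sum() == pytest.approx(un["raw"].sum(), rel=0.10)

    def test_degenerate_gc_is_identity_with_warning(self, genome, fragment_sample):
        table = bin_counts(fragment_sample, genome)
        table.data["gc"] = 0.41
        table = filter_bins(table)
        with pytest.warns(UserWarning):
            out = gc_correct(table)
        un = out.unmasked()
        assert (un["corrected"] == un["raw"]).all()

    def test_too_few_bins_errors(self, genome, fragment_sample):
        table = filter_bins(bin_counts(fragment_sample, genome))
        table.data.loc[40:, "masked"] = True
        with pytest.raises(ValueError):
            gc_correct(table)


class TestChromosomeProfile:
    def _profiled(self, genome, sample):
        return profile_sample(sample, genome)

    def test_autosomal_fractions_sum_to_one(self, genome, male_sample):
        prof = self._profiled(genome, male_sample)
        total = sum(prof.fraction(c) for c in AUTOSOMES)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in prof.fractions.values())

    def test_rescaling_invariance(self, genome, male_sample):
        table = gc_correct(filter_bins(bin_counts(male_sample, genome)))
        p1 = chromosome_profile(table)
        table.data["corrected"] *= 3.7
        p2 = chromosome_profile(table)
        for c in p1.fractions:
            assert p2.fraction(c) == pytest.approx(p1.fraction(c))

    def test_equal_counts_give_uniform_autosomes(self, genome):
        table = bin_counts(
            make_fragments(genome, [(c, 0, 100, 60, False) for c in AUTOSOMES]), genome
        )
        table.data["corrected"] = table.data["raw"].astype(float)
        table.data["masked"] = table.data["raw"] == 0
        prof = chromosome_profile(table)
        for c in AUTOSOMES:
            assert prof.fraction(c) == pytest.approx(1 / 22)

    def test_missing_correction_errors(self, genome, male_sample):
        table = filter_bins(bin_counts(male_sample, genome))
        with pytest.raises(ValueError):
            chromosome_profile(table)

    def test_male_chry_percentage_through_pipeline(self, genome, male_sample):
        """GC-corrected %chrY for FF=10% male ~ 0.1*0.170% + 0.9*0.002%."""
        prof = self._profiled(genome, male_sample)
        assert prof.pct_chry == pytest.approx(0.1 * 0.170 + 0.9 * 0.002, rel=0.10)

    def test_tsv_round_trip(self, tmp_path, genome, male_sample):
        table = gc_correct(filter_bins(bin_counts(male_sample, genome)))
        path = tmp_path / "bins.tsv"
        table.to_tsv(path)
        back = BinTable.from_tsv(path)
        assert np.allclose(back.data["corrected"].dropna(), table.data["corrected"].dropna())
        prof_a = chromosome_profile(table)
        prof_b = chromosome_profile(back)
        assert prof_a.fractions == pytest.approx(prof_b.fractions)
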