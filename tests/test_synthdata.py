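"""Generators: determinism, planted-parameter recovery, count invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripedit import synthdata
from ripedit.formats import BASE_COLUMNS
from ripedit.synthdata import (
    EnrichmentTruth,
    SimulationError,
    simulate_editing_truth,
    simulate_enrichment_truth,
    simulate_pileups,
    simulate_reference,
    simulate_rip_counts,
    simulate_sanger_peaks,
)


class TestReference:
    def test_zero_snp_density(self):
        bundle = simulate_reference(n_genes=1, snp_density=0.0, seed=1)
        assert bundle.snp_sites == []

    def test_seed_determinism(self):
        b1 = simulate_reference(n_genes=10, seed=7)
        b2 = simulate_reference(n_genes=10, seed=7)
        assert b1.sequences == b2.sequences
        assert b1.features == b2.features
        assert b1.snp_sites == b2.snp_sites

    def test_snp_count_in_binomial_interval(self):
        density = 1e-3
        bundle = simulate_reference(n_genes=50, snp_density=density, seed=3)
        total_len = sum(len(s) for s in bundle.sequences.values())
        # SNPs cannot land in repeat regions, so the eligible length excludes them
        repeat_len = sum(e - s for _, s, e, _, _, cls in bundle.features
                         if cls == "repeat-region")
        lo, hi = stats.binom.interval(0.99, total_len - repeat_len, density)
        assert lo <= len(bundle.snp_sites) <= hi

    def test_snp_ref_matches_sequence_and_avoids_repeats(self):
        bundle = simulate_reference(n_genes=20, snp_density=2e-3, seed=5)
        repeats = {
            (c, p)
            for c, s, e, _, _, cls in bundle.features if cls == "repeat-region"
            for p in range(s + 1, e + 1)
        }
        for contig, pos, ref, alt in bundle.snp_sites:
            assert bundle.sequences[contig][pos - 1] == ref
            assert ref != alt
            assert (contig, pos) not in repeats

    def test_every_gene_has_core_features(self):
        bundle = simulate_reference(n_genes=6, seed=2)
        by_gene = {}
        for _, _, _, _, gene, cls in bundle.features:
            by_gene.setdefault(gene, set()).add(cls)
        assert len(by_gene) == 6
        for classes in by_gene.values():
            assert {"5'UTR", "CDS", "3'UTR"} <= classes

    def test_feature_intervals_inside_contig(self):
        bundle = simulate_reference(n_genes=6, seed=2)
        for contig, start, end, _, _, _ in bundle.features:
            assert 0 <= start < end <= len(bundle.sequences[contig])

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0}, {"n_genes": 3, "length_range": (0, 10)},
        {"n_genes": 3, "snp_density": 1.5},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(SimulationError):
            simulate_reference(seed=1, **kwargs)


class TestEditingTruth:
    def test_empty(self, small_bundle):
        truth = simulate_editing_truth(small_bundle, n_sites=0, seed=1)
        assert truth.sites == [] and truth.differential_sites == []

    def test_differential_count_by_construction(self, small_bundle):
        truth = simulate_editing_truth(small_bundle, n_sites=20, n_diff=5, seed=2)
        assert len(truth.sites) == 20
        assert len(truth.differential_sites) == 5

    def test_sites_on_sense_adenosines_and_off_snps(self, small_bundle):
        truth = simulate_editing_truth(small_bundle, n_sites=25, n_diff=5, seed=3)
        snp_keys = small_bundle.snp_keys()
        assert truth.keys() & snp_keys == set()
        for s in truth.sites:
            base = small_bundle.sequences[s["contig"]][s["pos"] - 1]
            assert base == ("A" if s["strand"] == "+" else "T")
            for f in s["fractions"].values():
                assert 0.0 <= f <= 1.0

    def test_planted_delta_mean_matches_distribution(self):
        bundle = simulate_reference(n_genes=30, seed=4)
        truth = simulate_editing_truth(
            bundle, n_sites=220, n_diff=200,
            delta_dist=("uniform", 0.10, 0.30), seed=5,
        )
        mags = np.abs([s["delta"] for s in truth.differential_sites])
        # clipping at [0,1] can only shrink magnitudes; compare on unclipped ones
        se = (0.30 - 0.10) / np.sqrt(12) / np.sqrt(len(mags))
        assert abs(np.mean(mags) - 0.20) < 3 * se + 0.01

    def test_too_many_sites_raises(self):
        bundle = simulate_reference(n_genes=1, length_range=(60, 80), seed=1)
        with pytest.raises(SimulationError, match="adenosine"):
            simulate_editing_truth(bundle, n_sites=10_000, seed=1)


class TestPileups:
    def test_no_signal_no_error_means_no_alt(self):
        bundle = simulate_reference(n_genes=2, snp_density=0.0, seed=6)
        truth = simulate_editing_truth(bundle, n_sites=0, seed=6)
        tables = simulate_pileups(bundle, truth, mean_coverage=30,
                                  error_rate=0.0, n_replicates=1,
                                  condition="A", seed=6)
        df = tables[0].df
        for row in df.itertuples(index=False):
            for base in "ACGT":
                if base != row.ref:
                    assert getattr(row, f"{base}_fwd") == 0
                    assert getattr(row, f"{base}_rev") == 0

    def test_site_fraction_within_binomial_interval(self):
        bundle = simulate_reference(n_genes=2, snp_density=0.0, seed=7)
        truth = simulate_editing_truth(
            bundle, n_sites=1, base_fraction_dist=("constant", 0.3), seed=7
        )
        tables = simulate_pileups(bundle, truth, mean_coverage=1000,
                                  error_rate=0.0, n_replicates=1,
                                  condition="A", seed=7)
        s = truth.sites[0]
        alt = "G" if s["ref"] == "A" else "C"
        df = tables[0].df
        row = df[(df["contig"] == s["contig"]) & (df["pos"] == s["pos"])].iloc[0]
        n_alt = row[f"{alt}_fwd"] + row[f"{alt}_rev"]
        cov = sum(row[c] for c in BASE_COLUMNS)
        lo, hi = stats.binom.interval(0.999, cov, 0.3)
        assert lo <= n_alt <= hi

    def test_het_snp_alt_fraction_near_half(self):
        bundle = simulate_reference(n_genes=3, snp_density=2e-3, seed=8)
        assert bundle.snp_sites  # need at least one planted SNP
        truth = simulate_editing_truth(bundle, n_sites=0, seed=8)
        tables = simulate_pileups(bundle, truth, mean_coverage=500,
                                  error_rate=0.0, n_replicates=1,
                                  condition="A", seed=8)
        df = tables[0].df
        contig, pos, ref, alt = bundle.snp_sites[0]
        row = df[(df["contig"] == contig) & (df["pos"] == pos)].iloc[0]
        n_alt = row[f"{alt}_fwd"] + row[f"{alt}_rev"]
        cov = sum(row[c] for c in BASE_COLUMNS)
        lo, hi = stats.binom.interval(0.999, cov, 0.5)
        assert lo <= n_alt <= hi

    def test_counts_nonnegative_and_deterministic(self, small_bundle, small_truth):
        t1 = simulate_pileups(small_bundle, small_truth, mean_coverage=20,
                              n_replicates=2, condition="B", seed=9)
        t2 = simulate_pileups(small_bundle, small_truth, mean_coverage=20,
                              n_replicates=2, condition="B", seed=9)
        for a, b in zip(t1, t2):
            assert a.equals(b)
            assert (a.df[BASE_COLUMNS].to_numpy() >= 0).all()

    def test_unknown_condition_rejected(self, small_bundle, small_truth):
        with pytest.raises(SimulationError, match="condition"):
            simulate_pileups(small_bundle, small_truth, condition="Z", seed=1)


class TestRipCounts:
    def test_null_construction_has_unit_ror(self):
        truth = simulate_enrichment_truth(
            [f"g{i}" for i in range(20)], n_bound=0,
            baseline_dist=("constant", 100.0), dispersion=0.0, seed=1,
        )
        assert (truth.planted_log2_ror() == 0).all()

    def test_planted_ror_recovered_from_normalized_means(self):
        truth = simulate_enrichment_truth(
            ["g0"], n_bound=1, bound_ror=4.0,
            baseline_dist=("constant", 500.0), dispersion=0.05, seed=2,
        )
        cm = simulate_rip_counts(truth, n_replicates=50, seed=3)
        sheet = cm.sheet
        cells = {}
        for assay in ("IP", "input"):
            for cond in ("A", "B"):
                cols = sheet.loc[(sheet["assay"] == assay)
                                 & (sheet["condition"] == cond), "sample"]
                cells[(assay, cond)] = cm.counts.loc["g0", cols].to_numpy(float)
        per_rep = np.log2(
            (cells[("IP", "A")] / cells[("input", "A")])
            / (cells[("IP", "B")] / cells[("input", "B")])
        )
        se = per_rep.std(ddof=1) / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - 2.0) < 3 * se + 0.05

    def test_zero_baseline_gene_gives_zero_row(self):
        truth = EnrichmentTruth(genes={"gz": (0.0, 1.0, 1.0, 0.05),
                                       "g1": (50.0, 1.0, 1.0, 0.05)})
        cm = simulate_rip_counts(truth, seed=4)
        assert (cm.counts.loc["gz"] == 0).all()
        assert (cm.counts.loc["g1"] > 0).any()

    def test_library_factor_scales_expectation(self):
        truth = simulate_enrichment_truth(
            [f"g{i}" for i in range(200)], n_bound=0,
            baseline_dist=("constant", 200.0), dispersion=0.0, seed=5,
        )
        factors = np.ones(12)
        factors[0] = 3.0
        cm = simulate_rip_counts(truth, library_factors=factors,
                                 n_replicates=3, seed=6)
        ratio = cm.counts.iloc[:, 0].mean() / cm.counts.iloc[:, 1].mean()
        assert 2.7 < ratio < 3.3

    def test_bad_library_factors_rejected(self):
        truth = simulate_enrichment_truth(["g0"], n_bound=0, seed=1)
        with pytest.raises(SimulationError):
            simulate_rip_counts(truth, library_factors=[1.0], seed=1)


class TestSangerPeaks:
    @pytest.mark.parametrize("fraction, expect_zero", [
        (0.0, "G_height"), (1.0, "A_height"),
    ])
    def test_extremes_noise_free(self, fraction, expect_zero):
        peaks = simulate_sanger_peaks([fraction], noise_sd=0.0, seed=1)
        assert peaks.iloc[0][expect_zero] == 0.0

    def test_half_fraction_symmetric(self):
        peaks = simulate_sanger_peaks([0.5], total_height=800, noise_sd=0.0, seed=1)
        assert peaks.iloc[0]["A_height"] == peaks.iloc[0]["G_height"] == 400.0

    def test_noise_truncated_at_zero(self):
        peaks = simulate_sanger_peaks([0.0] * 200, total_height=10,
                                      noise_sd=50, seed=2)
        assert (peaks[["A_height", "G_height"]].to_numpy() >= 0).all()
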