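"""Editing-site discovery: strand logic, confidence model, filters, indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from ripedit import synthdata
from ripedit.editcall import (
    SiteCounts,
    call_candidate_sites,
    editing_fraction,
    editing_index,
    site_confidence,
    site_counts,
)
from ripedit.formats import IntervalSet, SiteSet

from conftest import make_pileup


def sc(alt, ref, other=0, strand="+"):
    base = "A" if strand == "+" else "T"
    return SiteCounts(contig="c", pos=1, strand=strand, ref=base,
                      ref_fwd=ref // 2, ref_rev=ref - ref // 2,
                      alt_fwd=alt // 2, alt_rev=alt - alt // 2, other=other)


class TestSiteCounts:
    def test_plus_strand_tally(self):
        pileup = make_pileup([("c", 10, "A", {"A": (45, 45), "G": (6, 4)})])
        feats = IntervalSet([("c", 0, 100, "+", "g|CDS")])
        [s] = site_counts(pileup, feats)
        assert (s.alt_count, s.ref_count, s.strand) == (10, 90, "+")

    def test_minus_strand_antisense_rule(self):
        pileup = make_pileup([("c", 10, "T", {"T": (45, 45), "C": (5, 5)})])
        feats = IntervalSet([("c", 0, 100, "-", "g|CDS")])
        [s] = site_counts(pileup, feats)
        assert (s.alt_count, s.ref_count, s.strand) == (10, 90, "-")

    def test_non_adenosine_reference_excluded(self):
        pileup = make_pileup([("c", 10, "C", {"C": (50, 50), "T": (5, 5)})])
        feats = IntervalSet([("c", 0, 100, "+", "g|CDS")])
        assert site_counts(pileup, feats) == []

    def test_unannotated_position_uses_higher_alt_convention(self):
        # ref A outside any feature: only the + convention applies
        pileup = make_pileup([("c", 10, "A", {"A": (40, 40), "G": (10, 10)})])
        [s] = site_counts(pileup, None)
        assert s.strand == "+" and s.alt_count == 20

    def test_other_base_reads_counted(self):
        pileup = make_pileup([("c", 10, "A", {"A": (40, 40), "G": (5, 5),
                                              "T": (2, 1)})])
        [s] = site_counts(pileup, None)
        assert s.other == 3 and s.coverage == 93 and s.informative == 90


class TestEditingFraction:
    @pytest.mark.parametrize("alt, ref, expected", [
        (20, 80, 0.20), (0, 50, 0.0),
    ])
    def test_ratio(self, alt, ref, expected):
        assert editing_fraction(sc(alt, ref)) == pytest.approx(expected)

    def test_dp4_style_sum_then_ratio(self):
        s = SiteCounts(contig="c", pos=1, strand="+", ref="A",
                       ref_fwd=70, ref_rev=10, alt_fwd=15, alt_rev=5)
        assert editing_fraction(s) == pytest.approx(0.20)

    def test_zero_informative_is_undefined_not_zero(self):
        s = sc(0, 0, other=5)
        assert editing_fraction(s) is None


class TestConfidence:
    def test_no_alt_evidence_below_threshold(self):
        assert site_confidence(sc(0, 20)) < 0.99

    @pytest.mark.parametrize("alt, cov", [(300, 1000), (1, 20)])
    def test_matches_quadrature_oracle(self, alt, cov):
        ref = cov - alt
        got = site_confidence(sc(alt, ref), error_rate=1e-3)
        # independent oracle: numeric integration of the Beta posterior
        a, b = alt + 0.5, ref + 0.5
        norm = integrate.quad(
            lambda p: stats.beta.pdf(p, a, b), 1e-3, 1)[0]
        assert got == pytest.approx(norm, abs=1e-6)
        if alt == 300:
            assert got > 0.99

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            site_confidence(sc(5, 5), error_rate=1.0)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            site_confidence(sc(0, 0))


@settings(max_examples=60, derandomize=True)
@given(alt=st.integers(0, 99), cov=st.integers(10, 100))
def test_confidence_monotone_in_alt_and_coverage(alt, cov):
    alt = min(alt, cov - 1)
    c1 = site_confidence(sc(alt, cov - alt))
    c2 = site_confidence(sc(alt + 1, cov - alt - 1))
    assert c2 >= c1 - 1e-12
    # at fixed fraction above the error rate, more coverage -> more confidence
    f = 0.2
    c_lo = site_confidence(sc(int(20 * f), 20 - int(20 * f)))
    c_hi = site_confidence(sc(int(200 * f), 200 - int(200 * f)))
    assert c_hi >= c_lo - 1e-12


class TestCallCandidates:
    def test_empty_pileups_give_empty_result(self):
        assert call_candidate_sites([make_pileup([])] * 3) == []

    def test_three_position_toy(self):
        """One position fails coverage in a replicate, one is SNP-masked,
        one passes all criteria."""
        def rep(cov_at_5):
            return make_pileup([
                ("c", 5, "A", {"A": (cov_at_5 // 2 - 5, cov_at_5 - cov_at_5 // 2 - 5),
                               "G": (5, 5)}),
                ("c", 9, "A", {"A": (20, 20), "G": (10, 10)}),
                ("c", 13, "A", {"A": (20, 20), "G": (10, 10)}),
            ])

        reps = [rep(60), rep(60), rep(19)]  # position 5 underpowered in rep 3
        mask = SiteSet.from_pairs([("c", 9)])
        sites = call_candidate_sites(reps, snp_mask=mask)
        assert [s.pos for s in sites] == [13]
        assert sites[0].fractions == pytest.approx([1 / 3] * 3)

    def test_recovery_and_snp_exclusion(self, small_bundle, small_truth,
                                        small_pileups):
        mask = SiteSet.from_pairs(
            (c, p) for c, p, _, _ in small_bundle.snp_sites)
        sites = call_candidate_sites(
            small_pileups["A"], snp_mask=mask,
            features=small_bundle.feature_intervals(),
        )
        called = {s.key for s in sites}
        assert called & small_bundle.snp_keys() == set()
        truth_keys = small_truth.keys()
        sens = len(called & truth_keys) / len(truth_keys)
        assert sens >= 0.9
        # nothing called outside the planted truth at this error rate
        assert called <= truth_keys

    def test_unmasked_het_snp_gets_allelic_balance_warning(self):
        rows = [("c", 7, "A", {"A": (30, 30), "G": (31, 29)})]
        reps = [make_pileup(rows) for _ in range(3)]
        [site] = call_candidate_sites(reps, snp_mask=None)
        assert site.allelic_balance_warning


class TestEditingIndex:
    def test_hand_built_example(self):
        """(coverage, G reads) = (100,10), (50,5), (50,0) -> 7.5%."""
        pileup = make_pileup([
            ("c", 1, "A", {"A": (45, 45), "G": (5, 5)}),
            ("c", 2, "A", {"A": (23, 22), "G": (3, 2)}),
            ("c", 3, "A", {"A": (25, 25)}),
        ])
        regions = IntervalSet([("c", 0, 10, "+", "alu")])
        [res] = editing_index([pileup], regions, mismatch="AtoG")
        assert res.value == pytest.approx(7.5)
        assert (res.numerator, res.denominator) == (15, 200)

    def test_no_mismatches_all_indices_zero(self):
        pileup = make_pileup([
            ("c", 1, "A", {"A": (10, 10)}),
            ("c", 2, "C", {"C": (10, 10)}),
            ("c", 3, "G", {"G": (10, 10)}),
            ("c", 4, "T", {"T": (10, 10)}),
        ])
        regions = IntervalSet([("c", 0, 10, "+", "r")])
        for res in editing_index([pileup], regions, mismatch="all"):
            assert res.value == 0.0

    def test_minus_strand_pools_antisense(self):
        # T->C on the reference within a minus-strand region reports as AtoG
        pileup = make_pileup([("c", 1, "T", {"T": (40, 40), "C": (10, 10)})])
        regions = IntervalSet([("c", 0, 10, "-", "r")])
        [res] = editing_index([pileup], regions, mismatch="AtoG")
        assert res.value == pytest.approx(20.0)

    def test_matches_brute_force_oracle(self, small_bundle, small_truth,
                                        small_pileups):
        repeats = small_bundle.repeat_intervals()
        if len(repeats) == 0:
            pytest.skip("no repeat regions drawn in fixture bundle")
        pileup = small_pileups["A"][0]
        results = editing_index([pileup], repeats, mismatch="all")
        # oracle: per-position summation over a dict of counts
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for res in results:
            x, y = res.mismatch.split("to")
            num = den = 0
            seen = set()
            for contig, start, end, strand, _ in repeats:
                sub = pileup.df[(pileup.df["contig"] == contig)
                                & (pileup.df["pos"] > start)
                                & (pileup.df["pos"] <= end)]
                for _, row in sub.iterrows():
                    if (contig, row["pos"]) in seen:
                        continue
                    seen.add((contig, row["pos"]))
                    ref = row["ref"] if strand != "-" else comp[row["ref"]]
                    if ref != x:
                        continue
                    yb = y if strand != "-" else comp[y]
                    num += row[f"{yb}_fwd"] + row[f"{yb}_rev"]
                    den += sum(row[f"{b}_{d}"] for b in "ACGT"
                               for d in ("fwd", "rev"))
            assert res.numerator == num and res.denominator == den
            if den:
                assert res.value == pytest.approx(100 * num / den, rel=1e-12)

    def test_invariant_to_row_order_and_region_split(self):
        rows = [("c", i, "A", {"A": (20, 20), "G": (2, 1)}) for i in range(1, 9)]
        pileup = make_pileup(rows)
        whole = IntervalSet([("c", 0, 8, "+", "r")])
        split = IntervalSet([("c", 0, 3, "+", "r1"), ("c", 3, 8, "+", "r2")])
        [r1] = editing_index([pileup], whole, mismatch="AtoG")
        [r2] = editing_index([pileup], split, mismatch="AtoG")
        assert (r1.numerator, r1.denominator) == (r2.numerator, r2.denominator)

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            editing_index([make_pileup([])], IntervalSet([]))

    def test_zero_denominator_undefined(self):
        pileup = make_pileup([("c", 1, "C", {"C": (10, 10)})])
        [res] = editing_index([pileup], IntervalSet([("c", 0, 5, "+", "r")]),
                              mismatch="AtoG")
        assert res.value is None


def test_fraction_estimator_unbiased_at_high_coverage():
    """Mean absolute estimation error < 0.01 at coverage 1000, 500 sites."""
    bundle = synthdata.simulate_reference(
        n_genes=40, length_range=(1500, 2000), snp_density=0.0, seed=31)
    truth = synthdata.simulate_editing_truth(bundle, n_sites=500, seed=32)
    [pileup] = synthdata.simulate_pileups(
        bundle, truth, mean_coverage=1000, error_rate=1e-3,
        n_replicates=1, condition="A", seed=33)
    scs = {s.key: s for s in site_counts(pileup, bundle.feature_intervals())}
    errors = []
    for s in truth.sites:
        est = editing_fraction(scs[(s["contig"], s["pos"])])
        errors.append(est - s["fractions"]["A"])
    assert len(errors) == 500
    # unbiasedness: the signed errors average out well below a percentage
    # point; per-site |error| is bounded by binomial sampling noise
    assert abs(np.mean(errors)) < 0.01
    assert np.mean(np.abs(errors)) < 0.02
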