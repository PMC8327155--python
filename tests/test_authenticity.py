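"""Damage profiles, degradation scores, -delta%, coverage, screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coproscope import authenticity as au


def read(codes, ed=None):
    codes = list(codes)
    n_mm = sum(1 for c in codes if len(c) == 2 and c[0] != c[1])
    return au.ReadRecord(length=60, strand="+", five_prime=codes,
                         edit_distance=ed if ed is not None else n_mm)


class TestDamageProfile:
    def test_direct_counts(self):
        reads = [read(["CT"] + ["AA"] * 9)] * 30 + \
                [read(["CC"] + ["AA"] * 9)] * 70
        prof = au.fit_damage_profile(reads)
        assert prof.rates[0] == pytest.approx(0.30)
        assert prof.c_sites[0] == 100
        assert np.isnan(prof.rates[1])      # no C sites at position 2

    def test_all_match_gives_zero(self):
        prof = au.fit_damage_profile([read(["CC"] * 10)] * 5)
        np.testing.assert_allclose(prof.rates, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            au.fit_damage_profile([])

    def test_simulated_decay_recovered(self):
        from coproscope.simulate import DamageSimSpec, simulate_reads
        reads = simulate_reads(DamageSimSpec(n_reads=50_000, p0=0.3, lam=0.5,
                                             baseline=0.01, seed=11))
        prof = au.fit_damage_profile(reads)
        assert prof.rates[0] == pytest.approx(0.31, abs=0.01)
        p0, lam = au.fit_damage_decay(prof, baseline=0.01)
        assert p0 == pytest.approx(0.3, rel=0.2)
        assert lam == pytest.approx(0.5, rel=0.2)


class TestDegradationScore:
    def test_single_mismatch_closed_form(self):
        prof = au.DamageProfile(rates=np.full(10, 0.3),
                                c_sites=np.full(10, 1))
        s = au.degradation_score(read(["CT"] + ["AA"] * 9), prof, 0.01)
        assert s == pytest.approx(math.log(0.3 / 0.01), abs=1e-9)

    def test_no_c_sites_scores_zero(self):
        prof = au.DamageProfile(rates=np.full(10, 0.3),
                                c_sites=np.full(10, 1))
        assert au.degradation_score(read(["AA"] * 10), prof, 0.01) == 0.0

    def test_profile_equal_baseline_scores_zero(self):
        prof = au.DamageProfile(rates=np.full(10, 0.01),
                                c_sites=np.full(10, 1))
        for r in (read(["CT"] * 3 + ["CC"] * 7), read(["CC"] * 10)):
            assert au.degradation_score(r, prof, 0.01) == pytest.approx(0.0)

    def test_additive_and_antisymmetric(self):
        prof = au.DamageProfile(rates=np.full(10, 0.3),
                                c_sites=np.full(10, 1))
        s1 = au.degradation_score(read(["CT"] + ["AA"] * 9), prof, 0.01)
        s2 = au.degradation_score(read(["AA", "CT"] + ["AA"] * 8), prof, 0.01)
        s12 = au.degradation_score(read(["CT", "CT"] + ["AA"] * 8), prof, 0.01)
        assert s12 == pytest.approx(s1 + s2)
        # swapping model and null flips the sign
        swapped = au.DamageProfile(rates=np.full(10, 0.01),
                                   c_sites=np.full(10, 1))
        s_swap = au.degradation_score(read(["CT"] + ["AA"] * 9), swapped, 0.3)
        assert s_swap == pytest.approx(-s1)

    def test_invalid_baseline(self):
        prof = au.DamageProfile(rates=np.full(10, 0.3),
                                c_sites=np.full(10, 1))
        with pytest.raises(ValueError):
            au.degradation_score(read(["CC"] * 10), prof, 0.0)

    def test_damaged_fraction_monotone_in_amplitude(self):
        from coproscope.simulate import DamageSimSpec, simulate_reads
        fracs = []
        for p0 in (0.0, 0.1, 0.3):
            reads = simulate_reads(DamageSimSpec(n_reads=4000, p0=p0,
                                                 lam=0.5, seed=3))
            prof = au.fit_damage_profile(reads)
            fracs.append(np.mean([au.degradation_score(r, prof, 0.01) > 1
                                  for r in reads]))
        assert fracs[0] < fracs[1] < fracs[2]


class TestNegativeDifferenceProportion:
    @pytest.mark.parametrize("hist,expected", [
        ([10, 5, 2, 1], 1.0),
        ([1, 2, 3], 0.0),
        ([5, 7, 3, 4], 4 / 7),
    ])
    def test_examples(self, hist, expected):
        assert au.negative_difference_proportion(hist) == \
            pytest.approx(expected, abs=1e-12)

    def test_flat_histogram_warns_zero(self):
        with pytest.warns(UserWarning):
            assert au.negative_difference_proportion([3, 3, 3]) == 0.0

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            au.negative_difference_proportion([5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=12))
    def test_bounds_and_extremes(self, hist):
        if all(a == b for a, b in zip(hist, hist[1:])):
            return      # flat case covered separately
        v = au.negative_difference_proportion(hist)
        assert 0.0 <= v <= 1.0
        diffs = [a - b for a, b in zip(hist, hist[1:])]
        if all(d >= 0 for d in diffs) and any(d > 0 for d in diffs):
            assert v == 1.0
        if all(d <= 0 for d in diffs) and any(d < 0 for d in diffs):
            assert v == 0.0


class TestCoverage:
    @pytest.mark.parametrize("depths,length,expected", [
        ([1] * 100, 1000, (0.1, 10.0)),
        ([], 500, (0.0, 0.0)),
        ([2] * 50, 50, (2.0, 100.0)),
    ])
    def test_examples(self, depths, length, expected):
        assert au.coverage_stats(depths, length) == \
            pytest.approx(expected)

    def test_bad_genome_length(self):
        with pytest.raises(ValueError):
            au.coverage_stats([1], 0)


class TestScreening:
    def test_published_bacterial_row_passes(self):
        s = au.TaxonSummary("Bifidobacterium adolescentis", reads=790,
                            pmds_gt1_reads=177, ct5_pct=10.1, neg_delta=1.0)
        assert au.screen_taxon(s, au.BACTERIAL_RULES).passed

    def test_failing_reads_names_reason(self):
        s = au.TaxonSummary("x", reads=400, pmds_gt1_reads=177,
                            ct5_pct=10.1, neg_delta=1.0)
        res = au.screen_taxon(s, au.BACTERIAL_RULES)
        assert not res.passed and res.reasons == ("reads",)

    def test_published_dietary_row_passes(self):
        s = au.TaxonSummary("Ovis aries", reads=214, ct5_pct=11.7,
                            neg_delta=1.0)
        assert au.screen_taxon(s, au.DIETARY_RULES).passed

    def test_missing_pmds_field_under_bacterial_rules(self):
        s = au.TaxonSummary("x", reads=900, ct5_pct=10.0, neg_delta=1.0)
        with pytest.raises(ValueError, match="PMDS"):
            au.screen_taxon(s, au.BACTERIAL_RULES)

    def test_all_56_published_rows_pass_bacterial_screen(self):
        rows = au.load_solarolo_bacterial_table()
        assert len(rows) == 56
        results = [au.screen_taxon(r, au.BACTERIAL_RULES) for r in rows]
        assert all(r.passed for r in results)

    def test_all_published_dietary_rows_pass(self):
        rows = au.load_solarolo_dietary_table()
        assert len(rows) == 3
        assert all(au.screen_taxon(r, au.DIETARY_RULES).passed for r in rows)

    def test_row_at_exact_pmds_bound_passes(self):
        # one published row sits exactly at 50 damage-supporting reads
        rows = {r.taxon: r for r in au.load_solarolo_bacterial_table()}
        r = rows["Lactobacillus acidophilus"]
        assert r.pmds_gt1_reads == 50
        assert au.screen_taxon(r, au.BACTERIAL_RULES).passed


def test_read_records_tsv_round_trip(tmp_path):
    from coproscope.simulate import DamageSimSpec, simulate_reads
    reads = simulate_reads(DamageSimSpec(n_reads=50, seed=5))
    p = tmp_path / "reads.tsv"
    au.write_records_tsv(reads, p)
    back = au.read_records_tsv(p)
    assert len(back) == 50
    assert all(a.five_prime == b.five_prime and
               a.edit_distance == b.edit_distance
               for a, b in zip(reads, back))
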