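"""Tests for the cohort statistics pipeline against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from erykal import (
    CohortConfig,
    CohortTable,
    DomainError,
    MeasurementRecord,
    analyze_cohort,
    correlation_screen,
    derived_panel,
    filter_spikes,
    generate_cohort,
    histogram_bins,
    spearman,
    summarize,
    trajectory,
)
from erykal.simulate import forward_hemolysate


def spearman_oracle(x, y):
    """Independent rho: explicit average-rank construction + Pearson on ranks."""
    def avg_ranks(a):
        a = np.asarray(a, dtype=float)
        order = np.argsort(a, kind="stable")
        ranks = np.empty(len(a))
        i = 0
        sorted_a = a[order]
        while i < len(a):
            j = i
            while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestFilterSpikes:
    def test_documented_extremes(self):
        # raw extremes 50.4 and 240.0 are spikes; 120 stays
        kept, rep = filter_spikes([50.4, 120.0, 240.0])
        assert list(kept) == [120.0]
        assert (rep.n_input, rep.n_spikes, rep.n_kept) == (3, 2, 1)
        assert tuple(rep.spike_indices) == (0, 2)

    def test_inclusive_bounds(self):
        kept, rep = filter_spikes([60.0, 210.0])
        assert rep.n_spikes == 0 and list(kept) == [60.0, 210.0]

    def test_empty(self):
        kept, rep = filter_spikes([])
        assert (rep.n_input, rep.n_spikes, rep.n_kept) == (0, 0, 0)
        assert len(kept) == 0

    def test_bad_thresholds(self):
        with pytest.raises(DomainError):
            filter_spikes([100.0], lo=210, hi=60)

    @given(st.lists(st.floats(0, 300), max_size=40))
    def test_partition(self, values):
        """Kept and spikes partition the input: disjoint, exhaustive, ordered."""
        s = pd.Series(values)
        kept, rep = filter_spikes(s)
        assert rep.n_kept + rep.n_spikes == rep.n_input == len(values)
        assert set(kept.index).isdisjoint(rep.spike_indices)
        assert sorted(list(kept.index) + list(rep.spike_indices)) == list(range(len(values)))
        assert list(kept.index) == sorted(kept.index)  # input order preserved
        assert ((kept >= rep.lo) & (kept <= rep.hi)).all()


class TestSummarize:
    def test_constant_series(self):
        s = summarize([100.0, 100.0, 100.0])
        assert (s.mean, s.sd, s.median) == (100.0, 0.0, 100.0)

    def test_two_values(self):
        s = summarize([90.0, 110.0])
        assert (s.mean, s.median, s.min, s.max) == (100.0, 100.0, 90.0, 110.0)

    def test_single_value_sd_undefined(self):
        assert summarize([5.0]).sd is None

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            summarize([])

    def test_quartiles_linear_interpolation(self):
        # hand-computed type-7 quartiles on a 5-element set
        s = summarize([1.0, 2.0, 3.0, 4.0, 10.0])
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
        s2 = summarize([1.0, 2.0, 3.0, 4.0])
        assert s2.q1 == pytest.approx(1.75)
        assert s2.q3 == pytest.approx(3.25)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=60))
    def test_textbook_mean_sd(self, values):
        a = np.asarray(values)
        s = summarize(a)
        mean = sum(values) / len(values)
        sd = (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
        assert s.mean == pytest.approx(mean, rel=1e-12, abs=1e-9)
        assert s.sd == pytest.approx(sd, rel=1e-9, abs=1e-9)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


class TestSpearman:
    def test_perfect_inversion(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == -1.0

    def test_perfect_agreement(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]).rho == 1.0

    def test_constant_series_degenerate(self):
        r = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert r.degenerate and r.rho is None and r.p_value is None

    def test_too_short(self):
        with pytest.raises(DomainError):
            spearman([1, 2], [2, 1])

    def test_pairwise_complete_deletion(self):
        r = spearman([1, 2, 3, np.nan, 5], [5, 4, 3, 2, np.nan])
        assert r.n == 3  # rows with a NaN in either series are dropped
        assert r.rho == -1.0

    def test_too_few_complete_pairs(self):
        with pytest.raises(DomainError):
            spearman([1, 2, np.nan, 4], [1, 2, 3, np.nan])

    def test_exact_permutation_small_n(self):
        r = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4], method="exact")
        # P(|rho| >= 0.9) over all 120 permutations of n=5
        assert r.p_value == pytest.approx(1 / 12)

    def test_exact_refused_for_large_n(self):
        x = list(range(12))
        with pytest.raises(DomainError):
            spearman(x, x, method="exact")

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=50),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_oracle(self, x, seed):
        y = np.random.default_rng(seed).permutation(len(x)).astype(float)
        xs = np.asarray(x)
        if np.all(xs == xs[0]):
            return
        r = spearman(xs, y)
        assert r.rho == pytest.approx(spearman_oracle(xs, y), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)


class TestCorrelationScreen:
    def test_constant_chloride_gives_exact_minus_one(self, rng):
        """With Cl fixed, K_er.exc and pK_er are strictly monotone images of
        K_er, so their rank correlation is -1 exactly."""
        k_er = rng.uniform(61, 209, size=50)
        _, exc, pk = derived_panel(k_er, 100.0)
        df = pd.DataFrame({"k_hem": 0.0, "k_pl": 0.0, "ht": 40.0,
                           "k_er_exc": exc, "p_k_er": pk})
        res = correlation_screen(CohortTable(df), [("k_er_exc", "p_k_er")])
        assert res[0].rho == -1.0

    def test_unknown_variable_lists_columns(self):
        table = generate_cohort(CohortConfig(n=10, seed=0)).with_panels()
        with pytest.raises(DomainError, match="available"):
            correlation_screen(table, [("k_er", "nope")])

    def test_short_table_flagged(self):
        table = generate_cohort(CohortConfig(n=2, seed=0)).with_panels()
        res = correlation_screen(table, [("k_er", "k_pl")])
        assert res[0].degenerate and res[0].rho is None


class TestHistogram:
    def test_documented_bins(self):
        df = histogram_bins([61.0, 61.0, 75.0], bin_width=10.0)
        assert list(df["left"]) == [60.0, 70.0]
        assert list(df["count"]) == [2, 1]

    def test_counts_sum_to_n(self, rng):
        values = rng.uniform(60, 210, 500)
        df = histogram_bins(values, 5.0)
        assert df["count"].sum() == 500

    def test_empty(self):
        assert len(histogram_bins([], 10.0)) == 0

    def test_skewed_cohort_mean_above_median(self, default_cohort):
        """The synthetic K_er distribution is right-tailed: mean > median."""
        out = analyze_cohort(default_cohort)
        s = out["stats"]["k_er"]
        assert s.mean > s.median


class TestTrajectory:
    @staticmethod
    def _patient_table(k_series, pid="icu1"):
        recs = []
        for day, k_er in k_series:
            recs.append(
                MeasurementRecord(
                    k_hem=forward_hemolysate(k_er, 4.0, 40.0),
                    k_pl=4.0, ht=40.0, cl=100.0, patient_id=pid, time=day,
                )
            )
        return CohortTable.from_records(recs).with_panels()

    def test_improving_patient_deltas_negative(self):
        # peritonitis-style course: K_er falls on days 1, 3, 5 with improvement
        table = self._patient_table([(1, 180.0), (3, 150.0), (5, 120.0)])
        traj = trajectory(table, "icu1")
        assert list(traj["time"]) == [1.0, 3.0, 5.0]
        assert (traj["delta_k_er"].dropna() < 0).all()

    def test_single_timepoint(self):
        traj = trajectory(self._patient_table([(1, 100.0)]), "icu1")
        assert len(traj) == 1 and traj["delta_k_er"].isna().all()

    def test_deficit_recovery_band_transition(self):
        # pump-depression course: 55 -> 92 mmol/L crosses into the normal band
        traj = trajectory(self._patient_table([(1, 55.0), (3, 92.0)]), "icu1")
        assert list(traj["band"]) == ["deficit", "normal"]

    def test_unknown_patient(self):
        with pytest.raises(DomainError, match="unknown patient"):
            trajectory(self._patient_table([(1, 100.0)]), "ghost")


class TestAnalyzeCohort:
    def test_bookkeeping_and_headline_stats(self, default_cohort):
        out = analyze_cohort(default_cohort)
        rep = out["filter"]
        assert (rep.n_input, rep.n_spikes, rep.n_kept) == (370, 14, 356)
        s = out["stats"]["k_er"]
        # at n=356 the standard error of the mean is 26.8/sqrt(356) ~ 1.42,
        # so recovery is checked to 3 standard errors (tighter bands belong
        # to the n=1000 calibration tests)
        assert s.mean == pytest.approx(125.1, abs=3 * 26.8 / 356**0.5)
        assert s.sd == pytest.approx(26.8, abs=3.0)

    def test_empty_table(self):
        out = analyze_cohort(generate_cohort(CohortConfig(n=0, seed=0)))
        assert out["filter"].n_input == 0 and out["correlations"] == []
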