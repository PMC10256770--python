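"""Creatinine landmarks, weight normalization, longitudinal and rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cryobank.outcomes import (
    LabSeries,
    OutcomesError,
    creatinine_summary,
    lab_series_to_long,
    long_to_lab_series,
    longitudinal_compare,
    normalize_weight,
    storage_correlation,
    summarize,
)
from cryobank.synthetic import gen_transplant_labs


def make_series(creatinine, weight=None, days=None, group="nanowarmed",
                storage=10.0):
    days = days if days is not None else list(range(-1, len(creatinine) - 1))
    data = {"creatinine": creatinine}
    if weight is not None:
        data["weight"] = weight
    return LabSeries(
        animal_id="r1", group=group,
        data=pd.DataFrame(data, index=pd.Index(days, name="day")),
        storage_days=storage,
    )


class TestCreatinineSummary:
    def test_constant_series(self):
        s = make_series([0.5] * 10)
        cs = creatinine_summary(s)
        assert cs.peak_value == 0.5
        assert cs.peak_day == -1
        assert cs.first_day_below == -1  # first recorded day
        assert cs.terminal_value == 0.5

    def test_peaked_trajectory_landmarks(self):
        """Peak 4.0 on day 3, crossing 2.0 on day 19 -> (4.0, 3, 19)."""
        days = np.arange(-1, 31)
        cr = np.where(
            days <= 0, 0.5,
            np.where(days <= 3, 0.5 + (4.0 - 0.5) * days / 3,
                     4.0 * np.exp(-(days - 3) * np.log(2.0) / 15.9)),
        )
        s = make_series(cr.tolist(), days=days.tolist())
        cs = creatinine_summary(s, threshold=2.0)
        assert cs.peak_value == pytest.approx(4.0)
        assert cs.peak_day == 3
        assert cs.first_day_below == 19

    def test_never_normalizing_series(self):
        s = make_series([1.0, 2.0, 3.0, 4.0, 5.0])
        assert creatinine_summary(s, threshold=2.0).first_day_below is None

    def test_infinite_threshold_returns_peak_day(self):
        s = make_series([0.5, 1.0, 4.0, 3.0, 2.5])
        cs = creatinine_summary(s, threshold=float("inf"))
        assert cs.first_day_below == cs.peak_day


class TestNormalizeWeight:
    def test_constant_weight(self):
        s = make_series([0.5] * 5, weight=[500.0] * 5)
        assert np.allclose(normalize_weight(s).to_numpy(), 1.0)

    def test_ten_percent_gain(self):
        s = make_series([0.5] * 12, weight=[500.0] * 11 + [550.0])
        assert normalize_weight(s).iloc[-1] == pytest.approx(1.10)

    def test_missing_baseline_rejected(self):
        s = make_series([0.5] * 5)
        s.data["weight"] = [np.nan, 500, 500, 500, 500]
        with pytest.raises(OutcomesError):
            normalize_weight(s)

    def test_baseline_ratio_is_one(self):
        labs = gen_transplant_labs("nanowarmed", n_animals=2, seed=0)
        for s in labs:
            assert normalize_weight(s).loc[-1] == pytest.approx(1.0)


class TestLongitudinalCompare:
    def group(self, values, group="a"):
        return [
            make_series([v, v], days=[-1, 0], group=group) for v in values
        ]

    def test_identical_groups(self):
        a = self.group([1.0, 2.0, 3.0, 4.0])
        r = longitudinal_compare(a, a, day=0, variable="creatinine")
        assert r.pvalue > 0.95

    def test_exact_wilcoxon_enumeration(self):
        """{1,2,3} vs {4,5,6}: exact two-sided p = 0.1, verified by brute
        force over all C(6,3) = 20 rank assignments."""
        a = self.group([1.0, 2.0, 3.0])
        b = self.group([4.0, 5.0, 6.0], group="b")
        r = longitudinal_compare(a, b, day=0, variable="creatinine")
        assert r.test == "wilcoxon"
        assert r.pvalue == pytest.approx(0.1, abs=1e-12)

        # independent enumeration of the null distribution of the rank sum
        ranks = range(1, 7)
        observed = 1 + 2 + 3
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        mean_sum = np.mean(sums)
        extreme = sum(
            abs(s - mean_sum) >= abs(observed - mean_sum) for s in sums
        )
        assert extreme / len(sums) == pytest.approx(0.1)

    def test_separated_ttest(self, rng):
        a = [make_series([v, v], days=[-1, 0]) for v in rng.normal(0, 1, 5)]
        b = [make_series([v, v], days=[-1, 0]) for v in rng.normal(3, 1, 5)]
        r = longitudinal_compare(a, b, day=0, variable="creatinine", test="ttest")
        assert r.test == "ttest"
        assert r.pvalue < 0.01

    def test_variable_map_routes_potassium_to_ttest(self):
        a = self.group([1.0, 2.0])
        for s in a:
            s.data["potassium"] = [4.0, 4.5]
        r = longitudinal_compare(a, a, day=0, variable="potassium")
        assert r.test == "ttest"

    def test_symmetry_in_group_order(self, rng):
        a = self.group(rng.normal(0, 1, 6).tolist())
        b = self.group(rng.normal(1, 1, 6).tolist(), group="b")
        r1 = longitudinal_compare(a, b, day=0, variable="creatinine")
        r2 = longitudinal_compare(b, a, day=0, variable="creatinine")
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_empty_group_rejected(self):
        a = self.group([1.0, 2.0])
        with pytest.raises(OutcomesError):
            longitudinal_compare(a, a, day=5, variable="creatinine")


class TestStorageCorrelation:
    def test_concordant(self):
        r = storage_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.tau == pytest.approx(1.0)

    def test_discordant(self):
        r = storage_correlation([1, 2, 3, 4], [40, 30, 20, 10])
        assert r.tau == pytest.approx(-1.0)

    def test_three_pair_fixture_brute_force(self):
        """{(1,2),(2,1),(3,3)}: tau = 1/3 by direct pair enumeration."""
        x, y = [1, 2, 3], [2, 1, 3]
        r = storage_correlation(x, y)
        conc = disc = 0
        for i, j in itertools.combinations(range(3), 2):
            s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
            conc += s > 0
            disc += s < 0
        assert (conc - disc) / 3 == pytest.approx(1 / 3)
        assert r.tau == pytest.approx(1 / 3)

    def test_constant_input_flagged(self):
        r = storage_correlation([5, 5, 5], [1, 2, 3])
        assert r.degenerate
        assert np.isnan(r.tau)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(OutcomesError):
            storage_correlation([1, 2], [1, 2])


class TestSyntheticCohortProperties:
    def test_early_significant_late_not(self):
        """Synthetic cohorts (control vs nanowarmed, n = 5 each): creatinine
        differs strongly on early days and is not significantly different
        from day 14 onward, in >= 90% of seeded replicates."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            ctrl = gen_transplant_labs("control", n_animals=5, seed=seed)
            nano = gen_transplant_labs("nanowarmed", n_animals=5, seed=1000 + seed)
            early = longitudinal_compare(ctrl, nano, day=3, variable="creatinine")
            late = [
                longitudinal_compare(ctrl, nano, day=d, variable="creatinine")
                for d in (28, 30)
            ]
            hits += early.pvalue < 0.05 and all(t.pvalue > 0.05 for t in late)
        assert hits / n_rep >= 0.9

    def test_no_storage_correlation_in_generator(self):
        """Storage duration is drawn independently of outcome severity, so
        Kendall correlations with creatinine landmarks are weak."""
        nano = gen_transplant_labs("nanowarmed", n_animals=10, seed=3)
        peaks = [creatinine_summary(s).peak_value for s in nano]
        storage = [s.storage_days for s in nano]
        r = storage_correlation(storage, peaks)
        assert abs(r.tau) < 0.6

    def test_summarize_bundles_egfr(self):
        s = gen_transplant_labs("control", n_animals=1, seed=0)[0]
        out = summarize(s, egfr=lambda series: 2.0)
        assert out.egfr_mL_min == 2.0
        assert out.weight_ratio.loc[-1] == pytest.approx(1.0)


def test_long_csv_round_trip(tmp_path):
    series = gen_transplant_labs("nanowarmed", n_animals=2, seed=4)
    df = lab_series_to_long(series)
    path = tmp_path / "labs.csv"
    df.to_csv(path, index=False)
    back = long_to_lab_series(pd.read_csv(path))
    assert len(back) == 2
    orig = {s.animal_id: s for s in series}
    for s in back:
        o = orig[s.animal_id]
        assert s.storage_days == o.storage_days
        pd.testing.assert_series_equal(
            s.data["creatinine"], o.data["creatinine"], check_names=False,
            check_index_type=False,
        )
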