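import numpy as np
import pandas as pd
import pytest

from ecfctox import nested_ss, build_table, percentages_from_ss, load_variance_component_table


def _obs(groups):
    """groups: {donor: {clone: [values]}} → observation frame."""
    rows = [(d, c, v) for d, clones in groups.items()
            for c, vals in clones.items() for v in vals]
    return pd.DataFrame(rows, columns=["donor_id", "clone_id", "ic_value"])


def _random_nested(rng, balanced=True):
    groups = {}
    for d in range(rng.integers(2, 5)):
        clones = {}
        n_clones = 2 if balanced else rng.integers(1, 4)
        for c in range(n_clones):
            n_obs = 3 if balanced else rng.integers(1, 5)
            clones[f"d{d}c{c}"] = rng.normal(d, 1.0, size=n_obs).tolist()
        groups[f"d{d}"] = clones
    return _obs(groups)


def _statsmodels_sequential(obs):
    """Independent oracle: sequential RSS reductions of nested OLS fits."""
    import statsmodels.formula.api as smf
    df = obs.copy()
    y = df["ic_value"].to_numpy()
    tss = float(((y - y.mean()) ** 2).sum())
    rss_d = float(smf.ols("ic_value ~ C(donor_id)", df).fit().ssr)
    rss_dc = float(smf.ols("ic_value ~ C(donor_id) + C(clone_id)", df).fit().ssr)
    return tss - rss_d, rss_d - rss_dc, rss_dc


class TestNestedSS:
    def test_hand_computed_example(self):
        obs = _obs({"D1": {"c1": [1, 3], "c2": [2, 4]},
                    "D2": {"c3": [5, 7], "c4": [6, 8]}})
        row = nested_ss(obs)
        assert row.ss_donor == pytest.approx(32.0)
        assert row.ss_clone == pytest.approx(2.0)
        assert row.ss_within == pytest.approx(8.0)
        y = obs["ic_value"].to_numpy()
        assert row.ss_total == pytest.approx(((y - 4.5) ** 2).sum())
        assert (row.pct_donor, row.pct_clone, row.pct_within) == (
            pytest.approx(76.19, abs=0.01), pytest.approx(4.76, abs=0.01),
            pytest.approx(19.05, abs=0.01))

    def test_all_equal_flagged_with_zero_percentages(self):
        obs = _obs({"D1": {"c1": [2, 2]}, "D2": {"c2": [2, 2]}})
        row = nested_ss(obs)
        assert row.all_equal
        assert row.pct_donor == row.pct_clone == row.pct_within == 0.0

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError, match="2 donors"):
            nested_ss(_obs({"D1": {"c1": [1, 2], "c2": [3, 4]}}))

    def test_clone_in_two_donors_rejected(self):
        obs = pd.DataFrame({"donor_id": ["D1", "D2"], "clone_id": ["c1", "c1"],
                            "ic_value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="more than one donor"):
            nested_ss(obs)

    @pytest.mark.parametrize("balanced", [True, False])
    def test_conservation_and_oracle_equivalence(self, balanced):
        rng = np.random.default_rng(42 if balanced else 43)
        for _ in range(25):
            obs = _random_nested(rng, balanced=balanced)
            if obs["donor_id"].nunique() < 2:
                continue
            row = nested_ss(obs)
            y = obs["ic_value"].to_numpy()
            tss = ((y - y.mean()) ** 2).sum()
            assert row.ss_total == pytest.approx(tss, rel=1e-9)
            sd, sc, sw = _statsmodels_sequential(obs)
            assert row.ss_donor == pytest.approx(sd, rel=1e-8, abs=1e-9)
            assert row.ss_clone == pytest.approx(sc, rel=1e-8, abs=1e-9)
            assert row.ss_within == pytest.approx(sw, rel=1e-8, abs=1e-9)

    def test_clone_relabel_within_donor_keeps_donor_ss(self):
        rng = np.random.default_rng(9)
        obs = _random_nested(rng)
        row1 = nested_ss(obs)
        swapped = obs.copy()
        # swap two clone labels inside the first donor
        d0 = swapped["donor_id"].iloc[0]
        clones = swapped.loc[swapped["donor_id"] == d0, "clone_id"].unique()
        if len(clones) >= 2:
            mapping = {clones[0]: clones[1], clones[1]: clones[0]}
            swapped.loc[swapped["donor_id"] == d0, "clone_id"] = (
                swapped.loc[swapped["donor_id"] == d0, "clone_id"]
                .map(lambda c: mapping.get(c, c)))
        row2 = nested_ss(swapped)
        assert row2.ss_donor == pytest.approx(row1.ss_donor, rel=1e-12)


class TestPercentages:
    def test_reference_menadione_shares(self):
        ref = load_variance_component_table()
        r = ref[(ref.chemical == "Menadione") & (ref.level == 10)].iloc[0]
        pd_, pc_, pw_, flag = percentages_from_ss(r.ss_donor, r.ss_clone, r.ss_within)
        assert pd_ == pytest.approx(43.3, abs=0.05)
        assert pc_ == pytest.approx(26.3, abs=0.05)
        assert not flag

    def test_shares_sum_to_hundred(self):
        ref = load_variance_component_table()
        for r in ref.itertuples():
            pd_, pc_, pw_, _ = percentages_from_ss(r.ss_donor, r.ss_clone, r.ss_within)
            assert pd_ + pc_ + pw_ == pytest.approx(100.0, abs=1e-9)


class TestBuildTable:
    def test_row_count_and_flags(self):
        rng = np.random.default_rng(3)
        recs = []
        for chem in ["A", "B"]:
            for lv in range(10, 100, 10):
                for d in ["D1", "D2"]:
                    for c in ["1", "2"]:
                        for day in [1, 2, 3]:
                            recs.append((d, f"{d}c{c}", chem, day, lv,
                                         rng.lognormal(), True))
        ic_long = pd.DataFrame(recs, columns=["donor_id", "clone_id", "chemical",
                                              "day", "level", "ic_um", "defined"])
        table = build_table(ic_long, chemicals=["A", "B"])
        assert len(table) == 18
        assert not table["incomplete"].any()
        assert set(table["largest"]) <= {"donor", "clone", "days"}

    def test_undefined_rows_excluded_and_flagged(self):
        recs = []
        for d in ["D1", "D2"]:
            for day in [1, 2]:
                recs.append((d, f"{d}c1", "A", day, 10, 1.0 + (d == "D2"), d == "D1" or day == 1))
        ic_long = pd.DataFrame(recs, columns=["donor_id", "clone_id", "chemical",
                                              "day", "level", "ic_um", "defined"])
        table = build_table(ic_long, chemicals=["A"], levels=(10,))
        assert len(table) == 1
        assert table.iloc[0]["n_obs"] == 3
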