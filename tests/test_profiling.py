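import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clppkit.plate_io import GROUP_NAMES, default_catalog
from clppkit.profiling import (
    aggregate_groups,
    group_summary,
    minmax_normalize,
    scale_to_baseline,
)


def auc_table(values=None, sample_id="S1-d0", day=0, reactor=1):
    cat = default_catalog()
    if values is None:
        values = {n: 1.0 for n in cat.names}
    return pd.DataFrame(
        [
            dict(
                sample_id=sample_id, reactor_id=reactor, treatment="aerobic",
                day=day, matrix="solid", substrate=n, auc=v, imputed=False,
            )
            for n, v in values.items()
        ]
    )


class TestAggregateGroups:
    def test_unit_aucs_give_group_sizes(self):
        out = aggregate_groups(auc_table())
        acts = dict(zip(out["group"], out["activity"]))
        assert acts == {
            "amines": 2.0, "amino_acids": 6.0, "carbohydrates": 10.0,
            "carboxylic_acids": 9.0, "polymers": 4.0,
        }

    def test_zero_aucs_give_zero_groups(self):
        cat = default_catalog()
        out = aggregate_groups(auc_table({n: 0.0 for n in cat.names}))
        assert (out["activity"] == 0.0).all()

    def test_random_aucs_match_membership_list_oracle(self):
        rng = np.random.default_rng(3)
        cat = default_catalog()
        values = {n: float(rng.uniform(0, 50)) for n in cat.names}
        out = aggregate_groups(auc_table(values))
        membership = dict(cat.entries)
        for g in GROUP_NAMES:
            expected = sum(v for n, v in values.items() if membership[n] == g)
            got = float(out.loc[out["group"] == g, "activity"].iloc[0])
            assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_substrate_is_hard_error(self):
        t = auc_table()
        t = t[t["substrate"] != "Glycogen"]
        with pytest.raises(ValueError, match="Glycogen"):
            aggregate_groups(t)

    def test_aggregation_linearity(self):
        rng = np.random.default_rng(4)
        cat = default_catalog()
        x = {n: float(rng.uniform(0, 5)) for n in cat.names}
        y = {n: float(rng.uniform(0, 5)) for n in cat.names}
        both = {n: x[n] + y[n] for n in cat.names}
        ax = aggregate_groups(auc_table(x))["activity"].to_numpy()
        ay = aggregate_groups(auc_table(y))["activity"].to_numpy()
        axy = aggregate_groups(auc_table(both))["activity"].to_numpy()
        assert axy == pytest.approx(ax + ay)


def series_table(activities, group="carbohydrates", reactor=1):
    days = [0, 57, 114][: len(activities)]
    return pd.DataFrame(
        [
            dict(
                sample_id=f"S{reactor}-d{d}", reactor_id=reactor, treatment="aerobic",
                day=d, matrix="solid", group=group, activity=a,
            )
            for d, a in zip(days, activities)
        ]
    )


class TestScaleToBaseline:
    def test_series_divided_by_day0(self):
        out = scale_to_baseline(series_table([4.0, 2.0, 1.0]))
        assert list(out["scaled"]) == pytest.approx([1.0, 0.5, 0.25])

    def test_zero_baseline_gives_missing(self):
        out = scale_to_baseline(series_table([0.0, 2.0, 1.0]))
        assert out["scaled"].isna().all()

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scaling_is_unit_free(self, c):
        base = series_table([4.0, 2.0, 1.0])
        scaled_c = scale_to_baseline(base.assign(activity=base["activity"] * c))
        assert scaled_c["scaled"].to_numpy() == pytest.approx([1.0, 0.5, 0.25])


class TestMinmaxNormalize:
    def test_examples(self):
        t = pd.DataFrame({"variable": "x", "value": [2.0, 4.0, 6.0]})
        out = minmax_normalize(t, "value")
        assert list(out["x_norm"]) == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_variable_is_error(self):
        t = pd.DataFrame({"variable": "x", "value": [3.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(t, "value")

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        values=st.lists(
            st.integers(-1000, 1000).map(float), min_size=3, max_size=12, unique=True
        ),
    )
    @settings(max_examples=60, deadline=None)
    def test_affine_invariance_and_bounds(self, a, b, values):
        t = pd.DataFrame({"variable": "x", "value": values})
        base = minmax_normalize(t, "value")["x_norm"].to_numpy()
        shifted = minmax_normalize(t.assign(value=t["value"] * a + b), "value")[
            "x_norm"
        ].to_numpy()
        assert shifted == pytest.approx(base, abs=1e-9)
        assert base.min() == 0.0 and base.max() == 1.0
        assert ((base >= 0) & (base <= 1)).all()


class TestGroupSummary:
    def frame(self, values):
        return pd.DataFrame(
            dict(
                treatment="aerobic", day=763, group="amines",
                scaled=values, matrix="solid",
            )
        )

    def test_equal_values_zero_se(self):
        out = group_summary(self.frame([2.0, 2.0, 2.0]))
        assert out["se"].iloc[0] == 0.0

    def test_hand_computed_se(self):
        out = group_summary(self.frame([1.0, 2.0, 3.0]))
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["se"].iloc[0] == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-3)

    def test_design_n_conventions(self, noiseless_run):
        scaled = noiseless_run.result.scaled
        solids = scaled[scaled["matrix"] == "solid"]
        pooled = group_summary(solids, by=("day", "group"))
        n_by_day = pooled.groupby("day")["n"].max()
        assert n_by_day[0] == 9
        assert n_by_day[57] == 6 and n_by_day[114] == 6 and n_by_day[358] == 6
        per_treatment = group_summary(solids, by=("treatment", "day", "group"))
        final = per_treatment[per_treatment["day"] == 763]
        assert set(final["n"]) == {3}


def test_carbohydrates_collapse_below_5_percent_of_baseline(noiseless_run):
    scaled = noiseless_run.result.scaled
    carbs = scaled[
        (scaled["group"] == "carbohydrates")
        & (scaled["matrix"] == "solid")
        & (scaled["day"] == 763)
    ]
    assert carbs["scaled"].mean() < 0.05
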