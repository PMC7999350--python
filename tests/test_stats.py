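"""Factorial ANOVA, Fisher's LSD letters, and pattern classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phenoleaf import (
    PatternClass,
    PipelineError,
    anova_fixed,
    classify_pattern,
    fisher_lsd,
)


def balanced_table(levels, n, rng, effects=None):
    """Balanced full-factorial table with iid N(0,1) noise plus optional
    additive effects keyed by (factor_name, level)."""
    factors = [f"F{i}" for i in range(len(levels))]
    rows = []
    for combo in itertools.product(*(range(L) for L in levels)):
        for _ in range(n):
            y = rng.normal()
            if effects:
                for f, lv in zip(factors, combo):
                    y += effects.get((f, lv), 0.0)
            rows.append({**{f: f"l{lv}" for f, lv in zip(factors, combo)}, "response": y})
    return pd.DataFrame(rows), tuple(factors)


def design_table(n=6, rng=None):
    """The 2x3x2x5 layer-mean design with n replicates per cell."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for var in ("Barke", "Bojos"):
        for co2 in ("LC", "AC", "EC"):
            for light in ("LL", "HL"):
                for loc in ("AD", "UM", "MM", "LM", "AB"):
                    for _ in range(n):
                        rows.append(
                            {"Var": var, "CO2": co2, "Light": light, "Loc": loc,
                             "response": rng.normal()}
                        )
    return pd.DataFrame(rows)


class TestAnovaStructure:
    def test_four_way_df_column(self):
        """df for the balanced 2x3x2x5, n=6 design: every term is the product
        of (levels - 1); the residual has 360 - 60 = 300 df."""
        anova = anova_fixed(design_table(n=6))
        df = dict(zip(anova["term"], anova["df"]))
        assert df["Var"] == 1 and df["CO2"] == 2 and df["Light"] == 1 and df["Loc"] == 4
        assert df["Var x CO2"] == 2 and df["Var x Light"] == 1 and df["CO2 x Light"] == 2
        assert df["Var x Loc"] == 4 and df["CO2 x Loc"] == 8 and df["Light x Loc"] == 4
        assert df["Var x CO2 x Light"] == 2 and df["Var x CO2 x Loc"] == 8
        assert df["Var x Light x Loc"] == 4 and df["CO2 x Light x Loc"] == 8
        assert df["Var x CO2 x Light x Loc"] == 8
        assert df["Residual"] == 300
        assert anova["df"].sum() == 359  # total df = N - 1

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(2, 4), min_size=2, max_size=4),
        st.integers(2, 3),
    )
    def test_df_closed_form_property(self, levels, n):
        rng = np.random.default_rng(17)
        table, factors = balanced_table(levels, n, rng)
        anova = anova_fixed(table, factors=factors)
        df = dict(zip(anova["term"], anova["df"]))
        for r in range(1, len(levels) + 1):
            for subset in itertools.combinations(range(len(levels)), r):
                term = " x ".join(factors[i] for i in subset)
                assert df[term] == int(np.prod([levels[i] - 1 for i in subset]))
        assert df["Residual"] == len(table) - int(np.prod(levels))


class TestAnovaValues:
    def test_constant_response(self):
        table = design_table(n=2)
        table["response"] = 3.7
        anova = anova_fixed(table)
        body = anova[anova["term"] != "Residual"]
        assert (body["F"] == 0).all() and (body["p"] == 1).all()

    def test_two_group_equals_t_squared(self):
        """One 2-level factor: F equals the pooled-variance t statistic squared."""
        rng = np.random.default_rng(3)
        a, b_ = rng.normal(0, 1, 8), rng.normal(0.6, 1, 8)
        table = pd.DataFrame(
            {"G": ["a"] * 8 + ["b"] * 8, "response": np.concatenate([a, b_])}
        )
        anova = anova_fixed(table, factors=("G",))
        t_stat, p_t = sps.ttest_ind(a, b_, equal_var=True)
        row = anova[anova["term"] == "G"].iloc[0]
        assert row["F"] == pytest.approx(t_stat**2, rel=1e-10)
        assert row["p"] == pytest.approx(p_t, rel=1e-10)

    def test_near_separated_groups_large_f(self):
        table = pd.DataFrame(
            {"G": ["a", "a", "b", "b"], "response": [0.0, 1e-6, 1.0, 1.0 + 1e-6]}
        )
        row = anova_fixed(table, factors=("G",)).iloc[0]
        assert row["F"] > 1e9 and row["p"] < 1e-4

    def test_matches_statsmodels_oracle(self):
        """Full three-way decomposition agrees with the OLS route."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(11)
        effects = {("F0", 0): 0.5, ("F1", 2): -0.3}
        table, factors = balanced_table([2, 3, 2], 4, rng, effects)
        anova = anova_fixed(table, factors=factors)
        model = smf.ols("response ~ C(F0) * C(F1) * C(F2)", data=table).fit()
        oracle = sm.stats.anova_lm(model, typ=2)
        name_map = {
            "C(F0)": "F0", "C(F1)": "F1", "C(F2)": "F2",
            "C(F0):C(F1)": "F0 x F1", "C(F0):C(F2)": "F0 x F2",
            "C(F1):C(F2)": "F1 x F2", "C(F0):C(F1):C(F2)": "F0 x F1 x F2",
        }
        ours = anova.set_index("term")
        for sm_name, term in name_map.items():
            assert ours.loc[term, "sum_sq"] == pytest.approx(
                oracle.loc[sm_name, "sum_sq"], rel=1e-9
            )
            assert ours.loc[term, "F"] == pytest.approx(oracle.loc[sm_name, "F"], rel=1e-9)

    def test_unbalanced_rejected(self):
        table = design_table(n=2).iloc[:-1]
        with pytest.raises(PipelineError) as e:
            anova_fixed(table)
        assert e.value.code == "UNBALANCED"

    def test_empty_cell_rejected(self):
        table = design_table(n=2)
        table = table[~((table["Var"] == "Barke") & (table["Loc"] == "MM"))]
        with pytest.raises(PipelineError) as e:
            anova_fixed(table)
        assert e.value.code == "EMPTY_CELL"

    def test_single_replicate_rejected(self):
        with pytest.raises(PipelineError) as e:
            anova_fixed(design_table(n=1))
        assert e.value.code == "NO_RESIDUAL"


class TestFisherLsd:
    def test_lsd_value_and_separation(self):
        """MS_resid=1, n=6, df=10: LSD = 2.228 * sqrt(1/3) ~ 1.286; means 10
        and 12 separate."""
        grouping = fisher_lsd({"lo": 10.0, "hi": 12.0}, 6, 1.0, 10)
        assert grouping.lsd == pytest.approx(2.2281 * np.sqrt(2 / 6), abs=1e-3)
        assert grouping.letters["lo"] == "a" and grouping.letters["hi"] == "b"

    def test_equal_means_share_letter(self):
        grouping = fisher_lsd({"x": 5.0, "y": 5.0}, 6, 1.0, 10)
        assert grouping.letters["x"] == grouping.letters["y"]

    def test_three_means_grouping(self):
        """With LSD ~1.286: 10 and 10.5 are indistinguishable, 12 differs from
        both (pairwise enumeration: |12-10.5| = 1.5 > LSD)."""
        grouping = fisher_lsd({"a": 10.0, "b": 10.5, "c": 12.0}, 6, 1.0, 10)
        assert grouping.letters["a"] == "a"
        assert grouping.letters["b"] == "a"
        assert grouping.letters["c"] == "b"

    def test_chained_overlap(self):
        """Adjacent overlaps with distinct extremes produce a shared middle letter."""
        grouping = fisher_lsd({"a": 10.0, "b": 11.0, "c": 12.0}, 6, 1.0, 10)
        assert grouping.letters["a"] == "a"
        assert grouping.letters["b"] == "ab"
        assert grouping.letters["c"] == "b"

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8))
    def test_share_letter_iff_within_lsd(self, means):
        """Invariant: two means share a letter exactly when |diff| <= LSD."""
        cells = {f"m{i}": v for i, v in enumerate(means)}
        grouping = fisher_lsd(cells, 6, 4.0, 12)
        for i in cells:
            for j in cells:
                share = bool(set(grouping.letters[i]) & set(grouping.letters[j]))
                expected = abs(cells[i] - cells[j]) <= grouping.lsd
                assert share == expected

    def test_no_residual_df(self):
        with pytest.raises(PipelineError) as e:
            fisher_lsd({"a": 1.0}, 6, 1.0, 0)
        assert e.value.code == "NO_RESIDUAL"


class TestClassifyPattern:
    def test_surface_dominant(self):
        assert classify_pattern([5, 3, 2, 3, 4]) == PatternClass.SURFACE_DOMINANT

    def test_lower_mesophyll_dominant(self):
        assert classify_pattern([2, 2, 3, 5, 4]) == PatternClass.LOWER_MESOPHYLL_DOMINANT

    def test_flat(self):
        assert classify_pattern([1, 1, 1, 1, 1]) == PatternClass.FLAT

    def test_mm_peak_warns(self):
        with pytest.warns(UserWarning):
            assert classify_pattern([1, 2, 5, 2, 1]) == PatternClass.LOWER_MESOPHYLL_DOMINANT

    def test_um_peak_warns(self):
        with pytest.warns(UserWarning):
            assert classify_pattern([1, 5, 2, 2, 1]) == PatternClass.SURFACE_DOMINANT
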