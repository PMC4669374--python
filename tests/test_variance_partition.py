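"""ANOVA decomposition, eta-squared shares and compact letter displays."""

import itertools

import numpy as np
import pandas as pd
import pytest

from soilpah import datasets
from soilpah.exceptions import (
    DegenerateVarianceError,
    InvalidVarianceError,
    UnbalancedDesignError,
)
from soilpah.variance_partition import (
    eta_squared,
    expand_means_to_replicates,
    q_critical,
    tukey_letters,
    two_way_anova,
)


def _frame(values, a, b, n):
    rows = []
    it = iter(values)
    for la in range(a):
        for lb in range(b):
            for _ in range(n):
                rows.append({"hydrocarbon": f"A{la}", "dose_mg_per_kg": lb, "value": next(it)})
    return pd.DataFrame(rows)


def _brute_force_ss(df):
    """Independent SS computation via explicit loops over cells and margins."""
    a_levels = sorted(df["hydrocarbon"].unique())
    b_levels = sorted(df["dose_mg_per_kg"].unique())
    grand = df["value"].mean()
    n = len(df) / (len(a_levels) * len(b_levels))
    ss_a = ss_b = ss_ab = ss_err = 0.0
    for la in a_levels:
        ma = df[df["hydrocarbon"] == la]["value"].mean()
        ss_a += len(b_levels) * n * (ma - grand) ** 2
    for lb in b_levels:
        mb = df[df["dose_mg_per_kg"] == lb]["value"].mean()
        ss_b += len(a_levels) * n * (mb - grand) ** 2
    for la in a_levels:
        for lb in b_levels:
            cell = df[(df["hydrocarbon"] == la) & (df["dose_mg_per_kg"] == lb)]["value"]
            ma = df[df["hydrocarbon"] == la]["value"].mean()
            mb = df[df["dose_mg_per_kg"] == lb]["value"].mean()
            ss_ab += n * (cell.mean() - ma - mb + grand) ** 2
            ss_err += float(((cell - cell.mean()) ** 2).sum())
    return ss_a, ss_b, ss_ab, ss_err


def test_ss_decomposition_matches_brute_force_on_random_designs(rng):
    """100 random balanced layouts up to 4 x 4 x 5."""
    for _ in range(100):
        a = int(rng.integers(2, 5))
        b = int(rng.integers(2, 5))
        n = int(rng.integers(2, 6))
        values = rng.normal(10.0, 3.0, a * b * n)
        df = _frame(values, a, b, n)
        table = two_way_anova(df)
        ss = _brute_force_ss(df)
        for term, expected in zip(("type", "dose", "type:dose", "error"), ss):
            assert table.terms[term].sum_of_squares == pytest.approx(expected, abs=1e-8)
        total = df["value"].var(ddof=0) * len(df)
        assert table.total_ss == pytest.approx(total, rel=1e-10)


def test_ss_matches_statsmodels_oracle(rng):
    """Independent cross-check via OLS anova_lm on a few random instances."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for _ in range(5):
        df = _frame(rng.normal(5, 2, 4 * 3 * 3), 4, 3, 3)
        fit = ols("value ~ C(hydrocarbon) * C(dose_mg_per_kg)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        table = two_way_anova(df)
        assert table.terms["type"].sum_of_squares == pytest.approx(
            ref.loc["C(hydrocarbon)", "sum_sq"], rel=1e-9
        )
        assert table.terms["dose"].sum_of_squares == pytest.approx(
            ref.loc["C(dose_mg_per_kg)", "sum_sq"], rel=1e-9
        )
        assert table.terms["type:dose"].sum_of_squares == pytest.approx(
            ref.loc["C(hydrocarbon):C(dose_mg_per_kg)", "sum_sq"], rel=1e-9
        )
        assert table.terms["error"].sum_of_squares == pytest.approx(
            ref.loc["Residual", "sum_sq"], rel=1e-9
        )
        assert table.terms["type"].p_value == pytest.approx(
            ref.loc["C(hydrocarbon)", "PR(>F)"], abs=1e-10
        )


def test_pure_dose_effect_and_degenerate_cases():
    # 2x2, n=2, pure dose effect, zero noise
    values = [1, 1, 5, 5, 1, 1, 5, 5]
    table = two_way_anova(_frame(values, 2, 2, 2))
    assert table.terms["type"].sum_of_squares == pytest.approx(0.0, abs=1e-12)
    assert table.terms["type:dose"].sum_of_squares == pytest.approx(0.0, abs=1e-12)
    assert table.terms["error"].sum_of_squares == pytest.approx(0.0, abs=1e-12)
    assert eta_squared(table)["dose"] == pytest.approx(100.0)
    # all identical -> degenerate flag, eta undefined
    flat = two_way_anova(_frame([3.0] * 8, 2, 2, 2))
    assert flat.degenerate
    with pytest.raises(DegenerateVarianceError):
        eta_squared(flat)


def test_unbalanced_design_rejected():
    df = _frame(list(range(12)), 2, 3, 2)
    with pytest.raises(UnbalancedDesignError):
        two_way_anova(df.iloc[:-1])
    with pytest.raises(UnbalancedDesignError):
        two_way_anova(_frame(list(range(6)), 2, 3, 1))


def test_eta_shares_sum_to_100_and_are_affine_invariant(rng):
    df = _frame(rng.normal(0, 1, 3 * 4 * 3), 3, 4, 3)
    shares = eta_squared(two_way_anova(df))
    assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)
    scaled = df.assign(value=df["value"] * -7.3 + 11.0)
    shares2 = eta_squared(two_way_anova(scaled))
    for term in shares:
        assert shares2[term] == pytest.approx(shares[term], abs=1e-8)


def test_eta_reconstruction_from_printed_count_means():
    """Replicates injected into the printed count-table means at the printed
    error share recover the dose share to within a couple of points."""
    means = datasets.load_activity_table("organotrophic_count")
    reps = expand_means_to_replicates(means, n=3, error_share_percent=5.20)
    table = two_way_anova(reps)
    shares = eta_squared(table)
    assert shares["error"] == pytest.approx(5.20, abs=1e-6)
    assert shares["dose"] == pytest.approx(63.59, abs=2.0)
    assert shares["type"] == pytest.approx(17.35, abs=2.0)
    # cell means preserved exactly by the residual pattern
    back = reps.groupby(["hydrocarbon", "dose_mg_per_kg"])["value"].mean()
    for _, row in means.iterrows():
        assert back[(row["hydrocarbon"], row["dose_mg_per_kg"])] == pytest.approx(row["value"])


def test_q_critical_monte_carlo_agrees_with_exact(rng):
    exact = q_critical(0.01, 4, 32, method="exact")
    mc = q_critical(0.01, 4, 32, method="montecarlo", rng=rng)
    assert mc == pytest.approx(exact, rel=0.03)


def test_letters_two_equal_groups_share_a():
    disp = tukey_letters({"x": 5.0, "y": 5.0}, group_n=3, ms_error=1.0, df_error=8)
    assert disp.letters == ("a", "a")


def test_letters_fully_separated_groups():
    disp = tukey_letters(
        {"g1": 0.0, "g2": 100.0, "g3": 200.0}, group_n=3, ms_error=1.0, df_error=8
    )
    assert disp.letters == ("a", "b", "c")


def test_letters_match_printed_pyrene_urease_pattern():
    """Doses 0/1000/2000/4000 at the printed means with small scatter give
    four distinct groups labelled d/c/b/a from the highest mean down."""
    means = {0: 2.76, 1000: 2.22, 2000: 1.63, 4000: 1.14}
    disp = tukey_letters(means, group_n=3, ms_error=0.02**2, df_error=8, alpha=0.01)
    assert dict(zip(disp.labels, disp.letters)) == {0: "d", 1000: "c", 2000: "b", 4000: "a"}


def test_letter_sharing_iff_not_significant(rng):
    """Exhaustive biconditional against the pairwise HSD decision matrix."""
    for _ in range(50):
        k = int(rng.integers(2, 7))
        means = rng.normal(0, 2, k)
        ms_error = float(rng.uniform(0.01, 4.0))
        disp = tukey_letters(list(means), group_n=3, ms_error=ms_error, df_error=12)
        for i, j in itertools.combinations(range(k), 2):
            significant = abs(means[i] - means[j]) > disp.hsd
            assert disp.shares_letter(i, j) == (not significant), (means, ms_error)


def test_more_error_never_more_letter_classes(rng):
    means = list(rng.normal(0, 1, 5))
    classes = []
    for ms in (0.001, 0.01, 0.1, 1.0, 10.0):
        disp = tukey_letters(means, group_n=3, ms_error=ms, df_error=10)
        classes.append(len(set("".join(disp.letters))))
    assert classes == sorted(classes, reverse=True)


def test_letter_input_validation():
    with pytest.raises(InvalidVarianceError):
        tukey_letters({"a": 1.0, "b": 2.0}, group_n=3, ms_error=0.0, df_error=8)
    with pytest.raises(InvalidVarianceError):
        tukey_letters({"a": 1.0}, group_n=3, ms_error=1.0, df_error=8)
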