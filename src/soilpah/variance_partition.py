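"""Balanced two-way ANOVA with eta-squared shares and Tukey letter displays.

The experimental design is a balanced, fully crossed two-factor layout
(PAH type x dose, n replicates per cell).  The classical decomposition is
computed from scratch by explicit mean subtraction:

    SS_A     = b n sum_a (ybar_a - ybar)^2
    SS_B     = a n sum_b (ybar_b - ybar)^2
    SS_AB    = n sum_ab (ybar_ab - ybar_a - ybar_b + ybar)^2
    SS_error = sum (y - ybar_cell)^2

with F = MS_term / MS_error and p from the F distribution.  Effect sizes
are eta-squared percentages, 100 * SS_term / SS_total, which sum to 100
exactly (SS_total = sum of the four terms for a balanced design) and are
invariant under affine rescaling of the data.

Homogeneous groups are annotated with compact letter displays from Tukey's
HSD at a fixed significance level (default 0.01): with equal group sizes
the "not significantly different" relation is a threshold graph on the
sorted means, so its maximal cliques are maximal runs of consecutive means
spanning at most the HSD width; each run receives one letter.  Two groups
share a letter if and only if their difference is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateVarianceError,
    InvalidVarianceError,
    UnbalancedDesignError,
)

TERM_TYPE = "type"
TERM_DOSE = "dose"
TERM_INTERACTION = "type:dose"
TERM_ERROR = "error"
TERMS = (TERM_TYPE, TERM_DOSE, TERM_INTERACTION, TERM_ERROR)


@dataclass(frozen=True)
class AnovaTerm:
    sum_of_squares: float
    degrees_of_freedom: int
    mean_square: float
    f_statistic: float | None
    p_value: float | None


@dataclass(frozen=True)
class AnovaTable:
    """Term-wise decomposition; ``degenerate`` flags an all-constant response."""

    terms: dict[str, AnovaTerm]
    total_ss: float
    degenerate: bool

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in TERMS:
            t = self.terms[name]
            rows.append(
                {
                    "term": name,
                    "sum_of_squares": t.sum_of_squares,
                    "df": t.degrees_of_freedom,
                    "mean_square": t.mean_square,
                    "F": t.f_statistic,
                    "p_value": t.p_value,
                }
            )
        return pd.DataFrame(rows)


def two_way_anova(
    records: pd.DataFrame,
    factor_a: str = "hydrocarbon",
    factor_b: str = "dose_mg_per_kg",
    value_col: str = "value",
) -> AnovaTable:
    """Classical balanced two-way ANOVA with interaction.

    Requires a complete crossed design with a common cell size n >= 2;
    anything else raises :class:`UnbalancedDesignError` (unbalanced SS
    typologies are deliberately out of scope).
    """
    df = records[[factor_a, factor_b, value_col]].dropna()
    a_levels = sorted(df[factor_a].unique().tolist(), key=str)
    b_levels = sorted(df[factor_b].unique().tolist(), key=str)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise UnbalancedDesignError("need >= 2 levels of each factor")
    counts = df.groupby([factor_a, factor_b])[value_col].size()
    if len(counts) != a * b or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "design must be complete and balanced (same n in every cell)"
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise UnbalancedDesignError("need n >= 2 replicates per cell to estimate error")

    y = df[value_col].to_numpy(float)
    grand = y.mean()
    mean_a = df.groupby(factor_a)[value_col].mean()
    mean_b = df.groupby(factor_b)[value_col].mean()
    mean_cell = df.groupby([factor_a, factor_b])[value_col].mean()

    ss_a = b * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a * n * float(((mean_b - grand) ** 2).sum())
    ss_ab = n * float(
        sum(
            (mean_cell[(la, lb)] - mean_a[la] - mean_b[lb] + grand) ** 2
            for la in a_levels
            for lb in b_levels
        )
    )
    fitted = pd.MultiIndex.from_frame(df[[factor_a, factor_b]]).map(mean_cell).to_numpy(float)
    ss_err = float(((y - fitted) ** 2).sum())
    ss_total = ss_a + ss_b + ss_ab + ss_err

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (n - 1)
    degenerate = ss_total <= 0

    def term(ss: float, dof: int, is_error: bool) -> AnovaTerm:
        ms = ss / dof if dof else float("nan")
        if is_error or degenerate or ss_err == 0:
            return AnovaTerm(ss, dof, ms, None, None)
        f_stat = ms / (ss_err / df_err)
        return AnovaTerm(ss, dof, ms, f_stat, float(stats.f.sf(f_stat, dof, df_err)))

    terms = {
        TERM_TYPE: term(ss_a, df_a, False),
        TERM_DOSE: term(ss_b, df_b, False),
        TERM_INTERACTION: term(ss_ab, df_ab, False),
        TERM_ERROR: term(ss_err, df_err, True),
    }
    return AnovaTable(terms=terms, total_ss=ss_total, degenerate=degenerate)


def eta_squared(table: AnovaTable) -> dict[str, float]:
    """Eta-squared percentage per term; the shares sum to 100 exactly."""
    if table.degenerate or table.total_ss <= 0:
        raise DegenerateVarianceError("all values identical: variance shares undefined")
    return {
        name: 100.0 * t.sum_of_squares / table.total_ss for name, t in table.terms.items()
    }


def q_critical(alpha: float, n_groups: int, df_error: int, method: str = "exact",
               rng: np.random.Generator | None = None, n_draws: int = 200_000) -> float:
    """Upper-alpha quantile of the studentized range.

    ``method="exact"`` uses the studentized-range distribution; a seeded
    Monte-Carlo estimator (``method="montecarlo"``) is available as a
    fallback and for cross-checking.
    """
    if method == "exact":
        return float(stats.studentized_range.ppf(1.0 - alpha, n_groups, df_error))
    if method == "montecarlo":
        rng = rng if rng is not None else np.random.default_rng(0)
        z = rng.standard_normal((n_draws, n_groups))
        s = np.sqrt(rng.chisquare(df_error, n_draws) / df_error)
        q = (z.max(axis=1) - z.min(axis=1)) / s
        return float(np.quantile(q, 1.0 - alpha))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: shared letter <=> not significantly different."""

    labels: tuple
    means: tuple[float, ...]
    letters: tuple[str, ...]
    alpha: float
    hsd: float

    def shares_letter(self, label_i, label_j) -> bool:
        li = self.letters[self.labels.index(label_i)]
        lj = self.letters[self.labels.index(label_j)]
        return bool(set(li) & set(lj))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.labels, "mean": self.means, "letters": self.letters}
        )


def tukey_letters(
    group_means: Mapping[object, float] | Sequence[float],
    group_n: int,
    ms_error: float,
    df_error: int,
    alpha: float = 0.01,
    q_method: str = "exact",
    ascending: bool = True,
    rng: np.random.Generator | None = None,
) -> LetterDisplay:
    """Tukey-HSD homogeneous groups as a compact letter display.

    Two groups differ significantly when |mean_i - mean_j| exceeds
    ``HSD = q(1-alpha; k, df) * sqrt(MS_error / n)``.  Letters are assigned
    to maximal runs of consecutive sorted means spanning at most HSD; with
    ``ascending=True`` (the report-table convention) the letter 'a' goes to
    the run containing the smallest mean.  Ties in means keep input order.
    """
    if isinstance(group_means, Mapping):
        labels = list(group_means.keys())
        means = [float(group_means[k]) for k in labels]
    else:
        means = [float(m) for m in group_means]
        labels = list(range(len(means)))
    k = len(means)
    if k < 2:
        raise InvalidVarianceError("need >= 2 groups for a letter display")
    if not ms_error > 0:
        raise InvalidVarianceError(f"ms_error must be > 0, got {ms_error!r}")
    if group_n < 2 or df_error < 1:
        raise InvalidVarianceError("need group_n >= 2 and df_error >= 1")

    q = q_critical(alpha, k, df_error, method=q_method, rng=rng)
    hsd = q * np.sqrt(ms_error / group_n)

    order = sorted(range(k), key=lambda i: (means[i], i))
    sorted_means = [means[i] for i in order]
    # Maximal runs [i, j] with sorted_means[j] - sorted_means[i] <= hsd.
    # Two-pointer sweep: the right endpoint is monotone in i, and a run is
    # maximal exactly when it extends further right than the previous one.
    maximal: list[tuple[int, int]] = []
    j = 0
    for i in range(k):
        if j < i:
            j = i
        while j + 1 < k and sorted_means[j + 1] - sorted_means[i] <= hsd:
            j += 1
        if not maximal or j > maximal[-1][1]:
            maximal.append((i, j))

    def letter(idx: int) -> str:
        # supports > 26 groups as aa, ab, ... (never needed for 4-dose columns)
        out = ""
        idx += 1
        while idx:
            idx, rem = divmod(idx - 1, 26)
            out = chr(ord("a") + rem) + out
        return out

    if not ascending:
        maximal = list(reversed(maximal))
    letters_sorted = ["" for _ in range(k)]
    for li, (lo, hi) in enumerate(maximal):
        for pos in range(lo, hi + 1):
            letters_sorted[pos] += letter(li)
    letters = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        letters[orig] = letters_sorted[pos]
    return LetterDisplay(
        labels=tuple(labels),
        means=tuple(means),
        letters=tuple(letters),
        alpha=alpha,
        hsd=float(hsd),
    )


def expand_means_to_replicates(
    cell_means: pd.DataFrame,
    n: int = 3,
    error_share_percent: float = 5.0,
    factor_a: str = "hydrocarbon",
    factor_b: str = "dose_mg_per_kg",
    value_col: str = "value",
) -> pd.DataFrame:
    """Deterministic replicate expansion of a cell-mean table (synthetic).

    Report tables publish only cell means; replicate-requiring stages
    (ANOVA, letters) can still run on them by injecting zero-sum residuals
    (+d, -d, 0, ...) into every cell, with d chosen so that the error term
    accounts for exactly ``error_share_percent`` of the total sum of
    squares.  Cell means are preserved exactly; the output is synthetic by
    construction and labelled as such.
    """
    if not 0 < error_share_percent < 100:
        raise InvalidVarianceError("error_share_percent must be in (0, 100)")
    if n < 2:
        raise InvalidVarianceError("need n >= 2 replicates")
    means = cell_means[[factor_a, factor_b, value_col]].copy()
    # Between-cell (model) SS with n replicates per cell.
    y = np.repeat(means[value_col].to_numpy(float), n)
    grand = y.mean()
    ss_model = n * float(((means[value_col] - grand) ** 2).sum())
    if ss_model <= 0:
        raise DegenerateVarianceError("constant cell means: cannot scale residuals")
    ss_error = error_share_percent / (100.0 - error_share_percent) * ss_model
    n_cells = len(means)
    delta = np.sqrt(ss_error / (2.0 * n_cells))
    pattern = np.zeros(n)
    pattern[0], pattern[1] = delta, -delta
    rows = []
    for _, row in means.iterrows():
        for rep in range(n):
            rows.append(
                {
                    factor_a: row[factor_a],
                    factor_b: row[factor_b],
                    "replicate": rep + 1,
                    value_col: float(row[value_col]) + pattern[rep],
                }
            )
    return pd.DataFrame(rows)
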