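"""Colony-development (CD) and ecophysiological-diversity (EP) indices.

Both indices summarise *when* colonies emerge on a plate observed daily for
``D`` days, and thereby the r/K-strategist balance of the cultivable
community:

* ``CD = 100 * sum_i f_i / i`` where ``f_i`` is the proportion of all
  colonies that appeared on day ``i``.  Early emergence (fast-growing
  r-strategists) is weighted most: CD = 100 when everything appears on day
  1 and 100/D when everything appears on day D.
* ``EP = -sum_i p_i log10 p_i`` is the base-10 Shannon entropy of the daily
  appearance proportions, with the usual convention 0*log 0 = 0.  EP = 0
  for single-day emergence and log10(D) (= 1 for D = 10) for perfectly
  uniform emergence, i.e. a maximally even mix of strategies.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyGroupError
from .plate_counts import ColonyAppearanceSeries, daily_fractions


def cd_index(series: ColonyAppearanceSeries | Sequence[int]) -> float:
    """Colony development index in (100/D, 100].

    The daily counts are first normalised to proportions of the total, so
    the index is invariant to the absolute number of colonies.
    """
    fractions = daily_fractions(series)
    days = np.arange(1, fractions.size + 1, dtype=float)
    return float(100.0 * np.sum(fractions / days))


def ep_index(series: ColonyAppearanceSeries | Sequence[int], log_base: float = 10.0) -> float:
    """Ecophysiological diversity index: Shannon entropy of daily proportions.

    ``log_base`` defaults to 10, giving the conventional [0, log10 D] range
    ([0, 1] for the standard 10-day window); a natural-log variant is
    available by passing ``log_base=math.e`` but is never the default.
    """
    p = daily_fractions(series)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p) / np.log(log_base)))


def colony_index_frame(series: Iterable[ColonyAppearanceSeries]) -> pd.DataFrame:
    """CD and EP per plate, as a tidy frame keyed by sample/treatment/replicate."""
    rows = []
    for s in series:
        rows.append(
            {
                "sample_id": s.sample_id,
                "hydrocarbon": s.treatment.hydrocarbon,
                "dose_mg_per_kg": s.treatment.dose_mg_per_kg,
                "replicate": s.replicate,
                "cd": cd_index(s),
                "ep": ep_index(s),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "hydrocarbon", "dose_mg_per_kg", "replicate", "cd", "ep"]
    )


def index_summary(results: pd.DataFrame, group_by: str = "hydrocarbon") -> pd.DataFrame:
    """Mean and sample standard deviation of CD and EP per group.

    A group with a single result reports sd = 0 by convention.
    """
    if len(results) == 0:
        raise EmptyGroupError("no index results to summarise")
    grouped = results.groupby(group_by)
    out = grouped.agg(
        n=("cd", "size"),
        cd_mean=("cd", "mean"),
        cd_sd=("cd", lambda x: x.std(ddof=1)),
        ep_mean=("ep", "mean"),
        ep_sd=("ep", lambda x: x.std(ddof=1)),
    ).reset_index()
    out[["cd_sd", "ep_sd"]] = out[["cd_sd", "ep_sd"]].fillna(0.0)
    return out
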