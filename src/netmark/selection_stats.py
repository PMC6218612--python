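"""Null model for feature-selection frequency.

With F screened features and selected sets of size S, the chance that a
designated feature lands in one random set is hypergeometric:
h(1 | F, S, 1) = S / F. Treating the N_fold selected sets as independent
draws (an approximation — the folds overlap in subjects), the number of
appearances of a feature is Binomial(N_fold, S/F); a feature selected n
times is flagged when the exact upper tail P(X >= n) falls below alpha.

F varies across folds because each screen retains a different count; the
null uses the mean screened count across folds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import RunResults

__all__ = [
    "FrequencyNull",
    "selection_probability",
    "frequency_pvalue",
    "expected_histogram",
    "significant_features",
]

DEFAULT_ALPHA = 0.001


@dataclass
class FrequencyNull:
    """Parameters of the binomial selection-frequency null."""

    f_total: int       # screened feature count F
    set_size: int      # S, features per selected set
    n_sets: int        # N_fold, number of selection sets
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not 1 <= self.set_size <= self.f_total:
            raise ValueError("need 1 <= set_size <= f_total")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def p_select(self) -> float:
        return selection_probability(self.f_total, self.set_size)


def selection_probability(f_total: int, set_size: int) -> float:
    """Probability a designated feature is included when set_size items are
    drawn without replacement from f_total: h(1 | F, S, 1) = S / F."""
    if not 1 <= set_size <= f_total:
        raise ValueError("need 1 <= set_size <= f_total")
    # hypergeometric pmf at 1 with a single marked item reduces to S/F
    return float(stats.hypergeom.pmf(1, f_total, 1, set_size))


def frequency_pvalue(n: int, null: FrequencyNull) -> float:
    """Exact binomial upper tail P(X >= n), X ~ Binomial(N_fold, S/F)."""
    if not 0 <= n <= null.n_sets:
        raise ValueError(f"n must lie in [0, {null.n_sets}]")
    return float(stats.binom.sf(n - 1, null.n_sets, null.p_select))


def frequency_cutoff(null: FrequencyNull) -> int:
    """Smallest appearance count flagged at alpha."""
    for n in range(null.n_sets + 1):
        if frequency_pvalue(n, null) < null.alpha:
            return n
    return null.n_sets + 1


def expected_histogram(null: FrequencyNull, n_features: int) -> np.ndarray:
    """Expected number of features appearing exactly n times under the
    null, for n = 0..N_fold."""
    pmf = stats.binom.pmf(np.arange(null.n_sets + 1), null.n_sets,
                          null.p_select)
    return n_features * pmf


def significant_features(results: RunResults, alpha: float = DEFAULT_ALPHA,
                         feature_ids: list[str] | None = None) -> pd.DataFrame:
    """Tally appearances of every feature over all selection sets and flag
    those more frequent than the binomial null allows.

    Columns: feature_id, frequency, p_value, significant; sorted by
    frequency descending. When ``feature_ids`` is given, never-selected
    features appear with frequency 0 (p-value 1).
    """
    if not results.traces:
        raise ValueError("no selection traces in results")
    counts: Counter[str] = Counter()
    for t in results.traces:
        counts.update(t.sfs_order)
    if feature_ids is not None:
        for fid in feature_ids:
            counts.setdefault(fid, 0)
    n_sets = len(results.traces)
    set_size = max(len(t.sfs_order) for t in results.traces)
    f_total = max(int(round(results.mean_screened_count)), set_size)
    null = FrequencyNull(f_total, set_size, n_sets, alpha)
    rows = [
        {"feature_id": fid, "frequency": n,
         "p_value": frequency_pvalue(n, null),
         "significant": frequency_pvalue(n, null) < alpha}
        for fid, n in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["frequency", "feature_id"], ascending=[False, True]).reset_index(drop=True)
    df.attrs["null"] = null
    return df
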