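"""Outcome typing, per-split association tests, and Bonferroni correction.

At every valid branch point the left and right subclusters are compared
against each clinical outcome with a test chosen by the outcome's data type:

* categorical -> Fisher's exact test (exact for 2x2 and, when feasible, for
  r x 2 tables by enumeration; Monte-Carlo fallback with a recorded seed),
* continuous  -> two-sample t-test (Welch by default),
* survival    -> two-group log-rank test,
* custom      -> a user-supplied function ``f(left_ids, right_ids, column)``
  returning ``(statistic, p)``.

Because a dendrogram partitions the cohort into cascaded non-overlapping
groups, the tests across splits are independent, and the family-wise
correction multiplies each raw p-value by the number of valid cluster pairs
(not additionally by the number of outcomes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .tree import ClusterPair

__all__ = [
    "OutcomeTable",
    "AssociationResult",
    "infer_outcome_type",
    "fisher_exact",
    "t_test",
    "logrank_test",
    "run_associations",
    "bonferroni_adjust",
    "results_to_frame",
]

#: numeric columns with at most this many distinct values are inferred categorical
CATEGORICAL_MAX_LEVELS = 5

#: default seed for the Monte-Carlo Fisher fallback, recorded in the result
FISHER_MC_SEED = 20210916
FISHER_MC_SAMPLES = 20000
_FISHER_ENUM_LIMIT = 500_000


class SkipTest(Exception):
    """A test precondition failed; the (pair, outcome) result is skipped."""


def infer_outcome_type(column: pd.Series, max_levels: int = CATEGORICAL_MAX_LEVELS) -> str:
    """Infer ``categorical`` vs ``continuous`` for a single outcome column.

    Booleans, strings and low-cardinality numeric codings are categorical;
    other numeric columns are continuous.  Survival outcomes cannot be
    inferred from a single column and must be declared as (time, event) pairs.
    """
    vals = column.dropna()
    if vals.empty:
        raise ValueError(f"outcome '{column.name}' has no observed values")
    if isinstance(vals.dtype, pd.CategoricalDtype) or vals.dtype == bool or vals.dtype == object:
        return "categorical"
    if pd.api.types.is_numeric_dtype(vals):
        if vals.nunique() <= max_levels:
            return "categorical"
        return "continuous"
    return "categorical"


@dataclass
class OutcomeTable:
    """Per-sample clinical variables with typed columns.

    Parameters
    ----------
    data : DataFrame indexed by sample ID.
    survival : mapping of outcome name -> (time_column, event_column); the two
        raw columns are replaced by one survival outcome under the given name.
    types : explicit type declarations (``categorical``/``continuous``/
        ``custom``) overriding inference.
    """

    data: pd.DataFrame
    survival: dict = field(default_factory=dict)
    types: dict = field(default_factory=dict)
    max_levels: int = CATEGORICAL_MAX_LEVELS

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in outcomes: {dupes}")
        self.types = dict(self.types)
        used = set()
        for name, (tcol, ecol) in self.survival.items():
            for c in (tcol, ecol):
                if c not in self.data.columns:
                    raise ValueError(f"survival declaration for '{name}' references missing column '{c}'")
            t = self.data[tcol].dropna()
            e = self.data[ecol].dropna()
            if (t < 0).any():
                raise ValueError(f"survival times in '{tcol}' must be non-negative")
            if not set(e.unique()) <= {0, 1, True, False}:
                raise ValueError(f"event column '{ecol}' must be binary 0/1")
            self.types[name] = "survival"
            used.update((tcol, ecol))
        for col in self.data.columns:
            if col in used or col in self.types:
                continue
            self.types[col] = infer_outcome_type(self.data[col], self.max_levels)
        self._survival_cols = used

    @property
    def outcome_names(self) -> list:
        """Testable outcome names: plain columns plus declared survival outcomes."""
        names = [c for c in self.data.columns if c not in self._survival_cols]
        names += [s for s in self.survival if s not in names]
        return names

    def column(self, name: str):
        """Return the values for an outcome: a Series, or a (time, event) frame."""
        if name in self.survival:
            tcol, ecol = self.survival[name]
            return self.data[[tcol, ecol]].rename(columns={tcol: "time", ecol: "event"})
        return self.data[name]


@dataclass
class AssociationResult:
    """Result of one (valid cluster pair x outcome) test."""

    cid_left: int
    cid_right: int
    outcome: str
    test: str
    statistic: float
    p_raw: float
    p_adj: float | None
    n_left: int
    n_right: int
    summary_left: str
    summary_right: str
    status: str = "ok"  # "ok" or "skipped: <reason>"


# ---------------------------------------------------------------------------
# individual tests
# ---------------------------------------------------------------------------

def _split_values(members_left, members_right, column):
    ids = column.index if isinstance(column, (pd.Series, pd.DataFrame)) else None
    if ids is None:
        raise TypeError("outcome column must be a pandas Series/DataFrame indexed by sample ID")
    left = column.loc[column.index.intersection(list(members_left))].dropna()
    right = column.loc[column.index.intersection(list(members_right))].dropna()
    return left, right


def _fisher_r2_exact(counts: np.ndarray):
    """Exact two-sided p for an r x 2 table by enumerating all tables with the
    observed margins; returns None when the enumeration is infeasible."""
    row = counts.sum(axis=1)
    n_left = int(counts[:, 0].sum())
    n = int(row.sum())
    ranges = [range(max(0, r - (n - n_left)), min(r, n_left) + 1) for r in row]
    size = np.prod([len(r) for r in ranges])
    if size > _FISHER_ENUM_LIMIT:
        return None

    log_denom = math.lgamma(n + 1) - math.lgamma(n_left + 1) - math.lgamma(n - n_left + 1)

    def log_prob(ks):
        lp = -log_denom
        for r, k in zip(row, ks):
            lp += math.lgamma(r + 1) - math.lgamma(k + 1) - math.lgamma(r - k + 1)
        return lp

    obs = log_prob(counts[:, 0])
    p = 0.0
    for ks in product(*ranges):
        if sum(ks) != n_left:
            continue
        lp = log_prob(ks)
        if lp <= obs + 1e-9:
            p += math.exp(lp)
    return min(p, 1.0)


def _fisher_r2_montecarlo(counts: np.ndarray, seed: int, n_samples: int):
    row = counts.sum(axis=1).astype(int)
    n_left = int(counts[:, 0].sum())
    rng = np.random.default_rng(seed)

    # the fixed-margins denominator cancels when comparing probabilities
    def log_prob(ks):
        return sum(
            math.lgamma(r + 1) - math.lgamma(k + 1) - math.lgamma(r - k + 1)
            for r, k in zip(row, ks)
        )

    obs = log_prob(counts[:, 0])
    draws = rng.multivariate_hypergeometric(row, n_left, size=n_samples)
    hits = sum(1 for ks in draws if log_prob(ks) <= obs + 1e-9)
    return (hits + 1) / (n_samples + 1)


def fisher_exact(members_left, members_right, column: pd.Series):
    """Fisher's exact test on the levels x {left, right} contingency table.

    Returns ``(statistic, p_raw, test_name)``; the statistic is the odds ratio
    for 2x2 tables and NaN otherwise.  Levels unobserved after missing-value
    removal are dropped; fewer than 2 remaining levels raises :class:`SkipTest`.
    """
    left, right = _split_values(members_left, members_right, column)
    if left.empty or right.empty:
        raise SkipTest("empty side after missing-value removal")
    levels = sorted(set(left.unique()) | set(right.unique()), key=str)
    if len(levels) < 2:
        raise SkipTest("fewer than 2 observed levels")
    counts = np.array(
        [[(left == lv).sum(), (right == lv).sum()] for lv in levels], dtype=int
    )
    if counts.shape[0] == 2:
        odds, p = stats.fisher_exact(counts, alternative="two-sided")
        return float(odds), float(p), "fisher"
    p = _fisher_r2_exact(counts)
    if p is not None:
        return float("nan"), float(p), "fisher"
    p = _fisher_r2_montecarlo(counts, FISHER_MC_SEED, FISHER_MC_SAMPLES)
    return float("nan"), float(p), f"fisher-mc(seed={FISHER_MC_SEED})"


def t_test(members_left, members_right, column: pd.Series, kind: str = "welch"):
    """Two-sided two-sample t-test (Welch by default, ``kind='pooled'`` optional)."""
    left, right = _split_values(members_left, members_right, column)
    if len(left) < 2 or len(right) < 2:
        raise SkipTest("fewer than 2 non-missing values on one side")
    x, y = left.to_numpy(float), right.to_numpy(float)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            raise SkipTest("zero variance on both sides with equal means")
    res = stats.ttest_ind(x, y, equal_var=(kind == "pooled"))
    return float(res.statistic), float(res.pvalue), "t-welch" if kind == "welch" else "t-pooled"


def logrank_test(members_left, members_right, column: pd.DataFrame):
    """Two-group log-rank test; ``column`` has 'time' and 'event' columns."""
    from lifelines.statistics import logrank_test as _lifelines_logrank

    left, right = _split_values(members_left, members_right, column)
    if left.empty or right.empty:
        raise SkipTest("empty side after missing-value removal")
    if left["event"].sum() + right["event"].sum() == 0:
        raise SkipTest("no events in pooled data")
    res = _lifelines_logrank(
        left["time"], right["time"],
        event_observed_A=left["event"], event_observed_B=right["event"],
    )
    return float(res.test_statistic), float(res.p_value), "logrank"


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _summary(values, kind: str) -> str:
    if kind == "categorical":
        counts = values.value_counts().sort_index()
        return "; ".join(f"{k}:{v}" for k, v in counts.items())
    if kind == "survival":
        return f"events={int(values['event'].sum())}/n={len(values)}"
    if len(values) == 0:
        return "n=0"
    return f"{values.mean():.4g}±{values.std(ddof=1):.4g}"


def run_associations(
    pairs: list[ClusterPair],
    outcomes: OutcomeTable,
    custom_tests: dict | None = None,
    t_test_kind: str = "welch",
) -> list[AssociationResult]:
    """Run the appropriate test for every (valid pair, outcome) combination.

    One result per combination is always emitted; tests whose preconditions
    fail are reported with ``status='skipped: <reason>'`` rather than dropped.
    Raw p-values are not yet adjusted -- see :func:`bonferroni_adjust`.
    """
    custom_tests = custom_tests or {}
    valid = [p for p in pairs if p.is_valid]
    if not valid:
        warnings.warn("no valid cluster pairs: nothing to test", UserWarning, stacklevel=2)
        return []

    results: list[AssociationResult] = []
    for pair in valid:
        for name in outcomes.outcome_names:
            kind = outcomes.types.get(name, "custom")
            column = outcomes.column(name)
            left, right = _split_values(pair.members_left, pair.members_right, column)
            summary_l = _summary(left, kind)
            summary_r = _summary(right, kind)
            stat = p = float("nan")
            test_name, status = kind, "ok"
            try:
                if name in custom_tests:
                    stat, p = custom_tests[name](pair.members_left, pair.members_right, column)
                    test_name = "custom"
                    if not (0 <= p <= 1):
                        raise ValueError(
                            f"custom test for outcome '{name}' returned p={p} outside [0, 1]"
                        )
                elif kind == "categorical":
                    stat, p, test_name = fisher_exact(pair.members_left, pair.members_right, column)
                elif kind == "continuous":
                    stat, p, test_name = t_test(
                        pair.members_left, pair.members_right, column, kind=t_test_kind
                    )
                elif kind == "survival":
                    stat, p, test_name = logrank_test(pair.members_left, pair.members_right, column)
                else:
                    raise SkipTest(f"no test registered for outcome type '{kind}'")
            except SkipTest as exc:
                status = f"skipped: {exc}"
            results.append(
                AssociationResult(
                    cid_left=pair.cid_left,
                    cid_right=pair.cid_right,
                    outcome=name,
                    test=test_name,
                    statistic=stat,
                    p_raw=p,
                    p_adj=None,
                    n_left=len(left),
                    n_right=len(right),
                    summary_left=summary_l,
                    summary_right=summary_r,
                    status=status,
                )
            )
    return results


def bonferroni_adjust(
    results: list[AssociationResult], m: int, across_outcomes: bool = False, n_outcomes: int = 1
) -> list[AssociationResult]:
    """Set ``p_adj = min(1, p_raw * m)`` with ``m`` = number of valid pairs.

    The factor is the number of valid cluster pairs only; set
    ``across_outcomes=True`` to additionally multiply by ``n_outcomes``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    factor = m * (n_outcomes if across_outcomes else 1)
    for r in results:
        r.p_adj = min(1.0, r.p_raw * factor) if np.isfinite(r.p_raw) else float("nan")
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate results for export (TSV/JSON)."""
    cols = [
        "cid_left", "cid_right", "outcome", "test", "statistic",
        "p_raw", "p_adj", "n_left", "n_right",
        "summary_left", "summary_right", "status",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
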