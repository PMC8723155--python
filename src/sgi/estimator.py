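"""scikit-learn-style estimator tying the subgroup-identification stages together."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .associations import (
    OutcomeTable,
    bonferroni_adjust,
    results_to_frame,
    run_associations,
)
from .tree import assign_cluster_ids, build_tree, enumerate_valid_pairs, resolve_min_size

__all__ = ["SubgroupIdentification"]


class SubgroupIdentification(BaseEstimator):
    """Hierarchical subgroup identification with branch-point association testing.

    Clusters the samples hierarchically, enumerates every branch point where
    both subclusters reach ``min_size`` samples ("valid cluster pairs"), tests
    each valid pair against every clinical outcome with an automatically
    dispatched test (Fisher's exact / t-test / log-rank), and Bonferroni-adjusts
    the p-values by the number of valid pairs.

    Parameters
    ----------
    metric : str or "precomputed", default "euclidean"
        Distance metric; with "precomputed", ``fit`` expects a square distance
        matrix (e.g. a fused multi-omics distance) instead of a data matrix.
    linkage : str, default "ward"
        Agglomeration rule (ward/average/complete/single/...).
    min_size : float or int, default 0.05
        Minimum subcluster size for a testable pair; fractions of the sample
        size are rounded up.
    p_threshold : float, default 0.05
        Adjusted-p cutoff used by ``significant_`` and the plots.
    t_test : {"welch", "pooled"}, default "welch"
        Flavor of the two-sample t-test for continuous outcomes.
    correct_across_outcomes : bool, default False
        If True, the Bonferroni factor additionally includes the number of
        outcomes (the default factor is the number of valid pairs only).

    Attributes
    ----------
    tree_ : MergeTree
        The fitted clustering.
    splits_ : list of ClusterPair
        All n-1 splits with heap-style cluster IDs and validity flags.
    n_valid_pairs_ : int
        The Bonferroni factor m.
    min_size_count_ : int
        The resolved absolute size threshold.
    results_ : list of AssociationResult
    results_frame_ : DataFrame
        One row per (valid pair, outcome).
    labels_ : ndarray
        Top-split membership per sample (cluster ID 2 or 3), in input order.

    Examples
    --------
    >>> model = SubgroupIdentification(min_size=0.05)
    >>> model.fit(data, outcomes)           # doctest: +SKIP
    >>> model.significant_                  # doctest: +SKIP
    """

    def __init__(
        self,
        metric: str = "euclidean",
        linkage: str = "ward",
        min_size=0.05,
        p_threshold: float = 0.05,
        t_test: str = "welch",
        correct_across_outcomes: bool = False,
    ):
        self.metric = metric
        self.linkage = linkage
        self.min_size = min_size
        self.p_threshold = p_threshold
        self.t_test = t_test
        self.correct_across_outcomes = correct_across_outcomes

    # ------------------------------------------------------------------

    def fit(self, X, outcomes=None, custom_tests: dict | None = None):
        """Cluster ``X``, enumerate valid pairs and (optionally) test outcomes.

        Parameters
        ----------
        X : DataFrame (samples x features), or a square distance matrix when
            ``metric="precomputed"``.
        outcomes : OutcomeTable or DataFrame indexed by sample ID, optional.
            A plain DataFrame gets its column types inferred.
        custom_tests : mapping outcome name -> callable, optional.
        """
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if isinstance(self.min_size, float) and not (0 < self.min_size < 0.5):
            raise ValueError("fractional min_size must be in (0, 0.5)")
        if self.metric == "precomputed":
            if not isinstance(X, pd.DataFrame):
                X = pd.DataFrame(np.asarray(X, dtype=float))
            self.tree_ = build_tree(None, distance=X, linkage=self.linkage)
        else:
            self.tree_ = build_tree(X, distance=self.metric, linkage=self.linkage)
        self.n_samples_ = self.tree_.n_leaves
        self.min_size_count_ = resolve_min_size(self.min_size, self.n_samples_)
        self.splits_, self.n_valid_pairs_ = enumerate_valid_pairs(
            assign_cluster_ids(self.tree_), self.min_size
        )

        top = self.splits_[0]
        self.labels_ = np.array(
            [top.cid_left if s in top.members_left else top.cid_right for s in self.tree_.leaf_ids]
        )

        if outcomes is not None:
            if not isinstance(outcomes, OutcomeTable):
                outcomes = OutcomeTable(outcomes)
            self.outcomes_ = outcomes
            self.results_ = run_associations(
                self.splits_, outcomes, custom_tests=custom_tests, t_test_kind=self.t_test
            )
            if self.results_:
                bonferroni_adjust(
                    self.results_,
                    self.n_valid_pairs_,
                    across_outcomes=self.correct_across_outcomes,
                    n_outcomes=len(outcomes.outcome_names),
                )
            self.results_frame_ = results_to_frame(self.results_)
        else:
            self.outcomes_ = None
            self.results_ = []
            self.results_frame_ = results_to_frame([])
        return self

    def fit_predict(self, X, outcomes=None):
        """Fit and return the top-split cluster labels (IDs 2 and 3)."""
        return self.fit(X, outcomes).labels_

    # ------------------------------------------------------------------

    @property
    def significant_(self) -> pd.DataFrame:
        """Rows of ``results_frame_`` with status ok and p_adj <= p_threshold."""
        df = self.results_frame_
        if df.empty:
            return df
        return df[(df["status"] == "ok") & (df["p_adj"] <= self.p_threshold)]

    def membership(self, cid: int) -> frozenset:
        """Sample IDs belonging to heap-style cluster ``cid`` (1 = full cohort)."""
        if cid == 1:
            return frozenset(self.tree_.leaf_ids)
        for p in self.splits_:
            if p.cid_left == cid:
                return p.members_left
            if p.cid_right == cid:
                return p.members_right
        raise KeyError(f"no cluster with ID {cid}")

    def summary(self) -> dict:
        """Machine-readable run summary."""
        return {
            "n_samples": self.n_samples_,
            "min_size": self.min_size_count_,
            "min_size_param": self.min_size,
            "n_valid_pairs": self.n_valid_pairs_,
            "n_outcomes": len(self.outcomes_.outcome_names) if self.outcomes_ else 0,
            "n_results": len(self.results_),
            "n_significant": int(len(self.significant_)),
            "p_threshold": self.p_threshold,
            "metric": self.metric,
            "linkage": self.linkage,
        }
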