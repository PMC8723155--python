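"""Synthetic omics + outcomes datasets with planted subgroup structure.

The generator emulates the shape of a clinical metabolomics cohort: a samples
x features matrix of standardized abundances with group mean shifts on a
subset of features, and an outcomes table whose variables track the planted
groups.  Groups form a nested binary partition (each split refines its
parent), mirroring the hierarchical subgroups the clustering is meant to
recover.  Noise is standard normal, survival times are exponential with
group-wise hazard ratios and independent uniform censoring -- the simplest
models matching the downstream tests' assumptions; no attempt is made to
mimic real metabolomics covariance structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associations import OutcomeTable

__all__ = ["PlantedSplit", "OutcomeEffect", "PlantedDesign", "generate_planted"]


@dataclass
class PlantedSplit:
    """One binary partition of a group into L/R halves.

    ``parent`` is a path string: ``""`` splits the whole cohort, ``"L"``
    splits the left half of the root split, etc.  Members of the L side are
    shifted by +delta_x/2 and the R side by -delta_x/2 (a separation of
    ``delta_x`` standard deviations) on the designated features.
    """

    parent: str = ""
    delta_x: float = 2.0
    features: tuple = ()


@dataclass
class OutcomeEffect:
    """One outcome variable tracking a planted split.

    ``kind`` is ``continuous`` (mean shift ``effect`` in SD units),
    ``categorical`` (log-odds shift ``effect`` for a binary level) or
    ``survival`` (hazard ratio ``effect`` between sides).
    """

    name: str
    kind: str = "continuous"
    split: str = ""
    effect: float = 1.5


@dataclass
class PlantedDesign:
    """Full specification of a synthetic cohort; ``seed`` fixes all randomness."""

    n_samples: int = 200
    n_features: int = 100
    splits: list = field(default_factory=lambda: [PlantedSplit(features=tuple(range(20)))])
    outcomes: list = field(default_factory=lambda: [OutcomeEffect("y")])
    censoring: float = 0.2
    seed: int = 0

    def __post_init__(self):
        paths = {s.parent for s in self.splits}
        for s in self.splits:
            if s.parent and s.parent[:-1] not in paths:
                raise ValueError(f"split of '{s.parent}' has no parent split '{s.parent[:-1]}'")
            if s.delta_x < 0:
                raise ValueError("effect sizes must be >= 0")
            if s.delta_x > 0 and len(s.features) == 0:
                raise ValueError(f"split of '{s.parent or '<root>'}' plants an effect on an empty feature subset")
            if any(f >= self.n_features for f in s.features):
                raise ValueError("feature index out of range")
        for o in self.outcomes:
            if o.kind not in ("continuous", "categorical", "survival"):
                raise ValueError(f"unknown outcome kind '{o.kind}'")
            if o.effect < 0 and o.kind != "continuous":
                raise ValueError("categorical/survival effects must be >= 0")


def _group_paths(design: PlantedDesign) -> pd.Series:
    """Assign each sample its leaf group path by deterministic nested halving."""
    n = design.n_samples
    paths = [""] * n
    depth = max((len(s.parent) for s in design.splits), default=0) + 1
    idx_of = {"": np.arange(n)}
    for d in range(depth):
        for parent, members in list(idx_of.items()):
            if len(parent) != d:
                continue
            half = len(members) // 2
            idx_of[parent + "L"] = members[:half]
            idx_of[parent + "R"] = members[half:]
    for s in design.splits:
        for side in "LR":
            for i in idx_of[s.parent + side]:
                paths[i] = s.parent + side if len(s.parent + side) > len(paths[i]) else paths[i]
    return pd.Series(paths, name="group")


def _side_sign(paths: pd.Series, split_path: str) -> np.ndarray:
    """+1 for samples on the L side of the given split, -1 for R, 0 elsewhere."""
    depth = len(split_path)
    sign = np.zeros(len(paths))
    for i, p in enumerate(paths):
        if len(p) > depth and p.startswith(split_path):
            sign[i] = 1.0 if p[depth] == "L" else -1.0
    return sign


def generate_planted(design: PlantedDesign):
    """Generate ``(data, outcomes, truth)`` from a planted design.

    Returns the samples x features DataFrame, an :class:`OutcomeTable`, and a
    truth DataFrame with each sample's group path.  Identical seeds produce
    identical outputs.
    """
    rng = np.random.default_rng(design.seed)
    n, p = design.n_samples, design.n_features
    sample_ids = [f"S{i:04d}" for i in range(n)]
    paths = _group_paths(design)
    paths.index = sample_ids

    X = rng.standard_normal((n, p))
    for s in design.splits:
        sign = _side_sign(paths, s.parent)
        X[:, list(s.features)] += np.outer(sign, np.full(len(s.features), s.delta_x / 2))
    data = pd.DataFrame(X, index=sample_ids, columns=[f"F{j:04d}" for j in range(p)])

    out = pd.DataFrame(index=sample_ids)
    survival = {}
    for o in design.outcomes:
        sign = _side_sign(paths, o.split)
        if o.kind == "continuous":
            out[o.name] = sign * o.effect / 2 + rng.standard_normal(n)
        elif o.kind == "categorical":
            logit = sign * o.effect / 2
            prob = 1 / (1 + np.exp(-logit))
            out[o.name] = np.where(rng.random(n) < prob, "A", "B")
        else:  # survival: exponential times, hazard ratio `effect` between sides
            log_hr = np.log(o.effect) if o.effect > 0 else 0.0
            rate = np.exp(sign * log_hr / 2)
            times = rng.exponential(1.0 / rate)
            censored = rng.random(n) < design.censoring
            ctimes = rng.uniform(0, times)
            out[f"{o.name}_time"] = np.where(censored, ctimes, times)
            out[f"{o.name}_event"] = (~censored).astype(int)
            survival[o.name] = (f"{o.name}_time", f"{o.name}_event")

    truth = paths.to_frame()
    return data, OutcomeTable(out, survival=survival), truth
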