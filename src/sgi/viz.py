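"""Annotated dendrogram, overview figure and per-association detail plots.

The tree is drawn top-down with a circle at every valid split; significant
(pair, outcome) associations are written at their split's position with the
outcome name and adjusted p.  The overview stacks three panels sharing the
leaf order: the annotated tree, one track per outcome (heatmap for
continuous, color bands for categorical, event markers for survival) with
significance dots aligned under their splits, and the data matrix itself.

Every plotting function returns layout metadata (leaf order, annotation
records, track order) so tests can assert alignment and annotation counts
without parsing pixels.  SVG output is deterministic: the same inputs produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colors

from .associations import AssociationResult, OutcomeTable
from .tree import ClusterPair, MergeTree

__all__ = ["TreeLayout", "plot_tree", "plot_overview", "plot_association"]

# fixed hash salt + no timestamps -> byte-identical SVG across runs
matplotlib.rcParams["svg.hashsalt"] = "sgi"
_SAVEFIG_KW = {"metadata": {"Date": None}}


@dataclass
class TreeLayout:
    """Geometry and annotation metadata returned by the plotting functions."""

    leaf_order: list  # sample IDs left-to-right
    split_xy: dict  # cid_left -> (x, height) of the split marker
    annotations: list  # records: {cid_left, cid_right, outcome, p_adj, x, y}
    tracks: list = field(default_factory=list)  # outcome names, top to bottom


def _save(fig, out):
    if out is not None:
        fig.savefig(out, **_SAVEFIG_KW)
        plt.close(fig)


def _tree_geometry(tree: MergeTree):
    """x position of every node with leaves at 0..n-1 in dendrogram order."""
    n = tree.n_leaves
    order = tree.leaf_order()
    leaf_x = np.empty(n)
    leaf_x[order] = np.arange(n)
    x = np.empty(2 * n - 1)
    x[:n] = leaf_x
    y = np.zeros(2 * n - 1)
    for i, (a, b) in enumerate(tree.merges):
        x[n + i] = (x[a] + x[b]) / 2
        y[n + i] = tree.heights[i]
    return x, y, [tree.leaf_ids[i] for i in order]


def _draw_tree(ax, tree: MergeTree, splits, results, p_threshold):
    n = tree.n_leaves
    x, y, leaf_order = _tree_geometry(tree)
    for i, (a, b) in enumerate(tree.merges):
        h = tree.heights[i]
        ax.plot([x[a], x[a], x[b], x[b]], [y[a], h, h, y[b]], color="0.3", lw=0.9)

    # map cluster pairs to their merge node via the member sets
    members = tree.members()
    node_of = {ms: n + i for i, ms in enumerate(members)}
    split_xy = {}
    for p in splits:
        node = node_of[p.members_left | p.members_right]
        if p.is_valid:
            ax.plot(x[node], y[node], "o", mfc="white", mec="0.2", ms=6, zorder=3)
        split_xy[p.cid_left] = (float(x[node]), float(y[node]))

    annotations = []
    if results:
        sig = [
            r for r in results
            if r.status == "ok" and r.p_adj is not None and r.p_adj <= p_threshold
        ]
        for r in sig:
            px, py = split_xy[r.cid_left]
            ax.annotate(
                f"{r.outcome}\np={r.p_adj:.2g}",
                (px, py),
                textcoords="offset points",
                xytext=(4, 4),
                fontsize=7,
                color="firebrick",
            )
            annotations.append(
                {"cid_left": r.cid_left, "cid_right": r.cid_right,
                 "outcome": r.outcome, "p_adj": r.p_adj, "x": px, "y": py}
            )
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_xticks([])
    ax.set_ylabel("height")
    for side in ("top", "right", "bottom"):
        ax.spines[side].set_visible(False)
    return TreeLayout(leaf_order=leaf_order, split_xy=split_xy, annotations=annotations)


def plot_tree(
    tree: MergeTree,
    splits: list[ClusterPair],
    results: list[AssociationResult] | None = None,
    p_threshold: float = 0.05,
    out=None,
    figsize=(8, 4),
) -> TreeLayout:
    """Draw the dendrogram with valid-split markers and significant associations.

    Returns a :class:`TreeLayout`; if ``out`` is given the figure is written
    there (format from the extension; SVG output is reproducible).
    """
    if not results:
        import warnings

        warnings.warn("no association results: tree drawn without annotations",
                      UserWarning, stacklevel=2)
    fig, ax = plt.subplots(figsize=figsize)
    layout = _draw_tree(ax, tree, splits, results or [], p_threshold)
    fig.tight_layout()
    _save(fig, out)
    return layout


def _draw_track(ax, values, kind, leaf_order):
    n = len(leaf_order)
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_yticks([])
    ax.set_xticks([])
    if kind == "survival":
        t = values["time"].reindex(leaf_order).to_numpy(float)
        e = values["event"].reindex(leaf_order).to_numpy(float)
        tmax = np.nanmax(t) if np.isfinite(t).any() else 1.0
        norm = colors.Normalize(0, tmax or 1.0)
        ax.imshow(t[None, :], aspect="auto", cmap="viridis", norm=norm,
                  extent=(-0.5, n - 0.5, 0, 1))
        ev = np.where(e == 1)[0]
        ax.plot(ev, np.full(len(ev), 0.5), "k.", ms=2)
        return
    vals = values.reindex(leaf_order)
    if kind == "categorical":
        levels = sorted(vals.dropna().unique(), key=str)
        lut = {lv: i for i, lv in enumerate(levels)}
        arr = np.array([lut.get(v, np.nan) for v in vals], dtype=float)
        cmap = matplotlib.colormaps["tab10"].resampled(max(len(levels), 1))
        ax.imshow(arr[None, :], aspect="auto", cmap=cmap,
                  vmin=-0.5, vmax=max(len(levels), 1) - 0.5,
                  extent=(-0.5, n - 0.5, 0, 1))
    else:
        arr = vals.to_numpy(float)
        ax.imshow(arr[None, :], aspect="auto", cmap="viridis",
                  extent=(-0.5, n - 0.5, 0, 1))


def plot_overview(
    tree: MergeTree,
    splits: list[ClusterPair],
    results: list[AssociationResult],
    outcomes: OutcomeTable,
    data: pd.DataFrame,
    p_threshold: float = 0.05,
    out=None,
    figsize=(9, 8),
) -> TreeLayout:
    """Tree + per-outcome tracks + data heatmap, all sharing the leaf order.

    Significance dots in the track panel sit at the x position of their split,
    horizontally aligned with the split markers on the tree above.
    """
    missing = set(tree.leaf_ids) - set(data.index)
    if missing:
        raise ValueError(f"data is missing tree samples: {sorted(map(str, missing))}")

    names = outcomes.outcome_names
    n_tracks = len(names)
    heights = [3] + [0.35] * n_tracks + [3]
    fig, axes = plt.subplots(
        len(heights), 1, figsize=figsize,
        gridspec_kw={"height_ratios": heights, "hspace": 0.15},
    )
    axes = np.atleast_1d(axes)
    layout = _draw_tree(axes[0], tree, splits, results, p_threshold)
    leaf_order = layout.leaf_order

    sig_by_outcome: dict[str, list] = {}
    for r in results:
        if r.status == "ok" and r.p_adj is not None and r.p_adj <= p_threshold:
            sig_by_outcome.setdefault(r.outcome, []).append(layout.split_xy[r.cid_left][0])
    for ax, name in zip(axes[1:-1], names):
        _draw_track(ax, outcomes.column(name), outcomes.types[name], leaf_order)
        for sx in sig_by_outcome.get(name, []):
            ax.plot(sx, 0.5, "o", color="red", ms=4, mec="white", mew=0.5, zorder=4)
        ax.set_ylabel(name, rotation=0, ha="right", va="center", fontsize=7)

    mat = data.reindex(leaf_order).to_numpy(float).T
    axes[-1].imshow(mat, aspect="auto", cmap="RdBu_r",
                    extent=(-0.5, len(leaf_order) - 0.5, 0, mat.shape[0]))
    axes[-1].set_xticks([])
    axes[-1].set_ylabel("features")
    layout.tracks = list(names)
    _save(fig, out)
    return layout


def plot_association(
    pair: ClusterPair,
    column,
    kind: str,
    p_adj: float | None = None,
    status: str = "ok",
    out=None,
    figsize=(4, 4),
):
    """Detail plot for one (pair, outcome): boxplots, proportion bars or KM curves.

    ``column`` is the outcome Series (or time/event frame for survival) indexed
    by sample ID; ``kind`` its outcome type.  Raises if the test was skipped.
    """
    if status != "ok":
        raise ValueError(f"association was not tested ({status})")
    left = column.loc[column.index.intersection(list(pair.members_left))].dropna()
    right = column.loc[column.index.intersection(list(pair.members_right))].dropna()
    labels = [f"cluster {pair.cid_left}", f"cluster {pair.cid_right}"]
    fig, ax = plt.subplots(figsize=figsize)
    meta = {"cid_left": pair.cid_left, "cid_right": pair.cid_right, "kind": kind}

    if kind == "continuous":
        ax.boxplot([left.to_numpy(float), right.to_numpy(float)], tick_labels=labels)
        ax.set_ylabel(getattr(column, "name", "value"))
    elif kind == "categorical":
        levels = sorted(set(left.unique()) | set(right.unique()), key=str)
        props = []
        for vals in (left, right):
            c = vals.value_counts()
            props.append([c.get(lv, 0) / max(len(vals), 1) for lv in levels])
        bottoms = np.zeros(2)
        cmap = matplotlib.colormaps["tab10"].resampled(max(len(levels), 1))
        for i, lv in enumerate(levels):
            h = [props[0][i], props[1][i]]
            ax.bar([0, 1], h, bottom=bottoms, label=str(lv), color=cmap(i))
            bottoms += h
        ax.set_xticks([0, 1], labels)
        ax.set_ylabel("proportion")
        ax.legend(fontsize=7)
        meta["proportions"] = {labels[0]: props[0], labels[1]: props[1]}
    elif kind == "survival":
        from lifelines import KaplanMeierFitter

        for vals, lab in ((left, labels[0]), (right, labels[1])):
            km = KaplanMeierFitter()
            km.fit(vals["time"], vals["event"], label=lab)
            km.plot_survival_function(ax=ax, ci_show=False)
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
    else:
        raise ValueError(f"no detail plot for outcome type '{kind}'")

    title = f"clusters {pair.cid_left} vs {pair.cid_right}"
    if p_adj is not None:
        title += f"  (adj. p = {p_adj:.3g})"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    _save(fig, out)
    return meta
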