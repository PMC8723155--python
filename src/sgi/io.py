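"""File readers/writers, run configuration and the end-to-end pipeline.

The pipeline runs cluster -> enumerate valid pairs -> test -> adjust -> plot
and writes everything a downstream analyst needs: the results table (TSV),
the merge table and Newick tree, the figures, and a machine-readable summary
(sample count, valid-pair count m, resolved size threshold, significant
count).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .associations import OutcomeTable
from .estimator import SubgroupIdentification
from .multiomics import fuse_distances
from .viz import plot_association, plot_overview, plot_tree

__all__ = ["RunConfig", "read_matrix", "read_distance", "read_outcomes", "run_pipeline"]

log = logging.getLogger("sgi")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dupes}")
    df.index = df.index.astype(str)
    return df


def read_matrix(path) -> pd.DataFrame:
    """Read a samples x features matrix (first column = sample ID, header = features)."""
    df = _read_table(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"{path}: non-numeric value at row '{row}', column '{col}'")
        df[col] = coerced
    return df


def read_distance(path) -> pd.DataFrame:
    """Read a square precomputed distance matrix with matching row/column IDs."""
    df = read_matrix(path)
    df.columns = df.columns.astype(str)
    if set(df.index) != set(df.columns):
        raise ValueError(f"{path}: row and column sample IDs differ")
    return df.reindex(columns=df.index)


def read_outcomes(path, survival: dict | None = None, types: dict | None = None,
                  sample_ids=None) -> OutcomeTable:
    """Read the outcomes table and align it to the clustering samples by ID.

    Outcome rows for samples absent from ``sample_ids`` are dropped with a
    warning; samples without an outcome row keep missing values.
    """
    df = _read_table(path)
    if sample_ids is not None:
        extra = [s for s in df.index if s not in set(map(str, sample_ids))]
        if extra:
            warnings.warn(f"{len(extra)} outcome rows have no matching sample and are ignored: "
                          f"{extra[:5]}{'...' if len(extra) > 5 else ''}", UserWarning, stacklevel=2)
            log.info("unmatched outcome samples ignored: %s", extra)
        df = df.reindex([str(s) for s in sample_ids])
    return OutcomeTable(df, survival=survival or {}, types=types or {})


@dataclass
class RunConfig:
    """Configuration of one pipeline run; YAML-loadable, CLI-overridable."""

    data: list = field(default_factory=list)  # data matrix paths
    distance: list = field(default_factory=list)  # precomputed distance paths
    outcomes: str | None = None
    metric: str = "euclidean"
    linkage: str = "ward"
    min_size: float = 0.05  # fraction of n (or absolute count if >= 1)
    p_threshold: float = 0.05
    survival: dict = field(default_factory=dict)  # name -> (time_col, event_col)
    types: dict = field(default_factory=dict)
    out_dir: str = "sgi_out"
    seed: int = 0
    log_level: str = "INFO"
    figures: bool = True

    def __post_init__(self):
        if isinstance(self.min_size, float) and not (0 < self.min_size < 0.5) and self.min_size < 1:
            raise ValueError("fractional min_size must be in (0, 0.5)")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "survival" in raw:
            raw["survival"] = {k: tuple(v) for k, v in raw["survival"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["survival"] = {k: list(v) for k, v in self.survival.items()}
        return d


def _build_distance(config: RunConfig):
    """Resolve the clustering input: single matrix, or fused multi-block distance."""
    dist_blocks = [read_distance(p) for p in config.distance]
    data_frames = [read_matrix(p) for p in config.data]
    if len(data_frames) + len(dist_blocks) == 0:
        raise ValueError("no input: provide at least one data or distance block")
    if len(data_frames) == 1 and not dist_blocks:
        return data_frames[0], None  # plain single-omics run
    from scipy.spatial.distance import pdist, squareform

    blocks = {}
    for i, df in enumerate(data_frames):
        d = squareform(pdist(df.to_numpy(float), metric=config.metric))
        blocks[f"data{i + 1}"] = pd.DataFrame(d, index=df.index, columns=df.index)
    for i, df in enumerate(dist_blocks):
        blocks[f"distance{i + 1}"] = df
    fused = fuse_distances(blocks)
    primary = data_frames[0] if data_frames else None
    return primary, fused


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all outputs to ``config.out_dir``.

    Returns the machine-readable summary (also written as ``summary.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run configuration: %s", json.dumps(config.to_dict(), default=str))

    stage = "read inputs"
    try:
        data, fused = _build_distance(config)
        outcomes = None
        if config.outcomes:
            ids = data.index if data is not None else fused.sample_ids
            outcomes = read_outcomes(config.outcomes, survival=config.survival,
                                     types=config.types, sample_ids=ids)

        stage = "cluster and test"
        if fused is not None:
            model = SubgroupIdentification(
                metric="precomputed", linkage=config.linkage,
                min_size=config.min_size, p_threshold=config.p_threshold,
            ).fit(fused.matrix, outcomes)
        else:
            model = SubgroupIdentification(
                metric=config.metric, linkage=config.linkage,
                min_size=config.min_size, p_threshold=config.p_threshold,
            ).fit(data, outcomes)

        stage = "export"
        model.results_frame_.to_csv(out / "results.tsv", sep="\t", index=False)
        model.tree_.to_merge_table().to_csv(out / "merge_table.tsv", sep="\t", index=False)
        (out / "tree.newick").write_text(model.tree_.to_newick() + "\n")
        for r in model.results_:
            if r.status != "ok":
                log.info("skipped %s at %d/%d: %s", r.outcome, r.cid_left, r.cid_right, r.status)

        if config.figures:
            stage = "plot"
            plot_tree(model.tree_, model.splits_, model.results_,
                      p_threshold=config.p_threshold, out=out / "tree.svg")
            if outcomes is not None and data is not None:
                plot_overview(model.tree_, model.splits_, model.results_, outcomes,
                              data, p_threshold=config.p_threshold, out=out / "overview.svg")

        summary = model.summary()
        summary["seed"] = config.seed
        summary["outputs"] = sorted(p.name for p in out.iterdir())
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
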