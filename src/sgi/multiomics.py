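"""Fusion of per-omics-block sample distance matrices.

Different omics layers (e.g. plasma, urine and saliva metabolomics) produce
distances on incomparable scales because they have different numbers of
variables.  Before joint clustering, each block's distance matrix is divided
by its maximum and the normalized matrices are summed:

    D = D1/max(D1) + D2/max(D2) + ... + Dl/max(Dl)

so every block contributes on a common [0, 1] scale and the fused matrix can
be fed to any linkage rule.  Blocks are unweighted; matrices from external
similarity methods (similarity network fusion, multiple kernel learning, ...)
plug in as precomputed blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FusedDistance", "fuse_distances"]


@dataclass
class FusedDistance:
    """Fused sample x sample distance with per-block normalization factors."""

    sample_ids: list
    matrix: pd.DataFrame
    block_names: list
    block_maxima: dict

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def _coerce_block(block, name, allow_positional):
    if isinstance(block, pd.DataFrame):
        if not block.index.equals(block.columns):
            if set(block.index) != set(block.columns):
                raise ValueError(f"block '{name}': row and column IDs differ")
            block = block.reindex(columns=block.index)
        return block
    if not allow_positional:
        raise ValueError(
            f"block '{name}' has no sample IDs; pass DataFrames or set allow_positional=True"
        )
    arr = np.asarray(block, dtype=float)
    return pd.DataFrame(arr, index=range(arr.shape[0]), columns=range(arr.shape[0]))


def fuse_distances(blocks, names=None, allow_positional: bool = False) -> FusedDistance:
    """Fuse l >= 1 square distance matrices into one by max-normalized summation.

    Parameters
    ----------
    blocks : sequence of square DataFrames (sample IDs on both axes) or a
        mapping name -> matrix.  Plain arrays are accepted only with
        ``allow_positional=True`` (IDs become positions).
    names : optional block names when ``blocks`` is a sequence.

    Every block must be symmetric with a zero diagonal and a positive maximum;
    samples are aligned across blocks by ID, and a mismatch in sample sets is
    an error.  The result is invariant to block order and to rescaling any
    block by a positive constant.
    """
    if isinstance(blocks, dict):
        names = list(blocks)
        blocks = list(blocks.values())
    else:
        blocks = list(blocks)
        names = list(names) if names is not None else [f"block{i + 1}" for i in range(len(blocks))]
    if len(blocks) < 1:
        raise ValueError("at least one distance block is required")
    if len(names) != len(blocks):
        raise ValueError("number of names must match number of blocks")

    frames = [_coerce_block(b, nm, allow_positional) for b, nm in zip(blocks, names)]
    ref_ids = list(frames[0].index)
    for nm, f in zip(names[1:], frames[1:]):
        if set(f.index) != set(ref_ids):
            only_ref = sorted(set(map(str, set(ref_ids) - set(f.index))))
            only_blk = sorted(set(map(str, set(f.index) - set(ref_ids))))
            raise ValueError(
                f"block '{nm}' sample set mismatch: missing {only_ref or 'none'}, "
                f"extra {only_blk or 'none'}"
            )

    fused = np.zeros((len(ref_ids), len(ref_ids)))
    maxima = {}
    off_diag = ~np.eye(len(ref_ids), dtype=bool)
    for nm, f in zip(names, frames):
        mat = f.reindex(index=ref_ids, columns=ref_ids).to_numpy(dtype=float)
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"block '{nm}' contains non-finite distances")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError(f"block '{nm}' is not symmetric")
        if not np.allclose(np.diag(mat), 0.0):
            raise ValueError(f"block '{nm}' diagonal is not zero")
        # max over off-diagonal entries (the diagonal is 0 by contract)
        mx = float(mat[off_diag].max()) if len(ref_ids) > 1 else 0.0
        if mx <= 0:
            raise ValueError(f"block '{nm}' is all zero: maximum undefined as a divisor")
        maxima[nm] = mx
        fused += mat / mx
    np.fill_diagonal(fused, 0.0)
    fused = (fused + fused.T) / 2  # enforce exact symmetry
    return FusedDistance(
        sample_ids=ref_ids,
        matrix=pd.DataFrame(fused, index=ref_ids, columns=ref_ids),
        block_names=names,
        block_maxima=maxima,
    )
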