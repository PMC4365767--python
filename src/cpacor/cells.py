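"""Reference-based white-cell composition estimation.

Houseman-style constrained projection: each sample's beta profile at a set
of cell-type-discriminative reference markers is projected onto the
reference matrix under a nonnegativity constraint,

    min_w || y - B0 w ||^2   s.t.  w >= 0,

with no sum-to-one constraint (the measured total white-cell count enters
the downstream regressions as its own covariate). Reference markers absent
from the array are dropped with a logged count; markers with missing beta
are dropped per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_model import BetaMatrix

__all__ = ["CellEstimates", "estimate_wbc", "read_reference", "write_reference"]

log = logging.getLogger(__name__)


@dataclass
class CellEstimates:
    """Nonnegative cell-type weights per sample plus fit diagnostics."""

    weights: pd.DataFrame           # samples x cell types
    markers_used: pd.Index
    residual_norm: pd.Series        # per-sample ||y - B0 w||


def estimate_wbc(beta: BetaMatrix, reference: pd.DataFrame) -> CellEstimates:
    """Estimate cell-type proportions for every sample by NNLS projection.

    ``reference`` is a markers x cell-types beta matrix. At least two
    reference markers must intersect the data. Rank deficiency of the
    intersected reference triggers a warning and a least-squares
    pseudo-inverse fallback (weights clipped at zero).
    """
    inter = reference.index.intersection(beta.marker_ids)
    n_absent = len(reference.index) - len(inter)
    if n_absent:
        log.info("dropping %d reference marker(s) absent from the array", n_absent)
    if len(inter) < 2:
        raise ValueError("fewer than 2 reference markers intersect the data")
    B0_full = reference.loc[inter].to_numpy()
    rank_ok = np.linalg.matrix_rank(B0_full) == B0_full.shape[1]
    if not rank_ok:
        log.warning("reference is rank-deficient on the intersected markers; "
                    "falling back to pseudo-inverse estimates clipped at zero")

    rows = beta.marker_ids.get_indexer(inter)
    Y = beta.beta[rows]                            # ref markers x samples
    K = B0_full.shape[1]
    n_s = Y.shape[1]
    W = np.zeros((n_s, K))
    rnorm = np.zeros(n_s)
    for j in range(n_s):
        ok = ~np.isnan(Y[:, j])
        y = Y[ok, j]
        B0 = B0_full[ok]
        if y.size < 2:
            W[j] = np.nan
            rnorm[j] = np.nan
            continue
        if rank_ok:
            W[j], rnorm[j] = nnls(B0, y)
        else:
            w = np.clip(np.linalg.pinv(B0) @ y, 0.0, None)
            W[j] = w
            rnorm[j] = float(np.linalg.norm(y - B0 @ w))
    weights = pd.DataFrame(W, index=beta.sample_ids, columns=reference.columns)
    return CellEstimates(weights=weights, markers_used=inter,
                         residual_norm=pd.Series(rnorm, index=beta.sample_ids))


def read_reference(path) -> pd.DataFrame:
    """Read a reference beta matrix TSV (marker_id + one column per cell type)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    if "marker_id" not in df.columns:
        raise ValueError("reference file missing required column: marker_id")
    return df.set_index("marker_id")


def write_reference(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, sep="\t", index_label="marker_id", float_format="%.12g")
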