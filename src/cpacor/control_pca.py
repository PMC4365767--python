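"""Control Probe Adjustment: PCA of control-probe intensities.

Technical batch structure (bisulfite batch, chip, scanner dye balance)
expresses itself in the intensities of the assay control probes. A PCA of
those intensities (negative controls excluded, one feature per control
probe per colour channel) gives per-sample scores; the leading components
(default 30) enter downstream regressions as covariates and absorb the
batch variation without requiring the experimental factors to be known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ControlManifest, RawIntensities

__all__ = ["ControlPCs", "control_feature_matrix", "control_pcs", "pca_scores"]

log = logging.getLogger(__name__)


@dataclass
class ControlPCs:
    """Sample scores, feature loadings, and explained-variance fractions."""

    scores: pd.DataFrame            # samples x k
    loadings: pd.DataFrame          # features x k
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def control_feature_matrix(raw: RawIntensities, control_manifest: ControlManifest,
                           log_transform: bool = False) -> pd.DataFrame:
    """One feature per (non-negative control probe, colour channel).

    Rows are features (ordered control id, then channel green before red),
    columns are samples. Features with zero variance are dropped with a log
    entry; raising on an all-negative manifest is deliberate because the
    PCA would have nothing to work with.
    """
    cats = control_manifest.df["category"].reindex(raw.control_ids)
    keep = (cats != "negative").to_numpy()
    if not keep.any():
        raise ValueError("no non-negative-control probes available for PCA")
    ids = raw.control_ids[keep]
    rows, names = [], []
    for i, cid in zip(np.flatnonzero(keep), ids):
        rows.append(raw.control_green[i])
        names.append(f"{cid}.green")
        rows.append(raw.control_red[i])
        names.append(f"{cid}.red")
    X = pd.DataFrame(np.vstack(rows), index=names, columns=raw.sample_ids)
    if log_transform:
        X = np.log1p(X)
    var = X.var(axis=1, ddof=1)
    dropped = var.index[var == 0]
    if len(dropped):
        log.info("dropping %d zero-variance control feature(s)", len(dropped))
        X = X.drop(index=dropped)
    return X


def pca_scores(X: np.ndarray, k: int, scale: bool = True
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of samples x features ``X`` via SVD.

    Columns are centred (and scaled to unit variance when ``scale``).
    Returns (scores [n x k], loadings [p x k], explained-variance ratios).
    Sign convention: within each component the largest-magnitude loading is
    positive, which makes results deterministic across LAPACK builds.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    kmax = min(n, p) - 1
    if k > kmax:
        raise ValueError(f"k={k} too large; at most {kmax} components available")
    Z = X - X.mean(axis=0)
    if scale:
        sd = Z.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = Z / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total_var = (s ** 2).sum()
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    flip = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    scores = U * s
    evr = (s ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, Vt.T, evr


def control_pcs(features: pd.DataFrame, k: int = 30, scale: bool = True
                ) -> ControlPCs:
    """PCA of the control feature matrix (features x samples).

    Features are centred and, by default, scaled to unit variance before
    the SVD (control categories span very different intensity magnitudes).
    Score columns are mutually orthogonal; explained-variance fractions are
    nonincreasing.
    """
    X = features.to_numpy().T                      # samples x features
    scores, loadings, evr = pca_scores(X, k, scale=scale)
    cols = [f"cpPC{i+1}" for i in range(k)]
    return ControlPCs(
        scores=pd.DataFrame(scores, index=features.columns, columns=cols),
        loadings=pd.DataFrame(loadings, index=features.index, columns=cols),
        explained_variance_ratio=evr,
    )
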