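"""Stratified quantile normalisation of intensities and beta computation.

The recommended scheme (``QN-I6``) quantile-normalises raw intensities
within six probe categories defined by probe type, colour channel and M/U
role: Type-I M red, Type-I U red, Type-I M green, Type-I U green, Type-II
red, Type-II green (Type II probes read M in green and U in red). Betas are
then computed as M / (M + U + offset) with the Illumina offset of 100.

Comparison variants: ``QN-I4`` (channel x probe type, M and U pooled),
``QN-I2`` (channel only), ``QN-B3`` (quantile normalisation of beta values
within Type II / Type I red / Type I green), and ``none`` (pass-through).

Quantile normalisation handles missing values limma-style: the reference
distribution is the mean of per-sample quantile functions on a common grid;
each sample's non-missing values are replaced by the reference evaluated at
their (fractional, interpolated) ranks, and tied input values receive the
mean of the reference values over their rank span, which keeps the
operation deterministic and idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import BetaMatrix, Manifest, RawIntensities

__all__ = [
    "SCHEMES",
    "stratify",
    "quantile_normalize",
    "compute_beta",
    "normalize",
]

SCHEMES = ("QN-B3", "QN-I2", "QN-I4", "QN-I6", "none")


def _canon_scheme(scheme: str) -> str:
    s = str(scheme).upper().replace("_", "-")
    if s in ("NONE", "RAW"):
        return "none"
    if s in ("QN-B3", "QN-I2", "QN-I4", "QN-I6"):
        return s
    raise ValueError(f"unknown normalisation scheme {scheme!r}; choose from {SCHEMES}")


def _intensity_category(scheme: str, probe_type: str, channel: str, role: str) -> str:
    """Category label for one (marker, M/U role) intensity vector."""
    if probe_type == "II":
        chan = "green" if role == "M" else "red"    # Type II routing
    elif probe_type == "I":
        chan = channel
    else:
        raise ValueError(f"unknown probe_type {probe_type!r}")
    if scheme == "QN-I2":
        return chan
    if scheme == "QN-I4":
        return f"Type{probe_type}-{chan}"
    if scheme == "QN-I6":
        if probe_type == "II":
            return f"TypeII-{chan}"
        return f"TypeI-{role}-{chan}"
    raise ValueError(f"{scheme} is not an intensity scheme")


def stratify(raw: RawIntensities, manifest: Manifest, scheme: str = "QN-I6",
             ) -> list[tuple[str, np.ndarray]]:
    """Split M/U intensities into normalisation categories.

    Returns ``[(label, submatrix), ...]`` where each submatrix stacks the
    intensity vectors (rows) assigned to that category; masked entries are
    NaN. Every (marker, role) pair lands in exactly one category, so the
    category sizes sum to 2 x n_markers.
    """
    scheme = _canon_scheme(scheme)
    if scheme == "none":
        raise ValueError("scheme 'none' defines no categories")
    if scheme == "QN-B3":
        raise ValueError("QN-B3 stratifies beta values, not intensities; "
                         "use normalize() directly")
    groups = _intensity_groups(raw, manifest, scheme)
    out = []
    M = np.where(raw.missing_mask, np.nan, raw.M)
    U = np.where(raw.missing_mask, np.nan, raw.U)
    for label, entries in groups.items():
        rows = [(M if role == "M" else U)[i] for i, role in entries]
        out.append((label, np.vstack(rows)))
    return out


def _intensity_groups(raw, manifest, scheme):
    ptype = manifest.df["probe_type"].to_numpy()
    chan = manifest.df["channel"].to_numpy()
    groups: dict[str, list[tuple[int, str]]] = {}
    for i in range(len(ptype)):
        for role in ("M", "U"):
            label = _intensity_category(scheme, ptype[i], chan[i], role)
            groups.setdefault(label, []).append((i, role))
    return groups


def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile-normalise columns (samples) of ``X``; NaN entries stay NaN.

    Reference distribution: the mean over samples of each sample's
    empirical quantile function evaluated on a common grid of length
    n_rows. Complete samples are replaced rank-for-rank by the reference;
    samples with missing values use interpolated fractional ranks. Tied
    values receive the mean of their reference span.
    """
    X = np.asarray(X, dtype=float)
    n_rows, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("quantile normalisation needs >= 2 samples")
    counts = (~np.isnan(X)).sum(axis=0)
    if (counts < 2).any():
        j = int(np.argmax(counts < 2))
        raise ValueError(f"sample column {j} has fewer than 2 non-missing values")

    grid = np.linspace(0.0, 1.0, n_rows)
    ref = np.zeros(n_rows)
    sorted_cols = []
    for j in range(n_samp):
        v = np.sort(X[~np.isnan(X[:, j]), j])
        sorted_cols.append(v)
        if v.size == n_rows:
            ref += v
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, v.size), v)
    ref /= n_samp

    out = np.full_like(X, np.nan)
    for j in range(n_samp):
        obs = np.flatnonzero(~np.isnan(X[:, j]))
        v = X[obs, j]
        nj = v.size
        order = np.argsort(v, kind="stable")
        if nj == n_rows:
            assigned_sorted = ref
        else:
            assigned_sorted = np.interp(np.linspace(0.0, 1.0, nj), grid, ref)
        res = np.empty(nj)
        res[order] = assigned_sorted
        uv, inv = np.unique(v, return_inverse=True)
        if uv.size < nj:                            # ties: average over the span
            sums = np.bincount(inv, weights=res)
            cnts = np.bincount(inv)
            res = (sums / cnts)[inv]
        out[obs, j] = res
    return out


def compute_beta(raw: RawIntensities, offset: float = 100.0) -> BetaMatrix:
    """beta = M / (M + U + offset); masked entries become NaN.

    The positive offset stabilises low-intensity probes and bounds beta
    strictly below 1.
    """
    if offset <= 0:
        raise ValueError("beta offset must be > 0")
    beta = raw.M / (raw.M + raw.U + offset)
    beta = np.where(raw.missing_mask, np.nan, beta)
    return BetaMatrix(raw.marker_ids, raw.sample_ids, beta, offset)


def normalize(raw: RawIntensities, manifest: Manifest, scheme: str = "QN-I6",
              offset: float = 100.0) -> BetaMatrix:
    """Run the selected normalisation scheme and return beta values.

    Intensity schemes (QN-I2/I4/I6): stratify -> quantile-normalise each
    category -> recombine -> compute beta. QN-B3 computes betas first and
    quantile-normalises them within Type II / Type I red / Type I green.
    Scheme "none" is compute_beta on the raw intensities.
    """
    scheme = _canon_scheme(scheme)
    if scheme == "none":
        return compute_beta(raw, offset)

    if scheme == "QN-B3":
        beta = compute_beta(raw, offset)
        ptype = manifest.df["probe_type"].to_numpy()
        chan = manifest.df["channel"].to_numpy()
        labels = np.where(ptype == "II", "TypeII",
                          np.where(chan == "red", "TypeI-red", "TypeI-green"))
        b = beta.beta.copy()
        for label in np.unique(labels):
            rows = labels == label
            b[rows] = quantile_normalize(b[rows])
        b = np.clip(b, 0.0, np.nextafter(1.0, 0.0))
        return BetaMatrix(raw.marker_ids, raw.sample_ids, b, offset)

    groups = _intensity_groups(raw, manifest, scheme)
    M = np.where(raw.missing_mask, np.nan, raw.M.copy())
    U = np.where(raw.missing_mask, np.nan, raw.U.copy())
    for entries in groups.values():
        rows = [(M if role == "M" else U)[i] for i, role in entries]
        normed = quantile_normalize(np.vstack(rows))
        for r, (i, role) in enumerate(entries):
            if role == "M":
                M[i] = normed[r]
            else:
                U[i] = normed[r]
    beta = M / (M + U + offset)
    return BetaMatrix(raw.marker_ids, raw.sample_ids, beta, offset)
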