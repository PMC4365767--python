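"""Core data containers and tab-separated readers/writers.

All downstream stages share four containers: a marker :class:`Manifest`
(probe geometry: chromosome, position, Infinium probe type, colour channel,
quality flags), a :class:`ControlManifest` (assay control probes and their
chemistry category), :class:`RawIntensities` (methylated / unmethylated
signal per marker per sample plus control-probe intensities in both colour
channels, with an explicit missingness mask), and a :class:`CovariateTable`
(phenotype and adjustment covariates per sample).

Conventions
-----------
* Coordinates are 1-based positions of the CpG site on the forward strand.
* Missingness is carried as an explicit boolean mask (intensities) or NaN
  (beta values), never as sentinel magic numbers.
* Marker order (manifest order) and sample order (covariate order) are the
  single source of truth; every operation preserves them.
* Flagged markers (non-CpG, cross-hybridising, SNP-in-probe) are retained
  throughout the pipeline and echoed in outputs, never silently dropped.

On-disk dialect: tab-separated text with a header row, decimal point ".",
missing values written as ``NA``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Manifest",
    "ControlManifest",
    "RawIntensities",
    "BetaMatrix",
    "CovariateTable",
    "AssociationResult",
    "read_dataset",
    "write_dataset",
    "write_association",
    "read_association",
    "FLAG_CATEGORIES",
    "PROBE_TYPES",
    "CHANNELS",
]

FLAG_CATEGORIES = ("non_cpg", "cross_hybridising", "snp_in_probe")
PROBE_TYPES = ("I", "II")
CHANNELS = ("red", "green", "both")

_NA = "NA"


class DatasetError(ValueError):
    """Raised when an input file or container violates a contract."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise DatasetError(msg)


@dataclass
class Manifest:
    """Marker annotation table, index = marker_id.

    Columns: ``chromosome`` (str; autosome label, "X" or "Y"), ``position``
    (int, 1-based bp), ``probe_type`` ("I" or "II"), ``channel`` ("red",
    "green" for Type I; "both" for Type II), ``flags`` (frozenset over
    :data:`FLAG_CATEGORIES`).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = {"chromosome", "position", "probe_type", "channel", "flags"}
        missing = required - set(df.columns)
        _check(not missing, f"manifest missing required column(s): {sorted(missing)}")
        _check(df.index.is_unique, "marker_id values must be unique")
        _check((df["position"] >= 1).all(), "marker positions must be >= 1")
        bad_type = ~df["probe_type"].isin(PROBE_TYPES)
        _check(not bad_type.any(), f"unknown probe_type for {list(df.index[bad_type][:3])}")
        bad_chan = ~df["channel"].isin(CHANNELS)
        _check(not bad_chan.any(), f"unknown channel for {list(df.index[bad_chan][:3])}")
        # Type II probes are read in both colour channels, Type I in exactly one
        is_ii = df["probe_type"] == "II"
        _check(
            (is_ii == (df["channel"] == "both")).all(),
            "probe_type II must have channel 'both' and vice versa",
        )
        for fl in df["flags"]:
            _check(
                frozenset(fl) <= set(FLAG_CATEGORIES),
                f"unknown flag(s) {set(fl) - set(FLAG_CATEGORIES)}",
            )

    @property
    def marker_ids(self) -> pd.Index:
        return self.df.index

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def is_autosomal(self) -> np.ndarray:
        return ~self.df["chromosome"].isin(["X", "Y"]).to_numpy()

    def subset(self, marker_ids) -> "Manifest":
        return Manifest(self.df.loc[marker_ids])

    @classmethod
    def read(cls, path) -> "Manifest":
        df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
        _check("marker_id" in df.columns, "manifest missing required column: marker_id")
        df = df.set_index("marker_id")
        flags = df.get("flags")
        if flags is None:
            df["flags"] = [frozenset()] * len(df)
        else:
            df["flags"] = [
                frozenset(str(f).split(",")) if isinstance(f, str) and f else frozenset()
                for f in flags.fillna("")
            ]
        df["position"] = df["position"].astype(int)
        return cls(df)

    def write(self, path) -> None:
        out = self.df.copy()
        out["flags"] = [",".join(sorted(f)) for f in out["flags"]]
        out.to_csv(path, sep="\t", index_label="marker_id")


@dataclass
class ControlManifest:
    """Control-probe table, index = control_id, column ``category``.

    The category ``negative`` identifies background (negative-control)
    probes used for background correction and detection P values; every
    other category (staining, extension, hybridization, bisulfite
    conversion, specificity, ...) monitors an assay chemistry step and
    feeds the control-probe PCA. The taxonomy is free-form apart from
    ``negative``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check("category" in self.df.columns, "control manifest missing required column: category")
        _check(self.df.index.is_unique, "control_id values must be unique")

    @property
    def control_ids(self) -> pd.Index:
        return self.df.index

    @property
    def negative_ids(self) -> pd.Index:
        return self.df.index[self.df["category"] == "negative"]

    @property
    def non_negative_ids(self) -> pd.Index:
        return self.df.index[self.df["category"] != "negative"]

    @classmethod
    def read(cls, path) -> "ControlManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        _check("control_id" in df.columns, "control manifest missing required column: control_id")
        return cls(df.set_index("control_id"))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="control_id")


@dataclass
class RawIntensities:
    """Methylated/unmethylated signal and control intensities.

    ``M`` and ``U`` are markers x samples arrays of nonnegative fluorescence
    intensities; ``missing_mask`` is True where a measurement has been set
    to missing (detection-P masking). ``control_green`` / ``control_red``
    are controls x samples intensities in each colour channel.
    """

    marker_ids: pd.Index
    sample_ids: pd.Index
    M: np.ndarray
    U: np.ndarray
    control_ids: pd.Index
    control_green: np.ndarray
    control_red: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.marker_ids = pd.Index(self.marker_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        self.control_ids = pd.Index(self.control_ids)
        self.M = np.asarray(self.M, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.control_green = np.asarray(self.control_green, dtype=float)
        self.control_red = np.asarray(self.control_red, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.M.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        shape = (len(self.marker_ids), len(self.sample_ids))
        _check(self.M.shape == shape, f"M has shape {self.M.shape}, expected {shape}")
        _check(self.U.shape == shape, f"U has shape {self.U.shape}, expected {shape}")
        _check(self.missing_mask.shape == shape, "missing_mask shape mismatch")
        cshape = (len(self.control_ids), len(self.sample_ids))
        _check(self.control_green.shape == cshape, "control_green shape mismatch")
        _check(self.control_red.shape == cshape, "control_red shape mismatch")
        for name, arr in [("M", self.M), ("U", self.U),
                          ("control_green", self.control_green),
                          ("control_red", self.control_red)]:
            _check(np.isfinite(arr).all(), f"{name} contains non-finite values")
            if (arr < 0).any():
                i, j = np.argwhere(arr < 0)[0]
                _check(False, f"{name} violates nonnegativity at row {i}, sample "
                              f"{self.sample_ids[j]!r} (intensities must be >= 0)")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "RawIntensities":
        return RawIntensities(
            self.marker_ids.copy(), self.sample_ids.copy(),
            self.M.copy(), self.U.copy(),
            self.control_ids.copy(), self.control_green.copy(), self.control_red.copy(),
            self.missing_mask.copy(),
        )

    def select_samples(self, keep) -> "RawIntensities":
        """Subset (and/or reorder) samples; ``keep`` is a list of sample ids."""
        idx = self.sample_ids.get_indexer(pd.Index(keep))
        _check((idx >= 0).all(), f"unknown sample id(s): {list(pd.Index(keep)[idx < 0][:3])}")
        return RawIntensities(
            self.marker_ids, pd.Index(keep),
            self.M[:, idx], self.U[:, idx],
            self.control_ids, self.control_green[:, idx], self.control_red[:, idx],
            self.missing_mask[:, idx],
        )

    def select_markers(self, keep_bool: np.ndarray) -> "RawIntensities":
        """Subset markers by boolean mask (marker order preserved)."""
        return RawIntensities(
            self.marker_ids[keep_bool], self.sample_ids,
            self.M[keep_bool], self.U[keep_bool],
            self.control_ids, self.control_green, self.control_red,
            self.missing_mask[keep_bool],
        )


@dataclass
class BetaMatrix:
    """Methylation fractions beta = M / (M + U + offset), markers x samples.

    Missing entries are NaN; non-missing entries lie in [0, 1) (the positive
    offset in the denominator keeps beta strictly below 1).
    """

    marker_ids: pd.Index
    sample_ids: pd.Index
    beta: np.ndarray
    offset: float = 100.0

    def __post_init__(self) -> None:
        self.marker_ids = pd.Index(self.marker_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        _check(self.offset > 0, "beta offset must be > 0")
        shape = (len(self.marker_ids), len(self.sample_ids))
        _check(self.beta.shape == shape, f"beta has shape {self.beta.shape}, expected {shape}")
        vals = self.beta[~np.isnan(self.beta)]
        _check(((vals >= 0) & (vals < 1)).all(), "non-missing beta values must lie in [0, 1)")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.beta)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.marker_ids.copy(), self.sample_ids.copy(),
                          self.beta.copy(), self.offset)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.marker_ids, columns=self.sample_ids)


@dataclass
class CovariateTable:
    """Per-sample phenotype and covariates, index = sample_id.

    Required columns: ``phenotype`` (binary 0/1 or real), ``age`` (years),
    ``sex`` ("M"/"F"). Optional: ``wbc_tot`` (measured total white-cell
    count), batch labels (``chip``, ``plate``, ...), and ``wbc_est_*``
    columns filled in by the cell-composition stage.
    """

    df: pd.DataFrame

    REQUIRED = ("phenotype", "age", "sex")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        _check(not missing, f"covariate table missing required column(s): {sorted(missing)}")
        _check(self.df.index.is_unique, "sample_id values must be unique")
        est = self.wbc_est_columns
        if est:
            _check((self.df[est].fillna(0) >= 0).to_numpy().all(),
                   "estimated cell fractions must be >= 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def wbc_est_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("wbc_est_")]

    def with_cell_estimates(self, estimates: pd.DataFrame) -> "CovariateTable":
        """Return a copy with ``wbc_est_<celltype>`` columns (sample-aligned)."""
        df = self.df.drop(columns=self.wbc_est_columns).copy()
        aligned = estimates.reindex(df.index)
        _check(not aligned.isna().any().any(), "cell estimates missing for some samples")
        for c in estimates.columns:
            df[f"wbc_est_{c}"] = aligned[c]
        return CovariateTable(df)

    def subset(self, sample_ids) -> "CovariateTable":
        return CovariateTable(self.df.loc[sample_ids])

    @classmethod
    def read(cls, path) -> "CovariateTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str})
        _check("sample_id" in df.columns, "covariate table missing required column: sample_id")
        return cls(df.set_index("sample_id"))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id", na_rep=_NA)


@dataclass
class AssociationResult:
    """Per-marker association summary.

    ``df`` is indexed by marker_id with columns ``chromosome``, ``position``,
    ``coef``, ``se``, ``p``, ``n_used``, ``call_rate``, ``flags`` and
    ``converged``; non-converged fits carry NaN p. Markers with call rate
    below the reporting threshold stay in the table (flagged, not dropped).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.df["p"]
        ok = p.dropna()
        _check(((ok > 0) & (ok <= 1)).all(), "P values must lie in (0, 1]")

    @property
    def pvalues(self) -> np.ndarray:
        return self.df["p"].to_numpy()


def _sorted_by_position(df: pd.DataFrame) -> pd.DataFrame:
    # stable chromosome ordering: numeric autosomes first, then X, Y
    def chrom_key(c: str):
        return (0, int(c)) if str(c).isdigit() else (1, {"X": 0, "Y": 1}.get(str(c), 2))

    order = sorted(range(len(df)), key=lambda i: (chrom_key(df["chromosome"].iloc[i]),
                                                  int(df["position"].iloc[i]),
                                                  str(df.index[i])))
    return df.iloc[order]


def write_association(result: AssociationResult, path) -> None:
    """Write one row per marker, ordered by (chromosome, position).

    Numeric fields are written with 12 significant digits so a read-back
    reproduces them to that precision; P = 1.0 serialises as "1.0".
    """
    df = _sorted_by_position(result.df.copy())
    out = pd.DataFrame({
        "marker_id": df.index,
        "chr": df["chromosome"].astype(str),
        "pos": df["position"].astype(int),
        "coef": df["coef"],
        "se": df["se"],
        "p": df["p"],
        "n": df["n_used"].astype(int),
        "call_rate": df["call_rate"],
        "flags": [",".join(sorted(f)) for f in df["flags"]],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep=_NA)


def read_association(path) -> AssociationResult:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chr": str, "flags": str})
    df = df.set_index("marker_id")
    df = df.rename(columns={"chr": "chromosome", "pos": "position", "n": "n_used"})
    df["flags"] = [frozenset(str(f).split(",")) if isinstance(f, str) and f else frozenset()
                   for f in df["flags"].fillna("")]
    df["converged"] = ~df["p"].isna()
    return AssociationResult(df)


# ---------------------------------------------------------------------------
# dataset-level I/O


def _control_intensity_path(intensity_path) -> str:
    stem, ext = os.path.splitext(os.fspath(intensity_path))
    return stem + ".controls" + (ext or ".tsv")


def write_dataset(manifest: Manifest, control_manifest: ControlManifest,
                  raw: RawIntensities, covariates: CovariateTable,
                  manifest_path, control_manifest_path, intensity_path,
                  covariate_path, control_intensity_path=None) -> None:
    """Write the four dataset files (plus control intensities alongside).

    Marker intensities go to ``intensity_path`` in wide form: one ``<sample>.M``
    and one ``<sample>.U`` column per sample; masked entries are written NA.
    Control intensities go to ``control_intensity_path`` (default:
    ``<intensity stem>.controls.tsv``) with ``<sample>.G`` / ``<sample>.R``
    columns.
    """
    manifest.write(manifest_path)
    control_manifest.write(control_manifest_path)
    covariates.write(covariate_path)

    cols = {}
    M = raw.M.copy()
    U = raw.U.copy()
    M[raw.missing_mask] = np.nan
    U[raw.missing_mask] = np.nan
    for j, s in enumerate(raw.sample_ids):
        cols[f"{s}.M"] = M[:, j]
        cols[f"{s}.U"] = U[:, j]
    pd.DataFrame(cols, index=raw.marker_ids).to_csv(
        intensity_path, sep="\t", index_label="marker_id", na_rep=_NA, float_format="%.12g")

    cpath = control_intensity_path or _control_intensity_path(intensity_path)
    ccols = {}
    for j, s in enumerate(raw.sample_ids):
        ccols[f"{s}.G"] = raw.control_green[:, j]
        ccols[f"{s}.R"] = raw.control_red[:, j]
    pd.DataFrame(ccols, index=raw.control_ids).to_csv(
        cpath, sep="\t", index_label="control_id", na_rep=_NA, float_format="%.12g")


def read_dataset(manifest_path, control_manifest_path, intensity_path,
                 covariate_path, control_intensity_path=None
                 ) -> tuple[Manifest, ControlManifest, RawIntensities, CovariateTable]:
    """Read and cross-validate the four dataset files.

    Sample order follows the covariate table; intensity columns are aligned
    to it and any sample present in one file but not the other is a fatal
    error naming the sample. Marker rows must match the manifest exactly.
    """
    manifest = Manifest.read(manifest_path)
    control_manifest = ControlManifest.read(control_manifest_path)
    covariates = CovariateTable.read(covariate_path)

    inten = pd.read_csv(intensity_path, sep="\t", dtype={"marker_id": str})
    _check("marker_id" in inten.columns, "intensity file missing required column: marker_id")
    inten = inten.set_index("marker_id")

    unknown = inten.index.difference(manifest.marker_ids)
    _check(unknown.empty, f"intensity file contains unknown marker id(s): {list(unknown[:3])}")
    absent = manifest.marker_ids.difference(inten.index)
    _check(absent.empty, f"intensity file lacks manifest marker(s): {list(absent[:3])}")
    inten = inten.reindex(manifest.marker_ids)

    inten_samples = []
    for c in inten.columns:
        if c.endswith(".M"):
            inten_samples.append(c[:-2])
    for s in inten_samples:
        _check(f"{s}.U" in inten.columns, f"intensity file lacks U column for sample {s!r}")
    missing_cov = set(inten_samples) - set(covariates.sample_ids)
    _check(not missing_cov,
           f"intensity sample(s) absent from covariates: {sorted(missing_cov)[:3]}")
    missing_int = set(covariates.sample_ids) - set(inten_samples)
    _check(not missing_int,
           f"covariate sample(s) absent from intensities: {sorted(missing_int)[:3]}")
    samples = covariates.sample_ids

    M = inten[[f"{s}.M" for s in samples]].to_numpy(dtype=float)
    U = inten[[f"{s}.U" for s in samples]].to_numpy(dtype=float)
    missing_mask = np.isnan(M) | np.isnan(U)
    M = np.where(np.isnan(M), 0.0, M)
    U = np.where(np.isnan(U), 0.0, U)

    cpath = control_intensity_path or _control_intensity_path(intensity_path)
    cint = pd.read_csv(cpath, sep="\t", dtype={"control_id": str}).set_index("control_id")
    unknown = cint.index.difference(control_manifest.control_ids)
    _check(unknown.empty, f"control intensity file contains unknown id(s): {list(unknown[:3])}")
    cint = cint.reindex(control_manifest.control_ids)
    _check(not cint.isna().any().any(), "control intensities must be complete")
    cg = cint[[f"{s}.G" for s in samples]].to_numpy(dtype=float)
    cr = cint[[f"{s}.R" for s in samples]].to_numpy(dtype=float)

    raw = RawIntensities(manifest.marker_ids, samples, M, U,
                         control_manifest.control_ids, cg, cr, missing_mask)
    return manifest, control_manifest, raw, covariates
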