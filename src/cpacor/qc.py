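"""Quality control: background correction, detection-P calling, call rates,
sex checks and outlier metrics.

Detection P values follow the negative-control convention: per sample and
colour channel the background is summarised by the median and the
normal-consistent MAD of the negative-control intensities; a probe's total
signal (M + U) is compared against the upper tail of a Normal whose mean and
spread are the sums over the channels the probe reads (both channels for
Type II, twice the design channel for Type I). The upper tail is evaluated
as the double-precision complement 1 - Phi(z), whose smallest positive
value is machine epsilon (~2.2e-16); smaller tails are reported at that
floor rather than as zero so log-scale diagnostics stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ControlManifest, CovariateTable, Manifest, RawIntensities, BetaMatrix

__all__ = [
    "DetectionP",
    "QCReport",
    "background_correct",
    "detection_pvalues",
    "apply_detection_mask",
    "call_rates",
    "sex_check",
    "outlier_rate",
    "qc_filter",
    "DETECTION_P_FLOOR",
]

#: smallest positive value a 1 - CDF computation can produce after clamping
DETECTION_P_FLOOR = float(np.finfo(float).eps)


@dataclass
class DetectionP:
    """Detection P values, markers x samples.

    ``p`` is the reported matrix, floored at machine epsilon so values lie
    in (0, 1] and log-scale plots never hit zero. ``p_raw`` keeps the
    unfloored double-precision complement (which underflows to exactly 0
    for very bright probes); thresholding uses it, so a stringent cutoff
    like 1e-16 — below the reporting floor — still distinguishes detected
    probes (underflow, true tail < cutoff) from background.
    """

    marker_ids: pd.Index
    sample_ids: pd.Index
    p: np.ndarray
    p_raw: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not ((self.p > 0) & (self.p <= 1)).all():
            raise ValueError("detection P values must lie in (0, 1]")
        if self.p_raw is None:
            self.p_raw = self.p


@dataclass
class QCReport:
    sample_call_rate: pd.Series
    marker_call_rate: pd.Series
    excluded_samples: pd.DataFrame        # columns: sample_id, reason
    marker_outlier_rate: pd.Series | None = None
    sex_verdicts: pd.Series | None = None

    def kept_samples(self) -> pd.Index:
        return self.sample_call_rate.index.difference(
            pd.Index(self.excluded_samples["sample_id"]), sort=False)


def _negative_split(raw: RawIntensities, control_manifest: ControlManifest):
    neg = control_manifest.df["category"].reindex(raw.control_ids) == "negative"
    neg = neg.to_numpy()
    if not neg.any():
        raise ValueError("no negative-control probes present; background "
                         "estimation requires at least one")
    return raw.control_green[neg], raw.control_red[neg]


def background_correct(raw: RawIntensities, control_manifest: ControlManifest,
                       quantile: float = 0.05, floor: float = 1.0) -> RawIntensities:
    """Subtract a per-sample, per-channel background level from all signals.

    The background is a low quantile (default 5th percentile) of the
    negative-control intensities in that channel; corrected intensities are
    max(intensity - b, floor) so they stay positive. Control probes are
    corrected identically. Type II probes read M in green and U in red;
    Type I probes read both signals in their design channel, so the
    subtraction is routed by probe geometry.

    Returns a new :class:`RawIntensities`; the input is not modified. The
    marker routing requires a manifest, so this function is usually called
    through :func:`cpacor.pipeline.run_cpacor`; standalone use routes via
    ``raw._manifest`` if attached, else applies the green background to M
    and red to U (the Type II majority convention).
    """
    neg_g, neg_r = _negative_split(raw, control_manifest)
    bg = np.quantile(neg_g, quantile, axis=0)       # per sample
    br = np.quantile(neg_r, quantile, axis=0)

    manifest: Manifest | None = getattr(raw, "_manifest", None)
    out = raw.copy()
    if manifest is not None:
        ptype = manifest.df["probe_type"].to_numpy()
        chan = manifest.df["channel"].to_numpy()
        bm = np.empty_like(out.M)
        bu = np.empty_like(out.U)
        ii = ptype == "II"
        bm[ii], bu[ii] = bg[None, :], br[None, :]
        ired = (~ii) & (chan == "red")
        bm[ired] = bu[ired] = br[None, :]
        igrn = (~ii) & (chan == "green")
        bm[igrn] = bu[igrn] = bg[None, :]
    else:
        bm, bu = np.broadcast_to(bg, out.M.shape), np.broadcast_to(br, out.U.shape)
    out.M = np.maximum(out.M - bm, floor)
    out.U = np.maximum(out.U - bu, floor)
    out.control_green = np.maximum(out.control_green - bg[None, :], floor)
    out.control_red = np.maximum(out.control_red - br[None, :], floor)
    if manifest is not None:
        out._manifest = manifest                    # type: ignore[attr-defined]
    return out


def attach_manifest(raw: RawIntensities, manifest: Manifest) -> RawIntensities:
    """Attach the manifest used for channel routing in QC steps."""
    if not raw.marker_ids.equals(manifest.marker_ids):
        raise ValueError("manifest markers do not match intensity rows")
    raw._manifest = manifest                        # type: ignore[attr-defined]
    return raw


def detection_pvalues(raw: RawIntensities, control_manifest: ControlManifest,
                      manifest: Manifest | None = None) -> DetectionP:
    """Detection P values from negative-control background distributions.

    Per sample and channel: centre mu = median, spread sigma = MAD scaled
    to be normal-consistent (x1.4826). For a Type I marker in channel c,
    p = upper tail of Normal(2 mu_c, 2 sigma_c) at M + U; for Type II,
    p = upper tail of Normal(mu_G + mu_R, sigma_G + sigma_R). The tail is
    computed as the double-precision complement and clamped below at
    :data:`DETECTION_P_FLOOR`, so output values lie in (0, 1] and never
    print as zero.
    """
    manifest = manifest or getattr(raw, "_manifest", None)
    if manifest is None:
        raise ValueError("detection_pvalues needs the marker manifest for routing")
    neg_g, neg_r = _negative_split(raw, control_manifest)
    mu_g = np.median(neg_g, axis=0)
    mu_r = np.median(neg_r, axis=0)
    sd_g = stats.median_abs_deviation(neg_g, axis=0, scale="normal")
    sd_r = stats.median_abs_deviation(neg_r, axis=0, scale="normal")
    if (sd_g == 0).any() or (sd_r == 0).any():
        raise ValueError("negative-control spread is zero for some sample; "
                         "add jitter or more negative controls")

    ptype = manifest.df["probe_type"].to_numpy()
    chan = manifest.df["channel"].to_numpy()
    total = raw.M + raw.U
    mu = np.empty_like(total)
    sd = np.empty_like(total)
    ii = ptype == "II"
    mu[ii] = (mu_g + mu_r)[None, :]
    sd[ii] = (sd_g + sd_r)[None, :]
    ired = (~ii) & (chan == "red")
    mu[ired] = (2 * mu_r)[None, :]
    sd[ired] = (2 * sd_r)[None, :]
    igrn = (~ii) & (chan == "green")
    mu[igrn] = (2 * mu_g)[None, :]
    sd[igrn] = (2 * sd_g)[None, :]

    z = (total - mu) / sd
    p_raw = 1.0 - stats.norm.cdf(z)                 # double-precision complement
    p = np.clip(p_raw, DETECTION_P_FLOOR, 1.0)
    return DetectionP(raw.marker_ids, raw.sample_ids, p, p_raw)


def apply_detection_mask(raw: RawIntensities, detp: DetectionP,
                         threshold: float) -> RawIntensities:
    """Set entries with detection P >= threshold to missing (inclusive).

    Intensities themselves are untouched; only the missingness mask grows.
    """
    if not 0 < threshold <= 1:
        raise ValueError("detection threshold must lie in (0, 1]")
    out = raw.copy()
    out.missing_mask = raw.missing_mask | (detp.p_raw >= threshold)
    manifest = getattr(raw, "_manifest", None)
    if manifest is not None:
        out._manifest = manifest                    # type: ignore[attr-defined]
    return out


def call_rates(raw: RawIntensities) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-marker fractions of non-missing measurements."""
    ok = ~raw.missing_mask
    sample = pd.Series(ok.mean(axis=0), index=raw.sample_ids, name="sample_call_rate")
    marker = pd.Series(ok.mean(axis=1), index=raw.marker_ids, name="marker_call_rate")
    return sample, marker


def sex_check(raw: RawIntensities, manifest: Manifest, covariates: CovariateTable,
              y_high: float = 0.5, y_low: float = 0.5) -> pd.Series:
    """Compare recorded sex against Y-chromosome call rates.

    Females have no Y chromosome, so their Y markers should fail detection;
    a female with Y call rate above ``y_high`` or a male below ``y_low`` is
    a mismatch. With no Y markers on the array every sample is
    "untestable".
    """
    y_rows = (manifest.df["chromosome"] == "Y").to_numpy()
    sex = covariates.df["sex"].reindex(raw.sample_ids)
    if not y_rows.any():
        return pd.Series("untestable", index=raw.sample_ids, name="sex_check")
    y_rate = (~raw.missing_mask[y_rows]).mean(axis=0)
    verdict = np.where(
        ((sex == "F") & (y_rate > y_high)) | ((sex == "M") & (y_rate < y_low)),
        "mismatch", "pass")
    return pd.Series(verdict, index=raw.sample_ids, name="sex_check")


def outlier_rate(beta: BetaMatrix, min_n: int = 4) -> pd.Series:
    """Per-marker rate of Tukey-fence outliers among non-missing betas.

    Outliers fall below Q1 - 1.5 IQR or above Q3 + 1.5 IQR, quartiles by
    linear interpolation; markers with fewer than ``min_n`` non-missing
    values get a missing rate.
    """
    b = beta.beta
    out = np.full(b.shape[0], np.nan)
    n_ok = (~np.isnan(b)).sum(axis=1)
    rows = np.flatnonzero(n_ok >= min_n)
    if rows.size:
        q1 = np.nanquantile(b[rows], 0.25, axis=1)
        q3 = np.nanquantile(b[rows], 0.75, axis=1)
        iqr = q3 - q1
        lo = q1 - 1.5 * iqr
        hi = q3 + 1.5 * iqr
        n_out = np.nansum((b[rows] < lo[:, None]) | (b[rows] > hi[:, None]), axis=1)
        out[rows] = n_out / n_ok[rows]
    return pd.Series(out, index=beta.marker_ids, name="outlier_rate")


def qc_filter(raw: RawIntensities, manifest: Manifest, covariates: CovariateTable,
              sample_threshold: float = 0.98, check_sex: bool = True,
              call_rate_markers: np.ndarray | None = None) -> QCReport:
    """Apply sample-level exclusions: call rate < threshold (strict) and
    sex mismatches. Returns a QCReport with machine-readable reasons.

    ``call_rate_markers`` (boolean over markers) restricts the call-rate
    computation — e.g. to autosomes, so that the structurally missing Y
    markers of female samples do not count against them — while the sex
    check still sees the full array.
    """
    if call_rate_markers is not None:
        s_rate, m_rate = call_rates(raw.select_markers(call_rate_markers))
    else:
        s_rate, m_rate = call_rates(raw)
    reasons = []
    low = s_rate.index[s_rate < sample_threshold]
    for s in low:
        reasons.append((s, "low_call_rate"))
    verdicts = None
    if check_sex:
        verdicts = sex_check(raw, manifest, covariates)
        for s in verdicts.index[verdicts == "mismatch"]:
            if s not in low:
                reasons.append((s, "sex_mismatch"))
    excluded = pd.DataFrame(reasons, columns=["sample_id", "reason"])
    if len(excluded) == raw.n_samples:
        raise ValueError("all samples excluded by QC")
    return QCReport(sample_call_rate=s_rate, marker_call_rate=m_rate,
                    excluded_samples=excluded, sex_verdicts=verdicts)
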