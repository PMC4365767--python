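"""Performance machinery: spike-in simulations, duplicate concordance, and
local-correlation diagnostics.

Spike-ins measure ranking power: raw beta values of case-labelled samples
at randomly chosen markers are increased by a defined fraction of the
per-marker SD, intensities are recomputed from the spiked betas (half of
the spiked probes altered on the methylated signal, half on the
unmethylated), and the pipeline under test is scored by the proportion of
spiked markers it ranks in the top k.

Duplicate concordance compares paired re-measurements at the marker level
(correlation across pairs per marker) and the sample level (correlation
across markers per pair); a paired Wilcoxon test compares two
normalisation schemes.

Local correlation profiles Pearson r between nearby autosomal markers
(pairs up to 5,000 bp apart, 5% most variable markers, sliding 300 bp
mean) and quantifies whether an adjustment removes distant correlation
preferentially (regression of the per-pair change in r on distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AssociationResult, BetaMatrix, Manifest, RawIntensities
from .association import ResidualMatrix

__all__ = [
    "SpikePlan",
    "make_spike_plan",
    "spike_intensities",
    "spike_rank_score",
    "duplicate_concordance",
    "compare_concordance",
    "replicate_regression",
    "pipeline_stage_scores",
    "permutation_calibration_study",
    "duplicate_inflation_study",
    "shortcut_agreement_study",
    "DistanceCorrelationProfile",
    "local_correlation",
    "correlation_difference_slope",
]

log = logging.getLogger(__name__)


@dataclass
class SpikePlan:
    """Which markers to spike, how hard, and on which signal.

    ``magnitude`` is a fraction of the per-marker beta SD (ddof=1, raw
    betas across all samples). ``alter`` maps each spiked marker to "M" or
    "U": the list of spiked ids is shuffled with ``seed`` and alternates
    between the two signals, so the split is half/half.
    """

    marker_ids: list
    magnitude: float
    seed: int = 0
    alter: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("spiked marker ids must be distinct")
        if not self.alter:
            rng = np.random.default_rng(self.seed)
            order = list(rng.permutation(self.marker_ids))
            self.alter = {mid: ("M" if i % 2 == 0 else "U")
                          for i, mid in enumerate(order)}


def make_spike_plan(manifest: Manifest, n: int = 100, magnitude: float = 1.0,
                    seed: int = 0, autosomal_only: bool = True) -> SpikePlan:
    """Randomly select ``n`` markers (default autosomal) to spike."""
    rng = np.random.default_rng(seed)
    ids = manifest.marker_ids[manifest.is_autosomal()] if autosomal_only \
        else manifest.marker_ids
    chosen = list(rng.choice(ids, size=n, replace=False))
    return SpikePlan(marker_ids=chosen, magnitude=magnitude, seed=seed)


def spike_intensities(raw: RawIntensities, beta_raw: BetaMatrix, plan: SpikePlan,
                      case_labels) -> RawIntensities:
    """Inject differential methylation into raw intensities.

    For each spiked marker and case sample the target beta is
    beta' = beta + magnitude x SD(marker) (capped below 1). Intensities
    are then recomputed so that beta' is exact under the offset convention:
    M-altered probes get M' = beta'(U + offset)/(1 - beta'); U-altered get
    U' = M(1 - beta')/beta' - offset. Negative results are set to zero.
    """
    missing = set(plan.marker_ids) - set(raw.marker_ids)
    if missing:
        raise ValueError(f"spiked marker(s) not on the array: {sorted(missing)[:3]}")
    case = np.asarray(case_labels).astype(bool)
    if case.size != raw.n_samples:
        raise ValueError("case_labels length must equal the number of samples")
    out = raw.copy()
    offset = beta_raw.offset
    rows = raw.marker_ids.get_indexer(pd.Index(plan.marker_ids))
    n_capped = 0
    for mid, i in zip(plan.marker_ids, rows):
        b = beta_raw.beta[i]
        sd = np.nanstd(b, ddof=1)
        target = b + plan.magnitude * sd
        capped = target >= 1.0
        if capped.any():
            n_capped += int((capped & case & ~np.isnan(b)).sum())
            target = np.where(capped, 1.0 - 1e-6, target)
        sel = case & ~np.isnan(b)
        bp = target[sel]
        if plan.alter[mid] == "M":
            new_m = bp * (out.U[i, sel] + offset) / (1.0 - bp)
            out.M[i, sel] = np.maximum(new_m, 0.0)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                new_u = out.M[i, sel] * (1.0 - bp) / bp - offset
            out.U[i, sel] = np.maximum(np.where(np.isfinite(new_u), new_u, 0.0), 0.0)
    if n_capped:
        log.info("spike targets capped below 1 for %d entries", n_capped)
    return out


def spike_rank_score(result: AssociationResult, plan: SpikePlan, k: int = 100
                     ) -> float:
    """Fraction of spiked markers ranked in the top ``k`` by association P.

    Ranking is by ascending p, ties broken by descending |coefficient|,
    then marker id; markers with missing p are unranked (sort last).
    """
    df = result.df
    missing = set(plan.marker_ids) - set(df.index)
    if missing:
        raise ValueError(f"result lacks spiked marker(s): {sorted(missing)[:3]}")
    order = pd.DataFrame({
        "p": df["p"].fillna(np.inf),
        "negabs": -df["coef"].abs().fillna(0.0),
        "id": df.index,
    }).sort_values(["p", "negabs", "id"], kind="mergesort")
    top = set(order.index[:k])
    return len(top & set(plan.marker_ids)) / len(plan.marker_ids)


# ---------------------------------------------------------------------------
# duplicate concordance


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray, min_n: int = 3) -> np.ndarray:
    ok = ~np.isnan(X) & ~np.isnan(Y)
    n = ok.sum(axis=1).astype(float)
    Xz = np.where(ok, X, 0.0)
    Yz = np.where(ok, Y, 0.0)
    sx, sy = Xz.sum(1), Yz.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (Xz * Yz).sum(1) - sx * sy / n
        vx = (Xz * Xz).sum(1) - sx * sx / n
        vy = (Yz * Yz).sum(1) - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[(n < min_n) | (vx <= 0) | (vy <= 0)] = np.nan
    return r


def duplicate_concordance(beta_a: BetaMatrix, beta_b: BetaMatrix,
                          pairing: pd.DataFrame, level: str = "sample"
                          ) -> pd.Series:
    """Pearson correlation between paired duplicate measurements.

    ``pairing`` has columns ``original`` / ``replicate`` and must be a
    bijection on the selected ids. Level "marker": r across pairs for each
    marker; level "sample": r across markers for each pair. Units with
    fewer than 3 complete observations get a missing r.
    """
    if pairing["original"].duplicated().any() or pairing["replicate"].duplicated().any():
        raise ValueError("pairing must be a bijection on the selected sample ids")
    ia = beta_a.sample_ids.get_indexer(pairing["original"])
    ib = beta_b.sample_ids.get_indexer(pairing["replicate"])
    if (ia < 0).any() or (ib < 0).any():
        raise ValueError("pairing refers to unknown sample ids")
    if not beta_a.marker_ids.equals(beta_b.marker_ids):
        raise ValueError("duplicate beta matrices must share markers")
    A = beta_a.beta[:, ia]
    Bm = beta_b.beta[:, ib]
    if level == "marker":
        r = _rowwise_pearson(A, Bm)
        return pd.Series(r, index=beta_a.marker_ids, name="r")
    if level == "sample":
        r = _rowwise_pearson(A.T, Bm.T)
        return pd.Series(r, index=pd.Index(pairing["original"], name="sample_id"),
                         name="r")
    raise ValueError("level must be 'marker' or 'sample'")


def compare_concordance(r_scheme_a: pd.Series, r_scheme_b: pd.Series):
    """Paired Wilcoxon signed-rank test between two schemes' correlation
    vectors (same units, same order). Returns (statistic, pvalue)."""
    a = r_scheme_a.to_numpy()
    b = r_scheme_b.to_numpy()
    ok = ~np.isnan(a) & ~np.isnan(b)
    res = stats.wilcoxon(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue)


def pipeline_stage_scores(design, magnitude: float = 0.4, n_spike: int = 20,
                          seed: int = 0) -> dict:
    """Spike-in rank score of each successive pipeline stage on one cohort.

    Generates a cohort from ``design`` (a ``CohortDesign``), spikes
    ``n_spike`` random autosomal markers in the case samples at
    ``magnitude`` x SD, and scores four analysis stages by the fraction of
    spiked markers ranked in the top ``n_spike``:

    - ``none``: raw betas, unadjusted per-marker logistic regression;
    - ``qn``: quantile-normalised (QN-I6) betas, unadjusted;
    - ``qn_cp``: QN betas adjusted for 30 control-probe PCs;
    - ``full``: QN betas adjusted for control PCs, age, sex, estimated
      cell fractions, measured total count and 5 residual PCs.

    Each stage removes a genuine noise source (dye/batch distortion,
    chip chemistry, cell-mixture variation), so power rises stage by
    stage when those sources are present in the design.
    """
    from . import qc as qc_mod
    from .association import (adjust_betas, build_design, residual_pcs,
                              two_stage_association)
    from .cells import estimate_wbc
    from .control_pca import control_feature_matrix, control_pcs
    from .data_model import Manifest as _Manifest
    from .normalization import compute_beta as _compute_beta, normalize
    from .synthetic import generate_cohort, generate_manifest, generate_reference

    manifest, controls = generate_manifest(design)
    reference = generate_reference(manifest, design)
    raw, cov, _ = generate_cohort(manifest, controls, reference, design)
    case = cov.df["phenotype"].to_numpy(dtype=float) > 0
    plan = make_spike_plan(manifest, n=n_spike, magnitude=magnitude, seed=seed)
    raw = spike_intensities(raw, _compute_beta(raw), plan, case)

    raw = qc_mod.attach_manifest(raw, manifest)
    raw = qc_mod.background_correct(raw, controls)
    masked = qc_mod.apply_detection_mask(
        raw, qc_mod.detection_pvalues(raw, controls), 1e-16)
    auto = manifest.is_autosomal()
    sub = masked.select_markers(auto)
    sub_manifest = _Manifest(manifest.df.loc[auto])
    y = cov.df["phenotype"].to_numpy(dtype=float)

    beta_raw = _compute_beta(sub)
    beta_qn = normalize(sub, sub_manifest, "QN-I6")
    pcs = control_pcs(control_feature_matrix(masked, controls), k=30)
    cov2 = cov.with_cell_estimates(estimate_wbc(beta_qn, reference).weights)

    scores = {}
    d_int = build_design(cov2, include=())
    scores["none"] = spike_rank_score(
        two_stage_association(adjust_betas(beta_raw, d_int), y), plan, k=n_spike)
    scores["qn"] = spike_rank_score(
        two_stage_association(adjust_betas(beta_qn, d_int), y), plan, k=n_spike)
    d_cp = build_design(cov2, control_pcs=pcs.scores, include=())
    scores["qn_cp"] = spike_rank_score(
        two_stage_association(adjust_betas(beta_qn, d_cp), y, design=d_cp),
        plan, k=n_spike)
    d0 = build_design(cov2, control_pcs=pcs.scores)
    rp = residual_pcs(adjust_betas(beta_qn, d0), k=5)
    d_full = build_design(cov2, control_pcs=pcs.scores, residual_pcs=rp.scores)
    scores["full"] = spike_rank_score(
        two_stage_association(adjust_betas(beta_qn, d_full), y, design=d_full),
        plan, k=n_spike)
    return scores


def _prepare_cohort(design, seed_shift=0):
    """Generate, QC and normalise one cohort; return the adjusted pieces."""
    from . import qc as qc_mod
    from .association import build_design
    from .cells import estimate_wbc
    from .control_pca import control_feature_matrix, control_pcs
    from .data_model import Manifest as _Manifest
    from .normalization import normalize
    from .synthetic import generate_cohort, generate_manifest, generate_reference

    manifest, controls = generate_manifest(design)
    reference = generate_reference(manifest, design)
    raw, cov, truth = generate_cohort(manifest, controls, reference, design)
    raw = qc_mod.attach_manifest(raw, manifest)
    raw = qc_mod.background_correct(raw, controls)
    masked = qc_mod.apply_detection_mask(
        raw, qc_mod.detection_pvalues(raw, controls), 1e-16)
    auto = manifest.is_autosomal()
    sub_manifest = _Manifest(manifest.df.loc[auto])
    beta = normalize(masked.select_markers(auto), sub_manifest, "QN-I6")
    pcs = control_pcs(control_feature_matrix(masked, controls), k=30)
    cov2 = cov.with_cell_estimates(estimate_wbc(beta, reference).weights)
    y = cov2.df["phenotype"].to_numpy(dtype=float)
    return {"manifest": manifest, "sub_manifest": sub_manifest,
            "controls": controls, "reference": reference, "beta": beta,
            "pcs": pcs, "cov2": cov2, "y": y, "truth": truth}


def permutation_calibration_study(n_samples: int = 500, n_markers: int = 2000,
                                  n_perm: int = 200, seed: int = 0,
                                  shuffle: bool = True):
    """Phenotype-permutation null on a synthetic cohort.

    ``shuffle=True`` reproduces the independence-restored experiment: each
    marker's quantile-normalised betas are permuted independently across
    samples (destroying inter-marker correlation) before control-PC
    adjustment and 200 phenotype-permutation rounds. ``shuffle=False``
    keeps the correlated markers and applies the full adjustment set
    (control PCs, age, sex, cell fractions, total count, 5 residual PCs).
    Returns a :class:`cpacor.association.NullSummary`.
    """
    from .association import (adjust_betas, build_design, permutation_null,
                              residual_pcs, shuffle_markers)
    from .synthetic import CohortDesign

    design = CohortDesign(n_samples=n_samples, n_markers=n_markers, seed=seed)
    parts = _prepare_cohort(design)
    beta, pcs, cov2, y = parts["beta"], parts["pcs"], parts["cov2"], parts["y"]
    if shuffle:
        dsn = build_design(cov2, control_pcs=pcs.scores, include=())
        source = adjust_betas(shuffle_markers(beta, seed=seed + 1), dsn)
    else:
        d0 = build_design(cov2, control_pcs=pcs.scores)
        rp = residual_pcs(adjust_betas(beta, d0), k=5)
        dsn = build_design(cov2, control_pcs=pcs.scores, residual_pcs=rp.scores)
        source = adjust_betas(beta, dsn)
    return permutation_null(source, y, n_perm=n_perm, seed=seed + 2)


def duplicate_inflation_study(seed: int = 0, n_pairs: int = 36,
                              n_markers: int = 2000,
                              batch_sd: float = 0.3) -> dict:
    """Replicate-regression inflation before/after each correction stage.

    Simulates ``n_pairs`` duplicate pairs measured in separate batches with
    control-probe-linked batch effects, then computes the genomic inflation
    factor of the paired replicate regression on raw betas (``raw``),
    quantile-normalised betas (``qn``), and QN betas with 30 control-probe
    PCs as covariates (``cp``) — the correction cascade of the duplicate
    comparison experiment.
    """
    from . import qc as qc_mod
    from .association import genomic_inflation
    from .control_pca import control_feature_matrix, control_pcs
    from .data_model import Manifest as _Manifest
    from .normalization import compute_beta as _compute_beta, normalize
    from .synthetic import (CohortDesign, concat_samples, generate_cohort,
                            generate_duplicates, generate_manifest,
                            generate_reference)

    design = CohortDesign(n_samples=n_pairs, n_markers=n_markers, seed=seed,
                          batch_sd=batch_sd)
    manifest, controls = generate_manifest(design)
    reference = generate_reference(manifest, design)
    raw, cov, truth = generate_cohort(manifest, controls, reference, design)
    rep, pairing = generate_duplicates(manifest, controls, truth, design, n_pairs)
    comb = qc_mod.attach_manifest(concat_samples(raw, rep), manifest)
    comb = qc_mod.background_correct(comb, controls)
    masked = qc_mod.apply_detection_mask(
        comb, qc_mod.detection_pvalues(comb, controls), 1e-16)
    auto = manifest.is_autosomal()
    sub = masked.select_markers(auto)
    sub_manifest = _Manifest(manifest.df.loc[auto])
    beta_raw = _compute_beta(sub)
    beta_qn = normalize(sub, sub_manifest, "QN-I6")
    pcs = control_pcs(control_feature_matrix(masked, controls), k=30)
    return {
        "raw": genomic_inflation(replicate_regression(beta_raw, pairing).pvalues),
        "qn": genomic_inflation(replicate_regression(beta_qn, pairing).pvalues),
        "cp": genomic_inflation(
            replicate_regression(beta_qn, pairing, pcs.scores).pvalues),
    }


def shortcut_agreement_study(n_samples: int = 500, n_markers: int = 2000,
                             seed: int = 0) -> dict:
    """R^2 between the two-stage residual shortcut and the direct fully
    adjusted per-marker logistic model, for -log10 p and coefficients."""
    from .association import (adjust_betas, build_design, marker_regression,
                              residual_pcs, two_stage_association)
    from .synthetic import CohortDesign

    design = CohortDesign(n_samples=n_samples, n_markers=n_markers, seed=seed)
    parts = _prepare_cohort(design)
    beta, pcs, cov2, y = parts["beta"], parts["pcs"], parts["cov2"], parts["y"]
    d0 = build_design(cov2, control_pcs=pcs.scores)
    rp = residual_pcs(adjust_betas(beta, d0), k=5)
    dsn = build_design(cov2, control_pcs=pcs.scores, residual_pcs=rp.scores)
    direct = marker_regression(y, beta, dsn, family="logistic")
    short = two_stage_association(adjust_betas(beta, dsn), y, design=dsn)
    ok = (direct.df["converged"] & short.df["converged"]).to_numpy()
    lp_d = -np.log10(direct.df["p"].to_numpy()[ok])
    lp_s = -np.log10(short.df["p"].to_numpy()[ok])
    r2_p = float(np.corrcoef(lp_d, lp_s)[0, 1] ** 2)
    r2_c = float(np.corrcoef(direct.df["coef"].to_numpy()[ok],
                             short.df["coef"].to_numpy()[ok])[0, 1] ** 2)
    return {"r2_neglog10_p": r2_p, "r2_coef": r2_c, "n_markers": int(ok.sum())}


def replicate_regression(beta: BetaMatrix, pairing: pd.DataFrame,
                         control_pcs: pd.DataFrame | None = None
                         ) -> AssociationResult:
    """Paired linear regression of replicate status on each marker's beta.

    The combined beta matrix holds both measurements of every pair;
    replicate status is 0 for the original and 1 for the repeat. Pair
    membership enters as fixed effects (one indicator per pair), so the
    marker coefficient is identified from within-pair differences and the
    residual variance reflects technical noise only — the paired analogue
    of regressing the replicate label on beta. Optional control-PC scores
    (sample-aligned) join the design; the Wald t test on the marker
    coefficient uses the full-model degrees of freedom.
    """
    from .association import marker_regression

    ids = list(pairing["original"]) + list(pairing["replicate"])
    idx = beta.sample_ids.get_indexer(pd.Index(ids))
    if (idx < 0).any():
        raise ValueError("pairing refers to samples absent from the beta matrix")
    sub = BetaMatrix(beta.marker_ids, pd.Index(ids), beta.beta[:, idx], beta.offset)
    n_pairs = len(pairing)
    y = np.concatenate([np.zeros(n_pairs), np.ones(n_pairs)])
    dummies = np.tile(np.eye(n_pairs), (2, 1))
    design = pd.DataFrame(dummies, index=sub.sample_ids,
                          columns=[f"pair{i}" for i in range(n_pairs)])
    if control_pcs is not None:
        aligned = control_pcs.reindex(sub.sample_ids)
        if aligned.isna().any().any():
            raise ValueError("control PC scores missing for some samples")
        for c in control_pcs.columns:
            design[c] = aligned[c].to_numpy()
    return marker_regression(y, sub, design, family="linear")


# ---------------------------------------------------------------------------
# local correlation


@dataclass
class DistanceCorrelationProfile:
    """Per-pair distances and correlations plus a sliding-window summary."""

    pairs: pd.DataFrame             # marker_i, marker_j, distance, r
    smoothed: pd.DataFrame          # center, mean_r, n_pairs
    window: int


def local_correlation(values, manifest: Manifest, raw_beta: BetaMatrix | None = None,
                      max_dist: int = 5000, top_frac: float = 0.05,
                      window: int = 300) -> DistanceCorrelationProfile:
    """Correlation between nearby autosomal markers as a function of distance.

    Marker selection: the ``top_frac`` most variable markers by raw-beta SD
    (``raw_beta`` defaults to ``values`` when that is a BetaMatrix; when
    profiling residuals, pass the raw betas the selection should be based
    on). All within-chromosome pairs at distance <= ``max_dist`` (inclusive)
    contribute a Pearson r; the smoothed curve is the mean r in a sliding
    window of ``window`` bp.
    """
    if isinstance(values, ResidualMatrix):
        V = values.residuals
        marker_ids = values.marker_ids
        if raw_beta is None:
            raise ValueError("profiling residuals requires raw_beta for the "
                             "variability selection")
    elif isinstance(values, BetaMatrix):
        V = values.beta
        marker_ids = values.marker_ids
        raw_beta = raw_beta or values
    else:
        raise TypeError("values must be a BetaMatrix or ResidualMatrix")

    auto = manifest.is_autosomal()
    sd = np.nanstd(raw_beta.beta, axis=1, ddof=1)
    sd = np.where(auto, sd, -np.inf)
    n_keep = max(2, int(round(top_frac * auto.sum())))
    keep_idx = np.sort(np.argsort(sd)[::-1][:n_keep])

    sub = manifest.df.iloc[keep_idx]
    rows = []
    for chrom, grp in sub.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        gids = grp.index.to_numpy()[order]
        gpos_idx = manifest.marker_ids.get_indexer(gids)
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                d = pos[b] - pos[a]
                if d > max_dist:
                    break
                if d == 0:
                    continue
                x = V[gpos_idx[a]]
                y = V[gpos_idx[b]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3:
                    continue
                xv, yv = x[ok], y[ok]
                if xv.std() == 0 or yv.std() == 0:
                    continue
                r = float(np.corrcoef(xv, yv)[0, 1])
                rows.append((gids[a], gids[b], int(d), r))
    if not rows:
        raise ValueError("no eligible marker pairs within max_dist on any chromosome")
    pairs = pd.DataFrame(rows, columns=["marker_i", "marker_j", "distance", "r"])

    half = window / 2.0
    centers = np.arange(half, max_dist + 1, max(1, window // 6))
    mean_r, n_pairs = [], []
    d = pairs["distance"].to_numpy()
    r = pairs["r"].to_numpy()
    for c in centers:
        sel = np.abs(d - c) <= half
        n_pairs.append(int(sel.sum()))
        mean_r.append(float(r[sel].mean()) if sel.any() else np.nan)
    smoothed = pd.DataFrame({"center": centers, "mean_r": mean_r, "n_pairs": n_pairs})
    return DistanceCorrelationProfile(pairs=pairs, smoothed=smoothed, window=window)


def correlation_difference_slope(profile_before: DistanceCorrelationProfile,
                                 profile_after: DistanceCorrelationProfile):
    """Regress the per-pair change in correlation on genomic distance.

    A negative slope with small p means the adjustment removed distant
    (putatively spurious) correlation preferentially while retaining
    short-range structure. Both profiles must cover the same pairs.
    Returns (slope per bp, pvalue).
    """
    a = profile_before.pairs.set_index(["marker_i", "marker_j"])
    b = profile_after.pairs.set_index(["marker_i", "marker_j"])
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("profiles share too few pairs")
    d = a.loc[common, "distance"].to_numpy(dtype=float)
    delta = (b.loc[common, "r"] - a.loc[common, "r"]).to_numpy()
    res = stats.linregress(d, delta)
    return float(res.slope), float(res.pvalue)
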