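"""End-to-end orchestration of the EWAS workflow.

The full run: background correction -> detection P values -> masking ->
call rates / sex check / sample filtering (optionally a two-pass history:
an initial permissive 0.05 mask for top-level QC, then the final stringent
threshold with call rates recomputed) -> stratified quantile normalisation
and beta computation -> control-probe PCA -> cell-composition estimation ->
covariate adjustment -> residual PCA -> per-marker association with the
complete covariate set. Sex-chromosome streams (X in males, X in females,
Y in males) run as separate invocations with stream-specific sample
filters and their own normalisation pools.

Every stage's parameters and exclusions are appended to a provenance log
(list of dict events, serialisable as line-delimited JSON) so a run can be
replayed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .association import (
    adjust_betas,
    build_design,
    marker_regression,
    permutation_null,
    residual_pcs,
)
from .cells import estimate_wbc
from .control_pca import control_feature_matrix, control_pcs
from .data_model import (
    AssociationResult,
    ControlManifest,
    CovariateTable,
    Manifest,
    RawIntensities,
)
from .normalization import normalize

__all__ = ["PipelineConfig", "PipelineResult", "run_cpacor"]

STREAMS = ("autosomal", "X-male", "X-female", "Y-male")


@dataclass
class PipelineConfig:
    """Pipeline settings; the defaults are the recommended analysis:
    detection P < 1e-16, sample call rate >= 98%, QN-I6 normalisation with
    beta offset 100, 30 control-probe PCs, 5 residual PCs, logistic
    per-marker regression on the autosomal stream."""

    detection_threshold: float = 1e-16
    initial_threshold: float = 0.05
    two_pass: bool = False
    sample_call_rate: float = 0.98
    scheme: str = "QN-I6"
    beta_offset: float = 100.0
    n_control_pcs: int = 30
    n_residual_pcs: int = 5
    family: str = "logistic"
    stream: str = "autosomal"
    check_sex: bool = True
    n_permutations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"stream must be one of {STREAMS}")


@dataclass
class PipelineResult:
    association: AssociationResult
    qc_report: qc_mod.QCReport
    beta: object
    control_pcs: pd.DataFrame
    residual_pcs: pd.DataFrame | None
    cell_estimates: pd.DataFrame | None
    null_summary: object | None
    provenance: list = field(default_factory=list)

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            for event in self.provenance:
                fh.write(json.dumps(event) + "\n")


def _stream_masks(manifest: Manifest, covariates: CovariateTable, stream: str):
    chrom = manifest.df["chromosome"]
    sex = covariates.df["sex"]
    if stream == "autosomal":
        return manifest.is_autosomal(), np.ones(len(sex), dtype=bool)
    if stream == "X-male":
        return (chrom == "X").to_numpy(), (sex == "M").to_numpy()
    if stream == "X-female":
        return (chrom == "X").to_numpy(), (sex == "F").to_numpy()
    if stream == "Y-male":
        return (chrom == "Y").to_numpy(), (sex == "M").to_numpy()
    raise ValueError(stream)


def run_cpacor(manifest: Manifest, control_manifest: ControlManifest,
               raw: RawIntensities, covariates: CovariateTable,
               reference: pd.DataFrame | None = None,
               config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full pipeline on one dataset and stream.

    ``reference`` (markers x cell types) enables the cell-composition
    stage; without it the design omits the estimated fractions. Returns
    association results for the stream's markers plus every intermediate
    covariate block and a provenance log.
    """
    config = config or PipelineConfig()
    prov: list[dict] = [{"stage": "config", **asdict(config)}]

    raw = qc_mod.attach_manifest(raw.copy(), manifest)
    raw = qc_mod.background_correct(raw, control_manifest)
    prov.append({"stage": "background_correct", "quantile": 0.05, "floor": 1.0})

    detp = qc_mod.detection_pvalues(raw, control_manifest, manifest)

    autosomal = manifest.is_autosomal()
    if config.two_pass:
        masked = qc_mod.apply_detection_mask(raw, detp, config.initial_threshold)
        report0 = qc_mod.qc_filter(masked, manifest, covariates,
                                   config.sample_call_rate, config.check_sex,
                                   call_rate_markers=autosomal)
        prov.append({"stage": "initial_qc", "threshold": config.initial_threshold,
                     "excluded": report0.excluded_samples.to_dict("records")})

    masked = qc_mod.apply_detection_mask(raw, detp, config.detection_threshold)
    prov.append({"stage": "detection_mask", "threshold": config.detection_threshold,
                 "n_masked": int(masked.missing_mask.sum())})

    report = qc_mod.qc_filter(masked, manifest, covariates,
                              config.sample_call_rate, config.check_sex,
                              call_rate_markers=autosomal)
    prov.append({"stage": "qc_filter", "sample_call_rate": config.sample_call_rate,
                 "excluded": report.excluded_samples.to_dict("records")})

    marker_mask, sample_mask = _stream_masks(manifest, covariates, config.stream)
    kept = [s for s in covariates.sample_ids
            if s in set(report.kept_samples()) and sample_mask[covariates.sample_ids.get_loc(s)]]
    if not kept:
        raise ValueError(f"no samples left for stream {config.stream!r}")
    sub_raw = masked.select_samples(kept).select_markers(marker_mask)
    sub_manifest = Manifest(manifest.df.loc[marker_mask])
    sub_cov = covariates.subset(kept)

    # stream-specific call-rate exclusion (e.g. X/Y call rates < threshold)
    s_rate, _ = qc_mod.call_rates(sub_raw)
    drop = s_rate.index[s_rate < config.sample_call_rate]
    if len(drop):
        prov.append({"stage": "stream_call_rate_filter",
                     "excluded": list(map(str, drop))})
        kept = [s for s in kept if s not in set(drop)]
        sub_raw = sub_raw.select_samples(kept)
        sub_cov = covariates.subset(kept)

    beta = normalize(sub_raw, sub_manifest, config.scheme, config.beta_offset)
    prov.append({"stage": "normalize", "scheme": config.scheme,
                 "offset": config.beta_offset})

    feats = control_feature_matrix(masked.select_samples(kept), control_manifest)
    cpcs = control_pcs(feats, k=config.n_control_pcs)
    prov.append({"stage": "control_pca", "k": config.n_control_pcs,
                 "explained": [float(v) for v in cpcs.explained_variance_ratio[:5]]})

    cells = None
    if reference is not None:
        est = estimate_wbc(beta, reference)
        cells = est.weights
        sub_cov = sub_cov.with_cell_estimates(cells)
        prov.append({"stage": "cell_composition",
                     "n_reference_markers": int(len(est.markers_used))})

    design1 = build_design(sub_cov, control_pcs=cpcs.scores)
    residuals = adjust_betas(beta, design1)
    rpcs = None
    rpc_scores = None
    if config.n_residual_pcs > 0:
        rpcs = residual_pcs(residuals, k=config.n_residual_pcs)
        rpc_scores = rpcs.scores
        prov.append({"stage": "residual_pca", "k": config.n_residual_pcs,
                     "n_complete_markers": rpcs.n_complete_markers,
                     "explained": [float(v) for v in rpcs.explained_variance_ratio]})

    design2 = build_design(sub_cov, control_pcs=cpcs.scores, residual_pcs=rpc_scores)
    y = sub_cov.df["phenotype"].to_numpy(dtype=float)
    assoc = marker_regression(y, beta, design2, family=config.family,
                              manifest=sub_manifest)
    prov.append({"stage": "association", "family": config.family,
                 "n_markers": int(len(assoc.df)),
                 "n_converged": int(assoc.df["converged"].sum())})

    nullsum = None
    if config.n_permutations > 0:
        residuals2 = adjust_betas(beta, design2)
        nullsum = permutation_null(residuals2, y, n_perm=config.n_permutations,
                                   seed=config.seed, design=design2)
        prov.append({"stage": "permutation_null", "n_perm": config.n_permutations,
                     "lambda_median": nullsum.lambda_median})

    return PipelineResult(association=assoc, qc_report=report, beta=beta,
                          control_pcs=cpcs.scores, residual_pcs=rpc_scores,
                          cell_estimates=cells, null_summary=nullsum,
                          provenance=prov)
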