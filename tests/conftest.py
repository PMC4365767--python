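"""Shared fixtures: one moderately sized synthetic cohort, QC'd and
normalised once per session, reused by most test modules."""

import logging

import numpy as np
import pytest

from cpacor import qc as qc_mod
from cpacor.association import build_design
from cpacor.cells import estimate_wbc
from cpacor.control_pca import control_feature_matrix, control_pcs
from cpacor.data_model import Manifest
from cpacor.normalization import normalize
from cpacor.synthetic import (
    CohortDesign,
    generate_cohort,
    generate_manifest,
    generate_reference,
)

logging.getLogger("cpacor").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(n_samples=120, n_markers=1000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    manifest, controls = generate_manifest(small_design)
    reference = generate_reference(manifest, small_design)
    raw, cov, truth = generate_cohort(manifest, controls, reference, small_design)
    return {"design": small_design, "manifest": manifest, "controls": controls,
            "reference": reference, "raw": raw, "cov": cov, "truth": truth}


@pytest.fixture(scope="session")
def small_masked(small_cohort):
    raw = qc_mod.attach_manifest(small_cohort["raw"].copy(),
                                 small_cohort["manifest"])
    raw = qc_mod.background_correct(raw, small_cohort["controls"])
    detp = qc_mod.detection_pvalues(raw, small_cohort["controls"])
    masked = qc_mod.apply_detection_mask(raw, detp, 1e-16)
    return {**small_cohort, "masked": masked, "detp": detp}


@pytest.fixture(scope="session")
def small_beta(small_masked):
    manifest = small_masked["manifest"]
    auto = manifest.is_autosomal()
    sub_manifest = Manifest(manifest.df.loc[auto])
    sub = small_masked["masked"].select_markers(auto)
    beta = normalize(sub, sub_manifest, "QN-I6")
    return {**small_masked, "beta": beta, "sub_manifest": sub_manifest,
            "sub_raw": sub}


@pytest.fixture(scope="session")
def small_adjusted(small_beta):
    pcs = control_pcs(control_feature_matrix(small_beta["masked"],
                                             small_beta["controls"]), k=20)
    est = estimate_wbc(small_beta["beta"], small_beta["reference"])
    cov2 = small_beta["cov"].with_cell_estimates(est.weights)
    design = build_design(cov2, control_pcs=pcs.scores)
    y = cov2.df["phenotype"].to_numpy(dtype=float)
    # "design" here is the regression design matrix (the CohortDesign object
    # stays available under small_cohort["design"])
    return {**small_beta, "pcs": pcs, "cells": est, "cov2": cov2,
            "design": design, "y": y}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
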