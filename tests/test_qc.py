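"""Background correction, detection-P calling, call rates, sex checks and
outlier rates, with hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from cpacor import qc as Q
from cpacor.data_model import BetaMatrix, ControlManifest, CovariateTable, Manifest, RawIntensities


def _tiny_raw(neg_green, neg_red, M, U, ptype="II", channel="both"):
    """One-marker, n-sample intensity set with crafted negative controls."""
    n = np.asarray(M).shape[0] if np.ndim(M) > 0 else 1
    M = np.atleast_2d(np.asarray(M, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n = M.shape[1]
    n_neg = len(neg_green)
    cg = np.tile(np.asarray(neg_green, dtype=float)[:, None], (1, n))
    cr = np.tile(np.asarray(neg_red, dtype=float)[:, None], (1, n))
    raw = RawIntensities(pd.Index(["m1"]), pd.Index([f"s{i}" for i in range(n)]),
                         M, U, pd.Index([f"neg{i}" for i in range(n_neg)]), cg, cr)
    ctl = ControlManifest(pd.DataFrame(
        {"category": ["negative"] * n_neg},
        index=pd.Index([f"neg{i}" for i in range(n_neg)], name="control_id")))
    man = Manifest(pd.DataFrame({
        "chromosome": ["1"], "position": [100], "probe_type": [ptype],
        "channel": [channel], "flags": [frozenset()],
    }, index=pd.Index(["m1"], name="marker_id")))
    Q.attach_manifest(raw, man)
    return raw, ctl, man


# negatives with median 100 and normal-consistent MAD exactly 10
_NEG_SIGMA10 = [100 - 2 * 6.744897501960818, 100 - 6.744897501960818, 100.0,
                100 + 6.744897501960818, 100 + 2 * 6.744897501960818]


def test_background_subtracts_negative_quantile():
    """Negatives all equal 100 -> background 100; probe at 150 corrects to
    50, and values below background clamp at the floor of 1."""
    raw, ctl, _ = _tiny_raw([100] * 5, [100] * 5, [[150.0, 60.0]], [[150.0, 60.0]])
    out = Q.background_correct(raw, ctl)
    np.testing.assert_allclose(out.M[0], [50.0, 1.0])
    np.testing.assert_allclose(out.U[0], [50.0, 1.0])
    # monotone: larger raw intensity never corrects below a smaller one
    raw2, ctl2, _ = _tiny_raw([100] * 5, [100] * 5, [[150.0, 151.0]], [[1.0, 2.0]])
    out2 = Q.background_correct(raw2, ctl2)
    assert out2.M[0, 1] >= out2.M[0, 0]


def test_background_requires_negative_controls(small_cohort):
    raw = small_cohort["raw"]
    no_neg = ControlManifest(pd.DataFrame(
        {"category": ["staining"] * len(raw.control_ids)},
        index=raw.control_ids))
    with pytest.raises(ValueError, match="negative"):
        Q.background_correct(raw, no_neg)


def test_detection_p_at_background_mean_is_half():
    """A Type II total exactly at mu_G + mu_R sits at the centre of the
    background distribution: p = 0.5 by symmetry."""
    raw, ctl, _ = _tiny_raw(_NEG_SIGMA10, _NEG_SIGMA10, [[100.0]], [[100.0]])
    detp = Q.detection_pvalues(raw, ctl)
    assert detp.p[0, 0] == pytest.approx(0.5, abs=1e-12)


def test_detection_p_normal_tail_oracle():
    """mu=100, sigma=10 per channel; Type II total 240 -> z = (240-200)/20
    = 2 -> upper tail 0.0227501 (frozen normal-table value)."""
    raw, ctl, _ = _tiny_raw(_NEG_SIGMA10, _NEG_SIGMA10, [[140.0]], [[100.0]])
    detp = Q.detection_pvalues(raw, ctl)
    assert detp.p[0, 0] == pytest.approx(0.022750131948, abs=1e-9)


def test_detection_p_type_one_uses_single_channel():
    """Type I red marker compares against Normal(2 mu_R, 2 sigma_R)."""
    raw, ctl, _ = _tiny_raw(_NEG_SIGMA10, _NEG_SIGMA10, [[140.0]], [[100.0]],
                            ptype="I", channel="red")
    detp = Q.detection_pvalues(raw, ctl)
    assert detp.p[0, 0] == pytest.approx(0.022750131948, abs=1e-9)


def test_detection_p_floor_is_machine_epsilon():
    """An extremely bright probe yields the double-precision complement
    floor (machine epsilon ~2.2e-16), never exactly zero."""
    raw, ctl, _ = _tiny_raw(_NEG_SIGMA10, _NEG_SIGMA10, [[50000.0]], [[50000.0]])
    detp = Q.detection_pvalues(raw, ctl)
    assert detp.p[0, 0] == np.finfo(float).eps
    assert detp.p[0, 0] > 0
    assert detp.p_raw[0, 0] == 0.0                  # underflow drives masking


def test_detection_mask_threshold_inclusive_and_monotone(small_masked):
    detp = small_masked["detp"]
    raw = small_masked["masked"]
    # p exactly at threshold is masked (>= is inclusive)
    t = float(np.median(detp.p_raw[detp.p_raw > 0]))
    masked_t = Q.apply_detection_mask(raw, detp, t)
    at = detp.p_raw == t
    if at.any():
        assert masked_t.missing_mask[at].all()
    # stricter threshold masks a superset
    m_strict = Q.apply_detection_mask(raw, detp, 1e-16)
    m_loose = Q.apply_detection_mask(raw, detp, 0.05)
    assert (m_loose.missing_mask <= m_strict.missing_mask).all()
    # threshold 1.0 masks only p_raw == 1 entries
    m_one = Q.apply_detection_mask(raw, detp, 1.0)
    np.testing.assert_array_equal(m_one.missing_mask,
                                  raw.missing_mask | (detp.p_raw >= 1.0))


def test_call_rate_arithmetic_and_double_counting():
    raw, ctl, man = _tiny_raw([100] * 5, [100] * 5,
                              [[10.0, 10.0, 10.0]], [[10.0, 10.0, 10.0]])
    raw.missing_mask[0, 0] = True
    s, m = Q.call_rates(raw)
    assert s.iloc[0] == pytest.approx(0.0)
    assert m.iloc[0] == pytest.approx(2 / 3)
    # per-sample and per-marker missing counts tally up
    assert (1 - s).sum() * raw.n_markers == pytest.approx(
        ((1 - m) * raw.n_samples).sum())


def test_sex_check_rules_and_cohort_direction(small_masked):
    manifest = small_masked["manifest"]
    cov = small_masked["cov"]
    masked = small_masked["masked"]
    verdicts = Q.sex_check(masked, manifest, cov)
    assert set(verdicts.unique()) <= {"pass", "mismatch"}
    # on a well-labelled synthetic cohort all samples pass
    assert (verdicts == "pass").all()
    # female Y call rates sit well below male ones at the stringent threshold
    y_rows = (manifest.df["chromosome"] == "Y").to_numpy()
    y_rate = (~masked.missing_mask[y_rows]).mean(axis=0)
    fem = (cov.df["sex"] == "F").to_numpy()
    assert y_rate[fem].mean() < y_rate[~fem].mean()
    # swapping one label produces a mismatch verdict
    flipped = cov.df.copy()
    flipped.iloc[0, flipped.columns.get_loc("sex")] = \
        "M" if flipped["sex"].iloc[0] == "F" else "F"
    v2 = Q.sex_check(masked, manifest, CovariateTable(flipped))
    assert v2.iloc[0] == "mismatch"


def test_sex_check_without_y_markers_is_untestable(small_masked):
    manifest = small_masked["manifest"]
    auto = manifest.is_autosomal()
    sub = small_masked["masked"].select_markers(auto)
    v = Q.sex_check(sub, Manifest(manifest.df.loc[auto]), small_masked["cov"])
    assert (v == "untestable").all()


def test_outlier_rate_hand_oracle():
    """{1,2,3,4,100}/100: Q1=0.02, Q3=0.04, IQR=0.02, upper fence 0.07 ->
    one outlier of five -> rate 0.2. A constant marker has rate 0."""
    beta = BetaMatrix(pd.Index(["a", "b"]), pd.Index(list("vwxyz")),
                      np.array([[.01, .02, .03, .04, .99],
                                [.5, .5, .5, .5, .5]]))
    rate = Q.outlier_rate(beta)
    assert rate["a"] == pytest.approx(0.2)
    assert rate["b"] == pytest.approx(0.0)


def test_outlier_rate_normal_tail(rng):
    """For Normal draws the Tukey-fence outlier rate converges to the
    closed-form tail mass beyond +-2.698 sigma (~0.7%)."""
    vals = rng.normal(0.5, 0.05, size=(200, 2000)).clip(0.0, 0.999)
    beta = BetaMatrix(pd.Index([f"m{i}" for i in range(200)]),
                      pd.Index([f"s{j}" for j in range(2000)]), vals)
    rate = Q.outlier_rate(beta)
    assert rate.mean() == pytest.approx(0.00698, abs=0.002)


def test_qc_filter_strict_threshold(small_masked):
    """Call rate exactly at the threshold is kept; below it is excluded."""
    masked = small_masked["masked"].copy()
    Q.attach_manifest(masked, small_masked["manifest"])
    n_m = masked.n_markers
    # force sample 0 below 98% and sample 1 exactly at 98%
    k_below = int(np.ceil(n_m * 0.02)) + 1
    masked.missing_mask[:, 0] = False
    masked.missing_mask[:k_below, 0] = True
    report = Q.qc_filter(masked, small_masked["manifest"], small_masked["cov"],
                         sample_threshold=0.98, check_sex=False)
    excluded = set(report.excluded_samples["sample_id"])
    assert masked.sample_ids[0] in excluded
    rate1 = report.sample_call_rate.iloc[1]
    if rate1 >= 0.98:
        assert masked.sample_ids[1] not in excluded
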