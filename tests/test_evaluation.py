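"""Spike-in arithmetic and ranking, duplicate concordance, replicate
regression and local-correlation diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cpacor.data_model import AssociationResult, BetaMatrix, Manifest, RawIntensities
from cpacor.evaluation import (
    SpikePlan,
    duplicate_concordance,
    local_correlation,
    make_spike_plan,
    spike_intensities,
    spike_rank_score,
)
from cpacor.normalization import compute_beta


def _raw_single(M, U, n_samples):
    return RawIntensities(
        pd.Index(["m1"]), pd.Index([f"s{j}" for j in range(n_samples)]),
        np.asarray(M, dtype=float)[None, :], np.asarray(U, dtype=float)[None, :],
        pd.Index(["c1"]), np.full((1, n_samples), 100.0),
        np.full((1, n_samples), 100.0))


def test_spike_plugin_arithmetic():
    """beta row (0.4, 0.5, 0.6) has SD exactly 0.1; spiking the case sample
    at magnitude 1 moves beta 0.4 -> 0.5 and M' = 0.5 x (900+100) / 0.5
    = 1000 (hand-derived)."""
    M = [2000.0 / 3.0, 1000.0, 1500.0]
    U = [900.0, 900.0, 900.0]
    raw = _raw_single(M, U, 3)
    beta = compute_beta(raw)
    np.testing.assert_allclose(beta.beta[0], [0.4, 0.5, 0.6], atol=1e-12)
    plan = SpikePlan(marker_ids=["m1"], magnitude=1.0, alter={"m1": "M"})
    out = spike_intensities(raw, beta, plan, case_labels=[True, False, False])
    assert out.M[0, 0] == pytest.approx(1000.0, abs=1e-9)
    assert out.M[0, 1] == M[1] and out.M[0, 2] == M[2]


def test_spike_magnitude_zero_is_identity(small_cohort):
    raw = small_cohort["raw"]
    beta = compute_beta(raw)
    plan = make_spike_plan(small_cohort["manifest"], n=10, magnitude=0.0, seed=1)
    out = spike_intensities(raw, beta, plan,
                            small_cohort["cov"].df["phenotype"] > 0)
    np.testing.assert_allclose(out.M, raw.M, atol=1e-9)
    np.testing.assert_allclose(out.U, raw.U, atol=1e-9)


def test_spike_round_trip_exact(small_cohort):
    """Recomputing beta from spiked intensities returns the target beta to
    1e-12 where no clipping occurred, for both M- and U-altered probes."""
    raw = small_cohort["raw"]
    beta = compute_beta(raw)
    case = (small_cohort["cov"].df["phenotype"] > 0).to_numpy()
    plan = make_spike_plan(small_cohort["manifest"], n=40, magnitude=0.3, seed=2)
    out = spike_intensities(raw, beta, plan, case)
    beta_out = compute_beta(out)
    rows = raw.marker_ids.get_indexer(pd.Index(plan.marker_ids))
    for mid, i in zip(plan.marker_ids, rows):
        sd = np.nanstd(beta.beta[i], ddof=1)
        target = beta.beta[i] + 0.3 * sd
        clip_free = (target < 1.0) & case
        if plan.alter[mid] == "U":                  # U' >= 0 required too
            clip_free &= (raw.M[i] * (1 - target) / np.clip(target, 1e-12, None)
                          - beta.offset) >= 0
        np.testing.assert_allclose(beta_out.beta[i, clip_free],
                                   target[clip_free], atol=1e-12)


def test_spike_plan_half_m_half_u(small_cohort):
    plan = make_spike_plan(small_cohort["manifest"], n=40, magnitude=1.0, seed=3)
    alters = list(plan.alter.values())
    assert alters.count("M") == 20 and alters.count("U") == 20


def test_rank_score_extremes_and_ties():
    ids = [f"m{i}" for i in range(10)]
    df = pd.DataFrame({
        "chromosome": ["1"] * 10, "position": range(1, 11),
        "coef": np.linspace(1, 0.1, 10), "se": [0.1] * 10,
        "p": [1e-8, 1e-7, 1e-6, 0.5, 0.5, 0.5, 0.9, 0.9, np.nan, np.nan],
        "n_used": [50] * 10, "call_rate": [1.0] * 10,
        "flags": [frozenset()] * 10, "converged": [True] * 8 + [False] * 2,
    }, index=pd.Index(ids))
    res = AssociationResult(df)
    plan = SpikePlan(marker_ids=["m0", "m1", "m2"], magnitude=1.0,
                     alter={"m0": "M", "m1": "U", "m2": "M"})
    assert spike_rank_score(res, plan, k=3) == 1.0
    # missing p sorts last: a spiked marker with NaN p is unranked
    plan2 = SpikePlan(marker_ids=["m8", "m9"], magnitude=1.0,
                      alter={"m8": "M", "m9": "U"})
    assert spike_rank_score(res, plan2, k=8) == 0.0


def test_rank_score_random_ranking_hypergeometric(rng):
    """Under random ranking the expected score is k/M (hypergeometric
    mean); the Monte-Carlo average stays within 3 SE."""
    M, k, n_spike, reps = 400, 40, 40, 150
    ids = [f"m{i}" for i in range(M)]
    base = pd.DataFrame({
        "chromosome": ["1"] * M, "position": range(1, M + 1),
        "coef": np.ones(M), "se": np.ones(M), "n_used": [50] * M,
        "call_rate": [1.0] * M, "flags": [frozenset()] * M,
        "converged": [True] * M,
    }, index=pd.Index(ids))
    plan = SpikePlan(marker_ids=ids[:n_spike], magnitude=1.0,
                     alter={i: "M" for i in ids[:n_spike]})
    scores = []
    for _ in range(reps):
        df = base.copy()
        df["p"] = rng.permutation(np.linspace(1e-6, 1.0, M))
        scores.append(spike_rank_score(AssociationResult(df), plan, k=k))
    expected = k / M
    se = np.std(scores, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(scores) - expected) < 3 * se


def test_duplicate_concordance_identity_and_inversion(rng):
    vals = rng.random((50, 8)) * 0.99
    ids = pd.Index([f"m{i}" for i in range(50)])
    a = BetaMatrix(ids, pd.Index([f"o{j}" for j in range(8)]), vals)
    b = BetaMatrix(ids, pd.Index([f"r{j}" for j in range(8)]), vals)
    pairing = pd.DataFrame({"original": a.sample_ids, "replicate": b.sample_ids})
    r = duplicate_concordance(a, b, pairing, level="marker")
    np.testing.assert_allclose(r, 1.0, atol=1e-12)
    binv = BetaMatrix(ids, b.sample_ids, (1 - vals) * 0.999)
    r2 = duplicate_concordance(a, binv, pairing, level="sample")
    np.testing.assert_allclose(r2, -1.0, atol=1e-6)
    # non-bijective pairing rejected
    bad = pd.DataFrame({"original": [a.sample_ids[0]] * 2,
                        "replicate": b.sample_ids[:2]})
    with pytest.raises(ValueError, match="bijection"):
        duplicate_concordance(a, b, bad)


def test_local_correlation_distance_boundary():
    """A pair at exactly 5,000 bp is included; at 5,001 bp it is not."""
    df = pd.DataFrame({
        "chromosome": ["1", "1", "1"],
        "position": [1000, 6000, 11001],
        "probe_type": ["II"] * 3, "channel": ["both"] * 3,
        "flags": [frozenset()] * 3,
    }, index=pd.Index(["a", "b", "c"], name="marker_id"))
    manifest = Manifest(df)
    rng = np.random.default_rng(1)
    vals = rng.random((3, 30)) * 0.99
    beta = BetaMatrix(df.index, pd.Index([f"s{j}" for j in range(30)]), vals)
    prof = local_correlation(beta, manifest, max_dist=5000, top_frac=1.0)
    pairs = set(map(tuple, prof.pairs[["marker_i", "marker_j"]].to_numpy()))
    assert ("a", "b") in pairs                      # 5,000 bp apart
    assert ("b", "c") not in pairs                  # 5,001 bp apart


def test_local_correlation_cluster_contrast():
    """Markers sharing a within-cluster factor (r ~ 0.6) show higher
    smoothed correlation below the cluster span than beyond it."""
    rng = np.random.default_rng(2)
    rows, chroms, positions = [], [], []
    n = 60
    for c in range(30):                             # 30 clusters of 3, 600 bp wide
        base = 20_000 * (c + 1)
        f = rng.normal(size=n)
        for j, off in enumerate((0, 300, 600)):
            chroms.append("1")
            positions.append(base + off)
            rows.append(0.5 + 0.1 * (np.sqrt(0.6) * f
                                     + np.sqrt(0.4) * rng.normal(size=n)))
    # distant cross-cluster pairs: append a second marker set 3 kb away
    df = pd.DataFrame({
        "chromosome": chroms, "position": positions,
        "probe_type": ["II"] * len(rows), "channel": ["both"] * len(rows),
        "flags": [frozenset()] * len(rows),
    }, index=pd.Index([f"m{i}" for i in range(len(rows))], name="marker_id"))
    beta = BetaMatrix(df.index, pd.Index([f"s{j}" for j in range(n)]),
                      np.clip(np.vstack(rows), 0.001, 0.999))
    prof = local_correlation(beta, Manifest(df), max_dist=5000, top_frac=1.0)
    sm = prof.smoothed
    near = sm.loc[(sm.center <= 600) & (sm.n_pairs > 0), "mean_r"].mean()
    assert near > 0.4                               # within-cluster correlation
    assert (prof.pairs["distance"] <= 5000).all()
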