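"""Synthetic Infinium-450K-style dataset generator.

Emulates the statistical structure the pipeline assumes, so every stage can
be exercised (and its failure modes provoked) without real array data:

* clustered marker positions -> local correlation between neighbouring CpGs;
* ~72% Type II / 28% Type I probes, Type I split between colour channels;
* chip-level multiplicative channel gains (dye/batch effects) that act on
  marker intensities *and* on control-probe intensities, so control probes
  carry the batch signal by construction;
* Dirichlet cell mixtures over a discriminative cell-type reference, giving
  blood-like covariation between markers plus a measured total-count
  covariate derived from the true proportions;
* bimodal marginal beta values (modes near 0 and 1);
* age / sex covariate effects, optional spiked case-control effects, and a
  Y-chromosome stream where female samples yield only background signal;
* duplicate-pair designs re-measured with fresh chips and fresh technical
  noise for concordance and replicate-regression analyses.

Every draw is controlled by ``CohortDesign.seed``; a :class:`TruthRecord`
returns the planted quantities (cell proportions, chip gains, effect sizes,
true betas) for use as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    FLAG_CATEGORIES,
    ControlManifest,
    CovariateTable,
    Manifest,
    RawIntensities,
)

__all__ = [
    "CohortDesign",
    "TruthRecord",
    "generate_manifest",
    "generate_reference",
    "generate_cohort",
    "generate_duplicates",
    "concat_samples",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")

# mean blood fractions x concentration 15: granulocyte-dominated mixtures
# with realistic between-person spread (granulocytes roughly 40-80%)
_DEFAULT_ALPHA = (2.25, 1.2, 0.6, 0.75, 1.2, 9.0)

_CONTROL_CATEGORIES = ("bisulfite_conversion", "staining", "extension",
                       "hybridization", "specificity")


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort.

    Noise scales: ``batch_sd`` is the log-scale SD of the per-chip,
    per-colour-channel gain factor; ``chem_batch_sd`` is the per-factor SD
    of ``n_chem_factors`` independent per-chip chemistry factors
    (bisulfite conversion, staining, extension, hybridisation,
    specificity) that shift measured betas on the logit scale through
    marker-specific loadings and are mirrored in the control-probe
    intensities — unlike a pure channel gain this component survives
    quantile normalisation and is what Control Probe Adjustment exists to
    remove; ``scanner_gamma_sd`` is the SD of a per-chip exponent
    perturbing the scanner's intensity response (obs = I^(1+gamma) scaled
    about the typical intensity), a monotone per-sample distortion that
    shifts betas marker-specifically but is removed exactly by quantile
    normalisation of intensities; ``noise_sd`` is
    the logit-scale SD of sample-specific biological marker noise (shared
    by technical replicates); ``measurement_sd`` is the log-scale SD of
    independent multiplicative measurement noise on each M and U signal
    (redrawn for technical replicates). ``spike_magnitude`` is in units of
    the per-marker beta SD, matching the spike-in convention used
    downstream.
    """

    n_samples: int = 500
    n_markers: int = 2000
    n_controls: int = 100
    n_negative_controls: int = 20
    n_chips: int | None = None          # default: ceil(n_samples / 12)
    n_cell_types: int = 6
    dirichlet_alpha: tuple = _DEFAULT_ALPHA
    batch_sd: float = 0.3
    chem_batch_sd: float | None = None     # default: (2/3) x batch_sd
    n_chem_factors: int = 5
    scanner_gamma_sd: float | None = None  # default: (4/15) x batch_sd
    noise_sd: float = 0.15
    measurement_sd: float = 0.08
    cell_signal_frac: float = 0.3
    age_effect_frac: float = 0.05
    sex_effect_frac: float = 0.02
    spike_frac: float = 0.0
    spike_magnitude: float = 0.0
    cluster_size_bp: int = 1000
    cluster_noise_sd: float = 0.2
    cluster_decay_bp: float = 400.0
    frac_x: float = 0.04
    frac_y: float = 0.02
    intensity_scale: float = 3000.0
    intensity_sdlog: float = 0.3
    control_noise_sd: float = 0.1
    background_scale: float = 100.0
    background_sdlog: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chips is None:
            self.n_chips = max(2, -(-self.n_samples // 12))
        # batch_sd is the single dial for batch-effect magnitude: the
        # chemistry and scanner-response components scale with it unless
        # set explicitly (at the default 0.3 they are 0.2 and 0.08)
        if self.chem_batch_sd is None:
            self.chem_batch_sd = (2.0 / 3.0) * self.batch_sd
        if self.scanner_gamma_sd is None:
            self.scanner_gamma_sd = (4.0 / 15.0) * self.batch_sd
        for name in ("n_samples", "n_markers", "n_controls",
                     "n_negative_controls", "n_chips", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cell_signal_frac", "age_effect_frac", "sex_effect_frac",
                     "spike_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha length must equal n_cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")

    @property
    def cell_types(self) -> tuple:
        if self.n_cell_types == len(DEFAULT_CELL_TYPES):
            return DEFAULT_CELL_TYPES
        return tuple(f"cell{k+1}" for k in range(self.n_cell_types))


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`generate_cohort`."""

    spiked_ids: list
    spike_directions: pd.Series          # +1 / -1 per spiked marker (beta scale)
    cell_proportions: pd.DataFrame       # samples x cell types
    chip_gains: pd.DataFrame             # chips x {green, red}
    chip_assignment: pd.Series           # sample -> chip index
    age_effects: pd.Series               # logit slope per year, 0 if unaffected
    sex_effects: pd.Series               # logit offset in females, 0 if unaffected
    true_beta: pd.DataFrame              # markers x samples, pre-intensity betas


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_manifest(design: CohortDesign) -> tuple[Manifest, ControlManifest]:
    """Generate a 450K-like marker manifest plus a control-probe manifest.

    Markers are placed in clusters of 2-8 sites spanning at most
    ``cluster_size_bp``, with cluster starts >= 10 kb apart, spread over
    chromosomes 1-22 plus X and Y (fractions ``frac_x`` / ``frac_y``).
    ~72% of markers are Type II (channel "both"); Type I markers are split
    evenly between red and green. Each quality-flag category is applied
    independently to ~1% of markers.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_markers

    # carve markers into clusters of 2-8
    sizes = []
    left = n
    while left > 0:
        s = int(rng.integers(2, 9))
        s = min(s, left)
        sizes.append(s)
        left -= s

    chroms, positions = [], []
    autosomes = [str(c) for c in range(1, 23)]
    pos_cursor: dict[str, int] = {}
    for s in sizes:
        u = rng.random()
        if u < design.frac_y:
            chrom = "Y"
        elif u < design.frac_y + design.frac_x:
            chrom = "X"
        else:
            chrom = autosomes[int(rng.integers(0, 22))]
        start = pos_cursor.get(chrom, 1) + int(rng.integers(10_000, 50_000))
        offsets = np.sort(rng.choice(design.cluster_size_bp + 1, size=s, replace=False))
        for off in offsets:
            chroms.append(chrom)
            positions.append(start + int(off))
        pos_cursor[chrom] = start + design.cluster_size_bp

    is_ii = rng.random(n) < 0.72
    channel = np.where(is_ii, "both",
                       np.where(rng.random(n) < 0.5, "red", "green"))
    flags = []
    flag_draws = {c: rng.random(n) < 0.01 for c in FLAG_CATEGORIES}
    for i in range(n):
        flags.append(frozenset(c for c in FLAG_CATEGORIES if flag_draws[c][i]))

    marker_ids = [f"cg{i:08d}" for i in range(n)]
    mdf = pd.DataFrame({
        "chromosome": chroms,
        "position": positions,
        "probe_type": np.where(is_ii, "II", "I"),
        "channel": channel,
        "flags": flags,
    }, index=pd.Index(marker_ids, name="marker_id"))

    n_neg = design.n_negative_controls
    n_other = design.n_controls - n_neg
    if n_other < len(_CONTROL_CATEGORIES):
        raise ValueError("n_controls too small for the control category taxonomy")
    cats = [_CONTROL_CATEGORIES[i % len(_CONTROL_CATEGORIES)] for i in range(n_other)]
    cats += ["negative"] * n_neg
    cdf = pd.DataFrame(
        {"category": cats},
        index=pd.Index([f"ctl{i:05d}" for i in range(design.n_controls)],
                       name="control_id"))
    return Manifest(mdf), ControlManifest(cdf)


def generate_reference(manifest: Manifest, design: CohortDesign,
                       n_reference: int = 500) -> pd.DataFrame:
    """Generate a discriminative cell-type reference beta matrix.

    Picks ``n_reference`` autosomal markers and draws, for each, one beta
    value per cell type in (0.02, 0.98) with a between-cell-type range of
    at least 0.3, so the reference has full column rank and cell mixtures
    are identifiable. Returns a markers x cell-types DataFrame.
    """
    if manifest.n_markers < n_reference:
        raise ValueError(f"manifest must contain >= {n_reference} markers")
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 101)))
    auto_ids = manifest.marker_ids[manifest.is_autosomal()]
    if len(auto_ids) < n_reference:
        raise ValueError("not enough autosomal markers for the reference")
    chosen = pd.Index(sorted(rng.choice(auto_ids, size=n_reference, replace=False)))

    K = design.n_cell_types
    vals = np.empty((n_reference, K))
    for i in range(n_reference):
        for _ in range(100):
            row = rng.uniform(0.02, 0.98, size=K)
            if row.max() - row.min() >= 0.3:
                break
        vals[i] = row
    return pd.DataFrame(vals, index=chosen, columns=list(design.cell_types))


def _cluster_blocks(manifest: Manifest, cluster_size_bp: int):
    """Recover the contiguous position clusters the manifest was built
    with: a new cluster starts at a chromosome change or a gap larger
    than the cluster span."""
    chrom = manifest.df["chromosome"].to_numpy()
    pos = manifest.df["position"].to_numpy()
    blocks = []
    start = 0
    for i in range(1, len(pos)):
        if chrom[i] != chrom[i - 1] or pos[i] - pos[i - 1] > cluster_size_bp:
            blocks.append(np.arange(start, i))
            start = i
    blocks.append(np.arange(start, len(pos)))
    return blocks


def _clustered_noise(rng, manifest, design, n_samples):
    """Logit-scale noise shared by neighbouring markers, with correlation
    decaying as exp(-distance / cluster_decay_bp) within each position
    cluster — the local-correlation structure of CpG neighbourhoods."""
    n_m = manifest.n_markers
    out = np.zeros((n_m, n_samples))
    if design.cluster_noise_sd <= 0:
        return out
    pos = manifest.df["position"].to_numpy()
    for idx in _cluster_blocks(manifest, design.cluster_size_bp):
        k = len(idx)
        z = rng.normal(0.0, 1.0, size=(k, n_samples))
        if k == 1:
            out[idx] = design.cluster_noise_sd * z
            continue
        dm = np.abs(pos[idx][:, None] - pos[idx][None, :])
        C = np.exp(-dm / design.cluster_decay_bp)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(k))
        out[idx] = design.cluster_noise_sd * (L @ z)
    return out


def _bimodal_base_beta(rng, n):
    """Marginal beta distribution with modes near 0 and 1 (array-like)."""
    comp = rng.random(n)
    out = np.empty(n)
    lo = comp < 0.4
    hi = (comp >= 0.4) & (comp < 0.8)
    mid = comp >= 0.8
    out[lo] = rng.beta(1.5, 10.0, size=lo.sum())
    out[hi] = rng.beta(10.0, 1.5, size=hi.sum())
    out[mid] = rng.beta(3.0, 3.0, size=mid.sum())
    return np.clip(out, 0.01, 0.99)


def _route_intensities(manifest, beta, T, g_green, g_red, eps_m, eps_u):
    """Route M/U signal to colour channels by probe type and apply gains.

    Type II probes read M in green and U in red; Type I probes read both
    signals in their design channel. ``g_green`` / ``g_red`` are per-sample
    gain vectors (chip gains expanded to samples).
    """
    ptype = manifest.df["probe_type"].to_numpy()
    chan = manifest.df["channel"].to_numpy()
    gm = np.empty_like(beta)
    gu = np.empty_like(beta)
    ii = ptype == "II"
    gm[ii] = g_green[None, :]
    gu[ii] = g_red[None, :]
    ired = (~ii) & (chan == "red")
    gm[ired] = g_red[None, :]
    gu[ired] = g_red[None, :]
    igrn = (~ii) & (chan == "green")
    gm[igrn] = g_green[None, :]
    gu[igrn] = g_green[None, :]
    M = beta * T * gm * eps_m
    U = (1.0 - beta) * T * gu * eps_u
    return M, U


def _draw_chip_gains(rng, n_chips, batch_sd):
    """Per-chip channel gains: a shared chip-brightness factor of log-SD
    ``batch_sd`` plus channel-specific dye factors of half that SD, so the
    two channels are correlated (as on real scanners) while the dye ratio
    — which is what distorts Type II betas — still varies between chips."""
    if batch_sd <= 0:
        return np.ones(n_chips), np.ones(n_chips)
    shared = rng.normal(0.0, batch_sd, size=n_chips)
    dg = rng.normal(0.0, batch_sd / 2.0, size=n_chips)
    dr = rng.normal(0.0, batch_sd / 2.0, size=n_chips)
    return np.exp(shared + dg), np.exp(shared + dr)


def _scanner_response(I, gamma, scale):
    """Power-law intensity response: obs = I^(1+gamma) anchored at the
    typical intensity ``scale``, so the centre of the distribution stays
    put while bright and dim signals move apart (or together). ``gamma``
    broadcasts against ``I`` (per-sample vector or full matrix). Because
    the exponent differs between colour channels, the induced beta
    distortion is intensity-dependent (not a monotone warp of beta), yet
    it is a monotone per-sample transform of each channel's intensities —
    exactly the kind of bias intensity-space quantile normalisation
    removes."""
    gamma = np.asarray(gamma)
    if gamma.ndim == 1:
        gamma = gamma[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp((1.0 + gamma) * (np.log(I) - np.log(scale)) + np.log(scale))
    return np.where(I > 0, out, 0.0)


def _technical_layer(rng, design, manifest, true_beta, female, chip_of_sample,
                     gains_green, gains_red, chem_load=None, chem_chip=None,
                     gamma_green=None, gamma_red=None):
    """Turn true betas into raw M/U intensities for one measurement round.

    ``chem_load`` (markers x factors) and ``chem_chip`` (chips x factors)
    shift the measured beta on the logit scale before intensities are
    formed: the multi-factor chemistry component of the batch effect.
    """
    n_markers, n_samples = true_beta.shape
    beta_meas = true_beta
    if chem_load is not None and chem_chip is not None:
        shift = (chem_load @ chem_chip.T)[:, chip_of_sample]
        clipped = np.clip(true_beta, 1e-6, 1 - 1e-6)
        beta_meas = _expit(_logit(clipped) + shift)
    T = rng.lognormal(np.log(design.intensity_scale), design.intensity_sdlog,
                      size=(n_markers, n_samples))
    eps_m = rng.lognormal(0.0, design.measurement_sd, size=(n_markers, n_samples))
    eps_u = rng.lognormal(0.0, design.measurement_sd, size=(n_markers, n_samples))
    g_green = gains_green[chip_of_sample]
    g_red = gains_red[chip_of_sample]
    M, U = _route_intensities(manifest, beta_meas, T, g_green, g_red, eps_m, eps_u)
    if gamma_green is not None:
        gG = gamma_green[chip_of_sample]
        gR = gamma_red[chip_of_sample]
        ptype = manifest.df["probe_type"].to_numpy()
        chan = manifest.df["channel"].to_numpy()
        Gm = np.empty_like(M)
        Gu = np.empty_like(U)
        ii = ptype == "II"
        Gm[ii], Gu[ii] = gG[None, :], gR[None, :]
        ired = (~ii) & (chan == "red")
        Gm[ired] = Gu[ired] = gR[None, :]
        igrn = (~ii) & (chan == "green")
        Gm[igrn] = Gu[igrn] = gG[None, :]
        M = _scanner_response(M, Gm, design.intensity_scale)
        U = _scanner_response(U, Gu, design.intensity_scale)

    # female samples have no Y chromosome: only background signal there
    y_rows = (manifest.df["chromosome"] == "Y").to_numpy()
    if y_rows.any() and female.any():
        shape = (int(y_rows.sum()), int(female.sum()))
        M[np.ix_(y_rows, female)] = rng.lognormal(
            np.log(design.background_scale), design.background_sdlog, size=shape)
        U[np.ix_(y_rows, female)] = rng.lognormal(
            np.log(design.background_scale), design.background_sdlog, size=shape)
    return M, U


def _control_layer(rng, design, control_manifest, chip_of_sample,
                   gains_green, gains_red, baselines, chem_chip=None,
                   gamma_green=None, gamma_red=None):
    """Control-probe intensities: category baseline x chip gain x chemistry
    response x noise. Each non-negative control probe responds primarily
    to the chemistry factor its category monitors (with small cross-
    loadings), so the factors are recoverable from the control PCA."""
    n_controls = len(control_manifest.control_ids)
    n_samples = len(chip_of_sample)
    neg = (control_manifest.df["category"] == "negative").to_numpy()
    noise_g = rng.lognormal(0.0, design.control_noise_sd, size=(n_controls, n_samples))
    noise_r = rng.lognormal(0.0, design.control_noise_sd, size=(n_controls, n_samples))
    chem = np.ones((n_controls, n_samples))
    if chem_chip is not None:
        chem = np.exp((baselines["chem_sens"] @ chem_chip.T)[:, chip_of_sample])
    cg = baselines["green"][:, None] * gains_green[chip_of_sample][None, :] \
        * chem * noise_g
    cr = baselines["red"][:, None] * gains_red[chip_of_sample][None, :] \
        * chem * noise_r
    # negatives are pure background (they still see the scanner gain)
    nbg_g = rng.lognormal(np.log(design.background_scale), design.background_sdlog,
                          size=(int(neg.sum()), n_samples))
    nbg_r = rng.lognormal(np.log(design.background_scale), design.background_sdlog,
                          size=(int(neg.sum()), n_samples))
    cg[neg] = nbg_g * gains_green[chip_of_sample][None, :]
    cr[neg] = nbg_r * gains_red[chip_of_sample][None, :]
    if gamma_green is not None:
        cg = _scanner_response(cg, gamma_green[chip_of_sample], design.intensity_scale)
        cr = _scanner_response(cr, gamma_red[chip_of_sample], design.intensity_scale)
    return cg, cr


def _control_baselines(rng, control_manifest, n_factors):
    """Fixed per-probe baseline intensity in each channel plus each probe's
    chemistry-factor sensitivity vector (category-aligned)."""
    cats = control_manifest.df["category"]
    uniq = [c for c in cats.unique() if c != "negative"]
    level = {c: rng.uniform(800.0, 5000.0) for c in uniq}
    factor_of = {c: i % n_factors for i, c in enumerate(uniq)}
    base_g = np.empty(len(cats))
    base_r = np.empty(len(cats))
    chem_sens = np.zeros((len(cats), n_factors))
    for i, c in enumerate(cats):
        if c == "negative":
            base_g[i] = base_r[i] = np.nan   # overwritten by background draws
        else:
            base_g[i] = level[c] * rng.lognormal(0.0, 0.25)
            base_r[i] = level[c] * rng.lognormal(0.0, 0.25)
            chem_sens[i] = rng.normal(0.0, 0.2, size=n_factors)
            chem_sens[i, factor_of[c]] += 1.0
    return {"green": base_g, "red": base_r, "chem_sens": chem_sens}


def generate_cohort(manifest: Manifest, control_manifest: ControlManifest,
                    reference: pd.DataFrame, design: CohortDesign,
                    ) -> tuple[RawIntensities, CovariateTable, TruthRecord]:
    """Generate raw intensities, covariates and ground truth for a cohort.

    True betas: logistic(logit(sum_k w_k B[m,k]) + age/sex effects + logit
    noise), where w ~ Dirichlet(alpha) per sample and B is a full
    markers x cell-types base matrix whose rows at reference markers equal
    the supplied reference. Spiked markers (``spike_frac`` > 0) shift case
    samples on the beta scale by ``spike_magnitude`` x per-marker SD.
    Intensities: per-probe LogNormal totals split into M/U, routed to
    colour channels, multiplied by chip channel gains exp(N(0, batch_sd))
    and independent measurement noise. Control probes see the same chip
    gains, so batch structure is recoverable from them.
    """
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 202)))
    n_m, n_s = design.n_markers, design.n_samples
    if manifest.n_markers != n_m:
        raise ValueError("manifest size does not match design.n_markers")
    cell_types = list(design.cell_types)
    if list(reference.columns) != cell_types:
        raise ValueError("reference columns must match design cell types")

    # full per-cell-type base beta matrix; reference rows override
    base = _bimodal_base_beta(rng, n_m)
    B = np.tile(base[:, None], (1, design.n_cell_types))
    has_cell_signal = rng.random(n_m) < design.cell_signal_frac
    delta = rng.normal(0.0, 0.7, size=(n_m, design.n_cell_types))
    B = _expit(_logit(np.clip(B, 0.01, 0.99)) + delta * has_cell_signal[:, None])
    ref_pos = manifest.marker_ids.get_indexer(reference.index)
    B[ref_pos] = reference.to_numpy()

    # samples
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n_s)], name="sample_id")
    sex = np.where(rng.random(n_s) < 0.5, "F", "M")
    female = sex == "F"
    age = np.clip(rng.normal(50.0, 10.0, size=n_s), 20.0, 80.0)
    case = (rng.random(n_s) < 0.5).astype(int)
    W = rng.dirichlet(design.dirichlet_alpha, size=n_s)          # samples x K
    chip_of_sample = np.arange(n_s) % design.n_chips

    # covariate effects
    age_slope = np.zeros(n_m)
    aff = rng.random(n_m) < design.age_effect_frac
    age_slope[aff] = rng.normal(0.0, 0.012, size=aff.sum())
    sex_off = np.zeros(n_m)
    aff = rng.random(n_m) < design.sex_effect_frac
    sex_off[aff] = rng.normal(0.0, 0.5, size=aff.sum())

    mix = B @ W.T                                                # markers x samples
    eta = _logit(np.clip(mix, 1e-6, 1 - 1e-6))
    eta += age_slope[:, None] * (age - age.mean())[None, :]
    eta += sex_off[:, None] * female[None, :]
    eta += _clustered_noise(rng, manifest, design, n_s)
    eta += rng.normal(0.0, design.noise_sd, size=(n_m, n_s))
    true_beta = _expit(eta)

    # spiked case-control effects on the beta scale
    spiked_ids: list = []
    directions = pd.Series(dtype=float)
    if design.spike_frac > 0 and design.spike_magnitude > 0:
        n_spike = int(round(design.spike_frac * n_m))
        auto = manifest.is_autosomal()
        pool = np.flatnonzero(auto)
        spike_idx = rng.choice(pool, size=n_spike, replace=False)
        sd = true_beta[spike_idx].std(axis=1, ddof=1)
        dirs = np.where(rng.random(n_spike) < 0.5, 1.0, -1.0)
        shift = (design.spike_magnitude * sd * dirs)[:, None] * case[None, :]
        true_beta[spike_idx] = np.clip(true_beta[spike_idx] + shift, 1e-6, 1 - 1e-6)
        spiked_ids = list(manifest.marker_ids[spike_idx])
        directions = pd.Series(dirs, index=spiked_ids)

    gains_green, gains_red = _draw_chip_gains(rng, design.n_chips, design.batch_sd)
    K = design.n_chem_factors
    chem_chip = rng.normal(0.0, design.chem_batch_sd, size=(design.n_chips, K))
    chem_load = rng.normal(0.0, 1.0 / np.sqrt(K), size=(n_m, K))
    gamma_green = rng.normal(0.0, design.scanner_gamma_sd, size=design.n_chips)
    gamma_red = rng.normal(0.0, design.scanner_gamma_sd, size=design.n_chips)

    M, U = _technical_layer(rng, design, manifest, true_beta, female,
                            chip_of_sample, gains_green, gains_red,
                            chem_load, chem_chip, gamma_green, gamma_red)
    baselines = _control_baselines(rng, control_manifest, K)
    cg, cr = _control_layer(rng, design, control_manifest, chip_of_sample,
                            gains_green, gains_red, baselines, chem_chip,
                            gamma_green, gamma_red)

    wbc_tot = 4.0 + 8.0 * W[:, cell_types.index("Gran") if "Gran" in cell_types else -1] \
        + rng.normal(0.0, 0.5, size=n_s)

    cov = CovariateTable(pd.DataFrame({
        "phenotype": case,
        "age": age,
        "sex": sex,
        "wbc_tot": wbc_tot,
        "chip": [f"chip{c:03d}" for c in chip_of_sample],
    }, index=sample_ids))

    raw = RawIntensities(manifest.marker_ids, sample_ids, M, U,
                         control_manifest.control_ids, cg, cr)
    truth = TruthRecord(
        spiked_ids=spiked_ids,
        spike_directions=directions,
        cell_proportions=pd.DataFrame(W, index=sample_ids, columns=cell_types),
        chip_gains=pd.DataFrame({"green": gains_green, "red": gains_red}),
        chip_assignment=pd.Series(chip_of_sample, index=sample_ids),
        age_effects=pd.Series(age_slope, index=manifest.marker_ids),
        sex_effects=pd.Series(sex_off, index=manifest.marker_ids),
        true_beta=pd.DataFrame(true_beta, index=manifest.marker_ids,
                               columns=sample_ids),
    )
    # keep marker/probe-level technical parameters for duplicate re-measurement
    truth._control_baselines = baselines            # type: ignore[attr-defined]
    truth._covariates = cov                         # type: ignore[attr-defined]
    truth._chem_load = chem_load                    # type: ignore[attr-defined]
    return raw, cov, truth


def generate_duplicates(manifest: Manifest, control_manifest: ControlManifest,
                        truth: TruthRecord, design: CohortDesign,
                        n_pairs: int, seed: int | None = None,
                        ) -> tuple[RawIntensities, pd.DataFrame]:
    """Re-measure the first ``n_pairs`` samples in a fresh batch.

    True betas are identical to the originals; chips, chip gains, intensity
    totals, measurement noise and control-probe noise are all redrawn, so
    the two measurements differ only by the technical layer. Replicate
    samples are placed on fresh chips of 12 (mirroring a separate-batch
    re-run). Returns the replicate intensities (sample ids suffixed
    ``_rep``) and a pairing table with columns ``original`` / ``replicate``.
    """
    if n_pairs > truth.true_beta.shape[1]:
        raise ValueError("n_pairs exceeds the number of cohort samples")
    rng = np.random.default_rng(np.random.SeedSequence(
        (design.seed if seed is None else seed, 303)))
    orig_ids = truth.true_beta.columns[:n_pairs]
    true_beta = truth.true_beta[orig_ids].to_numpy()
    cov = truth._covariates.df.loc[orig_ids]        # type: ignore[attr-defined]
    female = (cov["sex"] == "F").to_numpy()

    n_rep_chips = max(1, -(-n_pairs // 12))
    chip_of_sample = np.arange(n_pairs) % n_rep_chips
    gains_green, gains_red = _draw_chip_gains(rng, n_rep_chips, design.batch_sd)
    chem_chip = rng.normal(0.0, design.chem_batch_sd,
                           size=(n_rep_chips, design.n_chem_factors))
    chem_load = truth._chem_load                    # type: ignore[attr-defined]
    gamma_green = rng.normal(0.0, design.scanner_gamma_sd, size=n_rep_chips)
    gamma_red = rng.normal(0.0, design.scanner_gamma_sd, size=n_rep_chips)

    M, U = _technical_layer(rng, design, manifest, true_beta, female,
                            chip_of_sample, gains_green, gains_red,
                            chem_load, chem_chip, gamma_green, gamma_red)
    baselines = truth._control_baselines            # type: ignore[attr-defined]
    cg, cr = _control_layer(rng, design, control_manifest, chip_of_sample,
                            gains_green, gains_red, baselines, chem_chip,
                            gamma_green, gamma_red)

    rep_ids = pd.Index([f"{s}_rep" for s in orig_ids], name="sample_id")
    raw = RawIntensities(manifest.marker_ids, rep_ids, M, U,
                         control_manifest.control_ids, cg, cr)
    pairing = pd.DataFrame({"original": list(orig_ids), "replicate": list(rep_ids)})
    return raw, pairing


def concat_samples(a: RawIntensities, b: RawIntensities) -> RawIntensities:
    """Column-concatenate two intensity sets sharing markers and controls."""
    if not a.marker_ids.equals(b.marker_ids) or not a.control_ids.equals(b.control_ids):
        raise ValueError("marker/control ids must match to concatenate samples")
    return RawIntensities(
        a.marker_ids, a.sample_ids.append(b.sample_ids),
        np.hstack([a.M, b.M]), np.hstack([a.U, b.U]),
        a.control_ids,
        np.hstack([a.control_green, b.control_green]),
        np.hstack([a.control_red, b.control_red]),
        np.hstack([a.missing_mask, b.missing_mask]),
    )
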