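"""Synthetic stroke cohorts with planted structural-covariance ground truth.

The generator emulates what the preprocessing of a longitudinal VBM study
hands to the covariance analysis: smoothed grey-matter probability volumes
at two timepoints (sub-acute ~3 months, chronic ~1 year post-stroke) for
every subject, a 17-test cognitive battery with a few percent of missing
cells, nuisance variables with cohort-typical distributions (age 67.41 sd
12.13 years, infarct volume mean ~5787 mm^3, scan interval 276.92 sd 26.14
days), and binary lesion masks placed away from the seed regions.

Ground-truth structure
----------------------
* Six networks, each a truncated-Gaussian voxel loading map peaking at its
  two seed spheres (plus weaker satellite foci), live on a desk-scale
  24 x 28 x 24 grid at 4-mm spacing so every mm-based computation (sphere
  radii, smoothing FWHM) exercises real unit conversion.
* Subject i's network-k integrity factor is
  ``f_ik = sqrt(a) u_i + sqrt(1-a) e_ik`` — a shared integrity latent u plus
  network-specific variation (share ``a`` defaults to 0.8).
* Cognition: a latent ``w = rho u + sqrt(1-rho^2) eta`` drives the coupled
  tests, so ``rho`` is, by construction, the model's brain-behaviour latent
  correlation.  Timed tests are generated "higher worse".
* Decline: a decline latent v scales per-network atrophy rates; chronic GM
  subtracts ``loading * rate * scan-interval-years``.  An analogous latent
  ``g = rho_change v + ...`` drives longitudinal test change.  Setting the
  coupling multipliers to zero yields exact null cohorts for calibration.

``SyntheticTruth`` records everything a recovery test needs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .battery import DEFAULT_TESTS, CognitiveBattery, ConfoundTable, log_transform_volume
from .exceptions import ConfigurationError, DataError
from .gm_maps import GMDataset, SeedSpec, build_gm_dataset, write_gm_dataset

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548

#: In-grid seed layout for the desk-scale grid: 2 seeds per network, mm.
SYNTH_SEEDS: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("l_IPS", "DAN", (-22.0, -30.0, 20.0)),
    ("r_IPS", "DAN", (22.0, -30.0, 20.0)),
    ("l_DLPFC", "ECN", (-26.0, 22.0, 16.0)),
    ("r_DLPFC", "ECN", (26.0, 22.0, 16.0)),
    ("l_FI", "SN", (-22.0, 14.0, -6.0)),
    ("r_FI", "SN", (22.0, 14.0, -6.0)),
    ("l_mPFC", "DMN", (-4.0, 38.0, -2.0)),
    ("l_PCC", "DMN", (-4.0, -38.0, 22.0)),
    ("l_IFG", "LN", (-32.0, 18.0, 2.0)),
    ("l_TPole", "LN", (-28.0, 6.0, -22.0)),
    ("l_HIPP", "MN", (-20.0, -16.0, -14.0)),
    ("r_HIPP", "MN", (20.0, -16.0, -14.0)),
)

#: Tests strongly coupled to baseline network integrity (>=1 per domain).
BASELINE_COUPLED_TESTS = (
    "digit_span",
    "tmt_a",
    "simple_rt",
    "bnt",
    "hvlt_delay",
    "rcf_copy",
)

#: Tests strongly coupled to longitudinal network decline.
CHANGE_COUPLED_TESTS = (
    "choice_rt",
    "cowat_fas",
    "rcf_delay",
    "tmt_a",
    "hvlt_delay",
    "digit_span",
)

#: Tests with no coupling at all (their truth coupling rows are zero);
#: the rest of the battery couples weakly, mirroring a battery where most
#: tests carry some network signal.
NULL_TESTS = ("cdt", "letter_number", "hvlt_recognition")

WEAK_COUPLING = 0.4

#: Plausible raw-score location/scale per test, so auto-scaling is exercised.
TEST_SCALES = {
    "digit_span": (16.0, 4.0),
    "tmt_a": (45.0, 18.0),
    "simple_rt": (320.0, 60.0),
    "choice_rt": (520.0, 90.0),
    "tmt_b": (110.0, 45.0),
    "digit_symbol": (45.0, 12.0),
    "letter_number": (9.0, 3.0),
    "bnt": (25.0, 4.0),
    "cowat_animals": (17.0, 5.0),
    "cowat_fas": (35.0, 12.0),
    "hvlt_immediate": (22.0, 5.0),
    "hvlt_delay": (8.0, 3.0),
    "hvlt_recognition": (10.0, 2.0),
    "rcf_delay": (14.0, 6.0),
    "rcf_copy": (32.0, 4.0),
    "cdt": (8.0, 2.0),
    "jlo": (22.0, 5.0),
}


@dataclasses.dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic generator."""

    n_subjects: int = 73
    n_networks: int = 6
    shape: tuple[int, int, int] = (24, 28, 24)
    spacing_mm: float = 4.0
    seed_radius_mm: float = 4.0
    smooth_fwhm_mm: float = 8.0
    # GM model
    baseline_gm: float = 0.55
    baseline_field_sd: float = 0.03
    loading_amplitude: float = 0.08
    loading_sigma_mm: float = 6.0
    satellite_amplitude: float = 0.5
    voxel_noise_sd: float = 0.015
    change_noise_sd: float = 0.01
    share_common: float = 0.8
    age_slope: float = 0.015
    # decline model (rate multiplies the loading map, per year)
    decline_mean: float = 1.0
    decline_sd: float = 0.5
    # behaviour model
    latent_r: float = 0.3
    latent_r_change: float = 0.3
    coupling_baseline: float = 1.0
    coupling_change: float = 1.0
    test_noise_sd: float = 0.5
    missing_rate: float = 0.04
    # demographics (cohort-typical)
    age_mean: float = 67.41
    age_sd: float = 12.13
    p_male: float = 51.0 / 73.0
    p_right_handed: float = 67.0 / 73.0
    scan_interval_mean_days: float = 276.92
    scan_interval_sd_days: float = 26.14
    infarct_volume_mean_mm3: float = 5786.62
    infarct_volume_sd_mm3: float = 9316.65
    lesion_severity: float = 0.5
    n_lesions: int = 1
    # largest infarct the desk-scale brain can host away from the seeds
    max_lesion_volume_mm3: float = 20000.0
    make_chronic: bool = True

    def __post_init__(self) -> None:
        if max(self.shape) > 48:
            raise ConfigurationError("grid dimensions above 48 are not desk-scale")
        if not 0 <= self.missing_rate < 0.5:
            raise ConfigurationError("missing_rate must be in [0, 0.5)")
        if self.loading_amplitude * 3 + self.baseline_gm + 0.2 > 1.2:
            raise ConfigurationError("loading amplitude incompatible with [0,1] GM")
        if not 0 < self.share_common <= 1:
            raise ConfigurationError("share_common must be in (0, 1]")
        if not 1 <= self.n_networks <= 6:
            raise ConfigurationError("n_networks must be between 1 and 6")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic cohort."""

    network_names: list[str]
    network_loadings: np.ndarray  # (n_networks, *grid), zero off-network
    factor_scores: np.ndarray  # subjects x networks, baseline integrity
    decline_rates: np.ndarray  # subjects x networks, per-year
    integrity_latent: np.ndarray  # u, subjects
    decline_latent: np.ndarray  # v, subjects
    cognition_latent: np.ndarray  # w, subjects
    cognition_change_latent: np.ndarray  # g, subjects
    coupling_baseline: np.ndarray  # tests x networks (signed, implied cov)
    coupling_change: np.ndarray  # tests x networks
    latent_r: float
    latent_r_change: float
    test_noise_sd: float
    voxel_noise_sd: float
    rng_seed: int | None

    def network_mask(self, k: int) -> np.ndarray:
        return self.network_loadings[k] > 0


@dataclasses.dataclass
class Cohort:
    """Everything one synthetic run produces."""

    subacute: GMDataset
    chronic: GMDataset | None
    battery_subacute: CognitiveBattery
    battery_chronic: CognitiveBattery | None
    confounds: ConfoundTable
    lesion_masks: np.ndarray  # subjects x grid, boolean
    seeds: list[SeedSpec]
    truth: SyntheticTruth
    config: CohortConfig


# ------------------------------------------------------------------ helpers


def grid_affine(shape: Sequence[int], spacing_mm: float) -> np.ndarray:
    """Isotropic affine centring the grid on mm origin."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spacing_mm
    aff[:3, 3] = -(np.asarray(shape, dtype=float) - 1) / 2 * spacing_mm
    return aff


def smooth_field(
    volume: np.ndarray, fwhm_mm: float, spacing_mm: float | Sequence[float]
) -> np.ndarray:
    """Gaussian smoothing with mm FWHM, mass-preserving (reflective edges)."""
    if fwhm_mm < 0:
        raise DataError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    sigma_vox = (fwhm_mm / FWHM_TO_SD) / spacing
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=float), sigma=sigma_vox, mode="reflect"
    )


def _mm_coords(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """(x, y, z) mm coordinates of every voxel centre, shape (*grid, 3)."""
    idx = np.indices(shape).astype(float)
    stacked = np.stack(
        [
            affine[d, 0] * idx[0] + affine[d, 1] * idx[1] + affine[d, 2] * idx[2] + affine[d, 3]
            for d in range(3)
        ],
        axis=-1,
    )
    return stacked


def _brain_mask(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """Ellipsoidal 'brain' support inside the grid."""
    mm = _mm_coords(shape, affine)
    extent = (np.asarray(shape, dtype=float) - 1) / 2 * np.diag(affine)[:3]
    semi = 0.92 * extent
    return ((mm / semi) ** 2).sum(axis=-1) <= 1.0


def synthetic_seed_table(
    radius_mm: float = 4.0,
    shape: Sequence[int] = (24, 28, 24),
    spacing_mm: float = 4.0,
) -> list[SeedSpec]:
    """The in-grid 12-seed layout used by the generator.

    The canonical coordinates are laid out for the default 24x28x24 grid at
    4-mm spacing; for other grids they are scaled with the grid extents so
    the seeds stay inside the synthetic brain.
    """
    ref = (np.array([24, 28, 24], dtype=float) - 1) / 2 * 4.0
    ext = (np.asarray(shape, dtype=float) - 1) / 2 * spacing_mm
    scale = ext / ref
    return [
        SeedSpec(name=n, network=net,
                 centre_mm=tuple(np.asarray(c) * scale), radius_mm=radius_mm)
        for n, net, c in SYNTH_SEEDS
    ]


def _network_loading_maps(
    config: CohortConfig,
    affine: np.ndarray,
    brain: np.ndarray,
    seeds: Sequence[SeedSpec],
) -> tuple[list[str], np.ndarray]:
    """Truncated-Gaussian loading map per network, peak 1 at seed centres."""
    mm = _mm_coords(config.shape, affine)
    networks = []
    for s in seeds:
        if s.network not in networks:
            networks.append(s.network)
    maps = np.zeros((len(networks),) + tuple(config.shape))
    sigma = config.loading_sigma_mm
    for k, net in enumerate(networks):
        bumps = np.zeros(config.shape)
        for s in seeds:
            if s.network != net:
                continue
            centre = np.asarray(s.centre_mm)
            d2 = ((mm - centre) ** 2).sum(axis=-1)
            bumps = np.maximum(bumps, np.exp(-d2 / (2 * sigma**2)))
            # a weaker satellite focus, mirrored in y and pulled toward the
            # axial plane, gives each network a distributed topography
            sat = centre * np.array([1.0, -0.7, 0.5])
            d2s = ((mm - sat) ** 2).sum(axis=-1)
            bumps = np.maximum(
                bumps, config.satellite_amplitude * np.exp(-d2s / (2 * sigma**2))
            )
        # crisp planted support: truncate the Gaussian profile so every
        # planted voxel carries a substantial loading and the off-network
        # loadings are exactly zero
        bumps[bumps < 0.3 * config.satellite_amplitude] = 0.0
        bumps[~brain] = 0.0
        maps[k] = bumps
    return networks, maps


def _smoothing_scale(config: CohortConfig) -> float:
    """sd shrinkage of white noise under the generator's smoothing kernel."""
    delta = np.zeros(config.shape)
    delta[tuple(np.asarray(config.shape) // 2)] = 1.0
    kernel = smooth_field(delta, config.smooth_fwhm_mm, config.spacing_mm)
    return float(np.sqrt((kernel**2).sum()))


def plant_lesions(
    shape: Sequence[int],
    affine: np.ndarray,
    volumes_mm3: np.ndarray,
    exclusion_centres_mm: np.ndarray,
    exclusion_radius_mm: float,
    rng: np.random.Generator,
    brain: np.ndarray | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Spherical lesion masks avoiding the seed spheres.

    ``volumes_mm3`` gives one target volume per subject (0 means no lesion);
    the realized mask volume is the count of in-sphere voxels times the
    voxel volume, which is what the confound table should use.
    """
    affine = np.asarray(affine, dtype=float)
    if brain is None:
        brain = _brain_mask(shape, affine)
    mm = _mm_coords(shape, affine)
    candidates = np.argwhere(brain)
    if len(candidates) == 0:
        raise DataError("no free voxels to place lesions")
    masks = np.zeros((len(volumes_mm3),) + tuple(shape), dtype=bool)
    for i, vol in enumerate(np.asarray(volumes_mm3, dtype=float)):
        if vol <= 0:
            continue
        radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        for _ in range(max_tries):
            c_idx = candidates[rng.integers(len(candidates))]
            centre = mm[tuple(c_idx)]
            gap = np.sqrt(((exclusion_centres_mm - centre) ** 2).sum(axis=1))
            if (gap > radius + exclusion_radius_mm).all():
                d2 = ((mm - centre) ** 2).sum(axis=-1)
                masks[i] = d2 <= radius**2
                break
        else:
            raise DataError(
                f"could not place a lesion of radius {radius:.1f} mm outside "
                "the seed exclusion zone"
            )
    return masks


# ------------------------------------------------------------------ cohort


def generate_cohort(
    config: CohortConfig | None = None, rng_seed: int | None = 0
) -> Cohort:
    """Draw one fully synthetic cohort; same seed, byte-identical output."""
    config = config or CohortConfig()
    rng = np.random.default_rng(rng_seed)
    shape = tuple(config.shape)
    affine = grid_affine(shape, config.spacing_mm)
    brain = _brain_mask(shape, affine)
    seeds = synthetic_seed_table(
        config.seed_radius_mm, shape, config.spacing_mm
    )[: 2 * config.n_networks]
    networks, patterns = _network_loading_maps(config, affine, brain, seeds)
    loadings = config.loading_amplitude * patterns  # GM units per factor sd
    n = config.n_subjects
    K = len(networks)

    # ---- latent structure
    a = config.share_common
    u = rng.standard_normal(n)
    f = np.sqrt(a) * u[:, None] + np.sqrt(1 - a) * rng.standard_normal((n, K))
    v = rng.standard_normal(n)
    rates = config.decline_mean + config.decline_sd * (
        np.sqrt(a) * v[:, None] + np.sqrt(1 - a) * rng.standard_normal((n, K))
    )
    rates = np.clip(rates, 0.0, None)

    # ---- demographics / confounds
    age = rng.normal(config.age_mean, config.age_sd, n).clip(30.0, 95.0)
    sex = (rng.random(n) < config.p_male).astype(float)
    hand = (rng.random(n) < config.p_right_handed).astype(float)
    interval_days = rng.normal(
        config.scan_interval_mean_days, config.scan_interval_sd_days, n
    ).clip(150.0, 400.0)
    tiv = 1.35e6 + 1.0e5 * sex + rng.normal(0.0, 1.0e5, n)
    # log-normal infarct volumes moment-matched to the cohort mean/sd
    m, s = config.infarct_volume_mean_mm3, config.infarct_volume_sd_mm3
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    target_volumes = rng.lognormal(mu, np.sqrt(sigma2), n).clip(
        0.0, config.max_lesion_volume_mm3
    )

    # ---- lesions (avoid all seed spheres)
    centres = np.array([s.centre_mm for s in seeds], dtype=float)
    lesions = plant_lesions(
        shape,
        affine,
        target_volumes if config.n_lesions > 0 else np.zeros(n),
        centres,
        config.seed_radius_mm,
        rng,
        brain=brain,
    )
    voxel_vol = float(config.spacing_mm**3)
    infarct_volume = lesions.reshape(n, -1).sum(axis=1) * voxel_vol

    # ---- baseline GM volumes
    base_field = smooth_field(
        rng.standard_normal(shape), 2 * config.smooth_fwhm_mm, config.spacing_mm
    )
    base_field /= max(base_field.std(), 1e-12)
    baseline = np.where(
        brain, config.baseline_gm + config.baseline_field_sd * base_field, 0.05
    )
    # network cortex carries systematically higher GM, which also keeps the
    # seed spheres safely inside the 0.45 group-mean mask
    baseline = baseline + 0.06 * patterns.max(axis=0) * brain
    noise_scale = _smoothing_scale(config)
    age_z = (age - config.age_mean) / config.age_sd
    struct = np.tensordot(f, loadings, axes=(1, 0))  # (n, *grid)
    sub = baseline[None] + struct
    sub -= config.age_slope * age_z[:, None, None, None] * brain[None]
    sub = np.where(lesions, sub * (1.0 - config.lesion_severity), sub)
    noise = np.empty_like(sub)
    for i in range(n):
        noise[i] = smooth_field(
            rng.standard_normal(shape), config.smooth_fwhm_mm, config.spacing_mm
        )
    sub_unclipped = sub + config.voxel_noise_sd * noise / noise_scale
    sub_vol = np.clip(sub_unclipped, 0.0, 1.0)

    chronic_gm = None
    if config.make_chronic:
        years = interval_days[:, None, None, None] / 365.0
        decline_field = np.tensordot(rates, loadings, axes=(1, 0)) * years
        noise2 = np.empty_like(sub)
        for i in range(n):
            noise2[i] = smooth_field(
                rng.standard_normal(shape), config.smooth_fwhm_mm, config.spacing_mm
            )
        chr_vol = np.clip(
            sub_unclipped
            - decline_field
            + config.change_noise_sd * noise2 / noise_scale,
            0.0,
            1.0,
        )

    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    subacute = build_gm_dataset(
        sub_vol, affine, subject_ids=subject_ids, timepoint="subacute"
    )
    if config.make_chronic:
        chronic_gm = build_gm_dataset(
            chr_vol,
            affine,
            subject_ids=subject_ids,
            timepoint="chronic",
            mask_threshold=0.45,
        )
        # the longitudinal analysis needs one shared voxel set
        shared = subacute.mask & chronic_gm.mask
        subacute = GMDataset(
            subject_ids, sub_vol[:, shared], shared, affine, "subacute"
        )
        chronic_gm = GMDataset(
            subject_ids, chr_vol[:, shared], shared, affine, "chronic"
        )

    # ---- cognition
    test_names = [t for t, _, _ in DEFAULT_TESTS]
    domain = {t: d for t, d, _ in DEFAULT_TESTS}
    direction = {t: s for t, _, s in DEFAULT_TESTS}
    dir_sign = np.array(
        [1.0 if direction[t] == "higher_better" else -1.0 for t in test_names]
    )
    def _weights(strong: tuple[str, ...], scale: float) -> np.ndarray:
        w = np.empty(len(test_names))
        for j, t in enumerate(test_names):
            if t in NULL_TESTS:
                w[j] = 0.0
            elif t in strong:
                w[j] = scale
            else:
                w[j] = WEAK_COUPLING * scale
        return w

    c_base = _weights(BASELINE_COUPLED_TESTS, config.coupling_baseline)
    c_chg = _weights(CHANGE_COUPLED_TESTS, config.coupling_change)
    rho = config.latent_r
    w = rho * u + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal(n)
    raw = dir_sign[None, :] * c_base[None, :] * w[:, None] + (
        config.test_noise_sd * rng.standard_normal((n, len(test_names)))
    )
    raw += (c_base == 0)[None, :] * (
        np.sqrt(max(1.0 - config.test_noise_sd**2, 0.0))
        * rng.standard_normal((n, len(test_names)))
    )
    means = np.array([TEST_SCALES[t][0] for t in test_names])
    scales = np.array([TEST_SCALES[t][1] for t in test_names])
    scores_sub = means[None, :] + scales[None, :] * raw

    rho_c = config.latent_r_change
    g = rho_c * v + np.sqrt(max(1 - rho_c**2, 0.0)) * rng.standard_normal(n)
    d_raw = -dir_sign[None, :] * c_chg[None, :] * g[:, None] + (
        config.test_noise_sd * rng.standard_normal((n, len(test_names)))
    )
    scores_chr = scores_sub + scales[None, :] * d_raw

    miss_sub = rng.random(scores_sub.shape) < config.missing_rate
    miss_chr = rng.random(scores_chr.shape) < config.missing_rate
    # never blank out an entire test
    for miss in (miss_sub, miss_chr):
        full = miss.all(axis=0)
        miss[:, full] = False
    scores_sub_m = np.where(miss_sub, np.nan, scores_sub)
    scores_chr_m = np.where(miss_chr, np.nan, scores_chr)

    battery_sub = CognitiveBattery(
        subject_ids, test_names, scores_sub_m, domain, direction
    )
    battery_chr = (
        CognitiveBattery(subject_ids, test_names, scores_chr_m, domain, direction)
        if config.make_chronic
        else None
    )

    confounds = ConfoundTable(
        subject_ids,
        pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "handedness": hand,
                "infarct_volume": infarct_volume,
                "log_infarct_volume": log_transform_volume(infarct_volume),
                "tiv": tiv,
                "scan_interval": interval_days,
            },
            index=subject_ids,
        ),
    )

    truth = SyntheticTruth(
        network_names=networks,
        network_loadings=loadings,
        factor_scores=f,
        decline_rates=rates,
        integrity_latent=u,
        decline_latent=v,
        cognition_latent=w,
        cognition_change_latent=g,
        coupling_baseline=np.outer(dir_sign * c_base, np.full(K, rho * np.sqrt(a))),
        coupling_change=np.outer(-dir_sign * c_chg, np.full(K, rho_c * np.sqrt(a))),
        latent_r=rho,
        latent_r_change=rho_c,
        test_noise_sd=config.test_noise_sd,
        voxel_noise_sd=config.voxel_noise_sd,
        rng_seed=rng_seed,
    )
    return Cohort(
        subacute=subacute,
        chronic=chronic_gm,
        battery_subacute=battery_sub,
        battery_chronic=battery_chr,
        confounds=confounds,
        lesion_masks=lesions,
        seeds=seeds,
        truth=truth,
        config=config,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Serialize a cohort in the formats the pipeline reads.

    GM volumes as per-subject NIfTI, battery/confound/seed tables as TSV,
    lesion masks as NIfTI, truth as JSON + per-network loading NIfTI.
    Returns an index of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index: dict = {}
    index["subacute"] = [
        str(p) for p in write_gm_dataset(cohort.subacute, out / "subacute", "gm")
    ]
    if cohort.chronic is not None:
        index["chronic"] = [
            str(p) for p in write_gm_dataset(cohort.chronic, out / "chronic", "gm")
        ]
    cohort.battery_subacute.to_frame().to_csv(
        out / "battery_subacute.tsv", sep="\t", na_rep=""
    )
    index["battery_subacute"] = str(out / "battery_subacute.tsv")
    if cohort.battery_chronic is not None:
        cohort.battery_chronic.to_frame().to_csv(
            out / "battery_chronic.tsv", sep="\t", na_rep=""
        )
        index["battery_chronic"] = str(out / "battery_chronic.tsv")
    cohort.confounds.frame.to_csv(out / "confounds.tsv", sep="\t")
    index["confounds"] = str(out / "confounds.tsv")
    meta = pd.DataFrame(
        {
            "test": cohort.battery_subacute.test_names,
            "domain": [cohort.battery_subacute.domain[t] for t in cohort.battery_subacute.test_names],
            "direction": [cohort.battery_subacute.direction[t] for t in cohort.battery_subacute.test_names],
        }
    )
    meta.to_csv(out / "battery_meta.tsv", sep="\t", index=False)
    index["battery_meta"] = str(out / "battery_meta.tsv")
    from .gm_maps import write_seed_table

    write_seed_table(cohort.seeds, out / "seeds.tsv")
    index["seeds"] = str(out / "seeds.tsv")
    lesion_dir = out / "lesions"
    lesion_dir.mkdir(exist_ok=True)
    affine = cohort.subacute.affine
    for sid, mask in zip(cohort.subacute.subject_ids, cohort.lesion_masks):
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), affine),
            str(lesion_dir / f"lesion_{sid}.nii.gz"),
        )
    index["lesions"] = str(lesion_dir)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = cohort.truth
    with open(truth_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "network_names": t.network_names,
                "factor_scores": t.factor_scores.tolist(),
                "decline_rates": t.decline_rates.tolist(),
                "integrity_latent": t.integrity_latent.tolist(),
                "decline_latent": t.decline_latent.tolist(),
                "cognition_latent": t.cognition_latent.tolist(),
                "cognition_change_latent": t.cognition_change_latent.tolist(),
                "coupling_baseline": t.coupling_baseline.tolist(),
                "coupling_change": t.coupling_change.tolist(),
                "latent_r": t.latent_r,
                "latent_r_change": t.latent_r_change,
                "rng_seed": t.rng_seed,
            },
            fh,
            indent=1,
        )
    for k, name in enumerate(t.network_names):
        nib.save(
            nib.Nifti1Image(t.network_loadings[k], affine),
            str(truth_dir / f"loading_{name}.nii.gz"),
        )
    index["truth"] = str(truth_dir)
    return index
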