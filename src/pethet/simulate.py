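"""Digital PET phantoms and simulated patient cohorts.

Every downstream stage of the package is testable without patient data
through two generators:

* **spherical tumour phantoms** with analytically known SUV profiles, so
  SUVmax/SUVmean/SUVpeak, MTV, TLG and AUC-CSH all have closed-form
  ground truth against which the voxel pipeline can be checked;
* **simulated cohorts** with the covariate structure, heterogeneity-index
  distributions and event rate of a pretreatment neuroblastoma series,
  with survival generated from an exponential proportional-hazards model
  so planted hazard ratios can be recovered by the analysis stage.

Phantom profiles (r = distance from tumour centre, R = tumour radius,
S = true SUVmax, all noise-free):

``homogeneous``       SUV = S everywhere; AUC-CSH = 1.
``two_level``         inner core (volume fraction ``core_volume_fraction``)
                      at S, shell at ``low_fraction * S``;
                      AUC-CSH = w + (1 - w) * low_fraction with w the core
                      volume fraction.
``radial_linear``     SUV(r) = S (1 - r/R); the volume fraction above
                      t*S is (1-t)^3, so AUC-CSH = 1/4.
``necrotic_core``     core at ``core_fraction * S`` (hypometabolic
                      necrosis), shell at S;
                      AUC-CSH = 1 - w (1 - core_fraction).
``uniform_histogram`` SUV(r) = S (1 - (r/R)^3); the SUV histogram is
                      exactly uniform on (0, S], so AUC-CSH = 1/2.

Voxel membership is voxel-centre-inside-sphere with voxel centres at
``index * spacing`` (no partial-volume weighting). Additive Gaussian
noise (clipped at zero) is applied to tumour voxels only; the analytic
truth always refers to the noise-free continuous profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

from .image_io import SUVVolume, TumourMask, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "random_phantom_spec",
    "write_phantom",
    "CohortSpec",
    "generate_cohort",
    "sample_auccsh",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

# 1.0 cm^3 sphere radius in mm, used for the analytic SUVpeak truths
_PEAK_RADIUS_MM = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

PROFILE_KINDS = (
    "homogeneous",
    "two_level",
    "radial_linear",
    "necrotic_core",
    "uniform_histogram",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one spherical digital tumour phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumour_centre: tuple[float, float, float] | None = None  # voxel coords
    tumour_radius_mm: float = 25.0
    profile_kind: str = "homogeneous"
    suv_max_true: float = 5.0
    profile_params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    background_suv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}; "
                             f"choose from {PROFILE_KINDS}")
        if self.tumour_centre is None:
            # an exact voxel centre, so the profile apex (SUVmax) is sampled
            centre = tuple(float(n // 2) for n in self.grid_shape)
            object.__setattr__(self, "tumour_centre", centre)
        if self.suv_max_true <= self.background_suv:
            raise ValueError("suv_max_true must exceed background_suv")
        if self.background_suv < 0 or self.noise_sd < 0:
            raise ValueError("background_suv and noise_sd must be >= 0")
        if self.tumour_radius_mm <= 0:
            raise ValueError("tumour_radius_mm must be positive")
        # the tumour must fit inside the grid (voxel centres at index*spacing)
        for c, n, s in zip(self.tumour_centre, self.grid_shape, self.voxel_spacing):
            if c * s - self.tumour_radius_mm < 0 or c * s + self.tumour_radius_mm > (n - 1) * s:
                raise ValueError(
                    f"tumour of radius {self.tumour_radius_mm} mm centred at voxel "
                    f"{self.tumour_centre} extends outside the {self.grid_shape} grid"
                )


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form lesion statistics of the noise-free continuous profile.

    ``suv_peak`` is the 1.0 cm^3 sphere average centred at the tumour
    centre, which is optimal for the radially non-increasing profiles;
    it is ``None`` for the necrotic-core profile (the optimal sphere
    centre sits in the shell and has no simple closed form) and when the
    peak sphere does not fit inside the tumour.
    """

    suv_max: float
    suv_mean: float
    suv_peak: float | None
    mtv_ml: float
    tlg: float
    auc_csh: float


def _profile_truth(spec: PhantomSpec) -> tuple[Callable[[np.ndarray], np.ndarray], PhantomTruth]:
    """Radial SUV profile f(r) plus its closed-form statistics."""
    S = spec.suv_max_true
    R = spec.tumour_radius_mm
    rho = _PEAK_RADIUS_MM
    kind = spec.profile_kind
    p = spec.profile_params
    mtv = (4.0 / 3.0) * math.pi * R**3 / 1000.0

    if kind == "homogeneous":
        def f(r): return np.full_like(r, S)
        mean = S
        peak = S if R >= rho else None
    elif kind == "two_level":
        w = float(p.get("core_volume_fraction", 0.5))   # volume fraction at S
        low = float(p.get("low_fraction", 0.5))         # shell level / S
        if not 0 < w < 1 or not 0 <= low < 1:
            raise ValueError("two_level needs 0<core_volume_fraction<1, 0<=low_fraction<1")
        rc = R * w ** (1.0 / 3.0)
        def f(r): return np.where(r <= rc, S, low * S)
        mean = S * (w + (1 - w) * low)
        if R < rho:
            peak = None
        elif rc >= rho:
            peak = S
        else:
            peak = S * (rc**3 + (rho**3 - rc**3) * low) / rho**3
    elif kind == "radial_linear":
        def f(r): return S * (1.0 - r / R)
        mean = S / 4.0
        peak = S * (1.0 - 0.75 * rho / R) if R >= rho else None
    elif kind == "necrotic_core":
        c = float(p.get("core_radius_fraction", 0.6))
        low = float(p.get("core_fraction", 0.1))        # core level / S
        if not 0 < c < 1 or not 0 <= low < 1:
            raise ValueError("necrotic_core needs 0<core_radius_fraction<1, 0<=core_fraction<1")
        rc = R * c
        def f(r): return np.where(r <= rc, low * S, S)
        w = c**3
        mean = S * (w * low + (1 - w))
        peak = None
    elif kind == "uniform_histogram":
        def f(r): return S * (1.0 - (r / R) ** 3)
        mean = S / 2.0
        peak = S * (1.0 - rho**3 / (2.0 * R**3)) if R >= rho else None
    else:  # pragma: no cover - guarded by PhantomSpec
        raise ValueError(kind)

    truth = PhantomTruth(
        suv_max=S,
        suv_mean=mean,
        suv_peak=peak,
        mtv_ml=mtv,
        tlg=mtv * mean,
        auc_csh=mean / S,
    )
    return f, truth


def generate_phantom(spec: PhantomSpec) -> tuple[SUVVolume, TumourMask, PhantomTruth]:
    """Build the voxelised phantom, its mask and the analytic truth.

    Voxels whose centres lie within ``tumour_radius_mm`` of the centre
    receive the profile SUV plus optional Gaussian noise (clipped at 0);
    all other voxels receive the background SUV. The mask marks exactly
    the tumour voxels. Same seed, same spec: bit-identical output.
    """
    f, truth = _profile_truth(spec)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    centre = np.asarray(spec.tumour_centre, dtype=float)
    axes = [ (np.arange(n) - c) * s for n, c, s in zip(spec.grid_shape, centre, spacing) ]
    di, dj, dk = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(di**2 + dj**2 + dk**2)
    inside = r <= spec.tumour_radius_mm

    values = np.full(spec.grid_shape, float(spec.background_suv))
    tumour_suv = f(r[inside])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        tumour_suv = tumour_suv + rng.normal(0.0, spec.noise_sd, size=tumour_suv.shape)
    values[inside] = np.clip(tumour_suv, 0.0, None)

    volume = SUVVolume(values, spec.voxel_spacing)
    mask = TumourMask(inside, spec.voxel_spacing, label="total_lesion")
    return volume, mask, truth


def random_phantom_spec(rng: np.random.Generator,
                        noise_sd: float | None = None) -> PhantomSpec:
    """Draw a random phantom spec spanning homogeneous to necrotic lesions."""
    kind = rng.choice(PROFILE_KINDS)
    radius = float(rng.uniform(12.0, 30.0))
    params: dict = {}
    if kind == "two_level":
        params = {"core_volume_fraction": float(rng.uniform(0.2, 0.8)),
                  "low_fraction": float(rng.uniform(0.1, 0.9))}
    elif kind == "necrotic_core":
        params = {"core_radius_fraction": float(rng.uniform(0.3, 0.8)),
                  "core_fraction": float(rng.uniform(0.0, 0.3))}
    return PhantomSpec(
        grid_shape=(40, 40, 40),
        voxel_spacing=(2.0, 2.0, 2.0),
        tumour_radius_mm=radius,
        profile_kind=str(kind),
        suv_max_true=float(rng.uniform(2.0, 12.0)),
        profile_params=params,
        noise_sd=float(rng.uniform(0.0, 0.3)) if noise_sd is None else noise_sd,
        background_suv=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_phantom(spec: PhantomSpec, out_dir: str | Path, stem: str = "phantom") -> dict[str, Path]:
    """Write the phantom as paired NIfTI files plus a JSON truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume, mask, truth = generate_phantom(spec)
    paths = {
        "volume": out_dir / f"{stem}_suv.nii.gz",
        "mask": out_dir / f"{stem}_mask.nii.gz",
        "sidecar": out_dir / f"{stem}.json",
    }
    write_volume(volume, paths["volume"])
    write_mask(mask, paths["mask"], affine=volume.affine)
    with open(paths["sidecar"], "w") as fh:
        json.dump({"spec": asdict(spec), "analytic_truth": asdict(truth)}, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# Simulated cohorts
# ---------------------------------------------------------------------------

#: Column dictionary of a simulated cohort table (order is the file order).
COHORT_COLUMNS = {
    "patient_id": "string identifier",
    "age_years": "age at diagnosis, years (truncated normal > 0)",
    "sex_male": "1 = male",
    "site_abdomen": "1 = primary lesion in the abdomen",
    "inss_stage": "INSS stage coded 1-4",
    "cog_risk": "COG risk group coded 0 low / 1 intermediate / 2 high",
    "mycn": "1 = MYCN acquired or amplified",
    "del_1p": "1 = chromosome 1p deletion",
    "del_11q": "1 = chromosome 11q deletion",
    "nse": "neuron-specific enolase, ng/mL",
    "ldh": "lactate dehydrogenase, U/L",
    "phox2b": "PHOX2B expression, arbitrary units",
    "bmi": "1 = bone-marrow involvement",
    "suv_max": "lesion SUVmax",
    "suv_mean": "lesion SUVmean (total lesion)",
    "suv_peak": "lesion SUVpeak",
    "mtv_total": "metabolic tumour volume, total lesion, mL",
    "mtv_40": "metabolic tumour volume, 40% SUVmax region, mL",
    "tlg_total": "total lesion glycolysis, total lesion",
    "tlg_40": "total lesion glycolysis, 40% region",
    "auccsh_total": "AUC-CSH, total-lesion delineation",
    "auccsh_40": "AUC-CSH, 40% SUVmax delineation",
    "followup_months": "observed follow-up, months",
    "event": "1 = relapse/progression/death within follow-up",
    "true_hazard": "generating hazard, events per month",
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated neuroblastoma cohort.

    The defaults reproduce the covariate structure of a 38-patient
    pretreatment series: mean age 3.636 +/- 2.166 years, 14/38 male,
    34/38 abdominal primaries, INSS stage distribution (2, 1, 6, 29)/38,
    COG risk distribution (2, 14, 22)/38, and a ~50 % (19/38) event rate
    over a follow-up horizon capped at 33.4 months. The heterogeneity
    index AUC-CSH_total is drawn from a two-component mixture whose
    components match the event / non-event subgroup statistics
    (0.410 +/- 0.062 and 0.515 +/- 0.101), with AUC-CSH_40% drawn from
    its own group components (0.541 +/- 0.039 / 0.581 +/- 0.049) with a
    Gaussian-copula correlation of 0.63 to the total-lesion index.

    Survival is exponential proportional hazards on the linear
    predictor ``sum(log_hr[k] * x_k)`` with uniform censoring on
    (0, censor_horizon]. ``baseline_hazard`` of ``None`` is calibrated
    numerically so the expected event fraction equals
    ``event_fraction_target``. Bone-marrow-involvement prevalence is
    not anchored to a reported count and defaults to 0.5.
    """

    n_patients: int = 38
    age_mean: float = 3.636
    age_sd: float = 2.166
    male_prob: float = 14 / 38
    abdomen_prob: float = 34 / 38
    stage_probs: tuple[float, ...] = (2 / 38, 1 / 38, 6 / 38, 29 / 38)
    cog_probs: tuple[float, ...] = (2 / 38, 14 / 38, 22 / 38)
    mycn_prob: float = 0.4
    del_1p_prob: float = 0.2
    del_11q_prob: float = 0.3
    bmi_prevalence: float = 0.5
    event_fraction_target: float = 19 / 38
    auccsh_mean_event: float = 0.410
    auccsh_sd_event: float = 0.062
    auccsh_mean_nonevent: float = 0.515
    auccsh_sd_nonevent: float = 0.101
    auccsh40_mean_event: float = 0.541
    auccsh40_sd_event: float = 0.039
    auccsh40_mean_nonevent: float = 0.581
    auccsh40_sd_nonevent: float = 0.049
    auccsh_correlation: float = 0.63
    log_hr: dict = field(default_factory=lambda: {
        "bmi": math.log(4.677),
        "auccsh_total": math.log(0.005),
    })
    baseline_hazard: float | None = None
    censor_horizon_months: float = 33.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("stage_probs", "cog_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for name in ("auccsh_sd_event", "auccsh_sd_nonevent",
                     "auccsh40_sd_event", "auccsh40_sd_nonevent", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.event_fraction_target < 1:
            raise ValueError("event_fraction_target must be in (0, 1)")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive (or None to calibrate); "
                             "an all-zero hazard cannot generate events")
        if self.censor_horizon_months <= 0:
            raise ValueError("censor_horizon_months must be positive")
        if not -1 < self.auccsh_correlation < 1:
            raise ValueError("auccsh_correlation must be in (-1, 1)")


def _truncated_normal_pair(rng: np.random.Generator, n: int,
                           mean1: float, sd1: float, mean2: float, sd2: float,
                           corr: float) -> tuple[np.ndarray, np.ndarray]:
    """Correlated normal pair truncated to (0, 1] by rejection."""
    out1 = np.empty(n)
    out2 = np.empty(n)
    need = np.arange(n)
    while need.size:
        z1 = rng.standard_normal(need.size)
        z2 = corr * z1 + math.sqrt(1 - corr**2) * rng.standard_normal(need.size)
        x1 = mean1 + sd1 * z1
        x2 = mean2 + sd2 * z2
        ok = (x1 > 0) & (x1 <= 1) & (x2 > 0) & (x2 <= 1)
        out1[need[ok]] = x1[ok]
        out2[need[ok]] = x2[ok]
        need = need[~ok]
    return out1, out2


def sample_auccsh(rng: np.random.Generator, n: int, event_group: bool,
                  spec: CohortSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (AUC-CSH_total, AUC-CSH_40%) pairs from one mixture component.

    ``event_group`` selects the event or non-event component of the
    heterogeneity-index mixture; values are truncated to (0, 1].
    """
    spec = spec or CohortSpec()
    if event_group:
        return _truncated_normal_pair(
            rng, n, spec.auccsh_mean_event, spec.auccsh_sd_event,
            spec.auccsh40_mean_event, spec.auccsh40_sd_event, spec.auccsh_correlation)
    return _truncated_normal_pair(
        rng, n, spec.auccsh_mean_nonevent, spec.auccsh_sd_nonevent,
        spec.auccsh40_mean_nonevent, spec.auccsh40_sd_nonevent, spec.auccsh_correlation)


def _event_probability(log_baseline: float, eta: np.ndarray, horizon: float) -> float:
    """Mean P(T <= C) for T ~ Exp(lam0 e^eta), C ~ U(0, horizon]."""
    lam = np.exp(log_baseline + eta)
    lh = lam * horizon
    return float(np.mean(1.0 - (1.0 - np.exp(-lh)) / lh))


def _calibrate_baseline(spec: CohortSpec, n_ref: int = 20000) -> float:
    """Baseline hazard giving the target expected event fraction.

    Uses a large reference draw of linear predictors under the spec's
    covariate distributions (fixed internal seed, so the calibration
    depends only on the spec parameters, not on ``spec.seed``).
    """
    rng = np.random.default_rng(987654321)
    ref = _draw_covariates(rng, n_ref, spec)
    eta = _linear_predictor(ref, spec.log_hr)
    def objective(log_lam0: float) -> float:
        return _event_probability(log_lam0, eta, spec.censor_horizon_months) \
            - spec.event_fraction_target
    return float(math.exp(optimize.brentq(objective, -15.0, 10.0, xtol=1e-10)))


def _lognormal(rng: np.random.Generator, n: int, median: float, sigma: float) -> np.ndarray:
    return median * np.exp(sigma * rng.standard_normal(n))


def _draw_covariates(rng: np.random.Generator, n: int, spec: CohortSpec) -> pd.DataFrame:
    """All covariates and imaging features except survival."""
    age = spec.age_mean + spec.age_sd * rng.standard_normal(n)
    while np.any(age <= 0):  # truncate at zero: ages are positive
        bad = age <= 0
        age[bad] = spec.age_mean + spec.age_sd * rng.standard_normal(int(bad.sum()))

    latent_event = rng.random(n) < spec.event_fraction_target
    auccsh_total = np.empty(n)
    auccsh_40 = np.empty(n)
    n_ev = int(latent_event.sum())
    if n_ev:
        auccsh_total[latent_event], auccsh_40[latent_event] = sample_auccsh(
            rng, n_ev, True, spec)
    if n - n_ev:
        auccsh_total[~latent_event], auccsh_40[~latent_event] = sample_auccsh(
            rng, n - n_ev, False, spec)

    # imaging features, internally consistent with the CSH identity:
    # SUVmean = AUC-CSH * SUVmax and TLG = MTV * SUVmean per delineation
    suv_max = _lognormal(rng, n, 4.0, 0.35)
    suv_mean = auccsh_total * suv_max
    suv_mean_40 = auccsh_40 * suv_max
    mtv_total = _lognormal(rng, n, 236.35, 0.73)
    mtv_40 = mtv_total * rng.beta(5.0, 4.7, size=n)
    suv_peak = suv_mean + rng.beta(4.0, 2.0, size=n) * (suv_max - suv_mean)

    return pd.DataFrame({
        "age_years": age,
        "sex_male": (rng.random(n) < spec.male_prob).astype(int),
        "site_abdomen": (rng.random(n) < spec.abdomen_prob).astype(int),
        "inss_stage": rng.choice([1, 2, 3, 4], size=n, p=spec.stage_probs),
        "cog_risk": rng.choice([0, 1, 2], size=n, p=spec.cog_probs),
        "mycn": (rng.random(n) < spec.mycn_prob).astype(int),
        "del_1p": (rng.random(n) < spec.del_1p_prob).astype(int),
        "del_11q": (rng.random(n) < spec.del_11q_prob).astype(int),
        "nse": _lognormal(rng, n, 100.0, 1.0),
        "ldh": _lognormal(rng, n, 500.0, 0.8),
        "phox2b": _lognormal(rng, n, 50.0, 1.0),
        "bmi": (rng.random(n) < spec.bmi_prevalence).astype(int),
        "suv_max": suv_max,
        "suv_mean": suv_mean,
        "suv_peak": suv_peak,
        "mtv_total": mtv_total,
        "mtv_40": mtv_40,
        "tlg_total": mtv_total * suv_mean,
        "tlg_40": mtv_40 * suv_mean_40,
        "auccsh_total": auccsh_total,
        "auccsh_40": auccsh_40,
    })


def _linear_predictor(table: pd.DataFrame, log_hr: dict) -> np.ndarray:
    eta = np.zeros(len(table))
    for name, coef in log_hr.items():
        if name not in table.columns:
            raise KeyError(f"log_hr refers to unknown covariate {name!r}")
        eta += coef * table[name].to_numpy(dtype=float)
    return eta


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulate a cohort table (one row per patient).

    Covariates are drawn independently per the spec's distributions; the
    heterogeneity indices come from the event/non-event mixture; event
    times follow an exponential proportional-hazards model on the
    ``log_hr`` covariates with uniform censoring on
    (0, censor_horizon]. Reproducible given ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    table = _draw_covariates(rng, spec.n_patients, spec)

    lam0 = spec.baseline_hazard if spec.baseline_hazard is not None \
        else _calibrate_baseline(spec)
    eta = _linear_predictor(table, spec.log_hr)
    hazard = lam0 * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, spec.censor_horizon_months, size=spec.n_patients)
    censor_time = np.maximum(censor_time, 1e-6)  # open at 0
    event = event_time <= censor_time

    table.insert(0, "patient_id", [f"P{i:04d}" for i in range(spec.n_patients)])
    table["followup_months"] = np.minimum(event_time, censor_time)
    table["event"] = event.astype(int)
    table["true_hazard"] = hazard
    return table[list(COHORT_COLUMNS)]


def write_cohort(table: pd.DataFrame, path: str | Path,
                 seed: int | None = None) -> None:
    """Write a cohort CSV with a commented header recording the seed."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# simulated cohort, rng seed = {seed}\n")
        table.to_csv(fh, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, skipping comment lines."""
    return pd.read_csv(path, comment="#")
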