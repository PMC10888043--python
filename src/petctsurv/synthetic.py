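"""Synthetic phantom cohorts with known survival ground truth.

Every subject carries one scalar *latent risk* (standard normal across the
cohort) that simultaneously drives

* the imaging phenotype — tumor radius on CT and PET hotspot intensity both
  increase monotonically in the latent risk,
* the clinical covariates — T/N stage category log-odds shift with it,
* the hazard — event times follow a Weibull proportional-hazards model whose
  linear predictor includes the latent risk, age and overall stage, with
  independent exponential censoring.

Because image, text and outcome share the latent factor, multi-modal fusion
is genuinely informative on these cohorts and ablations (image-only vs
image+text, PET+CT vs single modality) have a known ordering to recover.

Defaults are calibrated once by Monte Carlo and frozen: the Weibull
(shape 1.3, rate 1/1200 per day) with exponential censoring at rate 1/3500
per day yields roughly 30% censoring, a true-linear-predictor concordance
near 0.81, and a stage distribution close to a predominantly stage-III/IV
head-and-neck cohort.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .imaging import ImageVolume, write_volume
from .survival import ENDPOINTS, SurvivalTable

__all__ = [
    "PhantomParams",
    "ClinicalRecord",
    "SurvivalOutcome",
    "HazardModel",
    "Subject",
    "Cohort",
    "simulate_phantom_pair",
    "simulate_clinical",
    "simulate_survival",
    "generate_cohort",
    "write_cohort",
    "overall_stage_from_tn",
]

T_STAGES = ("T1", "T2", "T3", "T4")
N_STAGES = ("N0", "N1", "N2", "N3")
STAGES = ("I", "II", "III", "IV")

# categorical stage models: base log-probabilities and latent-risk slopes
_T_BASE = np.log([0.10, 0.20, 0.30, 0.40])
_T_SLOPE = np.array([0.0, 0.4, 0.8, 1.2])
_N_BASE = np.log([0.35, 0.25, 0.25, 0.15])
_N_SLOPE = np.array([0.0, 0.5, 1.0, 1.5])


@dataclass
class PhantomParams:
    """Geometry and noise of the 2-D-in-3-D phantom pairs."""

    image_side: int = 64
    n_slices: int = 4
    n_background_ellipses: int = 6
    tumor_radius_range: tuple[float, float] = (4.0, 14.0)
    pet_hotspot_gain: float = 3.0
    noise_sd: float = 0.02
    radius_jitter_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range must be positive and ordered")
        if hi >= self.image_side / 2 - 1:
            raise ValueError("tumor radius exceeds image bounds")


@dataclass
class ClinicalRecord:
    """Structured clinical covariates (the Q-Former text stream)."""

    age: int
    sex: str           # "male" | "female"
    t_stage: str       # T1..T4
    n_stage: str       # N0..N3
    m_stage: str       # always M0: no distant metastasis at diagnosis
    overall_stage: str # I..IV, deterministic in (t_stage, n_stage)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (18 <= self.age <= 90):
            raise ValueError(f"age {self.age} outside supported range [18, 90]")
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.t_stage not in T_STAGES or self.n_stage not in N_STAGES:
            raise ValueError("invalid T/N stage")
        if self.m_stage != "M0":
            raise ValueError("cohort inclusion requires M0 at diagnosis")
        expected = overall_stage_from_tn(self.t_stage, self.n_stage)
        if self.overall_stage != expected:
            raise ValueError(
                f"overall stage {self.overall_stage} inconsistent with "
                f"({self.t_stage}, {self.n_stage}) -> {expected}")

    @property
    def stage_ordinal(self) -> int:
        return STAGES.index(self.overall_stage)


@dataclass
class SurvivalOutcome:
    endpoint: str
    time: float   # days
    event: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint}")
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class HazardModel:
    """Weibull proportional hazards: S(t) = exp(-(rho*t)^kappa * exp(beta'x)).

    ``beta`` weights the covariate vector (latent risk, standardized age,
    centered stage ordinal). ``endpoint_scale`` multiplies the linear
    predictor per endpoint, ordering the endpoint-specific signal strengths.
    """

    weibull_shape: float = 1.3
    weibull_rate: float = 1.0 / 1200.0       # per day
    beta: np.ndarray = field(default_factory=lambda: np.array([1.5, 0.25, 0.25]))
    censor_rate: float = 1.0 / 3500.0        # per day; ~30% censoring
    endpoint_scale: dict = field(default_factory=lambda: {
        "MFS": 1.2, "OS": 1.0, "PFS": 0.9, "RFS": 0.6})

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.weibull_shape <= 0 or self.weibull_rate <= 0 or self.censor_rate <= 0:
            raise ValueError("kappa, rho and censor_rate must be positive")

    def linear_predictor(self, covariates: np.ndarray, endpoint: str = "OS") -> float:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.shape[-1] != self.beta.size:
            raise ValueError("covariate length does not match beta")
        return self.endpoint_scale[endpoint] * (covariates @ self.beta)


def overall_stage_from_tn(t_stage: str, n_stage: str) -> str:
    """Fixed monotone map from (T, N) to overall stage (M0 assumed)."""
    t, n = T_STAGES.index(t_stage), N_STAGES.index(n_stage)
    if t == 3 or n >= 2:
        return "IV"
    if t == 2 or n == 1:
        return "III"
    return "II" if t == 1 else "I"


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _soft_ellipses(side: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Additive soft-ellipse anatomy on [0, ~1)."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    img = np.zeros((side, side))
    for _ in range(n):
        cy, cx = rng.uniform(0.2 * side, 0.8 * side, size=2)
        ay, ax = rng.uniform(0.1 * side, 0.35 * side, size=2)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(theta) + dx * np.sin(theta)
        rx = -dy * np.sin(theta) + dx * np.cos(theta)
        d2 = (ry / ay) ** 2 + (rx / ax) ** 2
        img += rng.uniform(0.1, 0.3) * np.exp(-d2)
    return img


def simulate_phantom_pair(params: PhantomParams, latent_risk: float,
                          seed: int, subject_id: str = "") -> tuple[
                              ImageVolume, ImageVolume, ImageVolume]:
    """Paired CT/PET phantom volumes plus a tumor mask on the shared grid.

    CT shows soft-ellipse anatomy plus a tumor disc whose radius grows with
    the latent risk; PET shows a dimmer copy of the anatomy plus a hotspot
    whose peak equals ``pet_hotspot_gain * sigmoid(latent_risk)`` at the
    tumor center. Gaussian noise of sd ``noise_sd`` is added to both.

    The anatomical radius is a *jittered* readout of the latent risk
    (``radius_jitter_sd`` on the latent scale): tumor size is an imperfect
    surrogate of the underlying biology, while the metabolic hotspot tracks
    it directly — the reason PET adds prognostic value over CT, and what
    makes PET/CT fusion informative on these cohorts.
    """
    if not np.isfinite(latent_risk):
        raise ValueError("latent_risk must be finite")
    rng = np.random.default_rng(seed)
    side, ns = params.image_side, params.n_slices
    lo, hi = params.tumor_radius_range
    size_view = latent_risk + rng.normal(0.0, params.radius_jitter_sd)
    radius = lo + (hi - lo) * expit(size_view)          # anatomical (CT) radius
    met_radius = lo + (hi - lo) * expit(latent_risk)    # metabolic (PET) extent
    peak = params.pet_hotspot_gain * expit(latent_risk)

    anatomy = _soft_ellipses(side, params.n_background_ellipses, rng)
    tumor_slice = int(rng.integers(ns))
    margin = int(np.ceil(hi)) + 2
    cy, cx = rng.uniform(margin, side - margin, size=2)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    disc = d2 <= radius**2

    ct = np.repeat(anatomy[None], ns, axis=0) * 0.8
    ct[tumor_slice][disc] = 0.9
    pet = np.repeat(anatomy[None], ns, axis=0) * 0.15
    hot_region = d2 <= met_radius**2
    hot = peak * np.exp(-d2 / (2.0 * (met_radius / 2.0) ** 2))
    pet_slice = pet[tumor_slice]
    pet_slice[hot_region] = 0.0
    pet_slice += np.where(hot_region, hot, 0.0)
    # pin the exact analytic peak at the nearest pixel to the center
    pet_slice[int(round(cy)), int(round(cx))] = peak

    if params.noise_sd > 0:
        ct = ct + rng.normal(0, params.noise_sd, ct.shape)
        pet = pet + rng.normal(0, params.noise_sd, pet.shape)

    mask = np.zeros((ns, side, side))
    mask[tumor_slice][disc] = 1.0
    spacing = (3.0, 1.0, 1.0)
    return (
        ImageVolume(ct, spacing, "CT", subject_id),
        ImageVolume(pet, spacing, "PET", subject_id),
        ImageVolume(mask, spacing, "CT", subject_id),
    )


# ---------------------------------------------------------------------------
# clinical covariates and outcomes
# ---------------------------------------------------------------------------

def _categorical(base_log: np.ndarray, slope: np.ndarray, latent: float,
                 rng: np.random.Generator) -> int:
    logits = base_log + latent * slope
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def simulate_clinical(latent_risk: float, seed: int,
                      subject_id: str = "") -> ClinicalRecord:
    """Draw one clinical record whose stage distribution shifts with risk.

    Age ~ Normal(60, 10) truncated to [18, 90]; sex is male with probability
    0.79; T and N categories are drawn from softmax distributions whose
    log-odds increase with the latent risk; overall stage follows the fixed
    monotone (T, N) map.
    """
    rng = np.random.default_rng(seed)
    age = int(round(truncnorm.rvs((18 - 60) / 10, (90 - 60) / 10, loc=60,
                                  scale=10, random_state=rng)))
    age = int(np.clip(age, 18, 90))
    sex = "male" if rng.random() < 0.79 else "female"
    t_idx = _categorical(_T_BASE, _T_SLOPE, latent_risk, rng)
    n_idx = _categorical(_N_BASE, _N_SLOPE, latent_risk, rng)
    t_stage, n_stage = T_STAGES[t_idx], N_STAGES[n_idx]
    return ClinicalRecord(
        age=age, sex=sex, t_stage=t_stage, n_stage=n_stage, m_stage="M0",
        overall_stage=overall_stage_from_tn(t_stage, n_stage),
        subject_id=subject_id,
    )


def simulate_survival(model: HazardModel, covariates: np.ndarray, endpoint: str,
                      seed: int) -> SurvivalOutcome:
    """Inverse-transform Weibull-PH event time with exponential censoring."""
    rng = np.random.default_rng(seed)
    eta = model.linear_predictor(covariates, endpoint)
    u = rng.random()
    t_event = (1.0 / model.weibull_rate) * (-np.log(u) * np.exp(-eta)) ** (
        1.0 / model.weibull_shape)
    t_censor = rng.exponential(1.0 / model.censor_rate)
    time = max(min(t_event, t_censor), 1e-9)
    return SurvivalOutcome(endpoint=endpoint, time=float(time),
                           event=int(t_event <= t_censor))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    subject_id: str
    latent_risk: float
    ct: ImageVolume
    pet: ImageVolume
    mask: ImageVolume
    clinical: ClinicalRecord
    outcomes: dict[str, SurvivalOutcome]

    @property
    def covariates(self) -> np.ndarray:
        return np.array([
            self.latent_risk,
            (self.clinical.age - 60.0) / 10.0,
            self.clinical.stage_ordinal - 2.0,
        ])


@dataclass
class Cohort:
    subjects: list[Subject]
    params: PhantomParams
    model: HazardModel
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)

    def survival_table(self, endpoint: str = "OS") -> SurvivalTable:
        return SurvivalTable(
            [s.subject_id for s in self.subjects],
            [s.outcomes[endpoint].time for s in self.subjects],
            [s.outcomes[endpoint].event for s in self.subjects],
            endpoint,
        )

    def true_linear_predictor(self, endpoint: str = "OS") -> np.ndarray:
        return np.array([
            self.model.linear_predictor(s.covariates, endpoint)
            for s in self.subjects
        ])

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "subject_id": s.subject_id, "age": s.clinical.age,
            "sex": s.clinical.sex, "t_stage": s.clinical.t_stage,
            "n_stage": s.clinical.n_stage, "m_stage": s.clinical.m_stage,
            "overall_stage": s.clinical.overall_stage,
        } for s in self.subjects])


def _child_seeds(seed: int, n: int, label: str) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(
        int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big"),))
    return ss.generate_state(n) % (2**31)


def generate_cohort(n: int, params: PhantomParams | None = None,
                    model: HazardModel | None = None, seed: int = 0) -> Cohort:
    """A cohort is a pure function of (n, params, model, seed)."""
    params = params or PhantomParams()
    model = model or HazardModel()
    latent = np.random.default_rng(
        _child_seeds(seed, 1, "latent")[0]).normal(size=n)
    img_seeds = _child_seeds(seed, n, "image")
    clin_seeds = _child_seeds(seed, n, "clinical")
    subjects = []
    for i in range(n):
        sid = f"S{i:04d}"
        ct, pet, mask = simulate_phantom_pair(params, latent[i],
                                              int(img_seeds[i]), sid)
        clinical = simulate_clinical(latent[i], int(clin_seeds[i]), sid)
        cov = np.array([latent[i], (clinical.age - 60.0) / 10.0,
                        clinical.stage_ordinal - 2.0])
        outcomes = {}
        for ep in ENDPOINTS:
            surv_seed = int(_child_seeds(seed, n, f"survival:{ep}")[i])
            outcomes[ep] = simulate_survival(model, cov, ep, surv_seed)
        subjects.append(Subject(sid, float(latent[i]), ct, pet, mask,
                                clinical, outcomes))
    return Cohort(subjects, params, model, seed)


def write_cohort(n: int, params: PhantomParams | None = None,
                 model: HazardModel | None = None, out_dir: str = ".",
                 seed: int = 0, overwrite: bool = False) -> dict:
    """Write a cohort to disk: NIfTI pairs + masks, CSVs, JSON manifest."""
    params = params or PhantomParams()
    model = model or HazardModel()
    manifest_path = os.path.join(out_dir, "manifest.json")
    if os.path.exists(manifest_path) and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    cohort = generate_cohort(n, params, model, seed)
    for s in cohort.subjects:
        base = os.path.join(out_dir, "images", s.subject_id)
        write_volume(s.ct, base + "_ct.nii.gz")
        write_volume(s.pet, base + "_pet.nii.gz")
        write_volume(s.mask, base + "_mask.nii.gz")
    cohort.clinical_frame().to_csv(os.path.join(out_dir, "clinical.csv"),
                                   index=False)
    for ep in ENDPOINTS:
        cohort.survival_table(ep).to_csv(
            os.path.join(out_dir, f"survival_{ep.lower()}.csv"))
    manifest = {
        "n": n, "seed": seed,
        "phantom_params": asdict(params),
        "hazard_model": {**asdict(model), "beta": model.beta.tolist()},
        "endpoints": list(ENDPOINTS),
    }
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
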