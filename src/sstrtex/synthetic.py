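"""Textured lesion phantoms and survival cohorts with known ground truth.

The phantoms are digitized spheres on a regular voxel grid carrying one
of four texture models inside the mask:

* ``uniform``          — constant uptake (all heterogeneity features at
                         their analytic limits),
* ``smooth_gradient``  — a linear ramp along the first axis whose slope
                         grows with the heterogeneity level,
* ``correlated_field`` — Gaussian-smoothed white noise; the smoothing
                         length shrinks and the relative amplitude grows
                         with the heterogeneity level, so both the
                         within-mask variance and the co-occurrence
                         entropy rise monotonically with it,
* ``checker``          — a two-level checkerboard (the correlation = -1 /
                         entropy = 1 bit limit along a single offset).

Outcomes follow a proportional-hazards exponential model: patient i with
linear predictor x_i has event hazard ``baseline_hazard * exp(beta *
x_i)`` per month.  Random censoring is an independent exponential time
whose single global rate is calibrated so the cohort-mean probability of
being randomly censored equals ``censor_rate``; an administrative
horizon truncates follow-up on top of that.  Within a generated cohort
the linear predictor is the z-scored patient-level value of the linked
feature, measured on the noiseless phantoms themselves, so the simulated
hazard is exactly feature-linked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .errors import PhantomError
from .features import ExtractionConfig, FeatureVector, aggregate, extract_lesion
from .io import LesionMask, PetVolume, to_suv, write_mask, write_volume

TEXTURE_MODELS = ("uniform", "smooth_gradient", "correlated_field", "checker")

#: background activity as a fraction of mean lesion uptake, kept low so
#: SUVmax stays attributable to the lesion
BACKGROUND_FRACTION = 0.05

#: site prevalence used when sampling lesion locations (liver-dominant,
#: as typical for metastatic gastroenteropancreatic NET)
SITE_PREVALENCE = {"liver": 0.55, "lymph_node": 0.25, "bone": 0.15, "lung": 0.05}


@dataclass
class PhantomSpec:
    """One textured spherical lesion phantom."""

    diameter_mm: float = 25.0
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    texture_model: str = "correlated_field"
    heterogeneity_level: float = 0.5
    mean_uptake: float = 50.0  # kBq/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise PhantomError(f"diameter must be positive, got {self.diameter_mm}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomError(f"spacing components must be positive, got {self.spacing_mm}")
        if not 0.0 <= self.heterogeneity_level <= 1.0:
            raise PhantomError(
                f"heterogeneity_level must be in [0,1], got {self.heterogeneity_level}"
            )
        if self.texture_model not in TEXTURE_MODELS:
            raise PhantomError(
                f"unknown texture model {self.texture_model!r}; expected one of {TEXTURE_MODELS}"
            )
        if self.mean_uptake <= 0:
            raise PhantomError("mean_uptake must be positive")


@dataclass
class SurvivalSpec:
    """Exponential proportional-hazards outcome model."""

    baseline_hazard: float = 0.03  # events / month
    beta: float = 0.0  # log-hazard-ratio per unit of the linked feature
    linked_feature: str = "entropy"
    censor_rate: float = 0.0
    admin_censor_months: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise PhantomError(f"baseline_hazard must be positive, got {self.baseline_hazard}")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise PhantomError(f"censor_rate must be in [0,1], got {self.censor_rate}")
        if self.admin_censor_months <= 0:
            raise PhantomError("admin_censor_months must be positive")


@dataclass
class CohortSpec:
    """Ranges from which per-patient phantoms are drawn."""

    n_patients: int = 100
    lesions_per_patient: tuple[int, int] = (1, 3)  # uniform integer range
    diameter_range_mm: tuple[float, float] = (18.0, 40.0)
    heterogeneity_range: tuple[float, float] = (0.1, 0.9)
    mean_uptake_range: tuple[float, float] = (30.0, 120.0)  # kBq/mL
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    texture_model: str = "correlated_field"
    site_modulates_texture: bool = False
    weight_kg: tuple[float, float] = (75.0, 12.0)  # normal (mean, sd), clipped
    injected_MBq: tuple[float, float] = (124.0, 15.0)  # normal (mean, sd), clipped

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise PhantomError("n_patients must be nonnegative")


# ---------------------------------------------------------------------------
# lesion phantoms
# ---------------------------------------------------------------------------

def _texture_field(spec: PhantomSpec, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Positive multiplicative texture field (mean ~1 before rescaling)."""
    h = spec.heterogeneity_level
    if spec.texture_model == "uniform":
        return np.ones(shape)
    if spec.texture_model == "smooth_gradient":
        x = np.arange(shape[0], dtype=float)
        ramp = (x - x.mean()) / max(x.max() - x.min(), 1.0)
        return 1.0 + h * ramp[:, None, None] * np.ones(shape)
    if spec.texture_model == "checker":
        idx = np.indices(shape).sum(axis=0)
        return 1.0 + 0.5 * h * np.where(idx % 2 == 0, 1.0, -1.0)
    # correlated_field: smoothing length shrinks as heterogeneity grows
    noise = rng.standard_normal(shape)
    sigma_mm = 0.5 + 4.0 * (1.0 - h)
    sigma_vox = [sigma_mm / s for s in spec.spacing_mm]
    smooth = gaussian_filter(noise, sigma=sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    rel_sd = 0.05 + 0.35 * h
    return np.clip(1.0 + rel_sd * smooth, 0.05, None)


def generate_lesion_image(spec: PhantomSpec) -> tuple[PetVolume, LesionMask]:
    """Digitized textured sphere plus low uniform background.

    The mask is all voxels whose centers lie within ``diameter_mm / 2``
    of the grid center; in-mask values are the texture field rescaled so
    the within-mask mean equals ``mean_uptake``.  Identical spec and
    seed reproduce the output bit for bit.
    """
    if spec.diameter_mm < max(spec.spacing_mm):
        raise PhantomError(
            f"diameter {spec.diameter_mm} mm is smaller than one voxel "
            f"{max(spec.spacing_mm)} mm: phantom not representable"
        )
    margin = 2
    shape = tuple(
        int(np.ceil(spec.diameter_mm / s)) + 2 * margin for s in spec.spacing_mm
    )
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spec.spacing_mm)]
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spec.spacing_mm)], indexing="ij"
    )
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask = r2 <= (spec.diameter_mm / 2.0) ** 2
    if not mask.any():
        raise PhantomError(f"no voxel center inside a {spec.diameter_mm} mm sphere")
    rng = np.random.default_rng(spec.seed)
    field_ = _texture_field(spec, shape, rng)
    values = np.full(shape, BACKGROUND_FRACTION * spec.mean_uptake, dtype=float)
    inside = field_[mask]
    values[mask] = inside * (spec.mean_uptake / inside.mean())
    volume = PetVolume(values=values, spacing_mm=spec.spacing_mm)
    lesion = LesionMask(
        values=mask.astype(np.uint8), spacing_mm=spec.spacing_mm, lesion_id="phantom"
    )
    return volume, lesion


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------

def _censor_hazard(hazards: np.ndarray, censor_rate: float) -> float:
    """Global exponential censoring rate giving the requested mean
    random-censoring probability mu/(lambda_i + mu) across the cohort."""
    if censor_rate <= 0:
        return 0.0
    if censor_rate >= 1:
        return np.inf

    def mean_censor(log_mu: float) -> float:
        mu = np.exp(log_mu)
        return float(np.mean(mu / (hazards + mu))) - censor_rate

    return float(np.exp(brentq(mean_censor, -30.0, 30.0)))


def simulate_survival(
    linear_predictor,
    spec: SurvivalSpec,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw (time, event) pairs from the exponential PH model.

    Event times T_i ~ Exp(rate = baseline_hazard * exp(beta * x_i));
    observed time is min(T_i, C_i, admin horizon) with C_i the
    independent exponential censoring time.
    """
    x = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(x)):
        raise PhantomError("linear predictor must be finite")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    hazards = spec.baseline_hazard * np.exp(spec.beta * x)
    t_event = rng.exponential(1.0 / hazards)
    mu = _censor_hazard(hazards, spec.censor_rate)
    if mu > 0 and np.isfinite(mu):
        t_censor = rng.exponential(1.0 / mu, size=x.shape)
    elif mu == np.inf:
        t_censor = np.zeros_like(t_event)
    else:
        t_censor = np.full_like(t_event, np.inf)
    horizon = spec.admin_censor_months
    time = np.minimum(np.minimum(t_event, t_censor), horizon)
    event = t_event <= np.minimum(t_censor, horizon)
    time = np.maximum(time, 1e-9)  # strictly positive observed times
    return pd.DataFrame({"time_months": time, "event": event})


def expected_event_fraction(linear_predictor, spec: SurvivalSpec) -> float:
    """Closed-form P(event) averaged over the cohort.

    For T ~ Exp(lambda), C ~ Exp(mu) and horizon a:
    P(T <= min(C, a)) = lambda/(lambda+mu) * (1 - exp(-(lambda+mu) a)).
    """
    x = np.asarray(linear_predictor, dtype=float)
    hazards = spec.baseline_hazard * np.exp(spec.beta * x)
    mu = _censor_hazard(hazards, spec.censor_rate)
    rate = hazards + mu
    a = spec.admin_censor_months
    tail = 1.0 - np.exp(-rate * a) if np.isfinite(a) else 1.0
    return float(np.mean(hazards / rate * tail))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPatient:
    patient_id: str
    weight_kg: float
    injected_MBq: float
    lesions: list[tuple[PhantomSpec, str]] = field(default_factory=list)  # (spec, site)
    feature_value: float = np.nan  # patient-level linked feature (generator truth)


def _sample_site(rng: np.random.Generator) -> str:
    names = list(SITE_PREVALENCE)
    probs = np.array([SITE_PREVALENCE[n] for n in names])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def simulate_cohort(
    cohort: CohortSpec,
    pfs_spec: SurvivalSpec,
    os_spec: Optional[SurvivalSpec] = None,
    seed: int = 0,
    extraction: Optional[ExtractionConfig] = None,
) -> tuple[list[SimulatedPatient], pd.DataFrame]:
    """In-memory cohort: phantoms per patient plus a survival table.

    The per-patient linked-feature value is measured by running the
    package's own extraction on the noiseless phantoms (phantoms carry no
    scanner noise, so measured equals true) and aggregating per patient;
    its z-score is the linear predictor feeding the PFS- and OS-style
    outcome draws (independent noise, same latent predictor).
    """
    extraction = extraction or ExtractionConfig()
    if os_spec is None:
        os_spec = replace(pfs_spec, baseline_hazard=pfs_spec.baseline_hazard / 2.0)
    rng = np.random.default_rng(seed)
    patients: list[SimulatedPatient] = []
    for i in range(cohort.n_patients):
        n_lesions = int(rng.integers(cohort.lesions_per_patient[0], cohort.lesions_per_patient[1] + 1))
        weight = float(np.clip(rng.normal(*cohort.weight_kg), 40.0, 150.0))
        injected = float(np.clip(rng.normal(*cohort.injected_MBq), 50.0, 250.0))
        p = SimulatedPatient(
            patient_id=f"P{i:04d}", weight_kg=weight, injected_MBq=injected
        )
        # patient-level heterogeneity with small per-lesion jitter, so the
        # patient aggregate is a meaningful latent trait
        h_patient = rng.uniform(*cohort.heterogeneity_range)
        for j in range(n_lesions):
            h = float(
                np.clip(h_patient + rng.normal(0.0, 0.05), *cohort.heterogeneity_range)
            )
            spec = PhantomSpec(
                diameter_mm=float(rng.uniform(*cohort.diameter_range_mm)),
                spacing_mm=cohort.spacing_mm,
                texture_model=cohort.texture_model,
                heterogeneity_level=h,
                mean_uptake=float(rng.uniform(*cohort.mean_uptake_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            p.lesions.append((spec, _sample_site(rng)))
        patients.append(p)

    # generator-side truth: extract the linked feature from the phantoms
    feature = pfs_spec.linked_feature
    for p in patients:
        vectors = []
        for j, (spec, site) in enumerate(p.lesions):
            vol, mask = generate_lesion_image(spec)
            mask.lesion_id = f"{p.patient_id}_L{j}"
            mask.site = site
            vol = replace(
                vol, patient_weight_kg=p.weight_kg, injected_activity_MBq=p.injected_MBq
            )
            fv = extract_lesion(to_suv(vol), mask, extraction)
            if isinstance(fv, FeatureVector):
                vectors.append(fv)
        if vectors:
            p.feature_value = getattr(aggregate(vectors, "per_patient"), feature)

    values = np.array([p.feature_value for p in patients], dtype=float)
    if len(values) and np.nanstd(values) > 0:
        z = (values - np.nanmean(values)) / np.nanstd(values)
    else:
        z = np.zeros_like(values)
    z = np.nan_to_num(z)

    pfs = simulate_survival(z, pfs_spec, rng=np.random.default_rng(rng.integers(0, 2**31 - 1)))
    osv = simulate_survival(z, os_spec, rng=np.random.default_rng(rng.integers(0, 2**31 - 1)))
    table = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "weight_kg": [round(p.weight_kg, 2) for p in patients],
            "injected_MBq": [round(p.injected_MBq, 2) for p in patients],
            "pfs_months": np.round(pfs["time_months"].to_numpy(), 4),
            "pfs_event": pfs["event"].astype(int).to_numpy(),
            "os_months": np.round(osv["time_months"].to_numpy(), 4),
            "os_event": osv["event"].astype(int).to_numpy(),
            "true_" + feature: values,
        }
    )
    return patients, table


_COHORT_HEADER = (
    "patient_id,weight_kg,injected_MBq,pfs_months,pfs_event,os_months,os_event,"
    "ki67_pct,cga_ugl,cum_dose_GBq,lesion_id,site,volume_path,mask_path"
)


def generate_cohort(
    outdir: str | Path,
    cohort: CohortSpec,
    pfs_spec: SurvivalSpec,
    os_spec: Optional[SurvivalSpec] = None,
    seed: int = 0,
    extraction: Optional[ExtractionConfig] = None,
) -> Path:
    """Write phantoms, masks and the cohort CSV under ``outdir``.

    Returns the cohort-table path.  The same seed reproduces the table
    byte for byte.
    """
    outdir = Path(outdir)
    images = outdir / "images"
    try:
        images.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {images}: {exc}") from exc

    patients, table = simulate_cohort(
        cohort, pfs_spec, os_spec, seed=seed, extraction=extraction
    )
    rng = np.random.default_rng(seed + 1)  # clinical covariates only
    rows = [_COHORT_HEADER]
    for p, trow in zip(patients, table.itertuples(index=False)):
        ki67 = round(float(np.clip(rng.lognormal(1.8, 0.8), 0.5, 70.0)), 1)
        cga = round(float(rng.lognormal(5.5, 1.2)), 1)
        dose = round(float(rng.uniform(7.0, 30.0)), 1)
        for j, (spec, site) in enumerate(p.lesions):
            vol, mask = generate_lesion_image(spec)
            mask.lesion_id = f"{p.patient_id}_L{j}"
            mask.site = site
            vol = replace(
                vol, patient_weight_kg=p.weight_kg, injected_activity_MBq=p.injected_MBq
            )
            vpath = images / f"{p.patient_id}_L{j}_pet.nii"
            mpath = images / f"{p.patient_id}_L{j}_mask.nii"
            write_volume(vol, vpath)
            write_mask(mask, mpath)
            rows.append(
                ",".join(
                    str(v)
                    for v in (
                        p.patient_id,
                        trow.weight_kg,
                        trow.injected_MBq,
                        trow.pfs_months,
                        trow.pfs_event,
                        trow.os_months,
                        trow.os_event,
                        ki67,
                        cga,
                        dose,
                        mask.lesion_id,
                        site,
                        vpath.as_posix(),
                        mpath.as_posix(),
                    )
                )
            )
    table_path = outdir / "cohort.csv"
    table_path.write_text("\n".join(rows) + "\n")
    return table_path
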