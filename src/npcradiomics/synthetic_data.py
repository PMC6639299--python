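"""Self-contained synthetic cohorts with known ground truth.

A cohort consists of per-patient phantom MRI volumes with ellipsoidal tumor
masks, second-rater masks for a reproducibility subset, clinical covariates
correlated with a latent texture phenotype, and survival outcomes drawn from
an exponential proportional-hazards model with planted coefficients on a
small set of true radiomics features.

Two latent phenotypes are emulated:

* ``smooth`` -- long-correlation-length, low-amplitude intensity texture;
* ``heterogeneous`` -- short-correlation-length, high-amplitude texture.

The intensity field is a smooth radial base profile plus a Gaussian random
field (white noise convolved with an isotropic Gaussian kernel whose sigma is
the correlation length, renormalized to preserve the noise amplitude).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from . import features as feat
from .imaging_io import (ENDPOINTS, ClinicalRecord, EmptyROIError,
                         ImageVolume, ROIMask, SurvivalRecord,
                         write_clinical_table, write_mask,
                         write_survival_table, write_volume)

PHENOTYPES = ("smooth", "heterogeneous")

# Texture parameters of the two latent phenotypes: (correlation length in
# voxels, noise amplitude in intensity units on a ~100-unit base profile).
PHENOTYPE_TEXTURE = {
    "smooth": {"correlation_length": 3.0, "noise_amplitude": 6.0},
    "heterogeneous": {"correlation_length": 0.7, "noise_amplitude": 25.0},
}

# Default planted signal: two features that are robust to the dual-rater
# contour perturbation (high ICC, so the planted hazard survives the
# reproducibility screen) and nearly uncorrelated with each other (so
# neither marginal association cancels), one histogram-family and one
# wavelet-GLCM-family.
DEFAULT_TRUE_FEATURES = {
    "LL_HIST.kurtosis": 1.0,
    "LH_GLCM.correlation": -1.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """One synthetic tumor volume."""

    grid_shape: tuple[int, int, int] = (16, 32, 32)
    tumor_radius_range: tuple[float, float] = (5.0, 7.5)
    phenotype: str = "smooth"
    texture_params: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 4 for d in self.grid_shape):
            raise ValueError("grid_shape dimensions must be >= 4")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise ValueError("invalid tumor_radius_range")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")
        if hi >= min(self.grid_shape) / 2:
            raise ValueError("tumor_radius_range exceeds grid")

    @property
    def texture(self) -> dict:
        if self.texture_params is not None:
            return self.texture_params
        return PHENOTYPE_TEXTURE[self.phenotype]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A full cohort: images, dual-rater masks, clinical and survival data."""

    n_patients: int = 303
    split_fraction: float = 200 / 303
    true_features: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUE_FEATURES))
    baseline_hazard: float = 0.01        # events per month
    censoring_rate: float = 0.3
    rater2_perturbation: int = 1         # voxels of dilation/erosion
    heterogeneous_fraction: float = 0.5
    n_dual_contoured: int = 19
    grid_shape: tuple[int, int, int] = (16, 32, 32)
    tumor_radius_range: tuple[float, float] | None = None  # None = auto
    seed: int = 0

    @property
    def phantom_radius_range(self) -> tuple[float, float]:
        if self.tumor_radius_range is not None:
            return self.tumor_radius_range
        half = min(self.grid_shape) / 2
        return (0.63 * half, 0.93 * half)

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        unknown = set(self.true_features) - set(feat.FEATURE_ROSTER)
        if unknown:
            raise ValueError(f"unknown true_features: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Phantom rendering
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ROIMask]:
    """Render one phantom: ellipsoidal mask + textured intensity field.

    Deterministic given the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    lo, hi = spec.tumor_radius_range
    radii = rng.uniform(lo, hi, size=3)
    radii[0] = min(radii[0], shape[0] / 2 - 1.5)  # slice axis is thinnest
    center = np.array(shape) / 2 + rng.uniform(-1, 1, size=3)
    grids = np.meshgrid(*(np.arange(d, dtype=float) for d in shape),
                        indexing="ij")
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask = (dist2 <= 1.0).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("tumor does not cover any voxel")

    texture = spec.texture
    sigma = float(texture["correlation_length"])
    amp = float(texture["noise_amplitude"])
    # flat bulk with a small bright core: the core pins the ROI intensity
    # range, so the noise amplitude controls how much of that range the
    # bulk histogram occupies (texture features respond monotonically)
    base = 100.0 + 100.0 * np.exp(-16.0 * dist2)
    noise = rng.standard_normal(shape)
    if amp > 0:
        if sigma > 0:
            smoothed = ndimage.gaussian_filter(noise, sigma, mode="wrap")
            smoothed /= smoothed.std()      # restore unit variance
        else:
            smoothed = noise
        img = base + amp * smoothed
    else:
        img = base
    volume = ImageVolume(img, spacing=(3.0, 1.0, 1.0))
    return volume, ROIMask(mask)


def generate_rater2_mask(mask: ROIMask, magnitude: int,
                         seed: int = 0) -> ROIMask:
    """Morphologically perturbed second-rater contour.

    Randomly dilates or erodes by up to ``magnitude`` voxels; magnitude 0
    returns the mask unchanged.
    """
    if mask.n_voxels == 0:
        raise EmptyROIError("cannot perturb an empty mask")
    if magnitude == 0:
        return ROIMask(mask.voxels.copy(), lesion_kind=mask.lesion_kind,
                       patient_id=mask.patient_id)
    rng = np.random.default_rng(seed)
    iterations = int(rng.integers(1, magnitude + 1))
    op = ndimage.binary_dilation if rng.random() < 0.5 else ndimage.binary_erosion
    structure = ndimage.generate_binary_structure(3, 1)
    perturbed = op(mask.voxels.astype(bool), structure=structure,
                   iterations=iterations)
    if not perturbed.any():
        raise ValueError("perturbation emptied the mask")
    return ROIMask(perturbed.astype(np.uint8), lesion_kind=mask.lesion_kind,
                   patient_id=mask.patient_id)


# ---------------------------------------------------------------------------
# Survival generation
# ---------------------------------------------------------------------------

def generate_survival(features: pd.DataFrame, spec: SyntheticCohortSpec,
                      endpoint: str,
                      coefficients: dict | None = None,
                      ) -> list[SurvivalRecord]:
    """Exponential proportional-hazards event times with planted signal.

    The linear predictor is sum(coef * standardized feature); each patient's
    hazard is baseline_hazard * exp(lp).  Censoring is an independent
    exponential whose rate is tuned numerically so the expected censoring
    fraction matches ``spec.censoring_rate``.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    coefs = spec.true_features if coefficients is None else coefficients
    missing = set(coefs) - set(features.columns)
    if missing:
        raise ValueError(f"true features absent from matrix: {sorted(missing)}")
    lp = np.zeros(len(features))
    for name, beta in coefs.items():
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        lp += beta * z
    hazards = spec.baseline_hazard * np.exp(lp)
    rng = np.random.default_rng(
        (spec.seed * 7919 + ENDPOINTS.index(endpoint) + 1) % (2 ** 31))
    event_times = rng.exponential(1.0 / hazards)
    if spec.censoring_rate == 0:
        times, events = event_times, np.ones(len(features), dtype=int)
    else:
        c_rate = _censoring_rate_for(hazards, spec.censoring_rate)
        censor_times = rng.exponential(1.0 / c_rate, size=len(features))
        times = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    times = np.maximum(times, 1e-3)  # months; strictly positive
    return [SurvivalRecord(patient_id=str(pid), endpoint=endpoint,
                           time=float(t), event=int(e))
            for pid, t, e in zip(features.index, times, events)]


def _censoring_rate_for(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+h_i) = target."""
    def gap(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = np.log(hazards.min()) - 20, np.log(hazards.max()) + 20
    return float(np.exp(optimize.brentq(gap, lo, hi)))


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

# Stage mixtures conditioned on phenotype: the heterogeneous phenotype skews
# toward higher T stage, loosely echoing the observed stage distribution.
_T_PROBS = {"smooth": (0.45, 0.32, 0.18, 0.05),
            "heterogeneous": (0.10, 0.22, 0.40, 0.28)}
_N_PROBS = {"smooth": (0.20, 0.42, 0.28, 0.10),
            "heterogeneous": (0.07, 0.30, 0.42, 0.21)}


def _overall_stage(t: int, n: int) -> str:
    if t == 4 or n == 3:
        return "IV"
    if t == 3 or n == 2:
        return "III"
    if t == 2 or n == 1:
        return "II"
    return "I"


def generate_clinical(phenotypes: list[str], rng: np.random.Generator,
                      ids: list[str]) -> list[ClinicalRecord]:
    records = []
    for order, (pid, ph) in enumerate(zip(ids, phenotypes)):
        t = int(rng.choice(4, p=_T_PROBS[ph])) + 1
        n = int(rng.choice(4, p=_N_PROBS[ph]))
        age = float(np.clip(rng.normal(48.8, 12.7), 18, 85))
        sex = "male" if rng.random() < 0.746 else "female"
        records.append(ClinicalRecord(
            patient_id=pid, t_stage=t, n_stage=n,
            overall_stage=_overall_stage(t, n), age=round(age, 1),
            sex=sex, diagnosis_order=order))
    return records


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """On-disk cohort plus in-memory handles and the ground-truth manifest."""

    root: Path
    patient_ids: list[str]
    image_paths: dict
    mask_paths: dict
    rater2_paths: dict
    clinical_path: Path
    survival_path: Path
    manifest_path: Path
    manifest: dict
    feature_matrix: pd.DataFrame


def _carve_lymph_node(img: np.ndarray, primary: np.ndarray,
                      shape: tuple[int, int, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Add a small node lesion with phenotype-independent texture.

    The node is an ellipsoid displaced from the primary lesion; its voxels
    are re-rendered with a fixed middling texture drawn from an independent
    stream, so node-region features carry no survival signal.
    """
    radii = rng.uniform(3.2, 4.5, size=3)
    radii[0] = min(radii[0], shape[0] / 2 - 1)
    corner = rng.integers(0, 2, size=2)  # which in-plane corner quadrant
    center = np.array([
        shape[0] / 2,
        shape[1] * (0.25 if corner[0] else 0.75),
        shape[2] * (0.25 if corner[1] else 0.75),
    ]) + rng.uniform(-1, 1, size=3)
    grids = np.meshgrid(*(np.arange(d, dtype=float) for d in shape),
                        indexing="ij")
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    node = (dist2 <= 1.0) & ~primary.astype(bool)
    noise = rng.standard_normal(shape)
    smoothed = ndimage.gaussian_filter(noise, 2.0, mode="wrap")
    smoothed /= smoothed.std()
    img[node] = (120.0 + 80.0 * np.exp(-dist2) + 15.0 * smoothed)[node]
    return node.astype(np.uint8)


# Per-endpoint scaling of the planted coefficients: the signal is strongest
# for DFS/OS, attenuated for DMFS and absent for LRFS (whose model the
# pipeline is expected to report as unavailable).
ENDPOINT_SIGNAL_SCALE = {"DFS": 1.0, "OS": 0.8, "DMFS": 0.3, "LRFS": 0.0}


def sample_phenotypes(n: int, heterogeneous_fraction: float,
                      rng: np.random.Generator) -> list[str]:
    return ["heterogeneous" if rng.random() < heterogeneous_fraction
            else "smooth" for _ in range(n)]


def generate_cohort(spec: SyntheticCohortSpec,
                    out_dir: str | Path) -> CohortBundle:
    """Write a complete cohort (NIfTI volumes/masks, CSV tables, manifest)."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    images = root / "images"
    images.mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ids = [f"P{i:04d}" for i in range(n)]
    phenotypes = sample_phenotypes(n, spec.heterogeneous_fraction, rng)
    phantom_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    rater_seeds = rng.integers(0, 2 ** 31 - 1, size=n)

    image_paths, mask_paths, rater2_paths = {}, {}, {}
    rows = {}
    for pid, ph, pseed, rseed in zip(ids, phenotypes, phantom_seeds,
                                     rater_seeds):
        pspec = PhantomSpec(grid_shape=spec.grid_shape,
                            tumor_radius_range=spec.phantom_radius_range,
                            phenotype=ph, seed=int(pseed))
        volume, mask = generate_phantom(pspec)
        volume.patient_id = mask.patient_id = pid
        node_rng = np.random.default_rng(int(pseed) ^ 0x5F5F5F)
        node = _carve_lymph_node(volume.voxels, mask.voxels,
                                 spec.grid_shape, node_rng)
        image_paths[pid] = write_volume(volume, images / f"{pid}_image.nii.gz")
        mask_paths[pid] = write_mask(mask, images / f"{pid}_mask.nii.gz",
                                     spacing=volume.spacing)
        write_mask(ROIMask(node, lesion_kind="lymph_node", patient_id=pid),
                   images / f"{pid}_mask_lymph_node.nii.gz",
                   spacing=volume.spacing)
        rows[pid] = feat.extract_all(volume, mask)

    feature_matrix = pd.DataFrame.from_dict(rows, orient="index")
    feature_matrix.index.name = "patient_id"

    # second-rater masks for the reproducibility subset (earliest patients,
    # who fall in the training cohort under the chronological split)
    n_dual = min(spec.n_dual_contoured, n)
    for pid in ids[:n_dual]:
        rseed = int(rater_seeds[ids.index(pid)])
        _, mask = _reload(mask_paths[pid])
        r2 = _rater2_retry(mask, spec.rater2_perturbation, rseed)
        rater2_paths[pid] = write_mask(
            r2, images / f"{pid}_mask_rater2.nii.gz")
        _, node = _reload(images / f"{pid}_mask_lymph_node.nii.gz")
        node.lesion_kind = "lymph_node"
        r2n = _rater2_retry(node, spec.rater2_perturbation, rseed + 1)
        write_mask(r2n, images / f"{pid}_mask_lymph_node_rater2.nii.gz")

    clinical = generate_clinical(phenotypes, rng, ids)
    clinical_path = write_clinical_table(clinical, root / "clinical.csv")

    survival: list[SurvivalRecord] = []
    for endpoint in ENDPOINTS:
        scale = ENDPOINT_SIGNAL_SCALE[endpoint]
        coefs = {k: v * scale for k, v in spec.true_features.items()}
        survival.extend(generate_survival(feature_matrix, spec, endpoint,
                                          coefficients=coefs))
    survival_path = write_survival_table(survival, root / "survival.csv")

    manifest = {
        "seed": spec.seed,
        "n_patients": n,
        "split_fraction": spec.split_fraction,
        "phenotypes": dict(zip(ids, phenotypes)),
        "true_features": spec.true_features,
        "endpoint_signal_scale": ENDPOINT_SIGNAL_SCALE,
        "baseline_hazard": spec.baseline_hazard,
        "censoring_rate": spec.censoring_rate,
        "rater2_perturbation": spec.rater2_perturbation,
        "dual_contoured": ids[:n_dual],
        "phantom_seeds": {pid: int(s) for pid, s in zip(ids, phantom_seeds)},
    }
    manifest_path = root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    feature_matrix.to_csv(root / "features_generator.csv")

    return CohortBundle(root=root, patient_ids=ids, image_paths=image_paths,
                        mask_paths=mask_paths, rater2_paths=rater2_paths,
                        clinical_path=clinical_path,
                        survival_path=survival_path,
                        manifest_path=manifest_path, manifest=manifest,
                        feature_matrix=feature_matrix)


def _rater2_retry(mask: ROIMask, magnitude: int, seed: int) -> ROIMask:
    """Deterministically re-draw the perturbation if it would empty a
    small mask (erosion of a tiny lesion)."""
    for offset in range(8):
        try:
            return generate_rater2_mask(mask, magnitude,
                                        seed=seed + offset * 104729)
        except ValueError:
            continue
    dilated = ndimage.binary_dilation(mask.voxels.astype(bool))
    return ROIMask(dilated.astype(np.uint8), lesion_kind=mask.lesion_kind,
                   patient_id=mask.patient_id)


def _reload(mask_path: Path):
    import nibabel as nib
    arr = (np.asanyarray(nib.load(str(mask_path)).dataobj) != 0).astype(np.uint8)
    return None, ROIMask(arr)


def simulate_feature_matrix(n_patients: int, seed: int,
                            n_features: int | None = None,
                            correlation: float = 0.0,
                            columns: list | None = None) -> pd.DataFrame:
    """Gaussian stand-in feature matrix with roster column names.

    Used for statistical studies of the survival machinery where rendering
    image phantoms would add nothing: columns are (optionally equicorrelated)
    standard normals labelled with real roster names.  ``n_features`` keeps
    the first n roster names but always includes the default planted
    features; ``columns`` overrides the column set entirely.
    """
    rng = np.random.default_rng(seed)
    if columns is not None:
        names = list(columns)
    elif n_features:
        names = feat.FEATURE_ROSTER[:n_features]
        names += [f for f in DEFAULT_TRUE_FEATURES if f not in names]
    else:
        names = feat.FEATURE_ROSTER
    k = len(names)
    x = rng.standard_normal((n_patients, k))
    if correlation > 0:
        shared = rng.standard_normal((n_patients, 1))
        x = np.sqrt(1 - correlation) * x + np.sqrt(correlation) * shared
    ids = [f"P{i:04d}" for i in range(n_patients)]
    return pd.DataFrame(x, index=pd.Index(ids, name="patient_id"),
                        columns=names)
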