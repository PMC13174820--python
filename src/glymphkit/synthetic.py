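"""Synthetic acquisition schemes, DWI phantoms and cohort tables.

Everything the pipeline consumes can be generated here: multi-shell gradient
tables matching the two study acquisition schemes (an HCP-Aging-style
6 b0 + 45@b1500 + 45@b3000 protocol and an ADNI-style
14 b0 + 6@b500 + 56@b1000 + 56@b2000 protocol), voxel phantoms with
perivascular tubes of high anisotropic free-water content embedded in white
matter plus WMH blobs, Rician magnitude noise, and cohort tables with planted
linear cardiometabolic associations, diagnostic-group offsets and a serial
mediation chain.  All generators are pure functions of (spec, seed).

The phantoms emulate contrast and geometry, not anatomy: straight tubes,
spherical lesions, homogeneous compartments.  They exercise the estimators'
correctness, not their robustness to real-brain heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bitensor import AcquisitionScheme, BiTensorVoxel, simulate_signal
from .exceptions import InputError

__all__ = [
    "make_scheme",
    "tensor_from_eigs",
    "PhantomSpec",
    "render_phantom",
    "add_rician_noise",
    "CohortSpec",
    "make_cohort",
    "make_component_cohort",
    "default_recipes",
]


# --------------------------------------------------------------------------
# Acquisition schemes
# --------------------------------------------------------------------------

def _repulsion_directions(n: int, seed: int, n_iter: int = 200,
                          step: float = 0.05) -> np.ndarray:
    """Quasi-uniform unit directions by seeded electrostatic repulsion.

    Antipodally symmetric Coulomb forces (diffusion directions are axes, so
    g and -g are equivalent) relaxed by normalized gradient steps.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]
            d2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if sign < 0:
                d2[d2 < 1e-12] = np.inf  # a point and its own antipode
            force += np.sum(diff / (d2**1.5)[..., None], axis=1)
        # project onto the tangent plane and step
        force -= np.sum(force * v, axis=1, keepdims=True) * v
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        v = v + step * force / norm
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


_PRESETS: Mapping[str, tuple[tuple[float, int], ...]] = {
    # (b-value s/mm^2, number of volumes); b=0 listed first
    "hcpa": ((0.0, 6), (1500.0, 45), (3000.0, 45)),
    "adni": ((0.0, 14), (500.0, 6), (1000.0, 56), (2000.0, 56)),
}


def make_scheme(
    preset: str = "hcpa",
    seed: int = 0,
    shells: Sequence[tuple[float, int]] | None = None,
) -> AcquisitionScheme:
    """Build a multi-shell scheme from a named preset or custom shell list.

    ``hcpa``: 6 b0 + 45 @ b=1500 + 45 @ b=3000 (96 rows, 1.5 mm protocol).
    ``adni``: 14 b0 + 6 @ b=500 + 56 @ b=1000 + 56 @ b=2000 (132 rows).
    Directions are quasi-uniform on the sphere, deterministic given the seed;
    each shell gets its own direction set.
    """
    if shells is None:
        if preset not in _PRESETS:
            raise InputError(f"unknown preset {preset!r}; use one of "
                             f"{sorted(_PRESETS)} or pass shells=")
        shells = _PRESETS[preset]
    bvals_list: list[np.ndarray] = []
    bvecs_list: list[np.ndarray] = []
    for i, (b, count) in enumerate(shells):
        if count < 1:
            raise InputError("shell volume count must be >= 1")
        bvals_list.append(np.full(count, float(b)))
        if b <= 0:
            bvecs_list.append(np.zeros((count, 3)))
        else:
            bvecs_list.append(_repulsion_directions(count, seed=seed + 1000 * i))
    return AcquisitionScheme(bvals=np.concatenate(bvals_list),
                             bvecs=np.vstack(bvecs_list))


# --------------------------------------------------------------------------
# Tensors and tissue recipes
# --------------------------------------------------------------------------

def tensor_from_eigs(eigs: Sequence[float], axis: Sequence[float] = (0, 0, 1)) -> np.ndarray:
    """Symmetric tensor with eigenvalues ``eigs`` (descending), principal
    eigenvector along ``axis``; the two minor axes complete an orthonormal
    frame deterministically."""
    e = np.sort(np.asarray(eigs, dtype=float))[::-1]
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    w = np.cross(a, u)
    R = np.column_stack([a, u, w])
    return R @ np.diag(e) @ R.T


def default_recipes() -> dict[int, BiTensorVoxel]:
    """Ground-truth bi-tensor parameters per phantom label.

    1 = white matter (low FWVF, anisotropic tissue along z, free water near
    the isotropic 3.0e-3 ball); 2 = perivascular tube (high FWVF, fluid
    tensor elongated along the tube axis y); 3 = WMH lesion (moderately
    elevated free water, degraded tissue anisotropy).
    """
    return {
        1: BiTensorVoxel(
            S0=1.0, f=0.10,
            D_fluid=tensor_from_eigs([3.3e-3, 2.9e-3, 2.8e-3], axis=(0, 0, 1)),
            D_tissue=tensor_from_eigs([1.5e-3, 0.4e-3, 0.4e-3], axis=(0, 0, 1)),
        ),
        2: BiTensorVoxel(
            S0=1.0, f=0.90,
            D_fluid=tensor_from_eigs([4.2e-3, 2.4e-3, 2.4e-3], axis=(0, 1, 0)),
            D_tissue=tensor_from_eigs([1.2e-3, 0.5e-3, 0.5e-3], axis=(0, 1, 0)),
        ),
        3: BiTensorVoxel(
            S0=1.0, f=0.40,
            D_fluid=tensor_from_eigs([3.1e-3, 3.0e-3, 2.9e-3], axis=(1, 0, 0)),
            D_tissue=tensor_from_eigs([1.0e-3, 0.6e-3, 0.6e-3], axis=(0, 0, 1)),
        ),
    }


def random_bitensor_voxels(
    n: int,
    seed: int = 0,
    f_range: tuple[float, float] = (0.1, 0.9),
    fluid_md_range: tuple[float, float] = (2.2e-3, 3.8e-3),
    tissue_md_range: tuple[float, float] = (0.5e-3, 1.2e-3),
    fluid_fa_max: float = 0.35,
    tissue_fa_spread: float = 0.6,
) -> list[BiTensorVoxel]:
    """Random physiologically plausible bi-tensor voxels (deterministic).

    The fluid compartment stays CSF-like (mean diffusivity near free water,
    mild anisotropy as in perivascular channels); the tissue compartment is
    parenchyma-like with substantial anisotropy.  The two MD ranges do not
    overlap, honouring the label convention MD_fluid >= MD_tissue and keeping
    the mixture identifiable on multi-shell data.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        f = rng.uniform(*f_range)
        md_f = rng.uniform(*fluid_md_range)
        # spread eigenvalues around md with a bounded anisotropy
        af = rng.uniform(0.0, fluid_fa_max)
        ef = md_f * np.array([1 + af, 1 - af / 2, 1 - af / 2])
        md_t = rng.uniform(*tissue_md_range)
        at = rng.uniform(0.1, tissue_fa_spread)
        et = md_t * np.array([1 + at, 1 - at / 2, 1 - at / 2])
        out.append(BiTensorVoxel(
            S0=1.0, f=f,
            D_fluid=tensor_from_eigs(ef, rng.standard_normal(3)),
            D_tissue=tensor_from_eigs(et, rng.standard_normal(3)),
        ))
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + ground truth for a rectangular DWI phantom.

    White matter fills the grid; one straight perivascular tube runs the full
    extent of ``tube_axis``; WMH blobs are spheres at seeded positions.
    ``snr`` is S0 / sigma for Rician noise (None = noiseless).  The GM
    boundary is the x = 0 face and the deep boundary the opposite face, so
    the phantom doubles as a slab for depth mapping.
    """

    shape: tuple[int, int, int] = (10, 10, 10)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    tube_axis: int = 1
    tube_radius_mm: float = 1.8
    tube_center: tuple[float, float] | None = None  # in-plane, voxel units
    n_wmh: int = 1
    wmh_radius_mm: float = 2.0
    snr: float | None = None
    seed: int = 0
    recipes: Mapping[int, BiTensorVoxel] = field(default_factory=default_recipes)

    def __post_init__(self) -> None:
        for lab, vox in self.recipes.items():
            if not isinstance(vox, BiTensorVoxel):
                raise InputError(f"recipe for label {lab} is not a BiTensorVoxel")


def _tube_mask(spec: PhantomSpec) -> np.ndarray:
    shape = spec.shape
    sp = np.asarray(spec.spacing)
    other = [a for a in range(3) if a != spec.tube_axis]
    if spec.tube_center is None:
        center = [shape[a] / 2.0 - 0.5 for a in other]
    else:
        center = list(spec.tube_center)
    grid = np.indices(shape).astype(float)
    d2 = ((grid[other[0]] - center[0]) * sp[other[0]]) ** 2 + \
         ((grid[other[1]] - center[1]) * sp[other[1]]) ** 2
    return d2 <= spec.tube_radius_mm**2


def _wmh_mask(spec: PhantomSpec, exclude: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    shape = spec.shape
    sp = np.asarray(spec.spacing)
    mask = np.zeros(shape, dtype=bool)
    grid = np.indices(shape).astype(float)
    for _ in range(spec.n_wmh):
        for _attempt in range(50):
            c = rng.uniform(1, np.asarray(shape) - 2)
            d2 = sum(((grid[a] - c[a]) * sp[a]) ** 2 for a in range(3))
            blob = d2 <= spec.wmh_radius_mm**2
            if not (blob & exclude).any() and blob.any():
                mask |= blob
                break
    return mask


def render_phantom(
    spec: PhantomSpec,
    scheme: AcquisitionScheme,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Render a phantom into a 4-D DWI array.

    Returns ``(dwi, labels, truth_maps, masks)``: labels 1/2/3 as in
    :func:`default_recipes`; truth maps for FWVF, FWAD, FWMD, S0; masks for
    wm, pas, wmh, gm_boundary, deep_boundary and the all-voxel brain mask.
    Signals are the exact forward model per label, optionally corrupted with
    Rician noise at SNR = spec.snr.  Deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.ones(spec.shape, dtype=np.int16)
    tube = _tube_mask(spec)
    labels[tube] = 2
    wmh = _wmh_mask(spec, exclude=tube, rng=rng) if spec.n_wmh else np.zeros(spec.shape, bool)
    if (wmh & tube).any():
        raise InputError("overlapping phantom labels (tube and WMH)")
    labels[wmh] = 3

    dwi = np.zeros((*spec.shape, scheme.n_gradients))
    truth = {name: np.zeros(spec.shape) for name in ("FWVF", "FWAD", "FWMD", "S0")}
    from .bitensor import tensor_metrics

    for lab, vox in spec.recipes.items():
        sel = labels == lab
        if not sel.any():
            continue
        sig = simulate_signal(vox, scheme)
        dwi[sel] = sig
        mf = tensor_metrics(vox.D_fluid)
        truth["FWVF"][sel] = vox.f
        truth["FWAD"][sel] = mf.AD
        truth["FWMD"][sel] = mf.MD
        truth["S0"][sel] = vox.S0

    if spec.snr is not None:
        sigma = float(np.mean(truth["S0"][labels > 0])) / spec.snr
        dwi = add_rician_noise(dwi, sigma, seed=int(rng.integers(2**31)))

    gm_boundary = np.zeros(spec.shape, dtype=bool)
    gm_boundary[0, :, :] = True
    deep_boundary = np.zeros(spec.shape, dtype=bool)
    deep_boundary[-1, :, :] = True
    masks = {
        "brain": labels > 0,
        "wm": labels == 1,
        "pas": labels == 2,
        "wmh": labels == 3,
        "gm_boundary": gm_boundary,
        "deep_boundary": deep_boundary,
    }
    return dwi, labels, truth, masks


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Rician magnitude noise: |S + n1 + i n2| with n1, n2 ~ N(0, sigma)."""
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# --------------------------------------------------------------------------
# Cohort generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Planted statistical structure for a synthetic cohort.

    Linear effects are standardized slopes (SD of feature per SD of
    predictor).  The serial mediation chain is generated on its own latent
    columns (med_x -> med_m1 -> med_m2 -> med_y) with raw path coefficients
    a1, a2, b and direct effect c_prime; clinical columns (diastolic BP,
    precuneus pAs-FWAD, amyloid SUVR, MoCA) are affine images of those
    latents so the chain is recoverable on either scale.  Group proportions
    follow CN/MCI/AD; group offsets are in SD units of each feature.
    """

    n: int = 300
    beta_age_pas_fwvf: float = 0.30
    beta_age_wm_fwvf: float = 0.35
    beta_age_alps: float = -0.30
    beta_map_pas_fwad: float = -0.25
    a1: float = 0.2
    a2: float = -0.3
    b: float = -0.3
    c_prime: float = 0.0
    mediation_noise_sd: float = 1.0
    feature_noise_sd: float = 1.0
    group_props: tuple[float, float, float] = (0.55, 0.39, 0.06)
    group_fwvf_offsets: tuple[float, float, float] = (0.0, 0.4, 0.8)
    amyloid_feature_shift: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise InputError("group proportions must sum to 1")
        if self.mediation_noise_sd <= 0 or self.feature_noise_sd <= 0:
            raise InputError("noise SDs must be positive")


_REGIONS = ("precuneus", "ad_signature", "whole_brain")


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (phenotype table, subject feature table, truth record).

    Phenotype marginals loosely emulate an aging cohort (ages 36-100,
    realistic blood pressure, lipids and glycemia); this is plausibility, not
    distributional fidelity.  Features are linear functions of the planted
    predictors plus Gaussian noise on standardized scales, then mapped to
    physical units (FWVF in [0,1], diffusivities in mm^2/s).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    age = np.clip(rng.normal(58.6, 14.1, n), 36, 100)
    sex = rng.integers(0, 2, n)
    education = np.clip(rng.normal(16.5, 2.5, n), 8, 22)
    diastolic = np.clip(rng.normal(76, 10, n), 45, 120)
    systolic = np.clip(diastolic + rng.normal(48, 12, n), 80, 220)
    map_bp = (2 * diastolic + systolic) / 3.0
    bmi = np.clip(rng.normal(26.6, 4.5, n), 15, 50)
    hdl = np.clip(rng.normal(62, 18, n), 20, 140)
    hba1c = np.clip(rng.normal(5.5, 0.45, n), 4, 12)
    triglycerides = np.clip(rng.normal(105, 55, n), 30, 500)
    cholesterol = np.clip(rng.normal(192, 36, n), 90, 350)
    glucose = np.clip(rng.normal(92, 13, n), 60, 250)
    psqi = np.clip(rng.poisson(5.0, n), 0, 21)
    apoe4 = rng.random(n) < 0.30
    diagnosis = rng.choice(["CN", "MCI", "AD"], size=n, p=list(spec.group_props))
    group_idx = np.select([diagnosis == "CN", diagnosis == "MCI"], [0, 1], 2)
    group_off = np.asarray(spec.group_fwvf_offsets)[group_idx]

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    age_s, map_s = z(age), z(map_bp)

    # ---- serial mediation chain on latent columns -------------------------
    sd = spec.mediation_noise_sd
    med_x = rng.standard_normal(n)
    med_m1 = spec.a1 * med_x + rng.normal(0, sd, n)
    med_m2 = spec.a2 * med_m1 + rng.normal(0, sd, n)
    med_y = spec.b * med_m2 + spec.c_prime * med_x + rng.normal(0, sd, n)

    # amyloid status driven by diagnosis (more positives later in the spectrum)
    p_pos = np.asarray([0.3, 0.55, 0.9])[group_idx]
    amyloid_pos = rng.random(n) < p_pos
    amy = amyloid_pos.astype(float)

    fsd = spec.feature_noise_sd
    feat = {"subject": np.array([f"sub-{i:04d}" for i in range(n)])}
    for r in _REGIONS:
        fwvf_lat = (spec.beta_age_pas_fwvf * age_s + group_off
                    + spec.amyloid_feature_shift * amy + rng.normal(0, fsd, n))
        feat[f"pas_fwvf_{r}"] = np.clip(0.55 + 0.06 * fwvf_lat, 0.0, 1.0)
        fwad_lat = (spec.beta_map_pas_fwad * map_s
                    - spec.amyloid_feature_shift * amy + rng.normal(0, fsd, n))
        feat[f"pas_fwad_{r}"] = 3.0e-3 + 0.25e-3 * fwad_lat
        wm_lat = (spec.beta_age_wm_fwvf * age_s + group_off
                  + 0.5 * spec.amyloid_feature_shift * amy + rng.normal(0, fsd, n))
        feat[f"wm_fwvf_{r}"] = np.clip(0.15 + 0.035 * wm_lat, 0.0, 1.0)
    alps_lat = spec.beta_age_alps * age_s - 0.3 * group_off + rng.normal(0, fsd, n)
    feat["alps_index"] = np.clip(1.5 + 0.15 * alps_lat, 0.3, None)
    features = pd.DataFrame(feat)

    # clinical images of the mediation latents (affine, order-preserving)
    pas_fwad_prec_med = 3.0e-3 + 0.25e-3 * med_m1
    abeta_prec = 1.25 + 0.20 * med_m2
    moca = np.clip(np.round(26 + 2.2 * med_y), 0, 30)
    mmse = np.clip(np.round(28 + 1.5 * med_y + rng.normal(0, 0.5, n)), 0, 30)

    phenotype = pd.DataFrame({
        "subject": features["subject"],
        "age": age, "sex": sex, "education": education,
        "bmi": bmi, "systolic_bp": systolic, "diastolic_bp": diastolic,
        "map_bp": map_bp, "hdl": hdl, "hba1c": hba1c,
        "triglycerides": triglycerides, "total_cholesterol": cholesterol,
        "fasting_glucose": glucose, "psqi": psqi,
        "moca": moca, "mmse": mmse,
        "diagnosis": diagnosis, "apoe4_carrier": apoe4.astype(int),
        "amyloid_positive": amyloid_pos.astype(int),
        "med_x": med_x, "med_m1": med_m1, "med_m2": med_m2, "med_y": med_y,
        "abeta_suvr_precuneus_med": abeta_prec,
        "pas_fwad_precuneus_med": pas_fwad_prec_med,
    })
    for r in _REGIONS:
        phenotype[f"abeta_suvr_{r}"] = np.clip(
            1.0 + 0.35 * amy + rng.normal(0, 0.12, n), 0.6, None)
        phenotype[f"tau_suvr_{r}"] = np.clip(
            1.15 + 0.25 * amy * (group_idx > 0) + rng.normal(0, 0.10, n), 0.6, None)

    truth = {
        "spec": spec,
        "indirect": spec.a1 * spec.a2 * spec.b,
        "group_idx": group_idx,
        "amyloid_positive": amyloid_pos,
    }
    return phenotype, features, truth


def make_component_cohort(
    n_subjects: int = 200,
    n_components: int = 8,
    n_signal: int = 4,
    effect: float = 0.8,
    signal_noise_sd: float = 0.3,
    distractor_noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject pAs component tables where only the ``n_signal`` largest
    components carry a planted clinical association.

    Each subject has ``n_components`` components with strictly decreasing
    volumes.  The metric values of the largest ``n_signal`` components track
    a latent clinical variable (slope ``effect``) with small noise; smaller
    components are pure high-variance noise, so averaging beyond ``n_signal``
    dilutes the association.  Subjects carry a random extra component count
    so the inclusion fraction genuinely decreases with n.
    Returns (component_table, phenotype) for :func:`glymphkit.pas.optimize_n`.
    """
    rng = np.random.default_rng(seed)
    clin = rng.standard_normal(n_subjects)
    age = np.clip(rng.normal(60, 10, n_subjects), 40, 90)
    sex = rng.integers(0, 2, n_subjects)
    rows = []
    counts = n_components - (rng.random(n_subjects) < 0.3) * rng.integers(
        1, max(n_components - n_signal, 2), n_subjects)
    for i in range(n_subjects):
        k = int(counts[i])
        volumes = np.sort(rng.uniform(5, 100, k))[::-1]
        for j in range(k):
            if j < n_signal:
                fwad = effect * clin[i] + rng.normal(0, signal_noise_sd)
                fwvf = effect * clin[i] + rng.normal(0, signal_noise_sd)
            else:
                fwad = rng.normal(0, distractor_noise_sd)
                fwvf = rng.normal(0, distractor_noise_sd)
            rows.append({"subject": f"sub-{i:04d}", "volume_mm3": volumes[j],
                         "FWAD": fwad, "FWVF": fwvf})
    phenotype = pd.DataFrame({
        "subject": [f"sub-{i:04d}" for i in range(n_subjects)],
        "clinical": clin, "age": age, "sex": sex,
    })
    return pd.DataFrame(rows), phenotype
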