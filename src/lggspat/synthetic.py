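"""Synthetic longitudinal mask cohorts with known ground truth.

No public imaging archive ships co-registered preoperative /
pre-transformation / transformation mask triplets for low-grade glioma, so
this module generates them: voxelized ellipsoidal preoperative tumors at
clinically realistic volumes, a radially grown pre-transformation tumor,
and small spherical transformation foci placed at controlled signed
surface distances from the pre-transformation tumor. Every case carries
the labels the classifier is expected to recover, making the whole
pipeline testable end to end.

Placement modes
---------------
``inside``
    focus centered on a random voxel inside the preoperative tumor
    (overlaps it, distance 0 -> local, within).
``rim``
    focus centered on a preoperative boundary voxel (border overlap ->
    local, within).
``near``
    focus disjoint from the tumor at a surface distance inside the local
    band (local, outside).
``far``
    focus clearly separated, beyond the distant band (distant, outside).

Near/far placements are verified by measuring the voxelized surface
distance and accepted only when it falls within one voxel diagonal of the
target *and* clear of a +/- 2 mm exclusion band around the classification
threshold, so voxel-center quantization can never make the ground truth
ambiguous.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cases import Histology, PatientCase
from .classify import COMBINED, DISTANT, LOCAL, NOT_EVALUABLE, OUTSIDE, WITHIN
from .errors import PlacementError
from .volume import LabelVolume, write_label_volume

__all__ = [
    "FocusSpec",
    "SyntheticCaseSpec",
    "GroundTruth",
    "DEFAULT_RECIPE",
    "generate_case",
    "generate_cohort",
    "write_cohort",
]

#: Default cohort mixture. Scales follow a typical LGG transformation
#: cohort: preoperative volumes log-uniform with median ~30 ml (quartiles
#: ~13-67 ml), transformation foci log-uniform with median ~1.3 ml,
#: ~26% multifocal, clinical mixture ~91% local / 7% distant / 2% combined,
#: and treatment/histology label frequencies near the observed ones.
DEFAULT_RECIPE: dict = {
    "shape": (96, 96, 96),
    "spacing": (2.0, 2.0, 2.0),
    "preop_volume_ml_range": (6.0, 150.0),
    "focus_volume_ml_range": (0.3, 6.0),
    "growth_factor": 1.15,
    "category_probs": {"local": 0.91, "distant": 0.07, "combined": 0.02},
    "p_second_focus_local": 0.264,
    "local_mode_probs": {"inside": 0.70, "rim": 0.15, "near": 0.15},
    "near_distance_mm_range": (4.0, 16.0),
    "far_distance_mm_range": (24.0, 34.0),
    "center_jitter_mm": 4.0,
    "histology_probs": {
        "oligodendroglioma": 12 / 43,
        "astro_idh_mut": 16 / 43,
        "astro_idh_wt": 13 / 43,
        "lgg_nos": 2 / 43,
    },
    "p_resection": 21 / 43,
    "p_chemo": 14 / 43,
    "p_rt": 23 / 43,
    "p_missing_preop": 7 / 43,
    "local_threshold_mm": 20.0,
}


@dataclass(frozen=True)
class FocusSpec:
    """One transformation focus: size, placement mode, optional target distance."""

    radius_mm: float
    mode: str  # inside | rim | near | far
    target_distance_mm: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("inside", "rim", "near", "far"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        if self.mode in ("near", "far") and self.target_distance_mm is None:
            raise ValueError(f"{self.mode} placement requires target_distance_mm")
        if self.radius_mm <= 0:
            raise ValueError("focus radius must be positive")


@dataclass(frozen=True)
class SyntheticCaseSpec:
    """Full generator parameters for one case."""

    case_id: str
    preop_center_mm: tuple[float, float, float]
    preop_semiaxes_mm: tuple[float, float, float]
    foci: tuple[FocusSpec, ...]
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    growth_factor: float = 1.15
    jitter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    histology: Histology = Histology.LGG_NOS
    prior_resection: bool = False
    prior_chemo: bool = False
    prior_rt: bool = False
    include_preoperative: bool = True
    local_threshold_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.preop_semiaxes_mm) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.growth_factor < 1.0:
            raise ValueError("growth factor must be >= 1 (tumors do not shrink pre-transformation)")
        if not self.foci:
            raise ValueError("a case needs at least one transformation focus")
        margin = 2.0
        for f in self.foci:
            if f.mode == "near" and not 0 < f.target_distance_mm < self.local_threshold_mm - margin:
                raise ValueError(
                    f"near-mode target {f.target_distance_mm} mm must lie in "
                    f"(0, {self.local_threshold_mm - margin}) to keep ground truth unambiguous"
                )
            if f.mode == "far" and f.target_distance_mm < self.local_threshold_mm + margin:
                raise ValueError(
                    f"far-mode target {f.target_distance_mm} mm must be >= "
                    f"{self.local_threshold_mm + margin}"
                )
            if f.radius_mm < min(self.spacing):
                raise ValueError("focus radius must be at least one voxel")

    @property
    def affine(self) -> np.ndarray:
        """Diagonal affine centering the world origin on the grid."""
        aff = np.eye(4)
        for k in range(3):
            aff[k, k] = self.spacing[k]
            aff[k, 3] = -(self.shape[k] - 1) * self.spacing[k] / 2.0
        return aff


@dataclass(frozen=True)
class GroundTruth:
    """Intended labels for one generated case — the test oracle."""

    case_id: str
    focus_modes: tuple[str, ...]
    focus_labels: tuple[str, ...]
    clinical_category: str
    overlay_category: str
    n_foci: int
    multifocal: bool
    measured_distances_mm: tuple[float, ...] = field(default=())


# ---------------------------------------------------------------------------
# voxelization helpers (diagonal affines only — the generator's own grids)


def _world_axes(shape, spacing, affine) -> list[np.ndarray]:
    return [affine[k, 3] + np.arange(shape[k]) * spacing[k] for k in range(3)]


def _ellipsoid(shape, spacing, affine, center, semiaxes) -> np.ndarray:
    ax = _world_axes(shape, spacing, affine)
    t0 = ((ax[0] - center[0]) / semiaxes[0]) ** 2
    t1 = ((ax[1] - center[1]) / semiaxes[1]) ** 2
    t2 = ((ax[2] - center[2]) / semiaxes[2]) ** 2
    return (t0[:, None, None] + t1[None, :, None] + t2[None, None, :]) <= 1.0


def _sphere(shape, spacing, affine, center, radius) -> np.ndarray:
    return _ellipsoid(shape, spacing, affine, center, (radius,) * 3)


def _fits_grid(center, radius, shape, spacing, affine, margin_voxels=2) -> bool:
    for k in range(3):
        lo = affine[k, 3] + margin_voxels * spacing[k]
        hi = affine[k, 3] + (shape[k] - 1 - margin_voxels) * spacing[k]
        if center[k] - radius < lo or center[k] + radius > hi:
            return False
    return True


def _ellipsoid_surface_point(center, semiaxes, direction) -> np.ndarray:
    """Intersection of the ray from the center along ``direction`` with the surface."""
    n = direction / np.linalg.norm(direction)
    t = 1.0 / np.sqrt(((n / np.asarray(semiaxes)) ** 2).sum())
    return np.asarray(center) + t * n


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-6:
            return v / norm


# ---------------------------------------------------------------------------


_MAX_ATTEMPTS = 1000


def _place_focus(
    focus: FocusSpec,
    spec: SyntheticCaseSpec,
    preop: np.ndarray,
    rim_voxels: np.ndarray,
    dist_to_pretrans: np.ndarray,
    prior_centers: list[tuple[np.ndarray, float]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Voxelize one focus; returns (mask, center_mm, measured_distance_mm)."""
    shape, spacing, affine = spec.shape, np.asarray(spec.spacing), spec.affine
    voxel_diag = float(np.linalg.norm(spacing))
    margin = 2.0  # mm exclusion band around the threshold
    preop_idx = np.argwhere(preop)

    def separated(center: np.ndarray) -> bool:
        return all(
            np.linalg.norm(center - c) >= focus.radius_mm + r + 2 * voxel_diag
            for c, r in prior_centers
        )

    for _ in range(_MAX_ATTEMPTS):
        if focus.mode == "inside":
            idx = preop_idx[rng.integers(len(preop_idx))]
            center = affine[:3, 3] + idx * spacing
            target_ok = True
            measured = 0.0
        elif focus.mode == "rim":
            if not len(rim_voxels):
                raise PlacementError(f"{spec.case_id}: preoperative mask has no boundary voxels")
            idx = rim_voxels[rng.integers(len(rim_voxels))]
            center = affine[:3, 3] + idx * spacing
            target_ok = True
            measured = 0.0
        else:
            direction = _random_unit(rng)
            surface = _ellipsoid_surface_point(
                spec.preop_center_mm,
                np.asarray(spec.preop_semiaxes_mm) * spec.growth_factor,
                direction,
            )
            center = surface + (focus.target_distance_mm + focus.radius_mm) * direction
            target_ok = False  # verified below against the voxelized distance
        if not _fits_grid(center, focus.radius_mm, shape, spacing, affine):
            continue
        if not separated(center):
            continue
        mask = _sphere(shape, spacing, affine, center, focus.radius_mm)
        if not mask.any():
            continue
        if focus.mode in ("near", "far"):
            measured = float(dist_to_pretrans[mask].min())
            if measured <= 0 or abs(measured - focus.target_distance_mm) > voxel_diag:
                continue
            if focus.mode == "near" and measured >= spec.local_threshold_mm - margin:
                continue
            if focus.mode == "far" and measured <= spec.local_threshold_mm + margin:
                continue
        elif not (mask & preop).any():  # inside/rim must overlap by construction
            continue
        return mask, center, measured
    raise PlacementError(
        f"{spec.case_id}: could not place {focus.mode} focus "
        f"(r={focus.radius_mm:.1f} mm) after {_MAX_ATTEMPTS} attempts"
    )


def generate_case(spec: SyntheticCaseSpec) -> tuple[PatientCase, GroundTruth]:
    """Voxelize one case and its ground truth. Deterministic given the spec."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing, affine = spec.shape, np.asarray(spec.spacing), spec.affine

    preop_vox = _ellipsoid(shape, spacing, affine, spec.preop_center_mm, spec.preop_semiaxes_mm)
    if not preop_vox.any():
        raise PlacementError(f"{spec.case_id}: preoperative ellipsoid voxelizes to empty")
    pretrans_vox = _ellipsoid(
        shape, spacing, affine,
        spec.preop_center_mm,
        np.asarray(spec.preop_semiaxes_mm) * spec.growth_factor,
    )
    rim = np.argwhere(preop_vox & ~ndimage.binary_erosion(preop_vox))
    dist_to_pretrans = ndimage.distance_transform_edt(~pretrans_vox, sampling=spacing)

    trans_vox = np.zeros(shape, dtype=bool)
    placed: list[tuple[np.ndarray, float]] = []
    labels, measured_all = [], []
    for focus in spec.foci:
        mask, center, measured = _place_focus(
            focus, spec, preop_vox, rim, dist_to_pretrans, placed, rng
        )
        trans_vox |= mask
        placed.append((center, focus.radius_mm))
        labels.append(DISTANT if focus.mode == "far" else LOCAL)
        measured_all.append(measured)

    if any(spec.jitter_mm):
        shift = np.round(np.asarray(spec.jitter_mm) / spacing).astype(int)
        shifted = np.zeros_like(trans_vox)
        src = [slice(max(0, -s), min(n, n - s)) for s, n in zip(shift, shape)]
        dst = [slice(max(0, s), min(n, n + s)) for s, n in zip(shift, shape)]
        shifted[tuple(dst)] = trans_vox[tuple(src)]
        trans_vox = shifted

    case = PatientCase(
        case_id=spec.case_id,
        preoperative=LabelVolume(preop_vox, affine) if spec.include_preoperative else None,
        pre_transformation=LabelVolume(pretrans_vox, affine),
        transformation=LabelVolume(trans_vox, affine),
        histology=spec.histology,
        prior_resection=spec.prior_resection,
        prior_chemo=spec.prior_chemo,
        prior_rt=spec.prior_rt,
    )
    label_set = set(labels)
    clinical = labels[0] if len(label_set) == 1 else COMBINED
    if not spec.include_preoperative:
        overlay = NOT_EVALUABLE
    else:
        overlay = WITHIN if any(f.mode in ("inside", "rim") for f in spec.foci) else OUTSIDE
    truth = GroundTruth(
        case_id=spec.case_id,
        focus_modes=tuple(f.mode for f in spec.foci),
        focus_labels=tuple(labels),
        clinical_category=clinical,
        overlay_category=overlay,
        n_foci=len(spec.foci),
        multifocal=len(spec.foci) >= 2,
        measured_distances_mm=tuple(measured_all),
    )
    return case, truth


# ---------------------------------------------------------------------------
# cohort-level sampling


def _radius_from_volume_ml(v_ml: float) -> float:
    return (3.0 * v_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _sample_case_spec(case_id: str, recipe: dict, rng: np.random.Generator,
                      seed: int) -> SyntheticCaseSpec:
    shape = tuple(recipe["shape"])
    spacing = tuple(float(s) for s in recipe["spacing"])
    # preoperative ellipsoid: volume-preserving random anisotropy around a sphere
    volume_ml = _log_uniform(rng, *recipe["preop_volume_ml_range"])
    r = _radius_from_volume_ml(volume_ml)
    e = np.exp(rng.uniform(-0.25, 0.25, size=3))
    semiaxes = tuple(r * e / np.prod(e) ** (1 / 3))
    jitter = recipe["center_jitter_mm"]
    center = tuple(rng.uniform(-jitter, jitter, size=3))

    cats, probs = zip(*recipe["category_probs"].items())
    category = rng.choice(cats, p=np.asarray(probs) / np.sum(probs))
    modes, mode_p = zip(*recipe["local_mode_probs"].items())
    mode_p = np.asarray(mode_p) / np.sum(mode_p)

    def local_focus() -> FocusSpec:
        mode = str(rng.choice(modes, p=mode_p))
        target = (
            float(rng.uniform(*recipe["near_distance_mm_range"])) if mode == "near" else None
        )
        return FocusSpec(
            radius_mm=_radius_from_volume_ml(_log_uniform(rng, *recipe["focus_volume_ml_range"])),
            mode=mode,
            target_distance_mm=target,
        )

    def far_focus() -> FocusSpec:
        return FocusSpec(
            radius_mm=_radius_from_volume_ml(_log_uniform(rng, *recipe["focus_volume_ml_range"])),
            mode="far",
            target_distance_mm=float(rng.uniform(*recipe["far_distance_mm_range"])),
        )

    if category == "local":
        n_foci = 2 if rng.random() < recipe["p_second_focus_local"] else 1
        foci = tuple(local_focus() for _ in range(n_foci))
    elif category == "distant":
        foci = (far_focus(),)
    else:  # combined
        foci = (local_focus(), far_focus())

    hists, hist_p = zip(*recipe["histology_probs"].items())
    histology = Histology(str(rng.choice(hists, p=np.asarray(hist_p) / np.sum(hist_p))))

    return SyntheticCaseSpec(
        case_id=case_id,
        preop_center_mm=center,
        preop_semiaxes_mm=semiaxes,
        foci=foci,
        shape=shape,
        spacing=spacing,
        growth_factor=float(recipe["growth_factor"]),
        histology=histology,
        prior_resection=bool(rng.random() < recipe["p_resection"]),
        prior_chemo=bool(rng.random() < recipe["p_chemo"]),
        prior_rt=bool(rng.random() < recipe["p_rt"]),
        include_preoperative=bool(rng.random() >= recipe["p_missing_preop"]),
        local_threshold_mm=float(recipe["local_threshold_mm"]),
        seed=seed,
    )


def generate_cohort(
    n: int,
    seed: int = 0,
    recipe: dict | None = None,
) -> tuple[list[PatientCase], list[GroundTruth], pd.DataFrame]:
    """Generate ``n`` cases from a mixture recipe.

    Each case gets an independent random stream derived from ``(seed,
    index)``, so cohorts are reproducible and insertion of extra cases
    does not perturb earlier ones. Placement failures for one sampled
    geometry are retried with a fresh geometry (up to 20 per case) before
    giving up.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    recipe = {**DEFAULT_RECIPE, **(recipe or {})}
    cases, truths, rows = [], [], []
    for i in range(n):
        case_id = f"case_{i:04d}"
        for retry in range(20):
            rng = np.random.default_rng([int(seed) % (2**31), i, retry])
            case_seed = int(rng.integers(2**31))
            spec = _sample_case_spec(case_id, recipe, rng, case_seed)
            try:
                case, truth = generate_case(spec)
                break
            except PlacementError:
                continue
        else:
            raise PlacementError(f"case {i}: no feasible geometry after 20 recipe draws")
        cases.append(case)
        truths.append(truth)
        rows.append({
            "case_id": case_id,
            "clinical_category": truth.clinical_category,
            "overlay_category": truth.overlay_category,
            "n_foci": truth.n_foci,
            "multifocal": truth.multifocal,
            "focus_modes": ";".join(truth.focus_modes),
            "focus_labels": ";".join(truth.focus_labels),
            "histology": case.histology.value,
            "prior_resection": case.prior_resection,
            "prior_chemo": case.prior_chemo,
            "prior_rt": case.prior_rt,
            "has_preoperative": case.has_preoperative,
        })
    return cases, truths, pd.DataFrame(rows)


def write_cohort(cases: list[PatientCase], truth_table: pd.DataFrame,
                 out_dir: str | os.PathLike) -> str:
    """Write NIfTI masks + manifest.csv + ground_truth.csv; returns manifest path.

    The manifest is directly consumable by :func:`lggspat.read_case_manifest`.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for case in cases:
        paths = {}
        for key, vol in (
            ("preop", case.preoperative),
            ("pretransform", case.pre_transformation),
            ("transform", case.transformation),
        ):
            if vol is None:
                paths[key] = ""
                continue
            fname = f"{case.case_id}_{key}.nii.gz"
            write_label_volume(vol, os.path.join(out_dir, fname))
            paths[key] = fname
        rows.append({
            "case_id": case.case_id,
            "preop_path": paths["preop"],
            "pretransform_path": paths["pretransform"],
            "transform_path": paths["transform"],
            "histology": case.histology.value,
            "prior_resection": int(case.prior_resection),
            "prior_chemo": int(case.prior_chemo),
            "prior_rt": int(case.prior_rt),
        })
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    truth_table.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    return manifest_path
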