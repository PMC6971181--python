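"""Patient cases, analysis configuration, and cohort manifests.

A case bundles up to three co-registered timepoint masks: the preoperative
T2/FLAIR tumor, the T2/FLAIR tumor on the scan immediately preceding
malignant transformation, and the new contrast-enhancing transformation
volume on T1-gadolinium. The preoperative mask may be absent (historical
cohorts often lack digitized preoperative MRI); such cases remain eligible
for the clinical 2-cm rule, which only needs the pre-transformation mask.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from enum import Enum

from .errors import GridMismatchError, ValidationError
from .volume import LabelVolume, check_grid_compatibility, read_label_volume

__all__ = ["Histology", "PatientCase", "AnalysisConfig", "read_case_manifest"]


class Histology(str, Enum):
    """WHO-2016 molecular subgroups used for subgroup pattern tables."""

    OLIGODENDROGLIOMA = "oligodendroglioma"
    ASTRO_IDH_MUT = "astro_idh_mut"
    ASTRO_IDH_WT = "astro_idh_wt"
    LGG_NOS = "lgg_nos"


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis thresholds in one place.

    Attributes
    ----------
    local_threshold_mm:
        A transformation focus strictly closer than this to the
        pre-transformation T2 volume is *local*; the clinical rule uses
        2 cm. A focus at exactly the threshold is classified distant.
    min_overlap_voxels:
        Minimum voxel intersection for the overlay model to call a
        transformation "within" the reference volume (any overlap counts
        by default).
    min_component_ml:
        Connected components smaller than this are treated as segmentation
        noise and not counted as transformation foci.
    residual_threshold_ml:
        Pre-transformation tumor volumes strictly below this are flagged
        as small residual tumors.
    connectivity:
        3D neighborhood for component labeling (6, 18 or 26).
    overlay_reference:
        Which mask the overlay model compares against: the preoperative
        tumor (default) or, as a sensitivity analysis, the
        pre-transformation tumor.
    affine_tolerance_mm:
        Max elementwise affine difference for two masks to count as
        sharing one grid.
    """

    local_threshold_mm: float = 20.0
    min_overlap_voxels: int = 1
    min_component_ml: float = 0.01
    residual_threshold_ml: float = 10.0
    connectivity: int = 26
    overlay_reference: str = "preoperative"
    affine_tolerance_mm: float = 1e-3

    def __post_init__(self) -> None:
        if self.local_threshold_mm <= 0:
            raise ValidationError("local_threshold_mm must be > 0")
        if self.min_overlap_voxels < 1:
            raise ValidationError("min_overlap_voxels must be >= 1")
        if self.min_component_ml < 0:
            raise ValidationError("min_component_ml must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.overlay_reference not in ("preoperative", "pre_transformation"):
            raise ValidationError(
                f"overlay_reference must be 'preoperative' or 'pre_transformation', "
                f"got {self.overlay_reference!r}"
            )


@dataclass(frozen=True)
class PatientCase:
    """One patient's longitudinal mask triplet plus metadata."""

    case_id: str
    pre_transformation: LabelVolume
    transformation: LabelVolume
    preoperative: LabelVolume | None = None
    histology: Histology = Histology.LGG_NOS
    prior_resection: bool = False
    prior_chemo: bool = False
    prior_rt: bool = False
    affine_tolerance_mm: float = field(default=1e-3, compare=False)

    def __post_init__(self) -> None:
        if self.transformation.is_empty:
            raise ValidationError(
                f"case {self.case_id}: transformation mask is empty — a case without "
                "new enhancement is not a radiological transformation"
            )
        pairs = [("pre_transformation", self.pre_transformation)]
        if self.preoperative is not None:
            pairs.append(("preoperative", self.preoperative))
        for name, vol in pairs:
            check = check_grid_compatibility(self.transformation, vol, self.affine_tolerance_mm)
            if not check:
                raise GridMismatchError(
                    f"case {self.case_id}: transformation vs {name}: {check.reason}"
                )

    @property
    def has_preoperative(self) -> bool:
        return self.preoperative is not None


_REQUIRED_FIELDS = (
    "case_id",
    "preop_path",
    "pretransform_path",
    "transform_path",
    "histology",
    "prior_resection",
    "prior_chemo",
    "prior_rt",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


def _parse_flag(value: object, row: int, key: str) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValidationError(f"manifest row {row}: cannot parse boolean {key}={value!r}")


def _load_rows(path: str) -> list[dict]:
    if path.lower().endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise ValidationError(f"{path}: JSON manifest must be an array of objects")
        return rows
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def read_case_manifest(path: str | os.PathLike) -> list[PatientCase]:
    """Load a cohort manifest (CSV or JSON) and all referenced masks.

    Mask paths are resolved relative to the manifest's directory. Rows with
    an empty ``preop_path`` yield cases without a preoperative mask; they are
    eligible for the clinical rule only. Row numbering in error messages is
    1-based over data rows.
    """
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    rows = _load_rows(path)
    if not rows:
        raise ValidationError(f"{path}: manifest contains no cases")

    cases: list[PatientCase] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        missing = [k for k in _REQUIRED_FIELDS if k not in row]
        if missing:
            raise ValidationError(f"manifest row {i}: missing fields {missing}")
        case_id = str(row["case_id"]).strip()
        if not case_id:
            raise ValidationError(f"manifest row {i}: empty case_id")
        if case_id in seen:
            raise ValidationError(f"manifest row {i}: duplicate case_id {case_id!r}")
        seen.add(case_id)

        token = str(row["histology"]).strip().lower()
        try:
            histology = Histology(token)
        except ValueError:
            valid = ", ".join(h.value for h in Histology)
            raise ValidationError(
                f"manifest row {i} (case {case_id}): unknown histology {token!r}; "
                f"expected one of: {valid}"
            ) from None

        def resolve(p: object) -> str:
            p = str(p).strip()
            return p if os.path.isabs(p) else os.path.join(base, p)

        preop_path = str(row["preop_path"] or "").strip()
        preoperative = read_label_volume(resolve(preop_path)) if preop_path else None
        cases.append(
            PatientCase(
                case_id=case_id,
                preoperative=preoperative,
                pre_transformation=read_label_volume(resolve(row["pretransform_path"])),
                transformation=read_label_volume(resolve(row["transform_path"])),
                histology=histology,
                prior_resection=_parse_flag(row["prior_resection"], i, "prior_resection"),
                prior_chemo=_parse_flag(row["prior_chemo"], i, "prior_chemo"),
                prior_rt=_parse_flag(row["prior_rt"], i, "prior_rt"),
            )
        )
    return cases
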