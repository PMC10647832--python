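"""Data model and readers/writers for mpMRI studies, masks and cohort tables.

One *study* is a single mpMRI exam: three co-registered sequences
(T2-weighted ``t2``, apparent diffusion coefficient ``adc``, high b-value
``b``) on one voxel grid, plus a set of binary regions of interest.  ROI
roles follow the field's naming: the lesion (``L``), normally-appearing
peripheral and transition zone (``NAPZ``/``NATZ``), and the reference
tissues used for intensity normalization (gluteus maximus ``GM``,
``femoral_head``, ``bladder``).

Volumes and masks are stored as NIfTI (via :mod:`nibabel`); per-lesion
clinical and genomic records travel in a flat CSV cohort table.  No
resampling or registration is performed — every mask must share its
study's grid exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SEQUENCES: tuple[str, ...] = ("t2", "adc", "b")
MASK_ROLES: tuple[str, ...] = ("L", "NAPZ", "NATZ", "GM", "femoral_head", "bladder")
REFERENCE_ROLES: tuple[str, ...] = ("GM", "femoral_head", "bladder")

#: clinical T stages in increasing order of extent
T_STAGES: tuple[str, ...] = (
    "T1", "T1a", "T1b", "T1c",
    "T2", "T2a", "T2b", "T2c",
    "T3", "T3a", "T3b", "T4",
)


class StudyLayoutError(ValueError):
    """A study on disk is inconsistent (missing sequence, shape mismatch...)."""


class CohortValidationError(ValueError):
    """A cohort-table row fails validation; the message names the row."""


@dataclass
class VolumeGrid:
    """One MRI sequence as a 3D scalar field with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    sequence: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.sequence not in SEQUENCES:
            raise ValueError(f"unknown sequence {self.sequence!r}, expected one of {SEQUENCES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"volume ({self.sequence}) contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class RoiMask:
    """A binary region of interest aligned to a study grid."""

    mask: np.ndarray
    role: str
    lesion_id: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}, expected one of {MASK_ROLES}")
        if self.lesion_id is not None:
            self.lesion_id = str(self.lesion_id)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def key(self) -> str:
        return self.role if self.lesion_id is None else f"{self.role}_{self.lesion_id}"


@dataclass
class MpmriStudy:
    """Co-registered t2/adc/b volumes plus ROI and reference masks for one exam."""

    patient_id: str
    exam_id: str
    volumes: dict[str, VolumeGrid]
    masks: list[RoiMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in SEQUENCES if s not in self.volumes]
        if missing:
            raise StudyLayoutError(
                f"study {self.exam_id}: missing sequence(s) {missing}; "
                f"all of {SEQUENCES} are required"
            )
        shapes = {s: self.volumes[s].shape for s in SEQUENCES}
        if len(set(shapes.values())) != 1:
            raise StudyLayoutError(f"study {self.exam_id}: sequence shapes disagree: {shapes}")
        spacings = {s: self.volumes[s].spacing for s in SEQUENCES}
        if len(set(spacings.values())) != 1:
            raise StudyLayoutError(f"study {self.exam_id}: sequence spacings disagree: {spacings}")
        for m in self.masks:
            if m.mask.shape != self.shape:
                raise StudyLayoutError(
                    f"study {self.exam_id}: mask {m.key} shape {m.mask.shape} "
                    f"does not match grid {self.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes["t2"].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes["t2"].spacing

    def mask(self, role: str, lesion_id: str | None = None) -> RoiMask:
        """Return the unique mask with the given role (and lesion id for ``L``)."""
        hits = [
            m for m in self.masks
            if m.role == role and (lesion_id is None or m.lesion_id == str(lesion_id))
        ]
        if not hits:
            raise StudyLayoutError(f"study {self.exam_id}: no mask with role {role!r} "
                                   f"lesion_id={lesion_id!r}")
        if len(hits) > 1:
            raise StudyLayoutError(f"study {self.exam_id}: ambiguous mask query "
                                   f"role={role!r} lesion_id={lesion_id!r}")
        return hits[0]

    def lesion_masks(self) -> list[RoiMask]:
        return [m for m in self.masks if m.role == "L"]


@dataclass
class ClinicalRecord:
    """Per-lesion clinical variables.

    ``dre`` follows the three-level convention: 0 = no palpable
    abnormality, 1 = palpable abnormality, 2 = palpable abnormality
    suggestive of extraprostatic extension.  ``psad`` (PSA density,
    ng/mL/cc) may be given directly or derived from ``psa`` and
    ``prostate_volume``.
    """

    age: float
    psa: float | None = None
    prostate_volume: float | None = None
    psad: float | None = None
    dre: int = 0
    pirads: int = 3
    t_stage: str = "T1c"
    grade_group: int = 1
    pct_positive_cores: float | None = None

    def __post_init__(self) -> None:
        if self.dre not in (0, 1, 2):
            raise ValueError(f"dre must be 0, 1 or 2, got {self.dre}")
        if self.pirads not in (1, 2, 3, 4, 5):
            raise ValueError(f"pirads must be in 1..5, got {self.pirads}")
        if self.grade_group not in (1, 2, 3, 4, 5):
            raise ValueError(f"grade_group must be in 1..5, got {self.grade_group}")
        if self.t_stage not in T_STAGES:
            raise ValueError(f"unknown t_stage {self.t_stage!r}, expected one of {T_STAGES}")
        if self.psad is None:
            if self.psa is None or self.prostate_volume is None:
                raise ValueError("either psad or both psa and prostate_volume are required")
            self.psad = float(self.psa) / float(self.prostate_volume)
        elif self.psa is not None and self.prostate_volume is not None:
            implied = float(self.psa) / float(self.prostate_volume)
            if not np.isclose(implied, float(self.psad), rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"inconsistent psad: given {self.psad}, psa/volume = {implied:.6g}"
                )
        if self.pct_positive_cores is not None and not 0 <= self.pct_positive_cores <= 1:
            raise ValueError("pct_positive_cores must be a proportion in [0, 1]")

    @property
    def dre_positive(self) -> bool:
        """Dichotomized DRE per the modeling convention: 0 vs {1, 2}."""
        return self.dre > 0

    @property
    def pirads_high(self) -> bool:
        """Dichotomized PI-RADS per the modeling convention: 1–2 vs 3–5."""
        return self.pirads >= 3


@dataclass
class GenomicResult:
    """Decipher genomic-classifier score, a real in [0, 1]."""

    decipher_score: float

    def __post_init__(self) -> None:
        self.decipher_score = float(self.decipher_score)
        if not 0.0 <= self.decipher_score <= 1.0:
            raise ValueError(f"decipher_score must be in [0, 1], got {self.decipher_score}")


# ---------------------------------------------------------------------------
# NIfTI study I/O


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_study(study: MpmriStudy, out_dir: str | Path) -> Path:
    """Write a study as one NIfTI per sequence/mask plus a ``study.yaml`` layout.

    Returns the path of the layout file; :func:`read_study` accepts it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout: dict = {
        "patient_id": study.patient_id,
        "exam_id": study.exam_id,
        "spacing": list(study.spacing),
        "volumes": {},
        "masks": [],
    }
    for seq in SEQUENCES:
        vol = study.volumes[seq]
        fname = f"{seq}.nii"
        nib.save(nib.Nifti1Image(vol.values, _affine(vol.spacing)), out_dir / fname)
        layout["volumes"][seq] = fname
    for m in study.masks:
        fname = f"mask_{m.key}.nii"
        nib.save(
            nib.Nifti1Image(m.mask.astype(np.uint8), _affine(study.spacing)),
            out_dir / fname,
        )
        layout["masks"].append({"role": m.role, "lesion_id": m.lesion_id, "file": fname})
    layout_path = out_dir / "study.yaml"
    with open(layout_path, "w") as fh:
        yaml.safe_dump(layout, fh, sort_keys=False)
    logger.info("wrote study %s to %s", study.exam_id, out_dir)
    return layout_path


def read_study(layout_path: str | Path) -> MpmriStudy:
    """Read a study from a ``study.yaml`` layout written by :func:`write_study`.

    Validates shapes and spacings across sequences and masks; a mismatch
    raises :class:`StudyLayoutError` naming the offending file.
    """
    layout_path = Path(layout_path)
    if layout_path.is_dir():
        layout_path = layout_path / "study.yaml"
    with open(layout_path) as fh:
        layout = yaml.safe_load(fh)
    base = layout_path.parent
    spacing = tuple(layout["spacing"])

    volumes: dict[str, VolumeGrid] = {}
    for seq in SEQUENCES:
        if seq not in layout.get("volumes", {}):
            raise StudyLayoutError(f"{layout_path}: missing sequence {seq!r} in layout")
        img = nib.load(base / layout["volumes"][seq])
        volumes[seq] = VolumeGrid(np.asarray(img.dataobj, dtype=np.float64), spacing, seq)

    grid_shape = volumes["t2"].shape
    masks: list[RoiMask] = []
    for entry in layout.get("masks", []):
        img = nib.load(base / entry["file"])
        arr = np.asarray(img.dataobj)
        if arr.shape != grid_shape:
            raise StudyLayoutError(
                f"{entry['file']}: mask shape {arr.shape} does not match grid {grid_shape}"
            )
        masks.append(RoiMask(arr > 0, entry["role"], entry.get("lesion_id")))

    return MpmriStudy(
        patient_id=str(layout["patient_id"]),
        exam_id=str(layout["exam_id"]),
        volumes=volumes,
        masks=masks,
    )


# ---------------------------------------------------------------------------
# Cohort table I/O

#: canonical cohort-table columns (others are preserved as passthrough)
COHORT_KEY_COLUMNS = ("patient_id", "exam_id", "lesion_id")
COHORT_CLINICAL_COLUMNS = (
    "age", "psa", "prostate_volume", "psad", "dre", "pirads",
    "t_stage", "grade_group", "pct_positive_cores",
)


@dataclass
class CohortRow:
    """One lesion record from a cohort table."""

    patient_id: str
    exam_id: str
    lesion_id: str
    clinical: ClinicalRecord
    genomic: GenomicResult
    extra: dict = field(default_factory=dict)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def read_cohort_table(path: str | Path) -> list[CohortRow]:
    """Read and validate a per-lesion cohort CSV.

    Returns one :class:`CohortRow` per line; unknown columns land in
    ``extra``.  An empty file yields an empty cohort.  Out-of-range
    values raise :class:`CohortValidationError` naming the row index.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []

    known = set(COHORT_KEY_COLUMNS) | set(COHORT_CLINICAL_COLUMNS) | {"decipher_score"}
    rows: list[CohortRow] = []
    for idx, rec in df.iterrows():
        try:
            clinical = ClinicalRecord(
                age=float(rec["age"]),
                psa=_opt(rec.get("psa")),
                prostate_volume=_opt(rec.get("prostate_volume")),
                psad=_opt(rec.get("psad")),
                dre=int(rec["dre"]),
                pirads=int(rec["pirads"]),
                t_stage=str(rec.get("t_stage", "T1c")),
                grade_group=int(rec.get("grade_group", 1)),
                pct_positive_cores=_opt(rec.get("pct_positive_cores")),
            )
            genomic = GenomicResult(float(rec["decipher_score"]))
        except (ValueError, KeyError) as exc:
            raise CohortValidationError(f"{path}, row {idx}: {exc}") from exc
        extra = {c: rec[c] for c in df.columns if c not in known}
        rows.append(
            CohortRow(
                patient_id=str(rec["patient_id"]),
                exam_id=str(rec.get("exam_id", rec["patient_id"])),
                lesion_id=str(rec["lesion_id"]),
                clinical=clinical,
                genomic=genomic,
                extra=extra,
            )
        )
    logger.info("read %d cohort rows from %s", len(rows), path)
    return rows


def cohort_to_frame(rows: Iterable[CohortRow]) -> pd.DataFrame:
    """Flatten cohort rows into a DataFrame (inverse of :func:`read_cohort_table`)."""
    records = []
    for r in rows:
        rec = {
            "patient_id": r.patient_id,
            "exam_id": r.exam_id,
            "lesion_id": r.lesion_id,
            "age": r.clinical.age,
            "psa": r.clinical.psa,
            "prostate_volume": r.clinical.prostate_volume,
            "psad": r.clinical.psad,
            "dre": r.clinical.dre,
            "pirads": r.clinical.pirads,
            "t_stage": r.clinical.t_stage,
            "grade_group": r.clinical.grade_group,
            "pct_positive_cores": r.clinical.pct_positive_cores,
            "decipher_score": r.genomic.decipher_score,
        }
        rec.update(r.extra)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_cohort_table(rows: Iterable[CohortRow], path: str | Path) -> None:
    cohort_to_frame(rows).to_csv(path, index=False)
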