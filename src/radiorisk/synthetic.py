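"""Synthetic phantom mpMRI cohorts with clinical-genomic risk structure.

The real study data (mpMRI exams with biopsy-confirmed lesions, clinical
variables and Decipher genomic scores) are restricted, so this module
generates phantom cohorts that reproduce the statistical structure the
downstream analysis relies on:

* two lesion classes — low vs intermediate/high clinical-genomic risk —
  where non-low lesions have **lower T2 and ADC** signal, **higher high
  b-value** signal and **larger volume**;
* a class-dependent texture difference (smoothed in-lesion noise with a
  class-specific correlation length), giving the GLCM features a signal;
* class-correlated clinical variables — DRE positivity strongly
  enriched in non-low patients, higher PSA density and PI-RADS — and
  class-conditional Decipher scores (Beta distributed);
* reference tissues (gluteus maximus, femoral head, bladder) with
  distinct intensities, plus a random per-exam global intensity scale on
  T2W and BVAL so the normalization stage has real work to do.

Anatomy is deliberately schematic (boxes and ellipsoids): the goal is a
controllable statistical phantom, not a realistic prostate.  Clinical
variables are sampled so that the risk labels recomputed by
:mod:`radiorisk.risk` from the generated record agree with the intended
class by construction.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import binary_dilation, gaussian_filter

from radiorisk.io import (
    ClinicalRecord,
    GenomicResult,
    MpmriStudy,
    RoiMask,
    VolumeGrid,
    write_study,
)
from radiorisk.risk import (
    DecipherCategory,
    NccnGroup,
    RiskLabels,
    decipher_category,
    lesion_labels,
)

logger = logging.getLogger(__name__)

#: lesions-per-patient distribution (1..5), matching the biopsy-count
#: profile of a mixed active-surveillance / primary-treatment cohort
DEFAULT_LESION_COUNT_PROBS: dict[int, float] = {1: 0.321, 2: 0.128, 3: 0.256, 4: 0.115, 5: 0.180}

#: clean (post-normalization scale) tissue means per sequence
TISSUE_MEANS: dict[str, dict[str, float]] = {
    "t2": {"body": 180.0, "PZ": 250.0, "TZ": 210.0, "GM": 100.0,
           "femoral_head": 300.0, "bladder": 1000.0},
    "adc": {"body": 900.0, "PZ": 1500.0, "TZ": 1300.0, "GM": 700.0,
            "femoral_head": 600.0, "bladder": 2500.0},
    "b": {"body": 30.0, "PZ": 55.0, "TZ": 50.0, "GM": 100.0,
          "femoral_head": 40.0, "bladder": 20.0},
}

#: lesion shift relative to the host zone mean, common to both classes
LESION_BASE_SHIFT: dict[str, float] = {"t2": -30.0, "adc": -250.0, "b": 15.0}
#: in-lesion noise standard deviation per sequence
LESION_NOISE_SD: dict[str, float] = {"t2": 12.0, "adc": 100.0, "b": 10.0}


class CohortGenerationError(ValueError):
    """The grid cannot host the requested masks; the message names the constraint."""


@dataclass
class CohortConfig:
    """Study conditions of a phantom cohort.

    Effect sizes are mean shifts (non-low minus low class) in
    normalized intensity units; ``texture_effect`` is the extra
    Gaussian correlation length (voxels) of in-lesion noise in the
    non-low class; radii are ellipsoid semi-axes in mm.
    """

    n_patients: int = 78
    lesion_count_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_COUNT_PROBS))
    frac_low_risk: float = 0.576
    grid_shape: tuple[int, int, int] = (48, 48, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"t2": -40.0, "adc": -250.0, "b": 30.0})
    nat_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"t2": -12.0, "adc": -70.0, "b": 8.0})
    texture_effect: float = 0.8
    texture_sigma_low: float = 0.5
    radii_mm_low: tuple[tuple[float, float], tuple[float, float]] = ((3.5, 6.5), (3.2, 5.5))
    radii_mm_nonlow: tuple[tuple[float, float], tuple[float, float]] = ((4.5, 8.0), (3.4, 6.5))
    dre_positive_rate_by_class: tuple[float, float] = (0.02, 0.60)
    decipher_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (2.0, 6.0), "nonlow": (6.0, 3.0)})
    background_noise_frac: float = 0.05
    intensity_scale_range: tuple[float, float] = (0.7, 1.4)
    duplicate_exam_frac: float = 0.0
    dre_only_clinical: bool = False
    #: when dre_only_clinical is set, PI-RADS is drawn class-independently
    #: and T stage/PSA come from the low-compatible pool for every patient,
    #: leaving DRE as the only class-informative clinical variable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.frac_low_risk <= 1.0:
            raise ValueError("frac_low_risk must be in [0, 1]")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")
        if not all(0 <= p <= 1 for p in self.dre_positive_rate_by_class):
            raise ValueError("DRE rates must be probabilities")
        total = sum(self.lesion_count_probs.values())
        self.lesion_count_probs = {k: v / total for k, v in self.lesion_count_probs.items()}

    @classmethod
    def null(cls, **kwargs) -> "CohortConfig":
        """A cohort with zero planted imaging effect.

        Classes still exist (labels come from clinical/genomic draws)
        but images and lesion volumes are class-independent, so any
        image-based classifier should perform at chance.
        """
        base = cls(**kwargs)
        base.effect_sizes = {"t2": 0.0, "adc": 0.0, "b": 0.0}
        base.nat_effect_sizes = {"t2": 0.0, "adc": 0.0, "b": 0.0}
        base.texture_effect = 0.0
        base.radii_mm_nonlow = base.radii_mm_low
        return base


@dataclass
class LesionAppearance:
    """Generating parameters of one embedded lesion."""

    mean_shift: dict[str, float]
    noise_sd: dict[str, float]
    texture_sigma: float
    radii_mm: tuple[float, float, float]


@dataclass
class GroundTruth:
    """True class and generating parameters of one lesion."""

    is_low: bool
    labels: RiskLabels
    appearance: LesionAppearance | None = None


@dataclass
class LesionRecord:
    lesion_id: str
    clinical: ClinicalRecord
    genomic: GenomicResult
    truth: GroundTruth


@dataclass
class SyntheticCase:
    """One phantom exam with its per-lesion records."""

    study: MpmriStudy
    lesions: list[LesionRecord]

    @property
    def patient_is_low(self) -> bool:
        """Patient class = worst over its lesions (low only if all low)."""
        return all(rec.truth.is_low for rec in self.lesions)


# ---------------------------------------------------------------------------
# geometry helpers

def _box(shape, fx, fy, fz) -> tuple[slice, slice, slice]:
    return tuple(slice(int(round(f0 * n)), int(round(f1 * n)))
                 for (f0, f1), n in zip((fx, fy, fz), shape))


def _zone_masks(shape) -> dict[str, np.ndarray]:
    """Schematic anatomy: prostate zones plus reference-tissue blocks."""
    zones = {}
    for name, (fx, fy, fz) in {
        "prostate": ((0.26, 0.74), (0.24, 0.76), (0.26, 0.74)),
        "GM": ((0.04, 0.16), (0.04, 0.16), (0.30, 0.70)),
        "femoral_head": ((0.82, 0.95), (0.04, 0.16), (0.30, 0.70)),
        "bladder": ((0.35, 0.65), (0.80, 0.95), (0.35, 0.65)),
    }.items():
        m = np.zeros(shape, dtype=bool)
        m[_box(shape, fx, fy, fz)] = True
        zones[name] = m
    ymid = (int(round(0.24 * shape[1])) + int(round(0.76 * shape[1]))) // 2
    pz = zones["prostate"].copy(); pz[:, ymid:, :] = False
    tz = zones["prostate"].copy(); tz[:, :ymid, :] = False
    zones["PZ"], zones["TZ"] = pz, tz
    return zones


def _ellipsoid(shape, spacing, center_vox, radii_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(((g - c) * s / r) ** 2
             for g, c, s, r in zip(grids, center_vox, spacing, radii_mm))
    return d2 <= 1.0


def _place_ellipsoid(rng, zone, shape, spacing, radii_mm, forbidden,
                     container=None, n_tries=500):
    """Random ellipsoid centred in ``zone``, contained in ``container``
    (default: the zone itself), disjoint from ``forbidden``."""
    container = zone if container is None else container
    idx = np.argwhere(zone)
    if idx.size == 0:
        raise CohortGenerationError("placement zone is empty on this grid")
    for _ in range(n_tries):
        center = idx[rng.integers(len(idx))]
        mask = _ellipsoid(shape, spacing, center, radii_mm)
        if not (mask & ~container).any() and not (mask & forbidden).any():
            return mask
    raise CohortGenerationError(
        f"could not place an ellipsoid with semi-axes {tuple(radii_mm)} mm in a zone of "
        f"{len(idx)} voxels (grid {shape}, spacing {spacing}); enlarge grid_shape or "
        f"reduce lesion radii"
    )


# ---------------------------------------------------------------------------
# imaging

def embed_lesion(
    volume: VolumeGrid,
    mask: RoiMask,
    appearance: LesionAppearance,
    rng: np.random.Generator,
) -> VolumeGrid:
    """Shift and texture the in-mask voxels; everything else is untouched.

    The in-mask mean is shifted by the configured amount for the
    volume's sequence; texture is smoothed Gaussian noise (correlation
    length ``texture_sigma`` voxels) renormalized to zero mean and the
    configured SD over the mask.
    """
    if mask.n_voxels == 0:
        raise ValueError("embed_lesion requires a non-empty mask")
    seq = volume.sequence
    shift = appearance.mean_shift.get(seq, 0.0)
    noise_sd = appearance.noise_sd.get(seq, 0.0)
    values = volume.values.copy()
    if noise_sd > 0:
        noise = rng.standard_normal(volume.shape)
        if appearance.texture_sigma > 0:
            noise = gaussian_filter(noise, appearance.texture_sigma)
        sub = noise[mask.mask]
        sd = sub.std()
        noise_term = (sub - sub.mean()) / sd * noise_sd if sd > 0 else 0.0
    else:
        noise_term = 0.0
    values[mask.mask] += shift + noise_term
    return VolumeGrid(values, volume.spacing, seq)


def _background_volumes(rng, config: CohortConfig, zones) -> dict[str, VolumeGrid]:
    vols = {}
    for seq, means in TISSUE_MEANS.items():
        vals = np.full(config.grid_shape, means["body"])
        for tissue in ("PZ", "TZ", "GM", "femoral_head", "bladder"):
            vals[zones[tissue]] = means[tissue]
        vals += rng.standard_normal(config.grid_shape) * (
            config.background_noise_frac * np.abs(vals))
        vals = np.clip(vals, 0.1, None)
        vols[seq] = VolumeGrid(vals, config.voxel_spacing, seq)
    return vols


# ---------------------------------------------------------------------------
# clinical / genomic sampling

def _draw_decipher(rng, cls_low: bool, config: CohortConfig,
                   allowed: set[DecipherCategory]) -> float:
    a, b = config.decipher_params["low" if cls_low else "nonlow"]
    for _ in range(50):
        score = float(np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6))
        if decipher_category(score) in allowed:
            return score
    # clamp into the most probable allowed category for this class
    target = min(allowed) if cls_low else max(allowed)
    lo, hi = [(0.02, 0.44), (0.45, 0.595), (0.60, 0.97)][int(target)]
    return float(rng.uniform(lo, hi))


def _patient_stage_psa(rng, any_low: bool) -> tuple[str, float]:
    """Patient T stage and PSA, compatible with hosting a low-risk lesion."""
    if any_low:
        u = rng.random()
        if u < 0.60:
            return ("T1c" if rng.random() < 0.8 else "T2a"), float(rng.uniform(2.5, 9.5))
        if u < 0.85:
            return ("T1c" if rng.random() < 0.7 else "T2a"), float(rng.uniform(10.0, 19.5))
        return "T2b", float(rng.uniform(2.5, 9.5))
    u = rng.random()
    if u < 0.35:
        return ("T1c" if rng.random() < 0.7 else "T2a"), float(rng.uniform(2.5, 9.5))
    if u < 0.55:
        return ("T2b" if rng.random() < 0.6 else "T2c"), float(rng.uniform(4.0, 18.0))
    if u < 0.80:
        return ("T2a" if rng.random() < 0.5 else "T2c"), float(rng.uniform(10.0, 25.0))
    return ("T3a" if rng.random() < 0.7 else "T3b"), float(rng.uniform(6.0, 60.0))


def _choice(rng, options: dict) -> object:
    keys = list(options)
    probs = np.array([options[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _floor_group(t_stage: str, psa: float, age: float, vol: float) -> NccnGroup:
    from radiorisk.risk import nccn_group
    return nccn_group(ClinicalRecord(age=age, psa=psa, prostate_volume=vol,
                                     t_stage=t_stage, grade_group=1))


def _sample_lesion(rng, cls_low, config, age, psa, prostate_volume, t_stage,
                   dre, pirads_probs) -> tuple[ClinicalRecord, GenomicResult, RiskLabels]:
    floor = _floor_group(t_stage, psa, age, prostate_volume)

    if cls_low:
        allowed = {DecipherCategory.LOW}
        if floor == NccnGroup.LOW:
            allowed.add(DecipherCategory.INTERMEDIATE)
        score = _draw_decipher(rng, True, config, allowed)
        dec = decipher_category(score)
        if dec == DecipherCategory.INTERMEDIATE:
            gg = 1
        elif floor == NccnGroup.LOW:
            gg = _choice(rng, {1: 0.7, 2: 0.3})
        elif floor == NccnGroup.FAVORABLE_INTERMEDIATE:
            gg = _choice(rng, {1: 0.5, 2: 0.3, 3: 0.2})
        else:  # unfavorable floor: cell (unfav, low) is still low risk
            gg = 1
    else:
        score = _draw_decipher(rng, False, config,
                               {DecipherCategory.LOW, DecipherCategory.INTERMEDIATE,
                                DecipherCategory.HIGH})
        dec = decipher_category(score)
        if dec == DecipherCategory.LOW and floor < NccnGroup.HIGH_OR_VERY_HIGH:
            gg = _choice(rng, {4: 0.6, 5: 0.4})
        elif dec == DecipherCategory.INTERMEDIATE and floor == NccnGroup.LOW:
            gg = _choice(rng, {2: 0.45, 3: 0.35, 4: 0.12, 5: 0.08})
        else:
            gg = _choice(rng, {1: 0.25, 2: 0.25, 3: 0.2, 4: 0.18, 5: 0.12})

    record = ClinicalRecord(age=age, psa=psa, prostate_volume=prostate_volume,
                            dre=dre, pirads=int(_choice(rng, pirads_probs)),
                            t_stage=t_stage, grade_group=int(gg))
    from radiorisk.risk import nccn_group as _nccn
    if _nccn(record) == NccnGroup.FAVORABLE_INTERMEDIATE:
        record.pct_positive_cores = float(rng.uniform(0.05, 0.45))
    labels = lesion_labels(record, score)
    if labels.low_risk != cls_low:
        raise AssertionError(
            f"internal sampling error: intended class low={cls_low} but labels {labels}")
    return record, GenomicResult(score), labels


PIRADS_PROBS_LOW = {1: 0.15, 2: 0.25, 3: 0.25, 4: 0.25, 5: 0.10}
PIRADS_PROBS_NONLOW = {1: 0.02, 2: 0.08, 3: 0.15, 4: 0.35, 5: 0.40}


# ---------------------------------------------------------------------------
# cohort generation

def _generate_exam(rng, config: CohortConfig, patient_id: str, exam_id: str,
                   classes: list[bool], shared_clinical=None) -> SyntheticCase:
    zones = _zone_masks(config.grid_shape)
    volumes = _background_volumes(rng, config, zones)

    if shared_clinical is None:
        any_low = any(classes)
        patient_low = all(classes)
        age = float(np.clip(rng.normal(65.0, 8.0), 44.0, 82.0))
        prostate_volume = float(np.clip(rng.normal(45.0, 12.0), 20.0, 90.0))
        t_stage, psa = _patient_stage_psa(
            rng, any_low or config.dre_only_clinical)
        dre_rate = config.dre_positive_rate_by_class[0 if patient_low else 1]
        dre = 0 if rng.random() >= dre_rate else (1 if rng.random() < 0.75 else 2)
    else:
        age, prostate_volume, t_stage, psa, dre = shared_clinical
        patient_low = all(classes)

    occupied = np.zeros(config.grid_shape, dtype=bool)
    masks: list[RoiMask] = []
    records: list[LesionRecord] = []
    for i, cls_low in enumerate(classes, start=1):
        (rxy, rz) = config.radii_mm_low if cls_low else config.radii_mm_nonlow
        radii = (float(rng.uniform(*rxy)), float(rng.uniform(*rxy)), float(rng.uniform(*rz)))
        zone = zones["PZ"] if rng.random() < 0.75 else zones["TZ"]
        lesion_mask = _place_ellipsoid(
            rng, zone, config.grid_shape, config.voxel_spacing, radii,
            forbidden=binary_dilation(occupied), container=zones["prostate"])
        occupied |= lesion_mask
        roi = RoiMask(lesion_mask, "L", str(i))
        masks.append(roi)

        shift = {
            seq: LESION_BASE_SHIFT[seq]
            + (0.0 if cls_low else config.effect_sizes.get(seq, 0.0))
            for seq in volumes
        }
        sigma = config.texture_sigma_low + (0.0 if cls_low else config.texture_effect)
        appearance = LesionAppearance(shift, dict(LESION_NOISE_SD), sigma, radii)
        for seq in volumes:
            volumes[seq] = embed_lesion(volumes[seq], roi, appearance, rng)

        pirads_probs = (PIRADS_PROBS_LOW if (cls_low or config.dre_only_clinical)
                        else PIRADS_PROBS_NONLOW)
        clin, genomic, labels = _sample_lesion(
            rng, cls_low, config, age, psa, prostate_volume, t_stage, dre,
            pirads_probs)
        records.append(LesionRecord(str(i), clin, genomic,
                                    GroundTruth(cls_low, labels, appearance)))

    # normally-appearing tissue ROIs, disjoint from (dilated) lesions
    forbidden = binary_dilation(occupied)
    nat_masks = {}
    for role, zone_name in (("NAPZ", "PZ"), ("NATZ", "TZ")):
        radii = (float(rng.uniform(3.8, 5.2)), float(rng.uniform(3.8, 5.2)),
                 float(rng.uniform(3.3, 4.2)))
        m = _place_ellipsoid(rng, zones[zone_name], config.grid_shape,
                             config.voxel_spacing, radii, forbidden)
        nat_masks[role] = RoiMask(m, role)
        masks.append(nat_masks[role])

    # field effect in normally-appearing tissue for non-low patients
    if not patient_low and any(v != 0 for v in config.nat_effect_sizes.values()):
        nat_app = LesionAppearance(dict(config.nat_effect_sizes),
                                   {s: 0.3 * LESION_NOISE_SD[s] for s in LESION_NOISE_SD},
                                   config.texture_sigma_low, (0, 0, 0))
        for role in ("NAPZ", "NATZ"):
            for seq in volumes:
                volumes[seq] = embed_lesion(volumes[seq], nat_masks[role], nat_app, rng)

    for role in ("GM", "femoral_head", "bladder"):
        masks.append(RoiMask(zones[role], role))

    # arbitrary scanner scaling on the non-quantitative sequences
    s_t2 = float(rng.uniform(*config.intensity_scale_range))
    s_b = float(rng.uniform(*config.intensity_scale_range))
    volumes["t2"] = VolumeGrid(volumes["t2"].values * s_t2, config.voxel_spacing, "t2")
    volumes["b"] = VolumeGrid(volumes["b"].values * s_b, config.voxel_spacing, "b")

    study = MpmriStudy(patient_id, exam_id, volumes, masks)
    return SyntheticCase(study, records)


def generate_cohort(config: CohortConfig) -> list[SyntheticCase]:
    """Generate a phantom cohort; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    counts = sorted(config.lesion_count_probs)
    probs = np.array([config.lesion_count_probs[c] for c in counts])
    cases: list[SyntheticCase] = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:04d}"
        n_lesions = int(counts[rng.choice(len(counts), p=probs)])
        classes = [bool(rng.random() < config.frac_low_risk) for _ in range(n_lesions)]
        # crowded multi-lesion exams can defeat a single placement pass;
        # retry with fresh (still seeded) randomness before giving up
        for attempt in range(5):
            try:
                case = _generate_exam(rng, config, pid, f"{pid}_E1", classes)
                break
            except CohortGenerationError:
                if attempt == 4:
                    raise
        cases.append(case)
        if config.duplicate_exam_frac > 0 and rng.random() < config.duplicate_exam_frac:
            shared = (case.lesions[0].clinical.age, case.lesions[0].clinical.prostate_volume,
                      case.lesions[0].clinical.t_stage, case.lesions[0].clinical.psa,
                      case.lesions[0].clinical.dre)
            cases.append(_generate_exam(rng, config, pid, f"{pid}_E2", classes,
                                        shared_clinical=shared))
    n_low = sum(r.truth.is_low for c in cases for r in c.lesions)
    n_all = sum(len(c.lesions) for c in cases)
    logger.info("generated %d exams, %d lesions (%d low risk)", len(cases), n_all, n_low)
    return cases


def cohort_table(cases: list[SyntheticCase]) -> pd.DataFrame:
    """Flat per-lesion table with clinical fields, Decipher score and ground truth."""
    rows = []
    for case in cases:
        for rec in case.lesions:
            c = rec.clinical
            rows.append({
                "patient_id": case.study.patient_id,
                "exam_id": case.study.exam_id,
                "lesion_id": rec.lesion_id,
                "age": c.age, "psa": c.psa, "prostate_volume": c.prostate_volume,
                "psad": c.psad, "dre": c.dre, "pirads": c.pirads,
                "t_stage": c.t_stage, "grade_group": c.grade_group,
                "pct_positive_cores": c.pct_positive_cores,
                "decipher_score": rec.genomic.decipher_score,
                "true_low": rec.truth.is_low,
                "true_three_tier": int(rec.truth.labels.three_tier),
                "true_spratt_numeric": rec.truth.labels.spratt_numeric,
                "patient_true_low": case.patient_is_low,
            })
    return pd.DataFrame(rows)


def write_cohort(cases: list[SyntheticCase], config: CohortConfig,
                 out_dir: str | Path) -> Path:
    """Write a cohort to disk: NIfTI studies, cohort CSV and config YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_study(case.study, out_dir / "studies" / case.study.exam_id)
    table_path = out_dir / "cohort.csv"
    cohort_table(cases).to_csv(table_path, index=False)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    return table_path
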