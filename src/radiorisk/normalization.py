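"""Reference-tissue intensity normalization for T2-weighted and high b-value MRI.

MRI signal intensity has no absolute scale, so cross-exam comparability
requires mapping each exam onto a common intensity frame.  Two schemes
are implemented:

* **T2-weighted**: a multireference approach.  Mean intensities are
  measured inside three reference tissues that span the dynamic range —
  gluteus maximus (dark), femoral head (intermediate), bladder (bright)
  — and a monotone spline is fitted through ``(0, 0)`` and the three
  (measured mean, target) pairs, then applied voxel-wise.  Beyond the
  brightest knot the map continues linearly with the spline's end slope.
* **High b-value**: a single-reference rescale by the gluteus maximus
  mean, the only reference tissue reliably visible on b-value images.

ADC maps are physical quantities (diffusion coefficients) and are used
in native units; no normalization is applied to them.

Both maps are monotone non-decreasing, fix every reference tissue's mean
to its target exactly, and are idempotent: re-normalizing a normalized
volume changes nothing (to floating tolerance), because the re-measured
means already sit on the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from radiorisk.io import MpmriStudy, RoiMask, VolumeGrid

#: default T2W reference targets; arbitrary but fixed units spanning the
#: dark→bright range (GM < femoral head < bladder)
DEFAULT_T2_TARGETS: dict[str, float] = {"GM": 100.0, "femoral_head": 300.0, "bladder": 1000.0}
#: default b-value target for the gluteus maximus mean
DEFAULT_B_TARGET: float = 100.0


class NormalizationError(ValueError):
    """Reference masks empty or measured means unusable for a monotone map."""


@dataclass
class ReferenceTargets:
    """Fixed reference values the tissue means are mapped onto.

    ``t2`` lists (tissue role, target) pairs whose targets must be
    strictly increasing; ``b`` is the single GM target.
    """

    t2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_T2_TARGETS))
    b: float = DEFAULT_B_TARGET

    def __post_init__(self) -> None:
        vals = list(self.t2.values())
        if any(v <= 0 for v in vals) or self.b <= 0:
            raise ValueError("all reference targets must be positive")
        ordered = sorted(self.t2.items(), key=lambda kv: kv[1])
        if any(a[1] >= b[1] for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"t2 targets must be strictly increasing, got {self.t2}")


def _mask_mean(volume: VolumeGrid, mask: RoiMask) -> float:
    if mask.n_voxels == 0:
        raise NormalizationError(f"reference mask {mask.key!r} is empty")
    return float(volume.values[mask.mask].mean())


def _monotone_map(knots_x: np.ndarray, knots_y: np.ndarray, mode: str):
    """Build a monotone map through the knots, linear beyond the last one.

    ``mode='pchip'`` uses a monotone piecewise-cubic interpolant (exact on
    collinear knots, hence idempotent); ``mode='linear'`` is a
    piecewise-linear fallback with hand-checkable arithmetic.
    """
    if mode == "linear":
        def f(x: np.ndarray) -> np.ndarray:
            return np.interp(x, knots_x, knots_y) + np.where(
                x > knots_x[-1],
                (x - knots_x[-1])
                * (knots_y[-1] - knots_y[-2]) / (knots_x[-1] - knots_x[-2]),
                0.0,
            )
        return f
    if mode == "pchip":
        interp = PchipInterpolator(knots_x, knots_y, extrapolate=False)
        end_slope = float(interp.derivative()(knots_x[-1]))

        def f(x: np.ndarray) -> np.ndarray:
            out = interp(np.clip(x, knots_x[0], knots_x[-1]))
            return np.where(x > knots_x[-1],
                            knots_y[-1] + (x - knots_x[-1]) * end_slope, out)
        return f
    raise ValueError(f"unknown spline mode {mode!r}; use 'pchip' or 'linear'")


def normalize_t2(
    volume: VolumeGrid,
    reference_masks: dict[str, RoiMask],
    targets: ReferenceTargets | None = None,
    mode: str = "pchip",
) -> VolumeGrid:
    """Normalize a T2-weighted volume against three reference tissues.

    A monotone interpolating map through ``(0, 0)`` and the three
    (measured mean, target) knots is applied voxel-wise.  Negative input
    intensities are clamped to 0 first (magnitudes below the zero anchor
    are physically meaningless).

    Because the map is nonlinear, one pass fixes the knots but only
    approximately fixes the (noisy) tissue *means*; a short correction
    loop re-measures the means and composes further monotone maps until
    every reference mean sits on its target to 1e-12 relative, which
    also makes the whole operation idempotent.

    Raises
    ------
    NormalizationError
        If a reference mask is empty or the measured means do not
        increase in the same order as the targets (the map would not be
        single-valued); the message names the colliding tissues.
    """
    targets = targets or ReferenceTargets()
    pairs = sorted(targets.t2.items(), key=lambda kv: kv[1])
    roles = [role for role, _ in pairs]
    missing = [r for r in roles if r not in reference_masks]
    if missing:
        raise NormalizationError(f"missing reference mask(s) {missing} for t2 normalization")
    target_vals = np.array([t for _, t in pairs])

    values = np.clip(volume.values, 0.0, None)
    out = VolumeGrid(values, volume.spacing, volume.sequence)
    for iteration in range(50):
        measured = np.array([_mask_mean(out, reference_masks[r]) for r in roles])
        bad = np.flatnonzero(np.diff(measured) <= 0)
        if bad.size:
            collide = ", ".join(f"{roles[i]} (mean {measured[i]:.4g}) vs "
                                f"{roles[i + 1]} (mean {measured[i + 1]:.4g})" for i in bad)
            raise NormalizationError(
                "measured reference means are not strictly increasing in target "
                f"order: {collide}"
            )
        if measured[0] <= 0:
            raise NormalizationError(
                f"reference mean for {roles[0]} must be positive, got {measured[0]:.4g}"
            )
        if iteration > 0 and np.max(np.abs(measured / target_vals - 1.0)) < 1e-12:
            break
        f = _monotone_map(np.concatenate([[0.0], measured]),
                          np.concatenate([[0.0], target_vals]), mode)
        out = VolumeGrid(f(out.values), volume.spacing, volume.sequence)
    return out


def normalize_b(
    volume: VolumeGrid,
    gm_mask: RoiMask,
    gm_target: float = DEFAULT_B_TARGET,
) -> VolumeGrid:
    """Normalize a high b-value volume so the gluteus maximus mean equals the target."""
    gm_mean = _mask_mean(volume, gm_mask)
    if gm_mean <= 0:
        raise NormalizationError(f"GM mean must be positive for b normalization, got {gm_mean:.4g}")
    return VolumeGrid(volume.values * (gm_target / gm_mean), volume.spacing, volume.sequence)


def normalize_study(
    study: MpmriStudy,
    targets: ReferenceTargets | None = None,
    mode: str = "pchip",
) -> MpmriStudy:
    """Apply the per-sequence normalization to a whole study.

    T2W is spline-normalized against GM/femoral head/bladder, BVAL is
    rescaled by GM, and ADC passes through unchanged.
    """
    targets = targets or ReferenceTargets()
    refs = {r: study.mask(r) for r in ("GM", "femoral_head", "bladder")}
    volumes = {
        "t2": normalize_t2(study.volumes["t2"], refs, targets, mode=mode),
        "adc": study.volumes["adc"],
        "b": normalize_b(study.volumes["b"], refs["GM"], targets.b),
    }
    return MpmriStudy(study.patient_id, study.exam_id, volumes, study.masks)
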