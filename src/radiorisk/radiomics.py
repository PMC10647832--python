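"""First- and second-order radiomic features for mpMRI regions of interest.

The signature comprises, per ROI role (lesion ``L``, ``NAPZ``, ``NATZ``)
and per sequence (``t2``, ``adc``, ``b``):

* first-order **intensity** (``int``) statistics of the in-ROI voxel
  values, and
* five **Haralick texture** families — contrast (``con``), correlation
  (``cor``), energy (``ene``), entropy (``ent``), homogeneity (``hom``)
  — computed voxel-wise in 3D: a 5x5x5 window centred on each ROI voxel
  is rescaled locally to 0–255, a 128-bin grey-level co-occurrence
  matrix (GLCM) is accumulated over the 13 unit directions, and the five
  scalars are evaluated on the normalized matrix.

Each family is then summarized by nine histogram descriptors (10th/25th/
50th/75th/90th percentile, mean, SD, kurtosis, skewness), giving
3 x 6 x 9 = 162 features per ROI and 486 in total, named
``{ROI}_{sequence}_{family}_{descriptor}`` (e.g. ``L_adc_ene_90`` is the
90th percentile of the lesion's ADC energy texture map).  Tumor volume
(the ``HRS6`` surrogate, in cc) completes the 487-feature vector.

The local (per-window) rescaling, rather than a global volume
normalization, makes texture estimates comparable between tumor and
normally-appearing tissue windows with very different absolute levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from radiorisk.io import MpmriStudy, RoiMask, VolumeGrid, SEQUENCES

ROI_ROLES: tuple[str, ...] = ("L", "NAPZ", "NATZ")
#: feature families in canonical order: intensity first, then textures
FEATURE_FAMILIES: tuple[str, ...] = ("int", "con", "cor", "ene", "ent", "hom")
TEXTURE_FAMILIES: tuple[str, ...] = ("con", "cor", "ene", "ent", "hom")
DESCRIPTORS: tuple[str, ...] = ("10", "25", "50", "75", "90", "mean", "SD", "Kur", "Ske")
PERCENTILES: tuple[float, ...] = (10, 25, 50, 75, 90)

HRS6_NAME = "HRS6"


def _unit_offsets_3d() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique 3D direction classes at chessboard distance 1."""
    offsets = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        if off > tuple(-o for o in off):  # keep one representative per ± pair
            offsets.append(off)
    return tuple(offsets)


OFFSETS_13: tuple[tuple[int, int, int], ...] = _unit_offsets_3d()


@dataclass(frozen=True)
class TextureParams:
    """Conventions of the texture computation, recorded for provenance."""

    window_size: int = 5
    n_levels: int = 256     # local rescale range is [0, n_levels - 1]
    n_bins: int = 128       # bin = level // (n_levels // n_bins)
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13
    symmetric: bool = True
    entropy_base: float | None = None  # None = natural log
    min_roi_voxels: int = 10

    def __post_init__(self) -> None:
        if self.window_size % 2 != 1 or self.window_size < 3:
            raise ValueError("window_size must be an odd integer >= 3")
        if self.n_levels % self.n_bins != 0:
            raise ValueError("n_bins must divide n_levels evenly")
        if not self.offsets:
            raise ValueError("offset set must be non-empty")


@dataclass
class DescriptorSet:
    """The nine histogram descriptors of one sample of values."""

    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    mean: float
    sd: float
    kurtosis: float
    skewness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "10": self.p10, "25": self.p25, "50": self.p50,
            "75": self.p75, "90": self.p90, "mean": self.mean,
            "SD": self.sd, "Kur": self.kurtosis, "Ske": self.skewness,
        }


@dataclass
class GlcmMatrix:
    """A normalized grey-level co-occurrence matrix."""

    matrix: np.ndarray
    n_bins: int
    offsets: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (self.n_bins, self.n_bins):
            raise ValueError(f"GLCM must be {self.n_bins}x{self.n_bins}, "
                             f"got {self.matrix.shape}")
        if np.any(self.matrix < 0):
            raise ValueError("GLCM entries must be non-negative")
        total = self.matrix.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"GLCM must be normalized to sum 1, got sum {total}")


def feature_names(roi: str | None = None) -> list[str]:
    """Canonical radiomic feature names in deterministic order.

    With ``roi`` given, the 162 names for that ROI role; otherwise all
    486, ordered by (ROI, sequence, family, descriptor).  ``HRS6`` is
    not included (it is a volume, not an image statistic).
    """
    rois = (roi,) if roi is not None else ROI_ROLES
    for r in rois:
        if r not in ROI_ROLES:
            raise ValueError(f"unknown ROI role {r!r}, expected one of {ROI_ROLES}")
    return [
        f"{r}_{seq}_{fam}_{desc}"
        for r in rois
        for seq in SEQUENCES
        for fam in FEATURE_FAMILIES
        for desc in DESCRIPTORS
    ]


def all_feature_names() -> list[str]:
    """The full 487-name vector: 486 radiomic features plus tumor volume."""
    return [HRS6_NAME] + feature_names()


def histogram_descriptors(values) -> DescriptorSet:
    """Summarize a sample of values by the nine histogram descriptors.

    Percentiles use linear interpolation between order statistics; SD is
    the sample (n-1) convention; kurtosis is excess kurtosis; skewness
    and kurtosis are the standardized biased moment estimators.  A
    degenerate sample (SD = 0, including n = 1) reports skewness and
    kurtosis as 0.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("histogram_descriptors requires at least one finite value")
    p10, p25, p50, p75, p90 = np.percentile(v, PERCENTILES)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, fisher=True, bias=True))
    return DescriptorSet(float(p10), float(p25), float(p50), float(p75), float(p90),
                         mean, sd, kurt, skew)


def rescale_window(window, n_levels: int = 256) -> np.ndarray:
    """Rescale a window to integer grey levels in [0, n_levels - 1].

    Min maps to 0, max to ``n_levels - 1``, affine in between, rounded
    half-away-from-zero.  A constant window maps to all zeros.  NaN
    entries (outside the image, for boundary-clipped windows) stay NaN
    in an intermediate float pass and must be filtered by the caller;
    this public entry point requires a fully finite window.
    """
    w = np.asarray(window, dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise ValueError("rescale_window requires a fully finite window")
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.zeros(w.shape, dtype=np.int64)
    scaled = (w - lo) / (hi - lo) * (n_levels - 1)
    return np.floor(scaled + 0.5).astype(np.int64)  # half-away-from-zero (values >= 0)


def glcm_3d(
    window,
    n_bins: int = 128,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13,
    n_levels: int = 256,
    symmetric: bool = True,
) -> GlcmMatrix:
    """Grey-level co-occurrence matrix of one integer window.

    Counts co-occurring bin pairs (``bin = level // (n_levels//n_bins)``)
    over all in-window voxel pairs at the given offsets, optionally
    symmetrized, normalized to sum 1.
    """
    if not offsets:
        raise ValueError("offset set must be non-empty")
    w = np.asarray(window)
    if w.ndim != 3:
        raise ValueError("window must be 3D")
    if np.any(w < 0) or np.any(w > n_levels - 1):
        raise ValueError(f"window values must be integers in [0, {n_levels - 1}]")
    step = n_levels // n_bins
    bins = np.asarray(w, dtype=np.int64) // step
    counts = np.zeros((n_bins, n_bins), dtype=np.float64)
    for off in offsets:
        src = [slice(max(-o, 0), w.shape[ax] - max(o, 0)) for ax, o in enumerate(off)]
        dst = [slice(max(o, 0), w.shape[ax] + min(o, 0)) for ax, o in enumerate(off)]
        a = bins[tuple(src)].ravel()
        b = bins[tuple(dst)].ravel()
        np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("window too small for the given offsets: no voxel pairs")
    return GlcmMatrix(counts / total, n_bins, tuple(offsets))


def haralick_features(glcm: GlcmMatrix, entropy_base: float | None = None) -> dict[str, float]:
    """The five Haralick scalars of a normalized GLCM.

    energy = sum p^2; entropy = -sum p log p (natural log by default);
    contrast = sum (i-j)^2 p; homogeneity = sum p / (1 + (i-j)^2);
    correlation = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j), defined as
    0 when either marginal variance is zero (e.g. a constant window).
    """
    p = glcm.matrix
    n = glcm.n_bins
    idx = np.arange(n, dtype=np.float64)
    energy = float((p ** 2).sum())
    pos = p[p > 0]
    entropy = float(-(pos * np.log(pos)).sum())
    if entropy_base is not None:
        entropy /= np.log(entropy_base)
    d = idx[:, None] - idx[None, :]
    contrast = float((d ** 2 * p).sum())
    homogeneity = float((p / (1.0 + d ** 2)).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i, mu_j = float(pi @ idx), float(pj @ idx)
    var_i = float(pi @ idx ** 2) - mu_i ** 2
    var_j = float(pj @ idx ** 2) - mu_j ** 2
    if var_i <= 1e-12 or var_j <= 1e-12:
        correlation = 0.0
    else:
        cov = float((idx[:, None] * idx[None, :] * p).sum()) - mu_i * mu_j
        correlation = cov / np.sqrt(var_i * var_j)
    return {
        "ene": energy, "ent": entropy, "con": contrast,
        "hom": homogeneity, "cor": correlation,
    }


# ---------------------------------------------------------------------------
# Vectorized voxel-wise texture maps

def _texture_values(
    values: np.ndarray,
    roi: np.ndarray,
    params: TextureParams,
    chunk: int = 256,
) -> dict[str, np.ndarray]:
    """Five texture values for every ROI voxel (1D arrays, ROI order).

    Windows are clipped at image boundaries: out-of-image entries are
    excluded from both the local rescale and the pair counts.  Each
    window's result matches ``haralick_features(glcm_3d(rescale_window(w)))``
    on its in-image voxels.

    The GLCM is never materialized: moment features (contrast,
    homogeneity, correlation) are accumulated directly over the bin
    pairs, and the count-distribution features (energy, entropy) come
    from a sort/run-length pass over the joint pair codes.
    """
    w = params.window_size
    half = w // 2
    nb = params.n_bins
    step = params.n_levels // params.n_bins
    padded = np.pad(values.astype(np.float64), half, constant_values=np.nan)
    windows = sliding_window_view(padded, (w, w, w))
    sel = windows[roi]                      # (nvox, w, w, w)
    nvox = sel.shape[0]

    # per-offset index slices within a w^3 window
    pair_slices = []
    for off in params.offsets:
        src = tuple(slice(max(-o, 0), w - max(o, 0)) for o in off)
        dst = tuple(slice(max(o, 0), w + min(o, 0)) for o in off)
        pair_slices.append((src, dst))

    stride = nb * nb + 1                    # one slot past the largest joint code
    sentinel = nb * nb                      # joint code for invalid (clipped) pairs
    log_base = np.log(params.entropy_base) if params.entropy_base else 1.0

    out = {fam: np.empty(nvox) for fam in TEXTURE_FAMILIES}
    for start in range(0, nvox, chunk):
        win = sel[start:start + chunk]      # (c, w, w, w)
        c = win.shape[0]
        valid = np.isfinite(win)
        lo = np.nanmin(win, axis=(1, 2, 3), keepdims=True)
        hi = np.nanmax(win, axis=(1, 2, 3), keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(span > 0, (win - lo) / span * (params.n_levels - 1), 0.0)
        levels = np.floor(scaled + 0.5)
        bins = np.where(valid, levels // step, -1).astype(np.int64)

        a_parts, b_parts = [], []
        for src, dst in pair_slices:
            a_parts.append(bins[(slice(None),) + src].reshape(c, -1))
            b_parts.append(bins[(slice(None),) + dst].reshape(c, -1))
        a = np.concatenate(a_parts, axis=1)  # (c, P) one entry per unordered pair
        b = np.concatenate(b_parts, axis=1)
        ok = (a >= 0) & (b >= 0)
        n1 = ok.sum(axis=1).astype(np.float64)   # unordered pair count per voxel

        # moment features directly from the (symmetrized) pair distribution
        af = np.where(ok, a, 0).astype(np.float64)
        bf = np.where(ok, b, 0).astype(np.float64)
        diff2 = np.where(ok, (af - bf) ** 2, 0.0)
        out["con"][start:start + c] = diff2.sum(axis=1) / n1
        out["hom"][start:start + c] = np.where(ok, 1.0 / (1.0 + diff2), 0.0).sum(axis=1) / n1
        mu = (af + bf).sum(axis=1) / (2.0 * n1)
        e_i2 = (af ** 2 + bf ** 2).sum(axis=1) / (2.0 * n1)
        var = e_i2 - mu ** 2
        e_ij = (af * bf).sum(axis=1) / n1
        with np.errstate(invalid="ignore", divide="ignore"):
            out["cor"][start:start + c] = np.where(var > 1e-12, (e_ij - mu ** 2) / var, 0.0)

        # count-distribution features via sorted run-length encoding of the
        # ordered (symmetrized) joint codes, tagged by voxel row
        if params.symmetric:
            joint = np.concatenate(
                [np.where(ok, a * nb + b, sentinel), np.where(ok, b * nb + a, sentinel)],
                axis=1,
            )
        else:
            joint = np.where(ok, a * nb + b, sentinel)
        n_ordered = joint.shape[1] - (joint == sentinel).sum(axis=1)
        flat = (joint + stride * np.arange(c, dtype=np.int64)[:, None]).ravel()
        flat.sort()
        boundaries = np.flatnonzero(np.diff(flat)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [flat.size]])
        run_val = flat[starts]
        run_cnt = (ends - starts).astype(np.float64)
        keep = run_val % stride != sentinel
        run_row = run_val[keep] // stride
        run_cnt = run_cnt[keep]
        no = n_ordered.astype(np.float64)
        sum_sq = np.bincount(run_row, weights=run_cnt ** 2, minlength=c)
        sum_clogc = np.bincount(run_row, weights=run_cnt * np.log(run_cnt), minlength=c)
        out["ene"][start:start + c] = sum_sq / no ** 2
        out["ent"][start:start + c] = (np.log(no) - sum_clogc / no) / log_base
    return out


def texture_maps(
    volume: VolumeGrid,
    roi: RoiMask,
    params: TextureParams | None = None,
) -> dict[str, np.ndarray]:
    """Voxel-wise 3D Haralick texture maps over an ROI.

    For each ROI voxel a centred window is taken from the *full* image
    (context outside the ROI is used), locally rescaled, reduced to a
    GLCM and to the five Haralick scalars.  Returns five 3D maps with
    NaN outside the ROI.
    """
    params = params or TextureParams()
    if roi.n_voxels == 0:
        raise ValueError("texture_maps requires a non-empty ROI")
    vals = _texture_values(volume.values, roi.mask, params)
    maps = {}
    for fam, v in vals.items():
        full = np.full(volume.shape, np.nan)
        full[roi.mask] = v
        maps[fam] = full
    return maps


# ---------------------------------------------------------------------------
# Feature extraction

def hrs6_volume(mask: RoiMask, spacing) -> float:
    """Tumor volume in cc: true-voxel count times voxel volume."""
    return float(mask.mask.sum()) * float(np.prod(spacing)) / 1000.0


def extract_roi_features(
    study: MpmriStudy,
    roi: RoiMask,
    role: str | None = None,
    params: TextureParams | None = None,
) -> dict[str, float]:
    """The 162 named features of one ROI on a normalized study.

    Intensity descriptors come from the raw in-ROI (normalized)
    intensities; texture descriptors from the in-ROI voxel-wise texture
    values.  ``role`` overrides the name prefix (a lesion mask always
    reports under ``L``).
    """
    params = params or TextureParams()
    role = role or roi.role
    if role not in ROI_ROLES:
        raise ValueError(f"features are defined for roles {ROI_ROLES}, got {role!r}")
    if roi.n_voxels < params.min_roi_voxels:
        raise ValueError(
            f"ROI {roi.key} has {roi.n_voxels} voxels; "
            f"minimum for feature extraction is {params.min_roi_voxels}"
        )
    features: dict[str, float] = {}
    for seq in SEQUENCES:
        volume = study.volumes[seq]
        in_roi = volume.values[roi.mask]
        fam_values = {"int": in_roi}
        fam_values.update(_texture_values(volume.values, roi.mask, params))
        for fam in FEATURE_FAMILIES:
            desc = histogram_descriptors(fam_values[fam]).as_dict()
            for d, val in desc.items():
                features[f"{role}_{seq}_{fam}_{d}"] = val
    return features


def extract_lesion_features(
    study: MpmriStudy,
    lesion_id: str | None = None,
    params: TextureParams | None = None,
) -> dict[str, float]:
    """The full 487-feature vector for one lesion of a normalized study.

    Combines the lesion's 162 features, the shared NAPZ/NATZ features
    and the tumor-volume surrogate ``HRS6`` (lesion mask volume, cc).
    """
    params = params or TextureParams()
    lesion = study.mask("L", lesion_id) if lesion_id is not None else study.mask("L")
    features: dict[str, float] = {HRS6_NAME: hrs6_volume(lesion, study.spacing)}
    features.update(extract_roi_features(study, lesion, role="L", params=params))
    for role in ("NAPZ", "NATZ"):
        features.update(extract_roi_features(study, study.mask(role), params=params))
    canonical = all_feature_names()
    return {name: features[name] for name in canonical}


def extract_study_features(
    study: MpmriStudy,
    params: TextureParams | None = None,
) -> dict[str, dict[str, float]]:
    """Per-lesion 487-feature vectors for a normalized study.

    The NAPZ/NATZ features are shared by every lesion of the exam and
    computed once.  Returns ``{lesion_id: {name: value}}``.
    """
    params = params or TextureParams()
    nat: dict[str, float] = {}
    for role in ("NAPZ", "NATZ"):
        nat.update(extract_roi_features(study, study.mask(role), params=params))
    canonical = all_feature_names()
    out: dict[str, dict[str, float]] = {}
    for lesion in study.lesion_masks():
        feats = {HRS6_NAME: hrs6_volume(lesion, study.spacing)}
        feats.update(extract_roi_features(study, lesion, role="L", params=params))
        feats.update(nat)
        out[lesion.lesion_id or "1"] = {name: feats[name] for name in canonical}
    return out
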