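"""sCT-versus-CT evaluation: intensity differences, bone overlap, surfaces.

Metrics follow the clinical-evaluation convention for synthetic CT of
metastatic bone: voxelwise mean absolute difference (MAD) and mean signed
difference (MD, sCT minus CT) within a region mask; bone extracted from
each image by a 150-HU threshold applied within the mask; the Dice
similarity coefficient (DSC) and the directed sCT-to-CT root mean square
surface distance (RMSD) on the extracted bone.  For the lesion region the
surface distance is computed within the lesion mask dilated by a 3-cm
physical margin, while MAD/MD/DSC use the undilated mask.

All distances are physical (mm), honoring anisotropic voxel spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import nan

import numpy as np
from scipy import ndimage

__all__ = [
    "EvalConfig",
    "MetricReport",
    "CohortSummary",
    "mad",
    "md",
    "extract_bone",
    "dice",
    "surface_rmsd",
    "dilate_mask",
    "evaluate_case",
    "cohort_summary",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)

METRICS = ("mad", "md", "dsc", "rmsd")
REGIONS = ("bone", "lesion")


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation parameters.

    ``bone_threshold``: HU above which (inclusive) a voxel counts as bone.
    ``lesion_margin``: physical margin (mm) added to the lesion mask for
    the surface-distance computation only.
    ``symmetric_rmsd``: use the symmetric (both-directions) surface RMSD
    instead of the default directed sCT-surface-to-CT-surface one.
    """

    bone_threshold: float = 150.0
    lesion_margin: float = 30.0
    symmetric_rmsd: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.bone_threshold):
            raise ValueError("bone_threshold must be finite")
        if self.lesion_margin < 0:
            raise ValueError("lesion_margin must be >= 0")


@dataclass(frozen=True)
class MetricReport:
    """Per-case, per-region metric values.

    ``dsc``/``rmsd`` are NaN (with ``flagged`` set) when no bone was
    extracted in the region on one side — a flagged non-numeric entry,
    never a silent 0.
    """

    case_id: str
    region: str
    mad: float
    md: float
    dsc: float
    rmsd: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if np.isfinite(self.mad) and np.isfinite(self.md) and self.mad < abs(self.md) - 1e-9:
            raise ValueError("MAD cannot be smaller than |MD|")


@dataclass(frozen=True)
class CohortSummary:
    """Per metric and region: mean, sample SD (n-1 divisor) and n."""

    mean: dict = field(default_factory=dict)  # (region, metric) -> float
    sd: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)


def _region_values(sct, ct, mask):
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    sct = np.asarray(sct, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if sct.shape != ct.shape or sct.shape != mask.shape:
        raise ValueError("sCT, CT and mask must share one grid")
    return sct[mask] - ct[mask]


def mad(sct: np.ndarray, ct: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute sCT-to-CT difference (HU) within ``mask``."""
    return float(np.mean(np.abs(_region_values(sct, ct, mask))))


def md(sct: np.ndarray, ct: np.ndarray, mask: np.ndarray) -> float:
    """Mean signed difference (HU), sCT minus CT, within ``mask``."""
    return float(np.mean(_region_values(sct, ct, mask)))


def extract_bone(volume_hu: np.ndarray, mask: np.ndarray,
                 threshold: float = 150.0) -> np.ndarray:
    """Binary bone map: voxels >= ``threshold`` HU and inside ``mask``.

    An empty result is allowed (fully lytic regions) and handled by the
    callers via flagged report entries.
    """
    return (np.asarray(volume_hu) >= threshold) & np.asarray(mask, dtype=bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly on absence: returns 1 with a warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("Dice of two empty masks: returning 1 (agreement on absence)",
                      stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _surface(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(mask, _FACE_STRUCT, border_value=0)
    return mask & ~interior


def surface_rmsd(a: np.ndarray, b: np.ndarray, spacing,
                 symmetric: bool = False) -> float:
    """Root mean square surface distance (mm) from ``a``'s surface to ``b``'s.

    Directed by default (a = sCT-derived bone, b = CT-derived bone): for
    every boundary voxel center of ``a``, the Euclidean distance to the
    nearest boundary voxel center of ``b``, root-mean-squared.  Distances
    come from an exact Euclidean distance transform of the reference
    surface, sampled with the physical spacing.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    for name, m in (("first", a), ("second", b)):
        if not m.any():
            raise ValueError(f"cannot compute a surface distance: {name} mask is empty")
    sa, sb = _surface(a), _surface(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    forward = float(np.sqrt(np.mean(dist_to_b[sa] ** 2)))
    if not symmetric:
        return forward
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    backward = float(np.sqrt(np.mean(dist_to_a[sb] ** 2)))
    # RMS over the union of both surfaces' distances.
    sq = np.concatenate([dist_to_b[sa] ** 2, dist_to_a[sb] ** 2])
    return float(np.sqrt(sq.mean()))


def dilate_mask(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """All voxels whose center lies within ``margin_mm`` of the mask.

    Physical-space dilation: with spacing (1, 1, 2) mm the extent in
    voxels along the 2-mm axis is half that of the 1-mm axes.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def evaluate_case(
    sct: np.ndarray,
    ct: np.ndarray,
    bone_mask: np.ndarray,
    lesion_mask: np.ndarray,
    spacing,
    cfg: EvalConfig | None = None,
    case_id: str = "case",
) -> tuple[MetricReport, MetricReport]:
    """Evaluate one case; returns (bone report, lesion report).

    Bone region: MAD/MD over the bone mask on raw HU; DSC and RMSD on the
    150-HU extractions within the bone mask.  Lesion region: MAD/MD/DSC on
    the lesion mask; RMSD on extractions within the lesion mask dilated by
    the 3-cm margin.  A region where either image has no extracted bone
    yields NaN DSC/RMSD with ``flagged=True``.
    """
    cfg = cfg if cfg is not None else EvalConfig()
    reports = []
    lesion_rmsd_mask = dilate_mask(lesion_mask, cfg.lesion_margin, spacing)
    for region, mask, rmsd_mask in (("bone", bone_mask, bone_mask),
                                    ("lesion", lesion_mask, lesion_rmsd_mask)):
        v_mad = mad(sct, ct, mask)
        v_md = md(sct, ct, mask)
        ext_sct = extract_bone(sct, mask, cfg.bone_threshold)
        ext_ct = extract_bone(ct, mask, cfg.bone_threshold)
        v_dsc = dice(ext_sct, ext_ct) if (ext_sct.any() or ext_ct.any()) else nan
        ext_sct_r = extract_bone(sct, rmsd_mask, cfg.bone_threshold)
        ext_ct_r = extract_bone(ct, rmsd_mask, cfg.bone_threshold)
        flagged = not (ext_sct_r.any() and ext_ct_r.any() and np.isfinite(v_dsc))
        if ext_sct_r.any() and ext_ct_r.any():
            v_rmsd = surface_rmsd(ext_sct_r, ext_ct_r, spacing, cfg.symmetric_rmsd)
        else:
            warnings.warn(f"{case_id}/{region}: no extracted bone on one side; "
                          "flagging RMSD as undefined", stacklevel=2)
            v_rmsd = nan
        reports.append(MetricReport(case_id, region, v_mad, v_md, v_dsc, v_rmsd,
                                    flagged=flagged))
    return reports[0], reports[1]


def cohort_summary(reports: list[MetricReport]) -> CohortSummary:
    """Mean and sample SD (n-1) of each metric, per region.

    Flagged/NaN entries are excluded metric-wise; with a single value the
    mean is returned and the SD is NaN (undefined).
    """
    if not reports:
        raise ValueError("no reports to summarize")
    mean: dict = {}
    sd: dict = {}
    n: dict = {}
    for region in REGIONS:
        for metric in METRICS:
            vals = np.array([getattr(r, metric) for r in reports if r.region == region],
                            dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            key = (region, metric)
            mean[key] = float(vals.mean())
            sd[key] = float(vals.std(ddof=1)) if vals.size > 1 else nan
            n[key] = int(vals.size)
    return CohortSummary(mean, sd, n)
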