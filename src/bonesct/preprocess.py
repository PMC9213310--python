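"""Intensity normalization, patch extraction and augmentation.

MR magnitudes are clipped at a per-volume percentile (default the 95th,
which suppresses hyperintense outliers such as coupling fluid in a
treatment setup) and mapped affinely to [-1, 1] with 0 -> -1.  CT is
mapped affinely from the fixed Hounsfield range [-1024, 3071] to [-1, 1];
this map is exactly invertible, which is how network outputs are returned
to HU.  Training samples are paired 24^3 patches; augmentation (random
coronal/sagittal flips and a random rotation about the feet-head axis)
acts on whole volumes before patches are cut, so no patch corners are
lost to rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "NormalizedVolume",
    "PatchPair",
    "normalize_mr",
    "normalize_ct",
    "denormalize_ct",
    "extract_patches",
    "augment",
]

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass(frozen=True)
class NormalizedVolume:
    """A volume mapped to [-1, 1] plus the record needed to invert the map.

    For MR the record is the per-volume clip value (the chosen percentile
    of the raw magnitudes); for CT it is the fixed HU range, making the
    inversion exact.
    """

    values: np.ndarray
    source: str  # "mr" | "ct"
    record: dict

    def __post_init__(self) -> None:
        if self.source not in ("mr", "ct"):
            raise ValueError("source must be 'mr' or 'ct'")
        v = self.values
        if v.size and (v.min() < -1.0 - 1e-9 or v.max() > 1.0 + 1e-9):
            raise ValueError("normalized values outside [-1, 1]")


@dataclass(frozen=True)
class PatchPair:
    """Spatially aligned (2-channel MR, 1-channel CT) cubes."""

    mr_patch: np.ndarray  # (2, s, s, s)
    ct_patch: np.ndarray  # (s, s, s)
    origin: tuple[int, int, int]

    def __post_init__(self) -> None:
        s = self.ct_patch.shape
        if self.mr_patch.shape != (2, *s):
            raise ValueError("MR and CT patches are not spatially aligned")


def normalize_mr(volume: np.ndarray, percentile: float = 95.0) -> NormalizedVolume:
    """Clip an MR magnitude volume at a per-volume percentile, map to [-1, 1].

    The percentile is computed over all voxels with linear interpolation
    between order statistics (numpy's default definition).  Values are
    clipped to [0, p] and mapped affinely with 0 -> -1 and p -> +1.
    A volume whose percentile is 0 (e.g. constant zero) is rejected:
    degenerate normalization signals corrupt input.
    """
    volume = np.asarray(volume, dtype=float)
    p = float(np.percentile(volume, percentile))
    if p <= 0.0:
        raise ValueError(
            f"the {percentile:g}th percentile is {p:g}; "
            "cannot normalize a non-positive-intensity MR volume"
        )
    clipped = np.clip(volume, 0.0, p)
    values = 2.0 * clipped / p - 1.0
    return NormalizedVolume(values, "mr", {"clip": p, "percentile": percentile})


def normalize_ct(volume: np.ndarray) -> NormalizedVolume:
    """Map HU from the fixed range [-1024, 3071] to [-1, 1] (clipping first)."""
    volume = np.asarray(volume, dtype=float)
    clipped = np.clip(volume, HU_MIN, HU_MAX)
    values = 2.0 * (clipped - HU_MIN) / (HU_MAX - HU_MIN) - 1.0
    return NormalizedVolume(values, "ct", {"hu_min": HU_MIN, "hu_max": HU_MAX})


def denormalize_ct(normalized: NormalizedVolume | np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`normalize_ct`; returns HU."""
    if isinstance(normalized, NormalizedVolume):
        if normalized.source != "ct":
            raise ValueError("denormalize_ct requires a ct-normalized volume")
        lo = normalized.record["hu_min"]
        hi = normalized.record["hu_max"]
        v = normalized.values
    else:
        lo, hi = HU_MIN, HU_MAX
        v = np.asarray(normalized, dtype=float)
    return (v + 1.0) / 2.0 * (hi - lo) + lo


def _valid_origins(shape: Sequence[int], size: int) -> tuple[int, ...]:
    spans = [n - size + 1 for n in shape]
    if any(s <= 0 for s in spans):
        raise ValueError(f"volume of shape {tuple(shape)} is smaller than a "
                         f"{size}^3 patch")
    return tuple(spans)


def extract_patches(
    mr1: NormalizedVolume,
    mr2: NormalizedVolume,
    ct: NormalizedVolume,
    bone_mask: np.ndarray,
    size: int = 24,
    n_patches: int = 32,
    bone_fraction_min: float = 0.8,
    rng: np.random.Generator | None = None,
) -> list[PatchPair]:
    """Sample paired patches at random origins.

    At least ``bone_fraction_min`` of the patches are drawn from origins
    whose window intersects ``bone_mask`` (the evaluation region is bone);
    the remainder are drawn uniformly anywhere.  Sampling is with
    replacement, so ``n_patches`` is always honored.
    """
    rng = rng if rng is not None else np.random.default_rng()
    vols = np.stack([mr1.values, mr2.values, ct.values])
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if bone_mask.shape != vols.shape[1:]:
        raise ValueError("bone mask grid differs from the volumes")
    spans = _valid_origins(vols.shape[1:], size)

    # Origins whose patch window contains at least one bone voxel, via an
    # integral image (exact sliding-window counts).
    integ = np.pad(bone_mask.astype(np.int64), ((1, 0), (1, 0), (1, 0)))
    integ = integ.cumsum(0).cumsum(1).cumsum(2)
    s = size
    counts = (integ[s:, s:, s:] - integ[:-s, s:, s:] - integ[s:, :-s, s:]
              - integ[s:, s:, :-s] + integ[:-s, :-s, s:] + integ[:-s, s:, :-s]
              + integ[s:, :-s, :-s] - integ[:-s, :-s, :-s])
    hit = np.argwhere(counts > 0)

    n_bone = int(round(n_patches * bone_fraction_min))
    if len(hit) == 0:
        n_bone = 0
    patches: list[PatchPair] = []
    for k in range(n_patches):
        if k < n_bone:
            ox, oy, oz = hit[rng.integers(len(hit))]
        else:
            ox, oy, oz = (rng.integers(s) for s in spans)
        block = vols[:, ox:ox + size, oy:oy + size, oz:oz + size]
        patches.append(PatchPair(block[:2].copy(), block[2].copy(),
                                 (int(ox), int(oy), int(oz))))
    return patches


def augment(
    mr_pair: np.ndarray,
    ct: np.ndarray,
    rng: np.random.Generator | None = None,
    masks: Sequence[np.ndarray] = (),
    max_angle_deg: float = 45.0,
    *,
    flip_sag: bool | None = None,
    flip_cor: bool | None = None,
    angle: float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Randomly flip and rotate a whole case, identically on all channels.

    With probability 1/2 each, flip the sagittal (first) and coronal
    (second) axes; then rotate by an angle drawn uniformly in
    [-max_angle_deg, +max_angle_deg] about the feet-head (last) axis.
    Images use linear interpolation, masks nearest-neighbour; the same
    transform is applied to the MR channels, the CT target and any masks,
    so everything stays voxel-aligned.

    ``mr_pair`` has shape (2, nx, ny, nz); ``ct`` (nx, ny, nz).  The
    keyword-only arguments pin individual transform components (bypassing
    the rng draw), which makes specific transforms reproducible.
    """
    mr_pair = np.asarray(mr_pair, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if mr_pair.shape[1:] != ct.shape:
        raise ValueError("MR and CT grids differ")
    if rng is None and None in (flip_sag, flip_cor, angle):
        raise ValueError("need an rng unless all transform components are pinned")
    if flip_sag is None:
        flip_sag = bool(rng.random() < 0.5)
    if flip_cor is None:
        flip_cor = bool(rng.random() < 0.5)
    if angle is None:
        angle = float(rng.uniform(-max_angle_deg, max_angle_deg))

    def _xform(vol: np.ndarray, order: int) -> np.ndarray:
        out = vol
        if flip_sag:
            out = np.flip(out, axis=0)
        if flip_cor:
            out = np.flip(out, axis=1)
        if angle != 0.0:
            out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False,
                                 order=order, mode="constant", cval=out.min() if order else 0)
        return np.ascontiguousarray(out)

    mr_out = np.stack([_xform(mr_pair[c], 1) for c in range(mr_pair.shape[0])])
    ct_out = _xform(ct, 1)
    mask_out = [_xform(np.asarray(m, dtype=float), 0).astype(bool) for m in masks]
    return mr_out, ct_out, mask_out
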