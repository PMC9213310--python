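"""Digital MR/CT bone-metastasis phantoms.

Generates paired dual-echo spoiled gradient-echo MR and CT volumes of a
stylized long bone immersed in a water bath, with osteolytic, osteoblastic
or mixed lesions, plus ground-truth bone and lesion masks.  Every
downstream stage of the pipeline (normalization, registration, training,
evaluation) can be exercised on these phantoms without any external data.

Geometry is deliberately stylized (a flared tube of cortical bone around a
cancellous ring and a marrow core, wrapped in muscle and fat): the
pipeline's acceptance surface is metric- and property-based, not
anatomical realism.

Array convention: volumes are indexed ``(x, y, z)`` with physical voxel
spacing ``(sx, sy, sz)`` in mm; the feet-head axis is the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy import ndimage

from .registration import RigidTransform, resample

__all__ = [
    "Tissue",
    "TissueProperties",
    "AcquisitionParams",
    "LesionType",
    "LesionSpec",
    "PhantomSpec",
    "PhantomCase",
    "default_tissue_table",
    "build_label_map",
    "render_ct",
    "render_mr",
    "spgr_signal",
    "apply_misalignment",
    "make_cohort",
    "COHORT_COMPOSITION",
]


class Tissue(IntEnum):
    """Integer labels used in phantom label maps."""

    WATER = 0
    FAT = 1
    MUSCLE = 2
    MARROW = 3
    CANCELLOUS = 4
    CORTICAL = 5
    LESION_LYTIC = 6
    LESION_BLASTIC = 7


class LesionType:
    OSTEOLYTIC = "osteolytic"
    OSTEOBLASTIC = "osteoblastic"
    MIXED = "mixed"
    ALL = (OSTEOLYTIC, OSTEOBLASTIC, MIXED)


#: Default lesion-type composition of a nine-case cohort, mirroring the
#: clinical cohort the pipeline emulates (2 mixed, 3 lytic, 4 blastic,
#: in the clinical case order P1..P9).
COHORT_COMPOSITION: tuple[str, ...] = (
    LesionType.MIXED,
    LesionType.MIXED,
    LesionType.OSTEOBLASTIC,
    LesionType.OSTEOLYTIC,
    LesionType.OSTEOLYTIC,
    LesionType.OSTEOBLASTIC,
    LesionType.OSTEOBLASTIC,
    LesionType.OSTEOLYTIC,
    LesionType.OSTEOBLASTIC,
)


@dataclass(frozen=True)
class TissueProperties:
    """CT and MR properties of one tissue class.

    ``hu_mean``/``hu_sd`` parameterize the CT rendering; ``proton_density``
    (relative, in [0, 1]), ``t1``/``t2_star`` (ms) and ``fat_fraction``
    parameterize the spoiled gradient-echo MR signal.
    """

    name: str
    hu_mean: float
    hu_sd: float
    proton_density: float
    t1: float
    t2_star: float
    fat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2_star <= 0:
            raise ValueError(f"tissue {self.name!r}: t1 and t2_star must be > 0")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError(f"tissue {self.name!r}: fat_fraction outside [0, 1]")
        if not 0.0 <= self.proton_density <= 1.0:
            raise ValueError(f"tissue {self.name!r}: proton_density outside [0, 1]")


def default_tissue_table() -> dict[int, TissueProperties]:
    """Default tissue parameters.

    HU means/SDs are chosen to straddle the 150-HU bone-extraction
    threshold (cortical and cancellous above; marrow, muscle, fat, water
    below).  T1/T2* values are textbook 1.5-T orders of magnitude; they are
    stand-ins chosen for realistic contrast, not claimed literature values,
    and are fully config-exposed.
    """
    return {
        int(Tissue.WATER): TissueProperties("water", 0, 10, 1.00, 3000, 200, 0.0),
        int(Tissue.FAT): TissueProperties("fat", -100, 20, 0.95, 300, 40, 0.9),
        int(Tissue.MUSCLE): TissueProperties("muscle", 40, 15, 0.80, 900, 30, 0.05),
        int(Tissue.MARROW): TissueProperties("marrow", -50, 20, 0.90, 350, 40, 0.8),
        int(Tissue.CANCELLOUS): TissueProperties("cancellous", 300, 50, 0.50, 500, 15, 0.4),
        int(Tissue.CORTICAL): TissueProperties("cortical", 1200, 50, 0.05, 1000, 1.0, 0.0),
        # Lytic lesions destroy bone and fill with soft tumour tissue;
        # blastic lesions lay down dense sclerotic bone.
        int(Tissue.LESION_LYTIC): TissueProperties("lesion_lytic", 50, 30, 0.85, 800, 60, 0.05),
        int(Tissue.LESION_BLASTIC): TissueProperties("lesion_blastic", 700, 60, 0.25, 700, 8, 0.1),
    }


@dataclass(frozen=True)
class AcquisitionParams:
    """Dual-echo radiofrequency-spoiled gradient-echo acquisition.

    Defaults reproduce the treatment sequence the pipeline emulates:
    TE1/TE2/TR = 2.1/4.2/7 ms, flip 10 deg at 1.5 T.  ``fat_water_shift``
    is the chemical-shift frequency difference (about 3.5 ppm, 220 Hz at
    1.5 T), which puts TE 2.1 ms near opposed phase and TE 4.2 ms near in
    phase.  ``noise_sd`` is the magnitude-noise SD as a fraction of the
    maximum noiseless signal.
    """

    te1: float = 2.1
    te2: float = 4.2
    tr: float = 7.0
    flip_angle: float = 10.0
    field_strength: float = 1.5
    fat_water_shift: float = 220.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.te1 < self.te2 < self.tr:
            raise ValueError("require 0 < te1 < te2 < tr")
        if not 0 < self.flip_angle < 90:
            raise ValueError("flip_angle must be in (0, 90) degrees")


@dataclass(frozen=True)
class LesionSpec:
    """One spherical metastatic lesion inside the bone.

    ``center`` is a voxel index triple; ``radius`` is in mm (physical).
    ``hu_delta`` is added to the cancellous-bone HU mean inside the lesion
    (negative for the lytic component, positive for the blastic one); for
    mixed lesions it applies to the blastic half and its negation scaled
    by ``mixed_lytic_delta`` is not needed — each half uses its own
    tissue-class delta.  ``cortical_breach`` carves a contiguous window
    out of the cortical shell next to the lesion.
    """

    lesion_type: str
    center: tuple[int, int, int]
    radius: float
    cortical_breach: bool = False
    hu_delta: float | None = None

    def __post_init__(self) -> None:
        if self.lesion_type not in LesionType.ALL:
            raise ValueError(f"unknown lesion type {self.lesion_type!r}")
        if self.radius <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.hu_delta is not None:
            if self.lesion_type == LesionType.OSTEOLYTIC and self.hu_delta >= 0:
                raise ValueError("osteolytic lesion requires hu_delta < 0")
            if self.lesion_type == LesionType.OSTEOBLASTIC and self.hu_delta <= 0:
                raise ValueError("osteoblastic lesion requires hu_delta > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom: geometry, lesions, tissue table."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    cortical_thickness: float = 3.0   # mm
    bone_outer_radius: float = 14.0   # mm, at the shaft
    flare: float = 0.35               # relative radius increase at the top end
    muscle_thickness: float = 8.0     # mm
    fat_thickness: float = 5.0        # mm
    marrow_radius_frac: float = 0.65  # medullary cavity radius / inner radius
    # Cross-section ellipticity and a trochanter-like lateral bump break the
    # rotational symmetry of the tube, making rigid registration well-posed.
    ellipticity: float = 0.7
    bump_radius_frac: float = 0.7     # bump radius / bone_outer_radius; 0 disables
    lesions: tuple[LesionSpec, ...] = ()
    tissue_table: dict[int, TissueProperties] = field(default_factory=default_tissue_table)
    ct_blur_sigma: float = 0.5        # voxels; 0 disables the CT partial-volume blur
    mr_blur_sigma: float = 0.0        # voxels; MR left sharp by default
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")
        if len(self.shape) != 3:
            raise ValueError("shape must be a voxel triple")


@dataclass
class PhantomCase:
    """One synthetic patient: label map, CT, two MR echoes, masks."""

    case_id: str
    lesion_type: str
    label_map: np.ndarray
    ct: np.ndarray
    mr_echo1: np.ndarray
    mr_echo2: np.ndarray
    bone_mask: np.ndarray
    lesion_mask: np.ndarray
    spacing: tuple[float, float, float]
    true_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0
    #: CT-side bone mask; equals ``bone_mask`` unless the CT was misaligned.
    ct_bone_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {
            v.shape
            for v in (self.label_map, self.ct, self.mr_echo1, self.mr_echo2,
                      self.bone_mask, self.lesion_mask)
        }
        if len(shapes) != 1:
            raise ValueError(f"case {self.case_id}: volumes disagree on shape: {shapes}")
        if not self.bone_mask.any():
            raise ValueError(f"case {self.case_id}: empty bone mask")


# ---------------------------------------------------------------------------
# Label-map construction
# ---------------------------------------------------------------------------

_BONE_LABELS = (Tissue.MARROW, Tissue.CANCELLOUS, Tissue.CORTICAL,
                Tissue.LESION_LYTIC, Tissue.LESION_BLASTIC)
_LESION_LABELS = (Tissue.LESION_LYTIC, Tissue.LESION_BLASTIC)


def _physical_grid(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def build_label_map(spec: PhantomSpec) -> np.ndarray:
    """Render the tissue-label volume for ``spec``.

    Geometry is a pure function of the ``PhantomSpec`` (cohort-level
    anatomical variation is injected by randomizing its fields), so toggling
    image noise elsewhere never changes geometry.  Lesions outside the
    bone are rejected with the offending index named.
    """
    shape, spacing = spec.shape, spec.spacing
    x, y, z = _physical_grid(shape, spacing)
    extent = [n * s for n, s in zip(shape, spacing)]
    cx, cy = extent[0] / 2.0, extent[1] / 2.0

    # Bone axis along z with a flared (metaphysis-like) top end.
    zf = z / max(extent[2], 1e-9)
    r_outer = spec.bone_outer_radius * (1.0 + spec.flare * np.clip(3.0 * zf - 2.0, 0.0, 1.0))
    r = np.hypot(x - cx, (y - cy) / spec.ellipticity)

    labels = np.full(shape, int(Tissue.WATER), dtype=np.int16)
    labels[r < r_outer + spec.muscle_thickness + spec.fat_thickness] = int(Tissue.FAT)
    labels[r < r_outer + spec.muscle_thickness] = int(Tissue.MUSCLE)
    labels[r < r_outer] = int(Tissue.CORTICAL)
    r_inner = r_outer - spec.cortical_thickness
    labels[r < r_inner] = int(Tissue.CANCELLOUS)
    labels[r < r_inner * spec.marrow_radius_frac] = int(Tissue.MARROW)

    bone = (r < r_outer)
    if spec.bump_radius_frac > 0:
        # Solid cortical protuberance on the +x side near the flared end.
        br = spec.bump_radius_frac * spec.bone_outer_radius
        bc = (cx + spec.bone_outer_radius * (1.0 + spec.flare), cy, 0.8 * extent[2])
        d_bump = np.sqrt((x - bc[0]) ** 2 + (y - bc[1]) ** 2 + (z - bc[2]) ** 2)
        bump = (d_bump <= br) & (r >= r_inner)
        labels[bump] = int(Tissue.CORTICAL)
        bone |= bump
    for i, lesion in enumerate(spec.lesions):
        ci = tuple(int(c) for c in lesion.center)
        if not all(0 <= c < n for c, n in zip(ci, shape)):
            raise ValueError(f"lesion {i}: center {ci} outside the volume")
        if not bone[ci]:
            raise ValueError(f"lesion {i}: center {ci} lies outside the bone region")
        c_mm = np.array([c * s for c, s in zip(ci, spacing)])
        d = np.sqrt((x - c_mm[0]) ** 2 + (y - c_mm[1]) ** 2 + (z - c_mm[2]) ** 2)
        sphere = (d <= lesion.radius) & bone
        if lesion.lesion_type == LesionType.OSTEOLYTIC:
            lytic, blastic = sphere, np.zeros_like(sphere)
        elif lesion.lesion_type == LesionType.OSTEOBLASTIC:
            lytic, blastic = np.zeros_like(sphere), sphere
        else:  # mixed: split the sphere into two hemispheres along z
            lytic = sphere & (z <= c_mm[2])
            blastic = sphere & (z > c_mm[2])
        # Lesions replace cancellous bone and marrow; the cortical shell is
        # only invaded when the lesion breaches it.
        replaceable = np.isin(labels, (int(Tissue.CANCELLOUS), int(Tissue.MARROW)))
        labels[lytic & replaceable] = int(Tissue.LESION_LYTIC)
        labels[blastic & replaceable] = int(Tissue.LESION_BLASTIC)
        if lesion.cortical_breach:
            # Carve a contiguous window of shell adjacent to the lesion.
            breach = (labels == int(Tissue.CORTICAL)) & (d <= lesion.radius + spec.cortical_thickness)
            target = int(Tissue.LESION_LYTIC) if lesion.lesion_type != LesionType.OSTEOBLASTIC \
                else int(Tissue.LESION_BLASTIC)
            labels[breach] = target
    return labels


def bone_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    """Ground-truth bone mask: everything inside the outer bone surface.

    Mirrors a clinical bone segmentation: cortical shell, cancellous
    interior, the medullary (marrow) cavity and any intra-bone lesion.
    Including the marrow cavity is what gives the downstream 150-HU
    extraction its job — separating ossified tissue from marrow within
    the segmented bone.
    """
    return np.isin(labels, [int(t) for t in _BONE_LABELS])


def lesion_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    return np.isin(labels, [int(t) for t in _LESION_LABELS])


# ---------------------------------------------------------------------------
# CT rendering
# ---------------------------------------------------------------------------

def render_ct(
    label_map: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render a CT volume in HU from a label map.

    Per voxel HU ~ Normal(hu_mean, hu_sd) of its tissue, then a small
    Gaussian point-spread blur (``spec.ct_blur_sigma`` voxels) creates
    partial-volume boundary voxels.  With ``noise=False`` and blur sigma 0
    the rendering is an exact lookup of the tissue means.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC7]))
    present = np.unique(label_map)
    for lab in present:
        if int(lab) not in spec.tissue_table:
            raise KeyError(f"label {int(lab)} missing from the tissue table")
    means = np.zeros(int(present.max()) + 1)
    sds = np.zeros_like(means)
    for lab in present:
        tp = spec.tissue_table[int(lab)]
        means[int(lab)], sds[int(lab)] = tp.hu_mean, tp.hu_sd
    # A lesion's hu_delta overrides the lesion-tissue mean relative to the
    # cancellous base (negative delta -> lytic component, positive ->
    # blastic component).
    base = spec.tissue_table[int(Tissue.CANCELLOUS)].hu_mean
    for lesion in spec.lesions:
        if lesion.hu_delta is None:
            continue
        target = Tissue.LESION_LYTIC if lesion.hu_delta < 0 else Tissue.LESION_BLASTIC
        if int(target) < means.size:
            means[int(target)] = base + lesion.hu_delta
    ct = means[label_map].astype(np.float64)
    if noise:
        ct += rng.standard_normal(label_map.shape) * sds[label_map]
    if spec.ct_blur_sigma > 0:
        ct = ndimage.gaussian_filter(ct, spec.ct_blur_sigma)
    return ct


# ---------------------------------------------------------------------------
# MR rendering (spoiled gradient echo)
# ---------------------------------------------------------------------------

def spgr_signal(
    pd: float | np.ndarray,
    t1: float | np.ndarray,
    t2_star: float | np.ndarray,
    fat_fraction: float | np.ndarray,
    te: float,
    tr: float,
    flip_deg: float,
    fat_water_shift_hz: float,
) -> float | np.ndarray:
    """Steady-state spoiled gradient-echo magnitude signal.

    S(TE) = PD sin(a) (1 - E1) / (1 - cos(a) E1) exp(-TE/T2*)
            |(1 - ff) + ff exp(i 2 pi df TE)|,   E1 = exp(-TR/T1)

    with times in ms and the fat-water shift ``df`` in Hz (TE converted to
    seconds inside the chemical-shift phasor).  The two-compartment fat +
    water phasor makes near-opposed / near-in-phase echo times behave as
    in a real dual-echo acquisition.
    """
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr / t1)
    steady = pd * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
    decay = np.exp(-te / t2_star)
    phasor = np.abs((1.0 - fat_fraction)
                    + fat_fraction * np.exp(1j * 2.0 * np.pi * fat_water_shift_hz * te * 1e-3))
    return steady * decay * phasor


def render_mr(
    label_map: np.ndarray,
    spec: PhantomSpec,
    acq: AcquisitionParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the two echo magnitude volumes for ``label_map``.

    Additive Gaussian noise on the magnitude with SD ``acq.noise_sd`` times
    the maximum noiseless signal (Gaussian rather than Rician: at the
    simulated SNR the difference is immaterial and the noiseless limit
    stays exact).  Negative values after noise are clipped at 0 so the
    result remains magnitude data.
    """
    if acq.te2 >= acq.tr:
        raise ValueError("TE must be smaller than TR")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x317]))
    present = np.unique(label_map)
    nmax = int(present.max()) + 1
    pd = np.zeros(nmax)
    t1 = np.ones(nmax)
    t2s = np.ones(nmax)
    ff = np.zeros(nmax)
    for lab in present:
        tp = spec.tissue_table[int(lab)]
        pd[lab], t1[lab], t2s[lab], ff[lab] = tp.proton_density, tp.t1, tp.t2_star, tp.fat_fraction
    echoes = []
    for te in (acq.te1, acq.te2):
        sig_per_label = spgr_signal(pd, t1, t2s, ff, te, acq.tr, acq.flip_angle,
                                    acq.fat_water_shift)
        vol = sig_per_label[label_map].astype(np.float64)
        if spec.mr_blur_sigma > 0:
            vol = ndimage.gaussian_filter(vol, spec.mr_blur_sigma)
        if acq.noise_sd > 0:
            vol = vol + rng.standard_normal(label_map.shape) * acq.noise_sd * vol.max()
            np.clip(vol, 0.0, None, out=vol)
        echoes.append(vol)
    return echoes[0], echoes[1]


# ---------------------------------------------------------------------------
# Misalignment and cohort generation
# ---------------------------------------------------------------------------

def apply_misalignment(case: PhantomCase, transform: RigidTransform) -> PhantomCase:
    """Displace the CT side of a case by a rigid transform.

    The CT and a CT-side copy of the bone mask (stored as ``ct_bone_mask``)
    are resampled so that mapping their coordinates through ``transform``
    brings them back onto the MR grid; ``true_transform`` records the
    transform so registration recovery is checkable.  If part of the bone
    leaves the field of view a warning reports the clipped fraction.
    """
    import warnings

    inv = transform.inverse()
    moved_ct = resample(case.ct, inv, case.spacing, case.ct.shape, case.spacing,
                        interpolation="bspline", background=-1024.0)
    moved_bone = resample(case.bone_mask.astype(np.uint8), inv, case.spacing,
                          case.ct.shape, case.spacing,
                          interpolation="nearest", background=0).astype(bool)
    kept = moved_bone.sum() / max(case.bone_mask.sum(), 1)
    if kept < 0.999:
        warnings.warn(
            f"case {case.case_id}: misalignment clips {100 * (1 - kept):.1f}% "
            "of the bone out of the field of view",
            stacklevel=2,
        )
    return replace(case, ct=moved_ct, ct_bone_mask=moved_bone, true_transform=transform)


def _case_from_spec(spec: PhantomSpec, case_id: str, lesion_type: str,
                    acq: AcquisitionParams, ct_noise: bool = True) -> PhantomCase:
    labels = build_label_map(spec)
    ct = render_ct(labels, spec, noise=ct_noise)
    e1, e2 = render_mr(labels, spec, acq)
    return PhantomCase(
        case_id=case_id,
        lesion_type=lesion_type,
        label_map=labels,
        ct=ct,
        mr_echo1=e1,
        mr_echo2=e2,
        bone_mask=bone_mask_from_labels(labels),
        lesion_mask=lesion_mask_from_labels(labels),
        spacing=spec.spacing,
        seed=spec.seed,
    )


def _random_lesion(rng: np.random.Generator, spec: PhantomSpec, lesion_type: str) -> LesionSpec:
    """Place one lesion inside the cancellous/marrow compartment."""
    shape, spacing = spec.shape, spec.spacing
    extent = [n * s for n, s in zip(shape, spacing)]
    cx, cy = extent[0] / 2.0, extent[1] / 2.0
    r_inner = spec.bone_outer_radius - spec.cortical_thickness
    radius = float(rng.uniform(0.45, 0.7) * r_inner)
    # Radial offset keeps the sphere centre inside the bone interior.
    rho = float(rng.uniform(0.0, max(r_inner - radius * 0.5, 1.0)))
    phi = float(rng.uniform(0, 2 * np.pi))
    z_mm = float(rng.uniform(0.3, 0.6) * extent[2])
    center_mm = (cx + rho * np.cos(phi), cy + rho * np.sin(phi), z_mm)
    center = tuple(int(round(c / s)) for c, s in zip(center_mm, spacing))
    breach = lesion_type == LesionType.OSTEOLYTIC and bool(rng.random() < 0.5)
    return LesionSpec(lesion_type=lesion_type, center=center, radius=radius,
                      cortical_breach=breach)


def make_cohort(
    n: int = 9,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    acq: AcquisitionParams | None = None,
    composition: Sequence[str] | None = None,
) -> list[PhantomCase]:
    """Generate a cohort of phantoms with randomized anatomy and lesions.

    The default nine-case cohort has the lesion-type composition
    3 osteolytic / 4 osteoblastic / 2 mixed.  For other ``n`` the types
    are drawn from that same 3:4:2 distribution.  Bitwise reproducible
    for a fixed seed; per-case seeds are recorded on the cases.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 cases")
    base = base_spec if base_spec is not None else PhantomSpec()
    acq = acq if acq is not None else AcquisitionParams()
    master = np.random.default_rng(seed)
    case_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n)]
    if composition is None:
        if n == len(COHORT_COMPOSITION):
            composition = COHORT_COMPOSITION
        else:
            probs = np.array([3.0, 4.0, 2.0]) / 9.0
            types = (LesionType.OSTEOLYTIC, LesionType.OSTEOBLASTIC, LesionType.MIXED)
            composition = [types[i] for i in master.choice(3, size=n, p=probs)]
    elif len(composition) != n:
        raise ValueError("composition length must equal n")

    cases = []
    for i, (cseed, ltype) in enumerate(zip(case_seeds, composition)):
        rng = np.random.default_rng(np.random.SeedSequence([cseed, 0xA11]))
        spec_i = replace(
            base,
            bone_outer_radius=float(base.bone_outer_radius * rng.uniform(0.85, 1.15)),
            cortical_thickness=float(base.cortical_thickness * rng.uniform(0.85, 1.15)),
            flare=float(base.flare * rng.uniform(0.6, 1.4)),
            seed=cseed,
        )
        lesion = _random_lesion(rng, spec_i, ltype)
        spec_i = replace(spec_i, lesions=(lesion,))
        cases.append(_case_from_spec(spec_i, f"case{i + 1:02d}", ltype, acq))
    return cases
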