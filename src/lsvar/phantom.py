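"""Labeled CT-like voxel phantoms and measurements on them.

A :class:`LabeledVolume` pairs a 3D Hounsfield-unit grid with an integer
label grid on the same voxel lattice.  It stands in for a segmented
portal venous CT: Couinaud segments, spleen, hepatic veins and IVC are
regions of the label map, and the two quantities the scoring layer
needs — region volumes (voxel count × voxel volume) and ROI mean
attenuations — are read directly off the grids.

:func:`generate_phantom` builds such a volume from volumetric and
attenuation targets so that the whole measurement chain
(phantom → measurement → scores) is testable without any real scan.
Regions are connected blobs (balls in physical coordinates, clipped to
disjoint axis-aligned boxes) whose voxel counts match the requested
volumes exactly up to single-voxel rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import CapacityError, EmptyRoiError, MeasurementError
from .scores import AttenuationMeasurement, SegmentalVolumes

#: Versioned label code table. Couinaud segments I–VIII get codes 1–8.
LABEL_CODES: dict[str, int] = {
    "background": 0,
    "segment_I": 1,
    "segment_II": 2,
    "segment_III": 3,
    "segment_IV": 4,
    "segment_V": 5,
    "segment_VI": 6,
    "segment_VII": 7,
    "segment_VIII": 8,
    "spleen": 10,
    "hepatic_veins": 20,
    "ivc": 21,
}
LABEL_CODES_VERSION = "1"

SEGMENTS_I_III = (1, 2, 3)
SEGMENTS_IV_VIII = (4, 5, 6, 7, 8)
SPLEEN, HEPATIC_VEINS, IVC, BACKGROUND = 10, 20, 21, 0

#: HU of unlabeled background voxels (air).
BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D HU grid plus a same-shape integer label grid.

    ``spacing`` gives the voxel edge lengths in mm along the (x, y, z)
    axes; no further orientation metadata is interpreted.
    """

    hu: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.hu.shape != self.labels.shape:
            raise MeasurementError(
                f"hu shape {self.hu.shape} != labels shape {self.labels.shape}"
            )
        if self.hu.ndim != 3:
            raise MeasurementError(f"expected 3D grids, got {self.hu.ndim}D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MeasurementError(f"spacing must be 3 positive lengths, got {self.spacing}")
        known = set(LABEL_CODES.values())
        present = set(np.unique(self.labels).tolist())
        if not present <= known:
            raise MeasurementError(f"unknown label codes present: {sorted(present - known)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class PhantomSpec:
    """Targets for a synthetic labeled volume.

    Volumes are in ml, attenuations in HU.  ``noise_sd_hu`` is the
    standard deviation of the additive Gaussian HU noise applied to all
    non-background voxels (clipped afterwards to the valid HU range).
    With the default 3 HU it stays well below the ±20 HU LVCA tolerance
    so region means recover the specified attenuations.
    """

    vol_i_iii: float
    vol_iv_viii: float
    splenic_volume: float = 250.0
    vein_hu: float = 100.0
    ivc_hu: float = 100.0
    parenchyma_hu: float = 105.0
    spleen_hu: float = 100.0
    veins_contrasted: bool = True
    vein_volume_ml: float = 4.0
    ivc_volume_ml: float = 6.0
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd_hu: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vol_i_iii", "vol_iv_viii", "splenic_volume"):
            if getattr(self, name) <= 0:
                raise CapacityError(f"{name} must be positive, got {getattr(self, name)}")


def region_volume_ml(v: LabeledVolume, code: int) -> float:
    """Volume of one labeled region: voxel count × voxel volume, in ml.

    Returns 0.0 for a label absent from the grid.
    """
    if code not in LABEL_CODES.values():
        raise MeasurementError(f"unknown region code {code}")
    n = int(np.count_nonzero(v.labels == code))
    return n * v.voxel_volume_mm3 / 1000.0


def roi_mean_hu(v: LabeledVolume, code: int) -> float:
    """Arithmetic mean HU over the voxels of one labeled region."""
    mask = v.labels == code
    if not mask.any():
        raise EmptyRoiError(f"region code {code} is empty")
    return float(v.hu[mask].mean())


def measure_patient(v: LabeledVolume) -> tuple[SegmentalVolumes, AttenuationMeasurement]:
    """Extract segmental volumes and vein/IVC attenuations from a volume.

    The hepatic veins are treated as contrasted iff any vein voxels are
    labeled; their ROI mean is then reported as a single vein reading
    (the phantom does not model three separate veins).
    """
    for code in (*SEGMENTS_I_III, *SEGMENTS_IV_VIII):
        if not (v.labels == code).any():
            raise MeasurementError(f"missing liver segment label code {code}")
    if not (v.labels == IVC).any():
        raise MeasurementError(f"missing IVC label code {IVC}")

    vol_i_iii = sum(region_volume_ml(v, c) for c in SEGMENTS_I_III)
    vol_iv_viii = sum(region_volume_ml(v, c) for c in SEGMENTS_IV_VIII)
    splenic = region_volume_ml(v, SPLEEN)
    volumes = SegmentalVolumes(
        vol_i_iii=vol_i_iii,
        vol_iv_viii=vol_iv_viii,
        splenic_volume=splenic if splenic > 0 else None,
    )
    contrasted = bool((v.labels == HEPATIC_VEINS).any())
    measurement = AttenuationMeasurement(
        vein_hu=(roi_mean_hu(v, HEPATIC_VEINS),) if contrasted else (),
        ivc_hu=roi_mean_hu(v, IVC),
        veins_contrasted=contrasted,
    )
    return volumes, measurement


# ---------------------------------------------------------------------------
# Phantom generation

def _split_box(box, items, rng):
    """Recursively partition ``box`` among ``items`` = [(code, nvox, hu), ...].

    Binary space partition: the item list is split at the index that
    best balances voxel demand, and the box is cut along its longest
    axis proportionally.  Yields (box, item) leaves.
    """
    if len(items) == 1:
        yield box, items[0]
        return
    demands = np.array([it[1] for it in items], dtype=float)
    cum = np.cumsum(demands)
    total = cum[-1]
    # split index k in [1, len-1] minimizing demand imbalance
    k = int(np.argmin(np.abs(cum[:-1] - total / 2))) + 1
    left_frac = cum[k - 1] / total
    extents = [box[1] - box[0], box[3] - box[2], box[5] - box[4]]
    axis = int(np.argmax(extents))
    lo, hi = box[2 * axis], box[2 * axis + 1]
    cut = lo + int(round((hi - lo) * left_frac))
    cut = min(max(cut, lo + 1), hi - 1)
    left = list(box)
    right = list(box)
    left[2 * axis + 1] = cut
    right[2 * axis] = cut
    yield from _split_box(tuple(left), items[:k], rng)
    yield from _split_box(tuple(right), items[k:], rng)


def _carve_ball(labels, box, code, nvox, spacing, rng):
    """Label the ``nvox`` voxels of ``box`` nearest a jittered center.

    Nearest-by-physical-distance within a convex box gives a connected,
    roughly ellipsoidal blob with an exact voxel count.
    """
    x0, x1, y0, y1, z0, z1 = box
    capacity = (x1 - x0) * (y1 - y0) * (z1 - z0)
    if nvox > capacity:
        raise CapacityError(
            f"region code {code} needs {nvox} voxels but its box holds {capacity}"
        )
    sx, sy, sz = spacing
    xs = (np.arange(x0, x1) + 0.5) * sx
    ys = (np.arange(y0, y1) + 0.5) * sy
    zs = (np.arange(z0, z1) + 0.5) * sz
    center = np.array(
        [
            xs.mean() + rng.uniform(-0.1, 0.1) * (xs[-1] - xs[0] + sx),
            ys.mean() + rng.uniform(-0.1, 0.1) * (ys[-1] - ys[0] + sy),
            zs.mean() + rng.uniform(-0.1, 0.1) * (zs[-1] - zs[0] + sz),
        ]
    )
    d2 = (
        ((xs - center[0]) ** 2)[:, None, None]
        + ((ys - center[1]) ** 2)[None, :, None]
        + ((zs - center[2]) ** 2)[None, None, :]
    )
    flat = d2.ravel()
    idx = np.argpartition(flat, nvox - 1)[:nvox]
    ix, iy, iz = np.unravel_index(idx, d2.shape)
    labels[x0 + ix, y0 + iy, z0 + iz] = code


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Build a labeled voxel volume matching a :class:`PhantomSpec`.

    Deterministic for a fixed seed.  Region voxel counts equal the
    rounded targets, so measured volumes match the spec to within one
    voxel; HU fields equal the spec values plus zero-mean Gaussian
    noise.  Raises :class:`~lsvar.exceptions.CapacityError` when the
    targets cannot fit in the grid.
    """
    rng = np.random.default_rng(spec.seed)
    voxel_ml = float(np.prod(spec.spacing)) / 1000.0

    def nvox(volume_ml: float) -> int:
        n = int(round(volume_ml / voxel_ml))
        if n < 1:
            raise CapacityError(
                f"target {volume_ml} ml is below one voxel ({voxel_ml} ml)"
            )
        return n

    def split_even(total: int, parts: int) -> list[int]:
        base, rem = divmod(total, parts)
        return [base + (1 if i < rem else 0) for i in range(parts)]

    items: list[tuple[int, int, float]] = []
    for code, n in zip(SEGMENTS_I_III, split_even(nvox(spec.vol_i_iii), 3)):
        items.append((code, n, spec.parenchyma_hu))
    for code, n in zip(SEGMENTS_IV_VIII, split_even(nvox(spec.vol_iv_viii), 5)):
        items.append((code, n, spec.parenchyma_hu))
    items.append((SPLEEN, nvox(spec.splenic_volume), spec.spleen_hu))
    if spec.veins_contrasted:
        items.append((HEPATIC_VEINS, nvox(spec.vein_volume_ml), spec.vein_hu))
    items.append((IVC, nvox(spec.ivc_volume_ml), spec.ivc_hu))

    grid_vox = int(np.prod(spec.shape))
    demand = sum(n for _, n, _ in items)
    # box granularity needs slack; beyond ~85% occupancy leaf boxes overflow
    if demand > 0.85 * grid_vox:
        raise CapacityError(
            f"targets need {demand} voxels but the grid holds {grid_vox} "
            "(over 85% occupancy)"
        )

    labels = np.zeros(spec.shape, dtype=np.int16)
    full_box = (0, spec.shape[0], 0, spec.shape[1], 0, spec.shape[2])
    for box, (code, n, _) in _split_box(full_box, items, rng):
        _carve_ball(labels, box, code, n, spec.spacing, rng)

    hu = np.full(spec.shape, BACKGROUND_HU, dtype=np.float32)
    for code, _, base_hu in items:
        mask = labels == code
        hu[mask] = base_hu + rng.normal(0.0, spec.noise_sd_hu, int(mask.sum()))
    np.clip(hu, -1024.0, 3071.0, out=hu)
    return LabeledVolume(hu=hu, labels=labels, spacing=spec.spacing)


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_labeled_volume(v: LabeledVolume, outdir: str | Path, prefix: str = "phantom") -> None:
    """Write a phantom as paired NIfTI volumes plus a JSON code-table sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*v.spacing, 1.0])
    nib.save(nib.Nifti1Image(v.hu.astype(np.float32), affine), outdir / f"{prefix}_hu.nii.gz")
    nib.save(
        nib.Nifti1Image(v.labels.astype(np.int16), affine), outdir / f"{prefix}_labels.nii.gz"
    )
    sidecar = {"label_codes": LABEL_CODES, "version": LABEL_CODES_VERSION}
    (outdir / f"{prefix}_codes.json").write_text(json.dumps(sidecar, indent=2))


def load_labeled_volume(outdir: str | Path, prefix: str = "phantom") -> LabeledVolume:
    """Read a phantom written by :func:`save_labeled_volume`.

    Validates that the HU and label images agree in shape and affine.
    """
    outdir = Path(outdir)
    hu_img = nib.load(outdir / f"{prefix}_hu.nii.gz")
    lab_img = nib.load(outdir / f"{prefix}_labels.nii.gz")
    if hu_img.shape != lab_img.shape:
        raise MeasurementError(
            f"HU shape {hu_img.shape} != labels shape {lab_img.shape}"
        )
    if not np.allclose(hu_img.affine, lab_img.affine):
        raise MeasurementError("HU and label affines disagree")
    spacing = tuple(float(s) for s in hu_img.header.get_zooms()[:3])
    return LabeledVolume(
        hu=np.asarray(hu_img.get_fdata(), dtype=np.float32),
        labels=np.asarray(lab_img.get_fdata(), dtype=np.int16),
        spacing=spacing,  # type: ignore[arg-type]
    )
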