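"""Volume containers, NIfTI I/O, label-scheme handling, and brain-mask cropping.

The package works on skull-stripped, rigidly aligned T1-weighted volumes and
integer parcellations over a fixed five-label scheme: background plus the four
compartments of the ventricular system.  All grids are 3D numpy arrays indexed
``[i, j, k]``; world geometry (voxel spacing in mm, anatomical orientation)
comes from the NIfTI affine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Fixed parcellation scheme.  RLV/LLV are the right/left lateral ventricles.
LABEL_SCHEME: dict[int, str] = {
    0: "background",
    1: "right lateral ventricle",
    2: "left lateral ventricle",
    3: "third ventricle",
    4: "fourth ventricle",
}

#: Number of labels L, background included.
N_LABELS = len(LABEL_SCHEME)

#: Labels of actual ventricular compartments (background excluded).
VENTRICLE_LABELS = (1, 2, 3, 4)


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))


def _lr_axis_from_affine(affine: np.ndarray) -> int:
    codes = nib.orientations.aff2axcodes(affine)
    for axis, code in enumerate(codes):
        if code in ("L", "R"):
            return axis
    raise ValueError(f"no left-right axis identifiable from axis codes {codes}")


@dataclass
class IntensityVolume:
    """A 3D scalar image with voxel spacing and world orientation.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    affine:
        4x4 NIfTI voxel-to-world affine.  Spacing and the left-right axis are
        derived from it.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.data.ndim} axes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity grid contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm."""
        return _spacing_from_affine(self.affine)

    @property
    def lr_axis(self) -> int:
        """Grid axis running left-right (from the affine's axis codes)."""
        return _lr_axis_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @classmethod
    def from_spacing(cls, data: np.ndarray, spacing) -> "IntensityVolume":
        """Build an RAS-aligned volume from a grid and voxel spacing alone."""
        affine = np.diag([*spacing, 1.0])
        return cls(data, affine)


@dataclass
class LabelVolume:
    """A 3D integer parcellation over the fixed five-label scheme."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.data.ndim} axes")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label grid must have an integer dtype")
        bad = np.setdiff1d(np.unique(self.data), list(LABEL_SCHEME))
        if bad.size:
            raise ValueError(
                f"label grid contains values outside the scheme {sorted(LABEL_SCHEME)}: "
                f"{bad.tolist()}"
            )

    scheme = LABEL_SCHEME

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    @property
    def lr_axis(self) -> int:
        return _lr_axis_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def label_counts(self) -> dict[int, int]:
        return {l: int(np.count_nonzero(self.data == l)) for l in LABEL_SCHEME}

    def volumes_ml(self) -> dict[int, float]:
        """Per-label volume in ml (voxel count x voxel volume)."""
        vv = self.voxel_volume_ml
        return {l: c * vv for l, c in self.label_counts().items()}

    @classmethod
    def from_spacing(cls, data: np.ndarray, spacing) -> "LabelVolume":
        return cls(data, np.diag([*spacing, 1.0]))


@dataclass
class ProbabilityVolume:
    """Per-voxel label probabilities: ``data[l, i, j, k]``, simplex-normalized."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("probability grid must be 4D (labels x 3 spatial axes)")
        if np.any(self.data < -1e-5):
            raise ValueError("probabilities must be nonnegative")
        sums = self.data.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("channel vectors must sum to 1 (within 1e-5)")

    @property
    def n_labels(self) -> int:
        return self.data.shape[0]

    def argmax_labels(self) -> LabelVolume:
        """Hard decode; argmax ties break toward the lowest label index."""
        return LabelVolume(np.argmax(self.data, axis=0).astype(np.int16), self.affine)


@dataclass
class BrainMask:
    """Binary brain mask paired with an intensity or label volume."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D grid")
        if not self.data.any():
            raise ValueError("brain mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def bounding_box(self) -> tuple[tuple[int, int], ...]:
        """Inclusive (lo, hi) index bounds of the mask per axis."""
        bounds = []
        for axis in range(3):
            proj = np.any(self.data, axis=tuple(a for a in range(3) if a != axis))
            idx = np.nonzero(proj)[0]
            bounds.append((int(idx[0]), int(idx[-1])))
        return tuple(bounds)

    @classmethod
    def from_intensity(cls, volume: IntensityVolume) -> "BrainMask":
        """Fallback mask: the nonzero-intensity support of a skull-stripped image."""
        return cls(volume.data != 0, volume.affine)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path, kind: str = "intensity"):
    """Read a NIfTI-1 volume.

    ``kind`` selects the container: ``"intensity"``, ``"labels"`` or
    ``"mask"``.  Label and mask files are read as stored integers, never
    rescaled or interpolated; a label file holding values outside the scheme
    is rejected with a message listing the offending values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    affine = img.affine
    if kind == "intensity":
        return IntensityVolume(np.asarray(data, dtype=np.float32), affine)
    if kind == "labels":
        return LabelVolume(np.rint(data).astype(np.int16), affine)
    if kind == "mask":
        return BrainMask(data != 0, affine)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(volume, path) -> None:
    """Write a volume container to a NIfTI-1 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, LabelVolume):
        data = volume.data.astype(np.int16)
    elif isinstance(volume, BrainMask):
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


# ---------------------------------------------------------------------------
# Label remapping
# ---------------------------------------------------------------------------

def remap_labels(data, mapping: dict[int, int], default_background: bool = False,
                 affine: np.ndarray | None = None) -> LabelVolume:
    """Collapse an arbitrary integer labelling onto the five-label scheme.

    Typical use: converting a whole-brain protocol with one code per cortical
    and subcortical structure into the four ventricle labels plus background.
    ``mapping`` sends source codes to target codes in ``{0..4}``; with
    ``default_background`` set, unmapped codes go to 0, otherwise they are an
    error.  Voxel counts are conserved: the output count of each target label
    equals the summed counts of its source codes.
    """
    if isinstance(data, LabelVolume):
        affine = data.affine if affine is None else affine
        data = data.data
    data = np.asarray(data)
    if affine is None:
        affine = np.eye(4)
    for target in mapping.values():
        if target not in LABEL_SCHEME:
            raise ValueError(f"mapping target {target} outside the scheme")
    present = np.unique(data)
    unmapped = [int(c) for c in present if int(c) not in mapping]
    if unmapped and not default_background:
        raise ValueError(f"unmapped source codes {unmapped} (default_background is off)")
    out = np.zeros(data.shape, dtype=np.int16)
    for src, dst in mapping.items():
        if dst != 0:
            out[data == src] = dst
    return LabelVolume(out, affine)


def read_mapping_file(path) -> dict[int, int]:
    """Read a plain-text two-column (source target) label mapping file."""
    mapping: dict[int, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        src, dst = line.split()
        mapping[int(src)] = int(dst)
    return mapping


# ---------------------------------------------------------------------------
# Cropping around the brain mask
# ---------------------------------------------------------------------------

def crop_to_brain(volume, mask: BrainMask, target_shape):
    """Crop a volume to ``target_shape`` symmetrically around the brain mask.

    The mask bounding box is centered per axis; when the slack is odd the
    extra voxel goes to the high-index side.  If the centered window would
    leave the volume it is shifted minimally to fit (the bounding box stays
    inside).  Returns the cropped volume and the per-axis window offsets so
    predictions can be placed back into the original frame with :func:`uncrop`.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if volume.data.shape[:3] != mask.shape:
        raise ValueError("volume and mask shapes differ")
    bbox = mask.bounding_box()
    offsets = []
    for axis, (lo, hi) in enumerate(bbox):
        extent = hi - lo + 1
        target = target_shape[axis]
        size = volume.data.shape[axis]
        if extent > target:
            raise ValueError(
                f"mask bounding box extent {extent} exceeds target {target} on axis {axis}"
            )
        if target > size:
            raise ValueError(
                f"target {target} exceeds volume size {size} on axis {axis}; "
                "pad the input first"
            )
        start = lo - (target - extent) // 2
        start = min(max(start, 0), size - target)  # shift minimally to fit
        offsets.append(start)
    sl = tuple(slice(o, o + t) for o, t in zip(offsets, target_shape))
    cropped = volume.data[sl]
    out = type(volume)(cropped.copy(), volume.affine)
    return out, tuple(offsets)


def uncrop(prediction: LabelVolume, offsets, original_shape) -> LabelVolume:
    """Place a cropped-frame prediction back into the original frame.

    Voxels outside the crop window become background.  The window must lie
    entirely inside ``original_shape``.
    """
    offsets = tuple(int(o) for o in offsets)
    original_shape = tuple(int(s) for s in original_shape)
    for axis in range(3):
        if offsets[axis] < 0 or offsets[axis] + prediction.shape[axis] > original_shape[axis]:
            raise ValueError(
                f"crop window exceeds the original shape on axis {axis}: "
                f"offset {offsets[axis]} + size {prediction.shape[axis]} > "
                f"{original_shape[axis]}"
            )
    out = np.zeros(original_shape, dtype=prediction.data.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offsets, prediction.shape))
    out[sl] = prediction.data
    return LabelVolume(out, prediction.affine)


def write_crop_offsets(offsets, original_shape, path) -> None:
    """Record crop offsets in a sidecar JSON next to a cropped volume."""
    Path(path).write_text(json.dumps(
        {"offsets": list(offsets), "original_shape": list(original_shape)}))


def read_crop_offsets(path):
    d = json.loads(Path(path).read_text())
    return tuple(d["offsets"]), tuple(d["original_shape"])
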