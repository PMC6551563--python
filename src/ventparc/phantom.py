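"""Synthetic ventriculomegaly phantoms.

Generates brain-shaped intensity/label volume pairs with four disjoint
ventricular compartments whose sizes span normal anatomy to severe
ventriculomegaly.  The phantom emulates the inputs the parcellation network
is designed for: a skull-stripped T1-weighted-like volume (CSF dark, brain
tissue bright, background exactly zero), a five-label parcellation, and a
brain mask.  It does not attempt cortical folding or lesion modelling — it is
a geometric test-bed, not an anatomical simulator.

Geometry (in axis-normalized coordinates, +x = right, +y = anterior,
+z = superior):

* brain: a single ellipsoid;
* lateral ventricles: one curved, tapered tube per hemisphere, arched in the
  sagittal plane so the structure is not an axis-aligned blob;
* third ventricle: a thin mid-sagittal slab with an elliptical profile,
  between the lateral ventricles;
* fourth ventricle: a small midline ellipsoid inferior and posterior to the
  third ventricle.

A scalar ``enlargement`` dilates all compartments (with the largest
coefficient on the lateral ventricles, as in hydrocephalus); ventricular
voxel volume is monotonically non-decreasing in it at a fixed seed.  The
lateral ventricles are clipped to a fixed para-sagittal plane so that they
can never merge with the midline third ventricle, keeping the labels
disjoint by construction at any enlargement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import BrainMask, IntensityVolume, LabelVolume


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``noise_sd`` is relative to the CSF/tissue contrast; ``bias_amplitude``
    is the peak relative strength of the smooth multiplicative intensity
    bias; ``jitter_*`` add small rigid pose variability between subjects.
    The default 4 mm spacing puts phantom ventricular volumes in the tens-of-
    millilitre range typical of adult brains.
    """

    shape: tuple[int, int, int] = (48, 64, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    enlargement: float = 0.0
    noise_sd: float = 0.1
    bias_amplitude: float = 0.1
    jitter_translate_vox: float = 1.5
    jitter_rotate_deg: float = 5.0
    csf_intensity: float = 0.2
    tissue_intensity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 16 for s in self.shape):
            raise ValueError(f"shape components must be >= 16, got {self.shape}")
        if self.enlargement < 0:
            raise ValueError("enlargement must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be in [0, 1)")
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rx @ ry @ rz


def _lateral_curve(t: np.ndarray, side: int):
    """Center line and radius profile of one lateral ventricle.

    ``side`` is +1 for the right hemisphere, -1 for the left.  The tube is
    arched in the sagittal (y-z) plane and tapers toward both ends.
    """
    cx = side * (0.13 + 0.03 * np.sin(np.pi * t))
    cy = -0.22 + 0.44 * t
    cz = 0.10 - 0.45 * (t - 0.45) ** 2
    taper = 0.55 + 0.45 * np.sin(np.pi * np.clip(t, 0.0, 1.0))
    return cx, cy, cz, taper


def generate_phantom(spec: PhantomSpec):
    """Generate one phantom subject.

    Returns ``(image, labels, mask)``.  Identical spec (seed included) gives
    bit-identical output.  Raises if the requested enlargement would push a
    ventricle through the brain mask.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    # Axis-normalized coordinates centered on (N-1)/2 so that a grid flip is
    # an exact mirror of the coordinate system.
    ax = (np.arange(nx) - (nx - 1) / 2) / nx
    ay = (np.arange(ny) - (ny - 1) / 2) / ny
    az = (np.arange(nz) - (nz - 1) / 2) / nz
    ux, uy, uz = np.meshgrid(ax, ay, az, indexing="ij")

    # Rigid pose jitter: evaluate all implicit shapes in jittered coordinates.
    angles = np.deg2rad(rng.uniform(-spec.jitter_rotate_deg, spec.jitter_rotate_deg, 3))
    shift = rng.uniform(-spec.jitter_translate_vox, spec.jitter_translate_vox, 3)
    shift = shift / np.array(spec.shape, dtype=float)
    rot = _rotation_matrix(angles)
    pts = np.stack([ux.ravel(), uy.ravel(), uz.ravel()])
    pts = rot @ pts - shift[:, None]
    ux, uy, uz = (p.reshape(spec.shape) for p in pts)

    e = spec.enlargement
    labels = np.zeros(spec.shape, dtype=np.int16)

    # Brain mask: single connected ellipsoid.
    brain = (((ux - 0.0) / 0.42) ** 2
             + ((uy - 0.01) / 0.46) ** 2
             + ((uz - 0.02) / 0.40) ** 2) <= 1.0

    # Third ventricle: thin midline slab, fixed thickness, enlarging in-plane.
    w3 = max(0.018, 0.8 / nx)
    s3 = 1.0 + 0.22 * e
    third = (np.abs(ux) <= w3) & (
        ((uy - 0.0) / (0.11 * s3)) ** 2 + ((uz - 0.04) / (0.085 * s3)) ** 2 <= 1.0)

    # Lateral ventricles: curved tapered tubes, clipped to a fixed
    # para-sagittal plane so they can never merge with the midline slab.
    gap = w3 + 0.75 / nx
    rl = 0.050 * (1.0 + 0.30 * e)
    t_samples = np.linspace(0.0, 1.0, 24)
    lateral = {1: np.zeros(spec.shape, dtype=bool), 2: np.zeros(spec.shape, dtype=bool)}
    for label, side in ((1, 1), (2, -1)):
        for t in t_samples:
            cx, cy, cz, taper = _lateral_curve(np.array([t]), side)
            r2 = (rl * taper[0]) ** 2
            d2 = (ux - cx[0]) ** 2 + (uy - cy[0]) ** 2 + (uz - cz[0]) ** 2
            lateral[label] |= d2 <= r2
        lateral[label] &= (side * ux) >= gap

    # Fourth ventricle: small midline ellipsoid, inferior/posterior to third.
    s4 = 1.0 + 0.15 * e
    fourth = (((ux - 0.0) / (0.055 * s4)) ** 2
              + ((uy + 0.23) / (0.058 * s4)) ** 2
              + ((uz + 0.19) / (0.052 * s4)) ** 2) <= 1.0

    # Priority assignment keeps the grid single-valued (labels disjoint).
    for label, region in ((1, lateral[1]), (2, lateral[2]), (3, third), (4, fourth)):
        labels[(labels == 0) & region] = label

    for label in (1, 2, 3, 4):
        if not np.any(labels == label):
            raise ValueError(f"phantom geometry degenerate: label {label} is empty")

    interior = ndimage.binary_erosion(brain)
    ventricles = labels > 0
    if np.any(ventricles & ~interior):
        raise ValueError(
            f"enlargement {e} pushes a ventricle through the brain mask; "
            "reduce enlargement or use a larger grid")

    # Intensity model: tissue bright, CSF dark, background exactly zero;
    # multiplicative smooth bias, then additive noise inside the brain.
    contrast = spec.tissue_intensity - spec.csf_intensity
    image = np.zeros(spec.shape, dtype=np.float64)
    image[brain] = spec.tissue_intensity
    image[ventricles] = spec.csf_intensity

    coarse = rng.standard_normal((4, 4, 4))
    if spec.bias_amplitude > 0:
        bias = ndimage.zoom(coarse, np.array(spec.shape) / 4.0, order=3)
        bias = bias / max(np.abs(bias).max(), 1e-12)
        image *= 1.0 + spec.bias_amplitude * bias

    noise = rng.standard_normal(spec.shape)
    if spec.noise_sd > 0:
        image[brain] += spec.noise_sd * contrast * noise[brain]

    affine = np.diag([*spec.spacing, 1.0])
    return (IntensityVolume(image.astype(np.float32), affine),
            LabelVolume(labels, affine),
            BrainMask(brain, affine))


def generate_cohort(n: int, spec_template: PhantomSpec | None = None,
                    enlargement_range: tuple[float, float] = (0.0, 3.0),
                    seed: int = 0):
    """Generate ``n`` phantoms whose enlargements evenly span a range.

    Mirrors a training-set construction that covers the whole spectrum of
    ventricle sizes.  Per-subject seeds derive deterministically from the
    master ``seed``; two calls with the same arguments give identical cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = float(enlargement_range[0]), float(enlargement_range[1])
    if hi < lo:
        raise ValueError(f"empty enlargement range ({lo}, {hi})")
    if spec_template is None:
        spec_template = PhantomSpec()
    enlargements = np.linspace(lo, hi, n) if n > 1 else np.array([lo])
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    return [
        generate_phantom(replace(spec_template, enlargement=float(e), seed=int(s)))
        for e, s in zip(enlargements, seeds)
    ]
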