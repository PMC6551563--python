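"""Training-time data augmentation.

Three transforms, regenerated fresh every epoch: left-right flipping (with
the right/left lateral ventricle labels exchanged, since a mirrored right
ventricle IS a left ventricle), random rotation about each grid axis, and
smooth random elastic deformation.  Intensities are resampled trilinearly,
labels nearest-neighbour (so the label set {0..4} is always preserved);
voxels pulled in from outside the field of view are background/zero.

One epoch's augmented list is: the originals, their flips, and
``copies_per_image`` rotate+deform variants of each of those — with N
originals and two copies per image that is 6N items per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume, LabelVolume


@dataclass
class AugmentSpec:
    """Augmentation parameters.

    ``rotation_max_deg`` bounds the per-axis rotation (drawn uniformly in
    +/- max).  The elastic field is per-axis white noise smoothed with a
    Gaussian of scale ``elastic_sigma`` (mm) and scaled so its largest
    displacement is ``elastic_alpha`` (mm).
    """

    rotation_max_deg: float = 10.0
    elastic_sigma: float = 4.0
    elastic_alpha: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")
        if self.elastic_sigma <= 0:
            raise ValueError("elastic_sigma must be > 0")
        if self.elastic_alpha < 0:
            raise ValueError("elastic_alpha must be >= 0")


def flip_lr(image: IntensityVolume, labels: LabelVolume):
    """Mirror image and labels about the left-right axis and swap the
    right/left lateral ventricle labels (1 <-> 2).  An involution."""
    axis = image.lr_axis
    flipped = np.flip(labels.data, axis=axis)
    swapped = flipped.copy()
    swapped[flipped == 1] = 2
    swapped[flipped == 2] = 1
    return (IntensityVolume(np.flip(image.data, axis=axis).copy(), image.affine),
            LabelVolume(swapped, labels.affine))


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rx @ ry @ rz


def rotate(image: IntensityVolume, labels: LabelVolume, angles_deg):
    """Rotate both channels by the given per-axis angles about the volume
    center.  Trilinear for intensities, nearest-neighbour for labels."""
    rot = _rotation_matrix(np.deg2rad(np.asarray(angles_deg, dtype=float)))
    center = (np.asarray(image.data.shape) - 1) / 2.0
    # affine_transform maps output coords through the matrix: pull-back
    offset = center - rot.T @ center
    img = ndimage.affine_transform(image.data.astype(np.float32), rot.T,
                                   offset=offset, order=1, mode="constant", cval=0.0)
    lab = ndimage.affine_transform(labels.data, rot.T, offset=offset,
                                   order=0, mode="constant", cval=0)
    return (IntensityVolume(img, image.affine),
            LabelVolume(lab.astype(labels.data.dtype), labels.affine))


def random_rotate(image: IntensityVolume, labels: LabelVolume,
                  spec: AugmentSpec, draw_seed: int):
    """Rotate by one uniform +/- ``rotation_max_deg`` angle per grid axis."""
    rng = np.random.default_rng(draw_seed)
    angles = rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg, 3)
    if spec.rotation_max_deg == 0:
        return (IntensityVolume(image.data.copy(), image.affine),
                LabelVolume(labels.data.copy(), labels.affine))
    return rotate(image, labels, angles)


def elastic_deform(image: IntensityVolume, labels: LabelVolume,
                   spec: AugmentSpec, draw_seed: int):
    """Warp image and labels with one smooth random displacement field.

    Per-axis white noise is smoothed with a Gaussian of ``elastic_sigma`` mm
    and rescaled so the largest displacement magnitude is ``elastic_alpha``
    mm; both channels are pulled through the identical field."""
    if spec.elastic_alpha == 0:
        return (IntensityVolume(image.data.copy(), image.affine),
                LabelVolume(labels.data.copy(), labels.affine))
    rng = np.random.default_rng(draw_seed)
    shape = image.data.shape
    spacing = np.asarray(image.spacing)
    noise = rng.uniform(-1.0, 1.0, (3, *shape))
    disp = np.empty_like(noise)
    sigma_vox = spec.elastic_sigma / spacing
    for axis in range(3):
        disp[axis] = ndimage.gaussian_filter(noise[axis], sigma_vox)
    peak = np.abs(disp).max()
    if peak > 0:
        # displacement expressed in voxels of each axis
        disp = disp / peak * (spec.elastic_alpha / spacing).reshape(-1, 1, 1, 1)
    grid = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                       indexing="ij")
    coords = [g + d for g, d in zip(grid, disp)]
    img = ndimage.map_coordinates(image.data.astype(np.float32), coords,
                                  order=1, mode="constant", cval=0.0)
    lab = ndimage.map_coordinates(labels.data, coords, order=0,
                                  mode="constant", cval=0)
    return (IntensityVolume(img, image.affine),
            LabelVolume(lab.astype(labels.data.dtype), labels.affine))


def epoch_augment(originals, spec: AugmentSpec, copies_per_image: int = 2,
                  epoch_seed: int = 0):
    """Build one epoch's augmented training list.

    ``originals`` is a list of (image, labels) pairs.  The result is the
    originals, their left-right flips, and ``copies_per_image`` independent
    rotate-then-deform variants of each of those, shuffled deterministically
    from ``epoch_seed``: with N originals and 2 copies per image, 6N items.
    """
    if not originals:
        raise ValueError("originals must be nonempty")
    if copies_per_image < 0:
        raise ValueError("copies_per_image must be >= 0")
    base = list(originals)
    base += [flip_lr(img, lab) for img, lab in originals]
    items = list(base)
    ss = np.random.SeedSequence([int(epoch_seed), len(base)])
    draw_seeds = ss.generate_state(2 * copies_per_image * len(base)) % (2 ** 31)
    i = 0
    for img, lab in base:
        for _ in range(copies_per_image):
            r_img, r_lab = random_rotate(img, lab, spec, int(draw_seeds[i]))
            d_img, d_lab = elastic_deform(r_img, r_lab, spec, int(draw_seeds[i + 1]))
            items.append((d_img, d_lab))
            i += 2
    order = np.random.default_rng(epoch_seed).permutation(len(items))
    return [items[j] for j in order]
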