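"""Training loss and evaluation metrics for ventricle parcellation.

The loss is one minus the mean soft Dice coefficient over all L labels
(background included), with an epsilon guard so empty labels contribute a
term of 1 instead of 0/0.  Evaluation uses three complementary metrics, per
compartment and for the whole ventricular system (union of labels 1-4):

* DSC — volume overlap, ``2|S∩T| / (|S|+|T|)``, unitless in [0, 1];
* HD95 — the 95th-percentile symmetric boundary distance in mm, a
  robustified Hausdorff distance;
* AVD — absolute volume difference ``|V_S - V_T| / V_T x 100`` in percent.

HD95 is computed between boundary voxels (mask voxels with at least one
6-neighbour outside the mask), with distances in mm via the voxel spacing;
the 95th percentile (linear interpolation between order statistics) is taken
inside each directed distance set and the two directions are combined with a
max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volumes import LabelVolume, N_LABELS, VENTRICLE_LABELS

__all__ = ["dice_loss", "dsc", "hd95", "avd", "evaluate", "LossValue",
           "one_hot", "boundary_voxels"]


@dataclass
class LossValue:
    """Mean-Dice loss: ``value = 1 - mean(per_label_terms)``."""

    value: float
    per_label_terms: np.ndarray


def one_hot(labels: np.ndarray, n_labels: int = N_LABELS) -> np.ndarray:
    """One-hot encode an integer label grid to (L, D, H, W) float32."""
    labels = np.asarray(labels)
    out = np.zeros((n_labels, *labels.shape), dtype=np.float32)
    for l in range(n_labels):
        out[l] = labels == l
    return out


def dice_loss(P: np.ndarray, T: np.ndarray, epsilon: float = 1e-3) -> LossValue:
    """One minus the mean soft Dice coefficient of all the labels.

    ``P`` is a (L, D, H, W) probability field (simplex-normalized over the
    first axis); ``T`` is an integer label grid or a one-hot field of the
    same spatial shape.  For each label l the term is

        (eps + 2 sum_i P_il T_il) / (eps + sum_i P_il + sum_i T_il)

    and the loss is 1 minus their mean; ``epsilon`` avoids a zero denominator
    when a label is absent from both prediction and truth (the term is then
    ~eps/eps = 1, i.e. vacuously perfect).
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 4:
        raise ValueError("P must be (L, D, H, W)")
    L = P.shape[0]
    T = np.asarray(getattr(T, "data", T))
    if T.ndim == 3:
        if T.shape != P.shape[1:]:
            raise ValueError(f"shape mismatch: P spatial {P.shape[1:]} vs T {T.shape}")
        if T.max(initial=0) >= L:
            raise ValueError(f"label {int(T.max())} outside the {L}-label scheme")
        T = one_hot(T, L)
    elif T.shape != P.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs one-hot T {T.shape}")
    T = T.astype(np.float64)
    inter = (P * T).sum(axis=(1, 2, 3))
    terms = (epsilon + 2.0 * inter) / (epsilon + P.sum(axis=(1, 2, 3)) + T.sum(axis=(1, 2, 3)))
    return LossValue(float(1.0 - terms.mean()), terms)


def dsc(S: np.ndarray, T: np.ndarray) -> float:
    """Dice similarity coefficient between two binary masks.

    Defined as 1 when both masks are empty (vacuous perfect agreement) and 0
    when exactly one is empty.
    """
    S = np.asarray(S, dtype=bool)
    T = np.asarray(T, dtype=bool)
    if S.shape != T.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {T.shape}")
    ns, nt = int(S.sum()), int(T.sum())
    if ns + nt == 0:
        return 1.0
    return 2.0 * int((S & T).sum()) / (ns + nt)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (n, 3) of mask voxels with at least one 6-neighbour outside
    the mask; voxels beyond the grid edge count as outside."""
    mask = np.asarray(mask, dtype=bool)
    interior = np.ones_like(mask)
    for axis in range(3):
        lo = np.roll(mask, 1, axis=axis)
        hi = np.roll(mask, -1, axis=axis)
        # rolled-in faces are outside the grid
        sl_lo = [slice(None)] * 3
        sl_lo[axis] = 0
        lo[tuple(sl_lo)] = False
        sl_hi = [slice(None)] * 3
        sl_hi[axis] = -1
        hi[tuple(sl_hi)] = False
        interior &= lo & hi
    return np.argwhere(mask & ~interior)


def hd95(A: np.ndarray, B: np.ndarray, spacing=(1.0, 1.0, 1.0),
         percentile: float = 95.0) -> float:
    """95th-percentile symmetric boundary distance in mm.

    Raises on an empty mask (the distance is undefined there), distinctly
    from a shape mismatch.
    """
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if not A.any() or not B.any():
        raise ValueError("hd95 is undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    pa = boundary_voxels(A) * spacing
    pb = boundary_voxels(B) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def avd(S: np.ndarray, T: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Absolute volume difference in percent of the truth volume."""
    S = np.asarray(S, dtype=bool)
    T = np.asarray(T, dtype=bool)
    nt = int(T.sum())
    if nt == 0:
        raise ValueError("avd is undefined for an empty truth mask")
    vv = float(np.prod(spacing))
    vs, vt = int(S.sum()) * vv, nt * vv
    return abs(vs - vt) / vt * 100.0


#: Row labels of a metric report.
STRUCTURES = {1: "RLV", 2: "LLV", 3: "3rd", 4: "4th", "whole": "Whole"}


def evaluate(prediction: LabelVolume, truth: LabelVolume,
             spacing=None) -> pd.DataFrame:
    """Per-structure and whole-system DSC / HD95 / AVD for one subject.

    Returns a DataFrame indexed by structure name with columns ``dsc``,
    ``hd95_mm``, ``avd_pct``, ``volume_pred_ml``, ``volume_true_ml`` and
    ``applicable``.  A structure absent from BOTH volumes is flagged not
    applicable and its metrics are NaN rather than fabricated; a structure
    present in exactly one volume gets DSC 0 and NaN distances.  Spacing
    defaults to the truth volume's header spacing.
    """
    pred = np.asarray(getattr(prediction, "data", prediction))
    true = np.asarray(getattr(truth, "data", truth))
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if spacing is None:
        spacing = getattr(truth, "spacing", (1.0, 1.0, 1.0))
    vv_ml = float(np.prod(spacing)) / 1000.0
    rows = []
    targets = [(l, pred == l, true == l) for l in VENTRICLE_LABELS]
    targets.append(("whole", (pred > 0) & (pred <= 4), (true > 0) & (true <= 4)))
    for key, s, t in targets:
        ns, nt = int(s.sum()), int(t.sum())
        row = {
            "structure": STRUCTURES[key],
            "volume_pred_ml": ns * vv_ml,
            "volume_true_ml": nt * vv_ml,
            "applicable": ns + nt > 0,
        }
        if ns + nt == 0:
            row.update(dsc=np.nan, hd95_mm=np.nan, avd_pct=np.nan)
        else:
            row["dsc"] = dsc(s, t)
            row["hd95_mm"] = hd95(s, t, spacing) if (ns and nt) else np.nan
            row["avd_pct"] = avd(s, t, spacing) if nt else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("structure")
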