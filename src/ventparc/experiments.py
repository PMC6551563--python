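"""Canned desk-scale experiments on synthetic phantoms.

These functions define the package's reference CPU-scale study: a 12-subject
training cohort of 32^3 phantoms spanning the enlargement range, 2
validation and 4 held-out test subjects, the depth-3 network, and the full
augmentation protocol.  A smaller 16^3 setting compares the convergence
speed of the multi-level-fusion head against the single-level head.  All
randomness derives from one master seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .augment import AugmentSpec
from .network import NetworkSpec
from .phantom import PhantomSpec, generate_cohort
from .pipeline import TrainConfig, desk_config, evaluate_cohort, predict, train

ENLARGEMENT_RANGE = (0.0, 3.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def desk_phantom_sets(seed: int = 0, shape=(32, 32, 32),
                      n_train: int = 12, n_val: int = 2, n_test: int = 4):
    """The desk-scale cohorts: (train, val, test) lists of (image, labels)."""
    tpl = PhantomSpec(shape=shape, spacing=(4.0, 4.0, 4.0))
    s_train, s_val, s_test = _child_seeds(seed, 3)
    train_ph = generate_cohort(n_train, tpl, ENLARGEMENT_RANGE, seed=s_train)
    val_ph = generate_cohort(n_val, tpl, (0.75, 2.25), seed=s_val)
    test_ph = generate_cohort(n_test, tpl, ENLARGEMENT_RANGE, seed=s_test)
    strip = lambda cohort: [(img, lab) for img, lab, _ in cohort]
    return strip(train_ph), strip(val_ph), strip(test_ph)


def tiny_phantom_sets(seed: int = 0):
    """A minimal 20^3 train/val split for fast reproducibility checks."""
    tpl = PhantomSpec(shape=(20, 20, 20), spacing=(4.0, 4.0, 4.0),
                      jitter_translate_vox=1.0)
    s_train, s_val = _child_seeds(seed + 3, 2)
    train_set = [(i, l) for i, l, _ in
                 generate_cohort(3, tpl, (0.0, 1.5), seed=s_train)]
    val_set = [(i, l) for i, l, _ in
               generate_cohort(1, tpl, (1.0, 1.0), seed=s_val)]
    return train_set, val_set


def run_desk_training(seed: int = 0, epochs: int = 20, verbose: bool = False):
    """Train the desk preset on the desk cohorts; returns
    ``(model, log, heldout_summary)`` with the held-out per-structure
    mean/sd DSC, HD95 and AVD."""
    train_set, val_set, test_set = desk_phantom_sets(seed)
    config = replace(desk_config(seed=seed), epochs=epochs)
    model, log = train(train_set, val_set, config, verbose=verbose)
    preds = [(predict(img, model), lab) for img, lab in test_set]
    _, summary = evaluate_cohort(preds)
    return model, log, summary


def convergence_comparison(seed: int = 0, epochs: int = 12,
                           threshold: float = 0.35, verbose: bool = False):
    """Epochs needed to push validation loss below ``threshold`` for the
    fusion head vs the single-level head, same data and seed (16^3 setting).

    Returns ``{"fusion": int | None, "no_fusion": int | None}``.
    """
    # 20^3 grid with a narrower enlargement range and milder pose jitter:
    # at this resolution the full range would push ventricles into the
    # brain-mask margin for some subjects.
    tpl = PhantomSpec(shape=(20, 20, 20), spacing=(4.0, 4.0, 4.0),
                      jitter_translate_vox=1.0)
    s_train, s_val = _child_seeds(seed + 17, 2)
    train_set = [(i, l) for i, l, _ in
                 generate_cohort(6, tpl, (0.0, 2.0), seed=s_train)]
    val_set = [(i, l) for i, l, _ in
               generate_cohort(2, tpl, (0.5, 1.5), seed=s_val)]
    out = {}
    for key, fuse in (("fusion", True), ("no_fusion", False)):
        config = TrainConfig(
            network=NetworkSpec(depth=3, channels=(8, 16, 32),
                                fuse_multilevel=fuse, seed=seed),
            augment=AugmentSpec(rotation_max_deg=10.0, elastic_sigma=16.0,
                                elastic_alpha=4.0, seed=seed),
            epochs=epochs, seed=seed)
        _, log = train(train_set, val_set, config, verbose=verbose)
        out[key] = log.epochs_to_reach(threshold)
    return out
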