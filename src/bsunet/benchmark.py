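"""Desk-scale benchmark: train every variant on one patient-exclusive fold
of a seeded phantom cohort and measure held-out accuracy.

The small preset (64x64 phantoms, 1/8 channel widths, 50 epochs, 20
training / 5 test images) exercises the same protocol as the full-scale
study — two-stage cascade training included — at CPU scale.  The stage-1
conventional U-net is trained once per seed and shared: it is both the
``unet`` result and the frozen guidance source for the cascade variants.
"""
from __future__ import annotations

import numpy as np

from .architectures import VARIANTS
from .estimators import SMALL_PRESET, DiscSegmenter
from .metrics import MetricReport, boundary_dice, dice, mhd
from .errors import UndefinedMetricError
from .phantom import generate_cohort, small_params
from .training import cohort_arrays, make_folds

__all__ = ["case_report", "run_small_benchmark", "summarize_benchmark"]


def case_report(pred, label, spacing_mm: float = 1.5) -> MetricReport:
    """Metric report tolerating empty predictions (MHD becomes NaN)."""
    try:
        m = mhd(pred, label, spacing_mm)
    except UndefinedMetricError:
        m = float("nan")

    def safe_bdice(t):
        try:
            return boundary_dice(pred, label, t)
        except UndefinedMetricError:
            return 0.0

    return MetricReport(dice(pred, label) if (pred.sum() + label.sum()) else 0.0,
                        safe_bdice(1), safe_bdice(2), m)


def run_small_benchmark(seed: int, variants=VARIANTS, epochs: int | None = None,
                        n_patients: int = 20, total_slices: int = 25,
                        k: int = 5, fold: int = 0, verbose: int = 0):
    """Train the requested variants for one seed; returns
    ``{variant: [MetricReport per held-out case]}``."""
    preset = dict(SMALL_PRESET)
    if epochs is not None:
        preset["epochs"] = epochs
    cohort = generate_cohort(n_patients, small_params(seed=seed), seed,
                             total_slices=total_slices)
    split = make_folds(cohort, k, seed)
    train_ids, test_ids = split.fold_cases(fold)
    Xtr, ytr, _ = cohort_arrays(cohort, train_ids)
    Xte, yte, _ = cohort_arrays(cohort, test_ids)
    spacing = small_params().spacing_mm

    results: dict[str, list[MetricReport]] = {}
    stage1 = None
    if "unet" in variants or "cascaded_unet" in variants or "bsu_net" in variants:
        stage1 = DiscSegmenter(variant="unet", random_state=seed,
                               verbose=verbose, **preset)
        stage1.fit(Xtr, ytr)
    for variant in variants:
        if variant == "unet":
            est = stage1
        elif variant == "dilated_unet":
            est = DiscSegmenter(variant=variant, random_state=seed,
                                verbose=verbose, **preset)
            est.fit(Xtr, ytr)
        else:
            est = DiscSegmenter(variant=variant, random_state=seed,
                                verbose=verbose, **preset)
            est.fit(Xtr, ytr, stage1=stage1)
        pred = est.predict(Xte)
        results[variant] = [case_report(p, t, spacing)
                            for p, t in zip(pred, yte)]
    return results


def summarize_benchmark(results) -> dict:
    """Per-variant mean whole-area and 1-px boundary Dice."""
    out = {}
    for variant, reports in results.items():
        out[variant] = {
            "dsc_whole": float(np.mean([r.dsc_whole for r in reports])),
            "dsc_boundary_1px": float(np.mean([r.dsc_boundary_1px
                                               for r in reports])),
        }
    return out
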