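"""Evaluation metrics and reports.

Prediction accuracy is scored with the coefficient of determination R^2 per
profile feature. Profile-shape similarity uses two L2 metrics: the
point-wise profile distance (RMS of sample-wise torque differences, Nm/kg)
and the symmetric Chamfer distance between the curves viewed as 2-D point
sets in normalized (phase, torque) coordinates. The pipeline report mirrors
the standard three-way comparison: simulated (post-processed
optimal-assistance curves) vs ground truth (template curves from fitted
parameters) vs predicted (template curves from network outputs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import MetricError
from .predictor import TARGET_NAMES


def r_squared(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise MetricError("shape mismatch")
    if actual.size < 2:
        raise MetricError("need at least two observations")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("R^2 undefined: actual values have zero variance")
    ss_res = float(np.sum((actual - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def pointwise_distance(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """RMS of sample-wise differences between two equal-length curves."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise MetricError("curves must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def chamfer_distance(curve_a: np.ndarray, curve_b: np.ndarray,
                     torque_scale: float | None = None) -> float:
    """Symmetric Chamfer distance between two curves as 2-D point sets.

    Points are (phase/100, torque/torque_scale); the scale defaults to the
    joint maximum of both curves so the metric is dimensionless. Returns the
    mean of the two directed mean nearest-neighbour distances.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MetricError("point sets must be non-empty")
    if torque_scale is None:
        torque_scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))),
                           1e-12)
    pa = np.column_stack([np.linspace(0, 1, a.size), a / torque_scale])
    pb = np.column_stack([np.linspace(0, 1, b.size), b / torque_scale])
    d = cdist(pa, pb)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


def chamfer_points(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Chamfer distance between two explicit 2-D point sets."""
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if pa.size == 0 or pb.size == 0:
        raise MetricError("point sets must be non-empty")
    d = cdist(pa, pb)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


PAIR_LABELS = ("simulated_vs_ground_truth", "simulated_vs_predicted",
               "ground_truth_vs_predicted")


def profile_comparison_table(simulated: list, ground_truth: list,
                             predicted: list) -> pd.DataFrame:
    """The three pairwise shape comparisons, averaged over matched samples.

    Inputs are matched lists of 101-sample curves (Nm/kg). Returns a frame
    with one row per pair and columns ``pointwise`` and ``chamfer``.
    """
    if not len(simulated) == len(ground_truth) == len(predicted):
        raise MetricError("sample counts differ between sources")
    pairs = {
        "simulated_vs_ground_truth": (simulated, ground_truth),
        "simulated_vs_predicted": (simulated, predicted),
        "ground_truth_vs_predicted": (ground_truth, predicted),
    }
    rows = {}
    for label, (xs, ys) in pairs.items():
        pw = [pointwise_distance(x, y) for x, y in zip(xs, ys)]
        ch = [chamfer_distance(x, y) for x, y in zip(xs, ys)]
        rows[label] = {"pointwise": float(np.mean(pw)),
                       "chamfer": float(np.mean(ch))}
    return pd.DataFrame.from_dict(rows, orient="index")


def per_feature_r2(actual: np.ndarray, predicted: np.ndarray) -> dict:
    """R^2 per profile feature, keyed by canonical target name."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return {name: r_squared(actual[:, j], predicted[:, j])
            for j, name in enumerate(TARGET_NAMES)}


def evaluate_pipeline(sample_ids: list, simulated_curves: list,
                      gt_params: np.ndarray, predicted_params: dict,
                      gt_curves: list, predicted_curves: dict) -> dict:
    """Assemble the evaluation report.

    ``predicted_params``/``predicted_curves`` map a stage label (e.g.
    ``before_transfer``/``after_transfer``) to per-sample predictions matched
    to ``sample_ids``. Returns a JSON-serializable dict with per-feature R^2
    per stage and the 3x2 shape-comparison block per stage.
    """
    n = len(sample_ids)
    if len(simulated_curves) != n or len(gt_curves) != n or \
            len(gt_params) != n:
        raise MetricError("unmatched sample counts in evaluation inputs")
    report: dict = {"n_samples": n, "r2": {}, "profile_distances": {}}
    for stage, params in predicted_params.items():
        if len(params) != n:
            raise MetricError(f"unmatched sample count for stage {stage!r}")
        report["r2"][stage] = per_feature_r2(gt_params, np.asarray(params))
    for stage, curves in predicted_curves.items():
        if len(curves) != n:
            raise MetricError(f"unmatched sample count for stage {stage!r}")
        table = profile_comparison_table(simulated_curves, gt_curves, curves)
        report["profile_distances"][stage] = {
            label: dict(table.loc[label]) for label in table.index}
    return report


def condition_anova(long_table: pd.DataFrame):
    """Two-way ANOVA of metabolic power on condition and speed (plumbing).

    ``long_table`` needs columns ``E`` (W/kg), ``condition`` and ``speed``.
    Returns the statsmodels ANOVA table.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("E ~ C(condition) + C(speed) + C(condition):C(speed)",
                data=long_table).fit()
    return sm.stats.anova_lm(model, typ=2)
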