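"""Applying a signature to new data and evaluating it.

The signature response of an activation map is the dot product of its
in-mask voxels with the signature weights — a single scalar prediction.
Local pattern expression restricts the product to one contiguous region,
optionally with absolute weights so that the sign of the resulting
correlation with stimulus intensity is interpretable. Evaluation
constructs: leave-one-subject-out development/application, quartile-binned
prediction–outcome correlation, and forced-choice discrimination of high
versus low pain trials (with optional trial averaging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import GridSpec, WeightMap
from .develop import Region, SignatureDeveloper

__all__ = [
    "signature_response",
    "local_pattern_expression",
    "CorrelationReport",
    "intensity_correlation_analysis",
    "loso_develop_and_apply",
    "quartile_binned_correlation",
    "forced_choice_accuracy",
]


def _values_and_grid(obj):
    if isinstance(obj, WeightMap):
        return obj.values, obj.grid
    return np.asarray(obj, dtype=float), None


def signature_response(image, weight_map):
    """Dot product of an image (or stack) with a weight map.

    Grids are compared when both sides carry one; a mismatch is an error —
    maps are never silently resampled.
    """
    w, wgrid = _values_and_grid(weight_map)
    x, xgrid = _values_and_grid(image)
    if wgrid is not None and xgrid is not None and not wgrid.matches(xgrid):
        raise ValueError("image and weight map are on different grids")
    x = np.atleast_2d(x)
    if x.shape[1] != w.shape[0]:
        raise ValueError(
            f"image has {x.shape[1]} voxels, weight map has {w.shape[0]}"
        )
    out = x @ w
    return float(out[0]) if np.ndim(image) == 1 else out


def local_pattern_expression(image, region, weight_map, absolute: bool = True):
    """Signature response restricted to one region's voxels.

    With ``absolute=True`` the weights are replaced by their absolute
    values, so a positive correlation with stimulus intensity means the
    region's activation increases with intensity regardless of weight sign.
    """
    w, wgrid = _values_and_grid(weight_map)
    idx = region.voxel_indices if isinstance(region, Region) else np.asarray(region, int)
    if idx.size and (idx.min() < 0 or idx.max() >= w.shape[0]):
        raise ValueError("region voxels fall outside the mask")
    x, xgrid = _values_and_grid(image)
    if wgrid is not None and xgrid is not None and not wgrid.matches(xgrid):
        raise ValueError("image and weight map are on different grids")
    wr = np.abs(w[idx]) if absolute else w[idx]
    x = np.atleast_2d(x)
    out = x[:, idx] @ wr
    return float(out[0]) if np.ndim(image) == 1 else out


@dataclass
class CorrelationReport:
    """Region-wise correlations of local expression with stimulus intensity."""

    r: np.ndarray  # (n_subjects, n_regions), NaN where skipped
    z: np.ndarray  # Fisher z of r
    t: np.ndarray  # per-region one-sample t over subjects
    p: np.ndarray
    alpha_corrected: float
    significant: np.ndarray
    region_labels: list


def intensity_correlation_analysis(datasets, regions, weight_map,
                                   family_alpha: float = 0.05,
                                   absolute: bool = True) -> CorrelationReport:
    """Which regions' local expression tracks noxious stimulus intensity?

    Per subject and region, the Pearson correlation between trial-by-trial
    local pattern expression (absolute weights by default) and stimulus
    intensity is computed; correlations are Fisher z-transformed and a
    one-sample t-test across subjects is run per region, Bonferroni
    corrected at ``family_alpha / n_regions``.
    """
    if len(datasets) < 3:
        raise ValueError("need at least 3 subjects")
    m = len(regions)
    if m == 0:
        raise ValueError("no regions supplied")
    r = np.full((len(datasets), m), np.nan)
    for i, d in enumerate(datasets):
        keep = d.included()
        iv = d.intensity_values()[keep]
        if np.unique(iv).size < 2:
            warnings.warn(
                f"subject {d.subject_id}: constant stimulus intensity; skipped"
            )
            continue
        X = d.X[keep]
        for j, reg in enumerate(regions):
            expr = local_pattern_expression(X, reg, weight_map, absolute=absolute)
            if np.ptp(expr) == 0:
                continue
            r[i, j] = np.corrcoef(expr, iv)[0, 1]
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    t = np.empty(m)
    p = np.empty(m)
    for j in range(m):
        zj = z[:, j][~np.isnan(z[:, j])]
        if zj.size < 3:
            t[j], p[j] = np.nan, np.nan
            continue
        res = stats.ttest_1samp(zj, 0.0)
        t[j], p[j] = float(res.statistic), float(res.pvalue)
    alpha_corrected = family_alpha / m
    labels = [reg.label if isinstance(reg, Region) else f"region_{j + 1}"
              for j, reg in enumerate(regions)]
    return CorrelationReport(
        r=r, z=z, t=t, p=p, alpha_corrected=alpha_corrected,
        significant=p < alpha_corrected, region_labels=labels,
    )


def loso_develop_and_apply(datasets, developer: SignatureDeveloper | None = None,
                           **developer_params):
    """Leave-one-subject-out development and out-of-sample scoring.

    For each held-out subject, the group signature is aggregated from the
    remaining subjects' models only; the held-out subject's residualized
    trials are then scored with that map. The held-out subject never
    influences its own map (its per-subject model is excluded from the
    aggregate and the voxel-wise weighting uses the others' precisions), so
    perturbing their ratings leaves the map applied to them unchanged.

    Because per-subject decoders are independent of each other, each
    subject's model is fit once and the per-fold work is the aggregation.

    Returns
    -------
    dict with per-subject ``responses`` (on residualized held-out trials),
    ``residual_ratings``, ``weights`` (the map applied to that subject)
    and ``r`` (response–rating correlation).
    """
    from .develop import aggregate_group_map, fit_subject_model

    if len(datasets) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    dev = developer if developer is not None else SignatureDeveloper(**developer_params)

    residuals, models = [], []
    for d in datasets:
        X_res, y_res = dev.residualized(d)
        residuals.append((X_res, y_res))
        models.append(fit_subject_model(
            X_res, y_res, subject_id=d.subject_id,
            n_components=dev.n_components, cv_folds=dev.cv_folds,
            seed=dev.random_state, folds=dev.cv_scheme,
        ))

    out = {}
    for k, d in enumerate(datasets):
        train = [m for i, m in enumerate(models) if i != k]
        w = aggregate_group_map(train)
        X_res, y_res = residuals[k]
        resp = X_res @ w
        r = (np.nan if np.ptp(resp) == 0 or np.ptp(y_res) == 0
             else float(np.corrcoef(resp, y_res)[0, 1]))
        out[d.subject_id] = {
            "responses": resp, "residual_ratings": y_res,
            "weights": w, "r": r,
        }
    return out


def quartile_binned_correlation(predicted, actual) -> float:
    """Correlation of quartile-binned, z-scored predictions and outcomes.

    Both series are z-scored; trials are split into quartiles by the actual
    outcome (ties broken by a stable sort on trial index); each series is
    averaged within bins, and the Pearson correlation over the four bin
    means is returned. Needs at least 8 trials (two per quartile).
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual lengths differ")
    n = pred.size
    if n < 8:
        raise ValueError("quartile binning needs at least 8 trials")
    zp = (pred - pred.mean()) / pred.std(ddof=1)
    za = (act - act.mean()) / act.std(ddof=1)
    order = np.argsort(za, kind="stable")
    bins = np.array_split(order, 4)
    bp = np.array([zp[b].mean() for b in bins])
    ba = np.array([za[b].mean() for b in bins])
    return float(np.corrcoef(bp, ba)[0, 1])


def forced_choice_accuracy(responses, ratings, frac: float = 0.30,
                           n_avg: int = 1, seed: int | None = 0) -> float:
    """Two-alternative forced-choice accuracy, high vs low pain trials.

    Trials are ranked by rating; the top and bottom ``frac`` form the high
    and low classes. Each class is randomly grouped into sets of ``n_avg``
    trials whose responses are averaged (single trials when ``n_avg=1``);
    accuracy is the fraction of all high/low set pairs where the high set's
    average response exceeds the low set's (ties count 1/2). Averaging
    several trials reduces response noise, so accuracy is non-decreasing in
    ``n_avg`` in expectation.
    """
    resp = np.asarray(responses, dtype=float)
    rate = np.asarray(ratings, dtype=float)
    if resp.shape != rate.shape:
        raise ValueError("responses and ratings lengths differ")
    n = resp.size
    k = int(np.floor(frac * n))
    if k < n_avg or k < 1:
        raise ValueError(
            f"only {k} trials per class; cannot form one set of {n_avg}"
        )
    order = np.argsort(rate, kind="stable")
    low_idx, high_idx = order[:k], order[-k:]
    rng = np.random.default_rng(seed)

    def averaged(idx):
        idx = rng.permutation(idx)
        n_sets = len(idx) // n_avg
        return resp[idx[: n_sets * n_avg]].reshape(n_sets, n_avg).mean(axis=1)

    hi, lo = averaged(high_idx), averaged(low_idx)
    diff = hi[:, None] - lo[None, :]
    return float(np.mean((diff > 0) + 0.5 * (diff == 0)))
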