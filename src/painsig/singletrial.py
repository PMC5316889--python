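"""Beta-series single-trial estimation and quality control.

Trial-level activation maps are estimated from a voxels-by-time run with a
GLM holding one convolved boxcar regressor per trial ("beta series") plus
intercept, linear drift, caller-supplied nuisance columns (e.g. motion
parameters) and indicator columns for spike volumes. QC follows two rules:

* trials whose design regressor has a variance inflation factor above 2.5
  are flagged (never deleted) as collinearity-compromised;
* volumes whose concatenated slice-wise mean/s.d. feature vector has an
  outlying Mahalanobis distance (chi-square test, the stricter of
  Bonferroni and Benjamini–Hochberg correction) are flagged as spikes.

An alternative three-basis fit (canonical HRF shifted in time) yields
per-trial area-under-the-curve estimates for studies where the response
shape varies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "canonical_hrf",
    "DesignMatrix",
    "QCReport",
    "build_single_trial_design",
    "estimate_trial_betas",
    "detect_spikes",
    "flexible_basis_auc",
    "compute_vif",
]


def canonical_hrf(dt: float, duration: float = 32.0, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                  undershoot_disp: float = 1.0, ratio: float = 1.0 / 6.0,
                  time_shift: float = 0.0) -> np.ndarray:
    """Double-gamma haemodynamic response kernel, unit peak.

    The standard difference-of-gammas impulse response: a positive gamma
    peaking near 5 s minus a scaled gamma producing the post-stimulus
    undershoot near 15 s, sampled every ``dt`` seconds over ``duration``
    seconds and scaled so the maximum is 1. ``time_shift`` delays the
    kernel (used by the shifted three-basis set).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt) - time_shift
    tt = np.where(t > 0, t, 0.0)
    h = (stats.gamma.pdf(tt, a=peak_delay / peak_disp, scale=peak_disp)
         - ratio * stats.gamma.pdf(tt, a=undershoot_delay / undershoot_disp,
                                   scale=undershoot_disp))
    h[t <= 0] = 0.0
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / np.max(h)
    return h


@dataclass
class DesignMatrix:
    """Time-by-regressor design with per-regressor roles and trial VIFs."""

    matrix: np.ndarray
    labels: list  # per-column role: trial / spike / drift / nuisance / intercept
    names: list
    vif: np.ndarray = field(default=None)  # per trial regressor, design order

    def __post_init__(self):
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("one label per design column required")
        if self.vif is None:
            self.vif = compute_vif(self.matrix, self.trial_columns)

    @property
    def trial_columns(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == "trial")

    @property
    def n_trials(self) -> int:
        return len(self.trial_columns)


def compute_vif(X: np.ndarray, columns=None) -> np.ndarray:
    """Variance inflation factor 1/(1-R²) per requested column.

    Each column is regressed on all remaining columns; R² is centred when
    the other columns span an intercept, uncentred otherwise. Perfect
    collinearity yields ``inf`` rather than an exception.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if columns is None:
        columns = np.arange(p)
    has_const = any(np.ptp(X[:, j]) == 0 and np.any(X[:, j] != 0)
                    for j in range(p))
    out = np.empty(len(columns))
    for i, j in enumerate(columns):
        others = np.delete(np.arange(p), j)
        x = X[:, j]
        if others.size == 0:
            out[i] = 1.0
            continue
        coef, _, _, _ = np.linalg.lstsq(X[:, others], x, rcond=None)
        resid = x - X[:, others] @ coef
        ss_res = float(resid @ resid)
        if has_const:
            ss_tot = float(np.sum((x - x.mean()) ** 2))
        else:
            ss_tot = float(x @ x)
        if ss_tot <= 0:
            out[i] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def build_single_trial_design(events, n_scans: int, dt: float,
                              nuisance: np.ndarray | None = None,
                              spike_indices=(), add_drift: bool = True,
                              hrf: np.ndarray | None = None,
                              duration_key: str = "duration") -> DesignMatrix:
    """Build a beta-series design: one convolved boxcar per trial.

    Parameters
    ----------
    events : DataFrame with ``onset``/``duration`` (seconds) or sequence of
        ``(onset, duration)`` pairs, one per trial.
    n_scans : number of volumes.
    dt : sampling interval (the repetition time), seconds.
    nuisance : optional (n_scans, k) matrix of nuisance covariates.
    spike_indices : volumes to absorb with indicator columns.
    add_drift : include a linear drift column.
    hrf : impulse response to convolve with; default :func:`canonical_hrf`.

    The VIF of every trial regressor (1/(1-R²) against all other columns)
    is computed on the assembled matrix; a rank-deficient design yields
    infinite VIFs, not an exception.
    """
    if isinstance(events, pd.DataFrame):
        pairs = list(zip(events["onset"], events[duration_key]))
    else:
        pairs = [(float(o), float(d)) for o, d in events]
    for onset, _ in pairs:
        if onset < 0 or onset >= n_scans * dt:
            raise ValueError(f"event onset {onset} outside the run")
    if hrf is None:
        hrf = canonical_hrf(dt)

    t_grid = np.arange(n_scans)
    cols, labels, names = [], [], []
    for i, (onset, duration) in enumerate(pairs):
        box = ((t_grid >= onset / dt) & (t_grid < (onset + duration) / dt)).astype(float)
        cols.append(np.convolve(box, hrf)[:n_scans])
        labels.append("trial")
        names.append(f"trial_{i + 1:03d}")
    for v in spike_indices:
        ind = np.zeros(n_scans)
        ind[int(v)] = 1.0
        cols.append(ind)
        labels.append("spike")
        names.append(f"spike_{int(v)}")
    if add_drift:
        drift = np.linspace(-1, 1, n_scans)
        cols.append(drift)
        labels.append("drift")
        names.append("drift")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance columns must have length n_scans")
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            labels.append("nuisance")
            names.append(f"nuisance_{k + 1}")
    cols.append(np.ones(n_scans))
    labels.append("intercept")
    names.append("intercept")

    X = np.column_stack(cols)
    return DesignMatrix(matrix=X, labels=labels, names=names)


@dataclass
class QCReport:
    """Quality-control outcome: spike volumes and VIF-excluded trials."""

    spike_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    spike_stat: np.ndarray | None = None  # per-volume squared Mahalanobis distance
    chi2_threshold: float | None = None
    excluded_trials: dict = field(default_factory=dict)  # trial idx -> VIF
    vif: np.ndarray | None = None


def estimate_trial_betas(timeseries: np.ndarray, design: DesignMatrix,
                         vif_threshold: float = 2.5):
    """OLS beta-series estimates plus VIF-based trial exclusion flags.

    Returns ``(betas, report)`` where ``betas`` is (n_trials, n_vox) — the
    coefficients of the trial regressors only — and ``report.excluded_trials``
    maps 0-based trial indices with VIF above ``vif_threshold`` (2.5 by
    convention) to their VIF. Flagged trials keep their betas; exclusion is
    the caller's bookkeeping.
    """
    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("timeseries length does not match the design")
    if Y.shape[0] < X.shape[1]:
        raise ValueError(
            f"{Y.shape[0]} time points < {X.shape[1]} regressors: underdetermined"
        )
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    betas = coef[design.trial_columns]
    vif = design.vif
    excluded = {int(t): float(v) for t, v in enumerate(vif) if v > vif_threshold}
    report = QCReport(excluded_trials=excluded, vif=vif)
    return betas, report


def detect_spikes(volumes: np.ndarray, alpha: float = 0.05,
                  slice_axis: int = 2) -> QCReport:
    """Flag outlier volumes by slice-statistic Mahalanobis distance.

    For every volume, the mean and s.d. of each slice along ``slice_axis``
    are concatenated into a feature vector; squared Mahalanobis distances of
    the volumes in feature space are referred to a chi-square law with
    df = number of features, and volumes significant under the stricter of
    Bonferroni and Benjamini–Hochberg correction at ``alpha`` are flagged.

    ``volumes`` is 4-D ``(x, y, z, t)`` or 2-D ``(t, features)`` (already
    extracted features). A singular feature covariance is ridge-inflated
    with a warning; in the fully degenerate (zero variance) case nothing is
    flagged.
    """
    from statsmodels.stats.multitest import multipletests

    V = np.asarray(volumes, dtype=float)
    if V.ndim == 4:
        t_n = V.shape[-1]
        slices = np.moveaxis(V, slice_axis, 0)  # (z, ..., t)
        nz = slices.shape[0]
        feat = np.empty((t_n, 2 * nz))
        flat = slices.reshape(nz, -1, t_n)
        feat[:, :nz] = flat.mean(axis=1).T
        feat[:, nz:] = flat.std(axis=1).T
    elif V.ndim == 2:
        feat = V
        t_n = feat.shape[0]
    else:
        raise ValueError("volumes must be 4-D (x,y,z,t) or 2-D (t,features)")
    if t_n < 10:
        raise ValueError("need at least 10 volumes for spike detection")

    p_feat = feat.shape[1]
    centred = feat - feat.mean(axis=0)
    cov = centred.T @ centred / (t_n - 1)
    scale = np.trace(cov) / p_feat
    if scale <= 0:
        warnings.warn("zero-variance volumes: no spikes detectable")
        return QCReport(spike_indices=np.array([], int),
                        spike_stat=np.zeros(t_n), chi2_threshold=np.inf)
    # regularize if ill-conditioned
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn("singular slice-feature covariance: ridge-inflating diagonal")
        cov = cov + 1e-6 * scale * np.eye(p_feat)
    d2 = np.einsum("ij,ji->i", centred @ np.linalg.inv(cov), centred.T)
    pvals = stats.chi2.sf(d2, df=p_feat)

    bonf = pvals < alpha / t_n
    fdr = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    flags = bonf & fdr  # the stricter of the two corrections
    return QCReport(
        spike_indices=np.flatnonzero(flags),
        spike_stat=d2,
        chi2_threshold=float(stats.chi2.isf(alpha / t_n, df=p_feat)),
    )


def default_three_basis(dt: float, shifts=(0.0, 2.0, 4.0)) -> np.ndarray:
    """Canonical kernel shifted in time — the flexible pain-period basis."""
    return np.column_stack([canonical_hrf(dt, time_shift=s) for s in shifts])


def flexible_basis_auc(timeseries: np.ndarray, events, dt: float,
                       basis: np.ndarray | None = None,
                       nuisance: np.ndarray | None = None,
                       duration_key: str = "duration"):
    """Per-trial, per-voxel area under the fitted flexible response.

    Each trial is modelled with three basis regressors (boxcar convolved
    with time-shifted canonical kernels). After a joint least-squares fit,
    the fitted response of each trial is reconstructed on the kernel grid
    and its (signed) trapezoidal area under the curve is returned —
    a shape-robust amplitude estimate.

    Returns ``(auc, report)`` with ``auc`` of shape (n_trials, n_vox).
    """
    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n_scans = Y.shape[0]
    if basis is None:
        basis = default_three_basis(dt)
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] != 3:
        raise ValueError("basis_spec must define three kernels (columns)")

    if isinstance(events, pd.DataFrame):
        pairs = list(zip(events["onset"], events[duration_key]))
    else:
        pairs = [(float(o), float(d)) for o, d in events]
    n_trials = len(pairs)

    t_grid = np.arange(n_scans)
    cols, labels = [], []
    for onset, duration in pairs:
        box = ((t_grid >= onset / dt) & (t_grid < (onset + duration) / dt)).astype(float)
        for k in range(3):
            cols.append(np.convolve(box, basis[:, k])[:n_scans])
            labels.append("trial")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            labels.append("nuisance")
    cols.append(np.ones(n_scans))
    labels.append("intercept")
    X = np.column_stack(cols)
    if n_scans < X.shape[1]:
        raise ValueError("fewer time points than regressors")

    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    auc = np.empty((n_trials, Y.shape[1]))
    for t in range(n_trials):
        amps = coef[3 * t: 3 * t + 3]  # (3, n_vox)
        fitted = basis @ amps  # (kernel grid, n_vox)
        auc[t] = np.trapezoid(fitted, dx=dt, axis=0)
    report = QCReport()
    return auc, report
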