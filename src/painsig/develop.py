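"""Signature development: residualize, per-subject PCR, group aggregation.

The stimulus-intensity-independent signature is derived in two steps.

Within each subject, pain ratings and every voxel's trial series are
residualized against a design holding an intercept, indicator regressors
for each stimulus intensity level (the lowest dropped for identifiability)
and the reference-signature (nociceptive) response of each trial. The
residuals are orthogonal to the intensity subspace and to the reference
signature; what remains is the intensity-independent variation. A
principal component regression (PCR) decoder is then fit per subject to
predict residual ratings from residual voxel activity, with a 10-fold
cross-validated prediction–outcome correlation as that subject's precision
estimate.

At the group level, each subject's weight map is scaled by the s.d. of its
own weights and maps are averaged with the (non-negative) cross-validated
correlations as precision weights. Weighted one-sample t-tests across
subjects identify voxels with consistent contributions; FDR thresholding
and sign-split connected-component extraction produce contiguous pro-pain
and anti-pain subregions.

A univariate encoding–decoding baseline (per-voxel slopes of residual
activity on residual rating, averaged across subjects, inverted for
prediction) is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .grid import GridSpec, WeightMap

__all__ = [
    "SubjectModel",
    "GroupSignature",
    "Region",
    "residualize_subject",
    "SubjectPCR",
    "crossval_prediction_corr",
    "fit_subject_model",
    "aggregate_group_map",
    "weighted_one_sample_ttest",
    "bh_fdr",
    "extract_regions",
    "univariate_encode_decode",
    "SignatureDeveloper",
]


# ---------------------------------------------------------------------------
# residualization


def _residual_design(intensity_values: np.ndarray,
                     ref_responses: np.ndarray | None) -> np.ndarray:
    """Intercept + per-level indicators (lowest dropped) + reference response."""
    levels = np.unique(intensity_values)
    cols = [np.ones_like(intensity_values)]
    counts = {lev: int(np.sum(intensity_values == lev)) for lev in levels}
    for lev, cnt in counts.items():
        if cnt < 2:
            warnings.warn(
                f"intensity level {lev} has {cnt} trial(s); its residuals are 0"
            )
    for lev in levels[1:]:  # drop the lowest level for identifiability
        cols.append((intensity_values == lev).astype(float))
    if ref_responses is not None:
        if np.ptp(ref_responses) == 0:
            warnings.warn(
                "reference-signature responses have zero variance; dropping regressor"
            )
        else:
            cols.append(np.asarray(ref_responses, dtype=float))
    return np.column_stack(cols)


def residualize_subject(X: np.ndarray, ratings: np.ndarray,
                        intensity_values: np.ndarray,
                        reference_map: np.ndarray | WeightMap | None = None,
                        ref_responses: np.ndarray | None = None):
    """Remove intensity-level and reference-signature effects within subject.

    Parameters
    ----------
    X : (n_trials, n_vox) trial activation matrix.
    ratings : per-trial pain ratings.
    intensity_values : per-trial numeric stimulus intensity codes.
    reference_map : weight vector used to compute per-trial reference
        responses ``X @ w`` (ignored if ``ref_responses`` is given).
    ref_responses : per-trial reference responses, if precomputed.

    Returns
    -------
    X_res, y_res : residuals of the voxel data and the ratings against the
        design [intercept | intensity indicators | reference response].
        Both are orthogonal to every design column to 1e-8.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(ratings, dtype=float)
    iv = np.asarray(intensity_values, dtype=float)
    if not (len(y) == len(iv) == X.shape[0]):
        raise ValueError("trial counts of X, ratings and intensity disagree")
    if ref_responses is None and reference_map is not None:
        w = reference_map.values if isinstance(reference_map, WeightMap) else reference_map
        ref_responses = X @ np.asarray(w, dtype=float)
    D = _residual_design(iv, ref_responses)
    # residual-maker via least squares (rank-safe)
    coef_y, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    coef_X, _, _, _ = np.linalg.lstsq(D, X, rcond=None)
    return X - D @ coef_X, y - D @ coef_y


# ---------------------------------------------------------------------------
# per-subject principal component regression


class SubjectPCR(RegressorMixin, BaseEstimator):
    """Principal component regression decoder for one subject.

    Ratings are regressed on the leading principal-component scores of the
    (centred) trial-by-voxel matrix and the coefficients are mapped back to
    voxel space. With ``n_components="all"`` every component with nonzero
    singular value is kept, which equals unregularized least squares (the
    minimum-norm solution when voxels outnumber trials).

    Attributes
    ----------
    coef_ : (n_vox,) voxel weights.
    intercept_ : float.
    n_components_ : number of components retained.
    """

    def __init__(self, n_components="all"):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n_trials, n_vox) matching y")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int(np.sum(s > tol))
        if self.n_components == "all" or self.n_components is None:
            k = rank
        else:
            k = int(self.n_components)
            if k > rank:
                warnings.warn(
                    f"n_components={k} exceeds rank {rank}; clamping"
                )
                k = rank
        if k == 0 or np.allclose(yc, 0):
            self.coef_ = np.zeros(X.shape[1])
        else:
            # scores T = U_k s_k; regress yc on T, map back through V_k
            Uk, sk, Vk = U[:, :k], s[:k], Vt[:k]
            gamma = (Uk.T @ yc) / sk
            self.coef_ = Vk.T @ gamma
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_components_ = k
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def crossval_prediction_corr(X, y, k: int = 10, n_components="all",
                             seed: int | None = 0,
                             folds: str = "random") -> float:
    """K-fold cross-validated prediction–outcome correlation.

    Trials are partitioned into ``k`` folds (seeded random partition by
    default; ``folds="contiguous"`` uses run-contiguous blocks, useful when
    trial autocorrelation would inflate the estimate). A PCR decoder is fit
    on each training split; the Pearson correlation between the
    concatenated out-of-fold predictions and the outcomes is returned.
    Constant predictions give 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} trials, got {n}")
    pred = np.empty(n)
    if folds == "contiguous":
        splits = ((np.setdiff1d(np.arange(n), te), te)
                  for te in np.array_split(np.arange(n), k))
    else:
        splits = KFold(n_splits=k, shuffle=True, random_state=seed).split(X)
    for train, test in splits:
        model = SubjectPCR(n_components=n_components).fit(X[train], y[train])
        pred[test] = model.predict(X[test])
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        warnings.warn("constant cross-validated predictions; cv_r set to 0")
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1])


@dataclass
class SubjectModel:
    """One subject's decoder: weights, intercept and CV precision."""

    subject_id: str
    weights: np.ndarray
    intercept: float
    cv_r: float
    n_trials_used: int

    def __post_init__(self):
        if not -1.0 <= self.cv_r <= 1.0:
            raise ValueError("cv_r outside [-1, 1]")


def fit_subject_model(X_res, y_res, subject_id: str = "", n_components="all",
                      cv_folds: int = 10, seed: int | None = 0,
                      folds: str = "random") -> SubjectModel:
    """Fit the PCR decoder and its cross-validated precision for one subject."""
    model = SubjectPCR(n_components=n_components).fit(X_res, y_res)
    cv_r = crossval_prediction_corr(X_res, y_res, k=cv_folds,
                                    n_components=n_components, seed=seed,
                                    folds=folds)
    return SubjectModel(subject_id=subject_id, weights=model.coef_,
                        intercept=model.intercept_, cv_r=cv_r,
                        n_trials_used=len(y_res))


# ---------------------------------------------------------------------------
# group aggregation


def aggregate_group_map(models_or_maps, cv_rs=None) -> np.ndarray:
    """Precision-weighted average of s.d.-normalized subject maps.

    Each map is divided by the s.d. of its own weights (harmonizing scale
    across subjects/studies); the group map is the weighted mean with
    weights ``max(cv_r, 0)``. Negative precisions contribute nothing.
    """
    if cv_rs is None:
        maps = np.array([m.weights for m in models_or_maps], dtype=float)
        cv_rs = np.array([m.cv_r for m in models_or_maps], dtype=float)
    else:
        maps = np.asarray(models_or_maps, dtype=float)
        cv_rs = np.asarray(cv_rs, dtype=float)
    w = np.clip(cv_rs, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("no positive precision mass: all cv_r <= 0")
    sds = maps.std(axis=1)
    if (sds == 0).any():
        raise ValueError("a subject map has zero s.d.; cannot normalize")
    normed = maps / sds[:, None]
    return (w[:, None] * normed).sum(axis=0) / w.sum()


def weighted_one_sample_ttest(values: np.ndarray, weights: np.ndarray):
    """Weighted one-sample t-test (reliability-weights form), voxel-wise.

    Weights are normalized to sum to n; the weighted mean m and weighted
    variance s² = Σw(x−m)²/(n−1) give t = m/(s/√n) on n−1 df, two-tailed.
    With equal weights this is exactly the classical one-sample t-test.
    Zero-variance voxels give infinite t with the sign of m and p = 0.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))  # (n_subj, n_vox)
    w = np.asarray(weights, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    wn = w * n / w.sum()
    m = (wn[:, None] * x).sum(axis=0) / n
    s2 = (wn[:, None] * (x - m) ** 2).sum(axis=0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(s2 / n)
    zero = s2 == 0
    t[zero] = np.where(m[zero] > 0, np.inf, np.where(m[zero] < 0, -np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero & (m != 0)] = 0.0  # underflow by convention
    p[zero & (m == 0)] = 1.0
    if np.ndim(values) == 1:
        return float(t[0]), float(p[0])
    return t, p


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level ``q``."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# region extraction


_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class Region:
    """A contiguous same-sign subregion of a thresholded map."""

    label: str
    voxel_indices: np.ndarray  # indices into the grid's in-mask vector
    size: int
    mean_weight: float
    sign: int  # +1 pro-pain, -1 anti-pain


def extract_regions(grid: GridSpec, weights: np.ndarray,
                    surviving: np.ndarray, min_size: int = 15,
                    connectivity: int = 26, allowlist: dict | None = None):
    """Connected components of surviving voxels, split by weight sign.

    Positive- and negative-weight voxels are labelled separately (adjoining
    pro- and anti-pain blobs stay distinct). Components smaller than
    ``min_size`` are dropped unless their label appears in ``allowlist``
    (mapping label -> lower size bound) — mirroring small anatomical
    exceptions kept in region tables.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    weights = np.asarray(weights, dtype=float)
    surviving = np.asarray(surviving, dtype=bool)
    allowlist = allowlist or {}

    # map in-mask vector positions back into the volume
    pos_of_voxel = np.full(grid.shape, -1, dtype=int)
    pos_of_voxel[grid.mask] = np.arange(grid.n_vox)

    regions = []
    for sign, tag in ((1, "pos"), (-1, "neg")):
        vol = np.zeros(grid.shape, dtype=bool)
        sel = surviving & (np.sign(weights) == sign)
        vol[grid.mask] = sel
        labelled, n_comp = ndimage.label(vol, structure=structure)
        for comp in range(1, n_comp + 1):
            where = labelled == comp
            idx = pos_of_voxel[where]
            label = f"{tag}_{len([r for r in regions if r.sign == sign]) + 1:03d}"
            size = int(where.sum())
            bound = allowlist.get(label, min_size)
            if size < bound:
                continue
            regions.append(Region(
                label=label, voxel_indices=np.sort(idx), size=size,
                mean_weight=float(weights[idx].mean()), sign=sign,
            ))
    return regions


@dataclass
class GroupSignature:
    """Aggregated signature map with voxel-wise weighted-t inference."""

    grid: GridSpec
    weights: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q_mask: np.ndarray
    n_subjects: int
    precision_weights: np.ndarray
    regions: list

    def as_weight_map(self) -> WeightMap:
        return WeightMap(grid=self.grid, values=self.weights, name="signature")


# ---------------------------------------------------------------------------
# univariate encoding-decoding baseline


def univariate_encode_decode(residual_pairs, test_images=None):
    """Univariate encode–decode baseline.

    For each subject, the OLS slope of every voxel's residual activity on
    the residual rating is estimated (encoding); the group map is the
    unweighted average of subject maps; decoding a test image averages the
    per-voxel products ``beta_v * x_v`` over in-mask voxels.

    Parameters
    ----------
    residual_pairs : sequence of (X_res, y_res) per subject.
    test_images : optional (n, n_vox) images to decode.

    Returns
    -------
    beta_map : (n_vox,) group encoding map.
    predictions : (n,) decoded values, or None.
    """
    maps = []
    for X_res, y_res in residual_pairs:
        X_res = np.asarray(X_res, dtype=float)
        y = np.asarray(y_res, dtype=float)
        yc = y - y.mean()
        denom = float(yc @ yc)
        if denom == 0:
            raise ValueError("zero-variance residual ratings in a subject")
        Xc = X_res - X_res.mean(axis=0)
        maps.append(Xc.T @ yc / denom)
    beta_map = np.mean(maps, axis=0)
    preds = None
    if test_images is not None:
        imgs = np.atleast_2d(np.asarray(test_images, dtype=float))
        preds = imgs @ beta_map / beta_map.size
    return beta_map, preds


# ---------------------------------------------------------------------------
# the full developer


class SignatureDeveloper(BaseEstimator):
    """End-to-end signature development on a cohort of trial datasets.

    fit() residualizes each subject against intensity indicators and the
    reference-signature response, fits per-subject PCR decoders with
    cross-validated precision, aggregates a precision-weighted group map,
    runs voxel-wise weighted t-tests with FDR thresholding, and extracts
    signed contiguous regions.

    Parameters
    ----------
    reference_map : WeightMap or (n_vox,) array or None
        Nociceptive reference signature regressed out per trial.
    n_components : "all" or int
        PCR components per subject.
    cv_folds : int
        Folds for the prediction–outcome correlation.
    fdr_q : float
        FDR level for the voxel mask.
    min_region_size : int
        Minimum contiguous region size (voxels).
    connectivity : {6, 18, 26}
        Neighbourhood for connected components.
    allowlist : dict or None
        Region label -> lower size bound exceptions.
    random_state : int
        Seed for the CV partition.

    Attributes
    ----------
    weights_ : (n_vox,) group signature map.
    t_, p_, q_mask_ : voxel-wise weighted-t statistics, p-values, FDR mask.
    regions_ : list of :class:`Region`.
    subject_models_ : list of :class:`SubjectModel`.
    signature_ : :class:`GroupSignature`.
    """

    def __init__(self, reference_map=None, n_components="all", cv_folds=10,
                 fdr_q=0.05, min_region_size=15, connectivity=26,
                 allowlist=None, cv_scheme="random", random_state=0):
        self.reference_map = reference_map
        self.n_components = n_components
        self.cv_folds = cv_folds
        self.fdr_q = fdr_q
        self.min_region_size = min_region_size
        self.connectivity = connectivity
        self.allowlist = allowlist
        self.cv_scheme = cv_scheme
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _ref_values(self):
        ref = self.reference_map
        if ref is None:
            return None
        return ref.values if isinstance(ref, WeightMap) else np.asarray(ref, float)

    def residualized(self, dataset):
        """Residualize a dataset's included (painful, non-excluded) trials."""
        keep = dataset.included()
        X = dataset.X[keep]
        y = np.asarray(dataset.ratings, dtype=float)[keep]
        iv = dataset.intensity_values()[keep]
        return residualize_subject(X, y, iv, reference_map=self._ref_values())

    # -- estimator API -----------------------------------------------------

    def fit(self, datasets, y=None):
        if len(datasets) < 3:
            raise ValueError("need at least 3 subjects")
        grid = datasets[0].grid
        for d in datasets:
            if not d.grid.matches(grid):
                raise ValueError("datasets are on different grids")
        self.grid_ = grid

        models = []
        for d in datasets:
            X_res, y_res = self.residualized(d)
            models.append(fit_subject_model(
                X_res, y_res, subject_id=d.subject_id,
                n_components=self.n_components, cv_folds=self.cv_folds,
                seed=self.random_state, folds=self.cv_scheme,
            ))
        self.subject_models_ = models

        self.weights_ = aggregate_group_map(models)
        prec = np.clip([m.cv_r for m in models], 0.0, None)
        normed = np.array([m.weights / m.weights.std() for m in models])
        self.t_, self.p_ = weighted_one_sample_ttest(normed, prec)
        self.q_mask_ = bh_fdr(self.p_, q=self.fdr_q)
        self.regions_ = extract_regions(
            grid, self.weights_, self.q_mask_,
            min_size=self.min_region_size, connectivity=self.connectivity,
            allowlist=self.allowlist,
        )
        self.signature_ = GroupSignature(
            grid=grid, weights=self.weights_, t=self.t_, p=self.p_,
            q_mask=self.q_mask_, n_subjects=len(models),
            precision_weights=prec, regions=self.regions_,
        )
        return self

    def response(self, X):
        """Signature response (dot product) for trial images (n, n_vox)."""
        from .apply import signature_response

        return signature_response(X, self.weights_)

    def transform(self, X):
        return np.atleast_1d(self.response(X))
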