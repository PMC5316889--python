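"""Multilevel inference: hierarchical GLM, variance partitioning, mediation.

All models are two-level. The first level fits ordinary least squares
within each subject (trials are the observations); the second level
summarizes per-subject coefficients across subjects with an Empirical
Bayes weighting scheme — weights ``1/(v_i + tau^2)`` where ``v_i`` is the
first-level sampling variance of subject *i*'s coefficient and ``tau^2``
is the between-subject variance estimated by the method of moments
(DerSimonian–Laird, floored at zero). Significance of group coefficients
comes from a bootstrap that resamples subjects with replacement
(default 10,000 draws); R-squared terms are tested by permuting the tested
predictor's trial labels within each subject (default 5,000 draws).

Mediation decomposes the effect of a trial-level manipulation X (coded
+1/-1) on pain Y into indirect paths through one or more brain mediators M
(path a: X->M; path b: M->Y controlling X and the other mediators; direct
remainder c'), or through a serial chain X -> M1 -> M2 -> Y (three-path,
indirect a*d*b). The group indirect effect is the second-level summary of
the per-subject products ``a_i * b_i`` — not the product of group means —
so covariance between paths across subjects is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "zscore_within",
    "apply_coding",
    "MultilevelResult",
    "MultilevelGLM",
    "multilevel_glm",
    "variance_partition",
    "MediationResult",
    "MultilevelMediation",
    "mediate_multilevel",
    "mediate_three_path",
]

_VAR_FLOOR = 1e-12


def zscore_within(values_per_subject, subject_ids=None):
    """Standardize each subject's values to mean 0, s.d. 1 (sample s.d.).

    ``values_per_subject`` is a sequence of per-subject arrays; a subject
    with zero variance raises an error naming them.
    """
    out = []
    for i, v in enumerate(values_per_subject):
        v = np.asarray(v, dtype=float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            name = subject_ids[i] if subject_ids is not None else f"#{i}"
            raise ValueError(f"zero-variance values for subject {name}")
        out.append((v - v.mean()) / sd)
    return out


def apply_coding(labels, coding: dict) -> np.ndarray:
    """Map condition labels to +1/-1 codes; unknown labels are errors."""
    codes = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab not in coding:
            raise ValueError(f"condition label {lab!r} absent from coding map")
        codes[i] = coding[lab]
    return codes


# ---------------------------------------------------------------------------
# first level


def _ols(Z: np.ndarray, y: np.ndarray):
    """OLS fit returning (coef, coef variances, R2, sigma2)."""
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"{n} trials <= {p} regressors in a first-level fit")
    G = Z.T @ Z
    if np.linalg.matrix_rank(G) < p:
        raise ValueError("rank-deficient first-level design")
    Ginv = np.linalg.inv(G)
    coef = Ginv @ (Z.T @ y)
    resid = y - Z @ coef
    sigma2 = float(resid @ resid) / (n - p)
    var = sigma2 * np.diag(Ginv)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return coef, var, r2, sigma2


# ---------------------------------------------------------------------------
# second level: Empirical Bayes weighting + subject bootstrap


def _eb_mean(b: np.ndarray, v: np.ndarray | None):
    """EB-weighted mean along the last axis (vectorized over leading axes).

    With ``v`` given: DerSimonian–Laird tau^2, weights 1/(v+tau^2).
    Without: unweighted mean.
    """
    if v is None:
        return np.mean(b, axis=-1)
    v = np.maximum(v, _VAR_FLOOR)
    n = b.shape[-1]
    w = 1.0 / v
    sw = w.sum(axis=-1)
    bw = (w * b).sum(axis=-1) / sw
    q = (w * (b - bw[..., None]) ** 2).sum(axis=-1)
    c = sw - (w ** 2).sum(axis=-1) / sw
    with np.errstate(divide="ignore", invalid="ignore"):
        tau2 = np.where(c > 0, np.maximum(0.0, (q - (n - 1)) / c), 0.0)
    lam = 1.0 / (v + tau2[..., None])
    return (lam * b).sum(axis=-1) / lam.sum(axis=-1)


def _boot_pvalues(boot: np.ndarray, estimate: float):
    """Two- and one-tailed bootstrap p with a 1/(B+1) floor, plus z."""
    B = boot.shape[0]
    floor = 1.0 / (B + 1)
    p_le = np.mean(boot <= 0)
    p_ge = np.mean(boot >= 0)
    p_two = min(1.0, max(2.0 * min(p_le, p_ge), floor))
    p_one = max(p_le if estimate > 0 else p_ge, floor)
    sd = boot.std(ddof=1)
    z = estimate / sd if sd > 0 else np.sign(estimate) * np.inf
    return p_two, min(1.0, p_one), float(z)


@dataclass
class PathStat:
    """A second-level summary of one per-subject quantity."""

    per_subject: np.ndarray
    estimate: float
    se: float
    z: float
    p_two: float
    p_one: float


def _second_level(values, variances, idx, use_eb=True):
    """Group estimate + bootstrap inference for one per-subject quantity."""
    b = np.asarray(values, dtype=float)
    v = np.asarray(variances, dtype=float) if (use_eb and variances is not None) else None
    est = float(_eb_mean(b, v))
    boot = _eb_mean(b[idx], v[idx] if v is not None else None)
    p_two, p_one, z = _boot_pvalues(boot, est)
    return PathStat(per_subject=b, estimate=est, se=float(boot.std(ddof=1)),
                    z=z, p_two=p_two, p_one=p_one)


# ---------------------------------------------------------------------------
# multilevel GLM


@dataclass
class MultilevelResult:
    """Second-level GLM summary with bootstrap and R-squared terms."""

    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_boot: np.ndarray
    subject_coefs: np.ndarray  # (n_subjects, p)
    R2_full: float
    R2_reduced: np.ndarray  # per predictor, model without it
    unique_R2: np.ndarray
    perm_p: np.ndarray | None = None
    n_boot: int = 0
    n_perm: int = 0
    predictor_names: list = field(default_factory=list)


class MultilevelGLM(BaseEstimator):
    """Two-level GLM: per-subject OLS, EB-weighted group coefficients.

    Parameters
    ----------
    n_boot : int
        Subject-bootstrap draws for coefficient p-values.
    random_state : int or None
        Seed for the bootstrap.

    After ``fit(X_list, Y_list)`` — lists of per-subject (n_trials, p)
    designs (no intercept column; one is added) and outcome vectors:

    Attributes
    ----------
    coef_, se_, z_, p_boot_ : group coefficients and bootstrap inference.
    R2_full_, R2_reduced_, unique_R2_ : variance explained, averaged over
        subjects; unique R2 of predictor j is the drop when j is removed.
    result_ : :class:`MultilevelResult`.
    """

    def __init__(self, n_boot: int = 10000, random_state: int | None = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X_list, Y_list):
        n_subj = len(X_list)
        if n_subj < 3:
            raise ValueError("need at least 3 subjects")
        if len(Y_list) != n_subj:
            raise ValueError("X_list and Y_list lengths differ")
        X0 = np.asarray(X_list[0], dtype=float)
        p = 1 if X0.ndim == 1 else X0.shape[1]

        betas = np.empty((n_subj, p))
        varis = np.empty((n_subj, p))
        r2_full = np.empty(n_subj)
        r2_red = np.empty((n_subj, p))
        for i, (X, y) in enumerate(zip(X_list, Y_list)):
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            y = np.asarray(y, dtype=float).ravel()
            Z = np.column_stack([np.ones(len(y)), X])
            coef, var, r2, _ = _ols(Z, y)
            betas[i] = coef[1:]
            varis[i] = var[1:]
            r2_full[i] = r2
            for j in range(p):
                Zr = np.delete(Z, j + 1, axis=1)
                _, _, r2j, _ = _ols(Zr, y)
                r2_red[i, j] = r2j

        rng = np.random.default_rng(self.random_state)
        idx = rng.integers(0, n_subj, size=(self.n_boot, n_subj))
        stats_ = [_second_level(betas[:, j], varis[:, j], idx) for j in range(p)]

        self.subject_coefs_ = betas
        self.subject_coef_vars_ = varis
        self.coef_ = np.array([s.estimate for s in stats_])
        self.se_ = np.array([s.se for s in stats_])
        self.z_ = np.array([s.z for s in stats_])
        self.p_boot_ = np.array([s.p_two for s in stats_])
        self.R2_full_ = float(r2_full.mean())
        self.R2_reduced_ = r2_red.mean(axis=0)
        self.unique_R2_ = self.R2_full_ - self.R2_reduced_
        self.result_ = MultilevelResult(
            coef=self.coef_, se=self.se_, z=self.z_, p_boot=self.p_boot_,
            subject_coefs=betas, R2_full=self.R2_full_,
            R2_reduced=self.R2_reduced_, unique_R2=self.unique_R2_,
            n_boot=self.n_boot,
        )
        return self


def multilevel_glm(X_list, Y_list, n_boot: int = 10000,
                   seed: int | None = 0) -> MultilevelResult:
    """Functional wrapper over :class:`MultilevelGLM`."""
    return MultilevelGLM(n_boot=n_boot, random_state=seed).fit(X_list, Y_list).result_


def variance_partition(X_list, Y_list, predictors=None, n_perm: int = 5000,
                       seed: int | None = 0):
    """Unique-R2 terms with within-subject permutation p-values.

    The unique R2 of predictor *j* is the mean over subjects of
    ``R2_full - R2_without_j``. Its null distribution is built by shuffling
    predictor *j*'s trial labels within each subject (``n_perm`` draws;
    the reduced model is invariant under the shuffle) and two-tailed
    p-values are read off the permutation distribution with a
    ``1/(n_perm+1)`` floor.

    Returns a dict: ``unique_R2`` (p,), ``perm_p`` (p,), ``R2_full``,
    ``R2_reduced`` (p,), ``null_unique_R2`` (p, n_perm).
    """
    rng = np.random.default_rng(seed)
    n_subj = len(X_list)
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    Xs = []
    Ys = []
    for X, y in zip(X_list, Y_list):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xs.append(X)
        Ys.append(np.asarray(y, dtype=float).ravel())
    p = Xs[0].shape[1]
    if predictors is None:
        predictors = list(range(p))

    # observed terms
    r2_full = np.empty(n_subj)
    r2_red = np.empty((n_subj, p))
    for i, (X, y) in enumerate(zip(Xs, Ys)):
        Z = np.column_stack([np.ones(len(y)), X])
        _, _, r2_full[i], _ = _ols(Z, y)
        for j in range(p):
            _, _, r2_red[i, j], _ = _ols(np.delete(Z, j + 1, axis=1), y)
    R2_full = float(r2_full.mean())
    R2_reduced = r2_red.mean(axis=0)

    null_unique = np.full((p, n_perm), np.nan)
    perm_p = np.full(p, np.nan)
    for j in predictors:
        null_full = np.zeros(n_perm)
        for i, (X, y) in enumerate(zip(Xs, Ys)):
            n = len(y)
            xj = X[:, j]
            F = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            q = F.shape[1]
            G = F.T @ F
            Fy = F.T @ y
            yy = float(y @ y)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            # all permutations of xj at once
            perms = rng.permuted(np.broadcast_to(xj, (n_perm, n)).copy(), axis=1)
            C = perms @ F  # (n_perm, q)
            xx = float(xj @ xj)  # invariant under permutation
            xy = perms @ y  # (n_perm,)
            A = np.empty((n_perm, q + 1, q + 1))
            A[:, :q, :q] = G
            A[:, :q, q] = C
            A[:, q, :q] = C
            A[:, q, q] = xx
            rhs = np.empty((n_perm, q + 1))
            rhs[:, :q] = Fy
            rhs[:, q] = xy
            beta = np.linalg.solve(A, rhs[..., None])[..., 0]
            ss_res = yy - np.einsum("bk,bk->b", beta, rhs)
            null_full += np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        null_full /= n_subj
        null_unique[j] = null_full - R2_reduced[j]
        obs = R2_full - R2_reduced[j]
        p_hi = (1 + np.sum(null_unique[j] >= obs)) / (n_perm + 1)
        p_lo = (1 + np.sum(null_unique[j] <= obs)) / (n_perm + 1)
        perm_p[j] = min(1.0, 2.0 * min(p_hi, p_lo))

    return {
        "unique_R2": R2_full - R2_reduced,
        "perm_p": perm_p,
        "R2_full": R2_full,
        "R2_reduced": R2_reduced,
        "null_unique_R2": null_unique,
    }


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Per-subject and group path coefficients with bootstrap inference.

    ``paths`` maps path names (``a_1``, ``b_1``, ``c_prime``, ``c``,
    ``ab_1``; three-path adds ``a``, ``d_1`` and ``adb_1``) to
    :class:`PathStat`. Indirect effects are second-level summaries of
    per-subject products.
    """

    paths: dict
    mediator_names: list
    three_path: bool
    n_boot: int
    coding: dict | None = None
    covariates_used: bool = False

    def __getitem__(self, name) -> PathStat:
        return self.paths[name]


def _listwise(*arrays):
    """Drop rows with NaN in any array; return the filtered arrays."""
    stacked = [np.asarray(a, dtype=float) for a in arrays if a is not None]
    ok = np.ones(len(stacked[0]), dtype=bool)
    for a in stacked:
        ok &= np.all(np.isfinite(np.atleast_2d(a.T).T), axis=1)
    return ok


def _prep_mediation_inputs(X, M, Y, covariates, coding):
    X = np.asarray(X)
    if coding is not None and X.dtype.kind in "OUS":
        X = apply_coding(X, coding)
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    Y = np.asarray(Y, dtype=float).ravel()
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ok = _listwise(X, M, Y, C)
    return (X[ok], M[ok], Y[ok], C[ok] if C is not None else None)


def _subject_paths_two(X, M, Y, C):
    """Per-subject two-path mediation OLS fits."""
    n, q = M.shape
    cov_cols = [C] if C is not None else []
    out = {}
    Za = np.column_stack([np.ones(n), X] + cov_cols)
    for j in range(q):
        coef, var, _, _ = _ols(Za, M[:, j])
        out[f"a_{j + 1}"] = (coef[1], var[1])
    Zb = np.column_stack([np.ones(n), M, X] + cov_cols)
    coef, var, _, _ = _ols(Zb, Y)
    for j in range(q):
        out[f"b_{j + 1}"] = (coef[1 + j], var[1 + j])
    out["c_prime"] = (coef[1 + q], var[1 + q])
    Zc = np.column_stack([np.ones(n), X] + cov_cols)
    coef, var, _, _ = _ols(Zc, Y)
    out["c"] = (coef[1], var[1])
    for j in range(q):
        a, va = out[f"a_{j + 1}"]
        b, vb = out[f"b_{j + 1}"]
        # Goodman variance of the product, so the EB machinery applies
        out[f"ab_{j + 1}"] = (a * b, a * a * vb + b * b * va + va * vb)
    return out


def _subject_paths_three(X, M1, M2, Y, C):
    """Per-subject three-path (serial X -> M1 -> M2 -> Y) OLS fits."""
    n, q = M2.shape
    cov_cols = [C] if C is not None else []
    out = {}
    Za = np.column_stack([np.ones(n), X] + cov_cols)
    coef, var, _, _ = _ols(Za, M1)
    out["a"] = (coef[1], var[1])
    Zd = np.column_stack([np.ones(n), M1, X] + cov_cols)
    for j in range(q):
        coef, var, _, _ = _ols(Zd, M2[:, j])
        out[f"d_{j + 1}"] = (coef[1], var[1])
    Zb = np.column_stack([np.ones(n), M2, M1, X] + cov_cols)
    coef, var, _, _ = _ols(Zb, Y)
    for j in range(q):
        out[f"b_{j + 1}"] = (coef[1 + j], var[1 + j])
    out["c_prime"] = (coef[1 + q + 1], var[1 + q + 1])
    Zc = np.column_stack([np.ones(n), X] + cov_cols)
    coef, var, _, _ = _ols(Zc, Y)
    out["c"] = (coef[1], var[1])
    a, va = out["a"]
    for j in range(q):
        d, vd = out[f"d_{j + 1}"]
        b, vb = out[f"b_{j + 1}"]
        # extended Goodman variance of the triple product
        v = ((d * b) ** 2 * va + (a * b) ** 2 * vd + (a * d) ** 2 * vb
             + b * b * va * vd + d * d * va * vb + a * a * vd * vb
             + va * vd * vb)
        out[f"adb_{j + 1}"] = (a * d * b, v)
    return out


class MultilevelMediation(BaseEstimator):
    """Multilevel (two-level) mediation with subject bootstrap.

    Parameters
    ----------
    n_boot : int
        Bootstrap draws across subjects.
    three_path : bool
        Serial X -> M1 -> M2 -> Y chain instead of X -> M -> Y.
    coding : dict or None
        Condition-label -> +1/-1 map applied when X holds labels
        (anti-pain conditions +1, pro-pain -1 by convention).
    random_state : int or None

    ``fit`` takes per-subject lists: ``X_list``, ``M_list`` (each
    (n_trials,) or (n_trials, q)), ``Y_list``, optional ``cov_list`` and —
    for three-path — ``M1_list``. Missing trials are dropped listwise
    within subject, so the single-mediator decomposition
    ``c = c' + a*b`` holds exactly per subject.

    Attributes
    ----------
    result_ : :class:`MediationResult`; ``paths_`` is its path dict.
    """

    def __init__(self, n_boot: int = 10000, three_path: bool = False,
                 coding: dict | None = None, random_state: int | None = 0):
        self.n_boot = n_boot
        self.three_path = three_path
        self.coding = coding
        self.random_state = random_state

    def fit(self, X_list, M_list, Y_list, cov_list=None, M1_list=None):
        n_subj = len(X_list)
        if n_subj < 3:
            raise ValueError("need at least 3 subjects")
        if self.three_path and M1_list is None:
            raise ValueError("three-path mediation requires M1_list")
        per_subject = []
        for i in range(n_subj):
            C = cov_list[i] if cov_list is not None else None
            X, M, Y, C = _prep_mediation_inputs(
                X_list[i], M_list[i], Y_list[i], C, self.coding)
            if self.three_path:
                M1 = np.asarray(M1_list[i], dtype=float).ravel()[: len(Y)]
                per_subject.append(_subject_paths_three(X, M1, M, Y, C))
            else:
                per_subject.append(_subject_paths_two(X, M, Y, C))

        names = list(per_subject[0].keys())
        rng = np.random.default_rng(self.random_state)
        idx = rng.integers(0, n_subj, size=(self.n_boot, n_subj))
        paths = {}
        for name in names:
            vals = np.array([s[name][0] for s in per_subject])
            vars_ = None
            if per_subject[0][name][1] is not None:
                vars_ = np.array([s[name][1] for s in per_subject])
            paths[name] = _second_level(vals, vars_, idx)

        q = sum(1 for n_ in names if n_.startswith("b_"))
        self.paths_ = paths
        self.result_ = MediationResult(
            paths=paths,
            mediator_names=[f"M{j + 1}" for j in range(q)],
            three_path=self.three_path, n_boot=self.n_boot,
            coding=self.coding, covariates_used=cov_list is not None,
        )
        return self


def mediate_multilevel(X_list, M_list, Y_list, cov_list=None,
                       coding: dict | None = None, n_boot: int = 10000,
                       seed: int | None = 0) -> MediationResult:
    """Two-path multilevel mediation (one or more mediators)."""
    est = MultilevelMediation(n_boot=n_boot, coding=coding, random_state=seed)
    return est.fit(X_list, M_list, Y_list, cov_list=cov_list).result_


def mediate_three_path(X_list, M1_list, M2_list, Y_list, cov_list=None,
                       coding: dict | None = None, n_boot: int = 10000,
                       seed: int | None = 0) -> MediationResult:
    """Three-path multilevel mediation: X -> M1 -> M2 -> Y."""
    est = MultilevelMediation(n_boot=n_boot, three_path=True, coding=coding,
                              random_state=seed)
    return est.fit(X_list, M2_list, Y_list, cov_list=cov_list,
                   M1_list=M1_list).result_
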