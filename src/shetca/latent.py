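"""PLS / OPLS regression of bioactivity on the integration matrix.

Models are fitted by NIPALS with sequential deflation on a centred and
scaled predictor matrix (unit-variance or Pareto scaling) and a centred
response.  OPLS follows the orthogonal-signal-correction scheme: the
y-orthogonal structured variation is peeled off first and a single
predictive component is fitted on the filtered matrix, so the predictive
score is uncorrelated with every orthogonal score by construction.

Decision rules mirror common chemometrics practice for bioactivity
screening: a variable is called active from the coefficient plot when its
regression coefficient (in scaled space, "CoeffMLR") and its correlation
loading p(corr) are simultaneously positive, or from the VIP plot when
VIP exceeds a threshold (default 0.6) with positive p(corr).

Validation: response-permutation testing (default 200 permutations),
RMSEE, Hotelling T^2 and DModX with F-based 95 % limits, cross-validation
scores, and CV-ANOVA on the cross-validated residuals.  Cross-validation
uses round-robin 7-fold cross-validation by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FOLDS = 7
MAX_COMPONENTS = 10
Q2_IMPROVEMENT_LIMIT = 0.01
VIP_THRESHOLD = 0.6
N_PERMUTATIONS = 200


class Scaling(enum.Enum):
    UV = "UV"
    PARETO = "PARETO"


class ModelKind(enum.Enum):
    PLS = "PLS"
    OPLS = "OPLS"


@dataclass
class ScaledMatrix:
    """Centred and scaled predictor matrix with its back-transform info."""

    values: np.ndarray
    columns: list
    column_means: np.ndarray
    column_scale_weights: np.ndarray
    method: Scaling
    dropped_columns: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        return (np.asarray(X_new, dtype=float) - self.column_means) / self.column_scale_weights


def scale_matrix(X, method: Scaling | str = Scaling.UV) -> ScaledMatrix:
    """Centre columns and scale by sd (UV) or sqrt(sd) (Pareto).

    Constant columns carry no information and make UV scaling undefined;
    they are dropped with a warning recorded in ``dropped_columns``.
    """
    method = Scaling(method)
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        columns = list(range(values.shape[1]))
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to centre and scale")
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    values = values[:, keep]
    columns = [c for c, k in zip(columns, keep) if k]
    sd = sd[keep]
    means = values.mean(axis=0)
    weights = sd if method is Scaling.UV else np.sqrt(sd)
    return ScaledMatrix(
        values=(values - means) / weights,
        columns=columns,
        column_means=means,
        column_scale_weights=weights,
        method=method,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# NIPALS cores


def _nipals_pls(X: np.ndarray, y: np.ndarray, n_components: int):
    """Sequential PLS1 extraction with deflation of X and y."""
    Xd = X.copy()
    yd = y.copy()
    W, T, P, Q = [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w = w / nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p = Xd.T @ t / tt
        q = (yd @ t) / tt
        Xd -= np.outer(t, p)
        yd = yd - q * t
        W.append(w); T.append(t); P.append(p); Q.append(q)
    W = np.array(W).T if W else np.zeros((X.shape[1], 0))
    T = np.array(T).T if T else np.zeros((X.shape[0], 0))
    P = np.array(P).T if P else np.zeros((X.shape[1], 0))
    Q = np.array(Q)
    return W, T, P, Q, Xd, yd


def _pls_coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, Q)


def _opls_core(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Orthogonal-signal-correction decomposition followed by one
    predictive PLS component on the filtered matrix."""
    w = X.T @ y
    w = w / np.linalg.norm(w)
    Xd = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        W_o.append(w_o); T_o.append(t_o); P_o.append(p_o)
    t = Xd @ w
    tt = t @ t
    p = Xd.T @ t / tt
    q = (y @ t) / tt
    W_o = np.array(W_o).T if W_o else np.zeros((X.shape[1], 0))
    T_o = np.array(T_o).T if T_o else np.zeros((X.shape[0], 0))
    P_o = np.array(P_o).T if P_o else np.zeros((X.shape[1], 0))
    return w, t, p, q, W_o, T_o, P_o, Xd


def _opls_coefficients(w, q, W_o, P_o) -> np.ndarray:
    """Linear map scaled-x -> yhat, composed from the filtering chain."""
    p_vars = w.size
    Xi = np.eye(p_vars)
    for a in range(W_o.shape[1]):
        t_o = Xi @ W_o[:, a]
        Xi -= np.outer(t_o, P_o[:, a])
    return (Xi @ w) * q


# ---------------------------------------------------------------------------
# Model container


@dataclass
class LatentModel:
    kind: ModelKind
    n_predictive: int
    n_orthogonal: int
    scores: np.ndarray            # N x n_predictive
    orthogonal_scores: np.ndarray  # N x n_orthogonal
    weights: np.ndarray            # p x n_predictive
    loadings: np.ndarray           # p x n_predictive
    y_loadings: np.ndarray         # (n_predictive,)
    orthogonal_weights: np.ndarray
    orthogonal_loadings: np.ndarray
    coefficients: np.ndarray       # scaled space ("CoeffMLR")
    y_mean: float
    r2x: float
    r2y: float
    q2: float
    ssy_per_component: np.ndarray
    columns: list
    folds: int
    press: float
    cv_predictions: np.ndarray
    cv_scores: np.ndarray

    @property
    def n_components(self) -> int:
        return self.n_predictive + self.n_orthogonal

    def predict_scaled(self, Xs_values: np.ndarray) -> np.ndarray:
        """Predict y from rows already in the model's scaled space."""
        X = np.atleast_2d(np.asarray(Xs_values, dtype=float))
        return X @ self.coefficients + self.y_mean


def _cv_folds(n: int, folds: int):
    """Round-robin fold assignment: observation i belongs to fold i mod k.

    For an ordered fraction series this keeps every elution window
    represented in each training set; a compound confined to a few
    consecutive fractions would otherwise vanish entirely from training
    whenever its block is held out.
    """
    folds = min(folds, n)
    idx = np.arange(n)
    return [idx[idx % folds == k] for k in range(folds)]


def _cv_press(X, y, fit_fold, folds: int):
    """Generic leave-group-out PRESS; ``fit_fold(Xtr, ytr)`` must return a
    callable predicting centred-space y for new scaled rows."""
    n = y.size
    press = 0.0
    yhat_cv = np.full(n, np.nan)
    cv_scores = np.full(n, np.nan)
    for test_idx in _cv_folds(n, folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        Xtr = X[train] - X[train].mean(axis=0)
        ytr = y[train]
        ym = ytr.mean()
        predict, score = fit_fold(Xtr, ytr - ym)
        Xte = X[test_idx] - X[train].mean(axis=0)
        pred = predict(Xte) + ym
        yhat_cv[test_idx] = pred
        cv_scores[test_idx] = score(Xte)
        press += float(np.sum((y[test_idx] - pred) ** 2))
    return press, yhat_cv, cv_scores


def fit_pls(
    Xs: ScaledMatrix,
    y,
    n_components: int,
    folds: int = DEFAULT_FOLDS,
) -> LatentModel:
    """NIPALS PLS1 with leave-group-out Q^2."""
    X = Xs.values
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")
    y_mean = y.mean()
    yc = y - y_mean
    W, T, P, Q, Xres, yres = _nipals_pls(X, yc, n_components)
    A = W.shape[1]
    ssx = np.sum(X**2)
    ssy = np.sum(yc**2)
    r2x = 1.0 - np.sum(Xres**2) / ssx if ssx > 0 else 0.0
    r2y = 1.0 - np.sum(yres**2) / ssy if ssy > 0 else 0.0
    coef = _pls_coefficients(W, P, Q)
    ssy_comp = Q**2 * np.sum(T**2, axis=0) if A else np.zeros(0)

    def fold_fitter(Xtr, ytr_c):
        Wf, Tf, Pf, Qf, _, _ = _nipals_pls(Xtr, ytr_c, n_components)
        bf = _pls_coefficients(Wf, Pf, Qf)
        sign = 1.0
        if Wf.shape[1] and W.shape[1]:
            sign = np.sign(Wf[:, 0] @ W[:, 0]) or 1.0
        return (lambda Xte: Xte @ bf), (lambda Xte: sign * (Xte @ Wf[:, 0]) if Wf.shape[1] else np.zeros(len(Xte)))

    press, yhat_cv, cv_scores = _cv_press(X, y, fold_fitter, folds)
    q2 = 1.0 - press / ssy if ssy > 0 else 0.0
    return LatentModel(
        kind=ModelKind.PLS, n_predictive=A, n_orthogonal=0,
        scores=T, orthogonal_scores=np.zeros((n, 0)),
        weights=W, loadings=P, y_loadings=Q,
        orthogonal_weights=np.zeros((p, 0)), orthogonal_loadings=np.zeros((p, 0)),
        coefficients=coef, y_mean=y_mean, r2x=r2x, r2y=r2y, q2=q2,
        ssy_per_component=ssy_comp, columns=list(Xs.columns), folds=folds,
        press=press, cv_predictions=yhat_cv, cv_scores=cv_scores,
    )


def fit_opls(
    Xs: ScaledMatrix,
    y,
    n_orthogonal: int,
    folds: int = DEFAULT_FOLDS,
) -> LatentModel:
    """OPLS with one predictive and ``n_orthogonal`` orthogonal components."""
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    X = Xs.values
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if 1 + n_orthogonal > min(n - 1, p):
        raise ValueError("total components exceed the rank bound")
    y_mean = y.mean()
    yc = y - y_mean
    w, t, pl, q, W_o, T_o, P_o, Xfilt = _opls_core(X, yc, n_orthogonal)
    coef = _opls_coefficients(w, q, W_o, P_o)
    ssx = np.sum(X**2)
    ssy = np.sum(yc**2)
    modelled_x = np.sum((np.outer(t, pl)) ** 2)
    for a in range(T_o.shape[1]):
        modelled_x += np.sum(np.outer(T_o[:, a], P_o[:, a]) ** 2)
    r2x = modelled_x / ssx if ssx > 0 else 0.0
    yres = yc - q * t
    r2y = 1.0 - np.sum(yres**2) / ssy if ssy > 0 else 0.0
    ssy_comp = np.array([q**2 * (t @ t)])

    def fold_fitter(Xtr, ytr_c):
        wf, tf, plf, qf, W_of, T_of, P_of, _ = _opls_core(Xtr, ytr_c, n_orthogonal)
        bf = _opls_coefficients(wf, qf, W_of, P_of)
        sign = np.sign(wf @ w) or 1.0

        def score(Xte):
            Xw = Xte.copy()
            for a in range(W_of.shape[1]):
                t_o = Xw @ W_of[:, a]
                Xw = Xw - np.outer(t_o, P_of[:, a])
            return sign * (Xw @ wf)

        return (lambda Xte: Xte @ bf), score

    press, yhat_cv, cv_scores = _cv_press(X, y, fold_fitter, folds)
    q2 = 1.0 - press / ssy if ssy > 0 else 0.0
    return LatentModel(
        kind=ModelKind.OPLS, n_predictive=1, n_orthogonal=T_o.shape[1],
        scores=t[:, None], orthogonal_scores=T_o,
        weights=w[:, None], loadings=pl[:, None], y_loadings=np.array([q]),
        orthogonal_weights=W_o, orthogonal_loadings=P_o,
        coefficients=coef, y_mean=y_mean, r2x=r2x, r2y=r2y, q2=q2,
        ssy_per_component=ssy_comp, columns=list(Xs.columns), folds=folds,
        press=press, cv_predictions=yhat_cv, cv_scores=cv_scores,
    )


def select_components(
    Xs: ScaledMatrix,
    y,
    kind: ModelKind | str = ModelKind.PLS,
    limit: float = Q2_IMPROVEMENT_LIMIT,
    max_components: int = MAX_COMPONENTS,
    folds: int = DEFAULT_FOLDS,
) -> int:
    """Grow the model while cross-validated Q^2 improves by more than
    ``limit``; returns the retained count (predictive components for PLS,
    orthogonal components for OPLS)."""
    kind = ModelKind(kind)
    max_rank = min(Xs.shape[0] - 1, Xs.shape[1])
    best_q2 = -np.inf
    best_k = 1 if kind is ModelKind.PLS else 0
    start = 1 if kind is ModelKind.PLS else 0
    for k in range(start, max_components + 1):
        if kind is ModelKind.PLS:
            if k > max_rank or k == 0:
                break
            q2 = fit_pls(Xs, y, k, folds=folds).q2
        else:
            if 1 + k > max_rank:
                break
            q2 = fit_opls(Xs, y, k, folds=folds).q2
        if q2 > best_q2 + limit:
            best_q2, best_k = q2, k
        elif k > start:
            break
    return best_k


# ---------------------------------------------------------------------------
# Per-variable statistics and decision rules


def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in projection; normalised so mean(VIP^2) == 1.

    For OPLS only the predictive component enters (the decision rules
    concern y-predictive relevance).
    """
    W = model.weights
    ssy = model.ssy_per_component[: W.shape[1]]
    p = W.shape[0]
    if W.shape[1] == 0 or ssy.sum() == 0:
        return np.ones(p)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


def p_corr(model: LatentModel, Xs: ScaledMatrix) -> np.ndarray:
    """Correlation loading: Pearson correlation between the (first)
    predictive score vector and each scaled column."""
    t = model.scores[:, 0]
    X = Xs.values
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    denom = np.linalg.norm(tc) * np.linalg.norm(Xc, axis=0)
    out = np.zeros(X.shape[1])
    ok = denom > 0
    out[ok] = (Xc.T @ tc)[ok] / denom[ok]
    return out


def classify_by_coefficients(model: LatentModel, Xs: ScaledMatrix) -> pd.Series:
    """ACTIVE iff CoeffMLR > 0 and p(corr) > 0, both strict."""
    pc = p_corr(model, Xs)
    active = (model.coefficients > 0) & (pc > 0)
    return pd.Series(
        np.where(active, "ACTIVE", "INACTIVE"), index=model.columns, name="classification"
    )


def classify_by_vip(
    model: LatentModel, Xs: ScaledMatrix, threshold: float = VIP_THRESHOLD
) -> pd.Series:
    """ACTIVE iff VIP > threshold and p(corr) > 0 (both strict)."""
    pc = p_corr(model, Xs)
    active = (vip(model) > threshold) & (pc > 0)
    return pd.Series(
        np.where(active, "ACTIVE", "INACTIVE"), index=model.columns, name="classification"
    )


def model_summary(model: LatentModel, Xs: ScaledMatrix) -> pd.DataFrame:
    """Per-variable CoeffMLR, p(corr), VIP and both classifications."""
    return pd.DataFrame(
        {
            "coeff_mlr": model.coefficients,
            "p_corr": p_corr(model, Xs),
            "vip": vip(model),
            "call_coefficients": classify_by_coefficients(model, Xs).to_numpy(),
            "call_vip": classify_by_vip(model, Xs).to_numpy(),
        },
        index=pd.Index(model.columns, name="compound"),
    )


# ---------------------------------------------------------------------------
# Validation


@dataclass
class PermutationResult:
    original_r2y: float
    original_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    valid: bool


def _refit(Xs: ScaledMatrix, y, model: LatentModel) -> LatentModel:
    if model.kind is ModelKind.PLS:
        return fit_pls(Xs, y, model.n_predictive, folds=model.folds)
    return fit_opls(Xs, y, model.n_orthogonal, folds=model.folds)


def permutation_test(
    Xs: ScaledMatrix,
    y,
    model: LatentModel,
    n_permutations: int = N_PERMUTATIONS,
    seed: int = 0,
) -> PermutationResult:
    """Refit on response permutations; the model is credible when the
    original Q^2 exceeds every permuted Q^2."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    r2s, q2s = np.empty(n_permutations), np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(y)
        m = _refit(Xs, perm, model)
        r2s[i], q2s[i] = m.r2y, m.q2
    return PermutationResult(
        original_r2y=model.r2y,
        original_q2=model.q2,
        permuted_r2y=r2s,
        permuted_q2=q2s,
        valid=bool(model.q2 > q2s.max()),
    )


@dataclass
class ValidationReport:
    rmsee: float
    hotelling_t2: np.ndarray
    t2_limit: float
    dmodx: np.ndarray
    dmodx_limit: float
    residuals: np.ndarray
    residual_normal_quantiles: np.ndarray
    cv_scores: np.ndarray
    cv_anova_p: float
    cv_anova_f: float


def diagnostics(model: LatentModel, Xs: ScaledMatrix, y) -> ValidationReport:
    """RMSEE, Hotelling T^2, DModX, residual quantiles, CV-scores, CV-ANOVA."""
    y = np.asarray(y, dtype=float)
    n, p = Xs.shape
    A = model.n_components
    yhat = model.predict_scaled(Xs.values)
    resid = y - yhat
    if n <= A + 1:
        rmsee = np.nan
    else:
        rmsee = float(np.sqrt(np.sum(resid**2) / (n - 1 - A)))

    scores = np.hstack([model.scores, model.orthogonal_scores])
    var = scores.var(axis=0, ddof=1)
    var[var == 0] = np.inf
    t2 = np.sum(scores**2 / var, axis=1)
    if n > A:
        t2_limit = A * (n - 1) / (n - A) * stats.f.ppf(0.95, A, n - A)
    else:
        t2_limit = np.nan

    recon = model.scores @ model.loadings.T
    if model.n_orthogonal:
        recon = recon + model.orthogonal_scores @ model.orthogonal_loadings.T
    E = Xs.values - recon
    dof_row = max(p - A, 1)
    dof_all = max((n - A - 1) * dof_row, 1)
    s_i = np.sqrt(np.sum(E**2, axis=1) / dof_row)
    s0 = np.sqrt(np.sum(E**2) / dof_all)
    dmodx = s_i / s0 if s0 > 0 else np.zeros(n)
    dmodx_limit = float(np.sqrt(stats.f.ppf(0.95, dof_row, dof_all)))

    order = np.argsort(resid)
    probs = (np.arange(n) + 0.5) / n
    nq = np.empty(n)
    nq[order] = stats.norm.ppf(probs)

    f_stat, p_val = cv_anova(model, y)
    return ValidationReport(
        rmsee=rmsee,
        hotelling_t2=t2,
        t2_limit=float(t2_limit),
        dmodx=dmodx,
        dmodx_limit=dmodx_limit,
        residuals=resid,
        residual_normal_quantiles=nq,
        cv_scores=model.cv_scores,
        cv_anova_p=p_val,
        cv_anova_f=f_stat,
    )


def cv_anova(model: LatentModel, y) -> tuple[float, float]:
    """F-test of the cross-validated residuals against the variation of y
    around its mean: is the latent model better than the mean predictor?"""
    y = np.asarray(y, dtype=float)
    n = y.size
    A = model.n_components
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    press = model.press
    df1 = A
    df2 = n - A - 1
    if df1 < 1 or df2 < 1 or press <= 0:
        return np.nan, np.nan
    ss_reg = max(ss_tot - press, 0.0)
    f_stat = (ss_reg / df1) / (press / df2)
    return float(f_stat), float(stats.f.sf(f_stat, df1, df2))
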