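"""Latent-variable chemometrics: PCA and PLS with cross-validation diagnostics.

This module provides the multivariate engines used throughout the pipeline:

* :func:`preprocess` — mean-centering and unit-variance (UV) scaling with an
  invertible, recorded state.
* :func:`fit_pca` — principal component analysis with cumulative explained
  variation ``R2X(cum)``, a cross-validated ``Q2(cum)`` obtained by
  element-wise deletion, and distance-to-model (DModX) outlier diagnostics.
* :func:`fit_pls` — NIPALS partial least squares (PLS1) regression with
  ``R2Y`` and a leave-one-out ``Q2(cum)``.
* :func:`permutation_test` — response-permutation validation of a PLS model.

Conventions follow standard chemometrics practice: all variables are treated
on the preprocessed (centered, UV-scaled) scale; explained variation is
reported as a fraction of the total corrected sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "PcaModel",
    "PlsModel",
    "PermutationReport",
    "preprocess",
    "fit_pca",
    "fit_pls",
    "pls_coefficients",
    "permutation_test",
    "dmodx",
]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class DataMatrix:
    """A numeric matrix with recorded, invertible preprocessing state.

    Attributes
    ----------
    data:
        The (possibly preprocessed) values as a DataFrame.
    centered, uv_scaled:
        Flags recording which transforms have been applied.
    means, sds:
        Per-column statistics of the *original* data, stored so the
        preprocessing can be inverted exactly.
    """

    data: pd.DataFrame
    centered: bool = False
    uv_scaled: bool = False
    means: pd.Series | None = None
    sds: pd.Series | None = None

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def inverse_transform(self) -> pd.DataFrame:
        """Undo centering/scaling, recovering the original data."""
        out = self.data.copy()
        if self.uv_scaled:
            out = out * self.sds
        if self.centered:
            out = out + self.means
        return out


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DataMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def preprocess(X, center: bool = True, uv_scale: bool = True) -> DataMatrix:
    """Mean-center and/or scale columns to unit variance.

    Zero-variance columns cannot be UV-scaled; they are dropped with a
    warning. If every column is constant a ``ValueError`` is raised.
    """
    frame = _as_frame(X).astype(float)
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=1)
    if uv_scale:
        constant = sds.index[(sds == 0) | sds.isna()]
        if len(constant) == len(frame.columns):
            raise ValueError("all columns are constant; nothing to scale")
        if len(constant):
            warnings.warn(
                f"dropping {len(constant)} zero-variance column(s): "
                f"{list(constant)}",
                stacklevel=2,
            )
            frame = frame.drop(columns=constant)
            means = means.drop(constant)
            sds = sds.drop(constant)
    elif (sds == 0).all():
        raise ValueError("all columns are constant")
    out = frame
    if center:
        out = out - means
    if uv_scale:
        out = out / sds
    return DataMatrix(out, centered=center, uv_scaled=uv_scale, means=means, sds=sds)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """A fitted principal component model.

    ``scores`` is the N x A score matrix T, ``loadings`` the K x A loading
    matrix P (orthonormal columns). ``r2x`` holds the per-component explained
    variation and ``r2x_cum`` its cumulative sum; ``q2_cum`` is the
    cross-validated cumulative predictive ability; ``dmodx`` the normalized
    observation distances to the model plane.
    """

    n_components: int
    scores: pd.DataFrame
    loadings: pd.DataFrame
    r2x: np.ndarray
    r2x_cum: np.ndarray
    q2_cum: float | None
    dmodx: pd.Series
    ss_total: float = 0.0

    def project(self, X) -> pd.DataFrame:
        """Score new (already preprocessed) observations."""
        frame = _as_frame(X)
        T = frame.to_numpy(dtype=float) @ self.loadings.to_numpy()
        return pd.DataFrame(T, index=frame.index, columns=self.scores.columns)


def _orient_svd(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign: largest-|loading| element of each component positive
    for a in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    return U, Vt


def _em_pca_predict(
    Xmiss: np.ndarray,
    n_components: int,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Rank-A reconstruction of a matrix with missing cells (iterative SVD).

    Missing cells start at 0 (the column mean of centered data) and are
    repeatedly replaced by their rank-``n_components`` SVD reconstruction
    until the imputed values stabilize. Used only inside the element-wise
    cross-validation.
    """
    mask = ~np.isfinite(Xmiss)
    X = np.where(mask, 0.0, Xmiss)
    prev = X[mask]
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]
        X[mask] = recon[mask]
        delta = np.linalg.norm(X[mask] - prev)
        if delta <= tol * max(np.linalg.norm(X[mask]), 1.0):
            break
        prev = X[mask].copy()
    return recon


def _pca_q2_cum(Xv: np.ndarray, n_components: int, n_groups: int, seed: int) -> float:
    """Cross-validated Q2(cum) by element-wise group deletion.

    Cells are assigned to ``n_groups`` diagonal-stripe deletion groups; for
    each group the model is refit on the remaining cells with an
    EM/iterative-SVD imputation at the requested rank and the deleted cells
    are predicted from the reconstruction. Q2(cum) = 1 - PRESS / SS.
    """
    n, k = Xv.shape
    rng = np.random.default_rng(seed)
    # diagonal stripes with a small random row offset for robustness
    offs = rng.integers(0, n_groups, size=n)
    rows, cols = np.indices((n, k))
    groups = (rows + cols + offs[:, None]) % n_groups
    press = 0.0
    for g in range(n_groups):
        mask = groups == g
        E = Xv.copy()
        E[mask] = np.nan
        pred = _em_pca_predict(E, n_components)
        press += float(np.sum((Xv[mask] - pred[mask]) ** 2))
    ss = float(np.sum(Xv**2))
    return 1.0 - press / ss


def fit_pca(
    X,
    n_components: int,
    cv: bool = True,
    cv_groups: int = 7,
    cv_seed: int = 0,
) -> PcaModel:
    """Fit a PCA model on a preprocessed matrix.

    Components are the leading singular vectors (maximal explained
    variance); ``R2X(cum)`` is the cumulative fraction of the total sum of
    squares carried by the scores. ``Q2(cum)`` comes from element-wise
    7-group deletion (see :func:`_pca_q2_cum`); pass ``cv=False`` to skip it.
    """
    frame = _as_frame(X)
    Xv = frame.to_numpy(dtype=float)
    n, k = Xv.shape
    max_comp = min(n - 1, k)
    if n_components < 1 or n_components > max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for a {n}x{k} matrix"
        )
    U, s, Vt = np.linalg.svd(Xv, full_matrices=False)
    U, Vt = _orient_svd(U, Vt)
    ss_total = float(np.sum(Xv**2))
    if ss_total == 0:
        raise ValueError("matrix has zero total variance")
    A = n_components
    T = U[:, :A] * s[:A]
    P = Vt[:A].T
    r2x = (s[:A] ** 2) / ss_total
    r2x_cum = np.cumsum(r2x)
    comp_names = [f"PC{a + 1}" for a in range(A)]
    scores = pd.DataFrame(T, index=frame.index, columns=comp_names)
    loadings = pd.DataFrame(P, index=frame.columns, columns=comp_names)
    model = PcaModel(
        n_components=A,
        scores=scores,
        loadings=loadings,
        r2x=r2x,
        r2x_cum=r2x_cum,
        q2_cum=None,
        dmodx=pd.Series(np.zeros(n), index=frame.index),
        ss_total=ss_total,
    )
    model.dmodx = dmodx(model, frame)
    if cv:
        model.q2_cum = _pca_q2_cum(Xv, A, min(cv_groups, n), cv_seed)
    return model


def dmodx(model: PcaModel, X) -> pd.Series:
    """Normalized distance to the PCA model plane per observation.

    ``DModX_i = s_i / s0`` where ``s_i`` is the residual standard deviation
    of observation i and ``s0`` the pooled residual standard deviation of
    the training set, with SIMCA-style degree-of-freedom corrections. An
    observation lying exactly in the model plane has DModX 0.
    """
    frame = _as_frame(X)
    Xv = frame.to_numpy(dtype=float)
    P = model.loadings.to_numpy()
    E = Xv - (Xv @ P) @ P.T
    n, k = Xv.shape
    A = model.n_components
    dof_col = max(k - A, 1)
    s_i = np.sqrt(np.sum(E**2, axis=1) / dof_col)
    dof_total = max((n - A - 1) * (k - A), 1)
    s0 = np.sqrt(np.sum(E**2) / dof_total)
    ss_total = float(np.sum(Xv**2))
    # perfectly explained data: residuals are numerical noise, not distance
    if s0 == 0 or (ss_total > 0 and np.sum(E**2) <= 1e-12 * ss_total):
        return pd.Series(np.zeros(n), index=frame.index)
    return pd.Series(s_i / s0, index=frame.index)


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """A fitted PLS1 regression model (NIPALS).

    The coefficient vector ``b`` acts on the preprocessed predictors and
    produces the preprocessed response: ``y_hat = X_pre @ b``. ``r2y`` is the
    fraction of response variation explained on the training data and
    ``q2_cum`` the leave-one-out cross-validated analogue.
    """

    n_lv: int
    weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    b: pd.Series
    r2y: float
    q2_cum: float | None
    x_columns: list[str] = field(default_factory=list)
    y_mean: float = 0.0
    y_sd: float = 1.0
    x_means: np.ndarray | None = None
    x_sds: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        """Predict the response on the original scale for raw predictors."""
        Xv = _as_frame(X).to_numpy(dtype=float)
        Xp = (Xv - self.x_means) / self.x_sds
        return (Xp @ self.b.to_numpy()) * self.y_sd + self.y_mean

    def coefficients_raw(self) -> pd.Series:
        """Coefficients mapping raw predictors to the raw response scale."""
        return pd.Series(
            self.b.to_numpy() * self.y_sd / self.x_sds, index=self.b.index
        )


def _nipals_pls1(Xp: np.ndarray, yp: np.ndarray, n_lv: int):
    """Core NIPALS loop for a single response. Returns W, T, P, q."""
    E, f = Xp.copy(), yp.astype(float).copy()
    W, T, P, q = [], [], [], []
    for _ in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = E.T @ t / tt
        qa = float(f @ t / tt)
        E = E - np.outer(t, p)
        f = f - qa * t
        W.append(w)
        T.append(t)
        P.append(p)
        q.append(qa)
    if not W:
        raise ValueError("no PLS component could be extracted (degenerate data)")
    return (np.column_stack(W), np.column_stack(T), np.column_stack(P), np.array(q))


def _pls_coef(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(
    X,
    y,
    n_lv: int,
    scale_x: bool = True,
    scale_y: bool = True,
    loo: bool = True,
) -> PlsModel:
    """Fit a PLS1 model relating predictors X to a single response y.

    X and y are centered (and UV-scaled unless disabled) internally; the
    reported coefficients live on the preprocessed scale. ``Q2(cum)`` is
    computed by leave-one-out refitting with the preprocessing re-estimated
    inside each fold.
    """
    frame = _as_frame(X)
    Xv = frame.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = Xv.shape
    if len(yv) != n:
        raise ValueError("X and y have different numbers of rows")
    if np.std(yv) == 0:
        raise ValueError("response y is constant")
    rank = np.linalg.matrix_rank(Xv - Xv.mean(axis=0))
    if n_lv < 1 or n_lv > rank:
        raise ValueError(f"n_lv must be in [1, rank(X)={rank}]")

    def _prep(Xt, yt):
        xm = Xt.mean(axis=0)
        xs = Xt.std(axis=0, ddof=1) if scale_x else np.ones(Xt.shape[1])
        xs = np.where(xs > 0, xs, 1.0)
        ym = yt.mean()
        ys = yt.std(ddof=1) if scale_y else 1.0
        ys = ys if ys > 0 else 1.0
        return (Xt - xm) / xs, (yt - ym) / ys, xm, xs, ym, ys

    Xp, yp, xm, xs, ym, ys = _prep(Xv, yv)
    W, T, P, q = _nipals_pls1(Xp, yp, n_lv)
    b = _pls_coef(W, P, q)
    yhat = Xp @ b
    r2y = 1.0 - float(np.sum((yp - yhat) ** 2)) / float(np.sum(yp**2))

    q2 = None
    if loo:
        press, ss = 0.0, 0.0
        for i in range(n):
            keep = np.arange(n) != i
            Xt, yt = Xv[keep], yv[keep]
            Xpi, ypi, xmi, xsi, ymi, ysi = _prep(Xt, yt)
            try:
                Wi, Ti, Pi, qi = _nipals_pls1(Xpi, ypi, n_lv)
                bi = _pls_coef(Wi, Pi, qi)
            except (ValueError, np.linalg.LinAlgError):
                continue
            pred = ((Xv[i] - xmi) / xsi) @ bi * ysi + ymi
            press += (yv[i] - pred) ** 2
            ss += (yv[i] - ymi) ** 2
        q2 = 1.0 - press / ss if ss > 0 else None

    return PlsModel(
        n_lv=W.shape[1],
        weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
        b=pd.Series(b, index=frame.columns),
        r2y=r2y,
        q2_cum=q2,
        x_columns=list(frame.columns),
        y_mean=float(ym),
        y_sd=float(ys),
        x_means=xm,
        x_sds=xs,
    )


def pls_coefficients(model: PlsModel) -> pd.Series:
    """Named regression coefficients on the preprocessed predictor scale.

    A large positive coefficient marks a variable (here: a residue indicator)
    that is beneficial for a high response.
    """
    return model.b.copy()


# ---------------------------------------------------------------------------
# Permutation validation
# ---------------------------------------------------------------------------

@dataclass
class PermutationReport:
    """Outcome of a response-permutation validation.

    ``table`` has one row per model: the unpermuted baseline first
    (correlation 1), then ``n_perm`` models fit to shuffled responses. The
    intercepts of the regression lines of R2Y and Q2 on the absolute
    correlation with the original response summarize chance-correlation
    risk; conventional validity limits are R2 intercept < 0.3 and Q2
    intercept < 0.05.
    """

    n_perm: int
    table: pd.DataFrame
    r2_intercept: float
    q2_intercept: float
    valid: bool


def permutation_test(
    X,
    y,
    n_lv: int,
    n_perm: int = 100,
    seed: int = 0,
    scale_x: bool = True,
    scale_y: bool = True,
    r2_limit: float = 0.3,
    q2_limit: float = 0.05,
) -> PermutationReport:
    """Assess chance-correlation risk by refitting on permuted responses."""
    yv = np.asarray(y, dtype=float).ravel()
    if np.std(yv) == 0:
        raise ValueError("response y is constant; permutation test undefined")
    if n_perm < 10:
        warnings.warn("fewer than 10 permutations gives an unstable verdict", stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    base = fit_pls(X, yv, n_lv, scale_x=scale_x, scale_y=scale_y)
    rows.append({"correlation": 1.0, "r2y": base.r2y, "q2": base.q2_cum})
    for _ in range(n_perm):
        yp = rng.permutation(yv)
        m = fit_pls(X, yp, n_lv, scale_x=scale_x, scale_y=scale_y)
        corr = float(np.corrcoef(yp, yv)[0, 1])
        rows.append({"correlation": corr, "r2y": m.r2y, "q2": m.q2_cum})
    table = pd.DataFrame(rows)
    ac = np.abs(table["correlation"].to_numpy())
    r2_int = float(np.polyfit(ac, table["r2y"].to_numpy(), 1)[1])
    q2_int = float(np.polyfit(ac, table["q2"].to_numpy(dtype=float), 1)[1])
    return PermutationReport(
        n_perm=n_perm,
        table=table,
        r2_intercept=r2_int,
        q2_intercept=q2_int,
        valid=(r2_int < r2_limit) and (q2_int < q2_limit),
    )
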