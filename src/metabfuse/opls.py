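"""Orthogonal projections to latent structures (OPLS) regression.

OPLS splits X-variation into a part correlated with the response(s) Y and a
part orthogonal to it. Y-orthogonal components are extracted iteratively
(each orthogonal weight is the predictive loading stripped of its projection
onto the span of X'Y, the Y-covariance directions), X is deflated, and the
predictive model is then an ordinary NIPALS PLS on the filtered matrix, one
predictive component per response column.

Also implemented here: venetian-blind K-fold cross-validation with the
Q2 = 1 - PRESS/SS statistic and an automatic component-count stopping rule;
VIP (variable importance in projection) over the predictive components,
which satisfies mean(VIP^2) = 1; and the response-permutation validation
(R2/Q2 against |correlation with the original response|, with least-squares
intercepts) used to guard against overfitting.

Input X and Y are expected column-wise standardized / numerically coded;
centering is nevertheless re-done internally on the training rows so that
cross-validation predictions are well defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OPLSModel",
    "PermutationSummary",
    "fit_opls",
    "cross_validate",
    "vip",
    "permutation_test",
]

_MAX_ITER = 500
_TOL = 1e-12


def _first_pls_component(X: np.ndarray, Y: np.ndarray):
    """One NIPALS PLS2 component on centered X, Y: returns (w, t, p, c).

    The converged NIPALS weight satisfies w ∝ X'YY'X w, i.e. it is the first
    left singular vector of X'Y; that fixed point is computed directly (the
    power iteration converges arbitrarily slowly when the two leading
    singular values of X'Y nearly tie, which permuted responses routinely
    produce). For a single response column this reduces to w ∝ X'y exactly.
    """
    S = X.T @ Y
    if Y.shape[1] == 1:
        w = S[:, 0]
    else:
        U, _, _ = np.linalg.svd(S, full_matrices=False)
        w = U[:, 0]
    nrm = np.linalg.norm(w)
    if nrm < 1e-300:
        raise RuntimeError("degenerate component: X'Y vanished")
    w = w / nrm
    if w[np.argmax(np.abs(w))] < 0:  # deterministic sign convention
        w = -w
    t = X @ w
    c = Y.T @ t / (t @ t)
    p = X.T @ t / (t @ t)
    return w, t, p, c


def _nipals_pls(X: np.ndarray, Y: np.ndarray, n_comp: int):
    """NIPALS PLS2 with X- and Y-deflation; returns (W, T, P, C)."""
    Xd, Yd = X.copy(), Y.copy()
    W, T, P, C = [], [], [], []
    for _ in range(n_comp):
        if np.linalg.norm(Xd) < 1e-12 or np.linalg.norm(Yd) < 1e-12:
            break
        w, t, p, c = _first_pls_component(Xd, Yd)
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, c)
        W.append(w), T.append(t), P.append(p), C.append(c)
    return (np.column_stack(W), np.column_stack(T), np.column_stack(P), np.column_stack(C))


def _y_basis(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the Y-covariance directions span(X'Y)."""
    S = X.T @ Y
    q, r = np.linalg.qr(S)
    keep = np.abs(np.diag(r)) > 1e-12 * max(np.abs(np.diag(r)).max(), 1e-300)
    return q[:, keep]


@dataclass
class OPLSModel:
    """Fitted OPLS model: predictive (W, T, P, C) and orthogonal (W_o, T_o,
    P_o) parts, training R2Y, and the variable-importance vector."""

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    C: np.ndarray
    W_o: np.ndarray
    T_o: np.ndarray
    P_o: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    r2y_cum: float
    q2_cum: float = float("nan")
    variable_ids: list[str] | None = None
    response_ids: list[str] | None = None

    @property
    def n_pred(self) -> int:
        return self.W.shape[1]

    @property
    def n_orth(self) -> int:
        return self.W_o.shape[1]

    def filter_x(self, X: np.ndarray) -> np.ndarray:
        """Center and strip the fitted orthogonal components from new rows."""
        Xf = np.asarray(X, dtype=float) - self.x_mean
        for a in range(self.n_orth):
            t_o = Xf @ self.W_o[:, a]
            Xf = Xf - np.outer(t_o, self.P_o[:, a])
        return Xf

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xf = self.filter_x(X)
        B = self.W @ np.linalg.solve(self.P.T @ self.W, self.C.T)
        return Xf @ B + self.y_mean

    @property
    def vip(self) -> np.ndarray:
        return vip(self)

    def vip_series(self) -> pd.Series:
        ids = self.variable_ids or [f"x{j}" for j in range(self.W.shape[0])]
        return pd.Series(self.vip, index=ids, name="VIP")

    def to_json(self, path=None) -> str:
        payload = {
            "n_pred": self.n_pred,
            "n_orth": self.n_orth,
            "r2y_cum": self.r2y_cum,
            "q2_cum": self.q2_cum,
            "variable_ids": self.variable_ids,
            "response_ids": self.response_ids,
            **{
                k: getattr(self, k).tolist()
                for k in ("W", "T", "P", "C", "W_o", "T_o", "P_o", "x_mean", "y_mean")
            },
            "vip": self.vip.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_2d(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_opls(
    X: np.ndarray,
    Y: np.ndarray,
    n_orth: int,
    variable_ids: list[str] | None = None,
    response_ids: list[str] | None = None,
) -> OPLSModel:
    """Fit OPLS with ``n_orth`` Y-orthogonal components and one predictive
    component per Y column.

    With ``n_orth=0`` the model is exactly a NIPALS PLS. Raises on
    rank-deficient Y, on too few samples (need n > n_orth + q), and on
    NIPALS non-convergence.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    q = Y.shape[1]
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    if n <= n_orth + q:
        raise ValueError(f"need n_samples > n_orth + n_pred ({n} <= {n_orth + q})")
    Yc = Y - Y.mean(axis=0)
    if np.linalg.matrix_rank(Yc) < q:
        raise ValueError("rank-deficient Y (collinear or constant response columns)")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xf = X - x_mean
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        V = _y_basis(Xf, Yc)
        _, _, p_load, _ = _first_pls_component(Xf, Yc)
        w_o = p_load - V @ (V.T @ p_load)
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            warnings.warn("no Y-orthogonal variation left; stopping early")
            break
        w_o /= nrm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o), T_o.append(t_o), P_o.append(p_o)

    W, T, P, C = _nipals_pls(Xf, Yc, n_comp=q)
    B = W @ np.linalg.solve(P.T @ W, C.T)
    resid = Yc - Xf @ B
    r2y = 1.0 - float((resid**2).sum()) / float((Yc**2).sum())

    def stack(cols, rows):
        return np.column_stack(cols) if cols else np.empty((rows, 0))

    return OPLSModel(
        W=W,
        T=T,
        P=P,
        C=C,
        W_o=stack(W_o, p),
        T_o=stack(T_o, n),
        P_o=stack(P_o, p),
        x_mean=x_mean,
        y_mean=y_mean,
        r2y_cum=r2y,
        variable_ids=variable_ids,
        response_ids=response_ids,
    )


def vip(model: OPLSModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a) over the
    predictive components; mean(VIP^2) = 1 by construction."""
    W, T, C = model.W, model.T, model.C
    p = W.shape[0]
    ssy = np.array(
        [(T[:, a] @ T[:, a]) * (C[:, a] @ C[:, a]) for a in range(W.shape[1])]
    )
    if ssy.sum() <= 0:
        raise ValueError("model explains zero response variation; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


def _venetian_folds(n: int, folds: int) -> np.ndarray:
    return np.arange(n) % folds


def _stratified_venetian(Y: np.ndarray, folds: int) -> np.ndarray:
    """Venetian blinds over samples ordered by the first response column, so
    every training fold sees both ends of the response."""
    order = np.argsort(Y[:, 0], kind="stable")
    fold = np.empty(len(order), dtype=int)
    fold[order] = np.arange(len(order)) % folds
    return fold


def _fold_ok(Y: np.ndarray, fold: np.ndarray, folds: int) -> bool:
    for k in range(folds):
        tr = Y[fold != k]
        if np.any(tr.std(axis=0) == 0):
            return False
    return True


def _press_cols(
    X: np.ndarray, Y: np.ndarray, n_orth: int, fold: np.ndarray, folds: int
) -> np.ndarray:
    press = np.zeros(Y.shape[1])
    for k in range(folds):
        tr, te = fold != k, fold == k
        m = fit_opls(X[tr], Y[tr], n_orth)
        press += ((Y[te] - m.predict(X[te])) ** 2).sum(axis=0)
    return press


def _q2(X: np.ndarray, Y: np.ndarray, n_orth: int, fold: np.ndarray, folds: int) -> float:
    press = _press_cols(X, Y, n_orth, fold, folds)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum()
    return float(1.0 - press.sum() / ss_tot)


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    folds: int = 7,
    max_orth: int = 8,
    improvement: float = 0.01,
) -> tuple[np.ndarray, int]:
    """Q2 per orthogonal-component count and the chosen count.

    Folds are venetian blinds on the fixed sample order (deterministic); if a
    training fold would hold a constant response column, the assignment is
    re-stratified by response rank, and an error is raised if that still
    fails. An orthogonal component is accepted while it improves Q2 by more
    than ``improvement``.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, q = len(X), Y.shape[1]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least one sample per fold")
    fold = _venetian_folds(n, folds)
    if not _fold_ok(Y, fold, folds):
        fold = _stratified_venetian(Y, folds)
        if not _fold_ok(Y, fold, folds):
            raise ValueError("cannot form folds with non-constant response columns")
    # n_orth is capped so every training fold keeps n > n_orth + q
    min_train = min(int((fold != k).sum()) for k in range(folds))
    cap = min(max_orth, min_train - q - 1)
    q2s = [_q2(X, Y, a, fold, folds) for a in range(cap + 1)]
    chosen = 0
    for a in range(1, len(q2s)):
        if q2s[a] - q2s[a - 1] > improvement:
            chosen = a
        else:
            break
    return np.array(q2s), chosen


@dataclass
class PermutationSummary:
    """Per-permutation diagnostics plus regression intercepts.

    ``records`` columns: response, permutation, abs_corr, r2y, q2 — the R2Y
    and Q2 of the permuted response column (other columns held fixed). The
    intercepts come from an ordinary least-squares line through the permuted
    points and the unpermuted point at |corr| = 1.
    """

    records: pd.DataFrame
    r2_intercept: dict[str, float]
    q2_intercept: dict[str, float]
    r2y_unpermuted: dict[str, float]
    q2_unpermuted: dict[str, float]
    n_orth: int
    seed: int

    def valid(self) -> bool:
        """The conventional validity call: for every response, a negative Q2
        intercept and an unpermuted Q2 above every permuted one."""
        if not all(v < 0 for v in self.q2_intercept.values()):
            return False
        for name, q2u in self.q2_unpermuted.items():
            perm = self.records.loc[self.records["response"] == name, "q2"]
            if not (perm < q2u).all():
                return False
        return True


def _intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, icpt = np.polyfit(x, y, 1)
    return float(icpt)


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_orth: int,
    folds: int = 7,
    n_perm: int = 100,
    seed: int = 0,
    response_ids: list[str] | None = None,
) -> PermutationSummary:
    """Response-permutation validation, one response column at a time.

    For each of ``n_perm`` permutations of one Y column (other columns kept
    fixed), the model is refit with the same orthogonal-component count and
    fold scheme; |corr| with the original column, training R2Y and
    cross-validated Q2 are recorded. Degenerate permutations (identical to
    the original) are kept as drawn.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    q = Y.shape[1]
    names = response_ids or [f"y{k}" for k in range(q)]
    rng = np.random.default_rng(seed)
    fold = _venetian_folds(len(X), folds)
    if not _fold_ok(Y, fold, folds):
        fold = _stratified_venetian(Y, folds)

    def fit_eval(Ym: np.ndarray, k: int) -> tuple[float, float]:
        """Training R2 and cross-validated Q2 of response column k."""
        m = fit_opls(X, Ym, n_orth)
        Yc = Ym - Ym.mean(axis=0)
        resid = Yc - (m.predict(X) - m.y_mean)
        ss_tot = (Yc**2).sum(axis=0)
        r2_k = 1.0 - float(resid[:, k] @ resid[:, k]) / float(ss_tot[k])
        press = _press_cols(X, Ym, n_orth, fold, folds)
        q2_k = 1.0 - float(press[k]) / float(ss_tot[k])
        return r2_k, q2_k

    rows = []
    r2_icpt, q2_icpt, r2_u, q2_u = {}, {}, {}, {}
    for k, name in enumerate(names):
        r2_u[name], q2_u[name] = fit_eval(Y, k)
        corrs, r2s, q2s = [], [], []
        for b in range(n_perm):
            Yp = Y.copy()
            Yp[:, k] = rng.permutation(Y[:, k])
            r = np.corrcoef(Yp[:, k], Y[:, k])[0, 1]
            r2, q2v = fit_eval(Yp, k)
            corrs.append(abs(r)), r2s.append(r2), q2s.append(q2v)
            rows.append(
                {"response": name, "permutation": b, "abs_corr": abs(r), "r2y": r2, "q2": q2v}
            )
        xs = np.array(corrs + [1.0])
        r2_icpt[name] = _intercept(xs, np.array(r2s + [r2_u[name]]))
        q2_icpt[name] = _intercept(xs, np.array(q2s + [q2_u[name]]))
    return PermutationSummary(
        pd.DataFrame(rows), r2_icpt, q2_icpt, r2_u, q2_u, n_orth, seed
    )
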