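"""NIPALS partial least squares with Q² cross-validation, VIP and
label-permutation validation.

The discriminant flavour (PLS-DA) regresses the preprocessed metabolite
matrix X on a coded class response: a column-centered one-hot matrix over the
four capacity x age groups, a centered +/-1 column for a two-level factor, or
a standardized running-speed column.  Components are extracted one at a time
by the NIPALS iteration with X-deflation (Wold's PLS2); Y is left intact,
which yields the same scores because the extracted score vectors are mutually
orthogonal.

Model quality is summarised by R²X/R²Y (in-sample fractions of sum of squares
explained) and Q² = 1 - PRESS/SS from k-fold cross-validation in which the
column centering/scaling of X and the centering of Y are re-estimated on each
training split.  Validity against overfitting is assessed SIMCA-style: the
response rows are permuted G times, the model is refit each time, and the
regression lines of permuted R²Y and Q² on response similarity give the
R²/Q² intercepts; a negative Q² intercept indicates a non-overfit model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GROUP_ORDER, StudyDesign

logger = logging.getLogger("aerometab")

RESPONSE_MODES = ("four_class", "capacity", "age", "speed")


def build_response(design: StudyDesign, mode: str) -> np.ndarray:
    """Construct the centered response matrix for a PLS(-DA) model.

    ``four_class``: n x 4 one-hot over HCR-Y/LCR-Y/HCR-O/LCR-O, column
    centered.  ``capacity``/``age``: one centered +/-1 column (HCR resp. old
    coded +1).  ``speed``: one centered, unit-variance speed column.
    """
    if mode not in RESPONSE_MODES:
        raise ValueError(f"unknown response mode {mode!r}")
    if mode == "four_class":
        groups = design.groups
        Y = np.column_stack([(groups == g).astype(float) for g in GROUP_ORDER])
    elif mode == "capacity":
        Y = np.where(design.capacity == "HCR", 1.0, -1.0)[:, None]
    elif mode == "age":
        Y = np.where(design.age == "O", 1.0, -1.0)[:, None]
    else:
        speed = design.speed.astype(float)[:, None]
        sd = speed.std(ddof=1)
        if sd == 0:
            raise ValueError("running speed is constant; cannot build response")
        return (speed - speed.mean()) / sd
    return Y - Y.mean(axis=0)


@dataclass
class PLSModel:
    """Fitted NIPALS PLS model (X and Y centered by the caller)."""

    n_components: int
    weights: np.ndarray        # W, J x A
    x_loadings: np.ndarray     # P, J x A
    x_scores: np.ndarray       # T, n x A
    y_loadings: np.ndarray     # C, M x A
    r2x: np.ndarray            # cumulative, length A
    r2y: np.ndarray            # cumulative, length A
    q2: np.ndarray | None = None
    vip: np.ndarray | None = None
    y_coding: str = ""
    predictor_ids: list = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients B (J x M) so that Yhat = X @ B."""
        W, P, C = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, C.T)


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int = 2,
            tol: float = 1e-10, max_iter: int = 500,
            y_coding: str = "", predictor_ids=None) -> PLSModel:
    """Fit PLS by NIPALS with X-deflation.

    X must be column-centered (and typically unit-variance scaled); Y column
    centered.  The inner loop starts from the Y column with the largest
    variance and iterates to a relative score change below ``tol`` (or 500
    iterations).  Each weight vector's largest-magnitude element is made
    positive so results are deterministic.  Components whose residual X
    carries no variance are truncated with a warning.
    """
    X = np.array(X, dtype=float)
    Y = np.atleast_2d(np.array(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    n, J = X.shape
    ssx_total = float((X ** 2).sum())
    ssy_total = float((Y ** 2).sum())
    if ssx_total == 0:
        raise ValueError("X has zero variance")
    if ssy_total == 0:
        raise ValueError("Y has zero variance")
    A = int(n_components)
    M = Y.shape[1]
    W = np.zeros((J, A))
    P = np.zeros((J, A))
    T = np.zeros((n, A))
    C = np.zeros((M, A))
    r2x = np.zeros(A)
    r2y = np.zeros(A)
    Y0 = Y.copy()
    Xd = X.copy()
    a_done = 0
    for a in range(A):
        if float((Xd ** 2).sum()) <= ssx_total * 1e-14:
            warnings.warn(
                f"X exhausted after {a} components; requested {A}, truncating",
                RuntimeWarning, stacklevel=2,
            )
            break
        # NIPALS inner loop, written via the J x J kernel S = (Xd'Y)(Xd'Y)':
        # the classic u -> w -> t -> c -> u cycle updates w to S w (up to
        # normalisation), so power-iterating w on S yields the identical
        # iterate sequence at one matrix-vector product per pass.
        u = Y0[:, int(np.argmax(Y0.var(axis=0)))].copy()
        Z = Xd.T @ Y0
        S = Z @ Z.T
        w = Xd.T @ u
        nw = float(w @ w) ** 0.5
        if nw == 0:
            warnings.warn(
                f"component {a + 1} degenerate; truncating", RuntimeWarning, stacklevel=2
            )
            break
        w /= nw
        if Y0.shape[1] > 1:
            for _ in range(max_iter):
                w_new = S @ w
                nw = float(w_new @ w_new) ** 0.5
                if nw == 0:
                    break
                w_new /= nw
                # fixed-point detection up to sign (power iteration may alternate)
                d = w_new - w if float(w_new @ w) >= 0 else w_new + w
                w = w_new
                if float(d @ d) <= tol * tol:
                    break
        t = Xd @ w
        tt = float(t @ t)
        c = Y0.T @ t / tt if tt > 0 else None
        if c is None:
            warnings.warn(
                f"component {a + 1} degenerate; truncating", RuntimeWarning, stacklevel=2
            )
            break
        if tt <= ssx_total * 1e-14:
            warnings.warn(
                f"component {a + 1} carries no X variance; truncating",
                RuntimeWarning, stacklevel=2,
            )
            break
        # deterministic sign: largest |w| element positive
        flip = np.sign(w[int(np.argmax(np.abs(w)))]) or 1.0
        w, t, c = flip * w, flip * t, flip * c
        p = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        W[:, a], P[:, a], T[:, a], C[:, a] = w, p, t, c
        r2x[a] = 1.0 - float((Xd ** 2).sum()) / ssx_total
        resid_y = Y0 - T[:, : a + 1] @ C[:, : a + 1].T
        r2y[a] = 1.0 - float((resid_y ** 2).sum()) / ssy_total
        a_done = a + 1
    if a_done == 0:
        raise ValueError("no PLS component could be extracted")
    model = PLSModel(
        n_components=a_done,
        weights=W[:, :a_done],
        x_loadings=P[:, :a_done],
        x_scores=T[:, :a_done],
        y_loadings=C[:, :a_done],
        r2x=r2x[:a_done],
        r2y=r2y[:a_done],
        y_coding=y_coding,
        predictor_ids=list(predictor_ids) if predictor_ids is not None else [],
    )
    model.vip = compute_vip(model)
    return model


def compute_vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( J * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the response sum of squares explained by component a.  The mean
    of VIP² equals 1 by construction; a single predictor has VIP exactly 1.
    """
    W, T, C = model.weights, model.x_scores, model.y_loadings
    J, A = W.shape
    ssy = np.array([
        float(T[:, a] @ T[:, a]) * float(C[:, a] @ C[:, a]) for a in range(A)
    ])
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    denom = ssy.sum()
    if denom == 0:
        return np.full(J, np.nan)
    return np.sqrt(J * (wnorm2 @ ssy) / denom)


def _fold_assignment(n: int, folds: int, scheme: str, seed,
                     labels=None) -> np.ndarray:
    """Fold index per sample; stratified within class labels when given."""
    if scheme == "loo":
        return np.arange(n)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    assign = np.empty(n, dtype=int)
    strata = (np.zeros(n, dtype=int) if labels is None
              else pd.factorize(np.asarray(labels))[0])
    rng = np.random.default_rng(seed)
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        if scheme == "random":
            idx = rng.permutation(idx)
        elif scheme != "venetian_blinds":
            raise ValueError(f"unknown CV scheme {scheme!r}")
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cross_validate_q2(X: np.ndarray, Y: np.ndarray, n_components: int = 2,
                      folds: int = 7, scheme: str = "random", seed=0,
                      labels=None) -> np.ndarray:
    """Cumulative Q² per component from k-fold cross-validation.

    Q²_a = 1 - PRESS_a / SS where PRESS sums squared held-out prediction
    errors of models refit on each training split (X centering/scaling and Y
    centering re-estimated on the training rows) and SS sums squared held-out
    deviations from the training response means.  With class labels supplied,
    folds are stratified; a training split losing an entire class raises.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    n = X.shape[0]
    A = int(n_components)
    assign = _fold_assignment(n, folds, scheme, seed, labels=labels)
    press = np.zeros(A)
    ss = 0.0
    for f in np.unique(assign):
        test = assign == f
        train = ~test
        if labels is not None:
            if set(np.asarray(labels)[train]) != set(np.asarray(labels)):
                raise ValueError(
                    "a training split lost an entire class; use a stratified scheme"
                )
        xm = X[train].mean(axis=0)
        xs = X[train].std(axis=0, ddof=1)
        xs[xs == 0] = 1.0
        ym = Y[train].mean(axis=0)
        Xtr = (X[train] - xm) / xs
        Xte = (X[test] - xm) / xs
        Ytr = Y[train] - ym
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_pls(Xtr, Ytr, n_components=A)
        W, P, C = model.weights, model.x_loadings, model.y_loadings
        for a in range(A):
            aa = min(a + 1, model.n_components)
            B = W[:, :aa] @ np.linalg.solve(P[:, :aa].T @ W[:, :aa], C[:, :aa].T)
            Yhat = Xte @ B + ym
            press[a] += float(((Y[test] - Yhat) ** 2).sum())
        ss += float(((Y[test] - ym) ** 2).sum())
    return 1.0 - press / ss


@dataclass
class PermutationResult:
    """Outcome of a SIMCA-style label-permutation validation."""

    G: int
    observed_q2: float
    observed_r2y: float
    perm_q2: np.ndarray
    perm_r2y: np.ndarray
    perm_similarity: np.ndarray
    q2_intercept: float
    r2_intercept: float
    p_value: float

    def points_table(self) -> pd.DataFrame:
        """All (similarity, R²Y, Q²) points including the observed model."""
        return pd.DataFrame(
            {
                "similarity": np.append(self.perm_similarity, 1.0),
                "r2y": np.append(self.perm_r2y, self.observed_r2y),
                "q2": np.append(self.perm_q2, self.observed_q2),
                "permuted": [True] * self.G + [False],
            }
        )


def _similarity(Y_perm: np.ndarray, Y: np.ndarray) -> float:
    """Mean absolute column-wise Pearson correlation between responses."""
    cors = []
    for m in range(Y.shape[1]):
        a, b = Y_perm[:, m], Y[:, m]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        cors.append(abs(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(cors)) if cors else 0.0


def permutation_validate(X: np.ndarray, Y: np.ndarray, n_components: int = 2,
                         G: int = 200, folds: int = 7, scheme: str = "random",
                         seed=0, labels=None) -> PermutationResult:
    """Validate a PLS model by G random permutations of the response rows.

    For each permutation the model is refit and cross-validated; the
    permutation p-value uses the add-one estimator
    p = (1 + #{perm Q² >= observed Q²}) / (G + 1), and the R²/Q² intercepts
    come from least-squares lines through the G permuted points plus the
    observed point at similarity 1.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("constant response; nothing to permute")
    labels = None if labels is None else np.asarray(labels)
    rng = np.random.default_rng(seed)
    model = fit_pls(X, Y, n_components=n_components)
    observed_r2y = float(model.r2y[-1])
    observed_q2 = float(cross_validate_q2(
        X, Y, n_components=n_components, folds=folds, scheme=scheme,
        seed=rng.integers(2 ** 31), labels=labels)[-1])
    perm_q2 = np.empty(G)
    perm_r2y = np.empty(G)
    perm_sim = np.empty(G)
    for g in range(G):
        perm = rng.permutation(X.shape[0])
        Yp = Y[perm]
        lp = None if labels is None else labels[perm]
        perm_sim[g] = _similarity(Yp, Y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mp = fit_pls(X, Yp, n_components=n_components)
        perm_r2y[g] = float(mp.r2y[-1])
        perm_q2[g] = float(cross_validate_q2(
            X, Yp, n_components=n_components, folds=folds, scheme=scheme,
            seed=rng.integers(2 ** 31), labels=lp)[-1])
    p_value = (1.0 + float((perm_q2 >= observed_q2).sum())) / (G + 1.0)
    sims = np.append(perm_sim, 1.0)
    q2_line = np.polyfit(sims, np.append(perm_q2, observed_q2), 1)
    r2_line = np.polyfit(sims, np.append(perm_r2y, observed_r2y), 1)
    return PermutationResult(
        G=G,
        observed_q2=observed_q2,
        observed_r2y=observed_r2y,
        perm_q2=perm_q2,
        perm_r2y=perm_r2y,
        perm_similarity=perm_sim,
        q2_intercept=float(np.polyval(q2_line, 0.0)),
        r2_intercept=float(np.polyval(r2_line, 0.0)),
        p_value=p_value,
    )


def export_scores(model: PLSModel, design: StudyDesign) -> pd.DataFrame:
    """Per-sample t1/t2 score table with group labels, for score plots."""
    if model.n_components < 2:
        raise ValueError("score export needs at least 2 components")
    return pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "t1": model.x_scores[:, 0],
            "t2": model.x_scores[:, 1],
            "group": design.groups,
        }
    )
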