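"""Per-metabolite linear models: two-factor interaction regressions with a
joint F-test, running-speed association models, and Benjamini-Hochberg FDR.

Group model (per metabolite, on the transformed/scaled scale):

    metabolite ~ capacity + age + capacity:age

with treatment dummies, reference levels LCR and young, so beta_capacity is
the HCR effect among the young, beta_age the old effect among LCR, and
beta_interaction the extra old-HCR effect.  The reported joint p is the 3-df
partial F of the whole design block against the intercept-only model.

Speed model (per metabolite):

    speed ~ age + capacity + age:capacity
            + metabolite + metabolite:age + metabolite:capacity
            + metabolite:age:capacity

with a 4-df partial F for the metabolite-related block against the
design-only reduced model, BH-FDR corrected across metabolites per tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MetaboliteMatrix, StudyDesign

logger = logging.getLogger("aerometab")

GROUP_TERMS = ("capacity", "age", "interaction")
SPEED_TERMS = ("metabolite", "metabolite_age", "metabolite_capacity",
               "metabolite_age_capacity")


@dataclass
class OLSFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sse: float
    df_resid: int
    rank: int


def _ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = n - rank
    if rank < k or df <= 0:
        return OLSFit(beta, np.full(k, np.nan), np.full(k, np.nan),
                      np.full(k, np.nan), sse, df, rank)
    sigma2 = sse / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(beta, se, t, p, sse, df, rank)


def _partial_f(sse_reduced: float, sse_full: float, df_block: int,
               df_resid: int) -> tuple[float, float]:
    if df_resid <= 0 or sse_full <= 0:
        return np.nan, np.nan
    f = ((sse_reduced - sse_full) / df_block) / (sse_full / df_resid)
    f = max(f, 0.0)
    return float(f), float(stats.f.sf(f, df_block, df_resid))


def fit_group_model(values, design: StudyDesign, metabolite: str = "") -> dict:
    """OLS of a metabolite on capacity + age + capacity:age (dummy coding).

    Returns one result row: coefficients, SEs, per-term p-values, and the
    3-df joint F / p of the full design block versus intercept only.
    """
    design.require_full_factorial()
    y = np.asarray(values, dtype=float)
    cap = design.capacity_indicator
    old = design.age_indicator
    X = np.column_stack([np.ones_like(y), cap, old, cap * old])
    fit = _ols(X, y)
    if fit.rank < 4:
        raise ValueError("rank-deficient group model (empty design cell?)")
    sse_reduced = float(((y - y.mean()) ** 2).sum())
    joint_f, joint_p = _partial_f(sse_reduced, fit.sse, 3, fit.df_resid)
    row = {"metabolite": metabolite, "n_used": len(y)}
    for i, term in enumerate(GROUP_TERMS, start=1):
        row[f"beta_{term}"] = float(fit.beta[i])
        row[f"se_{term}"] = float(fit.se[i])
        row[f"p_{term}"] = float(fit.p[i])
    row["joint_F"] = joint_f
    row["joint_p"] = joint_p
    return row


def fit_speed_model(speed, values, design: StudyDesign,
                    metabolite: str = "") -> dict:
    """OLS of speed on the design plus the 4-term metabolite block.

    The joint 4-df partial F compares the full model against the design-only
    reduced model.  A singular full fit (e.g. a metabolite constant within a
    cell) yields a flagged row with missing p rather than an exception.
    """
    y = np.asarray(speed, dtype=float)
    m = np.asarray(values, dtype=float)
    cap = design.capacity_indicator
    old = design.age_indicator
    X_reduced = np.column_stack([np.ones_like(y), old, cap, old * cap])
    X_full = np.column_stack([X_reduced, m, m * old, m * cap, m * old * cap])
    fit_full = _ols(X_full, y)
    row = {"metabolite": metabolite, "n_used": len(y)}
    if fit_full.rank < X_full.shape[1]:
        logger.warning("speed model singular for metabolite %s; flagged", metabolite)
        for term in SPEED_TERMS:
            row[f"beta_{term}"] = np.nan
        row.update({"joint_F": np.nan, "joint_p": np.nan, "singular": True})
        return row
    fit_reduced = _ols(X_reduced, y)
    joint_f, joint_p = _partial_f(fit_reduced.sse, fit_full.sse, 4,
                                  fit_full.df_resid)
    for i, term in enumerate(SPEED_TERMS, start=4):
        row[f"beta_{term}"] = float(fit_full.beta[i])
    row.update({"joint_F": joint_f, "joint_p": joint_p, "singular": False})
    return row


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    Missing entries (NaN) are passed through and excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[mask] = out
    return q


def run_univariate_suite(matrix: MetaboliteMatrix, design: StudyDesign
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the group model for every metabolite and, when running speed is
    available, the speed-association model with per-tissue BH-FDR.

    Per-metabolite failures are logged and skipped, not fatal.
    """
    if matrix.sample_ids != design.sample_ids:
        raise ValueError("matrix and design must be aligned")
    group_rows, speed_rows = [], []
    for met in matrix.metabolite_ids:
        values = matrix.data[met].to_numpy()
        try:
            group_rows.append(fit_group_model(values, design, metabolite=met))
        except ValueError as exc:
            logger.warning("group model failed for %s: %s", met, exc)
        if design.has_speed:
            speed_rows.append(
                fit_speed_model(design.speed, values, design, metabolite=met)
            )
    group_table = pd.DataFrame(group_rows)
    speed_table = pd.DataFrame(speed_rows)
    if len(speed_table):
        speed_table["fdr_q"] = bh_fdr(speed_table["joint_p"].to_numpy())
    return group_table, speed_table
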