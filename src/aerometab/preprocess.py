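"""Per-metabolite Box-Cox transformation and unit-variance scaling.

For each metabolite the Box-Cox exponent lambda is chosen on a grid by a
design-residual criterion: residuals from the saturated two-factor cell-means
model (four group means) must have |skewness| < 2 and |excess kurtosis| < 2.
Among acceptable lambdas the one minimising |skew| + |kurtosis|/2 wins
(kurtosis is down-weighted because its sampling noise is larger at this n);
when no lambda meets the criterion the global minimiser is kept and the
metabolite is flagged infeasible.  Transformed columns are then mean-centered
and divided by their sample SD (unit-variance scaling), the standard
pretreatment before PLS in metabolomics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MetaboliteMatrix, StudyDesign

logger = logging.getLogger("aerometab")

#: Default lambda grid: -2.0 to 2.0 in steps of 0.1.
DEFAULT_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)

SKEW_LIMIT = 2.0
KURT_LIMIT = 2.0


@dataclass
class TransformSpec:
    """Chosen transformation and diagnostics for a single metabolite."""

    metabolite: str
    lam: float
    shift: float
    residual_skew: float
    residual_kurtosis: float
    feasible: bool
    scale_sd: float = np.nan
    retained: bool = True


def boxcox(values, lam: float) -> np.ndarray:
    """Box-Cox power transform: (x^lam - 1)/lam, or ln(x) at lam = 0.

    Strictly increasing in x for every lambda.  Values must be strictly
    positive; apply a shift first otherwise.
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values; apply a shift first")
    if lam == 0:
        return np.log(x)
    # expm1 form avoids catastrophic cancellation as lam -> 0
    return np.expm1(lam * np.log(x)) / lam


def required_shift(values) -> float:
    """Offset making values strictly positive: |min| + half the smallest positive value."""
    x = np.asarray(values, dtype=float)
    if np.all(x > 0):
        return 0.0
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("no positive values; cannot construct a Box-Cox shift")
    return float(abs(x.min()) + positive.min() / 2.0)


def _sample_moments(residuals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bias-corrected sample skewness and excess kurtosis along the last axis.

    Standard adjusted estimators (as in scipy's bias=False versions):
    G1 = g1 * sqrt(n(n-1))/(n-2), G2 = ((n+1)g2 + 6)(n-1)/((n-2)(n-3)).
    """
    r = residuals - residuals.mean(axis=-1, keepdims=True)
    n = r.shape[-1]
    m2 = (r ** 2).mean(axis=-1)
    m3 = (r ** 3).mean(axis=-1)
    m4 = (r ** 4).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g1 = m3 / m2 ** 1.5
        g2 = m4 / m2 ** 2 - 3.0
    skew = g1 * np.sqrt(n * (n - 1.0)) / (n - 2.0)
    kurt = ((n + 1.0) * g2 + 6.0) * (n - 1.0) / ((n - 2.0) * (n - 3.0))
    return skew, kurt


def _cell_residuals(values: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Residuals of the saturated cell-means model, along the last axis."""
    groups = design.groups
    residuals = np.array(values, dtype=float)
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"design cell {g} has fewer than 2 samples; "
                             "residual moments undefined")
        residuals[..., mask] -= residuals[..., mask].mean(axis=-1, keepdims=True)
    return residuals


def design_residual_moments(values, design: StudyDesign) -> tuple[float, float]:
    """Skewness and excess kurtosis of cell-means-model residuals.

    Fits the saturated two-factor model (one mean per capacity x age cell),
    pools the residuals and returns their bias-corrected sample skewness and
    excess kurtosis (Normal = 0).  Each occupied cell needs at least two
    samples for the residuals to carry information.
    """
    residuals = _cell_residuals(np.asarray(values, dtype=float), design)
    skew, kurt = _sample_moments(residuals)
    return float(skew), float(kurt)


def select_lambda(values, design: StudyDesign, grid=None,
                  metabolite: str = "") -> TransformSpec:
    """Pick the Box-Cox lambda whose design residuals look most Normal.

    Evaluates the residual-moment criterion at every grid lambda; among
    feasible lambdas (|skew| < 2 and |kurt| < 2) minimises |skew| + |kurt|/2,
    breaking ties toward lambda closest to 1 and then toward the smaller
    lambda.  If no lambda is feasible, the global minimiser is returned with
    ``feasible=False``.  Constant input yields a degenerate spec flagged for
    exclusion.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    x = np.asarray(values, dtype=float)
    shift = required_shift(x)
    x = x + shift
    if np.std(x, ddof=1) == 0:
        return TransformSpec(metabolite, np.nan, shift, np.nan, np.nan,
                             feasible=False, scale_sd=0.0, retained=False)
    # evaluate every grid lambda at once: rows of T are boxcox(x, lam)
    logx = np.log(x)
    lam_col = grid[:, None]
    with np.errstate(over="ignore"):
        T = np.where(lam_col == 0, logx[None, :],
                     np.expm1(np.where(lam_col == 0, 1.0, lam_col) * logx[None, :])
                     / np.where(lam_col == 0, 1.0, lam_col))
    skews, kurts = _sample_moments(_cell_residuals(T, design))
    records = [
        (float(lam), float(s), float(k), float(abs(s) + abs(k) / 2.0))
        for lam, s, k in zip(grid, skews, kurts)
        if np.isfinite(s) and np.isfinite(k)
    ]
    if not records:
        return TransformSpec(metabolite, np.nan, shift, np.nan, np.nan,
                             feasible=False, scale_sd=0.0, retained=False)
    feasible = [r for r in records
                if abs(r[1]) < SKEW_LIMIT and abs(r[2]) < KURT_LIMIT]
    pool = feasible if feasible else records
    # objective, then |lam - 1|, then lam: deterministic tie-break toward 1
    lam, skew, kurt, _ = min(pool, key=lambda r: (r[3], abs(r[0] - 1.0), r[0]))
    return TransformSpec(metabolite, lam, shift, skew, kurt,
                         feasible=bool(feasible))


def unit_variance_scale(data: pd.DataFrame, center: bool = True
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each column by its sample SD (ddof=1), mean-centering first.

    Zero-variance columns are dropped with a warning.  Returns the scaled
    frame and the SDs used.
    """
    sds = data.std(axis=0, ddof=1)
    constant = list(sds[sds == 0].index)
    if constant:
        logger.warning("dropping %d zero-variance metabolites: %s",
                       len(constant), constant)
        data = data.drop(columns=constant)
        sds = sds.drop(constant)
    out = data - data.mean(axis=0) if center else data.copy()
    out = out / sds
    return out, sds


def preprocess_matrix(
    matrix: MetaboliteMatrix,
    design: StudyDesign,
    grid=None,
    center: bool = True,
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Transform and scale every metabolite; return the matrix and a spec table.

    The spec table has one row per input metabolite (retained or not) with the
    chosen lambda, shift, residual moments, feasibility flag and scaling SD.
    """
    if matrix.sample_ids != design.sample_ids:
        raise ValueError("matrix and design must be aligned before preprocessing")
    specs: list[TransformSpec] = []
    transformed = {}
    for met in matrix.metabolite_ids:
        spec = select_lambda(matrix.data[met].to_numpy(), design, grid=grid,
                             metabolite=met)
        if spec.retained:
            transformed[met] = boxcox(matrix.data[met].to_numpy() + spec.shift,
                                      spec.lam)
        specs.append(spec)
    frame = pd.DataFrame(transformed, index=matrix.data.index)
    scaled, sds = unit_variance_scale(frame, center=center)
    by_name = {s.metabolite: s for s in specs}
    for met in frame.columns:
        if met in scaled.columns:
            by_name[met].scale_sd = float(sds[met])
        else:
            by_name[met].retained = False
            by_name[met].scale_sd = 0.0
    spec_table = pd.DataFrame(
        {
            "metabolite": [s.metabolite for s in specs],
            "lambda": [s.lam for s in specs],
            "shift": [s.shift for s in specs],
            "residual_skew": [s.residual_skew for s in specs],
            "residual_kurtosis": [s.residual_kurtosis for s in specs],
            "feasible": [s.feasible for s in specs],
            "scale_sd": [s.scale_sd for s in specs],
            "retained": [s.retained for s in specs],
        }
    )
    return (
        MetaboliteMatrix(scaled, tissue=matrix.tissue),
        spec_table,
    )
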