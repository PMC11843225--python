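"""Intelligence composites and confound residualization.

Three composites are built from ten cognitive task scores: crystallized
intelligence (CI; 2 language tasks), fluid intelligence (FI; 5 executive /
reasoning tasks), and general intelligence (G; a loading-weighted mean of
all 10 tasks, with loadings imported from the published factor analysis).
Both behavioral and gradient measures are residualized on the standard
confounds (age, sex, handedness, years of education, and mean framewise
displacement) by ordinary least squares before any modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COVARIATES, CRYSTALLIZED_TASKS, FLUID_TASKS, TASKS

__all__ = [
    "GFACTOR_WEIGHTS",
    "CRYSTALLIZED_TASKS",
    "FLUID_TASKS",
    "composite_score",
    "score_table",
    "residualize_confounds",
    "encode_covariates",
]

#: g-factor loadings per task (published factor-analysis weights).
GFACTOR_WEIGHTS = {
    "picture_vocabulary": 0.624,
    "oral_reading": 0.642,
    "card_sorting": 0.364,
    "flanker": 0.259,
    "list_sorting": 0.451,
    "progressive_matrices": 0.626,
    "picture_sequence": 0.354,
    "pattern_comparison": 0.232,
    "line_orientation": 0.578,
    "word_memory": 0.294,
}


def _zscore_frame(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=1)
    if (sd == 0).any():
        zero = list(sd.index[sd == 0])
        raise ValueError(f"constant task column(s) cannot be z-scored: {zero}")
    return (frame - frame.mean()) / sd


def composite_score(
    table: pd.DataFrame,
    which: str,
    weights: dict[str, float] | None = None,
    standardize: bool = True,
) -> pd.Series:
    """Compute one intelligence composite from task scores.

    CI and FI are unweighted means of their z-scored task subsets; G is the
    weighted mean ``sum(w_i z_i) / sum(w_i)`` over all ten z-scored tasks.
    ``standardize=False`` treats the columns as already z-scored (useful
    when feeding standardized profiles directly).
    """
    which = which.upper()
    if which == "CI":
        tasks, w = list(CRYSTALLIZED_TASKS), None
    elif which == "FI":
        tasks, w = list(FLUID_TASKS), None
    elif which == "G":
        w = dict(GFACTOR_WEIGHTS if weights is None else weights)
        tasks = list(w)
        if any(v <= 0 for v in w.values()):
            raise ValueError("g-factor weights must be strictly positive")
    else:
        raise ValueError(f"unknown composite {which!r}; expected CI, FI, or G")

    missing = [t for t in tasks if t not in table.columns]
    if missing:
        raise ValueError(f"missing task column(s): {missing}")
    sub = table[tasks].astype(float)
    if sub.isna().any().any():
        raise ValueError("task columns contain missing values")
    z = _zscore_frame(sub) if standardize else sub
    if w is None:
        out = z.mean(axis=1)
    else:
        ws = pd.Series(w)
        out = (z * ws).sum(axis=1) / ws.sum()
    out.name = which
    return out


def score_table(table: pd.DataFrame, weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Append CI, FI, and G columns to a behavioral table."""
    out = table.copy()
    for which in ("CI", "FI", "G"):
        out[which] = composite_score(table, which, weights=weights)
    return out


def encode_covariates(table: pd.DataFrame) -> np.ndarray:
    """Numeric confound matrix in the canonical column order.

    Sex is a 0/1 indicator and handedness a signed continuous score in the
    synthetic tables; any numeric encoding passes through unchanged.
    """
    missing = [c for c in COVARIATES if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    return table[list(COVARIATES)].to_numpy(dtype=float)


def residualize_confounds(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus the covariates.

    ``values`` may be a vector or an n x m matrix of columns to residualize
    jointly. The covariate matrix (with intercept) must be full rank;
    collinear columns are reported by index.
    """
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    y = values[:, None] if single else values
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, p = cov.shape
    if y.shape[0] != n:
        raise ValueError("values and covariates have different lengths")
    if n <= p + 1:
        raise ValueError("need more observations than covariates + intercept")
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [np.ones(n)]
        for j in range(p):
            trial = np.column_stack(cols + [cov[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(j)
            else:
                cols.append(cov[:, j])
        raise ValueError(f"collinear covariate column(s) at index {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid[:, 0] if single else resid
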