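"""Worked-example model: dynamic RMTL effects in older early-stage breast cancer.

A published SEER-based analysis of older (65+) early-stage breast-cancer
patients fitted the dynamic RMTL regression with death from breast cancer
as the event of interest and death from other causes as the competing
event, screening covariates by backward elimination.  The retained
coefficient set (valid for horizons between 2.5 and 10.5 years) is bundled
here as a ready-made fitted model so that coefficient curves, real-time
effects and individualized RMTL trajectories can be demonstrated without
access to the registry data.  Standard errors are not part of the bundle,
so the covariance is zero and only point estimates are meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regression import DynamicRMTLRegression, TimeBasis
from .restriction import TimeGrid

__all__ = ["breast_cancer_model", "example_patients"]

_FEATURES = ["age75", "t2", "n2", "n3", "grade2", "grade34",
             "er_pos", "pr_pos", "bcs", "chemo"]

#: (beta_k0, beta_k1, beta_k2) per row: intercept then the covariates above
_COEF = np.array([
    [-0.237, 0.140, 0.000],   # intercept
    [-0.104, 0.047, 0.000],   # age >= 75 vs 65-74
    [0.000, 0.000, 0.006],    # T2 vs T1
    [0.000, 0.000, 0.006],    # N2 vs N1
    [-0.404, 0.177, 0.000],   # N3 vs N1
    [0.000, 0.000, 0.002],    # grade II vs I
    [-0.233, 0.093, 0.000],   # grade III/IV vs I
    [0.291, -0.141, 0.005],   # ER positive vs negative
    [0.000, -0.027, 0.000],   # PR positive vs negative
    [0.000, 0.000, -0.003],   # breast-conserving surgery vs mastectomy
    [0.160, -0.092, 0.004],   # chemotherapy vs none
])


def breast_cancer_model() -> DynamicRMTLRegression:
    """The published older early-stage breast-cancer dynamic RMTL model.

    Returns a fitted :class:`~dynrmtl.regression.DynamicRMTLRegression`
    whose coefficient matrix holds the published point estimates; the
    active-term mask mirrors the published per-term retention (for
    example, the T2 effect keeps only its quadratic term).
    """
    model = DynamicRMTLRegression(degree=2)
    mask = _COEF != 0.0
    mask[0, 0] = True  # intercept constant term is always active
    basis = TimeBasis(mask)
    model.basis_ = basis
    model.coef_matrix_ = _COEF.copy()
    model.coef_ = np.array([_COEF[k, d] for k, d in basis.active_terms()])
    model.covariance_ = np.zeros((model.coef_.size, model.coef_.size))
    model.grid_ = TimeGrid(np.array([2.5, 10.5]), 10.5)
    model.n_features_in_ = len(_FEATURES)
    model.feature_names_in_ = list(_FEATURES)
    model.n_subjects_ = 3892
    model.n_dropped_rows_ = 0
    return model


def example_patients() -> pd.DataFrame:
    """Three illustrative covariate patterns (patients A, B and C).

    All three are aged 75+ with T2-stage, ER-negative, PR-negative
    disease; they differ in nodal stage, grade and treatment.
    """
    rows = {
        "A": dict(age75=1, t2=1, n2=0, n3=1, grade2=0, grade34=1,
                  er_pos=0, pr_pos=0, bcs=0, chemo=0),
        "B": dict(age75=1, t2=1, n2=0, n3=1, grade2=0, grade34=1,
                  er_pos=0, pr_pos=0, bcs=1, chemo=1),
        "C": dict(age75=1, t2=1, n2=0, n3=0, grade2=0, grade34=0,
                  er_pos=0, pr_pos=0, bcs=1, chemo=1),
    }
    return pd.DataFrame.from_dict(rows, orient="index")[_FEATURES]
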