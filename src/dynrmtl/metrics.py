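"""Horizon-indexed predictive performance for RMTL models.

Two metrics, both computed at a prediction horizon ``l`` on a
competing-risks cohort:

* a cause-specific concordance index — over comparable pairs, the
  proportion (IPCW-weighted) in which the subject who fails from the cause
  of interest earlier carries the *larger* predicted RMTL.  A subject with
  a cause-1 failure at ``t < l`` is comparable with anyone still under
  observation at ``t`` and with anyone who failed from the competing cause
  by ``t`` (the latter are known to accrue no cause-1 lost time).  Pair
  weights are inverse products of the censoring survival function, and
  prediction ties count 1/2, so constant predictions score exactly 0.5.

* a relative prediction error — the IPCW-weighted mean absolute difference
  between observed lost time at ``l`` and the predicted RMTL, as a
  proportion of the follow-up length ``l``.
"""

from __future__ import annotations

import numpy as np

from .restriction import censoring_km

__all__ = ["c_index_at", "relative_prediction_error"]


def c_index_at(time, status, predictions, horizon: float) -> float:
    """Competing-risks concordance of predicted RMTL at ``horizon``."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    pred = np.asarray(predictions, dtype=float)
    if pred.shape != time.shape:
        raise ValueError("one prediction per subject is required")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    G = censoring_km(time, status, horizon)

    case = (status == 1) & (time < horizon)
    if not case.any():
        raise ValueError("no cause-1 events before the horizon: "
                         "concordance undefined")
    ti = time[case]
    pi = pred[case]
    gi = G(ti, left=True)

    # comparable partners: later-or-still-at-risk subjects, and prior
    # competing-event subjects (who remain "at risk" of zero lost time)
    t_all, p_all = time, pred
    later = t_all[None, :] > ti[:, None]
    competing = (status[None, :] == 2) & (t_all[None, :] <= ti[:, None])
    comparable = later | competing
    # a case cannot be paired with itself
    case_idx = case.nonzero()[0]
    comparable[np.arange(case_idx.size), case_idx] = False

    gj = G(t_all, left=True)
    with np.errstate(divide="ignore"):
        wi = np.where(gi > 0, 1.0 / gi, 0.0)
        wj = np.where(gj > 0, 1.0 / gj, 0.0)
    w = np.where(later, wi[:, None] ** 2, wi[:, None] * wj[None, :])
    w = np.where(comparable, w, 0.0)

    diff = pi[:, None] - p_all[None, :]
    conc = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    denom = w.sum()
    if denom <= 0:
        raise ValueError("no comparable pairs at this horizon")
    return float((w * conc).sum() / denom)


def relative_prediction_error(time, status, predictions,
                              horizon: float, squared: bool = False) -> float:
    """IPCW-weighted prediction error as a proportion of follow-up length.

    Mean absolute (or squared, with ``squared=True``) difference between
    the observed restricted lost time and the predicted RMTL among
    observable subjects, weighted by ``1/G(T(l)-)`` and divided by ``l``.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    pred = np.asarray(predictions, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if pred.shape != time.shape:
        raise ValueError("one prediction per subject is required")
    before = time < horizon
    observable = ~(before & (status == 0))
    t_l = np.minimum(time, horizon)
    lost = np.where(before & (status == 1), horizon - time, 0.0)
    G = censoring_km(time, status, horizon)
    g = G(t_l[observable], left=True)
    w = np.where(g > 0, 1.0 / g, 0.0)
    err = np.abs(lost[observable] - pred[observable])
    if squared:
        err = err ** 2
    if w.sum() <= 0:
        raise ValueError("no observable subjects at this horizon")
    mean_err = float((w * err).sum() / w.sum())
    return (np.sqrt(mean_err) if squared else mean_err) / horizon
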