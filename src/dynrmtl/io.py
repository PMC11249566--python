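"""Cohort I/O, model serialization and synthetic fixture generation.

Cohort files are plain CSV with a ``time`` column (years), a ``status``
column coded 0 (censored) / 1 (event of interest) / 2 (competing event),
and any further columns treated as covariates.  Categorical covariates are
expanded to reference-coded indicators.  Fitted models round-trip through
a versioned JSON document.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from . import __version__
from .regression import DynamicRMTLRegression, TimeBasis
from .restriction import TimeGrid
from .simulation import GompertzScenario, calibrate_censoring, cohort_frame, true_beta

__all__ = [
    "read_cohort",
    "encode_covariates",
    "save_model",
    "load_model",
    "generate_fixture",
]

_MODEL_FORMAT = "dynrmtl-model"
_MODEL_FORMAT_VERSION = 1


class CohortError(ValueError):
    """Malformed cohort table."""


def read_cohort(path, covariates=None, categorical_refs=None):
    """Read and validate a cohort CSV.

    Returns ``(time, status, X)`` where ``X`` is the reference-coded
    covariate frame.  ``covariates`` restricts which columns are used
    (default: every column besides ``time``/``status``);
    ``categorical_refs`` maps column name to the reference level (default:
    first level in sorted order).
    """
    df = pd.read_csv(path)
    missing = {"time", "status"} - set(df.columns)
    if missing:
        raise CohortError(f"cohort file is missing columns {sorted(missing)}")
    time = pd.to_numeric(df["time"], errors="coerce")
    bad = df.index[time.isna() | (time < 0)].tolist()
    if bad:
        raise CohortError(f"non-numeric or negative time in rows {bad[:10]}")
    status = df["status"]
    bad = df.index[~status.isin([0, 1, 2])].tolist()
    if bad:
        raise CohortError(f"status outside {{0,1,2}} in rows {bad[:10]}")
    cols = (list(covariates) if covariates is not None
            else [c for c in df.columns if c not in ("time", "status")])
    absent = [c for c in cols if c not in df.columns]
    if absent:
        raise CohortError(f"configured covariates not in file: {absent}")
    X = encode_covariates(df[cols], categorical_refs)
    return time.to_numpy(float), status.to_numpy(np.int64), X


def encode_covariates(frame: pd.DataFrame,
                      categorical_refs=None) -> pd.DataFrame:
    """Reference-code categorical columns; numeric columns pass through."""
    refs = dict(categorical_refs or {})
    out = {}
    for col in frame.columns:
        s = frame[col]
        if s.dtype.kind in "biufc" and col not in refs:
            out[col] = s.astype(float)
            continue
        levels = sorted(s.astype(str).unique())
        ref = str(refs.get(col, levels[0]))
        if ref not in levels:
            raise CohortError(
                f"reference level {ref!r} not found in column {col!r} "
                f"(levels: {levels})")
        for lev in levels:
            if lev != ref:
                out[f"{col}_{lev}"] = (s.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=frame.index)


# ------------------------------------------------------------ model files

def _config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_model(model: DynamicRMTLRegression, path, seed=None,
               config=None) -> None:
    """Serialize a fitted model to versioned JSON (lossless round trip)."""
    model._check_fitted()
    doc = {
        "format": _MODEL_FORMAT,
        "format_version": _MODEL_FORMAT_VERSION,
        "package_version": __version__,
        "feature_names": list(model.feature_names_in_),
        "basis_mask": model.basis_.mask.astype(int).tolist(),
        "coef_matrix": model.coef_matrix_.tolist(),
        "covariance": model.covariance_.tolist(),
        "horizons": model.grid_.horizons.tolist(),
        "tau": model.grid_.tau,
        "n_subjects": model.n_subjects_,
        "params": model.get_params(),
        "provenance": {
            "seed": seed,
            "config_hash": _config_hash(config) if config is not None else None,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> DynamicRMTLRegression:
    """Reconstruct a fitted model from :func:`save_model` output."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from None
    if doc.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} document")
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {doc.get('format_version')} "
            f"unsupported (expected {_MODEL_FORMAT_VERSION})")
    params = doc.get("params", {})
    model = DynamicRMTLRegression(
        **{k: v for k, v in params.items()
           if k in DynamicRMTLRegression().get_params()})
    basis = TimeBasis(np.asarray(doc["basis_mask"], dtype=bool))
    model.basis_ = basis
    model.coef_matrix_ = np.asarray(doc["coef_matrix"], dtype=float)
    model.coef_ = np.array([model.coef_matrix_[k, d]
                            for k, d in basis.active_terms()])
    model.covariance_ = np.asarray(doc["covariance"], dtype=float)
    model.grid_ = TimeGrid(np.asarray(doc["horizons"], dtype=float),
                           float(doc["tau"]))
    model.feature_names_in_ = list(doc["feature_names"])
    model.n_features_in_ = len(model.feature_names_in_)
    model.n_subjects_ = int(doc["n_subjects"])
    model.n_dropped_rows_ = 0
    return model


# --------------------------------------------------------------- fixtures

#: log-linear perturbations of (log gamma, log |rho|) per indicator column;
#: a gamma entry shifts the cause-1 level, a rho entry bends its time
#: profile, producing a genuinely dynamic effect on the RMTL scale.
_SEER_LIKE_EFFECTS = {
    "age75": (0.25, 0.0),
    "t2": (0.35, -0.15),
    "nstage_N2": (0.30, 0.0),
    "nstage_N3": (0.55, 0.10),
    "grade_II": (0.15, -0.10),
    "grade_III&IV": (0.40, 0.0),
    "er_pos": (-0.35, 0.10),
    "pr_pos": (-0.15, 0.0),
    "bcs": (-0.15, -0.10),
    "chemo": (-0.25, 0.15),
}
_SEER_LIKE_BASE = {"log_gamma": np.log(0.45), "log_neg_rho": np.log(0.55),
                   "censoring_scale": 3.0}  # ~50% censoring, registry-like


def _seer_like_params(x: dict) -> tuple[float, float]:
    lg = _SEER_LIKE_BASE["log_gamma"]
    lr = _SEER_LIKE_BASE["log_neg_rho"]
    for name, (ag, ar) in _SEER_LIKE_EFFECTS.items():
        v = x.get(name, 0.0)
        lg += ag * v
        lr += ar * v
    return float(np.exp(lg)), float(-np.exp(lr))


def seer_like_true_rmtl(x: dict, l: float) -> float:
    """True RMTL of a covariate pattern under the seer-like mechanism."""
    g, r = _seer_like_params(x)
    val, _ = quad(lambda t: 1 - np.exp(-g * (np.exp(r * t) - 1) / r),
                  0.0, l, epsabs=1e-8, limit=200)
    return val


def seer_like_true_effect(name: str, l: float) -> float:
    """True dynamic effect of one indicator (others at reference)."""
    return seer_like_true_rmtl({name: 1.0}, l) - seer_like_true_rmtl({}, l)


def _generate_seer_like(n: int, rng: np.random.Generator) -> pd.DataFrame:
    race = rng.choice(["other", "white", "black"], size=n, p=[0.1, 0.8, 0.1])
    nstage = rng.choice(["N1", "N2", "N3"], size=n, p=[0.7, 0.2, 0.1])
    grade = rng.choice(["I", "II", "III&IV"], size=n, p=[0.25, 0.45, 0.3])
    binary = {
        "age75": 0.45, "married": 0.5, "t2": 0.35, "er_pos": 0.8,
        "pr_pos": 0.7, "bcs": 0.55, "slnb": 0.6, "chemo": 0.35,
        "radiation": 0.5,
    }
    df = pd.DataFrame({"race": race, "nstage": nstage, "grade": grade})
    for col, p in binary.items():
        df[col] = (rng.random(n) < p).astype(int)
    # event mechanism (race/married/slnb/radiation are pure-noise columns)
    time = np.empty(n)
    status = np.empty(n, dtype=np.int64)
    cscale = _SEER_LIKE_BASE["censoring_scale"]
    for i in range(n):
        x = {
            "age75": df.at[i, "age75"], "t2": df.at[i, "t2"],
            "nstage_N2": float(df.at[i, "nstage"] == "N2"),
            "nstage_N3": float(df.at[i, "nstage"] == "N3"),
            "grade_II": float(df.at[i, "grade"] == "II"),
            "grade_III&IV": float(df.at[i, "grade"] == "III&IV"),
            "er_pos": df.at[i, "er_pos"], "pr_pos": df.at[i, "pr_pos"],
            "bcs": df.at[i, "bcs"], "chemo": df.at[i, "chemo"],
        }
        g, r = _seer_like_params(x)
        p1 = 1.0 - np.exp(g / r)
        u = rng.uniform(1e-12, 1.0)
        if rng.random() < p1:
            t = np.log1p(-(r / g) * np.log1p(-u * p1)) / r
            cause = 1
        else:
            t = -np.log1p(-u) * 3.0  # competing times on a longer scale
            cause = 2
        c = rng.uniform(0.0, cscale)
        time[i] = min(t, c)
        status[i] = cause if t <= c else 0
    out = pd.DataFrame({"time": np.round(time, 6), "status": status})
    return pd.concat([out, df], axis=1)


def generate_fixture(kind: str, out_path, seed: int = 0, n: int = 1000,
                     scenario: GompertzScenario | None = None) -> Path:
    """Write a deterministic synthetic cohort CSV plus a truth JSON.

    ``kind="paper-sim"`` draws from the Gompertz two-exposure scenario;
    ``kind="seer-like"`` emulates a registry table with 12 covariates
    (three of them categorical) and known log-linear Gompertz effects.
    The companion ``<out>.truth.json`` records the generating parameters.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(seed)
    if kind == "paper-sim":
        sc = scenario if scenario is not None else GompertzScenario(n=n)
        sc = sc.with_(n=n)
        df = cohort_frame(sc, rng)
        truth = {
            "kind": kind, "seed": seed, "n": n,
            "gamma": sc.gamma, "rho": sc.rho,
            "p_z1": sc.p_z1, "p_z2": sc.p_z2,
            "censoring_rate": sc.censoring_rate,
            "censoring_theta": calibrate_censoring(sc),
            "true_beta": {str(l): true_beta(l, sc).tolist()
                          for l in (0.75, 1.0, 1.5)},
        }
    elif kind == "seer-like":
        df = _generate_seer_like(n, rng)
        truth = {
            "kind": kind, "seed": seed, "n": n,
            "base": _SEER_LIKE_BASE,
            "effects": {k: list(v) for k, v in _SEER_LIKE_EFFECTS.items()},
            "noise_columns": ["race", "married", "slnb", "radiation"],
            "true_effect_at_5y": {k: seer_like_true_effect(k, 5.0)
                                  for k in _SEER_LIKE_EFFECTS},
        }
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    df.to_csv(out_path, index=False)
    Path(str(out_path) + ".truth.json").write_text(
        json.dumps(truth, indent=1, default=float))
    return out_path
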