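"""Constrained multi-restart least-squares fitting of the adaptation models.

The objective is the summed squared residual of the predicted vs observed
acceleration- and deceleration-period displacements over all non-baseline
trials (both channels; for the scalar two-state model, total displacement).
Joint fits sum the objective over two experiments with one shared parameter
set, which breaks parameter trade-offs that a single schedule leaves open.

Ordering constraints (slow state retains more: a_slow >= a_fast; fast state
learns more: b_fast0 >= b_slow0) are enforced by reparameterization
(a_fast = a_slow * u, b_slow0 = b_fast0 * w with u, w in [0, 1]), so the
box-bounded search space is always feasible.  Each restart draws a uniform
initial point inside the bounds from a fixed seed and runs a trust-region
reflective least-squares solve; the best restart is polished with tight
tolerances and returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError
from .schedules import ExperimentSchedule
from .statespace import (
    Model1Params, Model2Params, TwoStateParams, _simulate_arrays,
    infer_model_id,
)

# ---------------------------------------------------------------------------
# Internal parameterization: model params <-> bounded search vector
# ---------------------------------------------------------------------------

# bounds bracket the published best-fit values by an order of magnitude
_SPACES = {
    "model1": {
        # name, lower, upper
        "names": ["a_slow", "u_ret", "b_fast0", "w_sens", "d_slow",
                  "d_fast", "p", "beta_slow", "beta_fast"],
        "lb": np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
        "ub": np.array([1.0, 1.0, 0.5, 1.0, 1.0, 1.0, 1.0, 1e-3, 1e-3]),
    },
    "model2": {
        "names": ["a_aim", "a_acc", "a_dec", "b_aim0", "b_acc0", "b_dec0",
                  "d_dec", "beta", "p"],
        "lb": np.zeros(9),
        "ub": np.array([1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 1.0, 1e-2, 1.0]),
    },
    "twostate": {
        "names": ["a_s", "u_ret", "b_f", "w_sens", "d_s", "d_f"],
        "lb": np.zeros(6),
        "ub": np.array([1.0, 1.0, 0.5, 1.0, 1.0, 1.0]),
    },
}


def _vector_to_params(model_id: str, z: np.ndarray):
    if model_id == "model1":
        return Model1Params(
            a_slow=z[0], a_fast=z[0] * z[1], b_fast0=z[2],
            b_slow0=z[2] * z[3], d_slow=z[4], d_fast=z[5], p=z[6],
            beta_slow=z[7], beta_fast=z[8],
        )
    if model_id == "model2":
        return Model2Params(
            a_aim=z[0], a_acc=z[1], a_dec=z[2], b_aim0=z[3], b_acc0=z[4],
            b_dec0=z[5], d_dec=z[6], beta=z[7], p=z[8],
        )
    return TwoStateParams(
        a_s=z[0], a_f=z[0] * z[1], b_f=z[2], b_s=z[2] * z[3],
        d_s=z[4], d_f=z[5],
    )


def _params_to_vector(model_id: str, params) -> np.ndarray:
    if model_id == "model1":
        u = params.a_fast / params.a_slow if params.a_slow > 0 else 0.0
        w = params.b_slow0 / params.b_fast0 if params.b_fast0 > 0 else 0.0
        return np.array([params.a_slow, u, params.b_fast0, w, params.d_slow,
                         params.d_fast, params.p, params.beta_slow,
                         params.beta_fast])
    if model_id == "model2":
        return np.array([params.a_aim, params.a_acc, params.a_dec,
                         params.b_aim0, params.b_acc0, params.b_dec0,
                         params.d_dec, params.beta, params.p])
    u = params.a_f / params.a_s if params.a_s > 0 else 0.0
    w = params.b_s / params.b_f if params.b_f > 0 else 0.0
    return np.array([params.a_s, u, params.b_f, w, params.d_s, params.d_f])


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Multi-restart settings: restart count, seed, solver tolerance."""

    n_restarts: int = 100
    seed: int = 0
    tolerance: float = 1e-12
    max_nfev: int | None = None
    extra_starts: tuple = ()  # optional additional initial parameter sets

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class FitResult:
    """Best-of-restarts fit: parameters, objective value, diagnostics."""

    params: object
    model_id: str
    sse: float
    n_obs: int
    restart_sses: np.ndarray
    converged: bool

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.sse / self.n_obs))

    @property
    def restart_spread(self) -> float:
        return float(np.max(self.restart_sses) - np.min(self.restart_sses))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params.as_dict(),
            "sse": self.sse,
            "rmse": self.rmse,
            "n_obs": self.n_obs,
            "restart_spread": self.restart_spread,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


def _predict(model_id: str, params, arr) -> tuple[np.ndarray, np.ndarray]:
    yA, yD, _, _, _ = _simulate_arrays(model_id, params, arr)
    return yA, yD


def _residuals_phase(data, params, model_id: str, arr) -> np.ndarray:
    yA_obs, yD_obs = data
    mask = arr["fit_mask"]
    if len(yA_obs) != len(mask) or len(yD_obs) != len(mask):
        raise FitError(
            f"data length {len(yA_obs)}/{len(yD_obs)} does not match schedule "
            f"length {len(mask)}"
        )
    yA, yD = _predict(model_id, params, arr)
    return np.concatenate([(yA - yA_obs)[mask], (yD - yD_obs)[mask]])


def _residuals_total(y_obs, params, model_id: str, arr) -> np.ndarray:
    mask = arr["fit_mask"]
    if len(y_obs) != len(mask):
        raise FitError(
            f"data length {len(y_obs)} does not match schedule length {len(mask)}"
        )
    yA, yD = _predict(model_id, params, arr)
    return ((yA + yD) - y_obs)[mask]


def objective_phase(data, params, model_id: str,
                    schedule: ExperimentSchedule) -> float:
    """Summed squared error over both displacement channels, baseline excluded.

    ``data`` is a (yA_obs, yD_obs) pair of arrays aligned to the schedule.
    """
    res = _residuals_phase(data, params, model_id, schedule.as_arrays())
    return float(res @ res)


def objective_joint(data_e1, data_e2, params, model_id: str,
                    schedules) -> float:
    """Joint two-experiment objective: sum of the per-experiment objectives."""
    if data_e1 is None or data_e2 is None:
        raise FitError("joint objective requires both experiments' series")
    s1, s2 = schedules
    return (objective_phase(data_e1, params, model_id, s1)
            + objective_phase(data_e2, params, model_id, s2))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


_RESIDUAL_CAP = 1e6  # large-sensitivity draws can destabilize the closed loop


def _make_residual_fn(model_id: str, datasets, arrays):
    def fn(z: np.ndarray) -> np.ndarray:
        params = _vector_to_params(model_id, z)
        with np.errstate(over="ignore", invalid="ignore"):
            parts = [
                _residuals_phase(d, params, model_id, a)
                for d, a in zip(datasets, arrays)
            ]
            res = np.concatenate(parts)
        return np.clip(np.nan_to_num(res, nan=_RESIDUAL_CAP,
                                     posinf=_RESIDUAL_CAP,
                                     neginf=-_RESIDUAL_CAP),
                       -_RESIDUAL_CAP, _RESIDUAL_CAP)

    return fn


def _run_restarts(fn, model_id: str, config: FitConfig, n_obs: int
                  ) -> FitResult:
    space = _SPACES[model_id]
    lb, ub = space["lb"], space["ub"]
    rng = np.random.default_rng(config.seed)
    starts = [rng.uniform(lb, ub) for _ in range(config.n_restarts)]
    for extra in config.extra_starts:
        z = np.clip(_params_to_vector(model_id, extra), lb, ub)
        starts.append(z)

    x_scale = np.maximum(ub - lb, 1e-8)
    best = None
    sses = []
    any_ok = False
    for x0 in starts:
        try:
            sol = least_squares(
                fn, x0, bounds=(lb, ub), method="trf",
                ftol=config.tolerance, xtol=config.tolerance,
                gtol=config.tolerance, x_scale=x_scale,
                max_nfev=config.max_nfev,
            )
        except Exception:
            sses.append(np.inf)
            continue
        any_ok = True
        sse = float(2.0 * sol.cost)
        sses.append(sse)
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None or not any_ok:
        raise FitError("all restarts failed to converge")

    # polish the winner with tight tolerances
    sol = least_squares(
        fn, best[1], bounds=(lb, ub), method="trf",
        ftol=1e-15, xtol=1e-15, gtol=1e-15, x_scale=x_scale,
    )
    sse = float(2.0 * sol.cost)
    if sse > best[0]:
        sse, x = best
    else:
        x = sol.x
    return FitResult(
        params=_vector_to_params(model_id, x), model_id=model_id,
        sse=sse, n_obs=n_obs, restart_sses=np.array(sses), converged=True,
    )


def fit(data, model_id: str, schedules, config: FitConfig | None = None
        ) -> FitResult:
    """Fit a model to one or more experiments' displacement series.

    ``data`` is a (yA_obs, yD_obs) pair, or a sequence of such pairs when
    ``schedules`` is a sequence of schedules (joint fit with one shared
    parameter set).  Observation count n_obs counts both channels of every
    fitted (non-baseline) trial.
    """
    cfg = config or FitConfig()
    if isinstance(schedules, ExperimentSchedule):
        schedules = [schedules]
        data = [data]
    if len(data) != len(schedules):
        raise FitError("need one dataset per schedule")
    arrays = [s.as_arrays() for s in schedules]
    datasets = []
    for d, a in zip(data, arrays):
        yA_obs, yD_obs = np.asarray(d[0], dtype=float), np.asarray(d[1], dtype=float)
        if len(yA_obs) != len(a["r"]) or len(yD_obs) != len(a["r"]):
            raise FitError(
                f"data length {len(yA_obs)}/{len(yD_obs)} does not match "
                f"schedule length {len(a['r'])}"
            )
        datasets.append((yA_obs, yD_obs))
    n_obs = int(sum(2 * a["fit_mask"].sum() for a in arrays))
    fn = _make_residual_fn(model_id, datasets, arrays)
    return _run_restarts(fn, model_id, cfg, n_obs)


def fit_two_state_total(total_series, schedule: ExperimentSchedule,
                        config: FitConfig | None = None) -> FitResult:
    """Fit the scalar two-state model to a total-displacement series."""
    cfg = config or FitConfig()
    arr = schedule.as_arrays()
    y_obs = np.asarray(total_series, dtype=float)

    def fn(z: np.ndarray) -> np.ndarray:
        params = _vector_to_params("twostate", z)
        with np.errstate(over="ignore", invalid="ignore"):
            res = _residuals_total(y_obs, params, "twostate", arr)
        return np.clip(np.nan_to_num(res, nan=_RESIDUAL_CAP,
                                     posinf=_RESIDUAL_CAP,
                                     neginf=-_RESIDUAL_CAP),
                       -_RESIDUAL_CAP, _RESIDUAL_CAP)

    n_obs = int(arr["fit_mask"].sum())
    return _run_restarts(fn, "twostate", cfg, n_obs)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Percentile confidence intervals from participant resampling."""

    intervals: dict[str, tuple[float, float]]
    samples: dict[str, np.ndarray]
    n_failed: int


def bootstrap_ci(cohort_series, model_id: str, schedules,
                 n_boot: int = 200, config: FitConfig | None = None,
                 ci: float = 95.0, seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap over participants.

    ``cohort_series`` is a list of per-participant datasets in the shape
    :func:`fit` accepts (one per participant, aligned to ``schedules``).
    Each batch resamples participants with replacement, averages their
    series element-wise, and refits; intervals are the interior ``ci``
    percent of each parameter's bootstrap distribution.
    """
    if len(cohort_series) < 2:
        raise FitError("bootstrap needs at least 2 participants")
    cfg = config or FitConfig(n_restarts=10)
    single = isinstance(schedules, ExperimentSchedule)
    rng = np.random.default_rng(seed)
    records: list[dict[str, float]] = []
    n_failed = 0
    n = len(cohort_series)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if single:
            mean_data = tuple(
                np.mean([np.asarray(cohort_series[i][c]) for i in idx], axis=0)
                for c in range(2)
            )
        else:
            mean_data = [
                tuple(
                    np.mean([np.asarray(cohort_series[i][e][c]) for i in idx],
                            axis=0)
                    for c in range(2)
                )
                for e in range(len(schedules))
            ]
        try:
            res = fit(mean_data, model_id, schedules, cfg)
        except FitError:
            n_failed += 1
            continue
        records.append(res.params.as_dict())
    if not records:
        raise FitError("every bootstrap batch failed")
    names = records[0].keys()
    samples = {k: np.array([r[k] for r in records]) for k in names}
    half = (100.0 - ci) / 2.0
    intervals = {
        k: (float(np.percentile(v, half)), float(np.percentile(v, 100.0 - half)))
        for k, v in samples.items()
    }
    return BootstrapResult(intervals=intervals, samples=samples,
                           n_failed=n_failed)
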