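"""State-space models of trial-by-trial saccade adaptation.

All three models share the linear learning/forgetting recurrence

    x(n+1) = D(n) (A x(n) + b(n) e(n)),      y(n) = C x(n)

where x is the hidden adaptation state (degrees), A is a diagonal retention
matrix, b is the error-sensitivity vector, e is the scalar visual error, and
D applies extra forgetting across a 30 s set break (identity on ordinary
trials).  The error is r - y on ordinary trials and exactly 0 on error-clamp
trials, where r is the perpendicular target jump in degrees.

The models differ in their states and read-out:

* two-state: slow/fast states, scalar total output y = x_s + x_f;
* model 1: slow/fast states; a fraction p of the summed state is expressed
  during the acceleration period of the saccade, 1-p during deceleration;
* model 2: an aim state shared across both periods (split p / 1-p) plus
  separate acceleration and deceleration states; only the deceleration
  state forgets across set breaks.

Error sensitivity grows with repeated exposure to a consistent error
(savings) and resets to its initial value when the perturbation reverses
sign.  Model 1 grows additively (b = b0 + beta * k); model 2 scales its
initial vector (b = b0 * (1 + beta * k)); k counts perturbation trials
since the last sign switch, including the current trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .errors import SaccadeAdaptError
from .schedules import ExperimentSchedule, TrialSpec

MODEL_IDS = ("twostate", "model1", "model2")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class TwoStateParams:
    """Standard two-state model: slow/fast retention, sensitivity, break decay."""

    a_s: float
    a_f: float
    b_s: float
    b_f: float
    d_s: float = 1.0
    d_f: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.a_f <= self.a_s <= 1.0):
            raise ValueError("need 0 <= a_f <= a_s <= 1")
        if not (0.0 <= self.b_s <= self.b_f):
            raise ValueError("need 0 <= b_s <= b_f")
        if not (0.0 <= self.d_s <= 1.0 and 0.0 <= self.d_f <= 1.0):
            raise ValueError("break retention factors must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class Model1Params:
    """Single controller with fast/slow states and a fixed expression split p."""

    a_slow: float
    a_fast: float
    b_slow0: float
    b_fast0: float
    d_slow: float
    d_fast: float
    p: float
    beta_slow: float = 0.0
    beta_fast: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.a_fast <= self.a_slow <= 1.0):
            raise ValueError("need 0 <= a_fast <= a_slow <= 1")
        if not (0.0 <= self.b_slow0 <= self.b_fast0):
            raise ValueError("need 0 <= b_slow0 <= b_fast0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if min(self.d_slow, self.d_fast) < 0 or max(self.d_slow, self.d_fast) > 1:
            raise ValueError("break retention factors must lie in [0, 1]")
        if min(self.beta_slow, self.beta_fast) < 0:
            raise ValueError("sensitivity growth rates must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class Model2Params:
    """Aim controller (split p / 1-p) plus independent accel/decel states.

    The reduced 9-parameter form shares one sensitivity growth rate beta
    across states and allows set-break forgetting only in the deceleration
    state.  The full 13-parameter variant is available through the optional
    fields: d_aim/d_acc and per-state growth rates (None means "use beta").
    """

    a_aim: float
    a_acc: float
    a_dec: float
    b_aim0: float
    b_acc0: float
    b_dec0: float
    d_dec: float
    beta: float
    p: float
    d_aim: float = 1.0
    d_acc: float = 1.0
    beta_acc: float | None = None
    beta_dec: float | None = None

    def validate(self) -> None:
        for name in ("a_aim", "a_acc", "a_dec", "d_aim", "d_acc", "d_dec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("b_aim0", "b_acc0", "b_dec0", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        if d["beta_acc"] is None:
            del d["beta_acc"]
        if d["beta_dec"] is None:
            del d["beta_dec"]
        return d


PARAM_TYPES = {
    "twostate": TwoStateParams,
    "model1": Model1Params,
    "model2": Model2Params,
}


def infer_model_id(params) -> str:
    for mid, cls in PARAM_TYPES.items():
        if isinstance(params, cls):
            return mid
    raise SaccadeAdaptError(f"unknown parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# Behavior trace
# ---------------------------------------------------------------------------


@dataclass
class BehaviorTrace:
    """Per-trial model output over one schedule.

    ``x`` and ``b`` hold the pre-update state and the error sensitivity in
    effect on each trial (rows = trials).  ``yA``/``yD`` are the horizontal
    displacements expressed during the acceleration and deceleration periods
    of the saccade; y = yA + yD is the total displacement.  For the scalar
    two-state model the total is split evenly between the two channels so
    that y = yA + yD holds universally.
    """

    model_id: str
    r: np.ndarray
    clamp: np.ndarray
    break_after: np.ndarray
    phase: np.ndarray
    e: np.ndarray
    yA: np.ndarray
    yD: np.ndarray
    x: np.ndarray
    b: np.ndarray

    @property
    def y(self) -> np.ndarray:
        return self.yA + self.yD

    def __len__(self) -> int:
        return len(self.e)

    def to_frame(self):
        import pandas as pd

        d = {
            "trial": np.arange(len(self)),
            "phase": self.phase,
            "r": self.r,
            "clamp": self.clamp.astype(int),
            "break_after": self.break_after.astype(int),
            "e": self.e,
            "yA": self.yA,
            "yD": self.yD,
            "y": self.y,
        }
        names = state_names(self.model_id)
        for j, nm in enumerate(names):
            d[f"x_{nm}"] = self.x[:, j]
            d[f"b_{nm}"] = self.b[:, j]
        return pd.DataFrame(d)


def state_names(model_id: str) -> tuple[str, ...]:
    if model_id == "model2":
        return ("aim", "acc", "dec")
    return ("slow", "fast")


# ---------------------------------------------------------------------------
# Elementary per-trial operations (reference building blocks)
# ---------------------------------------------------------------------------


def error_for_trial(trial: TrialSpec, y: float) -> float:
    """Visual error on one trial: r - y, forced to 0 on error-clamp trials."""
    return 0.0 if trial.clamp else trial.r - y


def observe_model1(x: np.ndarray, p: float) -> tuple[float, float]:
    """Split the summed state: fraction p during acceleration, 1-p during deceleration."""
    total = x[0] + x[1]
    return p * total, (1.0 - p) * total


def observe_model2(x: np.ndarray, p: float) -> tuple[float, float]:
    """Aim state split p/(1-p) across periods; accel/decel states act alone."""
    return p * x[0] + x[1], (1.0 - p) * x[0] + x[2]


def step_model1(x: np.ndarray, e: float, b: np.ndarray, break_after: bool,
                params: Model1Params) -> np.ndarray:
    if not (np.all(np.isfinite(x)) and np.isfinite(e)):
        raise SaccadeAdaptError("non-finite state or error")
    a = np.array([params.a_slow, params.a_fast])
    x_new = a * x + b * e
    if break_after:
        x_new = x_new * np.array([params.d_slow, params.d_fast])
    return x_new


def step_model2(x: np.ndarray, e: float, b: np.ndarray, break_after: bool,
                params: Model2Params) -> np.ndarray:
    if not (np.all(np.isfinite(x)) and np.isfinite(e)):
        raise SaccadeAdaptError("non-finite state or error")
    a = np.array([params.a_aim, params.a_acc, params.a_dec])
    x_new = a * x + b * e
    if break_after:
        x_new = x_new * np.array([params.d_aim, params.d_acc, params.d_dec])
    return x_new


def step_twostate(x: np.ndarray, e: float, b: np.ndarray, break_after: bool,
                  params: TwoStateParams) -> np.ndarray:
    if not (np.all(np.isfinite(x)) and np.isfinite(e)):
        raise SaccadeAdaptError("non-finite state or error")
    a = np.array([params.a_s, params.a_f])
    x_new = a * x + b * e
    if break_after:
        x_new = x_new * np.array([params.d_s, params.d_f])
    return x_new


@dataclass
class SensitivityTracker:
    """Running error-sensitivity state: exposure count and last error sign.

    On each perturbation trial the exposure count k increments; when the
    perturbation sign differs from the last experienced sign, k resets
    before incrementing.  Clamp and zero-perturbation trials leave k
    untouched.  The sensitivity vector in effect on trial n reflects k
    including trial n itself.
    """

    count: int = 0
    last_sign: int = 0

    def update(self, trial: TrialSpec) -> int:
        if trial.r != 0.0 and not trial.clamp:
            sign = 1 if trial.r > 0 else -1
            if self.last_sign != 0 and sign != self.last_sign:
                self.count = 0
            self.count += 1
            self.last_sign = sign
        return self.count


def update_sensitivity(b0: np.ndarray, trial: TrialSpec,
                       history: SensitivityTracker, params) -> np.ndarray:
    """Error sensitivity in effect on this trial, given exposure history."""
    k = history.update(trial)
    return _sensitivity_at(b0, k, params)


def _sensitivity_at(b0: np.ndarray, k: int, params) -> np.ndarray:
    if isinstance(params, Model1Params):
        return b0 + k * np.array([params.beta_slow, params.beta_fast])
    if isinstance(params, Model2Params):
        betas = np.array([
            params.beta,
            params.beta if params.beta_acc is None else params.beta_acc,
            params.beta if params.beta_dec is None else params.beta_dec,
        ])
        return b0 * (1.0 + k * betas)
    return np.asarray(b0, dtype=float)  # two-state: no growth


def _initial_sensitivity(params) -> np.ndarray:
    if isinstance(params, Model1Params):
        return np.array([params.b_slow0, params.b_fast0])
    if isinstance(params, Model2Params):
        return np.array([params.b_aim0, params.b_acc0, params.b_dec0])
    return np.array([params.b_s, params.b_f])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(schedule: ExperimentSchedule, params, model_id: str | None = None,
             ) -> BehaviorTrace:
    """Deterministically forward-simulate a model over a schedule.

    Per trial: observe with the current state, compute the error, update the
    error sensitivity (current trial included), apply the state update, then
    the set-break decay if flagged.  Initial states are zero.
    """
    if len(schedule.trials) == 0:
        raise SaccadeAdaptError("schedule is empty")
    mid = model_id or infer_model_id(params)
    if mid not in MODEL_IDS:
        raise SaccadeAdaptError(f"unknown model_id {mid!r}")
    if not isinstance(params, PARAM_TYPES[mid]):
        raise SaccadeAdaptError(
            f"params of type {type(params).__name__} do not match model {mid!r}"
        )
    arr = schedule.as_arrays()
    yA, yD, e, xs, bs = _simulate_arrays(mid, params, arr)
    return BehaviorTrace(
        model_id=mid, r=arr["r"], clamp=arr["clamp"],
        break_after=arr["break_after"], phase=arr["phase"],
        e=e, yA=yA, yD=yD, x=xs, b=bs,
    )


def _sensitivity_series(model_id: str, params, growth_count: np.ndarray
                        ) -> np.ndarray:
    """Per-trial sensitivity vectors (n x k), vectorized over the schedule."""
    k = growth_count[:, None].astype(float)
    if model_id == "model1":
        b0 = np.array([params.b_slow0, params.b_fast0])
        beta = np.array([params.beta_slow, params.beta_fast])
        return b0 + k * beta
    if model_id == "model2":
        b0 = np.array([params.b_aim0, params.b_acc0, params.b_dec0])
        betas = np.array([
            params.beta,
            params.beta if params.beta_acc is None else params.beta_acc,
            params.beta if params.beta_dec is None else params.beta_dec,
        ])
        return b0 * (1.0 + k * betas)
    b0 = np.array([params.b_s, params.b_f])
    return np.broadcast_to(b0, (len(growth_count), 2)).copy()


def _simulate_arrays(model_id: str, params, arr: dict[str, np.ndarray]):
    """Fast scalar inner loop over precomputed schedule arrays."""
    r = arr["r"]
    clamp = arr["clamp"]
    brk = arr["break_after"]
    n = len(r)
    b_series = _sensitivity_series(model_id, params, arr["growth_count"])

    e = np.empty(n)
    yA = np.empty(n)
    yD = np.empty(n)

    if model_id == "model2":
        xs = np.empty((n, 3))
        a0, a1, a2 = params.a_aim, params.a_acc, params.a_dec
        d0, d1, d2 = params.d_aim, params.d_acc, params.d_dec
        p = params.p
        q = 1.0 - p
        x0 = x1 = x2 = 0.0
        b = b_series
        for i in range(n):
            xs[i, 0] = x0
            xs[i, 1] = x1
            xs[i, 2] = x2
            ya = p * x0 + x1
            yd = q * x0 + x2
            yA[i] = ya
            yD[i] = yd
            ei = 0.0 if clamp[i] else r[i] - (ya + yd)
            e[i] = ei
            x0 = a0 * x0 + b[i, 0] * ei
            x1 = a1 * x1 + b[i, 1] * ei
            x2 = a2 * x2 + b[i, 2] * ei
            if brk[i]:
                x0 *= d0
                x1 *= d1
                x2 *= d2
        return yA, yD, e, xs, b_series

    # two-state-style models (2 components)
    xs = np.empty((n, 2))
    if model_id == "model1":
        a0, a1 = params.a_slow, params.a_fast
        d0, d1 = params.d_slow, params.d_fast
        p = params.p
    else:
        a0, a1 = params.a_s, params.a_f
        d0, d1 = params.d_s, params.d_f
        p = 0.5  # scalar model: split evenly so y = yA + yD still holds
    q = 1.0 - p
    x0 = x1 = 0.0
    b = b_series
    for i in range(n):
        xs[i, 0] = x0
        xs[i, 1] = x1
        total = x0 + x1
        yA[i] = p * total
        yD[i] = q * total
        ei = 0.0 if clamp[i] else r[i] - total
        e[i] = ei
        x0 = a0 * x0 + b[i, 0] * ei
        x1 = a1 * x1 + b[i, 1] * ei
        if brk[i]:
            x0 *= d0
            x1 *= d1
    return yA, yD, e, xs, b_series


def simulate_reference(schedule: ExperimentSchedule, params,
                       model_id: str | None = None) -> BehaviorTrace:
    """Naive per-trial reference simulation built from the elementary ops.

    Independent of the vectorized bookkeeping in :func:`simulate`; used as
    the oracle in equivalence tests.
    """
    mid = model_id or infer_model_id(params)
    n = len(schedule.trials)
    dim = 3 if mid == "model2" else 2
    x = np.zeros(dim)
    b0 = _initial_sensitivity(params)
    tracker = SensitivityTracker()
    e = np.empty(n)
    yA = np.empty(n)
    yD = np.empty(n)
    xs = np.empty((n, dim))
    bs = np.empty((n, dim))
    observe = {
        "model1": lambda x: observe_model1(x, params.p),
        "model2": lambda x: observe_model2(x, params.p),
        "twostate": lambda x: ((x[0] + x[1]) / 2.0, (x[0] + x[1]) / 2.0),
    }[mid]
    step = {"model1": step_model1, "model2": step_model2,
            "twostate": step_twostate}[mid]
    for i, trial in enumerate(schedule.trials):
        xs[i] = x
        ya, yd = observe(x)
        yA[i], yD[i] = ya, yd
        e[i] = error_for_trial(trial, ya + yd)
        b = update_sensitivity(b0, trial, tracker, params)
        bs[i] = b
        x = step(x, e[i], b, trial.break_after, params)
    arr = schedule.as_arrays()
    return BehaviorTrace(
        model_id=mid, r=arr["r"], clamp=arr["clamp"],
        break_after=arr["break_after"], phase=arr["phase"],
        e=e, yA=yA, yD=yD, x=xs, b=bs,
    )


def steady_state(params, r: float, model_id: str | None = None) -> np.ndarray:
    """Closed-form fixed point under constant perturbation r (no breaks, no growth).

    Solves x* = A x* + b (r - 1^T x*), i.e. (I - A + b 1^T) x* = b r.
    """
    mid = model_id or infer_model_id(params)
    b = _initial_sensitivity(params)
    if mid == "model1":
        a = np.array([params.a_slow, params.a_fast])
    elif mid == "model2":
        a = np.array([params.a_aim, params.a_acc, params.a_dec])
    else:
        a = np.array([params.a_s, params.a_f])
    k = len(b)
    M = np.diag(1.0 - a) + np.outer(b, np.ones(k))
    return np.linalg.solve(M, b * r)
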