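"""Synthetic participants: noisy per-trial behavioral tables.

Each participant is a noiseless model simulation of a schedule plus iid
Gaussian observation noise on the acceleration- and deceleration-period
displacement channels (default SD 0.25 deg per channel, a typical saccade
endpoint scatter).  Cohorts draw heterogeneous parameter sets around a
center by jittering in a transformed space (logit for retention/fraction
parameters, log for sensitivities), which keeps every draw inside the
model's constraint set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .errors import SaccadeAdaptError
from .schedules import ExperimentSchedule
from .statespace import (
    Model1Params, Model2Params, TwoStateParams, infer_model_id, simulate,
)

# parameter-name -> transform class, per model
_LOGIT = "logit"   # (0,1)-bounded rates and fractions
_LOG = "log"       # positive sensitivities / growth rates
_TRANSFORMS = {
    "model1": {
        "a_slow": _LOGIT, "a_fast": _LOGIT, "d_slow": _LOGIT, "d_fast": _LOGIT,
        "p": _LOGIT, "b_slow0": _LOG, "b_fast0": _LOG,
        "beta_slow": _LOG, "beta_fast": _LOG,
    },
    "model2": {
        "a_aim": _LOGIT, "a_acc": _LOGIT, "a_dec": _LOGIT, "d_dec": _LOGIT,
        "p": _LOGIT, "b_aim0": _LOG, "b_acc0": _LOG, "b_dec0": _LOG,
        "beta": _LOG,
    },
    "twostate": {
        "a_s": _LOGIT, "a_f": _LOGIT, "d_s": _LOGIT, "d_f": _LOGIT,
        "b_s": _LOG, "b_f": _LOG,
    },
}


@dataclass
class NoiseModel:
    """Additive iid Gaussian observation noise per displacement channel."""

    sigma_yA: float = 0.25
    sigma_yD: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_yA < 0 or self.sigma_yD < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class ParticipantRecord:
    """One synthetic participant: observed series plus generating truth."""

    participant_id: str
    model_id: str
    true_params: object
    schedule_id: str
    yA_obs: np.ndarray
    yD_obs: np.ndarray
    seed: int

    @property
    def y_obs(self) -> np.ndarray:
        return self.yA_obs + self.yD_obs

    def to_frame(self, schedule: ExperimentSchedule):
        import pandas as pd

        arr = schedule.as_arrays()
        return pd.DataFrame({
            "trial": np.arange(len(schedule)),
            "phase": arr["phase"],
            "r": arr["r"],
            "clamp": arr["clamp"].astype(int),
            "break_after": arr["break_after"].astype(int),
            "yA_obs": self.yA_obs,
            "yD_obs": self.yD_obs,
        })

    def manifest_entry(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "model_id": self.model_id,
            "schedule_id": self.schedule_id,
            "true_params": self.true_params.as_dict(),
            "seed": self.seed,
        }


def _logit(v: float) -> float:
    v = min(max(v, 1e-12), 1 - 1e-12)
    return float(np.log(v / (1 - v)))


def _expit(z: float) -> float:
    return float(1.0 / (1.0 + np.exp(-z)))


def sample_params(center, jitter: float, seed: int | None = None,
                  max_attempts: int = 1000):
    """Draw a constraint-satisfying parameter set around ``center``.

    ``jitter`` is the SD of a Gaussian perturbation applied on the
    transformed scale (logit for bounded parameters, log for positive
    ones); jitter = 0 returns the center exactly.  Draws violating the
    model's ordering constraints are rejected and redrawn.
    """
    model_id = infer_model_id(center)
    transforms = _TRANSFORMS[model_id]
    rng = np.random.default_rng(seed)
    if jitter == 0.0:
        return replace(center)
    for _ in range(max_attempts):
        kwargs = {}
        for name, kind in transforms.items():
            v = getattr(center, name)
            z = rng.normal(0.0, jitter)
            if kind == _LOG:
                kwargs[name] = v * float(np.exp(z)) if v > 0 else 0.0
            else:
                kwargs[name] = _expit(_logit(v) + z)
        candidate = replace(center, **kwargs)
        try:
            candidate.validate()
        except ValueError:
            continue
        return candidate
    raise SaccadeAdaptError(
        f"could not draw constraint-satisfying parameters in {max_attempts} attempts"
    )


def generate_participant(params, schedule: ExperimentSchedule,
                         noise: NoiseModel,
                         participant_id: str = "p000",
                         model_id: str | None = None) -> ParticipantRecord:
    """Noiseless simulation plus per-channel Gaussian observation noise."""
    mid = model_id or infer_model_id(params)
    trace = simulate(schedule, params, mid)
    rng = np.random.default_rng(noise.seed)
    n = len(trace)
    yA = trace.yA + rng.normal(0.0, noise.sigma_yA, n) if noise.sigma_yA else trace.yA.copy()
    yD = trace.yD + rng.normal(0.0, noise.sigma_yD, n) if noise.sigma_yD else trace.yD.copy()
    return ParticipantRecord(
        participant_id=participant_id, model_id=mid, true_params=params,
        schedule_id=schedule.experiment_id, yA_obs=yA, yD_obs=yD,
        seed=noise.seed,
    )


def generate_cohort(n: int, model_mix: dict[str, float], centers: dict[str, object],
                    schedule: ExperimentSchedule, noise: NoiseModel,
                    jitter: float = 0.1, seed: int = 0
                    ) -> list[ParticipantRecord]:
    """Reproducible cohort with largest-remainder allocation across models.

    ``model_mix`` maps model_id -> fraction (must sum to 1); ``centers``
    maps model_id -> center parameter set.  Per-participant seeds derive
    from the master seed via a spawned SeedSequence, so the cohort is fully
    determined by ``seed``.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    total = sum(model_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"model_mix fractions must sum to 1, got {total}")
    # largest-remainder apportionment
    items = sorted(model_mix.items())
    quotas = [(mid, n * frac) for mid, frac in items]
    counts = {mid: int(np.floor(q)) for mid, q in quotas}
    short = n - sum(counts.values())
    for mid, q in sorted(quotas, key=lambda kv: kv[1] - np.floor(kv[1]),
                         reverse=True)[:short]:
        counts[mid] += 1

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n)
    cohort: list[ParticipantRecord] = []
    i = 0
    for mid, c in sorted(counts.items()):
        for _ in range(c):
            pseed = int(children[2 * i].generate_state(1)[0] % (2**31))
            nseed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
            params = sample_params(centers[mid], jitter, seed=pseed)
            rec = generate_participant(
                params, schedule, replace(noise, seed=nseed),
                participant_id=f"p{i:03d}", model_id=mid,
            )
            cohort.append(rec)
            i += 1
    return cohort


def export_cohort(cohort: list[ParticipantRecord],
                  schedule: ExperimentSchedule, out_dir) -> None:
    """One CSV per participant plus a manifest JSON recording the truth."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in cohort:
        rec.to_frame(schedule).to_csv(out / f"{rec.participant_id}.csv",
                                      index=False)
        manifest.append(rec.manifest_entry())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
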