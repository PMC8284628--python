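"""Trial schedules for the three cross-axis saccade adaptation experiments.

A schedule is the modeled trial axis: the ordered list of primary-direction
trials, each carrying a perturbation magnitude ``r`` (degrees, signed), an
error-clamp flag, and a set-break flag.  Filler trials along other directions
carry no adaptation-relevant error and are not represented.

Experiment 1 alternates long perturbation periods with error-clamp periods
and inserts a 30 s set break in the middle of each period.  Experiment 2 is
a single long adaptation block (+5 deg), a short extinction block (-5 deg),
one final set break, and an error-clamp block in which spontaneous recovery
is measured.  Experiment 3 randomly interleaves isolated +/-5 deg target
jumps among no-jump control trials.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ScheduleError

PHASES = ("baseline", "perturbation", "extinction", "clamp", "control_pair")


@dataclass
class TrialSpec:
    """One modeled trial.

    index is the 0-based position on the modeled trial axis; r is the
    perturbation magnitude in degrees (0 for baseline/clamp/control);
    clamp=True forces the visual error to zero; break_after=True means a
    30 s set break follows this trial.
    """

    index: int
    phase: str
    r: float
    clamp: bool
    break_after: bool

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ScheduleError(f"unknown phase {self.phase!r}")


@dataclass
class ExperimentSchedule:
    """Ordered trial specifications for one experiment."""

    experiment_id: str
    trials: list[TrialSpec]
    notes: str = ""

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials):
            if t.index != i:
                raise ScheduleError(
                    f"trial indices must be 0..n-1 and contiguous; "
                    f"found index {t.index} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_breaks(self) -> int:
        return sum(t.break_after for t in self.trials)

    # -- array views used by the simulator and the fitter -----------------

    def as_arrays(self) -> dict[str, np.ndarray]:
        """Columnar view: r, clamp, break_after, phase, plus derived masks.

        ``fit_mask`` marks trials entering the least-squares objective
        (everything after the baseline block).  ``growth_count`` is the
        number of perturbation trials experienced since the last
        perturbation sign switch, counting the current trial; error
        sensitivity grows with this count and resets when the perturbation
        reverses direction.
        """
        n = len(self.trials)
        r = np.array([t.r for t in self.trials], dtype=float)
        clamp = np.array([t.clamp for t in self.trials], dtype=bool)
        brk = np.array([t.break_after for t in self.trials], dtype=bool)
        phase = np.array([t.phase for t in self.trials], dtype=object)
        fit_mask = phase != "baseline"
        is_pert = (r != 0.0) & ~clamp

        growth = np.zeros(n, dtype=np.int64)
        k = 0
        last_sign = 0
        for i in range(n):
            if is_pert[i]:
                sign = 1 if r[i] > 0 else -1
                if last_sign != 0 and sign != last_sign:
                    k = 0
                k += 1
                last_sign = sign
            growth[i] = k
        return {
            "r": r,
            "clamp": clamp,
            "break_after": brk,
            "phase": phase,
            "fit_mask": fit_mask,
            "is_perturbation": is_pert,
            "growth_count": growth,
        }

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "experiment_id": self.experiment_id,
            "trials": [asdict(t) for t in self.trials],
            "notes": self.notes,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentSchedule":
        payload = json.loads(text)
        trials = [TrialSpec(**t) for t in payload["trials"]]
        return cls(payload["experiment_id"], trials, payload.get("notes", ""))

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["index", "phase", "r", "clamp", "break_after"])
        for t in self.trials:
            w.writerow([t.index, t.phase, repr(t.r), int(t.clamp), int(t.break_after)])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, experiment_id: str = "custom") -> "ExperimentSchedule":
        rows = list(csv.DictReader(io.StringIO(text)))
        trials = [
            TrialSpec(
                index=int(row["index"]),
                phase=row["phase"],
                r=float(row["r"]),
                clamp=bool(int(row["clamp"])),
                break_after=bool(int(row["break_after"])),
            )
            for row in rows
        ]
        return cls(experiment_id, trials)


# ---------------------------------------------------------------------------
# Experiment 1
# ---------------------------------------------------------------------------


@dataclass
class Exp1Config:
    """Layout of the alternating adaptation / error-clamp experiment.

    Default reconstruction: 80 baseline trials, a 120-trial first
    perturbation period, twelve 80-trial periods alternating clamp and
    perturbation, and a 120-trial final clamp period; one set break in the
    middle of every period, so that adaptation<->clamp transitions never
    coincide with a break.
    """

    n_baseline: int = 80
    first_adaptation: int = 120
    final_clamp: int = 120
    period_length: int = 80
    n_adaptation_periods: int = 7
    n_clamp_periods: int = 7
    perturbation: float = 5.0
    break_mid_period: bool = True
    expected_total: int | None = 1280  # modeled (primary-direction) trials


def _period_trials(phase: str, length: int, r: float, clamp: bool,
                   mid_break: bool) -> list[tuple[str, float, bool, bool]]:
    rows = []
    break_at = length // 2 - 1 if (mid_break and length >= 2) else -1
    for j in range(length):
        rows.append((phase, r, clamp, j == break_at))
    return rows


def build_exp1_schedule(config: Exp1Config | None = None) -> ExperimentSchedule:
    """Build the alternating perturbation/error-clamp schedule."""
    cfg = config or Exp1Config()
    if cfg.n_adaptation_periods < 1:
        raise ScheduleError("need at least one adaptation period")
    if cfg.n_clamp_periods not in (0, cfg.n_adaptation_periods):
        raise ScheduleError(
            "n_clamp_periods must be 0 or equal n_adaptation_periods; got "
            f"{cfg.n_clamp_periods} vs {cfg.n_adaptation_periods}"
        )

    adapt_lengths = [cfg.first_adaptation] + [cfg.period_length] * (
        cfg.n_adaptation_periods - 1
    )
    if cfg.n_clamp_periods:
        clamp_lengths = [cfg.period_length] * (cfg.n_clamp_periods - 1) + [
            cfg.final_clamp
        ]
    else:
        clamp_lengths = []

    rows: list[tuple[str, float, bool, bool]] = []
    rows += [("baseline", 0.0, False, False)] * cfg.n_baseline
    for i, la in enumerate(adapt_lengths):
        rows += _period_trials("perturbation", la, cfg.perturbation, False,
                               cfg.break_mid_period)
        if i < len(clamp_lengths):
            rows += _period_trials("clamp", clamp_lengths[i], 0.0, True,
                                   cfg.break_mid_period)

    if cfg.expected_total is not None and len(rows) != cfg.expected_total:
        raise ScheduleError(
            f"schedule has {len(rows)} modeled trials; config requires "
            f"{cfg.expected_total}"
        )
    trials = [
        TrialSpec(i, ph, r, cl, br) for i, (ph, r, cl, br) in enumerate(rows)
    ]
    return ExperimentSchedule(
        "exp1", trials,
        notes="alternating adaptation/error-clamp with mid-period set breaks",
    )


# ---------------------------------------------------------------------------
# Experiment 2
# ---------------------------------------------------------------------------


@dataclass
class Exp2Config:
    """Adaptation -> extinction -> error-clamp (spontaneous recovery) layout.

    The one documented set break falls immediately before the error-clamp
    block; additional breaks inside the adaptation block can be supplied as
    0-based offsets into that block via ``adaptation_breaks``.
    """

    n_baseline: int = 80
    n_adaptation: int = 420
    n_extinction: int = 40
    n_clamp: int = 100
    perturbation: float = 5.0
    adaptation_breaks: tuple[int, ...] = ()


def build_exp2_schedule(config: Exp2Config | None = None) -> ExperimentSchedule:
    """Build the spontaneous-recovery schedule."""
    cfg = config or Exp2Config()
    for name in ("n_adaptation", "n_extinction", "n_clamp"):
        if getattr(cfg, name) < 1:
            raise ScheduleError(f"{name} must be >= 1")
    for off in cfg.adaptation_breaks:
        if not 0 <= off < cfg.n_adaptation:
            raise ScheduleError(
                f"adaptation break offset {off} outside block of "
                f"{cfg.n_adaptation} trials"
            )
    rows: list[tuple[str, float, bool, bool]] = []
    rows += [("baseline", 0.0, False, False)] * cfg.n_baseline
    for j in range(cfg.n_adaptation):
        rows.append(("perturbation", cfg.perturbation, False,
                     j in cfg.adaptation_breaks))
    for j in range(cfg.n_extinction):
        # final set break immediately precedes the error-clamp block
        rows.append(("extinction", -cfg.perturbation, False,
                     j == cfg.n_extinction - 1))
    rows += [("clamp", 0.0, True, False)] * cfg.n_clamp
    trials = [
        TrialSpec(i, ph, r, cl, br) for i, (ph, r, cl, br) in enumerate(rows)
    ]
    return ExperimentSchedule(
        "exp2", trials,
        notes="adaptation, extinction, set break, error clamp",
    )


# ---------------------------------------------------------------------------
# Experiment 3
# ---------------------------------------------------------------------------


@dataclass
class Exp3Config:
    """Randomly interleaved single-error trials among controls."""

    n_baseline: int = 64
    n_positive: int = 156
    n_negative: int = 156
    n_control: int = 624
    magnitude: float = 5.0


def build_exp3_schedule(config: Exp3Config | None = None,
                        seed: int = 0) -> ExperimentSchedule:
    """Build the single-error schedule.

    Each perturbation trial is inserted into a distinct gap between two
    consecutive control trials, which guarantees that every perturbation is
    preceded and followed by at least one control trial.
    """
    cfg = config or Exp3Config()
    n_pert = cfg.n_positive + cfg.n_negative
    n_gaps = cfg.n_control - 1
    if n_gaps < n_pert:
        raise ScheduleError(
            f"cannot isolate {n_pert} perturbation trials among "
            f"{cfg.n_control} control trials ({n_gaps} gaps available)"
        )
    rng = np.random.default_rng(seed)
    gaps = rng.choice(n_gaps, size=n_pert, replace=False)
    signs = np.concatenate(
        [np.full(cfg.n_positive, 1.0), np.full(cfg.n_negative, -1.0)]
    )
    rng.shuffle(signs)
    gap_sign = dict(zip(sorted(gaps.tolist()), signs))

    rows: list[tuple[str, float, bool, bool]] = []
    rows += [("baseline", 0.0, False, False)] * cfg.n_baseline
    for c in range(cfg.n_control):
        rows.append(("control_pair", 0.0, False, False))
        if c in gap_sign:
            rows.append(
                ("perturbation", cfg.magnitude * gap_sign[c], False, False)
            )
    trials = [
        TrialSpec(i, ph, r, cl, br) for i, (ph, r, cl, br) in enumerate(rows)
    ]
    return ExperimentSchedule(
        "exp3", trials,
        notes=f"isolated random +/-{cfg.magnitude} deg jumps, seed={seed}",
    )
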