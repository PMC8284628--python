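"""End-to-end reproduction pipeline and file validation.

``run_pipeline`` wires the modules together: build schedules, simulate the
reference parameter sets, generate a small synthetic cohort, fit the
models, and compute the behavioral statistics, writing everything as plain
CSV/JSON with a manifest (config echo, seeds, checksums).  Re-running with
the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import NoiseModel, export_cohort, generate_cohort
from .errors import ValidationError
from .fitting import FitConfig, fit
from .reference_params import REFERENCE_MODEL1, REFERENCE_MODEL2
from .schedules import (
    ExperimentSchedule, build_exp1_schedule, build_exp2_schedule,
    build_exp3_schedule,
)
from .statespace import simulate
from .stats import (
    learning_rate, recovery_windows_for_exp2, set_break_decay,
    spontaneous_recovery,
)

log = logging.getLogger("saccade_adapt")


@dataclass
class RunConfig:
    """Master configuration; every stochastic stage derives from one seed."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    cohort_size: int = 6
    noise_sigma: float = 0.25
    jitter: float = 0.1
    n_restarts: int = 10
    fit_cohort: bool = False


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full demo pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("")
    probe.unlink()

    log.info("stage=schedule seed=%d", config.seed)
    exp1 = build_exp1_schedule()
    exp2 = build_exp2_schedule()
    exp3 = build_exp3_schedule(seed=config.seed)
    for s in (exp1, exp2, exp3):
        (out / f"schedule_{s.experiment_id}.json").write_text(s.to_json())

    log.info("stage=simulate")
    for mid, params in (("model1", REFERENCE_MODEL1),
                        ("model2", REFERENCE_MODEL2)):
        for s in (exp1, exp2):
            trace = simulate(s, params, mid)
            trace.to_frame().to_csv(
                out / f"trace_{mid}_{s.experiment_id}.csv", index=False,
                float_format="%.10g",
            )

    log.info("stage=cohort n=%d sigma=%.3g", config.cohort_size,
             config.noise_sigma)
    noise = NoiseModel(config.noise_sigma, config.noise_sigma, seed=config.seed)
    cohort = generate_cohort(
        config.cohort_size, {"model2": 1.0}, {"model2": REFERENCE_MODEL2},
        exp2, noise, jitter=config.jitter, seed=config.seed,
    )
    export_cohort(cohort, exp2, out / "cohort")

    if config.fit_cohort:
        log.info("stage=fit restarts=%d", config.n_restarts)
        cfg = FitConfig(n_restarts=config.n_restarts, seed=config.seed)
        fits = []
        for rec in cohort:
            res = fit((rec.yA_obs, rec.yD_obs), "model2", exp2, cfg)
            fits.append({"participant_id": rec.participant_id,
                         **res.to_dict()})
        (out / "fits_model2.json").write_text(json.dumps(fits, indent=1))

    log.info("stage=stats")
    trace2 = simulate(exp2, REFERENCE_MODEL2, "model2")
    windows = recovery_windows_for_exp2(exp2)
    trace1 = simulate(exp1, REFERENCE_MODEL1, "model1")
    arr1 = exp1.as_arrays()
    breaks = np.flatnonzero(arr1["break_after"])
    pert_breaks = [b for b in breaks if arr1["phase"][b] == "perturbation"]
    report = {
        "spontaneous_recovery_total": spontaneous_recovery(
            trace2.y, windows),
        "exp1_first_block_rate_total": learning_rate(trace1.y, (80, 200)),
        "exp1_perturbation_break_decay_pct": set_break_decay(
            trace1.y, pert_breaks).mean_change,
    }
    (out / "stats_report.json").write_text(json.dumps(report, indent=1))

    files = sorted(p for p in out.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "checksums": {str(p.relative_to(out)): _checksum(p) for p in files},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# File validation
# ---------------------------------------------------------------------------

_BEHAVIOR_COLUMNS = ("trial", "phase", "r", "clamp", "break_after",
                     "yA_obs", "yD_obs")


def validate_files(paths) -> list[str]:
    """Schema-validate schedule (.json) and behavior (.csv) files.

    Returns a list of human-readable problem messages (empty = valid).
    """
    import csv as _csv

    problems: list[str] = []
    for p in map(Path, paths):
        if not p.exists():
            problems.append(f"{p}: file not found")
            continue
        if p.suffix == ".json":
            try:
                ExperimentSchedule.from_json(p.read_text())
            except Exception as exc:
                problems.append(f"{p}: invalid schedule ({exc})")
        elif p.suffix == ".csv":
            with open(p, newline="") as fh:
                reader = _csv.DictReader(fh)
                cols = reader.fieldnames or []
                missing = [c for c in _BEHAVIOR_COLUMNS if c not in cols]
                if missing:
                    problems.append(
                        f"{p}: missing column(s) {', '.join(missing)}")
                    continue
                last = -1
                for i, row in enumerate(reader, start=2):
                    try:
                        trial = int(row["trial"])
                        float(row["yA_obs"])
                        float(row["yD_obs"])
                    except (TypeError, ValueError):
                        problems.append(f"{p}: line {i}: malformed row")
                        continue
                    if trial <= last:
                        problems.append(
                            f"{p}: line {i}: non-monotone trial index "
                            f"({trial} after {last})")
                    last = trial
        else:
            problems.append(f"{p}: unknown file type {p.suffix!r}")
    return problems
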