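"""Pipeline orchestration: solve -> predict -> simulate -> lip, with
machine-readable artifacts and a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import psychometric_chronometric
from .config import RunConfig
from .lip_model import buildup_rates, urgency_signal
from .policy import PolicySolution, solve
from .simulate import simulate_experiment

__all__ = ["STAGES", "run_pipeline", "PipelineError"]

log = logging.getLogger("dotpomdp")

STAGES = ("solve", "predict", "simulate", "lip")


class PipelineError(RuntimeError):
    """Raised for stage-ordering problems (e.g. predict without a policy)."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_policy(sol: PolicySolution, path: Path) -> None:
    path.write_text(json.dumps(sol.to_dict(include_tables=True)))


def _write_boundaries(sol: PolicySolution, path: Path) -> None:
    t = np.arange(sol.horizon + 1)
    pd.DataFrame(
        {"t": t, "theta_R": sol.theta_right, "theta_L": sol.theta_left}
    ).to_csv(path, index=False)


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested stages in order and write their artifacts.

    Artifacts: policy.json + boundaries.csv (solve), curves.csv (predict),
    trials.csv + trial summary (simulate), lip.csv (lip), and manifest.json
    recording the config hash, seeds, package version and output checksums.
    Later stages require the solve stage in the same invocation or a
    previously written policy.json in ``outdir``.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    sol: PolicySolution | None = None
    policy_path = outdir / "policy.json"

    def ensure_policy(stage: str) -> PolicySolution:
        nonlocal sol
        if sol is None:
            if not policy_path.exists():
                raise PipelineError(
                    f"stage '{stage}' needs a solved policy; run the solve "
                    f"stage first (no {policy_path})"
                )
            sol = PolicySolution.from_dict(json.loads(policy_path.read_text()))
        return sol

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "solve":
            sol = solve(
                cfg.reward_params(),
                prior=cfg.prior_params(),
                n=cfg.mt.spikes_per_step,
                horizon=cfg.horizon,
            )
            _write_policy(sol, policy_path)
            _write_boundaries(sol, outdir / "boundaries.csv")
            outputs["policy.json"] = policy_path
            outputs["boundaries.csv"] = outdir / "boundaries.csv"
        elif stage == "predict":
            s = ensure_policy(stage)
            curves = psychometric_chronometric(s, cfg.mt_params(), cfg.coherences)
            curves.to_csv(outdir / "curves.csv", index=False)
            outputs["curves.csv"] = outdir / "curves.csv"
        elif stage == "simulate":
            s = ensure_policy(stage)
            summary, trials = simulate_experiment(
                cfg.coherences,
                cfg.n_trials,
                s,
                cfg.mt_params(),
                cfg.base_seed,
                return_trials=True,
            )
            summary.to_csv(outdir / "simulation_summary.csv", index=False)
            trials.to_csv(outdir / "trials.csv", index=False)
            outputs["simulation_summary.csv"] = outdir / "simulation_summary.csv"
            outputs["trials.csv"] = outdir / "trials.csv"
        elif stage == "lip":
            s = ensure_policy(stage)
            urgency, fit = urgency_signal(s, cfg.lip_params())
            slopes, scaling = buildup_rates(
                s, cfg.mt_params(), cfg.lip_params(), cfg.coherences
            )
            urgency.to_csv(outdir / "lip.csv", index=False)
            slopes.to_csv(outdir / "lip_buildup.csv", index=False)
            (outdir / "lip_fit.json").write_text(
                json.dumps(
                    {
                        "urgency_amplitude": fit.amplitude,
                        "urgency_half_time_steps": fit.half_time,
                        "urgency_fit_ok": fit.ok,
                        "buildup_scaling_per_unit_coherence": scaling,
                    }
                )
            )
            outputs["lip.csv"] = outdir / "lip.csv"
            outputs["lip_buildup.csv"] = outdir / "lip_buildup.csv"
            outputs["lip_fit.json"] = outdir / "lip_fit.json"
        timings[stage] = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", stage, timings[stage])

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.content_hash(),
        "config": json.loads(cfg.model_dump_json()),
        "base_seed": cfg.base_seed,
        "stages": list(stages),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {name: _checksum(p) for name, p in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
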