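"""End-to-end orchestration: simulate -> classify -> contrast -> aggregate.

All randomness flows from one root seed, split per session via
``numpy.random.SeedSequence``, so a rerun with the same configuration
produces byte-identical artifacts; the manifest records a SHA-256 hash of
every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .behavior_sim import paper_preset, preset_task_configs, simulate_session
from .metrics import classify_session, summaries_to_frame, summarize_by_movement
from .session_io import Phase, write_session
from .stats import (
    population_summary,
    session_contrast,
    test_results_to_frame,
)
from .task_engine import TargetLayout

log = logging.getLogger("seqreach")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full simulated-experiment run."""

    seed: int = 0
    preset: str = "anisomycin_session2_N"
    n_sessions: int = 6
    n_trials: int = 2000
    block_length_range: tuple[int, int] = (200, 500)
    alpha: float = 0.05
    chi2_correction: bool = False
    equal_var: bool = False
    outdir: str = "seqreach_run"

    def __post_init__(self) -> None:
        self.block_length_range = tuple(self.block_length_range)  # type: ignore[assignment]
        if self.n_sessions < 1 or self.n_trials < 1:
            raise ValueError("n_sessions and n_trials must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_length_range"] = list(self.block_length_range)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _monkey_for(i: int, n_sessions: int) -> str:
    # the six-injection configuration: four sessions in one subject, two in
    # the other
    return "N" if (i < 4 or n_sessions != 6) else "R"


def run_pipeline(config: RunConfig) -> dict:
    """Simulate ``n_sessions`` pre/post session pairs under the configured
    preset, run the full classification and statistical pipeline, and write
    every artifact plus a hash manifest under ``config.outdir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        agent, effect = paper_preset(config.preset)
        task_configs = preset_task_configs()
        layout = TargetLayout()
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("setup", str(exc)) from exc

    root = np.random.SeedSequence(config.seed)
    session_seeds = root.generate_state(2 * config.n_sessions)

    outputs: list[Path] = []
    effects = []
    summaries_by_session: dict[str, dict[Phase, list]] = {}

    for i in range(config.n_sessions):
        session_id = f"{config.preset}-{i + 1}"
        monkey = _monkey_for(i, config.n_sessions)
        pair_summaries: dict[Phase, list] = {}
        for j, phase in enumerate((Phase.PRE, Phase.POST)):
            seed = int(session_seeds[2 * i + j])
            log.info("simulating %s %s (seed %d)", session_id, phase.value, seed)
            try:
                session_log, truth = simulate_session(
                    task_configs,
                    layout,
                    agent,
                    effect=effect,
                    phase=phase,
                    n_trials=config.n_trials,
                    seed=seed,
                    block_length_range=config.block_length_range,
                    monkey_id=monkey,
                    session_id=session_id,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("simulate", f"{session_id}/{phase.value}: {exc}") from exc

            base = outdir / f"{session_id}.{phase.value.lower()}"
            write_session(session_log, base.with_suffix(".trials.tsv"))
            base.with_suffix(".truth.yaml").write_text(
                yaml.safe_dump(truth.to_dict(), sort_keys=True)
            )
            outputs += [base.with_suffix(".trials.tsv"), base.with_suffix(".truth.yaml")]

            try:
                classified = classify_session(session_log)
                classified.to_csv(base.with_suffix(".classified.tsv"), sep="\t", index=False)
                outputs.append(base.with_suffix(".classified.tsv"))
                pair_summaries[phase] = summarize_by_movement(classified)
                summaries_to_frame(pair_summaries[phase]).to_csv(
                    base.with_suffix(".summary.csv"), index=False
                )
                outputs.append(base.with_suffix(".summary.csv"))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("analyze", f"{session_id}/{phase.value}: {exc}") from exc

        try:
            results, eff = session_contrast(
                pair_summaries[Phase.PRE],
                pair_summaries[Phase.POST],
                alpha=config.alpha,
                session_id=session_id,
                chi2_correction=config.chi2_correction,
                equal_var=config.equal_var,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("contrast", f"{session_id}: {exc}") from exc
        test_results_to_frame(results).to_csv(outdir / f"{session_id}.tests.csv", index=False)
        (outdir / f"{session_id}.effect.json").write_text(
            json.dumps(eff.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        outputs += [outdir / f"{session_id}.tests.csv", outdir / f"{session_id}.effect.json"]
        effects.append(eff)
        summaries_by_session[session_id] = pair_summaries

    try:
        pop = population_summary(effects, summaries_by_session)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("population", str(exc)) from exc
    (outdir / "population.json").write_text(
        json.dumps(pop.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    outputs.append(outdir / "population.json")

    manifest = {
        "config": config.to_dict(),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
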