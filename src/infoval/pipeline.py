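"""Pipeline orchestration: design -> simulate -> fit -> compare -> recover -> export.

A single JSON :class:`RunConfig` drives the stages; every run writes a
manifest listing each artifact alongside the config hash, seed and package
version, so outputs are traceable and deterministic stages reproduce
byte-identically under the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import task_design
from .inference import SamplerConfig, compute_waic, fit_hierarchical, posterior_predictive
from .model_comparison import (
    compare_models,
    export_modulators,
    model_recovery,
    parabolic_family,
    parameter_recovery,
)
from .synthetic_data import (
    ChoiceDataset,
    GroupParameters,
    sample_subjects,
    simulate_dataset,
)
from .value_models import ModelSpec

__all__ = ["RunConfig", "run_pipeline", "TEST_PRESET"]

ALL_STAGES = ("design", "simulate", "fit", "compare", "recover", "export")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (JSON-serialisable)."""

    out_dir: str = "runs/latest"
    seed: int = 0
    stages: tuple = ALL_STAGES
    n_subjects: int = 26
    effort_reps: int = 4
    info_runs: int = 3
    catch_rate: float = 0.05
    generative_spec: dict = field(
        default_factory=lambda: ModelSpec().to_json()
    )
    candidate_specs: list = field(
        default_factory=lambda: [s.to_json() for s in parabolic_family()]
    )
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    recovery_sims: int = 10
    recovery_subjects: int = 8
    group_loc_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        ModelSpec.from_json(self.generative_spec)
        for s in self.candidate_specs:
            ModelSpec.from_json(s)

    @classmethod
    def test_preset(cls, **overrides) -> "RunConfig":
        """Small preset (2 chains x 200 draws, 8 subjects) for smoke runs."""
        base = dict(
            n_subjects=8, chains=2, warmup=200, draws=200,
            recovery_sims=1, recovery_subjects=4,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        obj = json.loads(Path(path).read_text())
        obj["stages"] = tuple(obj.get("stages", ALL_STAGES))
        return cls(**obj)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


TEST_PRESET = RunConfig.test_preset


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    A stage failure raises after writing a diagnostic manifest recording the
    stages completed so far.
    """

    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "config": asdict(config),
        "package_version": __version__,
        "artifacts": [],
        "stages_completed": [],
    }

    log_path = out / "run.log"
    log_lines: list[str] = [f"config_hash={config.hash()} seed={config.seed}"]

    def log(msg: str) -> None:
        log_lines.append(msg)
        log_path.write_text("\n".join(log_lines) + "\n")

    def record(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    gen_spec = ModelSpec.from_json(config.generative_spec)
    candidates = [ModelSpec.from_json(s) for s in config.candidate_specs]
    sampler = SamplerConfig(
        chains=config.chains,
        warmup=config.warmup,
        draws=config.draws,
        seed=config.seed,
    )
    group = GroupParameters.defaults()
    if config.group_loc_overrides:
        group = group.with_loc(**config.group_loc_overrides)

    data: ChoiceDataset | None = None
    try:
        if "design" in config.stages or "simulate" in config.stages:
            effort = task_design.effort_trials_frame(
                task_design.generate_effort_task(config.effort_reps, seed=config.seed)
            )
            info = task_design.info_trials_frame(
                task_design.generate_info_task(
                    runs=config.info_runs,
                    catch_rate=config.catch_rate,
                    seed=config.seed + 1,
                )
            )
            task_design.write_design(effort, out / "design" / "effort.tsv", "effort")
            task_design.write_design(info, out / "design" / "info.tsv", "info")
            record(out / "design" / "effort.tsv")
            record(out / "design" / "info.tsv")
            manifest["stages_completed"].append("design")
            log("design: wrote trial tables")

        if "simulate" in config.stages:
            subjects = sample_subjects(group, config.n_subjects, seed=config.seed + 2)
            data = simulate_dataset(gen_spec, subjects, effort, info, seed=config.seed + 3)
            data.to_dir(out / "dataset")
            for f in sorted((out / "dataset").iterdir()):
                record(f)
            manifest["stages_completed"].append("simulate")
            log(f"simulate: {config.n_subjects} subjects under {gen_spec.label}")

        if "fit" in config.stages:
            if data is None:
                data = ChoiceDataset.from_dir(out / "dataset")
            fit = fit_hierarchical(gen_spec, data, sampler)
            w = compute_waic(fit)
            ppc = posterior_predictive(fit, data, n_rep=100, seed=config.seed + 4)
            summary = {
                "spec": gen_spec.to_json(),
                "waic": w.waic,
                "elpd": w.elpd,
                "p_eff": w.p_eff,
                "converged": fit.converged,
                "max_rhat": fit.diagnostics["max_rhat"],
                "ppc_coverage": ppc["coverage"],
            }
            (out / "fit_summary.json").write_text(json.dumps(summary, indent=2))
            fit.subject_means().to_csv(out / "subject_means.tsv", sep="\t", index=False)
            record(out / "fit_summary.json")
            record(out / "subject_means.tsv")
            manifest["stages_completed"].append("fit")
            log(f"fit: {gen_spec.label} waic={w.waic:.1f} converged={fit.converged}")

            if "export" in config.stages:
                mods = export_modulators(fit, data)
                mods.to_csv(out / "modulators.tsv", sep="\t", index=False)
                record(out / "modulators.tsv")
                manifest["stages_completed"].append("export")

        if "compare" in config.stages:
            if data is None:
                data = ChoiceDataset.from_dir(out / "dataset")
            comp = compare_models(data, candidates, sampler)
            comp.table.to_csv(out / "comparison.tsv", sep="\t", index=False)
            record(out / "comparison.tsv")
            manifest["stages_completed"].append("compare")
            log(f"compare: best={comp.best}")

        if "recover" in config.stages:
            rec = model_recovery(
                candidates,
                n_sims=config.recovery_sims,
                n_subjects=config.recovery_subjects,
                seed=config.seed + 5,
                group=group,
                config=SamplerConfig.test_preset(config.seed + 5),
            )
            rec.confusion.to_csv(out / "model_recovery_confusion.tsv", sep="\t")
            par = parameter_recovery(
                gen_spec,
                n_sims=max(1, config.recovery_sims // 2),
                n_subjects=config.n_subjects,
                seed=config.seed + 6,
                group=group,
                config=SamplerConfig.test_preset(config.seed + 6),
            )
            par.param_correlations.to_csv(out / "parameter_recovery.tsv", sep="\t")
            record(out / "model_recovery_confusion.tsv")
            record(out / "parameter_recovery.tsv")
            manifest["stages_completed"].append("recover")
            log(f"recover: mean accuracy {rec.accuracy.mean():.2f}")
    except Exception as err:  # noqa: BLE001 - diagnostic manifest on any stage failure
        manifest["error"] = f"{type(err).__name__}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
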