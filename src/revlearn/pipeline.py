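"""End-to-end pipeline: simulate a cohort, fit models, run the analyses, report.

A :class:`RunConfig` (loadable from YAML) names the task design, the cohort,
the fitting grid and the analyses to run. :func:`run_pipeline` executes the
enabled stages in order, writes every artefact under ``output_dir`` and
finishes with a manifest recording the seed, configuration hash and a
checksum of every output file, so re-running the same configuration
reproduces all deterministic outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agents import CohortSpec, simulate_cohort
from .exceptions import ConfigError, PipelineError
from .fitting import GridSpec, compare_models, fit_dataset
from .io import write_fits, write_trials
from .models import AgentParams
from .stats import blockwise_contrast, condition_anova, learning_curve, winstay_betas
from .task import TaskConfig

log = logging.getLogger("revlearn")

DEFAULT_ANALYSES = {"winstay": True, "blockwise": True, "learning_curve": True,
                    "model_comparison": True}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; field paths mirror the YAML layout."""

    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    models: tuple[str, ...] = ("RW1", "RW2")
    likelihood_mode: str = "observed"
    fit_granularity: str = "block"
    analyses: dict = field(default_factory=lambda: dict(DEFAULT_ANALYSES))
    output_dir: Path = Path("revlearn_out")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        unknown = set(self.analyses) - set(DEFAULT_ANALYSES)
        if unknown:
            raise ConfigError(f"analyses: unknown toggle(s) {sorted(unknown)}")
        toggles = dict(DEFAULT_ANALYSES)
        toggles.update(self.analyses)
        self.analyses = toggles

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "task" in raw:
            task = dict(raw["task"])
            if "block_lengths" in task:
                task["block_lengths"] = tuple(task["block_lengths"])
            if "pair_rotation" in task:
                task["pair_rotation"] = tuple(tuple(p) for p in task["pair_rotation"])
            kwargs["task"] = TaskConfig(**task)
        if "cohort" in raw:
            cohort = dict(raw["cohort"])
            if "conditions" in cohort:
                cohort["conditions"] = tuple(cohort["conditions"])
            if "base_params" in cohort:
                cohort["base_params"] = AgentParams(**cohort["base_params"])
            kwargs["cohort"] = CohortSpec(**cohort)
        if "grid" in raw:
            grid = dict(raw["grid"])
            for key in ("alpha_range", "beta_range"):
                if key in grid:
                    grid[key] = tuple(grid[key])
            kwargs["grid"] = GridSpec(**grid)
        for key in ("likelihood_mode", "fit_granularity", "analyses",
                    "output_dir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "models" in raw:
            kwargs["models"] = tuple(raw["models"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["cohort"]["condition_effects"] = {
            k: dict(v) for k, v in self.cohort.condition_effects.items()}
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> fit -> analyse -> report and return artefact paths.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    outputs already written, plus the manifest, are left on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}
    results: dict = {"artefacts": artefacts}
    stage = "simulate"
    try:
        log.info("simulating cohort: %d subjects x %s",
                 config.cohort.n_subjects, config.cohort.conditions)
        cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
        trials, truth = simulate_cohort(cohort_spec, config.task)
        write_trials(trials, out / "trials.csv")
        truth.to_csv(out / "truth_params.csv", index=False)
        artefacts["trials"] = out / "trials.csv"
        artefacts["truth_params"] = out / "truth_params.csv"
        results["trials"] = trials

        if any(config.analyses.values()) or config.models:
            stage = "fit"
            if config.analyses.get("model_comparison") and config.models:
                log.info("fitting models %s (%s granularity)",
                         config.models, config.fit_granularity)
                fits = fit_dataset(trials, models=config.models,
                                   granularity=config.fit_granularity,
                                   grid=config.grid,
                                   likelihood_mode=config.likelihood_mode)
                write_fits(fits, out / "fits.csv")
                artefacts["fits"] = out / "fits.csv"
                results["fits"] = fits
                per_model = {m: fits[fits["model"] == m] for m in config.models}
                comparison = compare_models(per_model)
                comparison.table.to_csv(out / "model_comparison.csv", index=False)
                artefacts["model_comparison"] = out / "model_comparison.csv"
                results["model_comparison"] = comparison

        stage = "analyse"
        report_lines = [f"# revlearn report (seed {config.seed})", ""]
        if config.analyses.get("winstay"):
            betas = winstay_betas(trials)
            betas.to_csv(out / "winstay_betas.csv", index=False)
            artefacts["winstay_betas"] = out / "winstay_betas.csv"
            anova = condition_anova(betas, "beta_reward")
            results["winstay_anova"] = anova
            report_lines += [
                "## Win-stay regression (Analysis A)",
                f"Condition ANOVA on beta_reward: F({anova.df_between},{anova.df_within}) "
                f"= {anova.f_stat:.3f}, p = {anova.p_anova:.4f} "
                f"(n = {anova.n_subjects} subjects)",
            ]
            for pr in anova.pairs:
                report_lines.append(
                    f"- {pr.cond_a} vs {pr.cond_b}: t({pr.df}) = {pr.t_stat:.3f}, "
                    f"p_bonf = {pr.p_bonferroni:.4f}, Cohen's D = {pr.cohens_d:.3f}")
            report_lines.append("")
        if config.analyses.get("blockwise") and len(config.cohort.conditions) >= 2:
            if (out / "winstay_betas.csv").exists():
                betas = pd.read_csv(out / "winstay_betas.csv")
            else:
                betas = winstay_betas(trials)
            ref = config.cohort.conditions[-1]
            report_lines.append("## Block-wise contrasts (Analysis B)")
            for cond in config.cohort.conditions[:-1]:
                bw = blockwise_contrast(betas, cond, ref)
                bw.to_csv(out / f"blockwise_{cond}_vs_{ref}.csv", index=False)
                artefacts[f"blockwise_{cond}_vs_{ref}"] = out / f"blockwise_{cond}_vs_{ref}.csv"
                flagged = bw.loc[bw["significant"], "block"].tolist()
                report_lines.append(f"- {cond} vs {ref}: significant blocks {flagged or 'none'}")
            report_lines.append("")
        if config.analyses.get("learning_curve"):
            curve = learning_curve(trials, reversal_period=config.task.reversal_period)
            curve.to_csv(out / "learning_curve.csv", index=False)
            artefacts["learning_curve"] = out / "learning_curve.csv"
            results["learning_curve"] = curve
            report_lines += [
                "## Learning curve (Analysis C)",
                f"Smoothed high-probability choice rate: start "
                f"{curve['smoothed'].iloc[0]:.3f}, end {curve['smoothed'].iloc[-1]:.3f}",
                "",
            ]
        if "model_comparison" in results:
            comparison = results["model_comparison"]
            report_lines += ["## Model comparison (summed BIC)"]
            for _, row in comparison.table.iterrows():
                report_lines.append(f"- {row['model']}: {row['total_bic']:.2f}")
            report_lines.append(
                f"Winner: {comparison.winner or 'tie'}")
            report_lines.append("")

        stage = "report"
        (out / "report.md").write_text("\n".join(report_lines))
        artefacts["report"] = out / "report.md"
    except Exception as exc:  # persist the manifest, then surface the stage
        _write_manifest(config, artefacts, out, error=f"{stage}: {exc}")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    _write_manifest(config, artefacts, out)
    results["manifest"] = out / "manifest.json"
    return results


def _write_manifest(config: RunConfig, artefacts: dict, out: Path,
                    error: str | None = None) -> None:
    config_blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config_blob),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "outputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in artefacts.items() if Path(p).exists()},
    }
    if error:
        manifest["error"] = error
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
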