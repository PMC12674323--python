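"""Experiment orchestration and Table-style aggregation.

One scenario iteration composes the whole pipeline: simulate the
ground-truth cohort, sequence it, normalize four ways, detect responders
per data representation, score FP/FN against the truth, and (optionally)
partition community variance by treatment with PERMANOVA. Experiments
sweep the 5 x 6 effect-size / response-proportion grid for a direction
regime, with deterministic per-iteration seeds so any single iteration is
independently reproducible and results merge identically regardless of
execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, dda, io, normalization, sequencing, variance
from .community import BIDIRECTIONAL, POST, TREATMENT, UNIDIRECTIONAL, ScenarioSpec
from .config import SimulationConfig
from .normalization import ABSOLUTE, CLR, DESEQ, METHODS, RELATIVE, TMM

EXPERIMENT_DIRECTIONS = {1: UNIDIRECTIONAL, 2: BIDIRECTIONAL}

#: Which distance metrics summarize each data representation: the
#: compositionality-robust pair for CLR is (correlation of CLR values,
#: Aitchison); every other representation gets log-Pearson + Bray–Curtis.
METRICS_BY_METHOD = {
    ABSOLUTE: (variance.LOG_PEARSON, variance.BRAY_CURTIS),
    RELATIVE: (variance.LOG_PEARSON, variance.BRAY_CURTIS),
    TMM: (variance.LOG_PEARSON, variance.BRAY_CURTIS),
    DESEQ: (variance.LOG_PEARSON, variance.BRAY_CURTIS),
    CLR: (variance.LOG_PEARSON, variance.AITCHISON),
}


def _normalize_all(
    abund: pd.DataFrame,
    counts: pd.DataFrame | None,
    config: SimulationConfig,
) -> dict[str, normalization.NormalizedMatrix]:
    reps: dict[str, normalization.NormalizedMatrix] = {}
    for method in config.methods:
        if method == ABSOLUTE:
            reps[method] = normalization.as_absolute(abund)
            continue
        assert counts is not None
        if method == RELATIVE:
            reps[method] = normalization.relative_abundance(counts)
        elif method == CLR:
            reps[method] = normalization.clr_transform(counts, config.pseudocount)
        elif method == TMM:
            reps[method] = normalization.tmm_normalize(counts)
        elif method == DESEQ:
            reps[method] = normalization.deseq_normalize(counts)
        else:
            raise ValueError(f"unknown method: {method!r}")
    return reps


def _distance(
    norm: normalization.NormalizedMatrix, metric: str, post_cols: list[str]
) -> pd.DataFrame:
    sub = norm.values[post_cols]
    if metric == variance.LOG_PEARSON:
        if norm.method == CLR:
            return variance.log_pearson_distance(sub, already_log=True)
        eps = 0.0
        arr = sub.to_numpy()
        if (arr <= 0).any():
            eps = 0.5 * arr[arr > 0].min()
        return variance.log_pearson_distance(sub, pseudocount=eps)
    if metric == variance.BRAY_CURTIS:
        return variance.bray_curtis_distance(sub)
    if metric == variance.AITCHISON:
        # CLR values are already centered logs; Aitchison = their Euclidean
        return variance.euclidean_distance(sub)
    raise ValueError(f"unknown metric: {metric!r}")


def run_scenario(
    spec: ScenarioSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One full simulate -> sequence -> normalize -> test -> score pass.

    Returns ``(errors, permanova)``: per-method confusion counts and
    rates, and per-method-and-metric R² rows (empty when PERMANOVA is
    disabled in the config).
    """
    design = config.design()
    abund, truth, design = community.simulate_cohort_study(
        spec,
        rng,
        n_taxa=config.n_taxa,
        log_mean=config.log_mean,
        log_sd=config.log_sd,
        subject_log_sd=config.subject_log_sd,
        noise_fraction=config.noise_fraction,
        design=design,
        log_symmetric_noise=config.log_symmetric_noise,
    )
    needs_counts = config.run_permanova or any(m != ABSOLUTE for m in config.methods)
    counts = (
        sequencing.simulate_sequencing(abund, config.depth_mean, config.depth_sd, rng)
        if needs_counts
        else None
    )
    reps = _normalize_all(abund, counts, config)

    error_rows = []
    for method, norm in reps.items():
        result = dda.detect_responders(
            norm,
            design,
            alpha=config.alpha,
            mode=config.response_mode,
            change_scale=config.change_scale,
        )
        rates = dda.error_rates(
            result["flagged"].to_numpy(), truth, convention=config.rate_convention
        )
        error_rows.append(
            {
                "method": method,
                "tp": rates.tp,
                "fp": rates.fp,
                "tn": rates.tn,
                "fn": rates.fn,
                "fp_rate": rates.fp_rate,
                "fn_rate": rates.fn_rate,
            }
        )
    errors = pd.DataFrame(error_rows)

    perm_rows = []
    if config.run_permanova:
        post_cols = design.sample_names(POST)
        groups = np.asarray(design.group_labels)
        for method, norm in reps.items():
            for metric in METRICS_BY_METHOD[method]:
                d = _distance(norm, metric, post_cols)
                res = variance.permanova(d, groups, n_permutations=config.n_permutations, rng=rng)
                perm_rows.append(
                    {
                        "method": method,
                        "metric": metric,
                        "r_squared": res.r_squared,
                        "pseudo_f": res.pseudo_f,
                        "p_value": res.p_value,
                    }
                )
    permanova = pd.DataFrame(
        perm_rows, columns=["method", "metric", "r_squared", "pseudo_f", "p_value"]
    )
    return errors, permanova


@dataclass
class ExperimentResult:
    """Long-format results of one experiment sweep."""

    direction_regime: str
    master_seed: int
    errors: pd.DataFrame
    permanova: pd.DataFrame
    config: SimulationConfig


def _iteration_rng(master_seed: int, direction: str, scenario_idx: int, iteration: int):
    exp_code = 1 if direction == UNIDIRECTIONAL else 2
    ss = np.random.SeedSequence([int(master_seed), exp_code, scenario_idx, iteration])
    return np.random.default_rng(ss)


def run_experiment(
    direction_regime: str,
    config: SimulationConfig,
    master_seed: int,
    n_iterations: int | None = None,
    grid: list[ScenarioSpec] | None = None,
    progress: bool = False,
) -> ExperimentResult:
    """Sweep the scenario grid for one direction regime.

    Every (scenario, iteration) cell draws its generator from a seed
    sequence keyed on ``(master_seed, experiment, scenario index,
    iteration)``, so partial runs and reordered execution reproduce the
    same numbers.
    """
    if grid is None:
        grid = config.grid(direction_regime)
    if not grid:
        raise ValueError("scenario grid is empty")
    n_iterations = config.n_iterations if n_iterations is None else n_iterations
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    err_frames, perm_frames = [], []
    for scen_idx, spec in enumerate(grid):
        if progress:
            print(
                f"scenario {scen_idx + 1}/{len(grid)}: effect={spec.effect_size} "
                f"proportion={spec.proportion_responding}",
                flush=True,
            )
        for it in range(n_iterations):
            rng = _iteration_rng(master_seed, direction_regime, scen_idx, it)
            errors, permanova = run_scenario(spec, config, rng)
            for frame, sink in ((errors, err_frames), (permanova, perm_frames)):
                if frame.empty:
                    continue
                frame = frame.copy()
                frame.insert(0, "iteration", it)
                frame.insert(0, "proportion", spec.proportion_responding)
                frame.insert(0, "effect_size", spec.effect_size)
                frame.insert(0, "scenario", scen_idx)
                sink.append(frame)
    errors = pd.concat(err_frames, ignore_index=True)
    permanova = (
        pd.concat(perm_frames, ignore_index=True)
        if perm_frames
        else pd.DataFrame(
            columns=[
                "scenario", "effect_size", "proportion", "iteration",
                "method", "metric", "r_squared", "pseudo_f", "p_value",
            ]
        )
    )
    return ExperimentResult(direction_regime, master_seed, errors, permanova, config)


@dataclass
class SummaryTable:
    """Aggregated outputs: Table-style error summary plus figure grids."""

    error_summary: pd.DataFrame       # per method: max/mean FP & FN + fold changes
    scenario_error_means: pd.DataFrame  # per method x scenario mean rates
    delta_vs_relative: pd.DataFrame   # per scenario: method minus relative-abundance rates
    scenario_r2_means: pd.DataFrame   # per method x metric x scenario mean R²
    delta_r2: pd.DataFrame            # per method x scenario: composition metric minus log-Pearson


def scenario_means(errors: pd.DataFrame) -> pd.DataFrame:
    """Scenario-level mean FP/FN rates (mean over iterations)."""
    return (
        errors.groupby(["method", "scenario", "effect_size", "proportion"], as_index=False)[
            ["fp_rate", "fn_rate"]
        ].mean()
    )


def summarize(result: ExperimentResult) -> SummaryTable:
    """Aggregate an experiment into the headline error and variance tables.

    Scenario means (over iterations) are computed first; the experiment
    mean weights scenarios equally and the maximum is taken over scenario
    means. Fold changes divide each transformation's mean rate by the
    absolute-abundance mean.
    """
    scen = scenario_means(result.errors)
    rows = []
    for method, sub in scen.groupby("method"):
        rows.append(
            {
                "method": method,
                "max_fp": sub["fp_rate"].max(),
                "mean_fp": sub["fp_rate"].mean(),
                "max_fn": sub["fn_rate"].max(),
                "mean_fn": sub["fn_rate"].mean(),
            }
        )
    summary = pd.DataFrame(rows).set_index("method")
    order = [m for m in METHODS if m in summary.index]
    summary = summary.loc[order]
    if ABSOLUTE in summary.index:
        abs_fp = summary.loc[ABSOLUTE, "mean_fp"]
        abs_fn = summary.loc[ABSOLUTE, "mean_fn"]
        summary["mean_fp_fold_vs_absolute"] = (
            summary["mean_fp"] / abs_fp if abs_fp > 0 else np.nan
        )
        summary["mean_fn_fold_vs_absolute"] = (
            summary["mean_fn"] / abs_fn if abs_fn > 0 else np.nan
        )

    keys = ["scenario", "effect_size", "proportion"]
    delta_rows = []
    if RELATIVE in scen["method"].values:
        rel = scen[scen["method"] == RELATIVE].set_index(keys)
        for method in scen["method"].unique():
            if method in (RELATIVE, ABSOLUTE):
                continue
            sub = scen[scen["method"] == method].set_index(keys)
            delta = pd.DataFrame(
                {
                    "delta_fp": sub["fp_rate"] - rel["fp_rate"],
                    "delta_fn": sub["fn_rate"] - rel["fn_rate"],
                }
            ).reset_index()
            delta.insert(0, "method", method)
            delta_rows.append(delta)
    delta_vs_relative = (
        pd.concat(delta_rows, ignore_index=True)
        if delta_rows
        else pd.DataFrame(columns=["method", *keys, "delta_fp", "delta_fn"])
    )

    if not result.permanova.empty:
        r2 = (
            result.permanova.groupby(
                ["method", "metric", "scenario", "effect_size", "proportion"],
                as_index=False,
            )["r_squared"].mean()
        )
        d_rows = []
        for method, sub in r2.groupby("method"):
            wide = sub.pivot_table(index=keys, columns="metric", values="r_squared")
            comp_metric = (
                variance.AITCHISON if variance.AITCHISON in wide.columns else variance.BRAY_CURTIS
            )
            if variance.LOG_PEARSON not in wide.columns or comp_metric not in wide.columns:
                continue
            d = (wide[comp_metric] - wide[variance.LOG_PEARSON]).rename("delta_r2").reset_index()
            d.insert(0, "comparison_metric", comp_metric)
            d.insert(0, "method", method)
            d_rows.append(d)
        delta_r2 = (
            pd.concat(d_rows, ignore_index=True)
            if d_rows
            else pd.DataFrame(columns=["method", "comparison_metric", *keys, "delta_r2"])
        )
    else:
        r2 = pd.DataFrame(columns=["method", "metric", *keys, "r_squared"])
        delta_r2 = pd.DataFrame(columns=["method", "comparison_metric", *keys, "delta_r2"])

    return SummaryTable(
        error_summary=summary,
        scenario_error_means=scen,
        delta_vs_relative=delta_vs_relative,
        scenario_r2_means=r2,
        delta_r2=delta_r2,
    )


def write_results(result: ExperimentResult, out_dir: str | Path) -> None:
    """Write long-format results, summaries, and the config snapshot."""
    out = Path(out_dir)
    raw = out / "raw"
    summary_dir = out / "summary"
    raw.mkdir(parents=True, exist_ok=True)
    summary_dir.mkdir(parents=True, exist_ok=True)
    result.errors.to_csv(raw / "error_rates.tsv", sep="\t", index=False)
    result.permanova.to_csv(raw / "permanova.tsv", sep="\t", index=False)
    tables = summarize(result)
    tables.error_summary.to_csv(summary_dir / "error_summary.tsv", sep="\t")
    tables.scenario_error_means.to_csv(
        summary_dir / "scenario_error_means.tsv", sep="\t", index=False
    )
    tables.delta_vs_relative.to_csv(summary_dir / "delta_vs_relative.tsv", sep="\t", index=False)
    tables.scenario_r2_means.to_csv(summary_dir / "scenario_r2_means.tsv", sep="\t", index=False)
    tables.delta_r2.to_csv(summary_dir / "delta_r2.tsv", sep="\t", index=False)
    snapshot = dataclasses.asdict(result.config)
    snapshot["direction_regime"] = result.direction_regime
    snapshot["master_seed"] = result.master_seed
    import json

    (out / "config.json").write_text(json.dumps(snapshot, indent=2) + "\n")
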