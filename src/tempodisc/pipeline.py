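"""End-to-end orchestration: simulate -> timing -> fit -> stats -> report.

One master seed fans out deterministically to per-stage seeds (via
``numpy.random.SeedSequence(master).generate_state``), so a rerun with the
same config reproduces every CSV byte for byte, and each stage can be rerun
in isolation.  All tabular I/O is headered UTF-8 CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tempodisc.synthetic import SimulationConfig, simulate_dataset
from tempodisc.hierarchical import PriorSpec, SamplerConfig, fit_hierarchical_bhm
from tempodisc.discounting import (
    SUBJECTIVE_VARIANTS,
    build_subjective_delay_variant,
    compute_bayesian_r2,
)
from tempodisc.timing import (
    remove_outlier_trials,
    summarize_ratios,
    compute_ics_variables,
    fit_all_subjective_times,
    scalar_timing_summary,
)
from tempodisc.stats import (
    pearson_correlation,
    tls_fit,
    permutation_mean_difference,
    drop_one_regression,
    compare_nonoverlapping_dependent_correlations,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report",
           "validate_choices", "validate_timing"]

log = logging.getLogger("tempodisc")

ALL_VARIANTS = ("obj", "subjTel", "subjTep", "subjTpl", "subjTpp")

CHOICE_COLUMNS = {"subject_id", "task", "sooner_reward", "later_reward",
                  "delay", "choice"}
TIMING_COLUMNS = {"subject_id", "task", "actual_s", "reported_s"}

REQUIRED_TABLES = ("correlations", "corr_comparison", "dropone_sv",
                   "dropone_lv", "permutation")


def validate_choices(df: pd.DataFrame, name: str = "choices.csv") -> None:
    missing = CHOICE_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    bad = df.index[~df["choice"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"{name}: non-binary choice value at row {bad[0]}")
    for col, lo in (("sooner_reward", 0), ("later_reward", 0), ("delay", -1)):
        bad = df.index[~(df[col] > lo)]
        if len(bad):
            raise ValueError(f"{name}: invalid {col} at row {bad[0]}")
    bad = df.index[~df["task"].isin(["SV", "LV"])]
    if len(bad):
        raise ValueError(f"{name}: unknown task label at row {bad[0]}")


def validate_timing(df: pd.DataFrame, name: str = "timing.csv") -> None:
    missing = TIMING_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    for col in ("actual_s", "reported_s"):
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            raise ValueError(f"{name}: nonpositive {col} at row {bad[0]}")
    bad = df.index[~df["task"].isin(["estimation", "production"])]
    if len(bad):
        raise ValueError(f"{name}: unknown task label at row {bad[0]}")


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Either ``sim`` (synthetic mode) or both ``choices_path``/``timing_path``
    (real-data mode) supplies the input tables.
    """

    out_dir: str | Path = "tempodisc_run"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    sampler: SamplerConfig = field(
        default_factory=lambda: SamplerConfig(chains=4, iterations=1500, warmup=500)
    )
    priors: PriorSpec = field(default_factory=PriorSpec)
    variants: tuple = ALL_VARIANTS
    choices_path: str | None = None
    timing_path: str | None = None
    bonferroni_m: int = 4
    n_shuffles: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.variants) - set(ALL_VARIANTS)
        if bad:
            raise ValueError(f"unknown variants {sorted(bad)}")

    def stage_seeds(self) -> dict:
        """Fixed fan-out of the master seed to per-stage seeds (< 2^31)."""
        state = np.random.SeedSequence(self.seed).generate_state(3, dtype="uint64")
        names = ("simulate", "fit", "stats")
        return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


@dataclass
class RunReport:
    """Report tables plus provenance for one pipeline run."""

    tables: dict
    diagnostics: pd.DataFrame
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "tables": {k: df.to_dict(orient="records") for k, df in self.tables.items()},
            "diagnostics": self.diagnostics.to_dict(orient="records"),
            "provenance": self.provenance,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, stage: str) -> None:
    df.to_csv(path, index=False)
    log.info("stage=%s wrote=%s sha256=%s rows=%d", stage, path.name, _sha256(path), len(df))


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis chain and write every stage artifact.

    Stages: (1) simulate or load the choice and timing tables; (2) timing
    analysis (outlier removal, ratio summaries, ICS proxies, subjective-time
    fits, scalar-timing table); (3) hierarchical fits of each requested model
    variant; (4) inferential tables (per-variant cross-task correlation,
    dependent-correlation comparison against the objective model, drop-one
    regressions for each task, permutation tests of the timing variables
    between impulsivity subgroups).
    """
    if not config.variants:
        raise ValueError("no variants fitted: the variant list is empty")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    # ---- stage 1: data ----
    if config.choices_path is not None:
        choices = pd.read_csv(config.choices_path)
        timing = pd.read_csv(config.timing_path)
    else:
        sim = dataclasses.replace(config.sim, seed=seeds["simulate"])
        data = simulate_dataset(sim, out_dir=out)
        choices, timing = data["choices"], data["timing"]
    validate_choices(choices)
    validate_timing(timing)
    log.info("stage=data n_choices=%d n_timing=%d", len(choices), len(timing))

    # ---- stage 2: timing analysis ----
    kept, removed = remove_outlier_trials(timing)
    summary = summarize_ratios(kept)
    ics = compute_ics_variables(summary)
    timing_fits = fit_all_subjective_times(kept)
    scalar = scalar_timing_summary(kept)
    _write_csv(removed, out / "removed_trials.csv", "timing")
    _write_csv(ics, out / "timing_summary.csv", "timing")
    _write_csv(timing_fits, out / "timing_fits.csv", "timing")
    _write_csv(scalar.table, out / "scalar_timing.csv", "timing")

    # ---- stage 3: hierarchical fits per variant ----
    estimates: dict[str, pd.DataFrame] = {}
    diag_rows = []
    for vi, variant in enumerate(config.variants):
        vtrials = build_subjective_delay_variant(choices, timing_fits, variant)
        sampler = dataclasses.replace(
            config.sampler, seed=(seeds["fit"] + 7919 * vi) % (2 ** 31))
        fit = fit_hierarchical_bhm(vtrials, config.priors, sampler, variant=variant)
        est = fit.subject_estimates()
        est["bayes_r2_sv"] = [
            compute_bayesian_r2(fit, vtrials, sid, "SV") for sid in est["subject_id"]
        ]
        est["bayes_r2_lv"] = [
            compute_bayesian_r2(fit, vtrials, sid, "LV") for sid in est["subject_id"]
        ]
        estimates[variant] = est
        _write_csv(fit.summary(), out / f"posterior_summary_{variant}.csv", "fit")
        _write_csv(est, out / f"subject_estimates_{variant}.csv", "fit")
        d = fit.diagnostics.copy()
        d.insert(0, "variant", variant)
        d["converged"] = fit.converged
        diag_rows.append(d)
    diagnostics = pd.concat(diag_rows, ignore_index=True)

    # ---- stage 4: statistics ----
    corr_rows = []
    for variant in config.variants:
        est = estimates[variant]
        r, p = pearson_correlation(est["logk_sv_mean"], est["logk_lv_mean"])
        line = tls_fit(est["logk_sv_mean"], est["logk_lv_mean"])
        corr_rows.append({
            "variant": variant, "n": len(est), "pearson_r": r, "p": p,
            "tls_slope": line.slope, "tls_intercept": line.intercept,
        })
    correlations = pd.DataFrame(corr_rows)

    comp_rows = []
    if "obj" in config.variants:
        obj = estimates["obj"].set_index("subject_id")
        for variant in config.variants:
            if variant == "obj":
                continue
            alt = estimates[variant].set_index("subject_id").reindex(obj.index)
            cols = {
                "1": obj["logk_sv_mean"], "2": obj["logk_lv_mean"],
                "3": alt["logk_sv_mean"], "4": alt["logk_lv_mean"],
            }
            rs = {
                f"r{i}{j}": pearson_correlation(cols[i], cols[j])[0]
                for i, j in ("12", "34", "13", "14", "23", "24")
            }
            res = compare_nonoverlapping_dependent_correlations(
                rs["r12"], rs["r34"],
                {k: rs[k] for k in ("r13", "r14", "r23", "r24")},
                n=len(obj),
            )
            comp_rows.append({
                "variant": variant,
                "r_obj": res.r_baseline,
                "r_variant": res.r_alternative,
                "z": res.z,
                "p": res.p_value,
                "p_one_sided": res.p_one_sided,
                "significantly_better": bool(
                    res.p_value < 0.05 and res.r_alternative > res.r_baseline
                ),
            })
    corr_comparison = pd.DataFrame(comp_rows)

    base = "obj" if "obj" in config.variants else config.variants[0]
    merged = estimates[base].merge(ics[ics["ics_valid"]], on="subject_id")
    dropone = {}
    for resp, other in (("logk_sv_mean", "logk_lv_mean"),
                        ("logk_lv_mean", "logk_sv_mean")):
        preds = merged[["ICSe", "ICSp", "ICSError", other]].rename(
            columns={other: "logk_other"})
        dropone[resp] = drop_one_regression(
            merged[resp], preds, bonferroni_m=config.bonferroni_m)
    dropone_sv, dropone_lv = dropone["logk_sv_mean"], dropone["logk_lv_mean"]

    more_sv = merged["logk_sv_mean"] > merged["logk_lv_mean"]
    perm_rows = []
    for i, var in enumerate(("ICSe", "ICSp", "ICSError")):
        res = permutation_mean_difference(
            merged.loc[more_sv, var], merged.loc[~more_sv, var],
            n_shuffles=config.n_shuffles,
            seed=(seeds["stats"] + i) % (2 ** 31),
        )
        perm_rows.append({
            "variable": var,
            "mean_KSV_gt_KLV": float(merged.loc[more_sv, var].mean()),
            "mean_KLV_gt_KSV": float(merged.loc[~more_sv, var].mean()),
            "observed_diff": res.observed_diff,
            "p": res.p_value,
            "n_shuffles": res.n_shuffles,
        })
    permutation = pd.DataFrame(perm_rows)

    for name, df in (("correlations", correlations),
                     ("corr_comparison", corr_comparison),
                     ("dropone_sv", dropone_sv), ("dropone_lv", dropone_lv),
                     ("permutation", permutation)):
        _write_csv(df, out / f"{name}.csv", "stats")

    cfg_json = json.dumps(
        {
            "sim": config.sim.to_dict(),
            "sampler": dataclasses.asdict(config.sampler),
            "priors": dataclasses.asdict(config.priors),
            "variants": list(config.variants),
            "bonferroni_m": config.bonferroni_m,
            "n_shuffles": config.n_shuffles,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    provenance = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.seed,
        "stage_seeds": seeds,
        "versions": {
            "tempodisc": _pkg_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return RunReport(
        tables={
            "correlations": correlations,
            "corr_comparison": corr_comparison,
            "dropone_sv": dropone_sv,
            "dropone_lv": dropone_lv,
            "permutation": permutation,
        },
        diagnostics=diagnostics,
        provenance=provenance,
    )


def _pkg_version() -> str:
    from tempodisc import __version__

    return __version__


def write_report(report: RunReport, out_dir: str | Path,
                 formats: tuple = ("markdown", "json")) -> list[Path]:
    """Write the run report as Markdown and/or JSON with identical numbers."""
    missing = [t for t in REQUIRED_TABLES if t not in report.tables]
    if missing:
        raise ValueError(f"incomplete report; missing tables: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "json":
            path = out / "report.json"
            path.write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True))
        elif fmt == "markdown":
            path = out / "report.md"
            lines = ["# tempodisc run report", ""]
            for name, df in report.tables.items():
                lines += [f"## {name}", "", "```", df.to_string(index=False), "```", ""]
            lines += ["## diagnostics", "", "```",
                      report.diagnostics.to_string(index=False), "```", ""]
            lines += ["## provenance", "", "```",
                      json.dumps(report.provenance, indent=2, sort_keys=True), "```", ""]
            path.write_text("\n".join(lines))
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        written.append(path)
        log.info("stage=report wrote=%s sha256=%s", path.name, _sha256(path))
    return written
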