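"""Timing-task analysis: internal-clock-speed proxies and subjective time.

Raw trials from the estimation and production tasks are reduced, per
subject, to mean reported/actual ratios per interval, their across-interval
means (MTeRatio, MTpRatio), and three internal-clock-speed variables:

    ICSe     = MTeRatio                      (estimation proxy)
    ICSp     = 2 - MTpRatio                  (production proxy, reflected about 1)
    ICSError = (|MTeRatio - 1| + |MTpRatio - 1|) / 2

ICS values above 1 mean the subject's clock runs fast relative to a
stopwatch.  The production reflection breaks down when MTpRatio >= 2 (ICSp
would be <= 0), so such subjects are flagged invalid and their proxies
withheld from ICS-based analyses while remaining usable elsewhere.

The module also fits per-subject subjective-time functions (power
ST(t) = alpha * t^beta, or linear with beta fixed at 1), summarises scalar
timing (is SD/mean constant across intervals?), and provides the 100-point
normal-kernel density estimate used for plotting distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "TimingSummary",
    "SubjectiveTimeFit",
    "ScalarTimingResult",
    "remove_outlier_trials",
    "summarize_ratios",
    "compute_ics_variables",
    "fit_subjective_time",
    "fit_all_subjective_times",
    "scalar_timing_summary",
    "kernel_density_estimate",
]

TIMING_TASKS = ("estimation", "production")


def remove_outlier_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose report exceeds 3x the cell mean.

    Within each (task, actual interval) cell, the mean reported duration is
    computed pooled across subjects; trials with reported_s strictly greater
    than 3 times that mean are removed.  A single pass — the threshold is not
    recomputed after removal.  Returns (kept, removed).
    """
    if len(trials) == 0:
        raise ValueError("no timing trials")
    cell_mean = trials.groupby(["task", "actual_s"])["reported_s"].transform("mean")
    is_outlier = trials["reported_s"] > 3.0 * cell_mean
    return (
        trials[~is_outlier].reset_index(drop=True),
        trials[is_outlier].reset_index(drop=True),
    )


@dataclass
class TimingSummary:
    """Per-interval means/ratios and per-subject ratio summaries.

    ``per_interval``: subject_id, task, actual_s, mean_reported, ratio.
    ``per_subject``: subject_id, MTeRatio, MTpRatio, complete (False when a
    subject is missing an entire task).
    """

    per_interval: pd.DataFrame
    per_subject: pd.DataFrame


def summarize_ratios(trials: pd.DataFrame) -> TimingSummary:
    """Reduce timing trials to per-subject mean reported/actual ratios.

    Per subject, task and interval: the mean report over available
    repetitions (possibly fewer than scheduled after outlier removal), then
    the ratio to the actual interval; per task, the unweighted mean of the
    per-interval ratios (so intervals with unequal trial counts still
    contribute equally).
    """
    if len(trials) == 0:
        raise ValueError("no timing trials")
    per_int = (
        trials.groupby(["subject_id", "task", "actual_s"], sort=True)["reported_s"]
        .mean()
        .rename("mean_reported")
        .reset_index()
    )
    per_int["ratio"] = per_int["mean_reported"] / per_int["actual_s"]
    mt = (
        per_int.groupby(["subject_id", "task"])["ratio"]
        .mean()
        .unstack("task")
        .rename(columns={"estimation": "MTeRatio", "production": "MTpRatio"})
    )
    for col in ("MTeRatio", "MTpRatio"):
        if col not in mt.columns:
            mt[col] = np.nan
    mt["complete"] = mt["MTeRatio"].notna() & mt["MTpRatio"].notna()
    per_subject = mt.reset_index()[["subject_id", "MTeRatio", "MTpRatio", "complete"]]
    return TimingSummary(per_interval=per_int, per_subject=per_subject)


def compute_ics_variables(summary: TimingSummary | pd.DataFrame) -> pd.DataFrame:
    """Internal-clock-speed proxies from the ratio summaries.

    ICSe = MTeRatio; ICSp = 2 - MTpRatio; ICSError is the mean absolute
    deviation of the two ratios from 1.  ``ics_valid`` is False — and the
    proxies are withheld (NaN) — when MTpRatio >= 2 (the reflection about 1
    can no longer represent the subject's clock) or when a task is missing.
    """
    per_subject = summary.per_subject if isinstance(summary, TimingSummary) else summary
    out = per_subject.copy()
    valid = out["complete"] & (out["MTpRatio"] < 2.0)
    out["ICSe"] = np.where(valid, out["MTeRatio"], np.nan)
    out["ICSp"] = np.where(valid, 2.0 - out["MTpRatio"], np.nan)
    out["ICSError"] = np.where(
        valid,
        (np.abs(out["MTeRatio"] - 1.0) + np.abs(out["MTpRatio"] - 1.0)) / 2.0,
        np.nan,
    )
    out["ics_valid"] = valid
    return out[["subject_id", "MTeRatio", "MTpRatio",
                "ICSe", "ICSp", "ICSError", "ics_valid"]]


@dataclass
class SubjectiveTimeFit:
    """Least-squares subjective-time function for one subject-task."""

    subject_id: str
    source_task: str
    form: str            # "power" or "linear"
    alpha: float
    beta: float          # fixed at 1 for the linear form
    fit_error: float     # RMS residual, seconds

    def predict(self, t):
        return self.alpha * np.asarray(t, dtype=float) ** self.beta


def fit_subjective_time(trials: pd.DataFrame, form: str = "power") -> SubjectiveTimeFit:
    """Fit ST(t) = alpha * t^beta (or alpha * t) to one subject-task's trials.

    The power fit is nonlinear least squares on the natural scale, started
    from the log-log regression solution; the linear fit is the exact
    through-origin least-squares slope.  Requires at least two distinct
    intervals.
    """
    if form not in ("power", "linear"):
        raise ValueError(f"unknown form {form!r}")
    t = trials["actual_s"].to_numpy(float)
    y = trials["reported_s"].to_numpy(float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct intervals to fit subjective time")
    subject_id = str(trials["subject_id"].iloc[0]) if "subject_id" in trials else ""
    source_task = str(trials["task"].iloc[0]) if "task" in trials else ""

    if form == "linear":
        alpha = float(np.sum(t * y) / np.sum(t * t))
        beta = 1.0
    else:
        # log-log start values, then Gauss-Newton refinement on the raw scale
        b0, loga0 = np.polyfit(np.log(t), np.log(np.maximum(y, 1e-9)), 1)
        p0 = (float(np.exp(loga0)), float(np.clip(b0, 0.05, 5.0)))
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, a, b: a * tt ** b, t, y, p0=p0, maxfev=10000
            )
            alpha, beta = float(popt[0]), float(popt[1])
        except RuntimeError:
            alpha, beta = p0
    resid = y - alpha * t ** beta
    return SubjectiveTimeFit(
        subject_id=subject_id,
        source_task=source_task,
        form=form,
        alpha=alpha,
        beta=beta,
        fit_error=float(np.sqrt(np.mean(resid ** 2))),
    )


def fit_all_subjective_times(trials: pd.DataFrame) -> pd.DataFrame:
    """Both forms for every subject and timing task, as a tidy table."""
    rows = []
    for (sid, task), sub in trials.groupby(["subject_id", "task"], sort=True):
        for form in ("power", "linear"):
            f = fit_subjective_time(sub, form)
            rows.append({
                "subject_id": sid, "source_task": task, "form": form,
                "alpha": f.alpha, "beta": f.beta, "fit_error": f.fit_error,
            })
    return pd.DataFrame(rows)


@dataclass
class ScalarTimingResult:
    """Per-cell dispersion table plus the CV-constancy check.

    ``table``: task, actual_s, n_trials, mean, sd, cv — where sd is the
    pooled within-subject SD (root mean square of per-subject SDs) so that
    between-subject differences in clock speed do not inflate it.
    ``cv_slope``: per task, the slope of CV on interval with its p-value;
    scalar (Weber-law) timing predicts a flat line, while a counting
    strategy's constant SD predicts CV falling as 1/t.
    """

    table: pd.DataFrame
    cv_slope: dict


def scalar_timing_summary(trials: pd.DataFrame) -> ScalarTimingResult:
    """Check the scalar-timing signature: SD/mean constant across intervals."""
    counts = trials.groupby(["task", "actual_s"])["reported_s"].count()
    if (counts.groupby("task").size() < 2).any() or (counts < 2).any():
        raise ValueError("need >= 2 intervals with >= 2 trials each per task")
    per_subj = trials.groupby(["task", "actual_s", "subject_id"])["reported_s"].agg(
        ["mean", "std", "count"]
    )
    rows = []
    for (task, t), cell in per_subj.groupby(level=["task", "actual_s"]):
        sds = cell.loc[cell["count"] >= 2, "std"].to_numpy(float)
        if len(sds) == 0:
            raise ValueError(
                f"no subject has >= 2 trials in cell ({task}, {t}); "
                "cannot form within-subject SDs"
            )
        m = float(cell["mean"].mean())
        sd = float(np.sqrt(np.mean(sds ** 2)))  # pooled within-subject SD
        rows.append({
            "task": task,
            "actual_s": float(t),
            "n_trials": int(cell["count"].sum()),
            "mean": m,
            "sd": sd,
            "cv": sd / m,
        })
    table = pd.DataFrame(rows).sort_values(["task", "actual_s"]).reset_index(drop=True)
    cv_slope = {}
    for task, sub in table.groupby("task"):
        res = sps.linregress(sub["actual_s"], sub["cv"])
        cv_slope[task] = {"slope": float(res.slope), "p": float(res.pvalue)}
    return ScalarTimingResult(table=table, cv_slope=cv_slope)


def kernel_density_estimate(values, n_points: int = 100):
    """Normal-kernel density on equally spaced points covering the data.

    Bandwidth is the normal-reference rule sigma * (4 / (3 n))^(1/5); the
    grid extends three bandwidths beyond the data range so the density mass
    is captured.  Returns (grid, density), each of length ``n_points``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no finite values for density estimation")
    sigma = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    bw = sigma * (4.0 / (3.0 * len(x))) ** 0.2 if sigma > 0 else 1.0
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_points)
    z = (grid[:, None] - x[None, :]) / bw
    density = np.exp(-0.5 * z ** 2).sum(axis=1) / (len(x) * bw * np.sqrt(2 * np.pi))
    return grid, density
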