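"""Softmax-hyperbolic choice model: likelihood, point fits, and model variants.

The discounted value of a later reward A at delay D is A / (1 + k * D), with
the discount factor k in the units of the task (1/s for the seconds task,
1/day for the days task; no unit conversion is ever applied).  The
probability of choosing the later option is a logistic (softmax) function of
the value difference scaled by the decision noise tau:

    P(later) = sigma((A / (1 + e^logk * D) - sooner) / e^logtau)

Subjective-time variants replace the objective seconds-task delay by each
subject's fitted subjective duration ST(D) before evaluating the same
likelihood; days-task trials are never transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "SUBJECTIVE_VARIANTS",
    "hyperbolic_choice_probability",
    "dataset_log_likelihood",
    "MLEFit",
    "fit_subject_mle",
    "flag_delay_insensitive",
    "build_subjective_delay_variant",
    "compare_models_kfold",
    "compute_bayesian_r2",
]

#: variant label -> (timing task the fit came from, functional form)
SUBJECTIVE_VARIANTS = {
    "subjTep": ("estimation", "power"),
    "subjTel": ("estimation", "linear"),
    "subjTpp": ("production", "power"),
    "subjTpl": ("production", "linear"),
}

LOGK_BOUNDS = (-12.0, 2.0)
LOGTAU_BOUNDS = (-4.0, 3.0)


def hyperbolic_choice_probability(sooner_reward, later_reward, delay, logk, logtau):
    """Probability of choosing the later option under softmax-hyperbolic choice.

    All arguments broadcast as numpy arrays; scalars in give a scalar out.
    Strictly decreasing in delay and in logk for fixed offers; equals 0.5
    exactly when the discounted later value matches the sooner reward.
    """
    sooner = np.asarray(sooner_reward, dtype=float)
    later = np.asarray(later_reward, dtype=float)
    d = np.asarray(delay, dtype=float)
    logk = np.asarray(logk, dtype=float)
    logtau = np.asarray(logtau, dtype=float)
    for name, arr in (("sooner_reward", sooner), ("later_reward", later),
                      ("delay", d), ("logk", logk), ("logtau", logtau)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name}")
    if np.any(sooner <= 0) or np.any(later <= 0):
        raise ValueError("rewards must be positive")
    if np.any(d < 0):
        raise ValueError("delay must be >= 0")
    dv = later / (1.0 + np.exp(logk) * d) - sooner
    p = special.expit(dv / np.exp(logtau))
    return p if p.ndim else float(p)


def _effective_delay(trials: pd.DataFrame) -> np.ndarray:
    col = "delay_effective" if "delay_effective" in trials.columns else "delay"
    return trials[col].to_numpy(float)


def dataset_log_likelihood(trials: pd.DataFrame, subject_params: pd.DataFrame) -> float:
    """Bernoulli log likelihood of a choice table under per-subject parameters.

    ``subject_params`` has one row per (subject_id, task) with columns
    ``logk`` and ``logtau``.  Uses ``delay_effective`` when present, so the
    same routine scores objective and subjective-time variants.
    """
    required = {"subject_id", "task", "logk", "logtau"}
    if not required.issubset(subject_params.columns):
        raise ValueError(f"subject_params needs columns {sorted(required)}")
    params = subject_params.set_index(["subject_id", "task"])
    keys = pd.MultiIndex.from_frame(trials[["subject_id", "task"]])
    missing = keys.difference(params.index)
    if len(missing):
        sid = missing[0][0]
        raise KeyError(f"no parameters for subject {sid!r} (task {missing[0][1]!r})")
    aligned = params.reindex(keys)
    p_later = hyperbolic_choice_probability(
        trials["sooner_reward"].to_numpy(float),
        trials["later_reward"].to_numpy(float),
        _effective_delay(trials),
        aligned["logk"].to_numpy(float),
        aligned["logtau"].to_numpy(float),
    )
    choice = trials["choice"].to_numpy(float)
    p_later = np.clip(p_later, 1e-300, 1.0 - 1e-16)
    return float(np.sum(choice * np.log(p_later) + (1 - choice) * np.log1p(-p_later)))


def _neg_loglik(theta, sooner, later, delay, choice):
    logk, logtau = theta
    dv = later / (1.0 + np.exp(logk) * delay) - sooner
    z = dv / np.exp(logtau)
    # log sigma(z) = -log1p(exp(-z)), computed stably
    ll = np.where(choice == 1, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
    return -float(np.sum(ll))


@dataclass
class MLEFit:
    """Per-subject-task maximum-likelihood point estimate."""

    logk: float
    logtau: float
    loglik: float
    delay_insensitive: bool = False
    at_boundary: bool = False


def flag_delay_insensitive(trials: pd.DataFrame, p_threshold: float = 0.05,
                           rate_band: tuple = (0.05, 0.95)) -> bool:
    """Heuristic flag for subjects whose choices do not depend on delay.

    A subject is flagged when a within-subject logistic regression of choice
    on delay shows no delay effect (p > threshold) AND the overall
    later-choice rate is outside ``rate_band`` (i.e. near-always sooner or
    near-always later).  Constant choosers are flagged directly.
    """
    choice = trials["choice"].to_numpy(float)
    rate = choice.mean()
    if choice.min() == choice.max():
        return True
    in_band = rate_band[0] <= rate <= rate_band[1]
    delay = _effective_delay(trials)
    if delay.min() == delay.max():
        return not in_band
    import statsmodels.api as sm

    X = sm.add_constant((delay - delay.mean()) / delay.std())
    try:
        fit = sm.Logit(choice, X).fit(disp=0, maxiter=200)
        p_delay = fit.pvalues[1]
    except Exception:
        p_delay = 0.0  # perfect separation: delay fully determines choice
    return bool(p_delay > p_threshold and not in_band)


def fit_subject_mle(trials: pd.DataFrame, check_insensitive: bool = True) -> MLEFit:
    """Maximum-likelihood (logk, logtau) for one subject-task choice table.

    Bounded search over logk in [-12, 2] and logtau in [-4, 3], multi-start
    L-BFGS-B from a coarse grid.  Subjects with delay-insensitive choices are
    flagged and their estimate pinned at the relevant boundary.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    sooner = trials["sooner_reward"].to_numpy(float)
    later = trials["later_reward"].to_numpy(float)
    delay = _effective_delay(trials)
    choice = trials["choice"].to_numpy(float)

    if choice.min() == choice.max():
        # all-sooner => discounts everything (k at upper bound); all-later => k ~ 0
        logk = LOGK_BOUNDS[1] if choice[0] == 0 else LOGK_BOUNDS[0]
        ll = -_neg_loglik((logk, 0.0), sooner, later, delay, choice)
        return MLEFit(logk, 0.0, ll, delay_insensitive=True, at_boundary=True)

    args = (sooner, later, delay, choice)
    starts = [
        (lk, lt)
        for lk in (-9.0, -5.0, -2.0, 0.5)
        for lt in (-1.0, 0.5)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik, x0, args=args, method="L-BFGS-B",
            bounds=[LOGK_BOUNDS, LOGTAU_BOUNDS],
        )
        if best is None or res.fun < best.fun:
            best = res
    logk, logtau = best.x
    eps = 1e-6
    at_boundary = (
        min(logk - LOGK_BOUNDS[0], LOGK_BOUNDS[1] - logk) < eps
        or min(logtau - LOGTAU_BOUNDS[0], LOGTAU_BOUNDS[1] - logtau) < eps
    )
    return MLEFit(
        float(logk), float(logtau), -float(best.fun),
        delay_insensitive=flag_delay_insensitive(trials) if check_insensitive else False,
        at_boundary=bool(at_boundary),
    )


def build_subjective_delay_variant(
    trials: pd.DataFrame,
    fits: pd.DataFrame | None,
    variant: str,
) -> pd.DataFrame:
    """Attach ``delay_effective`` for one model variant.

    For the objective variant (``"obj"``), delay_effective = delay.  For a
    subjective variant, seconds-task (SV) delays are replaced by the
    subject's fitted subjective duration ST(delay) = alpha * delay^beta from
    the named (timing task, form) fit; days-task (LV) trials are untouched.

    ``fits`` needs columns subject_id, source_task, form, alpha, beta.
    """
    out = trials.copy()
    if variant == "obj":
        out["delay_effective"] = out["delay"].astype(float)
        return out
    if variant not in SUBJECTIVE_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected 'obj' or one of "
            f"{sorted(SUBJECTIVE_VARIANTS)}"
        )
    if fits is None:
        raise ValueError(f"variant {variant!r} requires subjective-time fits")
    source_task, form = SUBJECTIVE_VARIANTS[variant]
    sel = fits[(fits["source_task"] == source_task) & (fits["form"] == form)]
    sel = sel.set_index("subject_id")
    out["delay_effective"] = out["delay"].astype(float)
    sv = out["task"] == "SV"
    sv_subjects = out.loc[sv, "subject_id"].unique()
    missing = set(sv_subjects) - set(sel.index)
    if missing:
        raise KeyError(
            f"no {source_task}/{form} subjective-time fit for subject(s) "
            f"{sorted(missing)}"
        )
    alpha = sel["alpha"].reindex(out.loc[sv, "subject_id"]).to_numpy(float)
    beta = sel["beta"].reindex(out.loc[sv, "subject_id"]).to_numpy(float)
    out.loc[sv, "delay_effective"] = alpha * out.loc[sv, "delay"].to_numpy(float) ** beta
    return out


def _assign_folds(trials: pd.DataFrame, k: int, seed: int) -> np.ndarray:
    """Fold labels stratified by (subject, task, offer): every fold sees every
    subject, and repeats of one offer are spread across folds."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(trials), dtype=int)
    keys = trials.groupby(
        ["subject_id", "task", "delay", "later_reward"], sort=False
    ).indices
    for idx in keys.values():
        idx = np.asarray(idx)
        start = rng.integers(k)
        labels = (start + np.arange(len(idx))) % k
        folds[idx[rng.permutation(len(idx))]] = labels
    return folds


def _held_out_score(test: pd.DataFrame, params: pd.DataFrame, lapse: float) -> float:
    """Log predictive density of held-out trials under point estimates, with
    a small lapse rate mixed into the predictions: p -> lapse + (1-2*lapse)*p.
    Real choosers occasionally lapse, so no held-out choice is scored as
    arbitrarily surprising by an overconfident training fit."""
    aligned = params.set_index(["subject_id", "task"]).reindex(
        pd.MultiIndex.from_frame(test[["subject_id", "task"]]))
    dv = (test["later_reward"].to_numpy(float)
          / (1.0 + np.exp(aligned["logk"].to_numpy(float)) * _effective_delay(test))
          - test["sooner_reward"].to_numpy(float))
    p = special.expit(dv / np.exp(aligned["logtau"].to_numpy(float)))
    p = lapse + (1.0 - 2.0 * lapse) * p
    c = test["choice"].to_numpy(float)
    return float(np.sum(c * np.log(p) + (1 - c) * np.log1p(-p)))


def compare_models_kfold(
    trials_by_variant: dict[str, pd.DataFrame],
    k: int = 10,
    seed: int = 0,
    lapse: float = 0.01,
) -> pd.DataFrame:
    """Rank model variants by summed held-out log predictive density.

    Each variant is a choice table (same trials, different
    ``delay_effective``).  Folds are shared across variants and stratified by
    subject and offer; within each training fold every subject-task is fit by
    maximum likelihood and the held-out trials scored at the point estimate
    with a small lapse rate (see :func:`_held_out_score`).
    Returns one row per variant with elpd (sum over folds), the SE of the
    fold-wise differences from the best variant, and the rank.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    names = list(trials_by_variant)
    base = trials_by_variant[names[0]]
    folds = _assign_folds(base, k, seed)
    fold_scores = {name: np.zeros(k) for name in names}
    for name in names:
        df = trials_by_variant[name]
        if len(df) != len(base):
            raise ValueError("variants must share the same trials")
        for f in range(k):
            train = df[folds != f]
            test = df[folds == f]
            rows = []
            for (sid, task), sub in train.groupby(["subject_id", "task"], sort=False):
                fit = fit_subject_mle(sub, check_insensitive=False)
                rows.append({"subject_id": sid, "task": task,
                             "logk": fit.logk, "logtau": fit.logtau})
            params = pd.DataFrame(rows)
            fold_scores[name][f] = _held_out_score(test, params, lapse)
    elpd = {name: float(fold_scores[name].sum()) for name in names}
    best = max(elpd, key=elpd.get)
    records = []
    for name in names:
        diff = fold_scores[best] - fold_scores[name]
        se = float(np.std(diff, ddof=1) / np.sqrt(k)) if name != best else 0.0
        records.append({
            "variant": name,
            "elpd": elpd[name],
            "delta_elpd_from_best": elpd[best] - elpd[name],
            "se_delta": se,
        })
    out = pd.DataFrame(records).sort_values("elpd", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def compute_bayesian_r2(fit, trials: pd.DataFrame, subject_id: str, task: str,
                        max_draws: int = 400) -> float:
    """Bayesian r^2 of one subject-task fit, on the probability scale.

    Per posterior draw, r^2 = var(p) / (var(p) + mean(p * (1 - p))): the
    variance of the predicted choice probabilities over the subject's offers,
    against the Bernoulli residual variance those probabilities imply.
    Averaged over (a thinned set of) draws; always in [0, 1].
    """
    sub = trials[(trials["subject_id"] == subject_id) & (trials["task"] == task)]
    if len(sub) == 0:
        raise ValueError(f"no trials for subject {subject_id!r} in task {task!r}")
    logk, logtau = fit.subject_draws(subject_id, task)  # each (n_draws,)
    if len(logk) > max_draws:
        step = len(logk) // max_draws
        logk, logtau = logk[::step], logtau[::step]
    sooner = sub["sooner_reward"].to_numpy(float)
    later = sub["later_reward"].to_numpy(float)
    delay = _effective_delay(sub)
    dv = later[None, :] / (1.0 + np.exp(logk)[:, None] * delay[None, :]) - sooner[None, :]
    p = special.expit(dv / np.exp(logtau)[:, None])
    var_fit = p.var(axis=1)
    var_res = (p * (1.0 - p)).mean(axis=1)
    r2 = var_fit / (var_fit + var_res)
    return float(np.mean(r2))
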