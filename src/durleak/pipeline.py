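"""Per-participant analysis pipeline and cohort summary.

For each participant the pipeline

1. bins trials per condition (control/ensemble by signed duration
   difference, second minus first; the distractors condition both by the
   distractor difference for the psychometric slope and into per-combination
   counts for the leaking-model fit),
2. fits logistic psychometric functions with AIC-selected lapse rate and
   parametric-bootstrap intervals,
3. classifies the distractor tendency from the slope CI — central (CI > 0),
   repulsion (CI < 0) or null,
4. fits the leaking factor: the exponential-decay (leaking) variant for
   central-tendency participants, the Ricker variant for repulsion
   participants (the weighted-average leaking model assumes attraction, so
   repulsion participants are routed to the lateral-inhibition variant),
5. computes the variance ratio sigma^2_control / sigma^2_ensemble, the index
   of tolerance to the perceptual noise added by multiple stimuli.

The cohort summary counts tendencies, aggregates k over central-tendency
participants, and correlates the variance ratio with k (Pearson, df = n - 2)
over included central participants; outliers are removed only through an
explicit, auditable exclusion list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .leakfit import ComboCounts, LeakModelFit, fit_k
from .psychometric import BinnedResponses, PsychometricFit, fit_condition
from .simulate import Condition

__all__ = [
    "Tendency",
    "ParticipantResult",
    "CohortSummary",
    "bin_trials",
    "bin_responses",
    "aggregate_combos",
    "classify_tendency",
    "run_participant",
    "run_cohort",
    "summarize_cohort",
]

Tendency = Literal["central", "repulsion", "null"]

SCHEMA_VERSION = "1.0"


@dataclass
class ParticipantResult:
    """Per-participant roll-up of the full analysis."""

    participant: str
    control_fit: PsychometricFit | None = None
    ensemble_fit: PsychometricFit | None = None
    distractors_fit: PsychometricFit | None = None
    tendency: Tendency | None = None
    leak_fit: LeakModelFit | None = None
    variance_ratio: float = float("nan")
    pc_control: float = float("nan")
    pc_ensemble: float = float("nan")
    errors: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """Cohort-level aggregation of participant results."""

    n_central: int
    n_repulsion: int
    n_null: int
    k_values: list[float]
    k_mean: float
    k_sd: float
    correlation_r: float | None
    correlation_p: float | None
    correlation_df: int | None
    excluded: list[str]
    mean_pc_control: float = float("nan")
    mean_pc_ensemble: float = float("nan")
    mean_sd_control: float = float("nan")
    mean_sd_ensemble: float = float("nan")
    sd_ttest_t: float = float("nan")
    sd_ttest_p: float = float("nan")
    flags: list[str] = field(default_factory=list)


def _single_condition(trials: pd.DataFrame, condition: Condition) -> pd.DataFrame:
    if len(trials) == 0:
        raise ValueError("no trials supplied")
    present = trials["condition"].unique().tolist()
    if present != [condition]:
        raise ValueError(
            f"expected only condition {condition!r}, found {present}"
        )
    return trials


def bin_responses(trials: pd.DataFrame, condition: Condition) -> BinnedResponses:
    """Bin one participant-condition's trials by signed stimulus difference.

    Control: target difference t2 - t1.  Ensemble and distractors: the
    distractor-duration difference d2 - d1 (the same x-axis for both, which
    makes the two conditions' slopes directly comparable).  Differences are
    rounded to the millisecond to make bin identity exact.
    """
    trials = _single_condition(trials, condition)
    if condition == "control":
        x = trials["t2"].to_numpy() - trials["t1"].to_numpy()
    else:
        x = trials["d2"].to_numpy() - trials["d1"].to_numpy()
    x = np.round(x, 3)
    resp = trials["response"].to_numpy()
    levels = np.unique(x)
    n = np.array([(x == lv).sum() for lv in levels])
    m = np.array([resp[x == lv].sum() for lv in levels])
    return BinnedResponses(levels, n, m)


def aggregate_combos(trials: pd.DataFrame) -> ComboCounts:
    """Aggregate distractors-condition trials into per-combination counts."""
    trials = _single_condition(trials, "distractors")
    t_vals = np.unique(np.round(np.r_[trials["t1"], trials["t2"]], 3))
    if t_vals.size != 1:
        raise ValueError(f"expected one common target duration, got {t_vals}")
    key = trials.assign(
        _d1=np.round(trials["d1"], 3), _d2=np.round(trials["d2"], 3)
    )
    g = key.groupby(["_d1", "_d2"])["response"].agg(["count", "sum"]).reset_index()
    return ComboCounts(
        d1=g["_d1"].to_numpy(),
        d2=g["_d2"].to_numpy(),
        n=g["count"].to_numpy(),
        m=g["sum"].to_numpy(),
        t=float(t_vals[0]),
    )


def bin_trials(trials: pd.DataFrame, condition: Condition):
    """Condition-appropriate aggregation of one participant's trials.

    Control/ensemble return :class:`BinnedResponses`; the distractors
    condition returns :class:`ComboCounts` for the leaking-model fit (use
    :func:`bin_responses` for its psychometric binning).
    """
    if condition == "distractors":
        return aggregate_combos(trials)
    return bin_responses(trials, condition)


def classify_tendency(fit: PsychometricFit) -> Tendency:
    """Tendency label from the 95% CI of the distractors-condition slope."""
    if fit.ci_slope is None:
        raise ValueError("classify_tendency requires a bootstrap slope CI")
    lo, hi = fit.ci_slope
    if lo > 0:
        return "central"
    if hi < 0:
        return "repulsion"
    return "null"


def _percent_correct(trials: pd.DataFrame, condition: Condition) -> float:
    """Fraction of responses matching the sign of the physical difference."""
    if condition == "control":
        diff = trials["t2"].to_numpy() - trials["t1"].to_numpy()
    else:
        i1 = np.maximum(trials["t1"].to_numpy(), trials["d1"].to_numpy())
        i2 = np.maximum(trials["t2"].to_numpy(), trials["d2"].to_numpy())
        diff = i2 - i1
    resp = trials["response"].to_numpy()
    informative = diff != 0
    if not informative.any():
        return float("nan")
    correct = (resp[informative] == 1) == (diff[informative] > 0)
    return float(correct.mean())


def run_participant(
    trials: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
) -> ParticipantResult:
    """Full analysis of one participant's three-condition session.

    Stage failures are recorded in ``result.errors`` rather than raised, so
    one pathological participant cannot abort a cohort run.
    """
    pids = trials["participant"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected one participant, got {list(pids)}")
    result = ParticipantResult(participant=str(pids[0]))

    fits: dict[str, PsychometricFit] = {}
    for i, cond in enumerate(("control", "ensemble", "distractors")):
        sub = trials[trials["condition"] == cond]
        try:
            data = bin_responses(sub, cond)
            fits[cond] = fit_condition(data, n_boot=n_boot, seed=seed + i)
        except Exception as exc:  # recorded, not raised
            result.errors[f"psychometric_{cond}"] = str(exc)
    result.control_fit = fits.get("control")
    result.ensemble_fit = fits.get("ensemble")
    result.distractors_fit = fits.get("distractors")

    for cond in ("control", "ensemble"):
        sub = trials[trials["condition"] == cond]
        if len(sub):
            pc = _percent_correct(sub, cond)
            if cond == "control":
                result.pc_control = pc
            else:
                result.pc_ensemble = pc

    if result.distractors_fit is not None:
        try:
            result.tendency = classify_tendency(result.distractors_fit)
        except Exception as exc:
            result.errors["tendency"] = str(exc)

    if result.tendency in ("central", "repulsion"):
        variant = "leaking" if result.tendency == "central" else "ricker"
        try:
            counts = aggregate_combos(trials[trials["condition"] == "distractors"])
            result.leak_fit = fit_k(counts, variant)
        except Exception as exc:
            result.errors["leak_fit"] = str(exc)

    cf, ef = result.control_fit, result.ensemble_fit
    if cf is not None and ef is not None:
        if math.isfinite(cf.sd) and math.isfinite(ef.sd) and ef.sd > 0:
            result.variance_ratio = (cf.sd**2) / (ef.sd**2)
        else:
            result.errors["variance_ratio"] = "undefined psychometric SD"
    return result


def run_cohort(
    trials: pd.DataFrame, n_boot: int = 500, seed: int = 0
) -> list[ParticipantResult]:
    """Run the participant pipeline over every participant in a trial table."""
    results = []
    for j, (pid, sub) in enumerate(sorted(trials.groupby("participant"))):
        results.append(run_participant(sub, n_boot=n_boot, seed=seed + 1000 * j))
    return results


def summarize_cohort(
    results: Sequence[ParticipantResult],
    exclude: Sequence[str] = (),
) -> CohortSummary:
    """Aggregate participant results into a cohort summary.

    k statistics are over central-tendency participants with a converged
    leaking fit.  The Pearson correlation relates the variance ratio to k
    over central participants not in ``exclude``; fewer than 3 usable
    participants leaves the correlation absent and flagged.
    """
    exclude = list(exclude)
    tendencies = [r.tendency for r in results]
    n_central = sum(t == "central" for t in tendencies)
    n_repulsion = sum(t == "repulsion" for t in tendencies)
    n_null = sum(t is None or t == "null" for t in tendencies)

    central = [
        r
        for r in results
        if r.tendency == "central" and r.leak_fit is not None and r.leak_fit.converged
    ]
    k_values = [r.leak_fit.k_hat for r in central]
    k_mean = float(np.mean(k_values)) if k_values else float("nan")
    k_sd = float(np.std(k_values, ddof=1)) if len(k_values) > 1 else float("nan")

    flags: list[str] = []
    usable = [
        r
        for r in central
        if r.participant not in exclude and math.isfinite(r.variance_ratio)
    ]
    if len(usable) >= 3:
        vr = np.array([r.variance_ratio for r in usable])
        kk = np.array([r.leak_fit.k_hat for r in usable])
        r_val, p_val = stats.pearsonr(vr, kk)
        correlation_r, correlation_p = float(r_val), float(p_val)
        correlation_df = len(usable) - 2
    else:
        correlation_r = correlation_p = correlation_df = None
        flags.append("too_few_participants_for_correlation")

    pcc = [r.pc_control for r in results if math.isfinite(r.pc_control)]
    pce = [r.pc_ensemble for r in results if math.isfinite(r.pc_ensemble)]
    sdc = [
        r.control_fit.sd
        for r in results
        if r.control_fit is not None and math.isfinite(r.control_fit.sd)
    ]
    sde = [
        r.ensemble_fit.sd
        for r in results
        if r.ensemble_fit is not None and math.isfinite(r.ensemble_fit.sd)
    ]
    paired = [
        (r.control_fit.sd, r.ensemble_fit.sd)
        for r in results
        if r.control_fit is not None
        and r.ensemble_fit is not None
        and math.isfinite(r.control_fit.sd)
        and math.isfinite(r.ensemble_fit.sd)
    ]
    if len(paired) >= 3:
        a = np.array([p[0] for p in paired])
        b = np.array([p[1] for p in paired])
        t_val, t_p = stats.ttest_rel(a, b)
        sd_t, sd_p = float(t_val), float(t_p)
    else:
        sd_t = sd_p = float("nan")

    return CohortSummary(
        n_central=n_central,
        n_repulsion=n_repulsion,
        n_null=n_null,
        k_values=[float(k) for k in k_values],
        k_mean=k_mean,
        k_sd=k_sd,
        correlation_r=correlation_r,
        correlation_p=correlation_p,
        correlation_df=correlation_df,
        excluded=exclude,
        mean_pc_control=float(np.mean(pcc)) if pcc else float("nan"),
        mean_pc_ensemble=float(np.mean(pce)) if pce else float("nan"),
        mean_sd_control=float(np.mean(sdc)) if sdc else float("nan"),
        mean_sd_ensemble=float(np.mean(sde)) if sde else float("nan"),
        sd_ttest_t=sd_t,
        sd_ttest_p=sd_p,
        flags=flags,
    )
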