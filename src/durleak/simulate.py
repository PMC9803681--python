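"""Seeded synthetic 2AFC duration-comparison cohorts.

Emulates the three-condition design the analysis assumes:

* **distractors** — both targets fixed at 1.0 s; homogeneous distractors per
  sequence from {0.3, 0.7, 1.5, 3.0} s, always different between the two
  sequences: 12 ordered combinations x 30 repetitions = 360 trials.
* **ensemble** — same stimuli, but the judged interval is the whole array,
  i.e. from the onset of the first element to the offset of the last.  With
  duration-centred stimuli that interval is max(target, distractor).
* **control** — single targets per sequence from {0.3, 0.7, 1.5} s, always
  different: 6 ordered pairs x 30 repetitions = 180 trials.

Distractors-condition responses are drawn from the leaking model's Gaussian
decision rule, optionally mixed with lapses:
P(second longer) = lapse + (1 - 2*lapse) * p_second_longer(...).
Control/ensemble responses come from comparing the two physical interval
durations, each perturbed by zero-mean Gaussian noise with the condition's
SD (so the latent psychometric SD is sqrt(2) times the per-interval SD);
lapses replace the response with a fair coin flip.

Everything is reproducible: one integer seed per observer, and cohort seeds
are split into per-observer seeds with a fixed rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import LeakParams, p_second_longer

__all__ = [
    "DISTRACTOR_DURATIONS",
    "CONTROL_DURATIONS",
    "TARGET_DURATION",
    "REPETITIONS",
    "DesignSpec",
    "ObserverSpec",
    "distractors_design",
    "ensemble_design",
    "control_design",
    "default_designs",
    "make_design",
    "simulate_observer",
    "simulate_cohort",
    "study_cohort",
]

Condition = Literal["control", "ensemble", "distractors"]
ObserverVariant = Literal["leaking", "ricker", "ideal"]

#: Distractor duration set (seconds) for the distractors/ensemble conditions.
DISTRACTOR_DURATIONS = (0.3, 0.7, 1.5, 3.0)
#: Target duration set (seconds) for the control condition.
CONTROL_DURATIONS = (0.3, 0.7, 1.5)
#: Fixed target duration (seconds) in the distractors/ensemble conditions.
TARGET_DURATION = 1.0
#: Repetitions of every ordered duration pair per participant.
REPETITIONS = 30

TRIAL_COLUMNS = ["participant", "condition", "t1", "d1", "t2", "d2", "response"]
TRUTH_COLUMNS = [
    "participant",
    "variant",
    "k_true",
    "lapse",
    "control_sd",
    "ensemble_sd",
    "seed",
]

# Per-interval noise SDs chosen so the apparent psychometric SDs match typical
# performance: control ~0.35 s (= 0.25 * sqrt 2 on the target-difference axis)
# and ensemble ~1.1 s on the distractor-difference axis (which compresses the
# physical max(t, d) interval difference, inflating the apparent SD above
# 0.5 * sqrt 2).
DEFAULT_CONTROL_SD = 0.25
DEFAULT_ENSEMBLE_SD = 0.50


@dataclass(frozen=True)
class DesignSpec:
    """Stimulus design of one condition."""

    condition: Condition
    duration_set: tuple[float, ...]
    target_duration: float = TARGET_DURATION
    repetitions: int = REPETITIONS

    def __post_init__(self) -> None:
        ds = tuple(float(d) for d in self.duration_set)
        if len(set(ds)) != len(ds) or any(d <= 0 for d in ds):
            raise ValueError("duration_set values must be distinct and positive")
        if len(ds) < 2:
            raise ValueError("duration_set needs at least two durations")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        object.__setattr__(self, "duration_set", ds)


def distractors_design(repetitions: int = REPETITIONS) -> DesignSpec:
    return DesignSpec("distractors", DISTRACTOR_DURATIONS, repetitions=repetitions)


def ensemble_design(repetitions: int = REPETITIONS) -> DesignSpec:
    return DesignSpec("ensemble", DISTRACTOR_DURATIONS, repetitions=repetitions)


def control_design(repetitions: int = REPETITIONS) -> DesignSpec:
    return DesignSpec("control", CONTROL_DURATIONS, repetitions=repetitions)


def default_designs(repetitions: int = REPETITIONS) -> list[DesignSpec]:
    """The full three-condition session design."""
    return [
        control_design(repetitions),
        ensemble_design(repetitions),
        distractors_design(repetitions),
    ]


@dataclass(frozen=True)
class ObserverSpec:
    """Generating parameters of one simulated participant."""

    id: str
    variant: ObserverVariant = "leaking"
    k_true: float = 0.5
    lapse: float = 0.0
    control_sd: float = DEFAULT_CONTROL_SD
    ensemble_sd: float = DEFAULT_ENSEMBLE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant == "leaking" and not 0.0 <= self.k_true <= 1.0:
            raise ValueError("leaking observer needs 0 <= k_true <= 1")
        if self.variant == "ricker" and not self.k_true > 0:
            raise ValueError("ricker observer needs k_true > 0")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.control_sd <= 0 or self.ensemble_sd <= 0:
            raise ValueError("noise SDs must be positive")


def make_design(spec: DesignSpec) -> pd.DataFrame:
    """Expand a design into its ordered trial templates.

    All ordered pairs of distinct durations, repeated ``spec.repetitions``
    times: 12 pairs (360 templates) for distractors/ensemble, 6 pairs
    (180 templates) for control.  Columns: condition, t1, d1, t2, d2
    (d1/d2 are NaN in the control condition, where the targets themselves
    vary).
    """
    pairs = list(itertools.permutations(spec.duration_set, 2))
    rows = []
    for a, b in pairs:
        for _ in range(spec.repetitions):
            if spec.condition == "control":
                rows.append((spec.condition, a, np.nan, b, np.nan))
            else:
                rows.append(
                    (spec.condition, spec.target_duration, a, spec.target_duration, b)
                )
    return pd.DataFrame(rows, columns=["condition", "t1", "d1", "t2", "d2"])


def _physical_interval(condition: Condition, t: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Judged physical interval: the target itself (control) or the whole
    duration-centred array, onset of first to offset of last = max(t, d)."""
    if condition == "control":
        return t
    return np.maximum(t, d)


def simulate_observer(
    obs: ObserverSpec, designs: Sequence[DesignSpec] | None = None
) -> pd.DataFrame:
    """Simulate one observer's full session; returns trial records.

    Distractors condition: Bernoulli responses with probability
    lapse + (1 - 2*lapse) * p_second_longer under the observer's variant
    (``ideal`` observers ignore distractors entirely, p = 0.5).
    Control/ensemble: noisy comparison of physical interval durations, with
    lapses as fair coin flips.
    """
    if designs is None:
        designs = default_designs()
    rng = np.random.default_rng(obs.seed)
    frames = []
    for spec in designs:
        templ = make_design(spec)
        # trial order is randomised per condition, as in a blocked session
        templ = templ.sample(frac=1.0, random_state=rng.integers(0, 2**31 - 1))
        templ = templ.reset_index(drop=True)
        n = len(templ)
        if spec.condition == "distractors":
            if obs.variant == "ideal":
                p = np.full(n, 0.5)
            else:
                params = LeakParams(obs.variant, obs.k_true)
                p = np.asarray(
                    p_second_longer(
                        templ["t1"].to_numpy(),
                        templ["d1"].to_numpy(),
                        templ["t2"].to_numpy(),
                        templ["d2"].to_numpy(),
                        params,
                    )
                )
            p = obs.lapse + (1.0 - 2.0 * obs.lapse) * p
            resp = (rng.random(n) < p).astype(int)
        else:
            sd = obs.control_sd if spec.condition == "control" else obs.ensemble_sd
            i1 = _physical_interval(
                spec.condition, templ["t1"].to_numpy(), templ["d1"].to_numpy()
            )
            i2 = _physical_interval(
                spec.condition, templ["t2"].to_numpy(), templ["d2"].to_numpy()
            )
            x1 = i1 + rng.normal(0.0, sd, n)
            x2 = i2 + rng.normal(0.0, sd, n)
            resp = (x2 > x1).astype(int)
            if obs.lapse > 0:
                lapse_mask = rng.random(n) < 2.0 * obs.lapse
                resp = np.where(lapse_mask, rng.integers(0, 2, n), resp)
        out = templ.copy()
        out.insert(0, "participant", obs.id)
        out["response"] = resp
        frames.append(out)
    trials = pd.concat(frames, ignore_index=True)
    return trials[TRIAL_COLUMNS]


def _observer_seeds(cohort_seed: int, n: int) -> np.ndarray:
    """Fixed seed-splitting rule: per-observer seeds below 2**31."""
    rng = np.random.default_rng(cohort_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def simulate_cohort(
    n_obs: int,
    k_sampler: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
    variant: ObserverVariant = "leaking",
    lapse: float = 0.0,
    repetitions: int = REPETITIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_obs`` independent observers of one variant.

    ``k_sampler`` gives the (low, high) bounds of the uniform distribution
    the true leaking factors are drawn from.  Returns (trials, truth): the
    full trial table plus a ground-truth table for recovery scoring.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = k_sampler
    ks = rng.uniform(lo, hi, size=n_obs)
    seeds = _observer_seeds(seed + 1, n_obs)
    specs = [
        ObserverSpec(
            id=f"obs{i + 1:02d}",
            variant=variant,
            k_true=float(ks[i]),
            lapse=lapse,
            seed=int(seeds[i]),
        )
        for i in range(n_obs)
    ]
    return _run_cohort(specs, repetitions)


def study_cohort(
    seed: int = 0, repetitions: int = REPETITIONS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A 22-observer cohort mimicking the observed tendency split.

    19 central-tendency observers (leaking, k ~ uniform(0.05, 0.95)) and
    3 repulsion observers (ricker, k = 0.3 s, well inside the repulsive
    regime for the design's distractor differences).
    """
    rng = np.random.default_rng(seed)
    seeds = _observer_seeds(seed + 1, 22)
    specs = []
    for i in range(19):
        specs.append(
            ObserverSpec(
                id=f"obs{i + 1:02d}",
                variant="leaking",
                k_true=float(rng.uniform(0.05, 0.95)),
                seed=int(seeds[i]),
            )
        )
    for i in range(19, 22):
        specs.append(
            ObserverSpec(
                id=f"obs{i + 1:02d}",
                variant="ricker",
                k_true=0.3,
                seed=int(seeds[i]),
            )
        )
    return _run_cohort(specs, repetitions)


def _run_cohort(
    specs: Sequence[ObserverSpec], repetitions: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    designs = default_designs(repetitions)
    trials = pd.concat(
        [simulate_observer(obs, designs) for obs in specs], ignore_index=True
    )
    truth = pd.DataFrame(
        [
            (
                obs.id,
                obs.variant,
                obs.k_true,
                obs.lapse,
                obs.control_sd,
                obs.ensemble_sd,
                obs.seed,
            )
            for obs in specs
        ],
        columns=TRUTH_COLUMNS,
    )
    return trials, truth


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table CSV (durations to 3 decimals, UTF-8, comma)."""
    out = trials.copy()
    for col in ("t1", "d1", "t2", "d2"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    bad = ~df["condition"].isin(["control", "ensemble", "distractors"])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"trial CSV row {row}: unknown condition {df.loc[row, 'condition']!r}")
    if not df["response"].isin([0, 1]).all():
        raise ValueError("trial CSV responses must be 0 or 1")
    return df[TRIAL_COLUMNS]
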