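"""Duration-channel leaking model.

A target of duration ``t`` presented together with simultaneous distractors of
duration ``d`` is perceived with a bias toward the distractor duration.  The
perceived target duration is a weighted average

    t_hat = (t + d * w) / (1 + w)

where the target always carries unit weight and the distractor weight ``w``
depends on the similarity of the two durations.  Two weight functions are
supported:

``leaking``
    w = k ** |d - t| with leaking factor 0 <= k <= 1.  Weights lie in [0, 1],
    so the perceived duration is always pulled toward the distractor (central
    tendency).  k = 1 weighs every distractor fully; k -> 0 restricts the
    influence to distractors nearly identical to the target.

``ricker``
    w = (1 - ((d - t)/k)**2) * 2 ** (-(d - t)**2 / k**2) with k > 0 (seconds).
    A Ricker (Mexican-hat) profile implementing lateral inhibition between
    duration channels: attraction for |d - t| < k, repulsion beyond, fading to
    zero for very different durations.  The weight ranges from about -0.265
    to 1; k is the difference at which the effect changes sign.

A two-interval forced-choice response is modelled by comparing the two
perceived target durations under standard Gaussian decision noise:
P("second longer") = Phi(t_hat_2 - t_hat_1).

All durations are in seconds.  Because the leaking exponent is |d - t|, the
weight function is unit dependent: the same physical stimuli expressed in
milliseconds would give different weights.  Every function here assumes
seconds, matching the experimental design the package targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import ndtr

__all__ = [
    "LeakParams",
    "RICKER_MIN_WEIGHT",
    "RICKER_MIN_OFFSET",
    "leak_weight",
    "ricker_weight",
    "weight",
    "perceived_duration",
    "p_second_longer",
    "predict_increment",
]

Variant = Literal["leaking", "ricker"]

#: Analytic minimum of the Ricker weight, attained at |d - t| = k * sqrt(1 + 1/ln 2)
#: for every k > 0 (the profile is scale invariant in (d - t)/k).
RICKER_MIN_WEIGHT = -(1.0 / math.log(2)) * 2.0 ** (-(1.0 + 1.0 / math.log(2)))

#: Location of that minimum in units of k.
RICKER_MIN_OFFSET = math.sqrt(1.0 + 1.0 / math.log(2))

#: Probabilities are clamped to [EPS, 1 - EPS] before any logarithm.
EPS = 1e-9


@dataclass(frozen=True)
class LeakParams:
    """Weight-function variant plus its leaking factor.

    Parameters
    ----------
    variant:
        ``"leaking"`` (exponential-decay weight, central tendency only) or
        ``"ricker"`` (lateral-inhibition weight allowing repulsion).
    k:
        Leaking factor.  ``leaking``: dimensionless, 0 <= k <= 1.
        ``ricker``: seconds, k > 0 (the attraction/repulsion crossover).
    """

    variant: Variant
    k: float

    def __post_init__(self) -> None:
        if self.variant == "leaking":
            if not 0.0 <= self.k <= 1.0:
                raise ValueError(
                    f"leaking variant requires 0 <= k <= 1, got k={self.k}"
                )
        elif self.variant == "ricker":
            if not self.k > 0.0:
                raise ValueError(f"ricker variant requires k > 0, got k={self.k}")
        else:
            raise ValueError(f"unknown variant {self.variant!r}")


def _check_durations(*values) -> None:
    for v in values:
        if np.any(np.asarray(v) <= 0):
            raise ValueError("durations must be strictly positive (seconds)")


def leak_weight(d, t, k):
    """Exponential-decay distractor weight w = k**|d - t|.

    ``d`` and ``t`` are durations in seconds (scalars or arrays); ``k`` is the
    leaking factor in [0, 1].  Returns a weight in [0, 1].  The corner case
    k = 0 with d = t uses the convention 0**0 = 1 (a distractor identical to
    the target keeps full weight, which shifts nothing).
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"leaking factor must satisfy 0 <= k <= 1, got {k}")
    _check_durations(d, t)
    delta = np.abs(np.asarray(d, dtype=float) - np.asarray(t, dtype=float))
    w = float(k) ** delta  # 0.0 ** 0.0 == 1.0 both in Python and NumPy
    return w if w.ndim else float(w)


def ricker_weight(d, t, k):
    """Ricker-wavelet distractor weight implementing lateral inhibition.

    w = (1 - ((d - t)/k)**2) * 2**(-(d - t)**2 / k**2), k > 0 in seconds.

    Equals 1 at d = t, crosses zero exactly at |d - t| = k, is negative
    (repulsion) beyond, and decays to zero for |d - t| >> k.  The global
    minimum is ``RICKER_MIN_WEIGHT`` (about -0.2654) regardless of k.
    """
    if k <= 0:
        raise ValueError(f"ricker leaking factor must be > 0 seconds, got {k}")
    _check_durations(d, t)
    x = (np.asarray(d, dtype=float) - np.asarray(t, dtype=float)) / k
    x2 = x * x
    w = (1.0 - x2) * np.exp2(-x2)
    return w if w.ndim else float(w)


def weight(d, t, params: LeakParams):
    """Distractor weight under ``params.variant``."""
    if params.variant == "leaking":
        return leak_weight(d, t, params.k)
    return ricker_weight(d, t, params.k)


def perceived_duration(t, d, w):
    """Weighted-average perceived target duration (t + d*w) / (1 + w).

    ``w = 0`` returns the veridical target; ``w = 1`` the plain average of
    target and distractor.  Requires 1 + w > 0, which holds for both weight
    variants (w >= -0.266).
    """
    w = np.asarray(w, dtype=float)
    if np.any(1.0 + w <= 0):
        raise ValueError("perceived duration undefined for w <= -1")
    out = (np.asarray(t, dtype=float) + np.asarray(d, dtype=float) * w) / (1.0 + w)
    return out if out.ndim else float(out)


def p_second_longer(t1, d1, t2, d2, params: LeakParams):
    """Probability of judging the second target as longer.

    Each sequence i has target ``ti`` accompanied by homogeneous distractors
    of duration ``di``; the perceived targets are compared under standard
    Gaussian noise (zero mean, SD = 1 second):

        P = Phi(t_hat_2 - t_hat_1)

    The result is clamped to (EPS, 1 - EPS) so downstream log-likelihoods
    stay finite.
    """
    th1 = perceived_duration(t1, d1, weight(d1, t1, params))
    th2 = perceived_duration(t2, d2, weight(d2, t2, params))
    p = ndtr(np.asarray(th2) - np.asarray(th1))
    p = np.clip(p, EPS, 1.0 - EPS)
    return p if p.ndim else float(p)


def predict_increment(t, d_grid, params: LeakParams) -> np.ndarray:
    """Signed perceptual increment t_hat - t over a grid of distractor durations.

    Returns an array of shape (len(d_grid), 2) with columns (d, t_hat - t).
    The increment is zero at d = t, positive when the distractor attracts the
    percept upward, and (ricker variant only) negative for repulsive
    distractors on the long side of the target.
    """
    d_grid = np.atleast_1d(np.asarray(d_grid, dtype=float))
    if d_grid.size == 0:
        raise ValueError("d_grid must be non-empty")
    w = weight(d_grid, t, params)
    incr = perceived_duration(t, d_grid, w) - t
    return np.column_stack([d_grid, incr])
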