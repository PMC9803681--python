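"""Logistic psychometric-function fitting for binned 2AFC responses.

The proportion of "second interval lasted longer" responses is modelled as a
function of the signed stimulus difference x (second minus first, seconds):

    p(x) = lambda + (1 - 2*lambda) / (1 + exp(-beta * (x - alpha)))

alpha is the point of subjective equality (PSE, seconds), beta the logistic
rate (1/seconds, signed), and lambda a symmetric lapse rate bounded to
[0, LAPSE_MAX] applied at both asymptotes (appropriate for a two-interval
task with no guess asymmetry).  Fits maximize the binomial log-likelihood;
the lapse-free and lapse models are compared by AIC.  The latent standard
deviation of the psychometric function is derived from the slope as
pi / (|beta| * sqrt(3)), the SD of a logistic distribution with rate beta.

Confidence intervals come from a parametric bootstrap: per level, responses
are resampled Binomial(n, p_hat) and the selected model refitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln

__all__ = [
    "LAPSE_MAX",
    "BETA_MAX",
    "BinnedResponses",
    "PsychometricFit",
    "logistic_p",
    "fit_logistic",
    "select_by_aic",
    "derive_sd",
    "bootstrap_ci",
]

#: Upper bound of the symmetric lapse rate.
LAPSE_MAX = 0.1

#: Bound on |beta|; fits pinned here are flagged (perfect-separation data).
BETA_MAX = 500.0

_EPS = 1e-9
_ZERO_SLOPE_TOL = 1e-4


@dataclass(frozen=True)
class BinnedResponses:
    """Per-level response counts for one participant and condition.

    ``levels`` are signed stimulus differences in seconds (second minus
    first), strictly increasing; ``n`` trials and ``m`` "second longer"
    responses per level.
    """

    levels: np.ndarray
    n: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        n = np.asarray(self.n, dtype=int)
        m = np.asarray(self.m, dtype=int)
        if not (levels.ndim == 1 and levels.size == n.size == m.size):
            raise ValueError("levels, n, m must be 1-D arrays of equal length")
        if levels.size == 0 or np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be non-empty and strictly increasing")
        if np.any(n <= 0) or np.any(m < 0) or np.any(m > n):
            raise ValueError("counts must satisfy 0 <= m <= n with n > 0")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "m", m)

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood logistic fit with optional bootstrap intervals."""

    pse: float
    slope: float
    lapse: float
    sd: float
    loglik: float
    aic: float
    has_lapse: bool
    n_params: int
    converged: bool
    flags: tuple[str, ...] = ()
    ci_pse: tuple[float, float] | None = None
    ci_slope: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None


def logistic_p(x, pse: float, slope: float, lapse: float = 0.0):
    """Lapse-adjusted logistic psychometric function."""
    return lapse + (1.0 - 2.0 * lapse) * expit(slope * (np.asarray(x, float) - pse))


def _log_binom_const(data: BinnedResponses) -> float:
    n, m = data.n, data.m
    return float(np.sum(gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)))


def _nll(theta: np.ndarray, data: BinnedResponses, with_lapse: bool) -> float:
    lapse = theta[2] if with_lapse else 0.0
    p = logistic_p(data.levels, theta[0], theta[1], lapse)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -float(np.sum(data.m * np.log(p) + (data.n - data.m) * np.log1p(-p)))


def _nll_grad(
    theta: np.ndarray, data: BinnedResponses, with_lapse: bool
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its analytic gradient."""
    alpha, beta = theta[0], theta[1]
    lapse = theta[2] if with_lapse else 0.0
    x = data.levels
    sig = expit(beta * (x - alpha))
    p = np.clip(lapse + (1.0 - 2.0 * lapse) * sig, _EPS, 1.0 - _EPS)
    f = -float(np.sum(data.m * np.log(p) + (data.n - data.m) * np.log1p(-p)))
    dl_dp = data.m / p - (data.n - data.m) / (1.0 - p)
    core = (1.0 - 2.0 * lapse) * sig * (1.0 - sig)
    g_alpha = -float(np.sum(dl_dp * core * (-beta)))
    g_beta = -float(np.sum(dl_dp * core * (x - alpha)))
    if with_lapse:
        g_lapse = -float(np.sum(dl_dp * (1.0 - 2.0 * sig)))
        return f, np.array([g_alpha, g_beta, g_lapse])
    return f, np.array([g_alpha, g_beta])


def _start_grid(data: BinnedResponses) -> np.ndarray:
    lo, hi = data.levels[0], data.levels[-1]
    alphas = np.linspace(lo, hi, 5)
    betas = np.array([0.25, 1.0, 4.0, 16.0, 64.0])
    betas = np.concatenate([-betas[::-1], betas])
    grid = np.array([(a, b) for a in alphas for b in betas])
    return grid


def _separation(data: BinnedResponses) -> tuple[int, float] | None:
    """Detect perfect separation; returns (slope sign, cut midpoint) or None."""
    m, n = data.m, data.n
    for direction, lo_all_zero in ((1, m == 0), (-1, m == n)):
        hi_all_one = (m == n) if direction == 1 else (m == 0)
        for cut in range(1, data.n_levels):
            if lo_all_zero[:cut].all() and hi_all_one[cut:].all():
                mid = 0.5 * (data.levels[cut - 1] + data.levels[cut])
                return direction, float(mid)
    return None


def fit_logistic(
    data: BinnedResponses,
    with_lapse: bool = False,
    start: tuple[float, ...] | None = None,
) -> PsychometricFit:
    """Fit the logistic psychometric function by maximum likelihood.

    Multi-start over a coarse (PSE, slope) grid followed by bounded
    quasi-Newton (L-BFGS-B) refinement.  ``start`` replaces the grid with a
    single warm start (used by the bootstrap).  Requires at least 3 distinct
    levels, 4 when ``with_lapse``.  Never raises on poor data: degenerate or
    separated data produce a converged fit carrying warning ``flags``.
    """
    min_levels = 4 if with_lapse else 3
    if data.n_levels < min_levels:
        raise ValueError(
            f"need >= {min_levels} levels for with_lapse={with_lapse}, "
            f"got {data.n_levels}"
        )

    span = float(data.levels[-1] - data.levels[0])
    bounds = [
        (data.levels[0] - span, data.levels[-1] + span),
        (-BETA_MAX, BETA_MAX),
    ]
    if with_lapse:
        bounds.append((0.0, LAPSE_MAX))

    if start is not None:
        starts = np.atleast_2d(np.asarray(start, dtype=float))
        # near-flat data admit two near-equivalent optima related by the
        # reflection (pse, slope) -> (2*mid - pse, -slope); a warm start alone
        # traps refits on one side of slope = 0, so always offer the mirror
        mid = 0.5 * float(data.levels[0] + data.levels[-1])
        mirrored = starts.copy()
        mirrored[:, 0] = 2.0 * mid - mirrored[:, 0]
        mirrored[:, 1] = -mirrored[:, 1]
        starts = np.vstack([starts, mirrored])
    else:
        grid = _start_grid(data)
        if with_lapse:
            grid = np.column_stack([grid, np.full(len(grid), 0.02)])
        scores = np.array([_nll(theta, data, with_lapse) for theta in grid])
        starts = grid[np.argsort(scores)[:3]]

    best = None
    for theta0 in starts:
        res = minimize(
            _nll_grad,
            theta0,
            args=(data, with_lapse),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    pse, slope = float(theta[0]), float(theta[1])
    lapse = float(theta[2]) if with_lapse else 0.0
    n_params = 3 if with_lapse else 2
    loglik = -best.fun + _log_binom_const(data)
    aic = 2.0 * n_params - 2.0 * loglik

    flags: list[str] = []
    frac = data.m / data.n
    if np.all(data.m == 0) or np.all(data.m == data.n):
        flags.append("degenerate_data")
    sep = _separation(data)
    if sep is not None:
        # perfectly separated data: the likelihood increases without bound in
        # |beta|, so the MLE sits at the optimizer bound
        direction, cut = sep
        slope = direction * BETA_MAX
        pse = cut
        loglik = -_nll(
            np.array([pse, slope, lapse][: n_params]), data, with_lapse
        ) + _log_binom_const(data)
        aic = 2.0 * n_params - 2.0 * loglik
    if abs(slope) >= 0.999 * BETA_MAX:
        flags.append("slope_at_bound")
    if abs(slope) < _ZERO_SLOPE_TOL or np.allclose(frac, frac[0]):
        flags.append("flat_data")
    if not best.success:
        flags.append(f"optimizer: {best.message}")

    sd = derive_sd(slope)
    return PsychometricFit(
        pse=pse,
        slope=slope,
        lapse=lapse,
        sd=sd,
        loglik=float(loglik),
        aic=float(aic),
        has_lapse=with_lapse,
        n_params=n_params,
        converged=bool(best.success),
        flags=tuple(flags),
    )


def select_by_aic(
    fit_nolapse: PsychometricFit, fit_lapse: PsychometricFit
) -> PsychometricFit:
    """Keep the fit with the lower AIC; ties go to the fewer-parameter model."""
    if fit_lapse.aic < fit_nolapse.aic:
        return fit_lapse
    return fit_nolapse


def derive_sd(slope: float) -> float:
    """Latent SD of the psychometric function from its logistic rate.

    sd = pi / (|beta| * sqrt(3)): the standard deviation of a logistic
    distribution with rate beta.  A (near-)zero slope has no finite SD and
    returns NaN.
    """
    if abs(slope) < _ZERO_SLOPE_TOL:
        return float("nan")
    return float(np.pi / (abs(slope) * np.sqrt(3.0)))


def bootstrap_ci(
    data: BinnedResponses,
    fit: PsychometricFit,
    n_boot: int = 500,
    seed: int = 0,
) -> PsychometricFit:
    """Parametric-bootstrap 95% intervals for PSE and slope.

    Per level, responses are resampled m ~ Binomial(n, p_hat(level)) from the
    fitted curve and the same model refitted (warm-started at the fit);
    intervals are the 2.5/97.5 percentiles.  Deterministic given ``seed``.
    More than 10% failed refits flags the interval ``ci_unreliable``.
    """
    if n_boot <= 0:
        raise ValueError(f"n_boot must be positive, got {n_boot}")
    rng = np.random.default_rng(seed)
    p_hat = np.clip(
        logistic_p(data.levels, fit.pse, fit.slope, fit.lapse), _EPS, 1 - _EPS
    )
    start: tuple[float, ...] = (
        (fit.pse, fit.slope, fit.lapse) if fit.has_lapse else (fit.pse, fit.slope)
    )

    pses, slopes, failures = [], [], 0
    for _ in range(n_boot):
        m_b = rng.binomial(data.n, p_hat)
        boot = BinnedResponses(data.levels, data.n, m_b)
        try:
            refit = fit_logistic(boot, with_lapse=fit.has_lapse, start=start)
        except Exception:
            failures += 1
            continue
        if not refit.converged:
            failures += 1
            continue
        pses.append(refit.pse)
        slopes.append(refit.slope)

    flags = list(fit.flags)
    if failures > 0.1 * n_boot:
        flags.append("ci_unreliable")
    if not pses:
        return dataclasses.replace(
            fit, flags=tuple(flags), n_boot=n_boot, seed=seed
        )

    lo, hi = np.percentile(pses, [2.5, 97.5])
    slo, shi = np.percentile(slopes, [2.5, 97.5])
    return dataclasses.replace(
        fit,
        ci_pse=(float(lo), float(hi)),
        ci_slope=(float(slo), float(shi)),
        n_boot=n_boot,
        seed=seed,
        flags=tuple(flags),
    )


def fit_condition(
    data: BinnedResponses,
    n_boot: int = 500,
    seed: int = 0,
) -> PsychometricFit:
    """Full single-condition fit as used by the pipeline.

    Fits the lapse-free and (levels permitting) lapse models, keeps the AIC
    winner, and attaches bootstrap intervals.
    """
    fit0 = fit_logistic(data, with_lapse=False)
    if data.n_levels >= 4:
        fit1 = fit_logistic(data, with_lapse=True)
        chosen = select_by_aic(fit0, fit1)
    else:
        chosen = fit0
    return bootstrap_ci(data, chosen, n_boot=n_boot, seed=seed)
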