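"""Coupled logistic growth dynamics with signed polynomial interaction terms.

The model couples the cumulative search index ``x1`` and cumulative
consultation index ``x2`` through impact functions built from six structural
factors per equation (each variable at most quadratic)::

    dx1/dt = r1 * x1 * (1 - x1/K1) + f1(x1, x2)
    dx2/dt = r2 * x2 * (1 - x2/K2) + f2(x1, x2)

where ``f1`` is a signed linear combination of
``{x2, x2^2, x1*x2, x1*x2^2, x1^2*x2, x1^2*x2^2}`` (every term carries the
partner variable ``x2``) and ``f2`` of the mirror set
``{x1, x1^2, x1*x2, x1^2*x2, x1*x2^2, x1^2*x2^2}``.

Two integration schemes are provided: the lagged-state difference scheme
(forward Euler with daily step, increments floored at zero, matching the
estimator's design matrix exactly) and a fixed-step RK4 integration of the
underlying ODE.  On top of the deterministic core sit a noisy single-region
simulator and a multi-region ensemble generator that emulate observed daily
index data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import BehaviorSeries, CumulativePair

__all__ = [
    "SEARCH_FACTORS",
    "CONSULT_FACTORS",
    "ModelParams",
    "NoiseSpec",
    "SimulationError",
    "evaluate_factors",
    "predation_preset",
    "single_factor_preset",
    "simulate_deterministic",
    "simulate_noisy",
    "generate_ensemble",
    "draw_region_params",
]

#: Structural factors of the search-equation impact function f1 (canonical order).
SEARCH_FACTORS: tuple[str, ...] = ("x2", "x2^2", "x1*x2", "x1*x2^2", "x1^2*x2", "x1^2*x2^2")
#: Structural factors of the consultation-equation impact function f2.
CONSULT_FACTORS: tuple[str, ...] = ("x1", "x1^2", "x1*x2", "x1^2*x2", "x1*x2^2", "x1^2*x2^2")

_FACTOR_FUNCS = {
    "x1": lambda x1, x2: x1,
    "x2": lambda x1, x2: x2,
    "x1^2": lambda x1, x2: x1 * x1,
    "x2^2": lambda x1, x2: x2 * x2,
    "x1*x2": lambda x1, x2: x1 * x2,
    "x1*x2^2": lambda x1, x2: x1 * x2 * x2,
    "x1^2*x2": lambda x1, x2: x1 * x1 * x2,
    "x1^2*x2^2": lambda x1, x2: x1 * x1 * x2 * x2,
}


def evaluate_factors(names: tuple[str, ...], x1, x2) -> np.ndarray:
    """Evaluate the named structural factors at state ``(x1, x2)``.

    Accepts scalars or arrays; returns an array whose leading axis indexes
    the factors.
    """
    return np.asarray([_FACTOR_FUNCS[name](np.asarray(x1, float), np.asarray(x2, float)) for name in names])


class SimulationError(RuntimeError):
    """Raised when a trajectory leaves the finite range (overflow)."""


@dataclass
class ModelParams:
    """Parameters of the coupled logistic interaction model.

    ``a`` and ``b`` are coefficient vectors over :data:`SEARCH_FACTORS` and
    :data:`CONSULT_FACTORS` respectively; a zero entry means the factor is
    absent from the impact function.
    """

    r1: float
    r2: float
    K1: float
    K2: float
    a: np.ndarray = field(default_factory=lambda: np.zeros(6))
    b: np.ndarray = field(default_factory=lambda: np.zeros(6))
    x1_0: float = 1.0
    x2_0: float = 1.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (6,) or self.b.shape != (6,):
            raise ValueError("a and b must be length-6 coefficient vectors")
        if min(self.r1, self.r2, self.K1, self.K2) <= 0:
            raise ValueError("growth rates and carrying capacities must be positive")
        if self.x1_0 < 0 or self.x2_0 < 0:
            raise ValueError("initial values must be nonnegative")

    def rates(self, x1: float, x2: float) -> tuple[float, float]:
        """Right-hand sides of the two equations at state ``(x1, x2)``."""
        # overflow in a diverging trajectory surfaces as SimulationError, not warnings
        with np.errstate(over="ignore", invalid="ignore"):
            f1 = float(self.a @ evaluate_factors(SEARCH_FACTORS, x1, x2))
            f2 = float(self.b @ evaluate_factors(CONSULT_FACTORS, x1, x2))
            d1 = self.r1 * x1 * (1.0 - x1 / self.K1) + f1
            d2 = self.r2 * x2 * (1.0 - x2 / self.K2) + f2
        return d1, d2


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian observation noise on daily increments.

    ``sigma_frac`` is the noise standard deviation as a fraction of the
    corresponding carrying capacity; zero reproduces the deterministic
    trajectory exactly.
    """

    sigma_frac: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_frac < 0:
            raise ValueError("sigma_frac must be nonnegative")


def predation_preset() -> ModelParams:
    """Default generating preset with the predation sign structure.

    f1 = a1*x2^2 + a2*x1^2*x2 with a1 > 0, a2 < 0 (consultation inhibits
    search); f2 = b1*x1*x2 + b2*x1*x2^2 + b3*x1^2*x2 with b1, b2 > 0 and
    b3 < 0 (search promotes consultation).  Magnitudes are chosen so each
    interaction term is roughly 5-30% of the logistic term at mid-growth.
    """
    a = np.zeros(6)
    b = np.zeros(6)
    a[SEARCH_FACTORS.index("x2^2")] = 5.0e-6
    a[SEARCH_FACTORS.index("x1^2*x2")] = -7.0e-11
    b[CONSULT_FACTORS.index("x1*x2")] = 1.0e-6
    b[CONSULT_FACTORS.index("x1*x2^2")] = 6.0e-11
    b[CONSULT_FACTORS.index("x1^2*x2")] = -1.2e-11
    return ModelParams(r1=0.3, r2=0.3, K1=5.0e4, K2=2.0e4, a=a, b=b, x1_0=50.0, x2_0=20.0)


def single_factor_preset() -> ModelParams:
    """Preset with a single positive x1^2*x2^2 factor in each equation.

    Emulates a quieter, normalized period in which the only retained
    interaction is mutual reinforcement through the joint quadratic factor.
    """
    a = np.zeros(6)
    b = np.zeros(6)
    a[SEARCH_FACTORS.index("x1^2*x2^2")] = 1.0e-15
    b[CONSULT_FACTORS.index("x1^2*x2^2")] = 6.0e-16
    return ModelParams(r1=0.3, r2=0.3, K1=5.0e4, K2=2.0e4, a=a, b=b, x1_0=50.0, x2_0=20.0)


def _simulate_difference(params: ModelParams, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.empty(n_days)
    x2 = np.empty(n_days)
    x1[0], x2[0] = params.x1_0, params.x2_0
    for n in range(1, n_days):
        d1, d2 = params.rates(x1[n - 1], x2[n - 1])
        x1[n] = x1[n - 1] + max(d1, 0.0)
        x2[n] = x2[n - 1] + max(d2, 0.0)
        if not (math.isfinite(x1[n]) and math.isfinite(x2[n])):
            raise SimulationError(f"non-finite state at day {n + 1}; check parameter magnitudes")
    return x1, x2


def _simulate_rk4(params: ModelParams, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.empty(n_days)
    x2 = np.empty(n_days)
    x1[0], x2[0] = params.x1_0, params.x2_0
    h = 1.0
    for n in range(1, n_days):
        u, v = x1[n - 1], x2[n - 1]
        k1 = params.rates(u, v)
        k2 = params.rates(u + 0.5 * h * k1[0], v + 0.5 * h * k1[1])
        k3 = params.rates(u + 0.5 * h * k2[0], v + 0.5 * h * k2[1])
        k4 = params.rates(u + h * k3[0], v + h * k3[1])
        x1[n] = u + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        x2[n] = v + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if not (math.isfinite(x1[n]) and math.isfinite(x2[n])):
            raise SimulationError(f"non-finite state at day {n + 1}; check parameter magnitudes")
    return x1, x2


def simulate_deterministic(
    params: ModelParams, n_days: int, scheme: str = "difference", region_id: str = "sim"
) -> CumulativePair:
    """Forward-simulate the deterministic coupled model for ``n_days`` days.

    ``scheme='difference'`` applies the lagged-state daily recursion
    ``x(n) = x(n-1) + max(0, rhs(x(n-1)))``; ``scheme='ode-rk4'`` integrates
    the continuous system with fixed-step classical RK4 (step = 1 day).
    """
    if n_days < 2:
        raise ValueError("n_days must be at least 2")
    if scheme == "difference":
        x1, x2 = _simulate_difference(params, n_days)
    elif scheme == "ode-rk4":
        x1, x2 = _simulate_rk4(params, n_days)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'difference' or 'ode-rk4'")
    return CumulativePair(region_id=region_id, days=np.arange(1, n_days + 1), x1=x1, x2=x2)


def deterministic_daily(params: ModelParams, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """Daily index values implied by the difference scheme.

    Day 1 carries the initial cumulative value; later days carry the daily
    increments, so prefix sums reproduce the cumulative trajectories exactly.
    """
    pair = simulate_deterministic(params, n_days, scheme="difference")
    d1 = np.concatenate(([pair.x1[0]], np.diff(pair.x1)))
    d2 = np.concatenate(([pair.x2[0]], np.diff(pair.x2)))
    return d1, d2


def simulate_noisy(
    params: ModelParams, n_days: int, noise: NoiseSpec, region_id: str = "sim"
) -> BehaviorSeries:
    """Simulate one region's observed daily series with additive noise.

    Gaussian noise with sd ``sigma_frac * K`` (per channel) is added to every
    deterministic daily value and the result truncated below at zero.  The
    output is a pure function of ``(params, n_days, noise)``.
    """
    d1, d2 = deterministic_daily(params, n_days)
    rng = np.random.default_rng(noise.seed)
    if noise.sigma_frac > 0:
        d1 = d1 + rng.normal(0.0, noise.sigma_frac * params.K1, size=n_days)
        d2 = d2 + rng.normal(0.0, noise.sigma_frac * params.K2, size=n_days)
    d1 = np.maximum(d1, 0.0)
    d2 = np.maximum(d2, 0.0)
    return BehaviorSeries(
        region_id=region_id, days=np.arange(1, n_days + 1), search_daily=d1, consult_daily=d2
    )


_MAX_JITTER_RETRIES = 100


def jitter_params(base: ModelParams, heterogeneity: float, rng: np.random.Generator) -> ModelParams:
    """Draw one region's parameters by multiplicative lognormal jitter.

    Rates, capacities, initial values and the magnitudes of the interaction
    coefficients are each multiplied by an independent lognormal factor with
    relative sd ``heterogeneity``; signs of ``a`` and ``b`` are preserved.
    """
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be nonnegative")
    if heterogeneity == 0:
        return replace(base)
    # lognormal with unit mean and relative sd = heterogeneity
    sigma = math.sqrt(math.log1p(heterogeneity**2))
    mu = -0.5 * sigma**2

    def draw(size=None):
        return np.exp(rng.normal(mu, sigma, size=size))

    for _ in range(_MAX_JITTER_RETRIES):
        try:
            return ModelParams(
                r1=base.r1 * draw(),
                r2=base.r2 * draw(),
                K1=base.K1 * draw(),
                K2=base.K2 * draw(),
                a=base.a * draw(6),
                b=base.b * draw(6),
                x1_0=base.x1_0 * draw(),
                x2_0=base.x2_0 * draw(),
            )
        except ValueError:  # pragma: no cover - lognormal jitter keeps positivity
            continue
    raise RuntimeError("could not draw valid jittered parameters")


def draw_region_params(
    base: ModelParams, n_regions: int, heterogeneity: float, seed: int
) -> list[ModelParams]:
    """Seeded per-region parameter draws (lognormal jitter of ``base``)."""
    if n_regions < 1:
        raise ValueError("n_regions must be at least 1")
    param_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    return [jitter_params(base, heterogeneity, param_rng) for _ in range(n_regions)]


def generate_ensemble(
    base: ModelParams,
    n_regions: int = 32,
    heterogeneity: float = 0.06,
    n_days: int = 61,
    noise: NoiseSpec = NoiseSpec(),
) -> list[BehaviorSeries]:
    """Generate a multi-region synthetic ensemble of daily index series.

    Each region's parameters are a seeded lognormal jitter of ``base`` (sign
    pattern of the interaction coefficients preserved); observation noise is
    drawn from per-region substreams of ``noise.seed``.  Default shape (32
    regions x 61 days) mirrors a two-month multi-province study window.
    The region parameters are reproducible via :func:`draw_region_params`
    with ``seed = noise.seed``.
    """
    region_params = draw_region_params(base, n_regions, heterogeneity, noise.seed)
    noise_seeds = np.random.SeedSequence(noise.seed, spawn_key=(1,)).generate_state(n_regions)
    out = []
    for i, params_i in enumerate(region_params):
        noise_i = NoiseSpec(sigma_frac=noise.sigma_frac, seed=int(noise_seeds[i] % (2**31)))
        out.append(simulate_noisy(params_i, n_days, noise_i, region_id=f"region{i + 1:02d}"))
    return out
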