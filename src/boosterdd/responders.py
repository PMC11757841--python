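"""Simulated choice agents for the titration task.

A responder carries a subjective-value model (hyperbolic V = A/(1+kD),
exponential V = A·exp(−kD), a fixed currency threshold, or the two constant
strategies) and a logistic choice rule.  With temperature 0 the agent is
deterministic — immediate iff the offer is at least the subjective value, ties
going to the immediate option — and with temperature τ > 0 it chooses the
immediate reward with probability expit((offer − V)/τ), which recovers the
deterministic rule continuously as τ → 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ConfigurationError, DomainError
from .titration import Choice

__all__ = [
    "ResponderModel",
    "ResponderParams",
    "Responder",
    "PopulationSpec",
    "subjective_value",
    "choose",
    "sample_population",
]


class ResponderModel(str, Enum):
    HYPERBOLIC = "hyperbolic"
    EXPONENTIAL = "exponential"
    FIXED_THRESHOLD = "fixed_threshold"
    ALWAYS_IMMEDIATE = "always_immediate"
    ALWAYS_DELAYED = "always_delayed"


@dataclass(frozen=True, slots=True)
class ResponderParams:
    model: ResponderModel = ResponderModel.HYPERBOLIC
    k: float = 0.01  # per-day discount rate (hyperbolic / exponential)
    threshold: float = 1000.0  # currency (fixed_threshold)
    temperature: float = 0.0  # 0 => deterministic

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError(f"discount rate k must be >= 0, got {self.k}")
        if self.threshold < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.threshold}")
        if self.temperature < 0:
            raise ConfigurationError(f"temperature must be >= 0, got {self.temperature}")


def subjective_value(params: ResponderParams, amount: float, days: float) -> float:
    """Discounted value of ``amount`` at delay ``days`` under the agent's model."""
    if not amount > 0:
        raise DomainError(f"amount must be positive, got {amount}")
    if days < 0:
        raise DomainError(f"days must be >= 0, got {days}")
    m = params.model
    if m is ResponderModel.HYPERBOLIC:
        return amount / (1.0 + params.k * days)
    if m is ResponderModel.EXPONENTIAL:
        return amount * math.exp(-params.k * days)
    if m is ResponderModel.FIXED_THRESHOLD:
        return params.threshold
    if m is ResponderModel.ALWAYS_IMMEDIATE:
        return 0.0  # any positive offer beats the delayed reward
    if m is ResponderModel.ALWAYS_DELAYED:
        return math.inf  # no finite offer is accepted
    raise ConfigurationError(f"unknown responder model {m!r}")


def choose(
    params: ResponderParams,
    offer: float,
    amount: float,
    days: float,
    rng: np.random.Generator | None = None,
) -> Choice:
    """One intertemporal decision.

    Deterministic branch (temperature 0): immediate iff offer >= subjective
    value.  Stochastic branch: immediate with probability
    expit((offer − V)/temperature); the generator is consumed only here.
    """
    v = subjective_value(params, amount, days)
    if params.temperature == 0.0:
        return Choice.IMMEDIATE if offer >= v else Choice.DELAYED
    if rng is None:
        raise ConfigurationError("a Generator is required when temperature > 0")
    if math.isinf(v):
        p_immediate = 0.0
    else:
        z = (offer - v) / params.temperature
        p_immediate = 1.0 / (1.0 + math.exp(-z)) if abs(z) < 700 else (1.0 if z > 0 else 0.0)
    return Choice.IMMEDIATE if rng.random() < p_immediate else Choice.DELAYED


class Responder:
    """Binds params (and a generator, for stochastic agents) to ``choose``.

    Satisfies the responder protocol expected by ``titration.run_condition``.
    """

    def __init__(self, params: ResponderParams, rng: np.random.Generator | None = None):
        self.params = params
        self.rng = rng

    def choose(self, offer: float, amount: float, days: float) -> Choice:
        return choose(self.params, offer, amount, days, self.rng)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Responder({self.params})"


@dataclass(frozen=True, slots=True)
class PopulationSpec:
    """A population of discounting agents: log10 k ~ Normal(mu, sigma)."""

    n: int = 100
    model: ResponderModel = ResponderModel.HYPERBOLIC
    log10k_mu: float = -2.2
    log10k_sigma: float = 0.6
    temperature: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"population size must be >= 0, got {self.n}")
        if self.log10k_sigma < 0:
            raise ConfigurationError("log10k_sigma must be >= 0")


def sample_population(spec: PopulationSpec, rng: np.random.Generator) -> list[ResponderParams]:
    """Draw per-agent discount rates; seeded runs are bit-reproducible."""
    log10k = rng.normal(spec.log10k_mu, spec.log10k_sigma, size=spec.n)
    return [
        ResponderParams(model=spec.model, k=float(10.0**lk), temperature=spec.temperature)
        for lk in log10k
    ]
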