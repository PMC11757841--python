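"""Adjusting-amount delay-discounting titration.

Each condition offers repeated choices between a smaller immediate reward and
a fixed larger-later reward (default $2,000) at one delay.  The immediate
offer starts at half the delayed amount; it rises after a "delayed" choice and
falls after an "immediate" choice, and the adjustment is always half of the
previous one.  After the final (sixth) choice the offer that *would* have been
presented on a hypothetical seventh trial is taken as the indifference point:
the immediate amount subjectively equivalent to the delayed reward.

With the $1,000/$2,000 defaults the adjustment sequence is
500, 250, 125, 62.5, 31.25, 15.625, so every estimate lies on a grid of width
15.625 inside [15.625, 1984.375] and the estimate is within one half-step of
any deterministic responder's true subjective value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Protocol, Sequence, runtime_checkable

from .errors import ConfigurationError, ProtocolError, StateError

__all__ = [
    "Choice",
    "DelayCondition",
    "DEFAULT_DELAYS",
    "TaskConfig",
    "TrialRecord",
    "TitrationState",
    "IndifferencePoint",
    "initial_state",
    "apply_choice",
    "indifference_point",
    "run_condition",
    "run_task",
]


class Choice(str, Enum):
    """A single intertemporal decision, logged as ``I`` or ``D``."""

    IMMEDIATE = "I"
    DELAYED = "D"


@dataclass(frozen=True, slots=True)
class DelayCondition:
    """One delay to the larger-later reward.

    ``days`` is the numeric value used downstream for curve normalization;
    the label is what a participant would see.
    """

    label: str
    days: float

    def __post_init__(self) -> None:
        if not self.days > 0:
            raise ConfigurationError(f"delay {self.label!r} must have days > 0, got {self.days}")


#: Conventional day-values for the seven standard delay labels.
DEFAULT_DELAYS: tuple[DelayCondition, ...] = (
    DelayCondition("1 week", 7),
    DelayCondition("1 month", 30),
    DelayCondition("3 months", 90),
    DelayCondition("6 months", 180),
    DelayCondition("1 year", 365),
    DelayCondition("3 years", 1095),
    DelayCondition("10 years", 3650),
)


@dataclass(frozen=True, slots=True)
class TaskConfig:
    """Parameters of the adjusting-amount task.

    Parameters
    ----------
    delayed_amount
        The fixed larger-later reward (currency units).
    initial_immediate
        The first immediate offer; must lie strictly between 0 and
        ``delayed_amount``.
    n_trials
        Number of choices per delay condition.
    delays
        Delay conditions in strictly increasing day order.
    currency_precision
        Decimal places kept on presented offers; ``None`` (default) keeps full
        numeric precision, which preserves the exact halving sequence
        (62.5, 31.25, ...).
    """

    delayed_amount: float = 2000.0
    initial_immediate: float = 1000.0
    n_trials: int = 6
    delays: tuple[DelayCondition, ...] = DEFAULT_DELAYS
    currency_precision: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.initial_immediate < self.delayed_amount:
            raise ConfigurationError(
                "require 0 < initial_immediate < delayed_amount, got "
                f"{self.initial_immediate} / {self.delayed_amount}"
            )
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1, got {self.n_trials}")
        if len(self.delays) == 0:
            raise ConfigurationError("at least one delay condition is required")
        days = [d.days for d in self.delays]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("delays must be strictly increasing in day-value")
        labels = [d.label for d in self.delays]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("delay labels must be unique")

    @property
    def step_min(self) -> float:
        """Smallest applied adjustment = (A − I) / 2**n_trials (15.625 at defaults)."""
        return (self.delayed_amount - self.initial_immediate) / 2**self.n_trials

    def _round(self, offer: float) -> float:
        if self.currency_precision is None:
            return offer
        return round(offer, self.currency_precision)


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """One logged decision: the offer presented and the choice made."""

    delay: DelayCondition
    trial_index: int  # 1-based
    immediate_offer: float
    choice: Choice


@dataclass(frozen=True, slots=True)
class TitrationState:
    """Evolving offer/step pair for one delay condition.

    ``current_offer`` is the immediate amount that will be presented on the
    next trial; ``current_step`` is the adjustment that the next choice will
    trigger.  After ``t`` applied choices the step equals
    ``(delayed_amount − initial_immediate) / 2**(t+1)``.
    """

    config: TaskConfig
    delay: DelayCondition
    current_offer: float
    current_step: float
    history: tuple[TrialRecord, ...] = field(default_factory=tuple)

    @property
    def trials_done(self) -> int:
        return len(self.history)


@dataclass(frozen=True, slots=True)
class IndifferencePoint:
    """Estimated subjective value of the delayed reward at one delay."""

    delay: DelayCondition
    subjective_value: float


def initial_state(config: TaskConfig, delay: DelayCondition) -> TitrationState:
    """Start a condition: offer = initial_immediate, step = half the gap."""
    return TitrationState(
        config=config,
        delay=delay,
        current_offer=config._round(config.initial_immediate),
        current_step=(config.delayed_amount - config.initial_immediate) / 2.0,
    )


def _coerce_choice(choice: object) -> Choice:
    if isinstance(choice, Choice):
        return choice
    if isinstance(choice, str):
        try:
            return Choice(choice)
        except ValueError:
            try:
                return Choice[choice.upper()]
            except KeyError:
                pass
    raise ProtocolError(f"choice must be Choice.IMMEDIATE/'I' or Choice.DELAYED/'D', got {choice!r}")


def apply_choice(state: TitrationState, choice: Choice | str) -> TitrationState:
    """Record one choice and move the offer by the current step.

    A "delayed" choice means the standing offer was too small, so the offer
    increases; an "immediate" choice decreases it.  The step then halves.
    Returns a new state; the input is untouched.
    """
    cfg = state.config
    if state.trials_done >= cfg.n_trials:
        raise StateError(
            f"condition {state.delay.label!r} already has {cfg.n_trials} trials; "
            "no further choices can be applied"
        )
    choice = _coerce_choice(choice)
    record = TrialRecord(
        delay=state.delay,
        trial_index=state.trials_done + 1,
        immediate_offer=state.current_offer,
        choice=choice,
    )
    direction = 1.0 if choice is Choice.DELAYED else -1.0
    return TitrationState(
        config=cfg,
        delay=state.delay,
        current_offer=cfg._round(state.current_offer + direction * state.current_step),
        current_step=state.current_step / 2.0,
        history=state.history + (record,),
    )


def indifference_point(state: TitrationState) -> IndifferencePoint:
    """Offer of the hypothetical next trial after the final choice.

    ``apply_choice`` already moves the offer once more in the direction implied
    by each choice, so after ``n_trials`` choices ``current_offer`` *is* the
    hypothetical seventh-trial offer — the final presented offer adjusted by
    half of the last applied step.
    """
    cfg = state.config
    if state.trials_done != cfg.n_trials:
        raise StateError(
            f"condition {state.delay.label!r} incomplete: "
            f"{state.trials_done}/{cfg.n_trials} trials done"
        )
    return IndifferencePoint(delay=state.delay, subjective_value=state.current_offer)


@runtime_checkable
class SupportsChoose(Protocol):
    def choose(self, offer: float, amount: float, days: float) -> Choice: ...


def run_condition(
    responder: SupportsChoose,
    config: TaskConfig,
    delay: DelayCondition,
) -> tuple[IndifferencePoint, list[TrialRecord]]:
    """Drive one delay condition with a responder's decisions."""
    if not hasattr(responder, "choose"):
        raise ProtocolError(f"responder {responder!r} does not implement choose()")
    state = initial_state(config, delay)
    for _ in range(config.n_trials):
        choice = responder.choose(state.current_offer, config.delayed_amount, delay.days)
        state = apply_choice(state, choice)
    return indifference_point(state), list(state.history)


def run_task(
    responder: SupportsChoose,
    config: TaskConfig = TaskConfig(),
    *,
    presentation_order: Sequence[int] | None = None,
):
    """Run all delay conditions and assemble a discounting profile.

    ``presentation_order`` optionally permutes the order in which conditions
    are administered (indices into ``config.delays``); the returned profile
    always lists indifference points in ascending delay order, and the AuC is
    invariant to presentation order.
    """
    from .metrics import DiscountProfile  # local import: metrics builds on this module

    order = list(presentation_order) if presentation_order is not None else list(range(len(config.delays)))
    if sorted(order) != list(range(len(config.delays))):
        raise ConfigurationError("presentation_order must be a permutation of the delay indices")
    points: dict[int, IndifferencePoint] = {}
    log: list[TrialRecord] = []
    for idx in order:
        pt, records = run_condition(responder, config, config.delays[idx])
        points[idx] = pt
        log.extend(records)
    ordered = tuple(points[i] for i in range(len(config.delays)))
    return DiscountProfile(points=ordered, delayed_amount=config.delayed_amount, trial_log=tuple(log))
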