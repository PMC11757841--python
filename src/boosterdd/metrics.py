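"""Discounting-curve normalization and the Area-under-the-Curve statistic.

The AuC construction: plot subjective value against delay with both axes
normalized — delay as a fraction of the maximum delay, value as a fraction of
the delayed amount — prepend the anchor (0, 1) (zero delay, no discounting),
and sum trapezoids.  The result lies in (0, 1]: 1 for a non-discounter, near 0
for extreme discounting.  A hyperbolic fit V = A/(1 + kD) is provided for
parameter-recovery checks; the headline statistic is the model-free AuC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DomainError, FitError
from .titration import IndifferencePoint, TrialRecord

__all__ = ["DiscountProfile", "normalize", "auc", "fit_hyperbolic"]


@dataclass(frozen=True)
class DiscountProfile:
    """A participant's indifference points (ascending delay) plus trial log."""

    points: tuple[IndifferencePoint, ...]
    delayed_amount: float
    trial_log: tuple[TrialRecord, ...] = ()

    @property
    def days(self) -> np.ndarray:
        return np.array([p.delay.days for p in self.points], dtype=float)

    @property
    def subjective_values(self) -> np.ndarray:
        return np.array([p.subjective_value for p in self.points], dtype=float)

    @property
    def auc(self) -> float:
        return auc(self)


def normalize(profile: DiscountProfile) -> np.ndarray:
    """Normalized curve coordinates, anchor (0, 1) prepended.

    Returns an ``(n_points + 1, 2)`` array of (delay fraction, value fraction);
    x is delay / max delay, y is subjective value / delayed amount.
    """
    if len(profile.points) < 1:
        raise DomainError("profile has no indifference points")
    if not profile.delayed_amount > 0:
        raise DomainError(f"delayed_amount must be positive, got {profile.delayed_amount}")
    days = profile.days
    if np.any(np.diff(days) <= 0):
        raise DomainError("delays must be strictly increasing")
    x = days / days[-1]
    y = profile.subjective_values / profile.delayed_amount
    return np.column_stack([np.concatenate([[0.0], x]), np.concatenate([[1.0], y])])


def auc(profile: DiscountProfile) -> float:
    """Trapezoidal area under the normalized discounting curve, in (0, 1]."""
    xy = normalize(profile)
    return float(np.trapezoid(xy[:, 1], xy[:, 0]))


def fit_hyperbolic(profile: DiscountProfile) -> float:
    """Least-squares per-day discount rate k in V = A/(1 + kD), k >= 0.

    Minimizes the sum of squared residuals over the profile's indifference
    points.  A flat profile at the delayed amount yields k = 0.
    """
    if len(profile.points) < 2:
        raise DomainError("need at least 2 points to fit a discount rate")
    days = profile.days
    sv = profile.subjective_values
    amount = profile.delayed_amount

    def residuals(logk: np.ndarray) -> np.ndarray:
        return amount / (1.0 + np.exp(logk[0]) * days) - sv

    # Crude moment start: invert the hyperbola at each point, guard degeneracy.
    with np.errstate(divide="ignore", invalid="ignore"):
        k0 = np.nanmedian(np.clip((amount / np.clip(sv, 1e-9, None) - 1.0) / days, 1e-12, None))
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 1e-12
    sol = optimize.least_squares(residuals, x0=[np.log(k0)], method="lm", max_nfev=2000)
    if not np.isfinite(sol.cost):
        raise FitError(f"hyperbolic fit produced a non-finite optimum: {sol}")
    k = float(np.exp(sol.x[0]))
    # log-parameterization keeps k positive; collapse numerically-zero rates
    return 0.0 if k < 1e-10 else k
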