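"""Cumulative drug-release model, fitting, and the box-car release source.

Cargo release from the nanocarrier is described by the one-parameter-shape
Weibull law

    C(t) = a * (1 - exp(-(k t)^d)),   d = 1 by default,

with ``a`` the plateau cumulative release (% of load) and ``k`` the release
rate constant (1/min).  The ``d = 1`` special case is the first-order release
law used for all default analyses; a general shape exponent is exposed for
sensitivity studies.

For the transport model the release is idealised as a Heaviside box: a
constant mass rate ``dose / tau`` over the half-open interval ``[0, tau)``,
zero afterwards, so the time integral equals the dose exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .delivery_modes import DeliveryScenario

__all__ = [
    "ReleaseFit",
    "ReleaseSource",
    "FitError",
    "weibull_cumulative",
    "time_to_fraction",
    "fit_release",
    "release_source",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed on the given data."""


@dataclass(frozen=True)
class ReleaseFit:
    """Result of fitting the cumulative-release law to data.

    Attributes
    ----------
    a : float
        Plateau cumulative release, % of load.
    k : float
        Release rate constant, 1/min.
    se_a, se_k : float
        Asymptotic standard errors from the Jacobian at the optimum.
    rss : float
        Residual sum of squares.
    n_points : int
        Number of data points used.
    """

    a: float
    k: float
    se_a: float
    se_k: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 < self.a <= 100.0):
            raise ValueError(f"plateau a must be in (0, 100], got {self.a}")
        if self.k <= 0.0:
            raise ValueError(f"rate constant k must be > 0, got {self.k}")


def weibull_cumulative(
    t: float | np.ndarray, a: float, k: float, d: float = 1.0
) -> float | np.ndarray:
    """Cumulative release ``a * (1 - exp(-(k t)^d))`` at time ``t`` (min).

    Monotone non-decreasing in ``t`` and bounded by the plateau ``a``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("release times must be non-negative")
    if a <= 0.0 or k <= 0.0 or d <= 0.0:
        raise ValueError("a, k and d must all be > 0")
    out = a * (1.0 - np.exp(-((k * t_arr) ** d)))
    return float(out) if np.isscalar(t) else out


def time_to_fraction(k: float, frac: float, d: float = 1.0) -> float:
    """Time (min) at which the release reaches ``frac`` of its plateau.

    Inverse of :func:`weibull_cumulative` at fixed plateau:
    ``t = (-ln(1 - frac))^(1/d) / k``.
    """
    if k <= 0.0:
        raise ValueError("rate constant k must be > 0")
    if not (0.0 <= frac < 1.0):
        raise ValueError("fraction must satisfy 0 <= frac < 1 "
                         "(the plateau is reached only asymptotically)")
    if frac == 0.0:
        return 0.0
    return float((-np.log1p(-frac)) ** (1.0 / d) / k)


def fit_release(
    times: Sequence[float],
    observed: Sequence[float],
    weights: Sequence[float] | None = None,
    d: float = 1.0,
) -> ReleaseFit:
    """Fit the cumulative-release law to (time, cumulative %) data.

    Nonlinear least squares over ``(a, k)`` with the shape exponent ``d``
    held fixed.  Initial values: ``a0 = max(observed)``, ``k0`` from a
    log-linear regression of ``1 - C/a0``.  Standard errors are the
    asymptotic ones from the Jacobian at the optimum.

    Raises
    ------
    FitError
        For degenerate data (fewer than 3 points, all-zero signal, or a
        diverging fit).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(observed, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and observed must be 1-D arrays of equal length")
    if t.size < 3:
        raise FitError("need at least 3 data points to fit (a, k)")
    if np.any(t < 0.0):
        raise ValueError("release times must be non-negative")
    if np.ptp(t) == 0.0:
        raise FitError("all sample times are equal; k is not identifiable")
    if np.all(y <= 0.0):
        raise FitError("observed release is identically <= 0; nothing to fit")

    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))

    a0 = float(np.max(y))
    # log-linear slope of the remaining fraction gives a starting rate;
    # guard against the plateau points where 1 - C/a0 <= 0
    frac_left = 1.0 - y / (a0 * 1.05)
    ok = frac_left > 1e-6
    if ok.sum() >= 2 and np.ptp(t[ok]) > 0:
        slope = np.polyfit(t[ok], np.log(frac_left[ok]), 1)[0]
        k0 = max(-float(slope), 1e-3)
    else:
        k0 = 1.0 / max(float(np.median(t[t > 0])), 1e-6)

    def resid(theta: np.ndarray) -> np.ndarray:
        a, k = theta
        return w * (a * (1.0 - np.exp(-((k * t) ** d))) - y)

    sol = least_squares(
        resid,
        x0=[a0, k0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitError(f"release fit did not converge: {sol.message}")

    a_hat, k_hat = map(float, sol.x)
    rss = float(np.sum(sol.fun**2))
    dof = max(t.size - 2, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se_a, se_k = (float(np.sqrt(max(cov[i, i], 0.0))) for i in range(2))
    except np.linalg.LinAlgError:
        se_a = se_k = float("nan")

    return ReleaseFit(a=min(a_hat, 100.0), k=k_hat, se_a=se_a, se_k=se_k,
                      rss=rss, n_points=int(t.size))


@dataclass(frozen=True)
class ReleaseSource:
    """Box-car (Heaviside) release source for one delivery scenario.

    ``local(t)`` is the mass rate released into the target-organ capillary
    plasma and ``systemic(t)`` the mass rate entering the systemic
    compartment, both in dose units per minute.  Each is
    ``dose_component / tau`` on ``[0, tau)`` and zero elsewhere, so the
    integral over all time equals the dose component exactly.
    """

    local_dose: float
    systemic_dose: float
    tau: float

    def local(self, t: float | np.ndarray) -> float | np.ndarray:
        return self._box(t, self.local_dose)

    def systemic(self, t: float | np.ndarray) -> float | np.ndarray:
        return self._box(t, self.systemic_dose)

    def _box(self, t: float | np.ndarray, dose: float) -> float | np.ndarray:
        t_arr = np.asarray(t, dtype=float)
        out = np.where((t_arr >= 0.0) & (t_arr < self.tau), dose / self.tau, 0.0)
        return float(out) if np.isscalar(t) else out


def release_source(scenario: "DeliveryScenario") -> ReleaseSource:
    """Build the Heaviside release source for a delivery scenario.

    Carrier modes release ``f_seq * dose`` locally (into the target-organ
    capillaries) and the remainder systemically; free-drug infusion modes
    release the whole dose systemically.
    """
    local = scenario.f_seq * scenario.dose if scenario.is_carrier else 0.0
    return ReleaseSource(
        local_dose=local,
        systemic_dose=scenario.dose - local,
        tau=scenario.tau,
    )
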