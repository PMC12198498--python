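"""Spline-parameterised kinetic rates and the spliced/unspliced ODE system.

The model behind RNA velocity couples the unspliced (nascent) and spliced
(mature) mRNA abundance of a gene through three kinetic rates::

    dU/dt = alpha(t) - beta(t) * U
    dS/dt = beta(t) * U - gamma(t) * S

where ``alpha`` is the transcription rate, ``beta`` the splicing rate and
``gamma`` the degradation rate.  Here ``t`` is pseudotime on a normalised
[0, 1] trajectory domain and each rate is a smooth function of pseudotime,
represented as a natural cubic spline through a fixed grid of 8 nodes.

This module holds the rate representation (:class:`RateSpline`), the bundle
of rates plus initial conditions (:class:`KineticParams`) and the forward
integration of the ODE system (:func:`integrate_kinetics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

__all__ = [
    "RATE_MAX",
    "N_NODES",
    "DomainError",
    "IntegrationError",
    "RateSpline",
    "KineticParams",
    "Trajectory",
    "default_node_times",
    "eval_spline",
    "integrate_kinetics",
]

#: Upper bound on every kinetic rate, per unit of normalised pseudotime.
RATE_MAX = 6.7

#: Number of spline nodes per rate.
N_NODES = 8


class DomainError(ValueError):
    """Evaluation requested outside the pseudotime domain of a spline."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a solution."""


def default_node_times(n_nodes: int = N_NODES) -> np.ndarray:
    """Equispaced spline node positions on the normalised [0, 1] domain."""
    return np.linspace(0.0, 1.0, n_nodes)


def natural_spline_basis(node_times: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cardinal basis of the natural cubic interpolant on ``node_times``.

    Returns a ``(len(t), n_nodes)`` matrix ``B`` such that the natural cubic
    spline through node values ``y`` evaluates to ``B @ y``.  Interpolation is
    linear in the node values, which this basis makes explicit; the fitting
    module relies on it for analytic gradients.
    """
    node_times = np.asarray(node_times, dtype=float)
    eye = np.eye(node_times.size)
    cs = CubicSpline(node_times, eye, axis=0, bc_type="natural")
    return cs(np.asarray(t, dtype=float))


@dataclass(frozen=True)
class RateSpline:
    """One kinetic rate as a natural cubic spline through fixed nodes.

    Parameters
    ----------
    node_times
        Strictly increasing pseudotime positions of the spline nodes
        (normally 8 equispaced points on [0, 1]).
    node_values
        Non-negative rate values at the nodes, each within
        ``[0, RATE_MAX]``.

    Natural boundary conditions (zero second derivative at both end nodes)
    are used, and evaluation clips any between-node undershoot at zero since
    rates are physically non-negative.
    """

    node_times: np.ndarray
    node_values: np.ndarray
    _spline: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        nt = np.asarray(self.node_times, dtype=float)
        nv = np.asarray(self.node_values, dtype=float)
        if nt.ndim != 1 or nv.shape != nt.shape:
            raise ValueError("node_times and node_values must be 1-D and of equal length")
        if nt.size < 2:
            raise ValueError("a rate spline needs at least 2 nodes")
        if np.any(np.diff(nt) <= 0):
            raise ValueError("node_times must be strictly increasing")
        if np.any(~np.isfinite(nv)):
            raise ValueError("node_values must be finite")
        if np.any(nv < -1e-12) or np.any(nv > RATE_MAX + 1e-9):
            raise ValueError(f"node_values must lie in [0, {RATE_MAX}]")
        object.__setattr__(self, "node_times", nt)
        object.__setattr__(self, "node_values", np.clip(nv, 0.0, RATE_MAX))
        object.__setattr__(
            self, "_spline", CubicSpline(nt, self.node_values, bc_type="natural")
        )

    @classmethod
    def constant(cls, value: float, node_times: np.ndarray | None = None) -> "RateSpline":
        """A flat spline with every node at ``value``."""
        nt = default_node_times() if node_times is None else np.asarray(node_times, float)
        return cls(nt, np.full(nt.shape, float(value)))

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.node_times[0]), float(self.node_times[-1])

    def __call__(self, t) -> np.ndarray:
        """Evaluate the rate at pseudotime(s) ``t`` (clipped below at 0)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise DomainError(
                f"pseudotime outside spline domain [{lo}, {hi}]"
            )
        return np.maximum(self._spline(t), 0.0)


def eval_spline(spline: RateSpline, t):
    """Natural-cubic-spline rate value at pseudotime ``t`` (non-negative).

    Raises :class:`DomainError` when ``t`` lies outside the node range.
    """
    return spline(t)


@dataclass(frozen=True)
class KineticParams:
    """Transcription/splicing/degradation splines plus initial conditions.

    All three splines must share the same node grid; ``u0`` and ``s0`` are the
    unspliced/spliced levels at the first evaluation time.
    """

    alpha: RateSpline
    beta: RateSpline
    gamma: RateSpline
    u0: float
    s0: float

    def __post_init__(self) -> None:
        for r in (self.beta, self.gamma):
            if not np.array_equal(r.node_times, self.alpha.node_times):
                raise ValueError("alpha, beta and gamma must share one node grid")
        if self.u0 < 0 or self.s0 < 0:
            raise ValueError("initial conditions must be non-negative")

    @property
    def node_times(self) -> np.ndarray:
        return self.alpha.node_times


@dataclass(frozen=True)
class Trajectory:
    """Unspliced/spliced levels along an ordered pseudotime grid."""

    times: np.ndarray
    u: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        u = np.asarray(self.u, dtype=float)
        s = np.asarray(self.s, dtype=float)
        if not (t.shape == u.shape == s.shape) or t.ndim != 1:
            raise ValueError("times, u and s must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "s", s)


def integrate_kinetics(
    params: KineticParams,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
    label: str | None = None,
) -> Trajectory:
    """Solve the two-species kinetics ODE with time-varying spline rates.

    The system is integrated from ``times[0]`` (where ``u0, s0`` apply)
    through the last requested pseudotime with an adaptive-step solver and
    dense output at the requested times.

    Parameters
    ----------
    params
        Rates and initial conditions.
    times
        Strictly increasing evaluation pseudotimes, all inside the spline
        domain.
    rtol, atol
        Solver tolerances.
    label
        Optional identifier (e.g. a gene name) used in error messages.

    Raises
    ------
    DomainError
        If any requested time falls outside the spline domain.
    IntegrationError
        If the solver does not converge.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    lo, hi = params.alpha.domain
    if t[0] < lo - 1e-12 or t[-1] > hi + 1e-12:
        raise DomainError(f"requested times outside spline domain [{lo}, {hi}]")

    alpha, beta, gamma = params.alpha, params.beta, params.gamma

    def rhs(tt, y):
        a = alpha(tt)
        b = beta(tt)
        c = gamma(tt)
        u, s = y
        return (a - b * u, b * u - c * s)

    if t.size == 1:
        return Trajectory(t, np.array([params.u0]), np.array([params.s0]))

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        (float(params.u0), float(params.s0)),
        t_eval=t,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        who = f" for {label}" if label else ""
        raise IntegrationError(f"kinetics integration failed{who}: {sol.message}")
    return Trajectory(t, sol.y[0], sol.y[1])
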