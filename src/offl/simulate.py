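"""Numeric integration of compiled systems.

The translation rule yields an autonomous (or explicitly time-dependent)
first-order ODE system which any standard initial-value solver can handle.
The default solver is scipy's adaptive LSODA (stiff-capable, switching
automatically), at rtol 1e-8 / atol 1e-10; both method and tolerances are
overridable.  Populations are not clamped: the integrator follows the ODE
literally, and a warning is attached to the trajectory metadata if any
species dips below -atol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .compiler import generate_odes, make_rate_evaluator
from .core import OfflModel
from .errors import DomainError, IntegrationError, MissingBinding

__all__ = ["Trajectory", "integrate", "check_conservation"]

DEFAULT_OPTIONS = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}


@dataclass
class Trajectory:
    """Solution of a model on a fixed output grid.

    ``values[k, i]`` is species i (node-index order) at ``times[k]``;
    row 0 is the initial condition.
    """

    times: np.ndarray
    values: np.ndarray
    species_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.species_names.index(name)]


def integrate(model: OfflModel,
              parameter_bindings: Mapping[str, float] | None = None,
              t_end: float = 10.0, n_points: int = 201,
              options: Mapping | None = None) -> Trajectory:
    """Integrate *model* from its initial-value column over [0, t_end].

    Parameter values default to the model's own parameter table; explicit
    *parameter_bindings* override it entry by entry.  *options* are passed
    to the solver after the defaults (method LSODA, rtol 1e-8, atol 1e-10).
    """
    if t_end <= 0:
        raise DomainError(f"t_end must be positive, got {t_end}")
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points}")

    system = generate_odes(model)
    bindings = dict(model.parameter_values())
    bindings.update(parameter_bindings or {})
    try:
        rhs = make_rate_evaluator(system, bindings)
    except MissingBinding:
        raise

    opts = dict(DEFAULT_OPTIONS)
    opts.update(options or {})
    atol = opts.get("atol", DEFAULT_OPTIONS["atol"])

    times = np.linspace(0.0, float(t_end), int(n_points))
    y0 = np.asarray(model.initial_state(), dtype=float)
    sol = solve_ivp(rhs, (0.0, float(t_end)), y0, t_eval=times, **opts)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")

    values = sol.y.T
    meta = {"solver_options": opts, "nfev": int(sol.nfev),
            "message": sol.message}
    if np.any(values < -atol):
        worst = float(values.min())
        meta["negative_values"] = worst
        warnings.warn(
            f"trajectory goes negative (min {worst:g}); the ODE is "
            "integrated literally, with no positivity enforcement",
            RuntimeWarning, stacklevel=2)
    return Trajectory(times, values, model.species_names(), meta)


def check_conservation(trajectory: Trajectory,
                       linear_combination) -> float:
    """Max absolute drift of a linear combination of species over time.

    Returns max_k | w . X(t_k) - w . X(0) | for weight vector w.  Zero (to
    solver tolerance) certifies that the combination is conserved along the
    trajectory, e.g. total population when every interaction redeposits as
    many parcels as it draws.
    """
    w = np.asarray(linear_combination, dtype=float)
    if w.shape != (trajectory.values.shape[1],):
        raise DomainError(
            f"weight vector has length {w.size}, need "
            f"{trajectory.values.shape[1]}")
    totals = trajectory.values @ w
    return float(np.max(np.abs(totals - totals[0])))
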