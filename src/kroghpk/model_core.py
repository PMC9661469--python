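"""Coupled compartment + Krogh-cylinder drug-transport model.

Geometry and compartments
-------------------------
An infinite capillary of radius ``R_c`` supplies an annulus of tissue out to
the Krogh radius ``R_k`` (no-flux outer boundary); everything is expressed
per unit capillary length, so "volumes" are annulus areas (um^2).  The model
tracks

* ``C_p``   — free drug in the target-organ capillary plasma (uM),
* ``C_sys`` — drug in the systemic (rest-of-body) compartment (uM),
* ``C_f``   — free drug in the interstitium (uM per interstitial volume),
* ``C_bnd`` — protein-bound drug in the interstitium (uM),
* ``C_cell``— intracellular drug (uM, referenced to interstitial volume),
* ``M_el``  — cumulative mass eliminated from the systemic compartment.

Transport and kinetics
----------------------
Only the free fraction ``f_u * C_p`` crosses the capillary wall (permeability
``P``, Robin condition); bound drug cannot cross the wall and diffuses more
slowly (``D_b <= D_f``).  Protein binding and cellular uptake are saturable
Michaelis-Menten rates; unbinding and cellular efflux are first order.  The
target-organ capillary exchanges with the systemic compartment at rate
``k_out`` and the systemic compartment is cleared at rate ``k_el``.

The radial problem is discretised with a cell-centred finite-volume scheme
on exact annular volumes (method of lines), which makes total drug mass a
telescoping sum of face fluxes and hence conservation directly testable.
Units are um, min, uM throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .release_kinetics import release_source

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .delivery_modes import DeliveryScenario

__all__ = [
    "TransportParameters",
    "RadialGrid",
    "ModelState",
    "SimulationResult",
    "SolverError",
    "build_grid",
    "time_derivative",
    "simulate",
    "mass_balance_residual",
]

#: Default stiff-integrator tolerances (Michaelis-Menten kinetics plus thin
#: wall boundary layers make the system stiff).
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10  # uM

#: Concentrations more negative than -NEGATIVITY_TOL * max(concentration)
#: indicate integrator failure rather than roundoff.
NEGATIVITY_TOL = 1e-8


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails or produces unphysical output."""


@dataclass(frozen=True)
class TransportParameters:
    """Physiological and kinetic constants of the transport model.

    All defaults are configuration placeholders for a doxorubicin-like small
    molecule in lung tissue, not measured ground truth; every field is meant
    to be set from a config file for a specific drug/tissue pair.

    Parameters
    ----------
    R_c, R_k : float
        Capillary radius and Krogh (outer no-flux) radius, um; ``R_k > R_c``.
    D_f, D_b : float
        Interstitial diffusivities of free and protein-bound drug, um^2/min;
        binding to bulky plasma proteins slows diffusion, so ``D_b <= D_f``.
    P : float
        Capillary-wall permeability to free drug, um/min.
    f_u : float
        Free (protein-unbound) fraction of drug in plasma; only this fraction
        crosses the wall.
    V_bind, K_bind, k_unbind : float
        Michaelis-Menten protein-binding maximum rate (uM/min) and
        half-saturation (uM), and first-order unbinding rate (1/min);
        ``k_unbind = 0`` recovers irreversible binding.
    V_up, K_up, k_eff : float
        Michaelis-Menten cellular-uptake maximum rate (uM/min) and
        half-saturation (uM), and first-order cellular efflux/degradation
        rate (1/min; default 0, i.e. monotone intracellular accumulation).
    k_out : float
        Target-organ capillary <-> systemic exchange rate, 1/min.
    k_el : float
        Systemic elimination rate, 1/min.
    V_ratio : float
        Ratio of target-organ capillary plasma volume to systemic volume.
    phi_i : float
        Interstitial volume fraction of the tissue.
    """

    R_c: float = 5.0
    R_k: float = 155.0
    D_f: float = 9600.0
    D_b: float = 600.0
    P: float = 6.0
    f_u: float = 0.25
    V_bind: float = 10.0
    K_bind: float = 1.0
    k_unbind: float = 0.06
    V_up: float = 2.0
    K_up: float = 2.0
    k_eff: float = 0.0
    k_out: float = 1.0
    k_el: float = 0.02
    V_ratio: float = 0.02
    phi_i: float = 0.4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if not (self.R_k > self.R_c > 0.0):
            raise ValueError(
                f"need R_k > R_c > 0, got R_c={self.R_c}, R_k={self.R_k}")
        if not (0.0 <= self.f_u <= 1.0):
            raise ValueError(f"f_u must be in [0, 1], got {self.f_u}")
        if not (0.0 < self.phi_i <= 1.0):
            raise ValueError(f"phi_i must be in (0, 1], got {self.phi_i}")
        if self.D_b > self.D_f:
            raise ValueError(
                "bound-drug diffusivity D_b must not exceed D_f "
                f"(got D_b={self.D_b} > D_f={self.D_f})")
        if self.V_ratio <= 0.0:
            raise ValueError("V_ratio must be > 0")

    @property
    def V_cap(self) -> float:
        """Capillary plasma volume per unit length (um^2)."""
        return float(np.pi * self.R_c**2)

    @property
    def V_sys(self) -> float:
        """Systemic volume in the per-unit-length reference (um^2)."""
        return self.V_cap / self.V_ratio


@dataclass(frozen=True)
class RadialGrid:
    """Cell-centred annular finite-volume grid between ``R_c`` and ``R_k``.

    ``cell_volumes`` are exact annulus areas per unit capillary length,
    ``pi * (r_{i+1}^2 - r_i^2)``, so their sum reproduces the annulus area to
    roundoff.
    """

    n_cells: int
    r_centers: np.ndarray
    r_faces: np.ndarray
    cell_volumes: np.ndarray

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.r_faces.shape != (self.n_cells + 1,):
            raise ValueError("r_faces must have length n_cells + 1")
        if np.any(np.diff(self.r_faces) <= 0):
            raise ValueError("r_faces must be strictly increasing")

    @property
    def R_c(self) -> float:
        return float(self.r_faces[0])

    @property
    def R_k(self) -> float:
        return float(self.r_faces[-1])


def build_grid(R_c: float, R_k: float, n_cells: int) -> RadialGrid:
    """Discretise the Krogh annulus into ``n_cells`` uniform-width rings.

    Faces are uniform in radius; cell volumes are the exact annulus areas.
    """
    if not (R_k > R_c > 0.0):
        raise ValueError(f"need R_k > R_c > 0, got R_c={R_c}, R_k={R_k}")
    if int(n_cells) != n_cells or n_cells < 1:
        raise ValueError(f"n_cells must be a positive integer, got {n_cells}")
    n_cells = int(n_cells)
    r_faces = np.linspace(R_c, R_k, n_cells + 1)
    r_centers = 0.5 * (r_faces[:-1] + r_faces[1:])
    cell_volumes = np.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2)
    return RadialGrid(n_cells=n_cells, r_centers=r_centers,
                      r_faces=r_faces, cell_volumes=cell_volumes)


@dataclass
class ModelState:
    """Full model state (or its time derivative) at one instant."""

    C_p: float
    C_sys: float
    M_el: float
    C_f: np.ndarray
    C_bnd: np.ndarray
    C_cell: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int) -> "ModelState":
        return cls(0.0, 0.0, 0.0, np.zeros(n_cells), np.zeros(n_cells),
                   np.zeros(n_cells))

    def pack(self) -> np.ndarray:
        return np.concatenate(
            ([self.C_p, self.C_sys, self.M_el], self.C_f, self.C_bnd,
             self.C_cell))

    @classmethod
    def unpack(cls, y: np.ndarray, n_cells: int) -> "ModelState":
        n = n_cells
        return cls(float(y[0]), float(y[1]), float(y[2]),
                   y[3:3 + n], y[3 + n:3 + 2 * n], y[3 + 2 * n:3 + 3 * n])


@dataclass
class SimulationResult:
    """Time-resolved solution of one delivery scenario.

    Radial fields are arrays of shape ``(n_times, n_cells)``; compartments
    are 1-D arrays over ``times``.
    """

    times: np.ndarray
    C_p: np.ndarray
    C_sys: np.ndarray
    M_el: np.ndarray
    C_f: np.ndarray
    C_bnd: np.ndarray
    C_cell: np.ndarray
    scenario: "DeliveryScenario"
    params: TransportParameters
    grid: RadialGrid

    def state_at(self, i: int) -> ModelState:
        return ModelState(float(self.C_p[i]), float(self.C_sys[i]),
                          float(self.M_el[i]), self.C_f[i], self.C_bnd[i],
                          self.C_cell[i])

    def total_mass(self) -> np.ndarray:
        """Volume-weighted drug mass in all compartments plus eliminated mass.

        Mass per unit capillary length, in uM * um^2, at every output time.
        """
        p = self.params
        v_int = p.phi_i * self.grid.cell_volumes  # interstitial volume per cell
        tissue = (self.C_f + self.C_bnd + self.C_cell) @ v_int
        return (self.C_p * p.V_cap + self.C_sys * p.V_sys + tissue
                + self.M_el)

    def released_dose(self) -> np.ndarray:
        """Cumulative released (administered) dose at every output time."""
        tau = self.scenario.tau
        return self.scenario.dose * np.minimum(self.times / tau, 1.0)


def _wall_conductance(params: TransportParameters, grid: RadialGrid) -> float:
    """Effective wall->first-cell conductance (um/min).

    Series resistance of the membrane (1/P) and the half-cell diffusion path
    from the wall to the first cell centre; reduces to P as the grid refines.
    """
    if params.P == 0.0:
        return 0.0
    dr_half = grid.r_centers[0] - grid.R_c
    if params.D_f == 0.0:
        return 0.0 if dr_half > 0 else params.P
    return 1.0 / (1.0 / params.P + dr_half / params.D_f)


def _make_rhs(params: TransportParameters, scenario: "DeliveryScenario",
              grid: RadialGrid):
    """Return the packed right-hand side f(t, y) of the method-of-lines ODE."""
    p = params
    n = grid.n_cells
    src = release_source(scenario)

    V_cap, V_sys = p.V_cap, p.V_sys
    vols = grid.cell_volumes
    phi_vols = p.phi_i * vols
    dr = np.diff(grid.r_centers)  # centre-to-centre spacing (uniform grid)
    # interior face transmissibilities: flux = -D * 2*pi*r_face * dC/dr
    face_r = grid.r_faces[1:-1]
    trans = 2.0 * np.pi * face_r / dr if n > 1 else np.empty(0)
    g_wall = _wall_conductance(p, grid)
    wall_area = 2.0 * np.pi * p.R_c

    def laplacian(C: np.ndarray, D: float) -> np.ndarray:
        if n == 1 or D == 0.0:
            return np.zeros(n)
        flux = -D * trans * (C[1:] - C[:-1])  # mass/min across interior faces
        div = np.zeros(n)
        div[:-1] -= flux
        div[1:] += flux
        return div / vols

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        C_p, C_sys = y[0], y[1]
        C_f = y[3:3 + n]
        C_bnd = y[3 + n:3 + 2 * n]
        C_cell = y[3 + 2 * n:3 + 3 * n]

        # trans-wall mass flow, per unit capillary length (uM*um^2/min)
        J_wall = wall_area * g_wall * (p.f_u * C_p - C_f[0])

        bind = p.V_bind * C_f / (p.K_bind + C_f) if p.V_bind else np.zeros(n)
        unbind = p.k_unbind * C_bnd
        uptake = p.V_up * C_f / (p.K_up + C_f) if p.V_up else np.zeros(n)

        dC_f = laplacian(C_f, p.D_f) - bind + unbind - uptake
        dC_f[0] += J_wall / phi_vols[0]
        dC_bnd = laplacian(C_bnd, p.D_b) + bind - unbind
        dC_cell = uptake - p.k_eff * C_cell

        dC_p = (src.local(t) / V_cap - p.k_out * (C_p - C_sys)
                - J_wall / V_cap)
        dC_sys = (src.systemic(t) / V_sys
                  + p.k_out * p.V_ratio * (C_p - C_sys) - p.k_el * C_sys)
        dM_el = p.k_el * C_sys * V_sys

        out = np.empty_like(y)
        out[0], out[1], out[2] = dC_p, dC_sys, dM_el
        out[3:3 + n] = dC_f
        out[3 + n:3 + 2 * n] = dC_bnd
        out[3 + 2 * n:] = dC_cell
        return out

    return rhs


def time_derivative(state: ModelState, t: float, params: TransportParameters,
                    scenario: "DeliveryScenario",
                    grid: RadialGrid) -> ModelState:
    """Time derivative of every state component under the transport model.

    Raises
    ------
    ValueError
        If the state dimensions do not match the grid.
    SolverError
        If a state component is negative beyond integrator roundoff
        (signals a failed integration upstream).
    """
    n = grid.n_cells
    for name in ("C_f", "C_bnd", "C_cell"):
        arr = getattr(state, name)
        if np.shape(arr) != (n,):
            raise ValueError(f"{name} has shape {np.shape(arr)}, "
                             f"expected ({n},)")
    y = state.pack()
    scale = max(float(np.max(np.abs(y))), 1.0)
    if np.min(y) < -NEGATIVITY_TOL * scale:
        raise SolverError(
            f"state has negative components (min {np.min(y):.3e}); "
            "the upstream integration is not trustworthy")
    dy = _make_rhs(params, scenario, grid)(t, y)
    return ModelState.unpack(dy, n)


def _jac_sparsity(n: int) -> lil_matrix:
    """Sparsity pattern of the Jacobian for the stiff solver (3n+3 states)."""
    m = 3 * n + 3
    S = lil_matrix((m, m), dtype=np.int8)
    iF, iB, iC = 3, 3 + n, 3 + 2 * n
    S[0, [0, 1, iF]] = 1          # C_p: itself, C_sys, wall cell
    S[1, [0, 1]] = 1              # C_sys
    S[2, 1] = 1                   # M_el
    for i in range(n):
        nb = [iF + j for j in (i - 1, i, i + 1) if 0 <= j < n]
        S[iF + i, nb] = 1
        S[iF + i, iB + i] = 1     # unbinding source
        nbb = [iB + j for j in (i - 1, i, i + 1) if 0 <= j < n]
        S[iB + i, nbb] = 1
        S[iB + i, iF + i] = 1     # binding source
        S[iC + i, [iF + i, iC + i]] = 1
    S[iF, 0] = 1                  # wall cell sees C_p
    return S


def simulate(params: TransportParameters, scenario: "DeliveryScenario",
             grid: RadialGrid, t_eval: Sequence[float],
             rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL) -> SimulationResult:
    """Integrate the model from a zero initial state and report at ``t_eval``.

    Uses a stiff implicit method (BDF) with an analytic Jacobian sparsity
    pattern; the integration is split at the release cutoff ``tau`` so the
    discontinuous source does not degrade the error control.

    Raises
    ------
    SolverError
        On integrator non-convergence or concentrations more negative than
        integrator roundoff allows.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or t_eval.size == 0:
        raise ValueError("t_eval must be a non-empty 1-D sequence")
    if np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if t_eval[0] < 0:
        raise ValueError("t_eval must start at a non-negative time")

    n = grid.n_cells
    rhs = _make_rhs(params, scenario, grid)
    sparsity = _jac_sparsity(n)

    t_end = float(t_eval[-1])
    breaks = [0.0]
    if 0.0 < scenario.tau < t_end:
        breaks.append(float(scenario.tau))
    breaks.append(t_end)

    y = np.zeros(3 * n + 3)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    if t_eval[0] == 0.0:
        ts.append(np.array([0.0]))
        ys.append(y[:, None].copy())

    for a, b in zip(breaks[:-1], breaks[1:]):
        seg = t_eval[(t_eval > a) & (t_eval <= b)]
        sol = solve_ivp(rhs, (a, b), y, method="BDF", rtol=rtol, atol=atol,
                        t_eval=seg if seg.size else None,
                        jac_sparsity=sparsity, dense_output=False)
        if not sol.success:
            raise SolverError(
                f"integration failed on [{a}, {b}] min for mode "
                f"'{scenario.mode}': {sol.message}")
        if seg.size:
            ts.append(sol.t)
            ys.append(sol.y)
        # restart state for the next segment
        y = sol.y[:, -1] if sol.t[-1] == b else solve_ivp(
            rhs, (sol.t[-1], b), sol.y[:, -1], method="BDF", rtol=rtol,
            atol=atol, jac_sparsity=sparsity).y[:, -1]

    t_out = np.concatenate(ts)
    y_out = np.concatenate(ys, axis=1)
    if t_out.shape != t_eval.shape or not np.allclose(t_out, t_eval):
        raise SolverError("integrator did not report all requested times")

    scale = float(np.max(y_out)) if y_out.size else 0.0
    y_min = float(np.min(y_out))
    if scale > 0 and y_min < -NEGATIVITY_TOL * scale:
        raise SolverError(
            f"negative concentrations beyond tolerance (min {y_min:.3e}, "
            f"scale {scale:.3e}); tighten tolerances or refine the grid")
    if y_min < 0.0:
        warnings.warn("clipping slightly negative concentrations "
                      f"(min {y_min:.3e}) to zero", RuntimeWarning,
                      stacklevel=2)
        y_out = np.clip(y_out, 0.0, None)

    return SimulationResult(
        times=t_out,
        C_p=y_out[0], C_sys=y_out[1], M_el=y_out[2],
        C_f=y_out[3:3 + n].T, C_bnd=y_out[3 + n:3 + 2 * n].T,
        C_cell=y_out[3 + 2 * n:].T,
        scenario=scenario, params=params, grid=grid)


def mass_balance_residual(result: SimulationResult) -> float:
    """Worst-case relative mass-balance error over the reported times.

    ``max_t |(mass in all compartments + eliminated) - released| / dose``;
    defined as 0 for a zero-dose scenario.
    """
    dose = result.scenario.dose
    if dose == 0.0:
        return 0.0
    err = np.abs(result.total_mass() - result.released_dose())
    return float(np.max(err) / dose)
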