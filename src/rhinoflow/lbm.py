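"""D3Q19 lattice-Boltzmann solver with Smagorinsky LES closure.

Single-relaxation-time (BGK) collision on the D3Q19 stencil, with a local
eddy viscosity from the Smagorinsky subgrid model (constant ``cs``, filter
width = one lattice spacing) to keep transitional airflow stable at high
local Reynolds number.  Boundary conditions:

* **wall** - halfway bounce-back (no-slip; the physical wall sits midway
  between the last fluid node and the first solid node);
* **outlet** (cuboid surface) - velocity Dirichlet enforcing the configured
  volumetric flow rate: populations are set to equilibrium at the local
  density and a prescribed suction velocity pointing into the cuboid, which
  drives inhalation;
* **inlet** (sphere surface) - ambient-pressure condition: populations set
  to equilibrium at the reference density with the local velocity, so the
  sphere acts as an open reservoir of still air;
* cuboid-interior voxels are relaxed to the reference density every step so
  the cuboid behaves as an absorbing plenum (mass sink) behind the outlet
  surface.

The solver is sparse: populations are stored only for fluid voxels and
streaming uses precomputed indirect-addressing index tables, so the cost per
step scales with the number of fluid voxels, not the bounding box.  All
arithmetic is float64 and fully deterministic.

Unit conversion follows the standard diffusive/acoustic scaling: the lattice
spacing equals the voxel spacing, and the time step is chosen so the peak
expected lattice velocity stays below a Mach-number cap while the relaxation
time ``tau0 = 3 nu_lat + 0.5`` remains in its stable range.  Pressure in Pa
is ``(rho_lat - 1) * c_s^2 * (dx/dt)^2 * rho_air`` with ``c_s^2 = 1/3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .imaging import INLET, OUTLET, FlowDomain

__all__ = [
    "SolverConfig",
    "UnitMapping",
    "LatticeState",
    "LBMSolver",
    "InstabilityError",
    "physical_to_lattice",
    "step",
    "run",
    "reynolds_number",
]

# --------------------------------------------------------------------------
# D3Q19 stencil
# --------------------------------------------------------------------------
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)
# nudge the rest weight so the axis-0 reduction used for the density,
# f.sum(axis=0), gives exactly 1 on the uniform state f_i = w_i: that state
# is then a bitwise fixed point of collide+stream (bounce-back pairs share
# their weight, so streaming is exact too).
for _ in range(4):
    _err = np.repeat(W[:, None], 2, axis=1).sum(axis=0)[0] - 1.0
    if _err == 0.0:
        break
    W = W.copy()
    W[0] -= _err
OPP = np.array([int(np.nonzero((C == -c).all(axis=1))[0][0]) for c in C])
CS2 = 1.0 / 3.0
# index pairs for the six independent components of the momentum-flux tensor
_TENSOR_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_E = np.stack([C[:, a] * C[:, b] for a, b in _TENSOR_PAIRS], axis=1).astype(float)  # (19, 6)


class InstabilityError(RuntimeError):
    """Raised when the simulation produces NaN / non-positive density."""


@dataclass(frozen=True)
class SolverConfig:
    """Physical and numerical parameters of a flow run.

    ``flow_rate_ml_s`` is the total inhalation rate drawn through the outlet
    cuboid.  ``char_area_mm2`` is the smallest airway cross-section the flow
    passes; it sets the peak expected velocity and hence the time step
    (``None`` = measure it from the domain).  ``max_lattice_velocity`` caps
    the lattice Mach number; ``physical_duration_s`` is the simulated time
    of the initial run and ``optimization_duration_s`` that of the shorter
    warm-started runs inside the optimizer loop.
    """

    flow_rate_ml_s: float = 600.0
    air_kinematic_viscosity: float = 1.5e-5  # m^2/s
    air_density: float = 1.2  # kg/m^3
    smagorinsky_cs: float = 0.14
    physical_duration_s: float = 0.0125
    optimization_duration_s: float = 0.00625
    spacing_mm: float = 0.5
    max_lattice_velocity: float = 0.1
    convergence_tol: float = 0.05
    char_area_mm2: float | None = None
    body_force_lat: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_rate_ml_s <= 0:
            raise ValueError("flow_rate_ml_s must be positive")
        if not (0.0 < self.max_lattice_velocity < 0.3):
            raise ValueError("max_lattice_velocity must be in (0, 0.3)")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")


@dataclass(frozen=True)
class UnitMapping:
    """Invertible physical <-> lattice unit conversion."""

    dx_m: float
    dt_s: float
    tau0: float
    air_density: float

    @property
    def nu_lat(self) -> float:
        return (self.tau0 - 0.5) / 3.0

    def vel_to_lat(self, u_m_s):
        return np.asarray(u_m_s) * self.dt_s / self.dx_m

    def vel_to_phys(self, u_lat):
        return np.asarray(u_lat) * self.dx_m / self.dt_s

    def flow_to_lat(self, q_m3_s: float) -> float:
        return q_m3_s * self.dt_s / self.dx_m**3

    def pressure_to_phys(self, rho_lat):
        return (np.asarray(rho_lat) - 1.0) * CS2 * (self.dx_m / self.dt_s) ** 2 * self.air_density

    def steps_for(self, duration_s: float) -> int:
        return int(round(duration_s / self.dt_s))


def physical_to_lattice(cfg: SolverConfig, char_area_mm2: float | None = None) -> UnitMapping:
    """Choose the time step from the velocity cap and viscosity constraints.

    ``dx`` equals the voxel spacing.  ``dt`` is the largest value such that
    (a) the peak expected lattice velocity (flow rate / smallest airway
    cross-section) does not exceed ``max_lattice_velocity`` and (b)
    ``tau0 = 3 nu_phys dt / dx^2 + 0.5 <= 1.99``.
    """
    area = char_area_mm2 if char_area_mm2 is not None else cfg.char_area_mm2
    if area is None or area <= 0:
        raise ValueError("char_area_mm2 (smallest airway cross-section) is required")
    dx = cfg.spacing_mm * 1e-3
    u_char = (cfg.flow_rate_ml_s * 1e-6) / (area * 1e-6)  # m/s
    dt_vel = cfg.max_lattice_velocity * dx / u_char
    dt_visc = (1.99 - 0.5) / 3.0 * dx**2 / cfg.air_kinematic_viscosity
    dt = min(dt_vel, dt_visc)
    tau0 = 3.0 * cfg.air_kinematic_viscosity * dt / dx**2 + 0.5
    if not (0.5 < tau0 <= 1.99 + 1e-12):
        raise ValueError(
            f"no stable time step: tau0={tau0:.4f}; reduce the flow rate or refine the cap"
        )
    return UnitMapping(dx_m=dx, dt_s=dt, tau0=tau0, air_density=cfg.air_density)


@dataclass
class LatticeState:
    """Distribution populations on the fluid voxels of a domain.

    ``f`` has shape (19, n_fluid); ``fluid_flat_idx`` maps each column to a
    flat voxel index of ``shape`` so states can be transplanted onto a
    modified (grown) domain.  Macroscopic fields in physical units are
    materialized on demand.
    """

    f: np.ndarray
    fluid_flat_idx: np.ndarray
    shape: tuple[int, int, int]
    mapping: UnitMapping
    step_count: int = 0
    time_s: float = 0.0
    dp_trace_pa: np.ndarray = field(default_factory=lambda: np.empty(0))
    developed: bool = False
    # time averages over the developed tail of a run (LES mean field);
    # None for states produced by single steps
    mean_rho: np.ndarray | None = None
    mean_u_lat: np.ndarray | None = None

    # -- macroscopic fields -----------------------------------------------
    def density_lat(self) -> np.ndarray:
        return self.f.sum(axis=0)

    def velocity_field(self, prefer_mean: bool = True) -> np.ndarray:
        """(n0, n1, n2, 3) velocity in m/s; zero outside the fluid.

        Uses the time-averaged field when one was accumulated (turbulent
        fluctuations of the instantaneous LES field are not flow features).
        """
        if prefer_mean and self.mean_u_lat is not None:
            u = self.mean_u_lat
        else:
            rho = self.density_lat()
            u = (C.T.astype(float) @ self.f) / rho  # (3, n)
        out = np.zeros((*self.shape, 3))
        out.reshape(-1, 3)[self.fluid_flat_idx] = self.mapping.vel_to_phys(u).T
        return out

    def pressure_field(self, prefer_mean: bool = True) -> np.ndarray:
        """(n0, n1, n2) gauge pressure in Pa; zero outside the fluid."""
        rho = (
            self.mean_rho
            if (prefer_mean and self.mean_rho is not None)
            else self.density_lat()
        )
        p = self.mapping.pressure_to_phys(rho)
        out = np.zeros(self.shape)
        out.reshape(-1)[self.fluid_flat_idx] = p
        return out


def _equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order Maxwellian: rho (n,), u (3, n) -> (19, n)."""
    cu = C.astype(float) @ u
    usq = np.einsum("an,an->n", u, u)
    return W[:, None] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


class LBMSolver:
    """Sparse D3Q19 solver bound to one :class:`FlowDomain`."""

    def __init__(self, domain: FlowDomain, cfg: SolverConfig, mapping: UnitMapping | None = None):
        if cfg.spacing_mm != domain.spacing:
            cfg = replace(cfg, spacing_mm=domain.spacing)
        self.domain = domain
        self.cfg = cfg
        if mapping is None:
            has_bodies = domain.sphere_center is not None and domain.cuboid_center is not None
            area = cfg.char_area_mm2
            if area is None and has_bodies:
                area = domain.min_airway_area_mm2()
            elif area is None:
                # benchmark domains without bodies: any area below the true
                # minimum only shrinks dt; use the full mean cross-section.
                area = float(domain.fluid_mask.sum() / domain.shape[0]) * domain.spacing**2
            mapping = physical_to_lattice(cfg, char_area_mm2=area)
        self.mapping = mapping
        self._build(domain)

    # -- topology ----------------------------------------------------------
    def _build(self, domain: FlowDomain) -> None:
        fluid = domain.fluid_mask
        shape = fluid.shape
        flat = np.flatnonzero(fluid.reshape(-1))
        self.n = flat.size
        if self.n == 0:
            raise ValueError("domain has no fluid voxels")
        self.fluid_flat_idx = flat
        coords = np.stack(np.unravel_index(flat, shape), axis=1)  # (n, 3)
        id_grid = np.full(shape, -1, dtype=np.int64)
        id_grid.reshape(-1)[flat] = np.arange(self.n)

        # pull-streaming source id per direction: voxel x receives f_i from
        # x - c_i; -1 means the source is solid (or a non-periodic face) and
        # halfway bounce-back applies instead.
        src = np.empty((19, self.n), dtype=np.int64)
        for i in range(19):
            nb = coords - C[i]
            inside = np.ones(self.n, dtype=bool)
            for a in range(3):
                if a in domain.periodic_axes:
                    nb[:, a] %= shape[a]
                else:
                    inside &= (nb[:, a] >= 0) & (nb[:, a] < shape[a])
            ids = np.full(self.n, -1, dtype=np.int64)
            nb_in = nb[inside]
            ids[inside] = id_grid[nb_in[:, 0], nb_in[:, 1], nb_in[:, 2]]
            src[i] = ids
        self._src = src
        self._bb = src < 0  # bounce-back mask per (direction, voxel)

        lab = domain.labels.reshape(-1)[flat]
        self._inlet = np.flatnonzero(lab == INLET)
        self._outlet = np.flatnonzero(lab == OUTLET)

        # suction is applied only on outlet-surface voxels with at least one
        # face toward the airway ("active"); the rest of the cuboid interior,
        # including buried surface voxels, is an absorbing plenum at the
        # reference density.
        active, self._outlet_u = self._outlet_velocities()
        cub = domain.cuboid_mask().reshape(-1)[flat]
        plenum = cub.copy()
        if active is not None:
            plenum[self._outlet[active]] = False
            self._outlet = self._outlet[active]
        self._plenum = np.flatnonzero(plenum)

    def _outlet_velocities(self):
        """Active outlet voxels (facing the airway) and their suction velocity.

        Returns ``(active_index_into_self._outlet, u_lat (3, n_active))``.
        The discrete flux surface is the set of faces between outlet voxels
        and fluid voxels outside the cuboid; each active voxel draws a share
        of the flow rate proportional to its exposed face count.
        """
        if self._outlet.size == 0:
            return None, None
        dom = self.domain
        cub = dom.cuboid_mask()
        external_fluid = dom.fluid_mask & ~cub
        out_mask = np.zeros(dom.shape, dtype=bool)
        out_mask.reshape(-1)[self.fluid_flat_idx[self._outlet]] = True
        faces = np.zeros(dom.shape, dtype=np.int64)
        nvec = np.zeros((*dom.shape, 3))  # sum of exposed unit face normals
        for a in range(3):
            for s in (1, -1):
                # neighbour at +s*e_a is external fluid -> exposed face with
                # outward normal +s*e_a (pointing from the cuboid to the airway)
                shifted = np.roll(external_fluid, -s, axis=a)
                sl = [slice(None)] * 3
                sl[a] = -1 if s == 1 else 0
                shifted[tuple(sl)] = False  # roll wraps; array faces carry no flux
                exposed = out_mask & shifted
                faces += exposed
                nvec[..., a] += s * exposed
        n_faces = int(faces.sum())
        if n_faces == 0:
            raise ValueError("outlet cuboid has no exposed faces toward the airway")

        out_faces = faces.reshape(-1)[self.fluid_flat_idx[self._outlet]]
        active = np.flatnonzero(out_faces > 0)
        # u = -(Q/N) * n_vec gives a discrete face flux of exactly Q/N per
        # exposed face (opposing exposed faces cancel in n_vec and carry none)
        q_lat = self.mapping.flow_to_lat(self.cfg.flow_rate_ml_s * 1e-6)
        nv = nvec.reshape(-1, 3)[self.fluid_flat_idx[self._outlet[active]]]
        return active, -(q_lat / n_faces) * nv.T

    # -- state management ---------------------------------------------------
    def equilibrium_state(self) -> LatticeState:
        f = np.repeat(W[:, None], self.n, axis=1)
        return LatticeState(
            f=f, fluid_flat_idx=self.fluid_flat_idx, shape=self.domain.shape, mapping=self.mapping
        )

    def adopt(self, prev: LatticeState) -> LatticeState:
        """Transplant a state from a (sub-)domain; new voxels start at rest."""
        state = self.equilibrium_state()
        pos = np.searchsorted(prev.fluid_flat_idx, self.fluid_flat_idx)
        pos = np.clip(pos, 0, prev.fluid_flat_idx.size - 1)
        hit = prev.fluid_flat_idx[pos] == self.fluid_flat_idx
        state.f[:, hit] = prev.f[:, pos[hit]]
        return state

    # -- dynamics -----------------------------------------------------------
    def step_state(self, state: LatticeState) -> LatticeState:
        f = state.f
        rho = f.sum(axis=0)
        u = (C.T.astype(float) @ f) / rho
        feq = _equilibrium(rho, u)
        fneq = f - feq

        # Smagorinsky: effective relaxation time from the non-equilibrium
        # momentum flux Pi, tau = (tau0 + sqrt(tau0^2 + 18 sqrt(2) Cs^2 |Pi| / rho)) / 2
        tau0 = self.mapping.tau0
        cs = self.cfg.smagorinsky_cs
        if cs > 0:
            pi = fneq.T @ _E  # (n, 6)
            pi_norm = np.sqrt(
                pi[:, 0] ** 2 + pi[:, 1] ** 2 + pi[:, 2] ** 2
                + 2.0 * (pi[:, 3] ** 2 + pi[:, 4] ** 2 + pi[:, 5] ** 2)
            )
            tau = 0.5 * (tau0 + np.sqrt(tau0**2 + 18.0 * np.sqrt(2.0) * cs**2 * pi_norm / rho))
        else:
            tau = tau0

        f_post = f - fneq / tau
        if self.cfg.body_force_lat is not None:
            F = np.asarray(self.cfg.body_force_lat, dtype=float)
            f_post = f_post + (3.0 * W[:, None]) * (C.astype(float) @ F)[:, None]

        # streaming (pull) with halfway bounce-back where the source is solid
        f_new = np.empty_like(f)
        for i in range(19):
            fi = f_post[i][self._src[i]]
            bb = self._bb[i]
            fi[bb] = f_post[OPP[i]][bb]
            f_new[i] = fi

        # boundary conditions
        if self._outlet.size:
            rho_o = f_new[:, self._outlet].sum(axis=0)
            f_new[:, self._outlet] = _equilibrium(rho_o, self._outlet_u)
        if self._inlet.size:
            fi = f_new[:, self._inlet]
            rho_i = fi.sum(axis=0)
            u_i = (C.T.astype(float) @ fi) / rho_i
            f_new[:, self._inlet] = _equilibrium(np.ones(self._inlet.size), u_i)
        if self._plenum.size:
            fp = f_new[:, self._plenum]
            rho_p = fp.sum(axis=0)
            u_p = (C.T.astype(float) @ fp) / rho_p
            f_new[:, self._plenum] = _equilibrium(np.ones(self._plenum.size), u_p)

        return LatticeState(
            f=f_new,
            fluid_flat_idx=self.fluid_flat_idx,
            shape=self.domain.shape,
            mapping=self.mapping,
            step_count=state.step_count + 1,
            time_s=state.time_s + self.mapping.dt_s,
            dp_trace_pa=state.dp_trace_pa,
            developed=state.developed,
        )

    def _dp_pa(self, state: LatticeState) -> float:
        """Surface-averaged outlet minus inlet pressure (Pa); negative while inhaling."""
        if self._inlet.size == 0 or self._outlet.size == 0:
            return float("nan")
        rho = state.density_lat()
        p = self.mapping.pressure_to_phys(rho)
        return float(p[self._outlet].mean() - p[self._inlet].mean())

    def _check(self, state: LatticeState) -> None:
        rho = state.density_lat()
        if not np.isfinite(rho).all() or (rho <= 0).any():
            u = np.abs((C.T.astype(float) @ state.f)).max()
            raise InstabilityError(
                f"instability at step {state.step_count}: non-finite or non-positive density "
                f"(max |momentum| {u:.3g})"
            )

    def run(
        self,
        duration_s: float,
        initial: LatticeState | None = None,
        average_last_frac: float = 0.2,
    ) -> LatticeState:
        n_steps = self.mapping.steps_for(duration_s)
        state = self.equilibrium_state() if initial is None else self.adopt(initial)
        has_bc = self._inlet.size > 0 and self._outlet.size > 0
        trace = np.empty(n_steps)
        check_every = max(1, n_steps // 50)
        avg_from = n_steps - max(1, int(round(average_last_frac * n_steps)))
        sum_rho = np.zeros(self.n)
        sum_u = np.zeros((3, self.n))
        n_avg = 0
        for k in range(n_steps):
            state = self.step_state(state)
            trace[k] = self._dp_pa(state) if has_bc else np.nan
            if k >= avg_from and average_last_frac > 0:
                rho = state.density_lat()
                sum_rho += rho
                sum_u += (C.T.astype(float) @ state.f) / rho
                n_avg += 1
            if (k + 1) % check_every == 0:
                self._check(state)
        self._check(state)
        state.dp_trace_pa = trace
        if n_avg:
            state.mean_rho = sum_rho / n_avg
            state.mean_u_lat = sum_u / n_avg
        if has_bc and n_steps >= 10:
            tail = trace[-max(1, n_steps // 10):]
            spread = float(tail.max() - tail.min())
            scale = max(abs(float(tail.mean())), 1e-12)
            state.developed = spread <= self.cfg.convergence_tol * scale
        return state


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------
_solver_cache: dict[tuple[int, int], LBMSolver] = {}


def _get_solver(domain: FlowDomain, cfg: SolverConfig) -> LBMSolver:
    key = (id(domain), id(cfg))
    solver = _solver_cache.get(key)
    if solver is None or solver.domain is not domain or solver.cfg is not cfg:
        solver = LBMSolver(domain, cfg)
        _solver_cache.clear()
        _solver_cache[key] = solver
    return solver


def step(state: LatticeState, domain: FlowDomain, cfg: SolverConfig) -> LatticeState:
    """One collide-stream cycle (functional form; see :class:`LBMSolver`)."""
    return _get_solver(domain, cfg).step_state(state)


def run(
    domain: FlowDomain,
    cfg: SolverConfig,
    initial: LatticeState | None = None,
    duration_s: float | None = None,
) -> LatticeState:
    """Run from rest (or a warm state) for ``duration_s`` of physical time.

    Defaults to ``cfg.physical_duration_s`` for cold starts and
    ``cfg.optimization_duration_s`` when a warm initial state is supplied.
    Records the inlet-outlet pressure-drop trace and sets ``developed`` when
    the trace is steady over the last 10% of steps.
    """
    if (domain.labels == INLET).sum() == 0 and domain.sphere_center is not None:
        raise ValueError("domain has no inlet voxels")
    if duration_s is None:
        duration_s = cfg.physical_duration_s if initial is None else cfg.optimization_duration_s
    return _get_solver(domain, cfg).run(duration_s, initial=initial)


def reynolds_number(
    area_mm2: float, perimeter_mm: float, flow_rate_ml_s: float, viscosity_m2_s: float = 1.5e-5
) -> float:
    """Reynolds number from the hydraulic diameter of a cross-section.

    ``D_h = 4 A / P``; the mean velocity is the volume flux over the area.
    """
    if area_mm2 <= 0 or perimeter_mm <= 0 or flow_rate_ml_s <= 0 or viscosity_m2_s <= 0:
        raise ValueError("all inputs must be positive")
    area = area_mm2 * 1e-6
    dh = 4.0 * area / (perimeter_mm * 1e-3)
    v = flow_rate_ml_s * 1e-6 / area
    return v * dh / viscosity_m2_s
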