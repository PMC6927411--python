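"""Normal-mode path-integral molecular dynamics.

Each atom is a ring polymer of P beads; the free ring polymer is propagated
exactly in its normal-mode representation and the physical forces enter
through velocity-Verlet kicks.  The extended system samples the canonical
distribution of the ring-polymer Hamiltonian

    H_P = sum_s p_s^2/2m + sum_s (m/2) w_P^2 (x_s - x_{s+1})^2 + sum_s V(x_s)

at the elevated temperature T_P = P T (beta_P = beta/P, w_P = P/(beta hbar)),
which reproduces quantum structural and thermodynamic averages of the
physical system at temperature T.  With one bead and no thermostat the
engine reduces exactly to classical velocity-Verlet dynamics.

Temperature control is by massive Nose-Hoover chains: one chain of four
thermostats per Cartesian degree of freedom of every normal mode, with
thermostat time constants tied to each mode's frequency.  Constant pressure
uses an isotropic Martyna-Tobias-Klein barostat coupled to the centroid
mode; the internal pressure virial is obtained from a central-difference
volume derivative of the bead-summed potential energy.

Internally dynamics run in (amu, A, fs) units; potentials return kcal/mol
and are converted at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import Configuration
from .constants import ATM_TO_KCAL_A3, HBAR_MDU, KB, KB_MDU, KCAL_TO_MDU

__all__ = [
    "SimulationSpec", "RingPolymerState", "Trajectory",
    "normal_mode_matrix", "normal_mode_frequencies",
    "init_ring_polymer", "step", "step_npt", "run",
]

_SY_W1 = 1.0 / (2.0 - 2.0 ** (1.0 / 3.0))
_SY_WEIGHTS = (_SY_W1, 1.0 - 2.0 * _SY_W1, _SY_W1)
NHC_LENGTH = 4


@dataclass(frozen=True)
class SimulationSpec:
    """Ensemble, state point and integrator settings."""

    ensemble: str = "nvt"        # nvt | npt | nve
    temperature: float = 298.15  # K
    pressure: float = 1.0        # atm (NPT only)
    dt: float = 0.2              # fs
    n_beads: int = 32
    n_steps: int = 1000
    cutoff: float = 9.0          # A (periodic systems)
    seed: int = 0
    stride: int = 10             # trajectory output interval (steps)
    tau_thermostat: float = 50.0  # fs, centroid-mode NHC time constant
    tau_barostat: float = 500.0   # fs

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.ensemble not in ("nvt", "npt", "nve"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.n_steps < 0 or self.stride < 1:
            raise ValueError("n_steps >= 0 and stride >= 1 required")


@dataclass
class RingPolymerState:
    """Bead-resolved phase-space point plus thermostat/barostat state."""

    x: np.ndarray                # (P, N, 3) bead positions, A
    p: np.ndarray                # (P, N, 3) momenta, amu A/fs
    masses: np.ndarray           # (N,)
    box_edge: float | None
    temperature: float
    nhc_xi: np.ndarray | None = None   # (M, P, N, 3)
    nhc_vxi: np.ndarray | None = None
    baro_v: float = 0.0          # piston velocity p_eps / W
    baro_nhc_xi: np.ndarray | None = None
    baro_nhc_vxi: np.ndarray | None = None
    step_count: int = 0
    forces: np.ndarray | None = None   # cached bead forces (internal units)
    potential_beads: np.ndarray | None = None  # kcal/mol per bead

    @property
    def n_beads(self) -> int:
        return self.x.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.x.shape[1]


# ---------------------------------------------------------------------------
# normal-mode machinery

_NM_CACHE: dict = {}


def normal_mode_matrix(P: int) -> np.ndarray:
    """Orthogonal bead->mode transform; row 0 is the (scaled) centroid."""
    if P not in _NM_CACHE:
        C = np.empty((P, P))
        j = np.arange(P)
        C[0] = np.sqrt(1.0 / P)
        for k in range(1, P // 2 + 1):
            if P % 2 == 0 and k == P // 2:
                C[k] = np.sqrt(1.0 / P) * (-1.0) ** j
            else:
                C[k] = np.sqrt(2.0 / P) * np.cos(2.0 * np.pi * k * j / P)
        for k in range(P // 2 + 1, P):
            C[k] = np.sqrt(2.0 / P) * np.sin(2.0 * np.pi * (P - k) * j / P)
        if P == 1:
            C = np.ones((1, 1))
        _NM_CACHE[P] = C
    return _NM_CACHE[P]


def normal_mode_frequencies(P: int, temperature: float) -> np.ndarray:
    """Free ring-polymer mode frequencies w_k = 2/(beta_P hbar) sin(k pi/P)
    in rad/fs, ordered to match the rows of :func:`normal_mode_matrix`."""
    beta = 1.0 / (KB_MDU * temperature)
    w_p = P / (beta * HBAR_MDU)
    k = np.arange(P)
    k_eff = np.minimum(k, P - k)
    return 2.0 * w_p * np.sin(np.pi * k_eff / P)


def to_normal_modes(bead_block: np.ndarray) -> np.ndarray:
    """Transform a (P, ...) bead-resolved block to normal modes."""
    P = bead_block.shape[0]
    C = normal_mode_matrix(P)
    return np.tensordot(C, bead_block, axes=(1, 0))


def from_normal_modes(mode_block: np.ndarray) -> np.ndarray:
    P = mode_block.shape[0]
    C = normal_mode_matrix(P)
    return np.tensordot(C.T, mode_block, axes=(1, 0))


# ---------------------------------------------------------------------------
# force providers

class _PotentialProvider:
    """Adapts a Potential bound to a topology; converts to internal units."""

    def __init__(self, potential, config: Configuration):
        self.bound = potential.bound(config)

    def __call__(self, coords, box_edge, key=0):
        e, F = self.bound.energy_forces(coords, box_edge, key=key)
        return e, F

    def energy(self, coords, box_edge, key=0):
        return self.bound.energy(coords, box_edge, key=key)


def as_force_provider(potential, config=None):
    """Accept a Potential (with a Configuration) or a plain callable
    ``f(coords, box_edge) -> (E_kcal, F_kcal)``."""
    if hasattr(potential, "bound"):
        if config is None:
            raise ValueError("a Configuration is needed to bind a Potential")
        return _PotentialProvider(potential, config)
    return potential


def _eval_forces(provider, state: RingPolymerState):
    """Bead potential energies (kcal) and forces (internal units)."""
    P, N = state.n_beads, state.n_atoms
    F = np.empty((P, N, 3))
    V = np.empty(P)
    for s in range(P):
        try:
            e, f = provider(state.x[s], state.box_edge, key=s)
        except TypeError:
            e, f = provider(state.x[s], state.box_edge)
        V[s] = e
        F[s] = f
    return V, F * KCAL_TO_MDU


def _provider_energy(provider, coords, box_edge, key=0):
    if hasattr(provider, "energy"):
        return provider.energy(coords, box_edge, key=key)
    try:
        e, _ = provider(coords, box_edge, key=key)
    except TypeError:
        e, _ = provider(coords, box_edge)
    return e


# ---------------------------------------------------------------------------
# initialization

def init_ring_polymer(config, spec: SimulationSpec, masses=None,
                      thermal_spread: bool = False) -> RingPolymerState:
    """Beads at the classical positions, Maxwell-Boltzmann momenta at T_P.

    ``config`` is a Configuration (or a bare (N,3) coordinate array with
    explicit ``masses``).  With ``thermal_spread`` the non-centroid modes
    get their free-ring-polymer thermal width instead of zero.
    """
    if isinstance(config, Configuration):
        coords = config.coords
        masses = config.masses
        box = config.box_edge
    else:
        coords = np.asarray(config, dtype=float)
        if masses is None:
            raise ValueError("masses required for bare coordinate input")
        masses = np.asarray(masses, dtype=float)
        box = None
    if box is not None and spec.cutoff > box / 2.0 + 1e-9:
        raise ValueError(
            f"cutoff {spec.cutoff} A exceeds half the box edge {box / 2:.3f}"
        )
    P = spec.n_beads
    N = len(masses)
    rng = np.random.default_rng(spec.seed)
    kT_p = KB_MDU * spec.temperature * P
    x = np.repeat(coords[None], P, axis=0).astype(float)
    if thermal_spread and P > 1:
        freqs = normal_mode_frequencies(P, spec.temperature)
        modes = to_normal_modes(x)
        for k in range(1, P):
            sigma = np.sqrt(kT_p / masses / freqs[k] ** 2)
            modes[k] += rng.normal(size=(N, 3)) * sigma[:, None]
        x = from_normal_modes(modes)
    sigma_p = np.sqrt(kT_p * masses)[None, :, None]
    p = rng.normal(size=(P, N, 3)) * sigma_p
    state = RingPolymerState(
        x=x, p=p, masses=masses, box_edge=box,
        temperature=spec.temperature,
    )
    if spec.ensemble in ("nvt", "npt"):
        state.nhc_xi = np.zeros((NHC_LENGTH, P, N, 3))
        state.nhc_vxi = np.zeros((NHC_LENGTH, P, N, 3))
    if spec.ensemble == "npt":
        state.baro_nhc_xi = np.zeros(NHC_LENGTH)
        state.baro_nhc_vxi = np.zeros(NHC_LENGTH)
    return state


# ---------------------------------------------------------------------------
# thermostats

def _mode_thermostat_masses(spec: SimulationSpec, P: int) -> np.ndarray:
    """Q per mode (broadcast over atoms/dims): kT_P tau_k^2, with the
    centroid tau from the spec and tau_k = 1/w_k for internal modes."""
    kT_p = KB_MDU * spec.temperature * P
    tau = np.full(P, spec.tau_thermostat)
    if P > 1:
        freqs = normal_mode_frequencies(P, spec.temperature)
        tau[1:] = 1.0 / freqs[1:]
    return kT_p * tau**2  # (P,)


def _nhc_update(p_modes, masses, Q, kT, xi, vxi, dt2):
    """Massive NHC half-step acting on normal-mode momenta (in place).

    p_modes: (P,N,3); Q: (M,P,1,1); xi/vxi: (M,P,N,3).
    Returns the updated p_modes.
    """
    M = xi.shape[0]
    m3 = masses[None, :, None]
    for w in _SY_WEIGHTS:
        d = w * dt2
        d2 = d / 2.0
        d4 = d / 4.0
        pkin = p_modes**2 / m3
        G = (Q[M - 2] * vxi[M - 2] ** 2 - kT) / Q[M - 1]
        vxi[M - 1] += d2 * G
        for j in range(M - 2, -1, -1):
            s = np.exp(-d4 * vxi[j + 1])
            if j == 0:
                G = (pkin - kT) / Q[0]
            else:
                G = (Q[j - 1] * vxi[j - 1] ** 2 - kT) / Q[j]
            vxi[j] = (vxi[j] * s + d2 * G) * s
        scale = np.exp(-d * vxi[0])
        p_modes = p_modes * scale
        pkin = pkin * scale**2
        xi += d * vxi
        for j in range(M - 1):
            s = np.exp(-d4 * vxi[j + 1])
            if j == 0:
                G = (pkin - kT) / Q[0]
            else:
                G = (Q[j - 1] * vxi[j - 1] ** 2 - kT) / Q[j]
            vxi[j] = (vxi[j] * s + d2 * G) * s
        G = (Q[M - 2] * vxi[M - 2] ** 2 - kT) / Q[M - 1]
        vxi[M - 1] += d2 * G
    return p_modes


def _thermostat_half(state: RingPolymerState, spec: SimulationSpec):
    P = state.n_beads
    Q = _mode_thermostat_masses(spec, P)[None, :, None, None] \
        * np.ones((NHC_LENGTH, 1, 1, 1))
    kT_p = KB_MDU * spec.temperature * P
    pm = to_normal_modes(state.p)
    pm = _nhc_update(pm, state.masses, Q, kT_p, state.nhc_xi,
                     state.nhc_vxi, spec.dt / 2.0)
    state.p = from_normal_modes(pm)


# ---------------------------------------------------------------------------
# integration

def _free_rp_drift(state: RingPolymerState, spec: SimulationSpec,
                   scale_centroid: float = 1.0,
                   drift_factor: float | None = None):
    """Exact free-ring-polymer evolution over dt (normal modes); the
    centroid drifts ballistically (optionally with barostat scaling)."""
    dt = spec.dt
    P = state.n_beads
    m = state.masses[None, :, None]
    xm = to_normal_modes(state.x)
    pm = to_normal_modes(state.p)
    if drift_factor is None:
        xm[0] = xm[0] * scale_centroid + dt * pm[0] / m[0]
    else:
        xm[0] = xm[0] * scale_centroid + dt * pm[0] / m[0] * drift_factor
    if P > 1:
        freqs = normal_mode_frequencies(P, spec.temperature)
        for k in range(1, P):
            w = freqs[k]
            c, s = np.cos(w * dt), np.sin(w * dt)
            xk = xm[k].copy()
            xm[k] = c * xk + (s / (m[0] * w)) * pm[k]
            pm[k] = -m[0] * w * s * xk + c * pm[k]
    state.x = from_normal_modes(xm)
    state.p = from_normal_modes(pm)


def spring_energy(state: RingPolymerState, spec: SimulationSpec) -> float:
    """Ring-polymer spring energy (internal units)."""
    P = state.n_beads
    if P == 1:
        return 0.0
    freqs = normal_mode_frequencies(P, spec.temperature)
    xm = to_normal_modes(state.x)
    m = state.masses[None, :, None]
    e = 0.0
    for k in range(1, P):
        e += 0.5 * np.sum(m * freqs[k] ** 2 * xm[k][None] ** 2)
    return float(e)


def kinetic_energy(state: RingPolymerState) -> float:
    """Bead kinetic energy (internal units)."""
    return float(0.5 * np.sum(state.p**2 / state.masses[None, :, None]))


def instantaneous_temperature(state: RingPolymerState) -> float:
    """Temperature from the bead kinetic energy (each dof carries
    k_B T_P / 2 = P k_B T / 2)."""
    P, N = state.n_beads, state.n_atoms
    return 2.0 * kinetic_energy(state) / (3.0 * N * P * P * KB_MDU)


def conserved_quantity(state: RingPolymerState, spec: SimulationSpec) -> float:
    """Extended-system conserved quantity (kcal/mol)."""
    P = state.n_beads
    h = kinetic_energy(state) + spring_energy(state, spec)
    if state.potential_beads is not None:
        h += state.potential_beads.sum() * KCAL_TO_MDU
    if state.nhc_vxi is not None:
        kT_p = KB_MDU * spec.temperature * P
        Q = _mode_thermostat_masses(spec, P)[None, :, None, None]
        h += 0.5 * float(np.sum(Q * state.nhc_vxi**2))
        h += kT_p * float(np.sum(state.nhc_xi))
    if state.baro_nhc_vxi is not None and state.box_edge is not None:
        kT_p = KB_MDU * spec.temperature * P
        W = _piston_mass(state, spec)
        Qb = kT_p * spec.tau_barostat**2
        h += 0.5 * W * state.baro_v**2
        h += 0.5 * Qb * float(np.sum(state.baro_nhc_vxi**2))
        h += kT_p * float(np.sum(state.baro_nhc_xi))
        p_ext = spec.pressure * ATM_TO_KCAL_A3 * KCAL_TO_MDU
        h += P * p_ext * state.box_edge**3
    return h / KCAL_TO_MDU


def primitive_kinetic_estimator(state: RingPolymerState,
                                spec: SimulationSpec) -> float:
    """Primitive quantum kinetic-energy estimator (kcal/mol):
    3NP/(2 beta) - E_spring / P."""
    P, N = state.n_beads, state.n_atoms
    beta = 1.0 / (KB_MDU * spec.temperature)
    k = 1.5 * N * P / beta - spring_energy(state, spec) / P
    return k / KCAL_TO_MDU


def virial_kinetic_estimator(state: RingPolymerState,
                             spec: SimulationSpec) -> float:
    """Centroid-virial kinetic-energy estimator (kcal/mol):
    3N/(2 beta) - (1/2P) sum_s (x_s - xbar) . F_s."""
    P, N = state.n_beads, state.n_atoms
    beta = 1.0 / (KB_MDU * spec.temperature)
    if state.forces is None:
        raise ValueError("state carries no cached forces")
    xbar = state.x.mean(axis=0, keepdims=True)
    k = 1.5 * N / beta - np.sum((state.x - xbar) * state.forces) / (2.0 * P)
    return float(k) / KCAL_TO_MDU


def step(state: RingPolymerState, provider, spec: SimulationSpec
         ) -> RingPolymerState:
    """One NVT/NVE velocity-Verlet + exact-free-ring-polymer step."""
    if state.forces is None:
        state.potential_beads, state.forces = _eval_forces(provider, state)
    dt2 = spec.dt / 2.0
    if spec.ensemble == "nvt":
        _thermostat_half(state, spec)
    state.p = state.p + dt2 * state.forces
    _free_rp_drift(state, spec)
    state.potential_beads, state.forces = _eval_forces(provider, state)
    state.p = state.p + dt2 * state.forces
    if spec.ensemble == "nvt":
        _thermostat_half(state, spec)
    state.step_count += 1
    return state


# ---------------------------------------------------------------------------
# NPT

def _piston_mass(state: RingPolymerState, spec: SimulationSpec) -> float:
    kT_p = KB_MDU * spec.temperature * state.n_beads
    return 3.0 * (state.n_atoms + 1) * kT_p * spec.tau_barostat**2


def internal_pressure(state: RingPolymerState, provider,
                      spec: SimulationSpec) -> float:
    """Bead-averaged virial pressure (atm) from centroid kinetic energy and
    a central-difference volume derivative of the bead-summed potential."""
    p_int = _internal_pressure_mdu(state, provider, spec)
    return p_int / state.n_beads / (ATM_TO_KCAL_A3 * KCAL_TO_MDU)


def _internal_pressure_mdu(state, provider, spec) -> float:
    """P_int in internal units and the T_P convention (balances P * P_ext)."""
    L = state.box_edge
    V = L**3
    pm = to_normal_modes(state.p)
    twice_kc = float(np.sum(pm[0] ** 2 / state.masses[:, None]))
    dlnv = 1e-6
    s_hi = (1.0 + dlnv) ** (1.0 / 3.0)
    s_lo = (1.0 - dlnv) ** (1.0 / 3.0)
    xbar = state.x.mean(axis=0, keepdims=True)
    u_hi = u_lo = 0.0
    for s in range(state.n_beads):
        xs_hi = state.x[s] + xbar[0] * (s_hi - 1.0)
        xs_lo = state.x[s] + xbar[0] * (s_lo - 1.0)
        u_hi += _provider_energy(provider, xs_hi, L * s_hi, key=s)
        u_lo += _provider_energy(provider, xs_lo, L * s_lo, key=s)
    dudv = (u_hi - u_lo) * KCAL_TO_MDU / (2.0 * dlnv * V)
    return (twice_kc / 3.0) / V - dudv + \
        (state.n_beads - 1) * 0.0  # springs invariant under centroid scaling


def _baro_thermostat_half(state: RingPolymerState, spec: SimulationSpec,
                          W: float):
    # reuse the massive NHC update with a single "dof" of mass W
    kT_p = KB_MDU * spec.temperature * state.n_beads
    Q = kT_p * spec.tau_barostat**2 * np.ones((NHC_LENGTH, 1, 1, 1))
    pe = np.full((1, 1, 1), state.baro_v * W)
    pe = _nhc_update(pe, np.array([W]), Q, kT_p,
                     state.baro_nhc_xi.reshape(NHC_LENGTH, 1, 1, 1),
                     state.baro_nhc_vxi.reshape(NHC_LENGTH, 1, 1, 1),
                     spec.dt / 2.0)
    state.baro_v = float(pe.ravel()[0]) / W


def step_npt(state: RingPolymerState, provider, spec: SimulationSpec
             ) -> RingPolymerState:
    """One isotropic-MTK NPT step (barostat on the centroid mode)."""
    if state.box_edge is None:
        raise ValueError("NPT requires a periodic system")
    if state.forces is None:
        state.potential_beads, state.forces = _eval_forces(provider, state)
    dt = spec.dt
    dt2 = dt / 2.0
    P = state.n_beads
    N = state.n_atoms
    W = _piston_mass(state, spec)
    p_ext = spec.pressure * ATM_TO_KCAL_A3 * KCAL_TO_MDU  # internal units
    alpha = 1.0 + 3.0 / (3.0 * N)

    _baro_thermostat_half(state, spec, W)
    _thermostat_half(state, spec)
    # piston half kick
    V = state.box_edge**3
    p_int = _internal_pressure_mdu(state, provider, spec)
    g_eps = 3.0 * V * (p_int - P * p_ext) \
        + (3.0 / (3.0 * N)) * _twice_centroid_kinetic(state)
    state.baro_v += dt2 * g_eps / W
    # momentum half kick + centroid-momentum barostat scaling
    state.p = state.p + dt2 * state.forces
    _scale_centroid_momenta(state, np.exp(-dt2 * alpha * state.baro_v))
    # drift with box scaling
    a = dt * state.baro_v
    scale = np.exp(a)
    drift = np.exp(a / 2.0) * (np.sinh(a / 2.0) / (a / 2.0) if a != 0 else 1.0)
    _free_rp_drift(state, spec, scale_centroid=scale, drift_factor=drift)
    state.box_edge *= scale
    if state.box_edge < 2.0 * spec.cutoff:
        raise RuntimeError(
            f"box collapse: edge {state.box_edge:.3f} A fell below twice "
            f"the cutoff {spec.cutoff} A"
        )
    state.potential_beads, state.forces = _eval_forces(provider, state)
    _scale_centroid_momenta(state, np.exp(-dt2 * alpha * state.baro_v))
    state.p = state.p + dt2 * state.forces
    V = state.box_edge**3
    p_int = _internal_pressure_mdu(state, provider, spec)
    g_eps = 3.0 * V * (p_int - P * p_ext) \
        + (3.0 / (3.0 * N)) * _twice_centroid_kinetic(state)
    state.baro_v += dt2 * g_eps / W
    _thermostat_half(state, spec)
    _baro_thermostat_half(state, spec, W)
    state.step_count += 1
    return state


def _twice_centroid_kinetic(state) -> float:
    pm = to_normal_modes(state.p)
    return float(np.sum(pm[0] ** 2 / state.masses[:, None]))


def _scale_centroid_momenta(state, factor: float):
    pm = to_normal_modes(state.p)
    pm[0] *= factor
    state.p = from_normal_modes(pm)


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class Trajectory:
    """Bead-resolved frames plus per-frame scalars."""

    elements: list
    molecule_index: np.ndarray
    spec: SimulationSpec
    frames: list = field(default_factory=list)    # (P,N,3) arrays
    box_edges: list = field(default_factory=list)
    scalars: pd.DataFrame | None = None
    _rows: list = field(default_factory=list)

    def record(self, state: RingPolymerState, spec: SimulationSpec,
               pressure: float | None = None):
        self.frames.append(state.x.copy())
        self.box_edges.append(state.box_edge)
        row = {
            "step": state.step_count,
            "time_fs": state.step_count * spec.dt,
            "potential_kcal": float(state.potential_beads.mean())
            if state.potential_beads is not None else np.nan,
            "kinetic_primitive_kcal": primitive_kinetic_estimator(state, spec),
            "kinetic_virial_kcal": virial_kinetic_estimator(state, spec)
            if state.forces is not None else np.nan,
            "temperature_K": instantaneous_temperature(state),
            "conserved_kcal": conserved_quantity(state, spec),
            "box_edge_A": state.box_edge if state.box_edge else np.nan,
        }
        if pressure is not None:
            row["pressure_atm"] = pressure
        self._rows.append(row)

    def finalize(self):
        self.scalars = pd.DataFrame(self._rows)
        return self

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def configurations(self, frame: int):
        """One Configuration per bead of the given frame."""
        out = []
        for s in range(self.frames[frame].shape[0]):
            out.append(Configuration(
                elements=list(self.elements),
                coords=self.frames[frame][s].copy(),
                molecule_index=self.molecule_index.copy(),
                box_edge=self.box_edges[frame],
            ))
        return out


def run(config, potential, spec: SimulationSpec,
        state: RingPolymerState | None = None, masses=None,
        progress: bool = False) -> Trajectory:
    """Initialize and propagate; returns the recorded trajectory.

    Fully reproducible under ``spec.seed``.  ``state`` may carry over an
    equilibrated ring polymer from a previous run.  ``config`` is a
    Configuration, or a bare (N, 3) array with explicit ``masses``.
    """
    provider = as_force_provider(potential, config)
    if state is None:
        state = init_ring_polymer(config, spec, masses=masses)
    is_cfg = isinstance(config, Configuration)
    traj = Trajectory(
        elements=list(config.elements) if is_cfg else [],
        molecule_index=(config.molecule_index.copy() if is_cfg
                        else np.zeros(state.n_atoms, dtype=int)),
        spec=spec,
    )
    stepper = step_npt if spec.ensemble == "npt" else step
    state.potential_beads, state.forces = _eval_forces(provider, state)
    pressure = (internal_pressure(state, provider, spec)
                if spec.ensemble == "npt" else None)
    traj.record(state, spec, pressure)
    for i in range(spec.n_steps):
        state = stepper(state, provider, spec)
        if (i + 1) % spec.stride == 0:
            pressure = (internal_pressure(state, provider, spec)
                        if spec.ensemble == "npt" else None)
            traj.record(state, spec, pressure)
        if progress and (i + 1) % max(1, spec.n_steps // 10) == 0:
            print(f"  step {i + 1}/{spec.n_steps}")
    return traj.finalize()
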