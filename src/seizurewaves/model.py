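"""Mean-field cortical sheet with slow extracellular-potassium dynamics.

The fast subsystem is a two-population (excitatory/inhibitory) cortical
mean-field of the Steyn-Ross family: mean soma voltages driven by
conductance-weighted synaptic fluxes, second-order (critically damped)
synaptic filters, and a damped 2D wave equation carrying long-range
excitatory flux at finite axonal speed.  Inhibitory populations are also
coupled to their neighbours diffusively (gap junctions, strength ``D_ii``).
Three modifications tailor it to seizure dynamics:

1. no-flux boundary conditions on the square sheet;
2. depolarization block — a Gaussian roll-off multiplies the sigmoidal
   activation so firing approaches zero as the soma voltage rises past
   -20 mV;
3. a slow subsystem per grid cell: extracellular potassium ``K`` (unitless
   proportion) rises with local population activity, decays, and diffuses::

       dK/dt = -delta*K + C1*max(Qe/Qe_max + Qi/Qi_max - a0, 0) + C2*lap(K)

   and ``K`` in turn closes inhibitory gap junctions and depolarises both
   populations' resting voltages through first-order relaxation (time
   constants ``tau_D`` = 4 s, ``tau_V`` = 25 s) toward K-dependent targets
   (linear in K, clipped).

Seizure scenarios impose an excitability source — a localized rise of the
excitatory resting-voltage offset — that is fixed in space, redrawn at random
locations, or carried on an expanding distorted-circle wavefront (~1 mm/s).
Virtual electrodes (a 3x3 microarray of single cells and nine 12-cell
macro patches) sample excitatory population activity at 500 Hz.

The integrator is stochastic forward Euler; the time step must satisfy the
axonal-wave CFL bound and the diffusion bounds, checked up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recordings import ElectrodeLayout, Recording

__all__ = [
    "ModelParams",
    "SimConfig",
    "FieldState",
    "SimResult",
    "firing_rate",
    "laplacian",
    "step_potassium",
    "step_slow_coupling",
    "step_fast",
    "apply_scenario",
    "init_state",
    "run_simulation",
    "virtual_electrodes",
    "kinematic_waves",
]


@dataclass(frozen=True)
class ModelParams:
    """Mean-field and potassium parameters.

    Fast-subsystem values follow the anaesthesia-model parameter set this
    formulation inherits, with the overrides used for seizure dynamics:
    membrane time constants 0.02 s, axonal conduction speed 280 cm/s,
    subcortical noise scale factor 2.  Slow-subsystem constants:
    ``delta`` = 0.1 /s, ``c1`` = 0.15, ``c2`` = 1 cm^2/s, ``tau_d`` = 4 s,
    ``tau_v`` = 25 s.  The K-coupling gains and the depolarization-block
    width are exposed; defaults were fixed once to produce the staged
    seizure dynamics (mosaic -> local waves -> source-locked waves).
    """

    # --- fast subsystem -------------------------------------------------
    tau_e: float = 0.02          # s, excitatory membrane time constant
    tau_i: float = 0.02          # s, inhibitory membrane time constant
    q_max_e: float = 30.0        # /s, maximal excitatory firing rate
    q_max_i: float = 60.0        # /s, maximal inhibitory firing rate
    theta_e: float = -58.5       # mV, excitatory sigmoid threshold
    theta_i: float = -58.5       # mV, inhibitory sigmoid threshold
    sigma_e: float = 3.0         # mV, excitatory sigmoid width
    sigma_i: float = 5.0         # mV, inhibitory sigmoid width
    v_rev_e: float = 0.0         # mV, excitatory (AMPA) reversal
    v_rev_i: float = -70.0       # mV, inhibitory (GABA) reversal
    v_rest: float = -64.0        # mV, baseline resting voltage
    rho_e: float = 1.00e-3       # mV*s, excitatory synaptic gain
    rho_i: float = -1.05e-3      # mV*s, inhibitory synaptic gain
    gamma_e: float = 170.0       # /s, EPSP rate constant
    gamma_i: float = 50.0        # /s, IPSP rate constant
    n_alpha_ee: float = 2000.0   # long-range e->e connections
    n_alpha_ei: float = 2000.0   # long-range e->i connections
    n_beta_ee: float = 800.0     # local e->e connections
    n_beta_ei: float = 800.0     # local e->i connections
    n_beta_ie: float = 600.0     # local i->e connections
    n_beta_ii: float = 600.0     # local i->i connections
    phi_sc: float = 150.0        # /s, tonic subcortical excitatory flux
    noise_sf: float = 2.0        # subcortical noise scale factor
    noise_base: float = 0.02     # base white-noise amplitude multiplier
    axonal_speed: float = 280.0  # cm/s
    lambda_inv: float = 4.0      # /cm, inverse axonal length scale
    d_ee: float = 0.01           # cm^2, excitatory gap-junction diffusion
    d_ii_base: float = 1.0       # cm^2, baseline inhibitory gap-junction diffusion
    offset_e: float = 0.0        # mV, initial excitatory resting-voltage offset
    offset_i: float = 0.0        # mV, initial inhibitory resting-voltage offset
    # --- depolarization block -------------------------------------------
    block_center: float = -20.0  # mV, firing ~ zero beyond this voltage
    block_onset: float = -40.0   # mV, where the Gaussian roll-off begins
    block_width: float = 10.0    # mV, roll-off width (one sigma)
    # --- slow (potassium) subsystem -------------------------------------
    delta: float = 0.1           # /s, potassium decay rate
    c1: float = 0.15             # potassium source scale factor
    k_act_floor: float = 0.25    # resting activity level absorbed by uptake
    c2: float = 1.0              # cm^2/s, potassium diffusion coefficient
    tau_d: float = 4.0           # s, gap-junction relaxation time constant
    tau_v: float = 25.0          # s, resting-voltage relaxation time constant
    k_to_v_e: float = 15.0       # mV per unit K, excitatory resting-voltage gain
    k_to_v_i: float = 15.0       # mV per unit K, inhibitory resting-voltage gain
    k_to_d: float = 2.5          # fractional D_ii decrease per unit K
    d_ii_floor: float = 0.2      # cm^2, lower clip for D_ii target
    dv_max: float = 6.0          # mV, upper clip for K-driven depolarization
    offset_jitter_sd: float = 0.0  # mV, quenched per-cell excitability spread
    # --- seizure source --------------------------------------------------
    source_gain: float = 3.0     # threefold increase of the reference offset
    source_ref_offset: float = 1.5  # mV, unmodified-model resting offset

    def __post_init__(self):
        for name in ("tau_e", "tau_i", "gamma_e", "gamma_i", "q_max_e",
                     "q_max_i", "delta", "tau_d", "tau_v", "axonal_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Simulation grid, protocol and scenario.

    Defaults give the headline configuration: a 100x100 grid over a
    300 mm x 300 mm sheet (one cell ~ 9 mm^2 of cortex), 180 s protocol with
    the source inactive for 40 s, active for 100 s, inactive for 40 s, and
    the source at (75 mm, 75 mm).  ``reduced()`` builds the desk-scale
    variant (60x60 over 180 mm, 20/50/20 s).
    """

    grid_n: int = 100
    domain_mm: float = 300.0
    t_pre: float = 40.0
    t_active: float = 100.0
    t_post: float = 40.0
    scenario: str = "fixed_source"
    source_mm: tuple[float, float] = (75.0, 75.0)
    wavefront_speed_mm_s: float = 1.0
    wavefront_jitter_sd: float = 0.5    # lognormal sd of per-sector speed
    wavefront_n_sectors: int = 16
    wavefront_width_cells: float = 1.5
    wavefront_redraw: float = 4.0       # s, sector-speed renewal interval
    redraw_interval: float = 10.0       # s, random-source relocation period
    source_radius_cells: int = 0        # 0 = single-cell source
    seed: int = 0
    dt: float = 4e-4                    # s
    rate: float = 500.0                 # Hz, virtual-electrode sampling rate
    snapshot_every: float = 0.0         # s; 0 disables field snapshots

    @property
    def duration(self) -> float:
        return self.t_pre + self.t_active + self.t_post

    @property
    def dx_cm(self) -> float:
        return self.domain_mm / self.grid_n / 10.0

    @property
    def cell_mm(self) -> float:
        return self.domain_mm / self.grid_n

    def validate(self, params: ModelParams) -> None:
        if self.scenario not in (
            "fixed_source", "random_source", "expanding_wavefront", "quiescent"
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        sx, sy = self.source_mm
        if not (0 <= sx <= self.domain_mm and 0 <= sy <= self.domain_mm):
            raise ValueError("source position must lie on the grid")
        steps_per_sample = (1.0 / self.rate) / self.dt
        if abs(steps_per_sample - round(steps_per_sample)) > 1e-9:
            raise ValueError("dt must evenly divide the sampling interval")
        dx = self.dx_cm
        # long-range flux uses a symplectic/implicitly-damped update, stable
        # for omega_max*dt <= 2 with omega_max^2 = (v*Lambda)^2 + v^2*k_max^2,
        # k_max^2 = 8/dx^2; voltage diffusion keeps the explicit bound
        lam_r = params.axonal_speed * params.lambda_inv
        k_max = np.sqrt(8.0) / dx
        omega = np.hypot(lam_r, params.axonal_speed * k_max)
        d_max = max(params.c2, params.d_ii_base / params.tau_i,
                    params.d_ee / params.tau_e)
        cfl_diff = dx * dx / (4.0 * d_max)
        if omega * self.dt > 1.9 or self.dt > cfl_diff:
            raise ValueError(
                f"dt={self.dt} violates the stability bounds "
                f"(wave omega*dt = {omega * self.dt:.2f} must be <= 1.9; "
                f"diffusion bound {cfl_diff:.2e} s)"
            )

    @classmethod
    def reduced(cls, scenario: str = "fixed_source", seed: int = 0, **kw):
        """Desk-scale configuration: 60x60 grid over 180 mm, 20/50/20 s."""
        defaults = dict(
            grid_n=60, domain_mm=180.0, t_pre=20.0, t_active=50.0,
            t_post=20.0, source_mm=(45.0, 45.0), scenario=scenario, seed=seed,
            source_radius_cells=1,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class FieldState:
    """Per-cell fields of the fast and slow subsystems (2D arrays)."""

    v_e: np.ndarray
    v_i: np.ndarray
    phi_ee: np.ndarray
    phi_ee_d: np.ndarray
    phi_ei: np.ndarray
    phi_ei_d: np.ndarray
    phi_ie: np.ndarray
    phi_ie_d: np.ndarray
    phi_ii: np.ndarray
    phi_ii_d: np.ndarray
    lr_ee: np.ndarray      # long-range excitatory flux (wave equation)
    lr_ee_d: np.ndarray
    lr_ei: np.ndarray
    lr_ei_d: np.ndarray
    k: np.ndarray          # extracellular potassium proportion
    d_ii: np.ndarray       # inhibitory gap-junction coupling, cm^2
    dv_e: np.ndarray       # K-driven excitatory resting-voltage shift, mV
    dv_i: np.ndarray       # K-driven inhibitory resting-voltage shift, mV

    def assert_finite(self, step_index: int) -> None:
        for name in ("v_e", "v_i", "k"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise FloatingPointError(
                    f"non-finite {name} at step {step_index}: integration aborted"
                )


def firing_rate(
    v: np.ndarray, params: ModelParams, population: str = "e"
) -> np.ndarray:
    """Population firing rate with depolarization block (per second).

    Sigmoidal activation multiplied by a one-sided Gaussian roll-off: below
    ``block_onset`` the sigmoid is untouched; above it the rate falls off
    with width ``block_width`` so firing approaches zero as the voltage
    exceeds ``block_center`` (-20 mV).
    """
    v = np.asarray(v, float)
    if population == "e":
        q_max, theta, sigma = params.q_max_e, params.theta_e, params.sigma_e
    else:
        q_max, theta, sigma = params.q_max_i, params.theta_i, params.sigma_i
    c = np.pi / np.sqrt(3.0)
    with np.errstate(over="ignore"):
        q = q_max / (1.0 + np.exp(-c * (v - theta) / sigma))
    excess = np.maximum(v - params.block_onset, 0.0)
    return q * np.exp(-0.5 * (excess / params.block_width) ** 2)


def laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with no-flux (mirrored ghost cell) boundaries."""
    p = np.pad(f, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f
    ) / (dx * dx)


def step_potassium(
    state: FieldState,
    q_e: np.ndarray,
    q_i: np.ndarray,
    dt: float,
    dx_cm: float,
    params: ModelParams,
) -> None:
    """One Euler step of the potassium field (in place).

    ``dK/dt = -delta*K + c1*max(a - a0, 0) + c2*lap(K)`` with activity
    ``a = Qe/Qe_max + Qi/Qi_max`` and ``a0`` the resting activity absorbed
    by glial uptake (``k_act_floor``), so K measures the ictal *excess* of
    extracellular potassium.  The sum of K is conserved by the diffusion
    term under no-flux boundaries.
    """
    act = q_e / params.q_max_e + q_i / params.q_max_i
    src = params.c1 * np.maximum(act - params.k_act_floor, 0.0)
    state.k += dt * (
        -params.delta * state.k + src + params.c2 * laplacian(state.k, dx_cm)
    )
    np.maximum(state.k, 0.0, out=state.k)


def slow_targets(
    k: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-dependent targets for (D_ii, dV_e, dV_i): linear in K, clipped."""
    d_t = np.clip(
        params.d_ii_base * (1.0 - params.k_to_d * k),
        params.d_ii_floor, None,
    )
    dv_e_t = np.clip(params.k_to_v_e * k, 0.0, params.dv_max)
    dv_i_t = np.clip(params.k_to_v_i * k, 0.0, params.dv_max)
    return d_t, dv_e_t, dv_i_t


def step_slow_coupling(state: FieldState, dt: float, params: ModelParams) -> None:
    """Relax D_ii (tau 4 s) and resting-voltage shifts (tau 25 s) toward
    their K-dependent targets (in place)."""
    d_t, dv_e_t, dv_i_t = slow_targets(state.k, params)
    state.d_ii += dt / params.tau_d * (d_t - state.d_ii)
    np.maximum(state.d_ii, 0.0, out=state.d_ii)
    state.dv_e += dt / params.tau_v * (dv_e_t - state.dv_e)
    state.dv_i += dt / params.tau_v * (dv_i_t - state.dv_i)


def step_fast(
    state: FieldState,
    dt: float,
    dx_cm: float,
    params: ModelParams,
    rng: np.random.Generator | None,
    source_offset: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic Euler step of the fast subsystem (in place).

    ``source_offset`` (mV) is the scenario's excitability modification added
    to the excitatory resting voltage.  Returns the firing-rate fields
    (Q_e, Q_i) evaluated at the *start* of the step.
    """
    p = params
    q_e = firing_rate(state.v_e, p, "e")
    q_i = firing_rate(state.v_i, p, "i")

    # conductance-like reversal weighting, normalised at rest
    psi_e_on_e = (p.v_rev_e - state.v_e) / (p.v_rev_e - p.v_rest)
    psi_e_on_i = (p.v_rev_e - state.v_i) / (p.v_rev_e - p.v_rest)
    psi_i_on_e = (p.v_rev_i - state.v_e) / (p.v_rev_i - p.v_rest)
    psi_i_on_i = (p.v_rev_i - state.v_i) / (p.v_rev_i - p.v_rest)

    v_rest_e = p.v_rest + p.offset_e + state.dv_e + source_offset
    v_rest_i = p.v_rest + p.offset_i + state.dv_i

    dv_e = (
        v_rest_e - state.v_e
        + p.rho_e * psi_e_on_e * state.phi_ee
        + p.rho_i * psi_i_on_e * state.phi_ie
        + p.d_ee * laplacian(state.v_e, dx_cm)
    ) / p.tau_e
    dv_i = (
        v_rest_i - state.v_i
        + p.rho_e * psi_e_on_i * state.phi_ei
        + p.rho_i * psi_i_on_i * state.phi_ii
        + state.d_ii * laplacian(state.v_i, dx_cm)
    ) / p.tau_i

    # subcortical drive with white noise (scaled so spectral density is
    # dt-independent); kept nonnegative as a flux
    if rng is not None and p.noise_sf > 0:
        shape = state.v_e.shape
        amp = p.noise_sf * p.noise_base * np.sqrt(p.phi_sc / dt)
        sc_e = np.maximum(p.phi_sc + amp * rng.standard_normal(shape), 0.0)
        sc_i = np.maximum(p.phi_sc + amp * rng.standard_normal(shape), 0.0)
    else:
        sc_e = p.phi_sc
        sc_i = p.phi_sc

    ge2, gi2 = p.gamma_e**2, p.gamma_i**2
    dphi_ee_d = ge2 * (p.n_alpha_ee * state.lr_ee + p.n_beta_ee * q_e + sc_e) \
        - 2.0 * p.gamma_e * state.phi_ee_d - ge2 * state.phi_ee
    dphi_ei_d = ge2 * (p.n_alpha_ei * state.lr_ei + p.n_beta_ei * q_e + sc_i) \
        - 2.0 * p.gamma_e * state.phi_ei_d - ge2 * state.phi_ei
    dphi_ie_d = gi2 * (p.n_beta_ie * q_i) \
        - 2.0 * p.gamma_i * state.phi_ie_d - gi2 * state.phi_ie
    dphi_ii_d = gi2 * (p.n_beta_ii * q_i) \
        - 2.0 * p.gamma_i * state.phi_ii_d - gi2 * state.phi_ii

    v_lam = p.axonal_speed * p.lambda_inv
    v2 = p.axonal_speed**2

    state.v_e += dt * dv_e
    state.v_i += dt * dv_i
    state.phi_ee += dt * state.phi_ee_d
    state.phi_ee_d += dt * dphi_ee_d
    state.phi_ei += dt * state.phi_ei_d
    state.phi_ei_d += dt * dphi_ei_d
    state.phi_ie += dt * state.phi_ie_d
    state.phi_ie_d += dt * dphi_ie_d
    state.phi_ii += dt * state.phi_ii_d
    state.phi_ii_d += dt * dphi_ii_d
    # long-range flux: symplectic drift, then implicitly damped kick
    # (stable for omega*dt <= 2 rather than the explicit-Euler bound)
    state.lr_ee += dt * state.lr_ee_d
    state.lr_ei += dt * state.lr_ei_d
    damp = 1.0 / (1.0 + 2.0 * v_lam * dt)
    state.lr_ee_d += dt * (
        v_lam**2 * (q_e - state.lr_ee) + v2 * laplacian(state.lr_ee, dx_cm)
    )
    state.lr_ee_d *= damp
    state.lr_ei_d += dt * (
        v_lam**2 * (q_e - state.lr_ei) + v2 * laplacian(state.lr_ei, dx_cm)
    )
    state.lr_ei_d *= damp
    return q_e, q_i


try:  # fused stepper: ~5x faster than the vectorised path on small grids
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _fused_step(
        v_e, v_i, phi_ee, phi_ee_d, phi_ei, phi_ei_d, phi_ie, phi_ie_d,
        phi_ii, phi_ii_d, lr_ee, lr_ee_d, lr_ei, lr_ei_d,
        d_ii, dv_e_f, dv_i_f, src, noise_e, noise_i, q_e_out, q_i_out,
        dt, inv_dx2,
        tau_e, tau_i, q_max_e, q_max_i, theta_e, theta_i, sigma_e, sigma_i,
        v_rev_e, v_rev_i, v_rest, rho_e, rho_i, gamma_e, gamma_i,
        n_alpha_ee, n_alpha_ei, n_beta_ee, n_beta_ei, n_beta_ie, n_beta_ii,
        phi_sc, noise_amp, speed, lam_inv, d_ee,
        offset_e, offset_i, block_onset, block_width,
    ):
        n0, n1 = v_e.shape
        c = np.pi / np.sqrt(3.0)
        ge2 = gamma_e * gamma_e
        gi2 = gamma_i * gamma_i
        v_lam = speed * lam_inv
        v2 = speed * speed
        inv_e = 1.0 / (v_rev_e - v_rest)
        inv_i = 1.0 / (v_rev_i - v_rest)
        damp = 1.0 / (1.0 + 2.0 * v_lam * dt)
        dv_e_new = np.empty((n0, n1))
        dv_i_new = np.empty((n0, n1))
        for i in range(n0):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n0 - 1 else n0 - 1
            for j in range(n1):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n1 - 1 else n1 - 1
                ve = v_e[i, j]
                vi = v_i[i, j]
                # firing rates with depolarization block
                qe = q_max_e / (1.0 + np.exp(-c * (ve - theta_e) / sigma_e))
                ex = ve - block_onset
                if ex > 0.0:
                    qe *= np.exp(-0.5 * (ex / block_width) ** 2)
                qi = q_max_i / (1.0 + np.exp(-c * (vi - theta_i) / sigma_i))
                ex = vi - block_onset
                if ex > 0.0:
                    qi *= np.exp(-0.5 * (ex / block_width) ** 2)
                q_e_out[i, j] = qe
                q_i_out[i, j] = qi

                lap_ve = (v_e[im, j] + v_e[ip, j] + v_e[i, jm] + v_e[i, jp]
                          - 4.0 * ve) * inv_dx2
                lap_vi = (v_i[im, j] + v_i[ip, j] + v_i[i, jm] + v_i[i, jp]
                          - 4.0 * vi) * inv_dx2
                vre = v_rest + offset_e + dv_e_f[i, j] + src[i, j]
                vri = v_rest + offset_i + dv_i_f[i, j]
                dv_e_new[i, j] = (
                    vre - ve
                    + rho_e * (v_rev_e - ve) * inv_e * phi_ee[i, j]
                    + rho_i * (v_rev_i - ve) * inv_i * phi_ie[i, j]
                    + d_ee * lap_ve
                ) / tau_e
                dv_i_new[i, j] = (
                    vri - vi
                    + rho_e * (v_rev_e - vi) * inv_e * phi_ei[i, j]
                    + rho_i * (v_rev_i - vi) * inv_i * phi_ii[i, j]
                    + d_ii[i, j] * lap_vi
                ) / tau_i
        for i in range(n0):
            for j in range(n1):
                qe = q_e_out[i, j]
                qi = q_i_out[i, j]
                sc_e = phi_sc + noise_amp * noise_e[i, j]
                if sc_e < 0.0:
                    sc_e = 0.0
                sc_i = phi_sc + noise_amp * noise_i[i, j]
                if sc_i < 0.0:
                    sc_i = 0.0
                da = (ge2 * (n_alpha_ee * lr_ee[i, j] + n_beta_ee * qe + sc_e)
                      - 2.0 * gamma_e * phi_ee_d[i, j] - ge2 * phi_ee[i, j])
                db = (ge2 * (n_alpha_ei * lr_ei[i, j] + n_beta_ei * qe + sc_i)
                      - 2.0 * gamma_e * phi_ei_d[i, j] - ge2 * phi_ei[i, j])
                dc = (gi2 * n_beta_ie * qi
                      - 2.0 * gamma_i * phi_ie_d[i, j] - gi2 * phi_ie[i, j])
                dd = (gi2 * n_beta_ii * qi
                      - 2.0 * gamma_i * phi_ii_d[i, j] - gi2 * phi_ii[i, j])
                v_e[i, j] += dt * dv_e_new[i, j]
                v_i[i, j] += dt * dv_i_new[i, j]
                phi_ee[i, j] += dt * phi_ee_d[i, j]
                phi_ee_d[i, j] += dt * da
                phi_ei[i, j] += dt * phi_ei_d[i, j]
                phi_ei_d[i, j] += dt * db
                phi_ie[i, j] += dt * phi_ie_d[i, j]
                phi_ie_d[i, j] += dt * dc
                phi_ii[i, j] += dt * phi_ii_d[i, j]
                phi_ii_d[i, j] += dt * dd
        # long-range flux: symplectic drift then implicitly damped kick
        for i in range(n0):
            for j in range(n1):
                lr_ee[i, j] += dt * lr_ee_d[i, j]
                lr_ei[i, j] += dt * lr_ei_d[i, j]
        for i in range(n0):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < n0 - 1 else n0 - 1
            for j in range(n1):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < n1 - 1 else n1 - 1
                lap_le = (lr_ee[im, j] + lr_ee[ip, j] + lr_ee[i, jm]
                          + lr_ee[i, jp] - 4.0 * lr_ee[i, j]) * inv_dx2
                lap_li = (lr_ei[im, j] + lr_ei[ip, j] + lr_ei[i, jm]
                          + lr_ei[i, jp] - 4.0 * lr_ei[i, j]) * inv_dx2
                lr_ee_d[i, j] = damp * (
                    lr_ee_d[i, j]
                    + dt * (v_lam * v_lam * (q_e_out[i, j] - lr_ee[i, j])
                            + v2 * lap_le)
                )
                lr_ei_d[i, j] = damp * (
                    lr_ei_d[i, j]
                    + dt * (v_lam * v_lam * (q_e_out[i, j] - lr_ei[i, j])
                            + v2 * lap_li)
                )

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def init_state(config: SimConfig, params: ModelParams) -> FieldState:
    """Spatially uniform state at the (approximate) healthy fixed point.

    Voltages start at the offset resting values, synaptic and long-range
    fluxes at their steady-state values for the corresponding firing rates,
    and the slow variables at their K-equilibrium.
    """
    n = config.grid_n
    p = params
    v_e = np.full((n, n), p.v_rest + p.offset_e)
    v_i = np.full((n, n), p.v_rest + p.offset_i)
    q_e = firing_rate(v_e, p, "e")
    q_i = firing_rate(v_i, p, "i")
    act = q_e / p.q_max_e + q_i / p.q_max_i
    k_eq = p.c1 * np.maximum(act - p.k_act_floor, 0.0) / p.delta
    d_t, dv_e_t, dv_i_t = slow_targets(k_eq, p)
    z = np.zeros((n, n))
    return FieldState(
        v_e=v_e, v_i=v_i,
        phi_ee=p.n_alpha_ee * q_e + p.n_beta_ee * q_e + p.phi_sc,
        phi_ee_d=z.copy(),
        phi_ei=p.n_alpha_ei * q_e + p.n_beta_ei * q_e + p.phi_sc,
        phi_ei_d=z.copy(),
        phi_ie=p.n_beta_ie * q_i, phi_ie_d=z.copy(),
        phi_ii=p.n_beta_ii * q_i, phi_ii_d=z.copy(),
        lr_ee=q_e.copy(), lr_ee_d=z.copy(),
        lr_ei=q_e.copy(), lr_ei_d=z.copy(),
        k=k_eq, d_ii=d_t, dv_e=dv_e_t, dv_i=dv_i_t,
    )


class _Scenario:
    """Precomputes the scenario's per-step excitability modification."""

    def __init__(self, config: SimConfig, params: ModelParams,
                 rng: np.random.Generator):
        self.config = config
        self.params = params
        n = config.grid_n
        cell = config.cell_mm
        # cell-centre coordinates in mm; x varies along axis 1 (columns)
        xs = (np.arange(n) + 0.5) * cell
        self.xx, self.yy = np.meshgrid(xs, xs, indexing="xy")
        # active source: V_rest^e offset raised to source_gain * the
        # reference offset (the elevation is applied on top of offset_e)
        self.source_amp = (
            params.source_gain * params.source_ref_offset - params.offset_e
        )
        sx, sy = config.source_mm
        self.source_cell = (
            min(int(sy / cell), n - 1), min(int(sx / cell), n - 1)
        )
        if config.scenario == "random_source":
            n_draws = int(np.ceil(config.t_active / config.redraw_interval))
            self.random_cells = [
                (int(r), int(c))
                for r, c in zip(
                    rng.integers(0, n, n_draws), rng.integers(0, n, n_draws)
                )
            ]
        if config.scenario == "expanding_wavefront":
            # per-angular-sector radial speeds (lognormal, mean ~1 mm/s),
            # renewed every ``wavefront_redraw`` seconds so the fastest-
            # advancing (most strongly igniting) stretch of the front moves
            # around the ring over time; radii are the running integral of
            # the sector speeds
            s = config.wavefront_jitter_sd
            mu = -0.5 * np.log(1 + s * s)
            sig = np.sqrt(np.log(1 + s * s))
            n_draws = int(np.ceil(config.t_active / config.wavefront_redraw)) + 1
            self.sector_speeds = config.wavefront_speed_mm_s * rng.lognormal(
                mu, sig, (n_draws, config.wavefront_n_sectors)
            )
            # the ictal wavefront recruits the recorded territory: the ring
            # expands around the domain centre, so the electrodes sit in the
            # seizing region behind the front
            cx = cy = config.domain_mm / 2.0
            dxm = self.xx - cx
            dym = self.yy - cy
            self.radius = np.hypot(dxm, dym)
            ang = np.arctan2(dym, dxm)
            self.sector = (
                ((ang + np.pi) / (2 * np.pi) * config.wavefront_n_sectors)
                .astype(int) % config.wavefront_n_sectors
            )

    def _paint(self, out: np.ndarray, cell: tuple[int, int]) -> None:
        r = self.config.source_radius_cells
        n = self.config.grid_n
        r0, c0 = cell
        out[max(r0 - r, 0):min(r0 + r + 1, n),
            max(c0 - r, 0):min(c0 + r + 1, n)] = self.source_amp

    def offset(self, t: float) -> np.ndarray | float:
        """Excitatory resting-voltage modification field (mV) at time t."""
        cfg = self.config
        if cfg.scenario == "quiescent":
            return 0.0
        t_on = cfg.t_pre
        t_off = cfg.t_pre + cfg.t_active
        if t < t_on or t >= t_off:
            return 0.0
        out = np.zeros_like(self.xx)
        if cfg.scenario == "fixed_source":
            self._paint(out, self.source_cell)
        elif cfg.scenario == "random_source":
            i = min(
                int((t - t_on) / cfg.redraw_interval),
                len(self.random_cells) - 1,
            )
            self._paint(out, self.random_cells[i])
        elif cfg.scenario == "expanding_wavefront":
            # integrate sector speeds up to t (piecewise-constant renewal)
            tau = t - t_on
            n_full = int(tau / cfg.wavefront_redraw)
            rem = tau - n_full * cfg.wavefront_redraw
            r_sect = (
                self.sector_speeds[:n_full].sum(axis=0) * cfg.wavefront_redraw
                + self.sector_speeds[n_full] * rem
            )
            r_t = r_sect[self.sector]
            width = cfg.wavefront_width_cells * cfg.cell_mm
            on_front = np.abs(self.radius - r_t) <= width / 2.0
            out[on_front] = self.source_amp
        return out


def virtual_electrodes(
    config: SimConfig,
    ring_radius_cells: int = 8,
) -> tuple[ElectrodeLayout, ElectrodeLayout, list, list]:
    """Virtual electrode geometry on the simulation grid.

    Returns ``(micro_layout, macro_layout, micro_cells, macro_cells)`` where
    ``micro_cells`` holds one ``(row, col)`` per microelectrode (3x3 block of
    single cells at the domain centre) and ``macro_cells`` one list of twelve
    ``(row, col)`` per macroelectrode (3x4-cell patches, ~108 mm^2 at the
    headline cell size, in a ring around the microarray).  Positions are
    cell/patch centroids in mm in the domain frame.
    """
    n = config.grid_n
    cell = config.cell_mm
    c0 = n // 2
    micro_cells = [(c0 + dr, c0 + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    micro_pos = np.array(
        [((c + 0.5) * cell, (r + 0.5) * cell) for r, c in micro_cells]
    )
    micro = ElectrodeLayout(
        ids=tuple(f"v{k}" for k in range(9)), scale="micro", positions=micro_pos
    )
    macro_cells: list[list[tuple[int, int]]] = []
    macro_pos = []
    for k in range(9):
        ang = 2 * np.pi * k / 9.0
        rc = int(round(c0 + ring_radius_cells * np.sin(ang)))
        cc = int(round(c0 + ring_radius_cells * np.cos(ang)))
        cells = [
            (rc + dr, cc + dc) for dr in (-1, 0, 1) for dc in (-2, -1, 0, 1)
        ]
        cells = [
            (min(max(r, 0), n - 1), min(max(c, 0), n - 1)) for r, c in cells
        ]
        macro_cells.append(cells)
        pos = np.array([((c + 0.5) * cell, (r + 0.5) * cell) for r, c in cells])
        macro_pos.append(pos.mean(axis=0))
    macro = ElectrodeLayout(
        ids=tuple(f"V{k}" for k in range(9)),
        scale="macro",
        positions=np.array(macro_pos),
    )
    seen: set = set()
    for cells in macro_cells:
        for rc in cells:
            if rc in seen:
                raise ValueError("macro patches overlap; reduce patch size "
                                 "or increase ring radius")
            seen.add(rc)
    if seen & set(micro_cells):
        raise ValueError("macro patches overlap the microarray")
    return micro, macro, micro_cells, macro_cells


@dataclass
class SimResult:
    """Virtual recordings plus optional field snapshots and slow-field traces."""

    micro: Recording
    macro: Recording
    config: SimConfig
    params: ModelParams
    snapshots: list = field(default_factory=list)
    snapshot_times: list = field(default_factory=list)
    k_mean: np.ndarray | None = None
    k_times: np.ndarray | None = None


def run_simulation(
    config: SimConfig,
    params: ModelParams = ModelParams(),
    progress: bool = False,
) -> SimResult:
    """Integrate the field model and return virtual-electrode recordings.

    The virtual signals are the excitatory firing-rate fields sampled at
    ``config.rate`` (micro: single cells; macro: 12-cell patch means).
    Seizure onset/offset annotations mark source activation/deactivation.
    Identical configuration and seed give identical output.
    """
    config.validate(params)
    p = params
    rng = np.random.default_rng(config.seed)
    scen = _Scenario(config, p, rng)
    state = init_state(config, p)
    micro_l, macro_l, micro_cells, macro_cells = virtual_electrodes(config)
    m_rows = np.array([rc[0] for rc in micro_cells])
    m_cols = np.array([rc[1] for rc in micro_cells])
    M_rows = [np.array([rc[0] for rc in cells]) for cells in macro_cells]
    M_cols = [np.array([rc[1] for rc in cells]) for cells in macro_cells]

    n_steps = int(round(config.duration / config.dt))
    rec_every = int(round((1.0 / config.rate) / config.dt))
    n_rec = n_steps // rec_every
    micro_sig = np.empty((n_rec, 9))
    macro_sig = np.empty((n_rec, 9))
    snaps, snap_times = [], []
    snap_every = (
        int(round(config.snapshot_every / config.dt))
        if config.snapshot_every > 0 else 0
    )
    k_every = max(1, int(round(0.5 / config.dt)))
    k_mean, k_times = [], []
    dx = config.dx_cm
    # slow fields update on a coarser clock (still within the K-diffusion
    # stability bound); fast-field Euler at dt
    k_bound = 0.5 * dx * dx / (4.0 * max(p.c2, 1e-12))
    slow_every = max(1, min(int(round(0.01 / config.dt)),
                            max(1, int(k_bound / config.dt))))
    scen_every = max(1, int(round(0.025 / config.dt)))
    # quenched per-cell excitability disorder enters like a static source field
    jitter = (
        p.offset_jitter_sd * rng.standard_normal((config.grid_n, config.grid_n))
        if p.offset_jitter_sd > 0 else None
    )
    src_off: np.ndarray | float = 0.0
    q_e = firing_rate(state.v_e, p, "e")
    q_i = firing_rate(state.v_i, p, "i")
    i_rec = 0
    n = config.grid_n
    use_numba = _HAVE_NUMBA
    if use_numba:
        zeros_src = np.zeros((n, n))
        q_e = np.empty((n, n))
        q_i = np.empty((n, n))
        noise_on = rng is not None and p.noise_sf > 0
        noise_amp = (
            p.noise_sf * p.noise_base * np.sqrt(p.phi_sc / config.dt)
            if noise_on else 0.0
        )
        zeros_noise = np.zeros((n, n))
        kernel_consts = (
            config.dt, 1.0 / (dx * dx),
            p.tau_e, p.tau_i, p.q_max_e, p.q_max_i, p.theta_e, p.theta_i,
            p.sigma_e, p.sigma_i, p.v_rev_e, p.v_rev_i, p.v_rest,
            p.rho_e, p.rho_i, p.gamma_e, p.gamma_i,
            p.n_alpha_ee, p.n_alpha_ei, p.n_beta_ee, p.n_beta_ei,
            p.n_beta_ie, p.n_beta_ii, p.phi_sc, noise_amp,
            p.axonal_speed, p.lambda_inv, p.d_ee,
            p.offset_e, p.offset_i, p.block_onset, p.block_width,
        )
    for s in range(n_steps):
        t = s * config.dt
        if s % scen_every == 0:
            src_off = scen.offset(t)
            if jitter is not None:
                src_off = src_off + jitter
        if use_numba:
            src_arr = zeros_src if np.isscalar(src_off) else src_off
            if noise_on:
                ne = rng.standard_normal((n, n))
                ni = rng.standard_normal((n, n))
            else:
                ne = ni = zeros_noise
            _fused_step(
                state.v_e, state.v_i,
                state.phi_ee, state.phi_ee_d, state.phi_ei, state.phi_ei_d,
                state.phi_ie, state.phi_ie_d, state.phi_ii, state.phi_ii_d,
                state.lr_ee, state.lr_ee_d, state.lr_ei, state.lr_ei_d,
                state.d_ii, state.dv_e, state.dv_i,
                src_arr, ne, ni, q_e, q_i, *kernel_consts,
            )
        else:
            q_e, q_i = step_fast(state, config.dt, dx, p, rng, src_off)
        if s % slow_every == 0:
            dt_slow = slow_every * config.dt
            step_potassium(state, q_e, q_i, dt_slow, dx, p)
            step_slow_coupling(state, dt_slow, p)
        if (s + 1) % rec_every == 0 and i_rec < n_rec:
            micro_sig[i_rec] = q_e[m_rows, m_cols]
            for j in range(9):
                macro_sig[i_rec, j] = q_e[M_rows[j], M_cols[j]].mean()
            i_rec += 1
        if snap_every and s % snap_every == 0:
            snaps.append(q_e.copy())
            snap_times.append(t)
        if s % k_every == 0:
            k_mean.append(float(state.k.mean()))
            k_times.append(t)
        if s % 2000 == 0:
            state.assert_finite(s)
            if progress:
                print(f"  t={t:7.2f} s  K̄={state.k.mean():.3f}  "
                      f"Qe̅={q_e.mean():6.2f}", flush=True)
    state.assert_finite(n_steps)
    onset, offset = config.t_pre, config.t_pre + config.t_active
    meta = {"scenario": config.scenario, "seed": config.seed}
    micro_rec = Recording(
        samples=micro_sig[: i_rec], rate=config.rate, onset=onset,
        offset=offset, layout=micro_l, meta=dict(meta),
    )
    macro_rec = Recording(
        samples=macro_sig[: i_rec], rate=config.rate, onset=onset,
        offset=offset, layout=macro_l, meta=dict(meta),
    )
    return SimResult(
        micro=micro_rec, macro=macro_rec, config=config, params=p,
        snapshots=snaps, snapshot_times=snap_times,
        k_mean=np.array(k_mean), k_times=np.array(k_times),
    )


def kinematic_waves(
    layout: ElectrodeLayout,
    speed_mm_s: float,
    direction: float,
    freq: float = 7.0,
    bandwidth: float = 12.0,
    noise_sd: float = 0.2,
    amplitude: float = 1.0,
    duration: float = 180.0,
    rate: float = 500.0,
    onset: float = 60.0,
    offset: float | None = None,
    seed: int = 0,
    n_components: int = 60,
) -> Recording:
    """Ground-truth plane-wave recording for analysis tests.

    A shared band-limited stochastic waveform (random-phase sinusoids spread
    over ``bandwidth`` Hz around ``freq``) is delayed at each channel by the
    projection of its position onto the propagation unit vector divided by
    ``speed_mm_s``, plus independent Gaussian noise.  The waveform must be
    broadband within the analysis band: a pure tone has constant
    cross-spectral phase, so its group delay (phase *slope*) carries no
    information about the true lag.  Delays grow along ``direction``, so the
    fitted delay-gradient angle equals ``direction``.  Fractional-sample
    delays are exact (components are evaluated analytically at shifted
    times).  Ground truth is stored in ``meta``.
    """
    if speed_mm_s <= 0:
        raise ValueError("speed must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * rate))) / rate
    u = np.array([np.cos(direction), np.sin(direction)])
    delays = layout.positions @ u / speed_mm_s
    f_lo = max(freq - bandwidth / 2.0, 0.2)
    f_hi = freq + bandwidth / 2.0
    comp_f = np.linspace(f_lo, f_hi, n_components)
    comp_f = comp_f + rng.uniform(-0.5, 0.5, n_components) * (
        (f_hi - f_lo) / n_components
    )
    comp_phase = rng.uniform(0, 2 * np.pi, n_components)
    comp_amp = rng.uniform(0.5, 1.0, n_components)
    comp_amp *= amplitude / np.sqrt(0.5 * np.sum(comp_amp**2))  # unit-ish RMS
    sig = np.empty((len(t), len(layout)))
    for i, d in enumerate(delays):  # per channel to bound memory
        sig[:, i] = np.sum(
            comp_amp
            * np.sin(2 * np.pi * comp_f * (t[:, None] - d) + comp_phase),
            axis=1,
        )
    sig += noise_sd * rng.standard_normal(sig.shape)
    if offset is None:
        offset = duration
    return Recording(
        samples=sig, rate=rate, onset=onset, offset=offset, layout=layout,
        meta={
            "truth_speed_mm_s": speed_mm_s,
            "truth_direction": direction,
            "freq": freq,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def apply_scenario(
    t: float, config: SimConfig, params: ModelParams = ModelParams(),
    rng: np.random.Generator | None = None,
) -> np.ndarray | float:
    """Excitability-modification field (mV) at time ``t`` for a scenario.

    Functional wrapper over the scenario machinery used inside
    :func:`run_simulation`; randomized scenarios draw their schedule from
    ``rng`` (seeded from ``config.seed`` when omitted).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if t < 0 or t > config.duration:
        raise ValueError("t outside the protocol duration")
    return _Scenario(config, params, rng).offset(t)
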