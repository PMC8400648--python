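"""Synthetic inputs with known ground truth.

Three families of generators exercise the analysis pipeline end to end:

* stochastic trajectories with prescribed dynamics — free Brownian motion
  (diffusive liquid, known true D) and an Ornstein-Uhlenbeck bounded walk
  around fixed cage sites (sub-diffusive glass, known MSD plateau);
* a small binary Lennard-Jones glass former (80:20 composition with the
  canonical non-additive cross interaction) integrated with velocity
  Verlet, a stochastic velocity-rescaling thermostat and an isotropic
  Berendsen barostat, run over a sequential cool-down temperature
  protocol: equilibration then production at each grid temperature;
* thermal scans rho(T), D(T) built directly from a two-branch law with a
  known break temperature plus Gaussian noise.

All generators are bit-reproducible given a seed.  The toy engine works in
reduced Lennard-Jones units internally; its output is converted to the
analysis units (Å, fs, K, kPa, kJ/mol) by a declared :class:`UnitSystem`
(argon-like by default) at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dynamics import compute_msd, fit_diffusivity, unwrap
from .tg_estimation import ThermalScan
from .trajectory_io import Frame, ThermoSeries, Topology, Trajectory

__all__ = [
    "ScanTruth",
    "ToySystemParams",
    "UnitSystem",
    "generate_brownian_trajectory",
    "generate_caged_trajectory",
    "simulate_lj_glassformer",
    "run_thermal_protocol",
    "generate_thermal_scan",
    "write_scan_with_truth",
    "read_scan_with_truth",
]

KB_KJ_PER_MOL_K = 8.31446e-3   # kB in kJ/(mol K) per-mole convention


# ---------------------------------------------------------------------------
# thermal-scan generator

@dataclass
class ScanTruth:
    """Ground truth of a synthetic thermal scan.

    The density branch is continuous piecewise-linear with the liquid
    (high-T) slope more negative than the glass slope, as amorphous
    organics show a steeper volume increase with temperature above Tg.
    The diffusivity is a small constant floor below Tg and rises above it,
    continuously attached at Tg.  The default rise is linear in T
    (``d_law_kind="linear"``), the exactly break-structured law a
    two-segment estimator is defined against; an activation-type rise
    (``"arrhenius"``) is available, but note that its convexity over a
    wide grid displaces the best piecewise-linear knot from the true Tg
    by several kelvin even without noise, a property of the law rather
    than of any estimator.

    Defaults emulate a drug-like organic scanned from 200 to 500 K in
    10 K steps: Tg = 350 K, density ~1.2 g/cm³ with slopes −2e-4 (glass)
    and −8e-4 (liquid) g/cm³/K, diffusivities reaching ~5e-5 Å²/fs
    (5e-10 m²/s) at 500 K over a 1e-7 Å²/fs glassy floor, density noise
    0.002 g/cm³ (minor scatter) and diffusivity noise 1.5e-6 Å²/fs
    (relatively noisier, as transport coefficients from short runs are).
    """

    true_tg: float = 350.0                    # K
    rho_at_tg: float = 1.20                   # g/cm³
    glass_slope: float = -2.0e-4              # g/cm³/K
    liquid_slope: float = -8.0e-4             # g/cm³/K
    d_floor: float = 1.0e-7                   # Å²/fs
    d_law_kind: str = "linear"
    d_liquid_slope: float = 3.3e-7            # Å²/fs/K (linear law)
    d_prefactor: float = 8.62e-4              # Å²/fs (arrhenius law)
    activation_energy: float = 10.0           # kJ/mol (arrhenius law)
    rho_noise_sd: float = 2.0e-3              # g/cm³
    d_noise_sd: float = 1.5e-6                # Å²/fs
    T_grid: np.ndarray = field(
        default_factory=lambda: np.arange(200.0, 501.0, 10.0))

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if self.liquid_slope >= self.glass_slope:
            raise ValueError(
                "liquid density slope must be more negative than the glass "
                "slope (liquids expand more steeply)")
        if not self.T_grid.min() < self.true_tg < self.T_grid.max():
            raise ValueError("true_tg must lie inside the temperature grid")

    def rho_law(self, T: np.ndarray) -> np.ndarray:
        """Noise-free two-segment density branch."""
        T = np.asarray(T, dtype=float)
        d = T - self.true_tg
        return (self.rho_at_tg
                + np.where(d < 0, self.glass_slope, self.liquid_slope) * d)

    def d_law(self, T: np.ndarray) -> np.ndarray:
        """Noise-free diffusivity branch: floor below Tg, rise above."""
        T = np.asarray(T, dtype=float)
        if self.d_law_kind == "linear":
            rise = self.d_liquid_slope * (T - self.true_tg)
        elif self.d_law_kind == "arrhenius":
            boltz = np.exp(-self.activation_energy / (KB_KJ_PER_MOL_K * T))
            boltz_tg = np.exp(
                -self.activation_energy / (KB_KJ_PER_MOL_K * self.true_tg))
            rise = self.d_prefactor * (boltz - boltz_tg)
        else:
            raise ValueError(f"unknown d_law_kind {self.d_law_kind!r}")
        return np.where(T < self.true_tg, self.d_floor,
                        self.d_floor + rise)


def generate_thermal_scan(truth: ScanTruth, seed: int) -> ThermalScan:
    """Noisy thermal scan from a :class:`ScanTruth`, truth attached.

    Reported per-point standard deviations are the generating noise
    levels, which is what a well-calibrated aggregation would estimate.
    """
    T = truth.T_grid
    n_below = int(np.sum(T < truth.true_tg))
    n_above = int(np.sum(T >= truth.true_tg))
    if n_below < 3 or n_above < 3:
        raise ValueError("need at least 3 grid points on each side of Tg")
    rng = np.random.default_rng(seed)
    rho = truth.rho_law(T) + rng.normal(0.0, truth.rho_noise_sd, len(T))
    D = truth.d_law(T) + rng.normal(0.0, truth.d_noise_sd, len(T))
    return ThermalScan(
        T=T.copy(), rho=rho,
        rho_sd=np.full(len(T), truth.rho_noise_sd),
        D=D, D_sd=np.full(len(T), truth.d_noise_sd),
        truth=truth)


def write_scan_with_truth(scan: ThermalScan, path: str | Path) -> None:
    """Write a scan as TSV plus a JSON ground-truth sidecar (``.truth.json``)."""
    import pandas as pd

    df = pd.DataFrame({"T": scan.T, "rho": scan.rho, "rho_sd": scan.rho_sd,
                       "D": scan.D, "D_sd": scan.D_sd})
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if scan.truth is not None:
        side = asdict(scan.truth)
        side["T_grid"] = list(side["T_grid"])
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps(side, indent=1))


def read_scan_with_truth(path: str | Path) -> ThermalScan:
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    truth = None
    side = path.with_suffix(path.suffix + ".truth.json")
    if side.exists():
        raw = json.loads(side.read_text())
        raw["T_grid"] = np.array(raw["T_grid"])
        truth = ScanTruth(**raw)
    return ThermalScan(T=df["T"].to_numpy(), rho=df["rho"].to_numpy(),
                       rho_sd=df["rho_sd"].to_numpy(),
                       D=df["D"].to_numpy(), D_sd=df["D_sd"].to_numpy(),
                       truth=truth)


# ---------------------------------------------------------------------------
# stochastic trajectory generators

def _point_topology(n: int, name: str, mass: float = 1.0) -> Topology:
    names = np.array([name] * n, dtype=object)
    return Topology(atom_type=names.copy(), mass=np.full(n, mass),
                    charge=np.zeros(n), molecule_id=np.arange(n),
                    molecule_name=names)


def generate_brownian_trajectory(n_particles: int, true_D: float, dt: float,
                                 n_frames: int, box: float, seed: int
                                 ) -> Trajectory:
    """Free Brownian motion: i.i.d. Gaussian increments, var 2 D dt per axis.

    Wrapped positions go into the frames; the exact unwrapped coordinates
    and the true diffusivity are stored in ``ground_truth``.
    """
    if true_D < 0:
        raise ValueError("diffusivity must be non-negative")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, box, size=(n_particles, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * true_D * dt),
                       size=(n_frames - 1, n_particles, 3))
    unwrapped = np.concatenate(
        [start[None], start[None] + np.cumsum(steps, axis=0)])
    box_vec = np.full(3, float(box))
    frames = [Frame(time=i * dt, box=box_vec.copy(),
                    positions=np.mod(unwrapped[i], box), wrapped=True)
              for i in range(n_frames)]
    return Trajectory(
        frames=frames,
        topology=_point_topology(n_particles, "brownian"),
        ground_truth={"true_D": float(true_D), "unwrapped": unwrapped})


def generate_caged_trajectory(n_particles: int, cage_radius: float,
                              dt: float, n_frames: int, box: float,
                              seed: int, relaxation_time: float | None = None
                              ) -> Trajectory:
    """Bounded random walk: Ornstein-Uhlenbeck reversion to fixed cage sites.

    The per-axis stationary standard deviation is cage_radius/sqrt(3), so
    the long-lag MSD plateau is 2·cage_radius² (twice the stationary
    variance of the 3-D displacement).  Uses the exact OU discretization,
    so the plateau holds for any dt.  The default relaxation time of
    20 dt keeps the cage-rattling timescale well separated from typical
    trajectory lengths, so the plateau is reached within the fit window.
    """
    if cage_radius <= 0:
        raise ValueError("cage_radius must be positive")
    if cage_radius >= box / 4:
        raise ValueError("cage_radius must be below a quarter box")
    tau = relaxation_time if relaxation_time is not None else 20.0 * dt
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0.0, box, size=(n_particles, 3))
    sigma = cage_radius / np.sqrt(3.0)
    a = np.exp(-dt / tau)
    kick = sigma * np.sqrt(1.0 - a * a)
    disp = np.empty((n_frames, n_particles, 3))
    disp[0] = rng.normal(0.0, sigma, size=(n_particles, 3))
    for i in range(1, n_frames):
        disp[i] = a * disp[i - 1] + rng.normal(0.0, kick,
                                               size=(n_particles, 3))
    unwrapped = sites[None] + disp
    box_vec = np.full(3, float(box))
    frames = [Frame(time=i * dt, box=box_vec.copy(),
                    positions=np.mod(unwrapped[i], box), wrapped=True)
              for i in range(n_frames)]
    return Trajectory(
        frames=frames,
        topology=_point_topology(n_particles, "caged"),
        ground_truth={"true_D": 0.0, "unwrapped": unwrapped,
                      "msd_plateau": 2.0 * cage_radius ** 2,
                      "cage_radius": float(cage_radius)})


# ---------------------------------------------------------------------------
# binary Lennard-Jones glass former

@dataclass
class UnitSystem:
    """Conversion from reduced Lennard-Jones units to analysis units.

    Argon-like by default: sigma = 3.4 Å, epsilon/kB = 120 K, m = 40 u.
    Derived scales: time tau = sigma*sqrt(m/epsilon) in fs, pressure
    epsilon/sigma³ in kPa, energy per mole in kJ/mol.
    """

    sigma_angstrom: float = 3.4
    epsilon_kelvin: float = 120.0
    mass_amu: float = 40.0

    @property
    def energy_kj_per_mol(self) -> float:
        return self.epsilon_kelvin * KB_KJ_PER_MOL_K

    @property
    def time_fs(self) -> float:
        # tau = sigma*sqrt(m/eps); SI then to fs
        sigma_m = self.sigma_angstrom * 1e-10
        m_kg = self.mass_amu * 1.66053906660e-27
        eps_j = self.epsilon_kelvin * 1.380649e-23
        return sigma_m * np.sqrt(m_kg / eps_j) * 1e15

    @property
    def pressure_kpa(self) -> float:
        # eps/sigma^3 in Pa -> kPa
        eps_j = self.epsilon_kelvin * 1.380649e-23
        sigma_m = self.sigma_angstrom * 1e-10
        return eps_j / sigma_m ** 3 / 1e3


@dataclass
class ToySystemParams:
    """Binary Lennard-Jones glass-former parameters (reduced units).

    The default is the canonical 80:20 mixture with non-additive cross
    interaction (eps_AB = 1.5, sig_AB = 0.8) that vitrifies instead of
    crystallizing at desk scale, with a 2.5 sigma shifted-potential
    cutoff.
    """

    n_a: int = 120
    n_b: int = 30
    eps: tuple[float, float, float] = (1.0, 1.5, 0.5)    # AA, AB, BB
    sig: tuple[float, float, float] = (1.0, 0.8, 0.88)   # AA, AB, BB
    mass: tuple[float, float] = (1.0, 1.0)
    dt: float = 0.002
    cutoff_factor: float = 2.5
    temperature: float = 1.0       # reduced target
    pressure: float = 1.0          # reduced target
    thermostat_tau: float = 0.2    # reduced time
    barostat_tau: float = 0.5      # reduced time
    density: float = 1.2           # initial reduced number density
    seed: int = 0
    units: UnitSystem = field(default_factory=UnitSystem)

    def __post_init__(self) -> None:
        if self.n_a <= 0 or self.n_b < 0:
            raise ValueError("particle counts must be positive")
        if self.dt <= 0:
            raise ValueError("time step must be positive")

    @property
    def n(self) -> int:
        return self.n_a + self.n_b


class _LJEngine:
    """Internal O(N²) vectorized force engine in reduced units."""

    def __init__(self, params: ToySystemParams):
        p = params
        self.p = p
        n = p.n
        self.species = np.concatenate(
            [np.zeros(p.n_a, dtype=int), np.ones(p.n_b, dtype=int)])
        eps_m = np.array([[p.eps[0], p.eps[1]], [p.eps[1], p.eps[2]]])
        sig_m = np.array([[p.sig[0], p.sig[1]], [p.sig[1], p.sig[2]]])
        self.mass = np.where(self.species == 0, p.mass[0], p.mass[1])
        self.rng = np.random.default_rng(p.seed)
        L = (n / p.density) ** (1.0 / 3.0)
        self.box = np.full(3, L)
        self.pos = self._lattice_positions(n, L)
        self.vel = self._draw_velocities(p.temperature)
        # flattened upper-triangle pair tables
        self.pi, self.pj = np.triu_indices(n, k=1)
        si, sj = self.species[self.pi], self.species[self.pj]
        self.eps_p = eps_m[si, sj]
        self.sig2_p = sig_m[si, sj] ** 2
        rc = p.cutoff_factor * sig_m[si, sj]
        self.rc2_p = rc ** 2
        sr6 = (sig_m[si, sj] / rc) ** 6
        self.vshift_p = 4.0 * self.eps_p * (sr6 ** 2 - sr6)

    def _lattice_positions(self, n: int, L: float) -> np.ndarray:
        m = int(np.ceil(n ** (1.0 / 3.0)))
        grid = (np.indices((m, m, m)).reshape(3, -1).T + 0.5) * (L / m)
        idx = self.rng.permutation(len(grid))[:n]
        jitter = self.rng.normal(0.0, 0.01, size=(n, 3))
        return np.mod(grid[idx] + jitter, L)

    def _draw_velocities(self, T: float) -> np.ndarray:
        v = self.rng.normal(0.0, 1.0, size=(self.p.n, 3))
        v *= np.sqrt(T / self.mass)[:, None]
        v -= np.average(v, axis=0, weights=self.mass)   # zero total momentum
        return v

    def forces(self) -> tuple[np.ndarray, float, float]:
        """Forces, potential energy and pair virial W = sum r_ij . f_ij."""
        d = self.pos[self.pi] - self.pos[self.pj]
        d -= np.round(d / self.box) * self.box
        r2 = (d ** 2).sum(axis=1)
        inside = r2 < self.rc2_p
        r2 = np.where(inside, r2, 1.0)
        sr6 = (self.sig2_p / r2) ** 3
        pot = np.where(inside,
                       4.0 * self.eps_p * (sr6 ** 2 - sr6) - self.vshift_p,
                       0.0)
        if not np.all(np.isfinite(pot)):
            raise FloatingPointError("non-finite pair energy (overlap)")
        # f = 24 eps (2 sr12 - sr6) / r2 * d
        fac = np.where(inside,
                       24.0 * self.eps_p * (2.0 * sr6 ** 2 - sr6) / r2, 0.0)
        fpair = fac[:, None] * d
        n = self.p.n
        forces = np.empty_like(self.pos)
        for ax in range(3):
            forces[:, ax] = (np.bincount(self.pi, fpair[:, ax], n)
                             - np.bincount(self.pj, fpair[:, ax], n))
        virial = float((fac * (d ** 2).sum(axis=1)).sum())
        return forces, float(pot.sum()), virial

    def kinetic(self) -> float:
        return 0.5 * float((self.mass[:, None] * self.vel ** 2).sum())

    def temperature(self) -> float:
        return 2.0 * self.kinetic() / (3.0 * self.p.n)

    def _bussi_rescale(self, T_target: float) -> None:
        """Stochastic velocity rescaling (canonical-sampling thermostat)."""
        ndof = 3 * self.p.n
        ke = self.kinetic()
        ke_target = 0.5 * ndof * T_target
        c = np.exp(-self.p.dt / self.p.thermostat_tau)
        r1 = self.rng.normal()
        sum_r2 = float(self.rng.chisquare(ndof - 1))
        ke_new = (ke * c
                  + ke_target / ndof * (1.0 - c) * (sum_r2 + r1 ** 2)
                  + 2.0 * r1 * np.sqrt(ke * ke_target / ndof
                                       * (1.0 - c) * c))
        self.vel *= np.sqrt(max(ke_new, 1e-12) / ke)

    def _berendsen_box(self, P_inst: float, P_target: float) -> None:
        kappa = 0.2   # reduced compressibility scale; only the product matters
        mu = (1.0 - self.p.dt / self.p.barostat_tau
              * kappa * (P_target - P_inst)) ** (1.0 / 3.0)
        mu = float(np.clip(mu, 0.95, 1.05))
        self.box *= mu
        self.pos *= mu

    def run(self, n_steps: int, mode: str, sample_every: int = 10,
            store_frames: bool = True):
        """Integrate ``n_steps`` and return (frames, thermo) in reduced units.

        ``mode`` is NVE (no coupling), NVT (thermostat) or NPT
        (thermostat + barostat).  Sampled records: time, T, P, V, U, and
        H = U + KE + P_target·V (per box).
        """
        if mode not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble mode {mode!r}")
        p = self.p
        f, pot, vir = self.forces()
        frames: list[tuple[float, np.ndarray, np.ndarray]] = []
        recs: list[tuple[float, ...]] = []
        for step in range(n_steps):
            self.vel += 0.5 * p.dt * f / self.mass[:, None]
            self.pos += p.dt * self.vel
            self.pos = np.mod(self.pos, self.box)
            try:
                f, pot, vir = self.forces()
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"integration failed at step {step}: {exc}") from exc
            self.vel += 0.5 * p.dt * f / self.mass[:, None]
            vol = float(np.prod(self.box))
            T_inst = self.temperature()
            P_inst = (p.n * T_inst + vir / 3.0) / vol
            if mode in ("NVT", "NPT"):
                self._bussi_rescale(p.temperature)
            if mode == "NPT":
                self._berendsen_box(P_inst, p.pressure)
            if (step + 1) % sample_every == 0:
                t = (step + 1) * p.dt
                ke = self.kinetic()
                recs.append((t, T_inst, P_inst, vol, pot,
                             pot + ke + p.pressure * vol))
                if store_frames:
                    frames.append((t, self.box.copy(), self.pos.copy()))
        return frames, recs


def _toy_topology(params: ToySystemParams) -> Topology:
    labels = np.array(["A"] * params.n_a + ["B"] * params.n_b, dtype=object)
    mass = np.where(labels == "A", params.mass[0],
                    params.mass[1]) * params.units.mass_amu
    return Topology(atom_type=labels.copy(), mass=mass,
                    charge=np.zeros(params.n),
                    molecule_id=np.arange(params.n),
                    molecule_name=labels)


def _convert_output(params: ToySystemParams, frames_r, recs_r
                    ) -> tuple[Trajectory | None, ThermoSeries]:
    u = params.units
    traj = None
    if frames_r:
        traj = Trajectory(
            frames=[Frame(time=t * u.time_fs, box=box * u.sigma_angstrom,
                          positions=pos * u.sigma_angstrom, wrapped=True)
                    for t, box, pos in frames_r],
            topology=_toy_topology(params))
    recs = np.array(recs_r) if recs_r else np.empty((0, 6))
    thermo = ThermoSeries(
        time=recs[:, 0] * u.time_fs,
        temperature=recs[:, 1] * u.epsilon_kelvin,
        pressure=recs[:, 2] * u.pressure_kpa,
        volume=recs[:, 3] * u.sigma_angstrom ** 3,
        potential_energy=recs[:, 4] * u.energy_kj_per_mol,
        enthalpy=recs[:, 5] * u.energy_kj_per_mol,
    ) if len(recs) else ThermoSeries(time=np.empty(0))
    return traj, thermo


def simulate_lj_glassformer(params: ToySystemParams, n_steps: int,
                            mode: str = "NVT", sample_every: int = 10,
                            equil_steps: int = 0
                            ) -> tuple[Trajectory, ThermoSeries]:
    """Run the binary LJ glass former for ``n_steps`` in one ensemble.

    ``equil_steps`` discards an initial unsampled equilibration in the
    same ensemble (the lattice start needs relaxing before production
    dynamics are meaningful).  Returns the sampled trajectory and
    thermodynamic series converted to analysis units.  ``n_steps=0``
    returns the initial configuration and an empty thermodynamic series.
    """
    engine = _LJEngine(params)
    if equil_steps:
        engine.run(equil_steps, mode, sample_every=equil_steps,
                   store_frames=False)
    if n_steps == 0:
        u = params.units
        traj = Trajectory(frames=[Frame(time=0.0,
                                        box=engine.box * u.sigma_angstrom,
                                        positions=engine.pos
                                        * u.sigma_angstrom,
                                        wrapped=True)],
                          topology=_toy_topology(params))
        return traj, ThermoSeries(time=np.empty(0))
    frames_r, recs_r = engine.run(n_steps, mode, sample_every=sample_every)
    traj, thermo = _convert_output(params, frames_r, recs_r)
    if traj is None:
        raise ValueError("n_steps too small to sample any frame")
    return traj, thermo


def run_thermal_protocol(params: ToySystemParams,
                         T_grid: np.ndarray,
                         equil_steps: int = 2000,
                         prod_steps: int = 4000,
                         sample_every: int = 10,
                         msd_window: tuple[float, float] | None = None
                         ) -> ThermalScan:
    """Sequential cool-down/heat-up protocol on the toy glass former.

    ``T_grid`` is in reduced units, sorted in protocol order (descending
    for cooling); the particle state carries over between consecutive
    temperatures.  At each temperature an NPT equilibration of
    ``equil_steps`` precedes an NPT production of ``prod_steps``, from
    which the density (mean ± sd over samples) and the self-diffusivity
    (Einstein fit ± sd on the A species) are aggregated.  The returned
    scan is in analysis units with temperatures ascending.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if equil_steps <= 0 or prod_steps <= 0:
        raise ValueError("step counts must be positive")
    engine = _LJEngine(params)
    u = params.units
    topo = _toy_topology(params)
    total_mass = float(topo.mass.sum())
    rows = []
    for T_red in T_grid:
        engine.p.temperature = float(T_red)
        try:
            engine.run(equil_steps, "NPT", sample_every=equil_steps,
                       store_frames=False)
            frames_r, recs_r = engine.run(prod_steps, "NPT",
                                          sample_every=sample_every)
        except FloatingPointError as exc:
            raise RuntimeError(
                f"protocol failed at T*={T_red:g}: {exc}") from exc
        traj, thermo = _convert_output(params, frames_r, recs_r)
        from .structure import AMU_PER_ANG3_TO_G_PER_CM3

        rhos = total_mass / thermo.volume * AMU_PER_ANG3_TO_G_PER_CM3
        msd = compute_msd(unwrap(traj), species="A")
        dres = fit_diffusivity(msd, window=msd_window)
        rows.append((T_red * u.epsilon_kelvin,
                     float(rhos.mean()), float(rhos.std(ddof=1)),
                     dres.D, dres.D_sd))
    rows.sort(key=lambda r: r[0])
    arr = np.array(rows)
    return ThermalScan(T=arr[:, 0], rho=arr[:, 1], rho_sd=arr[:, 2],
                       D=arr[:, 3], D_sd=arr[:, 4])
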