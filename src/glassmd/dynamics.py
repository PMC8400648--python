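"""Mean-squared displacement and Einstein self-diffusivity.

The self-diffusivity is obtained from the Einstein relation in three
dimensions, D = (1/6) d<|r(t+tau) - r(t)|^2>/dtau, by a weighted linear fit
of the MSD over an explicit lag window.  The MSD is averaged over all
particles of the selected species and over all time origins (stride one
frame), computed with the standard FFT autocorrelation decomposition so the
cost is O(n log n) per particle rather than O(n^2).

For glassy (caged) dynamics the MSD plateaus; a fitted slope that is
negative or statistically indistinguishable from zero is reported as D = 0
with a sub-diffusive flag, mirroring the diffusive-liquid / sub-diffusive
glass dichotomy the pipeline is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Frame, Topology, Trajectory, TrajectoryError

__all__ = [
    "MSDCurve",
    "DiffusivityResult",
    "unwrap",
    "molecular_centers",
    "compute_msd",
    "fit_diffusivity",
    "diffusion_exponent",
    "ANG2_PER_FS_TO_M2_PER_S",
]

# 1 Å²/fs = 1e-20 m² / 1e-15 s
ANG2_PER_FS_TO_M2_PER_S = 1e-5


@dataclass
class MSDCurve:
    """Ensemble- and origin-averaged MSD on a strictly increasing lag grid."""

    lags: np.ndarray       # fs
    msd: np.ndarray        # Å²
    n_origins: np.ndarray  # time origins contributing per lag
    species: str | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if self.lags[0] == 0 and abs(self.msd[0]) > 1e-10:
            raise ValueError("MSD at zero lag must vanish")


@dataclass
class DiffusivityResult:
    """Einstein-fit self-diffusivity with its standard deviation.

    ``D`` is in Å²/fs (multiply by :data:`ANG2_PER_FS_TO_M2_PER_S` for
    m²/s); ``subdiffusive`` is set when the fitted MSD slope is negative or
    within ``zero_sigma`` standard deviations of zero.
    """

    D: float
    D_sd: float
    window: tuple[float, float]
    r_squared: float
    subdiffusive: bool = False

    @property
    def D_si(self) -> float:
        return self.D * ANG2_PER_FS_TO_M2_PER_S


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic wrapping by accumulating minimum-image increments.

    Requires that no particle moves half a box edge or more between
    consecutive frames (otherwise the minimum-image convention is ambiguous
    and an undersampling error is raised).
    """
    pos = traj.positions_array()
    boxes = traj.boxes_array()
    disp = np.diff(pos, axis=0)
    # minimum-image correction per interval, using the box of the later frame
    L = boxes[1:, None, :]
    shift = np.round(disp / L)
    corrected = disp - shift * L
    if np.any(np.abs(corrected) >= L / 2 * (1 - 1e-12)):
        raise TrajectoryError(
            "frame-to-frame displacement >= L/2: trajectory undersampled")
    unwrapped = np.empty_like(pos)
    unwrapped[0] = pos[0]
    unwrapped[1:] = pos[0] + np.cumsum(corrected, axis=0)
    frames = [Frame(time=f.time, box=f.box, positions=unwrapped[i],
                    wrapped=False)
              for i, f in enumerate(traj.frames)]
    return Trajectory(frames=frames, topology=traj.topology,
                      ground_truth=traj.ground_truth)


def molecular_centers(traj: Trajectory, topology: Topology | None = None
                      ) -> Trajectory:
    """Reduce each molecule to its mass-weighted center.

    Input must be unwrapped (centers of wrapped coordinates are meaningless
    across periodic images).  The reduced trajectory carries a one-site
    topology whose molecule names are preserved so species selection in
    :func:`compute_msd` keeps working.
    """
    topo = topology if topology is not None else traj.topology
    if topo is None:
        raise TrajectoryError("molecular_centers requires a topology")
    if any(f.wrapped for f in traj.frames):
        raise TrajectoryError("molecular_centers requires unwrapped input")
    if np.any(~np.isfinite(topo.mass)) or np.any(topo.mass <= 0):
        raise TrajectoryError("every atom needs a positive mass")
    mols, inverse = np.unique(topo.molecule_id, return_inverse=True)
    n_mol = len(mols)
    w = topo.mass
    mol_mass = np.bincount(inverse, weights=w, minlength=n_mol)
    pos = traj.positions_array()          # (T, n_atoms, 3)
    centers = np.empty((pos.shape[0], n_mol, 3))
    for ax in range(3):
        wp = pos[:, :, ax] * w
        centers[:, :, ax] = np.apply_along_axis(
            lambda row: np.bincount(inverse, weights=row, minlength=n_mol),
            1, wp) / mol_mass
    names = np.empty(n_mol, dtype=object)
    for k, mol in enumerate(mols):
        names[k] = topo.molecule_name[topo.molecule_id == mol][0]
    center_topo = Topology(
        atom_type=names.copy(), mass=mol_mass, charge=np.zeros(n_mol),
        molecule_id=np.asarray(mols), molecule_name=names)
    frames = [Frame(time=f.time, box=f.box, positions=centers[i],
                    wrapped=False)
              for i, f in enumerate(traj.frames)]
    return Trajectory(frames=frames, topology=center_topo,
                      ground_truth=traj.ground_truth)


def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of one particle's (T, 3) track via FFT autocorrelation."""
    T = x.shape[0]
    s2 = (x ** 2).sum(axis=1)
    # autocorrelation sum_t x(t).x(t+dt) per axis via FFT
    nfft = 1 << (2 * T - 1).bit_length()
    acf = np.zeros(T)
    for ax in range(3):
        f = np.fft.rfft(x[:, ax], nfft)
        acf += np.fft.irfft(f * f.conj(), nfft)[:T]
    # Kubo trick: MSD(dt) = (SAB(dt) - 2*acf(dt)) / (T - dt)
    cum = np.concatenate(([0.0], np.cumsum(s2)))
    total = cum[-1]
    m = np.arange(T)
    # sum over origins k of |r(k)|^2 + |r(k+m)|^2
    sab = cum[T - m] + (total - cum[m])
    counts = T - m
    return (sab - 2.0 * acf) / counts


def compute_msd(traj: Trajectory, species: str | None = None,
                max_lag_fraction: float = 0.5) -> MSDCurve:
    """Origin-averaged MSD for one species of an unwrapped trajectory.

    ``max_lag_fraction`` truncates the lag grid at that fraction of the
    trajectory length (long lags average over few origins and are noisy).
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    if any(f.wrapped for f in traj.frames):
        raise TrajectoryError("compute_msd requires an unwrapped trajectory")
    pos = traj.positions_array()
    if species is not None:
        if traj.topology is None:
            raise TrajectoryError("species selection requires a topology")
        sel = np.asarray(traj.topology.molecule_name) == species
        if not sel.any():
            raise TrajectoryError(f"no particles of species {species!r}")
        pos = pos[:, sel, :]
    T = pos.shape[0]
    msd = np.zeros(T)
    for p in range(pos.shape[1]):
        msd += _msd_fft_single(np.ascontiguousarray(pos[:, p, :]))
    msd /= pos.shape[1]
    msd[0] = 0.0
    times = traj.times
    max_lag = max(1, int(round(max_lag_fraction * (T - 1))))
    lags = times[:max_lag + 1] - times[0]
    return MSDCurve(lags=lags, msd=msd[:max_lag + 1],
                    n_origins=T - np.arange(max_lag + 1),
                    species=species)


def fit_diffusivity(msd: MSDCurve,
                    window: tuple[float, float] | None = None,
                    zero_sigma: float = 2.0,
                    plateau_fraction: float = 0.1) -> DiffusivityResult:
    """Einstein-relation diffusivity from a weighted linear fit of the MSD.

    The fit line is MSD = a + 6 D tau over the lag ``window`` (defaults to
    10%-50% of the maximum lag, skipping the short-time ballistic/cage
    regime and the noisy tail).  Weights are the per-lag origin counts.

    A fit is flagged sub-diffusive when the slope is negative, within
    ``zero_sigma`` formal standard deviations of zero, or when the fitted
    MSD growth across the window is below ``plateau_fraction`` of the mean
    MSD level — a plateau detector that stays robust where the formal
    slope uncertainty is underestimated because neighbouring MSD points
    share the same trajectory noise.  A negative slope also reports D = 0.
    """
    if window is None:
        lmax = msd.lags[-1]
        window = (0.1 * lmax, 0.5 * lmax)
    lo, hi = window
    if lo < msd.lags[0] - 1e-9 or hi > msd.lags[-1] + 1e-9:
        raise ValueError("fit window outside the available lag range")
    sel = (msd.lags >= lo) & (msd.lags <= hi)
    if sel.sum() < 5:
        raise ValueError("fit window must contain at least 5 lag points")
    x = msd.lags[sel]
    y = msd.msd[sel]
    w = msd.n_origins[sel].astype(float)
    W = np.diag(w)
    A = np.column_stack([np.ones_like(x), x])
    AtW = A.T * w
    cov_unscaled = np.linalg.inv(AtW @ A)
    beta = cov_unscaled @ (AtW @ y)
    resid = y - A @ beta
    dof = max(len(x) - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = cov_unscaled * s2
    slope, slope_sd = beta[1], float(np.sqrt(cov[1, 1]))
    ybar = np.average(y, weights=w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - float(resid @ (w * resid)) / ss_tot if ss_tot > 0 else 1.0
    D = slope / 6.0
    D_sd = slope_sd / 6.0
    growth = slope * (x[-1] - x[0])
    level = float(np.average(y, weights=w))
    plateau = level > 0 and growth < plateau_fraction * level
    sub = slope <= 0 or slope < zero_sigma * slope_sd or plateau
    if slope <= 0:
        D = 0.0
    return DiffusivityResult(D=max(D, 0.0), D_sd=D_sd, window=(lo, hi),
                             r_squared=r2, subdiffusive=bool(sub))


def diffusion_exponent(msd: MSDCurve,
                       window: tuple[float, float] | None = None) -> float:
    """Log-log slope alpha of MSD ~ tau^alpha over the lag window.

    The dynamical-regime diagnostic: alpha near 1 marks diffusive (liquid)
    dynamics, alpha well below 1 sub-diffusive caging (a plateauing MSD
    gives alpha near 0).  Uses the default 10%-50% lag window of
    :func:`fit_diffusivity` when none is given.
    """
    if window is None:
        lmax = msd.lags[-1]
        window = (0.1 * lmax, 0.5 * lmax)
    sel = (msd.lags >= window[0]) & (msd.lags <= window[1]) \
        & (msd.lags > 0) & (msd.msd > 0)
    if sel.sum() < 3:
        raise ValueError("need at least 3 positive points in the window")
    slope = np.polyfit(np.log(msd.lags[sel]), np.log(msd.msd[sel]), 1)[0]
    return float(slope)
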