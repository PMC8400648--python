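"""Densities, molar/excess volumes, radial distribution functions and
hydrogen-bond contact statistics.

The hydrogen-bond criterion is purely geometric: an H(donor)...acceptor
pair counts as a contact when the minimum-image distance is below a cutoff
(default 2.5 Å), with intramolecular pairs excluded.  No angular term is
applied; the bonding analysis in amorphous drug/nucleobase systems is
conventionally presented through site-site O-H...O / N-H...O distance
distributions, whose first-peak position and amplitude are extracted with
parabolic refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory_io import Frame, Topology, Trajectory, TrajectoryError

__all__ = [
    "StatePoint",
    "RDFCurve",
    "ContactStats",
    "mass_density",
    "molar_volume",
    "excess_volume",
    "compute_rdf",
    "first_peak",
    "hbond_contacts",
    "AMU_PER_ANG3_TO_G_PER_CM3",
]

# 1 u/Å³ = 1.66053906660e-24 g / 1e-24 cm³
AMU_PER_ANG3_TO_G_PER_CM3 = 1.66053906660


@dataclass
class StatePoint:
    """Aggregated state-point record: T (K), P (kPa), density (g/cm³) ± sd."""

    rho: float
    rho_sd: float
    box_volume: float            # Å³, mean
    temperature: float | None = None
    pressure: float | None = None
    molar_volume: float | None = None   # cm³/mol of molecules


@dataclass
class RDFCurve:
    """Site-site radial distribution function g(r) on a uniform bin grid."""

    r: np.ndarray            # bin centers, Å
    g: np.ndarray
    pair: tuple[str, str]
    bin_width: float
    n_frames: int
    pair_density: float      # N_A·N_B/V (ordered pairs per Å³), frame-averaged
    n_central: float         # frame-averaged N_A (central sites)

    def coordination_number(self, r_limit: float) -> float:
        """Integrate rho_B * 4 pi r² g(r) dr up to ``r_limit``.

        For a cross pair this is the mean number of B sites within
        ``r_limit`` of an A site (and for A = A, of another A site, the
        partner density being (N−1)/V).
        """
        sel = self.r <= r_limit
        shell = 4.0 * np.pi * self.r[sel] ** 2 * self.bin_width
        rho_b = self.pair_density / self.n_central
        return float(np.sum(rho_b * shell * self.g[sel]))


@dataclass
class ContactStats:
    """Distance-criterion hydrogen-bond contact statistics."""

    donor_sites: Sequence[str]
    acceptor_sites: Sequence[str]
    cutoff: float
    mean_contacts_per_donor: float
    n_contacts: int
    n_donors: int
    per_donor_type: dict[str, float]
    per_acceptor_type: dict[str, float]


def _as_frames(obj: Trajectory | Frame | Sequence[Frame]) -> list[Frame]:
    if isinstance(obj, Trajectory):
        return obj.frames
    if isinstance(obj, Frame):
        return [obj]
    return list(obj)


def mass_density(frames: Trajectory | Frame | Sequence[Frame],
                 topology: Topology) -> StatePoint:
    """Mass density in g/cm³, averaged over frames with its sd.

    Per frame, rho = (total mass) / (box volume), converted from u/Å³.
    """
    frs = _as_frames(frames)
    if not frs:
        raise TrajectoryError("mass_density requires at least one frame")
    total_mass = float(topology.mass.sum())
    rhos = []
    for fr in frs:
        v = fr.volume
        if v <= 0:
            raise TrajectoryError("zero or negative box volume")
        rhos.append(total_mass / v * AMU_PER_ANG3_TO_G_PER_CM3)
    rhos = np.asarray(rhos)
    return StatePoint(rho=float(rhos.mean()),
                      rho_sd=float(rhos.std(ddof=1)) if len(rhos) > 1 else 0.0,
                      box_volume=float(np.mean([f.volume for f in frs])))


def molar_volume(rho: float, mean_molar_mass: float) -> float:
    """Molar volume V_m = M̄/rho in cm³ per mole of molecules.

    ``mean_molar_mass`` is the mole-fraction-weighted mean molar mass of
    the mixture in g/mol.
    """
    if rho <= 0:
        raise ValueError("density must be positive")
    return mean_molar_mass / rho


def excess_volume(v_m_mix: float, x: Sequence[float],
                  v_m_pure: Sequence[float]) -> tuple[float, float]:
    """Excess molar volume and its percentage of the mixture molar volume.

    V_E = V_m,mix − Σ x_i V_m,pure,i; negative values indicate packing
    more efficient than the ideal (mole-fraction-additive) mixture.
    """
    x = np.asarray(x, dtype=float)
    v_m_pure = np.asarray(v_m_pure, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    v_ideal = float(x @ v_m_pure)
    v_e = v_m_mix - v_ideal
    return v_e, 100.0 * v_e / v_m_mix


def _min_image_distances(pos_a: np.ndarray, pos_b: np.ndarray,
                         box: np.ndarray, same: bool) -> np.ndarray:
    """Flat array of minimum-image pair distances (each unordered pair once)."""
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d -= np.round(d / box) * box
    r = np.sqrt((d ** 2).sum(axis=-1))
    if same:
        iu = np.triu_indices(len(pos_a), k=1)
        return r[iu]
    return r.ravel()


def compute_rdf(traj: Trajectory | Frame | Sequence[Frame],
                site_pair: tuple[str, str] | None = None,
                r_max: float = 10.0, n_bins: int | None = None,
                bin_width: float = 0.05,
                topology: Topology | None = None) -> RDFCurve:
    """Site-site radial distribution function under periodic minimum image.

    ``site_pair`` selects atoms by their ``atom_type`` label; ``None``
    uses all atoms for both sides.  Normalisation divides the observed
    pair histogram by the ideal-gas expectation of the selected site
    populations: N_A·N_B/V ordered pairs (N(N−1) for A = B) times the
    shell volume, using the per-frame box volume so constant-pressure
    trajectories are handled correctly.
    """
    frs = _as_frames(traj)
    topo = topology
    if topo is None and isinstance(traj, Trajectory):
        topo = traj.topology
    if n_bins is None:
        n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, r_max, n_bins + 1)
    if site_pair is not None:
        if topo is None:
            raise TrajectoryError("site selection requires a topology")
        sel_a = np.asarray(topo.atom_type) == site_pair[0]
        sel_b = np.asarray(topo.atom_type) == site_pair[1]
        if not sel_a.any() or not sel_b.any():
            raise TrajectoryError(f"empty selection for pair {site_pair}")
        same = site_pair[0] == site_pair[1]
    else:
        sel_a = sel_b = slice(None)
        same = True
        site_pair = ("all", "all")
    hist = np.zeros(n_bins)
    pair_density = 0.0
    n_central = 0.0
    for fr in frs:
        if r_max > fr.box.min() / 2 + 1e-9:
            raise TrajectoryError("r_max exceeds half the smallest box edge")
        pa = fr.positions[sel_a]
        pb = fr.positions[sel_b]
        r = _min_image_distances(pa, pb, fr.box, same)
        hist += np.histogram(r, bins=edges)[0]
        n_a = len(pa)
        n_b = len(pb)
        n_pairs = n_a * (n_a - 1) if same else n_a * n_b
        pair_density += n_pairs / fr.volume
        n_central += n_a
    pair_density /= len(frs)
    n_central /= len(frs)
    centers = 0.5 * (edges[1:] + edges[:-1])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # same-species histogram holds each unordered pair once -> ordered / 2
    ideal = pair_density * shell * len(frs)
    if same:
        ideal = ideal / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return RDFCurve(r=centers, g=g, pair=tuple(site_pair),
                    bin_width=float(edges[1] - edges[0]), n_frames=len(frs),
                    pair_density=pair_density, n_central=n_central)


def first_peak(rdf: RDFCurve,
               search_range: tuple[float, float] | None = None
               ) -> tuple[float | None, float | None]:
    """Position and amplitude of the first maximum of g(r) on a range.

    The maximum bin is refined by a parabola through the three bins around
    it.  Returns ``(None, None)`` when g(r) vanishes on the range or the
    maximum sits on the range boundary (monotone g(r): not a peak).
    """
    if search_range is None:
        search_range = (float(rdf.r[0]), float(rdf.r[-1]))
    sel = (rdf.r >= search_range[0]) & (rdf.r <= search_range[1])
    if not sel.any():
        raise ValueError("empty search range")
    r = rdf.r[sel]
    g = rdf.g[sel]
    if np.all(g <= 0):
        return None, None
    k = int(np.argmax(g))
    if k == 0 or k == len(g) - 1:
        return None, None
    y0, y1, y2 = g[k - 1], g[k], g[k + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    r_peak = r[k] + offset * rdf.bin_width
    amp = y1 - 0.25 * (y0 - y2) * offset
    return float(r_peak), float(amp)


def hbond_contacts(frames: Trajectory | Frame | Sequence[Frame],
                   topology: Topology | None = None,
                   cutoff: float = 2.5) -> ContactStats:
    """Distance-criterion hydrogen-bond contacts, frame-averaged.

    Donors are atoms with ``donor_flag`` (hydrogen sites), acceptors atoms
    with ``acceptor_flag``; an H...acceptor pair within ``cutoff`` under
    minimum image counts as one contact.  Pairs within the same molecule
    are excluded.  Mean contacts per donor and ranked per-site-type
    contributions are returned.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frs = _as_frames(frames)
    topo = topology
    if topo is None and isinstance(frames, Trajectory):
        topo = frames.topology
    if topo is None:
        raise TrajectoryError("hbond_contacts requires a topology")
    don = np.flatnonzero(topo.donor_flag)
    acc = np.flatnonzero(topo.acceptor_flag)
    if len(don) == 0 or len(acc) == 0:
        raise TrajectoryError("topology has no donor or no acceptor sites")
    same_mol = topo.molecule_id[don][:, None] == topo.molecule_id[acc][None, :]
    total = 0
    per_donor: dict[str, float] = {}
    per_acceptor: dict[str, float] = {}
    for fr in frs:
        d = fr.positions[don][:, None, :] - fr.positions[acc][None, :, :]
        d -= np.round(d / fr.box) * fr.box
        r = np.sqrt((d ** 2).sum(axis=-1))
        contact = (r < cutoff) & ~same_mol
        total += int(contact.sum())
        for i in np.flatnonzero(contact.any(axis=1)):
            t = str(topo.atom_type[don[i]])
            per_donor[t] = per_donor.get(t, 0.0) + contact[i].sum()
        for j in np.flatnonzero(contact.any(axis=0)):
            t = str(topo.atom_type[acc[j]])
            per_acceptor[t] = per_acceptor.get(t, 0.0) + contact[:, j].sum()
    nf = len(frs)
    per_donor = {k: v / nf for k, v in
                 sorted(per_donor.items(), key=lambda kv: -kv[1])}
    per_acceptor = {k: v / nf for k, v in
                    sorted(per_acceptor.items(), key=lambda kv: -kv[1])}
    return ContactStats(
        donor_sites=sorted({str(topo.atom_type[i]) for i in don}),
        acceptor_sites=sorted({str(topo.atom_type[j]) for j in acc}),
        cutoff=cutoff,
        mean_contacts_per_donor=total / (len(don) * nf),
        n_contacts=total,
        n_donors=len(don),
        per_donor_type=per_donor,
        per_acceptor_type=per_acceptor,
    )
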