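"""Geometric and occupancy features of cap-loop dynamics.

These are the quantities used to characterise loop opening in nDsbD
trajectories: the F70 ring-centre to C109 Sgamma distance, chi1 rotamer
series and populations, loop-opening event detection with hysteresis,
solvent-accessible surface area (Shrake-Rupley), hydrogen-bond occupancy,
side-chain RMSD relative to a reference, mass-density occupancy grids and
backbone phi/psi series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from loopdyn._geometry import dihedral, superpose, rmsd as _rmsd
from loopdyn.trajectory import TrajectoryEnsemble

log = logging.getLogger(__name__)

#: Aromatic ring carbons used for the ring centroid (Phe/Tyr).
RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

#: gamma heavy atom defining chi1 (N-CA-CB-gamma) per residue type.
CHI1_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "CYS": "SG", "SER": "OG", "THR": "OG1", "VAL": "CG1", "ILE": "CG1",
}

#: van der Waals radii (Angstrom, Bondi) for the SASA calculation.
VDW_RADII = {"H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "SE": 1.90}


@dataclass
class DistanceSeries:
    """Per-frame distance between an atom/group pair, in Angstrom."""
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class LoopEvent:
    """One loop-opening excursion: open at `start`, re-closed at `end` (ns)."""
    start: float
    end: float
    max_distance: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RotamerSeries:
    """chi1 time series (degrees in (-180, 180]) with rotamer-state labels."""
    times: np.ndarray
    chi1: np.ndarray
    states: np.ndarray  # strings: "gauche-", "gauche+", "trans"
    residue: int = 0


@dataclass
class OccupancyGrid:
    """Voxel visit counts plus max-normalised relative occupancy."""
    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    relative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        mx = self.counts.max()
        self.relative = self.counts / mx if mx > 0 else self.counts.astype(float)

    def n_voxels_above(self, level: float) -> int:
        """Number of voxels with relative occupancy >= level (iso-surface support)."""
        return int(np.sum(self.relative >= level))


def ring_center_distance(ens: TrajectoryEnsemble, ring_residue: int,
                         target_atom: tuple[int, str],
                         ring_atom_names: tuple[str, ...] = RING_ATOMS) -> DistanceSeries:
    """Distance from the unweighted centroid of an aromatic ring to a target atom.

    This is the loop-state coordinate of the analysis: the distance between
    the centre of the F70 aromatic ring and the C109 Sgamma atom, which is
    ~3-4 Angstrom in closed X-ray structures and ~11 Angstrom in the open
    complex structure.
    """
    ring_idx = []
    for name in ring_atom_names:
        ring_idx.append(ens.atom_index(ring_residue, name))
    t_idx = ens.atom_index(*target_atom)
    centers = ens.frames[:, ring_idx, :].mean(axis=1)
    d = np.linalg.norm(centers - ens.frames[:, t_idx, :], axis=1)
    label = f"ring({ring_residue})-{target_atom[1]}({target_atom[0]})"
    return DistanceSeries(times=ens.times, values=d, label=label)


def classify_rotamer(chi1: float | np.ndarray) -> np.ndarray | str:
    """Classify chi1 into rotamer wells.

    gauche- for chi1 in [-120, 0), gauche+ for [0, 120), trans otherwise;
    the wells are centred on the canonical -60 / +60 / 180 degree positions.
    """
    chi1_arr = np.asarray(chi1, dtype=float)
    out = np.full(chi1_arr.shape, "trans", dtype=object)
    out[(chi1_arr >= -120) & (chi1_arr < 0)] = "gauche-"
    out[(chi1_arr >= 0) & (chi1_arr < 120)] = "gauche+"
    if np.ndim(chi1) == 0:
        return str(out.item())
    return out.astype(str)


def chi1_series(ens: TrajectoryEnsemble, residue: int,
                gamma_atom: str | None = None) -> RotamerSeries:
    """chi1 dihedral (N-CA-CB-gamma heavy atom) per frame with rotamer states."""
    if gamma_atom is None:
        resname = str(ens.atoms["resname"].iloc[ens.select(resid=residue)[0]])
        gamma_atom = CHI1_GAMMA_ATOM.get(resname, "CG")
    idx = [ens.atom_index(residue, n) for n in ("N", "CA", "CB", gamma_atom)]
    p = ens.frames[:, idx, :]
    chi1 = dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    chi1 = np.atleast_1d(chi1)
    return RotamerSeries(times=ens.times, chi1=chi1,
                         states=classify_rotamer(chi1), residue=residue)


def rotamer_populations(series: RotamerSeries) -> dict[str, float]:
    """Fraction of frames in each populated rotamer state (fractions sum to 1)."""
    if len(series.states) == 0:
        raise ValueError("empty rotamer series")
    vals, counts = np.unique(series.states, return_counts=True)
    return {str(v): float(c) / len(series.states) for v, c in zip(vals, counts)}


def detect_loop_events(d: DistanceSeries, open_threshold: float = 10.0,
                       close_threshold: float = 6.0,
                       min_duration: float = 1.0) -> list[LoopEvent]:
    """Detect loop-opening events with a hysteresis state machine.

    An event opens at the first frame with distance >= ``open_threshold``
    (10 Angstrom by default) and closes at the first subsequent frame with
    distance < ``close_threshold`` (6 Angstrom, the closed-loop definition).
    Events shorter than ``min_duration`` (1 ns) are discarded.  Hysteresis
    prevents chatter in the partially-open 6-10 Angstrom band.  Event
    boundaries are frame times; no sub-frame interpolation and no merging
    of events separated by brief closures.
    """
    if open_threshold <= close_threshold:
        raise ValueError("open_threshold must exceed close_threshold")
    events: list[LoopEvent] = []
    t, v = d.times, d.values
    open_i: int | None = None
    for i in range(len(v)):
        if open_i is None:
            if v[i] >= open_threshold:
                open_i = i
        else:
            if v[i] < close_threshold:
                ev = LoopEvent(start=float(t[open_i]), end=float(t[i]),
                               max_distance=float(v[open_i:i].max()))
                if ev.duration >= min_duration:
                    events.append(ev)
                open_i = None
    if open_i is not None:
        ev = LoopEvent(start=float(t[open_i]), end=float(t[-1]),
                       max_distance=float(v[open_i:].max()))
        if ev.duration >= min_duration:
            events.append(ev)
    return events


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral quadrature)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa_series(ens: TrajectoryEnsemble, atom_selection: np.ndarray,
                probe: float = 1.4, n_points: int = 960,
                radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-frame solvent-accessible surface area (Angstrom^2) of a selection.

    Shrake-Rupley: each atom is covered with ``n_points`` quasi-uniform test
    points on its probe-expanded sphere; points inside any other atom's
    expanded sphere are buried.  All atoms of the ensemble act as occluders;
    the reported area sums over ``atom_selection`` only.
    """
    radii = radii or VDW_RADII
    try:
        r = np.array([radii[e] for e in ens.atoms["element"]])
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius for element {exc}") from exc
    r_exp = r + probe
    pts = _sphere_points(n_points)
    sel = np.asarray(atom_selection, dtype=int)
    out = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        x = ens.frames[f]
        area = 0.0
        for i in sel:
            test = x[i] + r_exp[i] * pts
            # neighbours whose expanded spheres can reach atom i's surface
            dij = np.linalg.norm(x - x[i], axis=1)
            nb = np.where((dij < r_exp + r_exp[i]) & (np.arange(len(x)) != i))[0]
            exposed = np.ones(n_points, dtype=bool)
            for j in nb:
                exposed &= np.linalg.norm(test - x[j], axis=1) >= r_exp[j]
            area += exposed.mean() * 4.0 * np.pi * r_exp[i] ** 2
        out[f] = area
    return out


def hbond_occupancy(ens: TrajectoryEnsemble, donor: tuple[int, str],
                    hydrogen: tuple[int, str] | None,
                    acceptor_set: list[tuple[int, str]],
                    d_cut: float = 3.5, angle_cut: float = 150.0) -> float:
    """Fraction of frames in which a hydrogen bond is formed.

    A frame counts when the donor-acceptor distance is <= ``d_cut`` AND the
    D-H...A angle is >= ``angle_cut``, taking the best acceptor per frame
    (e.g. either carboxyl oxygen of D68 accepting from the Y71 amide).
    When the hydrogen is absent a distance-only criterion is used and a
    warning logged.
    """
    d_idx = ens.atom_index(*donor)
    a_idx = [ens.atom_index(*a) for a in acceptor_set]
    dpos = ens.frames[:, d_idx, :]
    dist = np.stack([np.linalg.norm(ens.frames[:, j, :] - dpos, axis=1)
                     for j in a_idx], axis=1)  # (n_frames, n_acceptors)
    if hydrogen is None:
        log.warning("hbond_occupancy: no hydrogen given; falling back to a "
                    "distance-only criterion")
        ok = dist <= d_cut
        return float(np.mean(ok.any(axis=1)))
    h_idx = ens.atom_index(*hydrogen)
    hpos = ens.frames[:, h_idx, :]
    v1 = dpos - hpos
    bonded = np.zeros(ens.n_frames, dtype=bool)
    for k, j in enumerate(a_idx):
        v2 = ens.frames[:, j, :] - hpos
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        bonded |= (dist[:, k] <= d_cut) & (ang >= angle_cut)
    return float(np.mean(bonded))


def sidechain_rmsd(ens: TrajectoryEnsemble, reference_frame: int,
                   core_selection: np.ndarray, residue: int,
                   mask: np.ndarray | None = None) -> tuple[np.ndarray, float, float]:
    """Heavy-atom side-chain RMSD per frame after core superposition.

    Each frame is least-squares superposed on ``core_selection`` of the
    reference frame; the RMSD of the residue's side-chain heavy atoms is
    then computed without further fitting.  ``mask`` optionally restricts
    the summary (mean, sd) to a subset of frames, e.g. loop-closed frames.
    Returns (per-frame RMSD, mean, sd).
    """
    res_atoms = ens.select(resid=residue)
    names = ens.atoms["name"].to_numpy()[res_atoms]
    elements = ens.atoms["element"].to_numpy()[res_atoms]
    side = res_atoms[(~np.isin(names, ["N", "CA", "C", "O", "H", "HA"]))
                     & (elements != "H")]
    if len(side) == 0:
        raise ValueError(f"residue {residue} has no side-chain heavy atoms")
    ref = ens.frames[reference_frame]
    vals = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        fitted = superpose(ens.frames[f], ref, fit_idx=np.asarray(core_selection))
        vals[f] = _rmsd(fitted[side], ref[side])
    sel = vals if mask is None else vals[np.asarray(mask)]
    return vals, float(sel.mean()), float(sel.std())


def mass_density_grid(ens: TrajectoryEnsemble, atom_selection: np.ndarray,
                      spacing: float = 0.5) -> OccupancyGrid:
    """Voxel visit counts for selected atoms over all frames, max-normalised.

    Frames are assumed already superposed on a common core.  Counts sum to
    n_frames x n_selected; the relative occupancy (counts / max counts)
    supports iso-surface style thresholding, e.g. at the 0.12 level used to
    visualise the two F70 ring conformations.
    """
    if ens.n_frames == 0:
        raise ValueError("ensemble has no frames")
    sel = np.asarray(atom_selection, dtype=int)
    pts = ens.frames[:, sel, :].reshape(-1, 3)
    origin = np.floor(pts.min(axis=0) / spacing) * spacing
    ijk = np.floor((pts - origin) / spacing).astype(int)
    shape = ijk.max(axis=0) + 1
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, tuple(ijk.T), 1)
    return OccupancyGrid(origin=origin, spacing=spacing, counts=counts)


def backbone_dihedral_series(ens: TrajectoryEnsemble, residue: int
                             ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Backbone phi/psi series (degrees) for one residue.

    phi = C'(k-1)-N(k)-CA(k)-C'(k); psi = N(k)-CA(k)-C'(k)-N(k+1).  At a
    chain terminus the undefined angle is returned as None rather than
    fabricated.
    """
    def _maybe(resid: int, name: str) -> int | None:
        try:
            return ens.atom_index(resid, name)
        except KeyError:
            return None

    n_k = ens.atom_index(residue, "N")
    ca_k = ens.atom_index(residue, "CA")
    c_k = ens.atom_index(residue, "C")
    c_prev = _maybe(residue - 1, "C")
    n_next = _maybe(residue + 1, "N")
    phi = None
    psi = None
    if c_prev is not None:
        phi = np.atleast_1d(dihedral(ens.frames[:, c_prev], ens.frames[:, n_k],
                                     ens.frames[:, ca_k], ens.frames[:, c_k]))
    if n_next is not None:
        psi = np.atleast_1d(dihedral(ens.frames[:, n_k], ens.frames[:, ca_k],
                                     ens.frames[:, c_k], ens.frames[:, n_next]))
    return phi, psi
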