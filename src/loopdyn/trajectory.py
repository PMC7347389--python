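"""Trajectory container and multi-model PDB input/output.

A :class:`TrajectoryEnsemble` is the in-memory form used by every
trajectory-facing stage: an atom table (pandas DataFrame), a coordinate
array in Angstrom, and frame times in ns.  Multi-model PDB files are read
and written through MDAnalysis; each MODEL record becomes one frame.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

# Standard atomic masses for the elements that occur in proteins and in the
# toy scaffolds produced by loopdyn.synthetic.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

# provenance may end up in a REMARK or TITLE record depending on the writer
_PROVENANCE_RE = re.compile(r"(?:REMARK|TITLE)\s+.*?loopdyn\s+(.*)")


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (two-letter elements first)."""
    stripped = name.strip()
    if stripped[:2].upper() in ("SE", "CL", "BR", "FE", "ZN", "MG", "NA"):
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass
class TrajectoryEnsemble:
    """Topology plus coordinate frames with time stamps.

    Attributes
    ----------
    atoms : DataFrame with columns name, resid, resname, element, mass.
    frames : (n_frames, n_atoms, 3) coordinates in Angstrom.
    times : (n_frames,) strictly increasing times in ns.
    box : optional (6,) cell parameters (lengths in Angstrom, angles in deg).
    provenance : free-form metadata string (generator parameters, seed).
    """

    atoms: pd.DataFrame
    frames: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] != len(self.times):
            raise ValueError("frames and times length mismatch")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError("atom count mismatch between atom table and frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(self, resid: int | None = None, names: list[str] | None = None,
               resids: list[int] | None = None) -> np.ndarray:
        """Indices of atoms matching a residue id and/or a list of atom names."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if resid is not None:
            mask &= (self.atoms["resid"].to_numpy() == resid)
        if resids is not None:
            mask &= np.isin(self.atoms["resid"].to_numpy(), resids)
        if names is not None:
            mask &= np.isin(self.atoms["name"].to_numpy(), names)
        return np.where(mask)[0]

    def atom_index(self, resid: int, name: str) -> int:
        """Index of a single named atom; raises a selection error when absent."""
        idx = self.select(resid=resid, names=[name])
        if len(idx) == 0:
            raise KeyError(f"atom {name!r} not found in residue {resid}")
        if len(idx) > 1:
            raise KeyError(f"atom {name!r} in residue {resid} is not unique")
        return int(idx[0])


def load_ensemble(topology_path: str | Path,
                  trajectory_path: str | Path | None = None,
                  dt_ns: float | None = None) -> TrajectoryEnsemble:
    """Read a multi-model PDB (or topology + trajectory pair) into an ensemble.

    MODEL records of a multi-model PDB become frames.  Frame times are taken,
    in order of precedence, from ``dt_ns``, from a ``REMARK loopdyn dt_ns=..``
    provenance line written by this package, or from the trajectory reader;
    otherwise consecutive frames are spaced 1 ns apart.
    """
    topology_path = Path(topology_path)
    provenance = ""
    if topology_path.suffix.lower() in (".pdb", ".ent"):
        with open(topology_path) as fh:
            for line in fh:
                m = _PROVENANCE_RE.match(line)
                if m:
                    provenance = m.group(1).strip()
                    break
                if line.startswith(("ATOM", "HETATM", "MODEL")):
                    break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(trajectory_path))
    names = [a.name for a in u.atoms]
    elements = [_element_from_name(n) for n in names]
    atoms = pd.DataFrame({
        "name": names,
        "resid": [int(a.resid) for a in u.atoms],
        "resname": [a.resname for a in u.atoms],
        "element": elements,
        "mass": [ATOMIC_MASSES.get(e, 0.0) for e in elements],
    })
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    n = frames.shape[0]
    if dt_ns is None and provenance:
        m = re.search(r"dt_ns=([0-9.eE+-]+)", provenance)
        if m:
            dt_ns = float(m.group(1))
    if dt_ns is not None:
        times = np.arange(n) * dt_ns
    else:
        times = np.array([ts.time for ts in u.trajectory], dtype=float) / 1000.0  # ps -> ns
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            times = np.arange(n, dtype=float)
    box = None
    if u.dimensions is not None and np.any(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions, dtype=float)
    return TrajectoryEnsemble(atoms=atoms, frames=frames, times=times,
                              box=box, provenance=provenance)


def write_ensemble(ens: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB with a provenance REMARK line."""
    path = Path(path)
    n_atoms = ens.n_atoms
    u = mda.Universe.empty(n_atoms, n_residues=ens.atoms["resid"].nunique(),
                           atom_resindex=pd.factorize(ens.atoms["resid"])[0],
                           trajectory=True)
    u.add_TopologyAttr("names", ens.atoms["name"].tolist())
    grouped = ens.atoms.drop_duplicates("resid")
    u.add_TopologyAttr("resids", grouped["resid"].tolist())
    u.add_TopologyAttr("resnames", grouped["resname"].tolist())
    u.add_TopologyAttr("elements", ens.atoms["element"].str.capitalize().tolist())
    u.load_new(ens.frames, format="memory", order="fac")
    dt_ns = float(ens.times[1] - ens.times[0]) if ens.n_frames > 1 else 1.0
    remark = f"loopdyn dt_ns={dt_ns:g} {ens.provenance}".strip()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, remarks=remark) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def ca_rmsd(ens_a: TrajectoryEnsemble, ens_b: TrajectoryEnsemble,
            resid_range: tuple[int, int] = (12, 122),
            frame_a: int = 0, frame_b: int = 0) -> float:
    """Pairwise Calpha RMSD (Angstrom) between two structures after
    least-squares superposition over the shared residues in ``resid_range``.

    Residues present in only one structure are dropped, so structures with
    deletions (e.g. a loop-truncation variant) compare over the shared core.
    """
    from loopdyn._geometry import superpose, rmsd

    lo, hi = resid_range

    def _ca_map(ens: TrajectoryEnsemble, frame: int) -> dict[int, np.ndarray]:
        idx = ens.select(names=["CA"])
        out = {}
        for i in idx:
            r = int(ens.atoms["resid"].iloc[i])
            if lo <= r <= hi:
                out[r] = ens.frames[frame, i]
        return out

    ca_a = _ca_map(ens_a, frame_a)
    ca_b = _ca_map(ens_b, frame_b)
    shared = sorted(set(ca_a) & set(ca_b))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared Calpha atoms in the residue range")
    xa = np.array([ca_a[r] for r in shared])
    xb = np.array([ca_b[r] for r in shared])
    xa_fit = superpose(xa, xb)
    return rmsd(xa_fit, xb)
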