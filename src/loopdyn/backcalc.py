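"""Back-calculation of NMR observables from conformational ensembles.

Order parameters are computed with the Lipari-Szabo ensemble estimator

    S2 = (3/2) * sum_{a,b} <mu_a mu_b>^2 - 1/2

over blocks of trajectory (5 ns by default), after removal of overall
tumbling by superposing every frame on a reference structure.  The reported
value per residue is the mean over blocks, with errors from bootstrap
resampling of blocks (random sampling with replacement).

Residual dipolar couplings are back-calculated from an alignment tensor as

    D = kappa / R^3 * (Ax cos^2 t1 + Ay cos^2 t2 + Az cos^2 t3)

with kappa = -(3 / 8 pi^2) * gammaI * gammaS * mu0 * hbar, R the effective
N-H bond length (1.04 Angstrom), and t1..t3 the angles between the bond and
the tensor principal axes.  Agreement with observed couplings is scored by
the Q factor, rms(Dcalc - Dobs) / rms(Dobs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from loopdyn._geometry import kabsch_rotation, superpose
from loopdyn.trajectory import TrajectoryEnsemble

log = logging.getLogger(__name__)

# CODATA values
GAMMA_H = 2.6752218744e8    # rad s^-1 T^-1
GAMMA_N = -2.7126e7         # rad s^-1 T^-1 (15N, negative)
MU0 = 4.0e-7 * np.pi        # T^2 m^3 J^-1
HBAR = 1.054571817e-34      # J s

#: RDC prefactor kappa = -(3/8pi^2) gammaI gammaS mu0 hbar, in Hz m^3.
KAPPA = -(3.0 / (8.0 * np.pi ** 2)) * GAMMA_H * GAMMA_N * MU0 * HBAR


# An RDC table is a plain DataFrame with columns residue, D_obs and/or
# D_calc (Hz), optional error; the alias names the contract.
RDCSet = pd.DataFrame


@dataclass
class BondVectorSeries:
    """Unit bond vectors per frame for one residue, in the reference frame."""
    residue: int
    times: np.ndarray
    vectors: np.ndarray  # (n_frames, 3), unit norm

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("bond vectors must be unit length to 1e-6")


@dataclass
class OrderParameterSet:
    """S2 per residue with bootstrap error and the block length used."""
    residue: int
    s2: float
    error: float  # NaN when undefined (single block)
    block_length: float
    block_values: np.ndarray | None = None


@dataclass
class AlignmentTensor:
    """Traceless alignment tensor in its principal axis system.

    ``principal`` holds (Ax, Ay, Az) sorted |Az| >= |Ay| >= |Ax| and summing
    to zero; ``rotation`` maps laboratory-frame vectors into the principal
    axis system; ``condition_number`` reports the conditioning of the
    five-parameter fit that produced the tensor (NaN for constructed tensors).
    """
    principal: np.ndarray
    rotation: np.ndarray
    condition_number: float = float("nan")

    def __post_init__(self) -> None:
        self.principal = np.asarray(self.principal, dtype=float)
        if abs(self.principal.sum()) > 1e-8 * max(1.0, np.abs(self.principal).max()):
            raise ValueError("alignment tensor must be traceless")

    @property
    def saupe(self) -> np.ndarray:
        """The 3x3 Saupe matrix in the laboratory frame."""
        return self.rotation.T @ np.diag(self.principal) @ self.rotation

    @property
    def is_zero(self) -> bool:
        return bool(np.allclose(self.principal, 0.0))


def extract_bond_vectors(ens: TrajectoryEnsemble, reference_frame: int = 0,
                         atom_pair: tuple[str, str] = ("N", "H"),
                         core_selection: np.ndarray | None = None,
                         residues: list[int] | None = None) -> list[BondVectorSeries]:
    """Unit N->H bond vectors per residue after core superposition.

    Every frame is least-squares superposed on ``core_selection`` (default:
    all atoms) of the reference frame, removing overall tumbling; residues
    missing either atom of the pair are skipped with a log entry.
    """
    if residues is None:
        residues = sorted(ens.atoms["resid"].unique())
    if core_selection is None:
        core_selection = np.arange(ens.n_atoms)
    core_selection = np.asarray(core_selection)
    ref = ens.frames[reference_frame]
    aligned = np.empty_like(ens.frames)
    for f in range(ens.n_frames):
        aligned[f] = superpose(ens.frames[f], ref, fit_idx=core_selection)
    out = []
    for resid in residues:
        try:
            i = ens.atom_index(resid, atom_pair[0])
            j = ens.atom_index(resid, atom_pair[1])
        except KeyError:
            log.info("residue %d skipped: missing %s or %s", resid, *atom_pair)
            continue
        v = aligned[:, j, :] - aligned[:, i, :]
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        out.append(BondVectorSeries(residue=int(resid), times=ens.times, vectors=v))
    return out


def _s2_from_vectors(v: np.ndarray) -> float:
    """Lipari-Szabo ensemble S2 from (n, 3) unit vectors."""
    m = (v[:, :, None] * v[:, None, :]).mean(axis=0)  # <mu_a mu_b>
    return float(1.5 * np.sum(m * m) - 0.5)


def _block_slices(times: np.ndarray, block: float) -> list[slice]:
    """Consecutive, non-overlapping blocks of `block` ns (complete blocks only)."""
    t0 = times[0]
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    span = times[-1] - t0 + dt  # sampling extent, each frame covers one dt
    n_blocks = int(np.floor(span / block + 1e-9))
    slices = []
    for b in range(n_blocks):
        lo, hi = t0 + b * block, t0 + (b + 1) * block
        idx = np.where((times >= lo - 1e-12) & (times < hi - 1e-12))[0]
        if len(idx):
            slices.append(slice(idx[0], idx[-1] + 1))
    return slices


def compute_order_parameters(bvs: BondVectorSeries, block: float = 5.0
                             ) -> OrderParameterSet:
    """S2 in consecutive blocks (5 ns default); reported value = mean over blocks."""
    slices = _block_slices(bvs.times, block)
    if not slices:
        raise ValueError(f"series shorter than one block of {block} ns")
    vals = np.array([_s2_from_vectors(bvs.vectors[s]) for s in slices])
    return OrderParameterSet(residue=bvs.residue, s2=float(vals.mean()),
                             error=float("nan"), block_length=block,
                             block_values=vals)


def bootstrap_s2_errors(bvs: BondVectorSeries, block: float = 5.0,
                        n_boot: int = 200, seed: int = 0) -> OrderParameterSet:
    """Bootstrap error on the block-mean S2 (sampling blocks with replacement).

    With a single block the error is undefined and reported as NaN, not zero.
    """
    ops = compute_order_parameters(bvs, block=block)
    vals = ops.block_values
    if len(vals) < 2:
        log.warning("residue %d: single block, bootstrap error undefined", bvs.residue)
        return ops
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    means = vals[idx].mean(axis=1)
    ops.error = float(means.std())
    return ops


def _bond_unit_vectors(structure: TrajectoryEnsemble, residues: list[int],
                       atom_pair: tuple[str, str], frame: int = 0) -> np.ndarray:
    vs = []
    for r in residues:
        i = structure.atom_index(r, atom_pair[0])
        j = structure.atom_index(r, atom_pair[1])
        v = structure.frames[frame, j] - structure.frames[frame, i]
        vs.append(v / np.linalg.norm(v))
    return np.array(vs)


def fit_alignment_tensor(structure: TrajectoryEnsemble, observed: pd.DataFrame,
                         atom_pair: tuple[str, str] = ("N", "H"),
                         bond_length: float = 1.04, frame: int = 0
                         ) -> AlignmentTensor:
    """Least-squares five-parameter Saupe fit of the alignment tensor.

    ``observed`` is a DataFrame with columns ``residue`` and ``D_obs`` (Hz).
    Each observed coupling constrains the five independent elements of the
    traceless symmetric Saupe matrix linearly through the bond direction
    cosines; the fit is solved by SVD and its condition number reported.
    """
    residues = [int(r) for r in observed["residue"]]
    if len(residues) < 5:
        raise ValueError("at least 5 RDCs are required for a tensor fit")
    u = _bond_unit_vectors(structure, residues, atom_pair, frame=frame)
    scale = KAPPA / (bond_length * 1e-10) ** 3
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    # D/scale = Sxx x^2 + Syy y^2 + Szz z^2 + 2Sxy xy + 2Sxz xz + 2Syz yz,
    # with Szz = -Sxx - Syy
    design = np.column_stack([x * x - z * z, y * y - z * z,
                              2 * x * y, 2 * x * z, 2 * y * z])
    rhs = observed["D_obs"].to_numpy(dtype=float) / scale
    coef, _, rank, sv = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 5:
        raise ValueError("degenerate bond geometry: rank-deficient tensor fit")
    cond = float(sv[0] / sv[-1])
    sxx, syy, sxy, sxz, syz = coef
    s_mat = np.array([[sxx, sxy, sxz],
                      [sxy, syy, syz],
                      [sxz, syz, -sxx - syy]])
    evals, evecs = np.linalg.eigh(s_mat)
    order = np.argsort(np.abs(evals))  # |Az| >= |Ay| >= |Ax| with Az last
    principal = evals[order]
    rotation = evecs[:, order].T
    if np.linalg.det(rotation) < 0:
        rotation[0] *= -1
    tensor = AlignmentTensor(principal=principal, rotation=rotation,
                             condition_number=cond)
    if np.allclose(principal, 0.0, atol=1e-12 * max(1.0, np.abs(rhs).max())):
        log.warning("fitted alignment tensor is zero (isotropic sample?)")
    return tensor


def backcalc_rdc(structure: TrajectoryEnsemble, tensor: AlignmentTensor,
                 residues: list[int] | None = None,
                 atom_pair: tuple[str, str] = ("N", "H"),
                 bond_length: float = 1.04,
                 ensemble_average: bool = True) -> pd.DataFrame:
    """Back-calculate RDCs (Hz) for each residue from the alignment tensor.

    D = kappa/R^3 (Ax cos^2 t1 + Ay cos^2 t2 + Az cos^2 t3), averaged over
    frames when ``ensemble_average`` and the structure has several frames.
    Returns a DataFrame with columns residue, D_calc.
    """
    if residues is None:
        residues = sorted(int(r) for r in structure.atoms["resid"].unique())
    scale = KAPPA / (bond_length * 1e-10) ** 3
    frames = range(structure.n_frames) if ensemble_average else [0]
    rows = []
    for r in residues:
        try:
            i = structure.atom_index(r, atom_pair[0])
            j = structure.atom_index(r, atom_pair[1])
        except KeyError:
            continue
        vals = []
        for f in frames:
            v = structure.frames[f, j] - structure.frames[f, i]
            v = v / np.linalg.norm(v)
            cosines = tensor.rotation @ v  # components along principal axes
            vals.append(scale * float(np.dot(tensor.principal, cosines ** 2)))
        rows.append({"residue": r, "D_calc": float(np.mean(vals))})
    return pd.DataFrame(rows)


def q_factor(rdcs: pd.DataFrame) -> float:
    """Quality factor Q = rms(D_calc - D_obs) / rms(D_obs).

    ``rdcs`` must carry paired columns D_obs and D_calc.  Q = 0 means perfect
    agreement; Q is undefined (ValueError) when all observed couplings vanish.
    """
    d_obs = rdcs["D_obs"].to_numpy(dtype=float)
    d_calc = rdcs["D_calc"].to_numpy(dtype=float)
    denom = np.sqrt(np.mean(d_obs ** 2))
    if denom == 0:
        raise ValueError("Q factor undefined: all observed RDCs are zero")
    return float(np.sqrt(np.mean((d_calc - d_obs) ** 2)) / denom)
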