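"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* stationary bond-vector trajectories uniformly distributed in a cone
  (known analytic S2 = [cos t0 (1 + cos t0)/2]^2),
* full-coordinate toy loop trajectories with planted open/close events,
  chi1 rotamer schedules and a schedulable donor-acceptor hydrogen bond,
* 15N relaxation datasets forward-computed from known model-free
  parameters plus Gaussian noise,
* CPMG dispersion datasets from a two-state exchange model with
  Eyring/van't Hoff-consistent temperature dependence and linear shift
  drift,
* toy alignments with exact planted per-position composition.

Everything is deterministic for a fixed seed; no force field, thermostat
or water is involved — features, not physics, are under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from loopdyn._geometry import place_atom
from loopdyn.backcalc import BondVectorSeries
from loopdyn.dispersion import (R_GAS, KB_OVER_H, T_REF_C, ThermoParams,
                                TwoStateExchangeModel, simulate_cpmg_profile)
from loopdyn.modelfree import DiffusionModel, SpinConstants, forward_rates
from loopdyn.trajectory import TrajectoryEnsemble


@dataclass
class ConeModelSpec:
    """Bond vectors uniformly distributed (in solid angle) within a cone.

    half_angle in degrees; dt in ps; ``correlation_time`` (ps) sets an
    exponential memory (0 = frames independent).
    """
    half_angle: float
    n_frames: int
    dt: float = 25.0
    seed: int = 0
    correlation_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.half_angle <= 180.0):
            raise ValueError("half_angle must be in [0, 180] degrees")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def analytic_s2(self) -> float:
        """Closed-form S2 of the cone model, [cos t0 (1 + cos t0) / 2]^2."""
        c = np.cos(np.radians(self.half_angle))
        return float((c * (1.0 + c) / 2.0) ** 2)


@dataclass
class PlantedEvent:
    """A planted loop-opening excursion (times in ns, distance in Angstrom)."""
    start: float
    end: float
    open_distance: float = 12.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


@dataclass
class ModelFreeTruth:
    """Ground-truth model-free parameters for one residue."""
    S2: float
    tau_e: float = 0.0   # ps
    Rex: float = 0.0     # s^-1
    angle: float = 90.0  # degrees to the unique diffusion axis

    def __post_init__(self) -> None:
        if not (0.0 <= self.S2 <= 1.0):
            raise ValueError("S2 must be in [0, 1]")
        if self.tau_e < 0 or self.Rex < 0:
            raise ValueError("tau_e and Rex must be non-negative")


@dataclass
class ExchangeTruth:
    """Ground-truth two-state exchange, thermodynamically parameterized.

    pB and kex refer to 25 C; dH (kJ/mol) and dH_ddag (kJ/mol) fix the
    temperature dependence, with dS and dS_ddag derived so the 25 C values
    are reproduced exactly (van't Hoff / Eyring consistency).  shift_slope
    is the linear drift of dw in ppb/K, shared or per residue.
    """
    pB: float = 0.02
    kex: float = 1500.0
    dw: dict[int, float] = field(default_factory=dict)  # ppm per residue
    dH: float = -20.0
    dH_ddag: float = 0.0
    shift_slope: float | dict[int, float] = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pB < 0.5):
            raise ValueError("pB must be in (0, 0.5)")
        if self.kex <= 0:
            raise ValueError("kex must be positive")

    def thermo(self) -> ThermoParams:
        t_ref = T_REF_C + 273.15
        dg = -R_GAS * t_ref * np.log(self.pB / (1.0 - self.pB))  # J/mol, A->B
        d_s = (self.dH * 1000.0 - dg) / t_ref
        k_ab = self.pB * self.kex
        ds_ddag = (self.dH_ddag * 1000.0 / t_ref
                   + R_GAS * np.log(k_ab / (KB_OVER_H * t_ref)))
        slopes = self.shift_slope if isinstance(self.shift_slope, dict) \
            else {r: self.shift_slope for r in self.dw}
        return ThermoParams(dH=self.dH, dS=d_s, dH_ddag=self.dH_ddag,
                            dS_ddag=ds_ddag, shift_slope=dict(slopes))

    def model_at(self, temp_c: float) -> TwoStateExchangeModel:
        thermo = self.thermo()
        p_b, kex = thermo.exchange_model(temp_c)
        dw_t = {r: v + thermo.shift_slope[r] * 1e-3 * (temp_c - T_REF_C)
                for r, v in self.dw.items()}
        return TwoStateExchangeModel(pB=float(p_b), kex=float(kex), dw=dw_t)


def gen_cone_trajectory(spec: ConeModelSpec) -> BondVectorSeries:
    """Unit vectors uniform in a cone about +z; deterministic for fixed seed.

    With ``correlation_time`` tau_c > 0, each frame keeps the previous
    vector with probability exp(-dt/tau_c) and redraws otherwise, so the
    series decorrelates exponentially; the stationary distribution is the
    uniform cone either way.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    c0 = np.cos(np.radians(spec.half_angle))
    cos_t = rng.uniform(c0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    v = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    if spec.correlation_time > 0:
        keep = rng.random(n) < np.exp(-spec.dt / spec.correlation_time)
        for i in range(1, n):
            if keep[i]:
                v[i] = v[i - 1]
    times = np.arange(n) * spec.dt / 1000.0  # ps -> ns
    return BondVectorSeries(residue=1, times=times, vectors=v)


# ---------------------------------------------------------------------------
# Toy loop trajectory

_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")  # hexagon order
_RING_BOND = 1.39
_ROTAMER_CHI1 = {"gauche-": -60.0, "gauche+": 60.0, "trans": 180.0}


def _scaffold_atoms() -> pd.DataFrame:
    """Atom table of the minimal 5-residue scaffold.

    Residue 1 = ASP proxy (H-bond acceptor carboxyl), 2 = GLU proxy,
    3 = PHE proxy (6-membered ring + chi1 atoms), 4 = TYR proxy (amide
    donor N/H), 5 = CYS proxy (Sgamma target).  Only the atoms the feature
    operations need are present; this is deliberately not a full protein.
    """
    rows = []

    def add(resid, resname, names):
        for n in names:
            el = ("S" if n.startswith("S") else
                  "O" if n.startswith("O") else
                  "H" if n.startswith("H") else
                  "N" if n == "N" else "C")
            rows.append({"name": n, "resid": resid, "resname": resname,
                         "element": el})
    add(68, "ASP", ["N", "CA", "C", "CB", "OD1", "OD2"])
    add(69, "GLU", ["N", "CA", "C"])
    add(70, "PHE", ["N", "CA", "C", "CB"] + list(_RING_NAMES))
    add(71, "TYR", ["N", "H", "CA", "C"])
    add(109, "CYS", ["N", "CA", "C", "CB", "SG"])
    df = pd.DataFrame(rows)
    from loopdyn.trajectory import ATOMIC_MASSES
    df["mass"] = [ATOMIC_MASSES[e] for e in df["element"]]
    return df


def _expand_schedule(schedule, n_frames: int, rng: np.random.Generator,
                     choices: list[str]) -> np.ndarray:
    """Per-frame labels from either an explicit sequence or exact fractions.

    Fractions are realized as exact counts by largest-remainder rounding
    and then shuffled, so planted populations are recovered exactly.
    """
    if schedule is None:
        return np.array([choices[0]] * n_frames)
    if isinstance(schedule, dict):
        quota = {k: schedule[k] * n_frames for k in schedule}
        counts = {k: int(np.floor(q)) for k, q in quota.items()}
        short = n_frames - sum(counts.values())
        by_rem = sorted(quota, key=lambda k: quota[k] - counts[k], reverse=True)
        for k in by_rem[:short]:
            counts[k] += 1
        labels = np.concatenate([[k] * c for k, c in counts.items()])
        rng.shuffle(labels)
        return labels
    labels = np.asarray(schedule)
    if len(labels) != n_frames:
        raise ValueError("explicit schedule length must equal n_frames")
    return labels


def gen_loop_trajectory(events: list[PlantedEvent] | None = None,
                        rotamer_schedule=None, n_frames: int = 200,
                        dt: float = 0.1, seed: int = 0,
                        closed_distance: float = 4.0,
                        hbond_schedule=None, jitter: float = 0.2
                        ) -> TrajectoryEnsemble:
    """Toy 5-residue trajectory with planted loop events, rotamers and H-bond.

    The F70-proxy ring-centre to Sgamma-proxy distance equals
    ``closed_distance`` (4 Angstrom) outside planted events and the event's
    ``open_distance`` inside it; chi1 of the PHE proxy and the
    Y71-N/H ... D68-carboxyl hydrogen bond follow their schedules exactly;
    Gaussian jitter of sd ``jitter`` (Angstrom) is added to all coordinates.
    ``dt`` is the frame spacing in ns.
    """
    events = events or []
    span = n_frames * dt
    evs = sorted(events, key=lambda e: e.start)
    for a, b in zip(evs, evs[1:]):
        if b.start < a.end:
            raise ValueError("planted events must not overlap")
    for e in evs:
        if e.start < 0 or e.end > span + 1e-9:
            raise ValueError("planted event outside the trajectory span")
    rng = np.random.default_rng(seed)
    atoms = _scaffold_atoms()
    times = np.arange(n_frames) * dt

    chi_states = _expand_schedule(rotamer_schedule, n_frames, rng,
                                  choices=["gauche-"])
    if hbond_schedule is None:
        hb = np.ones(n_frames, dtype=bool)
    elif isinstance(hbond_schedule, float):
        hb = _expand_schedule({"on": hbond_schedule, "off": 1.0 - hbond_schedule},
                              n_frames, rng, choices=["on"]) == "on"
    else:
        hb = np.asarray(hbond_schedule, dtype=bool)

    dist = np.full(n_frames, closed_distance)
    for e in evs:
        dist[(times >= e.start - 1e-9) & (times < e.end - 1e-9)] = e.open_distance

    name_idx = {(int(r), n): i for i, (r, n) in
                enumerate(zip(atoms["resid"], atoms["name"]))}
    coords = np.zeros((n_frames, len(atoms), 3))

    # static part: CYS proxy with SG at the origin
    static = {
        (109, "SG"): [0.0, 0.0, 0.0], (109, "CB"): [0.0, 0.0, 1.8],
        (109, "CA"): [0.0, 1.2, 2.6], (109, "N"): [0.0, 2.5, 2.0],
        (109, "C"): [0.0, 1.2, 4.1],
        # donor amide (TYR proxy) off to the side, pointing +y
        (71, "N"): [6.0, -3.0, 0.0], (71, "H"): [6.0, -2.0, 0.0],
        (71, "CA"): [6.0, -4.4, 0.3], (71, "C"): [7.3, -5.1, 0.0],
        (69, "N"): [3.0, -6.0, 1.0], (69, "CA"): [4.3, -6.4, 0.6],
        (69, "C"): [5.0, -5.2, 0.0],
        (68, "N"): [1.2, -4.2, 1.9], (68, "CA"): [2.0, -5.3, 1.5],
        (68, "C"): [1.9, -6.6, 2.2], (68, "CB"): [3.4, -4.9, 1.3],
    }
    for key, xyz in static.items():
        coords[:, name_idx[key], :] = xyz

    # acceptor carboxyl follows the H-bond schedule: along the N->H axis,
    # 2.9 A from N when bonded (linear bond), 5.0 A when broken
    n_pos = np.array(static[(71, "N")])
    h_dir = np.array(static[(71, "H")]) - n_pos
    h_dir /= np.linalg.norm(h_dir)
    perp = np.array([0.0, 0.0, 1.0])
    d_acc = np.where(hb, 2.9, 5.0)[:, None]
    coords[:, name_idx[(68, "OD1")], :] = n_pos + d_acc * h_dir
    coords[:, name_idx[(68, "OD2")], :] = n_pos + d_acc * h_dir + 1.1 * perp

    # PHE proxy: chi1-defining atoms fixed in a local frame, CG from chi1,
    # ring hexagon built off CG, then the whole group translated rigidly so
    # the ring centre sits at dist(t) from SG along +x
    n3 = np.array([0.0, 1.45, 0.0])
    ca3 = np.array([0.0, 0.0, 0.0])
    cb3 = np.array([1.32, -0.75, 0.0])
    c3 = np.array([-1.0, -0.8, -0.7])
    e_dir = np.array([1.0, 0.0, 0.0])
    for f in range(n_frames):
        chi1 = _ROTAMER_CHI1[str(chi_states[f])]
        cg = place_atom(n3, ca3, cb3, 1.50, 113.8, chi1)
        u = cg - cb3
        u /= np.linalg.norm(u)
        ref = ca3 - cb3
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        center = cg + _RING_BOND * u
        ring = [center + _RING_BOND * (np.cos(k * np.pi / 3.0) * (-u)
                                       + np.sin(k * np.pi / 3.0) * v)
                for k in range(6)]
        group = {(70, "N"): n3, (70, "CA"): ca3, (70, "CB"): cb3, (70, "C"): c3}
        group.update({(70, nm): ring[k] for k, nm in enumerate(_RING_NAMES)})
        shift = dist[f] * e_dir - center
        for key, xyz in group.items():
            coords[f, name_idx[key], :] = xyz + shift
    if jitter > 0:
        coords += rng.normal(0.0, jitter, coords.shape)
        # the amide H rides its donor: re-place it along the planted N->H
        # direction after jitter, so the D-H...A angle reflects the schedule
        # rather than noise on a 1-Angstrom bond
        coords[:, name_idx[(71, "H")], :] = \
            coords[:, name_idx[(71, "N")], :] + 1.02 * h_dir
    prov = f"gen_loop_trajectory seed={seed} dt_ns={dt:g} jitter={jitter:g}"
    return TrajectoryEnsemble(atoms=atoms, frames=coords, times=times,
                              provenance=prov)


def gen_relaxation_dataset(truth: dict[int, ModelFreeTruth],
                           fields: list[float], noise_frac: float = 0.02,
                           diffusion: DiffusionModel | None = None,
                           constants: SpinConstants | None = None,
                           seed: int = 0, temperature: float = 25.0
                           ) -> pd.DataFrame:
    """Forward-computed T1/T2/NOE tables with Gaussian relative noise.

    The error columns carry the noise level (relative ``noise_frac`` of
    each value, floored at 1e-6 relative so errors stay positive for
    noiseless data).  One row per residue per field.
    """
    if not fields:
        raise ValueError("fields must be non-empty")
    diffusion = diffusion or DiffusionModel(tau_m=7.0, d_ratio=2.0)
    constants = constants or SpinConstants()
    rng = np.random.default_rng(seed)
    err_frac = max(noise_frac, 1e-6)
    rows = []
    for resid, tr in sorted(truth.items()):
        params = {"S2": tr.S2, "tau_e": tr.tau_e, "Rex": tr.Rex}
        for f in fields:
            r1, r2, noe = forward_rates(params, diffusion, constants, f,
                                        angle_deg=tr.angle)
            t1, t2 = 1.0 / r1, 1.0 / r2
            vals = np.array([t1, t2, noe])
            noisy = vals * (1.0 + noise_frac * rng.standard_normal(3)) \
                if noise_frac > 0 else vals
            rows.append({
                "residue": resid, "field": f, "temperature": temperature,
                "T1": noisy[0], "T1_err": err_frac * abs(vals[0]),
                "T2": noisy[1], "T2_err": err_frac * abs(vals[1]),
                "NOE": noisy[2], "NOE_err": err_frac * abs(vals[2]),
            })
    return pd.DataFrame(rows)


def gen_dispersion_dataset(truth: ExchangeTruth, fields: list[float],
                           temperatures: list[float] | None = None,
                           nu_grid: np.ndarray | None = None,
                           t_rel: float = 0.04, r20: float = 10.0,
                           noise_frac: float = 0.02, seed: int = 0
                           ) -> pd.DataFrame:
    """R2eff-vs-nuCPMG tables from the two-state forward model.

    Rates and populations across temperature follow the Eyring / van't Hoff
    parameterization of ``truth``; chemical shifts drift linearly about
    25 C.  The default grid is 13 points between 50 and 850 Hz.  Errors are
    the (relative) noise level, floored so they remain positive.
    """
    if nu_grid is None:
        nu_grid = np.linspace(50.0, 850.0, 13)
    nu_grid = np.asarray(nu_grid, dtype=float)
    if np.any(nu_grid <= 0) or np.any(nu_grid > 5000.0):
        raise ValueError("nu_cpmg grid outside the instrumentally sensible range")
    temperatures = temperatures or [T_REF_C]
    rng = np.random.default_rng(seed)
    err_frac = max(noise_frac, 1e-6)
    rows = []
    for temp in temperatures:
        model = truth.model_at(temp)
        for resid, dw_t in sorted(model.dw.items()):
            for f in fields:
                curve = simulate_cpmg_profile(model, f, nu_grid, t_rel,
                                              dw_ppm=dw_t, r20=r20)
                noisy = curve * (1.0 + noise_frac * rng.standard_normal(len(curve))) \
                    if noise_frac > 0 else curve
                for nu, y, y0 in zip(nu_grid, noisy, curve):
                    rows.append({
                        "residue": resid, "field": f, "temperature": temp,
                        "nu_cpmg": nu, "R2eff": y,
                        "R2eff_err": err_frac * abs(y0), "T_rel": t_rel,
                    })
    return pd.DataFrame(rows)


def gen_toy_msa(n_seqs: int, composition_per_position: list[dict[str, float]],
                seed: int = 0, reference_id: str = "ref") -> MultipleSeqAlignment:
    """Toy alignment with exact planted per-position composition.

    Each position's composition (fractions summing to 1; '-' allowed for
    gaps) is realized as exact counts by largest-remainder rounding and
    assigned to sequences in a seed-determined shuffle.  The first record
    is the reference (it receives the most common residue at each position,
    so it carries no gaps unless gaps dominate a column).
    """
    rng = np.random.default_rng(seed)
    cols = []
    for comp in composition_per_position:
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("per-position composition must sum to 1")
        labels = _expand_schedule(comp, n_seqs, rng, choices=list(comp))
        # the reference record must be gap-free: swap a non-gap residue
        # into row 0 without changing the exact column counts
        if labels[0] == "-":
            non_gap = np.where(labels != "-")[0]
            if len(non_gap) == 0:
                raise ValueError("a column cannot be all gaps")
            j = non_gap[0]
            labels[0], labels[j] = labels[j], labels[0]
        cols.append(labels)
    mat = np.array(cols).T  # (n_seqs, n_pos)
    records = []
    for i in range(n_seqs):
        sid = reference_id if i == 0 else f"seq{i}"
        records.append(SeqRecord(Seq("".join(mat[i])), id=sid, description=""))
    return MultipleSeqAlignment(records)
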