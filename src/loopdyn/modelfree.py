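"""Lipari-Szabo model-free analysis of 15N backbone relaxation.

The spectral density uses the axially symmetric rotational-diffusion form
(three Woessner components weighted by the angle between the N-H bond and
the unique diffusion axis) with the Lipari-Szabo internal-motion
correction.  Relaxation rates R1, R2 and the heteronuclear NOE follow from
the standard dipolar + CSA expressions evaluated at the five canonical
frequencies.  Fitting covers the usual model hierarchy

    1: S2            2: S2, tau_e       3: S2, Rex
    4: S2, tau_e, Rex                   5: S2f, S2s, tau_s

with staged model selection and Monte Carlo error estimates.

Constants default to the values used in the study: N-H bond length 1.02
Angstrom, 15N CSA (sigma_par - sigma_perp) of -160 ppm, D_par/D_perp = 2.0.
The overall correlation time tau_m is a required input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from loopdyn.backcalc import GAMMA_H, GAMMA_N, HBAR, MU0

log = logging.getLogger(__name__)

MODEL_PARAMS = {
    1: ("S2",),
    2: ("S2", "tau_e"),
    3: ("S2", "Rex"),
    4: ("S2", "tau_e", "Rex"),
    5: ("S2f", "S2s", "tau_s"),
}


@dataclass
class SpinConstants:
    """Interaction constants, fixed per run.

    rNH in Angstrom; CSA (sigma_par - sigma_perp) in ppm; csa_angle is the
    angle (degrees) between the CSA principal axis and the N-H bond,
    accounting for their non-colinearity.
    """
    rNH: float = 1.02
    csa: float = -160.0
    csa_angle: float = 17.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N


@dataclass
class DiffusionModel:
    """Axially symmetric overall rotational diffusion.

    tau_m is the effective correlation time in ns, defined as 1/(6 D_iso);
    d_ratio = D_par / D_perp; ``angle`` is the per-residue angle (degrees)
    between the N-H bond vector and the unique diffusion axis.
    """
    tau_m: float
    d_ratio: float = 2.0
    angle: float = 90.0

    def rates(self) -> tuple[float, float]:
        """(D_perp, D_par) in ns^-1."""
        d_iso = 1.0 / (6.0 * self.tau_m)
        d_perp = 3.0 * d_iso / (self.d_ratio + 2.0)
        return d_perp, self.d_ratio * d_perp


@dataclass
class ModelFreeResult:
    residue: int
    model: int
    params: dict[str, float]
    errors: dict[str, float] = field(default_factory=dict)
    chi2: float = float("nan")
    dof: int = 0
    converged: bool = True


def _axial_components(diffusion: DiffusionModel, angle_deg: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Woessner amplitudes A_k and correlation times tau_k (ns)."""
    d_perp, d_par = diffusion.rates()
    c = np.cos(np.radians(angle_deg))
    c2 = c * c
    amps = np.array([
        (1.5 * c2 - 0.5) ** 2,
        3.0 * c2 * (1.0 - c2),
        0.75 * (1.0 - c2) ** 2,
    ])
    taus = 1.0 / np.array([6.0 * d_perp,
                           5.0 * d_perp + d_par,
                           2.0 * d_perp + 4.0 * d_par])
    return amps, taus


def spectral_density(omega: float | np.ndarray, params: dict[str, float],
                     diffusion: DiffusionModel,
                     angle_deg: float | None = None) -> np.ndarray:
    """Model-free spectral density J(omega) in ns (omega in rad/ns).

    ``params`` holds S2 (or S2f/S2s) and optionally tau_e / tau_s in ps.
    With d_ratio = 1 the form reduces to the isotropic single-tau_m
    Lipari-Szabo expression J = (2/5)[S2 tau_m/(1+w^2 tau_m^2) + ...].
    """
    omega = np.asarray(omega, dtype=float)
    if angle_deg is None:
        angle_deg = diffusion.angle
    amps, taus = _axial_components(diffusion, angle_deg)
    if "S2f" in params:  # extended model: fast motion S2f (tau_f -> 0), slow S2s, tau_s
        s2_slow = params["S2s"]
        s2f = params["S2f"]
        s2 = s2f * s2_slow
        tau_i = params.get("tau_s", 0.0) / 1000.0  # ps -> ns
        amp_int = s2f * (1.0 - s2_slow)
    else:
        s2 = params["S2"]
        tau_i = params.get("tau_e", 0.0) / 1000.0  # ps -> ns
        amp_int = 1.0 - s2
    j = np.zeros_like(omega, dtype=float)
    for a_k, t_k in zip(amps, taus):
        j += a_k * s2 * t_k / (1.0 + (omega * t_k) ** 2)
        if amp_int > 0 and tau_i > 0:
            t_eff = t_k * tau_i / (t_k + tau_i)
            j += a_k * amp_int * t_eff / (1.0 + (omega * t_eff) ** 2)
    return 0.4 * j


def forward_rates(params: dict[str, float], diffusion: DiffusionModel,
                  constants: SpinConstants, field_mhz: float,
                  angle_deg: float | None = None) -> tuple[float, float, float]:
    """R1 (s^-1), R2 (s^-1) and heteronuclear NOE from the model-free J(w).

    Dipolar + CSA contributions at the five canonical frequencies; any Rex
    in ``params`` adds directly to R2.  ``field_mhz`` is the 1H frequency.
    """
    omega_h = 2.0 * np.pi * field_mhz * 1e6            # rad/s
    omega_n = omega_h * constants.gamma_n / constants.gamma_h
    # frequencies in rad/ns to match J in ns
    w = np.array([0.0, omega_n, omega_h - omega_n, omega_h, omega_h + omega_n]) * 1e-9
    jw = spectral_density(w, params, diffusion, angle_deg) * 1e-9  # ns -> s
    j0, jn, jhmn, jh, jhpn = jw
    r = constants.rNH * 1e-10
    d = MU0 * HBAR * constants.gamma_h * abs(constants.gamma_n) / (4.0 * np.pi * r ** 3)
    d2 = d * d
    # CSA interaction constant; non-colinearity of the CSA axis and the N-H
    # bond scales the CSA contribution by P2(cos beta) squared-equivalent
    # geometric factor applied to the spectral densities of the same motion.
    c = omega_n * (constants.csa * 1e-6) / np.sqrt(3.0)
    p2 = 0.5 * (3.0 * np.cos(np.radians(constants.csa_angle)) ** 2 - 1.0)
    c2 = c * c * p2 * p2
    r1 = 0.25 * d2 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = 0.125 * d2 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn) + params.get("Rex", 0.0)
    sigma = 0.25 * d2 * (6.0 * jhpn - jhmn)
    noe = 1.0 + (constants.gamma_h / constants.gamma_n) * sigma / r1
    return float(r1), float(r2), float(noe)


def fit_exponential_decay(delays: np.ndarray, intensities: np.ndarray,
                          baseline_noise: float, n_mc: int = 500,
                          seed: int = 0) -> tuple[float, float]:
    """Fit I(t) = I0 exp(-t/T); return (T, error) with errors from Monte Carlo.

    The error is the sd of T over ``n_mc`` replicates in which Gaussian noise
    of size ``baseline_noise`` (the spectrum baseline noise, in intensity
    units) is added to the intensities.
    """
    delays = np.asarray(delays, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(delays) < 3:
        raise ValueError("at least 3 relaxation delays are required")
    if np.any(intensities <= -3.0 * baseline_noise):
        log.warning("non-positive intensities beyond the noise level; "
                    "fit may be unreliable")

    def _fit(y: np.ndarray) -> float:
        pos = y > 0
        slope, icept = np.polyfit(delays[pos], np.log(y[pos]), 1)
        t0 = -1.0 / slope if slope < 0 else delays.max()
        i0 = np.exp(icept)

        def resid(p):
            return p[0] * np.exp(-delays / p[1]) - y

        sol = optimize.least_squares(resid, x0=[i0, t0],
                                     bounds=([0, 1e-6], [np.inf, np.inf]))
        return float(sol.x[1])

    t_fit = _fit(intensities)
    if n_mc <= 0 or baseline_noise == 0:
        return t_fit, 0.0
    rng = np.random.default_rng(seed)
    reps = np.empty(n_mc)
    for k in range(n_mc):
        reps[k] = _fit(intensities + rng.normal(0.0, baseline_noise, len(delays)))
    return t_fit, float(reps.std())


def noe_ratio(i_sat: float, i_unsat: float, noise: float) -> tuple[float, float]:
    """Heteronuclear NOE as the saturated/unsaturated peak-height ratio.

    The error is propagated from the baseline noise on both peak heights:
    sigma_NOE = |NOE| * sqrt((noise/I_sat)^2 + (noise/I_unsat)^2).
    """
    if i_unsat == 0:
        raise ValueError("unsaturated intensity must be non-zero")
    ratio = i_sat / i_unsat
    err = abs(ratio) * np.sqrt((noise / i_sat) ** 2 + (noise / i_unsat) ** 2) \
        if i_sat != 0 else abs(noise / i_unsat)
    return float(ratio), float(err)


def _pack_observations(res_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (R1, R2, NOE) observations and errors across fields for one residue."""
    obs, err, fields = [], [], []
    for _, row in res_df.iterrows():
        r1, r2 = 1.0 / row["T1"], 1.0 / row["T2"]
        obs.extend([r1, r2, row["NOE"]])
        err.extend([r1 * row["T1_err"] / row["T1"], r2 * row["T2_err"] / row["T2"],
                    row["NOE_err"]])
        fields.append(row["field"])
    return np.array(obs), np.array(err), np.array(fields)


def _model_residuals(theta: np.ndarray, names: tuple[str, ...],
                     res_df: pd.DataFrame, diffusion: DiffusionModel,
                     constants: SpinConstants, angle_deg: float,
                     obs: np.ndarray, err: np.ndarray) -> np.ndarray:
    params = dict(zip(names, theta))
    calc = []
    for _, row in res_df.iterrows():
        r1, r2, noe = forward_rates(params, diffusion, constants,
                                    row["field"], angle_deg)
        calc.extend([r1, r2, noe])
    return (np.array(calc) - obs) / err


_BOUNDS = {"S2": (0.0, 1.0), "S2f": (0.0, 1.0), "S2s": (0.0, 1.0),
           "tau_e": (0.0, 5000.0), "tau_s": (0.0, 5000.0), "Rex": (0.0, 50.0)}
_TAU_GRID = np.array([1.0, 5.0, 20.0, 50.0, 100.0, 200.0, 350.0, 700.0, 1500.0, 3000.0])


def _fit_one_model(model: int, res_df: pd.DataFrame, diffusion: DiffusionModel,
                   constants: SpinConstants, angle_deg: float,
                   obs: np.ndarray, err: np.ndarray,
                   x0: np.ndarray | None = None) -> tuple[dict[str, float], float]:
    names = MODEL_PARAMS[model]
    lo = np.array([_BOUNDS[n][0] for n in names])
    hi = np.array([_BOUNDS[n][1] for n in names])
    starts: list[np.ndarray] = []
    base = {"S2": 0.8, "S2f": 0.9, "S2s": 0.9, "Rex": 2.0}
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    elif any(n in ("tau_e", "tau_s") for n in names):
        for tau in _TAU_GRID:  # multi-start over a log grid of internal times
            starts.append(np.array([tau if n in ("tau_e", "tau_s") else base[n]
                                    for n in names]))
    else:
        for s2 in (0.5, 0.8, 0.95):
            starts.append(np.array([s2 if n in ("S2", "S2f", "S2s") else base[n]
                                    for n in names]))
    best: tuple[dict[str, float], float] | None = None
    for x0 in starts:
        sol = optimize.least_squares(
            _model_residuals, x0=np.clip(x0, lo + 1e-9, hi - 1e-9),
            bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            args=(names, res_df, diffusion, constants, angle_deg, obs, err))
        chi2 = float(2.0 * sol.cost)
        if best is None or chi2 < best[1]:
            best = (dict(zip(names, sol.x)), chi2)
    return best


def _select_model(fits: dict[int, tuple[dict, float]], n_obs: int,
                  alpha: float = 0.05) -> int:
    """Staged model selection (Mandel-style).

    Model 1 is accepted if its chi2 passes a goodness-of-fit test at level
    ``alpha``; otherwise the two-parameter models 2 and 3 are screened by
    F-test against model 1 and the better-fitting significant one chosen;
    models 4/5 are used only when no simpler model is adequate.
    """
    def gof(model: int) -> bool:
        chi2 = fits[model][1]
        dof = n_obs - len(MODEL_PARAMS[model])
        if dof <= 0:
            return False
        return chi2 < stats.chi2.ppf(1.0 - alpha, dof)

    def ftest(simple: int, complex_: int) -> bool:
        chi_s, chi_c = fits[simple][1], fits[complex_][1]
        extra = len(MODEL_PARAMS[complex_]) - len(MODEL_PARAMS[simple])
        dof_c = n_obs - len(MODEL_PARAMS[complex_])
        if dof_c <= 0:
            return False
        if chi_c <= 1e-10 * max(1.0, chi_s):  # perfect fit of the complex model
            return chi_s > 1e-10
        f = ((chi_s - chi_c) / extra) / (chi_c / dof_c)
        return f > stats.f.ppf(1.0 - alpha, extra, dof_c)

    if len(fits) == 1:
        return next(iter(fits))
    if 1 in fits and gof(1):
        return 1
    candidates = [m for m in (2, 3)
                  if m in fits and (1 not in fits or ftest(1, m))]
    adequate = [m for m in candidates if gof(m)]
    pool = adequate or candidates
    if pool:
        return min(pool, key=lambda m: fits[m][1])
    for m in (4, 5):
        if m in fits and n_obs - len(MODEL_PARAMS[m]) > 0 and gof(m):
            return m
    return min(fits, key=lambda m: fits[m][1])


def fit_model_free(data: pd.DataFrame, diffusion: DiffusionModel,
                   constants: SpinConstants | None = None,
                   angles: dict[int, float] | None = None,
                   n_mc: int = 500, seed: int = 0,
                   models: tuple[int, ...] = (1, 2, 3, 4, 5)
                   ) -> list[ModelFreeResult]:
    """Per-residue model-free fit with staged model selection and MC errors.

    ``data`` columns: residue, field (MHz), T1, T1_err, T2, T2_err, NOE,
    NOE_err (T in s), one row per residue per field.  The diffusion tensor
    is fixed externally; per-residue angles to the unique axis are supplied
    in ``angles`` (default: the DiffusionModel's angle for every residue).
    Monte Carlo errors are the parameter sd over ``n_mc`` refits of
    noise-perturbed data (errors column as sigma).
    """
    constants = constants or SpinConstants()
    rng = np.random.default_rng(seed)
    out: list[ModelFreeResult] = []
    for resid, res_df in data.groupby("residue"):
        angle = (angles or {}).get(int(resid), diffusion.angle)
        obs, err, _ = _pack_observations(res_df)
        n_obs = len(obs)
        fits: dict[int, tuple[dict, float]] = {}
        for m in models:
            if len(MODEL_PARAMS[m]) >= n_obs:
                continue
            fits[m] = _fit_one_model(m, res_df, diffusion, constants, angle, obs, err)
        if not fits:
            out.append(ModelFreeResult(residue=int(resid), model=0, params={},
                                       converged=False))
            log.warning("residue %s: no fittable model", resid)
            continue
        chosen = _select_model(fits, n_obs)
        params, chi2 = fits[chosen]
        result = ModelFreeResult(residue=int(resid), model=chosen, params=params,
                                 chi2=chi2, dof=n_obs - len(params))
        if n_mc > 0:
            names = MODEL_PARAMS[chosen]
            calc = obs - err * _model_residuals(
                np.array([params[n] for n in names]), names, res_df,
                diffusion, constants, angle, obs, err)
            samples = {n: [] for n in names}
            x_fit = np.array([params[n] for n in names])
            for _ in range(n_mc):
                perturbed = calc + rng.normal(0.0, err)
                p_mc, _ = _fit_one_model(chosen, res_df, diffusion, constants,
                                         angle, perturbed, err, x0=x_fit)
                for n in names:
                    samples[n].append(p_mc[n])
            result.errors = {n: float(np.std(samples[n])) for n in names}
        out.append(result)
    return out
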