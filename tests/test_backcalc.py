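"""Order parameters, bootstrap errors, alignment tensors, RDCs and Q factor."""

import numpy as np
import pandas as pd
import pytest

from loopdyn.backcalc import (AlignmentTensor, BondVectorSeries,
                              backcalc_rdc, bootstrap_s2_errors,
                              compute_order_parameters, extract_bond_vectors,
                              fit_alignment_tensor, q_factor, _s2_from_vectors)
from loopdyn.synthetic import ConeModelSpec, gen_cone_trajectory

from conftest import make_ensemble, random_rigid_motion


def random_tensor(rng, aniso=4e-4):
    """A traceless alignment tensor with a random orientation."""
    ax, ay = -0.25 * aniso, -0.75 * aniso
    az = -(ax + ay)
    rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(rot) < 0:
        rot[0] *= -1
    return AlignmentTensor(principal=np.array([ax, ay, az]), rotation=rot)


def random_nh_structure(rng, n_res=20, n_frames=1):
    rows, coords = [], []
    for i in range(n_res):
        npos = rng.normal(0.0, 10.0, 3)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        rows.extend([("N", i + 1), ("H", i + 1)])
        coords.extend([npos, npos + 1.02 * v])
    names = [r[0] for r in rows]
    resids = [r[1] for r in rows]
    frames = np.tile(np.asarray(coords)[None], (n_frames, 1, 1))
    return make_ensemble(frames, names, resids,
                         ["ALA"] * len(names),
                         elements=[n[0] for n in names],
                         times=np.arange(n_frames, dtype=float))


class TestOrderParameters:
    def test_constant_vector_gives_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        bvs = BondVectorSeries(residue=1, times=np.arange(100) * 0.1, vectors=v)
        ops = compute_order_parameters(bvs, block=5.0)
        assert ops.s2 == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_limit_approaches_zero(self, rng):
        v = rng.normal(size=(200000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        bvs = BondVectorSeries(residue=1, times=np.arange(len(v)) * 0.025,
                               vectors=v)
        ops = compute_order_parameters(bvs, block=5000.0)
        assert abs(ops.s2) < 0.01

    @pytest.mark.parametrize("half_angle", [15.0, 30.0, 60.0])
    def test_cone_matches_analytic_closed_form(self, half_angle):
        spec = ConeModelSpec(half_angle=half_angle, n_frames=400000, dt=25.0,
                             seed=20)
        bvs = gen_cone_trajectory(spec)
        ops = compute_order_parameters(bvs, block=5.0)
        assert ops.s2 == pytest.approx(spec.analytic_s2, abs=0.01)

    def test_block_longer_than_series_rejected(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        bvs = BondVectorSeries(residue=1, times=np.arange(10) * 0.1, vectors=v)
        with pytest.raises(ValueError):
            compute_order_parameters(bvs, block=5.0)

    def test_matches_p2_autocorrelation_plateau(self):
        # for a stationary series the ensemble estimator equals the long-time
        # plateau of the P2 autocorrelation function computed by brute force
        spec = ConeModelSpec(half_angle=40.0, n_frames=20000, dt=25.0, seed=7)
        bvs = gen_cone_trajectory(spec)
        v = bvs.vectors
        # brute-force plateau: average P2(mu(t) . mu(t+dt)) at large lags
        lags = range(50, 150)
        plateau = np.mean([
            np.mean(1.5 * np.sum(v[:-lag] * v[lag:], axis=1) ** 2 - 0.5)
            for lag in lags])
        s2 = _s2_from_vectors(v)
        assert s2 == pytest.approx(plateau, abs=0.02)


class TestBootstrap:
    def _blocky_series(self, block_s2s, frames_per_block=200):
        """Series whose consecutive blocks have prescribed S2 values built
        from cone segments."""
        parts = []
        for i, s2 in enumerate(block_s2s):
            c = (-1.0 + np.sqrt(1.0 + 8.0 * np.sqrt(s2))) / 2.0
            half = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
            spec = ConeModelSpec(half_angle=half, n_frames=frames_per_block,
                                 dt=25.0, seed=100 + i)
            parts.append(gen_cone_trajectory(spec).vectors)
        v = np.vstack(parts)
        times = np.arange(len(v)) * 0.025
        return BondVectorSeries(residue=1, times=times, vectors=v)

    def test_identical_blocks_zero_error(self):
        v = np.tile([0.0, 0.0, 1.0], (400, 1))
        bvs = BondVectorSeries(residue=1, times=np.arange(400) * 0.025,
                               vectors=v)
        ops = bootstrap_s2_errors(bvs, block=5.0, n_boot=100, seed=1)
        assert ops.error == pytest.approx(0.0, abs=1e-12)

    def test_single_block_error_undefined_not_zero(self):
        v = np.tile([0.0, 0.0, 1.0], (200, 1))
        bvs = BondVectorSeries(residue=1, times=np.arange(200) * 0.025,
                               vectors=v)
        ops = bootstrap_s2_errors(bvs, block=5.0, n_boot=100, seed=1)
        assert np.isnan(ops.error)

    def test_two_valued_blocks_match_binomial_closed_form(self):
        # equal numbers of blocks at two S2 levels: the bootstrap sd of the
        # mean approaches |a-b|/2 / sqrt(n_blocks) (binomial resampling)
        ops_all = compute_order_parameters(
            self._blocky_series([0.6, 0.8] * 10), block=5.0)
        a, b = ops_all.block_values[:2]
        bvs = self._blocky_series([0.6, 0.8] * 10)
        ops = bootstrap_s2_errors(bvs, block=5.0, n_boot=4000, seed=2)
        vals = ops.block_values
        expected = np.sqrt(np.mean((vals - vals.mean()) ** 2) / len(vals))
        assert ops.error == pytest.approx(expected, rel=0.1)

    def test_fixed_seed_is_deterministic(self):
        bvs = self._blocky_series([0.6, 0.8, 0.7, 0.9])
        e1 = bootstrap_s2_errors(bvs, block=5.0, n_boot=200, seed=3).error
        e2 = bootstrap_s2_errors(bvs, block=5.0, n_boot=200, seed=3).error
        assert e1 == e2


class TestExtractBondVectors:
    def test_static_structure_constant_vectors(self, rng):
        ens = random_nh_structure(rng, n_res=5, n_frames=4)
        out = extract_bond_vectors(ens)
        for bv in out:
            assert np.allclose(bv.vectors, bv.vectors[0])

    def test_rigid_rotations_removed_by_alignment(self, rng):
        ens = random_nh_structure(rng, n_res=8, n_frames=5)
        for f in range(1, ens.n_frames):
            rot, trans = random_rigid_motion(rng)
            ens.frames[f] = ens.frames[f] @ rot.T + trans
        out = extract_bond_vectors(ens)
        for bv in out:
            assert np.allclose(bv.vectors, bv.vectors[0], atol=1e-9)

    def test_residue_without_amide_proton_skipped(self, rng):
        ens = random_nh_structure(rng, n_res=4)
        ens.atoms.loc[(ens.atoms["resid"] == 2)
                      & (ens.atoms["name"] == "H"), "name"] = "XX"
        out = extract_bond_vectors(ens)
        assert [bv.residue for bv in out] == [1, 3, 4]


class TestAlignmentTensor:
    def test_noiseless_round_trip_recovery(self, rng):
        ens = random_nh_structure(rng)
        true = random_tensor(rng)
        obs = backcalc_rdc(ens, true).rename(columns={"D_calc": "D_obs"})
        fit = fit_alignment_tensor(ens, obs)
        assert np.allclose(np.sort(fit.principal), np.sort(true.principal),
                           rtol=1e-6)

    def test_zero_alignment_flagged(self, rng, caplog):
        ens = random_nh_structure(rng)
        obs = pd.DataFrame({"residue": range(1, 21), "D_obs": np.zeros(20)})
        fit = fit_alignment_tensor(ens, obs)
        assert fit.is_zero

    def test_too_few_rdcs_rejected(self, rng):
        ens = random_nh_structure(rng)
        obs = pd.DataFrame({"residue": [1, 2, 3, 4], "D_obs": [1.0] * 4})
        with pytest.raises(ValueError):
            fit_alignment_tensor(ens, obs)

    def test_degenerate_geometry_rejected(self):
        # all N-H bonds parallel: rank-deficient design matrix
        rows, coords = [], []
        for i in range(8):
            npos = np.array([3.0 * i, 0.0, 0.0])
            rows.extend([("N", i + 1), ("H", i + 1)])
            coords.extend([npos, npos + [0.0, 0.0, 1.02]])
        ens = make_ensemble(coords, [r[0] for r in rows],
                            [r[1] for r in rows], ["ALA"] * len(rows),
                            elements=[r[0][0] for r in rows])
        obs = pd.DataFrame({"residue": range(1, 9), "D_obs": np.ones(8)})
        with pytest.raises(ValueError, match="degenerate|rank"):
            fit_alignment_tensor(ens, obs)

    def test_noisy_recovery_within_sampling_error(self, rng):
        ens = random_nh_structure(rng)
        true = random_tensor(rng)
        clean = backcalc_rdc(ens, true)
        scale = np.sqrt(np.mean(clean["D_calc"] ** 2))
        errs = []
        for k in range(25):
            obs = clean.copy()
            obs["D_obs"] = obs["D_calc"] + rng.normal(0.0, 0.1 * scale,
                                                      len(obs))
            fit = fit_alignment_tensor(ens, obs)
            errs.append(np.sort(fit.principal) - np.sort(true.principal))
        errs = np.asarray(errs)
        # mean recovered components within ~3 sd of the replicate spread
        bias = np.abs(errs.mean(axis=0))
        sd = errs.std(axis=0) / np.sqrt(len(errs))
        assert np.all(bias < 3.5 * sd + 1e-12)


class TestBackcalcRDC:
    def test_bond_along_unique_axis(self):
        ens = make_ensemble([[0.0, 0.0, 0.0], [0.0, 0.0, 1.02]], ["N", "H"],
                            [1, 1], ["ALA"] * 2, elements=["N", "H"])
        az = 4e-4
        tensor = AlignmentTensor(principal=np.array([-az / 2, -az / 2, az]),
                                 rotation=np.eye(3))
        from loopdyn.backcalc import KAPPA
        d = backcalc_rdc(ens, tensor)["D_calc"].iloc[0]
        assert d == pytest.approx(KAPPA / (1.04e-10) ** 3 * az, rel=1e-10)

    def test_matches_independent_direction_cosine_oracle(self, rng):
        ens = random_nh_structure(rng, n_res=10)
        tensor = random_tensor(rng)
        got = backcalc_rdc(ens, tensor)
        from loopdyn.backcalc import KAPPA
        scale = KAPPA / (1.04e-10) ** 3
        for _, row in got.iterrows():
            i = ens.atom_index(int(row["residue"]), "N")
            j = ens.atom_index(int(row["residue"]), "H")
            v = ens.frames[0, j] - ens.frames[0, i]
            v /= np.linalg.norm(v)
            saupe = tensor.saupe
            expected = scale * float(v @ saupe @ v)
            assert row["D_calc"] == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_joint_rotation(self, rng):
        ens = random_nh_structure(rng, n_res=10)
        tensor = random_tensor(rng)
        d0 = backcalc_rdc(ens, tensor)["D_calc"].to_numpy()
        rot, _ = random_rigid_motion(rng)
        ens.frames = ens.frames @ rot.T
        rotated = AlignmentTensor(principal=tensor.principal,
                                  rotation=tensor.rotation @ rot.T)
        d1 = backcalc_rdc(ens, rotated)["D_calc"].to_numpy()
        np.testing.assert_allclose(d1, d0, atol=1e-10)


class TestQFactor:
    def test_perfect_agreement_is_zero(self):
        df = pd.DataFrame({"D_obs": [1.0, -2.0, 3.0],
                           "D_calc": [1.0, -2.0, 3.0]})
        assert q_factor(df) == 0.0

    def test_zero_calculated_gives_one(self):
        df = pd.DataFrame({"D_obs": [1.0, -2.0, 3.0],
                           "D_calc": [0.0, 0.0, 0.0]})
        assert q_factor(df) == pytest.approx(1.0)

    def test_all_zero_observed_undefined(self):
        df = pd.DataFrame({"D_obs": [0.0, 0.0], "D_calc": [1.0, 2.0]})
        with pytest.raises(ValueError):
            q_factor(df)

    def test_scale_covariance(self, rng):
        d = rng.normal(0.0, 10.0, 30)
        c = d + rng.normal(0.0, 1.0, 30)
        df = pd.DataFrame({"D_obs": d, "D_calc": c})
        df2 = pd.DataFrame({"D_obs": 7.3 * d, "D_calc": 7.3 * c})
        assert q_factor(df) == pytest.approx(q_factor(df2), rel=1e-12)

    def test_relative_noise_sets_q_level(self, rng):
        d = rng.normal(0.0, 10.0, 2000)
        sigma = 0.1
        rms = np.sqrt(np.mean(d ** 2))
        c = d + rng.normal(0.0, sigma * rms, len(d))
        df = pd.DataFrame({"D_obs": d, "D_calc": c})
        assert q_factor(df) == pytest.approx(sigma, rel=0.1)
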