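"""Basin simulator: analytic oracle, Gillespie paths, emissions, reconstruction."""

import json

import numpy as np
import pytest

import nacscore as ns
from nacscore.errors import ConfigurationError, ReconstructionError
from nacscore.geometry import PRO_R, PRO_S, ReactionCenter
from nacscore.synthetic import (GeometryEmission, nac_emission,
                                nonreactive_emission)


def _two_state(k12, k21):
    em = {PRO_S: nac_emission(), PRO_R: nonreactive_emission()}
    em2 = {PRO_S: nonreactive_emission(), PRO_R: nac_emission()}
    return ns.BasinModel(
        state_labels=("proS_NAC", "proR_NAC"),
        rates=np.array([[-k12, k12], [k21, -k21]]),
        emissions={"proS_NAC": em, "proR_NAC": em2},
        initial_distribution=np.array([0.5, 0.5]))


class TestStationaryDistribution:
    def test_symmetric_two_state(self):
        pi = ns.stationary_distribution(_two_state(1.0, 1.0))
        assert np.allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_detailed_balance_two_state(self):
        # k12=1, k21=3: pi proportional to (3, 1)
        pi = ns.stationary_distribution(_two_state(1.0, 3.0))
        assert np.allclose(pi, [0.75, 0.25], atol=1e-12)

    def test_uniform_three_state(self, basin_model_60):
        model = ns.make_basin_model(
            {"proS_NAC": 1 / 3, "proR_NAC": 1 / 3, "nonproductive_1": 1 / 3},
            hop_rate_per_ps=1.0)
        assert np.allclose(ns.stationary_distribution(model), 1 / 3, atol=1e-12)

    def test_residual_small(self, basin_model_60):
        pi = ns.stationary_distribution(basin_model_60)
        assert np.max(np.abs(pi @ basin_model_60.rates)) < 1e-10

    def test_make_basin_model_hits_requested_occupancies(self, basin_model_60):
        pi = ns.stationary_distribution(basin_model_60)
        assert np.allclose(pi, [0.30, 0.075, 0.625], atol=1e-12)


class TestBasinModelValidation:
    def test_reducible_chain_rejected(self):
        em = {PRO_S: nonreactive_emission(), PRO_R: nonreactive_emission()}
        with pytest.raises(ConfigurationError, match="irreducible"):
            ns.BasinModel(state_labels=("a", "b"),
                          rates=np.zeros((2, 2)),
                          emissions={"a": em, "b": em},
                          initial_distribution=np.array([0.5, 0.5]))

    def test_rows_must_sum_to_zero(self):
        em = {PRO_S: nonreactive_emission(), PRO_R: nonreactive_emission()}
        with pytest.raises(ConfigurationError, match="sum to zero"):
            ns.BasinModel(state_labels=("a", "b"),
                          rates=np.array([[1.0, 1.0], [1.0, -1.0]]),
                          emissions={"a": em, "b": em},
                          initial_distribution=np.array([0.5, 0.5]))

    def test_nac_state_with_nonreactive_emission_rejected(self):
        """A basin labeled as a NAC state must actually emit NAC geometry."""
        em_bad = {PRO_S: nonreactive_emission(), PRO_R: nonreactive_emission()}
        with pytest.raises(ConfigurationError, match="probability"):
            ns.BasinModel(state_labels=("proS_NAC", "x"),
                          rates=np.array([[-1.0, 1.0], [1.0, -1.0]]),
                          emissions={"proS_NAC": em_bad, "x": em_bad},
                          initial_distribution=np.array([0.5, 0.5]))

    def test_yaml_roundtrip(self):
        from pathlib import Path
        model = ns.BasinModel.from_yaml(
            Path(__file__).resolve().parent.parent / "examples" / "basin_model.yaml")
        assert model.state_labels == ("proS_NAC", "proR_NAC", "nonproductive_1")
        truth = ns.SyntheticTruth.from_model(model)
        assert truth.true_ee == pytest.approx(60.0, abs=1e-9)


class TestSimulateCtmc:
    def test_single_state_constant(self):
        model = ns.make_basin_model({"proS_NAC": 1.0})
        path = ns.simulate_ctmc(model, 100.0, seed=0)
        assert len(path.states) == 1
        assert np.all(path.state_at([0.0, 50.0, 100.0]) == 0)

    def test_same_seed_identical_path(self, basin_model_60):
        p1 = ns.simulate_ctmc(basin_model_60, 500.0, seed=11)
        p2 = ns.simulate_ctmc(basin_model_60, 500.0, seed=11)
        assert np.array_equal(p1.times, p2.times)
        assert np.array_equal(p1.states, p2.states)

    def test_long_run_occupancy_matches_stationary(self, basin_model_60):
        path = ns.simulate_ctmc(basin_model_60, 1e5, seed=3)
        occ = path.occupancy()
        pi = ns.stationary_distribution(basin_model_60)
        # relaxation is ~1/hop_rate = 1 ps; 1e5 ps gives plenty of effective
        # samples, so a 3-sigma-ish absolute band of 0.01 is conservative
        assert np.allclose(occ, pi, atol=0.01)

    def test_sample_time_out_of_range_rejected(self, basin_model_60):
        path = ns.simulate_ctmc(basin_model_60, 10.0, seed=0)
        with pytest.raises(ValueError):
            path.state_at([11.0])


class TestEmissions:
    def test_zero_sd_constant_geometry(self):
        em = GeometryEmission(d=(2.3, 0.0), theta1=(120.0, 0.0),
                              theta2=(160.0, 0.0))
        d, t1, t2 = em.draw(10, np.random.default_rng(0))
        assert np.all(d == 2.3) and np.all(t1 == 120.0) and np.all(t2 == 160.0)

    def test_pure_nac_path_classifies_as_nac(self):
        model = ns.make_basin_model({"proS_NAC": 1.0})
        path = ns.simulate_ctmc(model, 1000.0, seed=1)
        emitted = ns.emit_geometries(path, model, np.arange(1000.0), seed=2)
        samples = ns.geometries_to_samples(emitted)
        res = ns.score_samples(samples)
        assert res.nac_count[PRO_S] / res.frames_evaluated >= 0.99

    def test_deterministic_given_seed(self, basin_model_60):
        path = ns.simulate_ctmc(basin_model_60, 100.0, seed=5)
        t = np.arange(100.0)
        a = ns.emit_geometries(path, basin_model_60, t, seed=6)
        b = ns.emit_geometries(path, basin_model_60, t, seed=6)
        assert np.array_equal(a[PRO_S]["d"], b[PRO_S]["d"])
        assert np.array_equal(a[PRO_R]["theta2"], b[PRO_R]["theta2"])


class TestReconstruction:
    def _roundtrip(self, geo, seed=0):
        atoms = ns.reconstruct_coordinates(geo, seed=seed)
        by = {a.name: a for a in atoms}
        rc = ReactionCenter(fe=by["FE"], oxo=by["O1"], c_target=by["C6"],
                            h_pro_r=by["H6R"], h_pro_s=by["H6S"])
        return {lab: ns.evaluate_geometry(rc, lab) for lab in (PRO_S, PRO_R)}

    def test_roundtrip_on_emitted_samples(self, basin_model_60, rng):
        path = ns.simulate_ctmc(basin_model_60, 400.0, seed=8)
        emitted = ns.emit_geometries(path, basin_model_60, np.arange(200.0),
                                     seed=9)
        for j in range(200):
            geo = {h: (emitted[h]["d"][j], emitted[h]["theta1"][j],
                       emitted[h]["theta2"][j]) for h in (PRO_S, PRO_R)}
            out = self._roundtrip(geo, seed=rng)
            for lab in (PRO_S, PRO_R):
                assert out[lab].d == pytest.approx(geo[lab][0], abs=1e-6)
                assert out[lab].theta1 == pytest.approx(geo[lab][1], abs=1e-4)
                assert out[lab].theta2 == pytest.approx(geo[lab][2], abs=1e-4)

    def test_theta1_180_collinear_layout(self):
        geo = {PRO_S: (2.6, 180.0, 150.0), PRO_R: (4.0, 120.0, 120.0)}
        out = self._roundtrip(geo)
        assert out[PRO_S].theta1 == pytest.approx(180.0, abs=1e-4)
        # H sits on the Fe-O axis, beyond the oxo
        atoms = ns.reconstruct_coordinates(geo, seed=0)
        h_s = next(a for a in atoms if a.name == "H6S")
        assert np.allclose(h_s.coord[:2], 0.0, atol=1e-9)

    def test_zero_distance_rejected(self):
        geo = {PRO_S: (0.0, 120.0, 150.0), PRO_R: (4.0, 120.0, 120.0)}
        with pytest.raises(ReconstructionError):
            ns.reconstruct_coordinates(geo)

    def test_missing_hydrogen_rejected(self):
        with pytest.raises(ReconstructionError):
            ns.reconstruct_coordinates({PRO_S: (2.3, 120.0, 160.0)})


class TestWriteSyntheticTrajectory:
    def test_frame_count_inclusive_start(self, synthetic_traj):
        # 50 ps production at 5 ps snapshots -> 10 intervals + frame at t0
        frames = ns.read_multimodel_pdb(synthetic_traj["replica_paths"][0])
        assert len(frames) == 11

    def test_sidecar_consistent_with_stationary(self, synthetic_traj):
        sidecar = json.loads(synthetic_traj["truth_path"].read_text())
        pi = sidecar["pi"]
        s, r = pi["proS_NAC"], pi["proR_NAC"]
        assert sidecar["true_ee"] == pytest.approx(100 * (s - r) / (s + r))

    def test_bit_reproducible_given_seed(self, basin_model_60, tmp_path):
        proto = ns.ProtocolSpec(n_replicas=1, warmup_ps=0, equilibration_ps=0,
                                production_ps=20, snapshot_interval_ps=5,
                                nac_eval_interval_ps=5, name="t")
        ns.write_synthetic_trajectory(basin_model_60, proto, 13, tmp_path / "a")
        ns.write_synthetic_trajectory(basin_model_60, proto, 13, tmp_path / "b")
        a = (tmp_path / "a" / "replica_00.pdb").read_text()
        b = (tmp_path / "b" / "replica_00.pdb").read_text()
        assert a == b


class TestEvaluateProtocol:
    def test_deterministic_report(self, slow_basin_model_60):
        long_p, short_p = ns.equal_time_protocols(total_production_ps=500.0)
        df1 = ns.evaluate_protocol(slow_basin_model_60, [long_p, short_p],
                                   n_repeats=10, seed=4)
        df2 = ns.evaluate_protocol(slow_basin_model_60, [long_p, short_p],
                                   n_repeats=10, seed=4)
        assert df1.equals(df2)

    def test_fast_mixing_both_protocols_unbiased(self, basin_model_60):
        long_p, short_p = ns.equal_time_protocols(total_production_ps=2000.0)
        df = ns.evaluate_protocol(basin_model_60, [long_p, short_p],
                                  n_repeats=10, seed=5)
        assert (df["n_ee_defined"] == 10).all()
        assert np.all(np.abs(df["bias"]) < 10.0)
        assert (df["detection_rate"] == 1.0).all()
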