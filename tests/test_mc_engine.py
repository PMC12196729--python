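"""Transport-engine physics: launch, scattering, boundaries, bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from widefnirs.fixtures import make_ballistic_slab, make_homogeneous_halfspace
from widefnirs.head_model import OpticalProperties, scale_absorption
from widefnirs.head_model import RegionLabel as R
from widefnirs.mc_engine import (
    DetectorSpec,
    RECORD_ALL,
    RECORD_TOP_EXITS,
    SourceSpec,
    fresnel_top_boundary,
    launch_packet,
    packets_for_emitter,
    run_simulation,
    sample_scatter_direction,
)

#: detector large enough to cover the whole 150 mm top face from its centre
WHOLE_TOP = DetectorSpec(center=(75.0, 75.0), diameter=2 * 110.0)


class TestPacketBudget:
    @pytest.mark.parametrize(
        "diameter,base,expected",
        [(1, 5e7, 50_000_000), (5, 5e7, 1_250_000_000), (1, 1, 1), (2.0, 10, 40)],
    )
    def test_area_scaling(self, diameter, base, expected):
        assert packets_for_emitter(diameter, base) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            packets_for_emitter(0.0)
        with pytest.raises(ValueError):
            packets_for_emitter(1.0, 0)


class TestLaunch:
    def test_uniform_disk_radial_cdf(self):
        src = SourceSpec(center=(0.0, 0.0), diameter=5.0)
        rng = np.random.default_rng(7)
        radii = []
        for _ in range(10_000):
            state = launch_packet(src, rng)
            assert state.weight == 1.0
            assert state.position[2] == 0.0
            assert np.allclose(state.direction, [0, 0, 1])
            radii.append(np.hypot(state.position[0], state.position[1]))
        radii = np.asarray(radii)
        assert radii.max() <= 2.5
        # uniform disk: P(r <= x) = (x/Rmax)^2
        ks = stats.kstest(radii, lambda x: (x / 2.5) ** 2)
        assert ks.pvalue > 0.01

    def test_degenerate_disk(self):
        src = SourceSpec(center=(3.0, 4.0), diameter=0.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            state = launch_packet(src, rng)
            assert state.position[0] == 3.0 and state.position[1] == 4.0


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.89, -0.5])
    def test_mean_cosine_equals_g(self, g):
        rng = np.random.default_rng(11)
        incoming = np.array([0.0, 0.0, 1.0])
        cts = np.empty(100_000)
        for i in range(cts.size):
            out = sample_scatter_direction(g, incoming, rng)
            cts[i] = out @ incoming
        se = cts.std(ddof=1) / np.sqrt(cts.size)
        assert abs(cts.mean() - g) < 3 * se

    def test_output_is_unit_vector(self):
        rng = np.random.default_rng(3)
        incoming = np.array([0.6, 0.0, 0.8])
        for _ in range(200):
            out = sample_scatter_direction(0.9, incoming, rng)
            assert abs(np.linalg.norm(out) - 1.0) < 1e-9

    def test_rejects_invalid_g(self):
        with pytest.raises(ValueError):
            sample_scatter_direction(1.0, np.array([0, 0, 1.0]), np.random.default_rng())


class TestFresnel:
    def test_normal_incidence_reflectance(self):
        # ((n1-n2)/(n1+n2))^2 = (0.37/2.37)^2 for tissue-air
        rng = np.random.default_rng(5)
        outcomes = [
            fresnel_top_boundary(np.array([0, 0, -1.0]), 1.37, 1.0, rng)[0]
            for _ in range(200_000)
        ]
        frac = np.mean([o == "reflect" for o in outcomes])
        expected = ((1.37 - 1.0) / (1.37 + 1.0)) ** 2
        assert frac == pytest.approx(expected, abs=4 * np.sqrt(expected / 200_000))

    def test_total_internal_reflection(self):
        # beyond the critical angle asin(1/1.37) ~ 46.9 deg: always reflects
        theta = np.deg2rad(50.0)
        direction = np.array([np.sin(theta), 0.0, -np.cos(theta)])
        rng = np.random.default_rng(1)
        for _ in range(50):
            outcome, new_dir = fresnel_top_boundary(direction, 1.37, 1.0, rng)
            assert outcome == "reflect"
            assert new_dir[2] == -direction[2]

    def test_index_matched_transmits_unchanged(self):
        direction = np.array([0.3, 0.4, -np.sqrt(1 - 0.25)])
        rng = np.random.default_rng(2)
        outcome, new_dir = fresnel_top_boundary(direction, 1.37, 1.37, rng)
        assert outcome == "transmit"
        assert np.allclose(new_dir, direction, atol=1e-12)


class TestBallistic:
    @pytest.mark.parametrize("mua,thickness", [(0.1, 10.0), (0.0, 10.0), (0.2, 5.0)])
    def test_beer_lambert(self, mua, thickness):
        model = make_ballistic_slab(mua, thickness)
        res = run_simulation(
            model,
            SourceSpec(center=(50.0, 50.0), diameter=2.0),
            DetectorSpec(center=(50.0, 60.0), diameter=1.0),
            100,
            seed=9,
            record_mode=RECORD_ALL,
        )
        # straight transport to the absorbing bottom face
        assert np.all(res.status == 1)
        assert res.paths.sum(axis=1) == pytest.approx(thickness, rel=1e-12)
        assert res.exit_weight == pytest.approx(np.exp(-mua * thickness), rel=1e-12)


class TestSinglePacket:
    def test_propagate_matches_beer_lambert(self):
        from widefnirs.mc_engine import propagate_packet

        model = make_ballistic_slab(0.1, 10.0)
        state = launch_packet(SourceSpec(center=(50, 50), diameter=0.0),
                              np.random.default_rng(0))
        record = propagate_packet(state, model, seed=5)
        assert record.status == 1  # absorbing bottom face
        assert record.paths.sum() == pytest.approx(10.0, rel=1e-12)
        assert record.exit_weight == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_propagate_substream_reproducible(self, fast_medium):
        from widefnirs.mc_engine import PacketState, propagate_packet

        def fresh():
            return PacketState(position=np.array([75.0, 75.0, 0.0]),
                               direction=np.array([0.0, 0.0, 1.0]))

        a = propagate_packet(fresh(), fast_medium, seed=42, packet_index=3)
        b = propagate_packet(fresh(), fast_medium, seed=42, packet_index=3)
        c = propagate_packet(fresh(), fast_medium, seed=42, packet_index=4)
        np.testing.assert_array_equal(a.paths, b.paths)
        assert a.exit_weight == b.exit_weight
        assert not np.array_equal(a.paths, c.paths)


class TestConservation:
    def test_zero_absorption_exit_weights_are_one(self, fast_medium):
        props = OpticalProperties(mua=0.0, mus=1.0, g=0.5, n=1.0)
        model = make_homogeneous_halfspace(props)
        res = run_simulation(
            model, SourceSpec(center=(75, 75), diameter=1.0), WHOLE_TOP,
            5000, seed=4, record_mode=RECORD_ALL,
        )
        exited = res.status < 3
        assert np.all(res.exit_weight[exited] == 1.0)
        # with a top-spanning detector, detected energy equals top-exit count
        assert res.detected_energy == np.sum(res.status == 0)

    def test_energy_ledger_closes(self, head_model):
        res = run_simulation(
            head_model, SourceSpec(center=(75, 60), diameter=1.0),
            DetectorSpec(center=(75, 90), diameter=5.0), 10_000, seed=12,
        )
        total = res.w_top + res.w_bottom + res.w_lateral + res.w_terminated + res.w_absorbed
        assert total == pytest.approx(res.n_launched, rel=1e-6)


class TestReproducibility:
    def test_same_seed_bit_identical(self, fast_medium):
        src = SourceSpec(center=(75, 75), diameter=2.0)
        det = DetectorSpec(center=(75, 90), diameter=10.0)
        a = run_simulation(fast_medium, src, det, 5000, seed=77)
        b = run_simulation(fast_medium, src, det, 5000, seed=77)
        assert np.array_equal(a.exit_weight, b.exit_weight)
        assert np.array_equal(a.paths, b.paths)
        assert a.w_absorbed == b.w_absorbed

    def test_different_seed_differs(self, fast_medium):
        src = SourceSpec(center=(75, 75), diameter=2.0)
        det = DetectorSpec(center=(75, 90), diameter=10.0)
        a = run_simulation(fast_medium, src, det, 5000, seed=77)
        b = run_simulation(fast_medium, src, det, 5000, seed=78)
        assert a.w_absorbed != b.w_absorbed


class TestTrajectoryInvariance:
    def test_paths_identical_under_mua_change(self, head_model):
        """Trajectories depend only on mus/g/n, never on mua (exact equality)."""
        src = SourceSpec(center=(75, 60), diameter=1.0)
        det = DetectorSpec(center=(75, 90), diameter=10.0)
        base = run_simulation(head_model, src, det, 3000, seed=5,
                              record_mode=RECORD_TOP_EXITS)
        scaled_model = scale_absorption(head_model, R.SGM, 1.25)
        scaled = run_simulation(scaled_model, src, det, 3000, seed=5,
                                record_mode=RECORD_TOP_EXITS)
        assert np.array_equal(base.paths, scaled.paths)
        assert np.array_equal(base.exit_x, scaled.exit_x)
        # weights do change where the perturbed region was traversed
        touched = base.paths[:, int(R.SGM)] > 0
        assert np.all(base.exit_weight[touched] > scaled.exit_weight[touched])


class TestDetectionGeometry:
    def test_mirror_symmetry(self, fast_medium):
        """Mirrored detectors in a homogeneous medium detect alike."""
        src = SourceSpec(center=(75, 75), diameter=1.0)
        res = run_simulation(fast_medium, src, WHOLE_TOP, 20_000, seed=6,
                             record_mode=RECORD_TOP_EXITS)
        top = res.status == 0
        left = top & ((res.exit_x - 60.0) ** 2 + (res.exit_y - 75.0) ** 2 <= 25.0)
        right = top & ((res.exit_x - 90.0) ** 2 + (res.exit_y - 75.0) ** 2 <= 25.0)
        n1, n2 = left.sum(), right.sum()
        assert abs(n1 - n2) < 4 * np.sqrt(n1 + n2 + 1)

    def test_energy_linear_in_packet_count(self, fast_medium):
        """Detected energy per launched packet is constant in expectation."""
        src = SourceSpec(center=(75, 75), diameter=1.0)
        counts = [4000, 8000, 12000, 16000, 20000]
        per_packet = []
        for i, n in enumerate(counts):
            res = run_simulation(fast_medium, src, WHOLE_TOP, n, seed=100 + i)
            per_packet.append(res.detected_energy / n)
        spread = (max(per_packet) - min(per_packet)) / np.mean(per_packet)
        assert spread < 0.1
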