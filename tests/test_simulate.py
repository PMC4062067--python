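"""Unit tests for the screen simulator: library construction, bottleneck
sampling, infection, branching-process selection, array readout and
read-coverage generation, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

import orfscreen as o
from orfscreen.errors import OrfMismatchError, ParameterError
from orfscreen.simulate import AbundanceState, SimConfig, child_seeds


class TestMakeLibrary:
    def test_full_scale_pool_partition(self):
        # 12212 = 32 * 376 + 180: 33 full pools of 376 and one pool of 180
        lib = o.make_library(12212, pool_size=376, seed=0)
        sizes = lib.groupby("pool_id").size()
        assert len(sizes) == 33
        assert (sizes.iloc[:-1] == 376).all()
        assert sizes.iloc[-1] == 180

    def test_single_exact_pool(self):
        lib = o.make_library(376, pool_size=376, seed=0)
        assert lib["pool_id"].nunique() == 1

    def test_unique_ids_and_length_floor(self):
        lib = o.make_library(500, pool_size=100, seed=3)
        assert lib["orf_id"].is_unique
        assert (lib["length_nt"] >= 75).all()

    @pytest.mark.parametrize("n_orfs,pool_size", [(0, 10), (10, 0), (-1, 5)])
    def test_nonpositive_arguments_rejected(self, n_orfs, pool_size):
        with pytest.raises(ParameterError):
            o.make_library(n_orfs, pool_size)


class TestInitialRepresentation:
    def test_total_conserved_exactly(self, small_library):
        st = o.simulate_initial_representation(small_library, 12345, beta=1.0, seed=0)
        assert st.total == 12345

    def test_no_bias_is_symmetric(self):
        lib = o.make_library(2, pool_size=2, seed=0)
        st = o.simulate_initial_representation(lib, 10**6, beta=0.0, seed=1)
        # each count ~ Binomial(1e6, 0.5): stay within 4 SD of the mean
        sd = np.sqrt(1e6 * 0.25)
        assert abs(st.counts[0] - 5e5) < 4 * sd

    def test_length_bias_matches_analytic_ratio(self):
        # beta=1, lengths 500 and 1000 -> expected count ratio 2:1
        lib = o.make_library(2, pool_size=2, seed=0)
        lib["length_nt"] = [500, 1000]
        ratios = []
        for seed in range(100):
            st = o.simulate_initial_representation(lib, 10**6, beta=1.0, seed=seed)
            ratios.append(st.counts[0] / st.counts[1])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.01)

    def test_zero_cells(self, small_library):
        st = o.simulate_initial_representation(small_library, 0, seed=0)
        assert st.total == 0

    def test_negative_cells_rejected(self, small_library):
        with pytest.raises(ParameterError):
            o.simulate_initial_representation(small_library, -1, seed=0)


class TestInfection:
    def test_infected_fraction_matches_poisson(self):
        counts, frac = o.simulate_infection(10**6, moi=0.3, seed=0)
        expected = 1 - np.exp(-0.3)
        sd = np.sqrt(expected * (1 - expected) / 1e6)
        assert abs(frac - expected) < 3 * sd

    def test_zero_moi(self):
        counts, frac = o.simulate_infection(1000, moi=0.0, seed=0)
        assert (counts == 0).all() and frac == 0.0

    def test_single_cell_shape(self):
        counts, _ = o.simulate_infection(1, moi=0.3, seed=0)
        assert counts.shape == (1,) and counts[0] >= 0


class TestSelection:
    def test_deterministic_doubling_without_drug(self):
        st = AbundanceState(counts=np.array([5, 3]), generation=0)
        cfg = SimConfig(seed=0, n_doublings=3, noise_sigma=0.0)
        out = o.simulate_selection(st, cfg, drug_present=False)
        assert list(out.counts) == [40, 24]
        assert out.generation == 3

    def test_branching_mean_matches_m_to_g(self):
        # survival 0.4 then doubling: m = 0.8, E[N_g] = 1000 * 0.8**20 = 11.53
        cfg = SimConfig(seed=0, n_doublings=20, drug_kill_prob=0.6)
        finals = []
        for seed in range(200):
            st = AbundanceState(counts=np.array([1000]))
            out = o.simulate_selection(st, cfg, drug_present=True, seed=seed)
            finals.append(out.counts[0])
        assert np.mean(finals) == pytest.approx(1000 * 0.8**20, rel=0.10)

    def test_full_resistance_cancels_drug(self):
        st = AbundanceState(counts=np.array([7]))
        cfg = SimConfig(seed=0, n_doublings=4, drug_kill_prob=0.6,
                        resistance_effects={0: 2.5})
        out = o.simulate_selection(st, cfg, drug_present=True)
        assert out.counts[0] == 7 * 2**4

    def test_carrying_capacity_enforced(self):
        st = AbundanceState(counts=np.array([500, 500]))
        cfg = SimConfig(seed=0, n_doublings=10, carrying_capacity=10_000)
        out = o.simulate_selection(st, cfg, drug_present=False)
        assert out.total == 10_000

    def test_cell_by_cell_oracle(self):
        """Vectorized branching process agrees with a per-cell simulation."""
        kill, g, n0 = 0.4, 5, 50

        def brute(seed):
            rng = np.random.default_rng(seed)
            n = n0
            for _ in range(g):
                n = 2 * int((rng.random(n) < (1 - kill)).sum())
            return n

        cfg = SimConfig(seed=0, n_doublings=g, drug_kill_prob=kill)
        fast = [
            o.simulate_selection(
                AbundanceState(counts=np.array([n0])), cfg, True, seed=s
            ).counts[0]
            for s in range(300)
        ]
        slow = [brute(s) for s in range(300, 600)]
        m = 2 * (1 - kill)
        expected = n0 * m**g
        assert np.mean(fast) == pytest.approx(expected, rel=0.15)
        assert np.mean(fast) == pytest.approx(np.mean(slow), rel=0.15)


class TestArrayReadout:
    def test_identity_floor(self):
        d = AbundanceState(counts=np.array([0, 64]))
        cfg = SimConfig(seed=0, noise_sigma=0.0, intensity_floor=1.0)
        out = o.simulate_array_readout(d, d, cfg)
        assert list(out["drug"]) == [1.0, 64.0]

    def test_bleed_reproduces_false_positive_signal(self):
        # probe 0 receives 30% of ORF 1's signal: 0.3 * 1000 = 300
        H = np.array([[1.0, 0.3], [0.0, 1.0]])
        d = AbundanceState(counts=np.array([0, 1000]))
        cfg = SimConfig(seed=0, noise_sigma=0.0, crosshyb=H)
        out = o.simulate_array_readout(d, d, cfg)
        assert out["drug"].iloc[0] == pytest.approx(300.0)

    def test_noise_sd_matches_parameter(self):
        d = AbundanceState(counts=np.full(10_000, 1000))
        cfg = SimConfig(seed=7, noise_sigma=0.5, intensity_floor=1e-9)
        out = o.simulate_array_readout(d, d, cfg, seed=7)
        sd = np.log2(out["drug"]).std()
        assert sd == pytest.approx(0.5, rel=0.05)

    def test_invalid_bleed_matrix_rejected(self):
        H = np.array([[1.0, 1.5], [0.0, 1.0]])
        d = AbundanceState(counts=np.array([1, 1]))
        with pytest.raises(ParameterError):
            o.simulate_array_readout(d, d, SimConfig(seed=0, crosshyb=H))

    def test_mismatched_states_rejected(self):
        a = AbundanceState(counts=np.array([1, 2]))
        b = AbundanceState(counts=np.array([1, 2, 3]))
        with pytest.raises(OrfMismatchError):
            o.simulate_array_readout(a, b, SimConfig(seed=0))


class TestReadCoverage:
    def test_zero_reads(self, small_library):
        st = o.simulate_initial_representation(small_library, 1000, seed=0)
        profiles = o.simulate_read_coverage(st, small_library, 0, 50, seed=0)
        assert all((d == 0).all() for d in profiles.values())

    def test_full_cover_read(self):
        lib = o.make_library(1, pool_size=1, seed=0)
        lib["length_nt"] = 100
        st = AbundanceState(counts=np.array([10]))
        profiles = o.simulate_read_coverage(st, lib, 1, read_len=100, seed=0)
        assert (profiles["ORF00001"] == 1).all()

    def test_mean_depth_matches_lander_waterman(self):
        lib = o.make_library(1, pool_size=1, seed=0)
        lib["length_nt"] = 1000
        st = AbundanceState(counts=np.array([5]))
        profiles = o.simulate_read_coverage(st, lib, 10_000, read_len=50, seed=0)
        expected = 10_000 * 50 / 1000
        assert profiles["ORF00001"].mean() == pytest.approx(expected, rel=0.05)

    def test_total_base_coverage_exact(self, small_library):
        st = o.simulate_initial_representation(small_library, 1000, seed=0)
        profiles = o.simulate_read_coverage(st, small_library, 500, 50, seed=0)
        # every read contributes exactly min(read_len, length) bases
        lengths = dict(zip(small_library["orf_id"], small_library["length_nt"]))
        total = sum(int(d.sum()) for d in profiles.values())
        assert total <= 500 * 50
        assert total >= 500 * min(50, min(lengths.values()))


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_library):
        cfg = SimConfig(seed=42)
        a = o.simulate_screen(small_library, cfg, 5000, 2)
        b = o.simulate_screen(small_library, cfg, 5000, 2)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_child_seeds_are_stable(self):
        a = [s.generate_state(2).tolist() for s in child_seeds(9, 3)]
        b = [s.generate_state(2).tolist() for s in child_seeds(9, 3)]
        assert a == b
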