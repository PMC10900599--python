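import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import mcrand as mc
from mcrand.allocation import _F

from conftest import MASTER_SEED


def rng(seed=0):
    return np.random.default_rng(seed)


def make_pattern(centers, N=None, G=1, region_of=None):
    centers = np.asarray(centers)
    N = N or int(centers.max()) + 1
    region_of = np.asarray(region_of) if region_of is not None else np.zeros(N, int)
    return mc.RecruitmentPattern(
        times=np.arange(1.0, len(centers) + 1.0),
        centers=centers,
        regions=region_of[centers],
        rates=np.ones(N),
        activations=np.zeros(N),
    )


class TestAllocationFunctions:
    @pytest.mark.parametrize(
        "D,m,b,expected",
        [
            (0, 0, 2, 0.5),
            (2, 2, 2, 0.0),   # two identical assignments force the complement
            (1, 3, 2, 0.0),   # last slot of the block is forced
            (-1, 3, 2, 1.0),
            (0, 4, 2, 0.5),   # block boundary resets to a fair coin
            (1, 1, 3, 0.5 * (1 - 1 / 5)),
        ],
    )
    def test_pbd(self, D, m, b, expected):
        assert mc.phi_pbd(D, m, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "D,b,expected", [(0, 2, 0.5), (1, 2, 0.5), (2, 2, 0.0), (-2, 2, 1.0)]
    )
    def test_bsd(self, D, b, expected):
        assert mc.phi_bsd(D, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "D,b,expected", [(0, 2, 0.5), (1, 2, 0.25), (-2, 2, 1.0), (2, 2, 0.0)]
    )
    def test_eud(self, D, b, expected):
        assert mc.phi_eud(D, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "D,b,expected", [(0, 2, 0.5), (1, 2, 1 / 3), (2, 2, 0.0), (-2, 2, 1.0)]
    )
    def test_bud(self, D, b, expected):
        assert mc.phi_bud(D, b) == pytest.approx(expected)

    def test_out_of_corridor_states_rejected(self):
        for f in (mc.phi_bsd, mc.phi_eud, mc.phi_bud):
            with pytest.raises(ValueError):
                f(3, 2)
        with pytest.raises(ValueError):
            mc.phi_pbd(2, 1, 2)  # |D| > block position: unreachable
        with pytest.raises(ValueError):
            mc.phi_pbd(1, 2, 2)  # wrong parity

    @given(
        b=st.integers(1, 6),
        proc=st.sampled_from(["BSD", "EUD", "BUD"]),
        data=st.data(),
    )
    def test_symmetry_around_zero(self, b, proc, data):
        # F(-D) = 1 - F(D) on every reachable imbalance
        D = data.draw(st.integers(-b, b))
        assert float(_F(proc, -D, 0, b)) == pytest.approx(1.0 - float(_F(proc, D, 0, b)))

    @given(b=st.integers(1, 6), m=st.integers(0, 40), data=st.data())
    def test_pbd_symmetry(self, b, m, data):
        j = m % (2 * b)
        dmax = min(j, 2 * b - j)
        D = data.draw(st.integers(-dmax, dmax))
        if (D - j) % 2:
            D += 1 if D < dmax else -1
        assert mc.phi_pbd(-D, m, b) == pytest.approx(1.0 - mc.phi_pbd(D, m, b))


class TestDesignSpec:
    @pytest.mark.parametrize(
        "label,family",
        [
            ("U-PBD(2)", "unstratified"),
            ("R-BSD(4)", "region_stratified"),
            ("C-EUD(2)", "center_stratified"),
            ("DBR(2,4,8)", "dbr"),
            ("CRD", "crd"),
        ],
    )
    def test_label_round_trip(self, label, family):
        d = mc.DesignSpec.from_label(label)
        assert d.family == family
        assert d.label == label

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="unstratified"),  # missing procedure/b
            dict(family="unstratified", procedure="PBD", b=0),
            dict(family="dbr", b1=1, b2=0, b3=1),
            dict(family="crd", b=2),
            dict(family="nope"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mc.DesignSpec(**kwargs)


def _running_stratum_imbalance(labels, t, S):
    D = np.zeros(S, int)
    out = np.empty(len(t), int)
    for m, (s, tm) in enumerate(zip(labels, t)):
        D[s] += tm
        out[m] = D[s]
    return out


class TestAllocate:
    def test_crd_is_a_fair_coin(self):
        pat = make_pattern(rng(1).integers(0, 5, 200), N=5)
        res = mc.allocate(pat, mc.DesignSpec("crd"), rng(2))
        assert np.all(res.phi == 0.5)
        assert set(np.unique(res.delta)) <= {0, 1}

    def test_complete_blocks_balance_exactly(self):
        design = mc.DesignSpec.from_label("U-PBD(2)")
        pat = make_pattern([0, 0, 0, 0], N=1)
        for seed in range(40):
            res = mc.allocate(pat, design, rng(seed))
            assert res.state.trial_imbalance == 0

    @pytest.mark.parametrize(
        "label", ["U-PBD(2)", "U-BUD(2)", "U-EUD(2)", "U-BSD(2)", "U-BSD(3)"]
    )
    def test_mti_bound_at_trial_level(self, label):
        design = mc.DesignSpec.from_label(label)
        pat = make_pattern(rng(3).integers(0, 4, 300), N=4)
        for seed in range(10):
            res = mc.allocate(pat, design, rng(seed))
            D = np.cumsum(2 * res.delta.astype(int) - 1)
            assert np.abs(D).max() <= design.b

    @pytest.mark.parametrize("label", ["C-PBD(2)", "C-BSD(2)", "R-EUD(2)", "C-BUD(2)"])
    def test_mti_bound_within_strata(self, label):
        design = mc.DesignSpec.from_label(label)
        region_of = np.array([0, 0, 1, 1])
        pat = make_pattern(rng(4).integers(0, 4, 300), N=4, G=2, region_of=region_of)
        labels = pat.centers if design.family == "center_stratified" else pat.regions
        S = 4 if design.family == "center_stratified" else 2
        for seed in range(10):
            res = mc.allocate(pat, design, rng(seed))
            t = 2 * res.delta.astype(int) - 1
            assert np.abs(_running_stratum_imbalance(labels, t, S)).max() <= design.b

    def test_first_patient_of_each_stratum_is_a_coin_flip(self):
        design = mc.DesignSpec.from_label("C-PBD(2)")
        pat = make_pattern([2, 0, 1, 2, 0], N=3)
        res = mc.allocate(pat, design, rng(5))
        assert res.phi[0] == 0.5 and res.phi[1] == 0.5 and res.phi[2] == 0.5

    def test_imbalance_conservation_across_levels(self):
        region_of = np.array([0, 0, 1, 1, 2, 2])
        pat = make_pattern(rng(6).integers(0, 6, 240), N=6, G=3, region_of=region_of)
        for label in ("U-BSD(2)", "C-PBD(2)", "DBR(2,2,2)", "CRD"):
            res = mc.allocate(pat, mc.DesignSpec.from_label(label), rng(7))
            s = res.state
            assert s.trial_imbalance == s.center_imbalance.sum()
            assert s.trial_imbalance == s.region_imbalance.sum()
            assert s.center_counts.sum() == pat.n

    def test_mismatched_indices_rejected(self):
        pat = make_pattern([0, 1, 2], N=3)
        with pytest.raises(ValueError):
            mc.allocate_batch(
                pat.centers[None], pat.regions[None], 2, 1,
                mc.DesignSpec.from_label("C-BSD(2)"), rng(),
            )


class TestDynamicBalancing:
    def _state(self, N=4, G=2, center_imb=(), region_imb=(), trial=0):
        s = mc.AllocationState.empty(N, G)
        for i, v in center_imb:
            s.center_imbalance[i] = v
        for g, v in region_imb:
            s.region_imbalance[g] = v
        s.trial_imbalance = trial
        return s

    def test_center_threshold_forces_deterministically(self):
        s = self._state(center_imb=[(0, 2)], region_imb=[(0, 2)], trial=2)
        delta, phi = mc.dbr_next(s, 0, 0, 2, 2, 2, rng())
        assert (delta, phi) == (0, 0.0)

    def test_all_balanced_is_a_fair_coin(self):
        s = self._state()
        _, phi = mc.dbr_next(s, 1, 0, 2, 2, 2, rng())
        assert phi == 0.5

    def test_region_threshold_forces_toward_underrepresented(self):
        s = self._state(center_imb=[(0, 1)], region_imb=[(0, -4)], trial=-4)
        delta, phi = mc.dbr_next(s, 0, 0, 2, 4, 8, rng())
        assert (delta, phi) == (1, 1.0)

    def test_trial_threshold_is_last_resort(self):
        s = self._state(center_imb=[(0, 1)], region_imb=[(0, 1)], trial=3)
        delta, phi = mc.dbr_next(s, 0, 0, 2, 4, 3, rng())
        assert (delta, phi) == (0, 0.0)

    def test_forcing_strictly_reduces_triggering_imbalance(self):
        # whenever an assignment is deterministic, the level that triggered it
        # must shrink in absolute value
        region_of = np.array([0, 0, 1, 1])
        pat = make_pattern(rng(8).integers(0, 4, 400), N=4, G=2, region_of=region_of)
        design = mc.DesignSpec.from_label("DBR(2,2,2)")
        s = mc.AllocationState.empty(4, 2)
        r = rng(9)
        for m in range(pat.n):
            ci, gi = int(pat.centers[m]), int(pat.regions[m])
            before = (
                abs(s.center_imbalance[ci]),
                abs(s.region_imbalance[gi]),
                abs(s.trial_imbalance),
            )
            delta, phi = mc.dbr_next(s, ci, gi, design.b1, design.b2, design.b3, r)
            if phi in (0.0, 1.0):
                after = (
                    abs(s.center_imbalance[ci]),
                    abs(s.region_imbalance[gi]),
                    abs(s.trial_imbalance),
                )
                if before[0] == design.b1:
                    assert after[0] < before[0]
                elif before[1] >= design.b2:
                    assert after[1] < before[1]
                else:
                    assert after[2] < before[2]
            assert abs(s.center_imbalance[ci]) <= design.b1

    def test_batch_matches_sequential_dbr(self):
        region_of = np.array([0, 0, 1, 1])
        pat = make_pattern(rng(10).integers(0, 4, 120), N=4, G=2, region_of=region_of)
        design = mc.DesignSpec.from_label("DBR(2,4,4)")
        res = mc.allocate(pat, design, rng(11))
        # replay the sequential rule using the same uniforms is not possible,
        # so check the structural consequences instead
        t = 2 * res.delta.astype(int) - 1
        assert np.abs(_running_stratum_imbalance(pat.centers, t, 4)).max() <= design.b1


class TestChainAgreement:
    """The simulated imbalance distribution must match the exact Markov chain."""

    @pytest.mark.parametrize("proc", ["PBD", "BSD", "EUD", "BUD"])
    def test_final_imbalance_matches_exact_pmf(self, proc):
        b, n, reps = 2, 10, 100_000
        design = mc.DesignSpec("unstratified", procedure=proc, b=b)
        centers = np.zeros((reps, n), dtype=np.int32)
        delta, _ = mc.allocate_batch(
            centers, centers, 1, 1, design,
            rng(MASTER_SEED + ["PBD", "BSD", "EUD", "BUD"].index(proc)),
        )
        D = (2 * delta.astype(int) - 1).sum(axis=1)
        pmf = mc.exact_imbalance_pmf(proc, b, n)
        support = [d for d, p in pmf.items() if p > 1e-12]
        obs = np.array([(D == d).sum() for d in support])
        exp = np.array([pmf[d] for d in support]) * reps
        assert obs.sum() == reps  # no mass off the exact support
        p = stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
        assert p > 0.001
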