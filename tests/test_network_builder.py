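"""Population rounding, probability correction, weight scaling and
connectivity realization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cortcol.groups import GROUPS
from cortcol.model_core import CellTypeParams
from cortcol.network_builder import (
    ConnectivitySpec,
    PopulationSpec,
    build_populations,
    compute_weight,
    correct_probability,
    correct_probability_matrix,
    lesion_inhibitory_output,
    lognormalize_weights,
    realize_connectivity,
)

PARAMS = {
    g: CellTypeParams(group_id=g, V_rest=-70.0, V_th=-50.0, C_m=200.0,
                      g_L=10.0, tau_ref=2.0)
    for g in GROUPS
}


def uniform_fractions():
    return {g: 1.0 / len(GROUPS) for g in GROUPS}


class TestBuildPopulations:
    def test_counts_sum_exactly(self, bundle):
        pops = build_populations(bundle.fractions, 5000, bundle.params)
        assert sum(p.n_neurons for p in pops) == 5000
        assert all(p.n_neurons > 0 for p in pops)

    def test_doubling_is_proportional(self, bundle):
        a = build_populations(bundle.fractions, 5000, bundle.params)
        b = build_populations(bundle.fractions, 10000, bundle.params)
        for pa, pb in zip(a, b):
            assert abs(pb.n_neurons - 2 * pa.n_neurons) <= 1

    def test_all_mass_on_one_group(self):
        fr = {g: 0.0 for g in GROUPS}
        fr["E5"] = 1.0
        pops = build_populations(fr, 1234, PARAMS)
        by = {p.group_id: p.n_neurons for p in pops}
        assert by["E5"] == 1234

    def test_id_ranges_are_contiguous(self, bundle):
        pops = build_populations(bundle.fractions, 777, bundle.params)
        start = 0
        for p in pops:
            assert p.start == start
            start += p.n_neurons

    def test_bad_fraction_sum_rejected(self):
        fr = uniform_fractions()
        fr["E23"] += 0.05
        with pytest.raises(ValueError, match="sum"):
            build_populations(fr, 5000, PARAMS)


class TestCorrectProbability:
    def test_zero_stays_zero(self):
        assert correct_probability(0.0, 100.0) == 0.0

    def test_flat_profile_limit(self):
        # sigma -> inf: the disk averages coincide and P_new -> P_rep
        assert correct_probability(0.3, 1e6) == pytest.approx(0.3, rel=1e-6)

    def test_narrow_profile_limit(self):
        # sigma -> 0: all mass inside both disks, ratio (R0/R)^2 = 0.36
        assert correct_probability(0.5, 1.0, 125.0, 75.0) == pytest.approx(
            0.36 * 0.5, rel=1e-9
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.01, 1.0),
        s1=st.floats(1.0, 1e4),
        s2=st.floats(1.0, 1e4),
    )
    def test_monotone_in_sigma_and_bounded(self, p, s1, s2):
        lo, hi = 0.36 * p, p
        v1 = correct_probability(p, s1)
        assert lo - 1e-12 <= v1 <= hi + 1e-12
        if s1 < s2:
            assert v1 <= correct_probability(p, s2) + 1e-12

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            correct_probability(0.1, -5.0)
        with pytest.raises(ValueError):
            correct_probability(0.1, 100.0, R=0.0)

    def test_matrix_application(self, bundle):
        spec = bundle.connectivity_spec()
        out = correct_probability_matrix(spec)
        P = spec.P.to_numpy()
        O = out.to_numpy()
        assert np.all(O <= P + 1e-12)          # R > R0 shrinks
        assert np.all(O[P == 0] == 0)


class TestComputeWeight:
    def test_direct_arithmetic(self):
        assert compute_weight(5.0, 0.5, 100, 0.1) == pytest.approx(0.25)

    def test_size_scaling(self):
        w1 = compute_weight(5.0, 0.5, 100, 0.1)
        w2 = compute_weight(5.0, 0.5, 200, 0.1)
        assert w2 == pytest.approx(w1 / 2.0)

    def test_expected_group_input_is_size_invariant(self):
        # N_send * p * w = G * ws exactly, for any size
        G, ws, p = 5.0, 0.7, 0.13
        for n in (2500, 5000, 10000):
            w = compute_weight(G, ws, n, p)
            assert n * p * w == pytest.approx(G * ws, rel=1e-12)

    def test_zero_strength_gives_zero(self):
        assert compute_weight(5.0, 0.0, 100, 0.1) == 0.0

    def test_declared_but_impossible_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            compute_weight(5.0, 0.5, 100, 0.0)


def pair_spec(pre, post, p, ws=1.0, G=5.0, nmda_fraction=0.2):
    """Connectivity spec with a single nonzero group pair."""
    idx = list(GROUPS)
    P = pd.DataFrame(0.0, index=idx, columns=idx)
    S = pd.DataFrame(0.0, index=idx, columns=idx)
    sigma = pd.DataFrame(100.0, index=idx, columns=idx)
    P.loc[pre, post] = p
    S.loc[pre, post] = ws
    return ConnectivitySpec(P=P, S=S, sigma=sigma, G=G,
                            nmda_fraction=nmda_fraction)


def pair_pops(pre, post, n_pre, n_post):
    pops, start = [], 0
    for g in GROUPS:
        n = n_pre if g == pre else (n_post if g == post else 1)
        if g == pre == post:
            n = n_pre
        pops.append(PopulationSpec(g, n, PARAMS[g], start))
        start += n
    return pops


class TestRealizeConnectivity:
    def test_full_probability_inhibitory_pair(self):
        pops = pair_pops("PV23", "E23", 50, 60)
        table = realize_connectivity(pops, pair_spec("PV23", "E23", 1.0), 3)
        assert len(table) == 50 * 60
        assert set(table["receptor"]) == {"GABA"}

    def test_autapses_excluded(self):
        pops = pair_pops("PV4", "PV4", 40, 40)
        table = realize_connectivity(pops, pair_spec("PV4", "PV4", 1.0), 3)
        assert len(table) == 40 * 39
        assert not np.any(table["pre"].to_numpy() == table["post"].to_numpy())

    def test_zero_probability_empty(self):
        pops = pair_pops("E23", "E4", 50, 50)
        table = realize_connectivity(pops, pair_spec("E23", "E4", 0.0, ws=0.0),
                                     3)
        assert table.empty

    def test_receptor_split_binomial(self):
        # NMDA contacts drawn at p * 0.2: expectation 0.1 * 200 * 200 = 4000
        pops = pair_pops("E23", "E4", 200, 200)
        table = realize_connectivity(pops, pair_spec("E23", "E4", 0.5), 3)
        n_nmda = int((table["receptor"] == "NMDA").sum())
        expect = 0.2 * 0.5 * 200 * 200
        bound = 2.58 * np.sqrt(expect * (1 - 0.1))
        assert abs(n_nmda - expect) < bound

    def test_weights_follow_scaling_rule(self):
        pops = pair_pops("E23", "E4", 100, 100)
        table = realize_connectivity(pops, pair_spec("E23", "E4", 0.4, ws=0.8),
                                     3)
        assert np.allclose(table["weight"], 5.0 * 0.8 / (100 * 0.4))

    def test_reproducible_under_seed(self):
        pops = pair_pops("E23", "E4", 80, 80)
        spec = pair_spec("E23", "E4", 0.3)
        t1 = realize_connectivity(pops, spec, 7)
        t2 = realize_connectivity(pops, spec, 7)
        pd.testing.assert_frame_equal(t1, t2)
        t3 = realize_connectivity(pops, spec, 8)
        assert not t1.equals(t3)

    def test_dale_segregation(self, net600):
        table = net600.synapses
        exc = net600.excitatory_mask
        gaba_pre = table.loc[table["receptor"] == "GABA", "pre"].to_numpy()
        ampa_pre = table.loc[table["receptor"].isin(["AMPA", "NMDA"]),
                             "pre"].to_numpy()
        assert not exc[gaba_pre].any()
        assert exc[ampa_pre].all()

    def test_realized_counts_match_bernoulli(self, bundle, net600):
        # per-pair realized count within 4 binomial SD of expectation
        table = net600.synapses
        spec = net600.spec
        names = net600.group_names
        gi = net600.group_index
        pre_g = np.asarray(names, object)[gi[table["pre"].to_numpy()]]
        post_g = np.asarray(names, object)[gi[table["post"].to_numpy()]]
        sizes = net600.counts()
        for pre in GROUPS:
            for post in GROUPS:
                p = float(spec.P.loc[pre, post])
                n_pre, n_post = sizes[pre], sizes[post]
                if p == 0 or n_pre < 10 or n_post < 10:
                    continue
                pairs = n_pre * n_post - (n_pre if pre == post else 0)
                got = int(((pre_g == pre) & (post_g == post)).sum())
                sd = np.sqrt(pairs * p * (1 - p))
                assert abs(got - pairs * p) < 4 * sd + 1, (pre, post)


class TestWeightVariants:
    def test_lognormal_moments(self):
        table = pd.DataFrame(
            {
                "pre": np.zeros(100_000, dtype=np.int64),
                "post": np.ones(100_000, dtype=np.int64),
                "receptor": "AMPA",
                "weight": 0.7,
            }
        )
        out = lognormalize_weights(table, seed=5)
        w = out["weight"].to_numpy()
        assert w.mean() == pytest.approx(0.7, rel=0.02)
        assert w.std() / w.mean() == pytest.approx(1.0, rel=0.05)

    def test_zero_weights_stay_zero(self):
        table = pd.DataFrame(
            {"pre": [0, 1], "post": [2, 3], "receptor": "AMPA",
             "weight": [0.0, 0.5]}
        )
        out = lognormalize_weights(table, seed=5)
        assert out["weight"].iloc[0] == 0.0
        assert out["weight"].iloc[1] != 0.5
        assert out[["pre", "post", "receptor"]].equals(
            table[["pre", "post", "receptor"]]
        )

    def test_lesion_removes_only_gaba(self, net600):
        table = net600.synapses
        out = lesion_inhibitory_output(table)
        assert (out["receptor"] != "GABA").all()
        n_exc = int((table["receptor"] != "GABA").sum())
        assert len(out) == n_exc
        exc_only = table[table["receptor"] != "GABA"].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            lesion_inhibitory_output(exc_only), exc_only
        )
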