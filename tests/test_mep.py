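"""Site-parameter conversion and hierarchical pairing scores."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocryst.mep import (
    DEFAULT_ACCEPTOR_COEFFS,
    DEFAULT_DONOR_COEFFS,
    InteractionSite,
    MoleculeSites,
    cocrystal_pairing,
    delta_e,
    pairing_energy,
    rank_coformers,
    site_param_from_esp,
)
from conftest import sites_from_params


class TestSiteParam:
    @pytest.mark.parametrize(
        "esp,kind,expected",
        [
            (0.0, "donor", 0.0),
            (0.0, "acceptor", 0.0),
            # hand evaluation of the two-term quadratics
            (150.0, "donor",
             DEFAULT_DONOR_COEFFS[0] * 150.0**2 + DEFAULT_DONOR_COEFFS[1] * 150.0),
            (-180.0, "acceptor",
             DEFAULT_ACCEPTOR_COEFFS[0] * 180.0**2 + DEFAULT_ACCEPTOR_COEFFS[1] * 180.0),
        ],
    )
    def test_quadratic_map(self, esp, kind, expected):
        assert site_param_from_esp(esp, kind) == pytest.approx(expected)

    def test_hand_values(self):
        # alpha(150) = 1.62e-5*22500 + 9.62e-3*150 = 0.3645 + 1.443
        assert site_param_from_esp(150.0, "donor") == pytest.approx(1.8075)
        # beta(-180) = 1.46e-4*32400 + 9.30e-3*180 = 4.7304 + 1.674
        assert site_param_from_esp(-180.0, "acceptor") == pytest.approx(6.4044)

    @pytest.mark.parametrize("esp,kind", [(-1.0, "donor"), (1.0, "acceptor")])
    def test_sign_mismatch_rejected(self, esp, kind):
        with pytest.raises(ValueError, match=kind):
            site_param_from_esp(esp, kind)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            site_param_from_esp(1.0, "bridge")

    def test_custom_coefficients(self):
        assert site_param_from_esp(10.0, "donor", (0.0, 0.5)) == pytest.approx(5.0)


class TestPairingEnergy:
    def test_empty(self):
        res = pairing_energy([], [])
        assert res.energy == 0.0 and res.pairs == () and res.unpaired == ()

    def test_single_product(self):
        assert pairing_energy([2.0], [3.0]).energy == pytest.approx(-6.0)

    def test_rank_for_rank(self):
        # -(4*5 + 1*2) = -22, the rearrangement-inequality minimum
        assert pairing_energy([4.0, 1.0], [5.0, 2.0]).energy == pytest.approx(-22.0)

    def test_excess_sites_unpaired(self):
        res = pairing_energy([3.0, 2.0, 1.0], [4.0])
        assert len(res.pairs) == 1
        assert res.energy == pytest.approx(-12.0)
        assert len(res.unpaired) == 2

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        donors=st.lists(st.floats(0.0, 10.0), max_size=6),
        acceptors=st.lists(st.floats(0.0, 10.0), max_size=6),
    )
    def test_rearrangement_optimality(self, donors, acceptors):
        """Hierarchical pairing minimises E over all one-to-one assignments."""
        res = pairing_energy(donors, acceptors)
        small, large = sorted([donors, acceptors], key=len)
        best = 0.0 if not small else min(
            -sum(a * b for a, b in zip(small, perm))
            for perm in itertools.permutations(large, len(small))
        )
        assert res.energy == pytest.approx(best, abs=1e-9)


class TestCocrystalPairing:
    def test_worked_example_methods_differ(self, worked_pair):
        api, cf = worked_pair
        assert cocrystal_pairing(api, cf, "A").energy == pytest.approx(-22.0)
        assert cocrystal_pairing(api, cf, "B").energy == pytest.approx(-26.0)

    def test_identical_molecule_doubles_homomeric_energy(self):
        m = sites_from_params("m", [4.0, 2.0], [3.0, 1.0])
        e1 = pairing_energy([s.param for s in m.donors],
                            [s.param for s in m.acceptors]).energy
        for method in ("A", "B"):
            twin = sites_from_params("m2", [4.0, 2.0], [3.0, 1.0])
            assert cocrystal_pairing(m, twin, method).energy == pytest.approx(2 * e1)

    def test_methods_agree_for_pure_cross_systems(self):
        api = sites_from_params("api", [5.0, 2.0], [])
        cf = sites_from_params("cf", [], [4.0, 1.0])
        ea = cocrystal_pairing(api, cf, "A").energy
        eb = cocrystal_pairing(api, cf, "B").energy
        assert ea == pytest.approx(eb) == pytest.approx(-22.0)

    def test_unknown_method_rejected(self, worked_pair):
        with pytest.raises(ValueError, match="method"):
            cocrystal_pairing(*worked_pair, "C")


class TestDeltaE:
    def test_self_pairing_neutral(self):
        m = sites_from_params("m", [5.0, 1.5], [4.0, 0.5])
        for method in ("A", "B"):
            twin = sites_from_params("m", [5.0, 1.5], [4.0, 0.5])
            assert delta_e(m, twin, method).delta_e == pytest.approx(0.0)

    def test_single_site_closed_form(self):
        # dE(A) for one donor/acceptor each = (a1-a2)(b1-b2)
        api = sites_from_params("api", [5.0], [1.0])
        cf = sites_from_params("cf", [2.0], [4.0])
        score = delta_e(api, cf, "A")
        assert score.delta_e == pytest.approx((5.0 - 2.0) * (1.0 - 4.0))
        assert score.verdict == "favorable"

    def test_worked_example_verdicts(self, worked_pair):
        api, cf = worked_pair
        a = delta_e(api, cf, "A")
        assert a.delta_e == pytest.approx(4.0) and a.verdict == "unfavorable"
        b = delta_e(api, cf, "B")
        assert b.delta_e == pytest.approx(0.0) and b.verdict == "unfavorable"

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        alphas=st.lists(st.floats(0.1, 5.0), min_size=1, max_size=4),
        betas=st.lists(st.floats(0.1, 5.0), min_size=1, max_size=4),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_covariance(self, alphas, betas, k):
        """Scaling all parameters by k scales dE by k^2, verdict unchanged."""
        api = sites_from_params("api", alphas, betas)
        cf = sites_from_params("cf", betas, alphas)
        api_k = sites_from_params("api", [k * a for a in alphas], [k * b for b in betas])
        cf_k = sites_from_params("cf", [k * b for b in betas], [k * a for a in alphas])
        for method in ("A", "B"):
            base = delta_e(api, cf, method)
            scaled = delta_e(api_k, cf_k, method)
            assert scaled.delta_e == pytest.approx(k**2 * base.delta_e, abs=1e-7)

    def test_heteromeric_pair_addition_never_raises_delta_e(self):
        """Method A: a coformer donor/acceptor pair that can only pair across
        the interface leaves dE no higher."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            api = sites_from_params("api", rng.uniform(0.5, 5, 2), rng.uniform(0.5, 5, 2))
            a_cf = rng.uniform(0.5, 5, 1)
            b_cf = rng.uniform(0.5, 5, 1)
            cf_small = sites_from_params("cf", [], [])
            cf_big = sites_from_params("cf", list(a_cf), list(b_cf))
            before = delta_e(api, cf_small, "A").delta_e
            after = delta_e(api, cf_big, "A").delta_e
            assert after <= before + 1e-9


class TestRanking:
    def test_singleton(self, worked_pair):
        api, cf = worked_pair
        assert [s.coformer_id for s in rank_coformers(api, [cf], "A")] == ["cf"]

    def test_order_by_delta_e(self):
        api = sites_from_params("api", [5.0], [1.0])
        favorable = sites_from_params("cf_fav", [2.0], [4.0])  # dE = -9
        neutral = sites_from_params("cf_tie", [5.0], [1.0])  # self-like, dE = 0
        unfavorable = sites_from_params("cf_bad", [2.0], [0.5])  # dE = (5-2)(1-0.5) = +1.5
        ranking = rank_coformers(api, [unfavorable, neutral, favorable], "A")
        assert [s.delta_e for s in ranking] == pytest.approx([-9.0, 0.0, 1.5])
        assert ranking[0].coformer_id == "cf_fav"

    def test_tie_breaks_lexicographic(self):
        api = sites_from_params("api", [5.0], [1.0])
        twin_b = sites_from_params("b_cf", [5.0], [1.0])
        twin_a = sites_from_params("a_cf", [5.0], [1.0])
        ranking = rank_coformers(api, [twin_b, twin_a], "B")
        assert [s.coformer_id for s in ranking] == ["a_cf", "b_cf"]

    def test_empty_coformer_list_rejected(self, worked_pair):
        with pytest.raises(ValueError):
            rank_coformers(worked_pair[0], [], "A")


class TestMoleculeSites:
    def test_lists_sorted_descending(self):
        m = sites_from_params("m", [1.0, 3.0, 2.0], [0.5, 2.5])
        assert [s.param for s in m.donors] == [3.0, 2.0, 1.0]
        assert [s.param for s in m.acceptors] == [2.5, 0.5]

    def test_duplicate_site_ids_rejected(self):
        d = InteractionSite("s1", "donor", 0.0, 1.0)
        a = InteractionSite("s1", "acceptor", 0.0, 1.0)
        with pytest.raises(ValueError, match="s1"):
            MoleculeSites("m", [d], [a])

    def test_wrong_kind_in_list_rejected(self):
        a = InteractionSite("s1", "acceptor", 0.0, 1.0)
        with pytest.raises(ValueError, match="kind"):
            MoleculeSites("m", [a], [])
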