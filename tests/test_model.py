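"""Direct-interaction partition function: site weights, configuration
weights, DP vs enumeration, limits and invariants."""

import math

import numpy as np
import pytest

from conftest import make_site, max_rel_err, random_instance
from thermoseq.model import (ModelParams, brute_force_partition,
                             config_weight, partition_direct,
                             partition_limited_contact, predict_profile,
                             site_weight)


def simple_params(**kw):
    defaults = dict(binding_k={"A": 1.0, "R": 1.0},
                    alpha={"A": 2.0, "R": 0.5}, q_btm=0.1)
    defaults.update(kw)
    return ModelParams(**defaults)


ROLES = {"A": "activator", "R": "repressor"}


class TestSiteWeight:
    def test_optimal_site_identity(self):
        s = make_site("A", 0)
        assert site_weight(s, simple_params(), 1.0) == 1.0

    def test_zero_concentration(self):
        s = make_site("A", 0, llr=-1.3)
        assert site_weight(s, simple_params(), 0.0) == 0.0

    def test_mismatch_form(self):
        s = make_site("A", 0, llr=-2.0)
        p = simple_params(binding_k={"A": 3.0, "R": 1.0})
        assert site_weight(s, p, 0.5) == pytest.approx(3 * 0.5 * math.e ** -2)


class TestConfigWeight:
    def test_empty_configuration(self):
        w, q = config_weight([], simple_params(), {}, ROLES)
        assert (w, q) == (1.0, 1.0)

    def test_single_activator(self):
        s = make_site("A", 0)
        w, q = config_weight([s], simple_params(binding_k={"A": 2.0, "R": 1.0},
                                                alpha={"A": 3.0, "R": 0.5}),
                             {"A": 1.0}, ROLES)
        assert (w, q) == (2.0, 3.0)

    def test_adjacent_cooperative_pair(self):
        s1 = make_site("A", 0, length=6)
        s2 = make_site("A", 10, length=6)
        p = simple_params(omega={("A", "A"): 5.0})
        w, q = config_weight([s1, s2], p, {"A": 1.0}, ROLES)
        assert (w, q) == (5.0, 4.0)

    def test_overlapping_sites_rejected(self):
        s1 = make_site("A", 0, length=6)
        s2 = make_site("R", 3, length=6)
        with pytest.raises(ValueError, match="overlap"):
            config_weight([s1, s2], simple_params(), {"A": 1, "R": 1}, ROLES)


class TestPartitionDirect:
    def test_no_sites_basal(self):
        r = partition_direct([], simple_params(), {}, ROLES)
        assert (r.z_on, r.z_off) == (1.0, 1.0)
        assert r.expression == pytest.approx(0.1 / 1.1)

    @pytest.mark.parametrize("sites,z_off,z_on", [
        ([make_site("A", 0)], 2.0, 3.0),                      # 2 configs
        ([make_site("A", 0), make_site("A", 20)], 4.0, 9.0),  # 4 configs
        ([make_site("R", 0)], 2.0, 1.5),                      # repressor
    ])
    def test_hand_enumerated(self, sites, z_off, z_on):
        p = simple_params(coop_range=5.0)
        r = partition_direct(sites, p, {"A": 1.0, "R": 1.0}, ROLES)
        assert r.z_off == pytest.approx(z_off, rel=1e-12)
        assert r.z_on == pytest.approx(z_on, rel=1e-12)
        qb = 0.1
        assert r.expression == pytest.approx(qb * z_on / (qb * z_on + z_off))

    def test_repression_below_basal(self):
        p = simple_params()
        r = partition_direct([make_site("R", 0)], p, {"R": 1.0}, ROLES)
        assert r.expression < 0.1 / 1.1

    def test_overlap_exclusion(self):
        sites = [make_site("A", 0, length=6), make_site("R", 3, length=6)]
        r = brute_force_partition(sites, simple_params(), {"A": 1, "R": 1},
                                  ROLES)
        assert r.z_off == pytest.approx(3.0)   # 1 + q1 + q2, both-bound excluded

    def test_unsorted_sites_rejected(self):
        sites = [make_site("A", 50), make_site("A", 0)]
        with pytest.raises(ValueError, match="sorted"):
            partition_direct(sites, simple_params(), {"A": 1.0}, ROLES)

    def test_dp_equals_enumeration(self, rng):
        for _ in range(60):
            sites, p, c, roles = random_instance(rng, int(rng.integers(0, 11)))
            err = max_rel_err(partition_direct(sites, p, c, roles),
                              brute_force_partition(sites, p, c, roles))
            assert err < 1e-9

    def test_single_site_closed_form(self, rng):
        for _ in range(20):
            q = float(rng.uniform(0, 8))
            a = float(rng.uniform(1, 10))
            qb = float(rng.uniform(0.01, 1))
            p = ModelParams(binding_k={"A": q}, alpha={"A": a}, q_btm=qb)
            r = partition_direct([make_site("A", 0)], p, {"A": 1.0},
                                 {"A": "activator"})
            expect = qb * (1 + q * a) / (qb * (1 + q * a) + 1 + q)
            assert r.expression == pytest.approx(expect, abs=1e-12)


class TestLimitedContact:
    def test_additive_two_activators(self):
        """n_ma=1: both-bound configuration has Q = alpha + alpha."""
        sites = [make_site("A", 0), make_site("A", 20)]
        p = simple_params(n_ma=1, coop_range=5.0)
        r = partition_limited_contact(sites, p, {"A": 1.0, "R": 1.0}, ROLES)
        assert r.z_off == pytest.approx(4.0, rel=1e-12)
        assert r.z_on == pytest.approx(9.0, rel=1e-12)   # 1 + 2 + 2 + 4

    def test_no_activators_matches_direct(self, rng):
        sites = [make_site("R", 0), make_site("R", 30)]
        for n_ma in (1, 2, 3):
            p = simple_params(n_ma=n_ma)
            r1 = partition_limited_contact(sites, p, {"R": 0.7}, ROLES)
            r2 = partition_direct(sites, p.replace(n_ma=math.inf),
                                  {"R": 0.7}, ROLES)
            assert max_rel_err(r1, r2) < 1e-12

    def test_large_nma_approaches_full_contact(self):
        """With n_ma >= #sites the subset sum differs from forced full
        contact only by sub-maximal subsets; forced full contact is the
        multiplicative model (partition_direct)."""
        sites = [make_site("A", 0), make_site("A", 20)]
        p = simple_params(n_ma=2, coop_range=5.0)
        r = partition_limited_contact(sites, p, {"A": 1.0}, ROLES)
        # enumeration: Q(both) = a + a + a^2 = 8 -> Z_ON = 1 + 2 + 2 + 8
        assert r.z_on == pytest.approx(13.0, rel=1e-12)

    def test_dp_equals_enumeration(self, rng):
        for _ in range(40):
            n_ma = int(rng.integers(1, 4))
            sites, p, c, roles = random_instance(rng, int(rng.integers(0, 10)),
                                                 n_ma=n_ma)
            err = max_rel_err(partition_limited_contact(sites, p, c, roles),
                              brute_force_partition(sites, p, c, roles))
            assert err < 1e-9

    def test_infinite_nma_rejected(self):
        with pytest.raises(ValueError):
            partition_limited_contact([], simple_params(), {}, ROLES)


class TestInvariants:
    def test_neutral_alpha_gives_basal(self, rng):
        for _ in range(20):
            sites, p, c, roles = random_instance(rng, int(rng.integers(1, 9)))
            p = p.replace(alpha={t: 1.0 for t in p.alpha})
            r = partition_direct(sites, p, c, roles)
            assert r.z_on == pytest.approx(r.z_off, rel=1e-12)
            assert r.expression == pytest.approx(p.q_btm / (1 + p.q_btm))

    def test_omega_one_identical_to_no_coop(self, rng):
        for _ in range(20):
            sites, p, c, roles = random_instance(rng, int(rng.integers(1, 9)))
            p_one = p.replace(omega={k: 1.0 for k in p.omega})
            p_none = p.replace(omega={})
            r1 = partition_direct(sites, p_one, c, roles)
            r2 = partition_direct(sites, p_none, c, roles)
            assert (r1.z_on, r1.z_off) == (r2.z_on, r2.z_off)

    def test_monotone_in_activator_concentration(self, rng):
        for _ in range(20):
            sites, p, c, roles = random_instance(rng, int(rng.integers(1, 9)),
                                                 with_coop=False,
                                                 allow_overlap=False)
            act = [t for t in roles if roles[t] == "activator"][0]
            rep = [t for t in roles if roles[t] == "repressor"][0]
            grid = np.linspace(0, 3, 7)
            e_act = [partition_direct(sites, p, {**c, act: g}, roles).expression
                     for g in grid]
            e_rep = [partition_direct(sites, p, {**c, rep: g}, roles).expression
                     for g in grid]
            assert np.all(np.diff(e_act) >= -1e-12)
            assert np.all(np.diff(e_rep) <= 1e-12)

    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_saturation_limits(self, n):
        """q -> inf with n identical activator sites: expression tends to
        q_btm*alpha^n/(q_btm*alpha^n+1) (multiplicative) and the
        corresponding n*alpha form (additive)."""
        a, qb, q = 3.0, 0.2, 1e6
        sites = [make_site("A", 20 * i) for i in range(n)]
        p = ModelParams(binding_k={"A": q}, alpha={"A": a}, q_btm=qb,
                        coop_range=5.0)
        r = partition_direct(sites, p, {"A": 1.0}, {"A": "activator"})
        assert r.expression == pytest.approx(qb * a ** n / (qb * a ** n + 1),
                                             rel=1e-4)
        p1 = p.replace(n_ma=1)
        r1 = partition_limited_contact(sites, p1, {"A": 1.0},
                                       {"A": "activator"})
        assert r1.expression == pytest.approx(qb * n * a / (qb * n * a + 1),
                                              rel=1e-4)

    def test_overflow_rescaling(self):
        """Many strong sites overflow float range in raw form; the shared
        rescaling keeps the expression exact (saturation closed form)."""
        n, a, qb = 150, 2.0, 0.1
        sites = [make_site("A", 20 * i) for i in range(n)]
        p = ModelParams(binding_k={"A": 1e6}, alpha={"A": a}, q_btm=qb,
                        coop_range=5.0)
        r = partition_direct(sites, p, {"A": 1.0}, {"A": "activator"})
        # q_btm*a^n >> 1: expression ~ 1; exact form via logs
        log_on = math.log(qb) + n * math.log(a)
        expect = 1 / (1 + math.exp(-log_on))
        assert np.isfinite(r.expression)
        assert r.expression == pytest.approx(expect, rel=1e-3)


class TestPredictProfile:
    def test_zero_concentration_bin_is_basal(self):
        sites = [make_site("A", 0)]
        p = simple_params()
        conc = {"A": np.array([0.0, 1.0, 0.5]), "R": np.zeros(3)}
        prof = predict_profile(sites, p, conc, ROLES)
        assert prof[0] == pytest.approx(0.1 / 1.1)

    def test_bins_equal_single_bin_calls(self, rng):
        sites, p, c, roles = random_instance(rng, 6)
        conc = {t: rng.uniform(0, 1, 5) for t in c}
        prof = predict_profile(sites, p, conc, roles)
        for b in range(5):
            single = partition_direct(sites, p,
                                      {t: conc[t][b] for t in conc}, roles)
            assert prof[b] == pytest.approx(single.expression, rel=1e-12)

    def test_missing_tf_concentration_named(self):
        sites = [make_site("A", 0)]
        with pytest.raises(KeyError, match="A"):
            predict_profile(sites, simple_params(), {"R": np.ones(3)}, ROLES)
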