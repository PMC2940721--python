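"""Synthetic-fixture generators: PWMs, gradients, CRMs, datasets,
ortholog alignments."""

import math

import numpy as np
import pytest

from thermoseq.fitting import dataset_sites
from thermoseq.model import predict_profile
from thermoseq.motifs import annotate_sites, llr_score
from thermoseq.synth import (default_true_params, default_tf_specs, make_crm,
                             make_gradient, make_ortholog_alignment, make_pwm,
                             simulate_dataset, worst_word)


class TestMakePwm:
    def test_llr_max_closed_form(self):
        pwm = make_pwm("ACGTA", 0.91)
        assert pwm.llr_max == pytest.approx(5 * math.log(0.91 / 0.25))
        assert pwm.consensus == "ACGTA"

    def test_uniform_specificity_scores_zero(self, rng):
        pwm = make_pwm("ACGTA", 0.25)
        for _ in range(10):
            w = "".join(rng.choice(list("ACGT"), 5))
            assert llr_score(pwm, w) == pytest.approx(0.0, abs=1e-9)


class TestMakeGradient:
    def test_flat_is_constant(self):
        np.testing.assert_array_equal(make_gradient("flat", 30, level=0.5),
                                      np.full(30, 0.5))

    def test_anterior_non_increasing_posterior_non_decreasing(self):
        a = make_gradient("anterior", 50)
        p = make_gradient("posterior", 50)
        assert np.all(np.diff(a) <= 0)
        assert np.all(np.diff(p) >= 0)

    def test_stripe_peaks_at_center(self):
        g = make_gradient("stripe", 60, center=22)
        assert g.argmax() == 22

    def test_values_bounded(self):
        for kind in ("anterior", "posterior", "stripe", "flat"):
            g = make_gradient(kind, 40)
            assert g.min() >= 0 and g.max() <= 1


class TestMakeCrm:
    def test_full_strength_embeds_consensus(self):
        pwm = make_pwm("ACGGTCAA", 0.9, name="X")
        seq = make_crm([("X", 25, 1.0)], 100, {"X": pwm}, rng_seed=3)
        assert seq[25:33] == "ACGGTCAA"
        assert len(seq) == 100

    def test_empty_plan_is_pure_background(self):
        seq = make_crm([], 500, {}, rng_seed=1)
        assert len(seq) == 500
        counts = {b: seq.count(b) for b in "ACGT"}
        assert all(60 < c < 190 for c in counts.values())

    def test_overlapping_plan_rejected(self):
        pwm = make_pwm("ACGGTCAA", 0.9, name="X")
        with pytest.raises(ValueError, match="overlap"):
            make_crm([("X", 10, 1.0), ("X", 14, 1.0)], 100, {"X": pwm}, 0)

    def test_planted_recovery_rate(self, rng):
        """Plants at strength >= 0.6 stay above the 0.4 threshold and are
        recovered by annotation in (essentially) every draw."""
        pwm = make_pwm("ACGGTCAA", 0.85, name="X")
        recovered = 0
        n = 60
        for _ in range(n):
            strength = float(rng.uniform(0.6, 1.0))
            seq = make_crm([("X", 40, strength)], 150, {"X": pwm},
                           rng_seed=int(rng.integers(2 ** 31)))
            sites = annotate_sites(seq, [pwm], 0.4)
            if any(s.start == 40 for s in sites):
                recovered += 1
        assert recovered >= 0.95 * n


class TestSimulateDataset:
    def test_same_seed_identical(self):
        d1, t1 = simulate_dataset(rng_seed=4, n_crms=3, n_bins=15,
                                  crm_length=300)
        d2, t2 = simulate_dataset(rng_seed=4, n_crms=3, n_bins=15,
                                  crm_length=300)
        for c1, c2 in zip(d1.crms, d2.crms):
            assert c1.seq == c2.seq
            np.testing.assert_array_equal(c1.observed, c2.observed)
        assert t1.consensi == t2.consensi

    def test_observed_profiles_are_model_output_rescaled(self):
        ds, truth = simulate_dataset(rng_seed=4, n_crms=3, n_bins=15,
                                     crm_length=300, noise_sd=0.0)
        roles = ds.roles()
        for crm, sites in zip(ds.crms, dataset_sites(ds, 0.4)):
            pred = predict_profile(sites, truth.params, ds.conc, roles)
            np.testing.assert_allclose(crm.observed, pred / pred.max(),
                                       atol=1e-12)

    def test_noise_perturbs_but_stays_bounded(self):
        ds, _ = simulate_dataset(rng_seed=4, n_crms=3, n_bins=15,
                                 crm_length=300, noise_sd=0.1)
        for crm in ds.crms:
            assert crm.observed.min() >= 0 and crm.observed.max() <= 1

    def test_repressor_lowers_expression_where_it_is_high(self):
        """A CRM with repressor sites near activators expresses less in
        repressor-high bins than the same CRM rebuilt without them."""
        tfs = default_tf_specs()
        params = default_true_params(tfs)
        pwms = {"actA": make_pwm("ACGGTCAA", 0.9, name="actA"),
                "rep1": make_pwm("TTGGCACT", 0.9, name="rep1")}
        plan_full = [("actA", 100, 1.0), ("rep1", 130, 1.0),
                     ("actA", 200, 1.0), ("rep1", 230, 1.0)]
        plan_norep = [p for p in plan_full if p[0] == "actA"]
        conc = {"actA": make_gradient("flat", 30, level=0.8),
                "rep1": make_gradient("stripe", 30, center=15)}
        roles = {"actA": "activator", "rep1": "repressor"}
        seq_full = make_crm(plan_full, 400, pwms, rng_seed=8)
        seq_norep = make_crm(plan_norep, 400, pwms, rng_seed=8)
        pw = list(pwms.values())
        e_full = predict_profile(annotate_sites(seq_full, pw, 0.4), params,
                                 conc, roles)
        e_norep = predict_profile(annotate_sites(seq_norep, pw, 0.4), params,
                                  conc, roles)
        assert e_full[15] < e_norep[15] - 1e-6


class TestOrthologAlignment:
    def test_zero_rate_no_losses_identical(self):
        aln = make_ortholog_alignment("ACGTACGTACGT", species=4,
                                      mutation_rate=0.0, planted_losses=[],
                                      rng_seed=0)
        assert len(aln) == 4
        assert len({s for _, s in aln}) == 1

    def test_divergence_tracks_mutation_rate(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 4000))
        aln = make_ortholog_alignment(seq, species=2, mutation_rate=0.1,
                                      planted_losses=[], rng_seed=12)
        diff = sum(a != b for a, b in zip(aln[0][1], aln[1][1])) / 4000
        assert 0.07 < diff < 0.13

    def test_planted_loss_ablates_only_named_species(self):
        pwm = make_pwm("ACGGTCAA", 0.9, name="X")
        seq = make_crm([("X", 10, 1.0)], 60, {"X": pwm}, rng_seed=2)
        aln = make_ortholog_alignment(seq, species=3, mutation_rate=0.0,
                                      planted_losses=[(2, 0)], rng_seed=1,
                                      site_intervals=[(10, 18)],
                                      loss_words={0: worst_word(pwm)})
        assert aln[1][1][10:18] == seq[10:18]
        assert aln[2][1][10:18] == worst_word(pwm)
        cut = 0.4 * pwm.llr_max
        assert llr_score(pwm, aln[2][1][10:18]) < cut
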