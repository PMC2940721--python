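"""Validation harness: seeded random instances and end-to-end studies.

These routines generate randomized model instances and run the package's
own cross-checks — dynamic programming against enumeration, closed-form
limits, degeneracy reductions, monotonicity sweeps, the
simulate/fit/cross-validate recovery study with its permuted-PWM negative
control, the conservation-filter contrast, and an empirical scaling check
of the partition DP.  Everything is a pure function of the seeds passed in.
"""

from __future__ import annotations

import math
import time

import numpy as np

from .conservation import filter_strict, filter_turnover
from .evaluation import pearson_cc
from .fitting import FitOptions, ModelConfig, cross_validate, fit
from .model import (Dataset, ModelParams, TFSpec, brute_force_partition,
                    partition_direct, partition_limited_contact,
                    predict_profile)
from .motifs import BindingSite, annotate_sites, permute_pwm
from .srr import brute_force_srr, partition_srr
from .synth import (default_true_params, make_crm, make_gradient,
                    make_ortholog_alignment, make_pwm, simulate_dataset,
                    worst_word)


def _random_starts(rng, n_sites, span, allow_overlap):
    if allow_overlap:
        return np.sort(rng.integers(0, span, n_sites))
    # spacing >= 12 guarantees no overlap at site widths <= 8
    return np.arange(n_sites) * 12 + rng.integers(0, 4, n_sites)


def random_instance(rng, n_sites, n_tf=3, mode="direct", n_ma=math.inf,
                    span=300, with_coop=True, allow_overlap=True):
    """Random sites/parameters/concentrations for an oracle comparison.

    Overlapping sites are allowed by default; roles, cooperativity pairs,
    ranges and all weights are drawn from the generator.
    """
    tfs = [f"T{i}" for i in range(n_tf)]
    roles = {t: ("activator" if i % 2 == 0 else "repressor")
             for i, t in enumerate(tfs)}
    starts = _random_starts(rng, n_sites, span, allow_overlap)
    sites = [BindingSite(tfs[rng.integers(0, n_tf)], int(s),
                         int(rng.integers(4, 9)), "+",
                         float(-rng.uniform(0, 2)), 0.0)
             for s in starts]
    sites.sort(key=lambda s: (s.start, s.tf))
    omega = {}
    if with_coop:
        for a in tfs:
            for b in tfs:
                if a <= b and rng.random() < 0.4:
                    omega[frozenset((a, b))] = float(rng.uniform(0.5, 8))
    params = ModelParams(
        binding_k={t: float(rng.uniform(0, 5)) for t in tfs},
        alpha={t: (float(rng.uniform(1, 10)) if roles[t] == "activator"
                   else float(rng.uniform(0.05, 1))) for t in tfs},
        q_btm=float(rng.uniform(0.01, 1)),
        omega=omega,
        coop_range=float(rng.choice([20, 50, 1000])),
        beta={t: float(rng.uniform(0, 6)) for t in tfs
              if roles[t] == "repressor"},
        d_r=float(rng.choice([0, 30, 100, 400])),
        n_ma=n_ma, mode=mode)
    concs = {t: float(rng.uniform(0, 2)) for t in tfs}
    return sites, params, concs, roles


def random_srr_instance(rng, n_act, n_rep, allow_overlap=True, **kw):
    """Random SRR instance with fixed activator/repressor site counts."""
    _sites, params, concs, roles = random_instance(rng, 0, n_tf=2,
                                                   mode="srr", **kw)
    act_tf = [t for t in roles if roles[t] == "activator"][0]
    rep_tf = [t for t in roles if roles[t] == "repressor"][0]
    starts = _random_starts(rng, n_act + n_rep, 300, allow_overlap)
    which = np.array([act_tf] * n_act + [rep_tf] * n_rep)
    rng.shuffle(which)
    sites = [BindingSite(str(t), int(s), int(rng.integers(4, 9)), "+",
                         float(-rng.uniform(0, 2)), 0.0)
             for s, t in zip(starts, which)]
    sites.sort(key=lambda s: (s.start, s.tf))
    return sites, params, concs, roles


def _max_rel(r1, r2):
    def rel(a, b):
        return abs(a - b) / max(1e-300, abs(b))
    return max(rel(r1.z_on, r2.z_on), rel(r1.z_off, r2.z_off),
               rel(r1.expression, r2.expression))


def oracle_error_direct(seed: int, n_instances: int = 200) -> float:
    """Worst relative deviation of the direct-interaction DP from
    exhaustive enumeration over random instances of up to 10 sites."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        sites, p, c, roles = random_instance(rng, int(rng.integers(0, 11)))
        worst = max(worst, _max_rel(partition_direct(sites, p, c, roles),
                                    brute_force_partition(sites, p, c, roles)))
    return worst


def oracle_error_srr(seed: int, n_instances: int = 200) -> float:
    """Worst relative deviation of the SRR DP from the three-state
    enumeration, up to 6 activator and 6 repressor sites."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        sites, p, c, roles = random_srr_instance(
            rng, int(rng.integers(0, 7)), int(rng.integers(0, 7)))
        worst = max(worst, _max_rel(partition_srr(sites, p, c, roles),
                                    brute_force_srr(sites, p, c, roles)))
    return worst


def oracle_error_limited(seed: int, n_instances: int = 100) -> float:
    """Worst deviation of the limited-contact DP (n_ma in {1,2,3}) from
    subset enumeration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_ma = int(rng.integers(1, 4))
        sites, p, c, roles = random_instance(rng, int(rng.integers(0, 10)),
                                             n_ma=n_ma)
        worst = max(worst,
                    _max_rel(partition_limited_contact(sites, p, c, roles),
                             brute_force_partition(sites, p, c, roles)))
    return worst


def closed_form_errors(seed: int) -> dict:
    """Single-site exact formula and high-concentration saturation limits."""
    rng = np.random.default_rng(seed)
    roles = {"A": "activator"}
    single_err = 0.0
    for _ in range(50):
        q = float(rng.uniform(0, 8))
        a = float(rng.uniform(1, 10))
        qb = float(rng.uniform(0.01, 1))
        p = ModelParams(binding_k={"A": q}, alpha={"A": a}, q_btm=qb)
        site = BindingSite("A", 0, 6, "+", 0.0, 0.0)
        r = partition_direct([site], p, {"A": 1.0}, roles)
        expect = qb * (1 + q * a) / (qb * (1 + q * a) + 1 + q)
        single_err = max(single_err, abs(r.expression - expect))
    sat_mult = 0.0
    sat_add = 0.0
    a, qb, q = 3.0, 0.2, 1e6
    for n in (1, 2, 4):
        sites = [BindingSite("A", 20 * i, 6, "+", 0.0, 0.0)
                 for i in range(n)]
        p = ModelParams(binding_k={"A": q}, alpha={"A": a}, q_btm=qb,
                        coop_range=5.0)
        r = partition_direct(sites, p, {"A": 1.0}, roles)
        lim = qb * a ** n / (qb * a ** n + 1)
        sat_mult = max(sat_mult, abs(r.expression - lim) / lim)
        r1 = partition_limited_contact(sites, p.replace(n_ma=1),
                                       {"A": 1.0}, roles)
        lim1 = qb * n * a / (qb * n * a + 1)
        sat_add = max(sat_add, abs(r1.expression - lim1) / lim1)
    return {"single_site_abs_err": single_err,
            "saturation_mult_rel_err": sat_mult,
            "saturation_add_rel_err": sat_add}


def degeneracy_errors(seed: int) -> dict:
    """Neutral-alpha basal reduction, omega=1 equivalence, SRR/DirectInt
    agreement without repressors, and out-of-range repressor neutrality."""
    rng = np.random.default_rng(seed)
    neutral = omega_one = srr_direct = rep_neutral = 0.0
    for _ in range(30):
        sites, p, c, roles = random_instance(rng, int(rng.integers(1, 9)))
        p1 = p.replace(alpha={t: 1.0 for t in p.alpha})
        r = partition_direct(sites, p1, c, roles)
        neutral = max(neutral,
                      abs(r.expression - p1.q_btm / (1 + p1.q_btm)))
        a = partition_direct(sites, p.replace(omega={k: 1.0
                                                     for k in p.omega}), c,
                             roles)
        b = partition_direct(sites, p.replace(omega={}), c, roles)
        omega_one = max(omega_one, abs(a.expression - b.expression))
    for _ in range(30):
        sites, p, c, roles = random_srr_instance(rng, int(rng.integers(1, 7)),
                                                 0)
        r1 = partition_srr(sites, p, c, roles)
        r2 = partition_direct(sites, p.replace(mode="direct"), c, roles)
        srr_direct = max(srr_direct, _max_rel(r1, r2))
    # repressor far outside every activator's d_r (and coop) neighborhood
    for _ in range(20):
        _s, p, c, roles = random_srr_instance(rng, 0, 0, with_coop=False)
        act = [t for t in roles if roles[t] == "activator"][0]
        rep = [t for t in roles if roles[t] == "repressor"][0]
        p = p.replace(d_r=50.0, coop_range=50.0)
        sites = [BindingSite(act, 0, 6, "+", 0.0, 0.0),
                 BindingSite(rep, 500, 6, "+", 0.0, 0.0)]
        with_rep = partition_srr(sites, p, c, roles)
        without = partition_srr(sites[:1], p, c, roles)
        rep_neutral = max(rep_neutral,
                          abs(with_rep.expression - without.expression))
    return {"neutral_alpha_abs_err": neutral,
            "omega_one_abs_err": omega_one,
            "srr_no_repressor_rel_err": srr_direct,
            "distal_repressor_abs_err": rep_neutral}


def monotonicity_violations(seed: int, n_instances: int = 100) -> int:
    """Count of monotonicity violations (activator conc up, repressor conc
    up, beta up) beyond 1e-12 across random instances; expected 0.

    Instances use non-overlapping, non-cooperative sites: overlap makes
    TFs compete for DNA, which legitimately breaks monotonicity (an
    effective repressor can silence a weak site that competes with a
    stronger overlapping one).
    """
    rng = np.random.default_rng(seed)
    violations = 0
    grid = np.linspace(0, 3, 6)
    for _ in range(n_instances):
        sites, p, c, roles = random_instance(rng, int(rng.integers(1, 9)),
                                             with_coop=False,
                                             allow_overlap=False)
        act = [t for t in roles if roles[t] == "activator"][0]
        rep = [t for t in roles if roles[t] == "repressor"][0]
        e_act = [partition_direct(sites, p, {**c, act: g}, roles).expression
                 for g in grid]
        e_rep = [partition_direct(sites, p, {**c, rep: g}, roles).expression
                 for g in grid]
        if np.any(np.diff(e_act) < -1e-12) or np.any(np.diff(e_rep) > 1e-12):
            violations += 1
        s2, p2, c2, roles2 = random_srr_instance(rng, 3, 2,
                                                 with_coop=False,
                                                 allow_overlap=False)
        rep2 = [t for t in roles2 if roles2[t] == "repressor"][0]
        e_beta = [partition_srr(s2, p2.replace(beta={rep2: b}), c2,
                                roles2).expression
                  for b in (0.0, 1.0, 10.0)]
        if np.any(np.diff(e_beta) > 1e-12):
            violations += 1
    return violations


def recovery_study(seed: int, restarts: int = 5, cv_folds: int = 10) -> dict:
    """Simulate (noise-free), refit, cross-validate, and run the
    permuted-PWM negative control under the identical protocol."""
    ds, _truth = simulate_dataset(rng_seed=seed)
    config = ModelConfig()
    options = FitOptions(restarts=restarts, rng_seed=seed + 1,
                         cv_folds=cv_folds)
    res = fit(ds, config, options)
    cvcc, _ = cross_validate(ds, config, options)
    permuted = {name: permute_pwm(pwm, seed + 100 + i)
                for i, (name, pwm) in enumerate(ds.pwms.items())}
    ds_perm = Dataset(crms=ds.crms, tfs=ds.tfs, conc=ds.conc, pwms=permuted)
    res_perm = fit(ds_perm, config, options)
    return {"train_avg_cc": res.train_score,
            "cvcc": cvcc,
            "permuted_train_avg_cc": res_perm.train_score,
            "permuted_gap": res.train_score - res_perm.train_score}


def conservation_study(seed: int, n_crms: int = 6, n_species: int = 4) -> dict:
    """Planted-turnover contrast: lineage-specific losses hurt the strict
    filter but not the turnover-tolerant filter.

    Each CRM carries planted activator/repressor sites; its observed
    profile is the model readout of the full reference annotation.  One
    planted site per CRM is lost in exactly one non-reference species.
    """
    rng = np.random.default_rng(seed)
    tf_names = ["actA", "actP", "rep1"]
    roles = {"actA": "activator", "actP": "activator", "rep1": "repressor"}
    pwms = {}
    for name in tf_names:
        cons = "".join(rng.choice(list("ACGT"), 8))
        pwms[name] = make_pwm(cons, 0.9, name=name)
    conc = {"actA": make_gradient("anterior", 40),
            "actP": make_gradient("posterior", 40),
            "rep1": make_gradient("stripe", 40, center=20)}
    params = default_true_params([TFSpec(n, roles[n]) for n in tf_names])
    width = 8
    cc_strict, cc_turn = [], []
    for _c in range(n_crms):
        n_sites = int(rng.integers(3, 6))
        positions = np.sort(rng.choice(np.arange(20, 480, 12), n_sites,
                                       replace=False))
        plan = [(tf_names[int(rng.integers(0, 3))], int(pos), 1.0)
                for pos in positions]
        seq = make_crm(plan, 520, pwms, rng_seed=int(rng.integers(2 ** 31)))
        intervals = [(pos, pos + width) for _, pos, _ in plan]
        lost_site = int(rng.integers(0, len(plan)))
        lost_species = int(rng.integers(1, n_species))
        aln = make_ortholog_alignment(
            seq, species=n_species, mutation_rate=0.08,
            planted_losses=[(lost_species, lost_site)],
            rng_seed=int(rng.integers(2 ** 31)),
            site_intervals=intervals,
            loss_words={lost_site: worst_word(pwms[plan[lost_site][0]])})
        sites = annotate_sites(seq, list(pwms.values()), 0.4)
        observed = predict_profile(sites, params, conc, roles)
        strict_sites = filter_strict(aln, sites, pwms, n_species)
        turn_sites = filter_turnover(aln, sites, pwms, n_species,
                                     min_species=n_species - 1)
        cc_strict.append(pearson_cc(
            predict_profile(strict_sites, params, conc, roles), observed))
        cc_turn.append(pearson_cc(
            predict_profile(turn_sites, params, conc, roles), observed))
    return {"strict_avg_cc": float(np.mean(cc_strict)),
            "turnover_avg_cc": float(np.mean(cc_turn)),
            "strict_cc_drop": float(np.mean(cc_turn) - np.mean(cc_strict))}


def complexity_ratios(seed: int, base_n: int = 250, doublings: int = 3,
                      repeats: int = 5) -> list:
    """Empirical per-doubling runtime ratios of the direct DP with a
    bounded cooperativity range (linear scaling gives ratios near 2)."""
    rng = np.random.default_rng(seed)
    tfs = ["T0", "T1"]
    roles = {"T0": "activator", "T1": "repressor"}
    params = ModelParams(binding_k={t: 1.0 for t in tfs},
                         alpha={"T0": 3.0, "T1": 0.3}, q_btm=0.1,
                         omega={frozenset(("T0", "T0")): 4.0},
                         coop_range=50.0)
    concs = {t: 1.0 for t in tfs}
    times = []
    sizes = [base_n * 2 ** d for d in range(doublings + 1)]
    for n in sizes:
        span = 10 * n      # constant site density
        starts = np.sort(rng.integers(0, span, n))
        sites = [BindingSite(tfs[rng.integers(0, 2)], int(s), 6, "+",
                             float(-rng.uniform(0, 2)), 0.0)
                 for s in starts]
        sites.sort(key=lambda s: (s.start, s.tf))
        best = math.inf
        for _ in range(repeats):
            t0 = time.perf_counter()
            partition_direct(sites, params, concs, roles)
            best = min(best, time.perf_counter() - t0)
        times.append(best)
    return [times[i + 1] / times[i] for i in range(doublings)]
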