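"""Short-range repression (SRR / quenching) partition function.

In the SRR model a bound repressor does not contact the BTM.  Each
repressor site is in one of three states: unbound, bound-only (bound, but
inert), or bound-effective (bound and rendering its neighborhood, within
d_r bp edge-to-edge, inaccessible to activator binding).  A configuration
is legitimate iff no bound activator lies within d_r of a bound-effective
repressor.  W(sigma) is the usual product of site weights and cooperativity
bonuses, multiplied by beta_R for every bound-effective site; Q(sigma)
collects activator alphas only.

The DP processes sites in start order and merges partial configurations
that are indistinguishable to all future sites.  The relevant history is:
the last bound site (overlap + cooperativity adjacency), the last bound
activator (a future bound-effective repressor must clear it), and the last
bound-effective repressor (a future activator must clear it); each entry is
dropped as soon as it falls out of its interaction range, which keeps the
state space small and the runtime polynomial (near-linear for bounded
ranges).  Exactness is guaranteed against the 3^R * 2^A enumeration oracle.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np

from .motifs import BindingSite
from .model import (ModelParams, PartitionResult, ROLE_ACTIVATOR,
                    ROLE_REPRESSOR, _activator_q_term, _adjacent_omega,
                    _as_profiles, _SiteArrays, site_weight, _RESCALE_TRIGGER)

_FAR = -1


def _check_srr(params: ModelParams, roles: Mapping[str, str],
               tfs: Sequence[str]) -> None:
    for tf in tfs:
        if roles[tf] == ROLE_REPRESSOR and tf not in params.beta:
            raise ValueError(f"repressor {tf!r} lacks a beta parameter")


def _interval_gap(a: BindingSite, b: BindingSite) -> int:
    """Edge-to-edge distance between two non-overlapping site intervals."""
    return max(b.start - a.end, a.start - b.end)


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_srr(sites: Sequence[BindingSite], params: ModelParams,
                    concs: Mapping[str, float], roles: Mapping[str, str],
                    block_repressors: bool = False) -> PartitionResult:
    """Exact enumeration over 3^(#repressor) * 2^(#activator) site states."""
    sites = sorted(sites, key=lambda s: (s.start, s.tf))
    _check_srr(params, roles, {s.tf for s in sites})
    conc = {k: float(np.atleast_1d(v)[0]) for k, v in concs.items()}
    options = []
    n_states = 1
    for s in sites:
        k = 3 if roles[s.tf] == ROLE_REPRESSOR else 2
        options.append(range(k))
        n_states *= k
    if n_states > 3 ** 13:
        raise ValueError("brute force SRR state count too large")
    z_on = 0.0
    z_off = 0.0
    for assign in itertools.product(*options):
        bound = [(s, st) for s, st in zip(sites, assign) if st > 0]
        if any(a.overlaps(b) for (a, _), (b, _) in
               itertools.combinations(bound, 2)):
            continue
        effective = [s for s, st in bound if st == 2]
        acts = [s for s, st in bound if roles[s.tf] == ROLE_ACTIVATOR]
        if any(_interval_gap(e, a) <= params.d_r
               for e in effective for a in acts):
            continue
        if block_repressors:
            reps = [s for s, _ in bound if roles[s.tf] == ROLE_REPRESSOR]
            if any(_interval_gap(e, r) <= params.d_r
                   for e in effective for r in reps if r is not e):
                continue
        bound_sites = [s for s, _ in bound]
        w = _adjacent_omega(bound_sites, params)
        for s in bound_sites:
            w *= site_weight(s, params, conc[s.tf])
        for s in effective:
            w *= params.beta[s.tf]
        qterm = _activator_q_term([params.alpha[s.tf] for s in acts],
                                  params.n_ma)
        z_off += w
        z_on += w * qterm
    expr = params.q_btm * z_on / (params.q_btm * z_on + z_off)
    return PartitionResult(z_on, z_off, float(expr))


# ---------------------------------------------------------------------------
# State-merging DP
# ---------------------------------------------------------------------------

def _collapse(key, sa, params, i, with_contacts, block_repressors):
    """Drop history entries that no future site (start >= start_i) can see."""
    j, a, r = key[0], key[1], key[2]
    start_i = sa.starts[i]
    if j != _FAR and sa.ends[j] <= start_i and \
            start_i - sa.ends[j] > params.coop_range:
        j = _FAR
    if a != _FAR and start_i - sa.ends[a] > params.d_r:
        a = _FAR
    if r != _FAR and start_i - sa.ends[r] > params.d_r:
        r = _FAR
    if block_repressors:
        p = key[3]
        if p != _FAR and start_i - sa.ends[p] > params.d_r:
            p = _FAR
        rest = key[4:] if with_contacts else ()
        return (j, a, r, p) + rest
    rest = key[3:] if with_contacts else ()
    return (j, a, r) + rest


def _srr_pass(sa: _SiteArrays, params: ModelParams, q: np.ndarray,
              alpha_act: np.ndarray, is_act: np.ndarray, n_bins: int,
              with_contacts: bool, block_repressors: bool):
    """One DP pass; returns (total vector, log_scale vector).

    Without contacts the value of a state is sum of W (and the caller
    multiplies alphas in; see _srr_totals).  With contacts, states carry a
    contact count c and an any-activator-bound flag, and the value sums
    W times the product of contacted alphas (exactly c of them).
    """
    n_ma = params.n_ma if params.n_ma != math.inf else None
    empty = (_FAR, _FAR, _FAR) + ((_FAR,) if block_repressors else ()) \
        + ((0, False) if with_contacts else ())
    states = {empty: np.ones(n_bins)}
    log_scale = np.zeros(n_bins)
    for i in range(len(sa)):
        merged: dict = {}
        for key, val in states.items():
            ck = _collapse(key, sa, params, i, with_contacts, block_repressors)
            if ck in merged:
                merged[ck] = merged[ck] + val
            else:
                merged[ck] = val
        states = merged
        additions: dict = {}

        def _add(key, vec):
            if key in additions:
                additions[key] = additions[key] + vec
            else:
                additions[key] = vec

        tf_i = sa.tfs[i]
        start_i = sa.starts[i]
        beta_i = params.beta.get(tf_i, 0.0)
        for key, val in states.items():
            j, a, r = key[0], key[1], key[2]
            p = key[3] if block_repressors else _FAR
            if j != _FAR and sa.ends[j] > start_i:
                continue                      # overlaps last bound site
            wfac = 1.0
            if j != _FAR and start_i - sa.ends[j] <= params.coop_range:
                wfac = params.omega_value(tf_i, sa.tfs[j])
            base = val * (q[i] * wfac)
            if is_act[i]:
                if r != _FAR:
                    continue                  # blocked by effective repressor
                if with_contacts:
                    c, any_act = key[-2], key[-1]
                    head = (i, i, _FAR) + ((p,) if block_repressors else ())
                    _add(head + (c, True), base)              # no contact
                    if c < n_ma:
                        _add(head + (c + 1, True), base * alpha_act[i])
                else:
                    head = (i, i, _FAR) + ((p,) if block_repressors else ())
                    _add(head, base * alpha_act[i])
            else:
                if block_repressors and r != _FAR:
                    continue
                tail = key[4:] if (with_contacts and block_repressors) else \
                    (key[3:] if with_contacts else ())
                newp = (i,) if block_repressors else ()
                _add((i, a, r) + newp + tail, base)           # bound-only
                if a == _FAR and (not block_repressors or p == _FAR):
                    _add((i, _FAR, i) + newp + tail, base * beta_i)
        for key, vec in additions.items():
            if key in states:
                states[key] = states[key] + vec
            else:
                states[key] = vec
        peak = max(v.max() for v in states.values())
        if peak > _RESCALE_TRIGGER:
            colmax = np.maximum.reduce([v for v in states.values()])
            f = np.where(colmax > _RESCALE_TRIGGER, 1.0 / colmax, 1.0)
            for key in states:
                states[key] = states[key] * f
            log_scale -= np.log(f)
    return states, log_scale


def _srr_totals(sites, params, conc, roles, n_bins, block_repressors):
    if isinstance(sites, _SiteArrays):
        sa = sites
    else:
        sa = _SiteArrays(sorted(sites, key=lambda s: (s.start, s.tf)))
    _check_srr(params, roles, set(sa.tfs))
    if len(sa) == 0:
        one = np.ones(n_bins)
        return one, np.zeros(n_bins), one, np.zeros(n_bins)
    q = sa.qmat(params, conc, n_bins)
    is_act = np.array([roles[tf] == ROLE_ACTIVATOR for tf in sa.tfs])
    alpha_act = np.where(is_act, sa.alpha_vec(params), 1.0)
    # Z_OFF: alphas play no role; reuse the no-contact pass with alpha = 1
    states_off, ls_off = _srr_pass(sa, params, q, np.ones(len(sa)), is_act,
                                   n_bins, False, block_repressors)
    z_off = np.sum([v for v in states_off.values()], axis=0)
    if params.n_ma == math.inf:
        states_on, ls_on = _srr_pass(sa, params, q, alpha_act, is_act,
                                     n_bins, False, block_repressors)
        z_on = np.sum([v for v in states_on.values()], axis=0)
    else:
        states_on, ls_on = _srr_pass(sa, params, q, alpha_act, is_act,
                                     n_bins, True, block_repressors)
        parts = [v for k, v in states_on.items()
                 if k[-2] >= 1 or not k[-1]]
        z_on = np.sum(parts, axis=0)
    return z_on, ls_on, z_off, ls_off


def _srr_expression(z_on, ls_on, z_off, ls_off, q_btm):
    log_num = math.log(q_btm) + np.log(z_on) + ls_on
    log_den = np.logaddexp(log_num, np.log(z_off) + ls_off)
    return np.exp(log_num - log_den)


def partition_srr(sites: Sequence[BindingSite], params: ModelParams,
                  concs: Mapping[str, float], roles: Mapping[str, str],
                  block_repressors: bool = False) -> PartitionResult:
    """Exact Z_ON/Z_OFF of the SRR model (matches brute_force_srr).

    Repressor sub-states: bound-only contributes q(S) to W and nothing to
    Q; bound-effective contributes beta_R * q(S) to W and forbids activator
    binding within d_r.  Activators enter Q per the activation mode (n_ma).
    """
    prof, n_bins = _as_profiles(concs)
    z_on, ls_on, z_off, ls_off = _srr_totals(sites, params, prof, roles,
                                             n_bins, block_repressors)
    expr = _srr_expression(z_on, ls_on, z_off, ls_off, params.q_btm)
    with np.errstate(over="ignore"):
        return PartitionResult(float(z_on[0] * np.exp(ls_on[0])),
                               float(z_off[0] * np.exp(ls_off[0])),
                               float(expr[0]))


def _srr_profile(sites, params, conc, roles,
                 block_repressors: bool = False) -> np.ndarray:
    prof, n_bins = _as_profiles(conc)
    z_on, ls_on, z_off, ls_off = _srr_totals(sites, params, prof, roles,
                                             n_bins, block_repressors)
    return _srr_expression(z_on, ls_on, z_off, ls_off, params.q_btm)


def competition_mode(sites: Sequence[BindingSite], params: ModelParams,
                     concs: Mapping[str, float],
                     roles: Mapping[str, str]) -> PartitionResult:
    """Repression by competitive binding: SRR with d_r = 10 bp.

    At this range a bound-effective repressor can only silence overlapping
    or immediately adjacent activator sites, which models repressors that
    act purely by competing for DNA rather than by quenching a neighborhood.
    """
    return partition_srr(sites, params.replace(d_r=10.0), concs, roles)
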