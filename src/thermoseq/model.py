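"""Core thermodynamic model: configuration weights and partition functions.

Expression of a CRM is modeled as the equilibrium fractional occupancy of
the promoter by the basal transcriptional machinery (BTM).  A configuration
sigma assigns bound/unbound states to annotated sites; its TF-DNA weight
W(sigma) multiplies per-site weights q(S) and cooperativity bonuses omega
for adjacent bound partner sites, and its TF-BTM weight Q(sigma) collects
the alpha interaction terms of bound TFs.  With

    Z_ON  = sum_sigma W(sigma) Q(sigma)
    Z_OFF = sum_sigma W(sigma)

the predicted expression is q_btm * Z_ON / (q_btm * Z_ON + Z_OFF), where
q_btm is the statistical weight of BTM binding at the promoter.

The exact dynamic program sums over the nearest occupied site to the left:

    Z_OFF(i) = q(i) * (1 + sum_{j in Phi(i)} omega(i,j) * Z_OFF(j))
    Z_ON(i)  = q(i) * alpha_f(i) * (1 + sum_{j in Phi(i)} omega(i,j) * Z_ON(j))

with Phi(i) the non-overlapping sites left of i, and totals
Z = 1 + sum_i Z(i).  Because Phi(i) grows monotonically as sites are
processed in start order, the sums are maintained as running prefix sums
plus a bounded window scan for cooperativity corrections, giving linear
time when the cooperativity range is bounded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .motifs import BindingSite

ROLE_ACTIVATOR = "activator"
ROLE_REPRESSOR = "repressor"

_RESCALE_TRIGGER = 1e250


@dataclass(frozen=True)
class TFSpec:
    """A transcription factor: fixed role plus declared cooperativity partners."""

    name: str
    role: str
    coop_partners: frozenset = frozenset()

    def __post_init__(self):
        if self.role not in (ROLE_ACTIVATOR, ROLE_REPRESSOR):
            raise ValueError(f"TF {self.name}: role must be activator/repressor")
        object.__setattr__(self, "coop_partners", frozenset(self.coop_partners))

    @property
    def is_activator(self) -> bool:
        return self.role == ROLE_ACTIVATOR


@dataclass
class ModelParams:
    """All free and structural parameters of the model.

    binding_k lumps the association constant of the optimal site and the
    concentration normalization (K(S_max)*nu).  alpha is the TF-BTM
    interaction weight (>1 activators, <1 repressors).  omega maps an
    (unordered) TF pair to a cooperativity weight applied to adjacent bound
    sites within coop_range bp (edge-to-edge).  beta weights the
    bound-effective state of repressors in the short-range repression (SRR)
    model, whose blocking range is d_r.  n_ma caps the number of
    simultaneous activator-BTM contacts (1 = additive, inf = multiplicative).
    """

    binding_k: dict
    alpha: dict
    q_btm: float
    omega: dict = field(default_factory=dict)
    coop_range: float = 50.0
    beta: dict = field(default_factory=dict)
    d_r: float = 250.0
    n_ma: float = math.inf
    mode: str = "direct"

    def __post_init__(self):
        self.omega = {frozenset(k): float(v) for k, v in self.omega.items()}
        if self.mode not in ("direct", "srr"):
            raise ValueError("mode must be 'direct' or 'srr'")
        if self.n_ma != math.inf and (int(self.n_ma) != self.n_ma or self.n_ma < 1):
            raise ValueError("n_ma must be a positive integer or inf")

    def omega_value(self, tf1: str, tf2: str) -> float:
        return self.omega.get(frozenset((tf1, tf2)), 1.0)

    def replace(self, **kw) -> "ModelParams":
        import copy
        new = copy.deepcopy(self)
        for k, v in kw.items():
            setattr(new, k, v)
        new.__post_init__()
        return new


@dataclass
class CRM:
    name: str
    seq: str
    observed: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)


@dataclass
class Dataset:
    """CRMs with observed profiles, TF specs, and bin-aligned concentrations."""

    crms: list
    tfs: list
    conc: dict                      # tf name -> (B,) array in [0, 1]
    pwms: dict = field(default_factory=dict)

    def __post_init__(self):
        self.conc = {k: np.asarray(v, dtype=float) for k, v in self.conc.items()}
        bins = {len(v) for v in self.conc.values()}
        bins |= {len(c.observed) for c in self.crms}
        if len(bins) > 1:
            raise ValueError(f"profiles disagree on bin count: {sorted(bins)}")

    @property
    def n_bins(self) -> int:
        return len(next(iter(self.conc.values())))

    def tf_by_name(self, name: str) -> TFSpec:
        for tf in self.tfs:
            if tf.name == name:
                return tf
        raise KeyError(name)

    def roles(self) -> dict:
        return {tf.name: tf.role for tf in self.tfs}


@dataclass
class PartitionResult:
    z_on: float
    z_off: float
    expression: float


def _check_sorted(sites: Sequence[BindingSite]) -> None:
    for a, b in zip(sites, sites[1:]):
        if b.start < a.start:
            raise ValueError("sites must be sorted by start")


def site_weight(site: BindingSite, params: ModelParams, conc: float) -> float:
    """Statistical weight q(S) = binding_k * [TF]_rel * exp(LLR - LLR_max)."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return params.binding_k[site.tf] * conc * math.exp(site.llr - site.llr_max)


def _adjacent_omega(bound: Sequence[BindingSite], params: ModelParams) -> float:
    """Product of cooperativity weights over adjacent bound partner pairs."""
    w = 1.0
    for a, b in zip(bound, bound[1:]):
        gap = b.start - a.end
        if 0 <= gap <= params.coop_range:
            w *= params.omega_value(a.tf, b.tf)
    return w


def _activator_q_term(alphas: Sequence[float], n_ma: float) -> float:
    """TF-BTM term over bound activators under the limited-contact model.

    Sums products of alpha over all nonempty contact subsets of size at
    most n_ma; the empty activator set contributes 1 (basal).  n_ma = 1
    recovers the additive model Q = sum(alpha_i); n_ma = inf is implemented
    as forced full contact, Q = prod(alpha_i).
    """
    if not alphas:
        return 1.0
    if n_ma == math.inf:
        return float(np.prod(alphas))
    # elementary symmetric polynomials e_1..e_cap via Newton's triangle
    cap = min(int(n_ma), len(alphas))
    e = np.zeros(cap + 1)
    e[0] = 1.0
    for a in alphas:
        upper = min(cap, len(alphas))
        e[1:upper + 1] = e[1:upper + 1] + a * e[0:upper]
    return float(e[1:].sum())


def config_weight(config: Sequence[BindingSite], params: ModelParams,
                  concs: Mapping[str, float],
                  roles: Mapping[str, str]) -> tuple:
    """(W, Q) of a single configuration of bound sites.

    W multiplies site weights and cooperativity bonuses; Q multiplies the
    alpha of every bound TF (direct multiplicative), with activators pooled
    through the limited-contact term when n_ma is finite.  In SRR mode only
    activators enter Q.  Bound sites must not overlap.
    """
    bound = sorted(config, key=lambda s: s.start)
    for a, b in zip(bound, bound[1:]):
        if a.overlaps(b):
            raise ValueError("bound sites overlap")
    w = _adjacent_omega(bound, params)
    for s in bound:
        w *= site_weight(s, params, concs[s.tf])
    act_alphas = [params.alpha[s.tf] for s in bound
                  if roles[s.tf] == ROLE_ACTIVATOR]
    q = _activator_q_term(act_alphas, params.n_ma)
    if params.mode == "direct":
        for s in bound:
            if roles[s.tf] == ROLE_REPRESSOR:
                q *= params.alpha[s.tf]
    return w, q


# ---------------------------------------------------------------------------
# Vectorized DP engines (all bins at once)
# ---------------------------------------------------------------------------

class _SiteArrays:
    """Start/end/TF arrays for a sorted site list, shared across DP calls."""

    def __init__(self, sites: Sequence[BindingSite]):
        _check_sorted(sites)
        self.sites = list(sites)
        self.starts = np.array([s.start for s in sites], dtype=np.int64)
        self.ends = np.array([s.end for s in sites], dtype=np.int64)
        self.tfs = [s.tf for s in sites]
        self.tf_names = sorted(set(self.tfs))
        lookup = {tf: i for i, tf in enumerate(self.tf_names)}
        self.tf_idx = np.array([lookup[tf] for tf in self.tfs], dtype=np.int64)
        self.qrel = np.array([math.exp(s.llr - s.llr_max) for s in sites])
        self.end_order = np.argsort(self.ends, kind="stable")
        self._conc_cache: tuple | None = None

    def __len__(self):
        return len(self.sites)

    def _conc_matrix(self, conc: Mapping[str, np.ndarray],
                     n_bins: int) -> np.ndarray:
        # concentrations are fixed across a fit; cache the stacked matrix
        cached = self._conc_cache
        if cached is not None and cached[0] is conc:
            return cached[1]
        mat = np.empty((len(self.tf_names), n_bins))
        for i, tf in enumerate(self.tf_names):
            if tf not in conc:
                raise KeyError(f"no concentration profile for TF {tf!r}")
            mat[i] = np.asarray(conc[tf])
        self._conc_cache = (conc, mat)
        return mat

    def qmat(self, params: ModelParams, conc: Mapping[str, np.ndarray],
             n_bins: int) -> np.ndarray:
        """q(i, bin) = binding_k * conc * exp(llr - llr_max)."""
        cmat = self._conc_matrix(conc, n_bins)
        k = np.array([params.binding_k[tf] for tf in self.tf_names])
        return (k[self.tf_idx] * self.qrel)[:, None] * cmat[self.tf_idx]

    def alpha_vec(self, params: ModelParams) -> np.ndarray:
        a = np.array([params.alpha[tf] for tf in self.tf_names])
        return a[self.tf_idx]


def compile_sites(sites: Sequence[BindingSite]) -> _SiteArrays:
    """Precompile a sorted site list for repeated partition calls."""
    return _SiteArrays(sites)


def _as_profiles(concs: Mapping, n: int | None = None):
    """Normalize concentrations to tf -> (B,) arrays; scalars become B=1."""
    out = {}
    bins = None
    for k, v in concs.items():
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if bins is None:
            bins = len(arr)
        elif len(arr) != bins:
            raise ValueError("concentration profiles disagree on bin count")
        out[k] = arr
    return out, (bins if bins is not None else 1)


class _Scaler:
    """Shared per-bin rescaling of all DP accumulators.

    Z_ON and Z_OFF are rescaled by the same factor, which cancels in the
    expression ratio; `unit` tracks the rescaled constant 1 and log_scale
    the log of the true/stored ratio.
    """

    def __init__(self, n_bins: int):
        self.unit = np.ones(n_bins)
        self.log_scale = np.zeros(n_bins)

    def maybe_rescale(self, rows: list) -> None:
        n_bins = len(self.unit)
        flats = [r.reshape(-1, n_bins) for r in rows]
        colmax = np.maximum.reduce([fl.max(axis=0) for fl in flats])
        if colmax.max() > _RESCALE_TRIGGER:
            f = np.where(colmax > _RESCALE_TRIGGER, 1.0 / colmax, 1.0)
            for r in rows:
                r *= f
            self.unit *= f
            self.log_scale -= np.log(f)

    def true_value(self, stored: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            return stored * np.exp(self.log_scale)


def _omega_window(sa: _SiteArrays, params: ModelParams, i: int,
                  recent: list) -> list:
    """(j, omega-1) for bound predecessors within the cooperativity range."""
    if not params.omega:
        return []
    out = []
    for j in reversed(recent):
        gap = sa.starts[i] - sa.ends[j]
        if gap > params.coop_range:
            break
        w = params.omega_value(sa.tfs[i], sa.tfs[j])
        if w != 1.0:
            out.append((j, w - 1.0))
    return out


def _dp_direct_arrays(sa: _SiteArrays, params: ModelParams, q: np.ndarray,
                      alpha: np.ndarray):
    """Nearest-bound-site recurrences over all bins; stored Zs + scaler."""
    n, n_bins = q.shape
    zoff = np.zeros((n, n_bins))
    zon = np.zeros((n, n_bins))
    scaler = _Scaler(n_bins)
    acc_off = np.zeros(n_bins)
    acc_on = np.zeros(n_bins)
    recent: list = []
    ptr = 0
    for i in range(n):
        while ptr < n and sa.ends[sa.end_order[ptr]] <= sa.starts[i]:
            j = int(sa.end_order[ptr])
            acc_off += zoff[j]
            acc_on += zon[j]
            recent.append(j)
            ptr += 1
        base_off = scaler.unit + acc_off
        base_on = scaler.unit + acc_on
        for j, wm1 in _omega_window(sa, params, i, recent):
            base_off = base_off + wm1 * zoff[j]
            base_on = base_on + wm1 * zon[j]
        zoff[i] = q[i] * base_off
        zon[i] = alpha[i] * q[i] * base_on
        if zoff[i].max(initial=0.0) > _RESCALE_TRIGGER or \
           zon[i].max(initial=0.0) > _RESCALE_TRIGGER:
            scaler.maybe_rescale([zoff, zon, acc_off, acc_on])
    total_off = scaler.unit + zoff.sum(axis=0)
    total_on = scaler.unit + zon.sum(axis=0)
    return total_on, total_off, scaler


def _expression(total_on, total_off, q_btm):
    return q_btm * total_on / (q_btm * total_on + total_off)


def _result(total_on, total_off, scaler, q_btm, n_bins, profile: bool):
    expr = _expression(total_on, total_off, q_btm)
    z_on = scaler.true_value(total_on)
    z_off = scaler.true_value(total_off)
    if profile:
        return z_on, z_off, expr
    return PartitionResult(float(z_on[0]), float(z_off[0]), float(expr[0]))


def partition_direct(sites: Sequence[BindingSite], params: ModelParams,
                     concs: Mapping[str, float],
                     roles: Mapping[str, str] | None = None) -> PartitionResult:
    """Exact Z_ON/Z_OFF of the Direct Interaction model (multiplicative Q).

    Every bound TF, activator or repressor, contributes its alpha to Q.
    Linear time in the number of sites when coop_range is bounded.
    """
    prof, n_bins = _as_profiles(concs)
    sa = sites if isinstance(sites, _SiteArrays) else _SiteArrays(sites)
    if len(sa) == 0:
        e = params.q_btm / (params.q_btm + 1.0)
        return PartitionResult(1.0, 1.0, e)
    q = sa.qmat(params, prof, n_bins)
    alpha = sa.alpha_vec(params)
    on, off, sc = _dp_direct_arrays(sa, params, q, alpha)
    return _result(on, off, sc, params.q_btm, n_bins, profile=False)


def _dp_limited_arrays(sa: _SiteArrays, params: ModelParams, q: np.ndarray,
                       alpha: np.ndarray, is_act: np.ndarray):
    """Limited-contact DP: the direct recurrence plus a contact-count
    dimension 0..n_ma.

    Y[i, c] sums configurations ending at bound site i whose chosen contact
    subset has size exactly c (weights include contacted alphas and, in
    direct mode, bound repressors' alphas).  Y0[i] restricts to
    repressor-only configurations (Q = 1 contribution handled separately,
    since zero-contact assignments are excluded once an activator is bound).
    """
    n_ma = int(params.n_ma)
    n, n_bins = q.shape
    Y = np.zeros((n, n_ma + 1, n_bins))
    Y0 = np.zeros((n, n_bins))
    zoff = np.zeros((n, n_bins))
    scaler = _Scaler(n_bins)
    acc = np.zeros((n_ma + 1, n_bins))
    acc0 = np.zeros(n_bins)
    acc_off = np.zeros(n_bins)
    rep_alpha = np.where(is_act, 1.0, alpha) if params.mode == "direct" \
        else np.ones(n)
    recent: list = []
    ptr = 0
    for i in range(n):
        while ptr < n and sa.ends[sa.end_order[ptr]] <= sa.starts[i]:
            j = int(sa.end_order[ptr])
            acc += Y[j]
            acc0 += Y0[j]
            acc_off += zoff[j]
            recent.append(j)
            ptr += 1
        base = acc.copy()
        base0 = acc0.copy()
        base_off = scaler.unit + acc_off
        for j, wm1 in _omega_window(sa, params, i, recent):
            base = base + wm1 * Y[j]
            base0 = base0 + wm1 * Y0[j]
            base_off = base_off + wm1 * zoff[j]
        zoff[i] = q[i] * base_off
        if is_act[i]:
            Y[i, 0] = q[i] * (scaler.unit + base[0])
            for c in range(1, n_ma + 1):
                contact = scaler.unit + base[c - 1] if c == 1 else base[c - 1]
                Y[i, c] = q[i] * (alpha[i] * contact + base[c])
        else:
            Y[i, 0] = q[i] * rep_alpha[i] * (scaler.unit + base[0])
            for c in range(1, n_ma + 1):
                Y[i, c] = q[i] * rep_alpha[i] * base[c]
            Y0[i] = q[i] * rep_alpha[i] * (scaler.unit + base0)
        if max(Y[i].max(initial=0.0), zoff[i].max(initial=0.0)) > _RESCALE_TRIGGER:
            scaler.maybe_rescale([Y, Y0, zoff, acc, acc0, acc_off])
    total_on = scaler.unit + Y[:, 1:, :].sum(axis=(0, 1)) + Y0.sum(axis=0)
    total_off = scaler.unit + zoff.sum(axis=0)
    return total_on, total_off, scaler


def partition_limited_contact(sites: Sequence[BindingSite], params: ModelParams,
                              concs: Mapping[str, float],
                              roles: Mapping[str, str]) -> PartitionResult:
    """Partition function with at most n_ma simultaneous activator-BTM contacts.

    Each bound activator either contacts the BTM (factor alpha) or not
    (factor 1); Q sums contact assignments of size 1..n_ma, except that the
    all-unbound-activator case contributes the basal Q = 1.  n_ma = 1 is the
    additive model Q = sum(alpha_i).
    """
    if params.n_ma == math.inf or params.n_ma < 1:
        raise ValueError("partition_limited_contact requires finite n_ma >= 1")
    prof, n_bins = _as_profiles(concs)
    sa = sites if isinstance(sites, _SiteArrays) else _SiteArrays(sites)
    if len(sa) == 0:
        return PartitionResult(1.0, 1.0, params.q_btm / (params.q_btm + 1.0))
    q = sa.qmat(params, prof, n_bins)
    alpha = sa.alpha_vec(params)
    is_act = np.array([roles[tf] == ROLE_ACTIVATOR for tf in sa.tfs])
    on, off, sc = _dp_limited_arrays(sa, params, q, alpha, is_act)
    return _result(on, off, sc, params.q_btm, n_bins, profile=False)


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

def _nonoverlapping_subsets(sites: Sequence[BindingSite]):
    """Yield every subset of pairwise non-overlapping sites (incl. empty)."""
    n = len(sites)
    for mask in range(1 << n):
        chosen = [sites[i] for i in range(n) if mask >> i & 1]
        ok = all(not a.overlaps(b)
                 for a, b in itertools.combinations(chosen, 2))
        if ok:
            yield chosen


def brute_force_partition(sites: Sequence[BindingSite], params: ModelParams,
                          concs: Mapping[str, float],
                          roles: Mapping[str, str]) -> PartitionResult:
    """Direct enumeration of all 2^n configurations (testing oracle).

    Exact but exponential; refuses more than 20 sites.
    """
    if len(sites) > 20:
        raise ValueError("brute force limited to 20 sites")
    conc_scalar = {k: float(np.atleast_1d(v)[0]) for k, v in concs.items()}
    z_on = 0.0
    z_off = 0.0
    for chosen in _nonoverlapping_subsets(list(sites)):
        w, qq = config_weight(chosen, params, conc_scalar, roles)
        z_off += w
        z_on += w * qq
    expr = _expression(z_on, z_off, params.q_btm)
    return PartitionResult(z_on, z_off, float(expr))


def predict_profile(sites: Sequence[BindingSite], params: ModelParams,
                    conc: Mapping[str, np.ndarray],
                    roles: Mapping[str, str]) -> np.ndarray:
    """Predicted expression across all bins for one CRM.

    Dispatches on params.mode / n_ma; bins are independent and computed in
    one vectorized DP pass.
    """
    if params.mode == "srr":
        from .srr import _srr_profile
        return _srr_profile(sites, params, conc, roles)
    prof, n_bins = _as_profiles(conc)
    sa = sites if isinstance(sites, _SiteArrays) else _SiteArrays(sites)
    if len(sa) == 0:
        return np.full(n_bins, params.q_btm / (params.q_btm + 1.0))
    q = sa.qmat(params, prof, n_bins)
    alpha = sa.alpha_vec(params)
    if params.n_ma == math.inf:
        on, off, sc = _dp_direct_arrays(sa, params, q, alpha)
    else:
        is_act = np.array([roles[tf] == ROLE_ACTIVATOR for tf in sa.tfs])
        on, off, sc = _dp_limited_arrays(sa, params, q, alpha, is_act)
    return _expression(on, off, params.q_btm)
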