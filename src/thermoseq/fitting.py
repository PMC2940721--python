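"""Parameter estimation for the thermodynamic expression model.

Free parameters (per-TF binding constants K(S_max)*nu, TF-BTM weights
alpha, the promoter weight q_btm, cooperativity weights omega for declared
pairs, and repressor betas in SRR mode) are mapped to unconstrained space
by logistic transforms that enforce the role bounds (activator alpha > 1,
repressor alpha < 1, positive weights) by construction.  Optimization
alternates a Nelder-Mead simplex stage on the average Pearson correlation
with a quasi-Newton (BFGS, central-difference gradients) stage on the sum
of squared errors, with seeded random restarts against local optima.

Both objectives compare profile *shapes*: the correlation is scale
invariant, and the SSE fits a free non-negative per-CRM scale in closed
form, matching expression data reported on a relative 0-to-1 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .evaluation import pearson_cc
from .model import (Dataset, ModelParams, ROLE_ACTIVATOR, ROLE_REPRESSOR,
                    predict_profile)
from .motifs import annotate_sites


@dataclass
class ModelConfig:
    """Structural model choices, fixed during fitting."""

    mode: str = "direct"
    n_ma: float = math.inf
    coop_pairs: tuple = ()         # pairs of TF names with free omega
    coop_range: float = 50.0
    d_r: float = 250.0
    site_threshold: float = 0.4
    block_repressors: bool = False

    def __post_init__(self):
        self.coop_pairs = tuple(frozenset(p) for p in self.coop_pairs)


@dataclass
class FitOptions:
    objective: str = "alternate"     # cc | sse | alternate
    restarts: int = 5
    rng_seed: int = 0
    max_iter_simplex: int = 120
    max_iter_gradient: int = 30
    grad_step: float = 1e-4
    cv_folds: int = 10
    bounds: dict = field(default_factory=dict)   # overrides by class name

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.objective not in ("cc", "sse", "alternate"):
            raise ValueError("objective must be cc, sse or alternate")


@dataclass
class FitResult:
    params: ModelParams
    train_score: float               # avg CC (cc/alternate) or SSE (sse)
    objective_trace: list
    rng_seed: int
    per_crm_cc: np.ndarray


# default parameter boxes; random starts are drawn log-uniformly inside
_DEFAULT_BOUNDS = {
    "binding_k": (1e-3, 1e3, "log"),
    "alpha_act": (1.0, 100.0, "linear"),      # open at 1: activators > 1
    "alpha_rep": (1e-3, 1.0, "log"),          # open at 1: repressors < 1
    "omega": (1.0, 100.0, "log"),
    "beta": (1e-6, 100.0, "linear"),
    "q_btm": (1e-4, 1.0, "log"),
}
_START_LO = {"alpha_act": 1.01, "beta": 1e-3}


class ParamSpace:
    """Packing of free parameters to/from an unconstrained vector."""

    def __init__(self, tfs, config: ModelConfig, bounds_override=None):
        self.config = config
        self.bounds = dict(_DEFAULT_BOUNDS)
        self.bounds.update(bounds_override or {})
        self.entries = []            # (class, key)
        for tf in tfs:
            self.entries.append(("binding_k", tf.name))
        for tf in tfs:
            cls = "alpha_act" if tf.is_activator else "alpha_rep"
            self.entries.append((cls, tf.name))
        self.entries.append(("q_btm", None))
        for pair in config.coop_pairs:
            self.entries.append(("omega", pair))
        if config.mode == "srr":
            for tf in tfs:
                if tf.role == ROLE_REPRESSOR:
                    self.entries.append(("beta", tf.name))

    @property
    def dim(self) -> int:
        return len(self.entries)

    def _box(self, cls):
        lo, hi, scale = self.bounds[cls]
        return lo, hi, scale

    def decode_one(self, cls, t):
        lo, hi, scale = self._box(cls)
        u = expit(t)
        if scale == "log":
            return math.exp(math.log(lo) + (math.log(hi) - math.log(lo)) * u)
        return lo + (hi - lo) * u

    def encode_one(self, cls, v):
        lo, hi, scale = self._box(cls)
        if scale == "log":
            u = (math.log(v) - math.log(lo)) / (math.log(hi) - math.log(lo))
        else:
            u = (v - lo) / (hi - lo)
        return float(logit(np.clip(u, 1e-12, 1 - 1e-12)))

    def make_params(self, t: np.ndarray) -> ModelParams:
        binding_k, alpha, omega, beta = {}, {}, {}, {}
        q_btm = None
        for (cls, key), ti in zip(self.entries, t):
            v = self.decode_one(cls, ti)
            if cls == "binding_k":
                binding_k[key] = v
            elif cls in ("alpha_act", "alpha_rep"):
                alpha[key] = v
            elif cls == "q_btm":
                q_btm = v
            elif cls == "omega":
                omega[key] = v
            elif cls == "beta":
                beta[key] = v
        return ModelParams(binding_k=binding_k, alpha=alpha, q_btm=q_btm,
                           omega=omega, coop_range=self.config.coop_range,
                           beta=beta, d_r=self.config.d_r,
                           n_ma=self.config.n_ma, mode=self.config.mode)

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        t = np.empty(self.dim)
        for i, (cls, _key) in enumerate(self.entries):
            lo, hi, _ = self._box(cls)
            lo = _START_LO.get(cls, lo)
            v = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            t[i] = self.encode_one(cls, v)
        return t


def dataset_sites(dataset: Dataset, threshold_frac: float = 0.4):
    """Annotated site lists per CRM, cached on the dataset."""
    cache = getattr(dataset, "_site_cache", None)
    if cache is None:
        cache = {}
        dataset._site_cache = cache
    if threshold_frac not in cache:
        pwms = list(dataset.pwms.values())
        cache[threshold_frac] = [annotate_sites(c.seq, pwms, threshold_frac)
                                 for c in dataset.crms]
    return cache[threshold_frac]


def dataset_compiled(dataset: Dataset, threshold_frac: float = 0.4):
    """Precompiled site arrays per CRM (fast path for repeated predicts)."""
    from .model import compile_sites
    cache = getattr(dataset, "_compiled_cache", None)
    if cache is None:
        cache = {}
        dataset._compiled_cache = cache
    if threshold_frac not in cache:
        cache[threshold_frac] = [compile_sites(s) for s in
                                 dataset_sites(dataset, threshold_frac)]
    return cache[threshold_frac]


def predict_dataset(params: ModelParams, dataset: Dataset,
                    sites=None, threshold_frac: float = 0.4):
    """Predicted expression profiles for every CRM."""
    if sites is None:
        sites = dataset_compiled(dataset, threshold_frac)
    roles = dataset.roles()
    return [predict_profile(s, params, dataset.conc, roles)
            for s in sites]


def objective_avg_cc(params: ModelParams, dataset: Dataset,
                     config: ModelConfig | None = None, sites=None) -> float:
    """Mean over CRMs of Pearson CC(predicted, observed); constant -> 0."""
    thr = config.site_threshold if config else 0.4
    preds = predict_dataset(params, dataset, sites, thr)
    return float(np.mean([pearson_cc(p, c.observed)
                          for p, c in zip(preds, dataset.crms)]))


def _scaled_sse(pred: np.ndarray, obs: np.ndarray) -> float:
    """min over s >= 0 of ||s*pred - obs||^2; s has a clipped closed form."""
    pp = float(pred @ pred)
    s = max(0.0, float(pred @ obs) / pp) if pp > 0 else 0.0
    r = s * pred - obs
    return float(r @ r)


def objective_sse(params: ModelParams, dataset: Dataset,
                  config: ModelConfig | None = None, sites=None) -> float:
    """Sum over CRMs of the per-CRM optimally rescaled squared error."""
    thr = config.site_threshold if config else 0.4
    preds = predict_dataset(params, dataset, sites, thr)
    return float(sum(_scaled_sse(p, c.observed)
                     for p, c in zip(preds, dataset.crms)))


def _central_grad(f, step):
    def grad(t):
        g = np.empty(len(t))
        for i in range(len(t)):
            e = np.zeros(len(t))
            e[i] = step
            g[i] = (f(t + e) - f(t - e)) / (2 * step)
        return g
    return grad


def fit(dataset: Dataset, config: ModelConfig,
        options: FitOptions | None = None) -> FitResult:
    """Train free parameters by restarted simplex / quasi-Newton stages.

    With objective='alternate', each restart runs (Nelder-Mead on -avgCC,
    then BFGS on SSE) twice; 'cc' and 'sse' run both stages on the single
    objective.  The best restart under the primary objective wins.
    Deterministic given options.rng_seed.
    """
    options = options or FitOptions()
    space = ParamSpace(dataset.tfs, config, options.bounds)
    sites = dataset_compiled(dataset, config.site_threshold)

    def f_cc(t):
        return -objective_avg_cc(space.make_params(t), dataset, config, sites)

    def f_sse(t):
        return objective_sse(space.make_params(t), dataset, config, sites)

    if options.objective == "alternate":
        schedule = [("simplex-cc", "nm", f_cc), ("bfgs-sse", "qn", f_sse)] * 2
        primary = f_cc
    elif options.objective == "cc":
        schedule = [("simplex-cc", "nm", f_cc), ("bfgs-cc", "qn", f_cc)]
        primary = f_cc
    else:
        schedule = [("simplex-sse", "nm", f_sse), ("bfgs-sse", "qn", f_sse)]
        primary = f_sse

    rng = np.random.default_rng(options.rng_seed)
    best_t, best_val, best_trace = None, np.inf, []
    for _restart in range(options.restarts):
        t = None
        for _try in range(20):
            cand = space.random_start(rng)
            if np.isfinite(primary(cand)):
                t = cand
                break
        if t is None:
            raise RuntimeError(
                "objective non-finite at every sampled start "
                f"(last draw: {space.make_params(cand)})")
        trace = []
        for label, kind, f in schedule:
            if kind == "nm":
                res = minimize(f, t, method="Nelder-Mead",
                               options={"maxiter": options.max_iter_simplex,
                                        "xatol": 1e-6, "fatol": 1e-9})
            else:
                res = minimize(f, t, method="BFGS",
                               jac=_central_grad(f, options.grad_step),
                               options={"maxiter": options.max_iter_gradient})
            if np.isfinite(res.fun) and res.fun <= f(t):
                t = res.x
            trace.append((label, float(f(t))))
        val = primary(t)
        if val < best_val:
            best_t, best_val, best_trace = t, val, trace

    params = space.make_params(best_t)
    preds = predict_dataset(params, dataset, sites)
    per_crm = np.array([pearson_cc(p, c.observed)
                        for p, c in zip(preds, dataset.crms)])
    if options.objective == "sse":
        score = objective_sse(params, dataset, config, sites)
    else:
        score = float(per_crm.mean())
    return FitResult(params=params, train_score=score,
                     objective_trace=best_trace, rng_seed=options.rng_seed,
                     per_crm_cc=per_crm)


def cross_validate(dataset: Dataset, config: ModelConfig,
                   options: FitOptions | None = None):
    """K-fold cross-validation over CRMs.

    Returns (cvcc, folds) where cvcc is the mean held-out CC over all CRMs
    and folds records, per fold, the held-out CRM names and their CCs (the
    partition matters and is reproducible from options.rng_seed).
    """
    options = options or FitOptions()
    n = len(dataset.crms)
    k = options.cv_folds
    if k > n or k < 2:
        raise ValueError(f"cv_folds={k} incompatible with {n} CRMs")
    rng = np.random.default_rng(options.rng_seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    all_sites = dataset_sites(dataset, config.site_threshold)
    all_compiled = dataset_compiled(dataset, config.site_threshold)
    roles = dataset.roles()
    records = []
    held_cc = np.empty(n)
    for f_idx, test_idx in enumerate(folds):
        if len(test_idx) < 1:
            raise ValueError("empty cross-validation fold")
        train_idx = np.setdiff1d(perm, test_idx)
        sub = Dataset(crms=[dataset.crms[i] for i in train_idx],
                      tfs=dataset.tfs, conc=dataset.conc, pwms=dataset.pwms)
        sub._site_cache = {config.site_threshold:
                           [all_sites[i] for i in train_idx]}
        sub._compiled_cache = {config.site_threshold:
                               [all_compiled[i] for i in train_idx]}
        fold_opts = FitOptions(
            objective=options.objective, restarts=options.restarts,
            rng_seed=(options.rng_seed * 1009 + 7919 * f_idx) % (2 ** 31),
            max_iter_simplex=options.max_iter_simplex,
            max_iter_gradient=options.max_iter_gradient,
            grad_step=options.grad_step, cv_folds=options.cv_folds,
            bounds=options.bounds)
        res = fit(sub, config, fold_opts)
        fold_rec = []
        for i in test_idx:
            pred = predict_profile(all_compiled[i], res.params,
                                   dataset.conc, roles)
            cc = pearson_cc(pred, dataset.crms[i].observed)
            held_cc[i] = cc
            fold_rec.append((dataset.crms[i].name, cc))
        records.append({"fold": f_idx, "held_out": fold_rec,
                        "train_score": res.train_score})
    return float(held_cc.mean()), records
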