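"""Model assessment: per-CRM correlations, knock-downs, best-K curves and
model-comparison significance.

The primary metric is the Pearson correlation coefficient (CC) between the
predicted and observed expression profiles of each CRM over a configurable
bin window; a model summary reports the average CC and the number of CRMs
exceeding CC 0.65.  Knock-down analysis re-predicts with one TF's
concentration zeroed (without refitting) to visualize that TF's
contribution.  Model comparison combines per-CRM bootstrap significance of
the CC improvement into one p-value by Fisher's method; this seeded
bin-bootstrap + Fisher combination is this package's convention for the
improvement test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CC_THRESHOLD = 0.65

# 60-bin trunk window (indices 20..79 of a 100-bin axis); datasets that are
# already trimmed use window=None
TRUNK_WINDOW = (20, 80)


def pearson_cc(x, y) -> float:
    """Pearson correlation; 0 when either vector is (numerically) constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx < 1e-12 or ny < 1e-12:
        return 0.0
    return float(xc @ yc / (nx * ny))


def _window_slice(profile: np.ndarray, window) -> np.ndarray:
    if window is None:
        return profile
    lo, hi = window
    return profile[lo:hi]


@dataclass
class EvalReport:
    per_crm_cc: dict            # CRM name -> CC
    avg_cc: float
    n_above: int                # CRMs with CC > CC_THRESHOLD (strict)
    window: tuple | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"crm": list(self.per_crm_cc),
                             "cc": list(self.per_crm_cc.values())})


def _predictions(params, dataset, sites=None, threshold_frac=0.4,
                 conc=None):
    from .fitting import dataset_compiled
    from .model import predict_profile
    if sites is None:
        sites = dataset_compiled(dataset, threshold_frac)
    conc = dataset.conc if conc is None else conc
    roles = dataset.roles()
    return [predict_profile(s, params, conc, roles) for s in sites]


def evaluate(params, dataset, window=None, sites=None,
             threshold_frac: float = 0.4, conc=None) -> EvalReport:
    """Per-CRM CC, average CC and the CC>0.65 count for a fitted model."""
    preds = _predictions(params, dataset, sites, threshold_frac, conc)
    per = {}
    for crm, pred in zip(dataset.crms, preds):
        per[crm.name] = pearson_cc(_window_slice(pred, window),
                                   _window_slice(crm.observed, window))
    ccs = np.array(list(per.values()))
    return EvalReport(per_crm_cc=per, avg_cc=float(ccs.mean()),
                      n_above=int((ccs > CC_THRESHOLD).sum()), window=window)


def knockdown(params, dataset, tf_name: str, window=None, sites=None,
              threshold_frac: float = 0.4) -> EvalReport:
    """Re-predict with one TF's concentration zeroed everywhere (no refit)."""
    if tf_name not in dataset.conc:
        raise KeyError(f"unknown TF {tf_name!r}")
    conc = dict(dataset.conc)
    conc[tf_name] = np.zeros_like(conc[tf_name])
    return evaluate(params, dataset, window=window, sites=sites,
                    threshold_frac=threshold_frac, conc=conc)


def best_k_curve(models: dict, dataset, knockdown_tfs: dict | None = None,
                 window=None, threshold_frac: float = 0.4) -> pd.DataFrame:
    """Average CC over each model's best K CRMs, for K = 1..#CRMs.

    For a model with a knock-down companion (knockdown_tfs[model] = TF),
    the companion curve averages the knocked-down CCs over the *same* top-K
    CRMs selected by the parent model, so the curves are comparable.
    """
    knockdown_tfs = knockdown_tfs or {}
    n = len(dataset.crms)
    rows = []
    for name, params in models.items():
        rep = evaluate(params, dataset, window=window,
                       threshold_frac=threshold_frac)
        ccs = np.array(list(rep.per_crm_cc.values()))
        order = np.argsort(-ccs, kind="stable")
        for k in range(1, n + 1):
            rows.append({"model": name, "K": k,
                         "avg_cc": float(ccs[order[:k]].mean())})
        if name in knockdown_tfs:
            tf = knockdown_tfs[name]
            kd = knockdown(params, dataset, tf, window=window,
                           threshold_frac=threshold_frac)
            kd_ccs = np.array(list(kd.per_crm_cc.values()))
            for k in range(1, n + 1):
                rows.append({"model": f"{name}-{tf}-kd", "K": k,
                             "avg_cc": float(kd_ccs[order[:k]].mean())})
    return pd.DataFrame(rows)


@dataclass
class CompareReport:
    per_crm: pd.DataFrame       # crm, cc_a, cc_b, delta, p
    combined_p: float
    n_better: int               # cc_a >= 0.65 and delta >= 0.05
    n_worse: int                # cc_b >= 0.65 and delta <= -0.05


def compare_models(params_a, params_b, dataset, window=None,
                   n_boot: int = 1000, rng_seed: int = 0,
                   threshold_frac: float = 0.4,
                   delta_threshold: float = 0.05) -> CompareReport:
    """Significance of the CC improvement of model A over model B.

    Per CRM, a seeded bootstrap over bins resamples the profiles and
    recomputes delta CC = CC_A - CC_B; the one-sided p is the tail fraction
    of resampled deltas at or below zero.  Per-CRM p-values are combined by
    Fisher's method.  Also reported: descriptive better/worse CRM counts
    at CC >= 0.65 and |delta CC| >= 0.05.
    """
    preds_a = _predictions(params_a, dataset, None, threshold_frac)
    preds_b = _predictions(params_b, dataset, None, threshold_frac)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for crm, pa, pb in zip(dataset.crms, preds_a, preds_b):
        obs = _window_slice(crm.observed, window)
        pa_w = _window_slice(pa, window)
        pb_w = _window_slice(pb, window)
        cc_a = pearson_cc(pa_w, obs)
        cc_b = pearson_cc(pb_w, obs)
        delta = cc_a - cc_b
        nb = len(obs)
        idx = rng.integers(0, nb, size=(n_boot, nb))
        worse = 0
        for draw in idx:
            d = pearson_cc(pa_w[draw], obs[draw]) - \
                pearson_cc(pb_w[draw], obs[draw])
            if d <= 0:
                worse += 1
        p = (1 + worse) / (n_boot + 1)
        rows.append({"crm": crm.name, "cc_a": cc_a, "cc_b": cc_b,
                     "delta": delta, "p": p})
    df = pd.DataFrame(rows)
    fisher_stat = -2.0 * np.log(df["p"]).sum()
    combined_p = float(stats.chi2.sf(fisher_stat, 2 * len(df)))
    n_better = int(((df["cc_a"] >= CC_THRESHOLD) &
                    (df["delta"] >= delta_threshold)).sum())
    n_worse = int(((df["cc_b"] >= CC_THRESHOLD) &
                   (df["delta"] <= -delta_threshold)).sum())
    return CompareReport(per_crm=df, combined_p=combined_p,
                         n_better=n_better, n_worse=n_worse)
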