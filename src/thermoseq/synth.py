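"""Synthetic fixtures: PWMs, concentration gradients, CRMs with planted
sites, model-generated expression data, and ortholog alignments with
planted site turnover.

The generator emulates the regime of an anterior-posterior patterning
system: ~1 kb CRMs, 60-bin spatial profiles on a 0-1 scale, a small TF set
of two activators (opposing sigmoid gradients) and two repressors (stripe
gradients), with observed profiles produced by the thermodynamic model
itself under known ground-truth parameters.  All generators are pure
functions of their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (CRM, Dataset, ModelParams, ROLE_ACTIVATOR,
                    ROLE_REPRESSOR, TFSpec, predict_profile)
from .motifs import BASES, DEFAULT_BACKGROUND, PWM, annotate_sites


def make_pwm(consensus: str, specificity: float, name: str = "TF",
             background=None) -> PWM:
    """PWM whose consensus base has probability `specificity` per position,
    the remainder split evenly over the other three bases."""
    if not 0 < specificity <= 1:
        raise ValueError("specificity must be in (0, 1]")
    spec = min(specificity, 1 - 3e-9)        # keep probabilities positive
    probs = np.full((len(consensus), 4), (1 - spec) / 3)
    for i, b in enumerate(consensus.upper()):
        probs[i, BASES.index(b)] = spec
    bg = DEFAULT_BACKGROUND if background is None else background
    return PWM(name, probs, bg)


def make_gradient(kind: str, bins: int, center: float | None = None,
                  steepness: float | None = None, level: float = 0.5,
                  amplitude: float = 1.0) -> np.ndarray:
    """Concentration profile over spatial bins, values in [0, 1].

    anterior: decreasing sigmoid; posterior: increasing sigmoid; stripe:
    Gaussian bump peaking at `center` (in bins); flat: constant `level`.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.arange(bins, dtype=float)
    center = bins / 2 if center is None else center
    steep = bins / 10 if steepness is None else steepness
    if kind == "flat":
        g = np.full(bins, level)
    elif kind == "anterior":
        g = amplitude / (1 + np.exp((x - center) / steep))
    elif kind == "posterior":
        g = amplitude / (1 + np.exp(-(x - center) / steep))
    elif kind == "stripe":
        g = amplitude * np.exp(-0.5 * ((x - center) / steep) ** 2)
    else:
        raise ValueError(f"unknown gradient kind {kind!r}")
    return np.clip(g, 0.0, 1.0)


def _degrade_word(pwm: PWM, frac: float) -> str:
    """Greedy per-position degradation of the consensus toward
    LLR ~ frac * llr_max (final LLR stays at or just above the target)."""
    mat = pwm.llr_matrix
    target = frac * pwm.llr_max
    codes = list(mat.argmax(axis=1))
    cur = pwm.llr_max
    while True:
        best = None                       # (new_llr, pos, base)
        for pos in range(pwm.width):
            for b in range(4):
                if b == codes[pos]:
                    continue
                new = cur - mat[pos, codes[pos]] + mat[pos, b]
                if new >= target - 1e-12 and (best is None or new < best[0]):
                    best = (new, pos, b)
        if best is None or best[0] >= cur:
            break
        cur, pos, b = best
        codes[pos] = b
    return "".join(BASES[c] for c in codes)


def make_crm(site_plan, length: int, pwms: dict, rng_seed: int,
             background=None) -> str:
    """Background sequence with planted sites.

    site_plan: list of (tf, position, strength_fraction); planted words are
    consensus words degraded to ~strength_fraction of the optimal LLR, so
    annotation at threshold 0.4 recovers plants with strength >= 0.5.
    """
    bg = DEFAULT_BACKGROUND if background is None else np.asarray(background)
    plan = sorted(site_plan, key=lambda p: p[1])
    for (tf_a, pos_a, _), (tf_b, pos_b, _) in zip(plan, plan[1:]):
        if pos_a + pwms[tf_a].width > pos_b:
            raise ValueError("planted sites overlap")
    for tf, pos, _ in plan:
        if pos < 0 or pos + pwms[tf].width > length:
            raise ValueError(f"planted site at {pos} outside sequence")
    rng = np.random.default_rng(rng_seed)
    seq = list("".join(rng.choice(list(BASES), size=length, p=bg)))
    for tf, pos, frac in plan:
        word = _degrade_word(pwms[tf], frac)
        seq[pos:pos + len(word)] = word
    return "".join(seq)


def default_tf_specs() -> list:
    return [TFSpec("actA", ROLE_ACTIVATOR), TFSpec("actP", ROLE_ACTIVATOR),
            TFSpec("rep1", ROLE_REPRESSOR), TFSpec("rep2", ROLE_REPRESSOR)]


def default_true_params(tfs, mode: str = "direct") -> ModelParams:
    """Ground-truth parameters in a mid-occupancy, clearly patterned regime."""
    binding_k = {tf.name: 2.0 for tf in tfs}
    alpha = {tf.name: (4.0 if tf.is_activator else 0.1) for tf in tfs}
    beta = {tf.name: 5.0 for tf in tfs if tf.role == ROLE_REPRESSOR}
    return ModelParams(binding_k=binding_k, alpha=alpha, q_btm=0.03,
                       beta=beta, mode=mode)


@dataclass
class SimTruth:
    params: ModelParams
    consensi: dict
    site_plans: list = field(default_factory=list)


def _random_consensus(rng, width):
    return "".join(rng.choice(list(BASES), size=width))


def simulate_dataset(rng_seed: int, n_crms: int = 10, n_bins: int = 60,
                     crm_length: int = 1000, tf_specs=None,
                     true_params: ModelParams | None = None,
                     noise_sd: float = 0.0, pwm_width: int = 8,
                     specificity: float = 0.85,
                     site_threshold: float = 0.4,
                     mode: str = "direct"):
    """Full synthetic study: returns (Dataset, SimTruth).

    Observed profiles are the model's own predictions on the annotated
    sites under the ground-truth parameters, rescaled per CRM to max 1,
    plus truncated Gaussian noise clipped to [0, 1].  Byte-identical for a
    given seed.
    """
    rng = np.random.default_rng(rng_seed)
    tfs = list(tf_specs) if tf_specs is not None else default_tf_specs()
    params = true_params if true_params is not None \
        else default_true_params(tfs, mode)
    consensi = {}
    pwms = {}
    for tf in tfs:
        cons = _random_consensus(rng, pwm_width)
        consensi[tf.name] = cons
        pwms[tf.name] = make_pwm(cons, specificity, name=tf.name)
    conc = {}
    acts = [tf for tf in tfs if tf.is_activator]
    reps = [tf for tf in tfs if not tf.is_activator]
    for i, tf in enumerate(acts):
        kind = "anterior" if i % 2 == 0 else "posterior"
        conc[tf.name] = make_gradient(kind, n_bins, center=n_bins / 2,
                                      steepness=n_bins / 10)
    for i, tf in enumerate(reps):
        conc[tf.name] = make_gradient("stripe", n_bins,
                                      center=(i + 1) * n_bins / (len(reps) + 1),
                                      steepness=n_bins / 12)
    for tf in tfs:
        if tf.name not in conc:
            conc[tf.name] = make_gradient("flat", n_bins, level=0.5)
    roles = {tf.name: tf.role for tf in tfs}
    crms = []
    plans = []
    margin = 10
    for c in range(n_crms):
        # diverse compositions: each TF plants 0-3 sites, >=1 activator site
        while True:
            counts = {tf.name: int(rng.integers(0, 4)) for tf in tfs}
            if any(counts[tf.name] > 0 for tf in acts):
                break
        plan = []
        occupied = []
        for tf in tfs:
            for _ in range(counts[tf.name]):
                for _try in range(200):
                    pos = int(rng.integers(margin,
                                           crm_length - pwm_width - margin))
                    if all(pos + pwm_width <= s or pos >= e
                           for s, e in occupied):
                        occupied.append((pos, pos + pwm_width))
                        strength = float(rng.uniform(0.6, 1.0))
                        plan.append((tf.name, pos, strength))
                        break
        seq = make_crm(plan, crm_length, pwms,
                       rng_seed=int(rng.integers(0, 2 ** 31)))
        sites = annotate_sites(seq, list(pwms.values()), site_threshold)
        profile = predict_profile(sites, params, conc, roles)
        peak = profile.max()
        if peak > 1e-12:
            profile = profile / peak
        if noise_sd > 0:
            profile = np.clip(profile + rng.normal(0, noise_sd, n_bins),
                              0.0, 1.0)
        crms.append(CRM(name=f"crm{c:02d}", seq=seq, observed=profile))
        plans.append(plan)
    dataset = Dataset(crms=crms, tfs=tfs, conc=conc, pwms=pwms)
    return dataset, SimTruth(params=params, consensi=consensi,
                             site_plans=plans)


def worst_word(pwm: PWM) -> str:
    """The minimal-LLR word; useful for ablating a planted site."""
    return "".join(BASES[i] for i in pwm.llr_matrix.argmin(axis=1))


def make_ortholog_alignment(seq: str, species: int, mutation_rate: float,
                            planted_losses, rng_seed: int,
                            site_intervals=(), loss_words: dict | None = None):
    """Gap-free alignment of `species` orthologs of a CRM (reference first).

    Neutral substitutions outside the protected site_intervals occur at
    mutation_rate per position; planted sites stay intact except the
    planted_losses, given as (species_index, site_index) pairs, whose
    intervals are ablated (by the provided loss_words[site_index], or by
    random substitution of every base).  Returns [(name, seq), ...].
    """
    if species < 1:
        raise ValueError("species must be >= 1")
    rng = np.random.default_rng(rng_seed)
    intervals = [(int(s), int(e)) for s, e in site_intervals]
    protected = np.zeros(len(seq), dtype=bool)
    for s, e in intervals:
        protected[s:e] = True
    losses = {(int(sp), int(si)) for sp, si in planted_losses}
    out = [("species0", seq)]
    for sp in range(1, species):
        chars = list(seq)
        for i in range(len(seq)):
            if not protected[i] and rng.random() < mutation_rate:
                others = [b for b in BASES if b != chars[i]]
                chars[i] = others[int(rng.integers(0, 3))]
        for (lsp, si) in sorted(losses):
            if lsp != sp:
                continue
            s, e = intervals[si]
            if loss_words and si in loss_words:
                chars[s:e] = loss_words[si]
            else:
                for i in range(s, e):
                    others = [b for b in BASES if b != seq[i]]
                    chars[i] = others[int(rng.integers(0, 3))]
        out.append((f"species{sp}", "".join(chars)))
    return out
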