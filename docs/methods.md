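# Methods

`thermoseq` predicts the spatial expression readout of a cis-regulatory
module (CRM) from its sequence, the binding specificities (PWMs) of a set
of transcription factors, and those factors' concentration profiles, using
an equilibrium statistical-thermodynamic model of promoter occupancy.  This
note documents the model, its parameters and conventions, the numerical
choices, what the synthetic test bed does and does not emulate, and known
limitations.

## The model

Gene expression (on a relative 0–1 scale) is equated with the fractional
occupancy of the promoter by the basal transcriptional machinery (BTM).  A
*configuration* σ assigns a state to every annotated binding site.  Its
TF–DNA statistical weight W(σ) and TF–BTM weight Q(σ) determine

    Z_ON  = Σ_σ W(σ)·Q(σ)        (BTM bound)
    Z_OFF = Σ_σ W(σ)             (BTM unbound)
    expression = q_btm·Z_ON / (q_btm·Z_ON + Z_OFF)

where q_btm is the statistical weight of BTM binding at the promoter (the
empty configuration contributes weight 1 to both sums, so expression never
falls to zero; with no sites, expression is the basal q_btm/(1+q_btm)).

A bound site S contributes

    q(S) = (K(S_max)·ν) · [TF]_rel · exp(LLR(S) − LLR(S_max))

the Berg–von Hippel mismatch form: K(S_max) (association constant of the
strongest site) and the concentration normalization ν only ever appear as a
product, fitted as one free parameter per TF (`binding_k`).  [TF]_rel is
the factor's relative concentration in the current spatial bin.  Adjacent
bound sites (no bound site in between) of declared partner TFs within
`coop_range` bp (edge-to-edge, inclusive of abutting sites) multiply W by a
cooperativity weight ω.

Two repression mechanisms are implemented:

- **Direct interaction**: every bound TF contributes a factor α to Q —
  α > 1 for activators, α < 1 for repressors.
- **Short-range repression (quenching)**: a bound repressor does not touch
  the BTM.  Each repressor site is unbound, *bound-only* (inert), or
  *bound-effective*: the effective state multiplies W by β_R and renders
  all DNA within `d_r` bp (edge-to-edge) inaccessible to activator
  binding.  β_R → 0 removes repression; β_R → ∞ deletes every activator
  site in range.  Setting d_r ≈ 10 bp reduces quenching to pure
  competitive binding (only overlapping/adjacent sites are silenced); the
  `competition_mode` wrapper documents that hypothesis.

Multiple bound activators combine through the **limited-contact** rule: at
most `n_ma` bound activators contact the BTM simultaneously, and Q sums the
α-products of all nonempty contact subsets of size ≤ n_ma (configurations
with no bound activator have Q = 1 from the basal state).  `n_ma = 1` is
the additive model Q = Σα_i (no transcriptional synergy); `n_ma = ∞` is
implemented as forced full contact, the multiplicative model Q = Πα_i,
which produces synergy even without cooperative DNA binding.  The two
regimes are distinguishable at saturating activator concentration, where n
identical sites drive expression to q_btm·αⁿ/(q_btm·αⁿ+1) versus
q_btm·nα/(q_btm·nα+1).

## Site annotation

Sites are called on both strands wherever the log-likelihood-ratio score
against the background distribution exceeds `threshold_frac` (default 0.4)
times the score of the optimal word, strictly.  The background is uniform
by default and configurable.  Conventions: 0-based half-open coordinates on
the plus strand; windows containing N are skipped; at a tied score on both
strands the plus strand is kept.  PWMs read from count matrices receive a
pseudocount (default 0.5 per cell) before normalization; matrices already
in probabilities are used as given, with zeros floored at 1e-6 so LLRs stay
finite.

## Exact computation

Summing 2ⁿ configurations is done exactly by dynamic programming over the
nearest bound site to the left:

    Z_OFF(i) = q(i)·(1 + Σ_{j∈Φ(i)} ω(i,j)·Z_OFF(j))

with Φ(i) the non-overlapping sites left of i, and the analogous α-weighted
recurrence for Z_ON.  Because Φ(i) only grows as sites are processed in
start order, the sums are maintained as running prefix sums plus a bounded
backward scan for cooperativity corrections: runtime is linear in the site
count when `coop_range` is bounded (the acceptance harness measures ~2× time
per doubling of sites).  The limited-contact model adds a contact-count
dimension (0..n_ma); repressor-only configurations are tracked separately
because the zero-contact assignment is excluded once an activator is bound.

The SRR partition function is a forward DP whose state records only what
future sites can still see: the last bound site (overlap exclusion and
cooperativity adjacency), the last bound activator (it blocks a future
bound-effective repressor within d_r), and the last bound-effective
repressor (it blocks future activators) — each collapsed as soon as it
falls out of range, which keeps the state space small.  Among mutually
non-overlapping sites sorted by start, interval ends are also sorted, so
"last" is always "nearest", making the collapsed state sufficient.

Every DP is validated against direct enumeration (2ⁿ configurations, or
3^R·2^A site states with legitimacy filtering in SRR) to relative error
< 1e-9 on hundreds of randomized instances with overlapping sites, random
cooperativity and all parameter ranges; the enumeration oracles are
independent code paths built on per-configuration weights.

Numerical safety: all DP accumulators share a per-bin scale factor that is
renormalized whenever values approach 1e250.  Z_ON and Z_OFF are rescaled
together, so the scale cancels in the expression ratio and predictions stay
exact even when the raw partition functions overflow double precision
(SRR combines its two passes in log space for the same reason).

## Fitting

Free parameters: per-TF `binding_k` and α, q_btm, one ω per declared
cooperative pair, and per-repressor β in SRR mode.  Each is mapped to an
unconstrained coordinate through a logistic transform over a bounded box
(binding_k ∈ [1e-3, 1e3] and q_btm ∈ [1e-4, 1] on a log scale, activator
α ∈ (1, 100], repressor α ∈ [1e-3, 1), ω ∈ [1, 100], β ∈ [0, 100]), so role
constraints hold by construction.  Optimization runs seeded random restarts
(default 5, starts drawn log-uniformly in the boxes); each restart
alternates a Nelder–Mead simplex stage on the negative average Pearson
correlation with a quasi-Newton (BFGS, central-difference gradients, step
1e-4) stage on the scaled sum of squared errors, twice.  Defaults are 120
simplex and 30 BFGS iterations per stage, enough for the synthetic study to
converge to train CC ≈ 1 while keeping a full fit in the tens of seconds.

Objectives compare profile shapes, since expression data are on a relative
scale: Pearson CC is scale-invariant (a constant profile is assigned CC 0
rather than NaN, penalizing flat predictions), and the SSE objective fits a
free per-CRM scale s ≥ 0 in closed form (s = ⟨pred,obs⟩/⟨pred,pred⟩ clipped
at zero).  K-fold cross-validation (default 10) partitions CRMs by a seeded
shuffle, refits on each training split and averages held-out CC over all
CRMs; the partition is recorded because CVCC depends on it.

## Evaluation and comparison

`evaluate` reports per-CRM CC, the average, and the number of CRMs with
CC > 0.65 (strict) over a configurable bin window (use bins 20–80 of a
100-bin axis to restrict to the trunk of an embryo).  `knockdown` re-predicts
with one TF's concentration zeroed, without refitting.  `best_k_curve`
averages each model's K best CRM correlations for K = 1..n, with knock-down
companion curves computed over the same K CRMs as their parent model.
`compare_models` assesses the improvement of one model over another: per
CRM, a seeded bootstrap over bins resamples profiles and recomputes ΔCC,
giving a one-sided p; per-CRM p-values combine by Fisher's method.  This
bin-bootstrap + Fisher procedure is this package's own convention for the
significance of improvement, and its output is labeled as such.

## Conservation filters

Given a gap-aware alignment of orthologous CRMs (reference first), a
reference site is mapped through alignment columns and rescored in each
species with the same PWM, strand and threshold; a gapped or
non-contiguously mapped window counts as non-conserved.  The strict filter
keeps sites above threshold in all of the first n species; the
turnover-tolerant filter requires only m of n (default ⌈n/2⌉+1), so a
deeply conserved site that suffered one lineage-specific loss survives.
The m-of-n rule is this package's documented criterion for "significant"
conservation.

## Synthetic test bed

The generator emulates an anterior–posterior patterning study: 10 CRMs of
1 kb, 60-bin profiles, two activators on opposing sigmoid gradients and two
repressors on stripe gradients, 8-bp PWMs with 0.85 consensus probability,
and 0–3 planted sites per TF per CRM at 0.6–1.0 of the optimal LLR.
Ground-truth parameters (binding_k = 2, activator α = 4, repressor α = 0.1,
q_btm = 0.03, β = 5) put the system in a mid-occupancy regime with clearly
patterned profiles (typical per-CRM dynamic range ≳ 0.4).  Observed
profiles are the model's own predictions on the annotated sites, rescaled
to max 1 per CRM, optionally with truncated Gaussian noise.  Planted-site
words are consensus words greedily degraded one position at a time to just
above the target LLR fraction, so plants at strength ≥ 0.5 are recovered by
annotation at the 0.4 threshold.

What passing the recovery study shows: the full pipeline (annotate →
predict → fit → cross-validate) can re-identify its own generating readout
from noise-free data, and fails (ΔCC ≥ 0.3) when PWM columns are permuted —
a negative control for annotation-driven signal.  What it does not show:
identifiability of individual parameters (shape objectives leave
binding_k/α partly confounded, and no uniqueness is claimed), robustness to
real biological noise, or correctness of the biological assignments on any
real dataset; real gradients, overlapping heterotypic site architecture and
chromatin context are all richer than the generator.

## Known limitations and scope choices

- Monotone response to activator/repressor concentration and to β holds
  for non-overlapping, non-cooperative sites and is asserted there.  Under
  site overlap the model legitimately violates it: overlapping sites
  compete for DNA, so strengthening one binder can displace a stronger
  one (this is the competitive-binding mechanism, not an artifact).
- The neutral reduction (all α = 1 ⇒ basal output) holds in the
  multiplicative model; the additive convention Q = Σα gives Q = k for k
  bound neutral activators by construction.
- Repression strength does not decay with distance inside d_r (hard
  cutoff), and overlapping repression zones simply union.
- Kinetics of initiation/elongation, nucleosomes and chromatin state are
  outside the model; equilibrium occupancy is the only readout.
- Heterotypic cooperativity is supported by the engine (declare any TF
  pair) but not exercised by the default fitting studies.
- Intermediate n_ma (1 < n_ma < ∞) uses the nonempty-contact-subset sum
  stated above; the two printed extremes (additive, multiplicative) are
  the validated, recommended settings.
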