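# Methods

## Model

Counts Y (features d = 1..D, samples n = 1..N) are treated as a noisy
window onto true abundances W_dn, decomposed as composition times scale:
W_dn = W^Comp_dn · W^Tot_n, or on logs, log W_dn = log W^Comp_dn +
log W^Tot_n.  Sequencing informs W^Comp only; W^Tot is unidentifiable from
the counts and must be asserted.  All logarithms in this package are base 2.

**Composition.**  The uncertainty of the observed counts is modelled with
K Monte-Carlo draws per sample from Dirichlet(Y_·n + prior).  The prior
(default 0.5 per cell) keeps the posterior proper in the presence of zero
counts; it is a parameter, not a constant.  Each draw carries its log2
geometric mean, log2 G_n^(k), since the CLR's implicit scale assertion is
Ŵ^Tot_n = 1/G_n.

**Scale models.**  Draws of log2 Ŵ^Tot_n (a K × N matrix) come from one of:

- *default*: −log2 G_n^(k) + ε, ε ~ N(0, γ²) i.i.d. per sample and
  instance.  γ = 0 reproduces the CLR exactly; γ is the standard deviation
  of the scale noise on the log2 scale.  Values of 0.2–0.5 are realistic
  for most designs; γ > 1 triggers an advisory warning.  The Gaussian shape
  is drawn once per (instance, sample) and multiplied by γ, so γ sweeps on
  a fixed seed differ only in amplitude.
- *informed*: the default model plus per-sample offsets log2 μ_n, with μ
  given per group.  Only ratios of μ are identifiable, so μ is normalised
  by the reference group's value before use; consequently rescaling all μ
  by any c > 0 leaves every output bit-identical.
- *user*: draws N(log2 μ_n, γ²) that *replace* the −log2 G_n term, or a
  full user-supplied K × N matrix.  Both informed and user modes are
  supported because the field's practice is ambiguous about whether group
  offsets should shift or replace the geometric-mean term; the mode used is
  recorded in the output provenance.
- *naive*: the default model at γ = 1e−3, used to read off the scale
  estimate the CLR is implicitly making (means over instances per sample,
  then per group; the group contrast is reported in log2 and as a fold).

**Anchoring μ on references.**  `estimate_mu_from_reference` treats a set
of presumed-invariant (housekeeping) features as the log-ratio denominator:
compositions are sampled on the full table and the scale draw is the
negative log2 geometric mean over the reference features only.  If the
references really are invariant in absolute abundance, the group contrast
of these draws recovers the true scale ratio; this is the estimator the
recovery checks exercise.  A `method="submatrix"` variant (Dirichlet on the
reference submatrix, ordinary default-model draws) is also provided; it
responds only to compositional shifts *within* the reference set and
returns a ratio of 1 when the references are exactly invariant, so it is
not the default.  `lvha_reference` proposes a reference set
deterministically: CLR variance (single point estimate with prior) below
the 25th percentile and mean relative abundance above the 75th, boundary
ties included; both quantiles are exposed.

**Inference.**  Per instance k, log2 scaled abundances are
log2 Ŵ^Comp_dn^(k) + log2 Ŵ^Tot_n^(k).  Welch's unequal-variance t (with
Satterthwaite degrees of freedom) and the Wilcoxon rank-sum test run per
feature across samples; Benjamini–Hochberg step-up correction is applied
across features within the instance.  Expected p and q are means over
instances.  Expected q is the mean of per-instance q, not BH applied to
expected p: each instance is a complete analysis and the expectation is
taken last, which is what makes scale and count uncertainty flow into the
significance call.  Per-instance q ≥ p guarantees eq ≥ ep per feature.

Effect sizes are nonparametric.  Per instance, samples are paired by random
permutations of group indices recycled to the larger group size m:
Δbtw_i = b[σ(i)] − a[τ(i)] (non-reference minus reference);
Δwin_g,i = |g[π(i)] − g[π′(i)]| per group with independent pairings, and
Δwin = max(Δwin_A, Δwin_B) elementwise.  Medians pooled over all pairings
and instances give `diff_btw`, `diff_win`, and `effect` = median of
Δbtw / max(Δwin, 1e−8).  The floor guards degenerate draws; the number of
floored elements is recorded in provenance.  The exact pairing scheme of
the estimator this reconstructs is not published; this implementation
guarantees the estimator's invariances (location invariance, label-swap
antisymmetry, μ-ratio identifiability) rather than numerical parity with
any other code.  Pairing substreams are keyed by condition label, which
makes label-swap antisymmetry exact to the bit.

`mean_log2_abundance` is the mean CLR value across samples and instances
(composition only), so it is invariant to the scale model.

## Statistical kernels

Welch t, the rank-sum test and BH are vectorised over (features ×
instances) arrays.  The rank-sum null distribution for tie-free data with
min(n_A, n_B) ≤ 10 is exact, computed from the Gaussian-binomial
coefficient recurrence and cached per group-size pair; otherwise a Normal
approximation with continuity correction is used, with the rank variance
computed directly from midranks (equivalent to the classical tie
correction).  Degenerate conventions: both variances zero gives p = 1 when
means agree and p = 0 when they differ (Welch); all values tied gives
p = 1 (rank-sum).  scipy's implementations are used as independent oracles
in the test suite, never as the pipeline path.

## Seeds and reproducibility

Every stochastic stage draws from its own substream derived from the user
seed via `SeedSequence` spawn keys: Dirichlet draws are keyed per (seed,
stage, sample) with all K instances generated in one block, scale noise per
(seed, stage), effect-size pairings per (seed, stage, group label), and
benchmark replicates per (seed, stage, replicate).  Identical seeds give
bit-identical outputs; the Dirichlet draws for a sample do not depend on
which other samples are present.

## Sensitivity analysis

`sen_analysis` reuses one set of Dirichlet draws across the γ grid
(ascending, non-negative), so differences between grid points isolate the
scale model.  Per feature it reports the smallest γ at which significance
(eq_t ≤ q_max) is lost: ∞ if never lost, NaN (with `ever_significant` =
False) if never significant, and a `regained` flag when significance
reappears at a larger γ — no monotonicity is forced on the indicator.
Default grid {0, 0.1, 0.2, 0.5, 0.75, 1}, bracketing the recommended
0.2–0.5 band.

## Synthetic benchmark

`nb_backbone` generates gamma-Poisson (negative-binomial) counts: feature
absolute abundances log2-uniform over (0, 12); library sizes log-uniform
over 1–4M reads (deep enough that the bottom of the abundance range stays
at tens of counts — at shallower depth the Dirichlet prior flattens
between-group geometric-mean shifts and scale recovery degrades);
dispersion φ with variance m + φm² (default 0.3, biological-replicate
scale; 0 gives Poisson).  A designated invariant subset (default 2.5% of
features, placed near the top of the abundance range, as housekeeping
transcripts are) is identical in absolute abundance across groups.

A group scale offset cannot be a uniform multiplier — that would leave the
composition, the only thing counts retain, unchanged.  Instead the extra
total mass of the offset group is carried by a small set of high-abundance
"scale driver" features (default 1% of features), as in real systems where
load differences concentrate in a few dominant taxa or transcripts.  The
naive estimator then recovers the offset up to a bias of
(n_drivers · log2 F)/D, which the defaults keep well under 0.1 log2.

`spike_thinning` implants truth by binomial thinning with keep probability
q_dn = 2^(b_d·x_n − max(0, b_d)), which lies in (0, 1] for either sign of
b_d and leaves the modelled between-group log2 fold change at b_d in
expectation; non-spiked features are untouched bit-for-bit.  Default truth
design: 5% of features with b ~ N(0, 2).  `run_benchmark` permutes labels
(destroying any residual real signal), spikes, runs the pipeline per γ and
scores FDR = FP/calls (0 for no calls, reported with n_calls) and
sensitivity = TP found/all TP.  Stratified curves restrict the TP set to
|b_d| ≥ τ, counting called sub-threshold TPs as false positives (they are
modelled to change by less than the difference of interest); a signed
(b_d ≥ τ) stratification is emitted alongside since either axis convention
is defensible.  Default replicate count 10; tests and the acceptance script
use 3 at 2000 features × 10+10 samples to keep runs to a few seconds each.

The *technical replicate regime* (`technical_replicate_regime`) emulates
deeply sequenced technical growth replicates of two genuinely different
conditions: 1000 abundant features (log2 abundance 8–12), 8–12M-read
libraries, near-pure counting noise (φ = 5e−4), and 95% of features
carrying small real effects b ~ N(0, 0.12).  It was calibrated to the
regime's qualitative signature — a majority of features significant under a
scale-naive analysis despite negligible differences and very low
dispersion — and is the setting in which a small γ removes more than half
the significant calls.

## What the synthetic data does and does not show

The generator reproduces the count-statistical structure of sequencing
experiments (compositionality, depth variation, overdispersion, known
implanted effects) but not: batch effects, correlated feature blocks
(operons, co-regulation), zero-inflation beyond the NB, multi-factor
designs, or real biological scale processes.  Passing the benchmark shows
the inference machinery controls FDR and recovers implanted scale/effect
truth under the stated noise model; it does not certify any particular
choice of γ or μ for a real dataset, which remains an analyst's assumption
(that visibility being the point of explicit scale models).

## Numerical choices and conventions

- Monte-Carlo instances default K = 128; expected values stabilise quickly
  and K is exposed everywhere.
- Reference condition level: lexicographically first, overridable; all
  between-group quantities are non-reference minus reference.
- Pre-filter: only all-zero features are removed by default (the Dirichlet
  prior handles sporadic zeros); `min_total` is available and removals are
  logged and recorded.
- Composition draws are clipped away from exact zero at the float-tiny
  boundary and renormalised before taking logs.
- Results TSV is written at 10 significant digits and round-trips to 1e−9.
- Dual cutoff: eq ≤ q_max AND |diff_btw| ≥ min_abs_diff; the conventional
  fold-change line at log2 1.4 (~2.6-fold) is the default in plot exports.

## Known limitations

Two-group designs only; no covariates, pairing, or moderated variance
estimators.  The informed model assumes group-constant μ (per-sample μ is
accepted but rarely estimable).  Exact rank-sum p-values are only used for
tie-free data; thinning can only implant effects by removing counts, so
extremely low-count features carry little implantable signal.
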