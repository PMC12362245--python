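# ssda — scale-simulation differential abundance

High-throughput sequencing measures only the *relative* composition of a
sample: the total size of the system the sample came from (total mRNA,
microbial load) is destroyed by library preparation and sequencing depth.
Every normalisation used for differential abundance quietly asserts a value
for that lost total — the centred log-ratio (CLR) asserts the reciprocal of
the per-sample geometric mean, 1/G_n — and when the assertion is wrong the
analysis fails silently, typically by declaring most of the dataset
"significant".

`ssda` makes the scale assumption explicit and probabilistic.  Writing the
true abundances as W_dn = W^Comp_dn · W^Tot_n, it

1. models count uncertainty with Dirichlet Monte-Carlo draws of the
   composition, Ŵ^Comp ≈ Dir(Y + prior);
2. replaces the CLR's point assertion with a *scale model* for log2 Ŵ^Tot_n:
   the **default** model −log2 G_n + N(0, γ²) adds uncertainty only (γ = 0
   recovers the plain CLR exactly), while the **informed/user** models
   N(log2 μ_n, γ²) also shift the location by per-group multipliers μ whose
   ratio can be anchored on housekeeping features;
3. tests each Monte-Carlo instance (Welch t and Wilcoxon rank-sum per
   feature, Benjamini–Hochberg across features) and reports the *expected*
   p- and q-values over instances, together with nonparametric effect sizes
   (median between-group difference, within-group dispersion, standardized
   effect — all log2).

A benchmark harness generates negative-binomial backbones, destroys real
signal by label permutation, implants known log2 fold changes by binomial
thinning, and scores calls as FDR and sensitivity against that truth.  A
sensitivity analysis reruns inference over a γ grid to show which features
owe their significance to the absence of scale uncertainty.

Intended users: anyone doing two-group differential abundance/expression on
count tables (bulk or single-cell transcriptomics, metatranscriptomics,
microbiome) who wants FDR control that survives scale mis-specification.

## Worked example

Build a semi-synthetic dataset with known truth (500 features, 10 + 10
samples, 5% true positives with effects b ~ N(0, 2) implanted by binomial
thinning) and analyse it with and without scale uncertainty:

```python
from ssda import (nb_backbone, spike_thinning, run_da, ScaleModelSpec,
                  dual_cutoff)

cm, _ = nb_backbone(n_features=500, n_per_group=10, seed=10)
spiked, truth = spike_thinning(cm, tp_fraction=0.05, effect_sd=2.0, seed=11)

for gamma in (0.0, 0.5):
    rt = run_da(spiked, scale=ScaleModelSpec.default(gamma),
                n_instances=128, seed=12)
    calls = dual_cutoff(rt, q_max=0.05)
    tp = set(truth.tp_ids)
    print(gamma, len(calls), len(set(calls) - tp), len(set(calls) & tp))
```

prints

```
0.0 9 0 9
0.5 6 0 6
```

— at γ = 0 (plain CLR) nine features pass expected q ≤ 0.05, all true
positives; adding 0.5 SD of scale uncertainty keeps the FDR at zero and
trades three weak calls away.  The top of the γ = 0.5 results table:

```
feature_id  diff_btw  diff_win  effect   ep_t   eq_t   ep_w   eq_w  mean_log2_abundance
    f00420    3.2464    1.3298  2.5720 0.0000 0.0004 0.0000 0.0037               4.1239
    f00450   -3.4430    1.4309 -2.3751 0.0000 0.0010 0.0001 0.0094              -1.7012
    f00115   -3.3877    1.6116 -2.0719 0.0000 0.0010 0.0000 0.0047               2.0327
```

`diff_btw` is the log2 between-group difference (non-reference minus
reference), `diff_win` the within-group dispersion, `effect` their
standardized ratio; `ep_*`/`eq_*` are expected p/q for the Welch t and
Wilcoxon tests.

The same pipeline is available from the shell:

```sh
ssda run --counts counts.tsv --conditions cond.tsv --gamma 0.5 \
         --instances 128 --prior 0.5 --seed 7 --out results.tsv
ssda sensitivity --counts counts.tsv --conditions cond.tsv \
         --gammas 0,0.1,0.2,0.5 --out-prefix sen
ssda benchmark --tp-fraction 0.05 --effect-sd 2 --reps 10 \
         --gammas 0,0.2,0.5 --out bench.tsv
ssda plotdata --results results.tsv --naive-results naive.tsv \
         --lfc-line 1.4 --out plot.tsv
```

Every run writes a `.meta.yaml` sidecar with all parameters, seeds and the
scale assumption in effect, so results are exactly reproducible.

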