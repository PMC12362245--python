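"""Synthetic and semi-synthetic benchmarking with known truth.

The harness builds negative-binomial count backbones, destroys any real
group signal by permuting labels, implants known log2 fold changes by
binomial thinning, and scores caller output as FDR (false discoveries over
all calls) and sensitivity (true positives found over all implanted true
positives), overall and stratified by the minimum modelled difference.

Because counts only retain composition, a group scale offset cannot be
realised by multiplying every feature equally — that would leave the data
untouched.  Instead the extra total mass of the offset group is carried by
a small set of high-abundance "scale driver" features, mimicking ecosystems
(e.g. a bloom or a dominant taxon) where load differences are concentrated
in few features.  The designated invariant (housekeeping-like) features
keep the same absolute abundance in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import TAG_BACKBONE, TAG_BENCHMARK, TAG_PERMUTE, TAG_THINNING, substream
from .counts_io import CountMatrix
from .inference import dual_cutoff, run_da
from .scale import ScaleModelSpec


@dataclass
class BackboneTruth:
    """Ground truth of a synthetic backbone, for parameter-recovery tests."""

    true_totals: np.ndarray  # per-sample absolute system totals
    invariant_ids: list[str]
    scale_feature_ids: list[str]
    group_scale_log2_offset: float


@dataclass
class BenchmarkTruth:
    """Thinning truth: which features carry implanted differences and how big."""

    tp_ids: list[str]
    b: pd.Series  # per-feature modelled log2 fold change; 0 outside tp_ids
    design: np.ndarray  # per-sample binary indicator used for thinning
    params: dict = field(default_factory=dict)


@dataclass
class BenchmarkScore:
    fdr: float
    sensitivity: float
    n_calls: int
    stratified: pd.DataFrame  # per |b| threshold
    stratified_signed: pd.DataFrame  # per signed b threshold


def nb_backbone(
    n_features: int = 2000,
    n_per_group: int = 10,
    mean_log2_range: tuple[float, float] = (0.0, 12.0),
    dispersion: float = 0.3,
    lib_size_range: tuple[float, float] = (1_000_000, 4_000_000),
    group_scale_log2_offset: float = 0.0,
    n_invariant: int | None = None,
    n_scale_features: int | None = None,
    invariant_log2_abundance: float = 10.0,
    seed: int = 0,
) -> tuple[CountMatrix, BackboneTruth]:
    """Negative-binomial count backbone with known totals.

    Feature absolute abundances are log2-uniform over ``mean_log2_range``;
    the ``n_invariant`` housekeeping-like features sit near
    ``invariant_log2_abundance`` (housekeeping transcripts are abundant) and
    are identical in both groups.  Library sizes are uniform on the log
    scale over ``lib_size_range``.  Counts are gamma-Poisson with
    ``dispersion`` phi (variance m + phi m^2); phi = 0 gives Poisson.  A
    non-zero ``group_scale_log2_offset`` multiplies the second group's total
    by 2**offset, carried by ``n_scale_features`` drivers.
    """
    if n_features < 1 or n_per_group < 2:
        raise ValueError("need >= 1 feature and >= 2 samples per group")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lo, hi = mean_log2_range
    if not lo < hi:
        raise ValueError("mean_log2_range must be increasing")
    if not 0 < lib_size_range[0] <= lib_size_range[1]:
        raise ValueError("invalid lib_size_range")
    if n_invariant is None:  # 2.5% of features, housekeeping-like subset
        n_invariant = max(2, round(0.025 * n_features))
    if n_scale_features is None:  # 1% of features carry any scale offset
        n_scale_features = max(1, round(0.01 * n_features))
    if n_invariant + n_scale_features > n_features:
        raise ValueError("invariant + scale features exceed n_features")
    rng = substream(seed, TAG_BACKBONE)
    d, n = n_features, 2 * n_per_group
    u = rng.uniform(lo, hi, size=d)
    inv_idx = np.arange(n_invariant)
    u[inv_idx] = invariant_log2_abundance + rng.uniform(-0.5, 0.5, size=n_invariant)
    scale_idx = np.arange(n_invariant, n_invariant + n_scale_features)
    # put the scale drivers among the more abundant features so the extra
    # mass needs only a modest per-feature multiplier
    u[scale_idx] = np.maximum(u[scale_idx], 0.75 * hi)
    base = np.exp2(u)

    conditions = np.array(["g1"] * n_per_group + ["g2"] * n_per_group, dtype=object)
    abundance = np.tile(base[:, None], (1, n))
    offset = float(group_scale_log2_offset)
    if offset != 0.0:
        if n_scale_features < 1:
            raise ValueError("a non-zero scale offset needs n_scale_features >= 1")
        total0 = base.sum()
        extra = (2.0**offset - 1.0) * total0
        factor = 1.0 + extra / base[scale_idx].sum()
        if factor <= 0:
            raise ValueError("scale offset too negative for the driver feature mass")
        abundance[np.ix_(scale_idx, np.flatnonzero(conditions == "g2"))] *= factor
    true_totals = abundance.sum(axis=0)

    lib = np.exp(rng.uniform(np.log(lib_size_range[0]), np.log(lib_size_range[1]), size=n))
    mean = lib[None, :] * abundance / true_totals[None, :]
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    else:
        lam = mean
    counts = rng.poisson(lam)
    feature_ids = [f"f{i:05d}" for i in range(d)]
    sample_ids = [f"s{j:02d}" for j in range(n)]
    cm = CountMatrix(feature_ids, sample_ids, counts, conditions=conditions)
    truth = BackboneTruth(
        true_totals=true_totals,
        invariant_ids=[feature_ids[i] for i in inv_idx],
        scale_feature_ids=[feature_ids[i] for i in scale_idx],
        group_scale_log2_offset=offset,
    )
    return cm, truth


def technical_replicate_regime(
    seed: int = 0, n_features: int = 1000, n_per_group: int = 10
) -> tuple[CountMatrix, "BenchmarkTruth"]:
    """Low-dispersion "technical replicate" benchmark regime.

    Emulates deeply sequenced technical growth replicates of two genuinely
    different conditions: abundant features (log2 abundance 8-12), libraries
    of 8-12M reads, near-pure counting noise (dispersion 5e-4), and small
    real differences — 95% of features carry b ~ N(0, 0.12) implanted by
    thinning.  In this regime most features are significant under a
    scale-naive analysis despite negligible differences and very low
    dispersion, which is what scale uncertainty is meant to temper.
    """
    rng = substream(seed, TAG_BACKBONE, "technical")
    backbone_seed, spike_seed = (int(s) for s in rng.integers(2**31, size=2))
    cm, _ = nb_backbone(
        n_features=n_features,
        n_per_group=n_per_group,
        mean_log2_range=(8.0, 12.0),
        dispersion=5e-4,
        lib_size_range=(8e6, 1.2e7),
        n_invariant=2,
        n_scale_features=1,
        seed=backbone_seed,
    )
    return spike_thinning(cm, tp_fraction=0.95, effect_sd=0.12, seed=spike_seed)


def permute_labels(cm: CountMatrix, seed: int = 0) -> CountMatrix:
    """Uniformly random label reassignment preserving group sizes."""
    if cm.conditions is None:
        raise ValueError("count matrix has no conditions attached")
    if cm.n_samples < 4:
        raise ValueError("need at least 4 samples to permute")
    rng = substream(seed, TAG_PERMUTE)
    return cm.with_conditions(rng.permutation(cm.conditions), reference=cm.reference)


def spike_thinning(
    cm: CountMatrix,
    tp_fraction: float = 0.05,
    effect_sd: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, BenchmarkTruth]:
    """Implant known log2 fold changes by binomial thinning.

    ``round(tp_fraction * D)`` features get b_d ~ N(0, effect_sd^2); each
    cell is thinned with keep probability q_dn = 2^(b_d x_n - max(0, b_d)),
    which lies in (0, 1] for either sign of b_d and leaves the modelled
    between-group log2 fold change at b_d in expectation.  Non-TP features
    are untouched.
    """
    if not 0 < tp_fraction < 1:
        raise ValueError("tp_fraction must be in (0, 1)")
    if effect_sd <= 0:
        raise ValueError("effect_sd must be > 0")
    if cm.conditions is None:
        raise ValueError("count matrix has no conditions attached")
    rng = substream(seed, TAG_THINNING)
    d = cm.n_features
    n_tp = int(round(tp_fraction * d))
    tp_idx = rng.choice(d, size=n_tp, replace=False)
    b = np.zeros(d)
    b[tp_idx] = rng.normal(0.0, effect_sd, size=n_tp)
    x = cm.group_indicator()
    counts = cm.counts.copy()
    q = np.exp2(b[tp_idx, None] * x[None, :] - np.maximum(b[tp_idx, None], 0.0))
    counts[tp_idx, :] = rng.binomial(cm.counts[tp_idx, :], q)
    out = CountMatrix(
        list(cm.feature_ids), list(cm.sample_ids), counts,
        conditions=cm.conditions.copy(), reference=cm.reference,
    )
    truth = BenchmarkTruth(
        tp_ids=[cm.feature_ids[i] for i in sorted(tp_idx)],
        b=pd.Series(b, index=pd.Index(cm.feature_ids, name="feature_id"), name="b"),
        design=x,
        params={"tp_fraction": tp_fraction, "effect_sd": effect_sd, "seed": int(seed)},
    )
    return out, truth


def _rates(calls: set, tp: set) -> tuple[float, float]:
    n_calls = len(calls)
    fdr = len(calls - tp) / n_calls if n_calls else 0.0
    sens = len(calls & tp) / len(tp) if tp else 0.0
    return fdr, sens


def score_calls(
    calls, truth: BenchmarkTruth, min_abs_b_grid=(0.0, 0.5, 1.0, 1.5, 2.0)
) -> BenchmarkScore:
    """FDR and sensitivity of a call set, overall and by modelled difference.

    At threshold tau the true-positive set is restricted to features with
    |b_d| >= tau; called TP features below the threshold count as false
    positives (they are modelled to change by less than the difference of
    interest).  A signed stratification (b_d >= tau) is reported alongside.
    FDR of an empty call set is 0 and is reported with n_calls.
    """
    calls = set(calls)
    known = set(truth.b.index)
    unknown = calls - known
    if unknown:
        raise ValueError(f"call(s) not among truth features: {sorted(unknown)[:5]}")
    tp = set(truth.tp_ids)
    fdr, sens = _rates(calls, tp)
    is_tp = truth.b.index.isin(truth.tp_ids)
    rows_abs, rows_signed = [], []
    for tau in min_abs_b_grid:
        tp_abs = set(truth.b.index[(truth.b.abs() >= tau) & is_tp])
        f_a, s_a = _rates(calls, tp_abs)
        rows_abs.append({"min_abs_b": tau, "fdr": f_a, "sensitivity": s_a,
                         "n_tp": len(tp_abs), "n_calls": len(calls)})
        tp_sgn = set(truth.b.index[(truth.b >= tau) & is_tp])
        f_s, s_s = _rates(calls, tp_sgn)
        rows_signed.append({"min_b": tau, "fdr": f_s, "sensitivity": s_s,
                            "n_tp": len(tp_sgn), "n_calls": len(calls)})
    return BenchmarkScore(
        fdr=fdr,
        sensitivity=sens,
        n_calls=len(calls),
        stratified=pd.DataFrame(rows_abs),
        stratified_signed=pd.DataFrame(rows_signed),
    )


def run_benchmark(
    backbone: CountMatrix,
    n_reps: int = 10,
    tp_fraction: float = 0.05,
    effect_sd: float = 2.0,
    gammas=(0.0, 0.2, 0.5),
    q_max: float = 0.05,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    min_abs_b_grid=(0.0, 0.5, 1.0, 1.5, 2.0),
) -> pd.DataFrame:
    """Permute -> thin -> call -> score, repeated; per-gamma means and SEs.

    Each replicate permutes the backbone labels (destroying any real
    signal), implants thinning effects and runs the pipeline at every gamma
    with significance calls at ``eq_t <= q_max``.  Returns a tidy table with
    one row per (gamma, replicate) plus per-gamma summary rows
    (``replicate == "mean"`` / ``"se"``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rs = substream(seed, TAG_BENCHMARK)
    rep_seeds = rs.integers(2**31, size=(n_reps, 3))
    rows = []
    for r in range(n_reps):
        permuted = permute_labels(backbone, seed=int(rep_seeds[r, 0]))
        spiked, truth = spike_thinning(
            permuted, tp_fraction=tp_fraction, effect_sd=effect_sd, seed=int(rep_seeds[r, 1])
        )
        for g in gammas:
            rt = run_da(
                spiked,
                scale=ScaleModelSpec.default(g),
                n_instances=n_instances,
                prior=prior,
                seed=int(rep_seeds[r, 2]),
            )
            calls = dual_cutoff(rt, q_max=q_max, min_abs_diff=0.0)
            score = score_calls(calls, truth, min_abs_b_grid)
            rows.append(
                {"gamma": g, "replicate": r, "fdr": score.fdr,
                 "sensitivity": score.sensitivity, "n_calls": score.n_calls}
            )
    df = pd.DataFrame(rows)
    summaries = []
    for g, grp in df.groupby("gamma"):
        mean = grp[["fdr", "sensitivity", "n_calls"]].mean()
        se = grp[["fdr", "sensitivity", "n_calls"]].sem() if len(grp) > 1 else mean * 0.0
        summaries.append({"gamma": g, "replicate": "mean", **mean.to_dict()})
        summaries.append({"gamma": g, "replicate": "se", **se.to_dict()})
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
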