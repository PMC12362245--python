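"""Differential-abundance inference over Monte-Carlo instances.

Each Monte-Carlo instance of the log2 scaled abundances is analysed as if it
were a complete dataset: Welch's unequal-variance t-test and the Wilcoxon
rank-sum test per feature, with Benjamini–Hochberg correction across
features within the instance.  The reported p- and q-values are the means
over instances ("expected" values), so both count uncertainty (Dirichlet)
and scale uncertainty (gamma, mu) propagate into significance.

Effect sizes are nonparametric: the between-group difference, the
within-group dispersion and their standardized ratio are medians over
random pairings of samples, pooled across instances.  Sign convention:
between-group quantities are non-reference minus reference.

The statistical kernels are vectorized over (features x instances) arrays;
scipy's scalar implementations serve as cross-checks in the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special

from ._rng import TAG_EFFECT, substream
from .counts_io import RESULT_COLUMNS, CountMatrix
from .posterior import sample_compositions
from .scale import (
    ScaledAbundanceDraws,
    ScaleDraws,
    ScaleModelSpec,
    naive_scale_estimate,
    scale_draws_for,
)

__all__ = [
    "welch_t",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "expected_tests",
    "effect_sizes",
    "run_da",
    "dual_cutoff",
]

#: floor for the effect-size denominator in degenerate draws
EFFECT_DENOM_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# test statistics


def welch_t(group_a, group_b, axis: int = -1):
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided.

    Returns ``(t, df, p)``; ``t`` is mean(A) - mean(B) over its standard
    error.  Degenerate convention when both group variances are zero:
    p = 1 if the means are equal, else p = 0.
    """
    a = np.moveaxis(np.asarray(group_a, dtype=float), axis, -1)
    b = np.moveaxis(np.asarray(group_b, dtype=float), axis, -1)
    axis = -1
    na, nb = a.shape[-1], b.shape[-1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va, vb = a.var(axis=axis, ddof=1), b.var(axis=axis, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, 1.0, df)
    p = 2.0 * special.stdtr(df, -np.abs(t))
    p = np.where(degenerate, np.where(ma == mb, 1.0, 0.0), p)
    if np.ndim(p) == 0:
        return float(t), float(df), float(p)
    return t, df, p


@lru_cache(maxsize=64)
def _rank_sum_u_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the null Mann-Whitney U for group sizes (n1, n2), no ties.

    Counts are the coefficients of the Gaussian binomial coefficient
    C(n1+n2, n1)_q, built by iterated multiplication with
    (1 - q^(n2+i)) / (1 - q^i).
    """
    c = np.zeros(n1 * n2 + 1)
    c[0] = 1.0
    for i in range(1, n1 + 1):
        hi = n2 + i
        if hi < len(c):
            c[hi:] -= c[: len(c) - hi].copy()
        for u in range(i, len(c)):  # divide by (1 - q^i)
            c[u] += c[u - i]
    return np.cumsum(c) / c.sum()


def wilcoxon_rank_sum(group_a, group_b, axis: int = -1, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(W, p)`` where W is the rank sum of group A.  The exact null
    distribution is used when min(nA, nB) <= 10 and no ties are present;
    otherwise the Normal approximation with continuity and tie corrections.
    All values tied gives p = 1.
    """
    a = np.moveaxis(np.asarray(group_a, dtype=float), axis, -1)
    b = np.moveaxis(np.asarray(group_b, dtype=float), axis, -1)
    axis = -1
    na, nb = a.shape[-1], b.shape[-1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    n = na + nb
    pooled = np.concatenate([a, b], axis=-1)
    order = np.argsort(pooled, axis=-1)
    srt = np.take_along_axis(pooled, order, axis=-1)
    has_ties = bool((srt[..., 1:] == srt[..., :-1]).any())
    if has_ties:
        from scipy.stats import rankdata

        ranks = rankdata(pooled, axis=-1, method="average")
    else:
        ranks = np.empty_like(pooled)
        np.put_along_axis(
            ranks, order, np.broadcast_to(np.arange(1.0, n + 1), pooled.shape), axis=-1
        )
    r_a = ranks[..., :na].sum(axis=-1)
    u = r_a - na * (na + 1) / 2.0
    mn = na * nb
    if method == "exact" or (method == "auto" and min(na, nb) <= 10 and not has_ties):
        cdf = _rank_sum_u_cdf(na, nb)
        umin = np.minimum(u, mn - u).astype(np.int64)
        p = np.minimum(1.0, 2.0 * cdf[umin])
    else:
        # variance of the rank sum under sampling without replacement; exact
        # under midranks, so tie correction is built in
        rbar = (n + 1) / 2.0
        pop_var = (ranks**2).sum(axis=axis) / n - rbar**2
        var_ra = na * nb / (n - 1.0) * pop_var
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.abs(u - mn / 2.0) - 0.5) / np.sqrt(var_ra)
        p = np.where(var_ra > 0, np.minimum(1.0, 2.0 * special.ndtr(-z)), 1.0)
    if np.ndim(p) == 0:
        return float(r_a), float(p)
    return r_a, p


def bh_adjust(p, axis: int = 0) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values along ``axis``; order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    squeeze = p.ndim == 1
    if squeeze:
        p = p[:, None]
        axis = 0
    p = np.moveaxis(p, axis, 0)
    m = p.shape[0]
    order = np.argsort(p, axis=0, kind="stable")
    ps = np.take_along_axis(p, order, axis=0)
    q = ps * (m / np.arange(1, m + 1)).reshape((m,) + (1,) * (p.ndim - 1))
    q = np.minimum.accumulate(q[::-1], axis=0)[::-1]
    np.clip(q, 0.0, 1.0, out=q)
    out = np.empty_like(q)
    np.put_along_axis(out, order, q, axis=0)
    out = np.moveaxis(out, 0, axis)
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Monte-Carlo aggregation


def _group_arrays(sad: ScaledAbundanceDraws, conditions, reference):
    conditions = np.asarray(conditions, dtype=object)
    levels = sorted(set(conditions))
    ref = reference if reference is not None else levels[0]
    other = next(l for l in levels if l != ref)
    a = sad.values[:, conditions == ref, :]
    b = sad.values[:, conditions == other, :]
    return a, b, ref, other


def expected_tests(
    sad: ScaledAbundanceDraws, conditions, reference: str | None = None
) -> dict:
    """Expected p and BH q per feature for Welch-t and Wilcoxon tests.

    For every instance both tests run per feature across samples and BH is
    applied across features within the instance; the expected values are the
    means over instances.
    """
    a, b, _, _ = _group_arrays(sad, conditions, reference)
    # (D, K, n) contiguous layout: the sample axis is the hot axis
    a = np.ascontiguousarray(np.swapaxes(a, 1, 2))
    b = np.ascontiguousarray(np.swapaxes(b, 1, 2))
    _, _, p_t = welch_t(b, a, axis=-1)  # (D, K)
    _, p_w = wilcoxon_rank_sum(b, a, axis=-1)
    q_t = bh_adjust(p_t, axis=0)
    q_w = bh_adjust(p_w, axis=0)
    return {
        "ep_t": p_t.mean(axis=1),
        "eq_t": q_t.mean(axis=1),
        "ep_w": p_w.mean(axis=1),
        "eq_w": q_w.mean(axis=1),
    }


def _paired_indices(rng, n_group: int, m: int, k: int) -> np.ndarray:
    """Random permutations of indices 0..n_group-1 recycled to length m, per instance."""
    base = np.tile((np.arange(m) % n_group)[:, None], (1, k))
    return rng.permuted(base, axis=0)


def effect_sizes(
    sad: ScaledAbundanceDraws,
    conditions,
    seed: int,
    reference: str | None = None,
    denom_floor: float = EFFECT_DENOM_FLOOR,
) -> dict:
    """Nonparametric difference, dispersion and standardized effect.

    Per instance, samples of the two groups are randomly paired (indices
    recycled to the larger group size m): the between-group difference is
    the paired non-reference minus reference value; the dispersion is the
    elementwise maximum of the absolute within-group differences under an
    independent random pairing per group.  Medians pooled over all pairings
    and instances give diff_btw, diff_win and effect = median of the
    elementwise standardized ratio, with the denominator floored at
    ``denom_floor``.

    Pairing substreams are keyed by condition label so that swapping which
    level is the reference negates diff_btw and effect exactly.
    """
    conditions = np.asarray(conditions, dtype=object)
    a, b, ref, other = _group_arrays(sad, conditions, reference)
    d, na, k = a.shape
    nb = b.shape[1]
    m = max(na, nb)
    idx = {}
    for label, n_group in ((ref, na), (other, nb)) if ref < other else ((other, nb), (ref, na)):
        rng = substream(seed, TAG_EFFECT, label)
        idx[label] = [
            _paired_indices(rng, n_group, m, k),  # between-group pairing
            _paired_indices(rng, n_group, m, k),  # within pairing pi
            _paired_indices(rng, n_group, m, k),  # within pairing pi'
        ]
    kk = np.arange(k)[None, :]
    d_btw = b[:, idx[other][0], kk] - a[:, idx[ref][0], kk]
    win_a = np.abs(a[:, idx[ref][1], kk] - a[:, idx[ref][2], kk])
    win_b = np.abs(b[:, idx[other][1], kk] - b[:, idx[other][2], kk])
    d_win = np.maximum(win_a, win_b)
    ratio = d_btw / np.maximum(d_win, denom_floor)
    n_floored = int(np.count_nonzero(d_win < denom_floor))
    return {
        "diff_btw": np.median(d_btw.reshape(d, -1), axis=1),
        "diff_win": np.median(d_win.reshape(d, -1), axis=1),
        "effect": np.median(ratio.reshape(d, -1), axis=1),
        "n_denominator_floored": n_floored,
    }


# ---------------------------------------------------------------------------
# orchestration


def run_da(
    cm: CountMatrix,
    scale: ScaleModelSpec | None = None,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    scale_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full pipeline: Dirichlet draws -> scale draws -> tests + effects.

    Parameters
    ----------
    scale
        Scale model specification; defaults to the uncertainty-only model
        with gamma = 0.5.
    scale_matrix
        Optional user-supplied (n_instances x n_samples) matrix of log2
        scale draws, overriding ``scale``.

    Returns a results table (one row per feature, columns as in
    ``counts_io.RESULT_COLUMNS``) with full provenance in ``.attrs``.
    """
    if cm.conditions is None:
        raise ValueError("count matrix has no conditions attached")
    if scale is None:
        scale = ScaleModelSpec.default(0.5)
    cd = sample_compositions(cm, n_instances=n_instances, prior=prior, seed=seed)
    log2_comp = np.log2(cd.values)
    if scale_matrix is not None:
        scale_matrix = np.asarray(scale_matrix, dtype=float)
        if scale_matrix.shape != (n_instances, cm.n_samples):
            raise ValueError(
                f"scale matrix must be {n_instances} instances x {cm.n_samples} samples"
            )
        sd = ScaleDraws(scale_matrix, ScaleModelSpec(mode="user", gamma=0.0, mu={}), seed)
    else:
        sd = scale_draws_for(scale, cd, cm.conditions, seed, cm.reference)
    # same combination as apply_scale, reusing the log2 composition pass
    sad = ScaledAbundanceDraws(
        log2_comp + sd.log2_values.T[None, :, :],
        {"prior": cd.prior, "gamma": sd.spec.gamma, "mode": sd.spec.mode,
         "composition_seed": cd.seed, "scale_seed": sd.seed},
    )
    tests = expected_tests(sad, cm.conditions, cm.reference)
    effects = effect_sizes(sad, cm.conditions, seed, cm.reference)
    clr = log2_comp - cd.log2_geo_mean[None, :, :]
    rt = pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "diff_btw": effects["diff_btw"],
            "diff_win": effects["diff_win"],
            "effect": effects["effect"],
            "ep_t": tests["ep_t"],
            "eq_t": tests["eq_t"],
            "ep_w": tests["ep_w"],
            "eq_w": tests["eq_w"],
            "mean_log2_abundance": clr.mean(axis=(1, 2)),
        },
        columns=RESULT_COLUMNS,
    )
    est = naive_scale_estimate(sd, cm.conditions, cm.reference)
    rt.attrs["provenance"] = {
        "mode": sd.spec.mode,
        "gamma": float(sd.spec.gamma),
        "prior": float(prior),
        "n_instances": int(n_instances),
        "seed": int(seed),
        "reference": cm.reference,
        "levels": list(cm.levels),
        "scale_estimate_per_group": est.per_group,
        "scale_diff_log2": est.diff_log2,
        "n_denominator_floored": effects["n_denominator_floored"],
    }
    return rt


def dual_cutoff(
    rt: pd.DataFrame, q_max: float = 0.05, min_abs_diff: float = 0.0, test: str = "t"
) -> list[str]:
    """Features passing both the expected-q and |difference| cutoffs."""
    if not 0 < q_max <= 1:
        raise ValueError("q_max must be in (0, 1]")
    if min_abs_diff < 0:
        raise ValueError("min_abs_diff must be >= 0")
    qcol = {"t": "eq_t", "w": "eq_w"}[test]
    sel = (rt[qcol] <= q_max) & (rt["diff_btw"].abs() >= min_abs_diff)
    return rt.loc[sel, "feature_id"].tolist()
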