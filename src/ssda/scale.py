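"""Probabilistic scale models.

Sequencing destroys the total size of the sampled system (total mRNA,
microbial load).  Any normalisation implicitly asserts a value for that
lost total; the CLR asserts the reciprocal of the per-sample geometric mean
composition, 1/G_n.  This module replaces the point assertion with a
probability model over log2 totals:

* ``default`` — mean -log2 G_n, spread gamma: uncertainty only, recovering
  the plain CLR exactly at gamma = 0;
* ``informed`` — the default model shifted by per-group log2 mu offsets;
* ``user``    — draws N(log2 mu_n, gamma^2) that replace -log2 G_n, or a
  full user-supplied draw matrix;
* ``naive``   — the default model at gamma = 1e-3, used to read off the
  scale estimate the CLR is implicitly making.

Only ratios of mu between groups are identifiable, so mu is normalised to
the reference group internally.  All logarithms are base 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import TAG_SCALE, substream
from .counts_io import CountMatrix
from .posterior import CompositionDraws, sample_compositions

#: gamma used by the naive model; small but non-zero so draws populate
NAIVE_GAMMA = 1e-3

#: analyst guidance: log2-scale noise beyond this is unusually large
GAMMA_ADVISORY = 1.0


def _check_gamma(gamma: float) -> float:
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma > GAMMA_ADVISORY:
        warnings.warn(
            f"gamma={gamma} exceeds {GAMMA_ADVISORY}; values of 0.2-0.5 are "
            "realistic for most designs",
            UserWarning,
            stacklevel=3,
        )
    return float(gamma)


@dataclass
class ScaleModelSpec:
    """Declarative description of a scale model.

    mode
        One of ``naive``, ``default``, ``informed``, ``user``.
    gamma
        Standard deviation, on the log2 scale, of the scale noise.
    mu
        Per-group scale multipliers ``{level: mu}`` (informed/user modes) or
        a per-sample array.  Dimensionless; only ratios matter.
    """

    mode: str = "default"
    gamma: float = 0.5
    mu: dict | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"naive", "default", "informed", "user"}:
            raise ValueError(f"unknown scale model mode {self.mode!r}")
        if self.mode == "naive":
            self.gamma = NAIVE_GAMMA
            self.mu = None
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.mode in {"informed", "user"} and self.mu is None:
            raise ValueError(f"mode={self.mode!r} requires mu")
        if isinstance(self.mu, dict) and any(v <= 0 for v in self.mu.values()):
            raise ValueError("all mu must be > 0")

    @classmethod
    def naive(cls) -> "ScaleModelSpec":
        return cls(mode="naive")

    @classmethod
    def default(cls, gamma: float = 0.5) -> "ScaleModelSpec":
        return cls(mode="default", gamma=gamma)

    @classmethod
    def informed(cls, mu, gamma: float = 0.5) -> "ScaleModelSpec":
        return cls(mode="informed", gamma=gamma, mu=mu)

    @classmethod
    def user(cls, mu, gamma: float = 0.5) -> "ScaleModelSpec":
        return cls(mode="user", gamma=gamma, mu=mu)


@dataclass
class ScaleDraws:
    """Monte-Carlo draws of log2 total scale, instances x samples."""

    log2_values: np.ndarray  # (n_instances, n_samples)
    spec: ScaleModelSpec
    seed: int

    def __post_init__(self) -> None:
        self.log2_values = np.asarray(self.log2_values, dtype=float)
        if self.log2_values.ndim != 2:
            raise ValueError("scale draws must be instances x samples")
        if not np.all(np.isfinite(self.log2_values)):
            raise ValueError("scale draws must be finite")


@dataclass
class ScaledAbundanceDraws:
    """Log2 scaled-abundance draws, features x samples x instances."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class ScaleEstimate:
    """Per-sample / per-group mean log2 scale with the group contrast."""

    per_sample: np.ndarray
    per_group: dict
    diff_log2: float  # non-reference minus reference
    fold: float  # 2 ** diff_log2


def _log2_mu_per_sample(mu, conditions, reference) -> np.ndarray:
    """Resolve mu to per-sample log2 offsets, normalised to the reference group."""
    conditions = np.asarray(conditions, dtype=object)
    if isinstance(mu, dict):
        levels = sorted(set(conditions))
        missing = [l for l in mu if l not in levels]
        if missing:
            raise ValueError(f"mu group label(s) {missing} absent from conditions")
        absent = [l for l in levels if l not in mu]
        if absent:
            raise ValueError(f"mu missing for group(s) {absent}")
        ref = reference if reference is not None else levels[0]
        norm = {l: v / mu[ref] for l, v in mu.items()}
        return np.array([np.log2(norm[l]) for l in conditions])
    mu = np.asarray(mu, dtype=float)
    if mu.shape != conditions.shape:
        raise ValueError("per-sample mu length must match conditions")
    if np.any(mu <= 0):
        raise ValueError("all mu must be > 0")
    levels = sorted(set(conditions))
    ref = reference if reference is not None else levels[0]
    ref_geo = np.exp2(np.mean(np.log2(mu[conditions == ref])))
    return np.log2(mu / ref_geo)


def default_scale(cd: CompositionDraws, gamma: float, seed: int) -> ScaleDraws:
    """Scale draws centred on the CLR assumption: -log2 G_n + N(0, gamma^2).

    gamma = 0 reproduces the CLR exactly.  The Gaussian perturbation is drawn
    once per (instance, sample) from a dedicated substream and multiplied by
    gamma, so sweeps over gamma on a fixed seed share the same noise shape.
    """
    gamma = _check_gamma(gamma)
    k, n = cd.n_instances, cd.n_samples
    eps = gamma * substream(seed, TAG_SCALE).standard_normal((k, n))
    log2_values = -cd.log2_geo_mean.T + eps
    return ScaleDraws(log2_values, ScaleModelSpec(mode="default", gamma=gamma), int(seed))


def make_scale_matrix(
    mu,
    gamma: float,
    conditions,
    n_instances: int,
    seed: int,
    reference: str | None = None,
) -> ScaleDraws:
    """Draw a full scale matrix from the log-normal model N(log2 mu_n, gamma^2).

    These draws *replace* the -log2 G_n term (user mode).  mu is given per
    group (dict) or per sample (array) and is normalised to the reference
    group before drawing, since only ratios are identifiable.
    """
    gamma = _check_gamma(gamma)
    log2_mu = _log2_mu_per_sample(mu, conditions, reference)
    n = len(log2_mu)
    eps = gamma * substream(seed, TAG_SCALE).standard_normal((n_instances, n))
    spec = ScaleModelSpec(mode="user", gamma=gamma, mu=mu if isinstance(mu, dict) else np.asarray(mu))
    return ScaleDraws(log2_mu[None, :] + eps, spec, int(seed))


def informed_scale(
    cd: CompositionDraws,
    mu,
    gamma: float,
    conditions,
    seed: int,
    reference: str | None = None,
) -> ScaleDraws:
    """Default model shifted by per-group log2 mu offsets (informed mode)."""
    base = default_scale(cd, gamma, seed)
    log2_mu = _log2_mu_per_sample(mu, conditions, reference)
    spec = ScaleModelSpec(mode="informed", gamma=base.spec.gamma, mu=mu)
    return ScaleDraws(base.log2_values + log2_mu[None, :], spec, int(seed))


def scale_draws_for(
    spec: ScaleModelSpec,
    cd: CompositionDraws,
    conditions,
    seed: int,
    reference: str | None = None,
) -> ScaleDraws:
    """Dispatch a ScaleModelSpec to the matching draw constructor."""
    if spec.mode in {"naive", "default"}:
        sd = default_scale(cd, spec.gamma, seed)
        sd.spec = spec
        return sd
    if spec.mode == "informed":
        return informed_scale(cd, spec.mu, spec.gamma, conditions, seed, reference)
    return make_scale_matrix(spec.mu, spec.gamma, conditions, cd.n_instances, seed, reference)


def apply_scale(cd: CompositionDraws, sd: ScaleDraws) -> ScaledAbundanceDraws:
    """Combine composition and scale: log2 W = log2 W_comp + log2 W_tot."""
    k, n = sd.log2_values.shape
    if (cd.n_samples, cd.n_instances) != (n, k):
        raise ValueError(
            f"shape mismatch: composition {cd.n_samples} samples x {cd.n_instances} "
            f"instances, scale {n} x {k}"
        )
    values = np.log2(cd.values) + sd.log2_values.T[None, :, :]
    prov = {"prior": cd.prior, "gamma": sd.spec.gamma, "mode": sd.spec.mode,
            "composition_seed": cd.seed, "scale_seed": sd.seed}
    return ScaledAbundanceDraws(values, prov)


def naive_scale_estimate(sd: ScaleDraws, conditions, reference: str | None = None) -> ScaleEstimate:
    """Mean log2 scale per sample and per group, with the group contrast.

    Averaging the rows of the scale matrix gives each sample's estimate; group
    means follow.  The group difference (non-reference minus reference) is
    reported in log2 and as a fold change.
    """
    conditions = np.asarray(conditions, dtype=object)
    per_sample = sd.log2_values.mean(axis=0)
    levels = sorted(set(conditions))
    per_group = {l: float(per_sample[conditions == l].mean()) for l in levels}
    ref = reference if reference is not None else levels[0]
    other = next(l for l in levels if l != ref)
    diff = per_group[other] - per_group[ref]
    return ScaleEstimate(per_sample, per_group, float(diff), float(2.0**diff))


def estimate_mu_from_reference(
    cm: CountMatrix,
    reference_ids,
    gamma: float = 0.5,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    method: str = "denominator",
) -> dict:
    """Estimate per-group mu from presumed-invariant (housekeeping) features.

    method="denominator" (default): compositions are sampled on the full
    table and the scale draw is the negative log2 geometric mean over the
    reference features only — the reference set acts as the CLR denominator.
    If the reference features are truly invariant in absolute abundance this
    recovers the between-group scale ratio.

    method="submatrix": compositions are sampled on the reference-feature
    submatrix and the ordinary default-model scale draws are averaged.  This
    responds only to compositional shifts *within* the reference set.

    Returns ``{level: mu}`` with the reference group's mu fixed at 1.
    """
    reference_ids = list(reference_ids)
    if len(reference_ids) < 2:
        raise ValueError("need at least 2 reference features")
    unknown = [f for f in reference_ids if f not in set(cm.feature_ids)]
    if unknown:
        raise ValueError(f"reference feature(s) not in the table: {unknown}")
    if cm.conditions is None:
        raise ValueError("count matrix has no conditions attached")
    mask = np.isin(np.asarray(cm.feature_ids, dtype=object), reference_ids)
    if method == "denominator":
        cd = sample_compositions(cm, n_instances=n_instances, prior=prior, seed=seed)
        geo_ref = np.log2(cd.values[mask]).mean(axis=0)  # (N, K)
        eps = _check_gamma(gamma) * substream(seed, TAG_SCALE).standard_normal(
            (cd.n_instances, cd.n_samples)
        )
        sd = ScaleDraws(-geo_ref.T + eps, ScaleModelSpec(mode="default", gamma=gamma), seed)
    elif method == "submatrix":
        sub = cm.select_features(mask)
        cd = sample_compositions(sub, n_instances=n_instances, prior=prior, seed=seed)
        sd = default_scale(cd, gamma, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    est = naive_scale_estimate(sd, cm.conditions, cm.reference)
    ref, other = cm.levels
    return {ref: 1.0, other: float(2.0 ** (est.per_group[other] - est.per_group[ref]))}


def lvha_reference(
    cm: CountMatrix,
    var_quantile: float = 0.25,
    abund_quantile: float = 0.75,
    prior: float = 0.5,
) -> list[str]:
    """Low-variance, high-abundance feature set for use as a reference.

    Computed on a single point estimate: proportions (Y + prior) column-
    normalised, CLR variance across samples below the ``var_quantile``
    quantile AND mean relative abundance above the ``abund_quantile``
    quantile.  Boundary ties are included.  Deterministic.
    """
    for q in (var_quantile, abund_quantile):
        if not 0 <= q <= 1:
            raise ValueError("quantiles must be in [0, 1]")
    p = cm.counts.astype(float) + prior
    p /= p.sum(axis=0, keepdims=True)
    clr = np.log2(p) - np.log2(p).mean(axis=0, keepdims=True)
    clr_var = clr.var(axis=1, ddof=1)
    mean_ab = p.mean(axis=1)
    keep = (clr_var <= np.quantile(clr_var, var_quantile)) & (
        mean_ab >= np.quantile(mean_ab, abund_quantile)
    )
    if not keep.any():
        raise ValueError(
            "no feature is both low-variance and high-abundance at these "
            "quantiles; loosen var_quantile/abund_quantile"
        )
    return [f for f, k in zip(cm.feature_ids, keep) if k]
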