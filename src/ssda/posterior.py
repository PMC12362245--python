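"""Dirichlet Monte-Carlo modelling of the composition.

Sequencing retains only the relative proportions of features within each
sample.  The count column of sample ``n`` is treated as a multinomial
realisation, and the uncertainty of the underlying composition is
represented by K Monte-Carlo draws from Dirichlet(Y_.n + prior).  Each draw
lives on the simplex; its log2 geometric mean is carried along because the
CLR's implicit total-scale assumption is exactly its reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import TAG_DIRICHLET, substream
from .counts_io import CountMatrix


@dataclass
class CompositionDraws:
    """Monte-Carlo draws of the composition.

    values
        (n_features, n_samples, n_instances) array; every (sample, instance)
        column is strictly positive and sums to one.
    log2_geo_mean
        (n_samples, n_instances) array of per-draw log2 geometric means.
    """

    values: np.ndarray
    log2_geo_mean: np.ndarray
    prior: float
    seed: int

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_instances(self) -> int:
        return self.values.shape[2]


def sample_compositions(
    cm: CountMatrix, n_instances: int = 128, prior: float = 0.5, seed: int = 0
) -> CompositionDraws:
    """Draw composition instances from Dirichlet(Y_.n + prior) per sample.

    Draws are generated by gamma normalisation, independently across samples
    and instances.  Each sample consumes its own seed substream, so results
    do not depend on how many other samples are processed alongside it.

    Parameters
    ----------
    n_instances
        Number of Monte-Carlo instances K (default 128).
    prior
        Per-cell pseudo-count added to every count; must be positive unless
        every feature of every sample has a non-zero count.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if prior < 0:
        raise ValueError("prior must be non-negative")
    d, n = cm.counts.shape
    alpha = cm.counts.astype(float) + prior
    if np.any(alpha.sum(axis=0) <= 0):
        raise ValueError("sample with zero total count and prior=0: degenerate Dirichlet")
    if np.any(alpha <= 0):
        raise ValueError("zero counts require a positive prior")
    values = np.empty((d, n, n_instances))
    for j in range(n):
        rng = substream(seed, TAG_DIRICHLET, j)
        g = rng.standard_gamma(alpha[:, j, None], size=(d, n_instances))
        values[:, j, :] = g / g.sum(axis=0, keepdims=True)
    # guard against underflow to exact zero in extreme columns
    tiny = np.finfo(float).tiny
    np.clip(values, tiny, None, out=values)
    values /= values.sum(axis=0, keepdims=True)
    log2_geo_mean = np.log2(values).mean(axis=0)
    return CompositionDraws(values, log2_geo_mean, float(prior), int(seed))


def geo_means(cd: CompositionDraws) -> np.ndarray:
    """Log2 geometric means per (sample, instance); pure function of values."""
    return np.log2(cd.values).mean(axis=0)
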