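"""Count-table and condition I/O.

The entry point of the pipeline is a feature x sample table of non-negative
integer read counts (features in rows, header row of sample IDs, first
column of feature IDs) together with a two-level condition assignment.
Counts are kept as integers; proportions and log values are always derived
downstream, never persisted in the input format.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: stable column order of the results table
RESULT_COLUMNS = [
    "feature_id",
    "diff_btw",
    "diff_win",
    "effect",
    "ep_t",
    "eq_t",
    "ep_w",
    "eq_w",
    "mean_log2_abundance",
]


class ValidationError(ValueError):
    """Raised when an input table violates the count-matrix contract."""


@dataclass
class CountMatrix:
    """Observed counts ``Y`` (features x samples) with two-group labels.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique row / column identifiers.
    counts
        Non-negative integer array of shape (n_features, n_samples).
    conditions
        Optional length-N two-level labels, one per sample.
    reference
        Reference condition level.  Defaults to the lexicographically first
        level.  Sign convention downstream: between-group differences are
        reported as non-reference minus reference.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    conditions: np.ndarray | None = None
    reference: str | None = None
    removed_features: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        d, n = self.counts.shape
        if d < 1 or n < 2:
            raise ValidationError(f"need at least 1 feature and 2 samples, got {d} x {n}")
        if len(self.feature_ids) != d or len(self.sample_ids) != n:
            raise ValidationError("ID lists do not match the counts dimensions")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValidationError(f"duplicate {name} IDs: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            flo = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(flo)) or np.any(flo != np.floor(flo)):
                bad = np.argwhere(~np.isfinite(flo) | (flo != np.floor(flo)))
                d0, n0 = bad[0]
                raise ValidationError(
                    f"non-integer count for feature {self.feature_ids[d0]!r}, "
                    f"sample {self.sample_ids[n0]!r}"
                )
            self.counts = flo.astype(np.int64)
        if np.any(self.counts < 0):
            d0, n0 = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for feature {self.feature_ids[d0]!r}, "
                f"sample {self.sample_ids[n0]!r}"
            )
        if self.conditions is not None:
            self.conditions = np.asarray(self.conditions, dtype=object)
            self._check_conditions()

    def _check_conditions(self) -> None:
        if len(self.conditions) != self.n_samples:
            raise ValidationError("conditions length does not match sample count")
        levels = sorted(set(self.conditions))
        if len(levels) != 2:
            raise ValidationError(
                f"two-group only: found {len(levels)} condition level(s) {levels}"
            )
        for lev in levels:
            if int(np.sum(self.conditions == lev)) < 2:
                raise ValidationError(f"condition level {lev!r} has fewer than 2 samples")
        if self.reference is None:
            self.reference = levels[0]
        elif self.reference not in levels:
            raise ValidationError(f"reference level {self.reference!r} not among {levels}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def levels(self) -> tuple[str, str]:
        """(reference level, non-reference level)."""
        if self.conditions is None:
            raise ValidationError("no conditions attached")
        other = next(l for l in sorted(set(self.conditions)) if l != self.reference)
        return self.reference, other

    def group_indicator(self) -> np.ndarray:
        """Binary indicator x_n: 0 for the reference group, 1 otherwise."""
        ref, _ = self.levels
        return (self.conditions != ref).astype(np.int64)

    def with_conditions(self, conditions, reference: str | None = None) -> "CountMatrix":
        return replace(
            self, conditions=np.asarray(conditions, dtype=object), reference=reference
        )

    def select_features(self, keep: np.ndarray) -> "CountMatrix":
        """Subset to the boolean mask or index array ``keep`` (feature axis)."""
        keep = np.asarray(keep)
        ids = [self.feature_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool \
            else [self.feature_ids[i] for i in keep]
        return replace(self, feature_ids=ids, counts=self.counts[keep])


def read_counts(path: str | os.PathLike, delimiter: str | None = None) -> CountMatrix:
    """Read a feature x sample count table (TSV by default, CSV for .csv)."""
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        counts = df.apply(pd.to_numeric).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return CountMatrix(feature_ids, sample_ids, counts)


def read_conditions(
    path: str | os.PathLike, sample_ids: list[str], reference: str | None = None
) -> np.ndarray:
    """Read a two-column (sample_id, condition) table, ordered to ``sample_ids``.

    A header row is tolerated: a first row whose first cell is not a known
    sample ID is skipped.  Exactly two condition levels are required and every
    sample must be covered.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("conditions file needs two columns: sample_id, condition")
    if str(df.iloc[0, 0]) not in set(sample_ids):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValidationError(f"conditions missing for sample(s): {missing}")
    labels = np.array([mapping[s] for s in sample_ids], dtype=object)
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValidationError(f"two-group only: found {len(levels)} level(s) {levels}")
    return labels


def filter_features(cm: CountMatrix, min_total: int = 0) -> CountMatrix:
    """Drop features whose total count is below ``max(min_total, 1)``.

    The default removes only all-zero rows; the Dirichlet prior handles
    sporadic zeros downstream.  Removed IDs are logged and recorded on the
    returned matrix (``removed_features``).
    """
    if min_total < 0:
        raise ValidationError("min_total must be >= 0")
    threshold = max(int(min_total), 1)
    totals = cm.counts.sum(axis=1)
    keep = totals >= threshold
    if not keep.any():
        raise ValidationError("all features removed by the pre-filter")
    removed = [f for f, k in zip(cm.feature_ids, keep) if not k]
    if removed:
        logger.info("filter_features removed %d feature(s): %s", len(removed), removed)
    out = cm.select_features(keep)
    out.removed_features = list(cm.removed_features) + removed
    return out


def write_results(rt: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as TSV with 10 significant digits."""
    missing = [c for c in RESULT_COLUMNS if c not in rt.columns]
    if missing:
        raise ValidationError(f"results table missing column(s): {missing}")
    rt[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", dtype={"feature_id": str})
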