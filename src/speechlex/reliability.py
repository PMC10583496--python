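"""Within-task-type reliability and cross-task intraindividual variability.

The analysis treats repeated speech tasks of the same type as parallel test
forms.  Raw feature values are first standardized to z-scores within each
(feature, task, group) stratum, so features on different scales become
comparable.  Reliability of a feature within a task type is the Pearson
correlation of the feature with itself across task pairs — a single ET1–ET2
correlation for the two expository tasks, and the Fisher-z average of the
three pairwise correlations for the three picture tasks.  Statistical
calibration comes from a resampling null: re-pair participants at random
(a derangement, so nobody is paired with themselves), recompute the mean
correlation, repeat; the observed mean is referred to that distribution.

Intraindividual variability (ITV) looks across *different* task types: the
standard deviation of one participant's five z-scores for a feature,
averaged over participants.  Low ITV means the person keeps their relative
standing regardless of the elicitation task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .corpus import TASK_TYPES, TASKS, FeatureMatrix
from .errors import PreconditionError, ValidationError

#: correlations are clipped to +/- (1 - 1e-12) before atanh so a degenerate
#: perfect correlation maps to a large finite Fisher z rather than infinity
_R_CLIP = 1.0 - 1e-12


def fisher_z(r):
    """Fisher variance-stabilizing transform, atanh(r), with clipping."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def fisher_mean(rs) -> float:
    """Back-transformed mean of Fisher-z-transformed correlations."""
    return float(np.tanh(np.mean(fisher_z(np.asarray(rs, dtype=float)))))


@dataclass(frozen=True)
class ReliabilityEstimate:
    feature_name: str
    task_type: str
    group: str
    r_mean: float
    n_pairs: int
    p_value: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None


@dataclass(frozen=True)
class NullDistribution:
    """Resampled null of grand-mean correlations for one task type x group."""

    task_type: str
    group: str
    values: np.ndarray  # one Fisher-averaged mean correlation per rep

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))

    def p_value(self, observed: float) -> float:
        """One-sided add-one-smoothed p: is the observed mean correlation
        larger than expected under random participant pairing?"""
        reps = len(self.values)
        return float((1 + np.sum(self.values >= observed)) / (1 + reps))


@dataclass(frozen=True)
class ITVResult:
    feature_name: str
    group: str
    itv: float


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float


def zscore(matrix: FeatureMatrix, stratify_by_group: bool = True) -> FeatureMatrix:
    """Standardize values within each (feature, task[, group]) stratum.

    Uses the sample (n-1) standard deviation.  Raises
    :class:`PreconditionError` naming the stratum if its values are constant
    or fewer than two.
    """
    df = matrix.df.copy()
    keys = ["feature_name", "task_id"] + (["group"] if stratify_by_group else [])
    for key, idx in df.groupby(keys, sort=False).groups.items():
        vals = df.loc[idx, "value"]
        if len(vals) < 2 or vals.nunique() < 2:
            raise PreconditionError(f"constant or undersized stratum {key!r}")
        df.loc[idx, "value"] = (vals - vals.mean()) / vals.std(ddof=1)
    return FeatureMatrix(df)


def _task_pairs(task_type: str) -> list[tuple[int, int]]:
    if task_type not in TASK_TYPES:
        raise ValidationError(f"task_type must be one of {tuple(TASK_TYPES)}")
    tasks = TASK_TYPES[task_type]
    return list(combinations(range(len(tasks)), 2))


def _standardized_blocks(z: FeatureMatrix, task_type: str, group: str):
    """(n, T, F) array of column-standardized values for one task type/group.

    Columns are re-centred and scaled (ddof=1) so each pairwise Pearson r is
    simply the cross-product sum over n-1, independent of how the matrix was
    stratified upstream.
    """
    tasks = TASK_TYPES[task_type]
    arr, pids = z.to_array(tasks=tasks, group=group)
    n = arr.shape[0]
    if n < 3:
        raise PreconditionError(f"group {group!r} has only {n} participants")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise PreconditionError(
            f"zero-variance feature column in group {group!r}, "
            f"task type {task_type!r}: correlation undefined"
        )
    return (arr - arr.mean(axis=0)) / sd, pids


def pairwise_correlations(z: FeatureMatrix, task_type: str, group: str) -> np.ndarray:
    """Pearson r of each feature with itself across task pairs.

    Returns an array of shape (n_pairs, n_features): 1 x F for the
    expository pair, 3 x F for the picture pairs.  Because z-scoring is an
    affine map per stratum, these equal the raw-value correlations.
    """
    blocks, _ = _standardized_blocks(z, task_type, group)
    n = blocks.shape[0]
    pairs = _task_pairs(task_type)
    out = np.empty((len(pairs), blocks.shape[2]))
    for i, (t1, t2) in enumerate(pairs):
        out[i] = np.einsum("nf,nf->f", blocks[:, t1, :], blocks[:, t2, :]) / (n - 1)
    return out


def within_feature_reliability(
    z: FeatureMatrix, task_type: str, group: str
) -> list[ReliabilityEstimate]:
    """Fisher-averaged within-feature reliability, one estimate per feature."""
    rs = pairwise_correlations(z, task_type, group)
    n_pairs = rs.shape[0]
    return [
        ReliabilityEstimate(
            feature_name=feat,
            task_type=task_type,
            group=group,
            r_mean=fisher_mean(rs[:, k]),
            n_pairs=n_pairs,
        )
        for k, feat in enumerate(z.feature_names)
    ]


def _derangements(rng: np.random.Generator, n: int, reps: int) -> np.ndarray:
    """reps uniformly random fixed-point-free permutations of range(n)."""
    if n < 2:
        raise PreconditionError("derangement needs n >= 2")
    out = np.empty((reps, n), dtype=np.intp)
    idx = np.arange(n)
    filled = 0
    while filled < reps:
        batch = max(reps - filled, 16)
        perms = rng.permuted(np.tile(idx, (batch, 1)), axis=1)
        good = perms[(perms != idx).all(axis=1)]
        take = min(len(good), reps - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def resample_null(
    z: FeatureMatrix,
    task_type: str,
    group: str,
    reps: int = 10_000,
    seed: int | None = None,
) -> NullDistribution:
    """Resampling null for the grand-mean within-feature correlation.

    Each rep draws one random derangement of the participants and re-pairs
    the left side of every task pair with the deranged right side, so every
    participant's values are compared with a *different* participant's
    values for the same features.  All per-feature, per-pair correlations of
    a rep are Fisher-averaged into a single mean correlation; ``reps`` such
    values form the null distribution.
    """
    if seed is None:
        raise ValidationError("resample_null requires an explicit seed")
    if reps < 100:
        warnings.warn(f"reps={reps} is very small for a resampling null",
                      RuntimeWarning, stacklevel=2)
    blocks, _ = _standardized_blocks(z, task_type, group)
    n = blocks.shape[0]
    if n < 4:
        raise PreconditionError(f"group {group!r} too small to resample (n={n})")
    rng = np.random.default_rng(seed)
    perms = _derangements(rng, n, reps)
    pairs = _task_pairs(task_type)
    zsum = np.zeros(reps)
    for t1, t2 in pairs:
        a = blocks[:, t1, :]
        b = blocks[:, t2, :]
        r = np.einsum("rnf,nf->rf", a[perms], b) / (n - 1)
        zsum += fisher_z(r).sum(axis=1)
    n_corr = len(pairs) * blocks.shape[2]
    return NullDistribution(task_type, group, np.tanh(zsum / n_corr))


def grand_mean_correlation(z: FeatureMatrix, task_type: str, group: str) -> float:
    """Fisher-averaged mean over all features and task pairs."""
    return fisher_mean(pairwise_correlations(z, task_type, group).ravel())


def compare_groups(
    r_mci: Sequence[float], r_intact: Sequence[float]
) -> GroupComparison:
    """Two-sample pooled-variance t-test on Fisher-z-transformed per-feature
    correlations; 95% CI of the mean difference back-transformed to r.

    With 16 features per group this is a t-test on 16 + 16 values, df = 30.
    """
    a = np.asarray(r_mci, dtype=float)
    b = np.asarray(r_intact, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"expected two equal-length correlation lists, got {a.shape} and {b.shape}"
        )
    za, zb = fisher_z(a), fisher_z(b)
    t, p = stats.ttest_ind(za, zb, equal_var=True)
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * za.var(ddof=1) + (len(b) - 1) * zb.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    tcrit = stats.t.ppf(0.975, df)
    diff = za.mean() - zb.mean()
    return GroupComparison(
        t=float(t),
        df=df,
        p=float(p),
        ci_low=float(np.tanh(diff - tcrit * se)),
        ci_high=float(np.tanh(diff + tcrit * se)),
    )


def intraindividual_variability(
    z: FeatureMatrix,
    group: str,
    mode: str = "per_participant_sd",
) -> list[ITVResult]:
    """ITV of each feature across the 5 tasks for one group.

    ``per_participant_sd`` (default): sample SD of each participant's five
    z-scores, averaged over the group's participants.  ``variance_pooled``:
    the per-task cross-participant SDs squared, summed over the five tasks
    and divided by the number of participants.
    """
    arr, pids = z.to_array(tasks=TASKS, group=group)
    if np.isnan(arr).any():
        raise ValidationError("missing task values in feature matrix")
    if mode == "per_participant_sd":
        per_person = arr.std(axis=1, ddof=1)  # (n, F)
        itvs = per_person.mean(axis=0)
    elif mode == "variance_pooled":
        per_task_sd = arr.std(axis=0, ddof=1)  # (T, F)
        itvs = (per_task_sd**2).sum(axis=0) / len(pids)
    else:
        raise ValidationError(f"unknown ITV mode {mode!r}")
    return [
        ITVResult(feature_name=feat, group=group, itv=float(v))
        for feat, v in zip(z.feature_names, itvs)
    ]
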