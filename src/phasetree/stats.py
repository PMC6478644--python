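"""Permutation group comparison with FDR correction and clinical correlation.

Group differences in subject-level network metrics are tested by permuting
the group labels: the test statistic is the difference of group means, the
two-sided p-value is the add-one estimator

    p = (1 + #{permutations with |dmean*| >= |dmean_obs|}) / (1 + n_perm),

which is never exactly zero and is valid for any number of random
permutations.  An exhaustive mode enumerates every distinct label assignment
instead (exact p, no add-one).  Raw p-values are corrected with the
Benjamini-Hochberg step-up procedure over the declared test family — the
global-metric family (2 metrics x 5 bands = 10 tests) and, for nodal
betweenness, additionally across areas (n_rois x 5 bands).

Association between a patient metric and a clinical disability score is
measured by the Pearson correlation, with an optional outlier-exclusion
policy: none (default), an explicit id list, or externally studentized
regression residuals exceeding a threshold (default 2.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "permutation_test",
    "fdr_correct",
    "correlate_with_clinical",
]


@dataclass
class GroupComparison:
    metric: str
    band: str
    observed: float  # mean(group b) - mean(group a)
    p_raw: float
    n_permutations: int
    p_fdr: float | None = None


@dataclass
class CorrelationResult:
    r: float
    p: float
    n_used: int
    excluded_ids: list = field(default_factory=list)
    policy: str = "none"


def permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool = False,
    metric: str = "",
    band: str = "",
) -> GroupComparison:
    """Two-sided label-permutation test on the difference of group means.

    ``labels`` must contain exactly two distinct values with at least two
    subjects each.  ``exhaustive=True`` enumerates all C(n, n_a) label
    assignments (feasible for small cohorts) and reports the exact p.
    Constant values across all subjects yield p = 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and aligned")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.size}")
    mask_a = labels == uniq[0]
    n_a = int(mask_a.sum())
    n = values.size
    if n_a < 2 or n - n_a < 2:
        raise ValueError("each group needs at least 2 subjects")

    observed = float(values[~mask_a].mean() - values[mask_a].mean())
    if np.ptp(values) == 0:
        warnings.warn("metric is constant across subjects; p set to 1")
        return GroupComparison(metric, band, observed, 1.0, 0)

    total = values.sum()

    def dmean_from_a(sum_a: np.ndarray) -> np.ndarray:
        return (total - sum_a) / (n - n_a) - sum_a / n_a

    if exhaustive:
        idx = np.array(list(combinations(range(n), n_a)))
        sums_a = values[idx].sum(axis=1)
        null = dmean_from_a(sums_a)
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        return GroupComparison(metric, band, observed, p, len(idx))

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # vectorized: draw n_perm independent permutations of the subject indices
    perm = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)[:, :n_a]
    sums_a = values[perm].sum(axis=1)
    null = dmean_from_a(sums_a)
    exceed = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (1 + exceed) / (1 + n_perm)
    return GroupComparison(metric, band, observed, p, n_perm)


def fdr_correct(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values over one test family.

    Accepts any array shape (the family is the flattened set) and returns
    adjusted p-values in the same shape.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty test family")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = multipletests(pvals.ravel(), method="fdr_bh")[1]
    return adj.reshape(pvals.shape)


def _studentized_outliers(x: np.ndarray, y: np.ndarray, threshold: float) -> np.ndarray:
    """Mask of points whose externally studentized residual exceeds threshold."""
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(OLSInfluence(model).resid_studentized_external)
    return np.abs(resid) > threshold


def correlate_with_clinical(
    metric: np.ndarray,
    scores: np.ndarray,
    subject_ids: list | None = None,
    policy: str = "none",
    exclude_ids: list | None = None,
    threshold: float = 2.5,
) -> CorrelationResult:
    """Pearson correlation of a per-patient metric with clinical scores.

    ``policy`` is one of ``none``, ``explicit-ids`` (drop ``exclude_ids``)
    or ``studentized`` (drop points with externally studentized residual
    above ``threshold``).  At least three subjects must remain.
    """
    metric = np.asarray(metric, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if metric.shape != scores.shape or metric.ndim != 1:
        raise ValueError("metric and scores must be 1-D and aligned")
    ids = list(subject_ids) if subject_ids is not None else list(range(metric.size))

    keep = np.ones(metric.size, dtype=bool)
    if policy == "explicit-ids":
        if not exclude_ids:
            raise ValueError("explicit-ids policy requires exclude_ids")
        keep = np.array([i not in set(exclude_ids) for i in ids])
    elif policy == "studentized":
        keep = ~_studentized_outliers(metric, scores, threshold)
    elif policy != "none":
        raise ValueError(f"unknown outlier policy {policy!r}")

    x, y = metric[keep], scores[keep]
    if x.size < 3:
        raise ValueError("need at least 3 subjects after exclusion")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in metric or scores")
    r, p = sstats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r),
        p=float(p),
        n_used=int(x.size),
        excluded_ids=[i for i, k in zip(ids, keep) if not k],
        policy=policy,
    )
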