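"""Time-course and endpoint inference on RA and protein matrices.

Per hPTM: a one-way fixed-effects ANOVA over passage groups asks whether the
time course moved at all; unadjusted pairwise two-sample t-tests localize
which passages differ; the endpoint contrast (first vs last passage, default
P0 vs P12) with its fold change calls naive/primed *markers*.  hPTM p-values
are reported raw, mirroring single-assay practice; protein-level ANOVA
p-values are Benjamini-Hochberg adjusted to Q-values.

The endpoint and pairwise t-tests default to the classical pooled-variance
Student's t (so the two-group ANOVA identity F = t^2 holds); Welch's
unequal-variance form is available via ``equal_var=False``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "anova_over_passages",
    "pairwise_passage_tests",
    "ttest_endpoint",
    "call_markers",
    "bh_qvalues",
    "cluster_profiles",
    "pca_scores",
    "StudyComparison",
    "compare_studies",
    "STANDARD_MERGE_LABELS",
    "standard_merge_label",
]

logger = logging.getLogger(__name__)


def _group_arrays(
    values: Sequence[float] | pd.Series, groups: Sequence[str]
) -> dict[str, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    out: dict[str, np.ndarray] = {}
    for label in pd.unique(g):
        arr = v[g == label]
        out[str(label)] = arr[~np.isnan(arr)]
    return out


def anova_over_passages(
    values: Sequence[float] | pd.Series, groups: Sequence[str]
) -> float:
    """One-way fixed-effects ANOVA p-value over passage groups.

    Degenerate inputs follow explicit conventions: all observations equal
    gives p = 1 (no evidence of any effect); fewer than two groups with two
    or more non-missing values gives a missing result.
    """
    by_group = [a for a in _group_arrays(values, groups).values() if a.size >= 2]
    if len(by_group) < 2:
        logger.warning("ANOVA skipped: fewer than 2 groups with >=2 values")
        return np.nan
    pooled = np.concatenate(by_group)
    if np.allclose(pooled, pooled[0]):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.f_oneway(*by_group)
    if np.isnan(p):
        # between-group variance zero with within-group variance positive
        return 1.0
    return float(p)


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if a.size < 2 or b.size < 2:
        return np.nan
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        return 1.0 if np.isclose(a[0], b[0]) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(p)


def pairwise_passage_tests(
    values: Sequence[float] | pd.Series,
    groups: Sequence[str],
    equal_var: bool = True,
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Symmetric passage x passage table of two-sided t-test p-values.

    Unadjusted by design: these localize which passages moved, after the
    ANOVA has already asked the global question.
    """
    arrays = _group_arrays(values, groups)
    labels = list(order) if order is not None else list(arrays)
    table = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            p = _two_sample_t(arrays[gi], arrays[gj], equal_var)
            table.loc[gi, gj] = p
            table.loc[gj, gi] = p
    return table


def ttest_endpoint(
    values: Sequence[float] | pd.Series,
    groups: Sequence[str],
    start: str,
    end: str,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """(p, fold change end/start, log2 fold change) for the endpoint contrast."""
    arrays = _group_arrays(values, groups)
    a, b = arrays.get(start, np.array([])), arrays.get(end, np.array([]))
    p = _two_sample_t(a, b, equal_var)
    if a.size == 0 or b.size == 0 or np.nanmean(a) == 0:
        if a.size and np.nanmean(a) == 0:
            logger.warning("zero-mean denominator in %s vs %s fold change", end, start)
        return p, np.nan, np.nan
    fc = float(np.mean(b) / np.mean(a))
    log2fc = float(np.log2(fc)) if fc > 0 else np.nan
    return p, fc, log2fc


def call_markers(
    ra_values: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    alpha_timecourse: float = 0.05,
    alpha_endpoint: float = 0.01,
    start: str = "P0",
    end: str = "P12",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-key time-course and endpoint statistics with marker flags.

    ``ra_values`` is keys x samples; ``groups`` maps sample name to passage.
    A key is *time-significant* when its ANOVA p < ``alpha_timecourse`` and a
    *marker* (naive/primed endpoint candidate) when the start-vs-end t-test
    p < ``alpha_endpoint``; the direction is the sign of the log2 fold
    change (positive = up in the naive endpoint).
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    glabels = [str(groups[c]) for c in ra_values.columns]
    records = []
    for label, row in ra_values.iterrows():
        vals = row.to_numpy(dtype=float)
        anova_p = anova_over_passages(vals, glabels)
        p, fc, log2fc = ttest_endpoint(vals, glabels, start, end, equal_var)
        records.append(
            {
                "key": label,
                "anova_p": anova_p,
                "endpoint_p": p,
                "fc_endpoint": fc,
                "log2fc": log2fc,
                "time_significant": bool(anova_p < alpha_timecourse)
                if not np.isnan(anova_p)
                else False,
                "marker": bool(p < alpha_endpoint) if not np.isnan(p) else False,
                "direction": (
                    "up_in_naive"
                    if log2fc > 0
                    else ("down_in_naive" if log2fc < 0 else "flat")
                )
                if not np.isnan(log2fc)
                else "undefined",
            }
        )
    return pd.DataFrame.from_records(records).set_index("key")


def bh_qvalues(pvalues: Sequence[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (missing p stays missing)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def cluster_profiles(
    protein_matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    threshold: float = 0.5,
    order: Sequence[str] | None = None,
) -> pd.Series:
    """Correlation-based average-linkage clustering of expression profiles.

    Profiles are per-passage means, standardized per protein; distance is
    1 - Pearson r; the dendrogram is cut at ``threshold``.  Constant
    (zero-variance) profiles cannot be correlated and become singletons.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    glabels = pd.Series([str(groups[c]) for c in protein_matrix.columns],
                        index=protein_matrix.columns)
    prof = protein_matrix.T.groupby(glabels).mean().T
    if order is not None:
        prof = prof[list(order)]
    sd = prof.std(axis=1, ddof=0)
    # relative tolerance: float noise on a constant profile is still constant
    flat = sd <= 1e-9 * (1.0 + prof.abs().max(axis=1))
    constant = prof.index[flat | sd.isna() | prof.isna().any(axis=1)]
    if len(constant):
        logger.warning(
            "%d constant/incomplete profiles assigned to singleton clusters",
            len(constant),
        )
    usable = prof.drop(index=constant)
    labels = pd.Series(0, index=protein_matrix.index, dtype=int)
    if len(usable) >= 2:
        z = usable.sub(usable.mean(axis=1), axis=0).div(
            usable.std(axis=1, ddof=0), axis=0
        )
        corr = np.corrcoef(z.to_numpy())
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        link = sch.linkage(squareform(dist, checks=False), method="average")
        cut = sch.fcluster(link, t=threshold, criterion="distance")
        labels.loc[usable.index] = cut
    elif len(usable) == 1:
        labels.loc[usable.index] = 1
    nxt = int(labels.max()) + 1
    for idx in constant:
        labels.loc[idx] = nxt
        nxt += 1
    return labels


def pca_scores(
    matrix: pd.DataFrame, unit_variance: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a samples x features matrix via centered (scaled) SVD.

    Features that are entirely missing, contain any gap, or have zero
    variance (when scaling) are dropped.  Component signs are fixed by
    making each component's largest-magnitude loading positive, so scores
    are fully deterministic.

    Returns (scores indexed by sample, explained variance per component);
    explained variances sum to the total variance of the analysed matrix.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.dropna(axis=1, how="any")
    x = x.loc[:, x.std(axis=0, ddof=1) > 0] if unit_variance else x
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 usable features")
    arr = x.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    if unit_variance:
        arr = arr / arr.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    # deterministic orientation: largest-|loading| entry of each PC positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    explained = s**2 / (arr.shape[0] - 1)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), explained


# Cross-study key harmonization: H3.1/H3.2 and H3.3 merge to the family,
# K36 and K37 merge to K36/37.
STANDARD_MERGE_LABELS: dict[str, str] = {"H31/H32": "H3", "H33": "H3", "H31": "H3"}


def standard_merge_label(key_label: str) -> str:
    """Map a key label onto the merged cross-study vocabulary."""
    vg, rest = key_label.split(" ", 1)
    vg = STANDARD_MERGE_LABELS.get(vg, vg)
    rest = rest.replace("K36/37", "K36#").replace("K36", "K36/37").replace(
        "K37", "K36/37"
    ).replace("K36/37#", "K36/37")
    return f"{vg} {rest}"


@dataclass
class StudyComparison:
    """Joined naive/primed fold changes for keys shared by two studies."""

    table: pd.DataFrame
    unmatched_first: list[str]
    unmatched_second: list[str]


def compare_studies(
    first: pd.DataFrame,
    second: pd.DataFrame,
    merge_label: Callable[[str], str] | None = standard_merge_label,
    suffixes: tuple[str, str] = ("_human", "_mouse"),
) -> StudyComparison:
    """Inner-join two marker tables on (optionally merged) key labels.

    Both tables must be indexed by key label and carry ``log2fc`` and
    ``marker`` columns, each already oriented naive-over-primed (e.g. human
    D37/D0 and mouse D0/D14).  Keys colliding after merging are an error:
    merge at the intensity level upstream, then compare.
    """
    frames = []
    for tbl, suffix in zip((first, second), suffixes):
        idx = [merge_label(k) if merge_label else k for k in tbl.index]
        dup = pd.Index(idx)[pd.Index(idx).duplicated()].unique().tolist()
        if dup:
            raise ValueError(
                f"labels collide after merging ({dup}); re-aggregate intensities "
                "with merge_keys before comparing"
            )
        sub = tbl[["log2fc", "marker"]].copy()
        sub.index = idx
        sub.columns = [f"log2fc{suffix}", f"sig{suffix}"]
        frames.append(sub)
    a, b = frames
    shared = a.index.intersection(b.index)
    joined = a.loc[shared].join(b.loc[shared]).sort_index()
    return StudyComparison(
        table=joined,
        unmatched_first=sorted(a.index.difference(b.index)),
        unmatched_second=sorted(b.index.difference(a.index)),
    )
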