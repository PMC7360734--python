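"""Inter-sample correlation of element-level open-chromatin patterns and
its comparison across mutation groups.

Samples that share a driver mutation may share which repeat copies are
open.  The element x sample binary overlap matrix is correlated between
samples (Pearson on binary indicators, i.e. the phi coefficient, or
Jaccard); the median pairwise correlation among mutated samples is then
compared with the median among non-mutated samples by permuting the
mutation labels over samples.  Permutation is over sample labels, not over
pairs: pairwise correlations sharing a sample are dependent, and label
permutation respects that dependence.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MergedIntervals, PeakSet, RepeatAnnotation

__all__ = [
    "build_overlap_matrix",
    "sample_correlation",
    "mutation_correlation_test",
    "CorrelationComparison",
]


@dataclass(frozen=True, eq=False)
class CorrelationComparison:
    mutation: str
    within_mut: np.ndarray
    within_wt: np.ndarray
    median_mut: float
    median_wt: float
    statistic: float          # median_mut - median_wt
    p_perm: float             # one-sided (mut more inter-correlated), add-one
    n_perm: int


def build_overlap_matrix(elements: RepeatAnnotation, dhs_sets: Sequence[PeakSet]) -> pd.DataFrame:
    """Binary element x sample matrix (1 = element overlapped by >=1 peak);
    rows with no positive entry are dropped."""
    if len(dhs_sets) < 2:
        raise ValueError("need >=2 samples to build an overlap matrix")
    ids = [e.element_id for e in elements.elements]
    cols = {}
    for ps in dhs_sets:
        idx = MergedIntervals(ps.peaks)
        cols[ps.sample_id] = idx.any_overlap(e.as_interval() for e in elements.elements).astype(np.int8)
    mat = pd.DataFrame(cols, index=ids)
    mat = mat.loc[mat.sum(axis=1) > 0]
    if mat.empty:
        raise ValueError("no element overlaps any sample's peaks; nothing to correlate")
    return mat


def sample_correlation(m: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Symmetric sample x sample correlation of binary overlap patterns.

    Pearson on a constant column is undefined; those pairs are returned as
    NaN (the caller sees which via ``isna``).  Jaccard of two all-zero
    columns is likewise NaN.
    """
    if m.shape[1] < 2:
        raise ValueError("need >=2 samples")
    X = m.to_numpy(dtype=float)
    n = X.shape[1]
    out = np.full((n, n), np.nan)
    if method == "pearson":
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
        out = np.asarray(C, dtype=float)
        out[sd == 0, :] = np.nan
        out[:, sd == 0] = np.nan
        np.fill_diagonal(out, 1.0)
    elif method == "jaccard":
        B = X > 0
        for i in range(n):
            for j in range(i, n):
                union = np.logical_or(B[:, i], B[:, j]).sum()
                if union == 0:
                    val = np.nan
                else:
                    val = np.logical_and(B[:, i], B[:, j]).sum() / union
                out[i, j] = out[j, i] = val
        np.fill_diagonal(out, 1.0)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return pd.DataFrame(out, index=m.columns, columns=m.columns)


def _within_group_values(C: np.ndarray, members: np.ndarray) -> np.ndarray:
    idx = np.where(members)[0]
    iu = np.triu_indices(len(idx), k=1)
    return C[np.ix_(idx, idx)][iu]


def mutation_correlation_test(
    corr: pd.DataFrame,
    mut_labels: Mapping[str, bool],
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    mutation: str = "mutation",
) -> CorrelationComparison:
    """Are samples sharing a mutation better inter-correlated than samples
    without it?

    Statistic: median(within-mutated pairwise r) - median(within-wild-type
    pairwise r); between-group pairs enter neither set.  One-sided add-one
    permutation p over ``n_perm`` relabelings of the samples.
    """
    samples = list(corr.index)
    labels = np.asarray([bool(mut_labels[s]) for s in samples])
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >=2 mutated and >=2 non-mutated samples")
    C = corr.to_numpy(dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    within_mut = _within_group_values(C, labels)
    within_wt = _within_group_values(C, ~labels)
    stat = float(np.nanmedian(within_mut) - np.nanmedian(within_wt))

    n_ge = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        s = np.nanmedian(_within_group_values(C, perm)) - np.nanmedian(
            _within_group_values(C, ~perm)
        )
        if s >= stat:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return CorrelationComparison(
        mutation=mutation,
        within_mut=within_mut,
        within_wt=within_wt,
        median_mut=float(np.nanmedian(within_mut)),
        median_wt=float(np.nanmedian(within_wt)),
        statistic=stat,
        p_perm=float(p),
        n_perm=n_perm,
    )
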