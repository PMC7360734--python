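"""Histone-mark overlap profiling of repeat elements, k-means clustering
of the overlap patterns, and enhancer/promoter state classification.

For each element the feature vector holds, for each of the four histone
marks (H3K27ac, H3K4me1, H3K4me3, H3K9me3) in each of two sample groups
(disease vs differentiated), the fraction of that group's samples whose
peak set overlaps the element.  The state call uses the disease-group
indicators only: H3K4me3 marks a promoter-like element (precedence over
enhancer calls, since H3K4me1 and H3K4me3 rarely co-occur on true
enhancers); H3K4me1 with H3K27ac is an active enhancer, H3K4me1 alone a
primed enhancer, H3K9me3 alone heterochromatin; nothing marked is
unmarked.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome import MergedIntervals, PeakSet, RepeatAnnotation

__all__ = [
    "MARKS",
    "STATE_GROUPS",
    "StateFeatures",
    "mark_overlap_fractions",
    "cluster_elements",
    "classify_state",
    "classify_states",
    "count_marked_elements",
]

MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K9me3")
STATE_GROUPS = ("AML", "differentiated")
STATES = ("promoter_like", "active_enhancer", "primed_enhancer", "heterochromatic", "unmarked")


@dataclass(frozen=True)
class StateFeatures:
    """Per-element overlap fractions and raw counts, mark x group."""

    fractions: pd.DataFrame   # elements x "{mark}|{group}" in [0,1]; NaN = group/mark absent
    counts: pd.DataFrame      # same shape, integer overlap counts
    n_samples: dict[str, int]  # per group
    family: pd.Series         # element_id -> family


def mark_overlap_fractions(
    elements: RepeatAnnotation,
    marksets: Sequence[PeakSet],
    groups: Mapping[str, str] | None = None,
) -> StateFeatures:
    """Fraction of each group's samples whose peaks for each mark overlap
    each element.  A mark x group combination with no samples yields NaN
    fractions (flagged by NaN rather than an error so partial panels can
    still be profiled)."""
    group_of = groups or {ps.sample_id: ps.group for ps in marksets}
    ids = [e.element_id for e in elements.elements]
    ivs = [e.as_interval() for e in elements.elements]
    n_samples = {g: 0 for g in STATE_GROUPS}
    sample_seen: dict[str, set[str]] = {g: set() for g in STATE_GROUPS}

    counts = pd.DataFrame(
        0, index=ids, columns=[f"{m}|{g}" for m in MARKS for g in STATE_GROUPS]
    )
    present = {col: False for col in counts.columns}
    for ps in marksets:
        g = group_of[ps.sample_id]
        if g not in STATE_GROUPS or ps.assay not in MARKS:
            continue
        sample_seen[g].add(ps.sample_id)
        col = f"{ps.assay}|{g}"
        present[col] = True
        idx = MergedIntervals(ps.peaks)
        counts[col] += idx.any_overlap(ivs).astype(int)
    for g in STATE_GROUPS:
        n_samples[g] = len(sample_seen[g])

    fractions = counts.astype(float)
    for col in counts.columns:
        g = col.split("|")[1]
        if not present[col] or n_samples[g] == 0:
            fractions[col] = np.nan
        else:
            fractions[col] = counts[col] / n_samples[g]
    family = pd.Series({e.element_id: e.family for e in elements.elements}, name="family")
    return StateFeatures(fractions=fractions, counts=counts, n_samples=n_samples,
                         family=family.loc[ids])


def family_mean_fractions(features: StateFeatures) -> pd.DataFrame:
    """Per-family average of each mark x group fraction."""
    df = features.fractions.copy()
    df["family"] = features.family
    return df.groupby("family").mean()


def cluster_elements(features: StateFeatures, k: int = 6, seed: int = 0,
                     n_init: int = 10) -> pd.Series:
    """K-means over the 8-dim fraction vectors (k-means++ init, Euclidean,
    best of ``n_init`` restarts).  Labels are renumbered by descending
    cluster mean of the disease-group H3K27ac fraction so that cluster 0 is
    always the most active one, making labels stable across element order.
    """
    X = features.fractions.fillna(0.0).to_numpy(dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of elements ({X.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    key = features.fractions["H3K27ac|AML"].fillna(0.0).to_numpy()
    order = np.argsort(
        [-key[raw == c].mean() if (raw == c).any() else np.inf for c in range(k)],
        kind="stable",
    )
    relabel = {int(old): new for new, old in enumerate(order)}
    return pd.Series([relabel[int(c)] for c in raw], index=features.fractions.index,
                     name="cluster")


def classify_state(fracs: Mapping[str, float], min_frac: float) -> str:
    """State of one element from its disease-group fractions.

    ``min_frac`` converts a fraction into a marked/unmarked indicator;
    the conventional choice is 2/n_disease_samples ("marked in at least
    two samples")."""
    def marked(mark: str) -> bool:
        v = fracs.get(f"{mark}|AML", np.nan)
        return bool(v >= min_frac) if not np.isnan(v) else False

    if marked("H3K4me3"):
        return "promoter_like"
    if marked("H3K4me1") and marked("H3K27ac"):
        return "active_enhancer"
    if marked("H3K4me1"):
        return "primed_enhancer"
    if marked("H3K9me3"):
        return "heterochromatic"
    return "unmarked"


def classify_states(features: StateFeatures, min_frac: float | None = None) -> pd.Series:
    """Vector of state calls; default threshold = 2 / n disease samples."""
    if min_frac is None:
        n = features.n_samples.get("AML", 0)
        if n == 0:
            raise ValueError("no disease samples; cannot derive default threshold")
        min_frac = 2.0 / n
    return pd.Series(
        [classify_state(row, min_frac) for _, row in features.fractions.iterrows()],
        index=features.fractions.index,
        name="state",
    )


def count_marked_elements(features: StateFeatures, mark: str, min_samples: int = 2,
                          group: str = "AML") -> int:
    """Number of elements overlapped by the mark in >= ``min_samples`` of
    the group's samples."""
    col = f"{mark}|{group}"
    if col not in features.counts.columns:
        raise KeyError(f"unknown mark {mark!r}")
    return int((features.counts[col] >= min_samples).sum())


def count_comarked_elements(features: StateFeatures, mark_a: str, mark_b: str,
                            min_samples: int = 2, group: str = "AML") -> int:
    """Elements carrying both marks in >= min_samples of the group's samples."""
    ca = features.counts[f"{mark_a}|{group}"] >= min_samples
    cb = features.counts[f"{mark_b}|{group}"] >= min_samples
    return int((ca & cb).sum())
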