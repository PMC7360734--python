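"""Element-to-gene association within a distance window and expression
contrasts between samples with and without open chromatin at the element.

Expression is consumed already normalised on a log2 scale (vst-like), so a
">4-fold" difference is a difference of 2 log2 units.  Distances use the
whole gene span; a gene and element overlapping in any way are at distance
zero.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Interval, RepeatAnnotation, RepeatElement

__all__ = [
    "GeneModel",
    "GeneAssociationResult",
    "genes_near_elements",
    "group_expression_by_dhs",
    "per_gene_dhs_contrast",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    span: Interval
    strand: str = "."


@dataclass(frozen=True)
class GeneAssociationResult:
    gene_id: str
    element_id: str
    distance: int
    n_dhs_pos: int
    mean_pos: float     # mean log2 expression in samples with a DHS at the element
    mean_neg: float
    log2_diff: float    # mean_pos - mean_neg
    flagged: bool       # log2_diff > 2 and mean_pos > 0
    defined: bool = True  # False when one side had no samples


def interval_distance(a: Interval, b: Interval) -> int:
    """0 on overlap, else the gap between nearest ends; infinite across
    chromosomes (returned as -1 sentinel is avoided; caller filters)."""
    if a.chrom != b.chrom:
        raise ValueError("distance undefined across chromosomes")
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def genes_near_elements(
    genes: Sequence[GeneModel],
    elements: RepeatAnnotation,
    max_dist: int = 50_000,
) -> list[tuple[GeneModel, RepeatElement, int]]:
    """All (gene, element, distance) pairs with distance <= max_dist."""
    out = []
    by_chrom: dict[str, list[RepeatElement]] = {}
    for e in elements.elements:
        by_chrom.setdefault(e.chrom, []).append(e)
    for g in genes:
        for e in by_chrom.get(g.span.chrom, []):
            d = interval_distance(g.span, e.as_interval())
            if d <= max_dist:
                out.append((g, e, d))
    return out


def group_expression_by_dhs(
    pairs: Sequence[tuple[GeneModel, RepeatElement, int]],
    expr: pd.DataFrame,
    dhs_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    min_pos_samples: int = 2,
) -> dict[str, np.ndarray]:
    """Partition genes by the open-chromatin status of their nearby
    elements and return each class's per-gene mean disease-sample
    expression.

    Classes: ``dhs_aml_and_diff`` — near an element open in >=
    ``min_pos_samples`` disease samples and >=1 differentiated sample;
    ``dhs_aml_only`` — open in disease only; ``dhs_neg`` — near elements
    with no qualifying open chromatin.  A gene near several elements is
    counted once, with aml-and-diff taking precedence over aml-only over
    negative.
    """
    aml_samples = [s for s in dhs_matrix.columns if groups.get(s) == "AML"]
    diff_samples = [s for s in dhs_matrix.columns if groups.get(s) == "differentiated"]
    expr_aml = [s for s in aml_samples if s in expr.columns]

    klass: dict[str, int] = {}  # gene -> 0 neg, 1 aml_only, 2 aml_and_diff
    skipped = 0
    for g, e, _d in pairs:
        if g.gene_id not in expr.index:
            skipped += 1
            continue
        if e.element_id in dhs_matrix.index:
            row = dhs_matrix.loc[e.element_id]
            n_aml = int(row[aml_samples].sum()) if aml_samples else 0
            n_diff = int(row[diff_samples].sum()) if diff_samples else 0
        else:
            n_aml = n_diff = 0
        if n_aml >= min_pos_samples:
            k = 2 if n_diff >= 1 else 1
        else:
            k = 0
        klass[g.gene_id] = max(klass.get(g.gene_id, 0), k)

    means = expr.loc[list(klass), expr_aml].mean(axis=1) if klass else pd.Series(dtype=float)
    out = {
        "dhs_aml_and_diff": means[[g for g, k in klass.items() if k == 2]].to_numpy(),
        "dhs_aml_only": means[[g for g, k in klass.items() if k == 1]].to_numpy(),
        "dhs_neg": means[[g for g, k in klass.items() if k == 0]].to_numpy(),
        "n_skipped": np.array([skipped]),
    }
    return out


def per_gene_dhs_contrast(
    gene: GeneModel,
    element: RepeatElement,
    expr_row: pd.Series,
    dhs_row: pd.Series,
    distance: int = 0,
) -> GeneAssociationResult:
    """Expression contrast for one (gene, element) pair: mean log2
    expression in samples where the element has a DHS versus samples where
    it does not.  Samples present in both series are used.  Flagged when
    the contrast exceeds 2 log2 units (>4-fold) and the DHS+ mean is > 0.
    """
    common = [s for s in dhs_row.index if s in expr_row.index]
    pos = [s for s in common if dhs_row[s] > 0]
    neg = [s for s in common if dhs_row[s] == 0]
    n_pos = len(pos)
    if not pos or not neg:
        return GeneAssociationResult(
            gene_id=gene.gene_id, element_id=element.element_id, distance=distance,
            n_dhs_pos=n_pos, mean_pos=float("nan"), mean_neg=float("nan"),
            log2_diff=float("nan"), flagged=False, defined=False,
        )
    mean_pos = float(expr_row[pos].mean())
    mean_neg = float(expr_row[neg].mean())
    diff = mean_pos - mean_neg
    return GeneAssociationResult(
        gene_id=gene.gene_id, element_id=element.element_id, distance=distance,
        n_dhs_pos=n_pos, mean_pos=mean_pos, mean_neg=mean_neg, log2_diff=diff,
        flagged=bool(diff > 2.0 and mean_pos > 0.0), defined=True,
    )


def contrast_table(
    pairs: Sequence[tuple[GeneModel, RepeatElement, int]],
    expr: pd.DataFrame,
    dhs_matrix: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-pair DHS+/DHS- contrasts over disease samples, as a table."""
    aml = [s for s in dhs_matrix.columns
           if groups.get(s) == "AML" and s in expr.columns]
    rows = []
    for g, e, d in pairs:
        if g.gene_id not in expr.index or e.element_id not in dhs_matrix.index:
            continue
        r = per_gene_dhs_contrast(g, e, expr.loc[g.gene_id, aml],
                                  dhs_matrix.loc[e.element_id, aml], distance=d)
        rows.append((r.gene_id, r.element_id, r.distance, r.n_dhs_pos, r.mean_pos,
                     r.mean_neg, r.log2_diff, r.flagged, r.defined))
    return pd.DataFrame(
        rows, columns=["gene", "element", "distance", "n_dhs_pos", "mean_pos",
                       "mean_neg", "log2_diff", "flagged", "defined"],
    )
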