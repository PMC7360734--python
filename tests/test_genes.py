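"""Gene-element distance pairing and DHS expression contrasts."""

import numpy as np
import pandas as pd
import pytest

from ervreg.genes import (
    GeneModel,
    contrast_table,
    genes_near_elements,
    group_expression_by_dhs,
    interval_distance,
    per_gene_dhs_contrast,
)
from ervreg.genome import Interval, RepeatAnnotation, RepeatElement


def _gene(gid, start, end, chrom="chr1"):
    return GeneModel(gid, Interval(chrom, start, end))


def _el(eid, start, end, chrom="chr1"):
    return RepeatElement(chrom, start, end, "FAM", eid)


def test_distance_gap_and_overlap():
    g = Interval("chr1", 1_000, 2_000)
    assert interval_distance(g, Interval("chr1", 2_500, 2_600)) == 500
    assert interval_distance(g, Interval("chr1", 1_500, 1_600)) == 0  # inside
    assert interval_distance(g, Interval("chr1", 100, 200)) == 800
    with pytest.raises(ValueError):
        interval_distance(g, Interval("chr2", 0, 10))


def test_distance_symmetric_zero_iff_overlap():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a = Interval("chr1", *sorted(rng.integers(0, 5_000, 2) + [0, 1])[:2])
        b = Interval("chr1", *sorted(rng.integers(0, 5_000, 2) + [0, 1])[:2])
        d1, d2 = interval_distance(a, b), interval_distance(b, a)
        assert d1 == d2 >= 0
        assert (d1 == 0) == a.overlaps(b)


def test_genes_near_elements_window():
    ann = RepeatAnnotation([_el("E1", 100_000, 100_400)])
    genes = [_gene("near", 40_000, 50_000), _gene("far", 0, 10_000),
             _gene("inside", 100_100, 100_200)]
    pairs = genes_near_elements(genes, ann, max_dist=50_000)
    got = {(g.gene_id, d) for g, _e, d in pairs}
    assert got == {("near", 50_000), ("inside", 0)}


def test_genes_near_elements_matches_min_gap_oracle():
    rng = np.random.default_rng(1)
    els = [_el(f"E{i}", int(s), int(s) + 300) for i, s in
           enumerate(rng.integers(0, 900_000, 30))]
    ann = RepeatAnnotation(els)
    genes = [_gene(f"G{i}", int(s), int(s) + 2_000) for i, s in
             enumerate(rng.integers(0, 900_000, 50))]
    pairs = {(g.gene_id, e.element_id): d for g, e, d in
             genes_near_elements(genes, ann, max_dist=30_000)}
    for g in genes:
        for e in els:
            # independent min-gap arithmetic
            if g.span.start < e.end and e.start < g.span.end:
                d = 0
            else:
                d = max(e.start - g.span.end, g.span.start - e.end)
            key = (g.gene_id, e.element_id)
            if d <= 30_000:
                assert pairs[key] == d
            else:
                assert key not in pairs


def _contrast(expr_vals, dhs_vals):
    samples = [f"s{i}" for i in range(len(expr_vals))]
    return per_gene_dhs_contrast(
        _gene("G", 0, 100), _el("E", 200, 300),
        pd.Series(expr_vals, index=samples), pd.Series(dhs_vals, index=samples),
    )


def test_contrast_flag_rule():
    # mean_pos 2.5, mean_neg 0.3 -> diff 2.2 > 2 and mean_pos > 0 -> flagged
    r = _contrast([2.5, 2.5, 0.3, 0.3], [1, 1, 0, 0])
    assert r.log2_diff == pytest.approx(2.2)
    assert r.flagged
    # identical groups -> no flag
    r0 = _contrast([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0])
    assert r0.log2_diff == 0.0 and not r0.flagged
    # big contrast but non-positive DHS+ mean -> no flag
    rneg = _contrast([-0.5, -0.5, -3.0, -3.0], [1, 1, 0, 0])
    assert rneg.log2_diff == pytest.approx(2.5) and not rneg.flagged


def test_contrast_undefined_when_one_sided():
    r = _contrast([1.0, 2.0], [1, 1])
    assert not r.defined and not r.flagged


def test_contrast_matches_hand_computation():
    rng = np.random.default_rng(2)
    for _ in range(100):
        vals = rng.normal(2, 1, size=8)
        dhs = rng.integers(0, 2, size=8)
        if dhs.sum() in (0, 8):
            continue
        r = _contrast(vals.tolist(), dhs.tolist())
        assert r.mean_pos == pytest.approx(vals[dhs == 1].mean())
        assert r.mean_neg == pytest.approx(vals[dhs == 0].mean())
        assert r.log2_diff == pytest.approx(r.mean_pos - r.mean_neg)


def _grouping_fixture():
    ann = RepeatAnnotation([_el("E_pos", 10_000, 10_400), _el("E_neg", 500_000, 500_400),
                            _el("E_both", 300_000, 300_400)])
    genes = [_gene("G_pos", 12_000, 14_000), _gene("G_neg", 502_000, 504_000),
             _gene("G_both", 302_000, 304_000)]
    samples = [f"a{i}" for i in range(4)] + ["d1"]
    groups = {**{f"a{i}": "AML" for i in range(4)}, "d1": "differentiated"}
    dhs = pd.DataFrame(0, index=["E_pos", "E_both"], columns=samples)
    dhs.loc["E_pos", ["a0", "a1"]] = 1
    dhs.loc["E_both", ["a0", "a1", "d1"]] = 1
    expr = pd.DataFrame(
        np.arange(15, dtype=float).reshape(3, 5),
        index=["G_pos", "G_neg", "G_both"], columns=samples,
    )
    return ann, genes, groups, dhs, expr


def test_group_partition_and_precedence():
    ann, genes, groups, dhs, expr = _grouping_fixture()
    pairs = genes_near_elements(genes, ann, max_dist=50_000)
    out = group_expression_by_dhs(pairs, expr, dhs, groups, min_pos_samples=2)
    assert len(out["dhs_aml_only"]) == 1      # G_pos
    assert len(out["dhs_aml_and_diff"]) == 1  # G_both
    assert len(out["dhs_neg"]) == 1           # G_neg


def test_gene_near_both_classes_counted_once_as_positive():
    ann = RepeatAnnotation([_el("E_pos", 10_000, 10_400), _el("E_neg", 20_000, 20_400)])
    genes = [_gene("G", 12_000, 14_000)]
    samples = ["a0", "a1", "a2"]
    groups = {s: "AML" for s in samples}
    dhs = pd.DataFrame([[1, 1, 0]], index=["E_pos"], columns=samples)
    expr = pd.DataFrame([[1.0, 1.0, 1.0]], index=["G"], columns=samples)
    pairs = genes_near_elements(genes, ann, max_dist=50_000)
    assert len(pairs) == 2
    out = group_expression_by_dhs(pairs, expr, dhs, groups)
    assert len(out["dhs_aml_only"]) == 1
    assert len(out["dhs_neg"]) == 0


def test_all_negative_degenerate_partition():
    ann = RepeatAnnotation([_el("E", 10_000, 10_400)])
    genes = [_gene("G", 12_000, 14_000)]
    samples = ["a0", "a1"]
    dhs = pd.DataFrame([[0, 0]], index=["E"], columns=samples)
    expr = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=samples)
    out = group_expression_by_dhs(
        genes_near_elements(genes, ann), expr, dhs, {s: "AML" for s in samples}
    )
    assert len(out["dhs_neg"]) == 1
    assert len(out["dhs_aml_only"]) == len(out["dhs_aml_and_diff"]) == 0


def test_planted_effect_orders_group_medians():
    rng = np.random.default_rng(3)
    n_genes, n_samples = 40, 12
    samples = [f"a{i}" for i in range(n_samples)]
    groups = {s: "AML" for s in samples}
    els, genes, rows = [], [], []
    dhs_rows = {}
    for i in range(n_genes):
        base = 200_000 * i
        eid, gid = f"E{i}", f"G{i}"
        els.append(_el(eid, base, base + 400))
        genes.append(_gene(gid, base + 2_000, base + 4_000))
        planted = i < 20
        dhs_rows[eid] = [1 if (planted and j < 6) else 0 for j in range(n_samples)]
        expr = rng.normal(2, 0.5, n_samples)
        if planted:
            expr[:6] += 2.0
        rows.append(expr)
    ann = RepeatAnnotation(els)
    dhs = pd.DataFrame.from_dict(dhs_rows, orient="index", columns=samples)
    expr = pd.DataFrame(rows, index=[g.gene_id for g in genes], columns=samples)
    out = group_expression_by_dhs(genes_near_elements(genes, ann), expr, dhs, groups)
    assert np.median(out["dhs_aml_only"]) > np.median(out["dhs_neg"])


def test_contrast_table_planted_links(dataset):
    """Planted enhancer-gene links are flagged by the >4-fold rule."""
    from ervreg.heterogeneity import build_overlap_matrix

    aml = [s for s, g in dataset.groups.items() if g == "AML"]
    mat = build_overlap_matrix(dataset.repeats,
                               [dataset.dnase[s] for s in sorted(aml)])
    pairs = genes_near_elements(dataset.genes, dataset.repeats)
    table = contrast_table(pairs, dataset.expression, mat, dataset.groups)
    link_genes = {l["gene"] for l in dataset.truth.links}
    flagged = set(table[table.flagged].gene)
    assert len(flagged & link_genes) >= 0.8 * len(link_genes)
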