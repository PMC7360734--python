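"""dCas9 peak classification, window signal ratios and guide matching."""

import numpy as np
import pytest

from ervreg.crispri import (
    CoverageTrack,
    GuideSpec,
    classify_dcas9_peaks,
    guide_matches,
    predict_guide_targets,
    proximal_genes,
    signal_log2_ratio,
)
from ervreg.genes import GeneModel
from ervreg.genome import GenomeLayout, Interval, RepeatAnnotation, RepeatElement

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_RC)[::-1]


def _two_family_annotation():
    els = []
    for i in range(250):
        els.append(RepeatElement("chr1", i * 3_000, i * 3_000 + 400, "LTR2B", f"LTR2B_{i:03d}"))
    for i in range(120):
        els.append(RepeatElement("chr2", i * 3_000, i * 3_000 + 350, "LTR2", f"LTR2_{i:03d}"))
    return RepeatAnnotation(els)


def test_classification_precedence_for_dual_overlap():
    ann = RepeatAnnotation([
        RepeatElement("chr1", 100, 500, "LTR2B", "b0"),
        RepeatElement("chr1", 400, 800, "LTR2", "a0"),
    ])
    peaks = [Interval("chr1", 350, 450)]  # overlaps both families
    classes, counts = classify_dcas9_peaks(peaks, ann, ["LTR2B", "LTR2"])
    assert classes[0].klass == "LTR2B"
    assert counts == {"LTR2B": 1, "LTR2": 0, "off_target": 0}


def test_class_counts_partition_peaks():
    rng = np.random.default_rng(0)
    ann = _two_family_annotation()
    peaks = [Interval(("chr1" if rng.random() < 0.5 else "chr2"),
                      int(s), int(s) + 200)
             for s in rng.integers(0, 700_000, size=300)]
    classes, counts = classify_dcas9_peaks(peaks, ann, ["LTR2B", "LTR2"])
    assert sum(counts.values()) == len(peaks)
    # brute-force reclassification
    for pc in classes:
        b = any(pc.peak.overlaps(e.as_interval())
                for e in ann.family_elements("LTR2B"))
        a = any(pc.peak.overlaps(e.as_interval())
                for e in ann.family_elements("LTR2"))
        expected = "LTR2B" if b else ("LTR2" if a else "off_target")
        assert pc.klass == expected


def test_empty_target_families_rejected():
    ann = _two_family_annotation()
    with pytest.raises(ValueError):
        classify_dcas9_peaks([], ann, [])


# ---------------------------------------------------------------------------
# coverage ratios
# ---------------------------------------------------------------------------

def _flat_track(value, length=10_000, chrom="chr1"):
    return CoverageTrack({chrom: (np.array([0]), np.array([length]),
                                  np.array([float(value)]))})


def test_identical_tracks_zero_ratio():
    t = _flat_track(2.0)
    peaks = [Interval("chr1", 4_000, 4_200)]
    (r,) = signal_log2_ratio(t, t, peaks)
    assert r.log2_ratio == pytest.approx(0.0)


def test_fourfold_ratio_approaches_two_with_small_pseudocount():
    sg, ctrl = _flat_track(4.0), _flat_track(1.0)
    peaks = [Interval("chr1", 4_000, 4_200)]
    (r,) = signal_log2_ratio(sg, ctrl, peaks, pseudocount=1e-9)
    assert r.log2_ratio == pytest.approx(2.0, abs=1e-6)
    assert r.signal_sg == pytest.approx(4.0 * 1_000)


def test_ratio_antisymmetric_under_track_swap():
    rng = np.random.default_rng(1)
    starts = np.arange(0, 10_000, 100)
    sg = CoverageTrack({"chr1": (starts, starts + 100, rng.random(100) + 0.1)})
    ctrl = CoverageTrack({"chr1": (starts, starts + 100, rng.random(100) + 0.1)})
    peaks = [Interval("chr1", int(s), int(s) + 300) for s in rng.integers(500, 9_000, 20)]
    fwd = signal_log2_ratio(sg, ctrl, peaks, pseudocount=0.5)
    rev = signal_log2_ratio(ctrl, sg, peaks, pseudocount=0.5)
    for a, b in zip(fwd, rev):
        assert a.log2_ratio == pytest.approx(-b.log2_ratio)


def test_window_truncated_at_chromosome_ends():
    genome = GenomeLayout({"chr1": 1_000})
    t = _flat_track(1.0, length=1_000)
    (r,) = signal_log2_ratio(t, t, [Interval("chr1", 0, 100)], genome=genome)
    assert r.truncated
    assert r.signal_sg == pytest.approx(550.0)  # [0, 550) instead of [-450, 550)


def test_window_sum_partial_overlaps():
    t = CoverageTrack({"chr1": (np.array([0, 100]), np.array([100, 200]),
                                np.array([1.0, 3.0]))})
    assert t.window_sum("chr1", 50, 150) == pytest.approx(50 * 1.0 + 50 * 3.0)
    assert t.window_sum("chr1", 300, 400) == 0.0


def test_planted_depletion_separates_on_and_off_target(dataset):
    """On-target peaks show depleted H3K27ac and gained H3K9me3."""
    peaks = dataset.dcas9_peaks.peaks
    classes, _ = classify_dcas9_peaks(
        peaks, dataset.repeats, list(dataset.config.crispri.target_families))
    for mark, expect_sign in (("H3K27ac", -1), ("H3K9me3", +1)):
        ratios = signal_log2_ratio(
            dataset.coverage[(mark, "sgRNA")], dataset.coverage[(mark, "control")],
            peaks, dataset.genome, mark)
        on = [r.log2_ratio for r, c in zip(ratios, classes) if c.klass != "off_target"]
        off = [r.log2_ratio for r, c in zip(ratios, classes) if c.klass == "off_target"]
        assert expect_sign * (np.median(on) - np.median(off)) > 0.3
        # off-target peaks sit mostly in unmodified coverage
        assert np.median(off) == pytest.approx(0.0, abs=0.1)


# ---------------------------------------------------------------------------
# proximal genes
# ---------------------------------------------------------------------------

def test_proximal_genes_distance_boundary():
    peaks = [Interval("chr1", 100_000, 100_200)]
    genes = [GeneModel("in49kb", Interval("chr1", 49_000, 51_000)),
             GeneModel("out51kb", Interval("chr1", 20_000, 48_999)),
             GeneModel("other_chrom", Interval("chr2", 100_000, 101_000))]
    df = proximal_genes(peaks, genes, max_dist=50_000)
    assert set(df.gene) == {"in49kb"}


def test_proximal_genes_joins_de_table():
    import pandas as pd
    peaks = [Interval("chr1", 10_000, 10_200)]
    genes = [GeneModel("g1", Interval("chr1", 12_000, 13_000))]
    de = pd.DataFrame({"log2FC": [-1.5], "padj": [0.01]}, index=["g1"])
    df = proximal_genes(peaks, genes, de_table=de)
    assert df.iloc[0].log2FC == -1.5


# ---------------------------------------------------------------------------
# guide matching
# ---------------------------------------------------------------------------

def test_exact_match_counts():
    guide = GuideSpec("ACGTACGTACGTACGTACGT", max_mismatches=0)
    seqs = {"FAM": {
        "e1": "TT" + guide.protospacer + "GG",
        "e2": "T" * 60,
        "e3": guide.protospacer,
        "e4": "G" * 30 + guide.protospacer[:10],  # partial only
        "e5": "C" + guide.protospacer + "A",
        "e6": "A" * 40, "e7": "C" * 40, "e8": "G" * 40, "e9": "T" * 40,
        "e10": "AC" * 20,
    }}
    df = predict_guide_targets([guide], seqs)
    assert df.iloc[0].copies_hit == 3
    assert df.iloc[0].fraction == pytest.approx(0.3)


def test_reverse_complement_counted():
    guide = GuideSpec("ACGTACGTACGTACGTAAAA", max_mismatches=0)
    seq = "GG" + _revcomp(guide.protospacer) + "CC"
    assert guide_matches(seq, guide)


def test_matching_invariant_under_reverse_complementing_sequences():
    rng = np.random.default_rng(2)
    guide = GuideSpec("".join(rng.choice(list("ACGT"), 20)), max_mismatches=2)
    seqs = {"FAM": {f"e{i}": "".join(rng.choice(list("ACGT"), 80)) for i in range(30)}}
    seqs["FAM"]["e0"] = "AA" + guide.protospacer + "TT"
    rc = {"FAM": {k: _revcomp(v) for k, v in seqs["FAM"].items()}}
    a = predict_guide_targets([guide], seqs)
    b = predict_guide_targets([guide], rc)
    assert a.iloc[0].copies_hit == b.iloc[0].copies_hit


def test_hamming_matching_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    guide = GuideSpec("".join(rng.choice(list("ACGT"), 12)), max_mismatches=2)

    def brute(seq):
        best = len(guide.protospacer) + 1
        for s in (seq, _revcomp(seq)):
            for off in range(len(s) - 12 + 1):
                d = sum(1 for a, b in zip(s[off:off + 12], guide.protospacer)
                        if a != b or a not in "ACGT")
                best = min(best, d)
        return best <= 2

    for _ in range(300):
        seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(12, 60)),
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        assert guide_matches(seq, guide) == brute(seq)


def test_short_sequences_skipped_and_counted():
    guide = GuideSpec("ACGTACGTACGTACGTACGT")
    df = predict_guide_targets([guide], {"FAM": {"e1": "ACGT"}})
    assert df.iloc[0].n_skipped == 1 and df.iloc[0].copies_hit == 0


def test_pam_requirement():
    guide = GuideSpec("ACGTACGTACGTACGTACGT", max_mismatches=0, pam="NGG")
    assert guide_matches("TT" + guide.protospacer + "TGG", guide)
    assert not guide_matches("TT" + guide.protospacer + "TTT", guide)


def test_synthetic_guide_targets_recovered(dataset):
    """Guide target predictions agree with the generator's manifest."""
    df = predict_guide_targets(
        dataset.guides,
        {f: dataset.element_seqs[f] for f in dataset.config.crispri.target_families},
    )
    truth = dataset.truth.guide_target_elements
    for _, row in df.iterrows():
        assert row.copies_hit == len(truth[row.family])
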