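"""PWM scanning, TF-family enrichment and DHS motif contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ervreg.genome import GenomeLayout, Interval, PeakSet, RepeatAnnotation, RepeatElement
from ervreg.motifs import (
    PWM,
    consensus_motif_map,
    dhs_motif_contrast,
    motif_family_frequency,
    read_meme,
    scan_pwm,
    scan_pwm_counts,
    tf_enrichment_grid,
    tf_family_enrichment,
    write_meme,
)

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_RC)[::-1]


def _random_pwm(rng, L, motif_id="m"):
    mat = rng.dirichlet(np.ones(4), size=L)
    return PWM(motif_id, mat)


def _consensus_pwm(seq):
    mat = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        mat[i, "ACGT".index(b)] = 1.0
    return PWM("cons", mat)


def _brute_scores(seq, pwm):
    """Direct python-loop log2-odds scores on both strands."""
    lo = pwm.log_odds()
    out = {}
    L = len(pwm)
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = mat.log_odds()
        for off in range(len(seq) - L + 1):
            window = seq[off:off + L]
            if set(window) - set("ACGT"):
                continue
            out[(off, strand)] = sum(
                lo[j, "ACGT".index(b)] for j, b in enumerate(window)
            )
    return out


def test_uniform_pwm_scores_zero_everywhere():
    pwm = PWM("uni", np.full((4, 4), 0.25))
    seq = "ACGTACGTAC"
    hits = scan_pwm(seq, pwm, threshold=0.0)
    # every window on both strands scores exactly 0 >= 0
    assert len(hits) == 2 * (len(seq) - 4 + 1)
    assert all(h.score == pytest.approx(0.0) for h in hits)


def test_consensus_pwm_closed_form():
    pwm = _consensus_pwm("ACGT")
    hits = [h for h in scan_pwm("TTACGTTT", pwm, threshold=7.9) if h.strand == "+"]
    assert len(hits) == 1
    assert hits[0].offset == 2
    assert hits[0].score == pytest.approx(4 * np.log2(1 / 0.25))


def test_scan_matches_exhaustive_window_oracle():
    rng = np.random.default_rng(0)
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pwm = _random_pwm(rng, 8)
        expected = _brute_scores(seq, pwm)
        got = {(h.offset, h.strand): h.score
               for h in scan_pwm(seq, pwm, threshold=-np.inf)}
        assert set(got) == set(expected)
        for k in expected:
            assert got[k] == pytest.approx(expected[k])


def test_strand_symmetry_property():
    """Hits on the reverse complement mirror offsets and flip strand."""
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    pwm = _random_pwm(rng, 7)
    fwd = scan_pwm(seq, pwm, threshold=2.0)
    rev = scan_pwm(_revcomp(seq), pwm, threshold=2.0)
    L = len(pwm)
    mirrored = {(len(seq) - h.offset - L, {"+": "-", "-": "+"}[h.strand],
                 round(h.score, 6)) for h in rev}
    assert {(h.offset, h.strand, round(h.score, 6)) for h in fwd} == mirrored


def test_non_acgt_windows_skipped_and_counted():
    pwm = _consensus_pwm("ACGT")
    hits, skipped = scan_pwm_counts("ACNGTACGT", pwm, threshold=-100)
    assert skipped == 3  # windows covering the N at position 2
    assert all("N" not in "ACNGTACGT"[h.offset:h.offset + 4] for h in hits)


def test_meme_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    pwms = [_random_pwm(rng, 6, "a"), _random_pwm(rng, 9, "b")]
    path = tmp_path / "m.meme"
    write_meme(pwms, path)
    back = read_meme(path)
    assert [p.motif_id for p in back] == ["a", "b"]
    for orig, rt in zip(pwms, back):
        assert np.allclose(orig.matrix, rt.matrix, atol=2e-5)


def test_pwm_validation():
    with pytest.raises(ValueError):
        PWM("bad", np.full((4, 4), 0.3))
    with pytest.raises(ValueError):
        PWM("bad", np.full((4, 3), 1 / 3))


# ---------------------------------------------------------------------------
# TF enrichment
# ---------------------------------------------------------------------------

def _tf_fixture(bound_frac, n_elements=60, seed=0):
    rng = np.random.default_rng(seed)
    genome = GenomeLayout({"chr1": 500_000})
    els = [RepeatElement("chr1", i * 5_000, i * 5_000 + 300, "FAM", f"FAM_{i:03d}")
           for i in range(n_elements)]
    peaks = [Interval("chr1", e.start + 100, e.start + 200)
             for e in els[: int(bound_frac * n_elements)]]
    ps = PeakSet("tf_rep1", "TF:TAL1", "cell_line", peaks)
    return genome, RepeatAnnotation(els), ps


def test_tf_enrichment_null_table_not_selected():
    genome, ann, _ = _tf_fixture(0.0)
    # TF peaks that blanket the genome hit real and shuffled equally
    peaks = [Interval("chr1", i * 1_000, i * 1_000 + 999) for i in range(500)]
    ps = PeakSet("tf", "TF:TAL1", "cell_line", peaks)
    (res,) = tf_family_enrichment(ps, ann, genome, seed=0)
    assert res.n_bound == res.n_bound_shuffled == len(ann.elements)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)


def test_tf_selection_requires_coverage_and_q():
    genome, ann, ps = _tf_fixture(0.5)
    grid = tf_enrichment_grid([ps], ann, genome, seed=1)
    row = grid.iloc[0]
    assert row.selected and row.frac_bound >= 0.05 and row.q < 0.05

    # strong q but coverage below 5% of elements: not selected
    genome2, ann2, ps2 = _tf_fixture(0.04, n_elements=200)
    grid2 = tf_enrichment_grid([ps2], ann2, genome2, seed=1)
    assert not grid2.iloc[0].selected


def test_fisher_p_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(3)
    from scipy.stats import fisher_exact
    for _ in range(200):
        n1, n2 = int(rng.integers(1, 50)), int(rng.integers(1, 50))
        a = int(rng.integers(0, n1 + 1))
        b = int(rng.integers(0, n2 + 1))
        _, p = fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="two-sided")
        # enumeration: sum of hypergeometric point masses <= P(observed)
        N, K, n = n1 + n2, a + b, n1
        p_obs = hypergeom.pmf(a, N, K, n)
        total = sum(
            hypergeom.pmf(k, N, K, n)
            for k in range(max(0, K - (N - n)), min(K, n) + 1)
            if hypergeom.pmf(k, N, K, n) <= p_obs * (1 + 1e-9)
        )
        assert p == pytest.approx(min(total, 1.0), rel=1e-6, abs=1e-12)


def test_replicate_averaging_groups_by_tf():
    genome, ann, ps1 = _tf_fixture(0.5, seed=4)
    _, _, ps2 = _tf_fixture(0.4, seed=5)
    ps2 = PeakSet("tf_rep2", "TF:TAL1", "cell_line", ps2.peaks)
    grid = tf_enrichment_grid([ps1, ps2], ann, genome, seed=2)
    assert len(grid) == 1
    assert grid.iloc[0].n_replicates == 2
    assert grid.iloc[0].frac_bound == pytest.approx((0.5 + 0.4) / 2)


# ---------------------------------------------------------------------------
# frequencies and contrasts
# ---------------------------------------------------------------------------

def test_motif_family_frequency_limits():
    ann = RepeatAnnotation(
        [RepeatElement("chr1", i * 1_000, i * 1_000 + 100, "FAM", f"FAM_{i}")
         for i in range(4)]
    )
    from ervreg.motifs import MotifHit
    none = motif_family_frequency({e.element_id: [] for e in ann.elements}, ann)
    assert none["FAM"] == 0.0
    all_hit = motif_family_frequency(
        {e.element_id: [MotifHit(e.element_id, 0, "+", 5.0)] for e in ann.elements}, ann
    )
    assert all_hit["FAM"] == 1.0


def test_consensus_map_recovers_planted_motif(dataset):
    fam = dataset.truth.enriched_families[0]
    df = consensus_motif_map({fam: dataset.consensus[fam]},
                             dataset.planted_pwms, threshold=6.0)
    offs = dataset.truth.planted_motif_offsets[fam]
    for pwm, off in zip(dataset.planted_pwms, offs):
        sub = df[(df.motif == pwm.motif_id) & (df.strand == "+")]
        assert off in set(sub.offset)


def test_consensus_map_reverse_complement_mirrors(dataset):
    fam = dataset.truth.enriched_families[0]
    seq = dataset.consensus[fam]
    fwd = consensus_motif_map({fam: seq}, dataset.planted_pwms, 6.0)
    rev = consensus_motif_map({fam: _revcomp(seq)}, dataset.planted_pwms, 6.0)
    for pwm in dataset.planted_pwms:
        L = len(pwm)
        f = {(r.offset, r.strand) for r in fwd[fwd.motif == pwm.motif_id].itertuples()}
        r = {(len(seq) - r.offset - L, {"+": "-", "-": "+"}[r.strand])
             for r in rev[rev.motif == pwm.motif_id].itertuples()}
        assert f == r


def test_dhs_contrast_perfect_separation_and_bh_monotone():
    hits = {}
    counts = {}
    for i in range(30):
        eid = f"e{i}"
        pos = i < 15
        counts[eid] = 6 if pos else 0
        hits[eid] = {"m_perfect": pos, "m_flat": True}
    df = dhs_motif_contrast(hits, counts, min_pos_samples=5)
    perfect = df[df.motif == "m_perfect"].iloc[0]
    flat = df[df.motif == "m_flat"].iloc[0]
    assert perfect.q < 0.01
    assert flat.p == pytest.approx(1.0)
    # BH never reorders q against p
    df_sorted = df.sort_values("p")
    assert (df_sorted.q.diff().dropna() >= -1e-12).all()


def test_dhs_contrast_excludes_intermediate_elements():
    hits = {f"e{i}": {"m": i % 2 == 0} for i in range(12)}
    counts = {f"e{i}": (6 if i < 4 else (2 if i < 8 else 0)) for i in range(12)}
    df = dhs_motif_contrast(hits, counts, min_pos_samples=5)
    assert df.iloc[0].n_pos == 4 and df.iloc[0].n_neg == 4


def test_dhs_contrast_requires_both_classes():
    with pytest.raises(ValueError):
        dhs_motif_contrast({"e0": {"m": True}}, {"e0": 6}, min_pos_samples=5)
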