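"""TF peak enrichment at element families, PWM motif scanning, and
DHS+/DHS- motif contrasts.

TF binding enrichment compares the fraction of a family's elements
overlapped by a TF's peaks against one length-preserving shuffle of the
elements (same shuffle engine as the open-chromatin null), with a
two-sided Fisher exact test on the resulting 2x2 table and
Benjamini-Hochberg correction across the TF x family grid.  A TF is
selected for a family when q < 0.05 and it covers at least 5% of the
family's elements.

Motif scanning is a log2-odds PWM scan of both strands, FIMO-style but
not bit-compatible with it: score(window) = sum log2(p_motif/p_background)
with zero probabilities smoothed to 1e-4, hit when score >= threshold.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genome import (
    GenomeLayout,
    MergedIntervals,
    PeakSet,
    RepeatAnnotation,
    shuffle_intervals,
)

__all__ = [
    "PWM",
    "MotifHit",
    "TFEnrichmentResult",
    "read_meme",
    "scan_pwm",
    "tf_family_enrichment",
    "tf_enrichment_grid",
    "motif_family_frequency",
    "consensus_motif_map",
    "dhs_motif_contrast",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_PSEUDO = 1e-4


@dataclass(frozen=True, eq=False)
class PWM:
    """Position probability matrix with background, scored as log2-odds."""

    motif_id: str
    matrix: np.ndarray              # L x 4, columns A,C,G,T; rows sum to 1
    background: np.ndarray = None   # length 4, sums to 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = self.background
        bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be L x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: position probabilities must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """L x 4 log2-odds with zero probabilities smoothed to 1e-4."""
        p = np.maximum(self.matrix, _PSEUDO)
        bg = np.maximum(self.background, _PSEUDO)
        return np.log2(p / bg[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])


@dataclass(frozen=True)
class MotifHit:
    element_id: str
    offset: int      # bp from element/sequence start (forward coordinates)
    strand: str
    score: float


@dataclass(frozen=True)
class TFEnrichmentResult:
    tf: str
    family: str
    n_bound: int
    n_elements: int
    frac_bound: float
    n_bound_shuffled: int
    odds_ratio: float
    enrichment: float  # frac_bound / max(frac_bound_shuffled, eps)
    p: float
    q: float = float("nan")
    selected: bool = False


def read_meme(path) -> list[PWM]:
    """Read a MEME-format motif file (minimal format) via Biopython."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    bg = getattr(record, "background", None)
    background = (
        np.asarray([bg[b] for b in _BASES], dtype=float) if bg else np.full(4, 0.25)
    )
    out = []
    for m in record:
        pwm = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in _BASES])
        out.append(PWM(m.name or m.base_id, pwm, background))
    return out


def write_meme(pwms: Sequence[PWM], path) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(_BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                # large nsites keeps probability -> count -> probability
                # conversion in downstream parsers lossless
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 100000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_LUT = np.full(256, 4, dtype=np.int64)
for _b, _i in _CODE.items():
    _LUT[ord(_b)] = _i


def scan_pwm(seq: str, pwm: PWM, threshold: float, element_id: str = "") -> list[MotifHit]:
    """Scan both strands of ``seq``; hits are windows scoring >= threshold.

    Offsets are relative to the forward sequence start for both strands.
    Windows containing non-ACGT characters are skipped (their count is not
    returned here; use :func:`scan_pwm_counts` when it matters).
    """
    hits, _ = scan_pwm_counts(seq, pwm, threshold, element_id)
    return hits


def scan_pwm_counts(seq: str, pwm: PWM, threshold: float,
                    element_id: str = "") -> tuple[list[MotifHit], int]:
    L = len(pwm)
    codes = _LUT[_encode(seq)]
    n = len(codes)
    if n < L:
        return [], 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows < 4).all(axis=1)
    n_skipped = int((~valid).sum())
    hits: list[MotifHit] = []
    pos_idx = np.arange(L)
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = mat.log_odds()
        safe = np.where(windows < 4, windows, 0)
        scores = lo[pos_idx, safe].sum(axis=1)
        for off in np.nonzero(valid & (scores >= threshold))[0]:
            hits.append(MotifHit(element_id, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits, n_skipped


def tf_family_enrichment(
    tf_peaks: PeakSet,
    elements: RepeatAnnotation,
    genome: GenomeLayout,
    seed: int | np.random.Generator = 0,
    min_frac: float = 0.05,
) -> list[TFEnrichmentResult]:
    """Per-family TF binding enrichment versus one shuffled element control.

    2x2 table: (bound, unbound) x (real, shuffled); two-sided Fisher exact
    p.  q-values and the ``selected`` flag are filled in later by
    :func:`tf_enrichment_grid` (BH runs across the whole TF x family grid).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tf = tf_peaks.assay.removeprefix("TF:")
    peak_idx = MergedIntervals(tf_peaks.peaks)
    out = []
    eps = 1e-9
    for family in elements.families:
        fam = elements.family_elements(family)
        if not fam:
            raise ValueError(f"family {family!r} has no elements")
        ivs = [e.as_interval() for e in fam]
        n = len(ivs)
        n_bound = int(peak_idx.any_overlap(ivs).sum())
        shuffled = shuffle_intervals(ivs, genome, rng)
        n_bound_shuf = int(peak_idx.any_overlap(shuffled).sum())
        table = [[n_bound, n - n_bound], [n_bound_shuf, n - n_bound_shuf]]
        odds, p = fisher_exact(table, alternative="two-sided")
        if not np.isfinite(odds):
            # Haldane-Anscombe continuity correction for degenerate tables
            a, b = n_bound + 0.5, n - n_bound + 0.5
            c, d = n_bound_shuf + 0.5, n - n_bound_shuf + 0.5
            odds = (a * d) / (b * c)
        frac = n_bound / n
        frac_shuf = n_bound_shuf / n
        out.append(
            TFEnrichmentResult(
                tf=tf, family=family, n_bound=n_bound, n_elements=n,
                frac_bound=frac, n_bound_shuffled=n_bound_shuf,
                odds_ratio=float(odds),
                enrichment=frac / max(frac_shuf, eps),
                p=float(p),
            )
        )
    return out


def tf_enrichment_grid(
    tf_peaksets: Sequence[PeakSet],
    elements: RepeatAnnotation,
    genome: GenomeLayout,
    seed: int = 0,
    min_frac: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full TF x family grid with BH correction and replicate averaging.

    Replicate peak sets of the same TF (same ``TF:<name>`` assay) are each
    tested, then averaged per (tf, family); the replicate-minimum q and the
    mean fraction drive selection.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ps in tf_peaksets:
        for r in tf_family_enrichment(ps, elements, genome, rng, min_frac):
            rows.append((r.tf, ps.sample_id, r.family, r.n_bound, r.n_elements,
                         r.frac_bound, r.n_bound_shuffled, r.odds_ratio,
                         r.enrichment, r.p))
    df = pd.DataFrame(rows, columns=["tf", "replicate", "family", "n_bound",
                                     "n_elements", "frac_bound", "n_bound_shuffled",
                                     "odds_ratio", "enrichment", "p"])
    if df.empty:
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    agg = df.groupby(["tf", "family"], as_index=False).agg(
        n_replicates=("replicate", "nunique"),
        frac_bound=("frac_bound", "mean"),
        enrichment=("enrichment", "mean"),
        odds_ratio=("odds_ratio", "mean"),
        p=("p", "min"),
        q=("q", "min"),
    )
    agg["selected"] = (agg["q"] < alpha) & (agg["frac_bound"] >= min_frac)
    return agg


def motif_family_frequency(
    hits_by_element: Mapping[str, Sequence[MotifHit]],
    elements: RepeatAnnotation,
) -> pd.Series:
    """Fraction of each family's elements carrying >=1 motif hit."""
    has_hit = {eid: bool(h) for eid, h in hits_by_element.items()}
    counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for e in elements.elements:
        totals[e.family] = totals.get(e.family, 0) + 1
        if has_hit.get(e.element_id, False):
            counts[e.family] = counts.get(e.family, 0) + 1
    return pd.Series(
        {f: counts.get(f, 0) / totals[f] for f in sorted(totals)}, name="frac_with_motif"
    )


def consensus_motif_map(
    consensus: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold: float = 6.0,
) -> pd.DataFrame:
    """Scan family consensus sequences for each motif; returns a hit table
    (family, motif, offset, strand, score)."""
    rows = []
    for family, seq in consensus.items():
        for pwm in pwms:
            for h in scan_pwm(seq, pwm, threshold, element_id=family):
                rows.append((family, pwm.motif_id, h.offset, h.strand, h.score))
    return pd.DataFrame(rows, columns=["family", "motif", "offset", "strand", "score"])


def dhs_motif_contrast(
    hits_by_element: Mapping[str, Mapping[str, bool]],
    dhs_counts: Mapping[str, int],
    min_pos_samples: int = 5,
) -> pd.DataFrame:
    """Motif frequency in open (DHS+) versus closed (DHS-) elements.

    DHS+ = open in >= ``min_pos_samples`` samples, DHS- = open in none;
    in-between elements are excluded.  ``hits_by_element`` maps element ->
    motif -> has-hit.  Two-sided Fisher p per motif, BH q across motifs.
    """
    pos = [e for e, c in dhs_counts.items() if c >= min_pos_samples]
    neg = [e for e, c in dhs_counts.items() if c == 0]
    if not pos or not neg:
        raise ValueError("both DHS+ and DHS- classes must be non-empty")
    motifs = sorted({m for per in hits_by_element.values() for m in per})
    rows = []
    for m in motifs:
        a = sum(1 for e in pos if hits_by_element.get(e, {}).get(m, False))
        b = sum(1 for e in neg if hits_by_element.get(e, {}).get(m, False))
        table = [[a, len(pos) - a], [b, len(neg) - b]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append((m, len(pos), len(neg), a / len(pos), b / len(neg),
                     float(odds), float(p)))
    df = pd.DataFrame(rows, columns=["motif", "n_pos", "n_neg", "freq_pos",
                                     "freq_neg", "odds_ratio", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
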