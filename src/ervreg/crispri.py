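"""CRISPRi epigenome-editing evaluation.

Classifies dCas9 binding peaks as on-target (overlapping one of the
targeted repeat families, with a stated precedence order) or off-target,
quantifies histone-mark coverage changes in fixed windows around peak
centres between the guide-expressing and control conditions, links peaks
to genes within a distance window, and predicts how many copies of a
family a set of guides can recognise by Hamming-distance matching of the
protospacers against element sequences (both strands).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Interval, PeakSet, RepeatAnnotation, MergedIntervals
from .genes import GeneModel, interval_distance

__all__ = [
    "PeakClassification",
    "SignalRatio",
    "GuideSpec",
    "CoverageTrack",
    "read_bedgraph",
    "classify_dcas9_peaks",
    "signal_log2_ratio",
    "proximal_genes",
    "predict_guide_targets",
]

OFF_TARGET = "off_target"


@dataclass(frozen=True)
class PeakClassification:
    peak: Interval
    klass: str  # a target family name, or "off_target"


@dataclass(frozen=True)
class SignalRatio:
    peak: Interval
    mark: str
    halfwidth: int
    signal_sg: float
    signal_ctrl: float
    log2_ratio: float
    truncated: bool = False


@dataclass(frozen=True)
class GuideSpec:
    protospacer: str
    max_mismatches: int = 0
    pam: str | None = None  # e.g. "NGG"; None disables PAM checking

    def __post_init__(self) -> None:
        if set(self.protospacer.upper()) - set("ACGT"):
            raise ValueError("protospacer must be over ACGT")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        object.__setattr__(self, "protospacer", self.protospacer.upper())


class CoverageTrack:
    """Per-base coverage from a bedGraph, stored as sorted step intervals."""

    def __init__(self, per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # per chrom: (starts, ends, values), sorted, non-overlapping
        self._per_chrom = dict(per_chrom)

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                per.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), float(parts[3]))
                )
        out = {}
        for chrom, rows in per.items():
            rows.sort()
            out[chrom] = (
                np.asarray([r[0] for r in rows], dtype=np.int64),
                np.asarray([r[1] for r in rows], dtype=np.int64),
                np.asarray([r[2] for r in rows], dtype=float),
            )
        return cls(out)

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end)."""
        if chrom not in self._per_chrom or end <= start:
            return 0.0
        s, e, v = self._per_chrom[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float((np.maximum(ov, 0) * v[lo:hi]).sum())


def read_bedgraph(path) -> CoverageTrack:
    return CoverageTrack.from_bedgraph(path)


def classify_dcas9_peaks(
    peaks: PeakSet | Sequence[Interval],
    repeats: RepeatAnnotation,
    target_families: Sequence[str],
) -> tuple[list[PeakClassification], dict[str, int]]:
    """Assign each peak to the first target family (in precedence order)
    whose elements it overlaps, else off_target.  The class counts always
    partition the peak set."""
    if not target_families:
        raise ValueError("target_families must be non-empty")
    ivs = list(peaks.peaks if isinstance(peaks, PeakSet) else peaks)
    fam_idx = {
        f: MergedIntervals(e.as_interval() for e in repeats.family_elements(f))
        for f in target_families
    }
    out = []
    counts = {f: 0 for f in target_families}
    counts[OFF_TARGET] = 0
    masks = {f: fam_idx[f].any_overlap(ivs) for f in target_families}
    for i, p in enumerate(ivs):
        klass = OFF_TARGET
        for f in target_families:
            if masks[f][i]:
                klass = f
                break
        counts[klass] += 1
        out.append(PeakClassification(p, klass))
    assert sum(counts.values()) == len(ivs)
    return out, counts


def signal_log2_ratio(
    cov_sg: CoverageTrack,
    cov_ctrl: CoverageTrack,
    peaks: Sequence[Interval],
    genome: GenomeLayout | None = None,
    mark: str = "",
    halfwidth: int = 500,
    pseudocount: float = 1.0,
) -> list[SignalRatio]:
    """log2((sg + c) / (ctrl + c)) of summed coverage in the window
    [centre - halfwidth, centre + halfwidth) around each peak centre
    (centre = floor((start+end)/2)).  Windows crossing chromosome ends are
    truncated to bounds and flagged."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out = []
    for p in peaks:
        centre = (p.start + p.end) // 2
        lo, hi = centre - halfwidth, centre + halfwidth
        truncated = False
        if lo < 0:
            lo, truncated = 0, True
        if genome is not None and p.chrom in genome.chroms and hi > genome.chroms[p.chrom]:
            hi, truncated = genome.chroms[p.chrom], True
        sg = cov_sg.window_sum(p.chrom, lo, hi)
        ctrl = cov_ctrl.window_sum(p.chrom, lo, hi)
        out.append(
            SignalRatio(
                peak=p, mark=mark, halfwidth=halfwidth, signal_sg=sg,
                signal_ctrl=ctrl,
                log2_ratio=float(np.log2((sg + pseudocount) / (ctrl + pseudocount))),
                truncated=truncated,
            )
        )
    return out


def proximal_genes(
    peaks: Sequence[Interval | PeakClassification],
    genes: Sequence[GeneModel],
    max_dist: int = 50_000,
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genes within ``max_dist`` of >=1 peak, annotated with the nearest
    peak's class; optionally joined to a differential-expression table
    indexed by gene (columns log2FC, padj preserved as given)."""
    classed = [
        (pc.peak, pc.klass) if isinstance(pc, PeakClassification) else (pc, "")
        for pc in peaks
    ]
    rows = []
    for g in genes:
        best = None
        for p, klass in classed:
            if p.chrom != g.span.chrom:
                continue
            d = interval_distance(g.span, p)
            if d <= max_dist and (best is None or d < best[0]):
                best = (d, klass)
        if best is not None:
            rows.append((g.gene_id, best[0], best[1]))
    df = pd.DataFrame(rows, columns=["gene", "distance", "nearest_peak_class"])
    if de_table is not None and not df.empty:
        df = df.join(de_table, on="gene")
    return df


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _min_hamming(seq: str, pattern: str) -> int:
    """Minimum Hamming distance of ``pattern`` over all windows of ``seq``
    (forward orientation only); ambiguity codes count as mismatches."""
    L = len(pattern)
    if len(seq) < L:
        return L + 1
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    acgt = np.isin(windows, np.frombuffer(b"ACGT", dtype=np.uint8))
    mism = (windows != pat[None, :]) | ~acgt
    return int(mism.sum(axis=1).min())


def guide_matches(seq: str, guide: GuideSpec) -> bool:
    """Does the guide recognise this sequence on either strand?"""
    for s in (seq.upper(), _revcomp(seq.upper())):
        if _min_hamming(s, guide.protospacer) <= guide.max_mismatches:
            if guide.pam is None:
                return True
            if _pam_adjacent(s, guide):
                return True
    return False


def _pam_adjacent(seq: str, guide: GuideSpec) -> bool:
    """PAM immediately 3' of a matching protospacer window."""
    L = len(guide.protospacer)
    pam = guide.pam.upper()
    codes = seq.upper()
    for off in range(len(codes) - L + 1):
        window = codes[off:off + L]
        mism = sum(1 for a, b in zip(window, guide.protospacer)
                   if a != b or a not in "ACGT")
        if mism > guide.max_mismatches:
            continue
        tail = codes[off + L: off + L + len(pam)]
        if len(tail) == len(pam) and all(
            p == "N" or p == t for p, t in zip(pam, tail)
        ):
            return True
    return False


def predict_guide_targets(
    guides: Sequence[GuideSpec],
    element_seqs: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Per family: how many copies are recognised by >=1 guide.

    ``element_seqs`` maps family -> element_id -> sequence.  An element is
    recognised when any guide matches either strand within the guide's
    mismatch budget (and adjacent PAM when configured).  Elements shorter
    than the protospacer are skipped and counted.
    """
    rows = []
    for family in sorted(element_seqs):
        seqs = element_seqs[family]
        n_hit = 0
        n_skipped = 0
        for eid in sorted(seqs):
            seq = seqs[eid]
            if all(len(seq) < len(g.protospacer) for g in guides):
                n_skipped += 1
                continue
            if any(guide_matches(seq, g) for g in guides):
                n_hit += 1
        n = len(seqs)
        rows.append((family, n_hit, n, n_hit / n if n else float("nan"), n_skipped))
    return pd.DataFrame(
        rows, columns=["family", "copies_hit", "family_size", "fraction", "n_skipped"]
    )
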