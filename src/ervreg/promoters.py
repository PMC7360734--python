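"""Element-derived promoter discovery.

Spliced (multi-exon) transcripts assembled per sample are screened for
transcription start sites falling inside repeat elements; elements whose
TSS activity is seen in two or more disease samples but in no
differentiated sample are called disease-specific element promoters.
Cross-sample identity is element-level: transcripts from different samples
are treated as the same promoter event when they start in the same element
on the same strand.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .genome import Interval, RepeatAnnotation

__all__ = [
    "TranscriptModel",
    "ElementPromoterCall",
    "transcript_tss",
    "read_transcripts_gtf",
    "element_tss_hits",
    "aml_specific_promoters",
    "splices_into_annotated_gene",
]


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    sample_id: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"transcript {self.transcript_id}: unstranded transcripts are rejected"
            )
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def multi_exon(self) -> bool:
        return len(self.exons) >= 2

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


@dataclass
class ElementPromoterCall:
    element_id: str
    family: str
    aml_samples_with_tss: set[str] = field(default_factory=set)
    diff_samples_with_tss: set[str] = field(default_factory=set)
    splices_into_gene: bool = False


def transcript_tss(t: TranscriptModel) -> tuple[str, int]:
    """TSS position: first base of the first exon on +, last base of the
    last exon on - (0-based)."""
    if t.strand == "+":
        return (t.chrom, t.exons[0].start)
    return (t.chrom, t.exons[-1].end - 1)


def read_transcripts_gtf(path, sample_id: str, multi_exon_only: bool = True) -> list[TranscriptModel]:
    """Parse a StringTie-style GTF (exon features grouped by transcript_id).

    Unstranded transcripts are dropped with a count kept internally; set
    ``multi_exon_only=False`` to keep single-exon transcripts.
    """
    exons: dict[str, list[Interval]] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if parts[2] != "exon":
                continue
            chrom, start1, end1, strand, attrs = parts[0], parts[3], parts[4], parts[6], parts[8]
            tid = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("transcript_id"):
                    tid = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if tid is None:
                raise ValueError(f"{path}:{lineno}: exon lacks transcript_id")
            # GTF is 1-based inclusive
            exons.setdefault(tid, []).append(Interval(chrom, int(start1) - 1, int(end1)))
            strands[tid] = strand
    out = []
    for tid, ex in exons.items():
        if strands[tid] not in {"+", "-"}:
            continue
        t = TranscriptModel(tid, sample_id, strands[tid], tuple(ex))
        if multi_exon_only and not t.multi_exon:
            continue
        out.append(t)
    out.sort(key=lambda t: t.transcript_id)
    return out


def element_tss_hits(
    transcripts_by_sample: Mapping[str, Sequence[TranscriptModel]],
    elements: RepeatAnnotation,
) -> tuple[dict[str, int], dict[str, dict[str, set[str]]]]:
    """Intersect transcript TSSs with elements.

    A TSS at position p hits an element when element.start <= p <
    element.end (half-open).  Returns (per-sample count of distinct
    transcripts whose TSS lies in any element, element -> strand ->
    samples with a TSS in it).
    """
    # point-in-interval via sorted per-chrom element arrays
    els = elements.elements
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int], int]] = {}
    by_chrom: dict[str, list[int]] = {}
    for i, e in enumerate(els):
        by_chrom.setdefault(e.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: els[i].start)
        starts = np.asarray([els[i].start for i in idxs])
        ends = np.asarray([els[i].end for i in idxs])
        max_len = int((ends - starts).max())
        per_chrom[chrom] = (starts, ends, idxs, max_len)

    counts: dict[str, int] = {}
    hits: dict[str, dict[str, set[str]]] = {}
    for sample, transcripts in transcripts_by_sample.items():
        n = 0
        for t in transcripts:
            chrom, pos = transcript_tss(t)
            if chrom not in per_chrom:
                continue
            starts, ends, idxs, max_len = per_chrom[chrom]
            j = int(np.searchsorted(starts, pos, side="right")) - 1
            hit_any = False
            # elements may nest: scan left while a start could still reach pos
            while j >= 0 and starts[j] > pos - max_len:
                if starts[j] <= pos < ends[j]:
                    e = els[idxs[j]]
                    hits.setdefault(e.element_id, {}).setdefault(t.strand, set()).add(sample)
                    hit_any = True
                j -= 1
            if hit_any:
                n += 1
        counts[sample] = n
    return counts, hits


def aml_specific_promoters(
    hits: Mapping[str, Mapping[str, set[str]]],
    elements: RepeatAnnotation,
    groups: Mapping[str, str],
    min_aml: int = 2,
) -> list[ElementPromoterCall]:
    """Elements with TSS activity in >= ``min_aml`` disease samples and in
    zero differentiated samples.  Activity is pooled per (element, strand)
    and the call requires one strand to satisfy both rules."""
    fam = {e.element_id: e.family for e in elements.elements}
    calls = []
    for element_id, per_strand in sorted(hits.items()):
        for strand, samples in sorted(per_strand.items()):
            aml = {s for s in samples if groups.get(s) == "AML"}
            diff = {s for s in samples if groups.get(s) == "differentiated"}
            if len(aml) >= min_aml and len(diff) == 0:
                calls.append(
                    ElementPromoterCall(
                        element_id=element_id,
                        family=fam.get(element_id, ""),
                        aml_samples_with_tss=aml,
                        diff_samples_with_tss=diff,
                    )
                )
                break  # one call per element
    return calls


def splices_into_annotated_gene(t: TranscriptModel, gene_exons: Iterable[Interval],
                                gene_strand: str | None = None) -> bool:
    """True when any exon after the first (in transcription order)
    overlaps an annotated gene exon on the same strand.

    ``gene_exons`` may carry strand in each Interval; a uniform
    ``gene_strand`` argument overrides it.
    """
    if not t.multi_exon:
        return False
    downstream = t.exons[1:] if t.strand == "+" else t.exons[:-1]
    for ex in downstream:
        for ge in gene_exons:
            gs = gene_strand if gene_strand is not None else ge.strand
            if gs not in {"+", "-"}:
                gs = t.strand  # unstranded annotation: accept
            if gs == t.strand and ex.overlaps(ge):
                return True
    return False
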