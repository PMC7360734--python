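"""Core genomic data types, standard-format I/O and interval arithmetic.

All coordinates are 0-based half-open internally.  Converters at the I/O
boundary handle BED/narrowPeak (native 0-based half-open) and RepeatMasker
``.out`` files (1-based inclusive, converted on read).

The two primitives everything else builds on are

* :class:`MergedIntervals` — a per-chromosome merged interval index that
  answers "does this query overlap anything?" in vectorised form, and
* :class:`IntervalShuffler` — the length-preserving uniform placement of
  intervals into the mappable genome that defines the permutation null of
  the enrichment tests.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Interval",
    "GenomeLayout",
    "RepeatElement",
    "RepeatAnnotation",
    "PeakSet",
    "MergedIntervals",
    "IntervalShuffler",
    "read_intervals",
    "write_bed",
    "count_overlaps",
    "shuffle_intervals",
]

_VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, slots=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """>=1 bp overlap under half-open semantics; strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent intervals; inputs sorted by start."""
    if len(starts) == 0:
        return starts, ends
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class GenomeLayout:
    """Chromosome sizes plus merged excluded (unmappable) regions.

    The excluded regions define the complement of the shuffle space: random
    placements avoid them entirely, mirroring how shuffled peak controls
    avoid unmappable parts of a reference assembly.
    """

    def __init__(self, chroms: Mapping[str, int], excluded: Iterable[Interval] = ()):
        self.chroms: dict[str, int] = dict(chroms)
        if not self.chroms:
            raise ValueError("GenomeLayout requires at least one chromosome")
        for name, length in self.chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in excluded:
            if iv.chrom not in self.chroms:
                raise ValueError(f"excluded interval on unknown chromosome {iv.chrom!r}")
            if iv.end > self.chroms[iv.chrom]:
                raise ValueError(
                    f"excluded interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.chroms[iv.chrom]}"
                )
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._excluded: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, pairs in per_chrom.items():
            pairs.sort()
            s = np.asarray([p[0] for p in pairs], dtype=np.int64)
            e = np.asarray([p[1] for p in pairs], dtype=np.int64)
            self._excluded[name] = _merge_sorted(s, e)

    @property
    def excluded(self) -> list[Interval]:
        out = []
        for name in self.chroms:
            if name in self._excluded:
                s, e = self._excluded[name]
                out.extend(Interval(name, int(a), int(b)) for a, b in zip(s, e))
        return out

    def mappable_gaps(self) -> list[Interval]:
        """Complement of the excluded regions, per chromosome."""
        gaps = []
        for name, length in self.chroms.items():
            pos = 0
            if name in self._excluded:
                s, e = self._excluded[name]
                for a, b in zip(s, e):
                    if a > pos:
                        gaps.append(Interval(name, pos, int(a)))
                    pos = max(pos, int(b))
            if pos < length:
                gaps.append(Interval(name, pos, length))
        return gaps

    def mappable_size(self) -> int:
        return sum(len(g) for g in self.mappable_gaps())

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in self.chroms:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.chroms[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chroms[iv.chrom]}"
            )

    @classmethod
    def from_files(cls, chrom_sizes_path, excluded_bed_path=None) -> "GenomeLayout":
        chroms: dict[str, int] = {}
        with open(chrom_sizes_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{chrom_sizes_path}:{lineno}: expected two columns")
                chroms[parts[0]] = int(parts[1])
        excluded: list[Interval] = []
        if excluded_bed_path is not None:
            excluded = read_intervals(excluded_bed_path, "bed")
        return cls(chroms, excluded)

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chroms.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True, slots=True)
class RepeatElement:
    """One located repeat copy with its family label."""

    chrom: str
    start: int
    end: int
    family: str
    element_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid element {self.element_id}: start/end")
        if not self.family:
            raise ValueError(f"element {self.element_id} has empty family label")

    def __len__(self) -> int:
        return self.end - self.start

    def as_interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand, self.element_id)


class RepeatAnnotation:
    """Located repeat elements with family labels — the units of every
    enrichment and association test."""

    def __init__(self, elements: Sequence[RepeatElement]):
        ids = [e.element_id for e in elements]
        if len(set(ids)) != len(ids):
            raise ValueError("element_ids must be unique")
        self.elements: list[RepeatElement] = sorted(
            elements, key=lambda e: (e.chrom, e.start, e.end, e.element_id)
        )
        self._by_family: dict[str, list[RepeatElement]] = {}
        for e in self.elements:
            self._by_family.setdefault(e.family, []).append(e)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def families(self) -> list[str]:
        return sorted(self._by_family)

    def family_elements(self, family: str) -> list[RepeatElement]:
        try:
            return self._by_family[family]
        except KeyError:
            raise KeyError(f"unknown repeat family {family!r}") from None

    def subset(self, families: Iterable[str]) -> "RepeatAnnotation":
        wanted = set(families)
        return RepeatAnnotation([e for e in self.elements if e.family in wanted])

    @classmethod
    def from_bed(cls, path, genome: GenomeLayout | None = None) -> "RepeatAnnotation":
        """BED-with-family dialect: the name field carries the family label;
        an optional 7th column carries a stable element id (ids are
        synthesised from coordinates when absent)."""
        elements = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4 or not parts[3] or parts[3] == ".":
                    raise ValueError(f"{path}:{lineno}: repeat record lacks a family name")
                try:
                    iv = _parse_bed_line(parts, narrow=False)
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed bed line: {exc}") from exc
                if genome is not None:
                    genome.validate_interval(iv)
                eid = (parts[6] if len(parts) > 6 and parts[6]
                       else f"{iv.name}|{iv.chrom}:{iv.start}-{iv.end}")
                elements.append(
                    RepeatElement(iv.chrom, iv.start, iv.end, iv.name, eid, iv.strand)
                )
        return cls(elements)

    @classmethod
    def from_repeatmasker(cls, path, genome: GenomeLayout | None = None) -> "RepeatAnnotation":
        ivs = read_intervals(path, "repeatmasker", genome=genome)
        elements = [
            RepeatElement(iv.chrom, iv.start, iv.end, iv.name,
                          f"{iv.name}|{iv.chrom}:{iv.start}-{iv.end}", iv.strand)
            for iv in ivs
        ]
        return cls(elements)

    def to_bed(self, path) -> None:
        """BED6 + element_id column (read back by :meth:`from_bed`)."""
        with open(path, "w") as fh:
            for e in self.elements:
                fh.write(
                    f"{e.chrom}\t{e.start}\t{e.end}\t{e.family}\t0\t{e.strand}\t{e.element_id}\n"
                )


_ASSAYS = {"DNase", "H3K27ac", "H3K4me1", "H3K4me3", "H3K9me3", "dCas9"}
GROUPS = ("AML", "cell_line", "differentiated", "CD34")


@dataclass
class PeakSet:
    """One sample's peak calls for one assay."""

    sample_id: str
    assay: str
    group: str
    peaks: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.assay in _ASSAYS or self.assay.startswith("TF:")):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def validate(self, genome: GenomeLayout) -> None:
        for p in self.peaks:
            genome.validate_interval(p)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(parts: list[str], narrow: bool) -> Interval:
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    name = parts[3] if len(parts) > 3 and parts[3] != "." else None
    score = None
    if len(parts) > 4 and parts[4] not in (".", ""):
        score = float(parts[4])
    strand = parts[5] if len(parts) > 5 and parts[5] in _VALID_STRANDS else "."
    return Interval(chrom, start, end, strand, name, score)


def read_intervals(path, fmt: str = "bed", genome: GenomeLayout | None = None) -> list[Interval]:
    """Read intervals from BED, narrowPeak or RepeatMasker ``.out``.

    BED/narrowPeak coordinates pass through unchanged (already 0-based
    half-open); RepeatMasker 1-based inclusive coordinates are converted.
    Malformed lines raise with the offending line number; out-of-bounds
    coordinates raise when a :class:`GenomeLayout` is supplied.
    """
    fmt = fmt.lower()
    if fmt not in {"bed", "narrowpeak", "repeatmasker"}:
        raise ValueError(f"unknown format {fmt!r}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            try:
                if fmt == "repeatmasker":
                    parts = line.split()
                    # two header lines plus blank separator in stock .out files
                    if parts[0] in {"SW", "score"}:
                        continue
                    chrom = parts[4]
                    start = int(parts[5]) - 1  # 1-based inclusive -> 0-based half-open
                    end = int(parts[6])
                    strand = "-" if parts[8] in {"C", "-"} else "+"
                    family = parts[9]
                    iv = Interval(chrom, start, end, strand, family)
                else:
                    if line.startswith(("track", "browser", "#")):
                        continue
                    parts = line.split("\t")
                    if len(parts) < 3:
                        raise ValueError("expected at least 3 tab-separated fields")
                    iv = _parse_bed_line(parts, narrow=(fmt == "narrowpeak"))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line: {exc}") from exc
            if genome is not None:
                try:
                    genome.validate_interval(iv)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    """Write BED6; missing name/score become '.' and 0."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = int(iv.score) if iv.score is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------

def _as_arrays(intervals) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per: dict[str, tuple[list[int], list[int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, ([], []))[0].append(iv.start)
        per[iv.chrom][1].append(iv.end)
    out = {}
    for chrom, (s, e) in per.items():
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)
        order = np.argsort(s, kind="stable")
        out[chrom] = (s[order], e[order])
    return out


class MergedIntervals:
    """Merged, sorted interval set per chromosome supporting vectorised
    any-overlap queries (>=1 bp, half-open)."""

    def __init__(self, intervals: Iterable = ()):
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {
            chrom: _merge_sorted(s, e) for chrom, (s, e) in _as_arrays(intervals).items()
        }

    @classmethod
    def from_arrays(cls, per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> "MergedIntervals":
        obj = cls()
        for chrom, (s, e) in per_chrom.items():
            order = np.argsort(s, kind="stable")
            obj._idx[chrom] = _merge_sorted(s[order], e[order])
        return obj

    def any_overlap_arrays(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Boolean mask: does each query [qs, qe) on `chrom` hit the set?"""
        if chrom not in self._idx or len(qs) == 0:
            return np.zeros(len(qs), dtype=bool)
        starts, ends = self._idx[chrom]
        # merged => both arrays sorted; first interval ending after qs must
        # start before qe for an overlap to exist
        j = np.searchsorted(ends, qs, side="right")
        hit = j < len(starts)
        jj = np.minimum(j, len(starts) - 1)
        hit &= starts[jj] < qe
        return hit

    def any_overlap(self, intervals: Iterable) -> np.ndarray:
        ivs = list(intervals)
        out = np.zeros(len(ivs), dtype=bool)
        per: dict[str, list[int]] = {}
        for i, iv in enumerate(ivs):
            per.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in per.items():
            qs = np.asarray([ivs[i].start for i in idxs], dtype=np.int64)
            qe = np.asarray([ivs[i].end for i in idxs], dtype=np.int64)
            out[np.asarray(idxs)] = self.any_overlap_arrays(chrom, qs, qe)
        return out

    def count_overlapping(self, intervals: Iterable) -> int:
        return int(self.any_overlap(intervals).sum())


def count_overlaps(query: Sequence[Interval], subject: RepeatAnnotation, family: str) -> tuple[int, int]:
    """(#query intervals hitting >=1 family element, #distinct elements hit).

    Each query counts once however many elements it touches, and vice versa.
    """
    fam = subject.family_elements(family)  # raises KeyError on unknown family
    if not query:
        return (0, 0)
    fam_idx = MergedIntervals(e.as_interval() for e in fam)
    n_query_hit = fam_idx.count_overlapping(query)
    q_idx = MergedIntervals(query)
    n_elements_hit = q_idx.count_overlapping(e.as_interval() for e in fam)
    return (n_query_hit, n_elements_hit)


# ---------------------------------------------------------------------------
# Shuffler
# ---------------------------------------------------------------------------

class IntervalShuffler:
    """Uniform length-preserving placement into the mappable genome.

    Each interval is placed independently, uniformly over *all* genome
    positions where it fits entirely outside excluded regions.  Placement is
    genome-wide by default (chromosome of origin not preserved), weighted by
    the number of valid start positions per chromosome; overlapping placed
    intervals are permitted.
    """

    def __init__(self, genome: GenomeLayout, per_chromosome: bool = False):
        self.genome = genome
        self.per_chromosome = per_chromosome
        gaps = genome.mappable_gaps()
        self._chrom_names = list(genome.chroms)
        code = {c: i for i, c in enumerate(self._chrom_names)}
        self._gap_chrom = np.asarray([code[g.chrom] for g in gaps], dtype=np.int64)
        self._gap_start = np.asarray([g.start for g in gaps], dtype=np.int64)
        self._gap_len = np.asarray([len(g) for g in gaps], dtype=np.int64)
        self._code = code

    def _place(self, lengths: np.ndarray, rng: np.random.Generator,
               gap_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Place each interval of the given length; returns (chrom codes, starts)."""
        chroms = np.empty(len(lengths), dtype=np.int64)
        starts = np.empty(len(lengths), dtype=np.int64)
        mask = gap_mask if gap_mask is not None else np.ones(len(self._gap_len), dtype=bool)
        for L in np.unique(lengths):
            valid = np.where(mask, np.maximum(self._gap_len - L + 1, 0), 0)
            total = int(valid.sum())
            if total == 0:
                raise ValueError(
                    f"interval of length {int(L)} does not fit in any mappable gap"
                )
            cum = np.cumsum(valid)
            sel = lengths == L
            u = rng.integers(0, total, size=int(sel.sum()))
            gidx = np.searchsorted(cum, u, side="right")
            offset = u - (cum[gidx] - valid[gidx])
            chroms[sel] = self._gap_chrom[gidx]
            starts[sel] = self._gap_start[gidx] + offset
        return chroms, starts

    def shuffle_arrays(self, lengths: np.ndarray, rng: np.random.Generator,
                       orig_chrom_codes: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Array-level fast path used by the enrichment permutation loop."""
        lengths = np.asarray(lengths, dtype=np.int64)
        if not self.per_chromosome:
            return self._place(lengths, rng)
        if orig_chrom_codes is None:
            raise ValueError("per-chromosome shuffling needs original chromosomes")
        chroms = np.empty(len(lengths), dtype=np.int64)
        starts = np.empty(len(lengths), dtype=np.int64)
        for c in np.unique(orig_chrom_codes):
            sel = orig_chrom_codes == c
            cc, ss = self._place(lengths[sel], rng, gap_mask=(self._gap_chrom == c))
            chroms[sel] = cc
            starts[sel] = ss
        return chroms, starts

    def shuffle(self, intervals: Sequence[Interval], rng: np.random.Generator) -> list[Interval]:
        if not intervals:
            return []
        lengths = np.asarray([len(iv) for iv in intervals], dtype=np.int64)
        try:
            orig = np.asarray([self._code[iv.chrom] for iv in intervals], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"interval on unknown chromosome {exc.args[0]!r}") from None
        try:
            chroms, starts = self.shuffle_arrays(lengths, rng, orig)
        except ValueError as exc:
            # re-raise identifying the offending interval
            for iv in intervals:
                if f"length {len(iv)}" in str(exc):
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} (length {len(iv)}) "
                        "does not fit in any mappable gap"
                    ) from exc
            raise
        return [
            replace(iv, chrom=self._chrom_names[int(c)], start=int(s), end=int(s) + len(iv))
            for iv, c, s in zip(intervals, chroms, starts)
        ]


def shuffle_intervals(intervals: Sequence[Interval], genome: GenomeLayout,
                      seed: int | np.random.Generator, per_chromosome: bool = False) -> list[Interval]:
    """Length-preserving uniform shuffle; deterministic given a seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return IntervalShuffler(genome, per_chromosome=per_chromosome).shuffle(list(intervals), rng)
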