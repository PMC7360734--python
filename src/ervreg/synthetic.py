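"""Self-contained synthetic dataset emulating the statistical structure of
a repeat-centric regulatory-chromatin study.

The generator emits a toy genome (a few megabase-scale chromosomes with
excluded blocks), a family-labelled repeat annotation, per-copy element
sequences derived from a family consensus by i.i.d. substitution (no
indels, so planted motif offsets stay exact), per-sample DNase and histone
peak sets, a spliced-transcript assembly per sample, a log2-scale
expression matrix with planted enhancer-gene effects, guide/control
coverage tracks with depleted H3K27ac and gained H3K9me3 at targeted
elements, and mutation labels — together with a ground-truth manifest of
every planted effect for parameter-recovery tests.

Planted structure, by module it is meant to exercise:

* ``enriched_families`` — elements of the named family are "active"
  (carry a DNase peak at a fixed internal offset) per sample with the
  stated probability, on top of uniform background peaks; fold
  enrichment of the defaults lands near 3x over the permutation null.
* ``mutation`` — a subgroup of disease samples shares activity draws
  with the stated mixing weight, planting inter-sample correlation.
* state clusters — enriched-family elements split into three chromatin
  classes (disease-active / constitutively-active / repressed) with
  distinct histone-mark overlap probabilities.
* ``links`` — designated genes adjacent to enriched elements gain a fixed
  log2 expression offset exactly in the samples where the element is
  active.
* ``crispri`` — guides lifted from the enriched-family consensus; copies
  still matching within the mismatch budget receive dCas9 peaks, with
  coverage tracks altered in windows around them.

Everything is driven by one :class:`numpy.random.Generator`; the same
seed reproduces the same dataset byte for byte.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    GenomeLayout,
    Interval,
    IntervalShuffler,
    MergedIntervals,
    PeakSet,
    RepeatAnnotation,
    RepeatElement,
    write_bed,
)
from .genes import GeneModel
from .promoters import TranscriptModel
from .crispri import CoverageTrack, GuideSpec, _min_hamming, _revcomp
from .motifs import PWM

__all__ = [
    "FamilySpec",
    "EnrichedFamilySpec",
    "MutationSpec",
    "LinkSpec",
    "CrisprSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "write_dataset",
    "self_audit",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K9me3")


@dataclass(frozen=True)
class FamilySpec:
    name: str
    n_copies: int
    length: int
    divergence: float = 0.08


@dataclass(frozen=True)
class EnrichedFamilySpec:
    name: str
    overlap_prob_aml: float = 0.30
    overlap_prob_diff: float = 0.02
    # only this fraction of copies is activatable at all, mirroring the
    # copy-level heterogeneity of real families (most copies stay closed
    # in every sample)
    frac_activatable: float = 0.5


@dataclass(frozen=True)
class MutationSpec:
    label: str = "NPM1"
    n_members: int = 10
    correlation_strength: float = 0.6


@dataclass(frozen=True)
class LinkSpec:
    n_links: int = 10
    delta_log2: float = 3.0
    sigma: float = 0.5


@dataclass(frozen=True)
class CrisprSpec:
    target_families: tuple[str, ...] = ("LTR2B", "LTR2")
    guide_source_family: str = "LTR2B"
    n_guides: int = 2
    guide_length: int = 20
    max_mismatches: int = 2
    k27ac_depletion: float = 0.5   # multiplicative on-target H3K27ac factor
    k9me3_gain: float = 3.0        # multiplicative on-target H3K9me3 factor
    n_offtarget_peaks: int = 30


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    excluded_fraction: float = 0.05
    families: tuple[FamilySpec, ...] = (
        FamilySpec("LTR2B", 300, 400, 0.08),
        FamilySpec("LTR2", 150, 350, 0.08),
        FamilySpec("LTR5B", 200, 450, 0.10),
        FamilySpec("LTR12C", 250, 500, 0.12),
        FamilySpec("LTR13A", 100, 300, 0.10),
    )
    n_aml_samples: int = 30
    n_diff_samples: int = 10
    n_cell_lines: int = 3
    background_peak_rate: float = 70e-6    # peaks per mappable bp
    peak_length: int = 150
    enriched_families: tuple[EnrichedFamilySpec, ...] = (
        EnrichedFamilySpec("LTR2B", 0.30, 0.02),
    )
    mutation: MutationSpec = field(default_factory=MutationSpec)
    links: LinkSpec = field(default_factory=LinkSpec)
    crispri: CrisprSpec = field(default_factory=CrisprSpec)
    n_genes: int = 200
    gene_length: int = 2_000
    # TF name -> probability that an enriched-family element carries a peak;
    # every TF also gets uniform background peaks
    tf_bind_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TAL1": 0.5, "CTCF": 0.0}
    )
    tf_background_peaks: int = 100
    tf_peak_length: int = 120
    n_promoter_elements: int = 30
    expr_baseline_mu: float = 2.0
    expr_baseline_sd: float = 1.0
    planted_motif_offsets: tuple[int, ...] = (50, 200)
    # family -> (source family, divergence): consensus derived from another
    # family's, emulating related subfamilies that share guide target sites
    related_consensus: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {"LTR2": ("LTR2B", 0.12)}
    )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        """Build a config from plain nested dicts/lists (YAML-friendly)."""
        kwargs = dict(d)
        if "families" in kwargs:
            kwargs["families"] = tuple(
                f if isinstance(f, FamilySpec) else FamilySpec(**f)
                for f in kwargs["families"]
            )
        if "enriched_families" in kwargs:
            kwargs["enriched_families"] = tuple(
                f if isinstance(f, EnrichedFamilySpec) else EnrichedFamilySpec(**f)
                for f in kwargs["enriched_families"]
            )
        for key, klass in (("mutation", MutationSpec), ("links", LinkSpec),
                           ("crispri", CrisprSpec)):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                kwargs[key] = klass(**kwargs[key])
        if "crispri" in kwargs and isinstance(kwargs["crispri"], CrisprSpec):
            cr = kwargs["crispri"]
            if isinstance(cr.target_families, list):
                object.__setattr__(cr, "target_families", tuple(cr.target_families))
        return cls(**kwargs)

    def aml_samples(self) -> list[str]:
        return [f"AML{i + 1:02d}" for i in range(self.n_aml_samples)]

    def diff_samples(self) -> list[str]:
        return [f"DIFF{i + 1:02d}" for i in range(self.n_diff_samples)]

    def cell_lines(self) -> list[str]:
        return [f"CL{i + 1:02d}" for i in range(self.n_cell_lines)]


@dataclass
class SyntheticTruth:
    """Manifest of every planted effect, re-derivable from the emitted files."""

    enriched_families: list[str]
    active: dict[str, dict[str, list[str]]]       # family -> element_id -> samples active
    activatable: dict[str, list[str]]             # family -> competent element_ids
    state_class: dict[str, str]                   # element_id -> planted chromatin class
    links: list[dict]                             # {element, gene, delta_log2, sigma}
    promoter_elements: list[str]
    aml_specific_promoters: list[str]
    mutation_label: str
    mutation_members: list[str]
    guide_protospacers: list[str]
    guide_target_elements: dict[str, list[str]]   # family -> element_ids recognised
    dcas9_on_target: list[str]                    # element ids with a dCas9 peak
    planted_motif_offsets: dict[str, list[int]]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeLayout
    repeats: RepeatAnnotation
    consensus: dict[str, str]
    element_seqs: dict[str, dict[str, str]]
    planted_pwms: list[PWM]
    groups: dict[str, str]
    dnase: dict[str, PeakSet]
    histone: list[PeakSet]
    tf_peaks: dict[str, PeakSet]
    transcripts: dict[str, list[TranscriptModel]]
    genes: list[GeneModel]
    expression: pd.DataFrame
    mutations: dict[str, bool]
    dcas9_peaks: PeakSet
    coverage: dict[tuple[str, str], CoverageTrack]   # (mark, condition) -> track
    guides: list[GuideSpec]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(codes)) < divergence
    if hit.any():
        # substitute with a uniformly chosen *different* base
        cur = np.searchsorted(_BASES, codes[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        codes[hit] = _BASES[(cur + shift) % 4]
    return bytes(codes).decode("ascii")


def _make_excluded(cfg: SyntheticConfig, rng: np.random.Generator) -> list[Interval]:
    out = []
    n_blocks = 4
    block = int(cfg.excluded_fraction * cfg.chrom_length / n_blocks)
    if block == 0:
        return out
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        # non-overlapping blocks at jittered regular anchors
        anchors = np.linspace(0, cfg.chrom_length - block, n_blocks + 2)[1:-1]
        for a in anchors[:n_blocks]:
            jitter = int(rng.integers(0, max(block, 1)))
            start = int(min(a + jitter, cfg.chrom_length - block))
            out.append(Interval(chrom, start, start + block))
    return out


def _place_elements(cfg: SyntheticConfig, genome: GenomeLayout,
                    rng: np.random.Generator) -> RepeatAnnotation:
    """Place family copies uniformly in mappable space, rejecting overlaps
    so element identities stay distinct."""
    shuffler = IntervalShuffler(genome)
    chrom_names = list(genome.chroms)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def collides(chrom: str, s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in occupied[chrom])

    elements = []
    for fam in cfg.families:
        placed = 0
        attempts = 0
        while placed < fam.n_copies:
            batch = fam.n_copies - placed
            codes, starts = shuffler.shuffle_arrays(
                np.full(batch, fam.length, dtype=np.int64), rng
            )
            for c, s in zip(codes, starts):
                chrom = chrom_names[int(c)]
                s = int(s)
                e = s + fam.length
                if collides(chrom, s, e):
                    continue
                occupied[chrom].append((s, e))
                strand = "+" if rng.random() < 0.5 else "-"
                elements.append(
                    RepeatElement(chrom, s, e, fam.name,
                                  f"{fam.name}_{placed:04d}", strand)
                )
                placed += 1
                if placed == fam.n_copies:
                    break
            attempts += 1
            if attempts > 200:
                raise ValueError(
                    f"cannot place {fam.n_copies} copies of {fam.name} "
                    "in the mappable space"
                )
    return RepeatAnnotation(elements)


def _planted_pwms(cfg: SyntheticConfig, rng: np.random.Generator) -> list[PWM]:
    """Two sharp synthetic motifs (near-consensus PWMs) to plant."""
    pwms = []
    for i, _off in enumerate(cfg.planted_motif_offsets):
        L = 8
        consensus = rng.integers(0, 4, size=L)
        mat = np.full((L, 4), 0.04)
        mat[np.arange(L), consensus] = 0.88
        pwms.append(PWM(f"motif{i + 1}", mat))
    return pwms


def _pwm_consensus_str(pwm: PWM) -> str:
    return "".join("ACGT"[int(i)] for i in pwm.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    chroms = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}
    genome = GenomeLayout(chroms, _make_excluded(cfg, rng))
    repeats = _place_elements(cfg, genome, rng)

    # --- sequences -------------------------------------------------------
    planted_pwms = _planted_pwms(cfg, rng)
    enriched_names = [f.name for f in cfg.enriched_families]
    consensus: dict[str, str] = {}
    motif_offsets: dict[str, list[int]] = {}
    for fam in cfg.families:
        if fam.name in cfg.related_consensus:
            src_name, div = cfg.related_consensus[fam.name]
            src = consensus.get(src_name)
            base = (_mutate(rng, src, div) if src is not None
                    else _random_seq(rng, max(fam.length, 1)))
            if len(base) < fam.length:
                base = base + _random_seq(rng, fam.length - len(base))
            seq = base[: fam.length]
        else:
            seq = _random_seq(rng, fam.length)
        offs = []
        if fam.name in enriched_names:
            for pwm, off in zip(planted_pwms, cfg.planted_motif_offsets):
                motif = _pwm_consensus_str(pwm)
                if off + len(motif) <= fam.length:
                    seq = seq[:off] + motif + seq[off + len(motif):]
                    offs.append(off)
        consensus[fam.name] = seq
        motif_offsets[fam.name] = offs

    element_seqs: dict[str, dict[str, str]] = {}
    for fam in cfg.families:
        per = {}
        for e in repeats.family_elements(fam.name):
            per[e.element_id] = _mutate(rng, consensus[fam.name], fam.divergence)
        element_seqs[fam.name] = per

    # --- sample layout ---------------------------------------------------
    aml = cfg.aml_samples()
    diff = cfg.diff_samples()
    cls = cfg.cell_lines()
    groups = {**{s: "AML" for s in aml}, **{s: "differentiated" for s in diff},
              **{s: "cell_line" for s in cls}}
    mut_members = aml[: cfg.mutation.n_members]
    mutations = {s: s in mut_members for s in aml}

    # --- element activity (the central planted truth) --------------------
    # activity[family] is an (n_copies, n_samples) boolean matrix
    all_samples = aml + diff + cls
    sample_pos = {s: i for i, s in enumerate(all_samples)}
    activity: dict[str, np.ndarray] = {}
    activatable: dict[str, np.ndarray] = {}
    rho = cfg.mutation.correlation_strength
    for spec in cfg.enriched_families:
        els = repeats.family_elements(spec.name)
        n_el = len(els)
        competent = rng.random(n_el) < spec.frac_activatable
        act = np.zeros((n_el, len(all_samples)), dtype=bool)
        shared = rng.random(n_el) < spec.overlap_prob_aml  # subgroup profile
        for s in all_samples:
            g = groups[s]
            p = spec.overlap_prob_aml if g in {"AML", "cell_line"} else spec.overlap_prob_diff
            indep = rng.random(n_el) < p
            if g == "AML" and mutations.get(s, False):
                use_shared = rng.random(n_el) < rho
                col = np.where(use_shared, shared, indep)
            else:
                col = indep
            act[:, sample_pos[s]] = col & competent
        activity[spec.name] = act
        activatable[spec.name] = competent

    # --- DNase peaks ------------------------------------------------------
    shuffler = IntervalShuffler(genome)
    chrom_names = list(genome.chroms)
    n_bg = int(round(cfg.background_peak_rate * genome.mappable_size()))

    def background_peaks() -> list[Interval]:
        codes, starts = shuffler.shuffle_arrays(
            np.full(n_bg, cfg.peak_length, dtype=np.int64), rng
        )
        return [
            Interval(chrom_names[int(c)], int(s), int(s) + cfg.peak_length)
            for c, s in zip(codes, starts)
        ]

    def element_peak(e: RepeatElement) -> Interval:
        # fixed internal offset emulating a localised footprint
        off = max((len(e) - cfg.peak_length) // 4, 0)
        start = e.start + off
        end = min(start + cfg.peak_length, e.end)
        return Interval(e.chrom, start, max(end, start + 1))

    dnase: dict[str, PeakSet] = {}
    for s in all_samples:
        peaks = background_peaks()
        for spec in cfg.enriched_families:
            els = repeats.family_elements(spec.name)
            col = activity[spec.name][:, sample_pos[s]]
            peaks.extend(element_peak(e) for e, a in zip(els, col) if a)
        dnase[s] = PeakSet(s, "DNase", groups[s], peaks)

    # --- histone marks & planted state classes ---------------------------
    # enriched-family elements split into three chromatin classes
    state_class: dict[str, str] = {}
    class_probs = {
        # mark overlap probability per (class, group)
        "aml_active": {"AML": {"H3K27ac": 0.6, "H3K4me1": 0.6, "H3K4me3": 0.05, "H3K9me3": 0.02},
                       "differentiated": {m: 0.03 for m in MARKS}},
        "constitutive": {"AML": {"H3K27ac": 0.6, "H3K4me1": 0.6, "H3K4me3": 0.05, "H3K9me3": 0.02},
                         "differentiated": {"H3K27ac": 0.6, "H3K4me1": 0.6, "H3K4me3": 0.05,
                                            "H3K9me3": 0.02}},
        "repressed": {"AML": {"H3K27ac": 0.02, "H3K4me1": 0.02, "H3K4me3": 0.02, "H3K9me3": 0.4},
                      "differentiated": {"H3K27ac": 0.02, "H3K4me1": 0.02, "H3K4me3": 0.02,
                                         "H3K9me3": 0.4}},
    }
    class_names = list(class_probs)
    for spec in cfg.enriched_families:
        els = repeats.family_elements(spec.name)
        assign = rng.integers(0, len(class_names), size=len(els))
        for e, a in zip(els, assign):
            state_class[e.element_id] = class_names[int(a)]
    background_mark_prob = 0.02

    histone: list[PeakSet] = []
    hist_samples = [(s, "AML") for s in aml] + [(s, "differentiated") for s in diff]
    for s, g in hist_samples:
        for mark in MARKS:
            peaks = []
            for e in repeats.elements:
                p = class_probs.get(state_class.get(e.element_id, ""), {}).get(g, {}).get(
                    mark, background_mark_prob
                )
                if rng.random() < p:
                    peaks.append(e.as_interval())
            histone.append(PeakSet(s, mark, g, peaks))

    # --- TF ChIP peaks ----------------------------------------------------
    tf_peaks: dict[str, PeakSet] = {}
    for tf_name in sorted(cfg.tf_bind_probs):
        p_bind = cfg.tf_bind_probs[tf_name]
        codes, starts = shuffler.shuffle_arrays(
            np.full(cfg.tf_background_peaks, cfg.tf_peak_length, dtype=np.int64), rng
        )
        peaks = [
            Interval(chrom_names[int(c)], int(s), int(s) + cfg.tf_peak_length)
            for c, s in zip(codes, starts)
        ]
        for spec in cfg.enriched_families:
            for e in repeats.family_elements(spec.name):
                if rng.random() < p_bind:
                    centre = (e.start + e.end) // 2
                    peaks.append(
                        Interval(e.chrom, max(centre - cfg.tf_peak_length // 2, 0),
                                 centre + cfg.tf_peak_length // 2)
                    )
        tf_peaks[tf_name] = PeakSet(f"{tf_name}_rep1", f"TF:{tf_name}", "cell_line", peaks)

    # --- transcripts ------------------------------------------------------
    primary = enriched_names[0] if enriched_names else cfg.families[0].name
    prim_els = repeats.family_elements(primary)
    prim_competent = (
        [e for e, c in zip(prim_els, activatable[primary]) if c]
        if primary in activatable else list(prim_els)
    )
    promoter_ids = [e.element_id for e in prim_competent[: cfg.n_promoter_elements]]
    promoter_set = set(promoter_ids)
    transcripts: dict[str, list[TranscriptModel]] = {}
    tss_offset = 20
    for s in aml + diff:
        ts = []
        if primary in activity:
            col = activity[primary][:, sample_pos[s]]
            for e, a in zip(prim_els, col):
                if not a or e.element_id not in promoter_set:
                    continue
                tss = e.start + tss_offset
                exon1 = Interval(e.chrom, tss, tss + 200)
                exon2_start = tss + 500
                exon2 = Interval(e.chrom, exon2_start, exon2_start + 300)
                if exon2.end > genome.chroms[e.chrom]:
                    continue
                ts.append(
                    TranscriptModel(f"{s}.{e.element_id}", s, "+", (exon1, exon2))
                )
        transcripts[s] = ts

    aml_specific = []
    if primary in activity:
        act = activity[primary]
        aml_idx = [sample_pos[s] for s in aml]
        diff_idx = [sample_pos[s] for s in diff]
        for i, e in enumerate(prim_els):
            if e.element_id not in promoter_set:
                continue
            if act[i, aml_idx].sum() >= 2 and act[i, diff_idx].sum() == 0:
                aml_specific.append(e.element_id)

    # --- genes & expression ----------------------------------------------
    genes: list[GeneModel] = []
    links: list[dict] = []
    link_elements = [e for e in prim_competent
                     if e.element_id not in promoter_set][: cfg.links.n_links]
    for i, e in enumerate(link_elements):
        start = e.end + 1_000
        end = start + cfg.gene_length
        if end > genome.chroms[e.chrom]:
            end = e.start - 1_000
            start = end - cfg.gene_length
        gid = f"LINKGENE{i + 1:03d}"
        genes.append(GeneModel(gid, Interval(e.chrom, start, end), "+"))
        links.append({"element": e.element_id, "gene": gid,
                      "delta_log2": cfg.links.delta_log2, "sigma": cfg.links.sigma})
    n_rand = cfg.n_genes - len(genes)
    codes, starts = shuffler.shuffle_arrays(
        np.full(n_rand, cfg.gene_length, dtype=np.int64), rng
    )
    for i, (c, s) in enumerate(zip(codes, starts)):
        genes.append(GeneModel(f"GENE{i + 1:04d}",
                               Interval(chrom_names[int(c)], int(s), int(s) + cfg.gene_length),
                               "+"))

    expr_samples = aml + diff
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.normal(cfg.expr_baseline_mu, cfg.expr_baseline_sd, size=len(genes))
    X = baseline[:, None] + rng.normal(0.0, cfg.links.sigma,
                                       size=(len(genes), len(expr_samples)))
    el_index = {e.element_id: i for i, e in enumerate(prim_els)}
    for link in links:
        gi = gene_ids.index(link["gene"])
        ei = el_index[link["element"]]
        for s in expr_samples:
            if primary in activity and activity[primary][ei, sample_pos[s]]:
                X[gi, sample_pos_of(expr_samples, s)] += link["delta_log2"]
    expression = pd.DataFrame(X, index=gene_ids, columns=expr_samples)

    # --- CRISPRi ----------------------------------------------------------
    cr = cfg.crispri
    guides: list[GuideSpec] = []
    src = consensus.get(cr.guide_source_family, next(iter(consensus.values())))
    for i in range(cr.n_guides):
        off = 60 + i * 100
        if off + cr.guide_length <= len(src):
            guides.append(GuideSpec(src[off:off + cr.guide_length], cr.max_mismatches))
    guide_targets: dict[str, list[str]] = {}
    on_target_elements: list[RepeatElement] = []
    for fam_name in cr.target_families:
        if fam_name not in element_seqs:
            continue
        hit_ids = []
        for e in repeats.family_elements(fam_name):
            seq = element_seqs[fam_name][e.element_id]
            recognised = any(
                min(_min_hamming(seq, g.protospacer),
                    _min_hamming(_revcomp(seq), g.protospacer)) <= g.max_mismatches
                for g in guides
            )
            if recognised:
                hit_ids.append(e.element_id)
                on_target_elements.append(e)
        guide_targets[fam_name] = hit_ids

    dcas9_ivs = []
    for e in on_target_elements:
        centre = (e.start + e.end) // 2
        dcas9_ivs.append(Interval(e.chrom, max(centre - 100, 0), centre + 100))
    # off-target placements must not land in a target element
    target_ids = {e.element_id for e in on_target_elements}
    tgt_idx = MergedIntervals(
        e.as_interval()
        for f in cr.target_families if f in element_seqs
        for e in repeats.family_elements(f)
    )
    n_off = 0
    attempts = 0
    while n_off < cr.n_offtarget_peaks and attempts < 100:
        codes, starts = shuffler.shuffle_arrays(
            np.full(cr.n_offtarget_peaks - n_off, 200, dtype=np.int64), rng
        )
        for c, s in zip(codes, starts):
            iv = Interval(chrom_names[int(c)], int(s), int(s) + 200)
            if not tgt_idx.any_overlap([iv])[0]:
                dcas9_ivs.append(iv)
                n_off += 1
                if n_off == cr.n_offtarget_peaks:
                    break
        attempts += 1
    dcas9_peaks = PeakSet("CRISPRi", "dCas9", "cell_line", dcas9_ivs)

    coverage = _make_coverage(genome, on_target_elements, cr)

    truth = SyntheticTruth(
        enriched_families=list(enriched_names),
        active={
            fam: {
                e.element_id: [all_samples[j] for j in np.nonzero(activity[fam][i])[0]]
                for i, e in enumerate(repeats.family_elements(fam))
            }
            for fam in activity
        },
        activatable={
            fam: [e.element_id for e, c in zip(repeats.family_elements(fam), activatable[fam]) if c]
            for fam in activatable
        },
        state_class=state_class,
        links=links,
        promoter_elements=promoter_ids,
        aml_specific_promoters=aml_specific,
        mutation_label=cfg.mutation.label,
        mutation_members=mut_members,
        guide_protospacers=[g.protospacer for g in guides],
        guide_target_elements=guide_targets,
        dcas9_on_target=sorted(target_ids),
        planted_motif_offsets=motif_offsets,
    )

    return SyntheticDataset(
        config=cfg, genome=genome, repeats=repeats, consensus=consensus,
        element_seqs=element_seqs, planted_pwms=planted_pwms, groups=groups,
        dnase=dnase, histone=histone, tf_peaks=tf_peaks,
        transcripts=transcripts, genes=genes,
        expression=expression, mutations=mutations, dcas9_peaks=dcas9_peaks,
        coverage=coverage, guides=guides, truth=truth,
    )


def sample_pos_of(samples: list[str], s: str) -> int:
    return samples.index(s)


def _make_coverage(genome: GenomeLayout, on_target: list[RepeatElement],
                   cr: CrisprSpec) -> dict[tuple[str, str], CoverageTrack]:
    """Flat unit coverage everywhere; the guide condition multiplies
    coverage in +/-500 bp windows around on-target peak centres."""
    factors = {"H3K27ac": cr.k27ac_depletion, "H3K9me3": cr.k9me3_gain}
    windows: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chroms}
    for e in on_target:
        centre = (e.start + e.end) // 2
        windows[e.chrom].append(
            (max(centre - 500, 0), min(centre + 500, genome.chroms[e.chrom]))
        )
    out: dict[tuple[str, str], CoverageTrack] = {}
    for mark, factor in factors.items():
        for cond in ("sgRNA", "control"):
            per: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            for chrom, length in genome.chroms.items():
                segs: list[tuple[int, int, float]] = []
                pos = 0
                wins = sorted(windows[chrom])
                merged: list[tuple[int, int]] = []
                for a, b in wins:
                    if merged and a <= merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                    else:
                        merged.append((a, b))
                for a, b in merged:
                    if a > pos:
                        segs.append((pos, a, 1.0))
                    segs.append((a, b, factor if cond == "sgRNA" else 1.0))
                    pos = b
                if pos < length:
                    segs.append((pos, length, 1.0))
                per[chrom] = (
                    np.asarray([s[0] for s in segs], dtype=np.int64),
                    np.asarray([s[1] for s in segs], dtype=np.int64),
                    np.asarray([s[2] for s in segs], dtype=float),
                )
            out[(mark, cond)] = CoverageTrack(per)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every component to standard text formats; returns a path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ds.genome.write_chrom_sizes(out / "chrom.sizes")
    write_bed(ds.genome.excluded, out / "excluded.bed")
    ds.repeats.to_bed(out / "repeats.bed")
    paths.update(chrom_sizes=str(out / "chrom.sizes"), excluded=str(out / "excluded.bed"),
                 repeats=str(out / "repeats.bed"))

    with open(out / "consensus.fasta", "w") as fh:
        for fam in sorted(ds.consensus):
            fh.write(f">{fam}\n{ds.consensus[fam]}\n")
    with open(out / "elements.fasta", "w") as fh:
        for fam in sorted(ds.element_seqs):
            for eid in sorted(ds.element_seqs[fam]):
                fh.write(f">{eid} family={fam}\n{ds.element_seqs[fam][eid]}\n")
    paths.update(consensus=str(out / "consensus.fasta"), elements=str(out / "elements.fasta"))

    dnase_dir = out / "dnase"
    dnase_dir.mkdir(exist_ok=True)
    for s, ps in ds.dnase.items():
        write_bed(ps.peaks, dnase_dir / f"{s}.bed")
    paths["dnase_dir"] = str(dnase_dir)

    hist_dir = out / "histone"
    hist_dir.mkdir(exist_ok=True)
    for ps in ds.histone:
        write_bed(ps.peaks, hist_dir / f"{ps.sample_id}_{ps.assay}.bed")
    paths["histone_dir"] = str(hist_dir)

    tf_dir = out / "tf"
    tf_dir.mkdir(exist_ok=True)
    for tf_name, ps in ds.tf_peaks.items():
        write_bed(ps.peaks, tf_dir / f"{tf_name}_rep1.bed")
    paths["tf_dir"] = str(tf_dir)

    from .motifs import write_meme
    write_meme(ds.planted_pwms, out / "motifs.meme")
    paths["motifs"] = str(out / "motifs.meme")

    gtf_dir = out / "transcripts"
    gtf_dir.mkdir(exist_ok=True)
    for s, ts in ds.transcripts.items():
        with open(gtf_dir / f"{s}.gtf", "w") as fh:
            for t in ts:
                for i, ex in enumerate(t.exons, start=1):
                    fh.write(
                        f"{ex.chrom}\tsynth\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{t.strand}\t.\ttranscript_id \"{t.transcript_id}\"; "
                        f"exon_number \"{i}\";\n"
                    )
    paths["transcripts_dir"] = str(gtf_dir)

    write_bed((g.span if g.span.name else
               Interval(g.span.chrom, g.span.start, g.span.end, g.strand, g.gene_id)
               for g in ds.genes), out / "genes.bed")
    ds.expression.round(6).to_csv(out / "expression.tsv", sep="\t",
                                  index_label="gene")
    with open(out / "mutations.tsv", "w") as fh:
        fh.write(f"sample\t{ds.truth.mutation_label}\n")
        for s, m in ds.mutations.items():
            fh.write(f"{s}\t{int(m)}\n")
    paths.update(genes=str(out / "genes.bed"), expression=str(out / "expression.tsv"),
                 mutations=str(out / "mutations.tsv"))

    write_bed(ds.dcas9_peaks.peaks, out / "dcas9_peaks.bed")
    cov_dir = out / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for (mark, cond), track in ds.coverage.items():
        with open(cov_dir / f"{mark}_{cond}.bedGraph", "w") as fh:
            for chrom in ds.genome.chroms:
                if chrom not in track._per_chrom:
                    continue
                s, e, v = track._per_chrom[chrom]
                for a, b, val in zip(s, e, v):
                    fh.write(f"{chrom}\t{a}\t{b}\t{val:.4f}\n")
    with open(out / "guides.txt", "w") as fh:
        for g in ds.guides:
            fh.write(f"{g.protospacer}\t{g.max_mismatches}\n")
    paths.update(dcas9=str(out / "dcas9_peaks.bed"), coverage_dir=str(cov_dir),
                 guides=str(out / "guides.txt"))

    with open(out / "groups.tsv", "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in ds.groups.items():
            fh.write(f"{s}\t{g}\n")
    paths["groups"] = str(out / "groups.tsv")

    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(ds.truth), fh, indent=1, sort_keys=True)
    paths["truth"] = str(out / "truth.json")
    return paths


def self_audit(ds: SyntheticDataset) -> None:
    """Verify by brute force that the manifest matches the emitted data.

    Raises AssertionError on any discrepancy.
    """
    # planted active elements really carry a peak in the stated samples
    for fam, per_el in ds.truth.active.items():
        els = {e.element_id: e for e in ds.repeats.family_elements(fam)}
        for eid, samples in per_el.items():
            e = els[eid]
            for s in samples:
                assert any(
                    p.chrom == e.chrom and p.start < e.end and e.start < p.end
                    for p in ds.dnase[s].peaks
                ), f"{eid} marked active in {s} but no peak overlaps it"
    # transcripts start inside their element
    for s, ts in ds.transcripts.items():
        for t in ts:
            eid = t.transcript_id.split(".", 1)[1]
            fam = eid.rsplit("_", 1)[0]
            e = {x.element_id: x for x in ds.repeats.family_elements(fam)}[eid]
            assert e.start <= t.exons[0].start < e.end
    # dCas9 on-target elements overlap a dCas9 peak
    els = {e.element_id: e for e in ds.repeats.elements}
    for eid in ds.truth.dcas9_on_target:
        e = els[eid]
        assert any(
            p.chrom == e.chrom and p.start < e.end and e.start < p.end
            for p in ds.dcas9_peaks.peaks
        ), f"on-target element {eid} has no dCas9 peak"
    # linked genes show the planted offset in active samples
    prim = ds.truth.enriched_families[0] if ds.truth.enriched_families else None
    if prim:
        for link in ds.truth.links:
            active = set(ds.truth.active[prim].get(link["element"], []))
            pos = [s for s in ds.expression.columns if s in active]
            neg = [s for s in ds.expression.columns if s not in active]
            if len(pos) >= 2 and len(neg) >= 2:
                diff = (ds.expression.loc[link["gene"], pos].mean()
                        - ds.expression.loc[link["gene"], neg].mean())
                assert diff > link["delta_log2"] / 2, (
                    f"planted link {link} not visible in expression"
                )
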