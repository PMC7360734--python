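"""End-to-end orchestration of the analysis stages over a data directory.

A single YAML config drives everything; every stochastic stage derives its
own random stream from the top-level seed, so a rerun with an identical
config reproduces identical outputs.  Stage outputs are TSV/JSON files in
the run directory plus a provenance block (config hash, seed, package
version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeLayout, Interval, PeakSet, RepeatAnnotation, read_intervals
from .enrichment import family_dhs_enrichment, results_to_frame, select_families_frame
from .heterogeneity import build_overlap_matrix, mutation_correlation_test, sample_correlation
from .chromatin import (
    classify_states,
    cluster_elements,
    count_comarked_elements,
    count_marked_elements,
    family_mean_fractions,
    mark_overlap_fractions,
)
from .promoters import aml_specific_promoters, element_tss_hits, read_transcripts_gtf
from .genes import GeneModel, contrast_table, genes_near_elements, group_expression_by_dhs
from .motifs import (
    consensus_motif_map,
    dhs_motif_contrast,
    motif_family_frequency,
    read_meme,
    scan_pwm,
    tf_enrichment_grid,
)
from .crispri import (
    CoverageTrack,
    GuideSpec,
    classify_dcas9_peaks,
    predict_guide_targets,
    proximal_genes,
    signal_log2_ratio,
)
from .synthetic import SyntheticConfig, generate, write_dataset

log = logging.getLogger("ervreg")

STAGES = ("synth", "enrich", "select", "heterogeneity", "states", "promoters",
          "assoc", "tf", "motif", "crispri")

DEFAULTS: dict = {
    "seed": 0,
    "data_dir": "data",
    "out_dir": "run",
    "enrich": {"n_shuffles": 1000},
    "select": {"min_aml_frac": 0.10},
    "heterogeneity": {"n_perm": 10000, "method": "pearson"},
    "states": {"k": 6, "elbow_max_k": 8},
    "promoters": {"min_aml": 2},
    "assoc": {"max_dist": 50000, "min_pos_samples": 2},
    "tf": {"min_frac": 0.05, "alpha": 0.05},
    "motif": {"threshold": 6.0, "min_pos_samples": 5},
    "crispri": {"halfwidth": 500, "pseudocount": 1.0, "max_dist": 50000},
    "synth": {},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _stage_seed(cfg: dict, stage: str) -> int:
    # stable per-stage stream under the top-level seed, kept below 2**31
    h = hashlib.sha256(f"{cfg['seed']}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# data-directory loaders
# ---------------------------------------------------------------------------

def load_genome(data_dir: Path) -> GenomeLayout:
    excl = data_dir / "excluded.bed"
    return GenomeLayout.from_files(data_dir / "chrom.sizes",
                                   excl if excl.exists() else None)


def load_groups(data_dir: Path) -> dict[str, str]:
    df = pd.read_csv(data_dir / "groups.tsv", sep="\t")
    return dict(zip(df["sample"], df["group"]))


def load_dnase(data_dir: Path, groups: dict[str, str]) -> dict[str, PeakSet]:
    out = {}
    for bed in sorted((data_dir / "dnase").glob("*.bed")):
        sample = bed.stem
        out[sample] = PeakSet(sample, "DNase", groups[sample], read_intervals(bed, "bed"))
    return out


def load_histone(data_dir: Path, groups: dict[str, str]) -> list[PeakSet]:
    out = []
    for bed in sorted((data_dir / "histone").glob("*.bed")):
        sample, mark = bed.stem.rsplit("_", 1)
        out.append(PeakSet(sample, mark, groups[sample], read_intervals(bed, "bed")))
    return out


def load_element_seqs(data_dir: Path) -> dict[str, dict[str, str]]:
    from Bio import SeqIO

    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(data_dir / "elements.fasta"), "fasta"):
        fam = dict(
            kv.split("=") for kv in rec.description.split()[1:] if "=" in kv
        ).get("family", rec.id.rsplit("_", 1)[0])
        out.setdefault(fam, {})[rec.id] = str(rec.seq).upper()
    return out


def load_genes(data_dir: Path) -> list[GeneModel]:
    return [
        GeneModel(iv.name, Interval(iv.chrom, iv.start, iv.end), iv.strand)
        for iv in read_intervals(data_dir / "genes.bed", "bed")
    ]


def _selected_repeats(data_dir: Path, out_dir: Path) -> RepeatAnnotation:
    repeats = RepeatAnnotation.from_bed(data_dir / "repeats.bed")
    sel_path = out_dir / "selected_families.json"
    if sel_path.exists():
        selected = json.load(open(sel_path))["selected"]
        if selected:
            return repeats.subset(selected)
    return repeats


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_synth(cfg: dict) -> None:
    synth_kwargs = dict(cfg.get("synth") or {})
    synth_kwargs.setdefault("seed", cfg["seed"])
    ds = generate(SyntheticConfig.from_dict(synth_kwargs))
    write_dataset(ds, cfg["data_dir"])


def stage_enrich(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    genome = load_genome(data_dir)
    repeats = RepeatAnnotation.from_bed(data_dir / "repeats.bed")
    groups = load_groups(data_dir)
    dnase = load_dnase(data_dir, groups)
    n_shuffles = cfg["enrich"]["n_shuffles"]
    rng = np.random.default_rng(_stage_seed(cfg, "enrich"))
    frames = []
    for sample in sorted(dnase):
        res = family_dhs_enrichment(dnase[sample], repeats, genome,
                                    n_shuffles=n_shuffles, seed=rng)
        frames.append(results_to_frame(res))
    pd.concat(frames, ignore_index=True).to_csv(out_dir / "enrichment.tsv",
                                                sep="\t", index=False)


def stage_select(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    df = pd.read_csv(out_dir / "enrichment.tsv", sep="\t")
    sel = select_families_frame(df, load_groups(data_dir),
                                cfg["select"]["min_aml_frac"])
    sel.pass_matrix.to_csv(out_dir / "pass_matrix.tsv", sep="\t")
    with open(out_dir / "selected_families.json", "w") as fh:
        json.dump({"selected": sorted(sel.selected)}, fh, indent=1)


def stage_heterogeneity(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    groups = load_groups(data_dir)
    repeats = _selected_repeats(data_dir, out_dir)
    dnase = load_dnase(data_dir, groups)
    aml_sets = [dnase[s] for s in sorted(dnase) if groups[s] == "AML"]
    mat = build_overlap_matrix(repeats, aml_sets)
    corr = sample_correlation(mat, cfg["heterogeneity"]["method"])
    corr.to_csv(out_dir / "sample_correlation.tsv", sep="\t")
    mut_df = pd.read_csv(data_dir / "mutations.tsv", sep="\t").set_index("sample")
    rows = []
    for mutation in mut_df.columns:
        labels = {s: bool(mut_df.loc[s, mutation]) for s in corr.index if s in mut_df.index}
        n_mut = int(sum(labels.values()))
        n_wt = len(labels) - n_mut
        if n_mut < 2 or n_wt < 2:
            log.warning("mutation %s skipped: %d mutated / %d wild-type samples",
                        mutation, n_mut, n_wt)
            rows.append((mutation, n_mut, n_wt, np.nan, np.nan, np.nan, np.nan))
            continue
        sub = corr.loc[list(labels), list(labels)]
        cmp_res = mutation_correlation_test(
            sub, labels, n_perm=cfg["heterogeneity"]["n_perm"],
            seed=_stage_seed(cfg, f"heterogeneity:{mutation}"), mutation=mutation,
        )
        rows.append((mutation, n_mut, n_wt,
                     cmp_res.median_mut, cmp_res.median_wt, cmp_res.statistic,
                     cmp_res.p_perm))
    pd.DataFrame(rows, columns=["mutation", "n_mut", "n_wt", "median_mut",
                                "median_wt", "statistic", "p_perm"]).to_csv(
        out_dir / "mutation_correlation.tsv", sep="\t", index=False)


def stage_states(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    groups = load_groups(data_dir)
    repeats = _selected_repeats(data_dir, out_dir)
    marksets = load_histone(data_dir, groups)
    feats = mark_overlap_fractions(repeats, marksets)
    feats.fractions.round(6).to_csv(out_dir / "state_features.tsv", sep="\t",
                                    index_label="element")
    family_mean_fractions(feats).round(6).to_csv(out_dir / "family_mark_fractions.tsv",
                                                 sep="\t")
    k = cfg["states"]["k"]
    seed = _stage_seed(cfg, "states")
    clusters = cluster_elements(feats, k=k, seed=seed)
    states = classify_states(feats)
    pd.DataFrame({"cluster": clusters, "state": states}).to_csv(
        out_dir / "element_states.tsv", sep="\t", index_label="element")
    # elbow report: within-cluster inertia across a k sweep
    from sklearn.cluster import KMeans
    X = feats.fractions.fillna(0.0).to_numpy()
    elbow = [
        (kk, float(KMeans(n_clusters=kk, n_init=5, random_state=seed).fit(X).inertia_))
        for kk in range(2, cfg["states"]["elbow_max_k"] + 1)
        if kk <= X.shape[0]
    ]
    pd.DataFrame(elbow, columns=["k", "inertia"]).to_csv(
        out_dir / "state_elbow.tsv", sep="\t", index=False)
    marked = {
        "H3K4me1": count_marked_elements(feats, "H3K4me1"),
        "H3K27ac": count_marked_elements(feats, "H3K27ac"),
        "both": count_comarked_elements(feats, "H3K4me1", "H3K27ac"),
    }
    with open(out_dir / "marked_counts.json", "w") as fh:
        json.dump(marked, fh, indent=1)


def stage_promoters(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    groups = load_groups(data_dir)
    repeats = _selected_repeats(data_dir, out_dir)
    transcripts = {
        gtf.stem: read_transcripts_gtf(gtf, gtf.stem)
        for gtf in sorted((data_dir / "transcripts").glob("*.gtf"))
    }
    counts, hits = element_tss_hits(transcripts, repeats)
    calls = aml_specific_promoters(hits, repeats, groups,
                                   min_aml=cfg["promoters"]["min_aml"])
    pd.DataFrame(
        [(c.element_id, c.family, len(c.aml_samples_with_tss),
          ",".join(sorted(c.aml_samples_with_tss))) for c in calls],
        columns=["element", "family", "n_aml_samples", "aml_samples"],
    ).to_csv(out_dir / "element_promoters.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(counts.items()), columns=["sample", "n_tss_in_elements"]).to_csv(
        out_dir / "tss_counts.tsv", sep="\t", index=False)


def stage_assoc(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    groups = load_groups(data_dir)
    repeats = _selected_repeats(data_dir, out_dir)
    genes = load_genes(data_dir)
    expr = pd.read_csv(data_dir / "expression.tsv", sep="\t", index_col=0)
    dnase = load_dnase(data_dir, groups)
    mat = build_overlap_matrix(repeats, [dnase[s] for s in sorted(dnase)])
    pairs = genes_near_elements(genes, repeats, cfg["assoc"]["max_dist"])
    dist = group_expression_by_dhs(pairs, expr, mat, groups,
                                   cfg["assoc"]["min_pos_samples"])
    rows = []
    for klass in ("dhs_aml_and_diff", "dhs_aml_only", "dhs_neg"):
        for v in dist[klass]:
            rows.append((klass, float(v)))
    pd.DataFrame(rows, columns=["class", "mean_log2_expr"]).to_csv(
        out_dir / "assoc_groups.tsv", sep="\t", index=False)
    contrast_table(pairs, expr, mat, groups).round(6).to_csv(
        out_dir / "assoc_contrasts.tsv", sep="\t", index=False)


def stage_tf(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    repeats = _selected_repeats(data_dir, out_dir)
    genome = load_genome(data_dir)
    peaksets = []
    for bed in sorted((data_dir / "tf").glob("*.bed")):
        tf_name = bed.stem.rsplit("_", 1)[0]
        peaksets.append(PeakSet(bed.stem, f"TF:{tf_name}", "cell_line",
                                read_intervals(bed, "bed")))
    grid = tf_enrichment_grid(peaksets, repeats, genome,
                              seed=_stage_seed(cfg, "tf"),
                              min_frac=cfg["tf"]["min_frac"],
                              alpha=cfg["tf"]["alpha"])
    grid.round(6).to_csv(out_dir / "tf_enrichment.tsv", sep="\t", index=False)


def stage_motif(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    groups = load_groups(data_dir)
    repeats = _selected_repeats(data_dir, out_dir)
    pwms = read_meme(data_dir / "motifs.meme")
    thr = cfg["motif"]["threshold"]
    seqs = load_element_seqs(data_dir)
    wanted = set(repeats.families)
    hits_by_element: dict[str, dict[str, bool]] = {}
    any_hits: dict[str, list] = {}
    for fam, per in seqs.items():
        if fam not in wanted:
            continue
        for eid, seq in per.items():
            per_motif = {}
            all_hits = []
            for pwm in pwms:
                h = scan_pwm(seq, pwm, thr, element_id=eid)
                per_motif[pwm.motif_id] = bool(h)
                all_hits.extend(h)
            hits_by_element[eid] = per_motif
            any_hits[eid] = all_hits
    motif_family_frequency(any_hits, repeats).to_csv(
        out_dir / "motif_frequency.tsv", sep="\t", header=True, index_label="family")
    from Bio import SeqIO
    consensus = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(data_dir / "consensus.fasta"), "fasta")
        if rec.id in wanted
    }
    consensus_motif_map(consensus, pwms, thr).round(4).to_csv(
        out_dir / "consensus_map.tsv", sep="\t", index=False)
    dnase = load_dnase(data_dir, groups)
    aml_sets = [dnase[s] for s in sorted(dnase) if groups[s] == "AML"]
    mat = build_overlap_matrix(repeats, aml_sets)
    dhs_counts = {eid: 0 for eid in hits_by_element}
    dhs_counts.update(mat.sum(axis=1).to_dict())
    try:
        contrast = dhs_motif_contrast(hits_by_element, dhs_counts,
                                      cfg["motif"]["min_pos_samples"])
        contrast.round(6).to_csv(out_dir / "motif_contrast.tsv", sep="\t", index=False)
    except ValueError as exc:
        log.warning("motif contrast skipped: %s", exc)


def stage_crispri(cfg: dict) -> None:
    data_dir, out_dir = Path(cfg["data_dir"]), Path(cfg["out_dir"])
    genome = load_genome(data_dir)
    repeats = RepeatAnnotation.from_bed(data_dir / "repeats.bed")
    peaks = read_intervals(data_dir / "dcas9_peaks.bed", "bed")
    target_families = list(cfg.get("crispri", {}).get("target_families")
                           or ("LTR2B", "LTR2"))
    target_families = [f for f in target_families if f in repeats.families]
    classes, counts = classify_dcas9_peaks(peaks, repeats, target_families)
    with open(out_dir / "dcas9_classes.json", "w") as fh:
        json.dump(counts, fh, indent=1)
    rows = []
    for mark in ("H3K27ac", "H3K9me3"):
        sg = CoverageTrack.from_bedgraph(data_dir / "coverage" / f"{mark}_sgRNA.bedGraph")
        ctrl = CoverageTrack.from_bedgraph(data_dir / "coverage" / f"{mark}_control.bedGraph")
        ratios = signal_log2_ratio(sg, ctrl, peaks, genome, mark,
                                   cfg["crispri"]["halfwidth"],
                                   cfg["crispri"]["pseudocount"])
        for pc, r in zip(classes, ratios):
            rows.append((r.peak.chrom, r.peak.start, r.peak.end, pc.klass, mark,
                         r.signal_sg, r.signal_ctrl, r.log2_ratio))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "class", "mark",
                                "signal_sg", "signal_ctrl", "log2_ratio"]).round(6).to_csv(
        out_dir / "dcas9_signal_ratios.tsv", sep="\t", index=False)
    genes = load_genes(data_dir)
    proximal_genes(classes, genes, cfg["crispri"]["max_dist"]).to_csv(
        out_dir / "dcas9_proximal_genes.tsv", sep="\t", index=False)
    guides_path = data_dir / "guides.txt"
    if guides_path.exists():
        guides = []
        for line in open(guides_path):
            seq, mm = line.split()
            guides.append(GuideSpec(seq, int(mm)))
        seqs = load_element_seqs(data_dir)
        predict_guide_targets(
            guides, {f: seqs[f] for f in target_families if f in seqs}
        ).round(6).to_csv(out_dir / "guide_targets.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "synth": stage_synth,
    "enrich": stage_enrich,
    "select": stage_select,
    "heterogeneity": stage_heterogeneity,
    "states": stage_states,
    "promoters": stage_promoters,
    "assoc": stage_assoc,
    "tf": stage_tf,
    "motif": stage_motif,
    "crispri": stage_crispri,
}

_REQUIRES = {
    "select": ["enrichment.tsv"],
}


def run(cfg: dict, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; returns a report."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"stages": {}, "seed": cfg["seed"], "version": __version__}
    for stage in ordered:
        for req in _REQUIRES.get(stage, []):
            if not (out_dir / req).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs {req} from an upstream stage that has not run"
                )
        t0 = time.time()
        _STAGE_FUNCS[stage](cfg)
        dt = time.time() - t0
        log.info("stage %-14s done in %.1fs", stage, dt)
        report["stages"][stage] = {"seconds": round(dt, 2)}
    blob = json.dumps(cfg, sort_keys=True).encode()
    report["config_sha256"] = hashlib.sha256(blob).hexdigest()
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
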