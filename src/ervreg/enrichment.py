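"""Per-sample permutation test for repeat-family enrichment of open
chromatin, and the multi-sample selection rule for disease-associated
families.

The null model: peaks of a sample are re-placed uniformly at random into
the mappable genome (lengths preserved) many times; for each repeat family
the distribution of "number of peaks overlapping the family" across the
random placements is the reference against which the observed count is
scored.  A family is called enriched in a sample when the empirical
two-tailed p-value is < 0.05, the fold enrichment (observed over null
mean) exceeds 2, and more than 20 distinct family copies are overlapped.
A family is selected overall when it is enriched in at least one cell
line and in strictly more than 10% of the disease samples.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    GenomeLayout,
    IntervalShuffler,
    MergedIntervals,
    PeakSet,
    RepeatAnnotation,
)

__all__ = [
    "EnrichmentResult",
    "FamilySelection",
    "empirical_p",
    "family_dhs_enrichment",
    "select_families",
    "results_to_frame",
]


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    family: str
    sample_id: str
    observed: int          # peaks overlapping >=1 family element
    elements_hit: int      # distinct family copies overlapped
    null_mean: float
    null_sd: float
    n_shuffles: int
    fold: float
    p_empirical: float
    passes: bool
    zero_null: bool = False  # null mean was exactly 0 (fold is eps-guarded)


@dataclass(frozen=True)
class FamilySelection:
    pass_matrix: pd.DataFrame     # families x samples, bool
    selected: frozenset[str]


def empirical_p(observed: float, null_values: Sequence[float]) -> float:
    """Two-tailed add-one empirical p-value.

    p = min(1, 2 * min[(1 + #{null >= obs}) / (N+1), (1 + #{null <= obs}) / (N+1)])

    The add-one correction counts the observation itself as one realisation
    of the null, so p is never 0 and never below 1/(N+1).
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empirical_p requires a non-empty null sample")
    n = null.size
    upper = (1 + int((null >= observed).sum())) / (n + 1)
    lower = (1 + int((null <= observed).sum())) / (n + 1)
    return min(1.0, 2.0 * min(upper, lower))


def family_dhs_enrichment(
    dhs: PeakSet,
    repeats: RepeatAnnotation,
    genome: GenomeLayout,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    per_chromosome: bool = False,
) -> list[EnrichmentResult]:
    """Permutation enrichment of one sample's peaks at every repeat family.

    The same ``n_shuffles`` random placements of the sample's peaks serve
    as the shared null for every family, which keeps the null coherent
    across families and costs one shuffle pass per sample.  Fold is
    observed / max(null_mean, eps) with eps = 0.5/n_shuffles; a zero null
    mean is flagged rather than reported as infinite.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    families = repeats.families
    fam_indices = {
        f: MergedIntervals(e.as_interval() for e in repeats.family_elements(f))
        for f in families
    }

    peaks = dhs.peaks
    shuffler = IntervalShuffler(genome, per_chromosome=per_chromosome)
    chrom_names = list(genome.chroms)
    code = {c: i for i, c in enumerate(chrom_names)}
    lengths = np.asarray([len(p) for p in peaks], dtype=np.int64)
    orig_codes = np.asarray([code[p.chrom] for p in peaks], dtype=np.int64)

    # observed counts
    observed: dict[str, int] = {}
    elements_hit: dict[str, int] = {}
    peak_idx = MergedIntervals(peaks)
    for f in families:
        idx = fam_indices[f]
        observed[f] = idx.count_overlapping(peaks)
        elements_hit[f] = peak_idx.count_overlapping(
            e.as_interval() for e in repeats.family_elements(f)
        )

    # shared null realisations
    null = np.zeros((n_shuffles, len(families)), dtype=np.int64)
    for s in range(n_shuffles):
        ccodes, starts = shuffler.shuffle_arrays(lengths, rng, orig_codes)
        ends = starts + lengths
        for j, f in enumerate(families):
            idx = fam_indices[f]
            hit = np.zeros(len(peaks), dtype=bool)
            for c in np.unique(ccodes):
                sel = ccodes == c
                hit[sel] = idx.any_overlap_arrays(chrom_names[int(c)], starts[sel], ends[sel])
            null[s, j] = int(hit.sum())

    eps = 0.5 / n_shuffles
    results = []
    for j, f in enumerate(families):
        nv = null[:, j]
        mean = float(nv.mean())
        sd = float(nv.std(ddof=1)) if n_shuffles > 1 else 0.0
        fold = observed[f] / max(mean, eps)
        p = empirical_p(observed[f], nv)
        results.append(
            EnrichmentResult(
                family=f,
                sample_id=dhs.sample_id,
                observed=observed[f],
                elements_hit=elements_hit[f],
                null_mean=mean,
                null_sd=sd,
                n_shuffles=n_shuffles,
                fold=fold,
                p_empirical=p,
                passes=(p < 0.05 and fold > 2 and elements_hit[f] > 20),
                zero_null=(mean == 0.0),
            )
        )
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [r.family for r in results],
            "sample": [r.sample_id for r in results],
            "observed": [r.observed for r in results],
            "elements_hit": [r.elements_hit for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "fold": [r.fold for r in results],
            "p": [r.p_empirical for r in results],
            "passes": [r.passes for r in results],
            "zero_null": [r.zero_null for r in results],
        }
    )


def select_families_frame(
    df: pd.DataFrame,
    groups: Mapping[str, str],
    min_aml_frac: float = 0.10,
) -> FamilySelection:
    """Selection rule applied to a tabulated enrichment frame with columns
    family, sample, passes (as written by the enrichment stage)."""
    for sample_id in df["sample"].unique():
        if sample_id not in groups:
            raise KeyError(f"sample {sample_id!r} missing from group labels")
    mat = df.pivot_table(index="family", columns="sample", values="passes",
                         aggfunc="any", fill_value=False).astype(bool)
    cell_lines = [s for s in mat.columns if groups[s] == "cell_line"]
    aml = [s for s in mat.columns if groups[s] == "AML"]
    if not cell_lines or not aml:
        raise ValueError("selection requires >=1 cell_line and >=1 AML sample")
    selected = set()
    for f in mat.index:
        if mat.loc[f, cell_lines].any() and mat.loc[f, aml].mean() > min_aml_frac:
            selected.add(f)
    return FamilySelection(pass_matrix=mat, selected=frozenset(selected))


def select_families(
    results: Mapping[str, Sequence[EnrichmentResult]],
    groups: Mapping[str, str],
    min_aml_frac: float = 0.10,
) -> FamilySelection:
    """Families enriched in >=1 cell-line sample AND in strictly more than
    ``min_aml_frac`` of disease (AML) samples."""
    for sample_id in results:
        if sample_id not in groups:
            raise KeyError(f"sample {sample_id!r} missing from group labels")
    cell_lines = [s for s in results if groups[s] == "cell_line"]
    aml = [s for s in results if groups[s] == "AML"]
    if not cell_lines or not aml:
        raise ValueError("selection requires >=1 cell_line and >=1 AML sample")

    families = sorted({r.family for rs in results.values() for r in rs})
    samples = list(results)
    mat = pd.DataFrame(False, index=families, columns=samples)
    for s, rs in results.items():
        for r in rs:
            mat.loc[r.family, s] = r.passes

    selected = set()
    for f in families:
        in_cell_line = bool(mat.loc[f, cell_lines].any())
        aml_frac = float(mat.loc[f, aml].sum()) / len(aml)
        if in_cell_line and aml_frac > min_aml_frac:
            selected.add(f)
    return FamilySelection(pass_matrix=mat, selected=frozenset(selected))
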