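"""Cohort-level summaries: per-genome tables, per-family tables, rank
correlations, non-parametric group comparisons and lifestyle flagging.

The survey questions these support: do longer genomes carry more tRNA
genes (Spearman rank correlation of tRNA count vs genome length); do
genomes with tRNA genes differ in length/GC from those without
(Mann-Whitney U on the two groups, medians with interquartile ranges);
and are cluster-carrying phages virulent or temperate (presence of an
integrase gene marks a temperate phage).

Conventions fixed here: quantiles use linear interpolation; the
Mann-Whitney U test is two-sided with continuity and tie correction
(normal approximation); Spearman p-values use the t approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import CdsRecord, GenomeRecord, TrnaGene
from .cluster_detection import TrnaCluster


@dataclass
class LifestyleCall:
    lifestyle: str  # virulent | temperate | unknown
    integrase_subtype: str | None = None  # serine | tyrosine | None


def classify_lifestyle(cds: list[CdsRecord]) -> LifestyleCall:
    """Temperate iff any CDS product mentions an integrase; the subtype is
    reported when the product names a serine or tyrosine integrase. With no
    CDS annotations at all the lifestyle is unknown."""
    if not cds:
        return LifestyleCall("unknown")
    subtype = None
    temperate = False
    for rec in cds:
        product = (rec.product or "").lower()
        if "integrase" in product:
            temperate = True
            if "serine" in product:
                subtype = "serine"
            elif "tyrosine" in product and subtype is None:
                subtype = "tyrosine"
    return LifestyleCall("temperate" if temperate else "virulent", subtype)


@dataclass
class GenomeSummary:
    genome_id: str
    length_bp: int
    gc_fraction: float
    n_trna: int
    n_clustered: int
    n_clusters: int
    fraction_clustered: float | None
    n_isotypes: int  # distinct determined isotypes among clustered genes
    lifestyle: str


def summarize_genomes(
    genomes: list[GenomeRecord],
    genes: list[TrnaGene],
    clusters: list[TrnaCluster],
    cds: list[CdsRecord] | None = None,
) -> list[GenomeSummary]:
    """One summary row per genome: tRNA counts, clustering and lifestyle.

    ``n_isotypes`` counts distinct determined isotypes (X excluded) among
    clustered genes; ``fraction_clustered`` is missing (None) for genomes
    without tRNA genes.
    """
    known = {g.genome_id for g in genomes}
    for c in clusters:
        if c.genome_id not in known:
            raise ValueError(f"cluster references unknown genome {c.genome_id!r}")
    genes_by_genome: dict[str, list[TrnaGene]] = {g.genome_id: [] for g in genomes}
    for t in genes:
        genes_by_genome.setdefault(t.genome_id, []).append(t)
    cds_by_genome: dict[str, list[CdsRecord]] = {g.genome_id: [] for g in genomes}
    for rec in cds or []:
        cds_by_genome.setdefault(rec.genome_id, []).append(rec)

    summaries = []
    for genome in genomes:
        gid = genome.genome_id
        my_clusters = [c for c in clusters if c.genome_id == gid]
        clustered_genes = [m for c in my_clusters for m in c.members]
        n_trna = len(genes_by_genome.get(gid, []))
        n_clustered = len(clustered_genes)
        isotypes = {m.isotype for m in clustered_genes} - {"X"}
        summaries.append(
            GenomeSummary(
                genome_id=gid,
                length_bp=genome.length_bp,
                gc_fraction=genome.gc_fraction,
                n_trna=n_trna,
                n_clustered=n_clustered,
                n_clusters=len(my_clusters),
                fraction_clustered=(n_clustered / n_trna) if n_trna else None,
                n_isotypes=len(isotypes),
                lifestyle=classify_lifestyle(cds_by_genome.get(gid, [])).lifestyle,
            )
        )
    return summaries


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float | None, float | None]:
    """Spearman rank correlation with average ranks for ties; p-value by the
    t approximation. Returns (None, None) for undefined cases (constant
    input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return None, None
    return float(rho), float(p)


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    statistic: float  # Mann-Whitney U for group a
    p_value: float | None


def median_iqr(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and (25th, 75th) percentiles, linear-interpolation quantiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return float(q50), (float(q25), float(q75))


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison with medians and IQRs.

    The statistic is U for group a (``U_a + U_b = n_a * n_b``). The p-value
    uses the tie-corrected normal approximation with continuity correction
    and is missing when either group has fewer than 3 observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_a, iqr_a = median_iqr(a)
    med_b, iqr_b = median_iqr(b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue) if (a.size >= 3 and b.size >= 3) else None
    return ComparisonResult(
        group_a=label_a,
        group_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=med_a,
        median_b=med_b,
        iqr_a=iqr_a,
        iqr_b=iqr_b,
        statistic=float(res.statistic),
        p_value=p,
    )


def summarize_families(
    summaries: list[GenomeSummary], metadata: dict[str, str] | pd.DataFrame
) -> pd.DataFrame:
    """Per-family table: genomes with tRNA genes over total, length and tRNA
    count ranges, and average GC, in the style of a cohort overview table.

    ``metadata`` maps genome_id -> family (dict, or a DataFrame with
    ``genome_id`` and ``family`` columns); genomes without a family are
    binned as "unclassified". Ranges and average GC are computed over the
    genomes of the family that carry at least one tRNA gene.
    """
    if isinstance(metadata, pd.DataFrame):
        metadata = dict(zip(metadata["genome_id"], metadata["family"]))
    rows = []
    families: dict[str, list[GenomeSummary]] = {}
    for s in summaries:
        fam = metadata.get(s.genome_id) or "unclassified"
        families.setdefault(fam, []).append(s)
    for fam in sorted(families):
        members = families[fam]
        with_trna = [s for s in members if s.n_trna > 0]
        row: dict[str, object] = {
            "family": fam,
            "n_with_trna": len(with_trna),
            "n_total": len(members),
            "genomes_with_trna": f"{len(with_trna)}/{len(members)}",
        }
        if with_trna:
            lengths = [s.length_bp for s in with_trna]
            counts = [s.n_trna for s in with_trna]
            gcs = [s.gc_fraction for s in with_trna]
            row.update(
                length_min_bp=min(lengths),
                length_max_bp=max(lengths),
                trna_range=_fmt_range(min(counts), max(counts)),
                avg_gc_pct=round(100.0 * float(np.mean(gcs)), 2),
            )
        else:
            row.update(
                length_min_bp=None, length_max_bp=None, trna_range="", avg_gc_pct=None
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt_range(lo: int, hi: int) -> str:
    return str(lo) if lo == hi else f"{lo}–{hi}"
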