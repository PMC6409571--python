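"""Synthetic genomes with planted tRNA gene clusters and biased CDSs.

The generator emulates the statistical structure of the viral genomes the
pipeline targets: genome lengths from a few kb up to ~1.2 Mb, 0-43 tRNA
genes per genome, planted clusters of 15-37 genes at densities of ~2-10
tRNA/kb, configurable GC content, and coding sequences with a controllable
synonymous-codon bias. Planted tRNA genes are coordinate intervals with
isotype/anticodon labels, not realistic tRNA sequences — the pipeline
consumes annotations and never re-predicts genes.

Every generated feature is recorded in a truth table so detection and
grouping can be checked against the planted ground truth. All randomness
flows from a single seed; identical specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import CdsRecord, GenomeRecord, TrnaGene, compute_gc
from .cluster_detection import DEFAULT_MIN_DENSITY, DEFAULT_MIN_GENES
from .codon_usage import SENSE_CODONS, SYNONYMOUS_FAMILIES, _CODON_TO_FAMILY

TRNA_GENE_LENGTH = 72  # bp; typical tRNA gene size


def safe_separation_bp(
    total_trna_genes: int, min_density: float = DEFAULT_MIN_DENSITY
) -> int:
    """Gap that guarantees no detection window can bridge two planted
    features: a window crossing a gap of g bp holds at most N genes over a
    span of at least g bp, so its density is below ``min_density`` whenever
    g > 1000 * N / min_density."""
    return int(1000 * max(total_trna_genes, 1) / min_density) + 500

_STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

# anticodons for the special isotypes (amber- and opal-suppressing tRNAs)
_SPECIAL_ANTICODONS = {"O": "CTA", "U": "TCA"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ClusterPlan:
    """One planted cluster: gene count, target density and isotype content."""

    n_genes: int = DEFAULT_MIN_GENES
    target_density: float = 3.0  # tRNA/kb
    signature: str = "random"  # isotype string, or "random"
    anticodons: list[str] | str = "random_synonymous"

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a cluster plan needs at least 2 genes")
        if self.target_density <= 0:
            raise ValueError("target_density must be > 0")
        if self.signature != "random" and len(self.signature) != self.n_genes:
            raise ValueError("signature length must equal n_genes")
        span = self.span_bp
        if self.n_genes * TRNA_GENE_LENGTH > span:
            raise ValueError(
                f"infeasible plan: {self.n_genes} genes of {TRNA_GENE_LENGTH} bp "
                f"cannot fit in the {span} bp span implied by density "
                f"{self.target_density}"
            )

    @property
    def span_bp(self) -> int:
        """Span implied by the density definition: n_genes / density kb."""
        return round(1000 * self.n_genes / self.target_density)


@dataclass
class SyntheticGenomeSpec:
    """Full parameterization of one synthetic genome."""

    genome_id: str = "synthetic"
    genome_length: int = 60_000
    gc_target: float = 0.44  # the cohort's median GC content
    clusters: list[ClusterPlan] = field(default_factory=list)
    n_loose_trna: int = 0
    n_cds: int = 0
    cds_length_codons: int = 200
    cds_codon_bias: tuple[frozenset[str], float] | None = None  # (designated, w)
    mcp_flag: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc_target <= 1:
            raise ValueError("gc_target must lie in [0, 1]")
        if self.cds_codon_bias is not None:
            designated, w = self.cds_codon_bias
            if w < 1:
                raise ValueError("bias weight w must be >= 1")
            bad = set(designated) - set(SENSE_CODONS)
            if bad:
                raise ValueError(f"designated codons must be sense codons: {sorted(bad)}")


@dataclass
class SyntheticGenome:
    """A generated genome with its annotations and planted truth."""

    genome: GenomeRecord
    trna_genes: list[TrnaGene]
    cds: list[CdsRecord]
    truth: pd.DataFrame  # feature_id, kind, cluster_id, start, end


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _plan_signature(plan: ClusterPlan, rng: np.random.Generator) -> str:
    if plan.signature != "random":
        return plan.signature
    return "".join(rng.choice(list(_STANDARD_AAS), size=plan.n_genes))


def _plan_anticodons(
    plan: ClusterPlan, signature: str, rng: np.random.Generator
) -> list[str | None]:
    if isinstance(plan.anticodons, list):
        return list(plan.anticodons)
    out: list[str | None] = []
    for iso in signature:
        if iso == "X":
            out.append(None)
        elif iso in _SPECIAL_ANTICODONS:
            out.append(_SPECIAL_ANTICODONS[iso])
        else:
            codon = rng.choice(SYNONYMOUS_FAMILIES[iso])
            out.append(_revcomp(codon))
    return out


def _gene_offsets(n: int, span: int) -> list[int]:
    """Uniformly spaced gene starts so the first gene begins at 0 and the
    last ends exactly at ``span``."""
    if n == 1:
        return [0]
    step = (span - TRNA_GENE_LENGTH) / (n - 1)
    return [round(k * step) for k in range(n)]


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate one genome: i.i.d. background sequence at the target GC,
    planted clusters at their target densities, well-separated loose tRNA
    genes, and CDSs with the requested codon bias.

    Placement is left to right with gaps larger than min_genes/min_density
    kb between tRNA features, so planted clusters can never merge with each
    other or with loose genes under the default detection thresholds.
    Raises before producing any output when the features cannot fit.
    """
    rng = np.random.default_rng(spec.seed)

    # --- feasibility: lay out tRNA features left to right
    margin = 1000
    total_trna = sum(p.n_genes for p in spec.clusters) + spec.n_loose_trna
    separation = safe_separation_bp(total_trna)
    cursor = margin
    cluster_layouts: list[tuple[int, ClusterPlan]] = []
    for plan in spec.clusters:
        cluster_layouts.append((cursor, plan))
        cursor += plan.span_bp + separation
    loose_starts = []
    for _ in range(spec.n_loose_trna):
        loose_starts.append(cursor)
        cursor += TRNA_GENE_LENGTH + separation
    trna_end = cursor - separation if (spec.clusters or spec.n_loose_trna) else margin
    if trna_end + margin > spec.genome_length:
        raise ValueError(
            f"infeasible packing: tRNA features need {trna_end + margin} bp "
            f"but genome_length is {spec.genome_length}"
        )

    seq = _random_sequence(rng, spec.genome_length, spec.gc_target)

    trna_genes: list[TrnaGene] = []
    truth_rows: list[dict] = []
    for cluster_id, (origin, plan) in enumerate(cluster_layouts):
        signature = _plan_signature(plan, rng)
        anticodons = _plan_anticodons(plan, signature, rng)
        for k, off in enumerate(_gene_offsets(plan.n_genes, plan.span_bp)):
            gene = TrnaGene(
                genome_id=spec.genome_id,
                start=origin + off,
                end=origin + off + TRNA_GENE_LENGTH,
                strand="+",
                isotype=signature[k],
                anticodon=anticodons[k],
            )
            trna_genes.append(gene)
            truth_rows.append(
                {
                    "feature_id": f"trna_{len(trna_genes) - 1}",
                    "kind": "cluster_trna",
                    "cluster_id": cluster_id,
                    "start": gene.start,
                    "end": gene.end,
                    "isotype": gene.isotype,
                }
            )
    for start in loose_starts:
        iso = str(rng.choice(list(_STANDARD_AAS)))
        codon = rng.choice(SYNONYMOUS_FAMILIES[iso])
        gene = TrnaGene(
            genome_id=spec.genome_id,
            start=start,
            end=start + TRNA_GENE_LENGTH,
            strand="+",
            isotype=iso,
            anticodon=_revcomp(codon),
        )
        trna_genes.append(gene)
        truth_rows.append(
            {
                "feature_id": f"trna_{len(trna_genes) - 1}",
                "kind": "loose_trna",
                "cluster_id": -1,
                "start": gene.start,
                "end": gene.end,
                "isotype": gene.isotype,
            }
        )

    # --- CDSs go after the tRNA features, separated by a small gap
    cds_records: list[CdsRecord] = []
    cds_cursor = trna_end + 200
    designated, w = spec.cds_codon_bias or (frozenset(), 1.0)
    for k in range(spec.n_cds):
        cds_len = spec.cds_length_codons * 3
        if cds_cursor + cds_len + margin > spec.genome_length:
            raise ValueError(
                "infeasible packing: CDSs do not fit after the tRNA features"
            )
        coding = _biased_codon_sequence(
            spec.cds_length_codons, designated, w, rng
        )
        strand = "+" if k % 2 == 0 else "-"
        placed = coding if strand == "+" else _revcomp(coding)
        seq[cds_cursor : cds_cursor + cds_len] = list(placed)
        product = (
            "major capsid protein"
            if (spec.mcp_flag and k == 0)
            else "hypothetical protein"
        )
        rec = CdsRecord(
            genome_id=spec.genome_id,
            cds_id=f"{spec.genome_id}_cds{k}",
            start=cds_cursor,
            end=cds_cursor + cds_len,
            strand=strand,
            product=product,
            sequence=coding,
        )
        cds_records.append(rec)
        truth_rows.append(
            {
                "feature_id": rec.cds_id,
                "kind": "cds",
                "cluster_id": -1,
                "start": rec.start,
                "end": rec.end,
                "isotype": "",
            }
        )
        cds_cursor += cds_len + 200

    sequence = "".join(seq)
    genome = GenomeRecord(
        genome_id=spec.genome_id,
        length_bp=spec.genome_length,
        gc_fraction=compute_gc(sequence),
        sequence=sequence,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "kind", "cluster_id", "start", "end", "isotype"],
    )
    return SyntheticGenome(genome=genome, trna_genes=trna_genes, cds=cds_records, truth=truth)


def _biased_codon_sequence(
    length_codons: int,
    designated: frozenset[str],
    w: float,
    rng: np.random.Generator,
) -> str:
    """ATG + biased body codons + TAA. Within each synonymous family the
    designated codons carry weight w, all others weight 1; amino acids are
    drawn uniformly."""
    if length_codons < 3:
        raise ValueError("a CDS needs at least 3 codons (start, body, stop)")
    n_body = length_codons - 2
    aas = rng.choice(list(_STANDARD_AAS), size=n_body)
    body: list[str] = [""] * n_body
    for aa in set(aas.tolist()):
        idx = np.flatnonzero(aas == aa)
        family = SYNONYMOUS_FAMILIES[aa]
        weights = np.array([w if c in designated else 1.0 for c in family])
        weights = weights / weights.sum()
        picks = rng.choice(len(family), size=idx.size, p=weights)
        for where, pick in zip(idx, picks):
            body[where] = family[pick]
    return "ATG" + "".join(body) + "TAA"


def generate_biased_cds(
    length_codons: int,
    designated: frozenset[str] | set[str],
    w: float,
    seed: int,
    cds_id: str = "synthetic_cds",
    genome_id: str = "synthetic",
) -> CdsRecord:
    """A standalone CDS with designated codons over-weighted by w within
    their synonymous families (w = 1 gives uniform synonymous usage)."""
    designated = frozenset(designated)
    bad = designated - set(SENSE_CODONS)
    if bad:
        raise ValueError(f"designated codons must be sense codons: {sorted(bad)}")
    if w < 1:
        raise ValueError("bias weight w must be >= 1")
    rng = np.random.default_rng(seed)
    seq = _biased_codon_sequence(length_codons, designated, w, rng)
    return CdsRecord(
        genome_id=genome_id,
        cds_id=cds_id,
        start=0,
        end=len(seq),
        strand="+",
        product="synthetic biased CDS",
        sequence=seq,
    )


def sample_designated_set(rng: np.random.Generator) -> frozenset[str]:
    """One designated codon per degenerate synonymous family (families of
    size 1 are excluded: their RSCU is pinned at 1)."""
    picks = []
    for fam in SYNONYMOUS_FAMILIES.values():
        if len(fam) > 1:
            picks.append(fam[int(rng.integers(len(fam)))])
    return frozenset(picks)


def generate_cohort(
    n_genomes: int,
    length_distribution: tuple = ("loguniform", 5_000, 1_200_000),
    trna_length_slope: float = 3e-5,
    noise: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort table of genome lengths and tRNA counts with a tunable
    length-count relationship.

    Lengths are drawn from ``length_distribution`` — ``("uniform", lo, hi)``
    or ``("loguniform", lo, hi)`` (the default spans the 5 kb - 1.2 Mb range
    of viral genomes). Counts are ``round(slope * length + eps)`` with
    Gaussian noise of standard deviation ``noise``, clipped at 0.
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    rng = np.random.default_rng(seed)
    kind, lo, hi = length_distribution
    if kind == "uniform":
        lengths = rng.uniform(lo, hi, size=n_genomes)
    elif kind == "loguniform":
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genomes))
    else:
        raise ValueError(f"unknown length distribution {kind!r}")
    lengths = lengths.round().astype(int)
    counts = np.round(
        trna_length_slope * lengths + rng.normal(0.0, noise, size=n_genomes)
    )
    counts = np.clip(counts, 0, None).astype(int)
    return pd.DataFrame(
        {
            "genome_id": [f"synth_{k}" for k in range(n_genomes)],
            "length_bp": lengths,
            "n_trna": counts,
        }
    )


# ---------------------------------------------------------------------------
# File emission (for the CLI's simulate command)
# ---------------------------------------------------------------------------


def write_genome_files(result: SyntheticGenome, out_dir: str | Path) -> None:
    """Emit genome.fasta, trna.tsv (simple dialect), cds.gff3 and truth.tsv."""
    from .annotation_io import write_report, write_trna_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gid = result.genome.genome_id
    with open(out / "genome.fasta", "w") as fh:
        fh.write(f">{gid}\n")
        seq = result.genome.sequence or ""
        for k in range(0, len(seq), 70):
            fh.write(seq[k : k + 70] + "\n")
    write_trna_table(result.trna_genes, out / "trna.tsv")
    with open(out / "cds.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {gid} 1 {result.genome.length_bp}\n")
        for rec in result.cds:
            attrs = f"ID={rec.cds_id};product={rec.product}"
            fh.write(
                f"{gid}\ttrnaclusterscan\tCDS\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t0\t{attrs}\n"
            )
    write_report(result.truth, out / "truth.tsv")
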