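"""Relative synonymous codon usage (RSCU) and cluster codon patterns.

RSCU measures synonymous codon bias: for a codon c in a synonymous family F,

    RSCU(c) = count(c) * |F| / sum of counts over F

so RSCU = 1 means the codon is used exactly as often as expected under
uniform synonymous usage, > 1 more often, < 1 less often. Stop codons are
excluded; families with zero total count are reported as missing, never 0.

A tRNA gene cluster supplies the codons that are the exact Watson-Crick
reverse complements of its members' anticodons. Comparing this supplied set
with the preferred codons (RSCU > 1) of a target — the whole genome or a
highly expressed gene such as the major capsid protein (MCP) — gives the
matching fraction, a measure of how well the cluster supports the target's
codon demand.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import product as iproduct

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .annotation_io import CdsRecord
from .cluster_detection import TrnaCluster

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in iproduct("ACGT", repeat=3)
)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid (1-letter) -> tuple of synonymous sense codons, standard code
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_CODON_TO_FAMILY: dict[str, tuple[str, ...]] = {
    c: fam for fam in SYNONYMOUS_FAMILIES.values() for c in fam
}


def anticodon_to_codon(anticodon: str) -> str:
    """The codon decoded by an anticodon under exact Watson-Crick pairing:
    its reverse complement (e.g. anticodon CAT -> codon ATG)."""
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or set(anticodon) - set("ACGT"):
        raise ValueError(f"anticodon must be a 3-mer over ACGT, got {anticodon!r}")
    return str(Seq(anticodon).reverse_complement())


@dataclass
class CodonCountTable:
    """Frame-0 codon counts for a genome or a single gene."""

    counts: dict[str, int]
    source_id: str = ""
    scope: str = "genome"  # or "gene"
    n_skipped: int = 0  # codons containing ambiguous bases

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        full.update({k.upper(): int(v) for k, v in self.counts.items()})
        unknown = set(full) - set(ALL_CODONS)
        if unknown:
            raise ValueError(f"non-standard codon keys: {sorted(unknown)}")
        if any(v < 0 for v in full.values()):
            raise ValueError("codon counts must be non-negative")
        self.counts = full


@dataclass
class RscuProfile:
    """Per-codon RSCU values; codons of unobserved families are absent."""

    rscu: dict[str, float]
    source_id: str = ""

    def preferred_set(self) -> frozenset[str]:
        """Sense codons with RSCU strictly greater than 1."""
        return frozenset(c for c, v in self.rscu.items() if v > 1.0)


def count_codons(
    cds: list[CdsRecord] | CdsRecord, source_id: str = "", scope: str = "genome"
) -> CodonCountTable:
    """Sum frame-0 codon counts over coding sequences.

    Codons containing non-ACGT characters are skipped and tallied in
    ``n_skipped``.
    """
    if isinstance(cds, CdsRecord):
        cds = [cds]
    counter: Counter[str] = Counter()
    skipped = 0
    for rec in cds:
        if rec.sequence is None:
            continue
        seq = rec.sequence.upper()
        for k in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[k : k + 3]
            if set(codon) - set("ACGT"):
                skipped += 1
            else:
                counter[codon] += 1
    return CodonCountTable(
        counts=dict(counter), source_id=source_id, scope=scope, n_skipped=skipped
    )


def compute_rscu(table: CodonCountTable) -> RscuProfile:
    """RSCU per sense codon: count * family size / family total.

    Families with zero total count are omitted from the profile entirely
    (missing, not zero); stop codons never appear.
    """
    rscu: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(table.counts[c] for c in family)
        if total == 0:
            continue
        size = len(family)
        for c in family:
            rscu[c] = table.counts[c] * size / total
    return RscuProfile(rscu=rscu, source_id=table.source_id)


@dataclass
class ClusterCodonPattern:
    """Codon and isotype copy numbers supplied by one cluster's tRNA genes."""

    genome_id: str
    cluster_index: int
    codon_copy_number: dict[str, int] = field(default_factory=dict)
    isotype_copy_number: dict[str, int] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        """Number of distinct codons the cluster supplies."""
        return len(self.codon_copy_number)

    @property
    def supplied_set(self) -> frozenset[str]:
        return frozenset(self.codon_copy_number)


def cluster_codon_pattern(cluster: TrnaCluster) -> ClusterCodonPattern:
    """Tally the codons decoded by a cluster's members (exact Watson-Crick)
    and their isotypes. Members with unknown anticodons contribute to the
    isotype tally only."""
    codons: Counter[str] = Counter()
    isotypes: Counter[str] = Counter()
    for g in cluster.members:
        isotypes[g.isotype] += 1
        if g.anticodon is not None:
            codons[anticodon_to_codon(g.anticodon)] += 1
    return ClusterCodonPattern(
        genome_id=cluster.genome_id,
        cluster_index=cluster.cluster_index,
        codon_copy_number=dict(codons),
        isotype_copy_number=dict(isotypes),
    )


@dataclass
class CodonMatchResult:
    """Overlap between a cluster's supplied codons and a target's preferred
    (RSCU > 1) codons; set semantics, copy numbers ignored."""

    genome_id: str
    cluster_index: int
    target_id: str
    preferred_set: frozenset[str]
    supplied_set: frozenset[str]

    @property
    def undefined(self) -> bool:
        return len(self.preferred_set) == 0

    @property
    def matching_fraction(self) -> float | None:
        if self.undefined:
            return None
        return len(self.preferred_set & self.supplied_set) / len(self.preferred_set)


def match_preferred_codons(
    pattern: ClusterCodonPattern, profile: RscuProfile
) -> CodonMatchResult:
    """Fraction of the target's preferred codons (RSCU > 1) that the cluster
    supplies. Undefined (fraction ``None``) when the profile has no codon
    above 1."""
    return CodonMatchResult(
        genome_id=pattern.genome_id,
        cluster_index=pattern.cluster_index,
        target_id=profile.source_id,
        preferred_set=profile.preferred_set(),
        supplied_set=pattern.supplied_set,
    )


def find_mcp(
    cds: list[CdsRecord], pattern: str = "major capsid"
) -> CdsRecord | None:
    """Locate the major capsid protein CDS by its product annotation.

    Matching is a case-insensitive substring/regex search; with multiple
    matches the longest CDS is chosen (all matches are logged).
    """
    rx = re.compile(pattern, re.IGNORECASE)
    matches = [rec for rec in cds if rx.search(rec.product or "")]
    if not matches:
        return None
    if len(matches) > 1:
        logger.info(
            "multiple CDS match %r: %s; choosing the longest",
            pattern,
            [m.cds_id for m in matches],
        )
    return max(matches, key=lambda r: (r.end - r.start, r.cds_id))


def pattern_matrix(patterns: list[ClusterCodonPattern]) -> pd.DataFrame:
    """Clusters-by-codons copy-number matrix (64 codon columns), the survey's
    heatmap-style summary of cluster codon inventories."""
    index = [f"{p.genome_id}:{p.cluster_index}" for p in patterns]
    data = [
        [p.codon_copy_number.get(c, 0) for c in ALL_CODONS] for p in patterns
    ]
    return pd.DataFrame(data, index=index, columns=list(ALL_CODONS))
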