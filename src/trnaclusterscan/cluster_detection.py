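"""Density-based detection of tRNA gene clusters.

A tRNA gene cluster is a maximal run of consecutive tRNA genes whose gene
density over the spanned sequence (first member's start to last member's
end) is at least ``min_density`` tRNA/kb and which contains at least
``min_genes`` genes. The survey defaults — 2 tRNA/kb and 15 genes, both
inclusive thresholds — are the conventional floor for calling an array of
tRNA genes a cluster in comparative genomics.

Detection enumerates every window of consecutive genes satisfying both
thresholds, keeps the maximal ones (no qualifying window strictly contains
them; this also realizes the merge of overlapping windows whose union still
qualifies, since such a union is itself a qualifying window), and resolves
any remaining overlaps deterministically: the window with the most genes is
committed first (ties broken leftmost) and the remainder re-scanned.
Reported clusters are therefore disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import CdsRecord, TrnaGene

DEFAULT_MIN_GENES = 15
DEFAULT_MIN_DENSITY = 2.0  # tRNA genes per kb of spanned sequence
FLANK_WINDOW_BP = 2000


@dataclass(frozen=True)
class ClusterScanParams:
    """Thresholds of the cluster definition."""

    min_genes: int = DEFAULT_MIN_GENES
    min_density: float = DEFAULT_MIN_DENSITY
    circular: bool = False

    def __post_init__(self) -> None:
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")
        if self.min_density <= 0:
            raise ValueError("min_density must be > 0")


@dataclass
class TrnaCluster:
    """A maximal dense run of tRNA genes on one genome."""

    genome_id: str
    members: list[TrnaGene]
    wraparound: bool = False
    cluster_index: int = 0

    @property
    def span_start(self) -> int:
        return self.members[0].start

    @property
    def span_end(self) -> int:
        return max(g.end for g in self.members)

    @property
    def n_genes(self) -> int:
        return len(self.members)

    @property
    def density(self) -> float:
        """tRNA genes per kb of spanned sequence."""
        span = self.span_end - self.span_start
        return self.n_genes / (span / 1000.0) if span > 0 else float("inf")

    @property
    def signature(self) -> str:
        """Member isotypes in genomic order."""
        return "".join(g.isotype for g in self.members)


def _qualifying_windows(
    genes: list[TrnaGene], lo: int, hi: int, params: ClusterScanParams
) -> list[tuple[int, int]]:
    """All windows [i, j] of consecutive genes within [lo, hi) meeting both
    thresholds. O(n^2); gene counts per genome are small."""
    wins = []
    for i in range(lo, hi):
        max_end = genes[i].end
        for j in range(i, hi):
            max_end = max(max_end, genes[j].end)
            count = j - i + 1
            if count < params.min_genes:
                continue
            span = max_end - genes[i].start
            density = count / (span / 1000.0) if span > 0 else float("inf")
            if density >= params.min_density:
                wins.append((i, j))
    return wins


def _detect_in_range(
    genes: list[TrnaGene], lo: int, hi: int, params: ClusterScanParams
) -> list[tuple[int, int]]:
    wins = _qualifying_windows(genes, lo, hi, params)
    if not wins:
        return []
    # maximality: discard windows strictly contained in another qualifying window
    winset = set(wins)
    maximal = [
        w
        for w in wins
        if not any(
            (a <= w[0] and w[1] <= b and (a, b) != w) for a, b in winset
        )
    ]
    maximal.sort()
    overlapping = any(
        maximal[k][1] >= maximal[k + 1][0] for k in range(len(maximal) - 1)
    )
    if not overlapping:
        return maximal
    # deterministic resolution: most genes first, tie leftmost; re-scan remainder
    best = max(maximal, key=lambda w: (w[1] - w[0], -w[0]))
    left = _detect_in_range(genes, lo, best[0], params)
    right = _detect_in_range(genes, best[1] + 1, hi, params)
    return sorted(left + [best] + right)


def detect_clusters(
    genes: list[TrnaGene],
    genome_length: int,
    params: ClusterScanParams | None = None,
) -> list[TrnaCluster]:
    """Find all tRNA gene clusters on one genome.

    Parameters
    ----------
    genes
        The genome's tRNA genes, sorted by start coordinate.
    genome_length
        Genome length in bp; needed for bounds checking and circular mode.
    params
        Thresholds; defaults to ``>= 15`` genes at ``>= 2`` tRNA/kb, linear.
    """
    params = params or ClusterScanParams()
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if any(genes[k].start > genes[k + 1].start for k in range(len(genes) - 1)):
        raise ValueError("tRNA genes must be sorted by start coordinate")
    if genes and (genes[0].start < 0 or max(g.end for g in genes) > genome_length):
        raise ValueError("tRNA gene coordinates outside [0, genome_length]")
    genome_id = genes[0].genome_id if genes else ""

    if not params.circular or not genes:
        windows = _detect_in_range(genes, 0, len(genes), params)
        return _windows_to_clusters(genes, windows, genome_id)

    return _detect_circular(genes, genome_length, params, genome_id)


def _windows_to_clusters(
    genes: list[TrnaGene], windows: list[tuple[int, int]], genome_id: str
) -> list[TrnaCluster]:
    clusters = []
    for idx, (i, j) in enumerate(windows):
        clusters.append(
            TrnaCluster(genome_id=genome_id, members=list(genes[i : j + 1]), cluster_index=idx)
        )
    return clusters


def _detect_circular(
    genes: list[TrnaGene], genome_length: int, params: ClusterScanParams, genome_id: str
) -> list[TrnaCluster]:
    """Scan a virtually doubled gene list so clusters may cross the origin.

    A cluster crossing the origin is reported once, with coordinates of its
    second arc shifted beyond ``genome_length`` and ``wraparound=True``.
    """
    n = len(genes)
    shifted = [
        TrnaGene(
            genome_id=g.genome_id,
            start=g.start + genome_length,
            end=g.end + genome_length,
            strand=g.strand,
            isotype=g.isotype,
            anticodon=g.anticodon,
        )
        for g in genes
    ]
    doubled = genes + shifted
    raw = _detect_in_range(doubled, 0, 2 * n, params)
    # a window must not contain two copies of the same gene
    raw = [(i, j) for i, j in raw if j - i + 1 <= n]
    clusters: list[TrnaCluster] = []
    seen: set[frozenset[int]] = set()
    for i, j in raw:
        member_idx = frozenset(k % n for k in range(i, j + 1))
        if member_idx in seen:
            continue
        seen.add(member_idx)
        members = doubled[i : j + 1]
        wraparound = i < n <= j
        if i >= n:  # same cluster as its unshifted copy
            continue
        clusters.append(
            TrnaCluster(
                genome_id=genome_id,
                members=members,
                wraparound=wraparound,
                cluster_index=len(clusters),
            )
        )
    return clusters


def fraction_clustered(
    genes: list[TrnaGene], clusters: list[TrnaCluster]
) -> float:
    """Fraction of a genome's tRNA genes that belong to any cluster (0 when
    the genome has no tRNA genes)."""
    if not genes:
        return 0.0
    member_keys = {
        (m.genome_id, m.start, m.end) for c in clusters for m in c.members
    }
    clustered = sum(1 for g in genes if (g.genome_id, g.start, g.end) in member_keys)
    return clustered / len(genes)


def extract_flank_genes(
    cluster: TrnaCluster,
    cds: list[CdsRecord],
    window: int = FLANK_WINDOW_BP,
    genome_length: int | None = None,
) -> list[tuple[CdsRecord, str]]:
    """CDS within or flanking (default 2 kb) a cluster's span.

    Returns ``(cds, tag)`` pairs where ``tag`` is ``"within"`` for CDS
    overlapping the span itself and ``"flanking"`` for CDS overlapping only
    the flanks. The flank region is clipped at genome bounds in linear mode.
    """
    lo = max(0, cluster.span_start - window)
    hi = cluster.span_end + window
    if genome_length is not None and not cluster.wraparound:
        hi = min(hi, genome_length)
    out = []
    for rec in cds:
        if rec.genome_id != cluster.genome_id:
            continue
        if rec.start < hi and rec.end > lo:
            within = rec.start < cluster.span_end and rec.end > cluster.span_start
            out.append((rec, "within" if within else "flanking"))
    return out
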