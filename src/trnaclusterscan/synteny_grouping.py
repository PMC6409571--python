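"""Grouping of tRNA gene clusters by isotype arrangement (synteny).

Two clusters belong to the same group when their isotype signatures — the
ordered string of single-letter isotypes along the genome — are identical up
to reading direction. Orientation is normalized by taking the
lexicographically smaller of a signature and its reversal, since a cluster
read from the opposite strand appears with its gene order reversed and no
reading strand is privileged.

Groups are labelled G1, G2, ... in decreasing member count; clusters whose
signature matches no other are singletons. Near-matches between singleton
signatures and group signatures (e.g. a variant differing by a terminal
deletion of a few genes) are reported with their Levenshtein distance rather
than merged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import pandas as pd

from .annotation_io import ISOTYPE_ALPHABET
from .cluster_detection import TrnaCluster


@dataclass
class ClusterGroup:
    """An equivalence class of clusters sharing an isotype arrangement."""

    group_id: str
    canonical_signature: str
    members: list[tuple[str, int]]  # (genome_id, cluster_index)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def _check_signature(signature: str) -> None:
    if not signature:
        raise ValueError("empty isotype signature")
    bad = set(signature) - ISOTYPE_ALPHABET
    if bad:
        raise ValueError(f"symbols outside the isotype alphabet: {sorted(bad)}")


def canonicalize_signature(signature: str) -> str:
    """Orientation-normalize a signature: the lexicographically smaller of
    the string and its reversal."""
    _check_signature(signature)
    rev = signature[::-1]
    return min(signature, rev)


def group_clusters(
    clusters: list[TrnaCluster], canonicalize: bool = True
) -> list[ClusterGroup]:
    """Partition clusters into groups of identical (canonical) signatures.

    Groups are numbered G1, G2, ... by decreasing size, ties broken by
    lexicographic canonical signature; single-member groups are singletons.
    Set ``canonicalize=False`` to treat orientation as significant.
    """
    buckets: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for c in clusters:
        sig = canonicalize_signature(c.signature) if canonicalize else c.signature
        buckets[sig].append((c.genome_id, c.cluster_index))
    ordered = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        ClusterGroup(group_id=f"G{k}", canonical_signature=sig, members=sorted(members))
        for k, (sig, members) in enumerate(ordered, start=1)
    ]


def signature_distance(a: str, b: str) -> int:
    """Levenshtein distance between two signatures, minimized over the two
    orientation pairings of their canonical forms."""
    ca, cb = canonicalize_signature(a), canonicalize_signature(b)
    d_fwd = edlib.align(ca, cb, task="distance")["editDistance"]
    d_rev = edlib.align(ca, cb[::-1], task="distance")["editDistance"]
    return min(d_fwd, d_rev)


def report_near_matches(
    groups: list[ClusterGroup], max_distance: int
) -> pd.DataFrame:
    """For each singleton, the multi-member groups whose canonical signature
    lies within ``max_distance`` edits; sorted by distance.

    Exact matches cannot occur (they would already share a group), so
    ``max_distance=0`` yields an empty table.
    """
    singletons = [g for g in groups if g.is_singleton]
    proper = [g for g in groups if not g.is_singleton]
    rows = []
    for s in singletons:
        for g in proper:
            d = signature_distance(s.canonical_signature, g.canonical_signature)
            if 0 < d <= max_distance:
                rows.append(
                    {
                        "singleton": s.group_id,
                        "singleton_signature": s.canonical_signature,
                        "group": g.group_id,
                        "group_signature": g.canonical_signature,
                        "distance": d,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["singleton", "singleton_signature", "group", "group_signature", "distance"],
    )
    if len(df):
        df = df.sort_values(["distance", "singleton", "group"]).reset_index(drop=True)
    return df
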