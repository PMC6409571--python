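"""Cluster detection: thresholds, maximality, disjointness, oracle equivalence."""

import numpy as np
import pytest

from trnaclusterscan.annotation_io import CdsRecord, TrnaGene
from trnaclusterscan.cluster_detection import (
    ClusterScanParams,
    detect_clusters,
    extract_flank_genes,
    fraction_clustered,
)

from conftest import make_gene, run_spanning, spaced_run

PARAMS = ClusterScanParams()


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def oracle_detect(genes, params):
    """Literal re-derivation: enumerate every consecutive window, keep those
    meeting both thresholds, drop windows contained in another qualifying
    window, then resolve overlaps by committing the window with the most
    genes (tie: leftmost) and recursing on the flanks."""

    def qualifies(i, j):
        count = j - i + 1
        if count < params.min_genes:
            return False
        span = max(g.end for g in genes[i : j + 1]) - genes[i].start
        if span <= 0:
            return True
        return count / (span / 1000.0) >= params.min_density

    def solve(lo, hi):
        wins = [
            (i, j)
            for i in range(lo, hi)
            for j in range(i, hi)
            if qualifies(i, j)
        ]
        if not wins:
            return []
        maximal = [
            w
            for w in wins
            if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in wins)
        ]
        maximal.sort()
        if all(maximal[k][1] < maximal[k + 1][0] for k in range(len(maximal) - 1)):
            return maximal
        best = max(maximal, key=lambda w: (w[1] - w[0], -w[0]))
        return sorted(solve(lo, best[0]) + [best] + solve(best[1] + 1, hi))

    return solve(0, len(genes))


# ---------------------------------------------------------------------------


class TestDetectClusters:
    def test_fifteen_genes_every_500bp_form_one_cluster(self):
        # span = 14*500 + 72 = 7072 bp -> density 15/7.072 ~ 2.121 >= 2
        genes = spaced_run(15, 500)
        (cluster,) = detect_clusters(genes, 50_000, PARAMS)
        assert cluster.n_genes == 15
        assert cluster.density == pytest.approx(15 / 7.072)
        assert [m.start for m in cluster.members] == [m.start for m in genes]

    def test_fourteen_genes_fail_min_genes(self):
        genes = spaced_run(14, 80)  # very dense but one gene short
        assert detect_clusters(genes, 50_000, PARAMS) == []

    def test_empty_gene_list(self):
        assert detect_clusters([], 10_000, PARAMS) == []

    def test_density_threshold_is_inclusive(self):
        # 15 genes spanning exactly 7500 bp -> density exactly 2.0
        genes = run_spanning(15, 7500)
        (cluster,) = detect_clusters(genes, 50_000, PARAMS)
        assert cluster.density == pytest.approx(2.0)
        # one bp wider fails
        wider = run_spanning(15, 7501)
        assert detect_clusters(wider, 50_000, PARAMS) == []

    def test_two_separated_runs_yield_two_clusters(self):
        genes = spaced_run(15, 300) + spaced_run(15, 300, start=30_000)
        clusters = detect_clusters(genes, 60_000, PARAMS)
        assert [c.n_genes for c in clusters] == [15, 15]
        assert clusters[0].span_end < clusters[1].span_start

    def test_unsorted_input_rejected(self):
        genes = [make_gene(1000), make_gene(0)]
        with pytest.raises(ValueError, match="sorted"):
            detect_clusters(genes, 10_000, PARAMS)

    def test_bad_genome_length_rejected(self):
        with pytest.raises(ValueError, match="genome_length"):
            detect_clusters([], 0, PARAMS)
        with pytest.raises(ValueError, match="outside"):
            detect_clusters([make_gene(100, 172)], 150, PARAMS)

    def test_signature_follows_genomic_order(self):
        isotypes = "PEMNACDEFGHIKLQ"
        genes = [
            make_gene(k * 300, isotype=iso) for k, iso in enumerate(isotypes)
        ]
        (cluster,) = detect_clusters(genes, 20_000, PARAMS)
        assert cluster.signature == isotypes
        assert len(cluster.signature) == cluster.n_genes

    def test_circular_cluster_crossing_origin(self):
        L = 50_000
        # 8 genes at the end of the genome + 7 at the start: contiguous
        # across the origin at 300 bp spacing
        tail = spaced_run(8, 300, start=L - 8 * 300)
        head = spaced_run(7, 300, start=100)
        genes = sorted(head + tail, key=lambda g: g.start)
        params = ClusterScanParams(circular=True)
        clusters = detect_clusters(genes, L, params)
        assert len(clusters) == 1
        assert clusters[0].wraparound
        assert clusters[0].n_genes == 15
        assert clusters[0].span_end > L  # second arc shifted past the origin
        # linear mode finds nothing
        assert detect_clusters(genes, L, PARAMS) == []


class TestReportedClusterInvariants:
    def random_instance(self, rng):
        n = int(rng.integers(0, 41))
        starts = np.sort(rng.integers(0, 20_000, size=n))
        return [make_gene(int(s), int(s) + 72) for s in starts]

    def test_thresholds_maximality_disjointness(self, rng):
        for _ in range(200):
            genes = self.random_instance(rng)
            clusters = detect_clusters(genes, 25_000, PARAMS)
            idx_of = {id(g): k for k, g in enumerate(genes)}
            claimed = set()
            for c in clusters:
                assert c.n_genes >= PARAMS.min_genes
                assert c.density >= PARAMS.min_density
                idx = {idx_of[id(m)] for m in c.members}
                # members are consecutive genes
                assert idx == set(range(min(idx), max(idx) + 1))
                # disjointness
                assert not idx & claimed
                claimed |= idx

    def test_maximality_against_neighbours(self, rng):
        for _ in range(100):
            genes = self.random_instance(rng)
            clusters = detect_clusters(genes, 25_000, PARAMS)
            idx_of = {id(g): k for k, g in enumerate(genes)}
            for c in clusters:
                lo = idx_of[id(c.members[0])]
                hi = idx_of[id(c.members[-1])]
                for ext_lo, ext_hi in ((lo - 1, hi), (lo, hi + 1)):
                    if ext_lo < 0 or ext_hi >= len(genes):
                        continue
                    ext = genes[ext_lo : ext_hi + 1]
                    span = max(g.end for g in ext) - ext[0].start
                    density = len(ext) / (span / 1000.0)
                    assert density < PARAMS.min_density

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(200):
            genes = self.random_instance(rng)
            clusters = detect_clusters(genes, 25_000, PARAMS)
            expected = oracle_detect(genes, PARAMS)
            idx_of = {id(g): k for k, g in enumerate(genes)}
            got = [
                (idx_of[id(c.members[0])], idx_of[id(c.members[-1])])
                for c in clusters
            ]
            assert got == expected


class TestFractionClustered:
    def test_all_clustered(self):
        genes = spaced_run(15, 300)
        clusters = detect_clusters(genes, 10_000, PARAMS)
        assert fraction_clustered(genes, clusters) == 1.0

    def test_partial(self):
        clustered = spaced_run(15, 300)
        loose = spaced_run(5, 9000, start=30_000)
        genes = clustered + loose
        clusters = detect_clusters(genes, 100_000, PARAMS)
        assert fraction_clustered(genes, clusters) == pytest.approx(15 / 20)

    def test_no_genes_or_clusters(self):
        assert fraction_clustered([], []) == 0.0
        assert fraction_clustered(spaced_run(3, 5000), []) == 0.0


class TestExtractFlankGenes:
    def cds_at(self, start, end):
        return CdsRecord("g1", f"c{start}", start, end, "+", "p")

    def cluster(self):
        genes = spaced_run(15, 300)
        (c,) = detect_clusters(genes, 100_000, PARAMS)
        return c  # span [0, 4272)

    def test_within_and_flanking_tags(self):
        c = self.cluster()
        inside = self.cds_at(c.span_start + 10, c.span_start + 400)
        near = self.cds_at(c.span_end + 1999, c.span_end + 2600)
        far = self.cds_at(c.span_end + 2001, c.span_end + 2600)
        other_genome = CdsRecord("g2", "x", 0, 300, "+", "p")
        result = extract_flank_genes(c, [inside, near, far, other_genome])
        tags = {rec.cds_id: tag for rec, tag in result}
        assert tags == {inside.cds_id: "within", near.cds_id: "flanking"}

    def test_flank_clipped_at_genome_bounds(self):
        c = self.cluster()
        beyond = self.cds_at(c.span_end + 100, c.span_end + 700)
        result = extract_flank_genes(c, [beyond], genome_length=c.span_end + 50)
        assert result == []
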