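"""Distance-based merging of repeat matches and strand-aware excision.

Homology maskers typically report one element copy as several fragmented
matches (indels, nested insertions and diverged internals break the
alignment). Merging matches whose gap is at most ``merge_dist`` re-joins
such fragments into one region per copy; each region is then excised from
the assembly and reverse-complemented when it lies on the minus strand, so
every excised sequence reads in element orientation.
"""

from __future__ import annotations

from itertools import groupby

from ._types import ExcisedMatch, GenomeAssembly, MatchRecord, MergedRegion, MgecdsError
from .formats import reverse_complement


def merge_matches(matches: list[MatchRecord], merge_dist: int) -> list[MergedRegion]:
    """Coalesce matches whose gap is <= merge_dist into single regions.

    Merging is transitive and ignores strand (fragments of one element often
    carry alternating strand calls); the region inherits the strand of its
    longest constituent match, ties resolving to '+'. Gap is measured
    between half-open ends (next.start - prev.end), so merge_dist=0 joins
    overlapping and abutting matches. Output is sorted by (contig, start).
    """
    if merge_dist < 0:
        raise MgecdsError("merge distance must be >= 0")
    regions: list[MergedRegion] = []
    ordered = sorted(matches, key=lambda m: (m.contig_id, m.start, m.end))
    for contig_id, group in groupby(ordered, key=lambda m: m.contig_id):
        cluster: list[MatchRecord] = []
        cluster_end = -1
        for m in group:
            if cluster and m.start - cluster_end > merge_dist:
                regions.append(_finish_cluster(contig_id, cluster, cluster_end))
                cluster, cluster_end = [], -1
            cluster.append(m)
            cluster_end = max(cluster_end, m.end)
        if cluster:
            regions.append(_finish_cluster(contig_id, cluster, cluster_end))
    return regions


def _finish_cluster(contig_id: str, cluster: list[MatchRecord], end: int) -> MergedRegion:
    # longest constituent sets strand; exact length ties fall back to '+'
    longest = max(cluster, key=lambda m: m.length)
    max_len = longest.length
    strands = {m.strand for m in cluster if m.length == max_len}
    strand = "+" if "+" in strands else "-"
    return MergedRegion(
        contig_id=contig_id,
        start=min(m.start for m in cluster),
        end=end,
        strand=strand,
        n_source_matches=len(cluster),
    )


def excise(assembly: GenomeAssembly, regions: list[MergedRegion]) -> list[ExcisedMatch]:
    """Cut each region out of the assembly, reverse-complementing '-' regions."""
    out: list[ExcisedMatch] = []
    for region in regions:
        if region.contig_id not in assembly:
            raise MgecdsError(f"region {region.region_id}: unknown contig")
        contig = assembly.contigs[region.contig_id]
        if region.end > len(contig):
            raise MgecdsError(
                f"region {region.region_id} extends past contig end {len(contig)}"
            )
        seq = contig[region.start : region.end]
        if region.strand == "-":
            seq = reverse_complement(seq)
        out.append(ExcisedMatch(region=region, sequence=seq))
    return out
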