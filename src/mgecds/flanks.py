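"""Flank extension of validated coding sequences.

Flanks are taken in ELEMENT orientation: the left flank is upstream of the
ORF 5' end on the element strand, which for a minus-strand element is the
genomic segment immediately AFTER its genome_end. This matches how flanks
are used downstream (target-site-duplication and promoter searches are
strand-relative). Flanks are clipped at contig boundaries — never an error —
and the achieved extents are recorded alongside the requested ones.
"""

from __future__ import annotations

from ._types import FlankedCds, GenomeAssembly, MgecdsError, ValidatedCds
from .formats import reverse_complement


def add_flanks(
    assembly: GenomeAssembly,
    validated: list[ValidatedCds],
    flank_left: int = 0,
    flank_right: int = 0,
) -> list[FlankedCds]:
    """Extend each validated CDS with genomic flanks in element orientation."""
    if flank_left < 0 or flank_right < 0:
        raise MgecdsError("flank lengths must be >= 0")
    out: list[FlankedCds] = []
    for cds in validated:
        orf = cds.orf
        if orf.genome_start < 0:
            raise MgecdsError(f"ORF {orf.orf_id} lacks genome coordinates")
        contig_id = orf.match_id.split(":", 1)[0]
        if contig_id not in assembly:
            raise MgecdsError(f"unknown contig {contig_id!r} for {orf.orf_id}")
        contig = assembly.contigs[contig_id]
        gs, ge = orf.genome_start, orf.genome_end
        if orf.genome_strand == "+":
            span_start = max(0, gs - flank_left)
            span_end = min(len(contig), ge + flank_right)
            actual_left = gs - span_start
            actual_right = span_end - ge
            seq = contig[span_start:span_end]
        else:
            # element 5' end sits at genome_end; upstream is genomic downstream
            span_start = max(0, gs - flank_right)
            span_end = min(len(contig), ge + flank_left)
            actual_left = span_end - ge
            actual_right = gs - span_start
            seq = reverse_complement(contig[span_start:span_end])
        out.append(
            FlankedCds(
                cds=cds,
                requested_left=flank_left,
                requested_right=flank_right,
                actual_left=actual_left,
                actual_right=actual_right,
                sequence=seq,
            )
        )
    return out
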