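"""ORF finding on excised matches and conserved-domain validation.

The coding-capacity test for a candidate element copy is: does the excised
match contain an open reading frame, and does that ORF contain an alignment
to every required conserved domain (e.g. reverse transcriptase and
endonuclease for non-LTR retroelements)? Domain alignments arrive as a
12-column tabular file from an external PSSM search; ORFs are found here.

ORF definition used throughout:

* one ORF per (frame, terminating stop codon), the stop included in the
  span and counted by the minimum-length filter, excluded from the
  translation;
* ``atg_only`` starts at the FIRST ATG after the previous in-frame stop
  (the maximal ATG-initiated variant); ``any_sense`` starts at the codon
  after the previous stop (or the frame start);
* a reading frame that runs into the sequence end without a stop yields an
  "open-ended" ORF flagged ``has_stop=False`` — these are truncated
  elements at match boundaries and can be filtered downstream.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from Bio.Data import CodonTable

from ._types import (
    DomainHit,
    DomainTable,
    ExcisedMatch,
    MergedRegion,
    MgecdsError,
    OrfRecord,
    ValidatedCds,
)
from .formats import reverse_complement

logger = logging.getLogger(__name__)


def _codon_table(genetic_code: int) -> CodonTable.CodonTable:
    try:
        return CodonTable.unambiguous_dna_by_id[genetic_code]
    except KeyError as exc:
        raise MgecdsError(f"unknown genetic code table id {genetic_code}") from exc


def translate(nt_seq: str, genetic_code: int = 1) -> str:
    """Codon-by-codon translation; trailing stop omitted, unknown codons -> X."""
    table = _codon_table(genetic_code)
    stops = set(table.stop_codons)
    aa = []
    for i in range(0, len(nt_seq) - 2, 3):
        codon = nt_seq[i : i + 3]
        if codon in stops:
            if i == len(nt_seq) - 3:
                break  # terminal stop: not part of the protein
            aa.append("*")
        else:
            aa.append(table.forward_table.get(codon, "X"))
    return "".join(aa)


def find_orfs(
    sequence: str,
    min_len: int = 1000,
    genetic_code: int = 1,
    start_policy: str = "atg_only",
    strand_policy: str = "plus_only",
    match_id: str = "",
) -> list[OrfRecord]:
    """Locate ORFs of span >= min_len on a (plus-oriented) match sequence.

    Defaults mirror the conventional ORF-finder policy: standard genetic
    code, minimum 1000 bp, ATG start, plus strand only.
    """
    table = _codon_table(genetic_code)
    if start_policy not in ("atg_only", "any_sense"):
        raise MgecdsError(f"unknown start policy {start_policy!r}")
    if strand_policy not in ("plus_only", "both"):
        raise MgecdsError(f"unknown strand policy {strand_policy!r}")
    orfs: list[OrfRecord] = []
    strands = ["+"] if strand_policy == "plus_only" else ["+", "-"]
    for strand in strands:
        s = sequence if strand == "+" else reverse_complement(sequence)
        for frame in range(3):
            for i, j, has_stop in _scan_frame(s, frame, set(table.stop_codons), start_policy):
                if j - i < min_len:
                    continue
                nt = s[i:j]
                if strand == "+":
                    start, end = i, j
                else:
                    start, end = len(s) - j, len(s) - i
                orfs.append(
                    OrfRecord(
                        match_id=match_id,
                        frame=frame,
                        strand=strand,
                        start=start,
                        end=end,
                        nt_seq=nt,
                        aa_seq=translate(nt, genetic_code),
                        has_stop=has_stop,
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def _scan_frame(
    s: str, frame: int, stops: set[str], start_policy: str
) -> Iterable[tuple[int, int, bool]]:
    """Yield (start, end, has_stop) spans for one reading frame."""
    seg_start = frame  # codon after the previous stop, or frame start
    first_atg: Optional[int] = None
    pos = frame
    last_codon_end = frame + 3 * ((len(s) - frame) // 3)
    while pos + 3 <= len(s):
        codon = s[pos : pos + 3]
        if codon in stops:
            if start_policy == "atg_only":
                if first_atg is not None:
                    yield first_atg, pos + 3, True
            elif pos + 3 - seg_start >= 3:
                yield seg_start, pos + 3, True
            seg_start = pos + 3
            first_atg = None
        elif first_atg is None and codon == "ATG":
            first_atg = pos
        pos += 3
    # open-ended tail: frame reaches the end of the last complete codon
    if start_policy == "atg_only":
        if first_atg is not None and last_codon_end > first_atg:
            yield first_atg, last_codon_end, False
    elif last_codon_end - seg_start >= 3:
        yield seg_start, last_codon_end, False


def group_hits(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


def validate_orfs(
    orfs: list[OrfRecord],
    hits: Iterable[DomainHit],
    domain_table: DomainTable,
    evalue_max: float = 0.01,
    known_match_ids: Optional[set[str]] = None,
) -> list[ValidatedCds]:
    """Keep ORFs containing a qualifying hit of EVERY required domain type.

    A hit qualifies for an ORF when its PSSM belongs to the domain type, its
    e-value is <= evalue_max, its interval lies fully inside the ORF span,
    and its frame orientation agrees with the ORF strand (reverse-frame hits
    support minus-strand ORFs only, forward hits plus-strand ORFs only).
    The lowest-e-value qualifying hit per type is recorded.
    """
    grouped = group_hits(hits)
    if known_match_ids is not None:
        for qid in list(grouped):
            if qid not in known_match_ids:
                logger.warning("skipping hits on unknown match id %r", qid)
                del grouped[qid]
    validated: list[ValidatedCds] = []
    for orf in orfs:
        candidates = grouped.get(orf.match_id, [])
        support: dict[str, DomainHit] = {}
        for dtype, pssms in domain_table.required_domains.items():
            best: Optional[DomainHit] = None
            for h in candidates:
                if h.pssm_id not in pssms or h.evalue > evalue_max:
                    continue
                if h.reverse_frame != (orf.strand == "-"):
                    continue
                if h.q_start < orf.start or h.q_end > orf.end:
                    continue
                if best is None or h.evalue < best.evalue:
                    best = h
            if best is None:
                break
            support[dtype] = best
        else:
            validated.append(ValidatedCds(orf=orf, supporting_hits=support))
    return validated


def filter_matches_with_hits(
    excised: list[ExcisedMatch], hits: Iterable[DomainHit], evalue_max: float = 0.01
) -> list[ExcisedMatch]:
    """Matches carrying at least one hit passing the e-value cut, any domain."""
    passing = {h.query_id for h in hits if h.evalue <= evalue_max}
    return [m for m in excised if m.match_id in passing]


def project_to_genome(orf: OrfRecord, region: MergedRegion) -> OrfRecord:
    """Fill in assembly coordinates for an ORF found on an excised region.

    The excised sequence is the region read in element orientation, so a
    position p on it maps to region.start + p for '+' regions and to
    region.end - p (mirrored) for '-' regions. The genome strand combines
    the region strand with the ORF strand on the excised sequence.
    """
    if orf.end > region.length:
        raise MgecdsError(
            f"ORF {orf.orf_id} extends past region {region.region_id}"
        )
    if region.strand == "+":
        gs, ge = region.start + orf.start, region.start + orf.end
    else:
        gs, ge = region.end - orf.end, region.end - orf.start
    flip = (region.strand == "-") != (orf.strand == "-")
    orf.genome_start, orf.genome_end = gs, ge
    orf.genome_strand = "-" if flip else "+"
    return orf
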