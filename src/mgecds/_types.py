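"""Core record types shared across the pipeline.

All genomic intervals are 0-based half-open on the forward strand of their
reference sequence (contig or excised match). Format-specific conventions
(1-based inclusive RepeatMasker / BLAST columns) are converted at the parser
boundary and never leak past it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STAGE_ORDER = ("consensus", "coords", "orfs", "flanks")


class MgecdsError(ValueError):
    """Base class for user-facing input/contract errors."""


@dataclass
class GenomeAssembly:
    """An in-memory assembly: contig id -> uppercase A/C/G/T/N string."""

    contigs: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.contigs


@dataclass
class ConsensusRecord:
    """One repeat-family consensus with its 'name#Type/Subtype' classification."""

    name: str
    mge_type: str
    mge_subtype: str
    sequence: str

    @property
    def classification(self) -> str:
        """The 'Type/Subtype' string (or just 'Type' when subtype is empty)."""
        if self.mge_subtype:
            return f"{self.mge_type}/{self.mge_subtype}"
        return self.mge_type


@dataclass
class MatchRecord:
    """One repeat-similarity hit on the assembly."""

    contig_id: str
    start: int
    end: int
    strand: str
    repeat_name: str = "."
    repeat_class: str = "."
    score: Optional[int] = None
    divergence_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MgecdsError(
                f"invalid match interval {self.start}..{self.end} on {self.contig_id}"
            )
        if self.strand not in "+-":
            raise MgecdsError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DomainHit:
    """A conserved-domain alignment interval on an excised match.

    Coordinates are nucleotide positions on the match plus strand,
    0-based half-open. ``reverse_frame`` marks hits whose raw tabular
    coordinates were reported qstart > qend (hit on a reverse frame).
    """

    query_id: str
    pssm_id: str
    q_start: int
    q_end: int
    evalue: float
    bitscore: float
    reverse_frame: bool = False

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise MgecdsError(f"invalid hit interval {self.q_start}..{self.q_end}")
        if self.evalue < 0:
            raise MgecdsError("negative e-value")


@dataclass
class DomainTable:
    """Required conserved-domain types and the PSSM accessions realising each."""

    required_domains: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dtype, pssms in self.required_domains.items():
            if not pssms:
                raise MgecdsError(f"domain type {dtype!r} has no PSSM ids")
            for p in pssms:
                if p in seen:
                    raise MgecdsError(
                        f"PSSM {p!r} listed under both {seen[p]!r} and {dtype!r}"
                    )
                seen[p] = dtype

    def type_of(self, pssm_id: str) -> Optional[str]:
        for dtype, pssms in self.required_domains.items():
            if pssm_id in pssms:
                return dtype
        return None


@dataclass
class RunParams:
    """Full parameter set for one pipeline run."""

    mge_keyword: str = "Penelope"
    merge_dist: int = 2000
    evalue_max: float = 0.01
    min_orf_len: int = 1000
    genetic_code: int = 1
    start_policy: str = "atg_only"  # atg_only | any_sense
    strand_policy: str = "plus_only"  # plus_only | both
    flank_left: int = 0
    flank_right: int = 0
    from_stage: str = "default"
    to_stage: str = "flanks"

    def __post_init__(self) -> None:
        if self.merge_dist < 0:
            raise MgecdsError("merge distance must be >= 0")
        if self.min_orf_len < 0 or self.flank_left < 0 or self.flank_right < 0:
            raise MgecdsError("lengths must be >= 0")
        if self.evalue_max <= 0:
            raise MgecdsError("e-value threshold must be > 0")
        if self.start_policy not in ("atg_only", "any_sense"):
            raise MgecdsError(f"unknown start policy {self.start_policy!r}")
        if self.strand_policy not in ("plus_only", "both"):
            raise MgecdsError(f"unknown strand policy {self.strand_policy!r}")
        for stage in (self.from_stage, self.to_stage):
            if stage not in STAGE_ORDER + ("default",):
                raise MgecdsError(f"unknown stage keyword {stage!r}")


@dataclass
class MergedRegion:
    """A strand-annotated interval produced by distance-d merging of matches."""

    contig_id: str
    start: int
    end: int
    strand: str
    n_source_matches: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise MgecdsError(f"invalid region {self.start}..{self.end}")
        if self.n_source_matches < 1:
            raise MgecdsError("region must contain at least one match")

    @property
    def region_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExcisedMatch:
    """A merged region's sequence, in element orientation."""

    region: MergedRegion
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.region.length:
            raise MgecdsError("excised sequence length disagrees with region span")

    @property
    def match_id(self) -> str:
        return self.region.region_id


@dataclass
class OrfRecord:
    """An open reading frame on an excised match.

    ``start``/``end`` index the excised (element-oriented) sequence;
    ``strand`` is relative to that sequence ('-' only arises under
    strand_policy='both'). The span includes the terminating stop codon
    when one exists; ``has_stop`` is False for open-ended ORFs that run
    into the sequence end. ``nt_seq`` is in reading orientation.
    """

    match_id: str
    frame: int
    strand: str
    start: int
    end: int
    nt_seq: str
    aa_seq: str
    has_stop: bool
    genome_start: int = -1
    genome_end: int = -1
    genome_strand: str = "+"

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def orf_id(self) -> str:
        return f"{self.match_id}|orf:{self.start}-{self.end}({self.strand})f{self.frame}"


@dataclass
class ValidatedCds:
    """An ORF with a qualifying conserved-domain hit of every required type."""

    orf: OrfRecord
    supporting_hits: dict[str, DomainHit] = field(default_factory=dict)


@dataclass
class FlankedCds:
    """A validated CDS extended with genomic flanks in element orientation."""

    cds: ValidatedCds
    requested_left: int
    requested_right: int
    actual_left: int
    actual_right: int
    sequence: str


@dataclass
class LengthStats:
    """Descriptive statistics over a set of sequence lengths."""

    n: int
    min: int = 0
    max: int = 0
    mean: float = 0.0
    median: float = 0.0
    sd: float = 0.0
    sd_note: str = ""
    histogram: list[tuple[int, int, int]] = field(default_factory=list)
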