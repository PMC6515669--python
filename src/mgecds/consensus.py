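"""Selection of MGE consensuses of interest from a classified repeat library.

A de-novo repeat library classifies each consensus as ``Type/Subtype`` (or
"Unknown"). The user names an element type at any taxonomic level — "LINE",
"LINE/L1", "Penelope", "BovB" — and records whose classification contains
that keyword (case-insensitively) are selected. Unclassified records are
set aside so they can be classified externally (e.g. by the CENSOR service)
and folded back in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._types import ConsensusRecord

logger = logging.getLogger(__name__)


@dataclass
class ConsensusPartition:
    """Exhaustive, disjoint split of a library into selected / unknown / rejected."""

    selected: list[ConsensusRecord] = field(default_factory=list)
    unknown: list[ConsensusRecord] = field(default_factory=list)
    rejected_count: int = 0

    @property
    def total(self) -> int:
        return len(self.selected) + len(self.unknown) + self.rejected_count


def check_types(library: list[ConsensusRecord]) -> dict[str, int]:
    """Count records per distinct 'Type/Subtype' string, most frequent first."""
    counts: dict[str, int] = {}
    for rec in library:
        counts[rec.classification] = counts.get(rec.classification, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def select_consensuses(library: list[ConsensusRecord], mge_keyword: str) -> ConsensusPartition:
    """Partition the library by a case-insensitive substring match on classification.

    Records typed "Unknown" go to the unknown bucket; records matching the
    keyword are selected; everything else is counted as rejected.
    """
    if not mge_keyword:
        raise ValueError("MGE keyword must be non-empty")
    key = mge_keyword.lower()
    part = ConsensusPartition()
    for rec in library:
        if rec.mge_type == "Unknown":
            part.unknown.append(rec)
        elif key in rec.classification.lower():
            part.selected.append(rec)
        else:
            part.rejected_count += 1
    if not part.selected and not part.unknown:
        logger.warning("no consensuses of type %s", mge_keyword)
    return part


def apply_censor(
    partition: ConsensusPartition, censor_map: dict[str, str], mge_keyword: str
) -> ConsensusPartition:
    """Move unknown records whose external classification matches the keyword.

    The selected set only ever grows; unmatched or unclassified records stay
    in the unknown bucket.
    """
    key = mge_keyword.lower()
    promoted: list[ConsensusRecord] = []
    remaining: list[ConsensusRecord] = []
    for rec in partition.unknown:
        classification = censor_map.get(rec.name)
        if classification is not None and key in classification.lower():
            promoted.append(rec)
        else:
            remaining.append(rec)
    if promoted:
        logger.info("CENSOR promoted %d unknown consensuses to selected", len(promoted))
    return ConsensusPartition(
        selected=partition.selected + promoted,
        unknown=remaining,
        rejected_count=partition.rejected_count,
    )
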