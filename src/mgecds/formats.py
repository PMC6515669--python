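"""Readers and writers for the external formats the pipeline touches.

Every parser converts to the internal convention (0-based half-open,
uppercase A/C/G/T/N, '+'/'-' strands) on the way in; writers convert back
on the way out. Conversions from 1-based inclusive formats are exactly
(begin-1, end).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from lxml import html as lxml_html

from ._types import (
    ConsensusRecord,
    DomainHit,
    DomainTable,
    GenomeAssembly,
    MatchRecord,
    MgecdsError,
    RunParams,
)

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map characters outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    cleaned = "".join(c if c in _VALID_BASES else "N" for c in seq)
    n_replaced = sum(1 for a, b in zip(seq, cleaned) if a != b)
    logger.info("replaced %d non-ACGTN characters with N", n_replaced)
    return cleaned


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA


def read_assembly(path: Union[str, Path]) -> GenomeAssembly:
    """Read a genome assembly FASTA into memory, normalised to A/C/G/T/N."""
    contigs: dict[str, str] = {}
    for rec in _iter_fasta(path):
        if rec.id in contigs:
            raise MgecdsError(f"duplicate contig identifier {rec.id!r} in {path}")
        contigs[rec.id] = normalize_sequence(str(rec.seq))
    return GenomeAssembly(contigs=contigs)


def read_consensus_library(path: Union[str, Path]) -> list[ConsensusRecord]:
    """Read a classified repeat library.

    Headers follow the de-novo repeat-discovery convention
    ``name#Type/Subtype``; the first '#' splits name from classification and
    the first '/' inside the classification splits Type from Subtype.
    Headers without '#' are classified "Unknown".
    """
    records: list[ConsensusRecord] = []
    seen: set[str] = set()
    for rec in _iter_fasta(path):
        header = rec.description if rec.description else rec.id
        token = header.split()[0]
        if "#" in token:
            name, classification = token.split("#", 1)
            if "/" in classification:
                mge_type, mge_subtype = classification.split("/", 1)
            else:
                mge_type, mge_subtype = classification, ""
            if not mge_type:
                mge_type = "Unknown"
        else:
            name, mge_type, mge_subtype = token, "Unknown", ""
        if not name:
            raise MgecdsError(f"empty record name in {path}")
        if name in seen:
            raise MgecdsError(f"duplicate consensus identifier {name!r} in {path}")
        seen.add(name)
        records.append(
            ConsensusRecord(
                name=name,
                mge_type=mge_type,
                mge_subtype=mge_subtype,
                sequence=normalize_sequence(str(rec.seq)),
            )
        )
    return records


def _iter_fasta(path: Union[str, Path]) -> Iterable[SeqRecord]:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MgecdsError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: Union[str, Path]) -> int:
    """Write (header, sequence) pairs as FASTA. Returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
            n += 1
    return n


def write_consensus_fasta(records: Iterable[ConsensusRecord], path: Union[str, Path]) -> int:
    return write_fasta(
        ((f"{r.name}#{r.classification}", r.sequence) for r in records), path
    )


# ---------------------------------------------------------------------------
# RepeatMasker .out


def parse_repeatmasker_out(path: Union[str, Path]) -> list[MatchRecord]:
    """Parse the RepeatMasker .out dialect.

    Three header lines, whitespace-separated columns; columns (1-based)
    5..9 are query, begin, end, (left), strand; begin/end are 1-based
    inclusive; strand is '+' or 'C' (complement). Coordinates convert to
    0-based half-open; 'C' maps to '-'.
    """
    matches: list[MatchRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3:
            continue  # banner + column headers + blank
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 11:
            raise MgecdsError(f"{path}:{lineno}: expected >=11 columns, got {len(f)}")
        try:
            score = int(f[0])
            div = float(f[1])
            begin = int(f[5])
            end = int(f[6])
        except ValueError as exc:
            raise MgecdsError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
        if begin > end:
            raise MgecdsError(f"{path}:{lineno}: begin {begin} > end {end}")
        strand_sym = f[8]
        if strand_sym == "+":
            strand = "+"
        elif strand_sym == "C":
            strand = "-"
        else:
            raise MgecdsError(f"{path}:{lineno}: unknown strand symbol {strand_sym!r}")
        matches.append(
            MatchRecord(
                contig_id=f[4],
                start=begin - 1,
                end=end,
                strand=strand,
                repeat_name=f[9],
                repeat_class=f[10],
                score=score,
                divergence_pct=div,
            )
        )
    return matches


def write_repeatmasker_out(matches: Iterable[MatchRecord], path: Union[str, Path]) -> int:
    """Write matches back out in the RepeatMasker .out dialect."""
    header = (
        "   SW  perc perc perc  query     position in query           matching"
        "  repeat          position in repeat\n"
        "score  div. del. ins.  sequence  begin  end      (left)   "
        "  repeat          class/family    begin end (left)  ID\n"
        "\n"
    )
    n = 0
    with open(path, "w") as fh:
        fh.write(header)
        for i, m in enumerate(matches, start=1):
            strand = "+" if m.strand == "+" else "C"
            fh.write(
                f"{m.score if m.score is not None else 0:>5d} "
                f"{m.divergence_pct if m.divergence_pct is not None else 0.0:5.1f} "
                f"0.0 0.0 {m.contig_id} {m.start + 1} {m.end} (0) {strand} "
                f"{m.repeat_name} {m.repeat_class} 1 {m.length} (0) {i}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED6


def write_bed(matches: Iterable[MatchRecord], path: Union[str, Path]) -> int:
    n = 0
    with open(path, "w") as fh:
        for m in matches:
            score = m.score if m.score is not None else 0
            fh.write(
                f"{m.contig_id}\t{m.start}\t{m.end}\t{m.repeat_name}\t{score}\t{m.strand}\n"
            )
            n += 1
    return n


def parse_bed(path: Union[str, Path]) -> list[MatchRecord]:
    matches: list[MatchRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise MgecdsError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise MgecdsError(f"{path}:{lineno}: malformed coordinate: {exc}") from exc
            if start >= end:
                raise MgecdsError(f"{path}:{lineno}: start {start} >= end {end}")
            if f[5] not in "+-":
                raise MgecdsError(f"{path}:{lineno}: unknown strand {f[5]!r}")
            score = int(f[4]) if re.fullmatch(r"-?\d+", f[4]) else None
            matches.append(
                MatchRecord(
                    contig_id=f[0],
                    start=start,
                    end=end,
                    strand=f[5],
                    repeat_name=f[3],
                    score=score,
                )
            )
    return matches


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6, 12 columns)


def parse_blast_tab(path: Union[str, Path]) -> list[DomainHit]:
    """Parse 12-column BLAST tabular output of a conserved-domain search.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. qstart/qend are 1-based inclusive
    nucleotide positions on the match plus strand; qstart > qend marks a
    hit on a reverse frame and is normalised by swapping before the
    coordinate conversion.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise MgecdsError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
            try:
                qstart, qend = int(f[6]), int(f[7])
                evalue = float(f[10])
                bitscore = float(f[11])
            except ValueError as exc:
                raise MgecdsError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
            reverse = qstart > qend
            if reverse:
                qstart, qend = qend, qstart
            hits.append(
                DomainHit(
                    query_id=f[0],
                    pssm_id=f[1],
                    q_start=qstart - 1,
                    q_end=qend,
                    evalue=evalue,
                    bitscore=bitscore,
                    reverse_frame=reverse,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[DomainHit], path: Union[str, Path]) -> int:
    n = 0
    with open(path, "w") as fh:
        for h in hits:
            qstart, qend = h.q_start + 1, h.q_end
            if h.reverse_frame:
                qstart, qend = qend, qstart
            fh.write(
                f"{h.query_id}\t{h.pssm_id}\t100.00\t{h.q_end - h.q_start}\t0\t0\t"
                f"{qstart}\t{qend}\t1\t{(h.q_end - h.q_start) // 3}\t"
                f"{h.evalue:g}\t{h.bitscore:.1f}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Domain table (CSV or TSV)


def parse_domain_table(path: Union[str, Path]) -> DomainTable:
    """Parse the two-column domain-type / PSSM-accession correspondence table.

    The delimiter (comma or TAB) is auto-detected per file.
    """
    required: dict[str, set[str]] = {}
    with open(path) as fh:
        text = fh.read()
    delim = "\t" if "\t" in text else ","
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = [c.strip() for c in line.split(delim)]
        if len(f) < 2 or not f[0] or not f[1]:
            raise MgecdsError(f"{path}:{lineno}: expected 'domain{delim}pssm_id'")
        required.setdefault(f[0], set()).add(f[1])
    if not required:
        raise MgecdsError(f"no rows in domain table {path}")
    return DomainTable(required_domains=required)  # validates pssm uniqueness


# ---------------------------------------------------------------------------
# CENSOR classification report (HTML)


def parse_censor_report(path_or_text: Union[str, Path]) -> dict[str, str]:
    """Extract (query name -> classification) pairs from a CENSOR HTML report.

    Targets the first table with >=2 columns; column 1 is the query name and
    the classification column is the one whose header mentions "Class" or
    "Repeat" (falling back to column 2 when headers are absent). The first
    occurrence of a name wins. Raises when no such table exists rather than
    guessing.
    """
    text: str
    p = Path(str(path_or_text))
    try:
        is_file = p.is_file()
    except OSError:
        is_file = False
    if is_file:
        text = p.read_text()
    else:
        text = str(path_or_text)
    try:
        doc = lxml_html.fromstring(text)
    except Exception as exc:  # noqa: BLE001 - malformed markup
        raise MgecdsError(f"no CENSOR results found: unparsable HTML ({exc})") from exc
    for table in doc.iter("table"):
        rows = [
            [" ".join(cell.text_content().split()) for cell in row.iter("td", "th")]
            for row in table.iter("tr")
        ]
        rows = [r for r in rows if r]
        if not rows or max(len(r) for r in rows) < 2:
            continue
        class_col = 1
        header = rows[0]
        has_header = any(
            re.search(r"class|repeat", cell, flags=re.IGNORECASE) for cell in header
        )
        if has_header:
            for i, cell in enumerate(header):
                if re.search(r"class|repeat", cell, flags=re.IGNORECASE):
                    class_col = i
                    break
            data_rows = rows[1:]
        else:
            data_rows = rows
        result: dict[str, str] = {}
        for r in data_rows:
            if len(r) <= class_col or not r[0]:
                continue
            result.setdefault(r[0], r[class_col])
        if result:
            return result
    raise MgecdsError("no CENSOR results found")


# ---------------------------------------------------------------------------
# JSON configuration


def write_config(path: Union[str, Path], params: RunParams, tool_paths: dict | None = None) -> None:
    """Persist the run parameters (and informational tool paths) as JSON."""
    payload = {
        "tool_paths": tool_paths or {},
        "params": {
            "mge_keyword": params.mge_keyword,
            "merge_dist": params.merge_dist,
            "evalue_max": params.evalue_max,
            "min_orf_len": params.min_orf_len,
            "genetic_code": params.genetic_code,
            "start_policy": params.start_policy,
            "strand_policy": params.strand_policy,
            "flank_left": params.flank_left,
            "flank_right": params.flank_right,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_config(path: Union[str, Path]) -> tuple[RunParams, dict]:
    data = json.loads(Path(path).read_text())
    return RunParams(**data.get("params", {})), data.get("tool_paths", {})
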