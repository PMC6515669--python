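"""Ground-truthed synthetic fixtures: toy genomes with planted retroelements.

The generator plants retroelement copies of four categories into random
background sequence and emits the companion annotation files the pipeline
consumes (repeat-match table in the masker's .out dialect, domain hits as
12-column tabular rows, the domain correspondence table), all derived from
a single seed:

* ``intact`` — a full ORF (ATG ... in-frame stop) carrying both an RT-like
  and an EN-like domain segment;
* ``missing_domain`` — same ORF but the EN segment is emitted only as a
  decoy hit with e-value 0.5, so it fails the default 0.01 threshold;
* ``disrupted`` — a premature in-frame stop splits the ORF into sub-length
  pieces;
* ``fragmented`` — the planted element is contiguous in the genome but its
  match annotation is split into two rows around an unannotated internal
  gap, the way homology maskers fragment diverged internals.

Background is uniform random nucleotide sequence, hence stop-codon rich, so
spurious long ORFs are improbable. Planted ORFs are >=1800 bp, comfortably
above the conventional 1000 bp minimum-length default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from ._types import DomainTable, GenomeAssembly, MatchRecord, MgecdsError
from .formats import reverse_complement, write_blast_tab, write_fasta, write_repeatmasker_out
from .regions import merge_matches
from ._types import DomainHit

# element geometry (element-local offsets, bp)
_UTR = 150
_ORF_LEN_SIMPLE = 1800  # intact / missing_domain / disrupted
_ORF_LEN_FRAG = 2700  # fragmented: room for a 1500 bp unannotated gap
_RT_OFFSET = (120, 570)  # relative to ORF start
_EN_BACK_OFFSET = (600, 150)  # (before ORF end, before ORF end)
_FRAG_SPLIT = 585  # relative to ORF start; gap starts here

_STOPS = ("TAA", "TAG", "TGA")
_RT_PSSM = "pfam00078"
_EN_PSSM = "cd09076"
_REPEAT_CLASS = "PLE/Penelope"


@dataclass
class PlantSpec:
    """What to plant. Defaults give the standard 50-element fixture suite."""

    n_contigs: int = 5
    contig_len: int = 120_000
    n_intact: int = 20
    n_missing_domain: int = 10
    n_disrupted: int = 10
    n_fragmented: int = 10
    fragment_gap: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_intact, self.n_missing_domain, self.n_disrupted, self.n_fragmented) < 0:
            raise MgecdsError("element counts must be >= 0")
        if self.fragment_gap <= 0:
            raise MgecdsError("fragment gap must be > 0")


@dataclass
class TruthRecord:
    """Ground truth for one planted element copy."""

    element_id: str
    contig: str
    start: int
    end: int
    strand: str
    category: str
    orf_start: int  # genomic; -1 when no intact ORF planted
    orf_end: int
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)  # genomic
    decoy_domains: set[str] = field(default_factory=set)
    pieces: list[tuple[int, int]] = field(default_factory=list)  # annotated match rows


def required_domain_table() -> DomainTable:
    return DomainTable(required_domains={"RT": {_RT_PSSM}, "EN": {_EN_PSSM}})


def write_domain_table_csv(path: Union[str, Path]) -> None:
    Path(path).write_text(f"RT,{_RT_PSSM}\nEN,{_EN_PSSM}\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _random_orf(rng: np.random.Generator, orf_len: int) -> str:
    """ATG + random non-stop codons + TAA, exactly orf_len bp."""
    assert orf_len % 3 == 0 and orf_len >= 9
    codons = []
    while len(codons) < orf_len // 3 - 2:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _build_element(rng: np.random.Generator, category: str, orf_len: int) -> tuple[str, dict]:
    """Element sequence (plus orientation) and element-local layout."""
    utr5 = _random_seq(rng, _UTR)
    # in-frame stop just before the ORF: blocks upstream ATG extension
    utr5 = utr5[: _UTR - 3] + "TAA"
    orf = _random_orf(rng, orf_len)
    if category == "disrupted":
        mid = 3 * (orf_len // 6)  # premature stop splits ORF into ~900 bp halves
        orf = orf[:mid] + "TAA" + orf[mid + 3 :]
    utr3 = _random_seq(rng, _UTR)
    seq = utr5 + orf + utr3
    orf_start = _UTR
    layout = {
        "orf": (orf_start, orf_start + orf_len),
        "RT": (orf_start + _RT_OFFSET[0], orf_start + _RT_OFFSET[1]),
        "EN": (
            orf_start + orf_len - _EN_BACK_OFFSET[0],
            orf_start + orf_len - _EN_BACK_OFFSET[1],
        ),
    }
    return seq, layout


def generate(spec: PlantSpec) -> tuple[GenomeAssembly, list[TruthRecord]]:
    """Plant elements into random background; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    categories = (
        ["intact"] * spec.n_intact
        + ["missing_domain"] * spec.n_missing_domain
        + ["disrupted"] * spec.n_disrupted
        + ["fragmented"] * spec.n_fragmented
    )
    rng.shuffle(categories)
    contigs = {f"ctg{i + 1}": [] for i in range(spec.n_contigs)}
    cursor = {name: 0 for name in contigs}
    truth: list[TruthRecord] = []
    for k, category in enumerate(categories):
        contig = f"ctg{(k % spec.n_contigs) + 1}"
        orf_len = _ORF_LEN_FRAG if category == "fragmented" else _ORF_LEN_SIMPLE
        spacing = int(rng.integers(2500, 6000))
        seq, layout = _build_element(rng, category, orf_len)
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor[contig] + spacing
        end = start + len(seq)
        if end + spacing > spec.contig_len:
            raise MgecdsError(
                f"planted content exceeds contig capacity on {contig} "
                f"(need {end + spacing}, have {spec.contig_len})"
            )
        contigs[contig].append((cursor[contig], _random_seq(rng, spacing)))
        contigs[contig].append((start, seq if strand == "+" else reverse_complement(seq)))
        cursor[contig] = end

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return start + a, start + b
            return end - b, end - a

        rec = TruthRecord(
            element_id=f"elem{k + 1:03d}_{category}",
            contig=contig,
            start=start,
            end=end,
            strand=strand,
            category=category,
            orf_start=-1,
            orf_end=-1,
        )
        if category != "disrupted":
            rec.orf_start, rec.orf_end = to_genomic(*layout["orf"])
        rec.domains = {"RT": to_genomic(*layout["RT"]), "EN": to_genomic(*layout["EN"])}
        if category == "missing_domain":
            rec.decoy_domains = {"EN"}
        if category == "fragmented":
            split = layout["orf"][0] + _FRAG_SPLIT
            p1 = (0, split)
            p2 = (split + spec.fragment_gap, len(seq))
            rec.pieces = [to_genomic(*p1), to_genomic(*p2)]
            rec.pieces.sort()
        else:
            rec.pieces = [(start, end)]
        truth.append(rec)
    # pad every contig to its declared length
    assembled = {}
    for name, chunks in contigs.items():
        tail = spec.contig_len - cursor[name]
        chunks.append((cursor[name], _random_seq(rng, tail)))
        assembled[name] = "".join(c for _, c in sorted(chunks))
        assert len(assembled[name]) == spec.contig_len
    truth.sort(key=lambda t: (t.contig, t.start))
    return GenomeAssembly(contigs=assembled), truth


def truth_matches(truth: list[TruthRecord]) -> list[MatchRecord]:
    """One MatchRecord per annotated piece, as a masker would report them."""
    matches = []
    for rec in truth:
        for i, (a, b) in enumerate(rec.pieces):
            matches.append(
                MatchRecord(
                    contig_id=rec.contig,
                    start=a,
                    end=b,
                    strand=rec.strand,
                    repeat_name=rec.element_id,
                    repeat_class=_REPEAT_CLASS,
                    score=1000 + i,
                    divergence_pct=5.0,
                )
            )
    matches.sort(key=lambda m: (m.contig_id, m.start))
    return matches


def truth_domain_hits(truth: list[TruthRecord], merge_dist: int) -> list[DomainHit]:
    """Domain hits keyed by the excised-match ids produced at merge_dist.

    Mirrors what a PSSM search over the excised matches would report: a hit
    row exists only where a domain interval is fully contained in a single
    excised region, with coordinates on the region's element-oriented plus
    strand. Real domains get e-value 1e-30; decoys get 0.5.
    """
    regions = merge_matches(truth_matches(truth), merge_dist)
    hits: list[DomainHit] = []
    for rec in truth:
        for dtype, (gs, ge) in rec.domains.items():
            region = next(
                (
                    r
                    for r in regions
                    if r.contig_id == rec.contig and r.start <= gs and ge <= r.end
                ),
                None,
            )
            if region is None:
                continue
            if region.strand == "+":
                qs, qe = gs - region.start, ge - region.start
            else:
                qs, qe = region.end - ge, region.end - gs
            evalue = 0.5 if dtype in rec.decoy_domains else 1e-30
            pssm = _RT_PSSM if dtype == "RT" else _EN_PSSM
            hits.append(
                DomainHit(
                    query_id=region.region_id,
                    pssm_id=pssm,
                    q_start=qs,
                    q_end=qe,
                    evalue=evalue,
                    bitscore=200.0 if evalue < 1 else 30.0,
                )
            )
    return hits


def emit_annotation_fixtures(
    truth: list[TruthRecord], outdir: Union[str, Path], merge_dist: int = 2000
) -> tuple[Path, Path]:
    """Write the masker .out and domain-hit tabular fixture files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out_path = outdir / "genome.out"
    blast_path = outdir / "domain_hits.tsv"
    write_repeatmasker_out(truth_matches(truth), out_path)
    write_blast_tab(truth_domain_hits(truth, merge_dist), blast_path)
    return out_path, blast_path


def emit_consensus_library(path: Union[str, Path], seed: int = 0) -> int:
    """A small classified repeat library for the consensus-selection stage."""
    rng = np.random.default_rng(seed)
    headers = [
        "rnd-1_family-1#PLE/Penelope",
        "rnd-1_family-2#PLE/Penelope",
        "rnd-2_family-7#PLE/Poseidon",
        "rnd-1_family-3#LINE/L1",
        "rnd-3_family-9#LINE/CR1",
        "rnd-2_family-4#DNA/hAT",
        "rnd-4_family-11",
        "rnd-4_family-12",
    ]
    return write_fasta(((h, _random_seq(rng, 300)) for h in headers), path)


def write_truth_tsv(truth: list[TruthRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "element_id\tcontig\tstart\tend\tstrand\tcategory\t"
            "orf_start\torf_end\tdomains\tdecoys\tpieces\n"
        )
        for t in truth:
            doms = ";".join(f"{d}:{a}-{b}" for d, (a, b) in sorted(t.domains.items()))
            pieces = ";".join(f"{a}-{b}" for a, b in t.pieces)
            fh.write(
                f"{t.element_id}\t{t.contig}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.category}\t{t.orf_start}\t{t.orf_end}\t{doms}\t"
                f"{','.join(sorted(t.decoy_domains))}\t{pieces}\n"
            )


def write_fixture_suite(
    spec: PlantSpec, outdir: Union[str, Path], merge_dist: int = 2000
) -> dict[str, Path]:
    """Regenerate the full fixture suite (genome + annotations) from a seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, truth = generate(spec)
    genome_path = outdir / "genome.fa"
    write_fasta(assembly.contigs.items(), genome_path)
    out_path, blast_path = emit_annotation_fixtures(truth, outdir, merge_dist)
    table_path = outdir / "domains.csv"
    write_domain_table_csv(table_path)
    truth_path = outdir / "truth.tsv"
    write_truth_tsv(truth, truth_path)
    lib_path = outdir / "library.fa"
    emit_consensus_library(lib_path, seed=spec.seed)
    return {
        "genome": genome_path,
        "repeatmasker_out": out_path,
        "blast_tab": blast_path,
        "domain_table": table_path,
        "truth": truth_path,
        "library": lib_path,
    }
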