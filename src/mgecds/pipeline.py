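"""Staged orchestration: consensus -> coords -> orfs -> flanks.

Heavy external tools (de-novo repeat discovery, similarity masking, PSSM
search) are consumed only through their standard output files, so each
stage declares the files it needs and any stage can be re-entered from
persisted intermediates. The run directory is named after the assembly;
every file written is recorded in a machine-readable manifest together
with its record count, so filter attrition is auditable.

Output file names follow the established inventory verbatim:
MGE_consensi.fa, Unknown_consensi.fa.classified, genome.out.bed,
MGE_excised_matchesX.fa, MGE_matches_with_hits_eX.fa, MGE_cdsX.fa,
MGE_cdsX_with_domains_eX.fa, MGE_cdsX_with_domains_eX_extended_LXRX.fa,
with X substituted by the relevant parameter (the e-value is rendered with
its leading "0." stripped: 0.01 -> e01).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import consensus as consensus_mod
from . import flanks as flanks_mod
from . import orfs as orfs_mod
from . import regions as regions_mod
from . import stats as stats_mod
from ._types import (
    STAGE_ORDER,
    DomainHit,
    ExcisedMatch,
    GenomeAssembly,
    MergedRegion,
    MgecdsError,
    OrfRecord,
    RunParams,
    ValidatedCds,
)
from .formats import (
    parse_bed,
    parse_blast_tab,
    parse_censor_report,
    parse_domain_table,
    parse_repeatmasker_out,
    read_assembly,
    read_consensus_library,
    write_bed,
    write_consensus_fasta,
    write_fasta,
)

logger = logging.getLogger(__name__)

_STAGE_INPUTS = {
    "consensus": ["library"],
    "coords": ["assembly", "coords"],
    "orfs": ["hits", "domain_table"],
    "flanks": ["assembly"],
}


@dataclass
class StagePlan:
    """A contiguous slice of the stage order plus per-stage input needs."""

    stages: list[str]
    required: dict[str, list[str]] = field(default_factory=dict)


def resolve_stages(params: RunParams) -> StagePlan:
    """Turn from_stage/to_stage keywords into an executable plan."""
    start = params.from_stage
    if start == "default":
        start = "consensus"
    i = STAGE_ORDER.index(start)
    j = STAGE_ORDER.index(params.to_stage)
    if i > j:
        raise MgecdsError(
            f"from-stage {params.from_stage!r} comes after to-stage {params.to_stage!r}"
        )
    stages = list(STAGE_ORDER[i : j + 1])
    return StagePlan(stages=stages, required={s: list(_STAGE_INPUTS[s]) for s in stages})


def format_evalue(evalue: float) -> str:
    """0.01 -> "01": general-format number with a leading '0.' stripped."""
    s = f"{evalue:g}"
    if s.startswith("0."):
        s = s[2:]
    return s


def output_name(kind: str, params: RunParams) -> str:
    """Deterministic substitution of the parameter placeholders."""
    e = format_evalue(params.evalue_max)
    names = {
        "consensi": "MGE_consensi.fa",
        "unknown_consensi": "Unknown_consensi.fa.classified",
        "matches_bed": "genome.out.bed",
        "excised": f"MGE_excised_matches{params.merge_dist}.fa",
        "matches_with_hits": f"MGE_matches_with_hits_e{e}.fa",
        "cds": f"MGE_cds{params.min_orf_len}.fa",
        "validated_cds": f"MGE_cds{params.min_orf_len}_with_domains_e{e}.fa",
        "validated_tsv": f"MGE_cds{params.min_orf_len}_with_domains_e{e}.tsv",
        "flanked": (
            f"MGE_cds{params.min_orf_len}_with_domains_e{e}"
            f"_extended_L{params.flank_left}R{params.flank_right}.fa"
        ),
    }
    try:
        return names[kind]
    except KeyError as exc:
        raise MgecdsError(f"unknown output kind {kind!r}") from exc


_REGION_ID_RE = re.compile(r"^(?P<contig>.+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$")


def parse_region_id(region_id: str, n_source_matches: int = 1) -> MergedRegion:
    m = _REGION_ID_RE.match(region_id)
    if not m:
        raise MgecdsError(f"unparsable region id {region_id!r}")
    return MergedRegion(
        contig_id=m.group("contig"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=m.group("strand"),
        n_source_matches=n_source_matches,
    )


class PipelineRun:
    """One staged run over a working directory named after the assembly."""

    def __init__(
        self,
        params: RunParams,
        inputs: dict[str, Union[str, Path]],
        outdir: Union[str, Path] = ".",
        make_plots: bool = False,
    ):
        self.params = params
        self.inputs = {k: Path(v) for k, v in inputs.items()}
        self.make_plots = make_plots
        assembly_path = self.inputs.get("assembly")
        run_name = assembly_path.stem if assembly_path else "run"
        self.workdir = Path(outdir) / run_name
        self.manifest: dict[str, dict] = {}
        self._assembly: Optional[GenomeAssembly] = None
        self._excised: Optional[list[ExcisedMatch]] = None
        self._validated: Optional[list[ValidatedCds]] = None

    # -- plumbing -----------------------------------------------------------

    @property
    def assembly(self) -> GenomeAssembly:
        if self._assembly is None:
            path = self._require("assembly", "coords")
            self._assembly = read_assembly(path)
        return self._assembly

    def _require(self, key: str, stage: str) -> Path:
        path = self.inputs.get(key)
        if path is None or not path.exists():
            raise MgecdsError(f"{stage} stage requires input {key!r} (file missing)")
        return path

    def _record(self, kind: str, path: Path, n_records: int) -> None:
        self.manifest[kind] = {"path": str(path), "n_records": n_records}
        logger.info("wrote %s (%d records)", path, n_records)

    def _write_set(self, kind: str, records: list[tuple[str, str]]) -> Path:
        path = self.workdir / output_name(kind, self.params)
        n = write_fasta(records, path)
        self._record(kind, path, n)
        self._write_stats(path, [len(seq) for _, seq in records])
        return path

    def _write_stats(self, fasta_path: Path, lengths: list[int]) -> None:
        st = stats_mod.compute_stats(lengths)
        stats_path = fasta_path.with_suffix(fasta_path.suffix + ".stats")
        stats_mod.write_stats(st, stats_path, label=fasta_path.name)
        if self.make_plots and st.n:
            stats_mod.plot_histogram(
                st, fasta_path.with_suffix(fasta_path.suffix + ".png"), title=fasta_path.name
            )

    # -- stages -------------------------------------------------------------

    def run(self) -> dict:
        plan = resolve_stages(self.params)
        self.workdir.mkdir(parents=True, exist_ok=True)
        for stage in plan.stages:
            logger.info("=== stage %s ===", stage)
            getattr(self, f"_stage_{stage}")()
        manifest_path = self.workdir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2) + "\n")
        return self.manifest

    def _stage_consensus(self) -> None:
        library = read_consensus_library(self._require("library", "consensus"))
        part = consensus_mod.select_consensuses(library, self.params.mge_keyword)
        censor_path = self.inputs.get("censor")
        if censor_path is not None:
            censor_map = parse_censor_report(censor_path)
            part = consensus_mod.apply_censor(part, censor_map, self.params.mge_keyword)
        logger.info(
            "library %d -> selected %d, unknown %d, rejected %d",
            part.total, len(part.selected), len(part.unknown), part.rejected_count,
        )
        path = self.workdir / output_name("consensi", self.params)
        self._record("consensi", path, write_consensus_fasta(part.selected, path))
        self._write_stats(path, [len(r.sequence) for r in part.selected])
        upath = self.workdir / output_name("unknown_consensi", self.params)
        self._record("unknown_consensi", upath, write_consensus_fasta(part.unknown, upath))

    def _stage_coords(self) -> None:
        coords_path = self._require("coords", "coords")
        if coords_path.suffix == ".bed":
            matches = parse_bed(coords_path)
        else:
            matches = parse_repeatmasker_out(coords_path)
        bed_path = self.workdir / output_name("matches_bed", self.params)
        self._record("matches_bed", bed_path, write_bed(matches, bed_path))
        regions = regions_mod.merge_matches(matches, self.params.merge_dist)
        logger.info(
            "%d matches -> %d regions at merge distance %d",
            len(matches), len(regions), self.params.merge_dist,
        )
        self._excised = regions_mod.excise(self.assembly, regions)
        self._write_set("excised", [(m.match_id, m.sequence) for m in self._excised])

    def _load_excised(self) -> list[ExcisedMatch]:
        if self._excised is not None:
            return self._excised
        path = self.workdir / output_name("excised", self.params)
        if not path.exists():
            raise MgecdsError(f"orfs stage requires excised matches ({path} missing)")
        excised = []
        for rec in read_consensus_library(path):  # plain headers, no '#'
            region = parse_region_id(rec.name)
            excised.append(ExcisedMatch(region=region, sequence=rec.sequence))
        self._excised = excised
        return excised

    def _stage_orfs(self) -> None:
        p = self.params
        excised = self._load_excised()
        hits = parse_blast_tab(self._require("hits", "orfs"))
        domain_table = parse_domain_table(self._require("domain_table", "orfs"))
        with_hits = orfs_mod.filter_matches_with_hits(excised, hits, p.evalue_max)
        self._write_set("matches_with_hits", [(m.match_id, m.sequence) for m in with_hits])
        all_orfs: list[OrfRecord] = []
        by_id = {m.match_id: m for m in excised}
        for m in excised:
            found = orfs_mod.find_orfs(
                m.sequence,
                min_len=p.min_orf_len,
                genetic_code=p.genetic_code,
                start_policy=p.start_policy,
                strand_policy=p.strand_policy,
                match_id=m.match_id,
            )
            for orf in found:
                orfs_mod.project_to_genome(orf, m.region)
            all_orfs.extend(found)
        logger.info("%d excised matches -> %d ORFs >= %d bp", len(excised), len(all_orfs), p.min_orf_len)
        self._write_set("cds", [(orf.orf_id, orf.nt_seq) for orf in all_orfs])
        validated = orfs_mod.validate_orfs(
            all_orfs, hits, domain_table, p.evalue_max,
            known_match_ids=set(by_id),
        )
        logger.info("%d ORFs -> %d validated CDS", len(all_orfs), len(validated))
        self._validated = validated
        self._write_set(
            "validated_cds", [(self._cds_header(v), v.orf.nt_seq) for v in validated]
        )
        tsv_path = self.workdir / output_name("validated_tsv", self.params)
        self._write_validated_tsv(validated, tsv_path)
        self._record("validated_tsv", tsv_path, len(validated))

    @staticmethod
    def _cds_header(v: ValidatedCds) -> str:
        orf = v.orf
        doms = " ".join(
            f"{d}={h.pssm_id}:{h.evalue:g}" for d, h in sorted(v.supporting_hits.items())
        )
        return (
            f"{orf.orf_id} loc={orf.genome_start}-{orf.genome_end}"
            f"({orf.genome_strand}) frame={orf.frame} {doms}"
        )

    def _write_validated_tsv(self, validated: list[ValidatedCds], path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "orf_id\tmatch_id\tframe\torf_strand\tstart\tend\t"
                "genome_start\tgenome_end\tgenome_strand\thas_stop\t"
                "aa_len\tsupporting_hits\n"
            )
            for v in validated:
                o = v.orf
                doms = ";".join(
                    f"{d}:{h.pssm_id}:{h.q_start}:{h.q_end}:{h.evalue:g}:{h.bitscore:g}"
                    for d, h in sorted(v.supporting_hits.items())
                )
                fh.write(
                    f"{o.orf_id}\t{o.match_id}\t{o.frame}\t{o.strand}\t{o.start}\t"
                    f"{o.end}\t{o.genome_start}\t{o.genome_end}\t{o.genome_strand}\t"
                    f"{int(o.has_stop)}\t{len(o.aa_seq)}\t{doms}\n"
                )

    def _load_validated(self) -> list[ValidatedCds]:
        if self._validated is not None:
            return self._validated
        path = self.workdir / output_name("validated_tsv", self.params)
        if not path.exists():
            raise MgecdsError(f"flanks stage requires coding sequences ({path} missing)")
        validated: list[ValidatedCds] = []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("orf_id")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                contig = f[1].split(":", 1)[0]
                gs, ge, gstrand = int(f[6]), int(f[7]), f[8]
                seq = self.assembly.contigs[contig][gs:ge]
                if gstrand == "-":
                    from .formats import reverse_complement

                    seq = reverse_complement(seq)
                orf = OrfRecord(
                    match_id=f[1], frame=int(f[2]), strand=f[3],
                    start=int(f[4]), end=int(f[5]), nt_seq=seq,
                    aa_seq=orfs_mod.translate(seq, self.params.genetic_code),
                    has_stop=bool(int(f[9])), genome_start=gs, genome_end=ge,
                    genome_strand=gstrand,
                )
                hits: dict[str, DomainHit] = {}
                if f[11]:
                    for item in f[11].split(";"):
                        d, pssm, qs, qe, ev, bs = item.split(":")
                        hits[d] = DomainHit(
                            query_id=f[1], pssm_id=pssm, q_start=int(qs),
                            q_end=int(qe), evalue=float(ev), bitscore=float(bs),
                        )
                validated.append(ValidatedCds(orf=orf, supporting_hits=hits))
        self._validated = validated
        return validated

    def _stage_flanks(self) -> None:
        p = self.params
        validated = self._load_validated()
        flanked = flanks_mod.add_flanks(self.assembly, validated, p.flank_left, p.flank_right)
        records = [
            (
                f"{fc.cds.orf.orf_id} flanks={fc.actual_left}/{fc.actual_right}"
                f" requested={fc.requested_left}/{fc.requested_right}",
                fc.sequence,
            )
            for fc in flanked
        ]
        self._write_set("flanked", records)


def run(
    params: RunParams,
    inputs: dict[str, Union[str, Path]],
    outdir: Union[str, Path] = ".",
    make_plots: bool = False,
) -> dict:
    """Execute the resolved stage plan; returns the output manifest."""
    return PipelineRun(params, inputs, outdir, make_plots).run()
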