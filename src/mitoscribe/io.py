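"""Readers and writers for the external formats the pipeline touches.

FASTA and GenBank go through Biopython; GFA 1.0 is a small hand-rolled
parser (S-lines with a DP depth tag, L-lines with NM-style overlap cigars).
All tabular reports are UTF-8 TSV with a header row.  Coordinates in every
file are 1-based inclusive.
"""

from __future__ import annotations

import io as _io
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation, ExactPosition, SeqFeature

from .graph import AssemblyGraph, GraphNode, ReadPath
from .model import FormatError, GeneFeature, GenomeRecord, GenomeSet

_FASTA_WRAP = 70


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> GenomeSet:
    """Read a (multi-)FASTA file into a GenomeSet.

    Topology defaults to linear; a header tag ``circular=true`` marks a
    record circular.  Sequences are uppercased and validated over {A,C,G,T,N}.
    """
    records: List[GenomeRecord] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            topo = "circular" if "circular=true" in rec.description.lower() else "linear"
            try:
                records.append(GenomeRecord(rec.id, str(rec.seq), topology=topo))
            except FormatError:
                raise
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSet(records)


def write_fasta(genome: GenomeSet | GenomeRecord, path: str) -> None:
    records = genome.records if isinstance(genome, GenomeSet) else [genome]
    with open(path, "w") as fh:
        for r in records:
            tag = " circular=true" if r.topology == "circular" else ""
            fh.write(f">{r.id}{tag}\n")
            for i in range(0, len(r.sequence), _FASTA_WRAP):
                fh.write(r.sequence[i : i + _FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# GenBank

_KIND_BY_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def _check_location(feat: SeqFeature, rid: str) -> None:
    loc = feat.location
    if loc is None:
        raise FormatError(f"{rid}: feature without location")
    if isinstance(loc, CompoundLocation) and loc.operator != "join":
        raise FormatError(
            f"{rid}: unsupported location operator {loc.operator!r} "
            "(only join/complement/plain ranges are accepted)"
        )
    for part in loc.parts:
        if not isinstance(part.start, ExactPosition) or not isinstance(
            part.end, ExactPosition
        ):
            raise FormatError(f"{rid}: fuzzy positions (<, >) are not supported")


def read_genbank(path: str) -> GenomeRecord:
    """Read one GenBank flatfile into a GenomeRecord with gene features.

    ``join()`` locations become exon lists; ``complement()`` sets strand "-"
    and stores exons 5'->3' in gene orientation.  Gene names come from the
    /gene qualifier with /product as fallback.
    """
    with open(path) as fh:
        try:
            rec = SeqIO.read(fh, "genbank")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(rec.seq) == 0:
        raise FormatError(f"{path}: missing or empty ORIGIN block")
    n = len(seq)
    topo = "circular" if rec.annotations.get("topology") == "circular" else "linear"
    features: List[GeneFeature] = []
    for feat in rec.features:
        kind = _KIND_BY_TYPE.get(feat.type)
        if kind is None:
            continue
        _check_location(feat, rec.id)
        name = feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))[0]
        strand = "-" if feat.location.strand == -1 else "+"
        exons = []
        for part in feat.location.parts:
            s, e = int(part.start) + 1, int(part.end)
            if e > n or s < 1:
                raise FormatError(
                    f"{rec.id}: feature {name} extends beyond sequence end ({e} > {n})"
                )
            exons.append((s, e))
        exons.sort()
        if strand == "-":
            exons = exons[::-1]
        features.append(GeneFeature(name, kind, strand, exons))
    return GenomeRecord(rec.id, seq, topology=topo, features=features)


# ---------------------------------------------------------------------------
# GFA 1.0

def read_gfa(path: str) -> AssemblyGraph:
    """Read a GFA 1.0 assembly graph (S-lines with optional DP:f depth tag,
    L-lines with <int>M overlap cigars)."""
    nodes: Dict[str, GraphNode] = {}
    links: List[Tuple[str, str, str, str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] not in "SL":
                continue
            f = line.split("\t")
            if f[0] == "S":
                if len(f) < 3:
                    raise FormatError(f"{path}:{ln}: malformed S-line")
                name, seq = f[1], f[2]
                depth: Optional[float] = None
                for tag in f[3:]:
                    parts = tag.split(":", 2)
                    if len(parts) == 3 and parts[0].upper() == "DP":
                        depth = float(parts[2])
                nodes[name] = GraphNode(seq.upper(), depth)
            elif f[0] == "L":
                if len(f) < 6:
                    raise FormatError(f"{path}:{ln}: malformed L-line")
                a, ao, b, bo, cig = f[1], f[2], f[3], f[4], f[5]
                ov = 0 if cig in ("*", "0M") else int(cig.rstrip("M"))
                links.append((a, ao, b, bo, ov))
    graph = AssemblyGraph(nodes=nodes)
    for a, ao, b, bo, ov in links:
        if a not in nodes or b not in nodes:
            missing = a if a not in nodes else b
            raise FormatError(f"{path}: L-line references unknown node {missing!r}")
        graph.add_edge(a, ao, b, bo, ov)
    return graph


def write_gfa(graph: AssemblyGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name in sorted(graph.nodes):
            node = graph.nodes[name]
            tag = f"\tDP:f:{node.depth:g}" if node.depth is not None else ""
            fh.write(f"S\t{name}\t{node.sequence}{tag}\n")
        for (a, ao, b, bo), ov in sorted(graph.edges.items()):
            fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t{ov}M\n")


# ---------------------------------------------------------------------------
# Read paths (2-column TSV: read_id <TAB> comma-separated oriented node list)

def read_read_paths(path: str) -> List[ReadPath]:
    out: List[ReadPath] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rid, pathspec = line.split("\t")
            steps = []
            for tok in pathspec.split(","):
                tok = tok.strip()
                node, orient = tok[:-1], tok[-1]
                if orient not in "+-":
                    raise FormatError(f"{path}: bad oriented node {tok!r}")
                steps.append((node, orient))
            out.append(ReadPath(rid, steps))
    return out


def write_read_paths(reads: Sequence[ReadPath], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tpath\n")
        for r in reads:
            fh.write(r.read_id + "\t" + ",".join(f"{n}{o}" for n, o in r.path) + "\n")


# ---------------------------------------------------------------------------
# GFF3 writer (features / introns export)

def write_gff3(record: GenomeRecord, path: str,
               introns: Optional[Iterable] = None) -> None:
    """Write the record's gene features (one gene line + exon lines) and,
    optionally, IntronRegion entries as GFF3."""
    type_by_kind = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {len(record)}\n")
        for feat in record.features:
            s, e = feat.span
            fh.write(
                f"{record.id}\tmitoscribe\t{type_by_kind[feat.kind]}\t{s}\t{e}\t.\t"
                f"{feat.strand}\t.\tID=gene-{feat.gene_name};Name={feat.gene_name}\n"
            )
            for xs, xe in feat.exons_genomic:
                fh.write(
                    f"{record.id}\tmitoscribe\texon\t{xs}\t{xe}\t.\t{feat.strand}\t.\t"
                    f"Parent=gene-{feat.gene_name}\n"
                )
        for ir in introns or []:
            s, e = ir.interval
            fh.write(
                f"{record.id}\tmitoscribe\tintron\t{s}\t{e}\t.\t{ir.strand}\t.\t"
                f"ID=intron-{ir.name};Name={ir.name}\n"
            )


# ---------------------------------------------------------------------------
# Aligned FASTA (MSA)

def read_alignment(path: str) -> Dict[str, str]:
    """Aligned FASTA -> ordered {sequence id: aligned sequence}."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no aligned sequences found")
    return out


def write_alignment(alignment: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")
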