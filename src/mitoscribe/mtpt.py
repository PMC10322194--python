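"""Mitochondrial plastid DNA (MTPT) detection.

Plastid-to-mitochondrion DNA transfer leaves homologous segments shared by
the two organelle genomes.  We find them by BLASTn local alignment between
the mitochondrial chromosomes and the plastome (reward +2, penalty -3,
gap open 5, gap extend 2, word size 9, E < 1e-5 — the standard somewhat
permissive nucleotide scheme for cross-genome homology), merge HSPs that
describe one mitochondrial locus, and bin each MTPT by percent identity
(70-80 / 80-90 / 90-100).  A mitochondrial segment homologous to both
copies of the plastome inverted repeat (IR) is one transfer event and is
counted once: merging is keyed on the mitochondrial locus, so hits to IRa
and IRb collapse.

The alignment engine is NCBI BLAST+ ``blastn``, invoked per call; results
are parsed into :class:`Hsp` objects carrying the aligned rows so identity
can be independently recomputed column by column.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._util import interval_union_length
from .model import GeneFeature, GenomeRecord, GenomeSet

_OUTFMT = (
    "6 qseqid sseqid qstart qend sstart send nident length pident evalue "
    "bitscore qseq sseq"
)


@dataclass(frozen=True)
class AlignParams:
    """BLASTn scoring for organelle cross-genome comparison."""

    word_size: int = 9
    reward: int = 2
    penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    evalue_cutoff: float = 1e-5
    dust: bool = False  # low-complexity masking off: organelle DNA is AT-rich


@dataclass
class Hsp:
    query_id: str
    subject_id: str
    query_interval: Tuple[int, int]  # 1-based inclusive, start <= end
    subject_interval: Tuple[int, int]
    strand: str  # subject strand relative to query, "+"/"-"
    score: float  # bit score
    identity: float  # matches / alignment columns, in (0, 1]
    length: int  # alignment columns
    e_value: float
    qseq: str = ""  # aligned rows (with gap dashes)
    sseq: str = ""


@dataclass
class MTPT:
    id: str  # MTPT1..n in mitochondrial coordinate order
    record_id: str
    mito_intervals: List[Tuple[int, int]]
    plastome_interval: Tuple[int, int]
    strand: str
    length: int  # mito bases covered, each counted once
    identity: float
    identity_bin: str  # "70-80" | "80-90" | "90-100" | "<70"
    genes: List[Tuple[str, str]] = field(default_factory=list)  # (name, complete|partial)


class BlastNotFoundError(RuntimeError):
    pass


def _require_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise BlastNotFoundError(
            "NCBI BLAST+ 'blastn' is required on PATH for local alignment"
        )
    return exe


def _write_fasta(records: Sequence[GenomeRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")


def _run_blastn(
    queries: Sequence[GenomeRecord], subject: GenomeRecord, params: AlignParams
) -> List[Hsp]:
    exe = _require_blastn()
    with tempfile.TemporaryDirectory(prefix="mitoscribe_blast_") as tmp:
        qpath = os.path.join(tmp, "query.fa")
        spath = os.path.join(tmp, "subject.fa")
        _write_fasta(queries, qpath)
        _write_fasta([subject], spath)
        cmd = [
            exe,
            "-task", "blastn",
            "-query", qpath,
            "-subject", spath,
            "-word_size", str(params.word_size),
            "-reward", str(params.reward),
            "-penalty", str(params.penalty),
            "-gapopen", str(params.gap_open),
            "-gapextend", str(params.gap_extend),
            "-evalue", str(params.evalue_cutoff),
            "-dust", "yes" if params.dust else "no",
            "-outfmt", _OUTFMT,
        ]
        res = subprocess.run(cmd, capture_output=True, text=True)
        if res.returncode != 0:
            raise RuntimeError(f"blastn failed: {res.stderr.strip()}")
        hsps: List[Hsp] = []
        for line in res.stdout.splitlines():
            f = line.rstrip("\n").split("\t")
            if len(f) < 13:
                continue
            qs, qe, ss, se = int(f[2]), int(f[3]), int(f[4]), int(f[5])
            strand = "+" if ss <= se else "-"
            hsps.append(
                Hsp(
                    query_id=f[0],
                    subject_id=f[1],
                    query_interval=(min(qs, qe), max(qs, qe)),
                    subject_interval=(min(ss, se), max(ss, se)),
                    strand=strand,
                    score=float(f[10]),
                    identity=int(f[6]) / int(f[7]),
                    length=int(f[7]),
                    e_value=float(f[9]),
                    qseq=f[11],
                    sseq=f[12],
                )
            )
        return hsps


def local_align(
    query: GenomeRecord, subject: GenomeRecord, params: AlignParams = AlignParams()
) -> List[Hsp]:
    """Local alignment (seed-and-extend under the affine +2/-3 scheme, via
    BLASTn) of one query against one subject; HSPs above the E-value cutoff
    are discarded by the engine."""
    if not query.sequence or not subject.sequence:
        raise ValueError("local_align requires non-empty sequences")
    return _run_blastn([query], subject, params)


def local_align_many(
    queries: GenomeSet, subject: GenomeRecord, params: AlignParams = AlignParams()
) -> List[Hsp]:
    """One blastn invocation for many query records against one subject."""
    return _run_blastn(list(queries), subject, params)


# ---------------------------------------------------------------------------
# MTPT assembly from HSPs

def identity_bin(identity: float) -> str:
    pct = identity * 100.0
    if pct >= 90.0:
        return "90-100"
    if pct >= 80.0:
        return "80-90"
    if pct >= 70.0:
        return "70-80"
    return "<70"


def _merge_clusters(
    hsps: List[Hsp], merge_gap: int
) -> List[List[Hsp]]:
    """Group HSPs of one mito record into clusters whose mito intervals
    overlap or abut within ``merge_gap`` bp (strand-agnostic: hits of one
    mito locus to the two IR copies land on opposite strands)."""
    clusters: List[List[Hsp]] = []
    for h in sorted(hsps, key=lambda h: h.query_interval):
        if clusters and h.query_interval[0] <= max(
            x.query_interval[1] for x in clusters[-1]
        ) + 1 + merge_gap:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    return clusters


def find_mtpts(
    mito: GenomeSet,
    plastome: GenomeRecord,
    params: AlignParams = AlignParams(),
    plastid_features: Optional[Sequence[GeneFeature]] = None,
    merge_gap: int = 10,
) -> List[MTPT]:
    """MTPTs between a multi-chromosome mitogenome and its plastome.

    HSPs are merged per mitochondrial locus; each MTPT's length counts every
    mito base once; numbering follows mitochondrial coordinate order.  When
    ``plastid_features`` is given, transferred gene content is annotated.
    """
    hsps = local_align_many(mito, plastome, params)
    by_record: Dict[str, List[Hsp]] = {}
    for h in hsps:
        by_record.setdefault(h.query_id, []).append(h)

    mtpts: List[MTPT] = []
    for rec in mito:  # preserve input record order
        for cluster in _merge_clusters(by_record.get(rec.id, []), merge_gap):
            rep = max(cluster, key=lambda h: (h.score, h.length))
            ivs = sorted(h.query_interval for h in cluster)
            merged: List[Tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1] + 1 + merge_gap:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            length = interval_union_length(h.query_interval for h in cluster)
            mtpts.append(
                MTPT(
                    id="",
                    record_id=rec.id,
                    mito_intervals=merged,
                    plastome_interval=rep.subject_interval,
                    strand=rep.strand,
                    length=length,
                    identity=rep.identity,
                    identity_bin=identity_bin(rep.identity),
                )
            )
    for i, m in enumerate(mtpts, 1):
        m.id = f"MTPT{i}"
    if plastid_features is not None:
        annotate_mtpt_genes(mtpts, plastid_features)
    return mtpts


def annotate_mtpt_genes(
    mtpts: Sequence[MTPT], plastid_features: Sequence[GeneFeature]
) -> Sequence[MTPT]:
    """List every plastid gene overlapping each MTPT's plastome interval;
    a gene is 'complete' when >= 95% of its exonic length is covered."""
    for m in mtpts:
        s, e = m.plastome_interval
        content: List[Tuple[str, str]] = []
        for feat in plastid_features:
            covered = 0
            for xs, xe in feat.exons_genomic:
                lo, hi = max(xs, s), min(xe, e)
                if lo <= hi:
                    covered += hi - lo + 1
            if covered == 0:
                continue
            status = "complete" if covered >= 0.95 * feat.length else "partial"
            content.append((feat.gene_name, status))
        m.genes = content
    return mtpts


def find_inverted_repeat(
    plastome: GenomeRecord, min_len: int = 1000, min_identity: float = 0.99
) -> Optional[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """The two arms of the plastome inverted repeat: the largest
    reverse-complement self-match of at least ``min_len``; None when the
    plastome has no IR that large."""
    hits = local_align(plastome, plastome, AlignParams())
    best = None
    for h in hits:
        if h.strand != "-" or h.length < min_len or h.identity < min_identity:
            continue
        if h.query_interval == h.subject_interval:
            continue  # a perfect palindrome matching itself
        if best is None or h.length > best.length:
            best = h
    if best is None:
        return None
    arms = sorted([best.query_interval, best.subject_interval])
    return arms[0], arms[1]


def mtpt_summary(
    mtpts: Sequence[MTPT], mito: GenomeSet, plastome: GenomeRecord
) -> dict:
    mito_ivs: Dict[str, List[Tuple[int, int]]] = {}
    for m in mtpts:
        mito_ivs.setdefault(m.record_id, []).extend(m.mito_intervals)
    combined = sum(interval_union_length(ivs) for ivs in mito_ivs.values())
    plast_cov = interval_union_length(m.plastome_interval for m in mtpts)
    return {
        "count": len(mtpts),
        "combined_bp": combined,
        "pct_of_mitogenome": 100.0 * combined / mito.total_length,
        "pct_of_plastome": 100.0 * plast_cov / len(plastome),
        "longest": max((m.length for m in mtpts), default=0),
        "shortest": min((m.length for m in mtpts), default=0),
        "bins": {
            b: sum(1 for m in mtpts if m.identity_bin == b)
            for b in ("70-80", "80-90", "90-100")
        },
    }
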