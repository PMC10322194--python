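"""Intron-based molecular markers for species discrimination.

Mitochondrial introns are named ``geneiNNN`` where NNN is the 1-based
coding-sequence position immediately 5' of the intron insertion point
(e.g. nad2i156 lies after CDS position 156 of nad2).  Cross-species
alignments of such introns carry indel blocks; each block with clean
flanks is a candidate variable locus, a species' allele being its exact
gap/substitution pattern over the locus columns.  A set of loci
discriminates a species pair when some locus assigns them different
alleles; ``minimal_discriminating_set`` searches subsets exhaustively in
increasing size.  ``insilico_pcr`` predicts amplicons for a primer pair on
a (possibly circular) template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from ._util import revcomp
from .model import GenomeRecord


@dataclass(frozen=True)
class IntronRegion:
    name: str  # geneiNNN
    gene: str
    strand: str
    interval: Tuple[int, int]  # genomic, 1-based inclusive, start <= end
    sequence: str  # in gene orientation


@dataclass(frozen=True)
class VariableLocus:
    name: str
    start_col: int  # 1-based alignment column
    end_col: int
    size: int  # footprint in alignment columns
    alleles: Mapping[str, str]  # species -> exact pattern over the columns

    def distinct_alleles(self) -> int:
        return len(set(self.alleles.values()))


@dataclass
class DiscriminationMatrix:
    species: List[str]
    loci: List[str]
    alleles: Dict[str, Dict[str, str]]  # species -> locus -> allele id

    def separated_by(self, locus: str, a: str, b: str) -> bool:
        return self.alleles[a][locus] != self.alleles[b][locus]

    def pairs(self) -> List[Tuple[str, str]]:
        return list(combinations(sorted(self.species), 2))

    def undistinguished_pairs(self, subset: Sequence[str]) -> List[Tuple[str, str]]:
        return [
            (a, b)
            for a, b in self.pairs()
            if not any(self.separated_by(l, a, b) for l in subset)
        ]


@dataclass
class DiscriminationResult:
    loci: Optional[List[str]]  # smallest discriminating subset, or None
    unresolved_pairs: List[Tuple[str, str]]  # pairs the full set cannot split


@dataclass(frozen=True)
class Amplicon:
    start: int  # 1-based position of the forward primer's 5' end
    end: int  # 1-based position of the reverse primer's 5' end (plus strand end)
    length: int
    sequence: str


# ---------------------------------------------------------------------------
# intron extraction

def extract_introns(record: GenomeRecord) -> List[IntronRegion]:
    """One region per inter-exon gap of every multi-exon gene, named by the
    cumulative spliced-CDS offset of the upstream exon boundary."""
    out: List[IntronRegion] = []
    for feat in record.features:
        if len(feat.exons) < 2:
            continue
        cumulative = 0
        for i in range(len(feat.exons) - 1):
            ex = feat.exons[i]  # gene orientation
            nx = feat.exons[i + 1]
            cumulative += ex[1] - ex[0] + 1
            if feat.strand == "+":
                interval = (ex[1] + 1, nx[0] - 1)
            else:
                interval = (nx[1] + 1, ex[0] - 1)
            seq = record.subseq(*interval)
            if feat.strand == "-":
                seq = revcomp(seq)
            out.append(
                IntronRegion(
                    name=f"{feat.gene_name}i{cumulative}",
                    gene=feat.gene_name,
                    strand=feat.strand,
                    interval=interval,
                    sequence=seq,
                )
            )
    return out


def intron_containing_genes(record: GenomeRecord) -> List[str]:
    return sorted({f.gene_name for f in record.features if len(f.exons) >= 2})


# ---------------------------------------------------------------------------
# variable loci

def find_variable_loci(
    alignment: Mapping[str, str],
    min_size: int = 5,
    flank: int = 20,
    name_prefix: str = "locus",
) -> List[VariableLocus]:
    """Maximal runs of non-conserved alignment columns whose ``flank``
    columns on both sides are gap-free in every species.  A locus' size is
    its footprint in columns; loci smaller than ``min_size`` are dropped."""
    if len(alignment) < 2:
        raise ValueError("need at least two aligned sequences")
    seqs = {k: v.upper() for k, v in alignment.items()}
    lengths = {len(v) for v in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    n = lengths.pop()
    species = sorted(seqs)
    variable = [len({seqs[sp][c] for sp in species}) > 1 for c in range(n)]
    gap_free = [all(seqs[sp][c] != "-" for sp in species) for c in range(n)]

    loci: List[VariableLocus] = []
    c = 0
    idx = 0
    while c < n:
        if not variable[c]:
            c += 1
            continue
        start = c
        while c < n and variable[c]:
            c += 1
        end = c - 1  # inclusive
        size = end - start + 1
        left_ok = start >= flank and all(gap_free[start - flank : start])
        right_ok = end + flank < n and all(gap_free[end + 1 : end + 1 + flank])
        if size >= min_size and left_ok and right_ok:
            idx += 1
            loci.append(
                VariableLocus(
                    name=f"{name_prefix}{idx}",
                    start_col=start + 1,
                    end_col=end + 1,
                    size=size,
                    alleles={sp: seqs[sp][start : end + 1] for sp in species},
                )
            )
    return loci


def build_matrix(loci: Sequence[VariableLocus]) -> DiscriminationMatrix:
    """Species x loci allele table; allele identity is the exact pattern
    string, so differing substitutions count as different alleles."""
    if not loci:
        raise ValueError("no loci supplied")
    species = sorted(loci[0].alleles)
    alleles = {
        sp: {l.name: l.alleles[sp] for l in loci} for sp in species
    }
    return DiscriminationMatrix(species, [l.name for l in loci], alleles)


def minimal_discriminating_set(matrix: DiscriminationMatrix) -> DiscriminationResult:
    """Exhaustive search over locus subsets in increasing size; ties are
    broken lexicographically.  If even the full set leaves species pairs
    unsplit, those pairs are reported and ``loci`` is None."""
    names = sorted(matrix.loci)
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            if not matrix.undistinguished_pairs(subset):
                return DiscriminationResult(list(subset), [])
    return DiscriminationResult(None, matrix.undistinguished_pairs(names))


# ---------------------------------------------------------------------------
# in-silico PCR

def _binding_sites(
    template: str, probe: str, max_mismatch: int, anchor: str
) -> List[int]:
    """0-based start positions where ``probe`` matches with <= max_mismatch
    and the anchored base ('last' = probe 3' end, 'first' = position 0 of
    the probe, which is the 3' end of a reverse-complemented primer) is an
    exact match."""
    L = len(probe)
    out = []
    for p in range(len(template) - L + 1):
        window = template[p : p + L]
        if anchor == "last" and window[-1] != probe[-1]:
            continue
        if anchor == "first" and window[0] != probe[0]:
            continue
        mm = sum(a != b for a, b in zip(window, probe))
        if mm <= max_mismatch:
            out.append(p)
    return out


def insilico_pcr(
    template: GenomeRecord,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
    max_product: int = 5000,
) -> List[Amplicon]:
    """Predicted PCR products: every (forward site, reverse-complement
    site) combination with at most ``max_mismatch`` mismatches per primer,
    an exact 3'-terminal base, non-overlapping primer sites, and a product
    no longer than ``max_product``.  Circular templates are searched across
    the origin; zero amplicons is a valid result."""
    fwd, rev = fwd.upper(), rev.upper()
    for name, primer in (("forward", fwd), ("reverse", rev)):
        if not 15 <= len(primer) <= 35:
            raise ValueError(f"{name} primer must be 15-35 nt, got {len(primer)}")
    n = len(template.sequence)
    circular = template.topology == "circular"
    search = template.sequence + (template.sequence if circular else "")
    rc_rev = revcomp(rev)
    f_sites = [p for p in _binding_sites(search, fwd, max_mismatch, "last") if p < n]
    r_sites = [p for p in _binding_sites(search, rc_rev, max_mismatch, "first")]
    out: List[Amplicon] = []
    seen: Set[Tuple[int, int]] = set()
    for p in f_sites:
        for q in r_sites:
            if q < p + len(fwd):
                continue  # primer sites must not overlap
            length = q + len(rc_rev) - p
            if length > max_product or length > n:
                continue
            key = (p % n, q % n)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                Amplicon(
                    start=p + 1,
                    end=(q + len(rc_rev) - 1) % n + 1,
                    length=length,
                    sequence=search[p : p + length],
                )
            )
    out.sort(key=lambda a: (a.start, a.length))
    return out
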