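"""Shared genome data model.

A :class:`GenomeRecord` is one named DNA sequence with a topology flag
(plant mitogenomes are frequently multi-chromosomal, each chromosome a
circle) and an optional list of gene features.  A :class:`GenomeSet` is an
ordered collection of records with unique ids, e.g. the 19 circular
chromosomes of a mitogenome.

Coordinates at every interface are 1-based inclusive (GenBank convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Tuple

from ._util import DNA_ALPHABET, revcomp


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass
class GeneFeature:
    """A gene on a record.

    ``exons`` are 1-based inclusive ``(start, end)`` genomic intervals,
    ordered 5'->3' in *gene* orientation; for a minus-strand gene the first
    exon therefore has the largest genomic coordinates.  Introns are the
    genomic gaps between consecutive exons.
    """

    gene_name: str
    kind: str  # "PCG" | "tRNA" | "rRNA"
    strand: str  # "+" | "-"
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("PCG", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon interval {s}..{e} reversed")

    @property
    def exons_genomic(self) -> List[Tuple[int, int]]:
        """Exons sorted by genomic coordinate regardless of strand."""
        return sorted(self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        g = self.exons_genomic
        return g[0][0], g[-1][1]

    @property
    def length(self) -> int:
        """Sum of exon lengths (spliced length)."""
        return sum(e - s + 1 for s, e in self.exons)

    def introns_genomic(self) -> List[Tuple[int, int]]:
        """Genomic gaps between consecutive exons, sorted by coordinate."""
        g = self.exons_genomic
        return [(g[i][1] + 1, g[i + 1][0] - 1) for i in range(len(g) - 1)]


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    topology: str = "linear"  # "circular" | "linear"
    features: List[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-IUPAC characters: "
                f"{''.join(sorted(bad))}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        """(G+C) / (A+C+G+T); N is excluded from numerator and denominator."""
        s = self.sequence
        gc = s.count("G") + s.count("C")
        acgt = gc + s.count("A") + s.count("T")
        return gc / acgt if acgt else 0.0

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice; on circular records the interval may wrap
        past the origin (start > end)."""
        n = len(self.sequence)
        if start < 1 or end > n and self.topology != "circular":
            raise IndexError(f"interval {start}..{end} outside record of length {n}")
        if start <= end:
            return self.sequence[start - 1 : end]
        if self.topology != "circular":
            raise IndexError("wrapping interval on a linear record")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Spliced gene sequence, in gene orientation."""
        parts = [self.subseq(s, e) for s, e in feat.exons_genomic]
        seq = "".join(parts)
        return revcomp(seq) if feat.strand == "-" else seq


@dataclass
class GenomeSet:
    records: List[GenomeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in GenomeSet: {dup}")

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> GenomeRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def gc_content(self) -> float:
        gc = acgt = 0
        for r in self.records:
            s = r.sequence
            g = s.count("G") + s.count("C")
            gc += g
            acgt += g + s.count("A") + s.count("T")
        return gc / acgt if acgt else 0.0

    def ids(self) -> List[str]:
        return [r.id for r in self.records]
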