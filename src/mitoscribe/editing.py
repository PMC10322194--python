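"""C-to-U RNA editing effects on mitochondrial coding sequences.

Plant mitochondrial transcripts undergo site-specific cytidine deamination
(C -> U).  Given per-gene edit-site tables (e.g. from a neural predictor,
with a posterior probability per site), this module applies the edits to
the coding sequence and characterizes each site's downstream effect: codon
position, synonymy under the standard genetic code, the amino-acid
transition, and creation of start (ACG -> AUG at codon 1) or stop codons.

Sequences are handled in DNA alphabet; an edited C is written as T (the
cDNA equivalent of U).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


class EditError(ValueError):
    pass


@dataclass(frozen=True)
class EditSite:
    gene: str
    cds_position: int  # 1-based index into the spliced coding sequence
    probability: float


@dataclass(frozen=True)
class EditEffect:
    site: EditSite
    codon_index: int  # 1-based
    codon_position: int  # 1 | 2 | 3
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    synonymous: bool
    creates_start: bool
    creates_stop: bool
    co_edited: bool


def read_edit_sites(path: str, min_probability: float = 0.9) -> List[EditSite]:
    """Read a TSV (gene, cds_position, probability); sites below the
    probability threshold are excluded at ingestion."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "cds_position", "probability"}
    if not required.issubset(df.columns):
        raise EditError(f"{path}: expected columns {sorted(required)}")
    out = [
        EditSite(str(r.gene), int(r.cds_position), float(r.probability))
        for r in df.itertuples()
        if float(r.probability) >= min_probability
    ]
    return out


def _validate(cds: str, sites: Sequence[EditSite]) -> None:
    if len(cds) % 3 != 0:
        raise EditError(f"CDS length {len(cds)} is not divisible by 3")
    seen = set()
    for s in sites:
        if not 1 <= s.cds_position <= len(cds):
            raise EditError(
                f"{s.gene}: position {s.cds_position} outside CDS of length {len(cds)}"
            )
        if s.cds_position in seen:
            raise EditError(f"{s.gene}: duplicate edit position {s.cds_position}")
        seen.add(s.cds_position)
        if cds[s.cds_position - 1] != "C":
            raise EditError(
                f"{s.gene}: base at position {s.cds_position} is "
                f"{cds[s.cds_position - 1]!r}, expected C"
            )


def apply_edits(cds: str, sites: Sequence[EditSite]) -> str:
    """The CDS with C -> T at each site and nothing else."""
    cds = cds.upper()
    _validate(cds, sites)
    chars = list(cds)
    for s in sites:
        chars[s.cds_position - 1] = "T"
    return "".join(chars)


def classify_edits(cds: str, sites: Sequence[EditSite]) -> List[EditEffect]:
    """Per-site effect against the original codon; when several accepted
    sites share a codon the effect is evaluated on the jointly edited codon
    and all of them are flagged co-edited."""
    cds = cds.upper()
    _validate(cds, sites)
    by_codon: Dict[int, List[EditSite]] = defaultdict(list)
    for s in sites:
        by_codon[(s.cds_position - 1) // 3].append(s)
    effects: List[EditEffect] = []
    for s in sorted(sites, key=lambda s: s.cds_position):
        ci = (s.cds_position - 1) // 3
        before = cds[ci * 3 : ci * 3 + 3]
        mates = by_codon[ci]
        after = list(before)
        for m in mates:
            after[(m.cds_position - 1) % 3] = "T"
        after = "".join(after)
        aa_b = _translate_codon(before)
        aa_a = _translate_codon(after)
        effects.append(
            EditEffect(
                site=s,
                codon_index=ci + 1,
                codon_position=(s.cds_position - 1) % 3 + 1,
                codon_before=before,
                codon_after=after,
                aa_before=aa_b,
                aa_after=aa_a,
                synonymous=aa_b == aa_a,
                creates_start=(ci == 0 and before == "ACG" and after == "ATG"),
                creates_stop=(aa_a == "*" and aa_b != "*"),
                co_edited=len(mates) > 1,
            )
        )
    return effects


def summarize_editing(effects_by_gene: Mapping[str, Sequence[EditEffect]]) -> dict:
    """Per-gene site counts, codon-position distribution, non-synonymous
    fraction, and the ranked amino-acid transition tally.  The top-3 share
    is reported relative to the non-synonymous events (the standard way
    these transitions are tabulated)."""
    per_gene = {g: len(effs) for g, effs in effects_by_gene.items()}
    all_effects = [e for effs in effects_by_gene.values() for e in effs]
    total = len(all_effects)
    nonsyn = [e for e in all_effects if not e.synonymous]
    positions = Counter(e.codon_position for e in all_effects)
    transitions = Counter((e.aa_before, e.aa_after) for e in nonsyn)
    ranked = transitions.most_common()
    top3 = sum(c for _, c in ranked[:3])
    return {
        "per_gene": per_gene,
        "total_sites": total,
        "nonsynonymous": len(nonsyn),
        "nonsynonymous_fraction": len(nonsyn) / total if total else 0.0,
        "codon_position_counts": {p: positions.get(p, 0) for p in (1, 2, 3)},
        "transitions": ranked,
        "top3_share_of_nonsynonymous": top3 / len(nonsyn) if nonsyn else 0.0,
        "starts_created": sorted(
            {g for g, effs in effects_by_gene.items() if any(e.creates_start for e in effs)}
        ),
        "stops_created": sorted(
            {g for g, effs in effects_by_gene.items() if any(e.creates_stop for e in effs)}
        ),
    }
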