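"""Characterize C-to-U RNA-editing effects on the simulated coding
sequences.

Ingests the edit-site table at the 0.9 probability threshold, classifies
every site (codon position, synonymy, amino-acid transition, start/stop
creation) and summarizes.  Writes results/editing/.
"""

import json
import os

import pandas as pd

from mitoscribe import editing as ed
from mitoscribe import io as mio

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
OUT = os.path.join(BASE, "editing")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cds_set = mio.read_fasta(os.path.join(BASE, "simulated", "cds.fasta"))
    sites = ed.read_edit_sites(
        os.path.join(BASE, "simulated", "edit_sites.tsv"), min_probability=0.9
    )
    by_gene = {}
    for s in sites:
        by_gene.setdefault(s.gene, []).append(s)

    effects, rows = {}, []
    for gene in sorted(by_gene):
        effects[gene] = ed.classify_edits(cds_set[gene].sequence, by_gene[gene])
        for e in effects[gene]:
            rows.append(
                {"gene": gene, "cds_position": e.site.cds_position,
                 "codon_position": e.codon_position,
                 "codon_before": e.codon_before, "codon_after": e.codon_after,
                 "aa_before": e.aa_before, "aa_after": e.aa_after,
                 "synonymous": e.synonymous,
                 "creates_start": e.creates_start, "creates_stop": e.creates_stop}
            )
    pd.DataFrame(rows).to_csv(
        os.path.join(OUT, "edit_effects.tsv"), sep="\t", index=False
    )

    s = ed.summarize_editing(effects)
    out = dict(s)
    out["transitions"] = [
        {"from": a, "to": b, "count": c} for (a, b), c in s["transitions"]
    ]
    with open(os.path.join(OUT, "edit_summary.json"), "w") as fh:
        json.dump(out, fh, indent=2)

    top = ", ".join(f"{a}->{b} x{c}" for (a, b), c in s["transitions"][:3])
    print(
        f"{s['total_sites']} edit sites; {s['nonsynonymous']} "
        f"({100 * s['nonsynonymous_fraction']:.1f}%) non-synonymous"
    )
    print(
        f"top transitions: {top} "
        f"({100 * s['top3_share_of_nonsynonymous']:.2f}% of non-synonymous events)"
    )
    print(
        f"start codons created by editing: {', '.join(s['starts_created'])}; "
        f"stop codons created: {', '.join(s['stops_created'])}"
    )


if __name__ == "__main__":
    main()
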