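# mitoscribe

Plant mitochondrial genomes are frequently **multi-chromosomal**: instead of
one master circle, the mitogenome assembles into a set of smaller circular
chromosomes whose shared repeats tangle the assembly graph. `mitoscribe` is a
Python toolkit for the downstream computational analyses such a genome calls
for:

* **Assembly-graph untangling** — resolve a GFA graph into circular
  chromosomes using node depth (copy number) and long-read path evidence,
  then audit completeness against the 24 core mitochondrial protein-coding
  genes (*atp1–9, cob, nad1–nad9, cox1–3, mttB, matR, ccmB/C/FC/FN*).
* **Repeat cataloguing** — microsatellites (SSRs) with per-motif-length
  minimum counts (10, 5, 4, 3, 3, 3 for mono- through hexanucleotides) and
  maximal dispersed repeats ≥ 30 bp within Hamming distance 3 in four
  relations (forward, reverse, complement, palindromic), filtered by a
  binomial E-value `E = N² Σ_{j≤m} C(L,j) 3^j 4^{-L} < 10⁻⁵`.
* **MTPT detection** — mitochondrial plastid DNA transfers, by BLASTn
  (+2/−3, gap 5/2, word size 9, E < 10⁻⁵) between mitogenome and plastome,
  with hits merged per mitochondrial locus so segments homologous to both
  plastome inverted-repeat (IR) copies count once, identity-binned
  70–80 / 80–90 / 90–100 %, and transferred gene content annotated.
* **C→U RNA-editing effects** — apply per-gene edit-site tables
  (probability ≥ 0.9) to coding sequences and classify every site: codon
  position, synonymy, amino-acid transition, and creation of start
  (ACG→AUG) or stop codons.
* **Intron indel markers** — extract introns (named *gene*iNNN by the CDS
  position 5′ of the insertion point, e.g. *nad2i156*), find indel variable
  loci in cross-species alignments, search the minimal species-discriminating
  locus set exhaustively, and predict PCR products in silico.
* **Synthetic data** — seeded generators that emulate the whole analysis
  setting (19 circular chromosomes, quadripartite plastome with IR, planted
  repeats/transfers/indels/edit sites) together with exact truth ledgers, so
  every stage is testable without downloads.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on the default
synthetic study (seed 1):

```bash
python analysis/01_simulate_study.py
python analysis/02_resolve_graph.py
python analysis/03_repeat_survey.py
python analysis/04_mtpt_scan.py
python analysis/05_editing_effects.py
python analysis/06_marker_discovery.py
```

which prints, among other lines:

```
mitogenome: 19 circular chromosomes, 61,310 bp, GC 45.57%
resolved 19 chromosomes (19 circular)
sequence-exact recovery of all planted chromosomes: True
8 SSRs (by motif length 1-6: [2, 2, 1, 1, 1, 1])
7 dispersed pairs by class {'forward': 3, 'reverse': 1, 'complement': 1, 'palindromic': 2}; ...
8 MTPTs, combined 2,696 bp (4.40% of the mitogenome, 13.47% of the plastome)
676 edit sites; 651 (96.3%) non-synonymous
top transitions: S->L x146, P->L x145, S->F x107 (61.14% of non-synonymous events)
start codons created by editing: nad1, nad4L; stop codons created: atp6, ccmFC
all 5 species discriminated; minimal locus set (4 of 4): ['nad2i156_v1', 'nad2i156_v2', 'nad4i976_v1', 'nad4i976_v2']
in-silico PCR nad2i156: {'A_albus': 348, 'A_konjac': 334, 'A_krausei': 340, ...}
```

Reading the output: the tangled 49-node graph resolves into the 19 planted
circles exactly (rotation- and strand-invariant comparison); every planted
repeat, plastid transfer (with its identity bin, the IR-duplicated one
counted once) and indel locus is recovered; the editing summary reproduces
the planted composition — 96.3 % of sites non-synonymous, the three dominant
transitions Ser→Leu, Pro→Leu and Ser→Phe together 61.14 % of non-synonymous
events; and the four intron loci (14/8/12/15 bp) are all required to tell
the five konjac species apart, visible as distinct in-silico product sizes.

The same stages are exposed as a CLI (`mitoscribe resolve|repeats|mtpt|
editing|markers|simulate`) for user-supplied FASTA/GFA/GenBank/TSV files.

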