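# ncxtools

A toolkit for mining Na+/Ca2+ exchanger (NCX / NCKX / CCX) gene families:

- **motif & PSWM search** — degenerate alpha-repeat patterns (e.g.
  `G(S/G)SAPE`, `GNG(A/S)PD`, `(G/S)(N/D)SxGD`) and log-odds
  position-specific weight matrices for divergent exchanger detection,
  including a paired alpha1→alpha2 search with a loop-spacing constraint;
- **subtype classification** — a fixed-precedence decision list over
  domain-annotation roles (potassium-dependent exchanger signature,
  exchanger domain, CalX-beta domain) and motif-pair evidence, assigning
  NCX, NCKX, CCX or UNCLASSIFIED with a recorded rationale;
- **ortholog mining** — Smith–Waterman / Needleman–Wunsch affine-gap
  alignment (BLOSUM62 defaults) and strict reciprocal-best-hit pairing;
- **codon alignments** — PAL2NAL-style back-translation of protein
  alignments onto coding sequences, with gap-column stripping;
- **molecular evolution** — pairwise and sliding-window nucleotide
  diversity (default 100 bp windows, 25 bp steps) with box-plot
  summaries, and Nei–Gojobori (1986) counting dN/dS with Jukes–Cantor
  correction, pooled over all row pairs for a global estimate;
- **in-silico PCR & gene-model bridging** — exact-match primer-site
  search, amplicon prediction, and tests of whether a mapped cDNA bridges
  two adjacent (split) gene predictions, with a merged-model proposal;
- **simulation** — seeded generators for exchanger-like proteins with
  planted motifs and for ortholog nucleotide pairs under a Jukes–Cantor
  kernel (with codon-aware and synonymous-only modes).

## Command line

`ncxtools` exposes one subcommand per stage:

```sh
ncxtools scan proteins.fa --pattern 'G(S/G)SAPE'
ncxtools pswm-build instances.fa --label ncx_a1 --out ncx_a1.pswm
ncxtools pswm-scan ncx_a1.pswm proteins.fa --min-relative-score 0.8
ncxtools classify proteins.fa --domains interproscan.tsv
ncxtools rbh species_a.fa species_b.fa
ncxtools pal2nal proteins.aln.fa cds.fa --out codon.aln.fa
ncxtools pi codon.aln.fa --window 100 --step 25 --gene ncx-1
ncxtools dnds proteins.aln.fa cds.fa
ncxtools pcr template.fa --forward TACGTGAGCC... --reverse TCGATACG...
ncxtools bridge models.tsv cdna_exons.tsv --model-a ga --model-b gb --cdna cd1
ncxtools simulate --what proteins --n-per-subtype 100 --seed 1
```

All tabular output is TSV with a commented header recording the tool
version and command line; logs go to stderr.

## Scope notes

Upstream multiple sequence alignment (MUSCLE/MAFFT), phylogenetic model
selection and tree inference, REL/MEME site- and branch-level likelihood
tests, and protein structure prediction are deliberately out of scope;
aligned input is consumed as-is, and the global dN/dS here is a pooled
pairwise counting estimate rather than a tree-based ancestor-counting
one.
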