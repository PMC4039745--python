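# immad

Discovery of **I**ntronic **M**otifs linked to **M**ultiple **A**lternative
splicing **D**ecisions in nematode gene models.

## The problem

Many genes produce several mRNA isoforms through alternative splicing. When a
single pre-mRNA is subject to *several independent* splicing decisions, the
cell faces a coordination problem: which combinations of alternate exons end
up in the same transcript. If coordination relies on intronic *cis*-regulatory
elements, those elements should be over-represented in the introns flanking
alternate exons of genes with **M**ultiple **A**lternative **S**plicing
decision **S**ites (MASS genes) relative to genes with a **S**ingle such site
(SASS genes).

`immad` implements that comparison as a reusable, fully tested pipeline over
standard inputs (GFF3 gene models + genome FASTA), aimed at *C. elegans*-style
annotations but agnostic to the organism:

1. **Classification.** An *alternative intron* is an intron (exact coordinate
   pair) present in some but not all isoforms. Alternative introns that merely
   reflect alternative transcription starts are removed. The remainder are
   clustered into *decision sites* — connected components under ≥1-base
   interval overlap, since overlapping alternative introns are the signature
   of one cassette-exon, mutually-exclusive-exon, A5SS or A3SS decision. Genes
   with one site are SASS, with ≥2 disjoint sites MASS.
2. **Screen.** All 4^k oligomers (k = 5, 6, 7) are counted in overlapping
   windows of the introns flanking alternate exons of each group. Per
   oligomer, a two-sided Fisher exact test on window counts compares the two
   groups; p-values are Bonferroni-corrected by the universe size 4^k
   (1024 / 4096 / 16384). The primary threshold is corrected p < 1E-5.
3. **Length-bias control.** MASS genes tend to be longer. Genes are re-sampled
   per 1-kb length bin so both groups share the bin distribution, and the
   screen is repeated at corrected p < 1E-2; unconfirmed oligomers are
   dropped.
4. **Motif groups.** Surviving oligomers are clustered (substring, or equal
   length with ≤1 mismatch) and summarized by a degenerate IUPAC consensus
   (e.g. `RAGAAG`, `ACYCCA`).
5. **Characterization.** Gene-frequency tests (fraction of genes with ≥1
   copy, robust to tandem repeats); inter-site distance distributions versus
   a simulated null that places two introns uniformly at random in
   length-matched transcripts; homologous and heterologous inter-motif
   distance histograms whose peaks expose minisatellites, transposon repeats
   and composite octamers; and a gene-level co-occurrence screen over all
   heterologous motif pairs (2×2 odds ratios, Fisher tests, Bonferroni), with
   a per-intron over-expectation filter so large introns do not dominate.

A seeded synthetic-data generator (`immad.synthetic_data`) builds multi-isoform
gene models with configurable event mixes, intron-length laws, GC content,
planted motifs at chosen fold-enrichments, and exact tandem-repeat arrays, so
every stage of the pipeline is testable without downloading annotation
releases.

## Worked example

Run the whole pipeline on a simulated genome of 80 genes in which the hexamer
`GATGAC` was planted into the flanking introns of MASS genes at 3× the SASS
rate:

```python
from immad.pipeline import run_full_pipeline

config = {
    "simulate": {
        "n_genes": 80,
        "seed": 11,
        "planted": [
            {"consensus": "GATGAC", "target_group": "MASS", "fold": 3.0, "rate": 0.003}
        ],
    },
    "params": {"ks": [6], "seed": 11},
}
report = run_full_pipeline(config, "out")
```

This prints nothing, but the returned report (also written to
`out/report.json`, alongside TSVs of every intermediate) contains:

```text
MASS genes: 26, SASS genes: 54
flanking introns: 179 (MASS) vs 148 (SASS)
significant oligomers (corrected p < 1e-5): ['GATGAC', 'TGATGA']
confirmed after length-matched subsampling: ['GATGAC']
motif groups: ['GATGAC']
gene-level frequency: 26/26 MASS vs 37/54 SASS (corrected p = 8.00e-04)
inter-site distances: median 116 vs null 199 (Mann-Whitney p = 7.96e-04)
```

Reading this: the screen recovers the planted hexamer (plus a one-base-shifted
shadow, `TGATGA`, which the subsampling confirmation correctly discards);
every MASS gene carries at least one copy versus 69% of SASS genes; and
consecutive decision sites sit closer together than random placement of two
introns in length-matched transcripts would predict — the same qualitative
signature the method is designed to detect in real annotations.

The same run is available from the shell:

```bash
immad simulate --config sim.yaml --out-prefix sim
immad classify --gff3 sim.gff3 --fasta sim.fa --out-prefix cls
immad run-all --config cfg.yaml --out-dir out
```

## Layout

- `immad.annotation_io` — GFF3/FASTA I/O, interval algebra, intron derivation
- `immad.splice_classifier` — alternative introns, decision sites, MASS/SASS
- `immad.kmer_enrichment` — k-mer counting, Fisher screens, pooled and
  gene-level comparisons, list-overlap enrichment
- `immad.motif_tools` — IUPAC clustering, matching, scrambled controls,
  reverse-complement overlap
- `immad.length_matching` — stratified subsampling, Mann-Whitney rank tests
- `immad.distance_analysis` — inter-site and inter-motif distances, simulated
  null, peak detection
- `immad.cooccurrence` — heterologous pair co-occurrence screen
- `immad.synthetic_data` — seeded gene-model and genome generator
- `immad.pipeline` / `immad.cli` — orchestration and the `immad` command

See `docs/methods.md` for the underlying model, parameter choices and known
limitations.
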