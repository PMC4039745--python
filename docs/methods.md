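# Methods

This note documents the statistical procedures implemented in `immad`, the
defaults they ship with, and the design choices made where several reasonable
concretizations exist. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Gene classification

**Coordinates.** All internal coordinates are 0-based half-open; GFF3 I/O uses
the standard 1-based inclusive convention. Interval algebra on half-open pairs
is unambiguous (`a` overlaps `b` iff `a.start < b.end and b.start < a.end`),
which is why the conversion happens at the parser boundary and nowhere else.

**Alternative introns.** An intron is *alternative* when its exact
(start, end) pair is absent from at least one isoform's intron chain. Identity
is coordinate-exact on purpose: a one-base shift of a splice site produces a
different intron, which is precisely what distinguishes A5SS/A3SS events.

**Transcription-start filter.** Isoforms that differ only in their first exon
generate spurious "alternative" first introns that reflect promoter choice,
not splicing. An overlap cluster of alternative introns is discarded when
(a) every member is the 5'-most intron of each isoform supporting it,
(b) all members — and the first introns of all other intron-bearing
isoforms — share one 3' splice site in transcript orientation, and
(c) the supporting isoforms start at genuinely different positions (distinct
first-exon 5' ends). Condition (c) matters: without it, an alternative-donor
event located in a gene's first intron satisfies (a) and (b) and would be
wrongly removed. The rule is deliberately conservative — it removes only
differences fully explainable by first-exon choice.

**Decision sites.** Alternative introns are clustered into connected
components under ≥1-base overlap, transitively closed. The threshold is one
base because any overlap between two alternative introns means they cannot be
excised independently from the same molecule — they compete for the same
pre-mRNA region and therefore constitute one decision. Genes with one site
are SASS, with two or more MASS; genes with no surviving alternative intron
are excluded (a signalled outcome, not an error).

**Flanking introns.** The sequence unit of all downstream screens. An intron
qualifies when it is a member of a decision site, or shares a boundary with an
exon not present with identical boundaries in all isoforms; introns discarded
by the transcription-start filter never re-enter through the adjacency rule.
The set is deduplicated by coordinates (isoforms share most introns), and all
sequences are extracted in transcript sense orientation — splicing elements
act on pre-mRNA, so minus-strand genes are reverse-complemented once at
extraction and every scanner downstream is sense-only. Whether regulatory
elements should additionally be scanned on the antisense strand is left as an
explicit non-default; nothing in the statistics changes if both strands are
pooled by the caller.

## Enrichment screen

Counting uses overlapping windows (step 1). Windows containing a non-ACGT
character are skipped and excluded from the window total, so ambiguity codes
reduce the denominator rather than silently inflating it.

Per oligomer, the 2×2 table is **windows**: `[[count_A, windows_A − count_A],
[count_B, windows_B − count_B]]`, tested with a two-sided Fisher exact test.
The window-based table makes the test frequency-based and robust to unequal
group sizes and intron lengths; the reported enrichment "ratio" is then the
per-window frequency ratio. The exact two-sided p is computed by summing the
conditional hypergeometric pmf over all tables at the observed margins whose
probability does not exceed the observed one (with a 1e-7 relative tolerance
for float ties) — identical in definition to `scipy.stats.fisher_exact`, but
vectorized over the support so the 4096-oligomer hexamer screen runs in
fractions of a second. The unit tests check this implementation against an
independent `math.comb`-based enumeration oracle.

Multiple testing uses a Bonferroni multiplier equal to the oligomer universe
size: 1024 (pentamers), 4096 (hexamers), 16384 (heptamers). Default
thresholds: corrected p < 1E-5 for the primary screen, < 1E-2 for the
confirmation screen on the length-matched subsample. Two-sided tests are used
throughout even though only enrichment (ratio > 1) is flagged; this is the
conservative choice when sidedness is not pre-registered. No compositional
background correction (e.g. Markov models) is applied — the screen is
deliberately a raw frequency comparison, and the scrambled-motif control
plus the subsampling confirmation carry the burden of excluding compositional
and structural confounders.

The gene-frequency test recomputes enrichment on gene presence/absence
(≥1 copy in any flanking intron), which is insensitive to tandem-repeat copy
number; the pooled comparison sums match counts of a whole motif list over
all windows, which is the right statistic for small ortholog subsets where
per-motif counts are sparse.

**List-overlap enrichment** (comparing a discovered motif list against a
published element list within a common universe) reports two summaries: the
observed/expected fold (expected = |query|·|reference| / universe) and the
sample odds ratio of the 2×2 membership table. They differ whenever the lists
are a non-negligible fraction of the universe, and published fold values do
not always state which definition was used — so both are emitted.

## Motif groups

Clustering joins two oligomers when one is a substring of the other, or when
they have equal length and Hamming distance ≤ 1 (the one-mismatch rule is not
applied across different lengths). The consensus aligns members on the offset
maximizing exact matches to the longest member (ties to the leftmost offset)
and writes the minimal IUPAC code per column ({C,T} → Y, {A,C,T} → H, …).
Matching counts overlapping occurrences; for mixed-length groups, members
shorter than the consensus are matched literally so every member always
matches its own group.

Scrambled controls draw one seeded random permutation of positions per motif
group and apply it to the consensus and all members. A single group-level
permutation (rather than independent per-member shuffles) preserves each
member's exact base composition *and* keeps the members consistent with the
scrambled consensus, so the control group remains matchable as a group. A
permutation colliding with any real member is redrawn up to 100 times;
composition-forced identities (homopolymers) are kept with a warning.

## Length matching

Genes are binned by total span length in 1-kb bins (the width is
configurable). For each bin, the group whose within-group proportion is
higher is down-sampled, uniformly at random, to the other group's proportion
computed on the *original* totals. Because the total fraction removed on each
side equals the total-variation distance between the two binned
distributions, both groups shrink by the same factor and the per-bin
proportions agree after subsampling up to integer rounding — a property the
test suite asserts directly. Intron-length bias is corrected implicitly:
flanking-intron length is strongly coupled to gene length, so matching gene
lengths suffices (the rank tests on both variables are available to verify
this on any dataset).

## Distance analyses

**Inter-site distance Δ** is the inner gap between consecutive decision-site
spans (downstream span start − upstream span end). Using the inner gap makes
Δ invariant to site widths; midpoint-to-midpoint distances would conflate
site size with spacing.

**Simulated null.** Per simulated transcript: draw a total length L from the
empirical gene-length distribution and two intron lengths from the empirical
flanking-intron-length distribution, place both intron spans uniformly at
random without overlap in [0, L] (rejection sampling, up to 1000 placement
attempts before redrawing L), and record the inner gap. The default pool size
is 6510 transcripts; the pool is fully seed-deterministic. The simulator's
mean is checked against an independently coded rejection-sampling oracle at
fixed L.

**Inter-motif distances** are computed within single introns only — a
distance never spans two introns. Homologous distances are differences of
consecutive start positions of one motif; heterologous distances are absolute
start differences between *consecutive occurrences of different motifs* in
the merged, position-sorted occurrence list. A distance value is reported as
a peak when it carries ≥ 5% of all intervals (the smallest fraction worth
interpreting, configurable), occurs ≥ 2 times, and is a local maximum against
its ±1-base neighbors. Tandem repeats of unit length u containing one motif
copy per unit produce a single peak at u, which is how minisatellite and
transposon-derived repeats surface without any dedicated repeat-finding
algorithm; composite octamers (two overlapping short motifs) produce peaks at
offsets of 1–3 bases.

## Co-occurrence

A gene "contains" a motif when at least one flanking intron carries more
copies than expected from the motif's pooled background density times the
intron's window count (a linear-in-length expectation). This filter prevents
very long introns — which accumulate copies of everything by chance — from
dominating gene-level counts. Each unordered heterologous pair is tested on
the gene-count 2×2 with a two-sided Fisher test, Bonferroni-corrected over
C(n_motifs, 2) pairs. The sample odds ratio ad/bc is reported; when a zero
cell makes it undefined, the Haldane–Anscombe 0.5 correction is applied and
the record flagged. A gene-exclusion re-test hook supports robustness checks
against single genes carrying private repeat arrays.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
defaults chosen to resemble worm annotations: ~32% of alternatively spliced
genes are MASS, cassette exons dominate the event mix (60% CE, 10% MXE,
15% A5SS, 15% A3SS), intron lengths are log-normal with median 65 bases
(σ = 0.7, floored at 30), exons log-normal with median 120, and intron GC is
0.32 (worm introns are AT-rich). MASS genes receive 2–3 non-overlapping
alternative regions, SASS exactly one; 2–4 isoforms per gene always include
the all-inclusion and all-exclusion variant vectors so every site is
genuinely alternative. About half the genes are placed on the minus strand to
keep orientation handling honest. Each gene occupies its own small contig
with 50-base pads — the screens operate per intron, so contig layout carries
no signal.

Motifs are planted by overwriting background bases (preserving intron length)
at Poisson rates per k-mer window: the non-target group receives the base
rate (default 0.005/window) and the target group fold × base. The base rate
is ~20× the random-background frequency of a hexamer, so the realized
between-group frequency ratio tracks the configured fold closely (the suite
asserts within 20%). Every plant is recorded in a truth table (genomic intron
coordinates, sense-relative offset, realized member) and must be recoverable
by the matcher. Tandem repeats are inserted as exact arrays into one
sufficiently long flanking intron of the target group.

What the generator does **not** emulate — and what passing tests therefore do
not certify about real data: splice-site consensus sequences (GT–AG ends),
positional composition gradients inside introns, branch points,
polypyrimidine tracts, correlated motif placement, overlapping genes, or
annotation noise (truncated isoforms, UTR mis-annotation). The generator
validates the *statistics*; biological sequence realism is out of scope.

## Problem sizes and numerical choices

The shipped test-suite simulations use a few hundred introns of ~200 bases
per group and 20-seed batteries for the error-rate and recovery properties;
the pipeline tests use 60–80 simulated genes with hexamer-only screens. These
sizes give the screens unambiguous power margins (corrected p below 1E-10 for
planted effects) while keeping the whole suite under a minute. The null pool
for inter-site distances defaults to 6510 transcripts. Fisher p-value ties
are resolved with a 1e-7 relative tolerance; Bonferroni corrections are
clipped at 1. All stochastic steps take explicit integer seeds, and the
pipeline derives per-stage seeds from the single config seed, so a config
reproduces its report byte for byte.

## Known limitations

- Classification is purely annotation-driven; isoforms missing from the
  input GFF3 (e.g. unannotated tissue-specific isoforms) silently reduce the
  decision-site count.
- The transcription-start filter cannot distinguish a true alternative
  promoter from an alternative first exon spliced from identical start
  positions if the annotation collapses their starts.
- The window-based Fisher table treats overlapping windows as independent
  trials; for highly repetitive oligomers this overstates the effective
  sample size, which is why the gene-frequency control and the repeat-aware
  distance analyses accompany every screen.
- The per-intron over-expectation filter uses a linear-in-length expected
  count; a compositional (per-base) expectation would differ for extreme GC
  outliers.
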