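# Methods

This note documents the models the package implements, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Redundancy collapse

De novo transcriptomes of polyploids carry the same locus many times:
byte-identical duplicates, truncated fragments, and near-copies whose
only difference is a misplaced read's worth of sequence at one end.
The collapse runs in two stages over a union-find so merge chains
resolve in a single pass:

* **Stage 1 (identical).** Sequences that are byte-identical, or
  identical to a full-length substring of a longer sequence, merge.
  The containment behaviour mirrors 100%-identity clustering with
  shorter-sequence coverage and can be disabled
  (`containment=False`) for a strictly exact-duplicate collapse —
  which of the two behaviours the upstream clustering tool exhibits at
  identity 1.0 depends on its coverage settings, so both are provided.
* **Stage 2 (trim containment).** For each transcript two variants are
  formed — minus the first `trim_len` nt and minus the last `trim_len`
  nt (default 150, the short-read length that motivates the rule);
  variants of ≤ `trim_len` nt are skipped. If a variant is an exact
  substring of another transcript, or that transcript an exact
  substring of the variant ("100% identity with 100% coverage of one
  of the sequences"), the two transcripts merge. Only the two
  single-end variants are formed, not a both-ends variant.

Within a block the longest sequence is retained; equal lengths break
lexicographically by id for determinism. The pipeline is a fixpoint:
idempotence is asserted by test rather than iterated. Input order
cannot affect the result because processing order is canonicalised
(descending length, then id).

## Expression statistics

**TPM.** `TPM_{t,s} = (c_{t,s}/L_t) / Σ_t (c_{t,s}/L_t) × 10⁶`, with
effective lengths in nucleotides. Columns sum to 10⁶ by construction.

**Expression filter.** A transcript is expressed in a condition when
every replicate has TPM ≥ 0.5. The boundary is inclusive ("minimum of
0.5"), and a zero-TPM replicate never counts as expressed, so a
threshold of 0 selects all-positive transcripts. The tested set for
differential expression is the union of the two condition-wise
expressed sets: the conditions' expressed repertoires differ, and
intersecting them would discard exactly the on/off transcripts a
drought contrast is after. `tpm_min=None` (CLI `--no-filter`) tests
everything with any counts.

**Differential expression.** A deliberately transparent two-group
negative-binomial Wald test, not a wrapper around an external tool:

1. *Size factors* by median-of-ratios against the per-transcript
   geometric mean, computed over transcripts positive in all samples.
2. *Dispersion* per transcript by method of moments on normalized
   counts, pooling within-condition variances (floored at 10⁻⁸), then
   pooled to the mean of its expression decile. The pooling is the
   empirical-Bayes limit: with 3 + 3 replicates a gene-wise estimate
   has four residual degrees of freedom and its spread around the
   decile trend is dominated by sampling noise, so the shrinkage
   weight on the trend goes to one. Partial-weight variants were
   evaluated and understate standard errors for genes whose estimate
   falls below the trend by chance, producing spurious extreme
   p-values under the global null; the trend estimator is calibrated
   (null BH rejections absent and raw p-values KS-uniform across
   seeds) while keeping > 90% power at |log2FC| = 2 for baseline
   means ≥ 50.
3. *Wald statistic* log2FC / SE with the delta-method standard error
   `Var(log2 μ̂) ≈ (μ + αμ²)/(n μ² ln²2)` per group; two-sided normal
   p-value; Benjamini–Hochberg across the tested set (via
   statsmodels); significance at adjusted p < 0.01 (strict).
   A half-count continuity correction applies only where a group mean
   is zero, which keeps the fold-change estimator exactly invariant
   to the arbitrary common scale of normalized counts (scaling one
   library by any factor leaves every log2FC unchanged).

Fold-change sign convention: deficit (I25%) over control (I100%), so
drought-induced transcripts are positive.

**qPCR.** Livak 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_calibrator;
inputs are technical-replicate mean Cts.

## Cluster admissibility and CDS trimming

Pairwise identity between alignment rows is matches over mutually
ungapped columns — alignment-length denominators would penalise
fragment pairs that genuinely overlap. Pairs sharing fewer than 30
mutually ungapped columns (configurable) are treated as non-overlapping:
identity over a handful of columns is noise. A cluster is NO_OVERLAP if
any query pair falls below that floor (this outranks LOW_IDENTITY),
LOW_IDENTITY below 50% identity, else ADMISSIBLE.

`trim_to_cds` removes columns outside the reference row's coding span,
taken as its longest forward-frame ATG→stop ORF; the Arabidopsis
ortholog anchors the cluster and is the default reference. Trimming is
idempotent.

## Duplication timing

Gene trees are rooted on the Arabidopsis ortholog (MRCA branch when
several outgroup tips are monophyletic; otherwise the first-listed tip,
with a warning). Bootstrap supports are carried across re-rooting by
bipartition, never by node, which is why the package keeps its own
lightweight tree structure behind the dendropy parser.

Classification on the rooted tree: maximal query-only clades are found;
a clade of ≥ 2 query tips whose sister contains a sunflower tip (and no
query tip) is a lineage-specific duplication group; a singleton query
tip whose sister contains a sunflower tip is an Asteraceae-event copy.
The decisive node is the group's parent — the guayule–sunflower node —
and a present support < 70 there (and only there) demotes the
assignment to UNRESOLVED; absent supports pass, so true trees are never
demoted. Cluster roll-up: all resolved assignments of one kind give
that kind, a mixture gives BOTH, none gives UNRESOLVED.

Open-design choices: a sister containing lettuce alongside sunflower
still licenses the Asteraceae call (the event then predates the
guayule–sunflower split a fortiori); a sister of only lettuce is
UNRESOLVED with a note, since neither topological model covers it;
polytomous decisive nodes are UNRESOLVED. Re-alignment loops for
poorly supported trees are out of scope — the package reports
UNRESOLVED instead of iterating alignments.

The classifier is verified two independent ways: an exhaustive truth
table of all 105 rooted binary topologies on {2 query, 2 sunflower,
1 outgroup} against a bipartition-rule oracle written before the
classifier (84 ASTERACEAE, 21 LINEAGE, 0 UNRESOLVED), and 100%
recovery of planted events on simulated families with true trees.

## ORF integrity and pseudogenization

`find_orfs` reports every forward-strand ATG→stop span (stop included)
of at least `min_codons` codons in the three frames; transcripts are
treated as oriented mRNA, so reverse-strand scanning is deliberately
absent. Members of a CDS-trimmed alignment are read in the reference
frame; disruptions are, earliest event first along the frame:

* a gap run whose length is not a multiple of three (frameshift),
* a fully aligned in-frame stop codon (premature stop),

counted only before 90% of the reference codon count, plus a missing
ATG within the first 10 reference codons (no start). The 90% boundary
and 10-codon window are reconstructions — "loss of ORF integrity" is
not quantified anywhere authoritative — chosen to tolerate ragged 3′
assembly ends and alternative start context; both are configurable.
Earliest-event precedence matters: a frameshift makes every downstream
reference-frame "stop" spurious, so a planted 1-nt deletion is reported
as a frameshift, not as the stops it manufactures. In-frame gap runs
are clean indels, not disruptions.

A cluster call is PARTIAL when at least one but not all members are
disrupted — the pseudogenization signature — NONE when all intact, ALL
when none survive.

## lncRNA cascade

Filters apply in fixed order, each transcript stamped with the first
stage that removed it: protein similarity (e ≤ 10⁻³), TE/housekeeping
RNA similarity (e ≤ 10⁻¹⁰), length ≥ 200 nt with longest ORF ≤ 100
codons, and overlap of the best sunflower-genome hit (e ≤ 10⁻²⁰; ties
by coverage then subject id) with an annotated gene/mRNA/CDS feature.
All e-value boundaries are inclusive; overlap is any shared base in
half-open coordinates — deliberately conservative, since a transcript
whose homologous locus is protein-coding is likely an incompletely
assembled coding gene rather than a lncRNA. The coding-capacity stage
is an ORF-length rule rather than a hexamer/codon-bias classifier;
the hit-table interface accepts externally computed scores if a
full coding-potential model is wanted. Similarity searches themselves
are consumed as tabular hits: the package does not embed a
genome-scale aligner.

Survivors are classed species_only / sunflower / sunflower_lettuce by
where homologs exist at the genome-hit threshold; a lettuce-only hit
is outside the nested phylogenetic expectation and falls back to
species_only with a warning. Best-hit loci intersecting provided
lncRNA annotations set the annotated-lncRNA flags.

## miRNA sponge analysis

The expectation score aligns the miRNA antiparallel to a same-length
site: per miRNA position (1 = 5′ end), Watson–Crick 0, G:U wobble 0.5,
mismatch 1.0, doubled for seed positions 2–13; the score is the sum,
and 0 means perfect complementarity. Scoring is on the DNA alphabet
(U→T at input; the wobble is evaluated as G·T). Scanning slides a
miRNA-length window over the transcript and reports windows at or
below the cutoff (default 5.0, a conventional stringency for plant
target prediction), ranked by expectation then position; overlapping
reported sites are flagged. Scoring is ungapped — no target bulges —
which captures the perfect, fully conserved sites the sponge analysis
is after; `score_duplex` is the single pluggable point if a
bulge-aware scorer is needed.

Site conservation maps the site interval through the focal row's gap
structure to alignment columns and takes the fraction of columns
identical across all rows (gaps count as differences); the conserved
flag defaults to complete (fraction 1.0) conservation. The sponge
report emits one row per conserved site across survivors × miRNAs and
is invariant to library order.

## Synthetic data: what it does and does not emulate

All generators are pure functions of `SimulationParams` (seed
mandatory) and return a truth bundle covering every emitted id.

* **Redundant transcriptome** — bases of 300–3000 nt; 20% exact
  duplicates, 20% fragments (either one end minus ≤ 150 nt or an
  internal substring > 150 nt, so every fragment is recoverable by
  the collapse rules).
* **Counts** — NB draws with baseline means log-uniform on [1, 10⁴],
  fixed dispersion 0.1, three biological replicates per condition, and
  library sizes varying threefold (log-uniform on [⅓, 3]) so an
  unnormalised test cannot pass silently. Planted fold changes have
  random sign and magnitude N(2, 0.5²) truncated at 0.5.
* **Gene families** — a root sequence of ATG-free 30-nt UTRs around a
  200-codon CDS evolves down
  (Arabidopsis,(Lactuca,(Helianthus,Parthenium))) at 0.03
  substitutions/site/branch, per-site uniform with rejection of
  internal stops, start/stop codon edits, and UTR ATG creation (so
  the reference's longest ORF is always the planted CDS). The
  duplication is planted either before the guayule–sunflower split
  (two sunflower + two guayule copies, each guayule copy sister to a
  sunflower copy) or on the guayule terminal branch (guayule copies
  mutual sisters). Optional pseudogenization plants one mid-CDS
  premature stop or 1-nt deletion in one guayule copy. No
  transition/transversion bias, rate heterogeneity, or indel process
  beyond the planted deletion: downstream stages test topology and
  ORF logic, not substitution-model realism.
* **lncRNA panel** — four classes with consistent hit tables and
  annotations: true lncRNAs (≥ 200 nt, longest ORF ≤ 100 codons),
  TE/rRNA decoys, protein-coding decoys, and lncRNA-like transcripts
  whose sunflower locus overlaps an annotated gene. A subset of true
  lncRNAs carries a perfect reverse-complement miR166 site at a
  recorded interval, replicated exactly in sunflower (and lettuce)
  homologs when planted conserved, or broken by one in-site
  substitution for the planted non-conserved cases. Homologs differ
  by five substitutions outside the site, so homolog alignments are
  gap-free.

Passing on these conditions demonstrates the logic is correct under
its stated model; it does not demonstrate robustness to real
mis-assembly, alignment error, annotation noise, or dispersion
heterogeneity beyond the expression trend.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to
run comfortably on a single CPU: collapse exactness on 100–500-base
transcriptomes over five seeds against an O(n²) oracle, DE calibration
on 20 × 2000-transcript null matrices, 100 + 100 simulated families,
three 200-sequence lncRNA panels, 1000 × 5-kb ORF-oracle comparisons.
Every random draw flows from a single integer seed; `run_all` twice
with the same seed produces byte-identical outputs, and all output
TSVs carry a version/seed/params-hash header so a results directory
can be reproduced from its own `params.yaml`.

## Known limitations

* The DE test is a calibrated simplification: no GLM fit, no shrunken
  fold changes, no outlier replacement, single-factor designs only.
  It will not numerically match dedicated tools.
* Collapse is exact-match only (no sub-100%-identity clustering or
  isoform-aware logic) and quadratic in transcript count; it is meant
  for the ≤ 10⁵-transcript scale, not read data.
* Duplication timing assumes the fixed four-taxon sampling; denser
  taxon sampling would need the sister-composition rules generalised,
  and no gene-tree/species-tree reconciliation is attempted.
* miRNA scoring has no bulges and no accessibility/energy term.
* The lncRNA cascade's coding-capacity stage is an ORF-length proxy,
  and decoy library choice (with its 10⁻¹⁰ threshold) is a knob, not
  a calibrated value.
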