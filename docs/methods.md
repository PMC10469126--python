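# Methods

This package implements the statistical core of a reference-genome-free
CRISPR off-target risk assessment on a de novo transcriptome: candidate
guide-binding sites are found on assembled transcript contigs, filtered by
expression evidence into "deleterious" off-targets, aggregated per gene
ontology (GO) term into the DANGER table, scored with the D-index, and
validated with a seeded permutation test. Everything upstream of the
assembled-transcriptome + expression-table boundary (read trimming, rRNA
removal, assembly, quantification, DE testing, ORF/gene identification, GO
term assignment) is consumed as plain-text tables, not recomputed.

## Site scanning

A guide is a 19–20 nt protospacer (concrete A/C/G/T) plus an IUPAC PAM
pattern (e.g. `NGG`, `NRR`). Every window of length
`len(protospacer) + len(PAM)` on both strands of every contig is a
candidate. Mismatches are counted over the protospacer only; the PAM is a
hard IUPAC filter with zero tolerance. This split follows the convention of
mismatch-bounded off-target searchers (Cas-OFFinder, Crisflash), whose
output format the site table reproduces: query sequence, contig, 0-based
forward-strand start of the window, site sequence read 5'→3' on the binding
strand with mismatched protospacer bases lowercased, strand, mismatch count.

Numerical/edge choices:

- Coordinates are 0-based half-open on the forward strand of the contig;
  minus-strand sites report the forward-strand start of the same window.
- A non-ACGT base in a contig counts as a protospacer mismatch and never
  satisfies a PAM symbol — ambiguous assembly sequence cannot *create*
  matches. Biopython's non-IUPAC `X` code is rejected in PAM patterns.
- Contigs shorter than the window are skipped; an empty transcriptome
  yields an empty site list.
- Output order is deterministic: contig order, then start, then `+` before
  `-`.
- Named search presets: `optimized` (≤8 mismatches, NGG) and `approximate`
  (≤11 mismatches, NRR).
- The scan is vectorised (uint8 base codes, sliding windows, per-symbol
  PAM lookup tables); the test suite holds it to set-equality with an
  independent pure-Python exhaustive search.

Both strands are scanned by default. Transcript contigs are single-stranded
molecules, but the DNA locus they witness is double-stranded and the guide
can bind either genomic strand, so both-strand scanning is the safer default;
it is configurable (`both_strands=False`).

Bulge/indel binding models and activity scores (CFD/MIT) are out of scope;
the mismatch count is the only binding descriptor.

## Expression screen

Two downregulation rules, each per transcript, both with *strict*
inequalities:

- **dTPM**: `ratio = mean(edited TPM) / mean(WT TPM)`; flagged when
  `ratio < t` (default `t = 0.4`). A transcript with WT mean 0 has an
  undefined ratio and is never flagged — absence in WT cannot evidence
  downregulation, and no pseudocount is introduced.
- **dDE**: consumes an external differential-expression table
  (transcript, M-value, P-value — e.g. a TMM/edgeR output); flagged when
  `M < 0` and `P < alpha` (default `alpha = 0.001`). No multiplicity
  correction is applied beyond the `alpha` cut; the rule is a screen, not
  an inference.

At least one WT and one edited sample are required (three per group is the
recommended design and the generator's default). DE-table transcripts
missing from the matrix are kept with a warning so an external DE run can
be wider than the quantified set.

## Deleterious join

A deleterious off-target site is a scanned site whose host transcript
carries the chosen flag (`dTPM`, `dDE`, or `either`). Before scoring, the
on-target gene is excluded entirely — the on-target sites themselves and
every site on any isoform of that gene — because its expression change
reflects the intended edit. By default the on-target gene(s) are those
carrying a 0-mismatch site; passing `target_gene` restricts exclusion to
the named gene, in which case perfect-match sites on *other* genes
(duplicated sequence) are retained as genuine off-targets. Exclusion is by
gene when a transcript→gene map is available, else by transcript. Sites on
transcripts without a gene assignment are carried as `unidentified` and
summarised per mismatch number, but cannot contribute to GO aggregation.

## DANGER table and D-index

For each GO term and mismatch number `m`, `N(m)` counts **distinct genes**
with at least one deleterious site at exactly `m` mismatches carrying that
term. A gene with several sites at one `m` counts once; a gene with sites
at several `m` values counts once per `m` (the per-`m` counting makes this
the only consistent reading). Annotations are used exactly as supplied —
no GO-graph propagation and no enrichment P-values; parent terms appear
only if present in the annotation table.

The per-term risk score is

    D-index = Σ_{m=0}^{m_max} N(m) · exp(4 − m)

Off-target activity decays roughly exponentially with mismatch count and
reported off-targets rarely exceed four mismatches, so the weight pivots at
`m = 4` (weight 1): genes at low `m` dominate, genes at high `m` contribute
little but are not discarded. Summation is plain double precision in
ascending `m`; counts are small enough that compensated summation would be
noise. `m = 0` is a legal input (duplicated-sequence perfect matches); the
intended on-target gene never reaches this stage.

The profile reports one record per GO term (with its `N_0..N_mmax`
counts), the total D-index, and the number of terms `N`.

## Permutation validation

Each term's observed D-index is compared with a null built by `n_null`
(default 100) seeded shuffles. One shuffle permutes the downregulation
flags across all screened transcripts and, independently, the mismatch
labels across all site rows — breaking the site–expression and
mismatch–gene associations while preserving both marginal distributions,
which is the minimal requirement for a permutation null here. The site
table being shuffled is the gene-annotated, on-target-excluded site set:
the exclusion reflects the known edit and should not be re-randomised.
After each shuffle the deleterious filter, the DANGER aggregation and the
D-index are recomputed (the production path is a vectorised engine proved
equal, in tests, to the stage-by-stage recomputation on identical
shuffles). Terms absent from a permutation contribute pseudo value 0.

The (1−L) bound is **parametric**: `mean + z(1 − L/2) · sd` with the
population (ddof=0) standard deviation over the `n_null` pseudo values. An
empirical quantile at the strict preset `L = 1E-15` is unreachable with
100 permutations, so the parametric normal reading is the only consistent
one; with the additional "above the null mean" clause the call is
effectively one-sided upper. A term is significant iff
`D > threshold` and `D > mean` (strict; with sd = 0 this reduces to
`D > mean`). Both conventions are pinned for reproducibility rather than
because the alternatives (sample sd, one-sided quantile) would change
calls materially at `n_null = 100`.

False-detection check: `n_extra` (default 10) fresh shuffles with seeds
disjoint from the null seeds (null seeds are `base_seed+1..+n_null`, extra
seeds the next `n_extra` integers) are scored against the existing null.
The false-positive rate is the fraction of the `n_extra × N` new
pseudo-D-indices called significant; `expected_false = rate × N`. The
expected-true count is reported under **both** subtraction conventions —
`total_minus_false` (all D-indices minus expected false) and
`significant_minus_false` (significant D-indices minus expected false,
clamped at 0) — because both readings are defensible; neither is silently
preferred.

Pipeline presets bundle the search and validation settings:
`approximate_dtpm` (NRR, ≤11 MM, t=0.4, L=5E-1), `optimized_dtpm`
(NGG, ≤8 MM, t=0.4, L=1E-15), `optimized_dde` (NGG, ≤8 MM, alpha=0.001,
L=1E-15).

## Synthetic data generator

The generator emulates the pipeline's input boundary with exact ground
truth. Guide-binding windows are planted by mutating the protospacer at
exactly the requested number of positions (uniformly chosen, substitutions
to a different base) with a concrete PAM drawn from the pattern; `+` and
`-` strand plantings are supported. Every contig is rejection-sampled
until the scanner finds exactly the planted sites below the cleanliness
bound, so truth is exact, not probabilistic. Replicate expression noise is
multiplicative log-normal with unit mean, parameterised by a coefficient
of variation (CV) — the simplest model respecting TPM positivity. The
synthetic DE table derives M-values from the true fold changes (log2, with
small noise) and P-values small for truly changed transcripts.

Presets (120 contigs of 1.8–2.2 kb; 3 WT + 3 edited replicates; CV 0.1;
base TPM 20–200):

- **strong** — an on-target (plus a second isoform of the on-target gene
  carrying a 3-MM site, to exercise gene-level exclusion), 22 planted
  off-target genes (6×1 MM, 6×2 MM, 5×3 MM, 5×4 MM) all downregulated
  (fold change 0.15) and all sharing one planted GO term; 40 background
  5–8 MM sites; 10% of background transcripts mildly down (0.25); 30
  background GO terms. Sized analytically so the planted term's D-index
  (≈183) clears `mean + z(1E-15)·sd` of its permutation null with margin.
- **mixed** — the strong signal over a heavier background (60 background
  sites, 25% background downregulation).
- **null** — no associations: 100 sites (3–8 MM), 30% downregulation and
  12 GO terms at 2–5 terms per gene, all assigned independently. The null
  preset is deliberately *dense*: each term's score must aggregate many
  flagged-site genes for the parametric bound to be calibrated. In a
  sparse regime most terms would owe their observed score to a single
  flagged gene, and conditioning on "the term has a score at all" biases
  the observed value above its unconditional null — an inflation that
  genome-scale data avoids by having thousands of genes per term.

What passing tests on these fixtures shows: correct mechanics,
deterministic reproducibility, calibrated type-I behaviour, and recovery
of a strong planted signal. What they do not show: behaviour under
assembly artefacts, correlated expression, annotation bias, or realistic
site-count scales (fixtures carry ~10² transcripts against ~10⁵ in real
assemblies — chosen so the full validation loop runs in seconds).

## Known limitations

- No bulge/indel off-target models and no activity-score weighting.
- dDE depends entirely on the supplied DE table; the package does not
  check how it was produced.
- GO annotations are taken flat; without propagation, sparse annotation
  sets understate parent-term risk.
- The parametric null bound assumes the pseudo-D-index distribution is
  summarised adequately by mean and sd; for terms with very few
  annotated genes it is conservative in the tail but the strict-L presets
  exist precisely to suppress such marginal calls.
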