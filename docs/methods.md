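# Methods

This note documents the models, parameters and design choices behind
`omixalign`, and what the simulation benchmark does and does not show.

## Relatedness scoring

Cross-dataset relatedness uses the GRM estimator over loci shared by
(chrom, pos, ref, alt), with alt-allele frequencies **pooled over the union
of the two datasets' samples**.  Pooling is a deliberate choice: when one
platform has few samples its own frequency estimates are unstable, and the
score of a duplicated genotype vector is biased downward by roughly
2/(number of pooled columns), which is negligible at cohort scale.  Loci
with pooled frequency outside `[maf_min, 1 − maf_min]` (default
`maf_min = 0.01`) are excluded; missing calls are deleted pair-wise per
locus, matching GRM conventions, and each pair records the number of loci
actually used.  Fewer than 200 usable shared SNPs is an error; fewer than
2000 (the recommended floor for reliable separation, especially between
sparse platforms such as RNA-seq vs ATAC-seq) triggers a warning.  The
extraction threshold defaults to 0.65 with a strict `>` comparison, but is
user-adjustable because the exact location of the valley between the
related and unrelated modes depends on the frequency source and on cohort
structure (related individuals shift it upward; with family data a higher
threshold should be chosen by inspecting the score distribution).

## Sex inference

The F statistic `(O_hom − E_hom)/(L − E_hom)` is computed per data over its
non-missing X loci, with `E_hom = Σ (1 − 2 p_i (1 − p_i))`; a floor of 100
usable loci (configurable) guards against noise, and a degenerate
denominator yields no call.  Explicit `(f_low, f_high)` thresholds are the
primary interface.  The automatic mode places the cut at the deepest
density valley between the two largest modes of a Gaussian KDE
(normal-reference bandwidth) and surrounds it with a ±0.1 ambiguity band
mapped to "unknown" rather than forcing a call; a distribution without two
modes is refused with instructions to supply thresholds, since platforms
with poor sex-chromosome coverage genuinely lack a bimodal F distribution.
Data left unknown but with a Y-chromosome call rate above half the male
median are assigned male; this tie-break rule is this package's own
construction.  XIST-based calls are a pure threshold (female iff > 2 TPM,
strictly).  X pseudo-autosomal regions are not excluded automatically;
users may pre-filter loci.

## Switch model and sorting

Features are implemented exactly as the difference equations give them, so
each lies in [−1, 1] and is antisymmetric under swapping the pair — this
makes the final assignment invariant to the stored orientation of every
edge (with `β0 = 0`).  Choices where the underlying procedure is
underdetermined:

* `n_a`/`n_b` count matching IDs over the whole group excluding the pair's
  two nodes; with one data per omics this bounds `x1` naturally, and a clip
  to [−1, 1] guards duplicate-rich groups.
* Unknown sexes contribute 0.25 per half-condition of S — the neutral
  midpoint of {0, 0.5}.
* Training pairs are mined from single-deviant groups whose correction is
  corroborated by sex; each pair enters the fit in both orientations with
  mirrored labels, and the fit then omits the intercept (the mirrored
  design makes its maximum-likelihood value exactly zero).  A small L2
  penalty (`ridge = 1e-4`) keeps coefficients finite on separable data.
* Below 10 training pairs the model falls back to fixed coefficients
  `(0, 4, 2, 1)`: relationship evidence dominates, then sex, then priority.
  These defaults are configurable and recorded in the output provenance.
* Edge weight is `|2p − 1|`, a linear, symmetric rescaling of the winning
  direction's probability that maps uncertainty to zero.  Probabilities
  within `1e-9` of 0.5 are treated as uncertain (no direction, weight 0).
* Node score = weighted indegree − weighted outdegree; matched and
  uncertain edges contribute nothing, so scores sum to zero within a group
  to machine precision.
* Ties at the top score are broken by (1) the larger number of group nodes
  carrying the candidate ID, (2) the higher omics priority, (3) the
  lexicographically smaller ID.  The tie-break chain is invented; ties are
  rare in practice but must be deterministic.
* Omics-priority ranks map to `P = (K − rank)/(K − 1)` over K distinct
  rank levels; platforms declared as combined (e.g. two DNA-derived arrays
  processed from one extraction) share one P and count once in N.  Without
  ranks, P is the per-omics sex-concordance rate.

Stringent mode discards groups with fewer than three data or with no ID
shared by at least two data before assignment; such groups are nearly
uncorrectable and would otherwise be coin flips.  Discarded groups and
isolated data keep their observed IDs and are reported `unresolved`.

## Simulation benchmark

The generator emulates the conditions of a multi-platform cohort study:
sample sizes 50–300, three to six omics types, one data per individual per
platform, exactly half the cohort female, 2% of individuals with mislabeled
reported sex (consistent across all their data, since reported sex is
individual-level metadata), and per omics `⌊q·n⌋` datasets mis-assigned
with `q` from 5% to 30%.  Mis-assignment is modeled as a derangement of
the selected data's IDs within processing batches of 25, so every selected
data is genuinely mislabeled and the mix-up count is exact; selections
leaving a batch with a single selected data are redrawn (a singleton cannot
be deranged).  Because every platform processes the cohort separately,
**each omics type receives its own random batch composition**; sharing one
layout across platforms would make two datasets of the same individual
receive the *same* wrong ID far too often (colliding derangements within
the common batch), which measurably inflates overcorrection and is not
what separate processing pipelines produce.

Ground-truth relatedness edges connect exactly the data pairs sharing a
true individual and are noise-free by default — the benchmark isolates the
re-alignment logic from genotyping noise, whose effect on pair extraction
is exercised separately by the relatedness module's subsampling benchmark
and separation tests.  Optional edge-dropout and false-edge knobs exist
(default 0) for robustness experiments.  Consequently, passing benchmarks
demonstrate the correctness of grouping, direction inference and sorting
under realistic mix-up structure; they do not demonstrate robustness to
miscalled genotypes, related individuals, or contamination, which real
deployments must still assess.

Each replicate trains its own switch model from the dataset's mineable
training pairs (falling back to the defaults when scarce), mirroring real
usage.  Scoring: corrected = mix-ups assigned their true ID / mix-ups
introduced; overcorrected = clean data assigned a wrong ID / mix-ups
introduced (the per-clean-data variant is also emitted).  Unresolved data
keep their observed ID and therefore count against correction.

Problem sizes used by the shipped benchmarks: the anchor-cell checks run
100 replicates at n = 300 for each condition; the grid trend runs the full
144-cell surface at 25 replicates per cell, which preserves the sign and
approximate magnitude of the size-versus-SD correlation at a fraction of
the cost of full replication.

## Numerical notes and limitations

* All randomness flows through `numpy` Generators seeded from explicit
  integers; identical (config, seed, replicate) triples reproduce datasets
  byte-identically.
* Genotype matrices are int8 with −1 as the missing sentinel; scores are
  accumulated in float64.
* Indels and multiallelic records are dropped at VCF read time; loci are
  keyed by 1-based VCF coordinates and never lifted over.
* FREEMIX values are accepted as user input only (they require BAM-level
  evidence that this package does not process).
* Family cohorts violate the assumption that relatedness > 0.65 implies
  identity; the stringent-mode annotations flag groups containing several
  matched-ID cliques, but the method should be applied to related
  individuals only with a raised threshold and manual review.
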