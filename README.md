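# omixalign

Detect and re-align mixed-up sample identities across multi-omics datasets.

## The problem

Integrative studies assay the same individuals on several omics platforms
(whole-genome sequencing, SNP arrays, RNA-seq, ATAC-seq, ...).  Sample
mix-ups — a dataset labeled with the wrong individual's ID — creep in during
collection, processing and data management, weaken statistical power (e.g.
in QTL mapping) and create false findings.  Because every omics dataset that
contains genotype information betrays the individual it really came from,
mix-ups can not only be *detected* but actively *repaired*: the data can be
re-assigned to the identity the genetics supports.

`omixalign` implements a two-step repair:

1. **Group by genetic relatedness.**  For data $j, k$ over $M$ shared
   biallelic SNPs with pooled alt-allele frequencies $p_i$,

   $$s_{jk} = \frac{1}{M}\sum_{i=1}^{M}
     \frac{(x_{ij} - 2p_i)(x_{ik} - 2p_i)}{2p_i(1-p_i)},$$

   the standard GRM estimator: near 1 for data from the same individual,
   near 0 for unrelated data.  Pairs with $s > 0.65$ form an undirected
   graph whose connected components ("groups") are presumed to stem from a
   single individual.  Edges are *matched* (same observed ID) or
   *mismatched* (different IDs — at least one is wrong).

2. **Assign the true ID per group.**  For each mismatched pair $(A, B)$ a
   logistic model estimates the probability that $B$ carries the true ID:

   $$\ln\frac{p}{1-p} = \beta_0 + \beta_1 x_1 + \beta_2 x_2 + \beta_3 x_3,$$

   with $x_1 = (n_B - n_A)/(N-2)$ (how many other data in the group echo
   each ID, over $N$ omics types), $x_2 = S_B - S_A$ (reported-sex versus
   genetics-based-sex agreement, 0.5 credit per condition), and
   $x_3 = P_B - P_A$ (user-ranked or sex-concordance-derived omics
   priority).  The model is trained on automatically mined high-confidence
   pairs (single-deviant groups whose correction is corroborated by sex).
   Each mismatched edge is then directed toward the more plausible ID with
   weight $|2p - 1|$, every node is scored by weighted indegree minus
   weighted outdegree (a modified topological sort), and the observed ID of
   the top-scoring node becomes the final ID of the whole group.

Genetics-based sexes come from the X-chromosome inbreeding statistic
$F = (O_{hom} - E_{hom})/(L - E_{hom})$ (bimodal over a cohort; males near
1, females near 0) with optional Y-call-rate support, and — for
transcriptomes — from XIST expression (female iff > 2 TPM).  Samples with
heterozygous rate > 0.3 and (when available) FREEMIX > 0.3 are flagged as
contaminated and should be excluded first.

A simulation module generates synthetic cohorts with known within-batch ID
shuffles and sex-mislabel noise, so the correction performance surface
(sample size × number of omics × mix-up proportion) is reproducible without
any real data.

## Worked example

Re-align a tiny cohort of two individuals over three platforms, where the
RNA-seq data of individual `s1` was mislabeled `s9` (relatedness table and
sex table as produced by the `relatedness` and `sexcheck` subcommands):

```bash
omixalign correct --relatedness rel.tsv --sex-table sex.tsv \
    --priorities WGS=1,Chip=2,RNA=3 --out-dir out
cat out/corrections.tsv
```

```text
omics_type  data_id_observed  data_id_final  verdict    group_id  node_score  model_source
WGS         s1                s1             unchanged  1          0.998178   default
Chip        s1                s1             unchanged  1          0.996998   default
RNA         s9                s1             corrected  1         -1.99518    default
WGS         s2                s2             unchanged  2          0          default
Chip        s2                s2             unchanged  2          0          default
RNA         s2                s2             unchanged  2          0          default
```

The mislabeled RNA data sits in `s1`'s group with a strongly negative
sort score (both directed edges point away from it), so it is re-assigned
`s1`; everything else is untouched.  With only two mineable training pairs
the model fell back to its default coefficients (`model_source=default`).

Benchmark one simulated study condition (300 samples, five omics, 30% of
IDs shuffled per omics within batches of 25, 2% sex mislabels):

```bash
omixalign simulate --n 300 --omics 5 --shuffle 0.3 --reps 20 --seed 7 \
    --out sim.tsv --out-summary sim_summary.tsv
```

```text
mean corrected: 91.44%  (SD 2.90%)  mean overcorrected: 0.067%
```

i.e. even with 30% of labels scrambled, nine out of ten mix-ups are
restored to their true individual, and almost no correctly labeled data is
disturbed.

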