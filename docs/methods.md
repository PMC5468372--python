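# Methods

## The analysis model

`uccomics` treats a unicyanobacterial consortium as a set of species-resolved
member genomes observed through two noisy channels: a metatranscriptome (read
counts over genes) and a metaproteome (spectral counts over peptides). Three
quantities organize the analysis:

* **Species activity shares.** A^T_{o,s} is the fraction of a sample's
  assigned reads attributed to organism *o*; A^P_{o,s} the fraction of its
  species-attributable spectral counts. Both sum to 1 per sample by
  construction.
* **Per-organism RPKM.** Within an organism, gene expression is reads per
  kilobase per million reads *of that organism*: RPKM = c/(L/10³)/(R_o/10⁶).
  The statistic is invariant to rescaling all of an organism's counts by a
  positive factor, so it supports within-species comparisons over time but is
  meaningless across species (each species has its own million-read basis).
  Within-species protein trends are analogously expressed as percentages of
  the species' spectral-count total.
* **Activity ratio.** ρ_{o,s} = A^T_{o,s}/A^P_{o,s}. Empirically this is a
  stable, taxon-specific property (differences in cell size, extraction
  efficiency, regulatory strategy), not a read-out of growth; the pipeline
  estimates it per (species, sample) and summarizes per species by the
  geometric mean over samples, which is the natural location parameter for a
  ratio and suppresses the heavy right tail that per-sample ratios of small
  counts produce.

## Read attribution

Member contigs are concatenated — genomes sorted by id, contigs by id within
genome, a deterministic order — with 10 `N` bases between contigs so that a
read overlapping a contig boundary cannot produce a spurious alignment; such
reads, multi-locus matches, and intergenic hits are tallied per category and
conserved (`assigned + unassigned = processed`). Assignment is exact: a read's
leading k-mer (k = 30) seeds candidate positions, the full read must verify,
and a unique verified locus is required. A read counts toward a gene when the
overlap is ≥50% of read length; equal-overlap ties are discarded as ambiguous.
Strandedness is ignored. Gapped alignment, sequencing-error models, and
mapping-quality are out of scope — attribution, not alignment robustness, is
the scientific object, and the simulator's reads are error-free by default.
Multi-mapping reads are discarded rather than fractionally split; the
per-organism basis counts only reads assigned to the organism's genes,
with intergenic hits tallied separately.

## Protein inference and quantification

Peptides are mapped to proteins by membership in the protein's in-silico
tryptic digest (cleave after K/R except before P, ≤2 missed cleavages,
peptide length 6–50; digestion via `pyteomics`). Inference applies (1) a
two-distinct-peptide threshold per protein and (2) greedy set cover over the
remaining proteins (largest number of unexplained peptides first, ties broken
lexicographically by protein id) followed by a pruning pass, so the retained
list is an irreducible cover of every peptide that some eligible protein can
explain. Exact minimum cover is NP-hard; an exhaustive mode (ascending-size
search, practical to ~20 eligible proteins) is used as an oracle in the tests,
where the greedy list matches the true minimum size on ≥95% of random
instances (99% in a typical run).

Peptides whose proteins span more than one species are excluded from species
shares by default (an equal-split fractional mode exists); within one species,
a peptide shared among retained proteins counts toward each of them (a
unique-peptides-only mode exists). Species shares are computed from
species-unique mapped peptides *before* parsimony: the minimal list governs
protein-level quantities, while the share estimator stays an unbiased
multinomial proportion.

## Limitation signatures

* **Phosphate.** P_score = log2(replicate-mean expression at the final day /
  first day) of the species' highest-affinity transporter, chosen by the
  affinity hierarchy pstS > yjbB > pitA. The default call threshold is
  P_score ≥ 1 (2-fold), deliberately conservative relative to the ~4-fold
  induction signals that motivate the score.
* **Nitrogen.** The amt (ammonium transporter) and glnA (glutamine
  synthetase) replicate-mean day series are compared on log2 scale:
  `low_expression` if either gene's mean RPKM is below 1; `coupled` if both
  series vary (log2 range ≥ 0.5) and their Pearson r ≥ 0.8; `decoupled`
  otherwise. The dynamic-range floor generalizes the zero-variance case: with
  only four time points the correlation of a flat-but-noisy series against
  any trend is uniformly distributed, so a series that does not vary beyond
  ~1.4-fold is treated as non-varying rather than correlated. Thresholds are
  parameters of `limitation_signatures`.
* **Concordance.** Transcript and protein fold changes between consecutive
  days (ratios of replicate-mean shares) are pooled across species and
  regressed (OLS, free intercept) on log2 scale; a linear-scale mode is
  retained as a flag. Zero-share endpoints make a fold change undefined; they
  are flagged, never imputed.

## Capability rules

The shipped rule set is negation-free, so acquiring genes can only add
capabilities (a property the tests assert). Dissimilatory nitrate reductases
(narGHIJ, napAB) count toward assimilation by default since they can
substitute for nasA; `strict_assimilatory` disables this. Rule evaluation on
incomplete genome bins reports absence as absence — predictions are
conservative, and bin completeness is echoed in the matrix rather than used to
impute content. Typed cells (rhodopsin motif class, phosphate-transporter
family) are labels, not booleans. Dependency prediction inverts the matrix;
the phosphate entry flags members lacking the high-affinity Pst system, whose
uptake is rate-limited when phosphate is scarce.

The RbcL classifier takes the sequence length and the residue at the position
aligned to the canonical catalytic glutamate (reference numbering 204,
reference length 470 by default); alignment to the reference is the caller's
responsibility, since no fixed numbering scheme covers all homologs.

## The synthetic community

The generator emulates the observed structure of the study system, not its raw
data: 19 members (1 cyanobacterium, 8 Alphaproteobacteria, 6
Gammaproteobacteria, 4 Bacteroidetes), days 7/14/21/28 × 3 replicates,
succession turnover (gammaproteobacteria decline ~4-fold in weight while
alphaproteobacteria and Bacteroidetes rise), the cyanobacterium at ~50–60% of
reads and ~85–88% of spectra, and planted detection biases spanning 0.2–16×
(lognormal jitter, log2 sd 0.1). Protein shares are constructed as
p_{o,s} ∝ a_{o,s}/b_o normalized per sample; the realized ratio truth
ρ = a/p (the planted bias times a common per-sample renormalization) is
recorded in `GroundTruth` and is what recovery is measured against.

Genomes are ~24 genes each (~20 kb) — large enough for distinct k-mers and
realistic digests, small enough that the full 20-seed recovery studies run in
about a minute. Because organisms have tens rather than thousands of genes,
absolute RPKM values are inflated relative to real genomes; all analyses use
ratios or correlations within an organism, which are unaffected. Expression is
a per-gene lognormal baseline times day-program multipliers: transporters ramp
geometrically to 4-fold in P-limited members, coupled members share one
amt/glnA trajectory (correlation exactly 1 in truth), decoupled members pair a
flat glnA with a 4-fold amt decline (the pattern observed for detritivorous
members), low-expression members sit below the floor, and each species carries
a constant rpoC analog whose estimated RPKM stability validates the
normalization. The transporter's baseline weight is kept near 2% of its
organism's expression mass so that its induction barely perturbs the
per-organism basis (true P_score ≈ 1.95, not 2.00, because the basis grows
slightly).

Reads are drawn multinomially over genes (weight = expression × length,
positions uniform within the gene, error-free, fully contained in the gene);
spectra are drawn multinomially over digest peptides (weight = species
spectral share × gene expression normalized within species). Statistical
recovery studies sample at the count level — the identical multinomial model —
while the base-level FASTQ path (`sample_reads` → `assign_reads`) is verified
separately to attribute ≥99% of 10⁵ error-free reads to their source gene.

What the simulator does **not** emulate: sequencing error profiles and
color-space artifacts, chromatography/ionization physics, FDR filtering of
spectral matches, genuine sequence homology between paralogs or across species
(proteins are random sequences, so cross-species shared peptides are rare),
and replicate-level biological variation (replicates share the same truth;
observed replicate spread is sampling noise). Passing recovery tests therefore
demonstrates correctness of the attribution/normalization/inference machinery
under the stated sampling model, not robustness to real instrument artifacts.

## Problem sizes and tolerances

Acceptance tests run 20 seeds at 10⁵ reads and 10⁴ spectra per sample (the
depths at which the share-recovery criterion of 3 multinomial SEs per cell is
meaningful); the acceptance script uses 10 seeds for its summary statistics.
Ratio recovery is judged per species on geometric means over the 12 samples
(per-cell ratios at ~10 spectra would measure sampling noise, not method
error); the P_score check is on the per-seed mean over planted-limited species
for the same reason. RPKM agreement with the brute-force oracle is required to
1e-9 relative error; share sums to 1 within 1e-12; within-species percentages
to 100 within 1e-9. Concordance noise levels (log2 sd 0.05/0.25/0.6, applied
to the protein side, which is empirically the more variable measurement) probe
slope recovery and the monotone decline of R².

## Known limitations

* Exact-match read assignment requires reads to be error-free substrings of
  the reference; it is a desk-scale attribution stand-in, not an aligner.
* Greedy parsimony can exceed the true minimum list on adversarial bipartite
  graphs (observed on ~1% of random instances); the exhaustive mode is
  exponential and limited to small protein sets.
* The nitrogen-coupling classifier uses four time points; its correlation
  threshold is coarse by necessity and exposed as a parameter.
* Capability predictions from incomplete bins inherit the bins' gaps;
  absence of evidence is reported as absence.
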