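# Methods

This note documents the models, estimators and numerical choices behind
`mitoscatac`, and what the synthetic-data generator does and does not
emulate.

## Coordinate frames and gene models

Nuclear intervals are 0-based half-open (BED convention); mitochondrial
positions are 1-based (`m.<pos>`). The bundled gene models use the standard
mouse (mm10/NC_005089, 16,299 bp) and human (hg19/rCRS, 16,569 bp)
mitochondrial coordinates. Mitochondrial *reference sequences* are
synthetic: seeded-random bases of the real length, with a few anchor codons
patched so that annotation of the canonical worked-example sites is
sequence-faithful (CYTB codon 359 = TTC so that m.15219T>C yields p.F359L;
the ND4 codon containing m.11185 = CGC so G>A yields Arg→His; fixed
reference bases at m.9821, m.15984, m.15728 and human m.310). Every
statistic in the package depends on coordinates, not on the surrounding
sequence content, so this synthetic reference changes nothing downstream;
the patched anchors exist purely so the annotation path can be exercised
end-to-end from generated data.

Protein annotation translates the codon containing the variant under the
vertebrate mitochondrial genetic code (NCBI table 2, via Biopython), on the
coding strand; the cDNA offset is `pos − start + 1` for plus-strand genes
and `end − pos + 1` for minus-strand genes. CDS lengths that are not
multiples of three end in an incomplete stop codon (completed by
polyadenylation in vivo); variants falling in those trailing bases are
reported noncoding. Positions covered by several genes (the compact mtDNA
has real overlaps, e.g. ATP8/ATP6) report all annotations, ordered
protein > tRNA > rRNA > D-loop.

## Genotyping model

Reads contribute to the cell × position × allele × strand tensor iff
MAPQ ≥ 30 and ≤ 2 mismatches; each base additionally requires Phred ≥ 20.
The tensor is dense (`int64`, shape cells × (L+1) × 4 × 2), which is the
right trade-off for cohorts up to a few hundred cells at this genome size
(~1 GB per 1,000 mouse cells); larger cohorts should be genotyped in
batches and pseudo-bulked. Reads overhanging the genome end are clipped;
origin-spanning reads are not modelled (the simulator never emits them) —
a documented limitation for the D-loop boundary.

The informative-variant screen computes, per (position, alt allele): cell
support, pseudo-bulk VAF, mean site coverage, the variance/mean ratio (VMR)
of per-cell VAFs, and strand concordance — the Pearson correlation across
sufficiently covered cells between plus- and minus-strand alt counts.
Candidates require concordance ≥ 0.65 and VMR ≥ 0.01 (both configurable;
these are the conventions of the established mitochondrial single-cell
genotyping tools). A strictly homoplasmic site has VMR 0 and is excluded as
uninformative by construction. Degenerate correlations (a zero-variance
strand) are defined as 0.

Strand concordance deserves a note: for a heteroplasmy whose per-cell VAF
distribution is nearly degenerate, plus- and minus-strand counts are two
thinned Poisson draws of the *same* rate and their correlation across cells
approaches `V/(V + E/(c/2))`, where `V` and `E` are the variance and mean
of per-cell VAF and `c` the site coverage. Realistic clonal heteroplasmies
are strongly overdispersed (a minority of cells at high VAF), which is what
makes them detectable; a variant at uniform 0.5% VAF in every cell is close
to the sequencing-error floor and is *correctly* rejected by this screen.

Bulk filters (flags computed independently, order-free, monotone under
tightening; failing variants returned flagged for audit): (1) allele-depth
ratio max/min ≥ 5 at pseudo-bulk level — a literal reading of "five-fold
difference in depth between the two alleles", exposed as a switch because a
near-balanced heteroplasmy (e.g. ~80% VAF) fails it by construction;
(2) ≤ 90% of alt reads on one strand; (3) bulk site depth ≥ 250; (4)–(6)
base quality/MAPQ/mismatch limits, enforced upstream and recorded;
(7) ≥ 50 cells with ≥ 1 passing alt read; plus a species-keyed poly-C
blacklist, default `{human: m.310}` (no mouse entry).

Per-cell VAF is `alt/(alt+ref)` summed over strands; cells with informative
coverage below 10 at the site are *missing*, never zero — imputing zero
would deflate VMR, concordance, burden and mean-VAF statistics. With no
cells masked, pseudo-bulk VAF is exactly the depth-weighted mean of
per-cell VAFs.

## Wilcoxon machinery

The two-sided unpaired Wilcoxon rank-sum test is exact for pooled sizes
≤ 26 without ties, using the classic rank-sum counting recursion; with ties
and pooled size ≤ 16 it enumerates all group assignments of the midranks.
Larger samples use the tie-corrected normal approximation with continuity
correction plus an Edgeworth term: the null is symmetric with excess
kurtosis `−(6/5)(n² + m² + nm + n + m)/(nm(N+1))` (tie-free), and the
fourth-order correction keeps the approximation within 0.01 of the exact
p-value already at 8-vs-8. Pairwise cell-type content matrices use raw
p < 0.01 with no multiple-testing correction, matching the convention of
significance heat maps for this analysis; α is a parameter.

## Differential accessibility

Accessibility is binarized (≥ 1 fragment in the peak). The test is a
likelihood-ratio test of logistic `detected ~ group + log(total fragments)`
against the covariate-only model, χ²₁ reference, BH across peaks;
significance requires q < 0.01 and a depth-normalized detection-rate fold
change ≥ 1.25 in either direction (pseudocount 1/n_cells — a fold change on
sparse binary rates is undefined without one). The per-peak fits share one
design matrix, so they are solved as a single batched Newton iteration
across peaks (ridge 10⁻⁹ keeps the step defined under perfect separation,
where the LR still converges); the implementation is cross-checked against
per-peak GLM fits in the tests. A Fisher-exact mode exists for tiny data.

The depth covariate must be a *genome-wide* complexity measure (total
fragments per cell). Using the row sums of a small peak matrix instead
leaks any planted group effect into the covariate and produces residual
confounding on null peaks; the generator therefore returns a genome-wide
total alongside the matrix, and the CLI/pipeline uses per-cell fragment
totals.

The permutation control re-runs the identical test on label permutations
preserving group sizes (default 100 replicates); on signal-free data the
median significant count is 0 and only a few percent of replicates find
even one peak.

Motif scanning slides PWM log-odds (background 0.25, floor 10⁻⁴) over both
strands; the default hit threshold is 80% of the maximum attainable score.
Enrichment is the hypergeometric upper tail of hit counts in the
significant-peak set against all tested peaks (no GC matching — peak
sequences here are synthetic), BH-adjusted.

## Synthetic-data generator

The generator's defaults describe the cohort structure the analysis
assumes: ~6,000 unique nuclear fragments per cell (log-normal, σ = 0.55),
a regular peak grid (500 bp every 5 kb over two 1 Mb toy chromosomes —
every statistic used is scale-free in genome length, so a desk-scale
nuclear genome suffices), peak enrichment 5 (which yields FRiP ≈ 0.36 and
TSS enrichment ≈ 5, peaks being centred on their TSS), mitochondrial
content Beta-distributed per cell type × age with young > aged means and
greater aged dispersion (cohort mean ≈ 50%), a 2% doublet rate and 0.5%
mitochondrial contamination. Heteroplasmies follow a zero-inflated Beta:
probability π of true VAF 0, else Beta(a, b); the default spectrum is
mostly sub-1% sites (π = 0.8, Beta(0.5, 50)) plus near-homoplasmic ones,
with the designated trio included for mouse. Per-cell depth acts on the
*odds* of peak detection, so the logistic differential model is correctly
specified under the null; the carrier effect multiplies the detection
probability itself, as a fold change on accessibility.

Read-level realism is deliberately limited: fixed-length reads, no indels
or soft-clips, no origin wrap-around, no duplicate marking, and MAPQ /
mismatch-count fields drawn as independent pass/fail labels at configured
rates rather than derived from alignment. Sequencing errors are injected
per base at the Phred-implied rate of a two-level quality model (default
Q30 with a 5% admixture of Q10 bases, exercising the base-quality filter).
Contamination is modelled as reads generated from a donor cell's variant
profile relabelled to the target barcode — foreign mtDNA under a singlet's
barcode — not whole-cell mixing. Barnyard collisions are cross-species
doublets (the partner is always the other species), which is what a
species-purity classifier can identify; same-species doublets are out of
scope. Consequently, passing tests demonstrate correctness of the
estimators under this statistical structure, not robustness to alignment
artifacts, chimeric reads or index hopping in real libraries.

Reads can be materialised either as the MRF v1 TSV layout (for I/O) or as
packed numpy arrays that feed the pileup directly; the two paths produce
byte-identical count tensors and are tested against each other. All
randomness flows from a single seed; equal seeds give byte-identical
outputs.

## Reference experiment sizes

The bundled experiments (`mitoscatac.experiments`) fix these study
conditions: planted-variant recovery uses 75 cells at 100× mean coverage
with ten clonally overdispersed sites (π = 0.04, Beta(0.8, 8)), so every
site has pseudo-bulk VAF ≫ 0.5% and ≥ 50 carrier cells, run over ten
seeds; the permutation null uses 400 cells × 150 peaks × 100 replicates;
barnyard recovery uses 5,000 droplets with 2% collisions and 0.5%
contamination; Wilcoxon calibration uses 1,000 null simulations at 30 cells
per group. These sizes were chosen as the smallest cohorts at which the
respective guarantees are comfortably identifiable.

## Known limitations

Dense tensors bound the practical cohort size for genotyping; no indel or
haplogroup calling; no clonal-lineage inference beyond carrier grouping;
no GC-matched motif background; cell-type labels and peak sets are inputs,
not computed (clustering, embedding and annotation are out of scope).
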