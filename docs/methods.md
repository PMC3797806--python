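# Methods

This note documents the models, rules and numerical choices behind
`lncvsd`, and what the synthetic-data generator does and does not emulate.

## Differential expression

Input intensities are scanner-scale (linear); `ExpressionMatrix`
log2-transforms them at load with a pseudocount of 1.0 (intensities can be
below 1, and log2(x+1) keeps the transform defined and monotone).
Quantile normalization replaces each sample's values by the cross-sample
means of the per-rank sorted values; ties receive the average of their tied
ranks' values via linear interpolation. The procedure is idempotent and
forces identical sorted columns to numerical precision.

The per-probe test is an unpaired two-sided Welch *t*-test. The study
design — two independent biological replicates per condition — defines no
pairing structure, so the unpaired test is the default; a `paired=True`
mode (pairing samples by within-group order) is provided for designs where
pairs genuinely exist. Within-group variances are floored at 1e−8 so that
noiseless fixtures give extreme but finite p-values instead of NaN; floored
records are flagged. The volcano filter applies *strict* inequalities at
both thresholds (fold-change > 2.0 and P < 0.05), so boundary cases are
excluded. P-values are deliberately not multiplicity-adjusted at this
stage; FDR correction belongs to the enrichment step.

Sample clustering uses average linkage on 1 − Pearson correlation between
sample vectors; a constant sample vector is an error naming the sample.

## Positional classification

All coordinates are 0-based half-open internally; GTF's 1-based closed
intervals are converted at the reader boundary (single convention, no
off-by-one drift). Class definitions, applied in precedence order (most
specific evidence wins; exonic before intronic, overlap before proximity):

| class | strand vs gene | geometry |
|---|---|---|
| exon_sense_overlapping | same | ≥1 bp overlap with a coding exon |
| intron_sense_overlapping | same | contained in the gene span, zero exonic overlap |
| natural_antisense | opposite | exonic overlap, or partial overlap without containment |
| intronic_antisense | opposite | contained in the gene span, zero exonic overlap |
| bidirectional | opposite | no overlap, TSS-to-TSS gap ≤ 1,000 bp |
| intergenic | — | none of the above |

The 1 kb bidirectional cap follows common usage for divergent promoter
pairs (the canonical examples sit tens of bp apart). "Antisense overlap"
is treated as the umbrella for opposite-strand overlap that is neither
contained nor exonic. Neighbors: the overlapping gene for overlap classes
(distance 0), the closest-TSS partner for bidirectional, otherwise the
nearest coding gene with span gap strictly below 100 kb. Nearest-neighbor
ties break toward the 5′ gene on the lncRNA's strand, then lexicographic
gene id, so output is deterministic. A lncRNA on a chromosome with no
indexed gene is intergenic with no neighbor — not an error.

A same-strand partial overlap that is neither exonic nor contained matches
no named class and falls through to intergenic with a distance-0 neighbor;
the generator never plants this geometry, and the brute-force oracle used
in tests applies the same convention.

Transcript length in the context summary is exonic (mature transcript)
length, binned at 200/1,000/2,000/3,000/5,000 bp with an under-200 catch
bin so the histogram always covers all inputs.

## Conservation

Per-transcript statistics are computed over exonic bases only (the mature
transcript is the unit of interest). Bases absent from the track are
excluded from denominators — "unaligned" is distinguished from
"unconserved" — and a transcript with zero covered bases carries an
undefined median and a zero conserved fraction, flagged via
`n_bases_covered == 0`. A base counts as conserved when its score is
≥ 0.5, boundary inclusive. The candidate-pipeline conservation cut is not
a published number; the default `min_conserved_fraction = 0.1` is
deliberately permissive and exposed as a knob. Multiple species tracks
(vertebrate/placental/primate subsets) are treated as independent named
inputs; no cross-track combination is computed.

## Enrichment

The primary test is the one-sided hypergeometric upper tail
(over-representation); the χ² alternative is Pearson's statistic without
continuity correction, flagged unreliable when any expected cell is below
5 and returning p = 1 on degenerate margins. FDR is Benjamini–Hochberg
(the field default where no method is named). The universe defaults to the
neighbor-gene universe — every coding gene that is the nearest neighbor of
a profiled lncRNA — matching the restriction of the analysis to closest
coding genes; any universe can be passed explicitly. Gene-set annotations
are flat: no ontology-ancestor propagation.

## qPCR

Replicate Ct values are averaged on the cycle scale before ΔCt (standard
ΔΔCt practice); replicate SD above 0.5 cycles sets a warning flag without
dropping the measurement. Amplification efficiency is fixed at perfect
doubling (plain 2^−ΔΔCt, no efficiency correction). When the calibrator is
a group, the baseline is that group's mean ΔCt per gene. Tissue
predominance is argmax of rq shares across the panel (shares sum to 1);
exact ties yield no predominant tissue, and a stricter share > 0.5 mode is
available. Cis-concordance: `no_association` when the neighbor's p ≥ α,
otherwise concordant/discordant by sign agreement of the log2 fold-changes.

## Candidate cascade

Stages run strictly in order — volcano → functional → conservation →
tissue predominance → cis-check — each consuming the previous stage's
survivors. The functional filter is a *membership* test (neighbor gene
annotated to a selected term), not an enrichment-significance test; the
enrichment statistics are reported separately. `stage_reached` counts
consecutive filters passed (0 means the lncRNA failed the differential
filter). lncRNAs absent from the Ct table cannot be tissue-tested and are
carried as `untested` rather than failed; they do not advance. All stage
outputs are written even when a stage empties the candidate list, and
reruns on identical inputs are byte-identical (fixed sort orders and float
formats).

## Synthetic data

The generator emulates the study conditions: a two-condition (VSD/NC)
design with two biological replicates per group by default, planted
|log2 fold-change| of 2 (fold-change 4), log2-scale Gaussian noise with
SD 0.2, six positional classes planted at equal counts, a five-tissue Ct
panel measured in triplicate against a GAPDH reference, and ~10% of
lncRNA probes differentially expressed. Each sub-generator draws from its
own RNG stream derived from `(seed, stream-offset)`, so outputs are
byte-identical under a fixed seed and modules can be regenerated
independently.

Geometry is planted constructively: coding genes are three-exon,
non-overlapping, on alternating strands; each overlap-class lncRNA is
embedded in a distinct host gene; intergenic lncRNAs alternate between a
known-gap neighbor (2–40 kb) and full isolation (>100 kb from any gene).
Spacing rules guarantee each planted lncRNA satisfies exactly its intended
class, which is what makes 100% recovery a meaningful correctness check
rather than a statistical outcome. Intensities are generated on the log2
scale and written linear (2^x) to exercise the downstream transform.
Differential probes are placed in the interior of the intensity range:
at synthetic scale (hundreds of probes rather than tens of thousands) an
edge probe's shifted values would fall outside the empirical distribution
and be clamped by quantile normalization — an artefact of small probe
counts, not of the method.

Conservation tracks cover every exonic base: background scores uniform in
[0, 0.5), planted element scores uniform in [0.5, 1], elements arriving at
a Poisson rate per kb of exon. Ct tables are noiseless by default so
planted ratios are exactly recoverable; a `ct_noise_sd` argument adds
replicate jitter when wanted.

What the generator does **not** emulate: probe-level microarray artefacts
(dye bias, spatial effects, background), nucleotide sequence, isoform
structure in lncRNAs (single-exon), overlapping or nested coding genes,
and realistic genome-scale distance distributions (intergenic gaps are
tens of kb, not the ~100 kb medians seen genome-wide). Passing tests
therefore demonstrate correctness of the computational rules on known
geometry and known effects — not robustness to real-array noise structure.

### The end-to-end bundle

`generate_bundle` plants a configurable number (default 2) of
fully-qualifying candidates — preferentially one natural-antisense and one
bidirectional lncRNA, one down- and one up-regulated, echoing the
antisense/divergent pair motif — whose neighbors are forced into the
cardiac gene set and dysregulated concordantly, and whose exons are fully
conserved and heart-predominant in the Ct panel. All other DE lncRNAs'
neighbors are excluded from the cardiac set, so exact recovery of the
planted pair is the correct outcome. End-to-end recovery checks run the
bundle at five replicates per group, the regime in which the volcano
filter's recall of planted 4-fold effects is essentially 1 (the
effect-recovery property is stated at n = 5); the config default remains
the study's two replicates, where recall at noise SD 0.2 is ~0.78 and
exact recovery is not guaranteed.

## Problem sizes

Defaults are desk-scale: 2 chromosomes of 5 Mb, 60 coding genes, 10
lncRNAs per class (60 total). Oracle-equivalence checks use 100 random
genomes of up to 200 coding genes and 120 lncRNAs; calibration checks use
10,000 probes; the planted-class recovery check uses 20 per class (120
lncRNAs). These sizes exercise every code path while keeping the whole
suite and the acceptance script in the seconds-to-minutes range.

## Known limitations

- Probe ids are transcript ids (one probe per transcript); probe-to-
  transcript reannotation is out of scope.
- The cis-concordance stage uses the expression-matrix differential
  records for the neighbor gene rather than a dedicated qPCR comparison.
- The χ² test and Fisher test are reported separately; no combination rule
  is applied.
- WIG/bedGraph parsing is plain-text only (no bigWig).
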