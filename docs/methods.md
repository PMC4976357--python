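# Methods

## The statistical problem

Two RNA-seq replicates per condition cannot support per-gene error control:
a pooled-variance two-sample t on 2+2 observations has 2 degrees of freedom
and its null tail is enormous. The screen here never claims individual
genes. It estimates, at every |T| cutoff, how many exceedances the *null*
would produce — from the only non-trivial relabelings a 2-vs-2 design
admits — and reports a gene list at a deliberately liberal false-discovery
level whose *composition* (≈ half true, the true half ≈ a random sample of
all DE genes) is what downstream pathway arguments consume.

## Count model of the simulator

The generator emulates a bulk RNA-seq experiment on edited and control
lines:

- gene mean expression μ_g is log-normal: ln μ_g ~ N(`baseline_mean_log_mu`,
  `baseline_mean_log_sigma`²); defaults 4.0 and 1.0 give a median of ~55
  counts with a realistic dynamic range of ~3 orders of magnitude;
- counts are negative binomial with Var = μ + φμ², the standard bulk
  RNA-seq noise model; default dispersion φ = 0.1;
- a Bernoulli(π₁) subset of genes (default π₁ = 0.1) receives a log2 fold
  change of ±`effect_log2fc` (default 2.0), sign symmetric at random,
  applied to the treated group;
- per-sample library-size factors are log-normal with CV
  `library_size_cv` (default 0.1);
- a fraction `rrna_fraction` (default 0.02) of genes is flagged as rRNA so
  the filtering stage has work to do;
- gene sets are uniform draws of `set_size` genes except for
  `n_enriched_sets` sets whose members are drawn with the odds of being DE
  multiplied by `enrichment_rho`; enriched sets are flagged
  "immunological" to give the off-target screen a planted positive.

Every generator call consumes one seeded RNG stream; identical configs give
bitwise-identical output.

What the simulator does **not** model: read-level effects (GC, fragment
length, positional bias), gene-gene correlation, batch structure, and
heavy-tailed outlier counts. Passing tests therefore demonstrate the
pipeline's arithmetic and its calibration *under the NB model*, not
robustness to every pathology of real libraries.

## Normalization

rRNA-flagged genes are dropped first (a stand-in for sequence-level rRNA
identification, which happens upstream in real pipelines). Depth is then
equalized by drawing, for each sample, a multivariate hypergeometric
subsample of its counts with the minimum column total as the draw size —
the count-level equivalent of randomly discarding reads. Column totals are
exactly equal integers afterwards, each gene's count never exceeds its
original, and the expected downsampled count is the original scaled by
(target/total). Binomial thinning is available (`method="binomial"`) but
only equalizes totals in expectation.

A caveat that matters for calibration: equal-total normalization carries
composition bias. A sign-symmetric log2 fold change is asymmetric on the
linear scale (mean factor (4 + 0.25)/2 ≈ 2.1 at |log2FC| = 2), so treated
libraries are systematically deeper and get thinned harder, which shifts
non-DE genes slightly between groups. This is a property of the
normalization contract itself (the reason depth-ratio methods like
median-of-ratios exist), and it is visible in the calibration numbers
below.

## FDR estimation and the putative set

- Statistic: pooled-variance two-sample t on log2(count+1) (`transform=
  "raw"` available). Genes with zero pooled variance score 0. An optional
  ε added to the denominator (`epsilon`, default 0) acts as a variance
  stabilizer; without it the extreme tail of the spectrum is dominated by
  near-zero-variance genes on both the observed and permuted sides.
- Permutations: all group-size-preserving relabelings, excluding the
  observed one, counting a label swap once (for 2-vs-2: exactly the two
  mixed partitions; for 3-vs-3: nine).
- FDR̂(t) = mean permuted exceedance / observed exceedance at each distinct
  observed |T| value, clipped to [0, 1].
- Monotonization: the reported curve at cutoff t is the minimum raw ratio
  over all cutoffs at most as stringent (the q-value construction), making
  the curve non-increasing in t. The putative set at level q is every gene
  passing the least stringent cutoff whose monotone FDR̂ ≤ q.

### Calibration, measured

Over 200 seeded end-to-end runs at the default conditions (10,000 genes,
2-vs-2, π₁ = 0.1, |log2FC| = 2, φ = 0.1), the level-0.5 putative list
realizes a mean false-discovery proportion of ≈ 0.56 (acceptance script
target `t1`). The ~6-point excess over the nominal level decomposes into
the composition bias above (the permutation exceedance undercounts the
post-normalization null tail by ~12% at practically relevant cutoffs) and
selection optimism: the extraction threshold is the first 0.5-crossing of a
ratio path averaged over only two permutations, so it lands preferentially
where that noisy path dips. Both effects are intrinsic to the procedure at
n = 2; the suite's calibration check asserts the idealized ±5-point band
and documents the miss rather than widening it.

## Enrichment and the off-target verdict

One-sided hypergeometric (Fisher) upper-tail p for over-representation,
exact at desk scale; the universe is the set of genes surviving
normalization. No multiple-testing correction is applied across sets — the
screen deliberately uses a liberal fixed α = 1e-4 so that *absence* of any
significant immune-flagged set is informative (Benjamini–Hochberg is
available as an option but is not the screening logic). The verdict
partitions significant sets by flag and is "clean" iff no immune-flagged
set has p < α.

`propagate_expectation` gives the mixture prediction used to reason about
detectability: a list that is π truly-DE overlaps a set at rate
π·rate_DE + (1−π)·rate_background.

### Dilution is only isolable when detection saturates

The claim "enrichment p of the putative list worsens as the FDR level
rises" holds when the level-0.1 list already contains essentially all
detectable DE genes, so that raising the level only adds background. In
power-limited regimes the opposite happens first — larger (more diluted)
lists gain more from size than they lose to dilution, and with ε = 0 the
stringent-level lists are additionally starved by the heavy null tail. The
dilution property test therefore runs in a saturated regime
(|log2FC| = 3, ε = 0.5, ρ = 10), where the median p degrades monotonically
across levels 0.1 → 0.5 → 0.9 by ~55 orders of magnitude; the power
behavior outside that regime is a real feature of the procedure, not a
defect.

## Guide design conventions

- Coordinates are 0-based, half-open; SNP labels (rs4073/−251 etc.) are
  display strings only.
- PAM = NGG on either strand; a candidate needs room for a full
  protospacer (length configurable, default 20) immediately 5′ of the PAM
  on its strand.
- Cut site: the blunt SpCas9 junction 3 bp 5′ of the PAM.
- Pair selection: g1 cuts strictly downstream of SNP1, g2 strictly
  upstream of SNP3, g1 before g2; if any qualifying pair's excised
  interval covers SNP2, only covering pairs are returned, ranked shortest
  excision first (minimal perturbation with the required coverage),
  ties by coordinate.
- Cloning oligos: forward = CACC + protospacer, reverse = AAAC +
  revcomp(protospacer) — the BbsI overhangs of the digested pX330 vector.
  The published IL-8 insert 1 forward oligo carries a 5-nt prefix (CAACC);
  the builder accepts a custom forward adapter so that oligo is
  reconstructable, and the reverse-oligo round trip pins down its
  protospacer unambiguously. The optional 5′ G-prepend for U6 transcription
  is off by default (the published inserts show none).
- No off-target scoring: genome-wide specificity search belongs to
  dedicated design tools and is out of scope; candidates are reported
  without scores.
- HDR templates substitute the requested ref/alt allele at each SNP and
  change nothing else; requesting any other base is an error naming the
  SNP.

## Summaries

Hierarchical clustering is agglomerative with Euclidean distance; linkage
defaults to average (complete/single available) since the clustering
contract specifies only the metric. The input is the log2(count+1)
normalized matrix restricted to the putative genes. Determinism: given
input order, scipy's agglomeration is deterministic; with all pairwise
distances distinct the topology is order-invariant (tested), while exact
tie behavior follows scipy's ordering. Dendrograms serialize to Newick with
branch lengths derived from merge heights. ΔΔCt: fold =
2^−[(ΔCt_sample) − (ΔCt_calibrator)]; the calibrator is configurable (in
the emulated qPCR design it is the stimulated reference condition).

## Problem sizes

The defaults everywhere are desk-scale choices: 10,000 genes (a realistic
screen quantifies ~35,000 transcripts; nothing in the machinery depends on
the count), 200 replicates for calibration means, 15–50 seeds for
Monte-Carlo property checks — enough for the Monte-Carlo standard errors
quoted in the tests.
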