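# Methods

This note documents the statistical models behind `nucorg`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Three-zone position assay

A tagged locus is scored in the focal plane where its GFP spot is
brightest, so the geometry is the two-dimensional cross-section of the
nucleus, not a sphere. The measurement is the spot-to-envelope distance
x expressed as a ratio to the nuclear diameter D, so x/D ∈ [0, 0.5].
The disc of unit diameter is partitioned into three concentric zones of
equal area; solving π(R² − r²) = πR²/3 with R = 1/2 gives the
separators on the ratio scale

    b1 = (1 − √(2/3))/2 ≈ 0.0918     (zone 1 | zone 2)
    b2 = (1 − √(1/3))/2 ≈ 0.2113     (zone 2 | zone 3)

Bins are half-open with ties assigned inward: zone 1 = [0, b1),
zone 2 = [b1, b2), zone 3 = [b2, 0.5]. Under uniform positioning each
zone holds 1/3 of spots, the "33% random line".

Inference: a Pearson χ² of the observed zone counts (raw counts, never
percentages) against the uniform expectation (n/3, n/3, n/3), df = 2,
where the upper-tail p equals exp(−χ²/2) exactly; and a Pearson χ² on
the 2×3 contingency table for two scored populations, without
continuity correction (expected cells < 5 warn rather than switching
method). Records with distance beyond the radius are dropped and
logged, not clamped — measurement error should stay visible.

Colocalization with clustered nuclear pores is a per-cell binary event;
the test is an exact two-sided binomial (point-probability method) of
k overlaps in n cells against the fixed random expectation p0 = 0.09,
a constant imported from prior work rather than derived from any
spatial pore model.

## Locus-level binding calls

Each array locus carries eleven 25-nt probe log2(IP/input) ratios (300-bp
loci; 100-bp loci on denser regions are mapped into their containing
300-bp locus by containment before track comparisons). The call is a
one-sided exact Wilcoxon signed-rank test of the probe values against
zero: zeros are dropped, tied absolute values share mid-ranks, and the
null distribution of the positive-rank sum W⁺ is the enumeration of all
2^m sign assignments, computed by convolution over the per-value rank
contributions (mid-ranks are doubled to integers first). A locus is
positive when the upper-side p is below α = 0.025 and negative when the
lower-side p is; for m > 25 a normal approximation with tie correction
takes over, though the designs handled here never leave the exact path.

The exact test is discrete: for eleven tie-free probes the largest
achievable level below 0.025 is 43/2048 ≈ 0.0210, so the realized
false-positive rate under a zero-effect null is ~2.1%, not 2.5%.
This matters downstream: the pooled coincidence percentage computed over
*called* A-positive loci is attenuated relative to the true conditional
overlap by roughly fA/(fA + (1 − fA)·α0) — with a bound fraction of 0.24
that is ≈ 0.92, i.e. a planted P(B|A) of 76% surfaces as ≈ 72% on the
naive called table. Recovery of the planted conditional overlap is
therefore measured on the generator's recorded ground-truth A set, which
separates overlap recovery from the false-positive rate (itself checked
by the null calibration).

Clusters are maximal runs of ≥ 2 consecutive positive loci on the grid;
"peaks" are clusters ranked by their maximum member log2 ratio (the
score is not defined more precisely by the source convention, and the
maximum matches the "peak" language), filtered at log2 > 0.8, top ten
reported. Subtelomere reports count positive loci intersecting the
terminal 10-kb zone of each chromosome arm. Promoter context uses a
400-bp upstream window of each start codon; a locus in the intergenic
gap between a divergent (head-to-head) gene pair and within 400 bp of at
least one of the two starts is a divergent promoter — mid-gap loci of
wide gaps stay intergenic.

Coincidence-table percentages round half-up to integers; all fourteen
printed percentages of the reference binding-correlation table reproduce
from their counts under this rule.

## Differential expression

Per gene, a two-sample t-test of mutant vs wild-type replicate log2
values (≥ 3 replicates per strain). The default is the pooled-variance
Student t rather than Welch: with three replicates per group under
normality the pooled test holds the nominal 5% level exactly, whereas
the Welch approximation is markedly conservative (realized size ≈ 3% in
a 10,000-gene null simulation), which would silently break the raw-p
thresholding convention. `equal_var=False` restores Welch when replicate
variances genuinely differ. Zero-variance degenerate genes report p = 1
when the group means are equal and p = 0 otherwise.

A gene is misregulated when |mean log2 difference| ≥ log2(1.25)
(boundary inclusive) *and* raw p < 0.05. No multiple-testing correction
is applied: this deliberately preserves the raw-p convention of the
analysis being reimplemented and is a fidelity choice, not a
recommendation. Overlap summaries report exact intersections with
half-up integer percentages; the top table ranks by the first mutant's
log2 ratio and parenthesizes the second mutant's entry when its p ≥
0.05; the class-effect summary restricts to genes significant in both
mutants before reporting per-class means.

## Synthetic data

The generators exist so every stage runs, and can be calibrated, without
external downloads; identical config + seed is bit-identical.

* **Spots** — a zone is drawn per cell from `zone_probs`, then the
  radial position is area-uniform within that zone's annulus (r =
  √(r_out² − u·(r_out² − r_in²)), u ~ U[0,1)); the uniform mixture is
  exactly area-uniform over the disc. Defaults: n = 200 cells per
  condition (per-condition counts are not stated by the source for most
  panels; 200 is a typical imaging-experiment scale and is used without
  claiming fidelity), diameter 2.0 µm (only the ratio matters),
  g1_fraction 0.5, coloc_prob 0.09 (the random expectation).
* **Tiling ChIP** — default grid of 8,441 detectable 300-bp loci over
  four chromosomes (1322 + 4857 + 1849 + 413), mirroring the scale of a
  four-chromosome tiling design. Factor A bound at fraction 0.24;
  factor B drawn jointly with P(B|A) = 0.76 and marginal 0.30 (the
  B-like factor deposits the H2A.Z variant at promoter-flanking
  nucleosomes of most genes, so it is taken as somewhat broader than A);
  bound probes ~ N(1.5, 0.5), unbound ~ N(0, 0.5) per probe. Planted
  positive sets are recorded as ground truth.
* **Expression** — per-gene baselines ~ N(8, 2), replicate noise
  sd 0.15 on the log2 scale (a typical replicate-array spread), three
  replicates per strain. The default design plants mutant-B down/up sets
  of 506/375 genes with 17%/15% of them shared with mutant A's sets
  (realized exactly by construction), planted effect magnitudes
  ~ U(0.4, 2.3) spanning the reported range, plus a 60-gene
  ribosomal-protein-like class planted strongly up in mutant A
  (U(1.4, 2.3)) and weakly, often sub-threshold, in mutant B
  (U(0, 0.8)). Because the RP class is planted in both mutants on top
  of the backbone sets, the realized *up*-set overlap exceeds the 15%
  backbone parameter; the overlap-recovery check therefore targets the
  clean down direction.

What the generators do **not** emulate: spatial pore-cluster geometry
(colocalization is a plain Bernoulli event), probe-level sequence or GC
effects and spatial autocorrelation along the array, intensity-dependent
microarray noise, correlated replicate structure, and any real genome
annotation. Passing recovery tests therefore demonstrates that the
statistical machinery is correct and calibrated under its stated
assumptions — not that the real deposited datasets would yield the
printed biological values, which are unreachable without those data.

## Problem sizes and runtime choices

Calibration checks use 10,000 Monte-Carlo repetitions (zone χ²), 10,000
genes (t-test null), and 10,000 loci (tiling null); recovery checks use
2,000 cells, the full 8,441-locus default grid, and a 6,000-gene
expression design. The end-to-end demo pipeline runs all three assays at
these scales in well under a minute on one CPU.

## Known limitations

* The exact signed-rank caller's discreteness means the realized locus
  false-positive rate is bounded by the largest achievable level below
  α, not α itself (2.10% at n = 11).
* The divergent-promoter rule is interval arithmetic on gene bounds; it
  does not consult transcript structure or UTRs.
* Raw-p thresholding (no FDR control) is preserved by design; gene-set
  sizes from `classify_changes` should not be read as FDR-controlled.
* The 100-bp → 300-bp containment mapping takes "any member positive"
  as positive, which is slightly anticonservative for the coarse locus.
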