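# nucorg

Quantitative analyses of subnuclear gene organization in budding yeast,
as a tested, reusable Python pipeline. It is aimed at chromatin and
nuclear-organization labs who score locus positions from live imaging,
call factor binding from tiling ChIP-chip arrays, and compare
replicate expression arrays between deletion mutants — and want the
statistics of those three assays to be explicit, calibrated and
reproducible.

## What it computes

**Three-zone position assay.** A GFP-tagged locus's distance to the
nuclear envelope, measured in the brightest focal plane, is expressed as
a ratio x/D to the nuclear diameter and binned into three concentric
zones of equal cross-sectional area (separators b₁ = (1−√(2/3))/2 ≈
0.092 and b₂ = (1−√(1/3))/2 ≈ 0.211 on the ratio scale). Uniform
positioning predicts 33% per zone; enrichment is tested with a Pearson
χ² against (n/3, n/3, n/3), df = 2 (p = e^(−χ²/2)), populations are
compared on the 2×3 table, and colocalization with clustered nuclear
pores is an exact two-sided binomial test of k/n against the 9% random
expectation.

**Tiling ChIP-chip binding calls.** Each 300-bp locus carries eleven
25-nt probe log2(IP/input) ratios; the locus is called bound when the
one-sided *exact* Wilcoxon signed-rank p of those values against zero
is below 0.025 (null enumerated over all 2^m sign assignments).
On top of the calls: clusters (runs of ≥ 2 consecutive positive loci),
top peaks (peak log2 > 0.8), per-chromosome coincidence of two factors'
positive sets with integer percentages, subtelomere (terminal 10 kb)
presence, paired-scatter Spearman correlation, and promoter-context
classification (divergent promoter / single promoter / ORF-internal /
other) from GFF3 annotations.

**Differential expression.** Per-gene two-sample t-tests on replicate
log2 intensities (pooled-variance Student t by default; see
`docs/methods.md` for why), misregulation = at least 1.25-fold change
with raw p < 0.05, exact set overlaps between mutants, ranked top
tables with parenthesized non-significant second-mutant entries, and
per-class (e.g. ribosomal-protein gene) effect summaries.

**Synthetic data.** Seeded generators for all three inputs — area-uniform
or zone-weighted spot populations, planted two-factor binding landscapes
with a tunable conditional overlap P(B|A), and expression matrices with
planted up/down sets — with ground truth recorded, so every stage can be
run and calibrated without external downloads.

## Worked example

```python
from nucorg import simulate as sim, zones, chip

# a population anchored at the periphery: 49/30/21% planted occupancy
spots = sim.simulate_spots(
    sim.SpotSimConfig(n_cells=2000, zone_probs=(0.49, 0.30, 0.21), seed=8))
print(zones.zone_report(spots, group_by="stage").to_string(index=False))

c = zones.test_colocalization(72, 322, 0.09)
print(f"coloc {c.k}/{c.n} = {c.percentage:.1f}% vs {c.p0:.0%}: p = {c.p:.2g}")

# two-factor binding landscape on the default 8,441-locus grid
t = sim.simulate_tiling(sim.TilingSimConfig(seed=8))
ta = chip.call_track(t.probes["A"])
tb = chip.call_track(t.probes["B"])
print(chip.coincidence(ta, tb).to_string(index=False))
```

prints

```
group    n  zone1_pct  zone2_pct  zone3_pct       chi2            p
   G1  979  51.276813  29.724208  18.998979 158.735444 3.396536e-35
    S 1021  47.796278  32.419197  19.784525 120.554358 6.636723e-27
coloc 72/322 = 22.4% vs 9%: p = 5.5e-13
chrom  detectable_loci  a_positive  coincident  a_positive_pct  coincident_pct
 chr3             1322         314         218              24              69
 chr4             4857        1163         840              24              72
 chr5             1849         454         317              25              70
chr6R              413         100          71              24              71
total             8441        2031        1446              24              71
```

Reading it: both cell-cycle stages show ~49% of spots in the outermost
zone against the 33% random line, and the χ² p-values reject uniformity
decisively. A 22.4% pore-overlap rate in 322 cells is far above the 9%
random expectation. On the simulated arrays, 24% of detectable loci are
called bound for factor A, of which 71% are also bound by factor B —
slightly below the planted 76% because ~2% of the called loci are false
positives that rarely coincide (the attenuation arithmetic is in
`docs/methods.md`).

There is also a CLI mirroring these steps (`nucorg simulate-spots`,
`zone-score`, `coloc-test`, `call-binding`, `clusters`, `coincidence`,
`subtelomere`, `context`, `diff-expr`, `overlap`, `top-table`, and
`nucorg run` for the end-to-end seeded demo; `--help` on any of them).

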