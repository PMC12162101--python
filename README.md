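# tmskit

A benchmarking toolkit for **targeted methylation sequencing (TMS)** —
hybrid-capture enrichment of CpG sites combined with enzymatic methyl
conversion — and its comparison against the other common ways of
measuring DNA methylation (methylation microarrays, RRBS, WGBS).

It is written for groups evaluating or optimizing a capture-based
methylation assay: it answers how much of the sequencing lands on
target, which CpG sites survive coverage filtering, what statistical
power a given coverage/sample-size budget buys, how well two
technologies agree on the same samples, and which sites are
differentially methylated between tissues.

## What it computes

- **Capture efficiency** (`tmskit.capture`): probe targets as 0-based
  half-open intervals expanded by a flank (default ±200 bp) and merged;
  on-target classification of CpG sites and sequenced fragments by gap
  tolerance; per-base target depth; expected-CpG counts of a probe set
  against any genome; CpG island shore (±2 kb) / shelf (2–4 kb)
  derivation.
- **Count matrices** (`tmskit.matrix`): assembly of per-sample cytosine
  reports into sites × samples matrices of (methylated, unmethylated)
  counts, the standard "coverage ≥ 5× in ≥ 75 % of samples" filter with
  explicit comparators, methylation levels m = M/(M+U), and
  per-annotation summaries.
- **Power simulation** (`tmskit.power`): resample an empirical coverage
  distribution, draw methylated counts under a two-group effect
  M_i ~ Binomial(c_i, p0 + δ·g_i), test each site with a binomial-GLM
  likelihood-ratio test, and report power across sample sizes
  n ∈ {100, 200, 400}, effect sizes δ ∈ [0, 0.20], and coverage
  multipliers k ∈ {1, 2, 4} at a nominal p < 0.001.
- **Concordance** (`tmskit.concordance`): OLS fits of per-site average
  methylation between technologies; microarray beta values
  β = M/(M+U+offset), whose offset makes β = 1 impossible and flattens
  the regression slope; matched-vs-permuted per-sample R² with a
  derangement null and a Welch t comparison.
- **Differential methylation** (`tmskit.differential`): per-site
  beta-binomial regression of a focal tissue against all others,
  logit(μ) = b0 + b1·focal with shared overdispersion ρ, LRT p-values,
  z = b1/se(b1), Benjamini–Hochberg FDR, and Fisher-exact overlap
  enrichment (log2 odds ratio) between significant-site sets.
- **QC** (`tmskit.qc`): conversion efficiency from CHH-context
  methylation (mammalian CHH is essentially unmethylated, so observed
  CHH methylation ≈ conversion failure), assembly N50/N90, and
  subsampling coverage curves.
- **Synthetic data** (`tmskit.simulate`): generates every input with
  known ground truth — reference + probes, bimodal beta-mixture
  methylomes with negative-binomial coverage, on/off-target fragment
  mixtures, array betas with offset, and in-silico MspI (C^CGG)
  digestion with 180–2000 bp size selection.

## Worked example

```python
import numpy as np
from tmskit import simulate, capture, matrix, power

# a 100 kb reference with ~2% CpG density and 120 bp probes
ref = simulate.gen_reference(chrom_length=100_000, cpg_rate=0.02, seed=1)

# hybrid-capture fragments: 78.5% placed on target
frags = simulate.gen_fragments(ref.probes, 20_000, on_target_prob=0.785,
                               genome_extent={"chr1": 100_000}, seed=1)
mask, summ = capture.proximity_mask(frags, ref.probes.intervals, tol=200)
print(f"on-target: {100 * summ.fraction_on_target:.1f}%")

# power at 20x coverage, delta = 10%, n = 100 vs 400
pool = power.CoveragePool.negbin(mean=20, seed=1)
cfg = power.PowerConfig(sample_sizes=(100, 400), deltas=(0.10,),
                        multipliers=(1,), seed=1)
print(power.estimate_power(cfg, pool)[["n", "delta", "k", "power"]])
```

prints

```
on-target: 78.3%
     n  delta  k  power
0  100    0.1  1  0.866
1  400    0.1  1  1.000
```

i.e., 78.3 % of the 20 000 simulated fragments fall within 200 bp of a
probe (the generator's mixture uses 78.5 %), and a 10 % methylation
difference at ~20× coverage is detected at p < 0.001 for 86.6 % of
sites with 100 samples but essentially always with 400.

A command-line interface mirrors the library
(`tmskit simulate | capture-qc | filter | qc | nx | power | concord |
diff-tissue`); run `tmskit --help`.

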