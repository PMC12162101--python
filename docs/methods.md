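# Methods

This note documents the models, conventions, and numerical choices
behind tmskit, and what the synthetic-data generators do and do not
emulate.

## Coordinates and site keys

BED intervals are 0-based half-open; cytosine reports are 1-based.
Every internal CpG site key is the 0-based position of the plus-strand
C of the CG dinucleotide. Because CpG methylation is palindromically
symmetric, `io.collapse_strands` folds a minus-strand record at 1-based
position p onto the plus-strand C at p−1 and sums the two strands'
counts; a flag preserves per-strand records for CHH-based QC. This is
the single point where the conversion happens. Chromosome names are
matched by exact string equality; `io.normalize_chrom` can strip a
`chr` prefix but nothing calls it implicitly.

"Within t bp" always means *gap* ≤ t, where the gap between two
half-open intervals is the number of integer positions strictly between
them and overlap (or adjacency) gives gap 0. A point site is a length-1
interval. The same predicate serves site-on-target (t = 200),
fragment-on-target (t = 200), and probe-covered-by-fragments (t = 0).

## Filtering

A site passes the coverage/missingness filter when the fraction of
samples with coverage ≥ min_cov is ≥ min_frac (defaults 5 and 0.75).
Whether published ">5×" thresholds mean ≥ or > is often ambiguous, so
both comparators are explicit configuration (`cov_cmp`, `frac_cmp`),
inclusive by default; the brute-force equivalence tests cover all four
combinations. Matrices are assembled by the union of sites with (0, 0)
fill so that missingness is observable rather than silently dropped.
"Variable" sites have mean (or, for differential testing, median)
methylation strictly between 10 % and 90 %; the published phrasing
"median methylation <90% or >10%" is read as the intended conjunction.

## Power simulation

Per grid cell (n, δ, k), each of `n_sites` (default 1000) simulated
sites draws per-sample coverages i.i.d. with replacement from the
empirical pool, multiplies them by k (k = 2, 4 emulates 2×/4× deeper
sequencing of the same library complexity), assigns a balanced binary
group label, and draws M_i ~ Binomial(c_i, p0 + δ·g_i). The default
baseline is symmetric, p0 = 0.5 − δ/2, so both groups straddle 50 %
methylation and cells are comparable across δ; a fixed p0 is available.
Power is the fraction of testable sites with p < a_sig (default 0.001).
Sites where a whole group has zero coverage are excluded from the
denominator and counted separately (they essentially never occur at the
default pool).

The per-site test is a binomial-GLM likelihood-ratio test. For a single
binary predictor the GLM maximum likelihood is attained at the
group-pooled proportions, so the deviance is computed in closed form,

D = 2·[ℓ(p̂₁, p̂₀) − ℓ(p̂)],  ℓ from x·log(p) terms with 0·log 0 = 0,

vectorized across sites and immune to complete separation. A pooled
two-sided Fisher exact test is the alternative (`test="pooled-fisher"`);
the two agree in rejection decision on ≥ 95 % of moderate-coverage
sites. Coverage base draws are shared across multipliers within a
(n, δ) cell so the k-contrast is paired rather than independent.

Problem sizes in the tests (20 000 null sites for calibration, 5 000
per cell for monotonicity) were chosen to make the Monte Carlo standard
error small relative to the assertions; the monotonicity checks allow
2·SE slack.

## Concordance and the array offset

Methylation levels are compared by simple y-on-x OLS (comparison
technology on x), with R² = 1 − SS_res/SS_tot; degenerate fits (n < 3
or zero variance) are reported as undefined rather than raised.
Microarray betas are modeled as β = S_m/(S_m + S_u + offset) with
intensities proportional to the methylation fraction (scale 1000) plus
truncated Gaussian noise. The offset (default 100, the conventional
value; configurable) makes β = 1 unattainable, flattens the global
slope below 1, and — because the hypermethylated mode has little
true variance — depresses the hypermethylated-subset R² relative to
all sites. These are the structural biases the concordance module is
designed to expose.

The matched-vs-permuted analysis computes one R² per sample pair over
mutually observed shared sites, then repeats it after replacing the
pairing with a seeded *derangement* (a permutation with no fixed
points). Allowing fixed points would only dilute the contrast; the
derangement makes every permuted pair a genuine mismatch. The two R²
distributions are compared with a Welch t test, with explicit handling
of zero-variance degeneracies.

## Beta-binomial differential testing

Counts at a variable site are modeled as
M_i ~ BetaBinomial(c_i, μ_i, ρ) with logit(μ_i) = b0 + b1·focal_i and a
single ρ (the intra-class correlation of the latent per-sample
methylation proportion) shared across arms. Parameters are estimated by
L-BFGS-B on (b0, b1, logit ρ) with bounds (|b| ≤ 20, logit ρ ∈
[−18, 5]), started from empirical arm proportions (with a ½-count
shrink) and ρ = 0.02. Below ρ = 1e−8 the likelihood switches to its
binomial limit; if the optimizer ends on the ρ floor, the closed-form
binomial solution is taken when it has higher likelihood, so the LRT
never suffers from a boundary artifact. The p-value is the chi-square
(1 df) upper tail of the LRT against b1 = 0; the standardized effect is
z = b1/se(b1) with the standard error from a central finite-difference
observed information (step 1e−4). Non-converged sites are excluded and
flagged, never silently dropped. q-values are Benjamini–Hochberg
(step-up), NaNs propagating.

Overlap of significant-site sets is summarized by a 2×2 Fisher exact
test; the odds-ratio point estimate and Wald CI apply the Haldane +0.5
correction only when a cell is zero, while the exact p always comes
from the uncorrected table.

## Synthetic data: what it emulates, what it does not

`gen_reference` plants CG dinucleotides at the requested density into a
CG-free background (so the CpG list is exactly the CG occurrences) and
anchors 120 bp probes on a 10 % subsample of CpGs. `simulate_truth`
draws baseline methylation from a two-component beta mixture (defaults
w = 0.5, Beta(1,10), Beta(10,1)), reproducing the bimodal genome-wide
profile of real methylomes; group effects add δ at eligible sites.
Counts use negative-binomial coverage (mean 20, size 5 — the ~20×
regime of a 96-plex capture run), optional between-sample
overdispersion (latent Beta with ICC ρ, default 0.02), and a
conversion-error floor e (default 0.5 %): M ~ Binomial(c,
π(1−e_inv) + (1−π)e). CHH rows are emitted with methylation probability
e, so CHH-based QC recovers the planted conversion error.

Fragment generation places a fragment entirely within ±200 bp of a
uniformly chosen probe with probability `on_target_prob` (default
0.785, the on-target regime of an optimized capture at 65 °C
annealing); off-target fragments are uniform over the genome,
*re-drawn* if they happen to land within the tolerance of a probe, so
the realized on-target count is exactly Binomial(n, p) — this makes the
generator's advertised rate the estimand rather than a lower bound.

The MspI digest cuts at C^CGG inside every (possibly overlapping) motif
occurrence and retains 180–2000 bp fragments; covered CpGs are all CGs
on retained fragments. Read-end geometry within a fragment is *not*
modeled — coverage of a retained fragment is all-or-nothing, which is
sufficient to reproduce RRBS's CpG-dense site selection but not its 3'
falloff.

For tissue-specific effects, `gen_tissue_matrix` draws baseline
proportions from Beta(2, 2) — tissue-specific differentially methylated
sites live at intermediate methylation, and the variable-site mask
would discard extreme baselines — and shifts the focal tissue by a
logit-scale effect (default 2) at planted sites, with six tissues × 16
samples mirroring a multi-tissue macaque design.

None of the generators model alignment, read-level sequencing error,
mappability, site-to-site coverage correlation, or SNP-induced
artifacts. Passing tests therefore demonstrate the statistical
machinery under the stated noise model, not robustness to those
real-data pathologies.

## Other numerical conventions

- Nx: descending sort, first length whose cumulative sum reaches
  ≥ x·total — the standard convention; the value is always an element
  of the input.
- Matrix thinning is read-level (Binomial coverage, hypergeometric
  methylated split), not scaling, so thinned matrices remain valid.
- Shore/shelf derivation applies island > shore > shelf precedence and
  merges collisions between neighboring islands; everything clips at 0.
- Expected-CpG counting merges expanded regions first (each CG counted
  once) and counts a boundary-straddling CG iff its C is inside, the
  same key convention as everywhere else.
- All generators accept explicit integer seeds and are reproducible
  byte-for-byte; grid simulations derive per-cell seeds from the master
  seed via `numpy.random.SeedSequence`.
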