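# Methods

## The model

A nucleus is represented by `n_chains` identical block-copolymer chains
confined to a hard sphere. Each chain is a bead-spring polymer in which one
bead stands for a fixed stretch of chromatin (default 5 kb) and carries one
of three class labels: euchromatic **A** domains, heterochromatic **B**
domains (default 1.5 Mb each, strictly alternating) and telomeric **TEL**
caps (default 1 Mb) at both ends. The default 20-Mb chain therefore holds
six A domains, six B domains and two telomeres: 4,000 beads.

The force field (energies in kT, lengths in bead diameters sigma):

* harmonic backbone bonds, `U = k/2 (r - r0)^2` with `k = 100`, `r0 = 1`;
* purely repulsive Weeks–Chandler–Andersen core between all bead pairs
  (epsilon = 1, cutoff 2^(1/6) sigma), bonded neighbors excluded;
* a like-type attractive Lennard-Jones tail of depth `E_AA` (A–A pairs) or
  `E_BB` (B–B pairs), acting within and across chains, truncated at
  2.5 sigma; A–B and all TEL pairs interact by excluded volume only;
* discrete bending energy `K_theta(i) (1 + cos theta_i)` at each interior
  bead, with the modulus set by the bead's domain class; TEL beads always
  use the baseline `K_theta_base = 1 kT`. The stiffness presets are
  expressed as multiples of that baseline: the untreated ("DMSO") preset is
  uniform `K_A = K_B = 1`; the HDAC-inhibited ("TSA") preset is
  `K_A = 18`, `K_B = 3` (ratio 6), leaving the attractions untouched;
* a hard, reflecting confinement sphere whose radius sets the bead volume
  fraction: `R = (N sigma^3 / (8 phi))^(1/3)`, default `phi = 0.10`.

Dynamics are overdamped Langevin (kT = 1, gamma = 1, default
`dt = 0.005 tau`), integrated with Euler–Maruyama; the deterministic force
displacement is capped at 0.15 sigma per step for stability while the
thermal noise is never clipped (clipping noise would cool the system). The
first half of every run is discarded as equilibration. Initial conformations
are confined self-avoiding random walks grown bead by bead with rejection
and single-bead backtracking. Every stochastic element is driven by an
explicit integer seed; a (configuration, seed) pair reproduces bit-identical
trajectories.

### Default attraction energies

The attraction well depths are free parameters normally obtained by fitting
the untreated condition (`fit_attraction`). The package defaults,
`E_AA = 0.8`, `E_BB = 0.7` kT, were chosen once from pilot desk-scale runs
as a mildly asymmetric pair that gives clear untreated compartmentalization
with the A–A enrichment dominating — the signature of the pluripotent-like
chromatin state the untreated preset represents. Fitted values on real data
are expected to differ; reproducing any particular absolute energy is a
non-goal.

### Two-stage calibration

`fit_attraction` fits `(E_AA, E_BB)` on a single-chain system against a
target cis compartment strength; `fit_stiffness` then fits `(K_A, K_B)` on
the multichain system against a target median trans-contact ratio, keeping
the attractions fixed. Both are exhaustive grid searches returning the full
objective table; ties break toward the smaller parameter sum, then
lexicographically, and an argmin on the grid edge is flagged
(`"grid boundary"`).

## Model observables

Contacts are geometric: two beads are in contact in a stored conformation
when their distance is below `r_contact` (default 2.5 sigma, matching the
attraction cutoff). Per chain, the **trans-contact ratio** is
T/(T+C) — inter-chain over total contacts; chains with no contacts report a
missing value rather than zero.

**Compartment strength** of a simulated map is (AA x BB)/AB^2 over per-class
O/E enrichments. Each enrichment is a ratio of sums — summed observed over
summed expected counts — where the cis expectation is the mean contact count
at each intra-chain bin separation pooled over chains, and the trans
expectation is the mean inter-chain pixel. Ratio-of-sums was chosen over the
mean of per-pixel ratios because desk-scale maps are sparse at long range
and the per-pixel ratio estimator is unstable there (a symmetric-parameter
control shows it can report a large spurious A/B asymmetry). By default all
cis separations contribute; `min_sep_bins` restricts the score to
inter-domain contacts when within-domain pairs carry no class contrast by
construction (as in the planted-checkerboard closed form). Telomeric beads
are excluded throughout.

**Radial positioning** is the distance to the confinement boundary,
`d = R - |x|`, per bead class; uniformly distributed beads give mean d = R/4.

## Contact-map analysis

Experimental-style maps live in a `ContactMap` with 0-based half-open bins,
upper-triangle sparse counts and per-bin balancing weights (NaN = masked;
masked bins propagate as missing, never zero). Balancing is iterative
correction to uniform marginals with the bottom 2% of covered bins masked.
The cis expected is the per-diagonal mean of the balanced matrix pooled over
chromosomes; trans expected is the global trans mean; O/E divides by these.
Compartment tracks are the leading eigenvector of the per-chromosome O/E
correlation matrix, sign-fixed against an orientation reference
(the planted track for synthetic data; GC content or activity for real
data). Saddles average O/E between genome-wide quantile groups of a track
(default 10 groups at toy scale, 20% corner fraction);
strength = (AA x BB)/AB^2 over corner means. Note that ranking bins by an
eigenvector estimated from the same map selects on noise and inflates the
corners; where an unbiased strength matters the track should come from an
independent replicate.

Depth matching thins every map to the minimum total cis count by an exact
without-replacement subsample (multivariate hypergeometric), so matched
totals are identical rather than merely equal in expectation.

## Loops and differential analysis

Loops are BEDPE records tagged with calling resolution and condition.
Multi-resolution deduplication merges records whose anchor midpoints both
fall within 20 kb (single-linkage, transitive) and keeps the finest
resolution. Classification follows anchor rules: CTCF (anchors within
±1 kb of a CTCF peak; both anchors by default, either-anchor behind a
flag), non-CTCF (no CTCF peak within ±2.5 kb of either anchor), and an
explicit `ambiguous` class for the 1–2.5 kb gap the two rules leave;
active/repressive states from histone-mark overlap at either anchor; TSS
loops within 2 kb; condition-unique H3K9me3 loops. Pile-ups average O/E
windows centered on loop pixels (out-of-bounds loops are skipped and
counted); the loop score is the mean of the central 3x3 pixels, and two
conditions are compared by a paired two-tailed t-test across those nine
values (zero-variance differences return p = 1 with a degenerate flag).

Differential looping sums raw counts over each loop's anchor-bin block per
replicate and tests the two-group contrast with a negative-binomial Wald
statistic: median-of-ratios size factors (an external size-factor vector,
e.g. depth-matched map totals, can be supplied — with few loops and an
asymmetric change the loop table itself is a biased reference);
method-of-moments dispersions shrunk 50/50 toward a fitted `a0 + a1/mu`
trend and floored at half the trend (per-loop under-dispersion with 2–3
replicates is noise and would make the tail anti-conservative); delta-method
standard error of the log2 ratio of condition means; normal reference;
Benjamini–Hochberg adjustment. Filters default to P_adj < 0.05,
|log2FC| > 0.5, baseMean >= 10; a preset with |FC| > 1.5 is available.
This is a deliberately minimal reimplementation of the standard NB-GLM
count framework — numerical parity with full GLM packages is a non-goal,
and a cross-check test verifies directional and approximate-magnitude
agreement with one on strong effects.

## Spike-in normalization

For samples carrying a fixed admixture of foreign-genome cells (default
8%), the downsampling factor is `dF_i = h_min / h_i` from per-sample target
(m) and spike-in (h) read counts, which equalizes effective spike-in depth;
a depth-corrected variant is available behind a flag. Thinning keeps each
unit with probability dF (seeded Bernoulli / binomial); after thinning,
target signal is proportional to m_i/h_i across samples in expectation.

## Synthetic data

The generator plants all ground truth: cis decay `P(s) ~ s^-alpha`
(default alpha = 1), a multiplicative checkerboard `1 + s sigma_i sigma_j`
(default s = 0.2) on a ±1 block track whose block signs are drawn at random
per chromosome (seeded) — with strictly alternating blocks the sign
autocorrelation at fixed separation is nonzero and the data-driven expected
would absorb part of the compartment signal — plus focal loops of
enrichment lambda applied as a flat 3x3-pixel plateau (so the pile-up
central score equals lambda in expectation; a Gaussian kernel is available),
and Poisson or negative-binomial replicate noise (default NB, phi = 0.05).
Toy genome: 4 chromosomes x 6 Mb at 20-kb bins. Annotations (CTCF/histone
peaks, TSSs) are placed at stated fractions of loop anchors so every loop
class downstream is non-empty. What the generator does **not** emulate:
read-level artifacts, mappability structure, TAD/insulation features,
trans-chromosomal translocations and distance-dependent noise — so green
tests certify the statistical machinery, not performance on any real
library's quirks.

## Problem sizes

All simulation-based checks run at desk scale, chosen once to keep the full
suite and the acceptance script practical on a single CPU: geometric
down-scaling of the chain by 1/10 or 1/20 (400- or 200-bead chains
preserving block proportions), 2–4 chains, 12,000–24,000 steps with samples
every 800 steps, and 2–3 seeds per condition (pooled counts for strength
estimates). Directional predictions (trans-ratio monotonicity in K_A, the
compartment-strength ordering swap, peripheral A displacement) are asserted
at that scale; absolute fitted values are not compared to any external
number. The full design (20 chains of 4,000 beads, 30 replicates) is
available through the same interfaces and the `--scale` flag.

Two generator subtleties matter when reading pile-up scores. Balancing
slightly deflates planted loop pixels because the footprint contributes to
its anchor bins' marginals; the default minimum anchor separation (15 bins)
keeps this below ~4% on the toy genome. And because planted loops multiply
the checkerboard, loop pixels carry a ±s compartment background whose mean
over a random loop draw fluctuates; quantitative lambda-recovery checks
therefore use a compartment-free (s = 0) truth.

## Known limitations

* Desk-scale chains shorten each domain to 30–60 beads while the stiffness
  presets keep persistence lengths of up to 18 sigma, so stiffened A
  domains are closer to rigid rods than at full scale; directional effects
  survive, but effect sizes are scale-dependent.
* Equilibration at desk scale is partial (runs are a few Rouse times of a
  single domain, far below the chain's global relaxation time); observables
  that depend on rare distal domain encounters have large seed-to-seed
  variance and are reported from pooled counts.
* The NB pipeline supports two-group designs only, with no covariates,
  independent filtering or LFC shrinkage.
* ICE balancing and O/E operate densely and are intended for toy-scale
  matrices (thousands of bins), not genome-wide high-resolution data.
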