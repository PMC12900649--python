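# stiffchrom

Tools for studying how a compartment-specific change in chromatin fiber
stiffness reshapes 3D genome folding, aimed at chromosome-conformation and
polymer-modeling researchers.

Histone hyperacetylation (for example after a pulse of the HDAC inhibitor
trichostatin A) increases interchromosomal contacts and weakens A–A
compartment interactions in cis. `stiffchrom` implements the mechanistic
model behind that observation — a confined multichain block-copolymer
nucleus in which A and B chromatin domains carry like-type attraction
energies (E_AA, E_BB) and domain-specific bending moduli (K_θ^A, K_θ^B) —
together with the contact-map statistics needed to compare model and data:

* **Nucleus model** — 20-Mb chains of 5-kb beads with alternating 1.5-Mb
  A/B domains and 1-Mb telomeres, 20 chains per nucleus; overdamped
  Langevin dynamics with WCA excluded volume, like-type LJ attraction,
  discrete bending energy K_θ(1 + cos θ) and a reflecting confinement
  sphere. Stiffness presets: uniform baseline ("dmso") and
  K_θ^A = 18, K_θ^B = 3 ("tsa").
* **Model observables** — per-chain trans-contact ratio T/(T+C),
  compartment strength (AA·BB)/AB² from O/E block enrichments, radial
  positioning relative to the confinement boundary, and grid-search fits of
  (E_AA, E_BB) against compartment strength and (K_A, K_B) against the
  median trans ratio.
* **Contact-map stack** — ICE balancing, distance-decay expected and O/E,
  per-chromosome eigenvector compartments, saddle profiles and corner
  strength, exact cis-depth matching, loop deduplication/classification,
  O/E pile-ups with central-3×3 scoring and paired t-tests, a
  negative-binomial Wald test for differential loops (BH-corrected), and
  spike-in downsampling factors dF = h_min/h_i with seeded thinning.
* **Synthetic data** — contact maps with planted decay exponent,
  checkerboard compartment amplitude, focal loop enrichments and
  Poisson/NB replicate noise, plus peak/TSS annotations and spike-in count
  tables, all reproducible from (config, seed) with a JSON truth sidecar.

See `docs/methods.md` for the model, estimators and default parameters.

## Worked example

Run the full synthetic contact-map workflow (two conditions × five
replicates at 6×10⁷ contacts, 60 planted loops of which 30% double their
strength in the second condition):

```sh
stiffchrom run-maps --outdir demo --seed 7
```

which prints (abridged):

```json
{
 "n_loops": 60,
 "n_called": 17,
 "sensitivity": 0.889,
 "fdr": 0.059,
 "saddle": [
  {"condition": "condA", "scope": "cis", "strength": 2.265},
  {"condition": "condB", "scope": "cis", "strength": 2.258}
 ],
 "pileups": [
  {"class": "CTCF", "n_loops": 30,
   "score_condA": 2.843, "score_condB": 3.634,
   "t": -25.59, "p": 5.84e-09},
  {"class": "non-CTCF", "n_loops": 27,
   "score_condA": 2.911, "score_condB": 3.670,
   "t": -33.81, "p": 6.39e-10}
 ]
}
```

Reading the numbers: the saddle strength ≈ 2.26 in both conditions recovers
the planted checkerboard amplitude s = 0.2 (closed form
((1+s)/(1−s))² = 2.25); the NB Wald test with the default thresholds
(P_adj < 0.05, |log2FC| > 0.5, baseMean ≥ 10) recalls 88.9% of the planted
differential loops at an observed false-discovery proportion of 5.9%; and
the pile-up central-3×3 scores rise from ≈2.9 to ≈3.6 in the perturbed
condition, a shift the paired t-test on the nine central pixels calls
highly significant for both CTCF and non-CTCF loop classes.

The polymer side is driven the same way:

```sh
stiffchrom simulate --preset tsa --scale 0.1 --n-chains 2 \
    --steps 16000 --seed 3 --out traj.tsv
stiffchrom run-model --outdir model_demo --seed 1 --scale 0.1
```

`run-model` chains the two-stage calibration (attraction fit on a single
chain, stiffness fit on the multichain system) and reports the
trans-contact ratio, cis A–A/B–B strengths and radial positions under both
stiffness presets, including whether the A–A/B–B ordering swapped.

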