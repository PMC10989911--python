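# Methods

## Model and assumptions

`panfactor` treats the pangenome coverage profile of one species across S
metagenomic samples as a nonnegative matrix **D** (gene families × samples,
RPKM) generated by K coexisting strains: `D ≈ P·S` with binary gene-content
profiles **P** and nonnegative per-sample strain loadings whose normalized
columns are the strain composition **S**. The model assumes

- the same strains are shared across samples while their proportions vary
  (the variation across samples is what makes the factorization
  identifiable — single-sample data can only support one strain);
- strains differ in accessory gene content (profiles that differ only by
  SNVs are invisible to the method);
- coverage of a present gene family is proportional to its strain's
  abundance, after RPKM normalization.

## Pipeline

1. **RPKM normalization** (optional, when raw counts are given):
   `rpkm = count · 1e9 / (gene_length_bp · library_size)`.
2. **Trim and filter.** Entries below the RPKM cutoff (default 10) are
   treated as mapping noise and set to 0; samples detecting fewer than
   0.9 · g_min gene families are discarded (g_min = minimum per-genome
   gene-family count in the reference pangenome); families left with no
   signal in any surviving sample are removed. Both thresholds are strict
   ("below"), so a value exactly at the threshold survives. Order of
   operations: trim → drop samples → drop empty families; family emptiness
   is re-evaluated on the surviving samples because a family supported only
   by a discarded sample carries no usable information.
3. **Sparse NMF.** Minimize
   `1/2 (‖D − P′S′‖_F² + η‖P′‖_F² + β Σ_j ‖S′_·j‖₁²)` over nonnegative
   factors by alternating nonnegative least squares; each subproblem is
   solved exactly with block principal pivoting on the normal equations, so
   the objective is monotone non-increasing and the best of `n_restarts`
   seeded runs is kept. Only the content factor is randomly initialized
   (uniform, scaled to the data magnitude); the composition factor comes
   from its exact first update, which makes every step equivariant under
   sample permutation.
4. **Binarization.** For each strain column, a Gaussian KDE (Silverman
   bandwidth, 512-point grid on [0, max]) of the strictly positive weights
   is scanned for local maxima. `p_max` is the peak whose right-tail element
   count matches the expected per-genome gene count `g_expected` most
   closely *from below* (ties → larger location; if every peak's tail is
   larger, the smallest tail wins). Presence is `weight ≥ θ` with
   `θ = 0.5·p_max`; the confidence score is 1 for called families and
   `(θ − w)/θ` otherwise.
5. **Composition.** Because the model's content matrix is binary, the
   composition is re-estimated by NNLS of D against the binarized profiles
   and then column-normalized to relative abundances.
6. **Rank selection.** Candidate ranks (default 1–12, capped by the matrix
   dimensions) are each fitted and scored against three plausibility
   criteria: every strain's mean relative abundance > τ₂ (0.1), every
   strain's called profile > τ₃·g_min (0.5·g_min) families, every strain
   pair's Jaccard distance > τ₁ (0.1). The selected rank is the **largest**
   candidate passing all three. Rank 1 passes vacuously, so "fewest strains
   satisfying the criteria" cannot be meant literally; the criteria act as
   rejectors of over-split solutions and, empirically, every rank above the
   true one produces a near-duplicate or near-empty strain that fails them.
   A user-supplied rank bypasses selection. Strains are reported in
   decreasing mean-abundance order.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `rpkm_cutoff` | 10 RPKM | mapping-noise floor; entries below are zeroed |
| `sample_min_fraction` | 0.9 | sample kept if ≥ 0.9·g_min families detected |
| `sparsity_weight` β | 0.01 | squared-L1 penalty on composition columns (dimensionless) |
| `smoothness_weight` η | (1e-4·max D)² | ridge pinning the content-factor scale |
| `max_iter`, `tol` | 2000, 1e-6 | ANLS stop: relative objective change |
| `n_restarts`, `seed` | 3, 1 | restarts; all randomness is seeded |
| `rank_min..rank_max` | 1..12 | candidate strain numbers |
| τ₁, τ₂, τ₃ | 0.1, 0.1, 0.5 | rank-rejection thresholds (see above) |
| `theta_fraction` | 0.5 | presence threshold as a fraction of p_max |

## Numerical choices

- **Ridge strength.** The conventional `max(D)²` ridge of the sparse-NMF
  literature assumes data of order one; on RPKM-scale matrices it dominates
  the objective and biases the fit (≈9 % reconstruction error on noiseless
  rank-4 input). The ridge's only essential role here is breaking the
  diagonal scale degeneracy between P′ and S′, so the default is the weak
  `(1e-4·max D)²`; the strong value remains available via the parameter.
- **Peak selection from below.** The nearest-peak rule (minimize
  |right-tail − expected| over all peaks) fails when the data matrix is
  dominated by the strains' union: the absent-mode peak near zero then
  carries the whole present cluster in its right tail and its count sits
  closest to `g_expected`, which would call essentially everything present.
  Matching from below always lands on the present-gene mode and reduces to
  the same answer whenever the profile is cleanly bimodal.
- **Composition refit.** An NMF factorization is only identified up to a
  positive diagonal (and, with overlapping profiles, a residual admixture
  freedom that the sparsity penalty mildly favours). Normalizing raw S′
  columns therefore distorts abundances even for exact factorizations.
  Refitting S against the binarized P removes both ambiguities; on
  noiseless and Poisson benchmarks it brings per-sample composition JSD
  from up to ~0.1 down to ~1e-5.
- **Degenerate inputs.** Weight columns with < 10 positive values or no
  spread fall back to `θ = 0.5·max` with a warning. Singular NNLS systems
  (duplicate or empty strain profiles at over-split ranks) are re-solved
  with a 1e-10 diagonal ridge. MCC returns 0 for a vanishing denominator.
  Ties in strain matching are broken toward the lowest predicted index, in
  nearest-reference annotation toward the lexicographically smallest genome
  ID (all ties reported).
- **JSD convention.** Base-2 logarithms make [0, 1] exact. Vectors are
  sorted in decreasing order and zero-padded to equal length before
  scoring, so permutations of the same abundance profile score 0 — the
  metric compares abundance *profiles*, not labelled strains. Strains below
  1 % relative abundance are dropped and the rest rescaled before reported
  compositions are scored (`filter_composition`).
- **PR ranking.** The confidence score equals 1 both for confident
  presences and confident absences, so gene families are ranked by the
  signed score `+confidence` (called present) / `−confidence` (called
  absent), the only monotone reading of confidence-ranked presence
  predictions. Precision/recall are evaluated at every distinct score and
  the area is trapezoidal, anchored at (0, first precision).

## Synthetic benchmark generator

`simulate` reproduces the validation design of read-level strain-mixture
benchmarks at the matrix level:

- a synthetic pangenome of K strains: a shared core block
  (`core_fraction`, default 0.4) plus independent Bernoulli accessory
  content (`accessory_presence_prob` 0.5), rejection-sampled until all
  pairwise Jaccard distances reach `min_pairwise_jaccard` (0.25 —
  subspecies-scale separation; realized distances ≈ 0.35);
- Dirichlet(α = 1) compositions over 20 samples, rejection-sampled to a 5 %
  minimum frequency, so each sample totals 20 depth units and one unit
  (`depth_unit_rpkm` = 100) is the signal of a strain at 5 %; a fixed
  permutation design (e.g. 5/10/25/60 % → 24 samples) is also available;
- noise: `none`, `poisson` (default; count noise around the expected RPKM),
  or `poisson_lognormal` (per-family multiplicative efficiency, emulating
  sequencing/mapping bias), plus optional Poisson background counts on
  families absent from every strain (emulating cross-mapping of unrelated
  reads).

What the generator does **not** emulate: read-level error profiles, gene
length variation within families, correlated mapping noise between
homologous families, strain gene content drawn from real phylogenies, and
reference pangenomes much larger than the strains' union. Passing the
benchmarks therefore shows the decomposition machinery is correct under the
stated statistical stressors, not that real-data performance will match;
on real profiles the dominant difficulties are mapping artefacts and
pangenome incompleteness, which enter upstream of this package.

Benchmark problem sizes used by the test suite and `scripts/acceptance.py`
(3000 families × 20 samples for the four-strain benchmark; 400–800 families
for unit-level checks) are desk-scale choices that keep a full rank scan in
the low minutes while leaving each strain's accessory signal hundreds of
families strong.

## Known limitations

- Strains sharing nearly identical gene content (Jaccard distance below
  τ₁) are merged by design; SNV-level variation is out of scope.
- At least ~10 samples with genuinely varying composition are needed for a
  stable factorization; a single sample degenerates to one strain.
- The expected gene count calibration assumes the reference pangenome's
  genomes are representative of the strains in the samples; a pangenome
  whose genomes are systematically smaller or larger than the community's
  strains shifts the binarization threshold.
- Rank selection scans every candidate rank with multiple restarts, so
  runtime grows roughly linearly in `rank_max`.
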