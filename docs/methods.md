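# Methods

## The generative model

The simulator formalizes the mechanism under study: sequencing reads a
vanishingly small multinomial sample from a fixed amplicon library, so two
runs of the same library disagree only through random sampling, while two
libraries built with different indexed primers also differ systematically.

1. **Pool.** `n_target` taxa enter equimolar. Amplification multiplies each
   by a lognormal(0, `target_bias_sigma`) factor; the result is renormalized
   to carry `1 − rare_total_fraction` of the pool. `n_rare` non-target taxa
   share `rare_total_fraction` with Zipf-decaying proportions
   k^(−`rare_tail_shape`).
2. **Libraries.** For each indexed primer p, θ_{i,p} ∝ a_i · ε_{i,p} with
   ε lognormal(0, `primer_bias_sigma`), renormalized per primer. θ is drawn
   once per primer and never per run.
3. **Runs.** Sample (p, r) is multinomial(N_{p,r}, θ_{·,p}) with N drawn
   uniformly from `depth_range`. Within-primer, between-run variation is
   therefore pure resampling by construction.

At the FASTQ level each amplicon is `index + forward primer + template +
revcomp(reverse primer + index)`; templates are random codon sequences with
no in-frame stops under translation table 5, kept ≥ 20 substitutions apart
so sequencing-error variants cannot precluster across taxa. Base qualities
are a constant Phred score (idealized; errors are injected independently of
the written qualities).

### Parameters, defaults, and why

| parameter | default | rationale |
|---|---|---|
| `n_target`, `n_rare` | 34, 86 | the mock community's target and observed non-target OTU counts |
| `n_primers`, `n_runs` | 7, 2 | the replicate design (14 communities) |
| `depth_range` | 45,609–78,387 reads | the observed per-sample read-count range |
| `rare_total_fraction` | 0.003 | non-target taxa hold 0.3% of reads |
| `target_bias_sigma` | 1.5 (ln scale) | makes the 34 target proportions span 2–3 orders of magnitude, the observed regime of amplification bias |
| `rare_tail_shape` | 2.5 | one dominant non-target OTU (~80% of rare reads) and ~78/86 taxa under 10 reads at these depths, matching the observed tail |
| `primer_bias_sigma` | 0.15 (ln scale) | calibrated so rarefied within-primer Bray–Curtis sits at 0.008–0.016 and between-primer at ~0.04–0.15, with the primer factor's Bray–Curtis R² ≈ 0.98 — the observed regime. This is a calibration, not an estimate: no quantitative index-bias model is available to fit |

The first five are study conditions; the two sigmas are free parameters
chosen once against the published regime and not revisited.

### What the generator does not emulate

- The real rare tail is flatter below its dominant member than a single
  power law: the simulator consequently yields ~6–8 detected non-target
  OTUs per trial where the real data show 16 ± 4. Incidence-based
  dissimilarities are correspondingly somewhat smaller (within-primer
  Jaccard ~0.12 vs ~0.3), though their qualitative behavior (positive
  before filtering, exactly 0 at the 30-read sweep threshold) matches.
- No PCR-cycle branching process, chimeras, index hopping beyond the
  optional index-conflict injection, per-cycle error profiles, or numts.
- No run-specific systematic effect: the small but significant run term in
  real abundance data has no counterpart here (run R² ≈ 0.002).

Passing tests on simulated data therefore validate the statistical
machinery and the random-sampling mechanism, not the full error structure
of a sequencer.

## Analysis choices

- **Metrics.** Jaccard on presence (count > 0), Bray–Curtis on counts.
  Empty-vs-empty pairs are defined as dissimilarity 0 (with a warning)
  rather than NaN so post-filter matrices stay total.
- **Rarefaction** is a multivariate-hypergeometric draw (without
  replacement) to a common depth; the published protocol's five draws are
  reproduced with five seeds. Jackknife subsampling is likewise without
  replacement.
- **Sweep semantics.** "OTUs with fewer than τ reads" uses dataset-wide
  totals on the rarefied table (strict <, i.e. keep totals ≥ τ); per-run
  totals appear only in the detection-frequency records.
- **PERMANOVA.** McArdle–Anderson trace formulation on the Gower-centred
  −½D² matrix; sequential (type-I) sums of squares, which are
  order-independent for the balanced 7 × 2 design (a warning is emitted for
  unbalanced designs); each term is tested against the residual under free
  permutation of sample labels; p = (c + 1)/(m + 1) so p is never 0. A
  residual below 10⁻¹² of the total is treated as exactly 0 and the
  pseudo-F reported as +inf. `n_perm="exact"` enumerates all n!
  permutations for small n.
- **PCoA.** Eigendecomposition of the centred matrix; coordinates are
  eigenvectors × √eigenvalue for positive eigenvalues only; negative
  eigenvalues are reported unmodified (no Lingoes/Cailliez correction —
  the least-intervention default). OTU scores are abundance-weighted
  averages of sample coordinates (the common biplot convention, recorded in
  the output's metadata); zero-total OTUs are omitted with a warning.
- **UPGMA.** Size-weighted average linkage; node height = merge
  dissimilarity / 2; distance ties are broken by the lexicographically
  smallest pair of cluster member ids, making the tree input-order
  invariant. Jackknife support compares unrooted-style leaf bipartitions,
  ignoring heights.
- **Read QC.** Merging scans all ungapped overlaps ≥ 16 bases and keeps the
  fewest-mismatch (ties: longest) overlap; agreeing consensus bases take
  max(Qf, Qr), disagreeing bases the higher-quality call with quality
  |Qf − Qr|. With the simulator's constant qualities a disagreement gets
  quality 0 and usually trips the expected-error filter — a conservative
  consequence of the posterior approximation. Index bases must match
  exactly; primer degeneracies (including inosine) match their full IUPAC
  sets. Preclustering uses Hamming distance on equal-length sequences only;
  unequal lengths never merge. Frameshift detection by reference alignment
  is out of scope: the screen covers in-frame stop codons (table 5:
  TAA/TAG), plus a length-offset flag (`possible_frameshift`) when an
  expected amplicon length is supplied. Only merged-read expected errors
  are filtered.
- **Target annotation** is exact normalized string matching of reference
  identifiers against OTU ids and labels; unmatched and ambiguous
  identifiers are warned about, never silently dropped. Fuzzy taxonomic
  matching is out of scope.

## Problem sizes used in tests and the acceptance script

The test suite exercises the full study conditions (14 samples at
45,609–78,387 reads) wherever the claim concerns the data regime: the
type-I-error check runs 400 such simulations at 199 permutations; the
detection-probability check uses 2,000 draws at depth 20,000; the
threshold-sweep and PERMANOVA-contrast checks run on one full-size rarefied
table. FASTQ-level end-to-end tests use reduced depths (~100–150 reads per
sample), since the pure-Python merge scan is the pipeline's slow step and
the round-trip property is size-independent. `scripts/acceptance.py` uses
one full-size simulation with 9,999 PERMANOVA permutations and completes in
a few seconds.

## Known limitations

- The deposited contingency table of the original experiment is not
  redistributable here; the reproduction battery in
  `tests/test_acceptance.py` documents the published values and runs once
  the table and its metadata are placed under `data/`.
- PERMDISP/beta-dispersion, restricted permutation strata, NMDS, UniFrac
  and α-diversity estimators are not implemented.
- OTU clustering, chimera detection, denoising and taxonomy assignment are
  upstream of this package's scope; the pipeline starts from demultiplexed
  preclusters or a finished OTU table.
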