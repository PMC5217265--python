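# Methods

`pooledscan` implements a pooled-DNA case/control association workflow:
allelotyping of DNA pools from two-channel array intensities, a per-SNP
Welch t-test scan, an LD-block/index-SNP candidate-selection rule, and an
individual-genotyping validation stage — together with a synthetic cohort
generator so that the whole workflow can be exercised and calibrated without
any external genotype data.

## Pooled allelotyping model

A DNA pool combines equimolar DNA from `n` same-diagnosis individuals.  For
each SNP the array reports two channel intensities `A` and `B`, one per
allele; the relative allele signal

    RAS = A / (A + B)

estimates the pool's frequency of the A-channel allele.  Entries with
`A + B = 0` are flagged missing and excluded from testing (they are counted
in a per-SNP missingness tally; they never propagate as NaN).  Association
is tested per SNP by a two-sided Welch t-test comparing RAS across case
pools versus control pools, with Welch–Satterthwaite degrees of freedom.
Each pool-array is one observation; replicate-array variance is not modelled
separately.  P-values are Bonferroni-corrected with `m` equal to the number
of SNPs actually tested in that scan (skip-flagged SNPs are excluded from
`m` but kept in the output — no probe filtering).

Degenerate inputs: a SNP with fewer than two non-missing pools in either
group, or zero variance in both groups with equal means, is reported with
`p = 1` and a skip flag.  Zero variance with *unequal* means (impossible
once any noise is present) is reported as an exact separation, `t = ±inf`,
`p = 0`.

### Pool quality control

With pooled samples there is no per-sample call rate, so outlier pools are
identified in principal-component space: per pool set (each set is a
separate hybridisation), the pools × SNPs RAS matrix is column-centred,
scores on the first 4 PCs are computed by SVD, and each pool's Euclidean
distance from the coordinate-wise median of the scores is converted to a
robust z (distance recentred by its median and scaled by 1.4826·MAD).
Pools with `z > 3.5` (configurable) are removed.  This is a reproducible,
auditable surrogate for by-eye PC inspection; the threshold is exposed
because no numeric criterion for the manual procedure exists.  A
controls-only removal policy is available via `restrict_groups`.  Sets with
fewer than `n_components + 1` pools skip QC with a recorded warning.

## Block selection

The candidate-selection rule exploits the fact that a truly associated
common variant is usually accompanied by associated neighbours in linkage
disequilibrium, whereas isolated small-`p` SNPs at unassociated positions
are usually noise.  A **block** is a maximal run of at least 10 consecutive
panel SNPs, each with scan `p < 0.005`, in which every adjacent pair is
separated by less than 30 kb on the same chromosome.  From each block the
**index SNPs** — members with `p < 1e-4` — are carried to validation,
ranked by ascending p (ties broken by position).

Numeric strictness: "less than 30 kb" and both p-thresholds are strict
inequalities; "at least 10" is inclusive.  A non-qualifying SNP terminates
a run regardless of distance (contiguity over the tested panel); the
alternative reading — skip non-qualifying SNPs and chain by distance alone —
is available as `bridge=True` for sensitivity analysis.  An inclusive index
threshold (`p <= 1e-4`) and a per-block cap on index SNPs are flags, since
more than one index SNP per block is legal.  Input tracks must already be
sorted with strictly increasing positions; unsorted or duplicated input is
an error, never silently reordered.

Blocks are found independently per scan round (pool set) and the per-round
candidate sets are merged by SNP id, recording per-round provenance and
best p — the union count is `|r1| + |r2| − |r1 ∩ r2|`.

Under an LD-free null (uniform p-values, 5 kb spacing) the probability that
10 consecutive SNPs all reach p < 0.005 is ~0.005^10 per start, so a
10,000-SNP null track essentially never yields a block; this false-positive
suppression is verified by simulation in the test suite.

## Validation stage

Candidates are re-tested on individual genotypes with an *allelic* 2×2
table (each individual contributes two alleles; missing genotypes drop out
of both margins).  The allelic model is used because the reported odds
ratios are per minor allele.  Conventions:

* **Fisher exact test** — two-sided by the point-probability method: the sum
  of hypergeometric probabilities (margins fixed) not exceeding that of the
  observed table.  Implemented in exact integer arithmetic, so inclusion of
  tied tables is deterministic with no floating tolerance.  Degenerate
  margins give `p = 1`.
* **Odds ratio and CI** — `OR = ad/bc` with the Woolf (normal-approximation)
  interval `exp(log OR ± z · sqrt(1/a + 1/b + 1/c + 1/d))`.  Any zero cell
  triggers the Haldane–Anscombe +0.5 correction for the OR/CI only — never
  for the exact test.  An all-zero row or column leaves the OR undefined
  (NaN, flagged).
* **Tiers** — `corrected` when `p < 0.05/n_tests` (the per-disease
  Bonferroni family threshold; `n_tests` is always passed explicitly,
  never inferred from a filtered list length); otherwise `suggestive` when
  `p < 0.05` and `OR ≥ 1.2` or `≤ 0.83`; otherwise `not_validated`.  The OR
  boundary is inclusive because validated effect sizes sit exactly on 0.83
  in the reference table; `strict_or=True` restores strict inequalities.
* **Direction concordance** — a candidate is *validated* only if the sign of
  its pooled-scan frequency shift matches the side of 1 of its OR, after
  allele-orientation harmonisation.  Orientation must be supplied; when
  unknown the concordance is `None`, never silently assumed.
* **Minor allele** — defined in controls; reported MAF and OR refer to it.
  If the dosage allele exceeds 0.5 in controls, the table is allele-flipped
  (and the scan orientation flipped accordingly) before reporting.

Cross-disease accounting counts a SNP for a disease when its tier is
corrected or suggestive; shared SNPs split further by whether both ORs lie
on the same side of 1.  Note that recomputing the shared-direction count
from the packaged table's printed ORs gives 5 of 11 shared SNPs, which does
not match every statement made about that table in its source; the count is
therefore always recomputed and reported, never asserted against a fixed
number.

## Synthetic cohort generator

The generator defines the study conditions under which all calibration and
recovery results are obtained.

* **LD model** — the panel is split into consecutive blocks of
  `ld_block_length` SNPs (blocks never span chromosomes).  Per haplotype
  and block one uniform `u` is drawn; a SNP with MAF `p` copies the block
  tag `1{u < p}` with probability `ld_r` and otherwise draws an independent
  Bernoulli(p).  Marginal frequencies are exact; the allelic correlation
  between two equal-MAF SNPs of a block is ≈ `ld_r²` (both must copy), so
  `ld_r = 0.95` yields r ≈ 0.9.  This is a deliberately simple, seedable
  surrogate: the block-selection algorithm needs correlated p-value runs,
  not a realistic recombination map.  `ld_r = 0` takes a fully vectorised
  LD-free path.
* **Disease model** — a risk locus with per-allele odds ratio `OR` shifts
  the case minor-allele frequency to `p' = OR·p/(1 − p + OR·p)`
  (multiplicative allelic model, matching the allelic 2×2 OR used in
  validation).  Case haplotypes draw the risk allele at `p'` and the block
  uniform is drawn conditionally on it, so block neighbours inherit an
  attenuated (×`ld_r`) shift — the mechanism block detection depends on.
  At most one effect locus per LD block is supported (error otherwise).
* **Panel** — by default one MAF per LD block, drawn Uniform(0.05, 0.5):
  SNPs in strong LD necessarily have near-equal allele frequencies, so a
  shared draw is the realistic default (per-SNP draws are a flag).  SNPs
  are evenly spaced (default 5 kb) with 1-based positions; gaps are
  `pos[i+1] − pos[i]` bp.
* **Pooling** — within each pool set, each diagnosis group is shuffled
  (seeded) and pools filled in order; individuals not filling a complete
  pool are excluded from that set.  The same cohort is re-pooled in every
  set by default (`reuse_across_sets=False` gives disjoint sub-cohorts —
  both designs occur in practice and the reference design is ambiguous on
  controls).  A per-group pool-size override exists because real designs
  vary pool size between groups within a set.
* **Array noise** — the true pooled fraction `f = Σdosage/(2·pool size)` is
  perturbed by additive Gaussian noise truncated to [0, 1], default
  `noise_sd = 0.02`.  No published quantification of pooled-array noise
  exists for this workflow; 0.02 makes a 40-allele pool's measurement error
  comparable to its sampling error, which is the regime where the two-set
  design is informative.  An optional per-pool, per-SNP additive shift
  plants systematic outliers for QC testing.
* **Determinism** — a single integer seed determines genotypes, pool
  membership, and noise (three independent streams derived from it);
  identical specs give byte-identical outputs.

What the generator does **not** emulate: realistic recombination/coalescent
structure, allele-frequency spectra, population stratification, platform
probe effects, or genotyping error in the validation stage.  Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated model, not performance on real arrays.

## Study-scale defaults and problem sizes

The packaged full-scale study (`paper_scale_spec`) uses 443 cases and 934
controls; pool set I has 21 case pools of 20 and 30 control pools of 24,
set II has 11 case pools and 10 control pools of 37 (leftover individuals
are excluded per set); a 10,000-SNP panel in 15-SNP blocks with
`ld_r = 0.95`; one seeded locus with OR 2.0 at MAF 0.2; noise sd 0.02.
Calibration suites use a 10,000-SNP LD-free null with 20+20 pools of 20 for
the type-I error of the scan, 1,000 simulated allelic tables (OR 1.5, MAF
0.3, 400/900) for CI coverage, and 50 full-pipeline replicates for the
end-to-end recovery rate.  These sizes give Monte-Carlo error well inside
the asserted bands while keeping a complete run in the low minutes on one
CPU.

## Known limitations

* The block criterion is operationalised purely by proximity +
  co-significance; no r² is computed from genotypes, and no genomic-control
  or mixed-model correction is applied (none is used in the reference
  workflow).
* The PCA-QC threshold is a surrogate for a manual judgement; its default
  (3.5) is a conventional robust-z cutoff, not a fitted value.
* The Woolf CI is a large-sample approximation; with very sparse cells the
  Haldane correction biases the OR toward the null.
* Validation reuses the simulated cohort's genotypes (as the underlying
  study genotyped the same patients it pooled), so discovery and validation
  are not independent samples; the corrected tier's calibration under the
  null is still guaranteed by the exact test.
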