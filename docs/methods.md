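# Methods

This note records the statistical models, estimator conventions and numerical
choices behind `weevilpop`, in the spirit of a methods supplement: what is
computed, under which assumptions, and where the genuinely open design
decisions fell.

## Genotype model

A panel is a complete individuals × loci grid of unordered diploid genotype
calls. A call is either a full allele pair or MISSING — half calls are not
representable, which keeps every downstream count unambiguous. SNP alleles
are single bases (registry = REF then ALTs from the VCF); SSR alleles are PCR
fragment lengths in base pairs, assumed already binned from electropherograms
(the integer-length model does not represent sequence-level SSR variation).
Optional per-call read depths support depth-gated filtering and are only
meaningful on called genotypes.

Supported formats: VCF 4.2 (GT + optional DP, via pysam), GenePop with
3-digit allele coding (2-digit files are rejected with a clear message rather
than guessed at), a simple CSV genotype table, a TSV population map and
Newick for phenograms. All sequence-facing coordinates in reports are 1-based
inclusive.

## Synthetic panels

The simulator is the package's substitute for the unpublished survey
genotypes: it generates panels whose generative parameters are known exactly,
so estimator recovery is checkable. Defaults mirror the survey design the
analysis assumes — 12 populations × 15 individuals, 220 SNP + 8 SSR.

* **Differentiation.** Balding–Nichols: ancestral frequency vector p per
  locus (uniform on the simplex; SSR allele counts configurable, default
  4–13 visible alleles), population vectors drawn from
  Dirichlet(p·(1−F_ST)/F_ST). F_ST = 0 short-circuits to the ancestral
  frequencies exactly. This is the simplest model with an interpretable
  F_ST knob; no demographic history is implied. Concentration parameters are
  floored at 1e-6 to avoid degenerate Dirichlet draws; this is numerically
  invisible at any realistic F_ST.
* **Inbreeding.** Genotypes are drawn from P(hom i) = pᵢ² + f·pᵢ(1−pᵢ),
  P(het ij) = 2pᵢpⱼ(1−f), so f is exactly the quantity Wright's F_is
  estimates. Negative f is accepted only while all genotype probabilities
  remain non-negative (otherwise an error — the model itself, not the
  implementation, breaks down there).
* **Null alleles** are inserted at the generative-frequency level: a null at
  frequency r joins the locus, visible frequencies are rescaled by (1−r),
  and genotypes are re-drawn under the same f. Visible/null is scored
  homozygous for the visible allele; null/null becomes MISSING. Modelling at
  the frequency level (rather than post-hoc relabelling) yields closed-form
  expectations — apparent visible frequency qᵢ/(1−r), called-genotype
  heterozygosity ((1−r)² − Σqᵢ²)/(1−r²) — used directly as test oracles.
* **Missingness** is independent per call at a fixed rate.
* **Determinism.** One `numpy` Generator per operation; panel overlays use
  sub-seeds derived from the config seed, so a config is a complete recipe
  and equal seeds give byte-identical panels.
* **SSR labels** are arithmetic progressions of fragment lengths (step =
  motif length), echoing real size ranges.
* **Sequence fixtures.** `make_contig_fixtures` plants perfect repeats in
  random backgrounds that are rejection-sampled against a brute-force regex
  repeat check, so the planted repeats are provably the only qualifying hits.
  What the simulator deliberately does **not** emulate: linkage between loci,
  mutation processes, stutter artefacts, allele dropout correlated with
  genotype, or non-equilibrium demography. Passing recovery tests therefore
  show estimator correctness under the stated model, not robustness to every
  real-data pathology.

## Marker discovery

* Filters follow the two-stage reading of the discovery protocol: per-call
  depth gating first (calls under the minimum depth become MISSING; skipped
  with a warning when no depths exist), then locus removal on minor-allele
  frequency and called-genotype count. Thresholds are strict where the
  protocol language is strict: MAF must be **>** 0.05 and call rate **>**
  the retention threshold, so values exactly at a boundary are removed.
  "Minor allele frequency" is the second most common allele's frequency
  (equal to 1 − major for biallelic loci). Filters are idempotent and their
  reports reconcile exactly (removed + retained = input).
* The SSR scanner reports maximal perfect tandem repeats of unit length 1–6
  under per-unit minimum repeat counts {1:10, 2:5, 3:5, 4:4, 5:4, 6:4}
  (configurable; the defaults are the smallest motifs a real panel of this
  kind contains). A repeat is reported under its leftmost phase as found, not
  a lexicographic canonical rotation; runs wholly contained in a
  shorter-unit run are suppressed (a (T)12 tract is not also (TT)6). N never
  appears inside a hit.
* Primer screening uses inclusive windows (length 18–23 nt, product 100–280
  bp, Tm 54–60 °C, pair ΔTm ≤ 0.5 °C) and the GC-fraction approximation
  Tm = 64.9 + 41·(GC − 16.4)/length. Commercial design tools use proprietary
  nearest-neighbour parameters; this formula is a transparent, swappable
  strategy (`tm_model=` accepts any callable) and is **not** expected to
  reproduce annealing temperatures printed alongside published primers.
  Hairpin/dimer thermodynamics and imperfect or compound repeats are out of
  scope.

## Diversity statistics

* He = 1 − Σpᵢ², computed over called genotypes only. A small-sample
  2n/(2n−1) correction is available (`unbiased=True`) but **off by
  default**, and the choice is recorded in the run manifest — different
  legacy programs differ here and the discrepancy is within rounding for
  n ≈ 180.
* PIC is Botstein's 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ²; the identity PIC ≤ He is
  property-tested on random simplex draws.
* F_is = 1 − H_o/H_e, undefined at He = 0. Undefined statistics propagate as
  `None` and are excluded from every aggregation — never coerced to 0.
* **Population-level F_is is the unweighted mean of defined per-locus F_is
  values**, not 1 − mean(H_o)/mean(H_e). Published per-population tables of
  this kind are inconsistent with the ratio-of-means form, so per-locus
  averaging was adopted and is documented; exact reproduction of any
  particular published F_is column is not claimed.
* HWE: Monte-Carlo exact test pooling the 2n called alleles and re-pairing
  uniformly (default 10 000 permutations), statistic = heterozygote count,
  two-sided p = 2·min(tail fractions) with add-one smoothing, capped at 1.
  The heterozygote-count statistic is simpler than genotype-probability
  ordering and adequate for deficiency/excess screening; it is deterministic
  under a seed.
* LD r²: each locus collapsed to major-allele dosage (0/1/2) over
  individuals called at both loci; r² is the squared Pearson correlation.
  The collapse is the documented convention for multi-allelic SSRs, where no
  single standard exists. No multiple-testing correction is applied to HWE
  or LD screens (matching the workflow this package emulates); the manifest
  says so.

## Null alleles

Brookfield-1 estimates r = (He − Ho)/(1 + He), clamped at 0 on heterozygote
excess (excess is evidence of no nulls, not an error). Classification:
negligible r < 0.05 ≤ moderate < 0.20 ≤ large (boundaries closed exactly as
stated). Correction rescales visible frequencies by (1−r) and adds NULL at r;
adjusted heterozygosities re-express the observed values on the
all-individuals scale:

    He_adj = 1 − (1−r)²(1 − He_obs) − r²
    Ho_adj = Ho_obs·(1 − r²) + 2r(1 − r)

The Ho adjustment restores the visible×null heterozygotes mis-scored as
homozygotes and rescales for the null/null calls that dropped out as missing.
With the **true** r these formulas cancel identically (He_adj = Ho_adj for an
equilibrium population; proved algebraically and asserted to 1e-6 in tests);
under the Brookfield-1 **estimate** the correction is approximate, because
the estimator itself is biased low when nulls also hide in the apparent
frequencies. Accordingly the package's claim — and its acceptance test — is
comparative bias reduction (median |adjusted F_is| under half the raw
median), not exact recovery. He/Ho inputs are computed over called genotypes
only; blank-handling conventions of legacy programs are not independently
verifiable, and this choice is recorded in output metadata. NAF is estimated
per scope: globally for per-marker tables, per population for the adjusted
F_is column.

## Structure

* Nei's standard genetic distance uses the classical ratio of locus-averaged
  J terms (J_x, J_y, J_xy averaged over loci first, then
  I = J_xy/√(J_x J_y), D = −ln I) — not a per-locus average of identities.
  Loci with no called data in either population of a pair are dropped
  pairwise. I = 0 yields an infinite-distance flag; before UPGMA, infinities
  are replaced by 1 + the largest finite distance (with a warning), which
  preserves the "farthest" ranking that average-linkage clustering consumes.
  D is not a metric; no triangle inequality is asserted.
* UPGMA: size-weighted average linkage, merge height = distance/2, ties
  broken by smallest (row, column) label order so trees are deterministic.
  Output is ultrametric by construction and reconstructs ultrametric inputs
  exactly (tested).
* PCA: design matrix of allele dosages (one column per registry allele minus
  one per locus), per-column mean imputation of missing cells, centring
  without unit-variance scaling (dosage columns share a scale; a `scale`
  flag exists), SVD. Published analyses of this kind rarely state their
  coding or missing-data handling; this convention is documented rather than
  asserted as identical. A panel with zero genotype variance returns a
  flagged degenerate result.

## Reports and pipeline

Tables print at 4 decimals with round-half-even; summary rows use the
unweighted column mean and the sample (n−1) standard deviation (published
"±" values are consistent with either SD convention at printed precision —
the choice is logged). Full-precision values are written to JSON alongside,
and every rendered number re-parses to its JSON value within the printed
rounding (tested). The run manifest lists each methodological switch in
effect (He correction, F_is aggregation, Tm model, tie-breaking, imputation),
making runs auditable; logs go to stderr, results to files. Exit codes:
0 success, 2 config error, 3 data error.

## Problem sizes in tests

Recovery tests run at the sizes where their tolerances have comfortable
Monte-Carlo headroom while the suite stays quick: inbreeding recovery at
n = 500 individuals × 200 SNP loci (±0.05 on f ∈ {0, 0.15, 0.3}); null-allele
bias at n = 500 × 100 SSR loci per true r ∈ {0.1, 0.2, 0.3}; scanner/oracle
equivalence on 1 000 random 150–320 bp contigs; clustering scenarios at
12 populations × 15 individuals with 80–200 loci. These sizes are the
package's own validation choices, stated here so they can be scaled up by
anyone wanting tighter Monte-Carlo bounds.

## Known limitations

* Brookfield-1 only; Oosterhout/Chakraborty estimators and joint maximum-
  likelihood estimation of (r, f) are not implemented.
* No F_ST/F_IT decomposition, AMOVA or rarefied allelic richness.
* The simulator's independence assumptions (loci, individuals, calls) mean
  linkage- or batch-driven artefacts are outside what the tests certify.
* BLAST-based uniqueness/contaminant screens and anything requiring external
  databases or wet-lab steps are out of scope by design.
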