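# Methods

This note documents the statistical procedure, the defaults and the design
choices behind `crossgsea`, including what the synthetic-data generators do
and do not emulate.

## The enrichment statistic

Genes are ranked by the signal-to-noise ratio between the two phenotype
classes,

    s2n_g = (mu_pos,g − mu_neg,g) / (sd_pos,g + sd_neg,g),

computed on log-scale expression with the sample (n−1) standard deviation.
Each class SD is floored at `0.2·|mu|`, and at the absolute value 0.2 when
the class mean is exactly zero.  The floor is the convention of the widely
used desktop implementation: without it, genes whose within-class variance
is accidentally tiny dominate the ranking regardless of effect size.  The
first-listed CLS class is the positive (treatment) class, so positive s2n
means up-regulated in treatment.  Ranking ties are broken lexicographically
by symbol so that runs are exactly reproducible.

For a gene set S with N_H members inside a ranked list of N genes, a running
sum walks the list from top to bottom; at a member ("hit") it rises by
`|s2n|^p / N_R` where `N_R = Σ_{hits} |s2n|^p`, at a non-member ("miss") it
falls by `1/(N − N_H)`.  The enrichment score ES is the running sum's
signed extremum of maximal absolute value, so ES ∈ [−1, 1] and the walk ends
at exactly 0.  The weight exponent defaults to p = 1 (weighted scores);
p = 0 reduces the statistic to the classical two-sample Kolmogorov–Smirnov
deviation between the hit and miss rank distributions, which the test suite
verifies against `scipy.stats.ks_2samp`, and the weighted form is verified
against both a naive Python transliteration of the recurrence and the
Bioconductor `fgsea` package's `calcGseaStat`.  A set whose hit weights are
all exactly zero (every member has metric 0 — possible only in degenerate
constant data) falls back to unweighted hit increments rather than dividing
by zero.

## Permutation significance

The null model permutes **phenotype labels**, not gene tags: each of
`n_perm` (default 1000) permutations reassigns class labels uniformly at
random with class sizes preserved, re-ranks every gene, and recomputes every
retained set's ES.  All sets share the same permutations, which the pooled
FDR construction below requires.  Permutations are sampled with replacement;
when `n_perm` exceeds the number of distinct assignments (small designs) a
warning is emitted rather than an error, since sampling remains valid.  The
generator is `numpy.random.default_rng(seed)` and the seed is a mandatory
parameter of every run.

* **Nominal p** — the fraction of same-sign null ES with |ES′| ≥ |ES|.  No
  pseudocount is added, so p = 0.000 is reportable (it means "beyond every
  permutation"); with no same-sign null values the p is reported as 0.
* **NES** — ES divided by the absolute mean of the same-sign null ES; sign
  preserved.  With no same-sign null scores the NES is undefined (NaN,
  logged) and the set is excluded from FDR pooling.
* **FDR q** — permuted ES are normalized per set the same way, pooled
  across sets, and q(NES*) = [fraction of pooled same-sign permuted NES at
  least as extreme] / [fraction of observed same-sign NES at least as
  extreme], clamped to [0, 1], followed by a step-up pass (each set takes
  the minimum raw q over same-sign sets with |NES| no larger than its own)
  so q is monotone non-increasing in |NES|.  The construction matches the
  pooled-permutation FDR of the reference tool in form; exact numeric parity
  with any particular release is not claimed — the test suite checks the
  definition against an independent brute-force evaluation.

Sets are retained only if their intersection with the ranked symbols has
between `min_size` = 10 and `max_size` = 500 genes (post-intersection size
is what results report).  Results are ordered up-regulated by decreasing
NES, then down-regulated by increasing NES.

## Normalization

The preprocessing emulates a GeneSpring-style recipe for ratio-mode
microarray data, in the order the recipe states it: floor intensities at
0.01 (removes non-positive values ahead of the log), log-transform,
per-sample 50th-percentile shift, per-probe median baseline, global median
re-centring.  Two points were genuinely open and are package decisions:

* the log base is not specified upstream; log₂ is the microarray
  convention and the default (`NormalizationConfig.log_base`);
* "each spot was normalized to the median of all spots" can be read
  per-probe or per-chip; the default applies the per-sample percentile
  shift and then the per-probe median baseline, and
  `NormalizationConfig.spot_baseline = "sample"` selects the per-chip
  reading instead.  Both modes are tested.  The final global re-centring is
  numerically a near no-op after the per-probe step but is kept for
  fidelity to the "baseline = median of all data" wording.

Because deposited expression files may already be normalized, every entry
point accepts either raw linear intensities (normalized internally) or
already-normalized log-scale values (`normalized: true` in the pipeline
config, `--skip-normalize` / `--normalized` on the CLI).

Probe collapse uses the max-probe rule: among probes sharing a symbol, the
probe with the largest across-sample mean contributes the whole row.  Mean
ties go to the probe appearing first in the matrix (stable and
deterministic).  Unannotated probes are dropped, matching the convention
that elements without symbols are invisible to gene-set testing.

## Annotation rules

Only BLAST hits with e-value strictly below 10⁻¹⁰ are eligible (the
upstream search is expected to have been run permissively, around e ≤ 0.01
with ten hits reported, so the hit table shows the full context; the reader
never truncates).  Selection: lowest e-value, then highest bit-score, then
— if accessions still tie — silent collapse when all tied accessions
resolve to one approved symbol (isoforms, lineage-specific duplicates),
otherwise `ambiguous_tie` with no assignment and a curation-queue row.
Ties are deliberately never auto-resolved across gene boundaries: that
mirrors how such cases must be examined individually, and the curation
report is the package's stand-in for that manual step.

Symbol reconciliation consults each source by protein accession, falling
back to linked mRNA accessions.  Disagreements that are alias-vs-approved
(one source's answer appears among another's aliases) resolve to the
approved symbol; anything else is a `symbol_conflict`, left unassigned.
The orthology cross-check maps the best zebrafish hit (same e-value rule)
through an ortholog table and compares after alias resolution; agreement,
disagreement, or unknown (no qualifying hit) is reported per probe and
never overrides the direct annotation.  Assigned symbols are always
approved symbols, never aliases — a property test enforces this.

Duplicate-symbol structure (several elements sharing one symbol) is
reported as (symbol, element-count) pairs plus the total number of elements
involved in any sharing; both one-gene-many-probes and post-duplication
paralogs produce it, indistinguishably at the sequence level, so both are
retained for the collapse step.

## Gene-set curation

Alias repair replaces set members that are aliases with their approved
symbol and deduplicates; members that are neither approved nor known
aliases are kept (they simply never match a ranked gene) and counted.
Repair is idempotent.  Platform pruning removes sets with fewer than
`min_mapped` = 10 members among the annotation's symbols; aliases are
resolved before pruning so the mapped count is computed on approved
symbols.  Keyword filtering is a case-insensitive OR-match over names and
descriptions.

## Synthetic data: what it does and does not emulate

`gen_expression` produces i.i.d. normal(0, `noise_sd`) log-scale values per
gene and sample — i.e. log-normal intensities — with planted sets shifted
by ±`effect_size` in the treatment class.  Defaults are the study scale the
pipeline targets: 12 samples per class (a 12-vs-12 treated/control
design), `noise_sd` = 1 on the log₂ scale, a 2,000-gene universe (kept
well below a real 15k platform so full-pipeline tests run in seconds), and
a planted effect of twice the noise SD for power checks.  The generator
does **not** emulate probe-level scanner artifacts, dye bias,
gene–gene correlation, heavy-tailed noise, or realistic EST sequences;
passing tests therefore demonstrate correctness of the statistics and
bookkeeping under the stated model, not robustness to every property of
real microarray data.  `gen_blast_fixture` and `gen_symbol_tables` plant
controlled fractions of score-resolved ties, ambiguous ties,
below-threshold queries, duplicate symbols, alias indirections, true
conflicts and orthology disagreements, each with a machine-readable answer
key that tests compare against exactly.

## Numerical and degenerate-input choices

* ES extremum ties (two running-sum points with equal |value|) resolve to
  the earlier rank (`argmax` convention).
* A set covering the entire ranked list, or missing from it entirely, is an
  error — there is nothing to contrast.
* Constant matrices normalize to all zeros; the s2n variance floor then
  makes every metric 0 and ranking falls back to the lexicographic
  tie-break.
* CLS numeric labels (0/1) map to class names in order of first appearance.
* GCT files must declare `#1.2` and contain no missing cells (upstream
  thresholding removes them); violations raise errors naming the line.
* Seeds below 2³¹ are derived via `numpy.random.SeedSequence` wherever one
  user seed drives several independent generators.

## Known limitations

* Exact numeric parity with any specific release of the desktop GSEA tool
  is not guaranteed (its internal orderings are not fully published);
  agreement is at the level of the statistic definitions, verified against
  independent oracles.
* Leading-edge subsets, gene-tag permutation mode and enrichment plots are
  not implemented.
* The reproduction tests for the original methylmercury study need its
  deposited supplementary files (and, for the broad collection, MSigDB C2
  v2.5); these are third-party data the package cannot ship.  The tests
  look under `data/paper_supplementary/` and state exactly which files are
  absent.
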