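# Methods

## Scientific setting

Intraocular pressure (IOP) is maintained by the balance between aqueous
humor production in the ciliary body and its drainage through the
trabecular meshwork (TM) and Schlemm's canal (SC). Genome-wide association
studies have mapped well over a hundred loci to IOP, far more than can be
followed up functionally. This package implements two complementary
analyses over that candidate list:

1. **An evidence funnel** that intersects candidate genes with layered
   expression and regulatory evidence — differential expression in
   glaucomatous TM tissue and SC cells, high expression in healthy outflow
   cells and tissue, microarray detection above background, SNP location in
   regulatory regions, eQTL support, response to cyclic mechanical
   stretch, and specific expression in outflow-pathway single-cell
   clusters — and tallies, per gene, how many filters it passes.
2. **A two-group differential correlation analysis** that asks, for every
   unordered gene pair, whether the within-group Pearson correlation of
   expression differs between control and glaucomatous tissue, with a
   network view of the significant pairs.

## The funnel filters

Each filter is a pure function from typed evidence records to an ordered,
duplicate-free gene set, so the funnel counts are fully reproducible from
the packaged table transcriptions.

| filter | rule | default |
|---|---|---|
| differential expression | \|FC\| ≥ t, regardless of p | t = 1.5, inclusive |
| stretch response | \|FC\| > 2 **and** p < 0.05 | both strict |
| high expression (cells/tissue) | FPKM ≥ t in ≥ 1 relevant context | t = 10, inclusive |
| detection above background | DABG ≤ t in the TM column | t = 0.05, inclusive |
| regulatory location / eQTL | boolean flags from the annotation table | — |
| cluster specificity | median expression > 0 in a whitelisted outflow cluster | 6 outflow clusters |

Design choices worth stating:

- **Inclusive vs. strict bounds.** The ordinary fold-change, FPKM and DABG
  bounds are inclusive; this is load-bearing (one gene sits exactly at
  DABG 0.05 and must pass). The stretch criterion is strict on both the
  fold change and the p-value.
- **Any-context semantics.** A gene measured in several cell types passes
  the high-expression filter if *any* context passes; this is required to
  reproduce the non-redundant high-expression count from per-context
  records.
- **Missing data always fail.** An all-NA row never passes a filter.
- **No alias remapping.** RPLP2 and RPLP2P1 (and similarly printed
  variants) are kept as distinct symbols; an alias map is a caller
  decision, not something the IO layer should silently apply.
- **The evidence tally** assigns one equally weighted boolean flag per
  filter and scores a gene by the number of true flags. The source
  narrative only says genes "passed multiple levels" of filtering; the
  explicit flag list and equal weighting are this package's
  operationalization, and alternative weightings can be built from the
  per-flag output.

## The differential correlation test

Within each group g with n_g samples, the Pearson correlation r_g of a
gene pair is Fisher-transformed, z_g = atanh(r_g), which is approximately
normal with variance 1/(n_g − 3). The two groups being independent, the
difference statistic is

    Z = (atanh(r₁) − atanh(r₂)) / √(1/(n₁−3) + 1/(n₂−3)),

with a two-sided p-value from the standard normal tail. No small-sample t
correction is applied; this is the classic independent-correlations test.
Benjamini–Hochberg adjustment runs over **all** enumerated pairs (the full
C(p, 2) universe by default; a focus-only mode restricts enumeration), and
pairs at FDR ≤ 0.1 are called differentially correlated. The 0.1 default
reflects the threshold the source analysis actually applied to its
headline result; it is a parameter everywhere. Output ordering is
deterministic: FDR, then |z| descending, then the lexicographic pair.

Preprocessing drops, in order: duplicated gene rows (first kept), genes
with any missing value (pairwise-complete correlation is deliberately not
used), genes with no expression, and genes constant within either group
(their correlation is undefined). Groups must retain at least 4 samples
because the standard error needs n − 3 > 0.

Group roles are a pure function of the labels (lexicographic order), so
relabelling the two groups swaps the roles: every z flips sign while p,
FDR and the significant set are unchanged — a symmetry the tests assert.

## The synthetic data generator

The microarray matrix underlying the original differential correlation
analysis is not publicly deposited, so the generator defines the study
conditions the statistical tests run under: 13 control vs. 14 case
samples over a universe of 157 focus genes plus 480 background genes
(overridable). Each group's samples are drawn i.i.d. from a multivariate
normal whose correlation matrix embeds every planted pair as a 2×2 block
(unit diagonal, the pair's r off-diagonal) with zeros elsewhere —
block-diagonal, hence positive definite by construction for |r| < 1.
A nonzero background correlation is supported only in equicorrelated mode
with the closed-form bound ρ > −1/(p−1) enforced. Planted pairs use
(r₁, r₂) = (0.95, −0.5) by default in the drivers, i.e. a correlation
difference of ≈ 5.4 standard errors at the default group sizes — a
strongly differential pair of the kind the analysis is meant to recover.

Expression values are exponentiated normals by default (intensity-scale
positivity); calibration work uses the Gaussian mode, under which the
planted Pearson correlations are exact in expectation. What the generator
does **not** emulate: probe effects, normalization artifacts, sample
covariates, heavy-tailed expression noise, and realistic background
co-expression structure. Passing calibration and power tests therefore
demonstrate correctness of the statistical machinery under its own
assumptions, not robustness to microarray artifacts.

## Calibration results and problem sizes

Simulation problem sizes were chosen so each study answers its question
with comfortable Monte-Carlo resolution: 200 null replicates of 50 genes
(245,000 null pairs) for type-I calibration, and 100 replicates of 30
genes with 5 planted pairs for power. Measured on these conditions:

- Raw type-I error at α = 0.05 is within 3 Monte-Carlo standard errors of
  0.05. Because pairs sharing a gene are dependent, the Monte-Carlo SE is
  computed from the across-replicate spread of per-replicate rejection
  fractions, not from a pooled binomial count.
- Planted pairs at Δz/SE ≈ 5.4 are recovered at FDR ≤ 0.1 with power
  above 0.99.
- **Known limitation:** the realized false-discovery proportion at
  FDR ≤ 0.1 averages ≈ 0.15 under these conditions, above the nominal
  0.1. The cause is the normal approximation's far-tail
  anticonservativeness at n = 13/14 (the null probability of p < 10⁻³ is
  ≈ 1.3 × 10⁻³), which the BH step-up inherits; false discoveries show no
  excess clustering around planted genes. At larger group sizes the
  approximation tightens and nominal control is recovered. Users drawing
  conclusions at these sample sizes should read "FDR ≤ 0.1" as
  approximate.

## Numerical choices

- Correlations entering atanh are clipped to 1 − 10⁻¹⁵ in magnitude to
  keep the transform finite for numerically perfect correlations; the
  scalar API instead raises on |r| ≥ 1 (preprocessing removes the
  degenerate inputs that would produce them).
- BH adjustment delegates to the standard step-up implementation in
  statsmodels; tests verify it against a brute-force min-over-tail
  oracle.
- Network edge weight is −log₁₀(FDR) capped at 16 (an FDR of exactly 0
  maps to the cap) so export formats never carry infinities.
- Unit conversion uses 272.38 g/mol for 17β-estradiol (standard value,
  parameterized) and half-up decimal rounding for display, since
  round-half-even drifts from printed tables. The ± values in the
  concentration table are treated as sample SDs (n − 1); the source does
  not state this, but all printed dual-unit rows are consistent under the
  conversion either way.

## Interfaces

The library modules are the primary interface; `analysis/01…05` are thin
narrative drivers writing their tables under `results/`. A single
`iopgenes` command exposes each step (`prioritize`, `diffcorr`,
`network`, `simulate`, `assay`, and the end-to-end `pipeline`), exists for
shell use and smoke testing, and contains no logic of its own.
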