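# Methods

## Data model

All calling operates on stranded per-position allele counts over the rCRS
mitochondrial reference (length 16569, 1-based inclusive coordinates — the
convention used for site labels such as A302C). The circular genome is
represented linearly; pileups are produced upstream of this package, so no
read-wrapping logic is needed. Positions absent from a pileup are zero
depth. Quality filtering belongs to the pileup producer: the SAM/BAM
adapter applies mapping quality ≥ 30 with base quality > 30 (bulk) or the
`-q 20 -Q 20` regime (single cells, where depth is too shallow to
recalibrate scores); the TSV dialect carries already-filtered counts, which
keeps the core deterministic.

Coverage summaries exclude a default mask of [3105, 3110]: the reference
carries an 'N' placeholder at 3107 that produces an artefactual depletion
in its neighbourhood. The exact window is configurable since the depleted
region has no sharp published boundary.

## Variant calling and filters

Candidates are enumerated per (position, non-reference allele) with a
frequency floor of 0.001 and ≥ 1 supporting read — deliberately permissive,
matching a minimum-variant-frequency caller. Four filters follow; each only
*adds* a failure reason, so the passing set is independent of filter order
(a property the test suite asserts by permutation):

- **Blacklist** — 13 recurrent artefacts from misalignment in the
  homopolymer tracts at 302–315 and 513–525 and around the 3107 'N'
  (A302C, C309T, C311T, C312T, C313T, G316C, C514A, A515G, A523C, C524G,
  C3106A, T3109C, C3110A). Keyed on (position, alt) exactly as printed;
  an optional position-only mode widens removal to any alternate allele at
  those positions, since the mechanism is positional. G316C lies just
  outside the 302–315 tract but is retained verbatim.
- **Strand filter** — requires > 2 alternate reads on each strand and a
  strictly balanced orientation, 0.3 < fwd/(fwd+rev) < 0.7. This is the
  only guard against strand-asymmetric error modes (NextSeq A-base errors,
  oxidative G→T/C→A damage); no explicit damage model is fitted.
- **VAF classification** — VAF > 0.9 is homoplasmic (germline-like;
  distinguishes individuals, not clones). VAF = 1 is retained as
  homoplasmic; calls strictly inside (0.9, 1) additionally carry a
  `homoplasmic_band` flag because that band is enriched for reference-bias
  and error artefacts. Downstream lineage work uses only heteroplasmic
  calls, so the flag is informational.
- **Reporting threshold** — heteroplasmies at VAF ≤ 0.01 are not reported
  for bulk samples. The 0.001 candidate floor and the 0.01 reporting cut
  are distinct config keys because they act at different stages; the
  reporting cut is applied uniformly to all bulk samples.

The **contamination screen** flags a sample when it has ≥ 30 passing
heteroplasmies (an order of magnitude above a normal somatic load; a
contaminated library in this regime showed 37) or when ≥ 50% of them match
common population variants — the signature of a second individual's
homoplasmies appearing as spurious heteroplasmy. Both thresholds are
configurable; the common-variant list is supplied as VCF or TSV.

## Single-cell genotyping

Variants are never *called* per cell: candidates from bulk (or merged
single-cell) data are re-counted in each cell, and only reads matching the
candidate's own alternate allele count as support. Positivity defaults to
`min_support = 1` (any read). A stricter ≥ 2-read convention is sometimes
used for display; the threshold is a config key and the default follows the
any-read rule. Detection rates are computed per variant in half-open depth
bins [k·10, (k+1)·10) — bin edges are not specified anywhere
authoritative, so the half-open convention is fixed here and asserted by
brute force in tests.

A cell is **carrier** on any clone-set detection regardless of coverage
(a positive read is evidence); **WT** requires zero detections *and* mean
mtDNA coverage > 40×, below which absence of evidence is uninformative and
the cell is **insufficient**. Because the genotype matrix only stores depth
at variant sites, the WT rule takes an explicit per-cell genome-wide mean
coverage vector (computed by `coverage_summary`) rather than inferring it
from the matrix.

The detection model: support is Binomial(d, f) for site depth d and
cellular VAF f, so P(detect) = P(X ≥ min_support), i.e. 1 − (1 − f)^d for
the any-read rule, and k linked variants combine as 1 − ∏(1 − R_i). These
closed forms serve as the independent oracle for the Monte-Carlo pipeline
in the test suite (agreement within 3·SE at 10,000 cells).

## Lineage inference

With per-base mutation rate r ≈ 1e-7 and n = 100–10,000 mtDNA copies, the
probability that a given site is mutated in one cell is P = n·r ∈
[1e-5, 1e-3], and the probability that N cells share a heteroplasmy through
independent origins is P^N — negligible for N ≥ 3, which motivates
`min_cells = 3` as the default support floor for a clone set (exposed as
config since "more than 3" is ambiguous between ≥ 3 and > 3; ≥ 3 is used).

Grouping variants into clone-defining sets automates what is otherwise a
manual reading of an UpSet intersection plot. Under the null that two
variants mark independent clones, the expected number of cells detecting
both is p₁·p₂·N (p_v = observed carrier frequency; the alternative reading
of p_v as clone prevalence gives the same test statistic under the any-read
rule, and the observed-frequency reading is the one that needs no extra
estimation). An edge joins the pair when the observed co-detection count
exceeds the Poisson 0.99 quantile at that mean; clone sets are the
connected components with ≥ min_cells carriers, and variants in small
components stay ungrouped. The quantile is a config key; 0.99 keeps the
per-pair false-link rate at 1% while the block structure of real clones
exceeds the bound by a wide margin.

"Normalisation by sequencing depth" of the expected intersection is an
interpretation (no formula is published): with `depth_adjust`, each
variant's effective per-read positivity f̂ is solved (bisection) so that
the mean of 1 − (1 − f̂)^d over cells reproduces the observed carrier
frequency, and the expectation becomes Σ_c q₁(d_c)·q₂(d_c). Unweighted
expectation is the default; the adjustment matters when depth varies
strongly across cells.

Assignment: detections in exactly one set → that clone; in ≥ 2 sets →
doublet (two cells in one library; excluded downstream); detections only in
ungrouped variants → unassigned (not WT — the cell has evidence, just not
interpretable); no detections → WT or unassigned per the coverage rule.

Population-level tables categorise each variant by presence (passing
heteroplasmic call with VAF above the reporting cut) across sorted
populations: present in ≥ 2 populations → shared (inherited along the
hierarchy), in one → population-specific; rows are ordered by breadth of
sharing, then position.

## Simulator

The generator emulates the structure the method consumes: cells draw a
clone by configured fractions; each clone variant draws a cellular VAF from
Beta(mean·κ, (1−mean)·κ) (κ = `vaf_concentration`; `None` = fixed VAF —
Beta chosen for unit-interval support and binomial conjugacy); per site,
depth comes from a constant/Poisson/lognormal model, alternate reads are
Binomial(depth, VAF), and the remaining reads split multinomially into
reference and the three non-reference alleles with probabilities
(1−e, e/3, e/3, e/3) — drawn as sequential conditional binomials so counts
are conserved exactly. Reads split between strands with probability 0.5 by
default. Doublets merge two complete, independently drawn cells (own depth
draws, additive counts); the partner clone is drawn from the same clone
fractions, so only the cross-clone portion — rate × (1 − Σ f_k²) — is
observable as a variant-set mixture, and tests compare flagged fractions
against that observable expectation.

Default conditions follow the regimes the method targets: depth mean 50
(Poisson), error rate 0 unless a test exercises error handling (1e-3, the
residual rate after quality filtering), strand probability 0.5, fixed
seeds throughout; detection-sensitivity runs use 10,000 cells at constant
depth 20 with VAFs 0.20/0.05/0.02/0.01, and clone-recovery runs use 150
cells, two clones (4 + 2 variants), constant depth 100, VAFs 0.10–0.30.

What it does **not** model: alignment artefacts (homopolymer misalignment
exists only through the blacklist), sequence-context error spectra,
UMI/duplicate structure, library-size variation within a cell beyond the
depth model, and genetic drift of heteroplasmy along the lineage (cellular
VAFs are drawn i.i.d. per cell, not propagated along a tree). Passing tests
therefore demonstrate the pipeline's statistical behaviour under binomial
sampling, not robustness to alignment artefacts in real data.

## Numerical choices and edge cases

- Strand-balance and blacklist inequalities are strict exactly as stated;
  depth-bin edges go to the upper bin.
- `detection_probability` uses the scipy binomial survival function;
  d = 0 returns 0.
- The effective-VAF inversion uses Brent's method on [0, 1−1e-12] with
  xtol 1e-12 and saturates at 1 when the carrier frequency is unreachable.
- Zero-depth cells contribute detection probability 0 in the
  depth-adjusted expectation.
- Empty pileups are valid (zero sites); recounting a candidate at a
  position absent from a cell yields support 0 / depth 0, not an error.
- All simulator randomness flows from one `numpy` Generator seeded by the
  config; identical configs are bit-identical, and the bulk simulator
  offsets the seed to decouple its stream from the cell stream.

## Known limitations

- Substitutions only; no indels, no nuclear variants, no phasing.
- No imputation of missing genotypes; dropout is handled by the combined
  rate over linked variants, not recovered.
- The clone model is a flat partition (plus shared/specific tables across
  populations); no multi-level phylogeny is reconstructed.
- With any-read positivity and error rates ≳ 1e-3 at depth ≳ 100, false
  single-read detections inflate the doublet count; raising `min_support`
  to 2 suppresses this at a modest sensitivity cost (see
  `examples/clone_inference.py`).
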