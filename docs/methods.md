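# Methods

## Scoring model

The pipeline scores a three-arm pooled knockout screen: Input cells harvested
at day 10 (before the selective perturbation), an Empty-vector arm and a
selected (YAP-expressing) arm both harvested at day 25, in biological
replicates. Scoring is deliberately simple and rank-free: reads-per-million
normalization within each sample, a hard raw-count exclusion, per-replicate
enrichment ratios on the linear normalized scale, a median over replicates,
and moment z-scores of the log2 median against the nontargeting controls.
There is no variance-stabilized test statistic (no negative-binomial GLM, no
robust rank aggregation) and no multiple-testing correction: hit calling is a
deterministic rule on per-gene guide counts, which keeps every decision
auditable at the cost of formal error control. The nontargeting pseudo-gene
readout exists precisely to make the empirical false-positive level visible.

Conventions that the procedure's prose description leaves open, fixed here:

* **Filter scope.** "Low-count guides are excluded" can be read per sample,
  per pair, or globally. Default is *pairwise*: a replicate's ratio is
  dropped only when one of its two member samples has raw count < 20. This
  preserves the most data; the global reading (`filter_scope="any_sample"`)
  is one config switch away.
* **Normalization order.** Sample totals are computed over the full library
  before any exclusion — normalize first, exclude later.
* **Median convention.** The median is taken on the linear ratio scale over
  valid replicates only; an even count uses the midpoint mean; fewer than
  `min_valid_replicates` (default 2) valid replicates yield a missing median,
  and missing medians never qualify a gene (such genes surface as
  `insufficient_data` rather than silently becoming `none`).
* **z-score construction.** z-scores use log2 of the median ratio so
  enrichment and depletion are symmetric, with mean and sample SD (ddof = 1)
  of the nontargeting controls as reference. If every reference guide has an
  identical ratio the SD is zero and the code raises, pointing to
  `zscore_reference="all"`.
* **Input rule.** The effector definition has two published readings: "at
  least one guide also enriched versus Input" and "at least two guides
  enriched ≥ 1.5-fold versus Input". The default follows the lenient reading
  (`input_rule_min_sgrnas=1`, `input_rule_fold=1.0`, i.e. any enrichment);
  the strict reading is `AnalysisConfig(input_rule_min_sgrnas=2,
  input_rule_fold=1.5)`. They are never blended; the strict prioritized set
  is provably a subset of the lenient one (tested).
* **Depletion threshold.** "Depleted ≥ 1.5-fold" means median ratio
  ≤ 1/1.5 — reciprocal symmetry on the linear scale. All threshold
  comparisons are inclusive.
* **Dual-qualifying genes.** With ≥ 4 guides a gene can satisfy both the
  effector and the inhibitor rule. The side with more qualifying guides
  wins; an exact tie is called `none`. This tie-break is symmetric under
  ratio inversion, which keeps the effector/inhibitor swap property exact.
* **Read mapping.** Reads carry the spacer at position 0 (the screen's
  sequencing recipe skipped the vector with dark cycles), so counting
  compares a fixed-offset 20-mer; the offset is configurable. Exact matching
  is the default; `one_mismatch` mode assigns a read to the unique guide
  within Hamming distance 1 and discards ties. Neither mode trims adapters,
  uses quality values, or searches the reverse complement.

## Synthetic screen generator

The generator emulates the composition-level behaviour of such a screen:

    base      ~ LogNormal(0, library_skew_sd)        per guide, per replicate
    input     = base
    empty     = base · LogNormal(0, drift_sd)
    selected  = base · LogNormal(0, drift_sd) · fold^active
    counts    ~ Poisson(depth · n · rel_abundance · eps),
                eps ~ LogNormal(−σ²/2, σ),  σ = baseline_dispersion

with `fold = effect_fold` for effector genes, `1/effect_fold` for inhibitors,
1 otherwise, and `active` an independent Bernoulli(`sgrna_active_prob`) flag
per guide — guide-efficacy heterogeneity is modelled explicitly because the
≥ 2-of-4 gene rule presumes some guides are inert. Abundances are
renormalized within each sample: sequencing measures composition, so a global
cytostatic effect enters only through relative abundance. The
Poisson-lognormal mixture gives negative-binomial-like overdispersion. Each
(stage, condition, replicate) draws from its own named substream of the
master seed, so identical config + seed is byte-identical and adding
replicates never perturbs earlier ones.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genes × sgrnas_per_gene + n_ntc | 950 × 4 + 50 | the screen design this package scores |
| n_replicates | 4 | biological quadruplicate |
| effector_fraction, inhibitor_fraction | 0.02, 0.02 | a targeted library enriched for candidates; ~19 true genes per class |
| effect_fold | 3.0 | a strong but not extreme growth rescue over 10 days of selection |
| sgrna_active_prob | 0.75 | typical fraction of functional guides in a well-designed library; a true hit usually has 2–4 active guides |
| mean_depth | 500 reads/guide | routine coverage for a 3,850-guide library; keeps Poisson noise well below biological noise |
| library_skew_sd | 0.5 (ln) | post-selection library representation spread |
| baseline_dispersion | 0.15 (ln) | count overdispersion ≈ NB α ≈ 0.02, a clean screen |
| drift_sd | 0.10 (ln) | passage drift day 10 → day 25 between arms of one replicate |

The noise defaults describe a *well-executed* screen (high replicate
concordance); they were fixed once from published screen-quality ranges and a
power sketch of the default design, not fitted to any test outcome. Under
them the default rules recover planted effectors with precision and recall
above 0.9 and call essentially no hits in null screens — so passing tests
show the procedure is correctly implemented and well-behaved under favourable
conditions, **not** that any particular biological screen meets them. Real
data differ in ways the generator deliberately omits: transduction
bottlenecks and MOI, puromycin selection kinetics, PCR amplification bias,
sequencing error (beyond the optional 1-mismatch counting mode), chromatin-
or position-dependent guide efficacy, and genes whose knockout is lethal
regardless of arm.

Synthetic spacers are uniform random 20-mers screened for pairwise Hamming
distance ≥ 2 (uniqueness alone can be requested), so exact-match counting of
emitted FASTQ fixtures is unambiguous; generation fails loudly if the draw
budget is exhausted rather than degrading separation.

## Synthetic reference screen

`rescuescreen.datasets` builds a fully synthetic stand-in for the published
screen-results table (no count-level data were deposited). It uses the real
library geometry, the handful of published spacer sequences, and pins the
validated genes to their reported qualitative outcomes — notably SAP30 as an
effector with exactly 3 of 4 functional guides and MORC2 as an inhibitor
with 4 of 4 — so the pipeline's rules can be exercised against known per-gene
guide counts. Every number derived from it is simulated, and checks against
it validate the scoring rules, not the original biology.

## Numerical and degenerate-input choices

* Ratios with a zero denominator (possible only when the low-count threshold
  is 0 and the pseudocount is 0) are invalid, never infinite.
* The pseudocount default is 0 — the scored procedure has none — and exists
  only for robustness on sparse synthetic data.
* Zero-total samples, empty libraries/ratio tables, malformed spacers,
  duplicate guides, unknown condition tokens, and truth/call gene-set
  mismatches all raise with the offending item named.
* Oracle equivalence (medians and z-scores versus a loop-based recomputation
  from raw counts) is asserted to 1e-12 on 50-guide matrices.

## Problem sizes used in validation

Statistical checks run at deliberately chosen sizes: null calibration uses 50
full-design (950-gene) screens; recovery uses 20 screens at the default
conditions; the class-assignment binomial check uses 200 seeds of a 300-gene
library; Monte-Carlo checks of the generative expectation use 150 simulated
screens against a 2,000-draw independent recomputation. FASTQ round-trip
identity runs on a 88-guide, 6-sample screen.

## Known limitations

* The hit rules provide no p-values or FDR; the NTC pseudo-gene rate is the
  only empirical error estimate.
* `one_mismatch` counting builds the full 1-neighbourhood lookup
  (61 × library size strings); fine to ~10⁵ guides, not genome-scale.
* The generator's replicates are exchangeable — no batch structure or
  replicate-specific depth.
* Recovery metrics treat the generator's truth labels as gold; they say
  nothing about biological validation of real hits.
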