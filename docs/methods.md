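# Methods

This note documents the models and numerical choices behind glycosurf, in
the order the pipeline runs.

## Input model

PSM tables are consumed as search-engine output: peptide sequence,
modification list, neutral monoisotopic observed mass (Da), an
identification confidence in [0, 1], protein accessions, and a sample
(replicate-run) label. The confidence is a posterior probability produced
upstream; this package does not recompute it, it filters on it. The default
threshold of 0.98 treats the cutoff as a per-PSM probability; if the
producer's figure is a set-level error rate (a 2% false-positive rate over
the accepted set) the per-PSM reading is the more conservative of the two.
Masses are neutral and monoisotopic throughout — any charge or m/z
conversion is the producer's responsibility.

## Glycopeptide qualification

Three rules, applied in a fixed order (sequon → deamidation → mass) so that
a record failing several reports the first deterministically:

1. **Sequon.** `N-x-[S/T]` with x ≠ P, all overlapping occurrences counted.
   A peptide ending in `N` or `N-x` (x ≠ P) carries *the start of* a
   sequon whose completion lies beyond the cleavage site; these truncated
   motifs are accepted by default and can be switched off
   (`allow_truncated_sequon=False`) for the strict full-motif reading.
2. **Deamidation.** PNGase F converts the glycosylated Asn to Asp, a
   +0.98402 Da shift. The package uses the exact chemical value; the
   commonly printed rounded figure (0.986 Da) is accepted on input labels,
   since a 0.002 Da discrepancy is below 1 ppm on any tryptic peptide and
   immaterial to the mass gate. By default the deamidation must sit on a
   sequon Asn; `deamidation_anywhere=True` relaxes this to any Asn.
3. **Mass.** |m_obs − m_theo| / m_theo × 10⁶ ≤ τ_ppm, default 20 ppm,
   with m_theo the residue-mass sum plus water plus all stated
   modification deltas. Residue monoisotopic masses come from the standard
   amino-acid table (pyteomics); Leu/Ile are matched literally as sequence
   characters and share a mass through that table.

Failures are returned as (record, reason) pairs, never exceptions:
rejection is data, not error.

## Proteoform grouping

Peptides are mapped to proteins by exact substring containment. Accessions
sharing a (gene, primary ID) pair in the isoform index merge into one
proteoform group, because peptides from shared isoform regions cannot be
attributed to a single isoform. A peptide hitting several groups is counted
in each (the "collective" reading); `shared_peptides="drop"` excludes
cross-group peptides instead. When the index designates no primary ID the
lexicographically smallest member accession is used, making the grouping
order-invariant and deterministic.

## Quantification

Spectral counts are tallied per group per replicate run. Depth
normalization multiplies each column by `sqrt(R₀ / T_r)` with reference
total R₀ = 400 — the square root deliberately corrects only half-way
(in log space) between forcing equal column totals and leaving depth
differences untouched, balancing the expectation of similar injected
amounts against the possibility of real differences. The source caption
for this procedure reads, verbatim, as a *division* by `sqrt(R₀ / T_r)`,
which would amplify deep replicates and contradict its own stated purpose;
both readings are implemented (`mode="rationale"` multiplies — the
default — and `mode="literal"` divides), and the mode is stamped into the
output metadata header so downstream consumers can tell which was used.

Replicate averaging produces one column per (day, condition) point. The
denominator is the *designed* replicate count (3 by default), not the
observed one: a replicate in which a group was never sampled contributes
zero. This biases low-abundance means downward slightly but keeps the
estimator honest about sampling failures.

## Marker discovery

* **Fold changes** use a pseudocount c = 0.5 (spectral counts are small
  integers): ratio = (late + c)/(early + c), flagged up at ≥ θ and down at
  ≤ 1/θ, θ = 2 by default. The flag is computed on the pseudocounted
  ratio, so values straddling the cutoff by less than the pseudocount
  effect flag as `none`.
* **Down-then-up overlap**: of the groups upregulated from the late
  DOX-high point to the final transgene-independent state, the percentage
  that had been downregulated across the initial induction interval. The
  denominator must be non-empty; an empty late-up set is an explicit error,
  not a zero.
* **Category composition**: per time point, detected groups (count > 0)
  are tabulated by functional category as percentages; dispersion is the
  per-category sample s.d. (ddof = 1) across time points and its
  unweighted mean. A single time point yields 0 with a warning.
* **PCA** runs on `log2(x+1)` averaged counts with samples as observations
  and groups as variables, column-centred; unit-variance scaling is off by
  default because spectral counts already share a scale. All components
  are kept, so variance ratios sum to 1 and scores preserve pairwise
  sample distances exactly.
* **Trajectory clustering**: K-means (best of `restarts` initializations,
  seeded) on per-group z-scored trajectories; flat trajectories map to the
  zero vector. K defaults to 10, with the F-class selection rule applied
  afterwards rather than forcing K = 2.
* **F-class cluster selection**: a cluster is selected iff its mean
  z-scored trajectory rises from day 0 to the first post-induction point
  and attains its maximum at an F-class end-state column. The F-class end
  state is defined as the sustained-DOX points in the final 40% of the
  course (day ≥ 18 of 30), not the single final sampling day: F-class-type
  trajectories plateau over the last third of the course (the archetype's
  last four points lie within ~2% of each other), so requiring the argmax
  to land exactly on day 30 would be decided by counting noise even for
  cluster means over dozens of groups.
* **Separating components and ranking**: for each contrast (F-class vs
  ESC, F-class vs MEF) the separating component is the PC with the largest
  centroid gap *in score units*. An earlier candidate definition —
  standardizing each component's gap by that component's score s.d. — was
  rejected: dividing by the per-component s.d. erases the variance
  weighting, so near-noise PCs with tiny eigenvalues win on chance
  alignment (in testing, a component explaining ~1% of variance could be
  chosen over the one visibly separating the states). A group's
  contribution on a component is |loading| / max|loading| on that
  component; the marker score is the minimum of the two contributions
  (alternatives `max` and product would reward one-sided separation), and
  ranking is descending by score with ties broken by primary ID.
* **ΔΔCt**: fold change 2^(−ΔΔCt) with
  ΔΔCt = (Ct_t − Ct_ref)_sample − (Ct_t − Ct_ref)_calibrator; the
  calibrator must be present for every gene. **Hierarchical clustering**
  defaults to Euclidean distance with average linkage; both are
  configurable.

## Synthetic data generator

The generator emulates the study conditions, not generic data: a 30-day
course sampled at 12 days (0, 3, 5, 8, 11, 14, 16, 19, 22, 25, 27, 30),
three arms (sustained DOX-high; DOX-low splitting at day 8; DOX withdrawn
at day 14), three technical replicates per point, plus an ESC reference
point. Five archetypes shape expected abundances:

* `early_down` — exponential collapse with day-2 level ≤ half of day 0;
* `fclass_up` — saturating rise `d²/(d²+8²)` under DOX, exponential decay
  after withdrawal;
* `esc_like` — low early, converging to the ESC level in withdrawn arms;
* `transient` — a Gaussian bump centred on day 10;
* `flat` — constant.

Default mix 0.3 / 0.1 / 0.1 / 0.2 / 0.3 over 500 groups. Each group gets a
single multiplicative lognormal baseline with mean 1 (σ = 0.5), so the
archetype curve is also the expected trajectory. One `fclass_up` group is
planted as the marker with a noise-free baseline and an F-class level
`marker_effect` × its floor (default 8-fold); at `marker_effect = 1` it is
indistinguishable in expectation from its archetype.

Counts are Poisson draws at per-replicate depth T_r ~ lognormal with mean
400 and σ = 0.3 (mean-corrected), matching the normalization reference so
that the identity case is exercised; a negative-binomial option
(`dispersion`) gamma-mixes the rate. The PSM-level generator embeds 1–3
tryptic peptides per group in generated protein sequences (a seventh of
groups get two isoform accessions sharing all peptides), places
carbamidomethyl on Cys and deamidation on the first sequon Asn, draws
observed masses within ±10 ppm of theory, and plants: sequon-less decoy
peptides (20% of peptides by default), one proline `NPS` non-sequon and
one C-terminally truncated sequon peptide in every fixture, a 2% spike of
+50 ppm masses (at least one guaranteed whenever the spike rate is
positive), and a 2% spike of sub-threshold confidences. All randomness
flows from the single config seed through named per-stage generators; no
global state.

**What the generator does not emulate.** Real CSC data has peptide-specific
detectability (length, hydrophobicity, charge), correlated technical noise
between co-eluting peptides, missed cleavages, partial deamidation, and —
importantly for the overlap statistic — a large class of fibroblast surface
proteins (collagens, integrins) that shut down early and *reappear* in the
final pluripotent state. The archetype set models MEF-down and ESC-up as
separate classes, so the synthetic down-then-up overlap is structurally
small (~10%), far below what a real reprogramming course shows; on
synthetic data that statistic is validated by oracle equivalence, not by
magnitude. Passing tests demonstrate the pipeline's correctness and its
ability to recover planted structure at realistic depths, not the field
values of any particular biological dataset.

## Problem sizes

The default analysis scale is 500 groups × 27 time-course points × 3
replicates (~32,000 PSMs at depth 400), which the full PSM-level pipeline
processes in a few seconds; the acceptance script's 20 seeded count-level
runs complete in under half a minute on one CPU. Unit tests use 12–120
group fixtures generated at test time.

## Known limitations

* Substring peptide-to-protein mapping is O(peptides × proteins); fine at
  surface-proteome scale (hundreds of groups), not built for whole-genome
  six-frame databases.
* No protein-level FDR or parsimony inference — grouping is by the
  designated isoform index only.
* The confidence column is trusted as calibrated; no recalibration.
* K-means determinism is guaranteed per seed, library and platform; exact
  cluster ids may differ across library versions (selection and ranking
  are invariant to relabelling).
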