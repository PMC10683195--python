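# Methods

## Quantification model

The Total Protein Approach treats a protein's share of the run's total MS
signal, divided by its molar mass, as its molar concentration per gram of
total protein: `c(i) = I(i) / (I_total · MW(i))` with `MW` in g/mol
(kDa × 1000).  The model assumes the summed intensity of a run is
proportional to the injected protein mass and that a protein's summed
peptide intensity is proportional to its mass share; both are
approximations that hold best after identical sample handling across runs.
The construction makes the per-run mass closure `Σ c(i)·MW(i) = 1` an exact
algebraic identity over the observed cells, which the tests exploit as an
invariant (tolerance 1e-9, in practice machine epsilon).

Concentrations can be rescaled to pmol per mg via a factor 10⁹ times a
`protein_mass_fraction` parameter (g protein per g tissue).  The default is
1.0, i.e. pmol per mg of *total protein*: no tissue-specific protein
content is assumed, and the parameter is exposed rather than guessed.

An intensity of zero in the input is "not quantified" and is stored as
missing, following MaxQuant semantics; this keeps the log₂ transform and
the validity filter well defined.

## Preprocessing

**Flag filter.** Reverse (decoy) hits and only-by-site identifications are
always removable and removed by default; contaminant removal is off by
default and available as a flag, since workflows differ on whether
contaminants are dropped before statistics.

**Validity filter.** A protein is retained iff it is quantified in at
least `min_frac` (default 0.7) of the runs of at least one group.  The
criterion counts *runs*, not biopsies: with 5 biopsies × 2 technical
replicates per group the default is 7 of 10 runs.  The filter is monotone
in `min_frac`, which is property-tested.

**Imputation.** Missing values are drawn i.i.d. from
`Normal(μ − downshift·σ, (width·σ)²)` with defaults width 0.5 and downshift
1.8.  μ and σ are the mean and SD of *all* observed cells of the matrix
("total-matrix" mode, the default); a per-column mode is available for data
with strong run-to-run shifts.  Observed cells are never modified, every
imputed cell is flagged in a provenance mask, and the draw is deterministic
under the configured seed.  Degenerate inputs (all-missing matrix, zero
spread) raise errors rather than imputing nonsense.

## Contrast statistics

The test statistic is the SAM-style moderated two-sample t:
`t = (x̄ − ȳ) / (s_p·√(1/n_x + 1/n_y) + S0)` with pooled variance (a Welch
variant is available by flag).  At S0 = 0 it reduces exactly to the
classical pooled Student statistic — verified against scipy to 1e-10 —
and |t| is non-increasing in S0 (property-tested).  S0 damps the
significance of proteins with tiny variances and tiny effects.

Significance uses a permutation-estimated FDR.  Sample labels of the two
compared groups are permuted (all `C(n, n_a)` distinct assignments when
that count is ≤ 10,000, otherwise `n_perm` uniform draws, default 250); for
each candidate threshold τ among the observed |t| values the FDR estimate
is `mean over permutations of #{null |t| ≥ τ} / #{observed |t| ≥ τ}`, and
the significance set is the largest threshold set with estimated FDR at or
below the nominal level (default 0.01).  Ties in |t| enter or leave
together.  The identity assignment is included in the null set, so the
smallest estimable FDR on a toy with `P` distinct assignments and `k`
clear positives is `2k/(P·k) = 2/P`; the 3-vs-3 oracle-equivalence tests
therefore run at FDR 0.15, above the 0.1 floor of the 20-assignment toy.

By default tests run at the run level (n = 10 per group in the reference
design), matching the run-based validity criterion.  A
`collapse_technical: mean` option averages technical replicates to n = 5
biological samples first; run-level testing treats technical replicates as
independent samples (pseudoreplication), which inflates significance for
proteins whose variance is dominated by biological noise — the option
exists precisely so users can check the stricter analysis.

Fold changes are differences of group-mean log₂ values, computed on the
imputed matrix (so every protein has a complete value); direction labels
(up/down) apply only to significant proteins and are antisymmetric under
swapping the group order.

**Overlap (Venn) summaries** between two contrasts report, per direction,
the intersection as a percentage of the union (inclusion–exclusion),
rounded to the nearest integer — the convention consistent with reporting
both shared-down and shared-up percentages from per-contrast counts.

**Pairwise Mann–Whitney** comparisons of absolute concentrations use the
exact null when sample sizes and ties allow, otherwise the tie-corrected
normal approximation, with star labels at the unusually strict thresholds
`**` p ≤ 10⁻³, `***` p ≤ 10⁻⁴, `****` p ≤ 10⁻⁵ used in per-protein
concentration panels.

## QC

Run–run Pearson correlation is computed on the filtered, *pre-imputation*
matrix using pairwise-complete observations (pairs with < 3 complete cells
are reported missing with a warning); imputation would artificially inflate
correlations between runs sharing many missing cells.  PCA runs on the
filtered + imputed run-by-protein matrix, centred per protein and unscaled
(Perseus-like; a scaling flag exists).  Component signs are fixed by making
each component's largest-|loading| entry positive, so scores are bitwise
reproducible.

## Pathway analysis

Over-representation is a one-sided hypergeometric tail
`P(X ≥ overlap)` per pathway with Benjamini–Hochberg adjustment across
pathways, computed offline from user-supplied GMT sets; it matches
brute-force enumeration exactly on small universes.  GMT members are
matched to the data by accession first, then gene symbol, case-insensitive.

Cross-contrast correlation takes the two contrasts' log₂ fold changes over
a pathway's member proteins and reports Pearson r with its two-sided p.
Membership is restricted by default to proteins significant in at least one
contrast (an all-members mode exists); at least 3 proteins are required for
a reported r.  The statistic is invariant under positive affine rescaling
of either fold-change vector.

## Synthetic data generator

Per protein, the log₂ intensity of a run is
`baseline + group shift + biological noise + technical noise`, with the
baseline Normal(23, 2) on the log₂ scale (typical of MaxQuant summed
intensities), molecular weights log-normal around 45 kDa, biological noise
(σ_bio = 0.35 by default) shared by the two technical replicates of a
biopsy and technical noise (σ_tech = 0.15) independent per run.  Group
shifts are pathway-structured: an effect table maps pathway → per-group
mean log₂ shift, with optional per-protein heterogeneity (`effect_sd`)
drawn once per protein and shared across shifted groups
(`effect_shared=True`) or independently per group — the knob that lets the
generator produce concordantly vs discordantly dysregulated tumors.

Cells are masked missing with probability
`logistic((mnar_midpoint − log₂ intensity) · mnar_slope)`, applied
independently per cell after technical noise — the simplest
missing-not-at-random model for left-censored label-free data.  The default
midpoint 20.6 and slope 2.0 were chosen (by a logistic-normal calculation,
then confirmed on one simulation) so that defaults produce ≈ 15% missing
cells overall with ≈ 85–87% of genuine proteins passing the 70% filter —
the regime a real cohort of this design sits in.  Decoy and contaminant
rows draw intensities from the same baseline law and are masked the same
way, so they survive parsing and die only by the flag filter, which is what
the filter tests need.

The generator does **not** simulate peptide/spectrum-level data, retention
times, shared peptides between protein groups, batch effects, or
inter-protein intensity correlations beyond the planted pathway structure.
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its statistical calibration under the stated noise model,
not performance on any particular real cohort.  The printed
replicate-correlation ranges of real tissue data are matched only
qualitatively (technical > biological > between-group), not numerically.

## Benchmark scenarios and problem sizes

The benchmark module runs: (1) pure-null FDR control — 1,000 proteins,
3 × 5 × 2 runs, no effects, no missingness, 20 seeds, 250 permutations;
(2) planted recovery — a 50-protein pathway shifted +1 log₂ in one tumor
group, σ_bio = σ_tech = 0.2, 10 seeds; (3) cross-contrast concordance —
the same pathway shifted +1 in both tumors with per-protein heterogeneity
SD 0.5, shared vs independent, 10 seeds; (4) the imputation law on ≥ 10⁵
imputed cells, where the observed cells are affinely standardized to sample
mean 20 and SD 2 exactly so the measurement isolates the imputation draws.
Scenarios (1)–(3) use complete matrices (no MNAR masking): they measure the
test's calibration and power under their stated noise conditions, not the
interaction with imputation, which is exercised separately.  These sizes
are the package's reference conditions; all run in seconds.

## Numerical and design notes

- Zero and negative intensities: zero → missing at parse time; negative →
  parse error with row/column context.
- A run whose observed intensities sum to zero cannot be TPA-normalized and
  raises an error naming the run.
- FDR thresholding uses the *mean* null exceedance over permutations (a
  median option exists); estimates are not monotonized across thresholds —
  the largest qualifying threshold set is taken directly.
- Output TSVs carry `#`-prefixed provenance lines (tool version, seed,
  config hash); the config hash covers parameters but not the output
  directory, so re-running the same analysis elsewhere yields byte-identical
  files.  Stage-wise CLI invocation and the monolithic runner write through
  the same functions and are byte-identical by construction (and by test).
- PCA sign fixing, seeded RNGs everywhere (one integer seed drives
  generation, imputation and permutation draws), and pandas' deterministic
  float formatting are what make the determinism checks exact.

## Known limitations

- The permutation FDR at run level inherits the pseudoreplication caveat
  above; collapse technical replicates for a conservative analysis.
- Total-matrix imputation assumes a roughly common scale across runs;
  per-column mode should be preferred if runs are strongly shifted.
- Enrichment treats pathways independently (no set-overlap correction) and
  is over-representation only, not rank-based.
- The pmol/mg-of-tissue scale is only as meaningful as the supplied
  protein-mass fraction.
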