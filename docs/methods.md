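# Methods

## Dose-response model

Seed survival and pod fertility after acute irradiation are modelled with
the single-hit multitarget (SHMT) curve

    rate(D) = 1 − (1 − e^(−D/D₀))^m ,

with `D` the absorbed dose in Gy, `D₀ > 0` the dose reducing single-hit
survival to 1/e, and `m ≥ 1` the extrapolation number. The model assumes
`m` identical targets per unit, each inactivated independently by
single-hit kinetics; it implies `rate(0) = 1`, monotone decline in dose,
and a shoulder of width `Dq = D₀·ln m` below which rates stay near 1.
`m = 1` removes the shoulder entirely (`Dq = 0`).

**Fitting.** Least squares on the rate scale (the experimental design
reports replicate-averaged rates, not raw counts; replicate rows sharing a
dose are averaged before fitting). The solver is
`scipy.optimize.least_squares` (Levenberg–Marquardt) restarted from a
coarse grid — by default 6 geometrically spaced `D₀` values in
`[max(D)/10, max(D)]` crossed with `m ∈ {1.05, 2, 4, 8, 16}` — because
shoulder curves have a flat ridge in `(D₀, m)` and a single start is
unreliable. The constraint `m ≥ 1` (hence `Dq ≥ 0`) is enforced by the
reparameterization `m = 1 + e^u`, and `D₀ > 0` by `D₀ = e^v`, so the solver
itself is unconstrained. Tests verify that the multi-start optimum is at
least as good as a dense 200×200 grid scan spanning the truth.

**Readouts.** The 50%-effect dose is found by bisection on the fitted
curve (`scipy.optimize.brentq`, absolute tolerance 0.01 Gy by default),
not by interpolating the raw data: the fitted curve pools information
across all dose points. Goodness of fit is `R² = 1 − SS_res/SS_tot` on the
replicate-averaged rate scale; constant observed rates make `R²` undefined
and return NaN. RBE divides a reference (low-LET) dose by a test
(high-LET) dose at a matched endpoint; reports round it to 2 decimals and
doses to whole Gy, full precision is kept internally. Relative yield is
*not* fitted with the SHMT model — the decline is too shallow and shows
low-dose stimulation — so the 50%-yield dose is a linear interpolation
between the bracketing tabulated points; an exact hit on the threshold
returns that dose, and a table that never crosses the threshold is an
error rather than an extrapolation.

Degenerate inputs: fewer than three distinct doses, or all rates equal to
1 (no decline), raise an insufficient-data error instead of returning an
arbitrary parameter vector.

## Variant pipeline

Raw per-line calls are reduced to induced-mutation sets in stages, each
tallied in a per-line provenance map so that removals are auditable:

1. **Quality.** Calls with `QUAL` below the threshold (default 20; the
   value is configurable because callers scale quality differently) are
   removed; calls lacking a quality are kept but flagged.
2. **Control subtraction.** A key present in *every* unirradiated control
   call set is pre-existing background, not induced. A stricter union mode
   (present in *any* control) is available. Keys are
   `(chrom, pos, ref, alt)` for small variants,
   `(type, chrom, pos, end)` for extent SVs and
   `(type, chrom, pos, mate-locus)` for breakends; SV matching is exact by
   default with a configurable ±N bp positional tolerance (exact is
   reproducible; caller breakpoint jitter can be absorbed when needed).
3. **Cross-line exclusion.** A key detected in ≥2 independent mutant lines
   cannot be an independent induction event and is removed from every
   line. The comparison spans all supplied lines (both mutagen groups);
   restricting it to one group is a call-site choice.
4. **Zygosity.** Small variants by allele frequency: AF ≥ 0.75 homozygous,
   0.25 ≤ AF < 0.75 heterozygous. The 0.75 boundary goes to the homozygous
   class because that rule is stated inclusively; AF < 0.25 calls are
   discarded as unreliable (configurable). SVs by genotype string: no zero
   allele → homozygous, exactly one zero → heterozygous, all-zero or
   missing genotypes drop out as non-variant/unknown.
5. **MNV merging.** Maximal runs of single-base substitutions at strictly
   consecutive positions (gap 0) on one chromosome, run length ≥ 2, merge
   into one multinucleotide variant. The MNV's AF is the mean constituent
   AF (order-independent) and its zygosity is the class of that mean.
   Constituent SBSs are conserved inside the MNV — merging is not a
   removal — and never enter Ts/Tv arithmetic.
6. **Scaffold filter.** SVs with either locus (anchor, end, or breakend
   mate) on a name outside the assembled chromosome set are set aside;
   unassembled scaffolds produce unreliable SV calls.

Filters are idempotent, and the two key-subtraction stages (control,
cross-line) commute; both properties are asserted on random fixtures.

## Spectrum and effect statistics

Retained events partition into SBS, INDEL deletion/insertion (length
change ≤ 50 bp), MNV, and DEL_SV / DUP_SV / BND_SV (> 50 bp). Length
classes split INDELs at 1 bp vs ≥ 2 bp and MNVs at 2 bp vs ≥ 3 bp (2 bp
runs are the dominant MNV class and are reported separately). Transitions
are A↔G and C↔T; the Ts/Tv ratio is flagged infinite/NaN when no
transversions or no SBSs remain. Group summaries are plain sums over lines
within a zygosity scope (homozygous-only, or homozygous+heterozygous) and
are permutation-invariant.

Cross-mutagen comparisons use Pearson's chi-squared on r×c count tables
(no continuity correction, df = (r−1)(c−1)) and the pooled-variance
two-sample Student's t (Welch by flag); both are `scipy.stats` behind the
package surface and both are cross-checked in tests against hand-written
summation formulas. Significance is reported at 0.05 with the
figure-legend convention N.S. / * / ** / ***. Replicate measurements are
reported as mean ± 1.97·SD (sample SD), implementing the stated reporting
convention as given. Zero marginals, zero pooled variance, or groups
smaller than two raise an inapplicable-test error rather than returning a
statistic.

Gene-effect summaries count annotations (a variant annotated against
several genes counts once per annotation). Region comparisons between
mutagen groups are restricted to the *commonly affected regions* — labels
observed in every group — and the retained share of effects is always
reported alongside, so the restriction is auditable; an empty intersection
falls back to the union with a warning. Impact levels are the standard
four-level annotator scale (MODIFIER/LOW/MODERATE/HIGH) and functional
classes (missense/nonsense/silent) apply only to coding substitutions.

## Synthetic data

The generator emulates the study design end to end so that every stage is
testable without sequencing data:

* **Dose response.** Per dose and replicate dish,
  `n_effect ~ Binomial(n_units, rate(D; D₀, m))` with ~20 seeds per dish,
  5 replicates for the carbon grid (0–180 Gy) and 3 for the gamma grid
  (0–400 Gy). Default truth parameters are chosen so the implied readouts
  match the published dose landmarks: carbon survival `(D₀, m) = (64.2, 6)`
  (Dq = 115 Gy, D50 ≈ 142 Gy), gamma survival `(88.1, 49)` (Dq ≈ 343,
  D50 ≈ 376), carbon fertility `(26.6, 45)` (Dq ≈ 101, D50 ≈ 111), gamma
  fertility `(69.1, 45)` (Dq ≈ 263, D50 ≈ 289).
* **Cohorts.** 16 lines per mutagen by default; per-line expected category
  counts are the published group totals divided by 16, drawn Poisson
  (independent induction events), with homozygous fractions 0.2051
  (carbon) and 0.3706 (gamma). Loci are uniform on a 20 × 1 Mb chromosome
  model (plus 10 scaffold names); a guard base around every drawn locus
  prevents accidental adjacency, so the only MNV runs are the planted
  ones, and the locus pool is shared across lines so induced keys are
  cohort-unique by construction. AFs come from uniform windows well inside
  the classification bands (homozygous [0.9, 1.0], heterozygous
  [0.35, 0.65]); an adversarial mode samples near the 0.25/0.75 boundaries
  instead. Planted noise: background keys present in both controls and
  every line, cross-line keys planted in exactly two lines, low-quality
  decoys, and a configurable fraction (default 0.4) of SV loci routed to
  scaffold names — SV expectations are inflated by 1/(1−fraction) so the
  retained spectrum keeps the configured magnitudes. Every record carries
  a ground-truth row (origin, category, zygosity).
* **Annotations.** Region/impact/class assigned by independent categorical
  draws from configurable frequency tables; functional classes are drawn
  only for exonic SBSs.

What the generator does **not** emulate: read-level errors, alignment
artefacts, caller-specific biases, positional clustering of damage, linked
inheritance between variants, and category-specific zygosity mixes (one
homozygous fraction per group, so the tiny published homozygous-SV counts
are not reproduced exactly). Passing end-to-end tests therefore shows the
*filtering and accounting logic* is correct under the stated statistical
structure, not that a real caller's output would be this clean.

All draws come from a single `numpy.random.Generator`; a fixed seed makes
cohorts, written VCFs and reports byte-identical across runs, which the
run manifest (command, seed, config hash, input checksums, stage counts)
makes reproducible from the command line.

## Problem sizes in tests and the acceptance script

Unit and property tests run the cohort generator at 4 lines per group with
per-line expectations scaled to 8% of the study magnitudes — large enough
to exercise every filter with planted records of each kind, small enough
for a fast suite. The homozygous-fraction recovery check uses 8 lines per
group at 25% scale (binomial 3σ criterion), and the acceptance script uses
16 lines per group at 50% scale plus the full published count tables,
which are inputs, not simulation targets. Shoulder-dose recovery under
binomial noise uses 200 simulated replicates of the carbon survival
design.

## Known limitations

* The SHMT fit reports no parameter uncertainty (no profile likelihood or
  bootstrap); `R²` and the grid-oracle tests are the only fit diagnostics.
* With few dose points past the shoulder, `D₀` and `m` trade off along a
  ridge; `Dq` and `D50` are the stable readouts, and individual parameter
  estimates should be interpreted cautiously for steep curves.
* VCF support is deliberately narrow: per-sample FORMAT/AF (INFO/AF
  fallback), SVTYPE/END/MATEID, biallelic splitting. Phasing, gVCF blocks
  and richer multi-allelic semantics are out of scope.
* Missense/silent ratios are undefined (flagged) when no silent
  substitutions are observed; small coding-SBS counts make these ratios
  noisy.
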