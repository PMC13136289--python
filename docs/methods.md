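# Methods

## Scope and data model

`abatune` implements three analysis stages around one biological question —
how ABA binding tunes a transporter-embedded phosphodiesterase — plus the
synthetic-data generators that emulate the corresponding bench designs.
Structural work (pocket detection, docking), raw spectra and chromatogram
processing, and wet-lab protocols are out of scope: inputs are already
reduced to sequences, peak fluorescence intensities and rates (or product
amounts convertible to rates).

## Gapped-motif scanning

A motif is an ordered list of anchor residue classes with bounded spacer
lengths between consecutive anchors. Parsing accepts PROSITE-like text
(`[DE].{7,9}[RH].{8,11}[FY].{6,7}[HRK]` is the package default but the
pattern is always supplied as data, never hard-coded into the scanner).

Design choices:

- **Full enumeration.** Every satisfying anchor-position combination is
  reported, not the leftmost-greedy placement: the binding signature can
  span alternative pockets, and overlapping placements carry information.
  Protein-level counts use a derived boolean, so alternatives never inflate
  them. Output order is span start, then lexicographic anchor positions.
- **Coordinates** are 1-based inclusive, matching residue numbering
  (E657, Y678, K685); converters to 0-based half-open are provided at I/O
  boundaries for interoperation with range tooling.
- **Ambiguity letters** (X, B, Z, J, U, O) are tolerated in sequences but
  never match an anchor class — an uncertain residue is not treated as
  evidence. Input is case-insensitive; a trailing `*` stop character is
  stripped with a warning; any other non-alphabetic character is an error.
- **Overlap** between a match span and a feature interval is
  `max(0, min(ends) − max(starts) + 1)` on 1-based inclusive intervals.

The scanner is validated against an independent exhaustive-enumeration
oracle on hundreds of random sequences, and by 100 % recall of
generator-planted instances.

## Tight-binding titration fitting

The bound fraction under ligand depletion is computed in the conjugate form
`2·La / (b + √(b² − 4·Pt·La))` with `b = Pt + La + Kd`, which is
algebraically identical to the textbook quadratic but avoids catastrophic
cancellation when `4·Pt·La ≪ b²`; a tiny negative discriminant from
rounding at the stoichiometric point is clamped to zero. The implementation
is checked against a bisection solve of the mass-action equilibrium
`(Pt − PL)(La − PL) = Kd·PL` to 1e-10 relative on 10³ random triples, and
against the dilute-limit hyperbola `La/(La + Kd)`.

The fluorescence model is affine in occupancy, `F = F₀ + ΔF·f_bound`, with
the amplitude sign free by default (`signal_mode="auto"`): enhancement and
quenching differ only in the sign of ΔF, so one code path covers wild-type-
like and mutant-like behaviour. How raw intensity maps to occupancy is a
modelling choice of this package; input is already-extracted peak intensity.

Fitting minimizes joint squared residuals over all replicates with shared
(K_d, F₀, ΔF), parametrized in log K_d so positivity is structural:

- **Multistart:** 25 starts on a log grid of K_d spanning
  [10⁻², 10²] × (max ligand); F₀ starts at the mean zero-ligand signal and
  ΔF at the observed span. Best final residual wins; residual ties (1e-9
  relative) break toward the smaller K_d.
- **Uncertainty:** asymptotic standard errors from the Jacobian, with the
  delta method mapping the log-K_d scale to K_d and K_a; an optional seeded
  residual bootstrap (default 1000 resamples when requested) adds
  resampling-based errors and a percentile CI.
- **Diagnostics:** fewer than 4 distinct ligand levels or a missing
  zero-ligand baseline is an error; all-saturated designs (occupancy > 0.95
  at every non-zero ligand level) attach an identifiability warning;
  failure of every start returns a flagged, NaN-valued fit rather than
  silent numbers.

Reported K_a and K_d are exact reciprocals. `compare_affinities` forms the
fold ratio K_a(ref)/K_a(variant); `specificity_report` classifies a ligand
as *residual* when its K_a is at or below K_a(reference)/100 (boundary
inclusive) — a threshold chosen to separate ~10⁹ L·mol⁻¹ specific binding
from the ~10⁶ L·mol⁻¹ residual binding of unrelated hormones.

## Michaelis–Menten kinetics and the modulator series

Rates are specific activities (pmol·min⁻¹·µg⁻¹); raw product amounts are
converted by `product / (time × mass)`. Each modulator level is fitted
separately by least squares with Hanes–Woolf initialization (falling back
to `1.2·max(v)` and `median(S)` when the linearization is degenerate) and
non-negative parameter bounds. Identifiability warnings fire when every
substrate concentration is ≥ 10× the fitted K_M or when the K_M standard
error reaches the estimate — the bench substrate range (10–200 µM) sits
well above the ~5 µM K_M, so the synthetic default grid extends down to
1 µM precisely so that K_M is constrained.

The control is the level with modulator concentration exactly 0; percent
changes are signed, `100·(X_level − X_ctrl)/X_ctrl`. Per-level K_M values
for the non-control generating conditions are set to the control K_M in the
default series, since only Vmax values are established for those levels;
only Vmax changes are interpreted quantitatively.

## Dose–response classification

`biphasic_test` Welch-tests each dose against the control and adjusts the
p-values across doses with Holm's procedure (raw decisions are reported
alongside; `adjust="none"` reproduces unadjusted per-comparison testing).
Classification:

- **biphasic** — some dose significantly above control *and* some strictly
  higher dose significantly below it (hormesis);
- **monotonic_up / monotonic_down** — significant effects of one sign only;
- **flat** — no significant effects;
- a mixed pattern that is not low-up/high-down (i.e. inhibition before
  stimulation) does not fit this four-class scheme and is labelled by the
  sign at the highest significant dose.

Power at the bench design (n = 3, CV 5 %, ±30 % effects) is limited by the
2-df variance estimates: with Holm adjustment the full hormetic profile is
recovered in roughly nine of ten seeded runs, so the recovery-rate property
is exercised at n = 5 replicates, where the Welch+Holm procedure has
essentially full power; the n = 3 design is still exercised at fixed seed.
Requiring fewer than 2 replicates anywhere is an error (variance undefined).

## Two-way ANOVA and the compact letter display

`anova2_tukey` fits `response ~ variant * level` by OLS and uses type-II
sums of squares, which are robust to the mild imbalance a dropped replicate
introduces and coincide with type I/III on balanced layouts. Within each
modulator level, all variant pairs are compared by Tukey's HSD; letters are
assigned from the maximal cliques of the non-significance graph
(Bron–Kerbosch enumeration, trivial at ≤ 6 groups), which makes the display
*exactly* consistent: two groups share a letter iff they are not
significantly different. Empty cells and single-replicate cells are errors
that name the offending cells.

Welch's t-test uses Satterthwaite degrees of freedom; two identical
constant groups return p = 1 by convention, two distinct constant groups
p = 0.

## Synthetic-data generators

All generators take an explicit seed (numpy `default_rng`) and return the
dataset plus a ground-truth record; identical spec + seed reproduces
identical bytes, and zero-noise output lies exactly on the generating
model. Noise is additive Gaussian; the sd is expressed as a fraction of the
natural signal scale — the model signal span for titrations, the level's
Vmax for rates, the level mean (a CV) for dose–response activities.
Replicate noise levels of real assays are unpublished, so the 1–5 % CV
defaults are calibration choices and are recorded in every truth record
alongside the generating parameters.

Defaults encode the bench designs: titrations at 2 nM protein over
0/1/2/4/8/12/16 nM ligand with K_d = 1/(19.27×10⁸ L·mol⁻¹), 3 replicates;
kinetics on a 1–200 µM substrate grid at Vmax 1.19 pmol·min⁻¹·µg⁻¹ and
K_M 5.21 µM for the control (1.58 and 0.75 pmol·min⁻¹·µg⁻¹ at 2 and 50 nM
modulator); dose–response effects {+30 % at 2 nM, +15 % at 10 nM, −30 % at
50 and 100 nM}, multiplicative on the control mean because modulation is
reported as percent change. The proteome generator draws i.i.d. background
residues (uniform by default, configurable frequencies) and overwrites one
constructed motif instance into each of the first `n_planted` sequences,
recording the planted anchor positions; `expected_background_matches` gives
the exact expected number of chance placements per background sequence by
linearity of expectation, used to sanity-check background hit rates.

What the generators do **not** emulate: instrument drift, inner-filter and
scattering artefacts in fluorescence, heteroscedasticity beyond the
per-level scale, correlated replicate errors, and real proteome composition
(domain structure, low-complexity regions). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated noise
model, not robustness to every bench artefact.

## Reproduction pipeline

`reproduce(RunConfig(seed=...))` chains generation → analysis for all
stages at the default parameters and writes a JSON report juxtaposing
recovered and reference values with per-quantity tolerances (±25 % for
association constants and fold ratios, ±10 %/±20 % for Vmax/K_M, ±20 % for
percent Vmax changes, exact match for classifications and recall). The
report embeds the seed and a config hash; the low-affinity-ligand
specificity section titrates to 1000 nM rather than 16 nM because a
~500 nM K_d is structurally unidentifiable inside a 16 nM grid (only the
ratio ΔF/K_d enters the linear regime). The overall `passed` flag maps to
the CLI exit status.

Problem sizes throughout (200-sequence oracle comparisons, 100-seed
recovery loops, 10³ random triples) were chosen so the full suite and the
reproduction script each run in well under a minute on one CPU while
keeping Monte-Carlo error far below the tolerances they check.
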