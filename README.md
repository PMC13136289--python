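# abatune

Quantitative analysis of how the plant stress hormone abscisic acid (ABA)
binds to and tunes a phosphodiesterase (PDE) embedded in the *Arabidopsis
thaliana* K⁺-uptake permease AtKUP5. The package is for biochemists and
computational biologists who work with receptor-like ABA-binding proteins
outside the canonical PYR/PYL/RCAR pathway: it scans proteomes for the
conserved ABA-binding sequence signature, fits tight-binding fluorescence
titrations, fits Michaelis–Menten kinetics across modulator concentrations,
and classifies biphasic (hormetic) dose–response profiles — with seeded
synthetic-data generators that stand in for raw bench measurements and close
the parameter-recovery loop.

## The models

**Motif scanning.** The ABA-binding signature is a gapped four-anchor motif,

```
[DE].{7,9}[RH].{8,11}[FY].{6,7}[HRK]
```

four constrained residue classes separated by bounded variable-length
spacers. A match is any strictly increasing position 4-tuple whose residues
lie in the anchor classes and whose spacer lengths respect the bounds; the
scanner enumerates *all* such placements (validated against an exhaustive
enumeration oracle), and per-protein counting collapses them to a boolean.
Coordinates are 1-based inclusive, matching residue numbering such as the
AtKUP5 binding site E657–K685 that overlaps the PDE catalytic center
Y669–E706 by 17 residues.

**Tight binding.** With 2 nM protein titrated by 0–16 nM ligand and a
sub-nanomolar K_d, free ligand is depleted by complex formation, so the
bound fraction follows the Morrison quadratic

```
[PL]/[P]t = ((Pt + La + Kd) − √((Pt + La + Kd)² − 4·Pt·La)) / (2·Pt)
```

the physical root of the mass-action equilibrium
(Pt − PL)(La − PL) = Kd·PL. Fluorescence maps to occupancy through
F = F₀ + ΔF·(bound fraction) with a *signed* amplitude, covering both
enhancement (wild-type-like) and quenching (mutant-like) in one code path.
`fit_titration` runs multistart nonlinear least squares over a log-spaced
K_d grid and reports K_d, K_a = 1/K_d, asymptotic standard errors and an
optional seeded bootstrap.

**Kinetics.** Rates v = Vmax·S/(K_M + S) are fitted per modulator (ABA)
level with Hanes–Woolf initialization; `modulator_series` expresses signed
percent changes of Vmax and K_M against the zero-ABA control, and
`biphasic_test` classifies an activity-vs-dose profile (per-level Welch
tests against control, Holm-adjusted) as flat, monotonic or biphasic.
Welch's t, two-way ANOVA (type II) with Tukey HSD and a compact letter
display cover the study-style statistics.

## Worked example

```python
from abatune import TitrationSpec, fit_titration, gen_titration

dataset, truth = gen_titration(TitrationSpec(seed=1, kd=1.0 / 19.27e8))
fit = fit_titration(dataset)
print(f"fitted Ka = {fit.ka_1e8:.2f} x 1e8 L/mol (Kd = {fit.kd_nM:.3f} nM)")
```

prints

```
fitted Ka = 19.42 x 1e8 L/mol (Kd = 0.515 nM)
```

a recovery of the generating wild-type association constant
(19.27 × 10⁸ L·mol⁻¹, i.e. K_d ≈ 0.52 nM) from a 3-replicate titration with
1 % noise. `examples/` holds one short script per capability — motif
scanning, binding fits, kinetics series, dose–response classification and
the end-to-end run; `python examples/fit_kinetics.py` prints the per-level
Vmax/K_M table with the +33 % (2 nM) and −37 % (50 nM) Vmax changes that
constitute the biphasic signature.

A thin CLI wraps the same functions:

```
abatune scan --fasta proteins.fasta --out matches.tsv --summary summary.json
abatune simulate --kind titration --seed 4 --out sim/
abatune fit-binding --csv sim/titration.csv --protein-nM 2
abatune fit-kinetics --csv assay.csv
abatune reproduce --seed 0 --out-dir run/
```

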