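# Methods

This note documents the models behind each module, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices that are not visible from the API.

## In-silico proteolysis

A protease is a P1 residue set (cut after), a P1′ blocker set (classically
proline), and optional context patterns around the scissile bond. A pattern
maps relative offsets from the P1 index to residue sets; *allow* patterns
override the P1′ blocker (trypsin cleaves K–P when tryptophan occupies P2),
*block* patterns add vetoes beyond it. Site indices are 0-based and denote
cleavage between `i` and `i+1`; a site therefore lies in `[0, len−2]`, and
with zero missed cleavages the peptides tile the sequence exactly.

Two rule dialects ship because the common web calculators disagree on
context rules and neither publishes a complete matrix:

- `peptidecutter`: trypsin carries the Keil-rule exception table (WKP/MRP
  rescues; CKD, DKD, CKH, CKY, KKR, CRK, RRH, RRR vetoes); chymotrypsin
  vetoes W–M (high specificity) and additionally M–Y (low specificity);
  pepsin (pH 1.3: P1 ∈ {F,L}; pH > 2: P1 ∈ {F,L,W,Y}) is a documented
  simplification of the Keil context matrix — blocked by proline at P1′ or
  P2 and by a basic residue (H/K/R) at P1′.
- `msdigest`: the same P1 sets with plain P1′ blocking and no context
  exceptions.

Every digestibility table records the dialect used. Normalized counts use
`n_sites × 20000 / mass` with the *mature* average mass, since subunit
digestibility is compared on a per-20 kDa basis. Rule sets serialize to
YAML and round-trip identically.

## Equilibrium unfolding

The spectral center of mass (Eq. form `CM = Σ I(λ)·λ / Σ I(λ)`) is computed
as a discrete sum on the raw wavelength grid — no interpolation — because
the quantity is defined on the recorded grid. The unfolded fraction is the
affine map `fu = (CM₀ − CMₓ)/(CM₀ − CM_max)` anchored at the 0 M and
maximal-denaturant references; values outside [0, 1] are retained (noise is
real) and a warning fires beyond ±0.1.

The fit is the standard linear-extrapolation two-state model:
`ΔG(x) = ΔG_w − m·x`, `fu = K/(1+K)` with `K = exp(−ΔG/RT)`,
R = 1.987×10⁻³ kcal/mol/K, T = 298.15 K (configurable). The fit refuses
data whose observed fu span is below 0.5 — without a bracketed transition
the midpoint is unidentifiable — and seeds the optimizer from the fu = 0.5
crossing. Optional folded/unfolded baselines are deliberately omitted: the
fu transformation already normalizes against reference spectra.

Default truth parameters for the synthetic series are ΔG_w = 5.5 kcal/mol
and m = 2.0 kcal/mol/M (Cm = 2.75 M): this reproduces a titration that is
essentially fully folded below 1.5 M GdnHCl and fully unfolded above 4 M.
Spectra are generated on the 315–436 nm instrument window at 1 nm steps as
Gaussian peaks of SD 12 nm moving from 340 nm (folded) to 360 nm
(unfolded). Real tryptophan emission is broader and asymmetric; a Gaussian
suffices here because only peak/CM positions are consumed downstream, and
the 12 nm width keeps edge truncation of the window below the 10⁻⁴ level
on fu.

## SAXS

**Guinier.** `ln I` is regressed on `q²` from the lowest positive-intensity
point. The window is chosen in two phases: first the upper bound is moved
to enforce `q_max·Rg ≤ 1.3` (iterating until Rg changes < 1%), then it is
shrunk while a quadratic term in `q²` still shifts Rg by more than 0.3% —
ideal Guinier data has no such term, so the refinement is a no-op there,
while real form factors (a sphere measured to qRg = 1.3 carries ~2% bias)
trigger a tighter window. The limit is configurable (1.0 is conventional
for elongated particles). Slope ≥ 0 raises "no Guinier decay".

**Kratky.** `q²I` and the dimensionless variant `(qRg)²I/I₀` are pointwise
transforms with no smoothing; for an ideal compact particle the
dimensionless curve peaks at `qRg = √3` with height `3/e`.

**IFT.** P(r) is represented on a uniform 101-point grid over [0, Dmax]
with both endpoints pinned to zero (they are excluded from the unknowns).
The forward model is `I(q) = 4π Σ P(r_j) sinc(q r_j) Δr`; the inverse
problem minimizes `‖(A·p − I)/σ‖² + α‖D₂p‖²` under `p ≥ 0`, solved by NNLS
on the stacked system. α defaults to an L-curve-style corner search over a
7-point log-spaced grid scaled by the operator norms. Missing σ is replaced
by the `sqrt(max(I, ε))` proxy and flagged. Real-space invariants come from
moments: `Rg² = ∫r²P dr / (2∫P dr)`, `I₀ = 4π∫P dr`.

**Dmax scan.** Each candidate support is inverted and scored by reduced
χ². The selected Dmax is the *smallest* candidate consistent with the best
fit, where consistent means `χ² ≤ χ²_min + 0.1(1 + χ²_min)` **and**
`χ² ≤ 100·χ²_min`: the blended first bound acts as absolute slack when the
best fit is essentially exact and relative slack when χ²_min is O(1), and
the ratio cap rejects supports whose misfit is orders of magnitude above
the minimum even when both numbers are tiny (the noiseless-data case).
Truncated supports (Dmax below the particle diameter) fail both; needlessly
wide supports fit equally well but are never preferred. Candidates below
2·Rg_Guinier raise a warning.

The synthetic scattering bodies are a sphere (closed-form amplitude
`3(sin qR − qR cos qR)/(qR)³`) and an ellipsoid of revolution averaged by
64-node Gauss–Legendre quadrature over orientation; truths are the closed
forms Rg = √(3/5)·R and √((2a²+c²)/5), Dmax = 2R and 2·max(a,c). Noise is
Gaussian with SD `(f₀ + f₁·q/q_max)·√(I·I₀ + 10⁻⁶I₀²)` — Poisson-like
counting statistics that grow toward high angle and stay positive at
form-factor zeros (defaults f₀ = 0.01, f₁ = 0.04). The default sphere
radius 54 Å puts the surrogate in the size class of a compact ~300 kDa
oligomer (Rg ≈ 41.8 Å). No bead-model reconstruction is attempted; shape
statements rest on Rg, Dmax and P(r).

## Competitive ELISA

`p = (A − A₀)/(A_max − A₀)` with A_max the zero-competitor maximum and A₀
the no-serum background (the standard competitive reading; assay
descriptions are often ambiguous here, so the convention is fixed and
documented). p is clipped to [10⁻⁶, 1 − 10⁻⁶] with a flag before the logit;
`logit p` is regressed on `log₁₀ C` by OLS after averaging replicate wells
(assays run in triplicate; fitting raw replicates is possible by passing
them as separate standards). Standards with p outside [0.1, 0.9] sit on
the flat rails and are flagged but retained. Inversion multiplies by the
dilution factor and flags extrapolation beyond the standards' span.

The faecal mass balance is explicit:
`recovered = Σ Cᵢ·Vᵢ·(totalᵢ/sampledᵢ)` — extract concentration × extract
volume, scaled from the sampled aliquot to the whole collection — because
published recovery figures rarely print their scaling terms. The synthetic
scenario feeds 2.1 mg, splits a configured 83% recovery across six
collections (0.12 g sampled from 0.2–0.6 g into 0.5 mL extracts), and
centers the standard curve on the expected extract concentration, as an
analyst planning dilutions would. Plate defaults (slope −1.5, A₀ 0.05,
A_max 1.5, triplicates) are plausible for an ABTS read at 405 nm.

## Sequences

Masses use embedded ExPASy-style residue tables (average to 4 decimals,
monoisotopic) plus one water (18.0153 / 18.010565 Da); `X` is rejected, not
imputed. Agreement with Biopython's independent tables is tested to
< 0.5 Da on 50-mers. Signal peptides are never predicted — they come from
GenBank `sig_peptide` features or a `sp=N` FASTA header token — matching a
workflow where prediction is an external step. Pairwise identity uses
global Needleman–Wunsch (match +1, mismatch 0, gap −1, configurable) with
identity = identical columns / alignment length; identity among co-optimal
alignments is not unique, so a substitution-matrix similarity
(BLOSUM62-positive columns) is exposed separately rather than conflated.

The sequence generator reaches exact per-protease site counts by greedy
random single-residue edits (accepting non-worsening moves, capped at
50 000 attempts); all-zero targets simply exclude the P1 residues from the
residue pool. Generated sequences are i.i.d. residues — they have no
composition bias, domain structure or homology, so digestion counts on them
validate the rule engine, not biological realism.

## What passing tests show — and do not

All ground truth is synthetic and matched to the generators' assumptions:
two-state unfolding with Gaussian peaks, ideal homogeneous scattering
bodies with Gaussian noise, an exactly log-linear ELISA response. Passing
therefore demonstrates correctness of the estimators under their stated
models and realistic noise, not robustness to aggregation, inner-filter
effects, interparticle interference, plate drift, or matrix effects in
faecal extracts. Problem sizes throughout (300-point scattering curves,
100-replicate recovery studies, 1000-sequence rule checks) were chosen so
the full suite runs in seconds while keeping Monte-Carlo error well inside
the asserted tolerances.
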