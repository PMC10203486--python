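# Methods

## Scope and model of the data

The package treats a direct-infusion, negative-mode ESI peak list as a set
of (m/z, intensity, S/N) triples. Each compound is assumed to appear as the
singly charged deprotonated ion only — [M−H]⁻, m/z = M − 1.007276 Da (the
proton mass, electron included) — with no adducts, clusters, multiply
charged species, isotopologues or in-source fragments. This is the dominant
ionization mode for phenolics in (−)ESI and is consistent with the catechin
anchor value (C₁₅H₁₄O₆ → 289.072 at three decimals), which the test suite
pins against an independent mass library.

## Spectral processing

Per acquisition: peaks with S/N strictly greater than 4 and relative
intensity at or above 0.1 % of the base peak of the same processed list are
retained (base peak defined after the S/N filter; the base peak itself
always survives). Any sample m/z within 5 ppm of a blank m/z is removed.
Technical duplicates are merged by greedy nearest-first matching at 5 ppm —
each peak used at most once, ties toward the lower-m/z pair — keeping only
peaks present in **all** replicates; consensus m/z is the intensity-weighted
mean and consensus intensity the arithmetic mean, so replicate count does
not inflate abundance. Chromatographic fractions are merged by union, with
peaks within 5 ppm combined by intensity **sum** (total intensity is
conserved). The 5 ppm matching tolerance is half the 10 ppm assignment
window, so two distinct assignable masses are never silently merged; it is
configurable everywhere.

## Formula assignment

Candidates are enumerated exhaustively over C 1–50, H 1–100, O 1–30, N 0–2,
S 0–2: the C/N/O/S grid is scanned and the hydrogen count solved from the
residual 10 ppm mass window, which is mathematically identical to a
five-deep loop (the test suite proves set equality against a naive
quintuple-loop oracle). A candidate must describe a possible neutral
molecule: rings-plus-double-bonds ≥ 0 under standard valences and H + N
even.

**Ranking.** The winner minimizes |mass error in ppm| **plus a
heteroatom-parsimony penalty of 3 ppm-equivalents per N or S atom** (exact
ties break toward fewer heteroatoms, then lower mass; the penalty is
configurable and 0 restores pure nearest-mass ranking). The penalty exists
because the CHNOS space contains near-degenerate substitutions —
CH₄S₂ ↔ O₅ (0.87 mDa), C₁₃N₂ ↔ H₈O₁₁ (0.47 mDa), C₂₁ ↔ H₁₂O₁₃S (0.14 mDa),
SH₄ ↔ C₃ (3.4 mDa) — that nearest-mass ranking resolves no better than a
coin flip at ppm-scale mass error. Measured on synthetic data at 2 ppm
error, pure nearest-mass ranking assigns ~61 % of peaks correctly; with the
penalty the rate is 93–97 %. The cost is deliberate: genuinely N₂- or
S₂-rich compositions will lose to CHO-rich alternatives within ~6 ppm, a
reasonable prior for phenolic extracts but not for, e.g., peptide-rich
samples. The penalty affects only the choice of winner; the enumerated
candidate list itself is complete and sorted by pure |error|.

## Molecular indices and phenolic definition

All indices are computed from integer element counts: elemental ratios
O/C, H/C, N/C, S/C; the heteroatom-subtracting double-bond equivalent
DBE = 1 + C − O − S − ½(N + H), which may be negative and differs from the
textbook rings-plus-unsaturations 1 + C − H/2 + N/2 (both are reported —
the first drives the headline summaries, the second is the standard
chemical quantity); the modified aromaticity index
AImod = (1 + C − ½O − S − ½(N + H)) / (C − ½O − N − S) with the common
FT-MS convention AImod = 0 when the denominator is non-positive or the
numerator negative; and NOSC = 4 − (4C + H − 3N − 2O − 2S)/C. A formula is
phenolic iff 0.6 < H/C < 1.5, 0.3 < O/C < 0.85 and AImod < 0.67, all
inequalities strict. Note the AImod numerator subtracts ½N together with
½H; with N = 0 this coincides with the more common form that subtracts ½H
only.

Summaries over an assigned peak list: the relative phenolic intensity is
the phenolic share of **total** processed-list intensity (assigned or not;
an alternative denominator over assigned peaks only would differ by the
unassigned share). The Gini–Simpson diversity DA = 1 − Σ pᵢ² is computed
over distinct formulas with peak intensities pooled per formula; weighted
average m/z and weighted indices use peak intensities as weights. All
summaries are invariant to rescaling every intensity by a constant.

## Mass-difference networks

Every unordered pair of node m/z is tested against every transformation
mass; an edge is emitted when |Δm/z − m_t| ≤ 2 ppm × the larger member m/z.
The ppm reference is a design choice: 2 ppm of a 57 Da residue mass would
be 0.1 mDa, far below instrumental accuracy, whereas both node masses carry
an error proportional to their own m/z. An absolute-mDa mode (default
0.5 mDa) is available, and the chosen mode is logged on every run. All
qualifying (pair, transformation) combinations are kept as parallel edges.
The built-in table (~44 entries: amino-acid condensation residues,
nucleobases, sugar residues, functional-group and small-metabolite
increments including glyoxylate, adenine, allantoin) is computed from
formulas at import time, grouped by heteroatom content (S → group 1,
N only → 2, N and O → 3, O only → 4), and fully user-replaceable via a CSV
with name/exact_mass (optional formula and group; a stated mass more than
1 mDa from its formula's mass is rejected).

## Dose–response model

Viability follows the four-parameter logistic
response = bottom + (top − bottom)/(1 + (d/EC50)^hill) on log₁₀ dose with
bottom ≥ 0. Fitting minimizes least squares of **log response** by default —
the maximum-likelihood choice under multiplicative (lognormal) count noise;
zero responses fall back to the linear scale. In simulation at cv = 0.1
this halves the EC50 error relative to linear-scale fitting (median
|relative bias| 13 % → ~6 % with single measurements, 4.4 % with duplicate
measurements). Initialization is a deterministic multistart grid (hill ∈
{0.5, 1, 2, 4} × EC50 at the dose quartiles); the standard error of EC50
comes from the curvature of the fit via the delta method on log₁₀ EC50; r²
is computed on the fitted scale; an EC50 outside the tested dose range is
flagged as extrapolated. A two-parameter variant fixes bottom = 0 and top
at the mean lowest-dose response.

## Synthetic data: what it emulates, and what it does not

The generator draws a library of distinct CHNOS formulas (45 % phenolic by
construction by default), gives them lognormal intensities, and renders
them as [M−H]⁻ peak lists with contaminant peaks shared at *identical* m/z
between samples and blank (so blank subtraction is exactly testable), S/N
proportional to intensity over a constant noise floor (half the
contaminants sit below S/N 4 by construction), two technical replicates,
three chromatographic fractions (mass tertiles), and per-treatment planted
phenolic intensity shares — defaults 2.04 % (control), 2.88 % (Cd), 3.02 %
(Cu), 2.95 % (Co); only two metal-culture reference values exist, so the
third is set at their midpoint. Group sizes default to the exposure
design: triplicate control, duplicate metals.

Choices a user should know about:

* **Mass error** is Gaussian in ppm, applied multiplicatively, total scale
  2 ppm by default, split 70 % / 30 % (in variance) into a per-peak
  *systematic* calibration residual shared by every acquisition of a batch
  and a per-acquisition random part. TOF calibration drifts slowly, so
  within one measurement sequence most of the error at a given m/z
  repeats. The split matters: fully independent 2 ppm errors would lose
  ~8 % of peaks at the 5 ppm replicate-consensus match and make
  misassignment contamination fluctuate between treatments.
* **Composition realism.** Phenolics use C 7–25 (ion m/z ≲ 650, where
  typical flavonoids, phenolic acids and small glycosides sit), O ≤ 15
  (13 when S is present), never N and S together; non-phenolics use
  C 5–28, O ≤ min(0.9 C, 12); N ≤ 1 and S ≤ 1 throughout, both rare. The
  excluded compositions are exactly those that are mass-degenerate with
  CHO alternatives at sub-mDa splits — unassignable in principle at 2 ppm
  accuracy — and are implausible phenolic-extract constituents.
* **Resolvability.** Accepted formulas keep ≥ 12 ppm mutual ion spacing;
  two species closer than the 5 ppm merge tolerance are unresolvable by
  definition, so a resolvable ground truth never contains such a pair.
* **Intensities.** Non-phenolic intensities are lognormal(μ = 6, σ = 1)
  capped at μ + 2σ (detector-saturation-like); phenolics use the narrower
  σ = 0.35 so that a 2–3 % planted share spread over ~100 formulas still
  clears the 0.1 % relative-intensity and S/N 4 cut-offs peak by peak. The
  planted share is enforced by alternating rescale/clip passes and is
  exact when the intensity floor does not bind (always slightly above
  target, monotonically, when it does — the per-group *realized* share is
  reported alongside the requested one).

Not simulated: isotopologue patterns, adduct diversity, chromatographic
peak shape, in-source fragmentation, retention-correlated intensity,
matrix effects. Passing tests therefore demonstrate correctness of the
*processing chain* under the stated error model, not robustness to those
real-data phenomena.

## What recovery the pipeline can and cannot promise

With zero mass error and zero intensity jitter, the full pipeline returns
the generator's formula set, phenolic subset, relative intensity share,
DA, weighted average m/z and weighted indices exactly (a frozen test). At
2 ppm error, ≥ 90 % of surviving peaks receive their true formula, and the
control group's planted-lowest phenolic share is recovered as strictly
lowest. The ~2 % relative gaps *between the metal treatments* are below
the irreducible contamination noise that the ~3–6 % residual
misassignment rate injects into the intensity share, so the full four-way
ordering is not a reliable output of the method at this error scale — a
limitation of the measurement, not of the implementation.

With duplicate or triplicate biological groups, the exact rank-sum test
cannot reach p < 0.05 (the minimum two-sided p at n = 2 vs 2 is 1/3, at
n = 3 vs 2 it is 0.2); the module computes exact enumeration p-values for
n ≤ 10, emits compact letters, and logs a warning that significance claims
at these sizes are fragile. No multiple-testing correction is applied by
default (α = 0.05 per test); Holm step-down is available behind a flag.

## Problem sizes used by the shipped analyses and tests

The analysis scripts and the end-to-end tests use 300-formula libraries
(~135 phenolics), 20 contaminants, 9 biological samples × 3 fractions × 2
technical replicates, and 200-seed EC50 simulations at 8 doses × 2
measurements — sizes at which every stage's behaviour is already stable
and a full run completes in well under a minute.
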