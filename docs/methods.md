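# Methods

This note records the models implemented in porephys, the defaults and
tolerances they carry, and the design choices made where more than one
reasonable convention exists.

## Coordinate model and annotation

Atomic models are read with gemmi from mmCIF or PDB into a flat atom list.
Author residue numbering is canonical throughout, because the literature on
these receptors refers to author numbers (β3 His267, α1 Ser272). For
altloc duplicates the highest-occupancy conformer is kept, ties broken by
altloc identifier order; waters are dropped by default since no ordered
pore water is part of the analyses the package supports.

Prime indices −2′..20′ along the pore-lining M2 helix map to author residue
numbers by a fixed offset from the 17′ anchor (β3 267, α1 272):
`residue(i′) = anchor + (i − 17)`. This assumes contiguous numbering across
M2, which holds for the receptor constructs targeted here; a chain with
non-contiguous numbering needs an explicit per-residue table instead of the
offset rule (not implemented until a real case requires it). Pentamer
positions A–E are assigned in the order chains are listed in the annotation
spec (deposition chain order by default, overridable in the TOML config);
position C carries the flag marking the subunit that sits where the γ
subunit would in synaptic-type receptors.

## Pore profile

The profile is a maximal-inscribed-sphere ("HOLE-style") calculation. At
each axial station the sphere centre is optimized within the plane
perpendicular to the pore axis by Nelder–Mead, seeded from the previous
station's centre and restarted from the axis whenever the search strays;
this makes the profile deterministic for a given model, step and radii
set. Defaults: step 0.25 Å; radius cap 10 Å in vestibule regions; stations
whose centre will not stay within 5 Å of the axis are flagged rather than
dropped. The profile is validated against an exhaustive 0.01 Å in-plane
grid search on small fixtures (agreement within 0.05 Å).

The van der Waals radii ship as the named set `hole-default`
(C 1.85, N 1.75, O 1.65, S 2.00, P 2.10, H 1.00 Å), matching the simple
radii conventionally used for channel profiling; unknown elements fall back
to 2.00 Å, and bare Zn²⁺ carries its 0.74 Å Pauling ionic radius so that a
bound ion can be profiled as a physical obstruction. Hetero atoms are
excluded by default (open-pathway profiling) and included with
`include_het=True` (blocked-pore profiling). A probe sphere (rather than a
capsule) is assumed throughout.

The pore axis is the least-squares line through the Cα ring centroids of
all resolvable prime indices, oriented extracellular → intracellular;
profile axial coordinates run the other way, zero at the −2′ ring centroid
and increasing extracellularly, which is how pLGIC profiles are plotted.
Gate diameter at a prime ring is twice the minimal profile radius within
±2 Å (default window) of that ring's axial position.

Helix tilt uses the principal (largest-variance) direction of the segment's
Cα coordinates, default segment 0′–20′, folded into [0°, 90°]. A principal
axis is preferred over a cylinder fit because it is robust for ~20-residue
helices; the declared tolerance for tilt comparisons is ±0.5° (convention
sensitivity), while constructed fixtures are recovered within ±0.2°.
Superposition is standard Kabsch (SVD with determinant correction),
cross-checked in the tests against an independent implementation. The
default atom for loop-C displacement measurements is the β3 Phe200 Cα
(apex of loop C); the published displacement figure depends on this choice,
so it is configurable and treated as indicative rather than a gate.

## Ideal-pore fixtures

The synthetic generator places each chain's Cα trace on a straight line
(the helix axis, one residue per 1.5 Å rise), pivoted at the 9′ residue and
tilted purely radially, so that the construction tilt, ring radii,
pentagon perimeters and minimal pore radius are exact closed forms. What
these fixtures do *not* emulate: side chains, helical wobble of the Cα
trace about the helix axis, sequence variety, or missing atoms. Passing
the oracle suite therefore demonstrates correctness of the geometry code,
not robustness to the full messiness of experimental models; the
jitter option (Gaussian coordinate noise applied after ground-truth
capture, seeded) covers moderate coordinate error, and the reader path is
exercised by writing fixtures as standard PDB.

## Free ion buffering

The chelator-buffered free metal concentration uses the linearized
excess-chelator relation `[M]free = α·K_d·[M]total/[L]total` with
`α = 1 + [H⁺]/K_a`, `[H⁺] = 10^(−pH)`. Defaults are the tricine/Zn²⁺
constants: K_d 10 μM, K_a 7.08×10⁻⁹ M, 10 mM tricine, pH 7.4. Direct
evaluation gives α = 6.6230 (and 6.6215 with [H⁺] rounded to 3.98×10⁻⁸ M),
whereas the value conventionally quoted for these recording conditions is
6.623777; the ~0.03 % difference is a rounding convention, not a model
disagreement, so `alpha_override` lets a user reproduce published tables
digit for digit. The formula is linear by construction; an exact 1:1
equilibrium solver (quadratic in free metal, conditional
K′ = α·K_d) is provided as a cross-check and diverges, as it should, when
the chelator is not in large excess (a warning is raised below 10-fold
excess).

## Gating simulation

Dwells are drawn directly from the open and closed mixture-of-exponentials
densities (component chosen with probability A_i, duration ~ Exp(τ_i)),
not from an underlying rate matrix. This is deliberate: the downstream
analysis estimates exactly these mixture parameters, so ground truth is
known without solving an eigenvalue problem, at the cost of not modelling
correlations between adjacent dwell classes. A Q-matrix mode would be the
natural extension if correlation structure ever matters.

Two schemes ship. `a1b3-like`: open τ 0.65/4.3 ms with areas 0.83/0.17,
unitary 1.3 pA — the published open-time phenotype of binary α1β3 receptors
at near-saturating GABA and −70 mV. `a1b3g2-like`: open τ 0.78/4.8 ms,
areas 0.39/0.61, 1.9 pA — the γ2-containing synaptic-type phenotype.
Closed-time mixtures are not published for these conditions, so they are a
package choice made once: 0.5/30 ms at 50:50 for `a1b3-like` (whole-record
P_o ≈ 0.08, matching the low open probability of the binary receptor) and
0.5/10 ms at 60:40 for `a1b3g2-like` (P_o ≈ 0.43).

Traces are rendered at 20 kHz with additive Gaussian noise followed by a
4-pole low-pass Bessel filter at 5 kHz — the standard acquisition chain —
implemented as a digital bilinear-transform design applied forward-only
(causal), mirroring an analog filter. Its 10–90 % step rise time matches
the textbook 0.3321/f_c relation within 15 %. Multiple independent
channels are summed sample-wise so simultaneous openings stack.

## Idealization

The unitary current comes from a Gaussian mixture over the all-points
amplitude distribution (scikit-learn EM under the hood); the baseline is
the dominant component's mean, matching the histogram convention, and the
open level is the nearest component separated from the baseline by more
than twice the summed standard deviations — an all-shut record therefore
raises rather than returning a fictitious unitary current.

Events are detected by 50 % threshold crossing, with multi-level thresholds
at (k − ½)×unitary for k = 1, 2, …; only level-1 occupancy defines open
dwells, and time at level ≥ 2 is tracked per event for the stacking rule
(reject a patch when stacked openings exceed 2 % of open time — strictly
greater, so an exactly-2 % record passes). Interior events shorter than
the dead time (default 80 μs) are merged into the flanking state, shortest
first, which is idempotent; no missed-event correction is applied to the
fitted time constants afterwards (deliberately, to match common practice
with half-amplitude idealization). First and last events are censored by
the record boundaries; they are flagged and excluded from dwell statistics
by default, since their true durations are unknown.

## Dwell-time fitting and selection

The default fit is maximum likelihood on raw durations with the mixture
density left-truncated at the dead time; the likelihood is maximized by
Nelder–Mead over (log τ_i, area logits) with 10 seeded multi-starts spread
log-uniformly over the data range, best objective kept. The alternative
`ls_histogram` route fits expected bin counts to a log-binned histogram
(25 bins per decade, Sigworth–Sine style) by Levenberg–Marquardt, for
comparability with legacy analyses. The two routes agree within 5 % on
single-exponential data at n = 10⁴.

Component count: for least-squares fits, nested models are compared by a
stepwise F-test, `F = ((SSR₁−SSR₂)/(df₁−df₂))/(SSR₂/df₂)` with
parameters-per-model 2n−1 (areas constrained to sum to 1) and α = 0.05;
for MLE fits, where an SSR is not defined, a likelihood-ratio χ² with two
extra degrees of freedom per component is used instead — a documented
substitution, not the same test. Equal SSRs retain the smaller model.

τ_crit between a fast and a slow closed component solves
`A_f·e^(−t/τ_f) = A_s·(1 − e^(−t/τ_s))` (equal *numbers* misclassified) by
bracketed root finding in (τ_f, τ_s). Several τ_crit conventions exist;
equal-numbers is the default here, with `equal_proportions` selectable.
For extreme area ratios the crossing can fall outside (τ_f, τ_s); that is
reported as an error rather than silently extending the bracket. Bursts
are maximal stretches containing an opening whose internal gaps are all
below τ_crit; zero bursts is a legal outcome (sparse low-P_o records).
Whole-record open probability is total open time over record duration.

## Dose–response

Hill and inhibition equations are fitted by least squares with the
midpoint parameterized as log₁₀(EC₅₀) for conditioning; fits are per cell
and summarized as mean pEC₅₀ ± s.e.m. on the log scale (the convention for
reporting potency), with the mean transformed back to molar. Inputs are
assumed normalized to each cell's maximal response. P_A is the ratio of
peak maximal agonist current to the peak current with a saturating
positive modulator co-applied; peak (not steady-state) currents are
assumed. An EC_f helper inverts the fitted curve:
`EC_f = EC₅₀·(f/(1−f))^(1/n)`.

## Test problem sizes

The statistical acceptance checks use 20 seeded simulations of ~10⁴ open
dwells per scheme for parameter recovery (median relative error of both τ
under 5 %, long-opening percentage within 3 points), 200 datasets for the
F-test false-positive rate (≥ 90 % single-component selections) and 40 per
scheme for its power (≥ 95 % two-component selections). These sizes give
stable pass/fail behaviour across seeds while keeping the full suite under
a minute of statistical computation.

## Known limitations

- The deposited receptor coordinate files are not redistributed; the tests
  that evaluate published gate metrics on them require the user to supply
  the mmCIF files locally, and fail with an explanatory message otherwise.
- No missed-event (dead-time) correction of fitted τ beyond likelihood
  truncation; no hidden-Markov idealization; no subconductance analysis.
- The pore profile uses a spherical probe and modeled atoms only — residues
  with disordered side chains contribute only their modeled atoms, so
  profiles through such regions are indicative.
- The simulator's phenomenological dwell model carries no open↔closed
  correlation structure and no ligand-concentration dependence.
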