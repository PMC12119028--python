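# Methods

## The COI gating model

`ryrgate` treats the RyR tetramer as an MWC system with three concerted
macrostates — closed (subsuming the primed sub-state), open, and
inactivated. All four monomers switch macrostate together; ligand binding
does not gate directly but re-weights the macrostate free energies.
Transitions are spontaneous and the model is equilibrium-only: no kinetic
rate constants, dwell times, or explicit ATP/caffeine binding steps (the
effect of ATP is absorbed into the allosteric factors of the groups fitted
with ATP present).

Each monomer has two divalent-binding sites: the activation site (ligands
Ca²⁺ with dissociation constant K_Ca, or Mg²⁺ with K_Mg) and the
unselective inhibition site (ligand M²⁺ = Ca²⁺ + Mg²⁺, constant K_M).
A macrostate's per-monomer statistical weight sums its six binding
configurations (activation empty/Ca/Mg × inhibition empty/M). In the full
parameterization every non-reference macrostate carries an allosteric
factor per site (f_Ca, f_Mg, f_M open; h_Ca, h_Mg, h_M inactivated) and an
interaction factor per doubly-occupied configuration (g_CaM, g_MgM closed;
f_CaM, f_MgM open; h_CaM, h_MgM inactivated). A factor < 1 increases the
affinity in that macrostate; 1 decouples it. Cross terms are the product
of the two single-site terms times the interaction factor — e.g. the
open-state Ca+M term is [Ca][M]/(f_CaM · f_Ca K_Ca · f_M K_M) — so setting
f_M = h_Ca = h_Mg = f_CaM = f_MgM = g_CaM = g_MgM = 1 collapses the full
form to the reduced 8-parameter form *by construction*; `form="reduced"`
is a view of the same code path, not a second formula.

The tetramer open probability is
P_O = (w_O⁴/K_O0) / (w_O⁴/K_O0 + w_C⁴ + w_I⁴/K_I0),
with K_O0 = K_I0 = 10 800 for the published parameter sets (the unliganded
channel closed ~10⁴:1; open and inactivated unliganded states taken as
thermodynamically equal). The 4th power is the concerted-tetramer
assumption; `microstate_oracle_po` checks it independently by enumerating
all 6⁴ per-macrostate occupation microstates and summing term products,
which must (and does, to < 1e-10 relative) reproduce w⁴.

### Units

Concentrations are stored in mol/l; every user-facing interface speaks µM
(`IonCondition.from_uM`, CSV columns `ca_uM`/`mg_uM`), with the single
conversion constant `MOLAR_PER_UM = 1e-6` in `coi_model`. Dissociation
constants are carried in µM as in the fitted tables; only concentration/K
ratios enter the weights, so the conventions meet consistently there.
[M] is always recomputed as [Ca] + [Mg], never stored independently.

### Numerical choices

Weights reach ~10⁷ at millimolar divalent concentrations and ~10¹³ at the
10 M probe used for asymptote checks; the three w⁴ terms are formed after
dividing by the largest weight, so P_O stays finite (verified at 10 mM and
10 M on both axes). The high-Ca plateau of P_O converges to its closed
form only like K_M/[Ca] per weight (~4·K_M/[Ca] in P_O), so closed-form
comparisons at 1e-6 relative tolerance are made at [Ca] ≥ 1e5 M where the
expansion has converged; at 10 M the agreement is ~2e-4, exactly the
truncation bound.

## Global fitting

The objective is the pooled chi-square Σ((P_O,model − P_O,obs)/SEM)² over
all groups; observations with SEM ≤ 0 are rejected rather than silently
unweighted. Every parameter has per-group status fixed(value), shared(tag)
or free; `table8_fitspec()` ships the published scheme — K_O0, K_I0, K_M,
f_Mg, h_MgM fixed everywhere, h_M fixed at 1 for the RyR2 groups, K_Ca and
K_Mg shared across groups, f_Ca free per group, h_CaM free for RyR2+ATP
and shared between the two ATP-free groups — eight free slots in total.

All constants and factors are strictly positive, so free parameters are
optimized as natural logarithms (no hard bounds; the optimizer's log-values
are clamped to ±500 only to keep exploratory steps finite on redundancy
ridges). Standard errors come from the covariance of the weighted
least-squares solution, mapped to the natural scale by the delta method
(SE(K) = K·SE(ln K)). The covariance is *not* rescaled by the reduced
chi-square by default, because the synthetic generator's SEMs are true
standard errors; `FitSpec(scale_covar=True)` restores the conventional
rescaling for real data of uncertain SEM quality.

Initialization defaults to the published values for the known group
labels, else 1 (log 0); `FitSpec.initial` overrides per free slot. Plain
Levenberg–Marquardt has a finite basin: from starts beyond roughly 2× the
truth on every parameter simultaneously it can run off along the h_M/h_CaM
ridge on noise-free data, so start near plausible values (or multi-start).

Per-parameter dependency is 1 − 1/VIF with VIF the diagonal of the inverse
correlation matrix of the estimates; values above 0.99 — or a singular or
absent covariance, which is the same pathology at full strength — raise a
near-redundancy warning in `FitResult.warnings`. The archetype is the
h_M–h_CaM pair: bell-shaped P_O curves constrain their product far more
tightly than either factor, so freeing both in one group is flagged.

Two coefficients of determination are reported: the primary unweighted
COD = 1 − SS_res/SS_tot over the pooled data (the standard definition) and
a 1/SEM²-weighted variant as a diagnostic; the published single COD value
does not state its weighting, so both are cheap to compare.

Reported values are invariant to observation and group ordering because
datasets are canonically sorted before fitting. `sensitivity_scan` re-fits
with one parameter pinned at each scan value (by default in the groups
where it is fixed — the published procedure for probing assumed values like
h_MgM and the RyR2 h_M), tabulating chi-square, COD and every co-fitted
parameter; scan-point failures are recorded and the scan continues.

## Synthetic data

`paper_design()` reproduces the published three-group layout: Ca-sweeps at
Mg = 0/600/940 µM (7/7/6 points, 0.1–100 µM) and Mg-sweeps at Ca =
0.1/0.41 µM (6/6 points, 20–1300 µM) for RyR2 with ATP; Ca-sweeps over
0.1–4000 µM without ATP for RyR2 (8 points) and RyR1 (7+7 points, two
source laboratories) — 8 relations, 54 points. Grids are log-spaced,
mirroring single-channel practice; the per-relation point counts are this
package's even-spread choice, since only the totals are published.

The default noise model (`gaussian_sem`) draws P_O + N(0, SEM) clipped to
[0, 1], with SEM = clip(0.15·P_O, 0.005, 0.10) — floor 0.005, 15%
relative, capped at 0.10 to match the SEM scale of the published figures.
`binomial_events` instead counts N independent gating observations
(default 400) and reports the exact sampling SEM √(p(1−p)/N). Everything
is deterministic under a fixed seed, including the replicate streams of
`recovery_experiment` (spawned from one `SeedSequence`).

What the generator does *not* emulate: gating time series and their
autocorrelation, lab-to-lab condition differences within a group,
non-Gaussian errors of very low-activity records, and luminal-Ca effects.
Passing recovery tests therefore demonstrate correctness of the estimator
under the stated error model at the published design — not that real
recordings satisfy that error model.

A consequence worth stating plainly: under this design the h_M/h_CaM pair
is identified essentially only through its product. Across 100 replicate
fits the six well-identified free parameters show nominal 2-SE coverage
(92–98%), while h_M (RyR1) and the shared −ATP h_CaM sit near 84–85% —
the linearized SEs understate the curvature of the ridge, and the product
is recovered several-fold more tightly than either factor. The dependency
diagnostic and the reported product are the intended remedy, matching how
the published analysis itself presents h_M·h_CaM.

## EF-hand identity score

The score compares a 12-residue loop position-by-position against allowed
residue sets derived from the canonical EF-hand pattern (position 1
restricted to D/N/S, position 2 unrestricted). x counts matches over all
12 positions, y over the six ion-binding positions, z over the three
critical ones; output is `x/y/z (total)`. The shipped table is calibrated
so that all published worked examples reproduce: beyond the naive pattern
sets it allows G at position 3, P at position 6 (both turn-forming, like
the canonical G), L at position 9, T at position 12, and rejects R at
position 11. The position-11 exclusion is what separates the two RyR2 EF1
variants (total 18) from a naive count of 19; 18 is the published total
and is two points above the RyR1 EF1 loop, which pins the calibration.
The table is data (YAML round-trip) and the worked-example test fails
loudly if any future edit breaks an example.

## Structure metrics

Residue numbering follows the coordinate file (author numbering); the
shipped domain tables map the core domains across isoform numbering
conventions. Insertion codes are rejected outright; for altlocs the
highest-occupancy conformer is kept.

The maximum interaction distance between an acidic donor (D/E) and a basic
acceptor (K/R) is d_D + d_A + 2.7 Å, where the side-chain reaches are
measured once from idealized all-trans extended side chains built from
standard internal coordinates (sp³ bonds 1.52–1.53 Å at 111°, carboxylate
C–O 1.25 Å and guanidinium C–N 1.33 Å at 120°), giving D 3.68, E 4.91,
K 6.30, R 7.27 Å. The endpoints are the Cα and the farthest O (donor) or
N (acceptor); the idealized-geometry source is this builder, shipped in
`_SIDECHAIN_ZMAT`.

RMSD₁₀₀ first superposes the structures on a separate alignment domain
(default: the Central-domain sub-intervals resolved in all RyR structures)
with a proper-rotation Kabsch fit, then computes the Cα RMSD over the
measured domain and normalizes: RMSD₁₀₀ = RMSD/(1 + ln √(N/100)).
Values > 2 Å are flagged significant. The normalization factor crosses
zero near N ≈ 14, where the formula is meaningless — domains that short
raise an error (the 13-residue S45 linker is the practical example), and
N < 20 warns.

The flexion angle needs an operational definition of the "horizontal
plane": here it is the plane perpendicular to the channel's four-fold
axis, estimated as the normal of the best-fit plane through the chain
centroids (≥3 chains required), sign-fixed to a non-negative z component;
an explicit `axis=` overrides both estimation and orientation for
fragments or unusual frames. The angle is arcsin of the dot product
between the unit Cα(348)→Cα(1052) vector and the axis — negative when the
shell reference line dips toward the membrane.

Toy-structure generators (ideal helical Cα traces, four-fold tetramers
with constructed tilts, rigid-motion copies) provide exact fixtures for
all of the above and write valid PDB/mmCIF via gemmi.

## Problem sizes and defaults used in the shipped checks

Oracle equivalence uses 50 random parameter/condition draws; recovery
coverage uses 100 replicates of the 54-point design (each global fit takes
tens of milliseconds); sensitivity scans use 4–5 scan points over the
published intervals. These sizes make the whole suite run in seconds while
keeping Monte-Carlo noise on coverage estimates at the few-percent level.

## Known limitations

* Equilibrium only; no kinetics, no explicit ATP/caffeine states, no
  luminal-Ca regulation.
* The fitted SEs are linearized; on the h_M/h_CaM ridge they understate
  uncertainty (see above) — profile likelihood would be the next step.
* Plain LM without multi-start; far-off initializations can stall.
* The EF-hand table is calibrated to the published worked examples, which
  constrain, but do not uniquely determine, every position set (P at
  position 6 vs K at position 8 was resolved in favour of the turn-forming
  proline).
* Structure metrics assume author numbering is consistent between compared
  structures; no sequence alignment is performed.
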