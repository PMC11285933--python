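# Methods

## Models

Both models are closed-loop hydraulic networks written as ODEs in stressed
volumes, compartment pressures and (where inertance exists) flows.

**Single-ventricle model (9 parameters).** States (V_lv, P_sa, P_sv). The
left ventricle is an active chamber, P_lv = E(t)(V_lv − V0); the aortic and
mitral valves are ideal diodes with forward resistances Z_ao and R_mv; the
systemic circulation is an arterial compliance C_sa, a lumped resistance
R_s and a venous compliance C_sv:

    dV_lv = Q_mv − Q_av
    dP_sa = (Q_av − Q_s)/C_sa,   Q_s = (P_sa − P_sv)/R_s
    dP_sv = (Q_s − Q_mv)/C_sv

**Ventricle-plus-atrium model (20 parameters).** States (V_lv, V_la, P_sas,
Q_sas, P_sat, Q_sat, P_svn). The atrium is a second active chamber whose
activation is shifted by E_shift = 0.92 s; the aortic sinus and systemic
artery are C–R–L compartments; arteriolar and capillary resistances act
purely in series with the arterial branch (R_sat + R_sar + R_scp — only
their sum enters the dynamics, which the tests assert as a swap symmetry);
the venous return is an R–C element into the atrium. This series-collapsed
topology is the one consistent with exactly the 20 named parameters.

**Activation.** Both chambers use the double-cosine normalized elastance:
cosine rise on [0, τ_es), cosine fall on [τ_es, τ_ep), zero until the cycle
ends (τ = 1 s), evaluated on (t − shift) mod τ. E(t) interpolates E_min to
E_max.

**Nominal values** are the package's built-in parameter tables
(`cvgsa.models.ONE_CHAMBER_PARAMS` / `TWO_CHAMBER_PARAMS`): elastances in
mmHg/mL, timings in s, resistances in mmHg·s/mL, compliances in mL/mmHg,
inertances in mmHg·s²/mL.

**Initial conditions and V0.** Defaults: V_lv = 500 mL (V_la = 20 mL),
arterial pressures 70 mmHg, venous 7 mmHg, flows 0; unstressed volumes
V0 = 0. Both choices are configurable, but with V0 = 0 every term of both
systems is positively homogeneous of degree 1 in the state, so the initial
total stressed volume only rescales the trajectory. Variance-ratio indices
and angle-based orthogonality are invariant to that rescaling — the
sensitivity results provably do not depend on the initial condition. The
run manifest records both anyway.

**Integration.** An adaptive Dormand–Prince 5(4) step with rtol = atol =
1e-8 integrates 16 cycles; 200 points of cycle 15→16 are the saved beat
(steady periodic to <1e-3 of channel range, asserted in tests). The solver
is a numba kernel that loops samples in a batch, which is what makes the
N(n+2)-evaluation pick-freeze budgets affordable (~1.7 ms per solve); rows
whose step size collapses are retried once with scipy's stiff BDF solver on
the identical right-hand side, then flagged. Flagged rows are deleted
*pairwise* — the same rows from f(A) and every f(AB_i) — and the effective
N is reported; a run aborts if more than 5% of rows fail. An independent
scipy DOP853 integration of the plain-numpy right-hand side serves as the
cross-check oracle in the tests (agreement to ~1e-5 of channel range).

## Sampling

Designs are generated on [0,1)ⁿ and scaled affinely to per-parameter
bounds; the default bounds are 0.5–1.5× nominal (symmetric multiplicative
window, keeps every parameter positive, configurable per parameter).

* `uniform` — i.i.d. draws. `lhs` — standard Latin hypercube (scipy),
  exactly one point per axis stratum.
* `golden` — additive recurrence frac(i·αⱼ) with αⱼ = φₙ⁻ʲ from the
  generalized golden ratio (the positive root of x^{n+1} = x + 1); a seed
  applies a Cranley–Patterson rotation.
* `lattice` — rank-1 lattice frac(i·z/N). The generating vector is
  Korobov-form (1, a, a², …) mod N with the multiplier chosen by a
  deterministic search minimizing the standard shift-invariant P₂
  worst-case-error criterion, so the vector is a pure function of (N, n);
  an explicit generator can be passed instead. Seeded rotation as above.
* `sobol` — scipy's Sobol' sequence, standard direction numbers,
  unscrambled, zero point kept, so prefixes of a longer sequence reproduce
  shorter designs exactly.

Pick-freeze systems use A,AB_i (column substitution; samples are rows). For
the QMC samplers A and B are the first/last n columns of one 2n-dimensional
design (so the pair inherits the joint low-discrepancy structure); for the
MC samplers they are two independently seeded draws.

One caveat the defaults inherit: a 0.5–1.5× window around τ_es = 0.3 and
τ_ep = 0.45 lets about 19% of draws invert the two timing parameters. The
evaluation kernel branches sequentially (rise while t < τ_es, fall while
t < τ_ep, else baseline), so inverted draws degenerate to an instantaneous
relaxation at τ_es and remain integrable; they are deliberately *not*
discarded, since rejecting a fifth of the design would bias the indices and
break the pick-freeze pairing. The strict `ParameterVector`/`elastance` API
still enforces τ_es < τ_ep for user-constructed inputs.

## Estimators and averaging

All four estimators divide their numerator by the matching convention's
variance, making S_T a variance ratio on the scale of [0,1] (Homma/Sobol'
can go negative at finite N; Jansen/Janon cannot, their numerators being
sums of squares). The Janon estimator uses pooled moments over f(A) and
f(AB_i); its numerator is computed as pooled-second-moment minus cross term,
which equals Var − Σf(A)f(AB_i)/N + f0² algebraically but cancels *exactly*
for an inactive parameter. The sign convention on the f0² term follows the
original Janon et al. estimator (the variant with the opposite sign, which
does not vanish for inactive parameters, is available behind
`compat_printed_sign=True`).

For continuous measurements the per-time-point indices are condensed by the
variance-weighted average TAS (weights: across-sample output variance at
each saved time, under the estimator's own moment convention). TAS entries
are convex combinations of the per-time indices (asserted as a property).
Orthogonality for continuous runs is computed on the m×n TAS matrix — the
m-dimensional per-parameter vectors the measure is defined on — not on the
m·T time-resolved stack; the mean-orthogonality ranking excludes the
self-distance diagonal (including it would rescale all means equally and
cannot reorder ranks).

## Uncertainty and convergence

Percentile bootstrap (default B = 1000, 95%): row indices are resampled
with replacement and applied jointly to f(A) and every f(AB_i). Because all
four estimators are functions of per-row sufficient statistics, each
replicate is a multinomial-weighted sum of row statistics and the whole
bootstrap is one (B×N)·(N×d) matrix product; the point estimate is always
the full-sample estimate, independent of the resampling seed.

Convergence over an increasing N grid is declared at the smallest grid
point whose ranking (mean-orthogonality ranks by default; a flag switches
to influence ranking) equals the previous and all later grid points, with
relative CI half-width ≤ 5% for every index above a floor (default 0.01 —
"error below 5%" is meaningless for null parameters, so they are exempt;
both the tolerance and floor are parameters). Sequence samplers reuse
prefixes of one design across the grid; the lattice is rebuilt per N (its
points depend on N); MC samplers redraw with per-N derived seeds.

## Reporting

Rank tables are (estimator, sampler) × parameter grids of orthogonality
ranks. Range tables take, per parameter, the max−min rank across one
stratum (all samplers at fixed estimator, or vice versa); the "mean
variation of the input set" is the mean of those ranges, reported to two
decimals with half-up rounding. Reference rank tables for all four
model/measurement combinations ship as CSV fixtures so the reporting
arithmetic is testable without re-running the pipelines. One fixture row is
not a permutation of 1..n (a typo in the published source table); builders
and loaders therefore warn rather than fail on non-permutation rows, with a
`strict` escalation.

## Problem sizes used in tests and the acceptance script

The shipped checks run the single-ventricle model at N = 2000 (22,000
solves per sampler; the five-sampler robustness check repeats this per
sampler) — the package's scaled-down replication size; production-scale
studies of this kind use N = 10,000–40,000 with B = 1000, which the same
code paths handle by changing the config. The Ishigami validation uses
N = 8192, where all four estimators sit within ~1e-3 of the closed-form
totals.

## Known limitations

* The synthetic models are the *actual* study objects here, not emulators
  of measured data: no measurement noise, no beat-to-beat variability, no
  pulmonary/right-heart circulation, fixed cycle length. Passing tests say
  nothing about fitting real patient waveforms.
* The orthogonality rankings (though internally converged — bit-stable
  from N ≈ 1000 upward, identical between Jansen and Janon) are sensitive
  to study conditions that published benchmarks of this design often leave
  unstated, most importantly the sampling bounds: with a different bounds
  window or a different continuous-data reduction, different rankings can
  result. The rank of near-tied parameters (mean-orthogonality gaps of
  ~0.002, e.g. E_min vs C_sv on the single-ventricle model) can flip
  between samplers at any practical N; robustness summaries should be read
  with those gaps in mind, and the per-parameter scores (not just ranks)
  are always reported for this reason.
* Homma/Sobol' estimates can be negative at small N; they are reported
  as-is (orthogonality is well-defined on them), never clipped.
* First-order indices, the Azzini estimator and dependent-input indices are
  out of scope.
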