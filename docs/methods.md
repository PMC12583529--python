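# Methods

`osctune` simulates seven deterministic ODE models of competitive biological
oscillators — two oscillatory subsystems coupled by mutual inhibition — and
quantifies how auxiliary positive and negative feedback loops reshape the
amplitude and frequency of their antiphase limit cycles.  This note records
the models' conventions, the numerical choices, and the limits of what the
package's tests can show.

## Models and control parameters

Every model exposes the same four nonnegative scalar controls on top of its
fixed constants:

| control | meaning |
|---------|---------|
| `k1`    | strength with which oscillator 2 inhibits oscillator 1 |
| `k2`    | the reverse inhibition |
| `pos`   | strength of the auxiliary positive-feedback loop(s) |
| `neg`   | strength of the auxiliary negative-feedback loop(s) |

Controls are magnitudes; inhibitory edges acquire their negative sign inside
the right-hand sides.  The mapping of `pos`/`neg` into model-internal
parameters: cell cycle, predator-prey and neuromechanical use `k_p = pos`,
`k_n = neg`; FitzHugh-Nagumo and Van der Pol use coupling entries
`a15 = a26 = pos`, `a13 = a24 = neg`; Goodwin uses `v_p = pos`, `v_n = neg`;
the Repressilator uses activation gains `a19 = a4,10 = pos` and degradation
couplings `c17 = c48 = neg`.

State counts: cell cycle 10, FitzHugh-Nagumo 12 (6 neurons × V, W), Goodwin
10, Repressilator 20 (10 genes × mRNA, protein), predator-prey 8, Van der
Pol 12 (6 regions × x, y), neuromechanical 12.

### Transcription conventions and resolved ambiguities

* **Hill terms** x^n/(θ^n + x^n) are evaluated with the regulator clamped at
  zero from below.  States can transiently dip slightly negative in stiff
  phases; clamping inside the regulatory term only (never the integrated
  state) avoids complex powers for n = 4 and n = 9 while leaving the
  dynamics in the physical regime untouched.
* **Cell cycle**: several primed degradation rates are published only as
  bare "k = 10" fragments; they are coded as named parameters
  (`kd_Cdh1_p`, `kd_Cdh1_pp`, `kd_Emi1_p`, `kd_E2F_p`) with value 10,
  matching the surrounding pattern, and can be overridden.
* **FitzHugh-Nagumo**: the synaptic sigmoid's threshold `V_th` and width
  `theta_th` carry no published value.  The package defaults are
  `V_th = 0` (the inflection of the cubic nullcline) and `theta_th = 0.5`
  (a graded synapse over the ±2 voltage swing); with these the default
  network shows robust antiphase oscillation at k1 = k2 = 1.
* **Goodwin**: the Ẏ2 synthesis term (v13 + v_p·W2 + v21·U2) and the
  U̇2 repression Hill in Y2 are implemented exactly as published even where
  a mirror-image form might be expected; `k1·Y2` and `k2·Y1` appear in the
  degradation lines as printed.
* **Repressilator**: double-digit subscripts are read as (row ≥ 10, column
  single digit), e.g. a_104 = a_{10,4} (gene 4 activates gene 10).
* **Predator-prey**: the Ẏ4 and Ẏ6 logistic growth terms reuse Y3 and Y5
  respectively, as published (a likely typo, retained deliberately).
* **Van der Pol**: the published coupling sum C_i = Σ_j a_ij·x_i contains
  the unit's own state; read literally there is no cross-coupling at all and
  mutual inhibition could never produce the antiphase rhythms this model is
  meant to show.  It is implemented as Σ_j a_ij·x_j.
* **Neuromechanical**: the gap-junction terms are implemented symmetrically
  (`u_gap13` pairs x1↔x3, `u_gap24` pairs x2↔x4); the published ẋ2 line
  names `u_gap14`, resolved as a typo for `u_gap24`.  The published ẏ1 has
  gain v4 on its self-excitation while ẏ2 does not; this asymmetry is
  retained as printed.

### Antiphase-preserving competition defaults

The study design fixes (k1, k2) high enough that the no-feedback system
oscillates antiphase, then sweeps the feedback controls.  Defaults were set
from pilot runs:

* cell cycle, FitzHugh-Nagumo, Goodwin, Repressilator, predator-prey:
  k1 = k2 = 1;
* Van der Pol: k1 = k2 = 0.3 — the linearly coupled pair has an unbounded
  antisymmetric mode for k ≳ 0.5 (the x-equation gains positive feedback
  that the μ(1−x²) damping cannot saturate), so "high" inhibition means
  0.3 here;
* neuromechanical: k1 = k2 = 2 — at k = 1 the muscle pair is bistable
  between the antiphase cycle and a small non-antiphase cycle, and the
  attractor reached depends on the random initial condition.

### Model-specific dynamic ranges (found, not chosen)

Two models restrict the feedback ranges that produce usable limit cycles:

* Van der Pol diverges for `pos` ≳ 0.12 (the positive loop through the
  strongly driven region 5 closes a linear amplification path); `neg` up to
  1 is fine.  Ratio experiments for this model therefore use the
  negative-dominant branch.
* The Repressilator's negative loop quenches oscillation for `neg` ≳ 0.25
  (the degradation multiplier 1 + C_i grows with Y7 ≈ 10·X7).
* The predator-prey model, at its published constants, has **no** limit
  cycle at all in the no-feedback baseline: the Rosenzweig-MacArthur Hopf
  condition K > h(γ+δ)/(γ−δ) = 1.3 is not met at K = 1.  Negative feedback
  ≳ 0.13 drives the predators extinct, positive feedback ≳ 0.2 produces
  unbounded mutualistic growth, and the small oscillatory window in between
  (driven by the predator-symbiont loop) never shows antiphase predator
  coexistence — strong competition produces competitive exclusion instead.
  The model is retained exactly as published; analyses that require an
  oscillatory baseline report it as undefined for this model.

## Integration

Adaptive Runge-Kutta (`scipy.integrate.solve_ivp`, RK45) with rtol 1e-8 /
atol 1e-10 by default, dense output resampled on a uniform grid (4000
intervals per horizon).  Initial conditions are drawn uniformly from
[0, 1]^n with a seeded generator; the seed is recorded in every trajectory
and output file.  A terminal event aborts integration as soon as any state
magnitude exceeds 1e4 (1e3 for Van der Pol sweeps), so runaway orbits fail
fast with a diagnostic instead of being tracked to overflow.

Default horizons cover tens of periods of each model's slowest observed
rhythm (cell cycle 800, FitzHugh-Nagumo 1200, Goodwin 600, Repressilator
2000, predator-prey 2000, Van der Pol 600, neuromechanical 60 time units).
Inside parameter sweeps, reduced settings are used for throughput (rtol
1e-6 / atol 1e-9, shorter horizons; LSODA for the Van der Pol sweeps, whose
metastable near-boundary orbits make explicit RK grind).  A step-halving
test confirms that the reduced settings move cell-cycle amplitude and
frequency by well under 0.5%.

**Burn-in.** The transient is located by scanning cycle-to-cycle peak
amplitudes of the two competitive observables and finding the first peak
after which all later relative changes stay below 1%; if no stable cycling
is detected the first half of the horizon is discarded.  Downstream
features use only the post-transient window.

## Feature extraction

* **Amplitude** = (max − min)/2 of the post-transient signal (half
  peak-to-trough).  The envelope measure is used because only ranges and
  ratios of amplitudes enter the headline statistics.
* **Frequency** = reciprocal mean inter-peak interval from
  prominence-filtered peak detection (prominence 25% of the amplitude),
  cross-checked against the dominant discrete-Fourier component; a >5%
  disagreement flags the record but the inter-peak estimate is kept.
* **Oscillation gate**: a trace counts as oscillatory only if its amplitude
  exceeds 1e-3 × max(|mean|, 1), at least 5 peaks are present, and the
  coefficient of variation of inter-peak intervals is below 5% (a regular
  limit cycle, not quasiperiodicity or noise).
* **Phase relation** = Pearson correlation of the mean-centered
  post-transient pair; r ≤ −0.8 is classified antiphase, r ≥ 0.8 in-phase,
  otherwise uncorrelated.  The −0.8 cutoff makes the continuous heatmap
  criterion operational as a binary gate.

Records that fail the oscillation gate or the antiphase gate are retained
in sweep outputs with flags but excluded from tunability statistics, where
they would otherwise contribute spurious zero-frequency states.

## Sweeps and headline statistics

* **Competition sweep**: k1 = k2 = k over a grid in [0, 1] with feedback
  off.
* **Feedback grid**: Cartesian (pos, neg) grid at fixed competition; the
  positive-only, negative-only and no-feedback configurations are its
  neg = 0 row, pos = 0 column and origin.
* **Normalized tunability** = (max − min)/reference of amplitude or
  frequency over a configuration's oscillatory antiphase records, the
  reference being the no-feedback baseline.  Because the hybrid grid
  contains both single-feedback slices, hybrid tunability is by
  construction at least as large as either single-feedback value whenever
  the baseline is oscillatory.
* **Ratio sweep (asymmetric feedback)**: for each dominant-to-recessive
  ratio r, the admissible (pos, neg) region is the envelope
  [0, min(r·b, 1)] × [0, b] with recessive base strength b = 0.1, sampled
  on an n × n sub-grid.  The published experiment reports a percentage per
  ratio, which requires a *region* of configurations per ratio rather than
  a single point; this envelope interpretation is the largest free choice
  in the pipeline and is isolated behind one function, with a single-point
  "line" semantics also selectable.
* **Accessible states**: the (frequency, amplitude) points of a
  configuration are binned on a shared 50 × 50 uniform grid whose edges
  span the pooled cloud of *all* ratios and configurations of a sweep,
  padded by 2%.  The **extra-domain percentage** is
  (N_h − N_s)/N_h × 100 with N_h the hybrid-occupied bins of one ratio's
  envelope and N_s the union of its positive-only and negative-only
  slices.  Sharing the bin edges across the whole sweep is what makes the
  curve interpretable: a tiny balanced envelope occupies few bins of the
  common grid (percentage near zero), a widening asymmetric envelope fills
  bins no single-feedback slice reaches.

### Resolution dependence — read before comparing numbers

The extra-domain percentage is a bin-counting statistic: N_h can never
exceed the number of sub-grid points evaluated, while N_s grows roughly
linearly with the sub-grid edge.  At the desk-scale resolutions used here
(15 × 15 sub-grids, three log-spaced ratios in [1, 20], 50 × 50 bins) an
upper bound of (225 − 29)/225 ≈ 87% applies even in the best case, so
percentages in the high 80s and 90s are only reachable with much denser
sub-grids.  Reported values state their grids; at these resolutions,
doubling the bin count to 100 × 100 raises the FitzHugh-Nagumo plateau by
roughly 10–15 percentage points (the hybrid cloud resolves into more bins
while the single-feedback slices do not), so values are comparable only at
matched binning.  A second, model-specific caveat:
for the cell cycle the recessive base strength 0.1 is dynamically inert
(its feedback enters through Hill terms ((0.1·x)/5)^4 ≈ 10⁻⁵), so the
hybrid envelope collapses onto the dominant-only line and the statistic
reflects bin noise more than dynamics.

## Synthetic signal fixtures

The feature extractor is tested against generated traces with closed-form
ground truth: sinusoids, asymmetric sawtooth "relaxation" waves, constants,
sinusoids under a decaying transient envelope, two-tone superpositions and
phase-shifted pairs, each optionally with seeded Gaussian noise.  These
fixtures emulate the *shape* classes of the model trajectories (smooth
quasi-sinusoidal cycles, fast-slow relaxation cycles, settled transients);
they do not emulate stiffness, seed-dependent attractor selection, or
integration error, so passing the fixture suite validates the measurement
code, not the simulations — the model-level checks do that separately.

## Determinism and seeds

Every source of randomness is a `numpy` generator seeded explicitly.  Sweep
points derive their seed from a SHA-256 hash of (global seed, model,
k1, k2, pos, neg), so results are independent of evaluation order and of
whether a point is shared between ratio sub-grids.  Identical configurations
reproduce byte-identical CSVs (floats printed at 17 significant digits).

## Known limitations

* Deterministic ODEs only: no stochastic variants, no time-delay terms.
* One trajectory per sweep point; multistable configurations (e.g. the
  neuromechanical model at moderate k) are represented by whichever
  attractor the seeded initial condition selects.
* The antiphase gate uses Pearson correlation of the settled traces; pairs
  with drifting relative phase classify as uncorrelated even if episodically
  antiphase.
* The extra-domain statistic is resolution-dependent (see above); compare
  values only at matched grids and binning.
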