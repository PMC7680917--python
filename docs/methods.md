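# Methods

## Model

Each oscillator is the two-variable photosensitive Oregonator with an added
first-order activator decay.  For a network of n all-to-all coupled
oscillators,

    du_j/dt = (1/ε)[u_j − u_j² − (f·v_j + φ_j(t))·(u_j − q)/(u_j + q)]
              − (α + deg_j·β)·u_j + β·Σ_{i~j} u_i
    dv_j/dt = u_j − v_j

where deg_j is the number of coupled neighbours (2 in the all-to-all
triple, so the term equals the equivalent form −(α+3β)u_j + β(u₁+u₂+u₃)
after the self contributions cancel).  The nonlinearity is the standard
Oregonator switching term (f·v + φ)(u − q)/(u + q); with the default
constants it gives a stable rest state u = v ≈ 2.004·10⁻⁴ under strong
illumination (φ ≈ 0.2) and a limit cycle of period ≈ 10.8 time units at the
residual illumination φ = 10⁻⁴ with α = 0.849 — both verified by the test
suite.

Illumination follows φ_j(t) = amp·(offset + tanh(−steepness·(t −
t_ilum(j)))) with fixed constants amp = 0.1, offset = 1.001, steepness =
10; these are deliberately not searchable traits.  `IlluminationSchedule`
also accepts a `phi_const` override that holds φ at a fixed value; this is
plumbing for period measurements at the post-switch-off level (10⁻⁴) and
has no role in classification runs.

## Parameters

| parameter | meaning | default | origin |
|---|---|---|---|
| ε | u/v time-scale ratio | 0.2 | fixed kinetic constant |
| q | Oregonator scaling constant | 2·10⁻⁴ | fixed kinetic constant |
| f | stoichiometric coefficient | 1.1 | fixed kinetic constant |
| α | activator decay rate (1/time) | searchable; 0.849 in the preset | moderates coupling strength |
| β | activator-exchange rate (1/time) | searchable; 0.251 in the preset | inter-oscillator coupling |
| t_start, t_end | affine input encoding endpoints (time) | 3.78, 12.10 in the preset | map x, y ∈ [0,1] to inhibition times |
| t_ilum(3) | fixed inhibition of the normal oscillator | 6.37 in the preset | third searchable channel |
| t_max | observation window (time) | 20.23 in the preset | readout horizon |
| h | RK4 step (time) | 10⁻⁴ | integration accuracy |
| store_stride | steps between stored samples | 100 (sampling 0.01) | readout grid |
| height_threshold | minimal counted peak height | 0.05 | separates spikes from the 2·10⁻⁴ baseline |

## Numerics

**Integration.** Classic fixed-step RK4 from t = 0 to t_max (no burn-in),
compiled with numba; the same arithmetic runs in a generic any-topology
kernel and a register-resident specialisation for the all-to-all triple,
kept bit-identical (tested).  The step count is round(t_max/h).  States are
sampled every `store_stride` steps plus the final state.  Halving h from
10⁻⁴ changes stored activator values by < 10⁻⁶, and the observed
convergence order exceeds 3.

**Initial condition.** Every run starts from the per-oscillator illuminated
steady state: the root of the single-oscillator fixed-point equation
(with v = u) at that oscillator's φ_j(0), found by bracketed Brent root
finding on u ∈ (10⁻¹², 1).  Coupling is ignored in the initial condition
because the exchange terms cancel exactly at a uniform state, and for all
practical schedules (t_ilum ≳ 0.5) every φ_j(0) saturates to the same
0.2001.  Period measurements also start from the strongly-illuminated rest
state: the steady state at the *measurement* φ would be an exact fixed
point of RK4 and the trajectory would never leave it.

**Peak detection.** A counted maximum is an interior strict local maximum
of the stored series (u[i−1] < u[i] ≥ u[i+1]) above an absolute height
threshold of 0.05 — two decades above the inhibited baseline and below
every observed spike amplitude (spikes are O(0.1–1)).  Endpoints are never
counted, making counts independent of where the window cuts a rising or
falling flank.  Batch classification counts maxima on the fly inside the
integration kernel with exactly this rule (tested for equality against
counting on stored trajectories).  Counts on 50-point samples are identical
at h = 10⁻⁴ and h = 10⁻³, so coarse steps are used where only counts
matter (GA runs, symmetry checks).

**Period.** The mean spacing of successive counted maxima after discarding
the first two (transient) maxima, at stored-grid resolution (±0.01); at
least four maxima are required, otherwise the system is reported as not
oscillating.

**Instability policy.** Non-finite states, |u| or |v| above 10³, or
activators below −10⁻⁶ abort the run with an error; nothing is clamped.
During evolution such genomes score fitness 0 and the search continues.

## Information-theoretic fitness

Entropies are plug-in estimates in bits; mutual information is computed as
H(G) + H(O) − H(G, O) from the (g, o) contingency table and clipped at 0 to
absorb ~10⁻¹⁶ cancellation residue.  No small-sample bias correction is
applied: with N = 800 records and two to three count categories the plug-in
bias is far below the differences that matter to selection.  The output
oscillator is the argmax of I(G; O_j), ties broken toward the lowest index.
The double-sum definition Σ p(g,o) log₂[p(g,o)/(p(g)p(o))] is kept in the
test suite as an independent oracle (agreement to 10⁻¹²).

## Decision rule

Each observed count maps to the majority label among training rows showing
that count; ties and counts never seen in training map to class 0
(background) — a deterministic convention; ties did not occur in any run we
report.  The rule is fitted on training responses and frozen for test
evaluation.  Prediction uses the MI-selected oscillator, not a hard-coded
channel (the preset network selects #3).

## Evolutionary search

Real-valued GA over 7 genes (role of oscillator #3 ∈ {normal, input_x,
input_y}, t_ilum(3), t_start, t_end, t_max, α, β).  Per generation: the top
20% survive unchanged with cached fitness; the remaining 80% are offspring
of two distinct parents drawn uniformly from the top 50%, recombined by
per-gene uniform crossover and mutated with per-gene probability 1/7
(≈ 1 mutation/genome).  Continuous mutations are uniform within ±10% of the
current value — the stated cap read as relative to the pre-mutation value,
with the uniform distribution as the maximum-entropy choice under that cap.
Consequences, documented as limitations: a gene at exactly 0 is immobile,
and mutation step sizes shrink with the gene value.  If crossover or
mutation leaves t_end ≤ t_start the two values are swapped (never
resampled); exact ties are nudged apart by ~10⁻⁹.

Initialization ranges (a design choice; the protocol does not state them):
t_start ∈ [0, 10], t_end ∈ [t_start + 0.5, 40], t_ilum(3) ∈ [0, 30],
t_max ∈ [5, 50], α ∈ [0, 1.5], β ∈ [0, 1].  They bracket the ≈ 10.8
oscillation period, contain the published optimum with margin, and avoid
exact zeros.  A single seeded generator drives initialization, parent
choice, crossover and mutation in that order, so runs are bit-reproducible.
Parent pooling is network-level (whole genomes are parents), the simpler
reading of the protocol.

## Benchmark geometries

The equal-area disk uses r = (2π)^(−1/2) ≈ 0.39894 — the only radius
consistent with equal sun/background areas.  Boundary points (distance
exactly r, or s exactly on a curve) are labeled inside; a measure-zero
convention fixed for reproducibility.

The horned region is bounded by printed even degree-14 polynomials F_U(p),
F_D(p) in p = x − y, s = x + y.  Between |p| = 0 and the horn tips the band
F_D ≤ s ≤ F_U is the fitted boundary; the in-square band width
min(F_U, 2−|p|) − max(F_D, |p|) first vanishes at |p| ≈ 0.6440 (where F_U
crosses the square edge s = |p|), and beyond the tips the high-order fits
oscillate with no geometric meaning (F_U(1) ≈ 2740, F_D(1) ≈ −49),
spuriously labeling ~8% of the square "inside" under a literal pointwise
test.  `horned_label` therefore treats the region as the connected band
clipped at the tips, which is what the fitted curves actually describe; the
raw pointwise rule remains available via `clip_at_tips=False`.  With the
clipped region the optimized network's single-maximum classification agrees
to ~99%, consistent with the reported behaviour; without it agreement drops
to ~92% purely through the extrapolation artifacts.

French-flag stripes are half-open: blue for x < 1/3, white for
1/3 ≤ x < 2/3, red for x ≥ 2/3.

## What the generators emulate — and what they do not

Synthetic datasets are i.i.d. uniform points of the unit square with exact
geometric labels, matching the study conditions (800 training records,
larger independent test samples).  They contain no label noise, no
measurement error on coordinates, and no experimental variability of real
BZ chemistry (droplet drift, bubble formation, parameter heterogeneity
between beads).  Passing tests therefore validate the computational claim —
that this network architecture separates these geometries — not the
robustness of a wet implementation.

## Problem sizes

Dataset sizes used by the tests and the acceptance script are the study's
training scale (800 points) and desk-scale reductions elsewhere: 5,000
test points (the original evaluation used 100,000) and 2,000 points for the
horned-region comparison; binomial dispersion at these sizes is ~0.3–0.7
percentage points, well inside the reported tolerances.  The full-size
evolutionary run (200 genomes × 1,000 generations × 800 records) is not
reproduced; the search is validated by a scaled run (20 genomes, 30
generations, 100 records, h = 10⁻³) that must improve monotonically and
end above the 95th percentile of 100 label-permutation MI baselines,
together with direct evaluation of the published optimum.  The GA being
stochastic with an unknown original seed, recovering the exact published
genome is not an expectation anywhere.

## Known limitations

* Fixed-step explicit RK4 only; no adaptive or implicit solvers.  Stiff
  parameter corners of genome space are handled by the blow-up guard and
  fitness penalty, not by solver switching.
* The peak detector is threshold-based on a fixed stored grid; detectors
  with sub-sample interpolation would shift period estimates by at most the
  sampling interval (0.01).
* Relative mutation makes zero-valued genes immobile (see above).
* The horned-region polynomials are consumed as printed; no re-fitting of
  the boundary from network responses is attempted.
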