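# Methods

This note records the models implemented in permeakit, the defaults and why
they were chosen, and what the synthetic data can and cannot establish.

## 1. The synthetic permeation model

### Landscape

The free-energy profile ΔG(z) along the membrane normal is a sum of Gaussian
bumps and wells on a zero baseline, mirrored about z = 0:

* flip-flop barrier: height 12 kcal/mol at z = 0, width 0.4 nm;
* interfacial barriers: height 3 kcal/mol at |z| = 2.4 nm, width 0.3 nm;
* leaflet wells: depth 0.3 kcal/mol at |z| = 1.4 nm, width 0.3 nm —
  i.e. the membrane-bound state is nearly isoenergetic with bulk water;
* ΔG(±z_max) = 0 with z_max = 4 nm (a constant shift enforces this exactly).

These defaults emulate the umbrella-sampling profile of an amphiphilic
cyclic decapeptide crossing a POPC bilayer: a rate-limiting flip-flop step
at the bilayer center, small headgroup barriers, and near-neutral
partitioning. The Gaussian parametrization was chosen because the gradient
is analytic (the integrator needs forces, not splines) and because each
printed feature (height, position) is one parameter, which makes
parameter-recovery tests direct. Mirrored feature pairs are summed before
accumulation so that G(−z) = G(z) holds exactly in floating point.

The diffusion profile D(z) is a logistic interpolation in |z| between a
bulk-water value (default 0.5 nm²/ns) and a membrane-interior value
(default 0.1 nm²/ns), switching at the headgroup position. No reference
D(z) exists for the system being emulated — the upstream analyses estimate
D(z) from data rather than positing it — so this default is a stand-in at
the order of magnitude typical for a peptide-sized solute, and quantitative
permeabilities of the emulated system are *not* recoverable from the
synthetic campaign. What is recoverable, and what the tests check, is the
internal consistency of each pipeline against the generator's ground truth.

### Dynamics

Trajectories follow the overdamped Langevin equation integrated with
Euler–Maruyama:

    dz = [ −β D(z) U'(z) + D'(z) ] dt + sqrt(2 D(z) dt) ξ,   ξ ~ N(0,1)

with U(z) = G(z) + k/2 (z − z₀)² including the optional umbrella restraint.
The D'(z) term is the Itô spurious-drift correction; without it a
position-dependent D would distort the stationary density (a dedicated test
verifies the stationary histogram stays flat on a flat landscape with
strongly varying D). Boundaries at ±(z_max + 0.5 nm) are reflecting.

Defaults: timestep 10⁻⁴ ns, save stride 10 (windows) or 100 (unbiased),
giving 10⁴–10⁵ saved points per trajectory. Before integrating, the code
checks that the largest deterministic displacement per step is small
against the finest scale the trajectory must resolve (the umbrella width
for windows) and refuses to run otherwise; at run time any step larger
than a 0.5 nm cap aborts with the offending step index. The integrator is
JIT-compiled and bit-reproducible for a fixed seed; per-trajectory seeds
derive from the campaign master seed and a CRC32 hash of (kind, index), so
streams are independent and stable.

### Campaign layout

The default campaign mirrors the study design it emulates: 41 umbrella
windows at z = 0.0–4.0 nm in 0.1 nm steps with umbrella constant
1000 kJ/mol/nm² (239.0 kcal/mol/nm²), and unbiased swarms of 75 replicas
from each of z = 0.0, 2.3, 2.4 and 2.6 nm — the two free-energy maxima and
two displaced variants — of 100 ns each, at T = 293.15 K. The quoted
umbrella unit in the emulated protocol (kJ/mol/Å²) would put the window
width at ~0.005 nm, far too stiff for 0.1 nm spacing to overlap; the
kJ/mol/nm² reading is the only self-consistent one and is the default
(the constant and its unit are configurable). Trajectories are written as
two-column GROMACS-style .xvg files plus a JSON manifest.

## 2. WHAM and window statistics

The unbiased density solves the standard self-consistent equations over
histogram bins (default width 0.05 nm, half the window spacing):

    p(b) ∝ Σ_i h_ib / Σ_i N_i exp(β(F_i − w_i(b))),
    F_i  = −kT log Σ_b p(b) exp(−β w_i(b))

iterated until the largest change in any window free energy F_i falls below
10⁻⁷ kcal/mol. ΔG = −kT log p is referenced to the bin containing z_ref
(default: the outermost window center, i.e. bulk water). The first 48% of
each window series is discarded as equilibration, matching the convention
of keeping the last 130 ns of a 250 ns production run. Symmetrization
averages G(z) and G(−z) wherever both are sampled and mirrors the covered
side elsewhere, so a half-ladder campaign (windows on [0, 4] nm only)
yields a full symmetric profile.

Per-window fluctuation statistics feed the diffusion estimator:
σ_z² = ⟨z²⟩ − ⟨z⟩², and τ_zz = (1/σ_z²)∫C(t)dt with C the autocovariance
(FFT-based), integrated by trapezoid **up to the first zero crossing of C**.
The defining integral has an infinite upper limit, so a truncation rule is
unavoidable; the first-zero-crossing window is the standard low-bias
choice. Its practical behavior matters for test design: the truncation
biases τ down by roughly exp(−t_cross/τ), and the statistical error of both
σ² and τ scales as sqrt(τ/T_run). Recovering τ to 10% therefore needs run
lengths of several hundred correlation times, which is what the tests use.
For white noise the estimator converges to half a sampling interval.

Errors: a moving-block bootstrap over the retained window series (block
length 5·τ_zz in frames, rounded up) preserves short-range autocorrelation.
How the reference implementation's bootstrap resamples is not documented at
this level of detail; block-bootstrapping the raw series is the stated
package choice. Replicate WHAM solutions are warm-started from the
converged window free energies; profile error bars are the across-replicate
standard deviation, and the ISDM pipeline reports mean ± sd of logP over
replicates (permeability uncertainties are quoted on the log10 scale
throughout).

## 3. ISDM

D(z₀) = σ_z²/τ_zz per window is interpolated linearly between window
centers (clamped at the ends) and extended evenly, D(−z) = D(z); nothing in
the estimator constrains D between windows, so linear interpolation is the
minimal assumption. The resistance R(z) = exp(βΔG(z))/D(z) is integrated by
trapezoid on the symmetrized grid and inverted: P = 1/∫R dz. For a flat
profile with constant D this reduces to P = D/(2 z_max) exactly, which the
tests exploit as a closed form (D = 1 nm²/ns, z_max = 4 nm → 12.5 cm/s).

## 4. Markov State Models

* **Discretization**: signed-z bins of 0.1 nm spanning ±(z_max + margin);
  half-open [lo, hi) with the last bin closed. Signed bins are required so
  the four metastable states (two waters, two leaflets) are representable.
* **Counting**: sliding-window pairs (t, t+τ); default lag 0.3 ns — three
  saved frames at the default unbiased stride — sitting on the
  implied-timescale plateau for the landscapes shipped; the lag is a
  parameter everywhere.
* **Connected set**: dead-end states (entered, never left within the lag)
  are pruned iteratively, then the largest *weakly* connected component is
  kept and rows are normalized. Weak rather than strong connectivity is
  deliberate: swarms launched at barrier tops produce transient, partly
  one-directional flux, and strong connectivity would silently discard the
  very transitions those swarms exist to record (it would also break the
  elementary count-and-normalize contract on short hand-checkable
  trajectories). The cost is that first-passage problems on a weakly
  connected model can be ill-posed; the MFPT solver detects unreachable
  targets and raises rather than returning garbage.
* **Estimators**: maximum-likelihood row normalization by default; a
  detailed-balance-constrained (reversible) MLE via fixed-point iteration
  is available behind a flag. π is the leading left eigenvector (or the
  reversible estimator's stationary vector).
* **Validation**: implied timescales t_i(τ) = −τ/ln|λ_{i+1}(τ)| across a
  lag ladder, and a Chapman–Kolmogorov test comparing [T(τ)^k] with
  directly estimated [T(kτ)], aggregated over metastable sets with
  π-restricted weights.
* **PCCA+**: inner-simplex algorithm on the dominant right eigenvectors;
  memberships by simplex-vertex transformation, clipped to [0,1] and
  renormalized; crisp sets by argmax. Semantic labels come from the
  π-weighted mean z of each set: |z| > 2.0 nm (the headgroup band) ⇒ water,
  the sign of z separates outer from inner. The threshold is configurable;
  when the data do not support four labeled sets (e.g. no flip-flop
  sampling) the labeling warns and downstream rate extraction raises a
  partition error — this is the honest outcome on the default 12 kcal/mol
  landscape, where unconstrained swarms cannot connect the two leaflets.
* **Rates**: k_in, k_out, k_flip are inverse MFPTs (linear-system solution,
  π-weighted source average), symmetrized over the two leaflets/directions
  since the landscape is even; whether one direction or the average is used
  upstream is not specified, and averaging halves the variance at no cost
  under symmetry.
* **Uncertainty**: each transition-matrix row is sampled from
  Dirichlet(counts + 1/n); MFPTs and rates are recomputed per sample and
  summarized as mean ± sd. This non-reversible posterior replaces a
  reversible Bayesian sampler: it is simpler, exactly defined, and its
  spread concentrates as 1/sqrt(counts), which the tests verify. It does
  not enforce detailed balance, so its samples are slightly wider than a
  reversible sampler's would be.

As a reporting operation, ΔG = −kT log π over the model bins reproduces the
generator landscape within 0.5 kcal/mol in well-sampled regions.

## 5. Liposome kinetics

Geometry: the planar patch uses per-lipid constants (25 lipids per leaflet,
0.656 nm² and 1.2 nm³ per lipid, 89 waters per lipid of 0.0305 nm³), giving
A_L = 16.4 nm², V_L = 60 nm³, V_W = 135.725 nm³. V_W is the *total* water
volume of the patch (both sides); the alternative per-side reading would
shift k_in-derived rates by a factor 2 and can be explored through the
geometry parameters. The liposome (radius r = 100 nm, volume ratio
V_wo:V_lo:V_li:V_wi = 1000:1:1:10) anchors V_wi to the full sphere volume
(4/3)πr³ — the only anchoring consistent with the fast-phase relation
P = (V_wi/A_l)·k = (r/3)·k — and both layer areas equal 4πr².

Rate mapping: every kinetic step obeys k = P·(A/V) with A the dividing
surface and V the donor volume. The planar donor volumes are V_W for entry
and V_L for exit and flip-flop; the liposome donors are the respective
compartment volumes (V_l ≡ V_lo = V_li is the liposome leaflet compartment,
*not* half the planar bilayer — the mapping must preserve P = kV/A exactly,
and the tests assert this identity for every rate).

The 4×4 generator K is diagonalized; for a connected chain exactly one
eigen-rate is zero (mass conservation) and the inner-water influx is a
three-exponential relaxation. A defective K (repeated eigenvalue without a
full eigenspace, condition number > 10¹²) raises and the stiff ODE solver
(LSODA, rtol 10⁻¹⁰) is the fallback; the two solutions agree to 10⁻⁸
relative on a random-rate battery. The biexponential fit of an influx
signal (plateau + two exponentials, log-linear tail initialization) is
provided for parity with luminescence-style analyses; note that the two
fast eigenmodes can enter S_wi(t) with opposite-sign amplitudes, in which
case the fitted fast rate approximates the fast band rather than bracketing
it — the pipeline therefore uses κ_fast = max κ_n directly.

The fast-phase convention P = (r/3)·κ_fast reports the fastest relaxation
of the compartment chain. Whenever entry/exit kinetics are faster than
flip-flop this sits orders of magnitude above the steady-state crossing
flux, which is why the package also provides the planar series-resistance
conversion (1/P = Σ 1/(k·V/A) over entry, flip-flop, exit) for
like-for-like comparison with ISDM; on a low-barrier landscape with
abundant sampling the two agree within a fraction of a log unit.

## 6. What the tests do and do not show

All campaigns used in tests are scaled to desk size: 41 windows of
20–100 ns (vs 250 ns emulated) and tens rather than hundreds of unbiased
replicas. These sizes were chosen so that every statistical tolerance in
the suite sits at ≳3× the expected estimator spread at that sampling, as
derived in §2. The suite establishes: exactness of the closed-form pieces
(resistance integral, master-equation solution, MFPT algebra, geometric
mapping), parameter recovery of the generator landscape by WHAM to
±0.5 kcal/mol, recovery of constant D to 10%, and cross-method agreement
at the planar level to <1 log unit on a low-barrier landscape.

The synthetic data are one-dimensional, memoryless along z, and use a
posited D(z). Real permeation involves orthogonal slow degrees of freedom
(peptide conformation, membrane deformation) that make the effective
dynamics along z non-Markovian at short lags, umbrella windows that
equilibrate slowly, and unknown position-dependent friction. Passing tests
therefore validate the *estimators and pipelines*, not the transferability
of any particular permeability value to a real membrane.

Known limitations: single 1D collective variable; no reversible Bayesian
sampler; no MBAR alternative to WHAM; the fluctuation estimator for D(z) is
biased at coarse saving intervals (τ must span many saved frames); the
liposome model is linear (no saturation, no polydispersity).
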