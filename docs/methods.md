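# Methods

## Kinetic model

The aptamer is modelled as a homogeneous continuous-time Markov chain on
the states U (open), K (kissing loop) and M (Mg²⁺-dependent alternative
fold), with every state directly accessible from every other state.  The
generator Q has off-diagonal entries k_X,Y (s⁻¹) and diagonal entries
−Σ_Y k_X,Y; the stationary distribution solves πQ = 0 with Σπ = 1 by a
dense linear solve after a strong-connectivity check.  State paths are
sampled exactly (Gillespie): the dwell in X is exponential with the total
exit rate, the successor is drawn proportionally to the branch rates.  The
last dwell is truncated at the requested duration so dwell times sum to the
path length exactly.  Reference rate tables for the Mg²⁺ and Gdm⁺
titrations are shipped as data; columns containing "n.d." entries do not
define a complete generator and are rejected by `complete_model`.
Initial states default to a stationary draw (molecules equilibrate in
buffer before imaging).  Cohort randomness uses one root seed with
per-molecule `SeedSequence` substreams, so any cohort is bit-reproducible.

## Trace synthesis

Traces emulate objective-type TIRF recordings at 100 ms integration:
per-frame state occupancies are the exact dwell-time fractions of each
frame, the frame's noise-free efficiency is the occupancy-weighted mean of
the state efficiencies (defaults 0.38 / 0.69 / 0.86), and channels are
donor = I·(1−E) + ε, acceptor = I·E + ε with I = 1000 counts/frame and
additive Gaussian channel noise ε (σ = I/12, an EMCCD-style approximation;
γ-correction is not modelled, matching uncorrected apparent E).

`state_sigma_e` (default 0.08) is the **apparent** per-state spread of
E = A/(D+A), the width a histogram shows.  Channel noise alone contributes
σ_ch(E) = (σ/I)·√((1−E)² + E²) ≈ 0.06–0.07 to that spread, so the renderer
draws the intrinsic per-frame jitter with variance
max(σ_E² − σ_ch², 0) — the rendered apparent width then matches the
configured value (verified to ±0.01 in the tests).  Treating 0.08 as
intrinsic and stacking channel noise on top would produce apparent widths
of ≈ 0.104, visibly wider than the experimental histograms and — more
importantly — wide enough to make the three-component area decomposition
statistically unidentifiable (see below).

Photobleaching is single-step: per-dye exponential bleach times (defaults:
donor 60 s, acceptor 40 s, chosen as typical cyanine photostabilities under
oxygen-scavenger imaging at these excitation levels).  After acceptor loss
all intensity moves to the donor (apparent E → 0); after donor loss both
channels carry zero-mean noise only (background after bleaching is not
separately modelled).  A configurable fraction of molecules (default 10%)
is donor-only (no acceptor ever); a `static_fraction` keeps molecules in
one state for the whole movie, because the experiments report both
interconverting and static molecules and the data do not decide whether
static molecules obey the same scheme with slow rates.  Blinking is not
modelled.

## Histogram pipeline

Apparent efficiencies from the first 20 frames (frames below 20% of the
trace's median total intensity are dropped) are binned at a width of
exactly 0.05 over [−0.2, 1.2], half-open bins [a, a+0.05) with a 1e-9
guard against floating-point edge error.  The donor-only peak is fitted
with a single Gaussian on bins with centers < 0.25 (the cut separates the
zero peak from the U state at 0.38) and subtracted everywhere, flooring at
zero counts.

The remaining histogram is decomposed into up to three Gaussian components
by unweighted least squares.  Two numerical choices matter here:

* **Shared width.**  All three states are recorded at the same intensity
  and integration time, so their apparent widths share one
  shot-noise/jitter budget.  With peak separations of only ≈ 2σ
  (0.69 vs 0.86 at σ ≈ 0.08), letting each width float makes the area
  split unidentifiable — the global least-squares optimum lets a slightly
  wider neighbour absorb tens of percent of a peak's area at negligible
  cost.  The default fit therefore shares one σ across the three state
  components (`shared_sigma=False` restores independent widths, bounds
  [0.02, 0.2]).
* **Parsimonious component count.**  Overlapping shared-width components
  can still split a single peak to chase bin noise.  The fit compares 1-,
  2- and 3-component models (all subsets of the initial means 0.38 / 0.69 /
  0.86, each mean confined to ±0.12 of its initialization) and accepts an
  additional component only when a nested F-test on the SSE reduction is
  significant at α = 0.05.  Components not supported by the data are
  reported with zero area and a degenerate flag rather than dropped.

Fractions are the ratios of component areas and sum to one by
construction.

## Trace QC, stitching and HMM

QC replaces the experiment's manual trace selection with thresholded
rules, all config-exposed: single-step (or no) photobleaching from a
least-squares change-point fit of the total and acceptor intensities
(donor bleach: total drops below 35% of its pre-step level; acceptor
bleach: acceptor drop with a compensating donor rise; a second downward
step ≥ 50% of the first flags a multi-step, non-single-molecule trace);
an acceptor signal above 10% of the total (else donor-only); and either
donor/acceptor Pearson correlation ≤ −0.3 (dynamic traces) or a total
intensity CV ≤ 0.15 (static traces).

QC-passing pre-bleach spans are stitched in input order up to 50,000
points, truncating only at whole-trace boundaries; joint indices are
recorded.  A three-state Gaussian-emission HMM is trained per condition on
the stitched trace by scaled Baum-Welch: emission means initialize at
(0.38, 0.69, 0.86) plus seeded N(0, 0.01) jitter, σ floor 0.01,
convergence at Δlog-likelihood < 1e-6 or 500 iterations, log-likelihood
non-decreasing by construction.  Decoding is Viterbi in log space with
ties broken toward the lower-mean state.  A five-state fit mode exists
only to check that no additional discernible states emerge.  Segmentation
quality is assessed on frames lying wholly within one ground-truth state;
frames spanning a transition are camera blends of two states and carry no
single true label.

## Dwell times and rate constants

A dwell is a maximal constant-label run that ends in an observed
transition; runs truncated by the trace start/end or by a stitch joint are
censored and excluded (joint-crossing label changes are concatenation
artifacts).  Single-frame dwells are retained.  Dwell histograms (bin =
one frame) are fitted with A·exp(−kt) by least squares; a closed-form
geometric estimator k = −ln(1 − 1/m̄)/Δt is available as a cross-check of
the frame-discretization behaviour (ceil-discretized exponential dwells
are exactly geometric).

Because the chain is memoryless, the dwell-time distribution in X does not
depend on the destination: per-destination dwell histograms share one
decay constant, and fitting them separately can only estimate the total
exit rate.  Reported per-transition constants therefore follow the kinetic
convention k_X,Y = k_X,exit · n_XY/n_X (pooled-exit fit times the observed
branching fraction), with the binomial branching error folded into the
standard error.  Transitions with fewer than `min_n` = 30 events, or whose
exit fit fails, are reported "n.d. (n = …)"; no single count threshold
reproduces every published n.d. entry (n.d. appears at n = 21–51 while
some n = 49 rates are reported), so the threshold is configurable and the
flag also triggers on fit failure.

**Known limitation — fast-rate bias.**  At 100 ms frames the fastest exit
rate here (U, 4.8 s⁻¹) gives k·Δt ≈ 0.5: a substantial fraction of dwells
is shorter than one or two frames, frames spanning a transition are blends
of two states, and majority-vote discretization merges quick
double-transitions.  Measured on ground-truth frame labels (no emission
noise at all), the dwell-fit pipeline recovers exit rates 7–20% low and
distorts branching for the fast transitions; transitions into M (exit·Δt ≤
0.16) recover within 15%.  The full pipeline inherits this bias, which
exceeds the ~2–5% statistical error at realistic transition counts.  It is
a property of the frame-level method itself (any analysis of the same
design shares it), not of this implementation; recovering fast rates to
statistical accuracy would require an explicit blur model or photon-level
inference, both out of scope.

## Accessible-volume FRET prediction

The AV3 scheme models the dye as a sphere on a flexible cylinder of length
L and width w (Cy3: L = 22.3 Å, w = 4.5 Å, radii 6.8/3.0/1.5 Å; Cy5:
L = 27.1 Å, w = 4.5 Å, radii 11.0/3.0/1.5 Å).  Grid points (default
spacing 0.8 Å) around the attachment atom are allowed when (a) a linker
path no longer than L connects them to the attachment without crossing the
molecular surface (probe radius w/2 plus per-element van der Waals radii:
C 1.70, N 1.55, O 1.52, P 1.80 Å), and (b) the dye sphere fits at the
endpoint; the clash test is repeated for the three dye radii and the
sub-clouds combined with equal 1/3 weight.  Path accessibility combines an
exact straight-line test with a Dijkstra search over free cells (5×5×5
connectivity, chamfer metric within ~2% of Euclidean), so the linker
cannot tunnel through the structure.  Atoms of the attachment residue do
not block the path (the covalent linker threads past its own residue) and
cells within 4 Å of the attachment are path-free for the same reason; both
still block endpoints.  ⟨E⟩ averages 1/(1 + (R/R₀)⁶) over cloud point
pairs (κ² = 2/3 folded into R₀ = 60 Å; exhaustive pairing up to 10⁶ pairs,
seeded Monte-Carlo beyond), and ⟨R⟩ is the mean pair distance.
Mean-of-E rather than E-of-mean-distance is the default because the dyes
explore their clouds quickly relative to the 100 ms frame; the alternative
is a one-line change on the returned cloud means.

The kissing-state worked example runs on a synthetic idealized construct
model built from standard helical parameters (rise 2.81 Å, twist 32.7°,
reduced atom set): the 9-bp P1 stem, two inter-loop C·G kissing pairs and
the 4-bp P2 stem stacked coaxially, Cy3 attached at the aminoallyl arm of
U3 and Cy5 at the 3′ oxygen of the final P2 residue.  The geometry was
fixed once from these construct facts; the predictor then returns
⟨E⟩ = 0.72 at ⟨R⟩ ≈ 49 Å.  It is a stand-in built by code, not
experimental coordinates.

## Coarse-grained Gō model

Three sites per nucleotide (P at the phosphorus, S at C4′, B at the base
centroid), reduced units throughout: energy in kT (298.15 K), length in
nm, time in τ (= 50 fs when mapped to physical time), masses ≈ residue
group masses (95/99/120).  Terms: harmonic bonds k_b (r−r₀)² with
k_b = 300 kT/nm² and angles k_a (θ−θ₀)² with k_a = 20 kT/rad² about
reference values; native contacts ε[(r₀/r)¹² − 2(r₀/r)⁶] with ε = 3 kT
(H-bond class) and 2 kT (stack/tertiary); generic non-native base-base
wells (consecutive stacks σ = 0.40 nm, ε = 1 kT; all other base pairs
σ = 0.55 nm, ε = 0.5 kT) so non-native folds such as the M-state's
alternative secondary structure are representable; excluded-volume
repulsion ε(σ/r)¹² with a single TIS-like diameter σ = 0.32 nm; and
Debye-Hückel repulsion between the −1 phosphates, Bjerrum length 0.7 nm,
screening length 1.36 nm (50 mM implicit monovalent), shifted to zero at
the 3 nm cutoff.  Well depths default to TIS-literature-scale values in
kT and are all config-exposed.

Native H-bond contacts come from an explicit base-pairing list (the
synthetic builders return theirs); distance classing alone cannot separate
Watson-Crick partners from cross-strand diagonal neighbours in a regular
helix, so a mutual-nearest-neighbour heuristic is only a fallback.  Stack
contacts are consecutive base pairs within 0.6 nm; tertiary contacts any
remaining site pairs ≥ 3 residues apart within 1.1 nm.  A non-interacting
3′-cap residue keeps its bonded terms but contributes no contacts, charge
or non-native interactions.

Because the generic non-native, excluded-volume and electrostatic terms
displace the potential minimum slightly from the raw reference
coordinates, the reference is relaxed (L-BFGS) before dynamics and for the
native-minimum property; the relaxed structure deviates from the raw
reference by ≲ 0.15 nm per site on the hairpin model and 200 random
perturbations (≤ 0.05 nm/site) never lower its energy.

Dynamics are leap-frog Langevin (BBK): with friction γ = 0 the scheme is
symplectic and conserves energy to < 0.5% over 10⁵ steps at h = 0.05 τ
(measured after a short equilibration of the thermal start; the half-step
kinetic-energy convention makes the instantaneous total wobble at the
(ωh)² ≈ 1% level without drifting).  The default γ = 0.1 τ⁻¹ encodes the
100-fold reduced-viscosity regime used to accelerate conformational
sampling; equipartition holds to 5%.  There are no periodic boundaries —
the 70 nm box is used only for divergence detection.  Mg²⁺ is represented
by a documented surrogate only: `mg_screening_factor` shortens the Debye
length (λ_eff = λ_D/(1+f)) and `native_scale` can uniformly scale the
native wells.  The simulator therefore supports the qualitative U/K/M
structural regimes but makes no quantitative claim about Mg²⁺ titrations.
Observables are the mass-weighted radius of gyration and the per-frame
AV-based FRET efficiency (CG sites act as exclusion spheres), binned at
0.05 for comparison with experimental histograms.

## What the synthetic data do and do not show

The generator emulates the statistical structure of the recordings
(Markovian state paths, camera-frame integration, channel noise,
donor-only molecules, single-step bleaching) but not optical PSFs, dye
blinking, γ-miscalibration, background drift, or molecule-to-molecule
heterogeneity of intensities and widths.  Passing recovery tests therefore
demonstrates the correctness and calibration of the analysis chain under
the stated noise model, not robustness to every artifact of real data.

## Problem sizes

Default test and acceptance problem sizes — cohorts of 120–1500 molecules,
20–400 frames per movie, stitched traces up to 50,000 points, 10⁵
integration steps on a 12-nt hairpin model — were chosen so every
statistical check has comfortable power while the whole suite runs on a
single CPU in minutes.
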