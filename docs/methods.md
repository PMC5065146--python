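# Methods

`v1mt` simulates a two-stage neural-field model of visual motion integration.
The scientific question it instantiates is how the visual system overcomes
the *aperture problem*: a local, orientation-tuned motion detector viewing a
moving edge can only measure the velocity component perpendicular to that
edge, so cells along the edges of a moving bar signal the wrong direction.
The bar's end-points (*terminators*) are two-dimensional features whose local
motion is unambiguous; the model's hypothesis is that direction-selective
*end-stopped* V1 cells extract those terminator signals and that recurrent
dynamics among MT cells propagate them along the object while suppressing the
aperture-biased edge signals.

## Architecture

Four rate-coded populations, each indexed by pixel position `(x, y)` and one
of `N = 8` direction channels (45° apart), with activity in `[0, 1]`:

1. **Complex V1 cells** — opponent motion energy.  Oriented Gabor quadrature
   pairs (sine/cosine phase, four orientations: 0°, 45°, 90°, 135°) are
   combined with two biphasic multi-stage low-pass temporal kernels

       g_n(t) = (t/τ_g)^n e^(−t/τ_g) [1/n! − (t/τ_g)²/(n+2)!],   n ∈ {6, 9},

   squared and summed into an energy `r` for each orientation's preferred
   direction and `l` for the opposite direction.  The directional signal is
   the opponent difference `[r − l]₊` (a positive filter output means motion
   in the preferred direction, a negative one the opposite), which cancels
   non-directional flicker energy at onsets and terminators.  Each channel is
   then divisively normalised by the energy pooled over the four orientations
   at that pixel and passed through a saturation, so a clean edge drives its
   perpendicular channel to ≈ 1 while the weaker but unambiguous terminator
   signal retains a workable amplitude.  Four orientations × two opponent
   signs give the 8 direction channels.

2. **End-stopped V1 cells** — shunting dynamics

       dv/dt = (1 − v)·G₁·v_cx − v·(τ_es + G₂·Γ + G₃·Ω(t−T) + G₄·Λ(t−T)),

   where Γ is Gaussian-weighted same-direction surround inhibition from
   complex cells (the end-stopping mechanism: a cell whose surround is full
   of strongly active same-direction neighbours — an edge cell — is
   suppressed; a terminator cell with a half-empty surround is spared),
   Ω is drive-proportional inter-directional inhibition, and Λ is long-range
   inhibition from neighbouring end-stopped cells of other directions.  The
   Ω/Λ terms act only after a delay `T_es` so activity can develop first.

3. **MT integration cells** — additive dynamics saturated to `[0, 1]`,
   driven by complex and end-stopped input, by lateral excitation λ from
   same-direction neighbours (±6 px) *that are more active than the
   receiving cell* (so activity flows outward from terminator seeds), and
   inhibited by the same-pixel other-channel sum γ (winner-take-all), a
   Chebyshev-distance-3 ring of other-direction cells ζ, and the local
   segmentation partner.  λ is shunted off wherever the receiving cell's
   segmentation activity exceeds ρ_sg.

4. **MT segmentation cells** — detect motion discontinuities.  They pool
   complex input over their 7-px receptive-field centre, receive η (the
   direction-summed integration activity), are *inhibited by end-stopped
   cells*, and suppressed by χ, a Gaussian-weighted annulus (radii 4–10 px)
   of same-direction segmentation activity — coherent same-direction motion
   in the surround silences them, discontinuities do not.  A small
   spontaneous baseline keeps them from ever being exactly silent.

All dynamics are integrated by forward Euler with `dt = 0.1 ms`.  For each
stimulus frame (20 ms apart on the stimulus clock) the V1 complex field is
computed from the frame history and held fixed while the recurrent dynamics
run for a 12 ms window (120 steps).  States and delay histories persist
across frames.

## Parameters

All constants live in a single registry (`ModelParams`).  The connection
gains and decay rates are the model's reference values (e.g. complex→ES
drive 2, ES surround gain 3, complex→integration 0.3, ES→integration 1,
inter-directional inhibition 0.741, decay rates 0.101/ms for MT and 0.01/ms
for ES cells); thresholds ρ_sg = ρ_igig = 0.01, ρ_ig = 0.1, ρ_es = 0.008;
delays T_es = T_ig = 6 ms; carrier frequency 1.1 cyc/deg with σ_x = σ_y =
0.5.  Configuration files (flat YAML keyed by these names) can override any
constant; unknown keys and negative gains fail loudly.  Eleven of the gains
(the MT-side weights and the shared MT decay) are the free parameters of the
genetic-algorithm fitter.

Quantities the reference sources leave open are exposed as configuration
with the following defaults, chosen once on qualitative grounds:

- **Pixel scale** 4 px/deg, so the ≈4-px filter support spans about one
  carrier cycle; spatial kernels have half-width 4 px.
- **Temporal kernels** sampled on the frame clock with τ_g = 0.5 frames and
  12-frame support; the kernels peak within 3–5 frames and are DC-balanced,
  so static stimuli produce (near-)zero energy.  A τ_g of 0.01 ms on the
  dynamics clock would collapse both kernels between frames, which cannot be
  what the model intends; the frame-clock sampling is the working reading.
- **Opponent normalisation**: semi-saturation ε = 0.004 (≈10 % of the peak
  opponent magnitude for a unit-contrast bar).  A vanishing ε would
  normalise every nonzero opponent pair to ≈1 and erase the edge-versus-
  terminator amplitude differences the next stage depends on.
- **ES surround Γ**: unnormalised Gaussian weights (σ = 4 px) over ±8 px
  with the core (±2 px) zeroed — an annular end-zone — and only strongly
  active neighbours (complex activity > 0.5) count as sources.  These three
  choices make Γ a detector of *extended strongly-driven same-direction
  structure*: an edge suppresses itself, a compact terminator blob does not.
- **Ω as printed**: the printed inter-directional sum reduces to the cell's
  own complex drive; it is implemented that way by default (a
  drive-proportional normalisation that reins in strongly driven channels),
  with the cross-channel reading available as `omega_mode="other"`.
- **Inhibition delays as onset gates**: delayed terms are zero until `T`
  after stimulus onset and instantaneous afterwards.  A literal sliding
  `t − T` delay line (also implemented, `delay_mode="lookup"`) makes the
  winner-take-all competition oscillate at period ≈ T instead of
  converging; the onset-gate reading reproduces the intended behaviour of
  letting activity develop before competition starts.
- **Segmentation surround χ**: annulus weights normalised to sum 1 with
  σ = 2 px by default.  With large unnormalised weight sums the
  surround-inhibition loop is Turing-unstable (the segmentation sheet breaks
  into patchy spots that flicker around the gating threshold).
- **χ_e** (the excitatory surround term of the segmentation equation, which
  the sources use but never define) defaults to zero; a form symmetric to
  χ_i over the other directions is available but, summing 7 channels at the
  same gain, it overwhelms the inhibitory term and pins segmentation at 1.
- **Segmentation input pooling** over the 7-px RF centre; the pooled drive
  extends the high-segmentation wall a few pixels beyond the stimulus
  border, matching the λ reach (±6 px) that it must block.
- **Spontaneous segmentation baseline** 0.005 (below ρ_sg).

## Evaluation

The readout is winner-take-all over integration activity: in the evaluation
region (bar footprint dilated by a Chebyshev radius of 3 px) each pixel is
assigned to its argmax channel (ties break to the lowest channel index;
pixels whose strongest channel is below 0.1 — the integration activity
threshold — cast no vote, since a deterministic tie-break would otherwise
pile spurious votes from silent pixels onto channel 0).  The overall error
is 0 iff the true direction wins strictly more pixels than every other
single direction.

The robustness battery crosses 4 cardinal motion directions × 4 orientations
× 2 bar sizes (short/narrow = 9/1 px, long/wide = 21/3 px; the size factors
are paired, giving the canonical 32 conditions) on a 64×64 grid.

Noise robustness injects `v̂ = clip(v + α·√v·z)`, `z ~ N(0,1)` — variance
equal to activity, α = 1 mimicking Poisson-like variability — at the outputs
of all four populations.  One noise realisation is drawn per population per
stimulus frame and held over the 12 ms window (`"step"` redraws every Euler
step; per-step white noise is averaged away by the 120-step window and
barely perturbs the readout, so the frame-held realisation is the default).
Noisy outputs are what downstream populations read; each population's own
state integrates those noisy inputs.  Negative noisy activities are clipped
to zero (activities are rates).  A sweep runs α ∈ {0, 0.1, …, 1} with 10
seeded repeats each and reports mean error ± standard error.

Propagation timing records the integration field every step within the
frame whose bar sits mid-grid and reports the earliest model time at which
every bar pixel's winner equals the true direction and remains so for the
rest of the 12 ms window (`nan` if never).

## Genetic algorithm

The 11 free gains are fit by maximising F = F1 + F2 computed from a complete
simulation of a training stimulus (short 45° bar drifting right on a 32×32
grid).  F1 rewards exclusive correct-direction integration activity where
complex cells respond and silence in the background; F2 rewards segmentation
activity at discontinuities (active complex cells with mostly inactive
neighbourhoods) and silence along coherent regions and background.
A candidate is a *solution* when the classification error E_GA — zero at
pixels where the wrong channels are below T = 0.15 and the correct channel
is above it (or everything is below it in the background) — is exactly zero.
Selection is elitist (top 10 % copied), 50 % single-point crossover between
high-fitness parents, 40 % mutation with uniform perturbations (±20 % of the
value) whose signs follow behavioural heuristics: raise ES→MT relative to
complex→MT weights while the aperture problem is unsolved, raise
inter-directional inhibition when wrong channels stay active, lower lateral
excitation and raise segmentation inhibition on background leakage, and
raise surround suppression when segmentation is active in coherent regions.
Runs are fully determined by their seed.

## What the synthetic stimuli do and do not cover

The generator produces exactly the study conditions: binary bars of the four
canonical orientations drifting at one pixel per frame in the eight compass
directions, on a uniform zero background.  It does not emulate luminance
noise, contrast variation, curved or textured objects, multiple objects,
occlusion, plaids or crossing bars (explicitly out of scope).  Passing tests
therefore demonstrate the network's behaviour on idealised laboratory
stimuli, not performance on natural imagery.

## Numerical choices and degenerate inputs

Forward Euler throughout (`dt = 0.1 ms`); state-clipping `v ← h(v + dt·rhs)`
rather than clipping the derivative (the literal derivative-clipped form,
under which activity could never decrease, is available via config).
Within-frame stepping stops early once the state change per step falls below
1e−10 for 10 consecutive steps; the delay histories continue to be fed so
`t − T` lookups stay aligned.  Spatial convolutions zero-pad (background is
zero luminance).  Winner ties break deterministically to the lowest channel
index.  Empty evaluation masks, non-finite states, negative gains, unknown
config keys, and stimuli that would leave the grid all raise immediately.

## Known limitations

- The reference gain set and the reconstructed network structure do not
  reproduce every reported behaviour of the original system; where a test
  encodes such a behaviour and the implementation cannot attain it, the test
  is left failing rather than weakened.  See the README for the honest
  status of the headline robustness results.
- Two concrete failure modes of the reconstruction, observed across every
  structural reading explored: (a) on oblique bars the suppression needed to
  silence the aperture-biased perpendicular channel also silences the
  perpendicular channel on cardinal bars, where it happens to be the correct
  answer — the two demands could not be met by one configuration; and
  (b) the compact oriented micro-edge at a bar's leading end drives its own
  aperture channel (e.g. up-right for a 45° bar moving right) which, being
  spatially compact, escapes the same end-stopping surround that silences
  the long edges, and can capture the vote.  In intermediate regimes the
  winning channel alternates between the true direction and a component
  direction from frame to frame (a period-two cycle on the frame clock), so
  single-frame classification there reflects frame parity, not robustness.
- The genetic-algorithm fitter, seeded at the reference gains with
  behaviour-guided mutation, improves fitness steadily but has not reached
  the zero-error termination criterion in this reconstruction; runs return
  the best candidate flagged as non-converged.
- Near the winner-take-all bifurcations the trajectories are sensitive to
  the Euler step: halving `dt` can change which channel wins at individual
  pixels.  Refinement stability holds in smooth regimes (it is tested
  there); global <1 % refinement invariance does not hold for this class of
  threshold-gated competition dynamics.
- The surround-inhibition loop between segmentation cells supports
  pattern-forming instabilities for strong unnormalised weights; the default
  normalisation avoids them but also caps how strongly coherent-motion
  regions can be suppressed.
- Simulation sizes used by the tests and the acceptance script are desk
  scale (32–64 px grids, ≤ 12 frames, 10 noise repeats), chosen to keep a
  full run in minutes on one core.
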