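# Methods

## Assay and units

The assay films up to eight stage 44–45 tadpoles swimming in a 100 mm
circular dish over a display that shows moving dots. All positions are in
millimetres in a dish-centred frame (x rightward, y upward), converted from
pixels through a user-supplied `mm_per_pixel` calibration (pixel centres at
integer coordinates). Durations are seconds, speeds mm/s, luminances
cd/m². The protocol defaults baked into `AssayConfig` are the published
constants of the paradigm: 30 Hz video, 5 mm encounter radius, 24 mm/s
avoidance threshold, 0.25 s response window, a 3 min pre-test with
background-isoluminant dots followed by a 5 min test, 10 mm dots moving at
2 cm/s, and photopic (190 cd/m²) or mesopic (0.65 cd/m²) backgrounds. The
display mapping from cd/m² to pixel value is linear with the background at
1.0; only contrast ratios matter downstream, so absolute photometry is not
modelled.

One printed figure in the source protocol gives 4 mm dots where the methods
give 10 mm; the default follows the methods value and the diameter is
configurable.

## Stimulus model

"Ballistic random walk" is realized as the minimal run-and-turn model:
straight runs at constant speed, run durations exponential with mean 1 s
(configurable), a uniformly random heading after each run, and specular
reflection at the wall (dish radius minus dot radius). Per-frame
displacement is exactly `dot_speed / frame_rate` except on reflection
frames, where the path is folded and the chord shortens. Dots are
independent and may overlap. Rendering uses anti-aliased discs (alpha from
the signed distance to the circle edge, ±half a pixel).

## Swimmer generator

The generator is the ground-truth source for every downstream stage, so its
defaults are the study conditions and its programmed behavior must be
recoverable by the scorer exactly.

**Speed process.** The published observation is a marginal distribution:
swimming speeds follow two power-law regimes on [0, 200] mm/s joined at
24 mm/s. The two exponents are not published; defaults are
α_low = 0.5, α_high = 2.5 (density continuous at the breakpoint), which
give ~76% of mass below the breakpoint — slow cruising punctuated by fast
bursts. Temporal persistence uses a Gaussian-copula autoregression: a
latent AR(1) Gaussian (autocorrelation time 0.5 s, a typical burst–glide
timescale at 30 Hz) mapped through the analytic inverse CDF. This is an
autoregression on a monotone transform of speed; it preserves the stated
marginal exactly, which a literal AR on log-speed would not.

**Headings.** Gaussian turning steps (σ = 0.25 rad/frame). At the wall the
animal slides along the boundary at full speed (thigmotaxis) rather than
bouncing; path length is conserved, so displacement-derived speeds match
applied speeds in every frame. (Dots, being screen objects, reflect
specularly instead.)

**Programmed escapes.** The generator mirrors the scorer's own event
segmentation per (animal, dot) pair — an encounter opens on a downward
crossing of the 5 mm radius and closes after three consecutive frames
outside once the response window has elapsed — and responds to each opening
with probability `p_avoid`. A response pins the speed for a 0.1 s latency
(a typical visuomotor startle delay), then applies an accelerating burst:
+Δv (default 40 mm/s) at burst start, ramping linearly to +2Δv over the
0.5 s burst, with the heading set directly away from the dot at burst
onset. The burst baseline is the peak applied speed over the preceding
~0.5 s (twice the smoothing support), so the jump is a jump relative to
anything the animal — possibly already bursting — was just doing. These
three choices (scorer-matched triggering, ramped burst, recent-peak
baseline) exist so that *every* programmed response produces a
super-threshold change of the smoothed speed inside the response window,
including encounters that begin while an earlier burst is still rising or
decaying; with a flat burst, an encounter opening mid-plateau would see no
speed change at all. A consequence is that applied speeds can exceed the
200 mm/s sampling range during chained startles; the [0, 200] range applies
to sampled locomotor speeds. Invisible dots never trigger a response.

**Mutual avoidance (optional).** `min_separation` adds conspecific
avoidance: agents steer away from neighbours inside 1.5× the separation and
never step within it (a blocked step holds position). It is off by default —
the study conditions are eight freely mixing animals — and exists to produce
sessions whose trajectories never approach each other, the stated condition
for identity-switch-free tracking validation.

**What the generator does not emulate.** Real videos have sensor noise
(optional Gaussian pixel noise approximates it), uneven illumination,
shadows and reflections at the dish wall, tail-beat body deformation, and
animals that genuinely touch. Passing tests therefore demonstrate
correctness of the measurement pipeline under controlled conditions, not
robustness to all real-world imaging artifacts.

## Detection and tracking

The background is a per-pixel temporal median over ~25 strided frames;
objects occupying a pixel in fewer than half the samples vanish from it.
An animal resting in one place for most of a clip melts into the median —
a known limitation of any median background; `track_video` accepts an
explicit background (e.g. from an empty-dish clip) for that case. Detection
thresholds `background − frame` at a contrast floor (default 20% of the
calibration frame's peak contrast, floor 0.05), labels connected
components, converts areas to mm², keeps components inside the plausible
body-size range (default 10–60 mm²; a 9 × 3 mm ellipse is ~21 mm²), and
ranks by closeness of area to the range midpoint, returning at most
`n_animals` per frame. Ties break deterministically (larger area, then
scan order).

Known dots are excluded twice. First, the expected stimulus frame (dots
rendered over the background) is folded into the per-frame background, so
an animal is segmented from whatever part of its body is darker than the
*expected* scene — an animal half-overlapping a dark dot is still found
from its protruding half, and an animal over a faint dot is found whole.
Second, any residual component whose centroid falls within the dot radius
plus 1 mm of a known dot centre is discarded. An animal fully inside a dark
dot of identical luminance is physically unobservable; those frames fall to
the tracker's interpolation.

Tracking maintains exactly `n_animals` tracks for the whole session (the
assay films a fixed group; no births or deaths). Each frame solves the
optimal (Hungarian) assignment on squared displacement, gated at
2 × 200 mm/s ÷ frame rate; a track missed for k frames has its gate scaled
by k, since it may have moved that much farther. Detections are canonically
ordered within a frame, so results are independent of detector output
order. Miss runs are filled by linear position interpolation (held at the
ends) and flagged; gaps longer than 1 s are logged.

## Kinematics

Speeds are frame-pair displacements times the frame rate, padded with the
final value to align with frames. Smoothing is a discrete Gaussian kernel
(σ = 2 frames ≈ 67 ms, truncated at ±4σ, unit-normalized, reflect
padding) — wide enough to suppress single-frame jitter, narrow enough not
to blur a 0.25 s response window. The σ is not published; 2 frames is this
package's choice. Raw speeds feed the distribution fit (shape must not be
smoothed); smoothed speeds feed event scoring (thresholding must be
noise-robust). Whether the original software smoothed positions or speeds
is ambiguous; this package smooths the speed series.

The breakpoint fit maximizes the two-segment power-law likelihood
(continuous density at the breakpoint) profiled over a 0.5 mm/s grid of
candidate breakpoints, with a lower speed cutoff of 0.5 mm/s (a power law
needs one) and each segment required to hold at least 50 samples. Because
the statistic is maximized over the grid, the likelihood-ratio against a
single power law is compared to a conservative χ²(2) 99.9% cutoff; fits
that fail it are flagged "single-regime" with the breakpoint reported at
the domain edge.

## Event scoring

Encounters open at downward crossings of the encounter radius — an animal
already within radius at recording start is not an encounter ("initial
encounter" requires approach) — and close once the distance has exceeded
the radius for 3 consecutive frames *and* the response window has elapsed,
whichever is later. The 3-frame closure rule is this package's resolution
of re-entry segmentation (the protocol does not state one); re-entry after
closure opens a new event, and overlapping events of one animal with
different dots are scored separately. The window in frames is
⌈0.25 s × 30 Hz⌉ = 8, so the last inspected sample sits at 0.267 s; the
ceiling guarantees at least one inspected frame at any frame rate.
"Velocity change" is the absolute change of smoothed speed relative to the
onset frame — decreases (freezing) count, and this is deliberate and
documented. Events whose window crosses the end of the recording are
censored and excluded from both numerator and denominator. Rates are
computed per animal and then averaged over animals with at least one
non-censored encounter. The false-positive path runs the identical code
against invisible-dot trajectories. Group-level inference (ANOVA and
post-tests across treatment groups) is out of scope; per-animal rate tables
are exported for standard statistics tools.

With the default generator the chance-level rate is ~0.2–0.3: heavy-tailed
baseline speeds cross the 24 mm/s change threshold by chance in a quarter
of windows, which is exactly what the invisible-dot control is for.

## Physiology metrics

ΔF/F uses F(t) = ROI(t) − background(t), F₀ the mean of the first 20
frames (configurable); a non-positive F₀ is an error, not a NaN. The FRET
readout is (CFP − bg) / (YFP − bg − β·(CFP − bg)) with a single scalar
bleed-through fraction β (default 0; the original pixel-wise bleed-through
estimation is out of scope). PSTHs count spikes in bins over [0, window)
after each onset and divide by bin width times trial count (default bin
100 ms, unpublished). The glycine reversal potential is the x-intercept of
an ordinary least-squares line through the I–V points (protocol grid −80 to
+10 mV in 10 mV steps); a quadratic term halving the residual sum of
squares raises a rectification warning. The fit form is unpublished; OLS is
this package's choice.

## Problem sizes and numerical choices

Validation runs at desk scale, chosen to make every check sharp but cheap:
ground-truth tracking on one rendered 60 s session (8 animals, 5 dots,
0.5 mm/px, ~14,400 animal-frames); scorer-vs-oracle equivalence on
500-frame sessions; generator–scorer consistency on 180 s sessions
(≥ 200 encounters); breakpoint recovery on ~10⁵ speed samples (420 s of
dotless simulation). Tracking accuracy is reported over frames where the
animal's body is clear of dot discs, because an animal inside an
isoluminant dark dot is unobservable in principle; on those clear frames
recovery is ≥ 99% within 1 mm with zero identity switches when trajectories
stay two body lengths apart. Coordinates round-trip through CSV at 1e-9 mm;
assignment costs are exact squared distances; the dual power-law CDF and
quantile function are analytic (no sampling error in the inverse-CDF map).

## Known limitations

- Two animals that touch merge into one blob; identity across such contacts
  rests on the displacement gate and can genuinely be lost. The recovery
  guarantee is conditional on separated trajectories.
- The median background absorbs animals that rest for most of a clip.
- Escape bursts during dense chained startles can exceed the sampled speed
  range; the marginal-distribution guarantee applies to undisturbed
  locomotion (`p_avoid = 0` or dotless sessions).
- The scorer's discrete window (⌈w·f⌉ frames) inspects up to one frame
  beyond the nominal window duration.
- Luminance calibration (cd/m² to pixel value) is linear by construction;
  display gamma is the user's problem.
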