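# Methods

This note documents the models, conventions and design choices behind
`pigwatch`, in the order data flows through the package.

## Dew point and BGHI

The dew point is computed with the Magnus form

    γ(T, RH) = ln(RH/100) + c·T/(b + T)
    DPT      = b·γ / (c − γ),      b = 238.88 °C,  c = 17.368,

the parameterization of the saturation vapor pressure curve
`es(T) = 6.1121·exp(c·T/(b+T))` hPa. This is the only reading of the
published constants under which `DPT = T` exactly at saturation, and the
test suite verifies it against an independent bisection solve of
`es(DPT) = es(T)·RH/100`. RH = 0 is outside the domain (the logarithm
diverges); dry-bulb input is restricted to −20…60 °C as a sanity guard.

`BGHI = BGT + 0.36·DPT + 41.5` is exact affine arithmetic. The published
class table leaves the intervals (67, 68] and (74, 75] unassigned; the
classes are implemented as contiguous half-open intervals with inclusive
upper bounds — stress ≤ 67 < comfort ≤ 74 < alert ≤ 76 < emergency — which
matches the prose description of the bands and guarantees every finite
index receives exactly one label. All thresholds (BGHI classes, RT/RR
limits, per-phase air temperature ranges, humidity bands) live in
`pigwatch.config` with the literature defaults and can be overridden from
YAML; the humidity "good" band defaults to 50–70 % (the prose ideal range)
with critical bounds < 40 % and > 90 %, since the tabulated humidity column
is internally inconsistent.

## Label I/O and geometry conventions

Pixel coordinates use the standard image convention: origin top-left,
half-open integer ranges `[x0, x1) × [y0, y1)`; denormalization rounds each
edge to the nearest integer. Boxes reaching past the image are clipped with
a warning rather than rejected (they are routine at pen walls). The
confidence filter keeps boxes with confidence ≥ 0.70 — the boundary is
inclusive because only "lower values" are removed — and ground-truth boxes
without a confidence always pass. Writing uses 6-decimal fixed point, so a
parse/write round trip is the identity to 1 × 10⁻⁶.

## Zone-occupancy inference

Occupancy is `OC = area(∪(box ∩ zone)) / area(zone)` with true union
semantics (duplicated boxes change nothing; OC is monotone under adding
boxes). The rectangle union is delegated to `shapely`; the tests check it
against an independent per-pixel rasterization oracle.

The 50 % rule is ambiguous about whose rectangle must be half-covered. The
default follows the occupancy equation's denominator: a zone is "in use"
when the union OC of all standing boxes reaches the threshold, and every
standing box touching an in-use zone is assigned the zone's behavior. A
per-detection alternative (intersection / box area ≥ threshold) is
selectable (`occupancy_rule="box"`). The rule is applied to drinkers as
well as feeders. A detection qualifying for both goes to the zone with the
larger per-detection intersection fraction, ties to the drinker — drinking
bouts are rare and short, so losing one costs more than losing a moment of
eating. Feeder zones are only considered inside the feed-distribution
windows; drinking counts at any time; `inactive_feeder` zones never produce
eating. No temporal smoothing is applied by default: counts are per frame,
with no animal identity tracking.

## Time budgets

`hours = frames / (FPS·3600)`. The printed form of the time equation
("Time (H) = FPS(3600)") is dimensionally incoherent; this reading is the
only one that reproduces the published hour values from frame counts. Two
frame rates exist — the capture rate and the detector throughput
`1000/(tp+ti+tnms)` — and durations always use the capture rate: how long a
behavior lasted depends on when frames were taken, not on how fast they
were processed. The per-animal budget divides pen-level pig-frame counts by
the group size, so a fully detected pen's budget sums to the observation
span. Reporting rounds hours to 4 decimals and percentages to 2, matching
the published tables.

## Detector and duration evaluation

Matching is greedy in descending confidence at IoU ≥ 0.5 per class; the
tests verify on exhaustive small instances that greedy TP counts equal the
optimal assignment's. AP integrates the all-points-interpolated
precision envelope (the convention of the YOLOv5 ecosystem; a 101-point
mode is available), mAP50-95 averages IoU 0.50:0.05:0.95, and the reported
"Average" rows are unweighted class means — the convention that reproduces
the published average rows from their class entries. Degenerate 0/0
precision or recall is reported as 0 with a warning rather than NaN.
Duration metrics are plain MAE, RMSE and `R² = 1 − SSres/SStot`; a constant
observed series leaves R² undefined (returned as `None`) while MAE/RMSE
remain valid.

## The synthetic pen

The simulator emulates the study conditions: 3 pigs per pen, a 640×360
scene with a feeder along the top wall, a drinker on the right wall and an
unused feeder that attracts false positives, a 16-h observation day
(06:00–22:00) at 1 frame·s⁻¹, and twice-daily feeding windows (07–09 h,
15–17 h).

**Microclimate.** Sinusoidal diurnal temperature peaking at 14:00 with
humidity in anti-phase plus Gaussian noise; regime means/amplitudes are set
to the published facility statistics (cooled 22.59 °C / 81.99 %, uncooled
30.43 °C / 54.62 %). The black-globe offset over dry-bulb (0.4 °C cooled,
0.6 °C uncooled) is calibrated so the long-run BGHI means land on the
published stall means (71.45 and 79.82). RT/RR respond piecewise-linearly
to the concurrent air temperature, anchored so a cooled pen stays under the
physiological limits while uncooled midday readings exceed the respiratory
threshold; this channel exists to exercise the physiology classifier, not
to model thermoregulation.

**Behavior dynamics.** A first-order Markov chain per pig at 1-s
resolution, using the constant-switch-rate mixture `P = (1−r)I + r·1πᵀ`
whose stationary distribution is exactly the target occupancy π. The
default `r = 0.05` gives mean bout lengths of roughly 20 s (drinking) to a
minute (lying) — short against real lying bouts, but the budget fractions,
not the dwell times, are the published quantity being emulated. Eating is
confined to the windows by splitting π into an in-window chain (eating
mass `π_eat/w` for window fraction w, non-eating behaviors keeping their
relative proportions) and an out-of-window chain with zero eating, whose
time-weighted mixture reproduces π exactly; a window closing mid-bout
interrupts the eater immediately. Target fractions are the published
budgets of detected time (cooled .680/.200/.115/.004, uncooled
.697/.168/.123/.012). When a per-second BGHI series is supplied, seconds
above the comfort band use the heat-stress targets, shifting budgets toward
drinking as heat spells do.

**Detector noise.** Per-detection Bernoulli misses; per-edge Gaussian box
jitter (2 px); confidences ~ Beta(76, 4), concentrating mass in the
reported 0.9–1 range so the 0.70 filter almost never removes a real
detection; spurious standing boxes at the unused feeder and on the soiled
floor (0.01/frame each) — the two reported false-positive sources. The miss
rate is regime-dependent: 0.05 cooled, 0.12 uncooled. The uncooled value is
calibrated once from the ratio of the published uncooled detected time to
observed time (≈ 0.88); it is also what makes the published sign structure
reproducible — the uncooled pen has a *larger* eating fraction of detected
time yet *fewer* detected eating hours, which is only consistent if its
detector misses more.

**What the simulator does not model.** Photorealistic appearance, pig
identity and trajectories (boxes are re-placed each frame), realistic bout
durations, occlusion structure (misses are independent), and the
annotation-vs-inference definition gap (synthetic ground truth is defined
by the same box-in-zone geometry the pipeline tests, so real-world
disagreement about when "eating" starts is absent). Passing tests therefore
demonstrate the inference arithmetic and its noise response, not detector
performance on real video.

## Conventions in the headline emulation test

Ground truth records both the *true* per-pig budget (the
manual-observation analog) and the *detected-frame* budget (what survived
the simulated detector). Under uniform Bernoulli misses the true-budget
deficit is structurally `p_miss × hours` — a predictable degradation the
suite asserts via the binomial expectation — whereas the published
manual-vs-automatic differences are net figures in which misses and false
positives partially cancel. The end-to-end tolerance test therefore
compares the pipeline's estimates against the detected-frame budget, which
isolates the inference stage this package implements, and holds it to the
published per-behavior discrepancies over a 16-h day.

## Problem sizes and determinism

Default simulations use 16-h days at 1 frame·s⁻¹ (57,600 frames, 3 pigs);
shorter spans are used where a property does not need a full day. Every
stochastic component draws from one `numpy` Generator per run, so a fixed
seed makes microclimate, states, detections and all downstream reports
byte-identical.
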