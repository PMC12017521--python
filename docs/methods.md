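# Methods

## Model

The foot is modelled in the vertical plane of the medial longitudinal
arch as two rigid segments — rearfoot and forefoot — firmly joined at the
navicular, plus a shank that directs the body load. Stance is divided at
foot flat and heel off into heel contact (HC), plantar contact (PC) and
push-off (PO), and a different free body governs each phase (README shows
the equations). Modelling assumptions inherited by every downstream
quantity:

* the foot's weight is neglected (small against the loads involved);
* during HC the body load equals the rearfoot vertical ground reaction
  and acts along the shank direction θB, measured from the in-plane x
  axis so that θB = π/2 is a vertical load;
* during PC the foot is quasi-static and the arch load is the root of
  the summed squares of the two plates' force components;
* the plantar-aponeurosis tension FPA bundles passive stretch and active
  intrinsic-muscle contraction into one force along the PA line of
  action. It is an *input*: a piecewise-linear curve in percent of
  stance, normalized by body weight. The bundled default
  (`archstiff/data/pa_tension_default.csv`: 0 → 0.05 → 0.3 → 1.0 → 0.2 BW
  at 0/15/50/80/100 %) is a plausible placeholder rising to a late-stance
  peak, not a measured curve; replace it via `pa_curve_path` for
  quantitative use.

The stiffness k = ΔF∥/Δh uses the component F∥ of the internal arch
force along the per-frame arch-height direction. On PC frames the
root-sum-square load is a magnitude; it is applied along the negative
height direction (compression lowers the arch), i.e. F∥ = −FAL. Note the
free-body structure itself makes F∥ discontinuous at the phase
boundaries (at foot flat the HC equations force FAy → (1−sin θB)FGR1 ≥ 0
while the PC convention is ≈ −body weight); per-phase slopes are
unaffected because each fit sees only its own phase.

During push-off the solved equations carry the PA term with a positive
sign (FAx = Ff2 + FPA − mF·ẍF); the assembled equations used by the
back-substitution tests follow the same convention.

## Signal processing

Moving-average filters with shrinking symmetric edge windows: 7 samples
for markers at 100 Hz, 21 samples for plate records at 1000 Hz, followed
by an anti-alias average (window = rate ratio rounded up to odd) and
decimation to the marker rate. Projection onto the MLA plane recomputes
the horizontal foot axis (calcaneus → first metatarsal head) each frame
(`plane: per_frame`; a stance-averaged `fixed` plane is available); the
vertical axis is world-vertical, so vertical forces and marker heights
are preserved exactly. The in-plane x origin is the first-frame
calcaneus ground position, making the planar representation invariant to
horizontal translation and to rotation about the vertical axis.

Event thresholds: 30 N summed vertical GRF with a 3-frame debounce for
heel strike / toe off; 20 mm marker height for foot flat (first
metatarsal) and heel off (calcaneus). The 20 mm value already absorbs
marker size; no radius correction is applied. Heights use the first
threshold crossing — no hysteresis — which is adequate for filtered
signals; flickering near the threshold would need a debounce like the
force channel's.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| marker_window / grf_window | 7 / 21 | samples | ~±30 ms smoothing at each native rate |
| grf_threshold_n | 30 | N | stance detection threshold |
| height_threshold_mm | 20 | mm | sub-phase marker-height threshold |
| debounce_frames | 3 | frames | rejects single-frame threshold flicker |
| com fractions | 0.5 / 0.5 | — | segment CoM at the midpoint of its bounding landmarks (CAL–NAV, NAV–MET1); no CoM location is defined by the marker set, and inertial terms are small at walking speeds |
| foot_mass_fraction | 0.0137 | — | standard anthropometry; split 0.6/0.4 rear/fore |
| gyration_fraction | 0.475 | — | J = m·(0.475·segment length)² |
| k_window_frames | 5 | frames | central-difference span for continuous k; smaller windows amplify differentiation noise |
| hc_fraction / po_fraction | 0.5 / 1/3 | — | fit windows: "beginning" of HC and "end" of PO made concrete |
| min Δh | 0.01 | mm | frames below this are flagged invalid, not infinite |

The per-phase fit reports RMSE normalized by the force *range* over the
fitted window (in percent): scale-free and insensitive to the arbitrary
offset of F∥.

The moment arm l_B of the body load about the rearfoot origin O (ground
projection of the calcaneus at heel strike) is the signed horizontal
offset of the ground intercept of the load line through the ankle marker
at angle θB. Segment orientations come from landmark-pair angles,
unwrapped with a π jump tolerance; accelerations are centered second
differences (one-sided copies at the ends).

## Synthetic gait generator

The generator is the package's oracle: it *inverts the estimator's own
equations*, so ground truth is exact by construction, and an independent
forward-dynamics simulation is deliberately out of scope. What it
emulates: the 12-marker layout reduced to one foot's six landmarks,
staggered plates (rear plate under the heel, fore plate under the
forefoot, a root-sum-square-preserving cross-fade during PC), stance
timing (0.7 s at 0.15/0.45/0.40 phase fractions), a standing lead-in
that defines the static NNHt, and the three-phase arch load/height
structure: h descends through HC and PC, dips briefly after heel off
(dip depth 10% of the configured drop), then rises rapidly; F∥ obeys the
configured slope against the *post-filter* arch height in every phase
interior. The push-off mid-segment slope is solved in closed form so the
end-of-push-off fit equals k_PO exactly while the terminal 15% of PO is
compliant (2×k_PC), reproducing the stiff–compliant–stiff–compliant
pattern.

Design choices worth knowing:

* Marker trajectories are designed so the *filtered* marker heights
  cross 20 mm exactly at the configured boundaries; the construction
  verifies this and raises `InfeasibleConfig` otherwise.
* Plate forces are recovered per frame by a minimum-norm inversion of
  the free-body equations in the (friction, vertical) pair, anchored to
  smooth reference profiles; the 1000 Hz records are then obtained by an
  equality-constrained minimum-curvature deconvolution so the analyzer's
  filter-and-decimate stage reproduces the inverted targets to machine
  precision.
* The heel-contact arch excursion is 43% of the configured drop (~7 mm
  by default). That is larger than a physiological HC excursion and, at
  k_HC = 0.12 kN/mm, forces heel-contact plate loads of 1–3 kN with
  friction ratios no real floor provides. This is deliberate: with
  0.5 mm marker noise the regressor variance over the short HC fit
  window must dominate the noise variance for the slope to be
  identifiable (errors-in-variables attenuation), and the free-body
  geometry near foot flat bounds the arch-directed force that
  physiological loads can produce. The generator therefore prioritizes
  exact, identifiable arch mechanics over plate-force realism.
* Vertical plate force steps, rather than tapers, at the stance edges
  (with two sub-threshold ramp frames) keep event detection exactly on
  the configured frames.

Hence: passing tests demonstrate that the pipeline solves the model
correctly and recovers known mechanics under realistic marker/plate
noise; they do not validate the model against real feet, where soft
tissue, marker placement error, the true FPA curve, and non-planar
motion all enter.

Noise: i.i.d. Gaussian, marker σ in mm at the marker rate, plate σ in N
at the plate rate, both seeded; the deterministic construction is cached
across seeds.

## Numerical choices

* Degenerate geometry raises (`DegenerateFrame`) rather than producing
  NaN: coincident landmarks, vertical foot axis (<1 mm horizontal span).
* Continuous k frames with |Δh| < 0.01 mm are invalid, not infinite;
  negative k is permitted (the arch force can drop while h still falls).
* Fits require ≥2 points and a non-constant abscissa (`DegenerateFit`).
* Curve R² resamples both curves to 101 points on a min-max-normalized
  abscissa and min-max scales ordinates; it is invariant to positive
  affine maps of either axis and asymmetric in the reference choice
  (report both orderings). A constant reference raises
  (`DegenerateReference`).
* The stiff/compliant label threshold is 3× the plantar-contact slope
  (fallback 0.02 kN/mm when that reference is non-positive); the window
  set (early HC, PC, early PO = first third, late PO = last 15%) is an
  implementation choice — the pattern itself is robust to moderate
  window changes because the slopes differ by an order of magnitude.

## Problem sizes

Default synthetic trials are 0.95 s (95 marker frames / 950 plate
samples) with a 70-frame stance; noisy-recovery statistics use 20 seeds.
These sizes keep the full test suite and the acceptance script in the
seconds-to-a-minute range while leaving every phase window ≥9 frames.

## Known limitations

2D model (out-of-plane GRF is dropped, not redistributed); no midfoot
segment; no windlass-mechanism or muscle-level modelling; C3D input is
not implemented (CSV dialects only); marker gap handling is linear
interpolation of ≤5-sample gaps; the bundled PA curve is a placeholder;
cohort statistics assume one summary row per subject.
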