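# archstiff

Dynamic linear stiffness of the medial longitudinal arch (MLA) across the
stance phase of walking, estimated with a phase division-based
multi-segment foot model.

## The problem

The foot arch bears body weight, absorbs ground impact, and stores and
returns elastic energy during gait. Its *linear* stiffness — force change
per millimetre of arch-height change — cannot be measured directly in
vivo, because the load transmitted through the arch is an internal force.
This package estimates that load from standard gait-lab data (3D marker
trajectories at ~100 Hz and dual 6-DOF force plates at ~1000 Hz) by
dividing stance into three phases and solving a planar free body in each:

* **Heel contact** (heel strike → foot flat): only the rearfoot touches
  the ground. With the body load FBW taken equal to the rearfoot's
  vertical ground reaction FGR1 acting along direction θB, Newton's
  second law for the rearfoot gives the internal force at the navicular
  connection:

      FAx = Ff1 + FPA − FGR1·cos θB − mR·ẍR
      FAy = (1 − sin θB)·FGR1 − mR·ÿR
      MA  = FGR1·lB + FAy·xA − FAx·yA − JR·θ̈R

* **Plantar contact** (foot flat → heel off): the foot is quasi-static
  and the arch load equals the root of the summed squares of both
  plates' components: FAL = √(FGR1² + Ff1² + FGR2² + Ff2²).

* **Push-off** (heel off → toe off): the forefoot free body with the
  model origin at the first metatarsophalangeal joint:

      FAx = Ff2 + FPA − mF·ẍF,  FAy = FGR2 − mF·ÿF,
      MA  = FAy·x′A + FAx·y′A + JF·θ̈F

FPA is the plantar-aponeurosis tension (combined passive stretch and
intrinsic-muscle effect), supplied as a body-weight-normalized curve over
percent of stance. Arch height h is the perpendicular distance from the
navicular marker to the calcaneus–first-metatarsal line; NNHt is h
normalized by the truncated foot length. The arch stiffness is

    k = ΔF∥ / Δh   [kN/mm],

with F∥ the component of the arch force along the direction in which h is
measured. Per-phase average stiffnesses k_HC, k_PC, k_PO are least-squares
line slopes over the beginning of heel contact, the plantar contact phase,
and the end of push-off.

Stance is detected from the summed vertical GRF with a 30 N threshold and
subdivided at 20 mm marker-height crossings of the heel and
first-metatarsal markers.

A first-class synthetic gait generator builds marker and plate data whose
arch mechanics follow prescribed per-phase stiffnesses, with exact ground
truth, so every pipeline stage is testable without laboratory data.

## Worked example

```sh
python examples/simulate_and_analyze.py
```

prints

```
detected phases: StancePhases(heel_strike=15, foot_flat=26, heel_off=57, toe_off=85)
k_HC = 0.1200 kN/mm   (target 0.12)
k_PC = 0.0070 kN/mm   (target 0.007)
k_PO = 0.0400 kN/mm   (target 0.04)
static NNHt = 0.162, max arch displacement = 0.081 NNHt
stance pattern: stiff-compliant-stiff-compliant
```

The three stiffnesses are the fitted per-phase slopes; the noise-free
synthetic trial is recovered to machine precision. The pattern line shows
the characteristic stiff–compliant–stiff–compliant transition of the arch
over one stance: stiff at touchdown, extremely compliant (k ≈ 0.007
kN/mm) while the sole is flat, abruptly stiff entering push-off, and
compliant again as the foot unloads. Other examples:
`examples/cohort_statistics.py` (cohort Mean/STD aggregation) and
`examples/compare_curves.py` (alignment-and-scale R² between two
load-deformation curves).

The same pipeline is scriptable from a shell:

```sh
archstiff simulate --seed 3 --out trial/
archstiff analyze --markers trial/markers.csv --forces trial/forces.csv \
    --meta trial/meta.yaml --out results/
archstiff summarize results/summary.json more/summary.json
archstiff compare-curves a.csv b.csv
```

Input dialects (wide marker CSV, long force CSV, YAML metadata) are
documented in `archstiff/io.py`; all tunables live in `RunConfig`
(`archstiff/config.py`).

## Limitations

The model is planar (the MLA plane), neglects foot gravity, uses a
configurable but externally supplied PA-tension curve (the bundled curve
is a placeholder shape — replace it with digitized values for
quantitative work), and reports quasi-stiffness of a load–deformation
loop, not a material property. See `docs/methods.md` for assumptions,
parameter defaults, and what the synthetic generator does and does not
emulate.
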