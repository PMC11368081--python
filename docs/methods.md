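# Methods

## Model and assumptions

The jumper is a planar (sagittal-plane) chain of four rigid segments —
foot, shank, thigh and HAT (head-arms-trunk) — standing on one leg whose
segment masses are doubled so the modelled leg carries both legs' mass.
Knee, hip and torso are frozen in the extended configuration at takeoff
and landing; only ankle plantarflexion `α` varies, because the ankle is
the joint whose landing-posture change is hardest to see by eye yet large
enough to matter. The kinematic-chain origin is the tiptoes: a
plantarflexed foot is rotated about the toes, raising the ankle by

```
Δ(α) = l_at · (sin(α + β) − sin β)
```

where `l_at` is the straight tiptoe-to-ankle distance and `β` its natural
standing inclination. Everything above the foot translates rigidly with
the ankle, so the whole-body CoM rise is

```
(1 − m_foot)·Δ(α) + m_foot·c_foot·Δ(α)
```

with foot mass fraction `m_foot` and foot-CoM position `c_foot` along the
toe-ankle line. A key consequence, exploited throughout the tests: the
shank/thigh/HAT length and CoM parameters cancel exactly from the
takeoff-landing CoM difference `h_diff`; only the foot parameters enter.

Flight is ballistic (no air resistance). True quantities follow the
constant-acceleration equations; the measured flight time under a CoM
difference is the positive root of the landing-height quadratic,

```
FT = (V_to + sqrt(V_to² − 2·g·h_diff)) / g .
```

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `g` | 9.81 | m·s⁻² | gravitational acceleration (configurable; the percentage error is provably g-invariant) |
| foot length | 0.152·H | m | anthropometric scaling from stature H |
| ankle height | 0.039·H | m | standing lateral-malleolus height |
| toe-ankle horizontal | 0.787 × foot length | m | tiptoe to malleolus, horizontal |
| `l_at` | ≈ 0.12582·H | m | exact hypotenuse of the two above (the often-quoted 0.126 is a display rounding; the package always uses the exact value) |
| `β` | ≈ 18.057 | ° | atan(0.039 / (0.152·0.787)), stature-independent |
| mass fractions | foot 0.029, shank 0.093, thigh 0.200, HAT 0.678 | – | Winter's segmental table with leg segments doubled for the single-leg model; sums to 1 |
| foot CoM | midpoint of the toe-ankle line | – | gives the analytic rise factor (1 − 0.029) + 0.029/2 = 0.9855 |
| takeoff angle | 40 | ° | plantarflexion at takeoff in the default grid |
| ankle changes | 0…40 in 1° steps | ° | landing angle = takeoff − change; 0° = flat foot |
| jump heights | 0.10, 0.20, 0.30, 0.40 | m | poor to above-average performances |
| statures | 100 values, 1.435–1.984 | m | ±3 SD around female/male averages, evenly spaced inclusive |

Segment length/CoM fractions for shank (0.246/0.433-from-proximal), thigh
(0.245/0.433) and HAT (remainder/0.626 from hip) affect only the absolute
standing CoM height, which nothing downstream consumes; they are included
so `standing_com_height` is physically sensible.

## Sign conventions

The canonical CoM difference is `h_diff = h_landing − h_takeoff`
(negative when landing flatter than takeoff — the error-inflating case),
and the flight equations consume it in that orientation. The
anthropometric estimator naturally produces the opposite orientation,
`ĥ_diff = l_at·(sin(α_to+β) − sin(α_land+β))` (positive in the
flatter-landing case). The correction entry points accept `ĥ_diff` in its
own orientation and negate internally, so the inversion

```
V_to = g·FT/2 + h_diff/FT ,  h = V_to²/(2g)
```

is the algebraically exact inverse of the measured-flight-time equation:
a flatter landing recovers a smaller height than `g·FT²/8`. Public
functions document which orientation they expect.

## Numerical choices

- `β` and `l_at/H` are computed once from the dimensionless fractions, so
  `β` is bit-identical across statures and all lengths scale exactly
  linearly with `H` (property-tested to 1e-12 relative).
- Angles are degrees at every interface and radians internally.
- Degenerate inputs: `h = 0` is allowed in forward ballistic operations
  (all-zero output) but rejected by the percentage error (undefined); a
  landing height above the flight apex (`h_diff > h`) raises a clear
  "unreachable landing height" error, as does an `h_diff`/`FT` pair whose
  implied takeoff velocity is negative.
- The grid is enumerated deterministically (stature outer, ankle change
  middle, jump height inner); CSV output uses a fixed dialect
  ('.' decimal, ',' separator, UNIX newlines, 6-decimal floats) so reruns
  are byte-identical.
- The correction-validation regression is ordinary least squares with an
  intercept (scipy `linregress`); r² is reported at full precision and
  rounded to two decimals only for display.

## What the simulation does and does not emulate

The grid reproduces idealised jumps: perfectly vertical ballistic flight,
posture change confined to the ankle, exact anthropometric scaling of
every individual, and error-free timing. Real measurements add device
timing resolution, arm-swing and knee/hip posture changes, horizontal
drift, and individual deviations from the scaling tables — none of which
is modelled. Passing tests therefore demonstrate the internal consistency
and magnitude of the ankle-position error mechanism, not the total error
budget of any particular device or athlete.

## Design choices

- The takeoff plantarflexion angle is fixed at 40° with landing angles
  40° down to 0° in 1° steps: the flat-foot landing bounds the posture
  change, and 41 integer positions complete the factorial design. Worked
  single-condition examples at stature 1.71 m are evaluated directly
  (1.71 m is not a grid node) rather than by perturbing the grid.
- The foot CoM midpoint placement keeps the CoM-rise factor analytic
  (0.9855) and the correction residual below 2 mm over the whole grid;
  the residual is exactly the foot-mass term the anthropometric estimator
  omits.
- Since the pipeline is closed-form, oracles in the test suite take the
  independent routes: a brute-force 2D rotation-matrix CoM model and a
  time-stepped projectile trajectory.

## Known limitations

- The correction needs the two ankle angles; errors in measuring them
  propagate roughly linearly into `ĥ_diff`.
- Individuals whose foot proportions deviate from the 0.152/0.039/0.787
  scaling will see proportional bias in `l_at`; the CLI accepts a directly
  measured toe-ankle distance for that reason.
- The model is planar and single-joint by construction; knee, hip, torso
  and arm contributions to landing-posture error are out of scope.
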