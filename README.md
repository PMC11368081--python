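# ftjump

Simulation and correction of the error in vertical jump-height estimation
by the **flight-time (FT) method** when the ankle position differs between
takeoff and landing.

## The problem

Jump mats, photocell systems and smartphone apps estimate jump height from
the airborne duration:

```
ĥ = g · FT² / 8
```

This is exact only if the centre of mass (CoM) is at the same height at
takeoff and landing. Jumpers usually take off strongly plantarflexed
(on tiptoes) and land with a flatter foot, so the CoM is lower at landing
by `h_diff = h_land − h_takeoff < 0`, the flight lasts longer, and the FT
method overestimates the jump. `ftjump` quantifies that error across
statures, ankle-position changes and jump heights, and implements an
anthropometric correction equation that recovers the true height.

**For whom:** sports scientists, biomechanists and practitioners who test
vertical jumps with FT-based devices and want to know — or remove — the
error introduced by landing posture.

## The model

- **Body:** a planar four-segment chain (foot, shank, thigh, HAT =
  head-arms-trunk) on a single leg with doubled segment masses, pivoting
  at the tiptoes. Foot length is `0.152·H` (stature `H`), the standing
  ankle (lateral malleolus) height `0.039·H`, and the toe-to-ankle
  horizontal distance 78.7 % of foot length, giving the toe-ankle line
  `l_at = √((0.039·H)² + (0.152·0.787·H)²) ≈ 0.126·H`
  at natural inclination `β ≈ 18.06°`.
- **Kinematics:** plantarflexion `α` (degrees, 0° = flat foot) rotates the
  foot about the toes; the ankle rises by `l_at·(sin(α+β) − sin β)`, every
  segment above the foot translates rigidly with it, and the whole-body
  CoM is the mass-weighted sum.
- **Flight:** ballistic equations `t_a = √(2h/g)`, `V_to = g·t_a`,
  `FT_true = 2·t_a`, and the measured flight time
  `FT = (V_to + √(V_to² − 2·g·h_diff)) / g`.
- **Correction:** with the anthropometric CoM-drop estimate
  `ĥ_diff = l_at·(sin(α_to+β) − sin(α_land+β))`, the corrected height is
  `ĥ_c = (g·FT/2 − ĥ_diff/FT)² / (2g)`.

The percentage error is independent of `g` (the composition collapses to
`ĥ = (√h + √(h − h_diff))²/4`).

## Worked example

```python
from ftjump import JumpCondition, simulate_condition

rec = simulate_condition(JumpCondition(H=1.984, h=0.10, alpha_to=40, alpha_land=0))
print(f"h_diff    = {rec.h_diff_m:.4f} m")
print(f"FT        = {rec.ft_s:.4f} s  (true {rec.ft_true_s:.4f} s)")
print(f"estimated = {rec.h_est_m*100:.2f} cm   error = {rec.h_error_pct:.1f} %")
print(f"corrected = {rec.h_corrected_m*100:.2f} cm")
```

prints

```
h_diff    = -0.1325 m
FT        = 0.3605 s  (true 0.2856 s)
estimated = 15.94 cm   error = 59.4 %
corrected = 9.92 cm
```

A 1.98 m jumper who truly jumps 10 cm but lands flat-footed after a 40°
plantarflexed takeoff is credited with ~15.9 cm — a ~59 % overestimate.
The correction, needing only stature and the two ankle angles, brings the
estimate back to within a millimetre of the truth.

The same pipeline is available from the shell:

```
ftjump single 1.984 0.10 40 0
ftjump grid -o grid.csv --summary summary.json
ftjump correct --ft 0.3606 --stature 1.984 --takeoff-angle 40 --landing-angle 0
```

`ftjump grid` simulates the full factorial design — 100 statures from
1.435 to 1.984 m, ankle-position changes 0–40° in 1° steps, jump heights
0.10–0.40 m, 16,400 conditions — and writes one CSV row per condition.

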