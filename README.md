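# cvloop

A lumped-parameter (0D) closed-loop cardiovascular simulator for studying
where to cannulate a continuous-flow left ventricular assist device (LVAD)
in a failing heart with valvular regurgitation.

Clinically, an LVAD can draw blood either from the left atrium (LAAO:
LA → aorta, less invasive, preferred for bridge-to-recovery) or from the
left ventricle (LVAO: LV → aorta). Which inlet is hemodynamically and
energetically better depends on whether the mitral or the aortic valve
leaks. `cvloop` reproduces this comparison computationally: a failing
canine-scale heart is simulated under three ventricular conditions —
no regurgitation ("normal", meaning heart failure with competent valves),
5 % aortic regurgitation (AR) and 5 % mitral regurgitation (MR) — in three
groups (no pump, LAAO, LVAO at a constant 40 mL/s), and each run is scored
by a panel of steady-state metrics: peak left-atrial and left-ventricular
pressures (LAPP, LVPP), aortic pressures, the pressure–volume (PV) loop
with its stroke work, ejection fraction (EF), and the myofilament ATP
consumption rate.

## Model

* **Circulation.** Eight compartments (LV, LA, RV, RA, systemic artery and
  vein, pulmonary artery and vein) in a closed loop; linear resistances,
  linear compliances floored at zero transmural pressure, and four diode
  valves. Total blood volume is conserved exactly by construction.
* **Leaky valves.** A regurgitant valve passes, under a reversed gradient,
  a fixed percentage SF of its forward-law flux:
  `Q = ΔP/R` forward, `Q = (ΔP/R)·SF/100` backward. SF = 5 defines the AR
  and MR conditions.
* **Contraction.** A paced intracellular Ca²⁺ transient (BCL 600 ms) gates
  a two-state cross-bridge model, `da/dt = f_app·H(Ca)·(1−a) − g_xb·a`,
  whose attached fraction `a` and the sarcomere single-overlap fraction
  SOVF(SL) produce active pressure. The ATP consumption rate is the
  detachment flux weighted by overlap, `E = g_xb·a·SOVF` (s⁻¹).
* **Heart failure.** The passive pressure–volume curve is scaled ×5 and the
  Ca²⁺ transient amplitude reduced by 70 %; the baseline is then calibrated
  so the unassisted heart ejects SV = 20 mL at EDV = 100 mL (EF 20 %).
* **LVAD.** An ideal flow generator (constant 40 mL/s) from LA or LV into
  the systemic artery, with a suction guard that derates flow if the inlet
  chamber approaches collapse (never active under the shipped conditions).

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```
python examples/02_baseline_pv_loop.py
```

prints

```
calibrated in 4 simulations: contractile gain 2.594, total blood volume 1057 mL
EDV 99.8 mL, ESV 79.8 mL -> SV 20.0 mL, EF 20.0%
LVPP 131.4 mmHg, LAPP 12.4 mmHg, mean aortic 117.2 mmHg
stroke work 2381 mmHg*mL, mean ATP rate 1.66 /s
```

— the calibrated severely failing baseline: a dilated ventricle that fills
to 100 mL but ejects only 20, with elevated left-atrial pressure driving
that filling. `examples/04_cannulation_grid.py` runs the full 3 × 3
experiment and evaluates the direction-of-effect trend checks; the
headline emergent result is that LA cannulation *without* regurgitation
traps blood in the LV — the pump raises aortic pressure above anything the
unloaded ventricle can generate, the aortic valve never opens, and EF and
stroke work are exactly zero (an isovolumically contracting chamber),
whereas under mitral regurgitation either cannulation unloads the heart,
cuts its ATP consumption and restores aortic pressure.

The same workflow is available from a shell:

```
cvloop calibrate --out calibrated.yaml
cvloop run --config calibrated.yaml --condition mr --group laao --out rundir/
cvloop grid --config calibrated.yaml --out griddir/
cvloop report --out trends.json
```

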