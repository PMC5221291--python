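# Methods

This note documents the model equations, the default parameterization and
its rationale, the calibration and measurement protocol, and the known
limits of the reduced approach.

## Scope and reduction

The package is a desk-scale, fully 0D re-expression of a cannulation-site
comparison originally posed with a 3D finite-element ventricle. Everything
spatial is collapsed: one calcium transient and one cross-bridge state per
ventricle, a quasi-spherical volume-to-sarcomere-length map, and a
Laplace-like attenuation standing in for wall mechanics. Absolute ATP
values and absolute pressure changes of a 3D model are therefore not
reproducible here by design; the package targets the *calibrated baseline
phenotype* quantitatively and the *directions* of the cannulation effects
qualitatively (the trend checks T1–T9 in `cvloop.experiments`).

## Contraction drive

The intracellular calcium transient is a normalized rise–decay pulse

    Ca(t) = Ca_dia + A·f · N·(1 − e^(−s/τ_r))·e^(−s/τ_d),   s = t mod BCL,

with N chosen so the pulse peak is exactly 1. Defaults: BCL 600 ms,
Ca_dia 0.1 µM, amplitude A 1.0 µM, τ_r 20 ms, τ_d 150 ms — canonical
ventricular magnitudes. Heart failure is an amplitude-only reduction,
f = 0.3 (a 70 % loss), with unchanged timing; the shape of the failing
transient beyond its amplitude is not otherwise constrained, and slowed
decay is deliberately not modeled. Both ventricles share one transient
(0D reduction; no activation sequence).

## Myofilament model

A two-state cross-bridge scheme replaces the full multi-state myofilament
system while preserving the two quantities the energetics needs — a
detachment flux and an overlap fraction:

    da/dt = f_app·H(Ca)·(1 − a) − g_xb·a,      H(Ca) = Ca^h / (Ca^h + Ca50^h)
    T_act = T_max · a · SOVF(SL)
    E     = g_xb · a · SOVF(SL)                 [ATP rate, s⁻¹]

`SOVF` is the classic piecewise-linear single-overlap fraction of thick
filaments built from the filament geometry (thick 1.65 µm, bare zone
0.1 µm, thin 1.2 µm). `g_xb·a` is the total detachment flux — each
detachment hydrolyses one ATP — and only overlapped cross-bridges cycle.

Defaults f_app = 80 s⁻¹, g_xb = 20 s⁻¹, Ca50 = 0.4 µM, h = 6: the twitch
then tracks the calcium pulse closely and relaxes essentially completely
within the 600 ms beat. This matters mechanically: slower detachment
leaves a residual diastolic cross-bridge tone that blocks ventricular
filling, making the dilated-but-compliant failing phenotype (EDV 100 mL at
a left-atrial pressure near 12 mmHg) unreachable.

There is no force–velocity relation and no strain dependence of the
detachment rate: `a(t)` is identical in every run regardless of load.
Consequences are discussed under *Limitations*.

## Chambers and vessels

Ventricular pressure is passive plus active:

    P_pas(v) = scale · β · (e^(κ(v−v0)) − 1)        (linear continuation below v0)
    SL(v)    = SL_ref · (v / v_ref)^(1/3)
    P(v, a)  = P_pas(v) + G · T_max·a·SOVF(SL(v)) · (v_ref / v)^(1/3)

Heart-failure stiffening multiplies the whole passive curve by
scale = 5. Atria and vessels are linear compliances floored at zero
transmural pressure (collapse floor); there is no active atrial
contraction — the "atrial kick" phase is simply the interval in which
venous filling holds P_LA above P_LV.

The LV coupling point `SL_ref = 1.70 µm` at `v_ref = 100 mL` places the
operating range on the *ascending limb* of the overlap function. This is a
deliberate 0D abstraction, not an anatomical claim about end-diastolic
sarcomere length: it encodes a steep force–volume (Frank–Starling)
relation whose force collapses as the chamber empties, which is what
limits ejection depth in a chamber model with load-independent activation.
With a flatter force–volume relation the regurgitant hearts eject to
unphysically small end-systolic volumes and the cannulation comparisons
lose their meaning.

## Circulation network and LVAD

Eight compartments in the loop RV → PA → PV → LA → LV → SA → SV → RA.
Valves are resistive diodes; the mitral and aortic valves optionally leak
SF % of the forward-law flux under a reversed gradient (equivalently, a
backward branch of resistance R·100/SF), which keeps the flow law
continuous at zero gradient — valve switching therefore needs no event
detection, and the system is integrated with a stiff-capable adaptive
solver (LSODA, rtol = atol = 1e−8, max step 5 ms) with dense output
resampled on a fixed 1 ms grid so identical configurations produce
identical tables. The mass balance sums every flow once as an outflow and
once as an inflow, so total blood volume is a linear first integral and is
conserved to machine precision by the integrator.

The pump is an ideal flow generator: preload- and afterload-insensitive,
40 mL/s, no cannula resistance or inertance. A suction guard derates the
flow linearly to zero if the inlet chamber falls below 10 % of its
unstressed volume; it never activates under the shipped conditions and
any activation is logged and flagged on the result.

### Default parameter values

Resistances (mmHg·s/mL): R_MI 0.04, R_AO 0.015, R_TR 0.03, R_PU 0.06,
R_SA 3.4, R_SV 0.03, R_PA 0.10, R_PV 0.02. Compliances (mL/mmHg): C_LA 4,
C_RA 8, C_SA 3, C_SV 40, C_PA 4, C_PV 8. These are the package's own
canine-scale choices — the source experiment does not print its circuit
values — selected so that, after calibration, (i) the control baseline
meets the stated phenotype and (ii) the cannulation physics is in the
regime the study describes. Two choices carry most of that weight:

* **R_AO small (0.015).** The transvalvular gradient during ejection sets
  how far LV peak pressure can exceed aortic pressure. Keeping that
  reserve small lets a 40 mL/s pump raise aortic pressure beyond the
  unloaded ventricle's reach, which is the mechanism of the trapped-blood
  (isovolumic) state under LA cannulation. Note SF ties the leak to the
  forward resistance, so a small R_AO also makes the "5 %" aortic leak
  volumetrically severe.
* **R_SA and C_SA large (3.4, 3.0).** The pump's continuous flux then
  lifts mean aortic pressure substantially above control with a flat
  waveform, and the aorta does not collapse during the diastolic
  regurgitant drain.

The initial volume distribution starts the arterial compartment near its
operating volume (330 mL); starting it at a resting value leaves a slow
R_SA·C_SA redistribution transient that is still visible at 20 s.

## Protocol, calibration and metrics

Each run simulates 20 s to reach a periodic regime; metrics are read from
the 18.6–19.2 s cycle. Calibration anchors the control/no-regurgitation
cell to SV 20 mL and EDV 100 mL (hence EF 20 %) with a damped Newton
iteration on two parameters — the LV contractile gain G (controls SV) and
total blood volume (controls preload, hence EDV) — with a forward-difference
Jacobian, each residual evaluation being a full simulation. From the
shipped fixture it converges in 4 simulations to residuals below 0.05 mL.

Cycle metrics: LAPP/LVPP are whole-cycle pressure maxima; "aortic
pressure" is the systemic-artery compartment (the network has no separate
aortic chamber); stroke work is the orientation-corrected shoelace area of
the PV loop; EF is reported both from the LV volume extrema and as the
fraction of EDV actually ejected through the aortic valve (they differ
under regurgitation or a pump); the ATP rate is the time-average of E for
the LV; regurgitant fraction is backward over forward valve volume.
Steady-state quality is reported as the relative change of the LV volume
and pressure waveforms (and of LVPP) between the last two cycles; the
calibrated baseline reaches ~0.1 %.

## What the trend checks show — and the one that fails

On the calibrated defaults, eight of the nine direction-of-effect checks
reproduce the expected cannulation physics, including the fully emergent
isovolumic trap (T1/T2: the normal+LAAO cell ejects *exactly* zero volume
once periodic), the AR-worsening of LA cannulation (T5), and the
MR-recovery by either cannulation (T7).

T6 — that LV cannulation under aortic regurgitation should consume *no
more* ATP than the unassisted AR heart — fails by about +1 % and is left
failing. The cause is structural: with load-independent kinetics, `a(t)`
is identical in every cell, so ATP differences reduce to differences in
overlap-weighted LV volume during the activity window. The unassisted AR
heart unloads itself by ejecting deeply through the valve *during
systole*, while the pump drains its 40 mL/s spread over the whole cycle;
during the high-activity phase the pumped ventricle is therefore never
smaller than the control one. Capturing the missing effect requires
work-dependent energetics (strain-dependent detachment), which is outside
the two-state reduction. The adjacent checks (T5, T7) are insensitive to
this because their ATP/stroke-work orderings are dominated by large volume
differences.

## Limitations

* Single lumped cell per ventricle: no spatial ATP maps, no dyssynchrony.
* No force–velocity or strain-dependent detachment: shortening costs no
  extra ATP (see T6 above); contractility is load-independent.
* No baroreflex or autoregulation: venous return rises freely with pump
  output.
* The "5 %" leak is a flux-law fraction, not a regurgitant-volume
  fraction; with the small default R_AO the AR condition is volumetrically
  severe.
* Atria are passive; coronary perfusion is represented only by aortic
  pressure as a surrogate.
* The synthetic calcium drive emulates only pacing rate and HF amplitude
  loss, not restitution, alternans or regional heterogeneity — passing
  tests show the circulatory consequences of a weakened, stiffened heart,
  not fidelity to any measured transient.
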