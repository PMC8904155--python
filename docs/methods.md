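# Methods

## Cells

Two RGC subtypes are parameterized: A2-monostratified (soma 20 µm, dendritic
field 320 µm, single stratification plane) and D1-bistratified (soma 12 µm,
field 144 µm, two planes).  A morphology is a tree of unbranched cylindrical
sections; the soma is a cylinder of equal length and diameter (its lateral
area then equals that of a sphere of the same diameter).  Axons are four
bands appended at the soma — axon hillock (AH), sodium-channel band (SOCB,
the high-Na initial segment), narrow segment (NS), distal axon (DA) — with
shipped default geometry AH 40 µm × 1.0 µm, SOCB 40 µm × 1.0 µm,
NS 90 µm × 0.6 µm, DA 1000 µm × 1.0 µm.  These band dimensions are
configurable stand-ins (the source tables give only channel densities, not
band geometry); no result in this package assumes the exact values.

Morphologies come from three sources: the stylized generator
(`rgcsim.synthetic`), SWC files, or the *reduced pair* used by the protocol
suite.  The reduced pair is a soma plus the four axon bands (distal axon
truncated to a compartment budget, default 30 compartments ≈ 300 µm of DA),
carrying the exact per-region conductance tables; the two models differ only
in soma diameter and preset densities, so comparisons between them are
controlled experiments.

The stylized generator emulates the two cells' gross geometry only: six
straight primary dendrites per stratification plane, tapering 1.5 → 0.5 µm,
reaching the field radius, with seeded azimuthal jitter.  It does **not**
reproduce real arbor topology, total dendritic membrane area (real arbors
carry several-fold more membrane), or branching statistics; passing tests on
stylized cells therefore demonstrate correct mechanics (discretization,
field coupling, protocol logic), not morphological realism.

### SWC dialect

Standard 7-column SWC, 1-based ids, radii in µm; type 1 = soma, 2 = axon
(mapped to DA), 3/4 = dendrite, unknown codes map to dendrite with a logged
warning.  Contiguous same-type runs become one section whose path is exactly
its own points; writing a loaded morphology back to SWC is a byte-stable
fixed point.  Per-section taper is lost on first serialization (SWC has no
section boundaries), which is inherent to the format.

## Membrane

Seven conductances plus leak:

| current | gating | kinetics |
|---|---|---|
| Na | m³h | Fohlmeister–Miller rate equations |
| K (delayed rectifier) | n⁴ | FM |
| K_A | a³h_A | FM |
| K_Ca | (Ca/K_d)²/(1+(Ca/K_d)²), K_d = 1 µM | Ca-gated only |
| Ca (L-type) | c³ | FM; Nernst E_Ca |
| T-type Ca | t_m² t_h | steady-state/τ form (V½ −57/−81 mV, τ 2/30 ms) |
| h (HCN) | q | q∞ half-activation −80 mV, slope 8 mV, τ 200 ms |

All rate coefficients live in `src/rgcsim/data/kinetics.yaml` as
linoid/exponential/sigmoid records; the linoid form's removable singularity
is evaluated by its analytic limit.  Reversal potentials: E_Na +35,
E_K −75, E_h −32, E_leak −65 mV.  No temperature scaling is applied
(Q10 = 1); kinetics are used at their 22 °C reference.

Maximum conductances per region follow the published A2/D1 tables, with the
derived rows g_KA = 3 g_K and g_KCa = 0.004 g_K applied in every region.
The axon table is shared by both cell types (the source does not split it by
type), and lists only Na and K (plus derived rows); axon Ca, h and T
densities are zero.

**Calcium pool.**  A single well-mixed submembrane shell of depth 0.1 µm
with first-order removal (τ = 1.5 ms) toward a 0.1 µM resting level feeds
the Nernst E_Ca (Ca_o = 1.8 mM) and the K_Ca activation.  Only *inward* Ca
current loads the pool: outward flux through Ca channels is negligible in
reality (GHK rectification), and without this rectification strong
depolarizing drive drains the pool, E_Ca runs away toward +350 mV and the
simulation spuriously diverges.

**Passive.**  C_m = 1 µF/cm², R_a = 110 Ω·cm, g_leak = 5·10⁻⁵ S/cm² at
−65 mV, 22 °C — standard mammalian-RGC modeling values, configurable.

## Extracellular field

The stimulating electrode is an equipotential disk (radius 100 µm) on the
boundary of a semi-infinite homogeneous medium (σ = 0.1 S/m), its center
50 µm above the soma.  The closed-form potential is exact for this geometry;
its far field is the half-space monopole I/(2πσz).  This replaces a voxel
volume-conductor model of the layered retina; the absolute current scale is
therefore calibration-dependent (thresholds here are a few tens of µA where
a layered model yields hundreds), and the homogeneous half-space decays
faster laterally than a layered retina would.  Only relative effects between
cells and stimulus parameters should be interpreted.  A solver seam
(`map_extracellular` producing per-compartment mV/µA scale factors) allows a
future voxel backend.

Cathodic current is negative into the medium, monopolar return at infinity.
The quasi-static assumption makes the per-compartment potential the product
of a unit-current scale factor and the instantaneous electrode current.

## Numerics

Implicit theta scheme: backward Euler (default) or Crank–Nicolson.  Each
step: (1) gates advance by the unconditionally stable implicit first-order
update `x' = (x + dt·α)/(1 + dt(α+β))` evaluated at the step-start voltage —
this keeps every gate in [0,1] for any bounded trajectory; (2) the Ca pool
advances implicitly; (3) the voltage system (membrane conductances
linearized about the new gates, axial coupling on V_m + V_e) is solved
exactly on the tree by Hines elimination.  dt defaults to 0.01 ms
(0.005 ms for 0.1 ms pulses).  Compartment length is capped at 10 µm
(soma/axon bands) and 25 µm (dendrite/DA).  Divergence (|V| > 1000 mV) is
reported with its time; several-hundred-mV transmembrane excursions during
strong pulses are genuine solutions, not failures, hence the high guard.

Because the gating and voltage updates are split, spike *times* converge at
O(dt) even under Crank–Nicolson (≈10–15 µs shift per dt halving at
dt = 0.01 ms).  Pointwise sup-norm differences between dt-refined
suprathreshold traces are therefore dominated by spike-time shift × upstroke
slope (~10 mV), while subthreshold accuracy is excellent (0.015% error
against the RC closed form at t = τ_m).  Users comparing traces across dt
should compare spike times and subthreshold segments, not pointwise
differences across spikes.

**Spike detection.**  Upward crossings of −20 mV with a 1.5 ms dead time.
The threshold is deliberately above small non-spike waveforms (failed
somatic invasions, stimulus-coupled deflections) so they are not counted;
the dead time guards against doublet counting on one action potential.

## Protocols

* **Threshold** — minimum amplitude with spike probability ≥ 1.0 (spikes per
  delivered pulse, at most one counted per period) at 120 Hz; doubling
  bracket then bisection onto a resolution grid (1 µA default, 5 µA for
  curve-matched scans), with a minimality certificate (the next lower grid
  point fails).  An exhaustive ascending scan is available as the
  independent route; both agree on the reduced pair.
* **Strength–duration / IPG sweeps** — per grid value, tune each cell at
  120 Hz, then measure rates at 200 Hz at the tuned currents; rate
  difference is D1 − A2 (positive = D1 more responsive).
* **Rate vs amplitude** — one simulation per 5 µA grid step; rate =
  probability × stimulus frequency (capped at one spike per pulse).
* **Saturation window** — widest contiguous amplitude interval whose
  probability stays within ±0.02 of the target level (default 0.5).
* **Differential response** — per-amplitude rate difference of two curves
  plus the amplitude gap to reach a target rate (default 20 Hz).
* **Channel swap** — identical stimulus on a base model and a copy with one
  maximum conductance replaced; spike-metric deltas reported.
* **Refractory** — two identical extracellular pulses at 1.5× the
  single-pulse threshold; minimal inter-pulse interval eliciting a second
  spike, bisection at 0.5 ms resolution (equals the exhaustive scan).  For
  conductance-swap comparisons the *same* probe amplitude is used for both
  variants, so the comparison is controlled.
* **Sag** — V(end of step) − V(minimum) during a ≥500 ms intracellular
  hyperpolarizing step (default −5 pA, chosen so the smallest soma stays in
  a physiological range).

Default train duration is 1000 ms; the test suite and the acceptance script
use 250 ms trains (30 pulses at 120 Hz, 50 at 200 Hz) — the package's chosen
problem size for its own verification runs — which changes absolute rates
only through edge effects.

## What the reduced models do and do not reproduce

Robustly reproduced on the reduced pair: strength–duration decay with
flattening toward 1.2 ms; interphase gaps lowering the tuned current;
soma enlargement raising the threshold (D1 at 20 µm needs ~13 µA more at
PW 0.5 ms); depolarizing sag appearing with, and growing with, the h
conductance (D1 > A2); Ca density setting spike width; K density setting
the resting level; exact determinism of swap experiments.

Not reproduced at this scale: the wide, amplitude-robust 50%-probability
saturation window of the A2 cell at 200 Hz, and its consequences (larger
D1 − A2 rate difference at short pulse widths, shrinking with an interphase
gap; refractory shortening by the h conductance).  With these kinetics at
22 °C, membrane recovery completes within ~3.5 ms (the measured paired-pulse
refractory), so every desk-scale morphology follows a 5 ms pulse period once
marginally above threshold; the long (tens of ms) refractoriness that gates
200 Hz following in the full-scale system is outside the model family's
reach here.  Tuned-current rate differences on the reduced pair are
accordingly knife-edge quantities and should not be over-interpreted.

One further directional note: for contiguous symmetric biphasic phases,
*anodic-first* stimulation lowers the threshold of the on-axis configuration
(the anodic first phase de-inactivates Na at the initiation site); the
classic cathodic advantage is a monophasic-pulse result and does not carry
over to this waveform family.

## Known limitations

Homogeneous half-space field (no retinal layers, no electrode-interface
impedance); stylized arbors under-represent dendritic membrane; shared axon
table for both cell types; single Ca shell (no buffering or diffusion); no
temperature scaling; no synaptic input or network context; deterministic
membrane (no channel noise), so spike probabilities are step-like in
amplitude rather than sigmoidal.
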