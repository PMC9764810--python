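# Methods

## Hydraulic model

All flow is treated as incompressible, Newtonian, fully developed laminar
flow (the electrical-circuit analogy): pressure ↔ voltage, volumetric flow ↔
current, and each conduit a resistor ΔP = R·Q. At the operating points of a
perfused vessel-on-chip (d ≈ 200 µm, v ≈ mm/s, μ ≈ 0.8 mPa·s) the Reynolds
number is of order 1 and entrance lengths are tens of micrometres against an
11 mm channel, so entrance effects, inertia and compliance are neglected
within a single solve. Interstitial flow through the hydrogel around the
lumen is ignored.

Closed forms used:

* circular conduit: R = 128 μ L / (π d⁴); wall shear stress τ = 32 μ Q/(π d³),
  equivalently τ = ΔP·d/(4L) over an isolated conduit and τ = 4 μ v_max/d
  from the centerline velocity of the parabolic profile (v̄ = v_max/2);
* rectangular duct (w ≥ h): the exact Fourier-series solution
  R = 12 μ L / (w h³ [1 − (h/w) Σₙ odd 192/(π⁵n⁵) tanh(n π w/2h)]), truncated
  when a term changes the sum by < 10⁻¹⁰ relative (n⁻⁵ decay: a handful of
  terms). It reproduces the square-duct constant R h⁴/(μL) = 28.454
  (fRe = 56.91) and the parallel-plate limit 12 μL/(w h³).

Units are SI everywhere internally; lab units (µm, cm, mbar = 100 Pa,
mPa·s, mL) are converted exactly once at I/O boundaries (config files, CLI
flags).

## Network solver

Modified nodal analysis: unknowns are the pressures of non-boundary nodes
plus one flow per "constrained" element (ideal pressure sources and
zero-resistance branches, whose drop is fixed rather than flow-dependent).
The rows are mass conservation at each free node plus one drop constraint
per constrained element. The system is solved by least squares so that
physically indeterminate floating subgraphs (everything behind closed
valves) receive the minimum-norm pressure with zero flow; the residual is
checked and a topology error raised if the equations are inconsistent.
Mass-conservation quality is reported relative to the largest element flow
(per-node normalization is meaningless at stagnant nodes).

Check valves are ideal diodes with a cracking pressure p_c: closed (Q = 0)
unless the forward drop exceeds p_c, open with the drop offset by p_c and a
constant open-state resistance (configurable; the off-board tubing can be
lumped into it). A consistent open/closed assignment is found by fixed-point
iteration (open a closed valve whose forward drop exceeds p_c, close an open
valve carrying reverse flow), falling back to exhaustive enumeration — at
most 2⁴ states for the rectifier bridge. Marginal states (a valve open
exactly at its cracking pressure with zero flow) are accepted; they carry no
flow and are physically equivalent to the closed assignment.

The board builder lays the feeder ladder A → F1 → … → Fn and the waste
ladder W1 → … → Wn → B as a counterflow ladder, so every sample's path
crosses the same number of loop segments; with equal segment resistances
this equalizes the per-sample driving ΔP. Default segment dimensions
(2 mm × 1 mm × 2 cm milled channels) are representative values chosen so the
loop resistance (≈ 1.4 × 10⁸ Pa·s/m³ per segment) is ~10³ times below the
branch resistance, giving a branch-ΔP spread of ≈ 0.5 % — they are config
inputs, not measurements of a particular board.

## Equalizing-resistor design

"Optimal" is defined as endpoint-WSS equality: the unique branch resistance

R_EQ = 128 μ L_v (d_max − d_min) / (π d_min d_max (d_max³ − d_min³))

makes τ(d_min) = τ(d_max) at fixed ΔP. The equalized profile
τ(d) = 32 μ ΔP/(128 μ L_v/d + π R_EQ d³) has its interior maximum at
d* = (128 μ L_v/(3π R_EQ))^¼ (≈ 237 µm for the default range); a minimax
criterion would differ negligibly over ranges this moderate and is not
implemented separately. For 180–300 µm, L_v = 1.1 cm, μ = 0.79 mPa·s:
R_EQ = 3.717 × 10¹⁰ Pa·s/m³; spread (max−min)/max = 8.93 %, equivalently
9.8 % of the minimum — both below the 10 % design goal. Spread metrics
(max/min ratio, relative difference, CV = sd/mean) are computed on a uniform
1 µm diameter grid with uniform weighting.

Lumens are modelled as circular cylinders of length 1.1 cm (the standard
channel length), ignoring the short vertical inlet/outlet segments and the
D-shaped cross-section that viscous-finger-patterned lumens can have; both
idealizations shift absolute WSS by a few percent but barely affect the
*relative* spread the design controls. Real assembled setups carry extra
series length in connectors and fittings, which is why a practically
installed tubing resistor (52 cm reported for one setup) can exceed the
ideal 47.3 cm computed for the bare geometry; the package treats such values
as setup-specific within ±15 %.

The drive-pressure calculator ΔP = τ·(π d³/32 μ)·(R_lumen + R_resistor)
assumes a uniform nominal diameter (the range midpoint by default): 1 Pa at
240 µm costs ≈ 2.5 mbar through the equalizing resistor, 1.8 mbar bare. The
operating envelope takes a controller full scale of 345 mbar and reports the
luminal back-pressure window [downstream consumption + cracking pressure +
reservoir head, full scale − upstream consumption − drive ΔP]; the
hydrostatic head of a full 15 mL reservoir column (≈ 8.5 cm at 1.76 cm²
cross-section) is ≈ 8 mbar. The upper bound excludes the drive ΔP even
though it is small (≈ 2.5 mbar at 1 Pa), so the window only reaches the full
scale in the zero-shear limit.

## Recirculation simulation

Quasi-static coupling: flow establishment (milliseconds) is instantaneous
against reservoir drainage (minutes–hours), so the valve network is
re-solved every step and only the two reservoir volumes carry state. Each
step: reservoir node pressure = commanded gas pressure + ρ g h(V); solve the
bridge; sense ΔP between the feeder and waste taps; update the command;
integrate volumes (conservation then holds to solver precision, ≲ 10⁻⁹
relative over a day). When the source reservoir drains to the switch
threshold (default 10 % of capacity) the high/low commands swap; the bridge
keeps the sample flow direction fixed through arbitrary switch schedules.

Control: a discrete positional PID with clamping anti-windup (output limited
to the 0–345 mbar controller range) regulates the sensed ΔP; the low side
holds the board back-pressure that sets luminal pressure. Reservoir liquid
levels are instrumented in the modelled setup, so their hydrostatic heads
are compensated by feedforward on the command; without this the slow drain
ramp leaves a PI tracking error proportional to the drain rate (~14 % at the
default gains and dt = 30 s), which is a property of the loop, not of the
bridge. Default gains (kp = 0.6, ki = 0.02 s⁻¹, kd = 0) are tuned for the
nearly static board plant at step sizes of seconds to a minute and are
stated in the config; a day at dt = 30 s (2 880 steps) runs in ~1 s and
drains a 13 mL charge through ~19 switches at ΔP = 1 mbar.

## Imaging quantifications

**Diameter / strain.** The lumen appears as a bright band; per scan line the
two wall edges are the half-maximum crossings of the intensity profile after
3 px uniform smoothing, localized by linear interpolation; the diameter is
the mean separation over 50 lines (mean ± sd reported, failure if fewer than
half the lines yield edges). Half-maximum crossing is invariant to
symmetric edge blur, which is why the fixture's ground truth is recovered
exactly on noise-free images. Circumferential strain between pressure
states is the pure ratio (pix_P − pix_0)/pix_0.

**PIV.** Frames are masked at the binary threshold (default 100 on the 8-bit
scale): background pixels are zeroed and particle intensities kept — the
intensity structure carries the sub-pixel information, and fully binarized
{0,1} images produce plateaued correlation surfaces with multi-pixel errors.
Each 24 px interrogation window is cross-correlated within its 48 px search
neighbourhood in the next frame; the correlation is energy-normalized
(window energy × candidate-patch energy), which removes the bias of
particles crossing patch borders; the peak is refined by a three-point
Gaussian fit per axis (offsets with |δ| > 1 px indicate a degenerate
neighbourhood and are dropped). Vectors with an ambiguous peak (< 5 % above
the strongest competitor outside the peak's 5 × 5 surroundings) or an empty
window are invalid, never silently zero. Multiple frame pairs are combined
by the per-location median. On rigid-shift fixtures the vector error is
< 0.2 px for integer and half-integer shifts. The WSS read-out takes the
per-row median axial displacement as the transverse profile, its maximum as
the Poiseuille centerline velocity, and applies τ = 4 μ v_max/d; window
averaging across the parabola biases v_max down by about (w/d)²/3 ≈ 0.5 %
for a 24 px window on a 200 px lumen.

**Tortuosity.** The junction image is thresholded, thinned to a 1 px
skeleton, and decomposed at junction pixels (≥ 3 skeleton neighbours in the
8-neighbourhood); each remaining connected path is a branch whose backbone
endpoints are found by a double-BFS sweep. Branch length Lb uses a
resampled polyline (chords through every 8th path pixel plus the endpoints):
summing raw 8-connected steps with (1, √2) weights overestimates smooth
curves by ~5 % (a rasterized semicircle reads ~1.66 instead of π/2 ≈ 1.571),
while the polyline estimator is within 0.6 % and, by the triangle
inequality, never below the end-to-end distance Le. The chamfer estimator
remains available as an option. The tortuosity index is Lb/Le per branch,
keeping branches with Lb > 10 µm; a straight border reads exactly 1.

## Synthetic fixtures — what they do and do not show

The generators emulate the *geometry and arithmetic* the pipelines must
handle: a blurred, noisy fluorescent tube of known diameter; bead fields
advected by an exact parabolic profile and rendered as Gaussian spots; a
polygonal border network with controllable zig-zag amplitude (full-span
strokes, so every lattice vertex is a 4-way crossing and the branch count is
exactly 2HV + H + V). They do not emulate out-of-focus light, bead
sedimentation or depth-of-correlation effects, uneven illumination,
photobleaching, or biological heterogeneity of junction morphology — so
passing recovery tests demonstrates the correctness of the measurement
arithmetic, not field robustness on real microscopy. Default fixture
conditions mirror the study conditions: 0.79 mPa·s medium, 180–300 µm
lumens, 8-bit intensities, 24/48/12 px PIV windows, 50 scan lines, 10 µm
branch filter.

## Problem sizes and numerical choices

Tests and the acceptance script run at the natural desk scale of the method:
1 µm design grids (121 points), 8-node random circuits against a dense
nondimensionalized least-squares oracle (pressures in kPa, flows in
kPa / 10¹¹ Pa·s·m⁻³, keeping the constraint matrix well conditioned),
day-long simulations at 30 s steps, 256 × 512 px fixtures. Determinism:
every stochastic fixture takes an explicit seed; hypothesis property tests
are derandomized. Degenerate inputs fail loudly: zero-width diameter
ranges, valveless bridges, blank images, empty skeletons and infeasible
operating envelopes raise typed errors rather than returning numbers.
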