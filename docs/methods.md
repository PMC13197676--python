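# Methods

This note documents the models, numerical choices and limitations of the
covfrag pipeline, stage by stage.

## Library triage (`covfrag.chemlib`)

Descriptors come from RDKit: heavy-atom count, molecular weight,
Wildman–Crippen logP (atom-contribution scheme), H-bond donor/acceptor
counts, strict rotatable bonds (non-ring single bonds between
non-terminal heavy atoms, amide C–N excluded) and topological PSA. These
are open, reproducible descriptors; no attempt is made to match any
commercial descriptor engine numerically, so the bundled table's QP-type
columns are carried as data, not recomputed.

The assembly filter keeps 6 ≤ heavy atoms ≤ 22 and logP ≤ 2, all
boundaries inclusive — "larger than 22 removed" keeps 22, "logP > 2
excluded" keeps 2.0. Heavy atoms rather than molecular weight serve as
the size criterion because halogen-rich electrophiles inflate MW without
adding bulk.

Warhead classification uses a versioned SMARTS set (v1) with deterministic
precedence CA, VS, AA, EO, SN. The α-cyano and sulfone patterns are
supersets of the bare acrylamide motif, so they must win over AA; SNAr is
matched last and requires the leaving-group-bearing aromatic carbon to
sit in an aromatic ring containing nitrogen (pyridine-type or
azole-type). The SN ring subtype is taken from the smallest aromatic ring
holding that carbon: fused aromatic systems are "bicyclic", otherwise the
ring size decides five- vs six-membered. Any exact production filter used
to assemble a given commercial library is unpublished; this set is a
documented, reproducible stand-in and classification labels should be
read as such.

## Turbidimetric solubility (`covfrag.solubility`)

The dilution ladder is geometric (factor 4/5 from 5 mM, 12 steps, ending
at 0.429 mM; displayed to 3 significant figures). Scattering at a cycle
is called when the mean extinction over 600–800 nm strictly exceeds the
blank mean plus `max(0.02 AU, 3×blank SD)` — the absolute floor guards
against a noise-free blank, the SD term adapts to noisy plates, and the
strict inequality makes the boundary case "clear". MIS and MFS are the
highest concentration below the lowest scattering concentration at the
first and last cycle respectively; this conservative rule means a clear
well sitting above a scattering one (non-monotone noise) cannot rescue
the call. No ordering between MIS and MFS is assumed: late precipitation
gives MFS < MIS, slow dissolution the reverse. Intrinsic compound
absorption in the scattering window is not corrected for and can bias
calls low; the three low-solubility calls in the bundled table should be
read with that caveat (none of them precipitated under screening
conditions).

## DTNB kinetics (`covfrag.dtnb`)

The molar response ε·l (AU/M) is calibrated per plate from the
fragment-free well's first-point absorbance at the known 50 µM TNB²⁻
start — DTNB is a disulfide dimer, so 25 µM DTNB reduces to 50 µM TNB²⁻.
Compound-background wells (no DTNB) are subtracted point-wise; TNB²⁻
concentrations are clipped at zero, the effective B₀ is the converted
first point, and the effective A₀ adjusts the nominal 100 µM load for any
TNB²⁻ consumed before the first read, making mass balance
A₀−A(t) = B₀−B(t) exact by construction. Wells whose converted fragment
concentration dips below −5% of A₀ are flagged rather than clipped.

The closed-form rate law is evaluated in a rearrangement that divides
through by the exponential on the appropriate side, so no overflow occurs
for any (A₀, B₀, k₂, t); |A₀−B₀| < 1e-9 M switches to the
equal-concentration branch A₀/(1+A₀k₂t). Agreement with direct numerical
integration of dA/dt = −k₂AB is better than 1e-6 relative everywhere
tested, including near-equal concentrations.

The fit floats k₂ only (A₀, B₀ fixed at effective values), initialised
from the two-point early-slope estimate ΔB/(A₀B₀Δt), unbounded: slight
baseline drift in background wells genuinely produces small negative
apparent k₂, and these are reported raw rather than refit — matching how
such entries appear in practice. Replicates aggregate as the mean with
SD = √(Σσᵢ²)/n.

Under the default conditions (5-min reads over 4 h, 0.005 AU noise) the
median recovery error is ~3–4% for k₂ ∈ [0.01, 3] M⁻¹s⁻¹ and < 0.1%
noise-free; slower rates approach the drift/noise floor, which is why the
capping floor of 1e-4 exists downstream.

## GSH stability (`covfrag.gsh`)

Relative AUC is the fragment/standard peak-area ratio normalised to its
t = 0 value; the ratio cancels injection variability exactly (rescaling
the standard by any constant leaves fits unchanged). The simple model is
e^(−kt); the plateau variant is implemented as (1−c)e^(−kt)+c with
c ∈ [0, 1) so that r(0) = 1 holds for any plateau — a literal "+c" on top
of a unit-amplitude exponential cannot pass through the normalised first
point. The plateau is a phenomenological description of reversible adduct
formation; no equilibrium constant is claimed.

Censoring: a missing fragment peak at t = 0 reports "≪ 0.033 h"; a
fragment present at t = 0 but below the relative detection limit
(default 0.01) at the first post-zero sample reports "≪ 0.33 h" whenever
the implied bound ln2·u/ln(1/d) ≤ 0.33 h (u = sample time, d = detection
limit) — for the canonical 20-min sample the bound is 0.05 h, and the
rule extends soundly to hourly schedules. Slow censoring ("> 100 h")
applies when k ≤ 0, the fitted t½ exceeds 1000 h, or the relative
standard error of k exceeds 100%; fitted values between 100 and 1000 h
are reported numerically. GSH rate constants are never corrected for the
parallel PBS degradation; instead the PBS half-life is reported alongside
and a strictly shorter PBS half-life raises the buffer-instability flag
(censored values compare by their bounds, "> 100 h" as +∞).

## DSF (`covfrag.dsf`)

Tm is the interior maximum of the first derivative of F(T), estimated by
Savitzky–Golay local-quadratic smoothing over a ~2 °C window; 1.5 °C at
each scan edge is excluded from the argmax so baseline curvature cannot
pose as a transition, ties break toward lower temperature, and the
discrete peak is refined by a quadratic vertex fit over the ±1 °C
neighbourhood (sub-grid resolution; noise-free curves on doubled grid
density move by < 0.05 °C, and 1%-amplitude noise gives max error
< 0.3 °C over the tested 40–55 °C range). Flat or monotone curves raise a
no-transition error: the derivative peak must exceed five times the
robust (MAD-based) noise of the interior derivative.

Hit thresholds are kept exactly as the source conventions state them:
strictly > 1 °C for the primary screen, ≥ 1 °C for the dose/time
summaries (lowest stabilizing concentration, earliest stabilizing time),
and ≤ −1 °C at the top concentration for the destabilization flag.

The specificity cascade over (ΔTm Y220C, ΔTm CL, ΔTm WT) uses inferred
thresholds (significant ≥ 1.0 °C, minimal |x| < 0.5 °C, destabilizing
≤ −1.0 °C), checked in order: cys220-selective requires both Y220C
constructs stabilized with a gap < 1 °C and a minimal WT shift; a gap
≥ 1 °C instead indicates additive surface arylation; CL-only
stabilization with WT destabilization is masked stabilization; WT
stabilization (or any remaining significant pattern not attributable to
Cys220) is nonspecific; all-below-1 °C is inactive. The gap condition
makes the first two classes disjoint; the fallback makes the classifier
total. The 0.5/1.0 °C thresholds are configuration, not measurements.

## Cross-assay integration (`covfrag.crossassay`)

Capping for plots and correlation: rate constants below 1e-4 (h⁻¹ or
M⁻¹s⁻¹) or negative are floored at 1e-4; half-lives above 1000 h or
negative cap at 1000 h; the two fast-censor tokens map to 0.01 h and
0.1 h. The GSH↔DTNB correlation is OLS on log₁₀-transformed capped pairs
(the data span ~5 decades; a linear-space switch exists). Slow-censored
("> 100 h") compounds enter through a configurable mapping: their 100 h
bound by default, or directly to the cap floor. The bundled tables censor
the fitted rate constants of 29 of the 64 usable compounds, so the
correlation computed from them is reconstruction-dependent: R² lands near
0.27 in log space under all mappings, while the slope reproduces the
published 0.31 under the cap-floor mapping. Recovering the published R²
would require the unpublished per-compound fitted constants; the pipeline
therefore always reports both regression-space variants rather than a
single headline number.

The mild-reactivity selection is t½(GSH) ∈ [1, 10] h inclusive on numeric
values only — censored bounds are not measurements of mildness.
Purity-failed compounds are excluded from correlation and selection,
mirroring the tables' footnotes.

## Synthetic data (`covfrag.synthetic`)

Generators draw from per-call `numpy.random.Generator` streams (seeded,
no global state; identical configuration is bit-identical). Noise models:
additive Gaussian for absorbance (default 0.005 AU) and fluorescence
(default 1% of amplitude), unit-mean multiplicative lognormal for
chromatographic areas (default CV 3%), additive Gaussian for the
turbidity baseline. Defaults mirror the assay protocols: 100 µM vs 50 µM
DTNB runs read every 5 min for 4 h; 24 h hourly or 4 h/20-min HPLC
schedules; 0.25 °C melt scans from 28 to 70 °C with two-state sigmoid
plus linear baselines; the 4/5 dilution ladder with a threshold-linear
scattering onset.

What the generators do not emulate: intrinsic compound absorbance
spectra, chromatographic peak-shape pathologies, dye-binding artifacts,
inner-filter effects, plate-position effects, or temperature gradients.
Passing round-trip tests therefore demonstrates correctness of the
estimators under the stated noise models, not robustness to every
instrument artifact.

## Problem sizes

The recovery studies use 100 simulated DTNB runs, 200 GSH series and 100
melt curves per evaluation, sizes at which the reported medians and
maxima are stable across seeds; the full test suite and the acceptance
script each run in well under a minute on a single core.
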