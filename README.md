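# covfrag

Analysis pipeline for the characterization of covalent fragment libraries:
cheminformatic triage, turbidimetric solubility, thiol-reactivity kinetics
(DTNB and glutathione assays), and differential scanning fluorimetry (DSF)
thermal-shift screening with three-construct specificity logic — the data
workflow behind electrophile-first fragment-based drug discovery against
targets such as the thermally destabilized p53-Y220C cancer mutant.

It is written for screening groups who have plate-reader absorbance
series, HPLC peak areas and melt curves in hand and need reproducible rate
constants, half-lives, solubility calls and hit lists — plus seeded
synthetic-data generators so every stage can be validated against known
ground truth without instrument data.

## The models

**Library triage.** Fragments keep a 6–22 heavy-atom window and
Wildman–Crippen logP ≤ 2; warheads are classified by a versioned SMARTS
set into acrylamides (AA), α-cyanoacrylamides (CA), epoxides (EO), vinyl
sulfones (VS) and SNAr-reactive heteroarenes (SN, subtyped by ring
system), with precedence CA, VS, AA, EO, SN. Rule-of-three profiling
flags MW > 300 g/mol, HBD > 3, HBA > 3, rotatable bonds > 3, PSA > 60 Å².

**DTNB kinetics.** With fragment A (100 µM) and the cysteine surrogate
TNB²⁻ B (50 µM, from 25 µM DTNB), the mixed second-order integrated rate
law

```
A(t) = A₀(A₀−B₀)·e^((A₀−B₀)k₂t) / (A₀·e^((A₀−B₀)k₂t) − B₀)
```

is fitted to background-corrected, self-calibrated concentration traces
(ε·l from a fragment-free well), giving k₂ in M⁻¹s⁻¹; the equal-
concentration limit A₀/(1+A₀k₂t) is used when A₀ ≈ B₀.

**GSH stability.** Internal-standard-normalised HPLC peak areas decay as
`r(t) = e^(−kt)` (pseudo-first order, t½ = ln2/k), or
`(1−c)e^(−kt) + c` for reversible binders whose relative AUC plateaus.
Fragments faster than the sampling schedule are censored («0.033 h /
«0.33 h), non-decaying ones reported as > 100 h; a PBS half-life shorter
than the GSH one flags hydrolytic instability.

**DSF.** Tm is the maximum of the smoothed first derivative dF/dT of the
melt curve; ΔTm = Tm(protein+compound) − Tm(protein), SDs combined in
quadrature. A compound is a primary-screen hit when any condition gives
ΔTm > 1 °C. Specificity compares shifts across T-p53C-Y220C, its
cysteine-light variant, and the pseudo-wild type.

**Integration.** Rate constants are floored at 10⁻⁴ for plotting and
correlation; DTNB k₂ is regressed against the GSH pseudo-first-order
constant in log₁₀ space; the mild-reactivity subset is t½(GSH) ∈ [1, 10] h.

## Worked example

```
$ python examples/03_dtnb_kinetics.py
calibrated molar response: 13842 AU/M (from the 50 uM TNB2- blank)
replicate k2: 2.613, 2.588, 2.607 M-1 s-1
aggregated k2 = 2.60 +- 0.01 M-1 s-1 (truth 2.6)
```

A triplicate plate run is simulated at the iodoacetamide benchmark rate
with realistic absorbance noise; the pipeline recalibrates the molar
response from the blank well, converts to concentrations, fits each
replicate and propagates the uncertainties — recovering the generating
k₂ = 2.6 M⁻¹s⁻¹ to 1%. The other numbered scripts in `examples/` walk
through triage, solubility, GSH, DSF and the cross-assay report the same
way. A thin `covfrag` CLI exposes each stage over CSV files
(`covfrag filter|solubility|dtnb|gsh|dsf|report|simulate|screen|verify`).

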