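"""DSF thermal-shift analysis: Tm, ΔTm, hit calling, specificity.

Simulates a strong covalent stabilizer of the p53-Y220C core domain:
protein-only and compound-treated melt curves per construct, Tm from the
first-derivative maximum, and three-construct specificity classification.
"""

from covfrag.dsf import MeltResult, call_hit, classify_specificity, compute_tm, delta_tm
from covfrag.synthetic import simulate_melt_curve

shifts = {}
for construct, ref_tm, shift in [
    ("T-p53C-Y220C", 46.0, 4.45),  # destabilized mutant, strongly rescued
    ("T-p53C-Y220C-CL", 46.5, 2.25),  # cysteine-light: Cys220-only effect
    ("T-p53C", 54.0, -0.3),  # pseudo-wild type lacks the target cysteine
]:
    ref = compute_tm(simulate_melt_curve(ref_tm, noise_cv=0.01, seed=1, construct=construct))
    sample = compute_tm(simulate_melt_curve(ref_tm + shift, noise_cv=0.01, seed=2, construct=construct))
    dt, _ = delta_tm(MeltResult(tm=sample), MeltResult(tm=ref))
    shifts[construct] = dt
    print(f"{construct:18s} Tm {ref:6.2f} -> {sample:6.2f} C   dTm = {dt:+.2f} C")

print("hit:", call_hit(list(shifts.values())))
call = classify_specificity(
    "SN054-like", shifts["T-p53C-Y220C"], shifts["T-p53C-Y220C-CL"], shifts["T-p53C"]
)
print("specificity:", call.label)
print(
    "Stabilization in both Y220C constructs with the Y220C shift well above"
    " the cysteine-light one indicates Cys220 binding plus additive"
    " non-specific surface arylation."
)
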