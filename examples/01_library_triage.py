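"""Library triage: descriptors, size/logP filter, warhead classification.

Profiles the bundled annotated mini-library and prints, per molecule, its
heavy-atom count, Wildman-Crippen logP, assigned warhead family, and
whether it would survive the library-assembly filter (6-22 heavy atoms,
logP <= 2) plus its rule-of-three violations.
"""

from covfrag.chemlib import apply_size_logp_filter, classify_warhead, compute_descriptors
from covfrag.synthetic import fixture_library

print(f"{'id':32s} {'HA':>3s} {'logP':>6s} {'family':8s} {'ring':14s} {'pass':5s} ro3-violations")
for structure, _family, _ring in fixture_library():
    d = compute_descriptors(structure)
    wh = classify_warhead(structure)
    dec = apply_size_logp_filter(d, id=structure.id)
    print(
        f"{structure.id:32s} {d.heavy_atoms:3d} {d.logp:6.2f} {wh.family:8s} "
        f"{wh.sn_ring:14s} {str(dec.pass_overall):5s} {','.join(sorted(dec.rule_of_three_violations)) or '-'}"
    )

print(
    "\nA 'True' pass means the fragment fits the screening window; SN ring"
    " subtypes distinguish six-membered, five-membered and fused SNAr cores."
)
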