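"""GSH stability assay: half-lives, plateau kinetics, censoring.

Three simulated HPLC series: a mildly reactive fragment (t1/2 = 2.2 h), a
reversible binder whose relative AUC levels off at ~0.5, and a fragment
too fast for even the 20-min schedule.
"""

from covfrag.gsh import Censoring, analyze_series, flag_buffer_instability
from covfrag.synthetic import simulate_gsh_series

LN2 = 0.6931471805599453

mild = analyze_series(simulate_gsh_series(LN2 / 2.2, cv=0.03, seed=1), model="simple")
print(f"mild fragment:      t1/2 = {mild.t_half:.2f} h (truth 2.2 h)")

reversible = analyze_series(
    simulate_gsh_series(4.0, plateau_c=0.5, schedule="fast20min", cv=0.03, seed=2),
    model="plateau",
)
print(
    f"reversible binder:  t1/2 = {reversible.t_half:.2f} h, plateau c = "
    f"{reversible.plateau_c:.2f} (relative AUC levels off instead of reaching 0)"
)

too_fast = analyze_series(simulate_gsh_series(60.0, schedule="fast20min", seed=3))
print(f"very hot fragment:  censored as '{too_fast.censoring.display}'")

verdict = flag_buffer_instability(9.1, 2.9, id="hydrolysing")
print(
    f"buffer check:       GSH 9.1 h vs PBS 2.9 h -> buffer_unstable={verdict.buffer_unstable}"
    " (degradation is hydrolytic, not thiol-driven)"
)
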