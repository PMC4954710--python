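"""Conditional cooperation and its moody variant in the lattice PDG.

In the CC+MCC regime (beta = 0.4, A = 0.5) a player's cooperation
probability rises with the fraction of neighbors that cooperated in the
previous round (f_C) -- but only if the player itself cooperated.  After
own defection the response is flat or falling: that asymmetry is "moody"
conditional cooperation.  We print the stratified curves, the OLS fits
p-tilde ~ alpha1 * f_C + alpha2, and the CC/MCC verdict.
"""

from bmcoop import LearnerParams, cc_curve, linear_fit, mcc_signature, run_pdg, square_lattice
from bmcoop.analysis import CONDITIONS

res = run_pdg(square_lattice(10), LearnerParams(beta=0.4, A=0.5),
              t_max=25, n_runs=300, seed=3)

print("mean p-tilde by f_C level")
print("f_C      all   prev_C  prev_D")
curves = {c: cc_curve(res, c) for c in CONDITIONS}
for i, level in enumerate(curves["all"].levels):
    row = [curves[c].mean[i] for c in CONDITIONS]
    print(f"{level:4.2f}   " + "  ".join(f"{v:6.3f}" for v in row))

fits = {c: linear_fit(res, c) for c in CONDITIONS}
print("\nlinear fits  p-tilde ~ alpha1 * f_C + alpha2")
for c in CONDITIONS:
    print(f"{c:7s}  alpha1 = {fits[c].alpha1:+.4f}   alpha2 = {fits[c].alpha2:.4f}")

sig = mcc_signature(fits)
print(f"\nCC (unconditioned slope > tau): {sig['cc']}")
print(f"MCC (slope > tau after C, < tau after D): {sig['mcc']}")
print(f"intercept ordering alpha2(C) >= alpha2(D): {sig['intercept_ordering_ok']}")
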