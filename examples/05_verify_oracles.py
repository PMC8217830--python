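"""Solver verification against independent references.

Same table as `oxywindow verify`: the time-marching solver against
closed-form slab solutions and a damped-Newton solution of the full
nonlinear steady system assembled independently of the solver stencils.
"""

from oxywindow import verify

for r in verify.run_all():
    status = "PASS" if r.passed else "FAIL"
    print(f"{status}  {r.measured:10.3e} < {r.tolerance:<8g}  {r.name}")
print("\nAll comparisons are solver-vs-oracle maximum differences; the last")
print("row is the deficit of the observed grid-convergence order from 2.")
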