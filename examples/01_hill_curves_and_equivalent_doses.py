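"""Hill curves, closed-form inversion, and effect-equivalent doses.

Two conditional dose-response curves that differ only in EC50 (e1=1, e2=2;
shared y0=1, y_inf=0, s=2) are the canonical case in which Loewe additivity
is internally consistent: every dose of one compound has a proportional
equivalent dose of the other.
"""

import numpy as np

from isobole import (
    equivalent_dose_1,
    equivalent_dose_2,
    hill_inverse,
    hill_response,
    make_pair,
)

pair = make_pair("lacc")
f1, f2 = pair.curve1, pair.curve2

print("conditional responses at selected doses")
for x in (0.0, 1.0, 2.0, np.inf):
    print(f"  f1({x:>4}) = {hill_response(f1, x):.4f}   "
          f"f2({x:>4}) = {hill_response(f2, x):.4f}")
# f1 crosses 0.5 at its EC50 of 1; f2 at 2; both start at y0=1.

y = 0.3
print(f"\ndoses reaching response {y}:")
print(f"  compound 1: {hill_inverse(f1, y):.6f}  (= sqrt(7/3))")
print(f"  compound 2: {hill_inverse(f2, y):.6f}  (= 2*sqrt(7/3))")

print("\nequivalent doses (proportional with ratio e1/e2 = 0.5):")
for x2 in (0.5, 1.0, 2.0, 4.0):
    print(f"  x1_equiv({x2}) = {equivalent_dose_1(pair, x2):.6f}")
print(f"  x2_equiv(1.0) = {equivalent_dose_2(pair, 1.0):.6f}")
# Because the curves are shifted copies on the log-dose axis, the map
# x2 -> x1_equiv is the straight line 0.5 * x2 through the origin.
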