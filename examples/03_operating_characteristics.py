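"""Frequentist operating characteristics of the reduced-control design.

Evaluates the 2:1 PSP design (85 treatment / 43 placebo, sigma = 8,
success when P(delta > 0 | data) > 0.975) with the robust MAP placebo
prior, sweeping the true placebo mean: delta = 0 gives the type I error
curve, delta = 4 the power curve at the clinically meaningful effect.
"""

import numpy as np

from ecborrow import freq_power, freq_sample_size, reduced_control_sizes
from ecborrow.psp import psp_operating_characteristics

print("frequentist benchmark:", freq_sample_size(0.025, 0.90, 4.0, 8.0), "per arm (1:1)")
print("reduced-control 2:1  :", reduced_control_sizes(0.025, 0.90, 4.0, 8.0, 2.0), "(n_t, n_c)")
print(f"85/43 z-test power   : {freq_power(85, 43, 0.025, 4.0, 8.0):.3f}\n")

grid = np.arange(5.0, 17.0 + 1e-9, 0.5)
t1 = psp_operating_characteristics(0.0, theta_c_grid=grid)
power = psp_operating_characteristics(4.0, theta_c_grid=grid)

print("true placebo mean | type I error | power(delta=4)")
for theta, a, p in zip(grid, t1.success_prob, power.success_prob):
    print(f"{theta:17.1f} | {100 * a:11.2f}% | {100 * p:13.2f}%")

imax = int(np.argmax(t1.success_prob))
print(
    f"\nmax type I error: {100 * t1.max_success_prob():.2f}% at true placebo mean "
    f"{grid[imax]:.1f}"
)
print(
    "Borrowing keeps the placebo arm at 43 patients; the robust prior's vague\n"
    "component caps the false-positive inflation under prior-data conflict,\n"
    "while power near the historical mean (10.9) exceeds the 85/43 z-test."
)
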