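"""Dynamic FBA with a Boolean regulatory rule (variant C2, rFBA).

At every step a small flux LP is solved; the rule inactivates the
second-substrate enzyme while the first substrate is available.
"""

import numpy as np

from diauxie import diauxic_index, make_batch, make_variant, simulate

traj = simulate(make_variant("C2"), make_batch(t_end=30))

switch = np.nonzero(traj.rates["r_s2"] > 0)[0]
print(f"S2 uptake starts at t = {traj.t[switch[0]]:.2f} "
      "(after S1 falls below the availability threshold)")
print(f"final biomass b = {traj.states['b'][-1]:.3f} "
      "(= initial biomass + both unit substrate pools)")
print(f"diauxic index d = {diauxic_index(traj).d:.3f}")
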