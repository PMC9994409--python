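"""Molecular crowding: inert proteins promote receptor dimerisation.

Adds 0, 100 or 200 inert crowder discs (diameter 5% of the box, moving
at half receptor speed) to a domain-free membrane and measures the
equilibrium dimeric fraction at reduced run length.  Crowders tighten
the space available to monomers, raising their encounter rate and
slowing the separation of freshly dissociated pairs.
"""

import dataclasses

from raftsim import run_replicates
from raftsim.experiments import apply_point, preset

spec = preset(5)  # crowding sweep: no confined domain
base = dataclasses.replace(spec.base, n_steps=50_000, window=20_000, seed=3)

print("inert crowders   receptors in dimeric form (%)")
for n in (0, 100, 200):
    stats = run_replicates(apply_point(base, {"n_inert": n}))
    s = stats["fraction_dimeric"]
    print(f"{n:14d}   {100 * s.mean:5.1f} +- {100 * (s.sd or 0):.1f}")

print()
print("Dimerisation rises steadily with crowder count even though the "
      "crowders never react with the receptors.")
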