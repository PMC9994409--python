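"""Map measured platelet/GPVI constants onto simulation units.

Prints the full derived-parameter table for the human platelet preset
(7.4 fl volume, 9600 GPVI copies) and the mouse preset.  The box length
(~0.3 um) is the patch of membrane served by one lipid raft; one tick
corresponds to ~0.43 ms; one receptor disc spans 3.8% of the box.
"""

from raftsim import scaling

for name, params in (("human", scaling.HUMAN), ("mouse", scaling.MOUSE)):
    print(f"--- {name} platelet ---")
    print(scaling.format_table(params))
    print()

s = scaling.derive(scaling.HUMAN)
print(
    f"One simulation box is {s.box_length * 1e9:.0f} nm across, holds "
    f"{s.receptors_per_box} receptor monomers, and one tick advances "
    f"real time by {s.timestep * 1e3:.2f} ms."
)
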