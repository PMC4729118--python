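"""Decompose values into horizon bands and invert the transform.

A horizon chart slices the value range [0, extent] into n equal bands;
a value fills the lower bands completely and at most one band partially.
Because the slicing is exact, summing the fills reconstructs the value —
that is what lets you spot-check a rendered chart against raw data.
"""

from horizonbed import HorizonConfig, decompose, reconstruct

cfg = HorizonConfig(n_bands=4, extent=100.0)

for value in [0.0, 37.5, -37.5, 100.0, 130.0]:
    stack = decompose(value, cfg)
    back = reconstruct(stack, cfg)
    print(
        f"value {value:>7.1f} -> sign {stack.sign:+d}, "
        f"fills {tuple(round(f, 3) for f in stack.fills)}, "
        f"clipped={stack.clipped} -> reconstructs to {back:.1f}"
    )

# Each band spans extent/n_bands = 25 value units.  37.5 fills band 0
# fully and band 1 halfway; -37.5 is the same stack with negative sign
# (drawn mirrored in the blue palette); 130 exceeds the extent, so it
# saturates all four bands and is flagged clipped, reconstructing to the
# clamp value 100.
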