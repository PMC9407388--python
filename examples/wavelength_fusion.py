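"""Fuse the characteristic wavelengths of two cultivation conditions.

Each condition's variable selection produces an importance-ordered
wavelength list.  Absorption features drift a little between conditions,
so any new-condition wavelength strictly within 30 nm of a base-condition
wavelength is a repeat and is dropped (the base wavelength wins).  The
fused list is the variable set a condition-robust model is built on.
"""

from specfuse import fuse_wavelengths

# importance-ordered selections for the two cultivation modes
open_field = [957, 1008, 2339, 920, 2248, 2394, 1137, 1976, 647, 602]
rain_shelter = [1257, 962, 905, 1137, 2337, 2300, 1541, 2378, 2386,
                1947, 1907, 1480, 1058, 2128, 811, 693]

fused = fuse_wavelengths(open_field, rain_shelter, offset=30)

print(f"inputs : {len(open_field)} base + {len(rain_shelter)} new wavelengths")
print(f"fused  : {len(fused)} wavelengths")
print("        ", ", ".join(f"{v:g}" for v in fused.values))
print("removed repeats (value -> anchor that displaced it):")
for value, anchor in fused.removed:
    print(f"         {value:g} -> {anchor:g}")
# Every removed value sat strictly within 30 nm of its anchor; the shared
# 1137 nm appears once.  The 19 survivors are the fused variable set.
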