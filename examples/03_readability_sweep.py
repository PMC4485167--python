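"""How dark must the strips be before the barcode scans?

Sweeps the target strip ODR on a 0.04 grid and reports the minimum
readable ODR for each character of the pair.  "+" only needs its two
narrow control bars to clear the darkness threshold; "-" additionally
needs the 0.5 mm white barrier inside each divided wide bar to blur
shut, so its floor is higher — faint positives are the hard case.
"""

import numpy as np

from barcodeassay import AssayLayout, min_readable_odr, readability_sweep

layout = AssayLayout(dpi=150)  # coarse raster; floors are dpi-stable
grid = np.arange(0.04, 1.0 + 1e-9, 0.04)

for character in ("+", "-"):
    floor = min_readable_odr(character, layout, odr_grid=grid)
    print(f"minimum readable ODR for {character!r}: {floor:.2f}")

print()
rows = readability_sweep(layout, odr_grid=np.arange(0.08, 1.0, 0.08))
for character in ("+", "-"):
    line = "".join("#" if r["readable"] else "."
                   for r in rows if r["character"] == character)
    print(f"{character!r}  ODR 0.08 {line} 0.96   (#=scans, .=fails)")

print()
print("Strips darker than the floor always scan (readability is")
print("monotone in ODR); below it, the qualitative barcode read fails")
print("even though densitometry can still quantify the strips.")
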