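"""Multiplexed barcodes: several analytes on one strip plate.

Two schemes: the character alphabet draws one glyph pair per analyte
(-/+ for the first, F/$ for the second, repeating); the paired-label
scheme spells a designator letter before each -/+ result, so a long
panel stays human-readable.  Every realization is itself a valid
Code 39 barcode: we render and re-scan one to prove it.
"""

import itertools

from barcodeassay import (
    decode_image,
    design_multiplex,
    parse_multiplex,
    realize_multiplex,
    render_barcode,
)

scheme = design_multiplex(["hCG", "AFP"])
print("character-alphabet template:", scheme.template())
for vector in itertools.product(["positive", "negative"], repeat=2):
    payload = realize_multiplex(scheme, list(vector))
    print(f"  {vector[0][:3]}/{vector[1][:3]} -> barcode payload {payload!r}")

paired = design_multiplex(["Alpha", "Beta"], mode="paired_label")
payload = realize_multiplex(paired, ["negative", "positive"])
print(f"\npaired-label realization: {payload!r}")
for call in parse_multiplex(payload, paired):
    print(f"  {call.analyte}: {call.result}")

scanned = decode_image(render_barcode(payload))
print(f"\nrendered and re-scanned: {scanned.payload!r} "
      f"(round trip {'ok' if scanned.payload == payload else 'FAILED'})")
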