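"""The Code 39 structure behind the assay's character pair.

Encodes "-" and "+", prints their 9-element wide/narrow patterns, and
shows why a four-strip assay can flip the read between them: the two
patterns agree on their first five elements and differ on the last
four — exactly the elements the binding strips realize.
"""

from barcodeassay import diff_elements, differential_positions, encode_char

for c in ("-", "+", "F", "$"):
    p = encode_char(c)
    print(f"{c!r}: {p.widths}   (b1 s1 b2 s2 b3 s3 b4 s4 b5)")

print()
print("'-' vs '+': differ at elements", differential_positions("-", "+"),
      f"({diff_elements('-', '+')} of 9; the first 5 agree)")
print("'F' vs '$': differ at elements", differential_positions("F", "$"))
print()
print("A positive assay darkens all four strips -> the two wide bars of")
print("'-' appear; a negative assay darkens only the controls -> the")
print("same plate reads as '+'.")
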