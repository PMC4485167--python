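"""Independent Code 39 oracle for the test suite.

Deliberately shares no code with the package: the character table is
regenerated from the symbology's published structure (the ten
two-of-five wide-bar codes cycled across four wide-space groups, plus
the four all-narrow-bar symbol characters), and the reader below
decodes noiseless full-contrast renders with plain midpoint
thresholding.  Agreement between this path and the package's encoder/
scanline decoder is what the oracle-equivalence tests assert.
"""

from __future__ import annotations

import numpy as np

# wide bar positions (1-based, of 5) for values 1..9, 0 — the classic
# two-of-five sequence
_BAR_CYCLE = {
    1: (1, 5), 2: (2, 5), 3: (1, 2), 4: (3, 5), 5: (1, 3),
    6: (2, 3), 7: (4, 5), 8: (1, 4), 9: (2, 4), 0: (3, 4),
}
# character groups sharing one wide space (1-based, of 4)
_GROUPS = [
    ("1234567890", 2),
    ("ABCDEFGHIJ", 3),
    ("KLMNOPQRST", 4),
    ("UVWXYZ-. *", 1),
]
# symbol characters: no wide bars, three wide spaces
_SYMBOLS = {"$": (1, 2, 3), "/": (1, 2, 4), "+": (1, 3, 4), "%": (2, 3, 4)}


def _build_table() -> dict[str, str]:
    table: dict[str, str] = {}
    for chars, wide_space in _GROUPS:
        for value, c in zip([1, 2, 3, 4, 5, 6, 7, 8, 9, 0], chars):
            wide_bars = _BAR_CYCLE[value]
            widths = []
            for i in range(9):
                if i % 2 == 0:
                    widths.append("W" if (i // 2 + 1) in wide_bars else "N")
                else:
                    widths.append("W" if (i // 2 + 1) == wide_space else "N")
            table[c] = "".join(widths)
    for c, wide_spaces in _SYMBOLS.items():
        widths = []
        for i in range(9):
            if i % 2 == 0:
                widths.append("N")
            else:
                widths.append("W" if (i // 2 + 1) in wide_spaces else "N")
        table[c] = "".join(widths)
    return table


ORACLE_TABLE: dict[str, str] = _build_table()
_REVERSE = {v: k for k, v in ORACLE_TABLE.items()}


def oracle_decode(image: np.ndarray) -> str | None:
    """Decode a noiseless, full-contrast render; None on any failure.

    Middle-row scan, fixed threshold at gray 128, wide/narrow split at
    the midpoint of the extreme run lengths, start/stop framing with a
    reversed retry.  Returns the payload without the framing '*'s.
    """
    row = np.asarray(image, dtype=float)[image.shape[0] // 2]
    dark = row < 128.0
    if not dark.any():
        return None
    idx = np.flatnonzero(dark)
    dark = dark[idx[0]:idx[-1] + 1]
    edges = np.flatnonzero(np.diff(dark.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [dark.size]))
    lengths = np.diff(bounds).astype(float)
    if (len(lengths) + 1) % 10 != 0:
        return None
    cut = 0.5 * (lengths.min() + lengths.max())

    def attempt(ls: np.ndarray) -> str | None:
        chars = []
        for k in range(0, len(ls), 10):
            widths = "".join("W" if x > cut else "N" for x in ls[k:k + 9])
            c = _REVERSE.get(widths)
            if c is None:
                return None
            chars.append(c)
        text = "".join(chars)
        if len(text) < 3 or not (text[0] == "*" and text[-1] == "*"):
            return None
        return text[1:-1]

    return attempt(lengths) or attempt(lengths[::-1])
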