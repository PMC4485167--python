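"""Code 39 pattern algebra.

Code 39 encodes each of its 44 characters as 9 elements — 5 bars
interleaved with 4 spaces — of which exactly 3 are wide and 6 narrow.
The symbology is self-checking and frames every message with the
start/stop character ``*``.  The assay design exploits character pairs
(``-``/``+``, ``F``/``$``) whose patterns coincide except on a handful
of elements, so that darkening or leaving blank a few physical strips
flips the decoded character.

Element indexing follows the bar/space interleave: b1 s1 b2 s2 b3 s3 b4
s4 b5 (1-based positions 1..9 in documentation and error messages).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

__all__ = [
    "CODE39_CHARACTERS",
    "START_STOP",
    "ElementPattern",
    "BarcodeSpec",
    "encode_char",
    "encode_string",
    "decode_pattern",
    "diff_elements",
    "differential_positions",
    "pattern_table",
    "export_table_json",
]

START_STOP = "*"

# Published Code 39 assignments, written as (wide-flags over the 5 bars,
# wide-flags over the 4 spaces).  "1" marks a wide element.
_BARS_SPACES: dict[str, tuple[str, str]] = {
    "0": ("00110", "0100"),
    "1": ("10001", "0100"),
    "2": ("01001", "0100"),
    "3": ("11000", "0100"),
    "4": ("00101", "0100"),
    "5": ("10100", "0100"),
    "6": ("01100", "0100"),
    "7": ("00011", "0100"),
    "8": ("10010", "0100"),
    "9": ("01010", "0100"),
    "A": ("10001", "0010"),
    "B": ("01001", "0010"),
    "C": ("11000", "0010"),
    "D": ("00101", "0010"),
    "E": ("10100", "0010"),
    "F": ("01100", "0010"),
    "G": ("00011", "0010"),
    "H": ("10010", "0010"),
    "I": ("01010", "0010"),
    "J": ("00110", "0010"),
    "K": ("10001", "0001"),
    "L": ("01001", "0001"),
    "M": ("11000", "0001"),
    "N": ("00101", "0001"),
    "O": ("10100", "0001"),
    "P": ("01100", "0001"),
    "Q": ("00011", "0001"),
    "R": ("10010", "0001"),
    "S": ("01010", "0001"),
    "T": ("00110", "0001"),
    "U": ("10001", "1000"),
    "V": ("01001", "1000"),
    "W": ("11000", "1000"),
    "X": ("00101", "1000"),
    "Y": ("10100", "1000"),
    "Z": ("01100", "1000"),
    "-": ("00011", "1000"),
    ".": ("10010", "1000"),
    " ": ("01010", "1000"),
    "*": ("00110", "1000"),
    "$": ("00000", "1110"),
    "/": ("00000", "1101"),
    "+": ("00000", "1011"),
    "%": ("00000", "0111"),
}

CODE39_CHARACTERS: str = "".join(_BARS_SPACES)

# Unicode variants users paste from formatted text.
_ALIASES = {"−": "-", "–": "-", "—": "-"}


def _canonical(c: str) -> str:
    return _ALIASES.get(c, c.upper() if c.isalpha() else c)


Role = Literal["bar", "space"]
WidthClass = Literal["wide", "narrow"]


@dataclass(frozen=True)
class ElementPattern:
    """The 9-element wide/narrow pattern of one Code 39 character."""

    character: str
    elements: tuple[tuple[Role, WidthClass], ...]

    def __post_init__(self) -> None:
        if len(self.elements) != 9:
            raise ValueError(
                f"pattern for {self.character!r} has {len(self.elements)} "
                "elements; Code 39 characters have exactly 9"
            )
        for i, (role, _) in enumerate(self.elements):
            expected = "bar" if i % 2 == 0 else "space"
            if role != expected:
                raise ValueError(
                    f"element {i + 1} of {self.character!r} is a {role}; "
                    f"bars and spaces must strictly alternate (expected {expected})"
                )
        n_wide = sum(w == "wide" for _, w in self.elements)
        if n_wide != 3:
            raise ValueError(
                f"pattern for {self.character!r} has {n_wide} wide elements; "
                "Code 39 requires exactly 3 of 9"
            )

    @property
    def widths(self) -> str:
        """The pattern as a 9-character string over ``{W, N}``."""
        return "".join("W" if w == "wide" else "N" for _, w in self.elements)

    def __iter__(self) -> Iterator[tuple[Role, WidthClass]]:
        return iter(self.elements)


def _interleave(bars: str, spaces: str) -> tuple[tuple[Role, WidthClass], ...]:
    out: list[tuple[Role, WidthClass]] = []
    for i in range(9):
        if i % 2 == 0:
            flag, role = bars[i // 2], "bar"
        else:
            flag, role = spaces[i // 2], "space"
        out.append((role, "wide" if flag == "1" else "narrow"))
    return tuple(out)


_TABLE: dict[str, ElementPattern] = {
    c: ElementPattern(c, _interleave(b, s)) for c, (b, s) in _BARS_SPACES.items()
}
_WIDTHS_TO_CHAR: dict[str, str] = {p.widths: c for c, p in _TABLE.items()}


def encode_char(c: str) -> ElementPattern:
    """Return the 9-element pattern of a single Code 39 character.

    Raises
    ------
    ValueError
        If ``c`` is not one of the 44 supported characters.
    """
    key = _canonical(c)
    if key not in _TABLE:
        raise ValueError(
            f"character {c!r} is not encodable in Code 39 "
            f"(supported: digits, A-Z, space, and - . $ / + % *)"
        )
    return _TABLE[key]


def decode_pattern(widths: str | Sequence[str]) -> str | None:
    """Map a 9-character ``W``/``N`` width string back to its character.

    Returns ``None`` for width sequences outside the table (Code 39 is
    self-checking: most single-element corruptions land here).
    """
    key = "".join(widths)
    return _WIDTHS_TO_CHAR.get(key)


@dataclass(frozen=True)
class BarcodeSpec:
    """A payload framed by start/stop characters, ready to render.

    ``full_sequence`` is ``"*" + payload + "*"``; consecutive characters
    are separated by a single narrow inter-character gap (a space).
    """

    payload: str

    def __post_init__(self) -> None:
        if not self.payload:
            raise ValueError("payload must contain at least one character")
        canon = "".join(_canonical(c) for c in self.payload)
        if START_STOP in canon:
            raise ValueError(
                "'*' is reserved as the start/stop character and cannot "
                "appear inside a payload"
            )
        for c in canon:
            if c not in _TABLE:
                raise ValueError(f"character {c!r} is not encodable in Code 39")
        object.__setattr__(self, "payload", canon)

    @property
    def full_sequence(self) -> str:
        return START_STOP + self.payload + START_STOP

    def patterns(self) -> list[ElementPattern]:
        return [encode_char(c) for c in self.full_sequence]


def encode_string(s: str) -> BarcodeSpec:
    """Frame a payload with start/stop characters.

    The result's ``full_sequence`` is ``*<s>*``; rendering inserts one
    narrow gap space between consecutive characters.
    """
    return BarcodeSpec(s)


def diff_elements(p: ElementPattern | str, q: ElementPattern | str) -> int:
    """Number of the 9 element positions at which two patterns differ."""
    return len(differential_positions(p, q))


def differential_positions(
    p: ElementPattern | str, q: ElementPattern | str
) -> tuple[int, ...]:
    """1-based element positions (1..9) where two patterns differ in width.

    For the assay pair ``("-", "+")`` this is exactly ``(6, 7, 8, 9)``:
    the two characters agree on their first five elements and differ on
    the last four, which is what lets a four-strip assay flip the read
    between them.
    """
    pp = encode_char(p) if isinstance(p, str) else p
    qq = encode_char(q) if isinstance(q, str) else q
    return tuple(
        i + 1
        for i, (a, b) in enumerate(zip(pp.elements, qq.elements))
        if a[1] != b[1]
    )


def pattern_table() -> dict[str, str]:
    """The full character table as ``{character: 9-char W/N string}``."""
    return {c: p.widths for c, p in _TABLE.items()}


def export_table_json(path: str | None = None) -> str:
    """Serialize the pattern table to JSON; write to ``path`` if given."""
    text = json.dumps(pattern_table(), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
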