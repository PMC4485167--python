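"""Assay semantics: qualitative calls, character polarity, multiplexing.

Polarity convention: characters are named for their barcode glyphs, not
the clinical result.  A *positive* test darkens all four strips, fusing
the divided wide bars, so the scanner reads the wide-bar character
("−"); a valid *negative* test darkens only the control lines, and the
narrow-bar character ("+") appears.  A control line without signal
voids the test regardless of the test lines.

Multiplexing either draws on the character alphabet — one glyph pair
(−/+ or F/$, repeating) per analyte — or pairs each analyte with a
letter designator followed by its −/+ result character ("A+B−").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .code39 import encode_char
from .densitometry import StripMeasurement

__all__ = [
    "QualCall",
    "MultiplexScheme",
    "DEFAULT_PAIR",
    "ALPHABET_PAIRS",
    "qualitative_call",
    "expected_character",
    "design_multiplex",
    "realize_multiplex",
    "parse_multiplex",
]

#: (positive_char, negative_char) — positive = the glyph whose wide bars
#: the strips complete.  F/$ polarity: "F" is taken as positive because,
#: like "−", its differential elements include the two wide bars the
#: strips form (a design assumption; either assignment would decode).
DEFAULT_PAIR: tuple[str, str] = ("-", "+")
ALPHABET_PAIRS: tuple[tuple[str, str], ...] = (("-", "+"), ("F", "$"))

Result = Literal["positive", "negative", "invalid"]


@dataclass(frozen=True)
class QualCall:
    """Qualitative outcome for one analyte with its evidence."""

    analyte: str
    result: Result
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MultiplexScheme:
    """How a multi-analyte barcode encodes its results.

    ``character_alphabet``: slot *i* holds analyte *i*'s result as one
    character of ``char_pairs[i]``.  ``paired_label``: slot *i* is a
    (designator letter, −/+ result) pair.
    """

    mode: Literal["character_alphabet", "paired_label"]
    analyte_order: tuple[str, ...]
    char_pairs: tuple[tuple[str, str], ...]
    strip_map: tuple[tuple[int, ...], ...] = ()

    def template(self) -> list[str]:
        """Human-readable slot template, e.g. ['(-|+)', '(F|$)']."""
        if self.mode == "character_alphabet":
            return [f"({p}|{n})" for p, n in self.char_pairs]
        return [f"{a}(-|+)" for a in self.analyte_order]


def _strip_odrs(strips: Sequence[StripMeasurement | float]) -> list[float]:
    return [s.odr if isinstance(s, StripMeasurement) else float(s) for s in strips]


def qualitative_call(
    strips: Sequence[StripMeasurement | float],
    signal_threshold_odr: float = 0.10,
    analyte: str = "analyte",
) -> QualCall:
    """Call one assay from its four strip ODRs.

    Strips 1 and 3 are test lines, 2 and 4 control lines.  Both
    controls must carry signal for the test to be valid; then signal on
    the test lines makes the call positive, its absence negative.  The
    default threshold 0.10 sits above blank-level ODRs (~0.04–0.07)
    and below the barcode-scan readability floor — quantification
    reaches lower than the qualitative barcode read.
    """
    odrs = _strip_odrs(strips)
    if len(odrs) != 4:
        raise ValueError(f"expected 4 strip measurements, got {len(odrs)}")
    tests, controls = odrs[0::2], odrs[1::2]
    evidence = {"strip_odrs": odrs, "threshold": signal_threshold_odr}
    if any(c < signal_threshold_odr for c in controls):
        result: Result = "invalid"
    elif all(t >= signal_threshold_odr for t in tests):
        result = "positive"
    else:
        result = "negative"
    return QualCall(analyte, result, evidence)


def expected_character(call: QualCall | Result,
                       pair: tuple[str, str] = DEFAULT_PAIR) -> str:
    """The character the scanner should read for a given call.

    positive → the pair's wide-bar character ("−"); negative → the
    narrow-bar character ("+").  An invalid call has no character: the
    strips do not form a decodable glyph.
    """
    result = call.result if isinstance(call, QualCall) else call
    pos, neg = pair
    encode_char(pos), encode_char(neg)
    if result == "positive":
        return pos
    if result == "negative":
        return neg
    raise ValueError("an invalid test has no expected character")


def design_multiplex(
    analytes: Sequence[str],
    mode: Literal["character_alphabet", "paired_label"] = "character_alphabet",
) -> MultiplexScheme:
    """Lay out a multi-analyte barcode.

    ``character_alphabet`` alternates the (−,+) and (F,$) glyph pairs
    across analytes; ``paired_label`` gives each analyte a letter
    designator (its first character, uppercased) followed by a −/+
    result slot.  Also returns, per analyte, the 1-based indices of its
    four binding strips in the composed barcode (each result glyph
    contributes four strips; designator letters are printed, not assay
    regions).
    """
    analytes = tuple(analytes)
    if not analytes:
        raise ValueError("need at least one analyte")
    if mode == "character_alphabet":
        pairs = tuple(ALPHABET_PAIRS[i % len(ALPHABET_PAIRS)]
                      for i in range(len(analytes)))
    elif mode == "paired_label":
        pairs = tuple(DEFAULT_PAIR for _ in analytes)
        seen: dict[str, str] = {}
        for a in analytes:
            d = a[0].upper()
            if not d.isalpha():
                raise ValueError(f"analyte {a!r} needs a letter designator")
            if d in seen:
                raise ValueError(
                    f"designator {d!r} is shared by {seen[d]!r} and {a!r}"
                )
            seen[d] = a
    else:
        raise ValueError(f"unknown multiplex mode {mode!r}")
    strip_map = tuple(
        tuple(range(4 * i + 1, 4 * i + 5)) for i in range(len(analytes))
    )
    return MultiplexScheme(mode, analytes, pairs, strip_map)


def realize_multiplex(scheme: MultiplexScheme,
                      results: Sequence[Result]) -> str:
    """The payload a given result vector produces under a scheme."""
    if len(results) != len(scheme.analyte_order):
        raise ValueError(
            f"{len(results)} results for {len(scheme.analyte_order)} analytes"
        )
    out = []
    for i, (res, pair) in enumerate(zip(results, scheme.char_pairs)):
        if res == "invalid":
            raise ValueError(f"analyte {i + 1}: an invalid test renders no character")
        c = expected_character(res, pair)
        if scheme.mode == "paired_label":
            out.append(scheme.analyte_order[i][0].upper() + c)
        else:
            out.append(c)
    return "".join(out)


def parse_multiplex(payload: str, scheme: MultiplexScheme) -> list[QualCall]:
    """Map a decoded payload back to per-analyte calls.

    ``character_alphabet``: each slot's character is matched against
    that analyte's glyph pair.  ``paired_label``: (designator, result)
    pairs, with "−" → positive and "+" → negative per the base
    polarity convention.  Mismatches report the first offending
    payload position (1-based).
    """
    n = len(scheme.analyte_order)
    calls: list[QualCall] = []
    if scheme.mode == "character_alphabet":
        if len(payload) != n:
            raise ValueError(
                f"payload {payload!r} has {len(payload)} characters; "
                f"scheme expects {n}"
            )
        for i, c in enumerate(payload):
            pos, neg = scheme.char_pairs[i]
            if c == pos:
                result: Result = "positive"
            elif c == neg:
                result = "negative"
            else:
                raise ValueError(
                    f"position {i + 1}: character {c!r} is not in the "
                    f"pair ({pos!r}, {neg!r})"
                )
            calls.append(QualCall(scheme.analyte_order[i], result,
                                  {"character": c}))
    else:
        if len(payload) != 2 * n:
            raise ValueError(
                f"payload {payload!r} has {len(payload)} characters; "
                f"scheme expects {2 * n} (designator + result per analyte)"
            )
        for i in range(n):
            designator, c = payload[2 * i], payload[2 * i + 1]
            expected_d = scheme.analyte_order[i][0].upper()
            if designator != expected_d:
                raise ValueError(
                    f"position {2 * i + 1}: designator {designator!r} does not "
                    f"match analyte {scheme.analyte_order[i]!r} ({expected_d!r})"
                )
            pos, neg = scheme.char_pairs[i]
            if c == pos:
                result = "positive"
            elif c == neg:
                result = "negative"
            else:
                raise ValueError(
                    f"position {2 * i + 2}: result character {c!r} is not in "
                    f"the pair ({pos!r}, {neg!r})"
                )
            calls.append(QualCall(scheme.analyte_order[i], result,
                                  {"designator": designator, "character": c}))
    return calls
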