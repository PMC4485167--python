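"""Scanline decoding: round trips, invariances, readability floors."""

import numpy as np
import pytest

from barcodeassay import (
    CODE39_CHARACTERS,
    AssayLayout,
    DecodeConfig,
    RenderScenario,
    binarize_runs,
    classify_and_decode,
    decode_image,
    extract_scanline,
    min_readable_odr,
    render_assay,
    render_barcode,
)
from barcodeassay.decode import Run
from conftest import negative_scenario, positive_scenario
from oracle_code39 import oracle_decode

PAYLOAD_CHARS = CODE39_CHARACTERS.replace("*", "")


class TestScanline:
    def test_profile_is_column_mean_of_central_band(self):
        img = render_barcode("+")
        p = extract_scanline(img)
        assert p.values.size == img.shape[1]
        r0, r1 = p.band_rows
        assert np.allclose(p.values, img[r0:r1].mean(axis=0))
        assert r1 - r0 == pytest.approx(0.2 * img.shape[0], abs=1)

    def test_noiseless_profile_is_two_level(self):
        layout = AssayLayout()
        img = render_barcode("+", layout)
        p = extract_scanline(img)
        assert set(np.unique(p.values)) <= {0.0, 255.0}

    def test_all_white_image_has_constant_255_profile(self):
        p = extract_scanline(np.full((50, 80), 255, dtype=np.uint8))
        assert np.all(p.values == 255.0)
        runs, lead, _ = binarize_runs(p)
        assert runs == [] and lead == 80

    def test_band_averaging_reduces_banded_noise(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(128, 30, size=(60, 1))  # per-row offsets
        img = np.clip(rows + rng.normal(0, 10, size=(60, 300)), 0, 255)
        band_var = extract_scanline(img).values.var()
        single_var = img[30].var()
        assert band_var < single_var

    def test_too_short_image_rejected(self):
        with pytest.raises(ValueError):
            extract_scanline(np.zeros((3, 50), dtype=np.uint8))


class TestBinarize:
    def test_noiseless_runs_match_rendered_module_widths(self):
        layout = AssayLayout()
        img = render_barcode("+", layout)
        runs, _, _ = binarize_runs(extract_scanline(img))
        n, w = layout.px(layout.narrow_mm), layout.px(layout.wide_mm)
        # "*+*": 9 elements per char + narrow gaps; edge rounding may
        # shift each run boundary by one pixel
        expected = []
        for k, c in enumerate("*+*"):
            if k:
                expected.append(n)
            from barcodeassay import encode_char
            expected.extend(w if wc == "wide" else n
                            for _, wc in encode_char(c).elements)
        assert len(runs) == len(expected)
        assert all(abs(r.length - e) <= 1 for r, e in zip(runs, expected))
        assert [r.dark for r in runs] == [i % 2 == 0 for i in range(len(runs))]

    def test_faint_strips_below_threshold_vanish(self):
        layout = AssayLayout()
        img = render_assay("-", layout, positive_scenario(0.10, blur_sigma=0.0))
        runs, _, _ = binarize_runs(extract_scanline(img))
        # the four faint strips merge into light runs: only the printed
        # bars of "*", "-", "*" minus the two divided bars remain
        dark = sum(r.dark for r in runs)
        assert dark == 5 + 3 + 5  # "*" bars + "-" printed bars + "*" bars

    def test_uniform_intensity_scaling_preserves_runs(self):
        img = render_barcode("A+")
        runs_full, _, _ = binarize_runs(extract_scanline(img))
        dimmed = (img.astype(float) * 0.5).round().astype(np.uint8)
        runs_dim, _, _ = binarize_runs(extract_scanline(dimmed))
        assert runs_full == runs_dim


class TestClassifyDecode:
    def test_runs_must_alternate(self):
        bad = [Run(True, 5), Run(True, 5), Run(False, 5)]
        assert classify_and_decode(bad).status == "unknown_pattern"

    def test_no_runs_is_no_start_stop(self):
        assert classify_and_decode([]).status == "no_start_stop"

    def test_missing_start_stop_detected(self):
        layout = AssayLayout()
        img = render_barcode("+", layout)
        runs, _, _ = binarize_runs(extract_scanline(img))
        # drop the first character ("*"): framing is gone
        assert classify_and_decode(runs[10:]).status == "no_start_stop"

    def test_corrupt_group_is_unknown_pattern(self):
        layout = AssayLayout()
        img = render_barcode("+", layout)
        runs, _, _ = binarize_runs(extract_scanline(img))
        runs = list(runs)
        runs[2] = Run(True, layout.px(layout.wide_mm))  # forge a wide bar
        res = classify_and_decode(runs)
        assert res.status in ("unknown_pattern", "no_start_stop")


class TestRoundTrip:
    @pytest.mark.parametrize("dpi", [150, 300, 600])
    def test_every_character_round_trips_at_full_contrast(self, dpi):
        layout = AssayLayout(dpi=dpi)
        for c in PAYLOAD_CHARS:
            res = decode_image(render_barcode(c, layout))
            assert (res.status, res.payload) == ("ok", c), c

    @pytest.mark.parametrize("dpi", [150, 300])
    def test_random_payloads_round_trip(self, dpi):
        rng = np.random.default_rng(dpi)
        layout = AssayLayout(dpi=dpi)
        for _ in range(20):
            payload = "".join(rng.choice(list(PAYLOAD_CHARS),
                                         size=rng.integers(1, 5)))
            res = decode_image(render_barcode(payload, layout))
            assert (res.status, res.payload) == ("ok", payload), payload

    def test_agreement_with_independent_reader_on_random_renders(self):
        rng = np.random.default_rng(2024)
        layout = AssayLayout(dpi=150)
        for _ in range(100):
            payload = "".join(rng.choice(list(PAYLOAD_CHARS),
                                         size=rng.integers(1, 4)))
            img = render_barcode(payload, layout)
            assert oracle_decode(img) == payload
            assert decode_image(img).payload == payload

    def test_mirrored_image_decodes_reversed(self):
        img = render_barcode("A+B")
        res = decode_image(img[:, ::-1])
        assert (res.status, res.payload) == ("ok", "A+B")
        assert res.orientation == "reversed"

    def test_palindromic_character_forward(self):
        res = decode_image(render_barcode("+"))
        assert res.orientation == "forward"

    @pytest.mark.parametrize("scale", [0.3, 0.5, 0.8, 1.0])
    def test_brightness_scale_invariance(self, scale):
        img = render_barcode("+$")
        dimmed = (img.astype(float) * scale).round().astype(np.uint8)
        res = decode_image(dimmed)
        assert (res.status, res.payload) == ("ok", "+$")


class TestAssayDecoding:
    def test_positive_assay_reads_minus(self, layout):
        img = render_assay("-", layout, positive_scenario(1.0))
        assert decode_image(img).payload == "-"

    def test_negative_assay_reads_plus(self, layout):
        img = render_assay("-", layout, negative_scenario(1.0))
        assert decode_image(img).payload == "+"

    def test_faint_strips_fail_both_characters(self, layout):
        for scen in (positive_scenario(0.10), negative_scenario(0.10)):
            res = decode_image(render_assay("-", layout, scen))
            assert res.payload not in ("-", "+")

    def test_dollar_f_pair_assay(self):
        layout = AssayLayout(character_pair=("F", "$"))
        pos = render_assay("F", layout, positive_scenario(1.0))
        neg = render_assay("F", layout, negative_scenario(1.0))
        assert decode_image(pos).payload == "F"
        assert decode_image(neg).payload == "$"

    def test_combined_multiplex_barcode_reads_plus_dollar(self, layout):
        # two-analyte negative/negative realization: "+$"
        img = render_barcode("+$", layout)
        assert decode_image(img).payload == "+$"


class TestReadability:
    def test_full_black_always_readable_on_trivial_grid(self, layout):
        assert min_readable_odr("-", layout, odr_grid=[1.0]) == 1.0
        assert min_readable_odr("+", layout, odr_grid=[1.0]) == 1.0

    def test_readability_monotone_in_strip_odr(self, layout):
        from barcodeassay import readability_sweep
        grid = np.arange(0.04, 1.0001, 0.08)
        rows = readability_sweep(layout, odr_grid=grid)
        for character in ("-", "+"):
            flags = [r["readable"] for r in rows if r["character"] == character]
            # once readable, readable at every darker level
            first = flags.index(True)
            assert all(flags[first:])

    def test_unreadable_grid_returns_none(self, layout):
        assert min_readable_odr("+", layout, odr_grid=[0.04, 0.08]) is None

    def test_character_outside_pair_rejected(self, layout):
        with pytest.raises(ValueError):
            min_readable_odr("Q", layout)
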