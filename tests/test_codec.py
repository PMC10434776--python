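"""Chromosome codec: one-hot encoding, strict/permissive decoding, interval maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hudopt import codec
from hudopt.errors import ConversionError, InvalidChromosomeError, InvalidDesignError

ROW1_CODE = "00101000010010000101011001"
ROW1_CHOICES = {
    "GM": 3, "GL": 1, "GF_frame": 2, "GA": 1,
    "GB": 2, "GC": 2, "GD": 2, "GE": 1, "GF_gear": 2,
}


def test_group_structure_totals_26_bits():
    assert codec.CHROMOSOME_LENGTH == 26
    widths = [g.bit_width for g in codec.GROUPS]
    assert widths == [4, 4, 4, 4, 2, 2, 2, 2, 2]
    assert all(g.arity == g.bit_width for g in codec.GROUPS)


def test_worked_example_roundtrip():
    design = codec.decode(ROW1_CODE)
    assert dict(design.choices) == ROW1_CHOICES
    assert codec.encode(design) == ROW1_CODE


def test_all_first_options_encode_to_leading_one_hot():
    design = codec.InterfaceDesign({g.name: 1 for g in codec.GROUPS})
    assert codec.encode(design) == "10001000100010001010101010"


def test_decode_encode_identity_exhaustive():
    """decode(encode(d)) == d over the entire 4^4 * 2^5 design space."""
    count = 0
    for design in codec.iter_valid_designs():
        assert codec.decode(codec.encode(design)) == design
        count += 1
    assert count == 8192


def test_valid_chromosomes_have_nine_set_bits():
    for i, design in enumerate(codec.iter_valid_designs()):
        if i % 311:  # sample the space, identity already checked exhaustively
            continue
        assert codec.encode(design).count("1") == 9


def test_strict_decode_rejects_non_one_hot_group():
    with pytest.raises(InvalidChromosomeError, match="G"):
        codec.decode("01100101111010101100110000", strict=True)
    with pytest.raises(InvalidChromosomeError, match="GM"):
        codec.decode("11" + "0" * 24, strict=True)


def test_permissive_decode_repairs_and_flags():
    rng = np.random.default_rng(7)
    design = codec.decode("01100101111010101100110000", strict=False, rng=rng)
    assert design.repaired_groups  # at least one group was repaired
    for name in design.repaired_groups:
        assert name in codec.GROUP_SLICES
    # repaired design is valid: re-encoding gives a one-hot string
    assert codec.is_valid_chromosome(codec.encode(design))


def test_malformed_strings_rejected():
    for bad in ("", "01", "2" * 26, "0" * 25, "0" * 27):
        with pytest.raises(InvalidChromosomeError):
            codec.decode(bad)


def test_invalid_design_errors():
    with pytest.raises(InvalidDesignError):
        codec.InterfaceDesign({"GM": 1})
    bad = {g.name: 1 for g in codec.GROUPS}
    bad["GB"] = 3  # out of range for a binary variable
    with pytest.raises(InvalidDesignError):
        codec.InterfaceDesign(bad)


@pytest.mark.parametrize(
    "code,value",
    [("1000", 0.5), ("0100", 1.5), ("0010", 2.5), ("0001", 3.5), ("10", 0.5), ("01", 1.5)],
)
def test_bits_to_float_midpoints(code, value):
    assert codec.bits_to_float(code) == value


@pytest.mark.parametrize(
    "x,width,code",
    [(0.5, 4, "1000"), (1.0, 4, "0100"), (3.999, 4, "0001"), (4.0, 4, "0001"), (2.0, 2, "01")],
)
def test_float_to_bits_interval_lookup(x, width, code):
    assert codec.float_to_bits(x, width) == code


def test_interval_conversions_are_mutual_inverses():
    for width in (2, 4):
        for k in range(width):
            code = "".join("1" if i == k else "0" for i in range(width))
            assert codec.float_to_bits(codec.bits_to_float(code), width) == code


def test_conversion_errors():
    with pytest.raises(ConversionError):
        codec.bits_to_float("1100")
    with pytest.raises(ConversionError):
        codec.bits_to_float("000")
    with pytest.raises(ConversionError):
        codec.float_to_bits(4.5, 4)
    with pytest.raises(ConversionError):
        codec.float_to_bits(-0.1, 2)


@st.composite
def designs(draw):
    return codec.InterfaceDesign(
        {g.name: draw(st.integers(1, g.arity)) for g in codec.GROUPS}
    )


@settings(max_examples=50, derandomize=True)
@given(designs())
def test_roundtrip_property(design):
    code = codec.encode(design)
    assert codec.is_valid_chromosome(code)
    assert codec.decode(code) == design


@settings(max_examples=50, derandomize=True)
@given(st.floats(0.0, 4.0, allow_nan=False))
def test_float_to_bits_total_on_range(x):
    code = codec.float_to_bits(x, 4)
    lo = code.index("1")
    assert lo <= x <= lo + 1 or (x == lo + 1)  # half-open, last closed
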