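"""One-hot chromosome codec for AR-HUD interface designs.

An interface design is a choice of nine discrete variables: main color
(GM), module arrangement (GL), frame shape (GF_frame) and information
font (GA) each have four options; the five module variants (GB navigation,
GC speed indicator, GD speed table, GE driving state, GF_gear gear status)
each have two.  A design is serialized as a 26-character bit-string: the
concatenation of one one-hot group per variable (4+4+4+4+2+2+2+2+2 bits),
option ``k`` of a group setting bit ``k``.

The genetic machinery occasionally needs a continuous view of a group:
each one-hot code is identified with a unit interval on a [0, arity]
axis (4-bit codes ``1000``/``0100``/``0010``/``0001`` map to [0,1) .. [3,4],
2-bit codes ``10``/``01`` to [0,1) and [1,2]).  :func:`bits_to_float`
returns the interval midpoint; :func:`float_to_bits` inverts it with
left-closed/right-open intervals (the last interval closed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ConversionError, InvalidChromosomeError, InvalidDesignError

__all__ = [
    "CHROMOSOME_LENGTH",
    "DesignVariableSpec",
    "GROUPS",
    "GROUP_SLICES",
    "InterfaceDesign",
    "encode",
    "decode",
    "bits_to_float",
    "float_to_bits",
    "is_valid_chromosome",
    "iter_valid_designs",
    "codes_to_matrix",
]


@dataclass(frozen=True)
class DesignVariableSpec:
    """One categorical design variable and its one-hot group.

    ``option_labels`` are carried as metadata only; the encoding depends
    solely on the option index.
    """

    name: str
    arity: int
    option_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.arity not in (2, 4):
            raise ValueError(f"arity must be 2 or 4, got {self.arity}")
        if self.option_labels and len(self.option_labels) != self.arity:
            raise ValueError("option_labels length must equal arity")

    @property
    def bit_width(self) -> int:
        return self.arity


#: Fixed group order; total bit width is 26.
GROUPS: tuple[DesignVariableSpec, ...] = (
    DesignVariableSpec("GM", 4, ("#2979FF", "#FE0000", "#4ADE80", "#F26D21")),
    DesignVariableSpec("GL", 4, ("arrangement-1", "arrangement-2", "arrangement-3", "arrangement-4")),
    DesignVariableSpec("GF_frame", 4, ("frame-1", "frame-2", "frame-3", "frame-4")),
    DesignVariableSpec("GA", 4, ("Roboto", "Avenir Next", "Burlingame", "Tipperary")),
    DesignVariableSpec("GB", 2, ("navigation-1", "navigation-2")),
    DesignVariableSpec("GC", 2, ("speed-indicator-1", "speed-indicator-2")),
    DesignVariableSpec("GD", 2, ("speed-table-1", "speed-table-2")),
    DesignVariableSpec("GE", 2, ("driving-state-1", "driving-state-2")),
    DesignVariableSpec("GF_gear", 2, ("gear-status-1", "gear-status-2")),
)

CHROMOSOME_LENGTH = sum(g.bit_width for g in GROUPS)
assert CHROMOSOME_LENGTH == 26

#: Bit slice of each group within the 26-bit string, in group order.
GROUP_SLICES: dict[str, slice] = {}
_off = 0
for _g in GROUPS:
    GROUP_SLICES[_g.name] = slice(_off, _off + _g.bit_width)
    _off += _g.bit_width
del _off, _g

_GROUP_BY_NAME = {g.name: g for g in GROUPS}


@dataclass(frozen=True)
class InterfaceDesign:
    """A concrete interface design: one 1-based option index per variable.

    ``repaired_groups`` records which groups were not one-hot in the
    source bit-string and had to be resolved during permissive decoding.
    """

    choices: Mapping[str, int]
    repaired_groups: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        names = set(self.choices)
        expected = set(_GROUP_BY_NAME)
        if names != expected:
            raise InvalidDesignError(
                f"design must choose exactly the nine variables; "
                f"missing={sorted(expected - names)}, unknown={sorted(names - expected)}"
            )
        for name, idx in self.choices.items():
            arity = _GROUP_BY_NAME[name].arity
            if not (isinstance(idx, (int, np.integer)) and 1 <= idx <= arity):
                raise InvalidDesignError(
                    f"option index for {name} must be in 1..{arity}, got {idx!r}"
                )

    def __getitem__(self, name: str) -> int:
        return int(self.choices[name])


def _check_bits(bits: str) -> str:
    if not isinstance(bits, str) or len(bits) != CHROMOSOME_LENGTH or set(bits) - {"0", "1"}:
        raise InvalidChromosomeError(
            f"chromosome must be a {CHROMOSOME_LENGTH}-character string over {{0,1}}, got {bits!r}"
        )
    return bits


def encode(design: InterfaceDesign) -> str:
    """Encode a design as its 26-bit one-hot chromosome string."""
    parts = []
    for g in GROUPS:
        idx = design[g.name]
        parts.append("".join("1" if k == idx - 1 else "0" for k in range(g.bit_width)))
    return "".join(parts)


def decode(
    bits: str,
    strict: bool = True,
    rng: np.random.Generator | None = None,
) -> InterfaceDesign:
    """Decode a 26-bit string to an :class:`InterfaceDesign`.

    In strict mode every group must be one-hot; a violation raises
    :class:`InvalidChromosomeError` naming the offending group.  In
    permissive mode a non-one-hot group is resolved by the same uniform
    repair rule the genetic operators use (a uniformly chosen set bit,
    or a uniformly chosen option if no bit is set) and listed in the
    result's ``repaired_groups``.
    """
    _check_bits(bits)
    if rng is None:
        rng = np.random.default_rng(0)
    choices: dict[str, int] = {}
    repaired: list[str] = []
    for g in GROUPS:
        code = bits[GROUP_SLICES[g.name]]
        ones = [i for i, c in enumerate(code) if c == "1"]
        if len(ones) == 1:
            choices[g.name] = ones[0] + 1
        elif strict:
            raise InvalidChromosomeError(
                f"group {g.name} = {code!r} is not one-hot"
            )
        else:
            repaired.append(g.name)
            pool = ones if ones else list(range(g.bit_width))
            choices[g.name] = int(rng.choice(pool)) + 1
    return InterfaceDesign(choices, tuple(repaired))


def is_valid_chromosome(bits: str) -> bool:
    """True iff every group of ``bits`` is one-hot."""
    try:
        _check_bits(bits)
    except InvalidChromosomeError:
        return False
    return all(bits[GROUP_SLICES[g.name]].count("1") == 1 for g in GROUPS)


def iter_valid_designs() -> Iterable[InterfaceDesign]:
    """Yield all 4^4 * 2^5 = 8192 valid designs in lexicographic order."""
    import itertools

    for combo in itertools.product(*(range(1, g.arity + 1) for g in GROUPS)):
        yield InterfaceDesign(dict(zip((g.name for g in GROUPS), combo)))


def bits_to_float(code: str) -> float:
    """Map a defined one-hot code to the midpoint of its unit interval."""
    if not isinstance(code, str) or len(code) not in (2, 4) or set(code) - {"0", "1"}:
        raise ConversionError(f"code must be a 2- or 4-bit binary string, got {code!r}")
    if code.count("1") != 1:
        raise ConversionError(f"code {code!r} is not a defined one-hot pattern")
    return code.index("1") + 0.5


def float_to_bits(x: float, width: int) -> str:
    """Inverse interval lookup: place ``x`` in its unit interval.

    Intervals are [k, k+1) for k < width-1 and [width-1, width] for the
    last, so the map is total on [0, width].
    """
    if width not in (2, 4):
        raise ConversionError(f"width must be 2 or 4, got {width}")
    if not np.isfinite(x) or x < 0 or x > width:
        raise ConversionError(f"value {x!r} outside [0, {width}]")
    k = min(int(np.floor(x)), width - 1)
    return "".join("1" if i == k else "0" for i in range(width))


def codes_to_matrix(codes: Iterable[str]) -> np.ndarray:
    """Stack bit-strings into a float (n, 26) 0/1 feature matrix.

    Raw bits are used as features directly; codes need not be one-hot
    (the printed training table itself contains non-one-hot rows).
    """
    rows = []
    for c in codes:
        _check_bits(c)
        rows.append([1.0 if ch == "1" else 0.0 for ch in c])
    return np.asarray(rows, dtype=float)
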