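"""Exception hierarchy shared across the package."""


class HudoptError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(HudoptError):
    """A design names an unknown variable or an out-of-range option."""


class InvalidChromosomeError(HudoptError):
    """A bit-string violates the chromosome contract (length or one-hot)."""


class ConversionError(HudoptError):
    """A binary/float interval conversion received an undefined input."""


class CorruptedFixtureError(HudoptError):
    """A packaged data table failed its checksum or row-count validation."""


class DegenerateInputError(HudoptError):
    """A statistic was requested on data with no variance."""


class DegenerateMapError(HudoptError):
    """An importance map is constant or carries zero mass."""


class ConfigError(HudoptError):
    """An optimizer or model configuration violates its invariants."""
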