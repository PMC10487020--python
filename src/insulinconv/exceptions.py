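"""Exception taxonomy shared across the package.

The distinction between a range refusal and a missing conversion model is
load-bearing for callers (and maps to distinct CLI exit codes), so both get
dedicated classes instead of a generic ValueError.
"""


class InsulinConvError(Exception):
    """Base class for all package errors."""


class ValidationError(InsulinConvError, ValueError):
    """Malformed input: non-finite values, bad specs, schema violations."""


class DegenerateDataError(InsulinConvError, ValueError):
    """Training data cannot support a fit (constant predictor, too few samples)."""


class RangeError(InsulinConvError, ValueError):
    """Requested conversion lies outside the model's supported input range."""

    def __init__(self, value: float, input_min: float, input_cap: float,
                 from_assay: str | None = None, to_assay: str | None = None):
        self.value = value
        self.input_min = input_min
        self.input_cap = input_cap
        self.from_assay = from_assay
        self.to_assay = to_assay
        pair = f" for {from_assay}->{to_assay}" if from_assay and to_assay else ""
        super().__init__(
            f"value {value:g} uIU/mL is out of supported range{pair}; "
            f"allowed range is [{input_min:g}, {input_cap:g}] uIU/mL"
        )


class PairUnavailableError(InsulinConvError, KeyError):
    """No fitted model exists for the requested directed assay pair."""

    def __init__(self, from_assay: str, to_assay: str):
        self.from_assay = from_assay
        self.to_assay = to_assay
        super().__init__(f"pair unavailable: no conversion model {from_assay}->{to_assay}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class ChainingError(InsulinConvError, ValueError):
    """Chained conversion impossible (no path, hop out of range, or refused)."""


class BundleError(InsulinConvError, ValueError):
    """Model bundle cannot be read (schema or version mismatch)."""
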