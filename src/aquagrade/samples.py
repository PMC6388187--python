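"""Well samples: one monitoring well's indicator -> concentration mapping."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import IncompleteSampleError, InputDataError


@dataclass(frozen=True)
class WellSample:
    """A single well's measured concentrations.

    Values are in the indicator's registered unit (mg/L for everything except
    the dimensionless pH and EC in uS/cm).  All values must be finite and
    nonnegative; pH, when present, must lie in the open interval (0, 14).
    """

    well_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, value in self.values.items():
            if value is None or not math.isfinite(value):
                raise InputDataError(
                    f"well {self.well_id!r}: non-finite value for {code!r}"
                )
            if code == "pH":
                if not 0.0 < value < 14.0:
                    raise InputDataError(
                        f"well {self.well_id!r}: pH {value} outside (0, 14)"
                    )
            elif value < 0:
                raise InputDataError(
                    f"well {self.well_id!r}: negative concentration "
                    f"{value} for {code!r}"
                )

    def __getitem__(self, code: str) -> float:
        try:
            return self.values[code]
        except KeyError:
            raise IncompleteSampleError(
                f"well {self.well_id!r} has no value for indicator {code!r}"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def require(self, codes) -> None:
        """Raise unless every indicator in *codes* is present."""
        missing = [c for c in codes if c not in self.values]
        if missing:
            raise IncompleteSampleError(
                f"well {self.well_id!r} is missing indicators: {missing}"
            )
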