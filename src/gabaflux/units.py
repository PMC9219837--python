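"""Small unit conversions used when relating model fluxes to culture data."""

from __future__ import annotations

__all__ = ["cdw_from_od", "OD_TO_CDW"]

#: Empirical conversion factor, g cell dry weight per liter per OD600 unit.
OD_TO_CDW = 0.27


def cdw_from_od(od600: float) -> float:
    """Convert an OD600 reading to cell dry weight (g/L): CDW = 0.27 x OD600."""
    if od600 < 0:
        raise ValueError(f"OD600 must be >= 0, got {od600}")
    return OD_TO_CDW * od600
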