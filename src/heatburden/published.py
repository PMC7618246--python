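"""Published central estimates of the 2023 global heatwave mortality burden.

These are the printed point estimates (excess deaths and excess deaths
attributable to human-induced climate change, by continent and sub-region)
from the published global assessment whose modelling framework this package
re-implements.  They are *inputs* to the proportion arithmetic — the package
recomputes regional shares and attributable proportions from them — never
outputs of this package.
"""

from __future__ import annotations

# excess deaths in 2023 (central estimates)
EXCESS_DEATHS: dict[str, float] = {
    "Africa": 2_881,
    "Americas": 23_467,
    "Asia": 85_611,
    "Europe": 66_443,
    "Oceania": 83,
}

GLOBAL_EXCESS_DEATHS: float = 178_486

# excess deaths attributable to human-induced climate change, with the
# corresponding total excess deaths of the same unit
ATTRIBUTABLE: dict[str, tuple[float, float]] = {
    # unit: (attributable deaths, excess deaths)
    "Global": (96_900, 178_486),
    "Southern Europe": (12_338, 19_522),
    "Eastern Europe": (5_563, 30_180),
    "Northern America": (9_666, 15_031),
}
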