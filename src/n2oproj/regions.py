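"""Region labels and default nitrogen-use-efficiency settings.

Eighteen agricultural subregions; countries are grouped under exactly one
region.  OECD membership controls the default target year of NUE policies.
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = (
    "BRA", "CAM", "CAN", "CAS", "CHN", "EQAF", "EU", "KAJ", "MIDE",
    "NAF", "NSA", "OCE", "RUS", "SAF", "SAS", "SEAS", "SSA", "USA",
)

OECD_REGIONS: frozenset[str] = frozenset({"EU", "USA", "CAN", "OCE", "KAJ"})

#: Default (nue_2010, nue_target) per region.  Targets: 0.75 for the EU and
#: USA, 0.60 for China and much of Asia, 0.70 elsewhere.
REGION_NUE: dict[str, tuple[float, float]] = {}
for _r in REGIONS:
    if _r in ("EU", "USA"):
        REGION_NUE[_r] = (0.68, 0.75)
    elif _r in ("CHN",):
        REGION_NUE[_r] = (0.35, 0.60)
    elif _r in ("SAS", "SEAS", "CAS", "KAJ"):
        REGION_NUE[_r] = (0.45, 0.60)
    else:
        REGION_NUE[_r] = (0.50, 0.70)

#: Default annual crop-N demand growth rate per region (yr^-1).
REGION_DEMAND_GROWTH: dict[str, float] = {
    r: (0.020 if r in ("EQAF", "NAF", "SAF", "SAS") else 0.010) for r in REGIONS
}


def is_oecd(region: str) -> bool:
    return region in OECD_REGIONS
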