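"""Dissected-keel damage scoring: codes, extent recoding, frequencies.

The dissected keel is divided into three parts (cranial, middle,
caudal).  For each damage type (deviation, fracture callus formation)
the protocol records:

* a size / count variable — deviation size {0: none, 1: <0.5 cm,
  2: >=0.5 cm}; fracture count {0..4} where 4 means ">= four" (a
  right-censored category); callus size {0, 1, 2};
* a localization code {0..7} encoding which subset of the three parts
  is affected (1 caudal, 2 middle, 3 cranial, 4 caudal+middle,
  5 middle+cranial, 6 caudal+cranial, 7 all three);
* a derived extent score {0..3} — the number of affected thirds.

Two veterinary operators scored the keels; ``operator`` is carried as a
mandatory covariate because every downstream regression adjusts for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FRACTURE_CENSOR_POINT = 4

#: localization code -> set of affected parts
_LOC_PARTS = {
    0: frozenset(),
    1: frozenset({"caudal"}),
    2: frozenset({"middle"}),
    3: frozenset({"cranial"}),
    4: frozenset({"caudal", "middle"}),
    5: frozenset({"middle", "cranial"}),
    6: frozenset({"caudal", "cranial"}),
    7: frozenset({"caudal", "middle", "cranial"}),
}

ORDINAL_VARIABLES = {
    "deviation_size": (0, 1, 2),
    "deviation_loc": tuple(range(8)),
    "deviation_extent": (0, 1, 2, 3),
    "fracture_count": (0, 1, 2, 3, 4),
    "fracture_loc": tuple(range(8)),
    "fracture_extent": (0, 1, 2, 3),
    "callus_size": (0, 1, 2),
    "callus_loc": tuple(range(8)),
    "callus_extent": (0, 1, 2, 3),
}

#: variables whose positive value defines "damage present" per type
_PRESENCE = {
    "deviation": "deviation_size",
    "fracture": "fracture_count",
    "callus": "callus_size",
}


def localization_to_extent(loc_code: int) -> int:
    """Number of keel thirds affected by the damage at this code.

    Score 1 when the damage sits in one third, 2 when it extends to two
    thirds, 3 when it covers all parts; 0 means no damage.
    """
    if loc_code not in _LOC_PARTS:
        raise ValueError(f"localization code must be in 0..7, got {loc_code}")
    return len(_LOC_PARTS[loc_code])


@dataclass
class KeelScore:
    """One bird's dissected-keel scoring record."""

    bird_id: str
    operator: str
    deviation_size: int = 0
    deviation_loc: int = 0
    fracture_count: int = 0
    fracture_censored: bool = False
    fracture_loc: int = 0
    callus_size: int = 0
    callus_loc: int = 0
    keel_length_cm: float | None = None
    keel_mid_depth_cm: float | None = None
    laying_status: bool | None = None
    deviation_extent: int = field(init=False)
    fracture_extent: int = field(init=False)
    callus_extent: int = field(init=False)

    def __post_init__(self) -> None:
        for prefix, size_name in (("deviation", "deviation_size"),
                                  ("fracture", "fracture_count"),
                                  ("callus", "callus_size")):
            loc = getattr(self, f"{prefix}_loc")
            size = getattr(self, size_name)
            if loc not in _LOC_PARTS:
                raise ValueError(
                    f"{self.bird_id}: {prefix}_loc must be in 0..7, got {loc}")
            if (loc == 0) != (size == 0):
                raise ValueError(
                    f"{self.bird_id}: {prefix}_loc={loc} inconsistent with "
                    f"{size_name}={size} (loc 0 iff no damage)")
        if not 0 <= self.fracture_count <= FRACTURE_CENSOR_POINT:
            raise ValueError(
                f"{self.bird_id}: fracture_count must be 0..4, "
                f"got {self.fracture_count}")
        if self.fracture_censored and self.fracture_count != FRACTURE_CENSOR_POINT:
            raise ValueError(
                f"{self.bird_id}: censored flag only valid at count "
                f"{FRACTURE_CENSOR_POINT}")
        self.deviation_extent = localization_to_extent(self.deviation_loc)
        self.fracture_extent = localization_to_extent(self.fracture_loc)
        self.callus_extent = localization_to_extent(self.callus_loc)

    @property
    def any_damage(self) -> bool:
        """Headline damage definition: any deviation or fracture."""
        return self.deviation_size > 0 or self.fracture_count > 0


def _values(scores, variable: str) -> list[int]:
    if variable not in ORDINAL_VARIABLES:
        raise ValueError(
            f"unknown variable {variable!r}; valid: "
            f"{sorted(ORDINAL_VARIABLES)}")
    return [getattr(s, variable) for s in scores]


def frequency_table(scores, variable: str) -> dict[int, float]:
    """Per-category proportions for one scoring variable.

    All defined categories are reported, including empty ones;
    proportions sum to 1.
    """
    if not scores:
        raise ValueError("empty score list")
    vals = _values(scores, variable)
    n = len(vals)
    return {c: vals.count(c) / n for c in ORDINAL_VARIABLES[variable]}


def co_frequency(scores, a: str, b: str) -> float:
    """Proportion of birds with damage (value > 0) on both variables."""
    if not scores:
        raise ValueError("empty score list")
    va, vb = _values(scores, a), _values(scores, b)
    return sum(1 for x, y in zip(va, vb) if x > 0 and y > 0) / len(va)


def damage_prevalence(scores) -> float:
    """Proportion of keels with any deviation or fracture."""
    if not scores:
        raise ValueError("empty score list")
    return sum(s.any_damage for s in scores) / len(scores)


def part_frequency(scores, damage: str) -> dict[str, float]:
    """Proportion of birds whose damage touches each keel part."""
    if damage not in _PRESENCE:
        raise ValueError(f"damage must be one of {sorted(_PRESENCE)}")
    if not scores:
        raise ValueError("empty score list")
    out = {"caudal": 0, "middle": 0, "cranial": 0}
    for s in scores:
        for part in _LOC_PARTS[getattr(s, f"{damage}_loc")]:
            out[part] += 1
    n = len(scores)
    return {k: v / n for k, v in out.items()}
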