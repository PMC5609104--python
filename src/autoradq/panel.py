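"""Receptor panel and cortical-area catalogue for the synthetic study design.

The study design mirrors a whole-cortex multi-receptor survey: 15 receptor
types of six transmitter systems measured in 44 iso- and periallocortical
areas of 3 postmortem brains, with every density resolved into the
supragranular (layers I-III), granular (layer IV) and infragranular
(layers V-VI) strata.

Laminar classes
---------------
``canonical``
    sg > g > ig in every area (the majority pattern).
``infragranular_peak``
    ig is the laminar maximum in every area (kainate).
``granular_peak``
    g is the laminar maximum in primary sensory areas (alpha4beta2, M2);
    outside those areas the receptor follows its base ratios.
``custom``
    receptor-specific ratios with no ordering guarantee (alpha1, 5-HT1A,
    which invert parts of the canonical sequence in some areas).

Default base densities (fmol/mg protein) respect the magnitude hierarchy of
the field: ionotropic glutamate and GABA receptors sit one to two orders of
magnitude above the modulatory aminergic/cholinergic receptors.  Exact
ratios are free parameters of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL = "canonical"
INFRAGRANULAR_PEAK = "infragranular_peak"
GRANULAR_PEAK = "granular_peak"
CUSTOM = "custom"

STRATA = ("sg", "g", "ig")

#: Fixed receptor sequence shared by all fingerprints of a collection.
RECEPTOR_ORDER = (
    "AMPA", "NMDA", "kainate",
    "GABAA", "GABAA/BZ", "GABAB",
    "M1", "M2", "M3", "alpha4beta2",
    "alpha1", "alpha2",
    "5-HT1A", "5-HT2", "D1",
)


@dataclass(frozen=True)
class ReceptorSpec:
    """Laminar base densities of one receptor type.

    ``base`` maps stratum -> density (fmol/mg protein) in a generic area;
    ``sensory_base`` (optional) replaces it in primary sensory areas, which
    is how the granular-peak exception of alpha4beta2 / M2 is expressed.
    """

    name: str
    laminar_type: str
    base: dict[str, float]
    sensory_base: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for d in (self.base, self.sensory_base):
            if d is None:
                continue
            unknown = set(d) - set(STRATA)
            if unknown:
                raise ValueError(f"{self.name}: unknown stratum label(s) {sorted(unknown)}")
            if set(d) != set(STRATA):
                raise ValueError(f"{self.name}: base densities must cover sg, g, ig")
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"{self.name}: base densities must be > 0")
        if self.laminar_type == CANONICAL:
            b = self.base
            if not (b["sg"] > b["g"] > b["ig"]):
                raise ValueError(f"{self.name}: canonical receptor needs sg > g > ig")
        if self.laminar_type == INFRAGRANULAR_PEAK:
            b = self.base
            if not (b["ig"] > b["sg"] and b["ig"] > b["g"]):
                raise ValueError(f"{self.name}: infragranular-peak receptor needs ig max")
        if self.laminar_type == GRANULAR_PEAK:
            sb = self.sensory_base
            if sb is None or not (sb["g"] > sb["sg"] and sb["g"] > sb["ig"]):
                raise ValueError(
                    f"{self.name}: granular-peak receptor needs sensory_base with g max")

    def densities(self, primary_sensory: bool) -> dict[str, float]:
        if primary_sensory and self.sensory_base is not None:
            return self.sensory_base
        return self.base


@dataclass(frozen=True)
class AreaSpec:
    """One cortical area: identity plus laminar-geometry flags.

    ``border_fractions`` are the cortical-depth fractions of the sg/g and
    g/ig borders (granular areas).  Agranular areas instead carry the depth
    fraction of the lower border of layer III; their nominal layer IV is the
    3%-of-depth stripe below that border.
    """

    name: str
    primary_sensory: bool = False
    agranular: bool = False
    border_fractions: tuple[float, float] = (0.55, 0.70)
    layer3_lower_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.agranular:
            f = self.layer3_lower_fraction
            if not (0.0 < f and f + 0.03 < 1.0):
                raise ValueError(f"{self.name}: layer3_lower_fraction out of range")
        else:
            f1, f2 = self.border_fractions
            if not (0.0 < f1 < f2 < 1.0):
                raise ValueError(f"{self.name}: need 0 < f1 < f2 < 1")

    def strata_bounds(self) -> tuple[float, float]:
        """(f1, f2) depth fractions actually used to cut the profile."""
        if self.agranular:
            return (self.layer3_lower_fraction, self.layer3_lower_fraction + 0.03)
        return self.border_fractions


def default_receptors() -> list[ReceptorSpec]:
    """The 15-receptor panel with its laminar classes and magnitude hierarchy."""
    def r(name, kind, sg, g, ig, sensory=None):
        base = {"sg": sg, "g": g, "ig": ig}
        sb = None
        if sensory is not None:
            sb = {"sg": sensory[0], "g": sensory[1], "ig": sensory[2]}
        return ReceptorSpec(name, kind, base, sb)

    return [
        r("AMPA", CANONICAL, 620.0, 470.0, 350.0),
        r("NMDA", CANONICAL, 1300.0, 1150.0, 700.0),      # dense in sg and g
        r("kainate", INFRAGRANULAR_PEAK, 400.0, 340.0, 640.0),
        r("GABAA", CANONICAL, 1500.0, 1400.0, 650.0),     # high III-IV, low V-VI
        r("GABAA/BZ", CANONICAL, 1800.0, 1700.0, 800.0),  # bilaminar, ig lowest
        r("GABAB", CANONICAL, 1400.0, 900.0, 600.0),
        r("M1", CANONICAL, 750.0, 550.0, 400.0),
        r("M2", GRANULAR_PEAK, 260.0, 360.0, 180.0, sensory=(280.0, 500.0, 200.0)),
        r("M3", CANONICAL, 520.0, 400.0, 300.0),
        r("alpha4beta2", GRANULAR_PEAK, 180.0, 130.0, 100.0, sensory=(200.0, 300.0, 120.0)),
        r("alpha1", CUSTOM, 480.0, 240.0, 380.0),         # granular minimum
        r("alpha2", CANONICAL, 340.0, 250.0, 180.0),
        r("5-HT1A", CUSTOM, 520.0, 120.0, 240.0),         # sg far highest, g lowest
        r("5-HT2", CANONICAL, 480.0, 440.0, 240.0),       # two upper bands, low V-VI
        r("D1", CANONICAL, 220.0, 160.0, 120.0),
    ]


#: the 44 surveyed areas; primary sensory = V1, 3b, 41; agranular = 4, 6, 24.
_AREA_NAMES = (
    "V1", "V2d", "V2v", "V3d", "V3A", "V3v", "V4v", "FG1", "FG2",
    "3a", "3b", "1", "2",
    "41", "42", "22",
    "4", "6",
    "24", "23", "31", "32",
    "44", "45",
    "8", "9", "10L", "10M", "11", "46", "47",
    "5L", "5M", "PFt", "PFm", "PGa", "PGp",
    "37L", "37M", "37B",
    "20", "21", "36", "38",
)
_PRIMARY_SENSORY = {"V1", "3b", "41"}
_AGRANULAR = {"4", "6", "24"}


def default_areas() -> list[AreaSpec]:
    """Catalogue of the 44 areas of the full study design."""
    return [AreaSpec(name,
                     primary_sensory=name in _PRIMARY_SENSORY,
                     agranular=name in _AGRANULAR)
            for name in _AREA_NAMES]


def granular_areas() -> list[AreaSpec]:
    """The 41 areas with a cytoarchitectonically visible layer IV."""
    return [a for a in default_areas() if not a.agranular]


def demo_areas() -> list[AreaSpec]:
    """Reduced 8-area catalogue for fast tests: 2 primary sensory, 1 agranular."""
    keep = ("V1", "V2v", "3b", "1", "41", "4", "PGp", "10L")
    by_name = {a.name: a for a in default_areas()}
    return [by_name[k] for k in keep]


def demo_receptors() -> list[ReceptorSpec]:
    """Reduced 6-receptor panel covering every laminar class."""
    keep = ("AMPA", "GABAA", "kainate", "M2", "alpha4beta2", "5-HT1A")
    by_name = {r.name: r for r in default_receptors()}
    return [by_name[k] for k in keep]
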