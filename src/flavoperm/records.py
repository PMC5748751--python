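"""Domain record types for the Caco-2 flavonoid permeability study.

The study measures bidirectional transport of 30 flavonoids across a Caco-2
monolayer. Each compound carries five kinds of information, cross-linked by
an integer compound id:

* its structure summary (subclass core plus a substituent map),
* bidirectional apparent permeability (Papp, cm/s) with an efflux ratio,
* cellular accumulation per transport direction (umol per g protein),
* solvent-stability / mass-balance quality-control values, and
* molecular descriptors with the measured -log10(Papp A->B) response used
  for structure-permeability modelling.

Papp values are stored internally in cm/s; delimited files and reports use
the conventional 1e-6 cm/s display scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class Subclass(str, Enum):
    """Flavonoid subclass defined by the C-ring core."""

    FLAVONE = "flavone"
    FLAVONOL = "flavonol"
    FLAVANONE = "flavanone"
    ISOFLAVONE = "isoflavone"
    CHALCONE = "chalcone"
    DIHYDROCHALCONE = "dihydrochalcone"


class Mechanism(str, Enum):
    """Transport mechanism class inferred from the efflux ratio."""

    PASSIVE = "passive"
    EFFLUX_IMPLICATED = "efflux_implicated"
    PREFERENTIAL_ABSORPTIVE = "preferential_absorptive"
    INDETERMINATE = "indeterminate"


class DirectionDiff(str, Enum):
    """Outcome of the A->B vs B->A accumulation t-test."""

    NS = "ns"
    P05 = "p<0.05"
    P01 = "p<0.01"
    UNEVALUABLE = "unevaluable"


class StabilityClass(str, Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    QUESTIONABLE = "questionable"
    UNKNOWN = "unknown"


class Split(str, Enum):
    TRAINING = "training"
    TEST = "test"
    EXCLUDED = "excluded"


#: Substituent position labels on the flavonoid skeleton (A/C ring then B ring).
POSITIONS = ("R3", "R5", "R6", "R7", "R8", "R2p", "R3p", "R4p", "R5p")

#: Substituent codes that denote a sugar moiety (see the structure-table footnote).
GLYCOSYL_CODES = frozenset({"Cglc", "Carb", "Orha", "ORG", "ONG", "NG"})

#: Canonical descriptor names used by the permeability model.
DESCRIPTOR_NAMES = ("QC3p", "E_sol", "SlogP_V3", "vsurf_ID1")

#: Cell literals treated as missing in delimited files.
MISSING_CODES = frozenset({"ND", "NT", "-"})


@dataclass(frozen=True)
class CompoundRecord:
    """Structure summary of one flavonoid."""

    compound_id: int
    name: str
    subclass: Subclass
    substituents: Mapping[str, str]
    is_glycoside: bool

    def __post_init__(self) -> None:
        missing = [p for p in POSITIONS if p not in self.substituents]
        if missing:
            raise ValueError(
                f"compound {self.compound_id}: missing substituent positions {missing}"
            )
        has_sugar = any(g in GLYCOSYL_CODES for g in self.substituents.values())
        if has_sugar != self.is_glycoside:
            raise ValueError(
                f"compound {self.compound_id}: is_glycoside={self.is_glycoside} "
                f"inconsistent with substituent map"
            )


@dataclass(frozen=True)
class TransportResult:
    """Bidirectional apparent permeability of one compound.

    ``papp_*`` fields are in cm/s. ``ratio_p`` is Papp(B->A)/Papp(A->B)
    recomputed from the means; ``ratio_p_printed`` preserves the value as
    published (which may differ in the last digit through rounding of the
    printed means).
    """

    compound_id: int
    papp_ab: float
    papp_ab_sd: float
    papp_ba: float
    papp_ba_sd: float
    ratio_p: float
    mechanism: Mechanism
    ratio_p_printed: float | None = None

    def __post_init__(self) -> None:
        for name in ("papp_ab", "papp_ab_sd", "papp_ba", "papp_ba_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"compound {self.compound_id}: {name} < 0")
        if self.papp_ab > 0 and self.papp_ba > 0:
            expected = self.papp_ba / self.papp_ab
            if abs(self.ratio_p - expected) > 0.005 * expected:
                raise ValueError(
                    f"compound {self.compound_id}: ratio_p {self.ratio_p} is not "
                    f"papp_ba/papp_ab ({expected:.6g}) within 0.5%"
                )


@dataclass(frozen=True)
class AccumulationResult:
    """Cellular accumulation (umol/g protein) per transport direction.

    ``None`` encodes a missing value; ``missing_code`` records whether the
    compound was not detected ("ND") or not tested ("NT"), which are distinct
    outcomes and both excluded from statistics.
    """

    compound_id: int
    ca_ab: float | None
    ca_ab_sd: float | None
    ca_ba: float | None
    ca_ba_sd: float | None
    ratio_c: float | None
    direction_diff: DirectionDiff
    missing_code: str | None = None
    ratio_c_printed: float | None = None

    def __post_init__(self) -> None:
        both = self.ca_ab is not None and self.ca_ba is not None
        if self.ratio_c is not None:
            if not both or self.ca_ab <= 0:
                raise ValueError(
                    f"compound {self.compound_id}: ratio_c present without both CA values"
                )
            expected = self.ca_ba / self.ca_ab
            if abs(self.ratio_c - expected) > 0.005 * expected:
                raise ValueError(
                    f"compound {self.compound_id}: ratio_c {self.ratio_c} is not "
                    f"ca_ba/ca_ab ({expected:.6g}) within 0.5%"
                )
        elif both and self.ca_ab > 0:
            raise ValueError(
                f"compound {self.compound_id}: ratio_c missing though both CA present"
            )


@dataclass(frozen=True)
class DescriptorSet:
    """Molecular descriptor values for one compound."""

    compound_id: int
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(
                    f"compound {self.compound_id}: descriptor {name} is not finite"
                )


@dataclass(frozen=True)
class PermeabilityObservation:
    """The modelling response: pPapp = -log10(Papp A->B in cm/s)."""

    compound_id: int
    ppapp_exp: float
    split: Split
    ppapp_pred_printed: float | None = None

    def __post_init__(self) -> None:
        if not self.ppapp_exp > 0:
            raise ValueError(
                f"compound {self.compound_id}: ppapp_exp must be positive"
            )


@dataclass(frozen=True)
class StabilityRecord:
    """Solvent stability and transport mass-balance of one compound."""

    compound_id: int
    relative_concentration: float | None
    recovery_ab: float | None = None
    recovery_ab_sd: float | None = None
    rsd_ab: float | None = None
    recovery_ba: float | None = None
    recovery_ba_sd: float | None = None
    rsd_ba: float | None = None
    stability_class: StabilityClass = StabilityClass.UNKNOWN

    def __post_init__(self) -> None:
        for name in (
            "relative_concentration",
            "recovery_ab",
            "recovery_ba",
            "rsd_ab",
            "rsd_ba",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"compound {self.compound_id}: {name} < 0")
        for direction in ("ab", "ba"):
            mean = getattr(self, f"recovery_{direction}")
            sd = getattr(self, f"recovery_{direction}_sd")
            rsd_v = getattr(self, f"rsd_{direction}")
            if mean and sd is not None and rsd_v is not None:
                expected = 100.0 * sd / mean
                # 1% relative, floored at 0.02 points + half-ulp of the
                # 2-decimal printed RSD for last-digit rounding
                if abs(rsd_v - expected) > max(0.01 * expected, 0.025):
                    raise ValueError(
                        f"compound {self.compound_id}: RSD {rsd_v} inconsistent "
                        f"with 100*SD/mean = {expected:.4f}"
                    )


@dataclass
class StudyDataset:
    """All record tables of one study, cross-linked by compound id."""

    compounds: dict[int, CompoundRecord] = field(default_factory=dict)
    transport: dict[int, TransportResult] = field(default_factory=dict)
    accumulation: dict[int, AccumulationResult] = field(default_factory=dict)
    stability: dict[int, StabilityRecord] = field(default_factory=dict)
    descriptors: dict[int, DescriptorSet] = field(default_factory=dict)
    observations: dict[int, PermeabilityObservation] = field(default_factory=dict)

    def validate_links(self) -> None:
        known = set(self.compounds)
        for table_name in ("transport", "accumulation", "stability", "descriptors", "observations"):
            unknown = set(getattr(self, table_name)) - known
            if unknown:
                raise ValueError(
                    f"{table_name} references unknown compound ids {sorted(unknown)}"
                )

    def training_ids(self) -> list[int]:
        return sorted(
            i for i, o in self.observations.items() if o.split is Split.TRAINING
        )

    def test_ids(self) -> list[int]:
        return sorted(i for i, o in self.observations.items() if o.split is Split.TEST)

    def glycoside_ids(self) -> list[int]:
        return sorted(i for i, c in self.compounds.items() if c.is_glycoside)


def papp_to_ppapp(papp: float) -> float:
    """Convert an apparent permeability (cm/s) to pPapp = -log10(Papp).

    Raises
    ------
    ValueError
        If ``papp`` is not strictly positive.
    """
    if papp <= 0:
        raise ValueError(f"papp must be > 0 to take -log10, got {papp}")
    return -math.log10(papp)


def ppapp_to_papp(ppapp: float) -> float:
    """Inverse of :func:`papp_to_ppapp`: returns Papp in cm/s."""
    return 10.0 ** (-ppapp)
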