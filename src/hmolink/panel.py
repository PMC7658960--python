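"""The 24-analyte HMO panel: structural classes and quantification limits.

Analytes are grouped into three structural classes used for class sums and
lactation-dynamics summaries:

* ``core`` — non-fucosylated neutral backbones (LNT, LNnT, Hex4HexNAc2, LNH)
  plus the two galactosyllactoses 3'GL and 6'GL, which are conventionally
  summed with the core class although they are not strictly core structures;
* ``fucosylated`` — every fucose-bearing analyte on the panel;
* ``sialylated`` — the sialic-acid-bearing analytes.

Limits of detection/quantification are method properties of the LC assay.
The published ones are the 2'FL LoQ (20 mg/L) and the 2'FL / LNFP-I LoDs
(3.9 and 2 mg/L); the remaining defaults are package assumptions at the
typical scale of the assay and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CORE_ANALYTES = ("LNT", "LNnT", "Hex4HexNAc2", "LNH", "3'GL", "6'GL")
FUCOSYLATED_ANALYTES = (
    "A-tetra", "2'FL", "LDFT", "3FL", "LNFP-I", "LNFP-II", "LNFP-III",
    "LNFP-V", "LNnFP-V", "LNnDFH", "LNDFH-I", "DFLNHa", "MFLNH-III",
)
SIALYLATED_ANALYTES = ("3'SL", "6'SL", "LSTb", "LSTc", "DSLNT")

ALL_ANALYTES = CORE_ANALYTES + FUCOSYLATED_ANALYTES + SIALYLATED_ANALYTES

#: Analytes whose synthesis requires active FUT2 (alpha-1,2-fucosylation).
FUT2_DEPENDENT = ("2'FL", "LNFP-I", "LDFT", "LNDFH-I", "DFLNHa", "A-tetra")

#: Analytes whose synthesis depends on FUT3 (alpha-1,3/4-fucosylation).
FUT3_DEPENDENT = ("LNFP-II", "3FL", "LNnDFH", "LNFP-III", "LNnFP-V")

_DEFAULT_LOQ = 10.0
_DEFAULT_LOD = 2.0

# published assay limits (mg/L); everything else uses the panel defaults
_KNOWN_LOQ = {"2'FL": 20.0}
_KNOWN_LOD = {"2'FL": 3.9, "LNFP-I": 2.0}


def _default_class_map() -> dict[str, str]:
    cmap: dict[str, str] = {}
    cmap.update({a: "core" for a in CORE_ANALYTES})
    cmap.update({a: "fucosylated" for a in FUCOSYLATED_ANALYTES})
    cmap.update({a: "sialylated" for a in SIALYLATED_ANALYTES})
    return cmap


def _default_loq_map() -> dict[str, float]:
    return {a: _KNOWN_LOQ.get(a, _DEFAULT_LOQ) for a in ALL_ANALYTES}


def _default_lod_map() -> dict[str, float]:
    return {a: _KNOWN_LOD.get(a, _DEFAULT_LOD) for a in ALL_ANALYTES}


@dataclass
class HMOPanel:
    """Analyte set with structural class map and quantification limits.

    Parameters
    ----------
    analytes : tuple of str
        Panel analyte names.
    class_map : dict
        analyte -> {"core", "fucosylated", "sialylated"}.
    loq_map, lod_map : dict
        Per-analyte limits of quantification / detection in mg/L
        (LoD <= LoQ wherever both are set).
    """

    analytes: tuple[str, ...] = ALL_ANALYTES
    class_map: dict[str, str] = field(default_factory=_default_class_map)
    loq_map: dict[str, float] = field(default_factory=_default_loq_map)
    lod_map: dict[str, float] = field(default_factory=_default_lod_map)

    def __post_init__(self) -> None:
        for a in self.analytes:
            if a not in self.class_map:
                raise ValueError(f"analyte {a!r} missing from class_map")
        for a, lod in self.lod_map.items():
            loq = self.loq_map.get(a)
            if loq is not None and lod > loq:
                raise ValueError(f"LoD > LoQ for analyte {a!r}")

    def members(self, hmo_class: str) -> tuple[str, ...]:
        """Analytes belonging to one structural class, in panel order."""
        return tuple(a for a in self.analytes if self.class_map[a] == hmo_class)

    def loq(self, analyte: str) -> float:
        return self.loq_map[analyte]

    def lod(self, analyte: str) -> float:
        return self.lod_map[analyte]

    def without_censoring(self) -> "HMOPanel":
        """Copy of the panel with all LoQ/LoD set to zero.

        Used by simulation protocols that study trend recovery free of
        left-censoring.
        """
        zeros = {a: 0.0 for a in self.analytes}
        return HMOPanel(self.analytes, dict(self.class_map), dict(zeros), dict(zeros))


DEFAULT_PANEL = HMOPanel()
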