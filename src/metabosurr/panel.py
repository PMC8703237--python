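"""Metabolite panel definitions.

A :class:`MetabolitePanel` names the markers that form the feature space of
every downstream model, assigns each marker to one biochemical class, and
carries an exclusion list for markers that should be dropped before modelling
(e.g. because they frequently fail to reach detection thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

MARKER_CLASSES = (
    "amino acids",
    "glycolysis-related",
    "ketone bodies",
    "fluid balance",
    "inflammation",
    "fatty acids",
    "lipoprotein lipids",
)

# Default 56-marker 1H-NMR panel: total lipid concentrations of lipoprotein
# subclasses, fatty-acid composition, and low-molecular-weight metabolites.
_DEFAULT_PANEL: dict[str, str] = {
    # amino acids (9)
    "ala": "amino acids",
    "gln": "amino acids",
    "gly": "amino acids",
    "his": "amino acids",
    "ile": "amino acids",
    "leu": "amino acids",
    "val": "amino acids",
    "phe": "amino acids",
    "tyr": "amino acids",
    # glycolysis-related (4)
    "glc": "glycolysis-related",
    "lac": "glycolysis-related",
    "cit": "glycolysis-related",
    "pyr": "glycolysis-related",
    # ketone bodies (2)
    "acace": "ketone bodies",
    "ace": "ketone bodies",
    # fluid balance (2)
    "alb": "fluid balance",
    "crea": "fluid balance",
    # inflammation (1)
    "gp": "inflammation",
    # fatty acids (12)
    "totfa": "fatty acids",
    "dha": "fatty acids",
    "la": "fatty acids",
    "faw3": "fatty acids",
    "faw6": "fatty acids",
    "mufa": "fatty acids",
    "pufa": "fatty acids",
    "sfa": "fatty acids",
    "unsat": "fatty acids",
    "totpg": "fatty acids",
    "totcho": "fatty acids",
    "apob_apoa1": "fatty acids",
    # lipoprotein lipid totals (26)
    "xxl_vldl_l": "lipoprotein lipids",
    "xl_vldl_l": "lipoprotein lipids",
    "l_vldl_l": "lipoprotein lipids",
    "m_vldl_l": "lipoprotein lipids",
    "s_vldl_l": "lipoprotein lipids",
    "xs_vldl_l": "lipoprotein lipids",
    "idl_l": "lipoprotein lipids",
    "l_ldl_l": "lipoprotein lipids",
    "m_ldl_l": "lipoprotein lipids",
    "s_ldl_l": "lipoprotein lipids",
    "xl_hdl_l": "lipoprotein lipids",
    "l_hdl_l": "lipoprotein lipids",
    "m_hdl_l": "lipoprotein lipids",
    "s_hdl_l": "lipoprotein lipids",
    "serum_c": "lipoprotein lipids",
    "vldl_c": "lipoprotein lipids",
    "ldl_c": "lipoprotein lipids",
    "hdl_c": "lipoprotein lipids",
    "hdl2_c": "lipoprotein lipids",
    "hdl3_c": "lipoprotein lipids",
    "serum_tg": "lipoprotein lipids",
    "vldl_tg": "lipoprotein lipids",
    "ldl_tg": "lipoprotein lipids",
    "hdl_tg": "lipoprotein lipids",
    "vldl_d": "lipoprotein lipids",
    "ldl_d": "lipoprotein lipids",
}


@dataclass(frozen=True)
class MetabolitePanel:
    """A named marker set with one biochemical class per marker.

    Parameters
    ----------
    classes:
        Mapping from marker name to its class label. Insertion order fixes
        the column order of every matrix built on this panel.
    exclusions:
        Marker names to drop when the panel is applied to a dataset.
    """

    classes: dict[str, str]
    exclusions: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = list(self.classes)
        if len(names) != len(set(names)):
            raise ValueError("panel marker names must be unique")
        bad = {c for c in self.classes.values()} - set(MARKER_CLASSES)
        if bad:
            raise ValueError(f"unknown marker classes: {sorted(bad)}")
        unknown = set(self.exclusions) - set(names)
        if unknown:
            raise ValueError(f"exclusions not in panel: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        """All marker names, in panel order (exclusions included)."""
        return list(self.classes)

    @property
    def retained(self) -> list[str]:
        """Marker names after applying the exclusion list, in panel order."""
        excl = set(self.exclusions)
        return [m for m in self.classes if m not in excl]

    def class_of(self, marker: str) -> str:
        return self.classes[marker]

    def markers_in_class(self, cls: str) -> list[str]:
        return [m for m, c in self.classes.items() if c == cls]

    def __len__(self) -> int:
        return len(self.classes)

    def with_exclusions(self, exclusions: list[str]) -> "MetabolitePanel":
        return MetabolitePanel(dict(self.classes), tuple(exclusions))


def default_panel(exclusions: tuple[str, ...] = ()) -> MetabolitePanel:
    """The default 56-marker panel of total lipids, fatty acids and
    low-molecular-weight metabolites."""
    return MetabolitePanel(dict(_DEFAULT_PANEL), tuple(exclusions))
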