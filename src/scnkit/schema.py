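"""Canonical morphometric feature schema.

The network nodes are 76 morphometric features: average cortical thickness
for the 31 Desikan-Killiany-Tourville (DKT) regions per hemisphere (62
features, mm) plus the volumes of 7 bilateral subcortical gray-matter
structures (14 features, mm^3).
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: The 31 cortical regions of the DKT protocol (per hemisphere).
DKT_CORTICAL_ROIS: tuple[str, ...] = (
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "transversetemporal",
    "insula",
)

#: Bilateral subcortical gray-matter structures (FreeSurfer aseg naming stem).
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
)

HEMISPHERES: tuple[str, ...] = ("lh", "rh")
SIDES: tuple[str, ...] = ("Left", "Right")


def _cortical_feature(hemi: str, roi: str) -> str:
    return f"{hemi}_{roi}_thickness"


def _subcortical_feature(side: str, structure: str) -> str:
    return f"{side}-{structure}"


@dataclass(frozen=True)
class FeatureSchema:
    """Registry of canonical feature names, ordering and units.

    Feature order is: all left-hemisphere thicknesses, all right-hemisphere
    thicknesses (DKT order), then Left/Right volume per subcortical
    structure. This ordering is the canonical node order of every network.
    """

    cortical_rois: tuple[str, ...] = DKT_CORTICAL_ROIS
    subcortical_structures: tuple[str, ...] = SUBCORTICAL_STRUCTURES
    hemispheres: tuple[str, ...] = HEMISPHERES
    sides: tuple[str, ...] = SIDES

    def __post_init__(self) -> None:
        names = self.feature_names
        if len(names) != len(set(names)):
            raise ValueError("feature names are not unique")

    @property
    def cortical_features(self) -> tuple[str, ...]:
        return tuple(
            _cortical_feature(h, r) for h in self.hemispheres for r in self.cortical_rois
        )

    @property
    def subcortical_features(self) -> tuple[str, ...]:
        return tuple(
            _subcortical_feature(s, st) for st in self.subcortical_structures for s in self.sides
        )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.cortical_features + self.subcortical_features

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def unit(self, feature: str) -> str:
        """Unit of a feature: ``mm`` for thickness, ``mm3`` for volume."""
        if feature in self.cortical_features:
            return "mm"
        if feature in self.subcortical_features:
            return "mm3"
        raise KeyError(f"unknown feature: {feature!r}")

    def is_volume(self, feature: str) -> bool:
        return self.unit(feature) == "mm3"

    def resolve(self, key: str) -> tuple[str, ...]:
        """Resolve a user key to canonical feature names.

        Accepts an exact feature name, a subcortical structure stem
        (e.g. ``"thalamus"`` -> both hemispheres), or a cortical ROI name
        (e.g. ``"precuneus"`` -> both hemispheres).
        """
        if key in self.feature_names:
            return (key,)
        low = key.lower()
        if low in (s.lower() for s in self.subcortical_structures):
            st = next(s for s in self.subcortical_structures if s.lower() == low)
            return tuple(_subcortical_feature(side, st) for side in self.sides)
        if low in self.cortical_rois:
            return tuple(_cortical_feature(h, low) for h in self.hemispheres)
        raise KeyError(f"cannot resolve {key!r} to any canonical feature")


DEFAULT_SCHEMA = FeatureSchema()
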