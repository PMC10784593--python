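"""Feature schema for regional brain morphometry.

The benchmark operates on 152 regional measures per subject: cortical
thickness and surface area for the 34 Desikan-Killiany regions in each
hemisphere (68 + 68 features) plus 16 subcortical volumes from the Aseg
segmentation (8 bilateral structures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

THICKNESS = "thickness"
SURFACE_AREA = "surface_area"
SUBCORTICAL_VOLUME = "subcortical_volume"

FEATURE_CLASSES = (THICKNESS, SURFACE_AREA, SUBCORTICAL_VOLUME)

#: 34 cortical regions of the Desikan-Killiany atlas (per hemisphere).
DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

#: 8 bilateral subcortical structures retained from the Aseg segmentation.
ASEG_STRUCTURES = (
    "lateral_ventricle", "thalamus", "caudate", "putamen",
    "pallidum", "hippocampus", "amygdala", "accumbens",
)

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature catalogue: name, measurement class and hemisphere.

    The canonical layout is 68 thickness features, then 68 surface-area
    features, then 16 subcortical volumes (152 in total).
    """

    names: tuple[str, ...]
    classes: tuple[str, ...]
    hemispheres: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not (len(self.names) == len(self.classes) == len(self.hemispheres)):
            raise ValueError("names, classes and hemispheres must align")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})
        if len(self._index) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self._index[name]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FEATURE_CLASSES}
        for c in self.classes:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def indices_for_class(self, cls: str) -> list[int]:
        return [i for i, c in enumerate(self.classes) if c == cls]

    def subset(self, subset: str) -> list[int]:
        """Column indices of a named feature subset.

        ``all``, ``thickness``, ``surface_area`` or ``subcortical``.
        """
        if subset == "all":
            return list(range(len(self.names)))
        key = {"thickness": THICKNESS, "surface_area": SURFACE_AREA,
               "subcortical": SUBCORTICAL_VOLUME}.get(subset)
        if key is None:
            raise ValueError(f"unknown feature subset {subset!r}")
        return self.indices_for_class(key)


def canonical_schema() -> FeatureSchema:
    """The 152-feature schema: 68 thickness + 68 surface area + 16 volumes."""
    names: list[str] = []
    classes: list[str] = []
    hemis: list[str] = []
    for cls, suffix in ((THICKNESS, "thick"), (SURFACE_AREA, "surf")):
        for hemi in HEMISPHERES:
            for region in DK_REGIONS:
                names.append(f"{hemi}_{region}_{suffix}")
                classes.append(cls)
                hemis.append(hemi)
    for hemi in HEMISPHERES:
        for structure in ASEG_STRUCTURES:
            names.append(f"{hemi}_{structure}_vol")
            classes.append(SUBCORTICAL_VOLUME)
            hemis.append(hemi)
    return FeatureSchema(tuple(names), tuple(classes), tuple(hemis))


def schema_from_names(names) -> FeatureSchema:
    """Reconstruct a schema from feature names following the canonical
    ``<hemi>_<region>_<thick|surf>`` / ``<hemi>_<structure>_vol`` convention.
    """
    canon = canonical_schema()
    classes = []
    hemis = []
    for name in names:
        try:
            i = canon.index_of(name)
        except KeyError:
            raise ValueError(f"unknown feature name: {name!r}") from None
        classes.append(canon.classes[i])
        hemis.append(canon.hemispheres[i])
    return FeatureSchema(tuple(names), tuple(classes), tuple(hemis))
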