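"""Catalog of the 98 coded Tree-Drawing Test features.

The Tree-Drawing Test (TDT) codes each drawing with binary presence/absence
indicators for 98 psychologically meaningful characteristics, grouped into 12
classes (overall layout, line quality, canopy shape, trunk, roots, ground,
attachments, ...).  The catalog fixes the canonical feature order used by every
other module: feature *i* of a coding matrix column always refers to entry *i*
of this catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# Class name -> ordered feature names.  Order (of classes and within classes)
# is the canonical column order of all coding matrices.
_CATALOG_SPEC: list[tuple[str, list[str]]] = [
    (
        "overall",
        [
            "huge tree",
            "small tree",
            "tree above",
            "tree below",
            "tree on the left",
            "tree on the right",
            "tilted trunk or crown",
            "cut at the edge of the tree and paper",
            "cut above",
            "cut on the left",
            "cut on the right",
            "cut below",
        ],
    ),
    (
        "line",
        [
            "thick lines",
            "light lines",
            "obvious differences in strength",
            "sloppy lines",
            "mainly short lines",
            "mainly long lines",
            "mainly trembling wavy lines",
        ],
    ),
    (
        "special mark",
        [
            "snakelike",
            "symmetrical",
        ],
    ),
    (
        "special tree type",
        [
            "dead tree",
            "simplified tree",
            "pine tree",
            "theme loss",
            "multiple trees",
        ],
    ),
    (
        "canopy",
        [
            "closed canopy",
            "open canopy",
            "zoned canopy",
            "large canopy",
            "small canopy",
            "squashed canopy",
            "full canopy",
            "emphasized canopy lines",
            "light canopy lines",
            "multi-layered canopy lines",
            "cloud-like canopy lines",
            "ringed canopy line",
            "quivering shaped canopy lines",
            "circular canopy lines",
            "black shadows in the canopy",
            "chaos in the canopy",
            "blank canopy",
            "detailed depicted canopy",
            "short wavy lines drawn in the canopy",
        ],
    ),
    (
        "branch",
        [
            "broken branches",
            "crossing branches",
            "vigorously growing branches",
            "drooping branches",
            "patchwork branches",
            "single-line branches",
            "parallel branches",
            "open branch ends",
            "sharp branch ends",
        ],
    ),
    (
        "leaf and flower",
        [
            "fruits or flowers in the canopy",
            "leaves",
            "fallen leaves",
        ],
    ),
    (
        "trunk",
        [
            "small trunk",
            "long trunk",
            "parallel trunk",
            "wide at the top and narrow at the bottom",
            "wide at the bottom of the trunk",
            "scars on the trunk",
            "black shadow on the trunk",
            "depiction of bark",
            "completely blank trunk",
            "emphasis on trunk edge lines",
            "light trunk edge lines",
            "trunk with small twigs",
        ],
    ),
    (
        "junction",
        [
            "trunk sealed at the top",
            "trunk open at the top",
            "trunk forms a 'M' shape at the top",
            "trunk sealed at the bottom",
            "trunk transitionally sealed at the bottom (drawing whisker-like roots)",
            "trunk open at the bottom",
            "trunk directly connects to the branches and the junction is hollow",
        ],
    ),
    (
        "root",
        [
            "drawn roots",
            "fibrous roots",
            "sharp roots",
            "crossing roots",
            "overly drawn roots",
            "exposed roots",
        ],
    ),
    (
        "ground",
        [
            "drawn ground line",
            "sloping ground line",
            "wavy ground line",
            "hilly ground line",
            "emphasized ground",
            "paper's base as ground line (only if depicted flowers and plants)",
            "ground line through the trunk",
        ],
    ),
    (
        "attachment",
        [
            "drawn attachments",
            "sun",
            "clouds",
            "flowers under the tree",
            "grass under the tree",
            "birds or bird's nests",
            "houses or people",
            "words",
            "wind and rain",
        ],
    ),
]

N_FEATURES = 98
N_CLASSES = 12


@dataclass(frozen=True)
class FeatureCatalog:
    """The ordered 98-feature / 12-class TDT coding scheme.

    Attributes
    ----------
    entries
        Ordered ``(feature_name, class_name)`` pairs; the canonical column
        order for coding matrices.
    classes
        The 12 class names, in catalog order.
    """

    entries: tuple[tuple[str, str], ...]
    classes: tuple[str, ...]
    _class_index: dict[str, list[int]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        idx: dict[str, list[int]] = {c: [] for c in self.classes}
        for i, (_, cls) in enumerate(self.entries):
            idx[cls].append(i)
        object.__setattr__(self, "_class_index", idx)

    @property
    def feature_names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def n_features(self) -> int:
        return len(self.entries)

    def class_of(self, feature_name: str) -> str:
        for name, cls in self.entries:
            if name == feature_name:
                return cls
        raise KeyError(feature_name)

    def features_in_class(self, class_name: str) -> list[str]:
        return [self.entries[i][0] for i in self.class_indices(class_name)]

    def class_indices(self, class_name: str) -> list[int]:
        """Column indices of a class's features, in catalog order."""
        if class_name not in self._class_index:
            raise KeyError(f"unknown feature class: {class_name!r}")
        return list(self._class_index[class_name])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature_name", "class_name"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_feature_catalog() -> FeatureCatalog:
    """Return the canonical 98-feature, 12-class TDT catalog."""
    entries = tuple(
        (name, cls) for cls, names in _CATALOG_SPEC for name in names
    )
    classes = tuple(cls for cls, _ in _CATALOG_SPEC)
    if len(entries) != N_FEATURES or len(classes) != N_CLASSES:  # pragma: no cover
        raise AssertionError("catalog definition corrupted")
    return FeatureCatalog(entries=entries, classes=classes)
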