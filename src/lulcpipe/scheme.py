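"""Land-cover class scheme and shared constants.

The pipeline works with eight general land-use/land-cover (LULC) classes.
Woody vegetation (mature forest plus shrubby secondary growth) is mapped as a
single spectral class and only later split temporally into ``forest`` and
``secondary`` — those two refined labels partition woody pixels in the final
map series. ``bare`` is carried through area bookkeeping but excluded from
trend and transition summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

# integer codes used in every categorical raster
WOODY = 0
WETLAND = 1
GRASSLAND = 2
CROP = 3
PALM = 4
SETTLEMENT = 5
WATER = 6
BARE = 7
# refined (post-split) codes; they replace WOODY in refined maps
FOREST = 8
SECONDARY = 9

#: MODIS-like grid cell edge length in metres.
PIXEL_SIZE_M = 231.3
#: Nominal per-pixel area in km^2 (0.2313 km squared, 4 significant figures).
PIXEL_AREA_KM2 = 0.0535
#: 16-day composites per year.
COMPOSITES_PER_YEAR = 23

VARIABLES = ("red", "nir", "mir", "ndvi", "evi")


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class labels plus the derived post-split labels.

    ``labels`` maps positionally onto the integer codes above, so
    ``labels[WOODY] == "woody"``.
    """

    labels: tuple[str, ...] = (
        "woody", "wetland", "grassland", "crop", "palm",
        "settlement", "water", "bare",
    )
    split_labels: tuple[str, ...] = ("forest", "secondary")
    excluded_from_change: tuple[str, ...] = ("bare",)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("class labels must be unique")

    @property
    def codes(self) -> dict[str, int]:
        d = {name: i for i, name in enumerate(self.labels)}
        d["forest"] = FOREST
        d["secondary"] = SECONDARY
        return d

    @property
    def names(self) -> dict[int, str]:
        return {v: k for k, v in self.codes.items()}

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def refined_labels(self) -> tuple[str, ...]:
        """Labels of the post-split maps: woody replaced by forest/secondary."""
        out = list(self.split_labels)
        out += [c for c in self.labels if c != "woody"]
        return tuple(out)


DEFAULT_SCHEME = ClassScheme()

#: Classes whose gain over forest/secondary counts as a deforestation driver.
DRIVER_CLASSES = (GRASSLAND, CROP, PALM, SETTLEMENT)
#: Classes whose conversion to secondary vegetation counts as reforestation.
REFORESTATION_SOURCES = (GRASSLAND, CROP, PALM)
WOODY_REFINED = (FOREST, SECONDARY)

__all__ = [
    "ClassScheme", "DEFAULT_SCHEME", "VARIABLES",
    "WOODY", "WETLAND", "GRASSLAND", "CROP", "PALM", "SETTLEMENT",
    "WATER", "BARE", "FOREST", "SECONDARY",
    "PIXEL_SIZE_M", "PIXEL_AREA_KM2", "COMPOSITES_PER_YEAR",
    "DRIVER_CLASSES", "REFORESTATION_SOURCES", "WOODY_REFINED",
]
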