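"""Cortical area atlas: labels, Talairach coordinates, and volumes.

The packaged reference atlas lists 52 gray-matter areas of the cerebral
cortex (26 per hemisphere) with their mean Talairach coordinates
(LR: left-right, negative = left; PA: posterior-anterior, negative =
posterior; IS: inferior-superior, negative = inferior) in mm and mean
volumes in mm^3, averaged over 18 adult subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AreaAtlas", "AtlasError", "load_atlas", "load_reference_atlas"]

_COLUMNS = ["label", "hemisphere", "x", "y", "z", "volume"]
_HEMIS = {"left", "right"}


class AtlasError(ValueError):
    """Raised for a missing, malformed, or inconsistent atlas table."""


@dataclass(frozen=True)
class AreaAtlas:
    """A labeled set of cortical areas with coordinates and volumes.

    ``frame`` has one row per area with columns ``label``, ``hemisphere``
    (``left``/``right``), ``x`` (LR, signed mm), ``y`` (PA, mm), ``z``
    (IS, mm) and ``volume`` (mm^3). Row order is the canonical area order
    used for matrices and leaf-order tie-breaking throughout the package.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in _COLUMNS if c not in f.columns]
        if missing:
            raise AtlasError(f"atlas table lacks columns {missing}")
        if f["label"].duplicated().any():
            dup = f.loc[f["label"].duplicated(), "label"].tolist()
            raise AtlasError(f"duplicate area labels: {dup}")
        if not set(f["hemisphere"]) <= _HEMIS:
            raise AtlasError("hemisphere must be 'left' or 'right'")
        if (f["volume"] <= 0).any():
            raise AtlasError("area volumes must be positive")
        if not np.isfinite(f[["x", "y", "z", "volume"]].to_numpy()).all():
            raise AtlasError("non-finite coordinate or volume")

    # -- basic accessors ---------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return self.frame["label"].tolist()

    @property
    def n_areas(self) -> int:
        return len(self.frame)

    @property
    def hemispheres(self) -> pd.Series:
        return self.frame["hemisphere"]

    def coordinates(self, rectify_lr: bool = False) -> np.ndarray:
        """(n, 3) array of (LR, PA, IS); ``rectify_lr`` takes |LR|."""
        xyz = self.frame[["x", "y", "z"]].to_numpy(dtype=float).copy()
        if rectify_lr:
            xyz[:, 0] = np.abs(xyz[:, 0])
        return xyz

    def stem(self, label: str) -> str:
        """Area name without the hemisphere prefix (homotopic pairs share it)."""
        return label.split("_", 1)[1] if "_" in label else label

    @property
    def stems(self) -> list[str]:
        return [self.stem(l) for l in self.labels]

    def homotopic_partner(self, label: str) -> str | None:
        """The same-named area of the opposite hemisphere, if present."""
        me = self.frame.set_index("label").loc[label]
        for other in self.labels:
            if other != label and self.stem(other) == self.stem(label):
                if self.frame.set_index("label").loc[other, "hemisphere"] != me["hemisphere"]:
                    return other
        return None

    def is_bilateral(self) -> bool:
        """True when both hemispheres are present with paired labels."""
        counts = self.frame["hemisphere"].value_counts()
        if set(counts.index) != _HEMIS or counts["left"] != counts["right"]:
            return False
        left = {self.stem(l) for l, h in zip(self.labels, self.hemispheres) if h == "left"}
        right = {self.stem(l) for l, h in zip(self.labels, self.hemispheres) if h == "right"}
        return left == right

    def subset(self, hemisphere: str) -> "AreaAtlas":
        if hemisphere not in _HEMIS:
            raise AtlasError(f"unknown hemisphere {hemisphere!r}")
        sub = self.frame[self.frame["hemisphere"] == hemisphere].reset_index(drop=True)
        return AreaAtlas(sub)

    def pairwise_distances(self, rectify_lr: bool = False) -> np.ndarray:
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.coordinates(rectify_lr=rectify_lr)))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_atlas(path: str | Path) -> AreaAtlas:
    """Load an atlas from a CSV with header label,hemisphere,x,y,z,volume."""
    path = Path(path)
    if not path.exists():
        raise AtlasError(f"atlas file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise AtlasError(f"could not parse atlas file {path}: {exc}") from exc
    return AreaAtlas(frame)


def load_reference_atlas() -> AreaAtlas:
    """The packaged 52-area reference atlas (26 areas per hemisphere)."""
    ref = resources.files("cortical_layout.data") / "talairach_52_areas.csv"
    with resources.as_file(ref) as path:
        atlas = load_atlas(path)
    if atlas.n_areas != 52 or not atlas.is_bilateral():
        raise AtlasError("packaged reference atlas is corrupt")
    return atlas
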