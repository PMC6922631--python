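"""Region atlas: names, hemispheres, bilateral pairing and barycenter coordinates.

The atlas fixes the region order used everywhere else: connectome rows,
metric tables and cohort columns are always aligned to it by name, never by
position in an input file.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

HEMISPHERES = ("left", "right", "midline")


@dataclass(frozen=True)
class RegionAtlas:
    """Immutable catalogue of gray-matter regions.

    Parameters
    ----------
    names : list of str
        Unique region names, one per lateralized region (e.g. ``Hippocampus_L``).
    hemisphere : list of str
        One of ``left``, ``right``, ``midline`` per region.
    pair_id : list of str
        Bilateral pair label shared by the left and right member of a pair;
        midline regions carry their own name.
    coords : (V, 3) ndarray
        Region barycenters in mm.
    """

    names: tuple
    hemisphere: tuple
    pair_id: tuple
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = len(self.names)
        if len(set(self.names)) != v:
            raise DataError("region names must be unique")
        if len(self.hemisphere) != v or len(self.pair_id) != v:
            raise DataError("atlas field lengths disagree")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise DataError(f"unknown hemisphere labels: {sorted(bad)}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (v, 3) or not np.all(np.isfinite(coords)):
            raise DataError("coordinates must be a finite (V, 3) array")
        object.__setattr__(self, "coords", coords)
        # pairing must be a bijection between left and right subsets
        left = {p for p, h in zip(self.pair_id, self.hemisphere) if h == "left"}
        right = {p for p, h in zip(self.pair_id, self.hemisphere) if h == "right"}
        if left != right:
            raise DataError(
                "bilateral pairing is not a bijection; unpaired labels: "
                f"{sorted(left ^ right)}"
            )
        for p, h in zip(self.pair_id, self.hemisphere):
            if h == "midline" and (p in left or p in right):
                raise DataError(f"midline region shares pair label {p!r} with a pair")
        counts = pd.Series(list(self.pair_id)).value_counts()
        if (counts > 2).any():
            raise DataError("a pair label occurs more than twice")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    @property
    def bilateral_labels(self) -> list:
        """Pair labels (and midline names) in order of first appearance."""
        seen, out = set(), []
        for p in self.pair_id:
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    @property
    def n_bilateral(self) -> int:
        return len(self.bilateral_labels)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DataError(f"region {name!r} not in atlas") from None

    def members_of(self, pair: str) -> list:
        """Lateralized region indices carrying a pair label."""
        idx = [i for i, p in enumerate(self.pair_id) if p == pair]
        if not idx:
            raise DataError(f"pair label {pair!r} not in atlas")
        return idx

    def lr_permutation(self) -> np.ndarray:
        """Permutation swapping left and right members of every pair."""
        perm = np.arange(self.n_regions)
        for pair in self.bilateral_labels:
            idx = self.members_of(pair)
            if len(idx) == 2:
                perm[idx[0]], perm[idx[1]] = idx[1], idx[0]
        return perm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "hemisphere": self.hemisphere,
                "pair": self.pair_id,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )


def read_atlas(path) -> RegionAtlas:
    """Read an atlas CSV with columns name, hemisphere, pair, x, y, z."""
    df = pd.read_csv(path)
    required = {"name", "hemisphere", "pair", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"atlas file missing columns: {sorted(missing)}")
    return RegionAtlas(
        names=tuple(df["name"].astype(str)),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        pair_id=tuple(df["pair"].astype(str)),
        coords=df[["x", "y", "z"]].to_numpy(float),
    )


def write_atlas(atlas: RegionAtlas, path) -> None:
    atlas.to_frame().to_csv(path, index=False)
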