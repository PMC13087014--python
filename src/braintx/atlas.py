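"""Parcellation geometry shared by every stage of the pipeline.

A :class:`RegionAtlas` carries region identities, lobe classes and 3-D
centroids (mm); the pairwise Euclidean distance matrix derived from the
centroids is the spatial frame for variograms and surrogate maps.  A
:class:`RegionMap` is a single scalar value per region (a w-score map, a
gene-expression map, a surrogate draw, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

#: Recognised lobe classes.  Cortical subtypes (frontal/temporal/parietal/
#: occipital) are allowed so atlases loaded from disk can keep finer labels.
LOBE_CLASSES = (
    "cortical",
    "subcortical",
    "cerebellar",
    "brainstem",
    "frontal",
    "temporal",
    "parietal",
    "occipital",
)


@dataclass(frozen=True)
class RegionAtlas:
    """Immutable region parcellation.

    Parameters
    ----------
    region_ids
        Unique short tokens, one per region (canonical ordering).
    labels
        Human-readable region names.
    lobe_classes
        One of :data:`LOBE_CLASSES` per region.
    centroids
        ``(n_regions, 3)`` array of centroid coordinates in mm.
    """

    region_ids: tuple[str, ...]
    labels: tuple[str, ...]
    lobe_classes: tuple[str, ...]
    centroids: np.ndarray
    distance_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = tuple(self.region_ids)
        if len(ids) == 0:
            raise ValueError("atlas needs at least one region")
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        centroids = np.asarray(self.centroids, dtype=float)
        if centroids.shape != (len(ids), 3):
            raise ValueError(
                f"centroids must have shape ({len(ids)}, 3), got {centroids.shape}"
            )
        if not np.all(np.isfinite(centroids)):
            raise ValueError("centroids must be finite")
        if len(self.labels) != len(ids) or len(self.lobe_classes) != len(ids):
            raise ValueError("labels/lobe_classes length mismatch")
        for lc in self.lobe_classes:
            if lc not in LOBE_CLASSES:
                raise ValueError(f"unknown lobe class {lc!r}")
        object.__setattr__(self, "region_ids", ids)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "lobe_classes", tuple(self.lobe_classes))
        object.__setattr__(self, "centroids", centroids)
        if len(ids) == 1:
            dmat = np.zeros((1, 1))
        else:
            dmat = squareform(pdist(centroids))
        object.__setattr__(self, "distance_matrix", dmat)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"region {region_id!r} not in atlas") from None

    def __eq__(self, other: object) -> bool:  # value equality, not identity
        if not isinstance(other, RegionAtlas):
            return NotImplemented
        return (
            self.region_ids == other.region_ids
            and np.array_equal(self.centroids, other.centroids)
        )

    def __hash__(self) -> int:
        return hash(self.region_ids)


@dataclass(frozen=True)
class RegionMap:
    """One finite scalar value per atlas region."""

    atlas: RegionAtlas
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.atlas.n_regions,):
            raise ValueError(
                f"expected {self.atlas.n_regions} values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("region map values must be finite")
        object.__setattr__(self, "values", values)

    def with_values(self, values: Sequence[float], name: str | None = None) -> "RegionMap":
        return RegionMap(self.atlas, np.asarray(values, dtype=float),
                         self.name if name is None else name)
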