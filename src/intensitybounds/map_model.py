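"""Domain types and I/O for aggregated-area disease maps.

An area map is a set of K spatial units (municipalities, counties, hex
cells, ...), each with a centroid, a population at risk ``n_i`` and an
observed case count ``c_i``.  All per-area vectors in this package are
index-aligned to the row order of the area table; the area order is the
file row order everywhere.

Centroid coordinates are treated as planar (Euclidean distances).  Users
with lon/lat data must project to a planar CRS first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

logger = logging.getLogger(__name__)

__all__ = [
    "AreaMap",
    "CaseVector",
    "read_area_table",
    "write_area_table",
    "build_adjacency",
    "write_intensity_table",
    "write_intensity_geojson",
]


class FormatError(ValueError):
    """A required column or structural element is missing from an input file."""


class ValidationError(ValueError):
    """Input values violate a domain invariant (negative count, duplicate id, ...)."""


@dataclass(frozen=True)
class AreaMap:
    """A study map of K areas with centroids, populations and optional adjacency.

    Parameters
    ----------
    ids
        Unique area identifiers, in canonical (file row) order.
    centroids
        ``(K, 2)`` array of planar centroid coordinates.
    populations
        Length-K vector of nonnegative populations at risk ``n_i``.
    adjacency
        Optional mapping ``id -> frozenset of first-order neighbour ids``.
        Must be symmetric and irreflexive when present.
    """

    ids: tuple[str, ...]
    centroids: np.ndarray
    populations: np.ndarray
    adjacency: Mapping[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        cent = np.ascontiguousarray(self.centroids, dtype=float)
        pop = np.asarray(self.populations, dtype=np.int64)
        object.__setattr__(self, "centroids", cent)
        object.__setattr__(self, "populations", pop)
        K = len(ids)
        if K < 1:
            raise ValidationError("an AreaMap needs at least one area")
        if len(set(ids)) != K:
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate area ids: {dup}")
        if cent.shape != (K, 2):
            raise ValidationError(f"centroids must have shape ({K}, 2), got {cent.shape}")
        if pop.shape != (K,):
            raise ValidationError("populations must be a length-K vector")
        if (pop < 0).any():
            bad = ids[int(np.argmax(pop < 0))]
            raise ValidationError(f"negative population for area {bad!r}")
        if pop.sum() <= 0:
            raise ValidationError("total population must be positive")
        # exact centroid ties make circular-window ordering ambiguous
        view = cent.view([("x", float), ("y", float)]).ravel()
        if len(np.unique(view)) != K:
            logger.warning(
                "coincident centroids detected; distance ties are broken by area index"
            )
        if self.adjacency is not None:
            adj = {str(a): frozenset(str(b) for b in nbrs) for a, nbrs in self.adjacency.items()}
            known = set(ids)
            for a, nbrs in adj.items():
                if a not in known:
                    raise ValidationError(f"adjacency references unknown area {a!r}")
                if a in nbrs:
                    raise ValidationError(f"adjacency is reflexive at area {a!r}")
                for b in nbrs:
                    if b not in known:
                        raise ValidationError(f"adjacency references unknown area {b!r}")
                    if a not in adj.get(b, frozenset()):
                        raise ValidationError(f"adjacency not symmetric: {a!r} -> {b!r}")
            object.__setattr__(self, "adjacency", adj)

    @property
    def n_areas(self) -> int:
        return len(self.ids)

    @property
    def total_population(self) -> int:
        return int(self.populations.sum())

    @property
    def index_of(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}

    def neighbor_indices(self) -> list[np.ndarray]:
        """Adjacency as index arrays aligned to area order (requires adjacency)."""
        if self.adjacency is None:
            raise ValidationError("area map has no adjacency; call build_adjacency first")
        idx = self.index_of
        return [
            np.array(sorted(idx[b] for b in self.adjacency.get(a, frozenset())), dtype=np.intp)
            for a in self.ids
        ]

    def with_adjacency(self, adjacency: Mapping[str, Iterable[str]]) -> "AreaMap":
        adj = {a: frozenset(nbrs) for a, nbrs in adjacency.items()}
        return AreaMap(self.ids, self.centroids, self.populations, adj)


@dataclass(frozen=True)
class CaseVector:
    """Observed (or replicated) case counts aligned with an :class:`AreaMap`."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1:
            raise ValidationError("case counts must be a 1-d vector")
        if (counts < 0).any():
            i = int(np.argmax(counts < 0))
            raise ValidationError(f"negative case count at row {i}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


_REQUIRED_COLUMNS = ("id", "x", "y", "population", "cases")


def read_area_table(path: str | Path) -> tuple[AreaMap, CaseVector]:
    """Read a CSV area table with columns id, x, y, population, cases.

    Row order is preserved as the canonical area order.  Lines starting
    with ``#`` are treated as comments (output files of this package carry
    a provenance header in that form).
    """
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"area table {path} is missing required column {col!r}")
    for col in ("population", "cases"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            row = int(np.argmax(vals.to_numpy() < 0))
            raise ValidationError(f"negative value in column {col!r} at row {row}")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"column {col!r} must contain integers")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"duplicate area id {dup!r}")
    amap = AreaMap(
        ids=tuple(df["id"]),
        centroids=df[["x", "y"]].to_numpy(dtype=float),
        populations=df["population"].to_numpy(dtype=np.int64),
    )
    cases = CaseVector(df["cases"].to_numpy(dtype=np.int64))
    return amap, cases


def write_area_table(
    amap: AreaMap,
    cases: CaseVector,
    path: str | Path,
    header: Mapping[str, object] | None = None,
) -> None:
    """Write an area table CSV readable by :func:`read_area_table`.

    ``header`` entries are written as leading ``# key=value`` comment lines.
    """
    df = pd.DataFrame(
        {
            "id": list(amap.ids),
            "x": amap.centroids[:, 0],
            "y": amap.centroids[:, 1],
            "population": amap.populations,
            "cases": cases.counts,
        }
    )
    _write_csv_with_header(df, path, header)


def _write_csv_with_header(
    df: pd.DataFrame, path: str | Path, header: Mapping[str, object] | None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for key, value in header.items():
                fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column CSV edge list (id_a, id_b)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("edge list needs two id columns")
    return [(str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False)]


def build_adjacency(
    amap: AreaMap,
    method: str = "delaunay",
    edges: Sequence[tuple[str, str]] | str | Path | None = None,
) -> AreaMap:
    """Attach a symmetric, irreflexive first-order adjacency to a map.

    ``method='file'`` consumes an explicit edge list (pairs of ids or a CSV
    path); edges are symmetrised, so orientation does not matter.
    ``method='delaunay'`` triangulates the centroids — a fallback for maps
    shipped without polygon or contiguity information.
    """
    if method == "file":
        if edges is None:
            raise ValidationError("method='file' requires an edge list")
        if isinstance(edges, (str, Path)):
            edges = read_edge_list(edges)
        known = set(amap.ids)
        adj: dict[str, set[str]] = {a: set() for a in amap.ids}
        for a, b in edges:
            if a not in known or b not in known:
                bad = a if a not in known else b
                raise ValidationError(f"edge references unknown area {bad!r}")
            if a == b:
                continue
            adj[a].add(b)
            adj[b].add(a)
        return amap.with_adjacency(adj)
    if method == "delaunay":
        if amap.n_areas < 3:
            raise ValidationError("Delaunay adjacency needs at least 3 areas")
        tri = Delaunay(amap.centroids)
        adj = {a: set() for a in amap.ids}
        for simplex in tri.simplices:
            for i in range(3):
                for j in range(i + 1, 3):
                    a, b = amap.ids[simplex[i]], amap.ids[simplex[j]]
                    adj[a].add(b)
                    adj[b].add(a)
        return amap.with_adjacency(adj)
    raise ValueError(f"unknown adjacency method {method!r}")


def write_intensity_table(
    ids: Sequence[str],
    q: np.ndarray,
    classes: np.ndarray,
    path: str | Path,
    header: Mapping[str, object] | None = None,
) -> None:
    """Write the per-area intensity quantiles and shading classes to CSV.

    ``q`` is printed with Python's shortest round-trip float representation,
    so re-reading the file reproduces the values bit-exactly.  Class 0 is
    the blank class: areas never part of any replicate cluster.
    """
    df = pd.DataFrame(
        {
            "id": list(ids),
            "q": [repr(float(v)) for v in q],
            "quantile_class": np.asarray(classes, dtype=int),
        }
    )
    _write_csv_with_header(df, path, header)


def write_intensity_geojson(
    amap: AreaMap,
    q: np.ndarray,
    classes: np.ndarray,
    path: str | Path,
    polygons: Mapping[str, dict] | None = None,
) -> None:
    """Write a GeoJSON FeatureCollection with q and quantile_class properties.

    Geometry is the provided polygon per area id when available, else the
    centroid as a Point.
    """
    features = []
    for i, area_id in enumerate(amap.ids):
        if polygons is not None and area_id in polygons:
            geometry = polygons[area_id]
        else:
            geometry = {"type": "Point", "coordinates": list(map(float, amap.centroids[i]))}
        features.append(
            {
                "type": "Feature",
                "id": area_id,
                "geometry": geometry,
                "properties": {"q": float(q[i]), "quantile_class": int(classes[i])},
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
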