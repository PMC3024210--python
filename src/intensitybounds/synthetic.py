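"""Synthetic hexagonal-lattice benchmark maps with injected clusters.

The benchmark is a rectangular array of 203 hexagonal cells (7 rows of
29), each with population 1000.  Centroids get a slight uniform jitter on
both axes so that no two inter-centroid distances tie, which would make
the circular-window ordering ambiguous.  Cases are distributed
multinomially with cell weights proportional to population, elevated by
a relative-risk factor inside the injected cluster — so the generated
maps are "noisy": the cluster shows up as a stochastic excess, not a
deterministic block of cases.

Shapes: a single circular cluster (at a very high or moderately high
relative risk), an L-shaped irregular cluster, a double circular cluster
whose two components carry different risks, and a null map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist

from .map_model import AreaMap, CaseVector, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "hex_grid", "cluster_labels", "inject_cases", "scenario", "SCENARIOS"]

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic benchmark map.

    ``rr`` holds one relative-risk factor per cluster component (inside
    vs. outside); ``radius`` is the circular-cluster radius in units of
    the lattice spacing (1.0 keeps a cell plus its six neighbours).
    ``l_arms`` gives the (horizontal, vertical) arm lengths of the
    L-shape, both measured in cells and including the corner cell.
    """

    shape: str  # circle | L | double | null
    rows: int = 7
    cols: int = 29
    cell_population: int = 1000
    jitter_scale: float = 0.05
    centers: tuple[tuple[int, int], ...] = ()
    radius: float = 1.0
    l_corner: tuple[int, int] = (1, 5)
    l_arms: tuple[int, int] = (7, 5)
    rr: tuple[float, ...] = ()
    expected_total_cases: int = 406
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "L", "double", "null"):
            raise ValidationError(f"unknown cluster shape {self.shape!r}")
        if not 0 <= self.jitter_scale < 0.5:
            raise ValidationError("jitter_scale must lie in [0, 0.5)")
        if self.shape != "null" and any(r <= 1 for r in self.rr):
            raise ValidationError("relative risk inside a cluster must exceed 1")
        if self.shape == "double" and len(self.rr) != 2:
            raise ValidationError("a double cluster needs two relative risks")


def _lattice(rows: int, cols: int) -> np.ndarray:
    """Unjittered offset-row hex centroids, spacing 1, row-major order."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c + 0.5 * (r % 2)
    y = r * _SQRT3_2
    return np.column_stack([x, y]).astype(float)


def hex_grid(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> AreaMap:
    """Build the jittered hexagonal map with hex-neighbour adjacency.

    Adjacency is computed on the unjittered lattice (cells at unit
    spacing), so every interior cell has exactly 6 neighbours.  The
    jitter is re-drawn in the (measure-zero) event that it leaves two
    pairwise distances exactly tied.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    K = spec.rows * spec.cols
    base = _lattice(spec.rows, spec.cols)
    ids = tuple(f"r{r}c{c}" for r in range(spec.rows) for c in range(spec.cols))
    for _attempt in range(10):
        jitter = rng.uniform(-spec.jitter_scale, spec.jitter_scale, size=(K, 2))
        cent = base + jitter
        if spec.jitter_scale == 0 or len(np.unique(pdist(cent))) == K * (K - 1) // 2:
            break
        logger.warning("tied pairwise distances after jitter; re-drawing")
    # hex neighbours sit at exactly unit distance on the clean lattice
    d = pdist(base)
    pairs = np.column_stack(np.triu_indices(K, k=1))[np.abs(d - 1.0) < 1e-9]
    adjacency: dict[str, set[str]] = {a: set() for a in ids}
    for i, j in pairs:
        adjacency[ids[i]].add(ids[j])
        adjacency[ids[j]].add(ids[i])
    pop = np.full(K, spec.cell_population, dtype=np.int64)
    return AreaMap(ids, cent, pop, {a: frozenset(v) for a, v in adjacency.items()})


def cluster_labels(spec: ScenarioSpec) -> np.ndarray:
    """Ground-truth component labels: 0 outside, 1.. per cluster component."""
    base = _lattice(spec.rows, spec.cols)
    labels = np.zeros(spec.rows * spec.cols, dtype=int)
    if spec.shape == "null":
        return labels
    if spec.shape in ("circle", "double"):
        for comp, (r0, c0) in enumerate(spec.centers, start=1):
            center = base[r0 * spec.cols + c0]
            inside = np.linalg.norm(base - center, axis=1) <= spec.radius + 1e-9
            if comp > 1 and (labels[inside] > 0).any():
                raise ValidationError("double-cluster components must be disjoint")
            labels[inside] = comp
        return labels
    # L-shape: horizontal arm along the corner row, vertical arm down the column
    r0, c0 = spec.l_corner
    h, v = spec.l_arms
    for c in range(c0, min(c0 + h, spec.cols)):
        labels[r0 * spec.cols + c] = 1
    for r in range(r0, min(r0 + v, spec.rows)):
        labels[r * spec.cols + c0] = 1
    return labels


def inject_cases(
    amap: AreaMap,
    labels: np.ndarray,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> CaseVector:
    """Draw the case map: multinomial with elevated weights inside the cluster.

    Cell weights are n_i * rr[component] inside and n_i outside, so with
    rr = 1 the draw reduces to the uniform-risk null.  The total case
    count is conserved exactly.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    if spec.shape != "null" and not (labels > 0).any():
        raise ValidationError("no cluster cells to inject cases into")
    weights = amap.populations.astype(float).copy()
    for comp, rr in enumerate(spec.rr, start=1):
        weights[labels == comp] *= rr
    return CaseVector(rng.multinomial(spec.expected_total_cases, weights / weights.sum()))


SCENARIOS: dict[str, ScenarioSpec] = {
    "A_circle_high": ScenarioSpec(shape="circle", centers=((3, 7),), rr=(8.0,)),
    "B_circle_moderate": ScenarioSpec(shape="circle", centers=((3, 7),), rr=(3.0,)),
    "C_Lshape": ScenarioSpec(shape="L", rr=(8.0,)),
    "D_double_high": ScenarioSpec(shape="double", centers=((3, 6), (3, 22)), rr=(8.0, 5.0)),
    "E_double_moderate": ScenarioSpec(shape="double", centers=((3, 6), (3, 22)), rr=(3.0, 2.0)),
    "null": ScenarioSpec(shape="null"),
}


def scenario(
    name: str, seed: int = 0, **overrides
) -> tuple[AreaMap, CaseVector, np.ndarray]:
    """Generate a ready benchmark: map, noisy cases and ground-truth labels.

    The label vector marks cluster components (1, 2, ...) with 0 outside;
    truth masks for recovery metrics are simply ``labels > 0``.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    spec = replace(SCENARIOS[name], seed=seed, **overrides)
    children = np.random.SeedSequence(spec.seed).spawn(2)
    amap = hex_grid(spec, np.random.default_rng(children[0]))
    labels = cluster_labels(spec)
    cases = inject_cases(amap, labels, spec, np.random.default_rng(children[1]))
    return amap, cases, labels
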