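"""Intensity bounds: Monte Carlo delineation uncertainty for scan clusters.

The observed case map is treated as one realization of a random vector
whose per-area means come from the observed counts (raw model, cell
probabilities c_i / C) or from empirical-Bayes smoothed expected counts.
Each of m multinomial replicates is rescanned for its most likely
cluster; the m maximal LLRs, sorted ascending, define the intensity
function f(j) = LLR_(j).  An area's intensity quantile is

    q(a_i) = (1/m) * argmax_{j : a_i in MLC_(j)} f(j)

— the rank quantile of the largest replicate LLR among the most likely
clusters containing the area — and 0 if it belongs to none.  Shading the
map by q yields intensity bounds: the darkest areas are near-certain
cluster members, blank areas were never in any replicate cluster.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .map_model import AreaMap, CaseVector, ValidationError
from .scan import CircularScanner
from .smoothing import marshall_local, smoothed_probabilities

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityResult",
    "replicate_cases",
    "intensity_run",
    "area_quantiles",
    "quantile_shading",
    "intensity_curve",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = (0.90, 0.95, 0.99, 1.0)


@dataclass(frozen=True)
class IntensityResult:
    """Ranked replicate LLRs, their cluster memberships and per-area quantiles.

    ``sorted_llr[j-1]`` is f(j); ``membership[j-1]`` holds the member area
    indices of MLC_(j) (empty for replicates with no case excess).  ``q``
    is index-aligned with the map's areas and takes values in
    {0, 1/m, ..., 1}.
    """

    m: int
    sorted_llr: np.ndarray
    membership: tuple[tuple[int, ...], ...]
    q: np.ndarray
    seed: int
    mean_model: str

    def __post_init__(self) -> None:
        f = np.asarray(self.sorted_llr, dtype=float)
        if len(f) != self.m or len(self.membership) != self.m:
            raise ValidationError("result length does not match replicate count m")
        if (np.diff(f) < 0).any():
            raise ValidationError("sorted LLRs must be nondecreasing")


def replicate_cases(
    cases: CaseVector, probabilities: np.ndarray, rng: np.random.Generator
) -> CaseVector:
    """One multinomial replicate V = (s_1, ..., s_K) of the case map.

    The total C is conserved exactly; areas with zero probability receive
    zero cases.
    """
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any():
        raise ValidationError("probabilities must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("all probabilities are zero; cases cannot be placed")
    if abs(total - 1.0) > 1e-12:
        raise ValidationError(f"probabilities sum to {total}, not 1")
    return CaseVector(rng.multinomial(cases.total, p))


def mean_model_probabilities(
    amap: AreaMap, cases: CaseVector, mean_model: str
) -> np.ndarray:
    """Multinomial cell probabilities for the chosen mean model."""
    if mean_model == "raw":
        if cases.total < 1:
            raise ValidationError("intensity run requires at least one case")
        return cases.counts / cases.total
    if mean_model == "smoothed":
        if amap.adjacency is None:
            raise ValidationError("smoothed mean model requires adjacency")
        return smoothed_probabilities(marshall_local(cases, amap), amap)
    raise ValueError(f"unknown mean model {mean_model!r}")


def _replicate_seeds(seed: int, m: int) -> list[np.random.SeedSequence]:
    # one child stream per replicate: checkpoint resume reproduces the
    # straight-through run bit-identically
    return np.random.SeedSequence(seed).spawn(m)


def intensity_run(
    amap: AreaMap,
    cases: CaseVector,
    m: int = 999,
    max_pop_fraction: float = 0.5,
    mean_model: str = "raw",
    seed: int = 0,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 50,
    progress_every: int | None = None,
    batch_size: int = 128,
) -> IntensityResult:
    """Run the full intensity procedure: replicate, rescan, rank, quantile.

    Parameters
    ----------
    m
        Number of Monte Carlo replicates.  The intensity map sharpens
        gradually with m; partial results are already interpretable.
    mean_model
        'raw' uses p_i = c_i / C; 'smoothed' uses local empirical-Bayes
        expected counts (requires adjacency on the map).
    checkpoint_path
        Optional JSON checkpoint, written every ``checkpoint_every``
        replicates.  An interrupted run resumed from its checkpoint yields
        exactly the same result as an uninterrupted one.

    Replicates whose scan finds no case excess occupy a rank with f(j) = 0
    and contribute no cluster membership.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if cases.total < 1:
        raise ValidationError("intensity run requires at least one case")
    p = mean_model_probabilities(amap, cases, mean_model)
    scanner = CircularScanner(amap, max_pop_fraction)
    config_key = _config_key(amap, cases, m, max_pop_fraction, mean_model, seed)

    llr = np.zeros(m)
    centers = np.full(m, -1, dtype=int)
    sizes = np.zeros(m, dtype=int)
    start = 0
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        start = _load_checkpoint(checkpoint_path, config_key, llr, centers, sizes)
        logger.info("resuming intensity run at replicate %d/%d", start, m)

    seeds = _replicate_seeds(seed, m)
    C = cases.total
    j = start
    while j < m:
        b = min(batch_size, m - j)
        sims = np.empty((b, amap.n_areas), dtype=np.int64)
        for k in range(b):
            rng = np.random.default_rng(seeds[j + k])
            sims[k] = rng.multinomial(C, p)
        llr[j : j + b], centers[j : j + b], sizes[j : j + b] = scanner.max_llr_batch(sims)
        j += b
        if progress_every and (j % progress_every < b):
            logger.info("intensity run: %d/%d replicates done", j, m)
        if checkpoint_path is not None and (j % checkpoint_every < b or j == m):
            _save_checkpoint(checkpoint_path, config_key, j, llr, centers, sizes)

    order = np.argsort(llr, kind="stable")
    sorted_llr = llr[order]
    membership = tuple(
        tuple(int(i) for i in scanner.members(centers[r], sizes[r])) if centers[r] >= 0 else ()
        for r in order
    )
    q = area_quantiles(membership, amap.n_areas)
    return IntensityResult(m, sorted_llr, membership, q, seed, mean_model)


def area_quantiles(
    ranked_membership: Sequence[tuple[int, ...]], n_areas: int
) -> np.ndarray:
    """Per-area quantiles from rank-ordered replicate cluster memberships.

    ``ranked_membership[j-1]`` is the member set of MLC_(j), ascending in
    LLR.  Since f is nondecreasing, the argmax of f(j) over the ranks
    containing an area is its highest such rank (ties in f resolve to the
    highest qualifying rank), so q_i = max{j : a_i in MLC_(j)} / m.
    """
    m = len(ranked_membership)
    q = np.zeros(n_areas)
    for rank0, members in enumerate(ranked_membership):
        if members:
            q[list(members)] = (rank0 + 1) / m
    return q


def quantile_shading(
    q: np.ndarray, levels: Sequence[float] = DEFAULT_LEVELS
) -> np.ndarray:
    """Classify intensity quantiles into shading classes.

    Class 0 (blank) is reserved for q = 0: areas never part of any
    replicate cluster.  Otherwise the class is the 1-based index of the
    first breakpoint >= q; values above the last breakpoint land in the
    last (darkest) class.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValidationError("at least one shading level is required")
    if (np.diff(levels) <= 0).any():
        raise ValidationError("shading levels must be strictly ascending")
    if levels[-1] > 1:
        raise ValidationError("shading levels must not exceed 1")
    q = np.asarray(q, dtype=float)
    classes = 1 + np.searchsorted(levels, q, side="left")
    classes = np.minimum(classes, len(levels))
    return np.where(q == 0, 0, classes)


def intensity_curve(result: IntensityResult) -> pd.DataFrame:
    """The intensity function as a (rank j, f(j)) table for plotting/export."""
    return pd.DataFrame(
        {"j": np.arange(1, result.m + 1), "f": np.asarray(result.sorted_llr)}
    )


# -- checkpointing -----------------------------------------------------------


def _config_key(amap, cases, m, frac, mean_model, seed) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(amap.centroids).tobytes())
    h.update(np.ascontiguousarray(amap.populations).tobytes())
    h.update(np.ascontiguousarray(cases.counts).tobytes())
    h.update(f"{m}|{frac}|{mean_model}|{seed}".encode())
    return h.hexdigest()[:16]


def _save_checkpoint(path, key, done, llr, centers, sizes) -> None:
    state = {
        "config_key": key,
        "done": int(done),
        "llr": llr[:done].tolist(),
        "centers": centers[:done].tolist(),
        "sizes": sizes[:done].tolist(),
    }
    tmp = Path(str(path) + ".tmp")
    tmp.write_text(json.dumps(state))
    tmp.replace(path)


def _load_checkpoint(path, key, llr, centers, sizes) -> int:
    state = json.loads(Path(path).read_text())
    if state.get("config_key") != key:
        logger.warning("checkpoint %s does not match this run; ignoring it", path)
        return 0
    done = int(state["done"])
    llr[:done] = state["llr"]
    centers[:done] = state["centers"]
    sizes[:done] = state["sizes"]
    return done
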