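"""Circular Poisson spatial scan statistic.

The scan considers every circular window: for each center area, the
nested sequence of zones formed by adding areas in increasing
centroid-distance order, up to a population cap.  For a zone ``z`` with
``c_z`` cases and population ``n_z`` on a map with ``C`` total cases and
``N`` total population, the expected count under the uniform-risk null is
``mu_z = C * n_z / N`` and the log-likelihood ratio is

    LLR(z) = c_z * log(c_z / mu_z) + (C - c_z) * log((C - c_z) / (C - mu_z))

when the inside relative risk ``I(z) = c_z / mu_z`` exceeds 1, and 0
otherwise.  The zone maximizing LLR over all windows is the most likely
cluster (MLC); its significance comes from Monte Carlo replication of the
null (cases multinomial with probabilities proportional to population).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.spatial.distance import cdist

from .map_model import AreaMap, CaseVector, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Zone",
    "ScanResult",
    "llr_poisson",
    "CircularScanner",
    "enumerate_circular_zones",
    "most_likely_cluster",
    "null_pvalue",
]


@dataclass(frozen=True)
class Zone:
    """A circular-window candidate cluster: a center area plus its nearest areas."""

    member_indices: tuple[int, ...]
    c_z: int
    n_z: int
    mu_z: float
    center_index: int

    def __len__(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class ScanResult:
    """Most likely cluster of a scan, with optional Monte Carlo p-value.

    ``mlc`` is None (and ``no_excess`` True) when no window shows any case
    excess over its null expectation, i.e. the maximal LLR is 0.
    """

    mlc: Zone | None
    llr: float
    no_excess: bool = False
    p_value: float | None = None
    n_null_replicates: int = 0


def llr_poisson(c_z: int, n_z: int, C: int, N: int) -> float:
    """Poisson log-likelihood ratio of a single zone.

    Returns 0 unless the zone shows an excess (I(z) > 1).  The boundary
    case c_z = C uses the continuity convention 0*log(0) = 0.
    """
    if not 0 <= c_z <= C:
        raise ValueError(f"c_z={c_z} outside [0, C={C}]")
    if not 0 < n_z <= N:
        raise ValueError(f"n_z={n_z} outside (0, N={N}]")
    if C < 1:
        raise ValueError("C must be >= 1")
    mu = C * n_z / N
    if c_z <= mu:
        return 0.0
    inside = c_z * math.log(c_z / mu)
    rem = C - c_z
    outside = rem * math.log(rem / (C - mu)) if rem > 0 else 0.0
    return inside + outside


def _llr_array(cz: np.ndarray, nz: np.ndarray, C: int, N: int) -> np.ndarray:
    """Vectorized LLR over matching-shape case/population arrays."""
    cz = np.asarray(cz, dtype=float)
    mu = C * np.asarray(nz, dtype=float) / N
    rem = C - cz
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(cz > 0, cz * np.log(np.where(cz > 0, cz, 1.0) / mu), 0.0)
        out_ratio = np.where(rem > 0, rem, 1.0) / (C - mu)
        outside = np.where(rem > 0, rem * np.log(out_ratio), 0.0)
    return np.where(cz > mu, inside + outside, 0.0)


def _xlogx_table(C: int) -> np.ndarray:
    """k * log(k) for k = 0..C, with 0*log(0) = 0."""
    k = np.arange(C + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        table = k * np.log(k)
    table[0] = 0.0
    return table


class CircularScanner:
    """Precomputed circular-window geometry for repeated scans of one map.

    Building the distance ordering once makes each scan of a replicated
    case vector a handful of vectorized array operations, which is what
    keeps the Monte Carlo intensity procedure fast.

    Parameters
    ----------
    amap
        The study map.
    max_pop_fraction
        Windows stop growing before their population exceeds this fraction
        of the total population (default 0.5, the conventional cap).
    """

    def __init__(self, amap: AreaMap, max_pop_fraction: float = 0.5):
        if not 0 < max_pop_fraction <= 1:
            raise ValueError("max_pop_fraction must be in (0, 1]")
        self.amap = amap
        self.max_pop_fraction = float(max_pop_fraction)
        self.N = amap.total_population
        dist = cdist(amap.centroids, amap.centroids)
        # stable argsort: exact distance ties are broken by area index
        self.order = np.argsort(dist, axis=1, kind="stable")
        pop_sorted = amap.populations[self.order]
        nz_cum = np.cumsum(pop_sorted, axis=1)
        cap = self.max_pop_fraction * self.N
        self.valid = nz_cum <= cap + 1e-9
        if not self.valid[:, 0].all():
            skipped = [amap.ids[i] for i in np.flatnonzero(~self.valid[:, 0])]
            logger.warning(
                "singleton zones exceed the population cap and are skipped for "
                "centers %s", skipped
            )
        kmax = int(self.valid.sum(axis=1).max())
        self.kmax = max(kmax, 1)
        self.order = self.order[:, : self.kmax]
        self.nz_cum = nz_cum[:, : self.kmax]
        self.valid = self.valid[:, : self.kmax]
        self._tables: tuple | None = None  # per-C log tables, built lazily

    def _log_tables(self, C: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-total-count tables: since every replicate conserves C, the
        window expectations mu and all k*log(k) values can be precomputed,
        turning each scan into table lookups and multiplies."""
        if self._tables is not None and self._tables[0] == C:
            return self._tables[1:]
        mu = C * self.nz_cum.astype(float) / self.N
        with np.errstate(divide="ignore"):
            log_mu = np.log(mu)
            log_cmu = np.log(C - mu)  # -inf only for the whole-map window
        xlogx = _xlogx_table(C)
        self._tables = (C, mu, log_mu, log_cmu, xlogx)
        return mu, log_mu, log_cmu, xlogx

    def _llr_from_cum(self, cz_cum: np.ndarray, C: int) -> np.ndarray:
        """LLR of every window from integer cumulative case counts.

        cz_cum has shape (..., n_centers, kmax); invalid windows get -1.
        """
        mu, log_mu, log_cmu, xlogx = self._log_tables(C)
        rem = C - cz_cum
        with np.errstate(invalid="ignore"):
            llr = xlogx[cz_cum] + xlogx[rem] - cz_cum * log_mu - rem * log_cmu
        llr = np.where(cz_cum > mu, llr, 0.0)
        llr[..., ~self.valid] = -1.0
        return llr

    # -- single-vector paths -------------------------------------------------

    def llr_all_windows(self, counts: np.ndarray) -> np.ndarray:
        """LLR of every (center, window size) pair; invalid windows are -1."""
        counts = np.asarray(counts, dtype=np.int64)
        C = int(counts.sum())
        cz_cum = np.cumsum(counts[self.order], axis=1)
        return self._llr_from_cum(cz_cum, C)

    def max_llr(self, counts: np.ndarray) -> tuple[float, int, int]:
        """Maximal LLR with its (center, size); deterministic tie-break.

        Ties are broken by smaller zone population, then fewer members,
        then lowest center index.
        """
        llr = self.llr_all_windows(counts)
        best = float(llr.max())
        if best <= 0.0:
            return max(best, 0.0), -1, 0
        centers, sizes = np.nonzero(llr == best)
        keys = np.lexsort((centers, sizes, self.nz_cum[centers, sizes]))
        k = keys[0]
        return best, int(centers[k]), int(sizes[k]) + 1

    def zone(self, counts: np.ndarray, center: int, size: int) -> Zone:
        members = tuple(int(i) for i in self.order[center, :size])
        c_z = int(np.asarray(counts)[list(members)].sum())
        n_z = int(self.nz_cum[center, size - 1])
        C = int(np.asarray(counts).sum())
        return Zone(members, c_z, n_z, C * n_z / self.N, center)

    # -- batched path for Monte Carlo ----------------------------------------

    def max_llr_batch(
        self, counts_matrix: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-row maximal LLR with window (center, size) for B case vectors.

        Rows are independent replicates; each must conserve the same total.
        Returns (llr, center, size) arrays; no-excess rows get llr 0,
        center -1, size 0.
        """
        counts_matrix = np.asarray(counts_matrix, dtype=np.int64)
        B = counts_matrix.shape[0]
        C = int(counts_matrix[0].sum())
        cz = counts_matrix[:, self.order]  # (B, K, kmax)
        np.cumsum(cz, axis=2, out=cz)
        llr = self._llr_from_cum(cz, C)
        flat = llr.reshape(B, -1)
        arg = np.argmax(flat, axis=1)
        best = flat[np.arange(B), arg]
        centers, sizes = np.divmod(arg, self.kmax)
        none = best <= 0.0
        best = np.where(none, np.maximum(best, 0.0), best)
        centers = np.where(none, -1, centers)
        sizes = np.where(none, 0, sizes + 1)
        return best, centers, sizes

    def members(self, center: int, size: int) -> np.ndarray:
        return self.order[center, :size]


def enumerate_circular_zones(
    amap: AreaMap, cases: CaseVector, max_pop_fraction: float = 0.5
) -> Iterator[Zone]:
    """Yield every distinct circular-window zone of a map.

    For each center the nested window sequence grows by centroid distance
    until the population cap; duplicate member sets arising from different
    centers are emitted once (for the first center producing them).
    """
    scanner = CircularScanner(amap, max_pop_fraction)
    counts = cases.counts
    seen: set[frozenset[int]] = set()
    for center in range(amap.n_areas):
        for size in range(1, int(scanner.valid[center].sum()) + 1):
            members = frozenset(int(i) for i in scanner.order[center, :size])
            if members in seen:
                continue
            seen.add(members)
            yield scanner.zone(counts, center, size)


def most_likely_cluster(
    amap: AreaMap, cases: CaseVector, max_pop_fraction: float = 0.5
) -> ScanResult:
    """Find the circular-window zone maximizing the Poisson LLR.

    If every window's LLR is 0 (cases proportional to population, or a
    uniform deficit), the result is flagged ``no_excess`` instead of
    returning an arbitrary zone.
    """
    if cases.total < 1:
        raise ValidationError("scan requires at least one case")
    if len(cases) != amap.n_areas:
        raise ValidationError("case vector length does not match map")
    scanner = CircularScanner(amap, max_pop_fraction)
    best, center, size = scanner.max_llr(cases.counts)
    if center < 0:
        return ScanResult(mlc=None, llr=0.0, no_excess=True)
    return ScanResult(mlc=scanner.zone(cases.counts, center, size), llr=best)


def null_pvalue(
    amap: AreaMap,
    cases: CaseVector,
    scan_llr: float,
    B: int = 999,
    seed: int | np.random.Generator = 0,
    max_pop_fraction: float = 0.5,
    batch_size: int = 256,
) -> float:
    """Monte Carlo p-value of an observed scan LLR under the uniform-risk null.

    Simulates B case maps multinomially with p_i = n_i / N, rescans each,
    and returns (1 + #{max LLR >= scan_llr}) / (1 + B) — strictly positive
    and exactly calibrated under the null.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scanner = CircularScanner(amap, max_pop_fraction)
    p = amap.populations / amap.total_population
    C = cases.total
    exceed = 0
    done = 0
    while done < B:
        b = min(batch_size, B - done)
        sims = rng.multinomial(C, p, size=b)
        llr, _, _ = scanner.max_llr_batch(sims)
        exceed += int(np.count_nonzero(llr >= scan_llr))
        done += b
    return (1 + exceed) / (1 + B)
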