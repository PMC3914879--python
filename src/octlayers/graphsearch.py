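"""Minimum-cost path extraction across the columns of a cost image.

Each boundary is modelled as one row position per column. A path is
feasible when it stays inside a per-column row interval (the *search
band*) and moves at most ``max_jump`` rows between adjacent columns. The
optimal path minimizes the sum of node costs along it, optionally plus a
per-step penalty proportional to the vertical jump; it is found exactly by
dynamic programming in O(depth x width x (2 max_jump + 1)).

Tie-breaking is fixed so results are bit-reproducible: among minimum-cost
paths the lexicographically smallest row sequence (columns read left to
right, smaller rows preferred) is returned. :func:`exhaustive_path`
enumerates every feasible path under the same objective and tie rule and
serves as an independent oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleBandError, InvalidInputError, InvalidParameterError, SearchSpaceError
from .preprocess import CostImage

_MAX_ENUMERATION = 1_000_000


@dataclass
class SearchBand:
    """Per-column inclusive row interval restricting the graph."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=int)
        self.hi = np.asarray(self.hi, dtype=int)
        if self.lo.shape != self.hi.shape or self.lo.ndim != 1:
            raise InvalidInputError("band lo/hi must be 1-D arrays of equal length")
        if np.any(self.lo > self.hi):
            bad = int(np.argmax(self.lo > self.hi))
            raise InvalidInputError(f"band lo > hi at column {bad}")
        if np.any(self.lo < 0):
            raise InvalidInputError("band lo must be >= 0")

    @property
    def width(self) -> int:
        return self.lo.size

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "SearchBand":
        rows, cols = shape
        return cls(lo=np.zeros(cols, dtype=int), hi=np.full(cols, rows - 1, dtype=int))

    @classmethod
    def around(cls, rows: np.ndarray, half_width: int, depth: int) -> "SearchBand":
        """Band of +/- ``half_width`` rows around a trace, clipped to the image."""
        rows = np.asarray(rows)
        lo = np.clip(np.floor(rows).astype(int) - half_width, 0, depth - 1)
        hi = np.clip(np.ceil(rows).astype(int) + half_width, 0, depth - 1)
        return cls(lo=lo, hi=hi)


@dataclass
class Boundary:
    """One boundary trace: a row position per column."""

    rows: np.ndarray
    name: str = ""
    total_cost: float | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 1:
            raise InvalidInputError("boundary rows must be 1-D")

    @property
    def width(self) -> int:
        return self.rows.size


def _check_instance(cost: CostImage, band: SearchBand, max_jump: int) -> tuple[np.ndarray, int, int]:
    costs = cost.costs
    depth, width = costs.shape
    if max_jump < 1:
        raise InvalidParameterError(f"max_jump must be a positive integer, got {max_jump}")
    if band.width != width:
        raise InvalidInputError(f"band width {band.width} != image width {width}")
    if np.any(band.hi >= depth):
        raise InvalidInputError("band hi exceeds image depth")
    # Forward reachability: a feasible path exists iff the running interval
    # stays non-empty.
    lo_r, hi_r = int(band.lo[0]), int(band.hi[0])
    for c in range(1, width):
        lo_r = max(int(band.lo[c]), lo_r - max_jump)
        hi_r = min(int(band.hi[c]), hi_r + max_jump)
        if lo_r > hi_r:
            raise InfeasibleBandError(
                f"no path with max_jump={max_jump} can reach column {c} "
                f"(band [{band.lo[c]}, {band.hi[c]}])"
            )
    return costs, depth, width


def shortest_path(
    cost: CostImage,
    band: SearchBand,
    max_jump: int,
    step_penalty: float = 0.0,
) -> Boundary:
    """Exact minimum-cost path by dynamic programming.

    Returns the feasible row sequence minimizing
    ``sum_c cost[r_c, c] + step_penalty * sum_c |r_c - r_{c-1}|``;
    ties resolved to the lexicographically smallest path (smaller rows
    first, left to right). ``step_penalty`` defaults to 0 (smoothness is
    enforced purely by ``max_jump``); a small positive value acts as an
    elasticity term that keeps the path straight across featureless
    stretches.
    """
    costs, depth, width = _check_instance(cost, band, max_jump)
    if step_penalty < 0:
        raise InvalidParameterError(f"step_penalty must be >= 0, got {step_penalty}")

    # Work in a row window covering the whole band to avoid O(depth) waste
    # when the band is narrow.
    r0 = int(band.lo.min())
    r1 = int(band.hi.max())
    n = r1 - r0 + 1
    lo = band.lo - r0
    hi = band.hi - r0
    sub = costs[r0 : r1 + 1, :]

    inf = np.inf
    # cost-to-go: G[r, c] = best cost of a path from column c to the end
    # starting at row r (including node (r, c)).
    G = np.full((n, width), inf)
    col = np.full(n, inf)
    col[lo[-1] : hi[-1] + 1] = sub[lo[-1] : hi[-1] + 1, -1]
    G[:, -1] = col
    for c in range(width - 2, -1, -1):
        nxt = G[:, c + 1]
        best = np.full(n, inf)
        for d in range(-max_jump, max_jump + 1):
            pen = step_penalty * abs(d)
            if d == 0:
                cand = nxt + pen
                np.minimum(best, cand, out=best)
            elif d > 0:
                # move down by d: successor row = r + d
                best[: n - d] = np.minimum(best[: n - d], nxt[d:] + pen)
            else:
                best[-d:] = np.minimum(best[-d:], nxt[:d] + pen)
        col = np.full(n, inf)
        sl = slice(lo[c], hi[c] + 1)
        col[sl] = sub[sl, c] + best[sl]
        G[:, c] = col

    first = G[lo[0] : hi[0] + 1, 0]
    if not np.isfinite(first).any():
        raise InfeasibleBandError("no feasible path in band")
    r = int(np.argmin(first)) + lo[0]  # argmin returns the first (smallest) row
    total = float(G[r, 0])
    rows = np.empty(width, dtype=int)
    rows[0] = r
    for c in range(1, width):
        best_val = inf
        best_row = -1
        for d in range(-max_jump, max_jump + 1):
            rr = r + d
            if rr < lo[c] or rr > hi[c]:
                continue
            val = step_penalty * abs(d) + G[rr, c]
            if val < best_val:
                best_val = val
                best_row = rr
            elif val == best_val and rr < best_row:
                best_row = rr
        rows[c] = best_row
        r = best_row
    return Boundary(rows=rows + r0, total_cost=total)


def exhaustive_path(
    cost: CostImage,
    band: SearchBand,
    max_jump: int,
    step_penalty: float = 0.0,
) -> Boundary:
    """Brute-force enumeration of all feasible paths (test oracle).

    Same objective and tie rule as :func:`shortest_path`. Refuses
    instances whose raw band-cell product exceeds 10^6 paths.
    """
    costs, depth, width = _check_instance(cost, band, max_jump)
    sizes = (band.hi - band.lo + 1).astype(float)
    if float(np.prod(sizes)) > _MAX_ENUMERATION:
        raise SearchSpaceError(
            f"search space of ~{float(np.prod(sizes)):.3g} paths exceeds {_MAX_ENUMERATION}"
        )

    best_cost = np.inf
    best_path: tuple[int, ...] | None = None

    def extend(c: int, r: int, acc: float, path: list[int]) -> None:
        nonlocal best_cost, best_path
        if c == width:
            key = tuple(path)
            if acc < best_cost or (acc == best_cost and (best_path is None or key < best_path)):
                best_cost = acc
                best_path = key
            return
        lo = int(band.lo[c])
        hi = int(band.hi[c])
        if c == 0:
            candidates = range(lo, hi + 1)
        else:
            candidates = range(max(lo, r - max_jump), min(hi, r + max_jump) + 1)
        for rr in candidates:
            step = 0.0 if c == 0 else step_penalty * abs(rr - r)
            path.append(rr)
            extend(c + 1, rr, acc + costs[rr, c] + step, path)
            path.pop()

    extend(0, -1, 0.0, [])
    if best_path is None:
        raise InfeasibleBandError("no feasible path in band")
    return Boundary(rows=np.array(best_path, dtype=float), total_cost=float(best_cost))


def parabolic_refine(cost: CostImage, boundary: Boundary) -> Boundary:
    """Optional sub-pixel refinement of an integer path.

    Fits a parabola through the cost at (r-1, r, r+1) in each column and
    shifts the row to the parabola vertex, clamped to +/- 0.5 px. Off by
    default in the pipeline; provided for callers who need sub-pixel
    traces.
    """
    costs = cost.costs
    depth = costs.shape[0]
    rows = boundary.rows.astype(int)
    out = boundary.rows.astype(float).copy()
    cols = np.arange(rows.size)
    inner = (rows > 0) & (rows < depth - 1)
    r = rows[inner]
    c = cols[inner]
    y0 = costs[r - 1, c]
    y1 = costs[r, c]
    y2 = costs[r + 1, c]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (y0 - y2) / denom
    delta = np.where(np.isfinite(delta), np.clip(delta, -0.5, 0.5), 0.0)
    out[inner] = r + delta
    return Boundary(rows=out, name=boundary.name, total_cost=boundary.total_cost)
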