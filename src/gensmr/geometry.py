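"""Detector geometry: clustered trap arrays, state spaces, and exposure matrices.

Spatial mark-resight models live on a planar, equal-area coordinate system;
everything here works in projected kilometres.  Longitude/latitude ingestion
and projection happen at file-reading time (see :mod:`gensmr.io`), never in
the model math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TrapArray",
    "StateSpace",
    "ExposureMatrices",
    "make_clustered_design",
    "make_state_space",
    "build_exposure",
]


@dataclass
class TrapArray:
    """A set of georeferenced detectors with an occasion-level operation schedule.

    Parameters
    ----------
    kind
        ``"live"`` (marking live-traps) or ``"camera"`` (resighting cameras).
    coords
        ``(J, 2)`` planar coordinates in km.
    operation
        ``(J, K)`` nonnegative effort per occasion.  For cameras this is
        typically 0/1 (operating or not during a weekly occasion); for
        live-traps a single column of trap-days is the convention here,
        because the marking "occasion" is one trap-day.
    trap_ids
        Optional detector labels; defaults to ``kind0, kind1, ...``.
    """

    kind: str
    coords: np.ndarray
    operation: np.ndarray
    trap_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("live", "camera"):
            raise ValueError(f"kind must be 'live' or 'camera', got {self.kind!r}")
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (J, 2) array")
        if self.coords.shape[0] < 1:
            raise ValueError("a trap array needs at least one detector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        self.operation = np.atleast_2d(np.asarray(self.operation, dtype=float))
        if self.operation.shape[0] != self.coords.shape[0]:
            raise ValueError("operation must have one row per detector")
        if np.any(self.operation < 0):
            raise ValueError("operation entries must be >= 0")
        if self.trap_ids is None:
            self.trap_ids = [f"{self.kind}{j}" for j in range(self.n_traps)]
        elif len(self.trap_ids) != self.n_traps:
            raise ValueError("trap_ids length must equal the number of detectors")

    @property
    def n_traps(self) -> int:
        return self.coords.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.operation.shape[1]

    def effort(self) -> np.ndarray:
        """Total effort per detector, summed over occasions."""
        return self.operation.sum(axis=1)

    def subset(self, keep: np.ndarray) -> "TrapArray":
        """Return a new array restricted to detectors where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        ids = [t for t, k in zip(self.trap_ids, keep) if k]
        return TrapArray(self.kind, self.coords[keep], self.operation[keep], ids)


@dataclass(frozen=True)
class StateSpace:
    """Rectangular state space (parameter estimation area) in km."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("state space must have positive extent on both axes")

    @property
    def area(self) -> float:
        """Area in km^2."""
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.xmax, self.ymin, self.ymax)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an ``(n, 2)`` array of points."""
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= self.xmin)
            & (pts[:, 0] <= self.xmax)
            & (pts[:, 1] >= self.ymin)
            & (pts[:, 1] <= self.ymax)
        )


@dataclass
class ExposureMatrices:
    """Individual-by-detector exposure, plus the per-occasion mark-status matrix.

    ``E_M[i, j]`` counts marking occasions (trap-days) on which marked
    individual ``i`` was exposed to live-trap ``j``; ``E_R[i, j]`` counts
    resighting occasions on which it was alive and camera ``j`` operated.
    ``m[i, k]`` encodes the status of marked individual ``i`` on resighting
    occasion ``k``: 0 = not yet marked, 1 = marked, 2 = dead (absorbing).
    Augmented (never-observed) individuals receive the full exposure rows
    ``aug_E_M`` / ``aug_E_R``.
    """

    E_M: np.ndarray | None  # (n_M, J_M)
    E_R: np.ndarray  # (n_M, J_R)
    m: np.ndarray  # (n_M, K_R)
    aug_E_M: np.ndarray | None  # (J_M,)
    aug_E_R: np.ndarray  # (J_R,)

    def __post_init__(self) -> None:
        self.E_R = np.atleast_2d(np.asarray(self.E_R, dtype=float))
        self.m = np.atleast_2d(np.asarray(self.m, dtype=int))
        self.aug_E_R = np.asarray(self.aug_E_R, dtype=float)
        if self.E_M is not None:
            self.E_M = np.atleast_2d(np.asarray(self.E_M, dtype=float))
            self.aug_E_M = np.asarray(self.aug_E_M, dtype=float)
        if np.any(self.E_R < 0) or (self.E_M is not None and np.any(self.E_M < 0)):
            raise ValueError("exposure entries must be nonnegative")
        if self.m.shape[0] != self.E_R.shape[0]:
            raise ValueError("m must have one row per marked individual")
        if not np.isin(self.m, (0, 1, 2)).all():
            raise ValueError("m codes must be in {0, 1, 2}")
        # death is absorbing: once code 2 appears it must persist
        dead = self.m == 2
        if np.any(dead[:, :-1] & ~dead[:, 1:]):
            raise ValueError("m code 2 (dead) must be absorbing")

    @property
    def n_marked(self) -> int:
        return self.E_R.shape[0]

    def expand_E_R(self, n_rows: int) -> np.ndarray:
        """Full (n_rows, J_R) exposure with augmented rows appended."""
        n_aug = n_rows - self.n_marked
        if n_aug < 0:
            raise ValueError("n_rows smaller than the number of marked individuals")
        return np.vstack([self.E_R, np.tile(self.aug_E_R, (n_aug, 1))])

    def expand_E_M(self, n_rows: int) -> np.ndarray | None:
        if self.E_M is None:
            return None
        n_aug = n_rows - self.n_marked
        return np.vstack([self.E_M, np.tile(self.aug_E_M, (n_aug, 1))])


def make_clustered_design(
    n_clusters: int,
    cluster_rows: int = 3,
    cluster_cols: int = 3,
    cell_spacing_km: float = 3.5,
    cluster_dx_km: float = 28.0,
    cluster_dy_km: float | tuple[float, float] = (36.0, 45.0),
    stagger: bool = True,
    kind: str = "camera",
    n_occasions: int = 17,
    dropout: np.ndarray | None = None,
) -> TrapArray:
    """Build a clustered detector array: ``n_clusters`` grids of
    ``cluster_rows x cluster_cols`` cells, one detector at each cell centre.

    Clusters are laid out on a near-square grid with ``cluster_dx_km``
    longitudinal spacing between cluster centres.  Latitudinal spacing may be
    a single value or a ``(low, high)`` pair applied to alternating row gaps;
    with ``stagger`` every second column of clusters is shifted up by half
    the mean latitudinal gap, giving the staggered layout used for expansive
    carnivore surveys.

    Each cell covers ``cell_spacing_km ** 2`` km^2, so a cluster covers
    ``cluster_rows * cluster_cols * cell_spacing_km ** 2`` km^2.

    Parameters
    ----------
    dropout
        Optional boolean mask of length ``n_clusters * cluster_rows *
        cluster_cols``; True drops that cell (supports realized arrays where
        some planned cells could not be occupied).
    """
    if n_clusters < 1 or cluster_rows < 1 or cluster_cols < 1:
        raise ValueError("cluster counts must be positive")
    if cell_spacing_km <= 0 or cluster_dx_km <= 0:
        raise ValueError("spacings must be positive")
    dy = np.atleast_1d(np.asarray(cluster_dy_km, dtype=float))
    if np.any(dy <= 0):
        raise ValueError("spacings must be positive")

    grid_cols = math.ceil(math.sqrt(n_clusters))
    grid_rows = math.ceil(n_clusters / grid_cols)
    # cumulative y for each cluster-grid row, alternating through dy
    row_y = np.concatenate([[0.0], np.cumsum([dy[i % len(dy)] for i in range(grid_rows - 1)])])
    half_shift = float(dy.mean()) / 2.0

    centers = []
    for idx in range(n_clusters):
        r, c = divmod(idx, grid_cols)
        cy = row_y[r] + (half_shift if (stagger and c % 2 == 1) else 0.0)
        centers.append((c * cluster_dx_km, cy))

    ox = (np.arange(cluster_cols) - (cluster_cols - 1) / 2.0) * cell_spacing_km
    oy = (np.arange(cluster_rows) - (cluster_rows - 1) / 2.0) * cell_spacing_km
    cells = []
    for cx, cy in centers:
        for dy_off in oy:
            for dx_off in ox:
                cells.append((cx + dx_off, cy + dy_off))
    coords = np.asarray(cells, dtype=float)

    if dropout is not None:
        dropout = np.asarray(dropout, dtype=bool)
        if dropout.shape[0] != coords.shape[0]:
            raise ValueError("dropout mask must have one entry per planned cell")
        coords = coords[~dropout]
        if coords.shape[0] == 0:
            raise ValueError("dropout removed every cell")

    operation = np.ones((coords.shape[0], n_occasions))
    return TrapArray(kind, coords, operation)


def make_state_space(
    arrays: TrapArray | Sequence[TrapArray], buffer_km: float = 25.0
) -> StateSpace:
    """Rectangular state space: the bounding box of all detector coordinates
    buffered by ``buffer_km`` on every side.

    The buffer should be about three times the detection-function spatial
    scale so that individuals outside the rectangle have negligible detection
    probability.
    """
    if isinstance(arrays, TrapArray):
        arrays = [arrays]
    arrays = [a for a in arrays if a is not None]
    if not arrays:
        raise ValueError("at least one trap array is required")
    if buffer_km <= 0:
        raise ValueError("buffer must be positive")
    coords = np.vstack([a.coords for a in arrays])
    return StateSpace(
        xmin=float(coords[:, 0].min() - buffer_km),
        xmax=float(coords[:, 0].max() + buffer_km),
        ymin=float(coords[:, 1].min() - buffer_km),
        ymax=float(coords[:, 1].max() + buffer_km),
    )


def build_exposure(
    live: TrapArray | None,
    cameras: TrapArray,
    n_marked: int,
    events: Sequence[tuple[int, int, str]] = (),
) -> ExposureMatrices:
    """Construct exposure matrices and the mark-status matrix ``m``.

    By default every marked individual is marked before resighting begins and
    survives the survey (``m`` all ones).  ``events`` adjusts individual rows
    on the resighting-occasion timeline; each event is
    ``(individual_index, occasion, kind)`` with 1-based occasions and kind in:

    - ``"enter"`` — exposure begins at that occasion (codes 0 before it are
      unchanged; exposure rows are zeroed before entry),
    - ``"marked"`` — the individual was live-captured mid-survey; its codes
      are 0 (unmarked) before the occasion and 1 from it onward,
    - ``"died"`` — codes become 2 from that occasion onward; an occasion
      ``<= 0`` means death before resighting started (all-2 row).

    Marking exposure ``E_M`` is the live-trap effort (trap-days) for every
    individual: marking precedes resighting, so resighting-period deaths do
    not reduce it.  ``E_R[i, j]`` sums camera operation over occasions on
    which individual ``i`` was alive and present.
    """
    K = cameras.n_occasions
    m = np.ones((n_marked, K), dtype=int)
    enter = np.ones(n_marked, dtype=int)

    died_at: dict[int, int] = {}
    marked_at: dict[int, int] = {}
    for ind, occ, kind in events:
        if not (0 <= ind < n_marked):
            raise ValueError(f"event refers to unknown individual {ind}")
        if kind == "died":
            died_at[ind] = occ
        elif kind == "marked":
            marked_at[ind] = occ
        elif kind == "enter":
            enter[ind] = occ
        else:
            raise ValueError(f"unknown event kind {kind!r}")

    for ind, occ in marked_at.items():
        if ind in died_at and died_at[ind] < occ:
            raise ValueError(
                f"individual {ind}: death on occasion {died_at[ind]} precedes "
                f"marking on occasion {occ}"
            )
        m[ind, : max(occ - 1, 0)] = 0
    for ind, occ in died_at.items():
        m[ind, max(occ - 1, 0):] = 2

    alive = (m != 2).astype(float)  # (n_M, K)
    for ind in range(n_marked):
        alive[ind, : enter[ind] - 1] = 0.0

    cam_op = cameras.operation  # (J_R, K)
    E_R = alive @ cam_op.T  # (n_M, J_R)
    aug_E_R = cam_op.sum(axis=1)

    if live is not None:
        effort = live.effort()  # (J_M,)
        E_M = np.tile(effort, (n_marked, 1))
        aug_E_M = effort.copy()
    else:
        E_M = None
        aug_E_M = None

    return ExposureMatrices(E_M=E_M, E_R=E_R, m=m, aug_E_M=aug_E_M, aug_E_R=aug_E_R)
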