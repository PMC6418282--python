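"""The shared observed-data container for spatial mark-resight analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ExposureMatrices, TrapArray

__all__ = ["SMRData", "UNMARKED_COLUMNS"]

#: Schema of the identity-free unmarked detection record table.  ``obs_sex``
#: is -1 (unknown), 0 (male) or 1 (female); ``occasion`` is 1-based.
UNMARKED_COLUMNS = ("trap", "occasion", "obs_sex")


@dataclass
class SMRData:
    """Observed marking, resighting, and telemetry data plus exposure.

    Attributes
    ----------
    live, cameras
        Detector arrays.  ``live`` may be None for camera-only (conSMR/SCR)
        data.
    y_mark
        ``(n_M, J_M)`` binomial marking counts (or None without a marking
        process).
    y_resight_marked
        ``(n_M, J_R, K_R)`` occasion-level known-identity camera counts for
        marked individuals; only occasions with mark-status code 1 may hold
        nonzero counts.
    marked_sex
        ``(n_M,)`` sexes of marked individuals (0 = male, 1 = female).
    unmarked
        DataFrame of identity-free detection records, one row per detection
        event, with columns :data:`UNMARKED_COLUMNS`.
    telemetry
        Per marked individual, an ``(L_i, 3)`` array of thinned
        ``(occasion, x, y)`` locations (at most one per occasion).
    exposure
        :class:`~gensmr.geometry.ExposureMatrices` for the marked rows plus
        augmented-row templates.
    """

    cameras: TrapArray
    exposure: ExposureMatrices
    y_resight_marked: np.ndarray
    marked_sex: np.ndarray
    unmarked: pd.DataFrame
    live: TrapArray | None = None
    y_mark: np.ndarray | None = None
    telemetry: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y_resight_marked = np.asarray(self.y_resight_marked, dtype=int)
        if self.y_resight_marked.ndim == 2 and self.y_resight_marked.size == 0:
            self.y_resight_marked = self.y_resight_marked.reshape(
                0, self.cameras.n_traps, self.cameras.n_occasions
            )
        self.marked_sex = np.asarray(self.marked_sex, dtype=int)
        if self.y_mark is not None:
            self.y_mark = np.atleast_2d(np.asarray(self.y_mark, dtype=int))
        if not isinstance(self.unmarked, pd.DataFrame):
            self.unmarked = pd.DataFrame(self.unmarked, columns=list(UNMARKED_COLUMNS))
        self.validate()

    @property
    def n_marked(self) -> int:
        return self.y_resight_marked.shape[0]

    @property
    def n_unmarked_records(self) -> int:
        return len(self.unmarked)

    def y_resight_marked_summed(self) -> np.ndarray:
        """Known-identity counts summed over occasions, ``(n_M, J_R)``."""
        return self.y_resight_marked.sum(axis=2)

    def validate(self) -> None:
        n_m, J_R, K = (
            self.n_marked,
            self.cameras.n_traps,
            self.cameras.n_occasions,
        )
        if self.y_resight_marked.shape != (n_m, J_R, K):
            raise ValueError("y_resight_marked must be (n_M, J_R, K_R)")
        if np.any(self.y_resight_marked < 0):
            raise ValueError("counts must be nonnegative")
        if self.marked_sex.shape != (n_m,):
            raise ValueError("marked_sex must have one entry per marked individual")
        if not np.isin(self.marked_sex, (0, 1)).all():
            raise ValueError("marked_sex entries must be 0 or 1")
        if self.exposure.n_marked != n_m:
            raise ValueError("exposure rows must match the number of marked individuals")
        if self.exposure.m.shape[1] != K:
            raise ValueError("mark-status matrix must have one column per occasion")
        # known-identity counts only while marked; none while unmarked or dead
        bad = (self.y_resight_marked.sum(axis=1) > 0) & (self.exposure.m != 1)
        if np.any(bad):
            raise ValueError(
                "known-identity resighting counts on occasions where the "
                "individual was not marked (or was dead)"
            )
        if self.y_mark is not None:
            if self.live is None:
                raise ValueError("marking counts supplied without a live-trap array")
            if self.y_mark.shape != (n_m, self.live.n_traps):
                raise ValueError("y_mark must be (n_M, J_M)")
            if self.exposure.E_M is None:
                raise ValueError("marking counts supplied without marking exposure")
            if np.any(self.y_mark > self.exposure.E_M):
                raise ValueError("marking counts exceed marking exposure")
        missing = [c for c in UNMARKED_COLUMNS if c not in self.unmarked.columns]
        if missing:
            raise ValueError(f"unmarked table lacks columns {missing}")
        if len(self.unmarked):
            if self.unmarked["trap"].min() < 0 or self.unmarked["trap"].max() >= J_R:
                raise ValueError("unmarked record trap index out of range")
            if self.unmarked["occasion"].min() < 1 or self.unmarked["occasion"].max() > K:
                raise ValueError("unmarked record occasion out of range")
            if not self.unmarked["obs_sex"].isin([-1, 0, 1]).all():
                raise ValueError("obs_sex must be -1 (unknown), 0, or 1")
        if len(self.telemetry) not in (0, n_m):
            raise ValueError("telemetry must have one entry per marked individual")
        for locs in self.telemetry:
            locs = np.atleast_2d(locs)
            if locs.size and locs.shape[1] != 3:
                raise ValueError("telemetry rows must be (occasion, x, y)")
            if locs.size:
                occ = locs[:, 0].astype(int)
                if len(np.unique(occ)) != len(occ):
                    raise ValueError("telemetry must be thinned to one location per occasion")
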