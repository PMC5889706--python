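"""Container and validation for a spatial mark-resight dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..habitat import StateSpace

__all__ = ["SMRData", "thin_locations"]


def thin_locations(
    xy: np.ndarray, times_s: np.ndarray, min_gap_s: float = 3600.0
) -> np.ndarray:
    """Greedy temporal thinning: keep the first fix, then each fix at least
    ``min_gap_s`` seconds after the last kept one.

    Returns the (n, 2) thinned coordinate array; input order must be
    chronological.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    times_s = np.asarray(times_s, dtype=float)
    if xy.shape[0] != times_s.size:
        raise ValueError("coordinates and timestamps disagree in length")
    if times_s.size == 0:
        return xy.reshape(0, 2)
    keep = [0]
    last = times_s[0]
    for i in range(1, times_s.size):
        if times_s[i] - last >= min_gap_s:
            keep.append(i)
            last = times_s[i]
    return xy[keep]


@dataclass
class SMRData:
    """All observed inputs to the generalized SMR model.

    Attributes
    ----------
    ycap
        (n_marked, n_traps) capture counts of the marked individuals.
    Ktrap
        (n_traps,) number of nights each trap was open.
    trap_xy, cam_xy
        (n_traps, 2) and (n_cameras, 2) station coordinates (m).
    ycam
        (n_marked, n_cameras, n_occasions) binary resight histories.
    nU
        (n_cameras, n_occasions) counts of unmarked-individual sightings.
    days
        (n_cameras, n_occasions) integer days since the most recent baiting.
    sex
        (n_marked,) sex codes, female = 1, male = 0.
    telemetry
        List of (n_i, 2) location arrays, one per marked individual (possibly
        empty), already thinned to >= 1 h spacing.
    state_space
        The discrete grid of candidate activity-center cells.
    individual_ids, trap_ids, camera_ids
        Optional labels preserved for I/O round-trips.
    """

    ycap: np.ndarray
    Ktrap: np.ndarray
    trap_xy: np.ndarray
    ycam: np.ndarray
    cam_xy: np.ndarray
    nU: np.ndarray
    days: np.ndarray
    sex: np.ndarray
    telemetry: list[np.ndarray]
    state_space: StateSpace
    individual_ids: list[str] = field(default_factory=list)
    trap_ids: list[str] = field(default_factory=list)
    camera_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ycap = np.atleast_2d(np.asarray(self.ycap, dtype=np.int64))
        self.Ktrap = np.asarray(self.Ktrap, dtype=np.int64)
        self.trap_xy = np.asarray(self.trap_xy, dtype=float).reshape(-1, 2)
        self.ycam = np.asarray(self.ycam, dtype=np.int8)
        self.cam_xy = np.asarray(self.cam_xy, dtype=float).reshape(-1, 2)
        self.nU = np.atleast_2d(np.asarray(self.nU, dtype=np.int64))
        self.days = np.atleast_2d(np.asarray(self.days, dtype=np.int64))
        self.sex = np.asarray(self.sex, dtype=np.int64)
        self.telemetry = [
            np.asarray(t, dtype=float).reshape(-1, 2) for t in self.telemetry
        ]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.n_marked)]
        if not self.trap_ids:
            self.trap_ids = [f"trap{j}" for j in range(self.n_traps)]
        if not self.camera_ids:
            self.camera_ids = [f"cam{j}" for j in range(self.n_cameras)]
        self.validate()

    @property
    def n_marked(self) -> int:
        return self.ycap.shape[0]

    @property
    def n_traps(self) -> int:
        return self.trap_xy.shape[0]

    @property
    def n_cameras(self) -> int:
        return self.cam_xy.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.nU.shape[1]

    def validate(self) -> None:
        """Raise ValueError naming the offending entry on any broken invariant."""
        nm, J = self.n_marked, self.n_traps
        C, K = self.n_cameras, self.n_occasions
        if self.ycap.shape not in ((nm, J), (0, 1) if J == 0 else (nm, J)):
            if not (nm == 0 and self.ycap.size == 0):
                raise ValueError(f"ycap shape {self.ycap.shape} != (n_marked, n_traps)")
        if self.Ktrap.size != J:
            raise ValueError("Ktrap length does not match the trap table")
        if (self.Ktrap < 0).any():
            raise ValueError("trap nights must be >= 0")
        bad = np.argwhere(self.ycap > self.Ktrap[None, :]) if nm and J else []
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"capture count exceeds trap nights for individual "
                f"{self.individual_ids[i]!r} at trap {self.trap_ids[j]!r} "
                f"({self.ycap[i, j]} > {self.Ktrap[j]})"
            )
        if (self.ycap < 0).any():
            raise ValueError("capture counts must be >= 0")
        if nm and self.ycam.shape != (nm, C, K):
            raise ValueError(
                f"ycam shape {self.ycam.shape} != (n_marked, n_cameras, n_occasions)"
            )
        if nm and not np.isin(self.ycam, (0, 1)).all():
            raise ValueError("ycam entries must be binary")
        if self.nU.shape != (C, K):
            raise ValueError(f"nU shape {self.nU.shape} != (n_cameras, n_occasions)")
        if (self.nU < 0).any():
            raise ValueError("unmarked counts must be >= 0")
        if self.days.shape != (C, K):
            raise ValueError(f"days shape {self.days.shape} != (n_cameras, n_occasions)")
        if (self.days < 0).any():
            raise ValueError("days since baiting must be >= 0")
        if self.sex.size != nm:
            raise ValueError("every marked individual needs a recorded sex")
        if nm and not np.isin(self.sex, (0, 1)).all():
            raise ValueError("sex codes must be 0 (male) or 1 (female)")
        if len(self.telemetry) != nm:
            raise ValueError("telemetry list must have one entry per marked individual")
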