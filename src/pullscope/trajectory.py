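"""Trajectory containers and plain-text I/O.

A :class:`Trajectory` stores an ordered stack of frames (coordinates in
nm) together with per-frame time, tether extension delta-x and applied
pulling force, plus run metadata.  Frames are stored densely as a
(n_frames, n_moieties, 3) array; :meth:`Trajectory.frames` yields light
:class:`Frame` views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Frame", "Trajectory"]


@dataclass
class Frame:
    """One snapshot: coordinates (nm) plus pulling bookkeeping."""

    coords: np.ndarray
    time: float = 0.0
    extension: float = 0.0
    force: float = 0.0
    run_id: int = 0
    q: float | None = None


@dataclass
class Trajectory:
    """Ordered frames sharing one moiety list."""

    coords: np.ndarray            # (n_frames, n, 3)
    time: np.ndarray
    extension: np.ndarray | None = None
    force: np.ndarray | None = None
    q: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (n_frames, n, 3)")
        if len(self.time) != len(self.coords):
            raise ValueError("time and coords length mismatch")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("extension", "force", "q"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.coords):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def n_moieties(self) -> int:
        return self.coords.shape[1]

    def frames(self):
        run = self.metadata.get("seed", 0)
        for k in range(self.n_frames):
            yield Frame(
                self.coords[k], float(self.time[k]),
                float(self.extension[k]) if self.extension is not None else 0.0,
                float(self.force[k]) if self.force is not None else 0.0,
                run_id=run,
                q=float(self.q[k]) if self.q is not None else None,
            )

    def compute_q(self, cmap, cdef) -> np.ndarray:
        """Attach and return the per-frame native fraction."""
        from .contacts import native_fraction
        self.q = np.array([native_fraction(c, cmap, cdef) for c in self.coords])
        return self.q

    # ----- plain-text I/O -------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        """Per-frame scalar record (time, extension, force, Q)."""
        data = {"time": self.time}
        for name in ("extension", "force", "q"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)

    def save_xyz(self, path) -> None:
        """Write frames as extended XYZ (coordinates in nm)."""
        n = self.n_moieties
        with open(path, "w") as fh:
            for k in range(self.n_frames):
                fh.write(f"{n}\ntime={self.time[k]:.6f}\n")
                for x, y, z in self.coords[k]:
                    fh.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")

    @classmethod
    def load_xyz(cls, path, table: pd.DataFrame | None = None) -> "Trajectory":
        frames, times = [], []
        with open(path) as fh:
            while True:
                head = fh.readline()
                if not head.strip():
                    break
                n = int(head)
                comment = fh.readline()
                t = len(times)
                for tok in comment.split():
                    if tok.startswith("time="):
                        t = float(tok[5:])
                frames.append([list(map(float, fh.readline().split()[1:4]))
                               for _ in range(n)])
                times.append(t)
        coords = np.array(frames)
        kwargs = {}
        if table is not None:
            for name in ("extension", "force", "q"):
                if name in table:
                    kwargs[name] = table[name].to_numpy()
            if "time" in table:
                times = table["time"].to_numpy()
        return cls(coords, np.asarray(times, dtype=float), **kwargs)
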