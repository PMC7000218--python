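"""Per-cell trace containers and their CSV round-trip.

A :class:`CellTrace` is the atom of fate analysis: one cell's time-indexed
CDK2 (or FRET) ratio series together with its recorded mitosis events and
lineage link. A :class:`TraceEnsemble` is an ordered collection of traces
sharing one acquisition time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACE_SCHEMA_VERSION = "1"

TRACE_COLUMNS = ["cell_id", "parent_id", "well", "condition", "t_hours", "cdk2_ratio"]


@dataclass
class CellTrace:
    """One cell's ratio time series plus mitosis events and lineage link.

    Parameters
    ----------
    cell_id : int
        Unique id within the ensemble.
    t : ndarray
        Sample times in hours, strictly increasing.
    ratio : ndarray
        Cytoplasm/nucleus reporter ratio at each sample.
    division_times : list of float
        Times (hours, on the same axis as ``t``) at which this lineage
        divided. Empty for cells never observed to divide.
    condition : str
        Growth-condition label (e.g. ``"ZD"``, ``"MM"``).
    parent_id : int or None
        Lineage link; ``None`` for founder cells.
    well : str
        Acquisition well label.
    """

    cell_id: int
    t: np.ndarray
    ratio: np.ndarray
    division_times: list[float] = field(default_factory=list)
    condition: str = ""
    parent_id: int | None = None
    well: str = "A1"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.t.shape != self.ratio.shape:
            raise ValueError("t and ratio must have the same shape")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace time axis must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)


@dataclass
class TraceEnsemble:
    """Ordered collection of cell traces on a shared time grid."""

    traces: list[CellTrace] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i: int) -> CellTrace:
        return self.traces[i]

    @property
    def time_grid(self) -> np.ndarray:
        if not self.traces:
            return np.empty(0)
        return self.traces[0].t

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (cell, timepoint)."""
        if not self.traces:
            return pd.DataFrame(columns=TRACE_COLUMNS)
        parts = []
        for tr in self.traces:
            parts.append(
                pd.DataFrame(
                    {
                        "cell_id": tr.cell_id,
                        "parent_id": -1 if tr.parent_id is None else tr.parent_id,
                        "well": tr.well,
                        "condition": tr.condition,
                        "t_hours": tr.t,
                        "cdk2_ratio": tr.ratio,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def division_frame(self) -> pd.DataFrame:
        """One row per recorded mitosis: (cell_id, t_hours)."""
        rows = [
            {"cell_id": tr.cell_id, "t_hours": t}
            for tr in self.traces
            for t in tr.division_times
        ]
        return pd.DataFrame(rows, columns=["cell_id", "t_hours"])

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, divisions: pd.DataFrame | None = None
    ) -> "TraceEnsemble":
        traces = []
        div_map: dict[int, list[float]] = {}
        if divisions is not None and len(divisions):
            for cid, grp in divisions.groupby("cell_id"):
                div_map[int(cid)] = sorted(float(t) for t in grp["t_hours"])
        for cid, grp in df.groupby("cell_id", sort=True):
            grp = grp.sort_values("t_hours")
            pid = int(grp["parent_id"].iloc[0])
            traces.append(
                CellTrace(
                    cell_id=int(cid),
                    t=grp["t_hours"].to_numpy(),
                    ratio=grp["cdk2_ratio"].to_numpy(),
                    division_times=div_map.get(int(cid), []),
                    condition=str(grp["condition"].iloc[0]),
                    parent_id=None if pid < 0 else pid,
                    well=str(grp["well"].iloc[0]),
                )
            )
        return cls(traces)
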