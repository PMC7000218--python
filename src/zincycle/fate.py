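"""Cell-fate analysis of mitosis-aligned CDK2 traces.

After aligning each trace to a mitosis, cells are classified by when (if
ever) the CDK2 ratio first crosses a commitment threshold:

* ``CDK2inc``    — crossing within the decision window (default 4 h):
  born committed to the next cycle;
* ``CDK2emerge`` — crossing after the window: delayed commitment;
* ``CDK2low``    — never crosses: quiescent.

Cells with too little post-mitosis followup are ``unclassifiable`` and are
excluded from fate fractions. A committed cell that rises only to an
intermediate plateau, holds it, and never divides again is flagged as
stalled (the S-phase stall phenotype of zinc-deficient cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import CellTrace, TraceEnsemble

FATE_CLASSES = ("CDK2inc", "CDK2emerge", "CDK2low")
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class ClassifierConfig:
    commit_threshold: float = 1.0  # ratio; reporter cytoplasmic == nuclear
    decision_window: float = 4.0  # hours after mitosis separating inc/emerge
    min_followup: float = 10.0  # hours of post-mitosis data required
    stall_high_threshold: float = 1.5  # plateau band upper edge (exclusive)
    stall_hold: float = 8.0  # hours the plateau must persist
    persistence: int = 2  # consecutive supra-threshold samples for a crossing

    def __post_init__(self) -> None:
        if not self.commit_threshold < self.stall_high_threshold:
            raise ValueError("commit_threshold must be < stall_high_threshold")
        if min(self.decision_window, self.min_followup, self.stall_hold) <= 0:
            raise ValueError("all durations must be positive")


@dataclass
class FateRecord:
    cell_id: int
    fate: str
    commit_time: float | None = None  # hours after mitosis
    stalled: bool = False
    plateau_ratio: float | None = None
    window_bin: str | None = None


def align_to_mitosis(
    ensemble: TraceEnsemble, event_index: int = 0
) -> tuple[list[CellTrace], list[int]]:
    """Re-zero each trace's time axis to its ``event_index``-th mitosis.

    Cells lacking that mitosis are excluded and their ids returned. Aligned
    traces keep only post-alignment division times (the alignment event is
    dropped), so aligning an already-aligned ensemble at the same event is
    a no-op.
    """
    aligned: list[CellTrace] = []
    excluded: list[int] = []
    for tr in ensemble:
        divs = sorted(tr.division_times)
        if len(divs) <= event_index:
            excluded.append(tr.cell_id)
            continue
        t0 = divs[event_index]
        if t0 == 0.0:
            aligned.append(tr)
            continue
        aligned.append(
            CellTrace(
                cell_id=tr.cell_id,
                t=tr.t - t0,
                ratio=tr.ratio.copy(),
                division_times=[d - t0 for d in divs],
                condition=tr.condition,
                parent_id=tr.parent_id,
                well=tr.well,
            )
        )
    return aligned, excluded


def _first_crossing(
    t: np.ndarray, ratio: np.ndarray, threshold: float, persistence: int
) -> float | None:
    """Time of the first upward threshold crossing that persists for
    ``persistence`` consecutive samples (suppresses single-sample noise)."""
    above = ratio >= threshold
    if persistence <= 1:
        idx = np.flatnonzero(above)
        return float(t[idx[0]]) if idx.size else None
    kernel = np.ones(persistence, dtype=int)
    runs = np.convolve(above.astype(int), kernel, mode="valid") == persistence
    idx = np.flatnonzero(runs)
    return float(t[idx[0]]) if idx.size else None


def classify_fate(
    trace: CellTrace, config: ClassifierConfig | None = None
) -> FateRecord:
    """Classify one mitosis-aligned trace.

    The trace must already be aligned (mitosis at t = 0). Followup is the
    time from mitosis to the next division or trace end; traces with less
    than ``min_followup`` are unclassifiable.
    """
    config = config or ClassifierConfig()
    post = trace.t > 0
    t_post, r_post = trace.t[post], trace.ratio[post]
    next_div = min((d for d in trace.division_times if d > 0), default=math.inf)
    followup = min(next_div, t_post[-1]) if t_post.size else 0.0
    if followup < config.min_followup:
        return FateRecord(cell_id=trace.cell_id, fate=UNCLASSIFIABLE)

    sel = t_post < next_div
    commit = _first_crossing(
        t_post[sel], r_post[sel], config.commit_threshold, config.persistence
    )
    if commit is None:
        fate = "CDK2low"
    elif commit <= config.decision_window:
        fate = "CDK2inc"
    else:
        fate = "CDK2emerge"
    rec = FateRecord(cell_id=trace.cell_id, fate=fate, commit_time=commit)
    if fate in ("CDK2inc", "CDK2emerge"):
        rec.stalled, rec.plateau_ratio = detect_stall(trace, config, commit_time=commit)
    return rec


def detect_stall(
    trace: CellTrace,
    config: ClassifierConfig | None = None,
    commit_time: float | None = None,
) -> tuple[bool, float | None]:
    """Decide whether a committed cell stalled at an intermediate plateau.

    Stalled iff, from commitment to trace end, the ratio stays within
    ``[commit_threshold - 0.1, stall_high_threshold)`` for at least
    ``stall_hold`` hours with no further mitosis. The plateau estimate is
    the median ratio over the final ``stall_hold`` hours.
    """
    config = config or ClassifierConfig()
    if commit_time is None:
        post = trace.t > 0
        commit_time = _first_crossing(
            trace.t[post], trace.ratio[post], config.commit_threshold,
            config.persistence,
        )
    if commit_time is None:
        return False, None
    if any(d > commit_time for d in trace.division_times):
        return False, None
    t_end = trace.t[-1]
    if t_end - commit_time < config.stall_hold:
        return False, None
    seg = trace.t >= commit_time
    lo = config.commit_threshold - 0.1
    hi = config.stall_high_threshold
    vals = trace.ratio[seg]
    if not np.all((vals >= lo) & (vals < hi)):
        return False, None
    tail = trace.t >= t_end - config.stall_hold
    return True, float(np.median(trace.ratio[tail]))


def classify_ensemble(
    ensemble: TraceEnsemble,
    config: ClassifierConfig | None = None,
    event_index: int = 0,
) -> pd.DataFrame:
    """Align to mitosis and classify every cell; one row per cell.

    Cells lacking the alignment mitosis get fate ``"no_mitosis"`` so both
    denominators (classified cells vs. all traces) can be reported.
    """
    aligned, excluded = align_to_mitosis(ensemble, event_index)
    rows = []
    for tr in aligned:
        rec = classify_fate(tr, config)
        rows.append(
            {"cell_id": rec.cell_id, "fate": rec.fate, "commit_time": rec.commit_time,
             "stalled": rec.stalled, "plateau_ratio": rec.plateau_ratio}
        )
    for cid in excluded:
        rows.append(
            {"cell_id": cid, "fate": "no_mitosis", "commit_time": None,
             "stalled": False, "plateau_ratio": None}
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "fate", "commit_time", "stalled", "plateau_ratio"]
    ).sort_values("cell_id", ignore_index=True)


def fate_fractions(records: pd.DataFrame) -> pd.Series:
    """Fractions of the three fate classes among classifiable cells."""
    classified = records[records["fate"].isin(FATE_CLASSES)]
    n = len(classified)
    if n == 0:
        return pd.Series({f: math.nan for f in FATE_CLASSES})
    return classified["fate"].value_counts(normalize=True).reindex(
        FATE_CLASSES, fill_value=0.0
    )


def bin_by_mitosis_window(
    ensemble: TraceEnsemble,
    t_perturb: float,
    window: float = 4.0,
    bin_range: tuple[float, float] = (-4.0, 16.0),
    config: ClassifierConfig | None = None,
) -> tuple[dict[str, list[FateRecord]], int]:
    """Group classified cells by when their first mitosis fell relative to a
    perturbation.

    Windows are half-open ``[a, a + window)`` in perturbation-relative time,
    so a mitosis exactly at the perturbation joins the first
    post-perturbation window. Returns the groups plus the count of cells
    whose mitosis fell outside ``bin_range`` (or that never divided).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo, hi = bin_range
    starts = np.arange(lo, hi, window)
    groups: dict[str, list[FateRecord]] = {
        _window_label(a, window): [] for a in starts
    }
    excluded = 0
    aligned, no_mitosis = align_to_mitosis(ensemble, 0)
    excluded += len(no_mitosis)
    first_div = {
        tr.cell_id: min(tr.division_times) for tr in ensemble if tr.division_times
    }
    for tr in aligned:
        rel = first_div[tr.cell_id] - t_perturb
        k = math.floor((rel - lo) / window)
        if rel < lo or rel >= hi:
            excluded += 1
            continue
        rec = classify_fate(tr, config)
        label = _window_label(lo + k * window, window)
        rec.window_bin = label
        groups[label].append(rec)
    return groups, excluded


def _window_label(start: float, window: float) -> str:
    return f"[{start:g},{start + window:g})"


def intermitotic_times(ensemble: TraceEnsemble) -> tuple[np.ndarray, float | None]:
    """Durations between consecutive divisions along each lineage, pooled,
    plus the mode of their 1-h-binned histogram (bin center; ``None`` when
    fewer than two linked divisions exist anywhere)."""
    durations: list[float] = []
    for tr in ensemble:
        divs = sorted(tr.division_times)
        durations.extend(np.diff(divs).tolist())
    arr = np.asarray(durations, dtype=float)
    if arr.size == 0:
        return arr, None
    edges = np.arange(0.0, math.floor(arr.max()) + 2.0)
    hist, _ = np.histogram(arr, bins=edges)
    mode = float(edges[int(np.argmax(hist))] + 0.5)
    return arr, mode


def sort_heatmap(
    ensemble: TraceEnsemble, mode: str = "end_activity", final_window: float = 2.0
) -> tuple[np.ndarray, list[int]]:
    """Stack traces into a matrix ordered for heatmap display.

    ``end_activity``: ascending mean ratio over the final ``final_window``
    hours (CDK2-low rows first). ``mitosis_time``: ascending time of first
    mitosis (never-dividing cells last). Ties break by cell_id.
    """
    if len(ensemble) == 0:
        return np.empty((0, 0)), []
    grid = ensemble.time_grid
    for tr in ensemble:
        if tr.t.shape != grid.shape or not np.allclose(tr.t, grid):
            raise ValueError("traces must share a common time grid")
    if mode == "end_activity":
        keys = [
            (float(tr.ratio[tr.t >= grid[-1] - final_window].mean()), tr.cell_id)
            for tr in ensemble
        ]
    elif mode == "mitosis_time":
        keys = [
            (min(tr.division_times) if tr.division_times else math.inf, tr.cell_id)
            for tr in ensemble
        ]
    else:
        raise ValueError(f"unknown sort mode {mode!r}")
    order = sorted(range(len(ensemble)), key=lambda i: keys[i])
    matrix = np.vstack([ensemble[i].ratio for i in order])
    return matrix, [ensemble[i].cell_id for i in order]


def cdk2_density(
    ensemble: TraceEnsemble, at: float, bins: int | np.ndarray = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram (density) of CDK2 ratios across cells at one
    time point. Integrates to 1 over the binned support."""
    vals = []
    for tr in ensemble:
        if tr.t[0] <= at <= tr.t[-1]:
            idx = int(np.argmin(np.abs(tr.t - at)))
            vals.append(tr.ratio[idx])
    if not vals:
        raise ValueError(f"no cells alive at t = {at}")
    arr = np.asarray(vals)
    if np.isscalar(bins) and arr.min() == arr.max():
        # degenerate support: widen symmetrically so density is defined
        hist, edges = np.histogram(arr, bins=int(bins),
                                   range=(arr.min() - 0.5, arr.max() + 0.5),
                                   density=True)
        return hist, edges
    hist, edges = np.histogram(arr, bins=bins, density=True)
    return hist, edges
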