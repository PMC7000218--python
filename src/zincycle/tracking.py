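"""Frame-to-frame tracking, mitosis detection, and proliferation curves.

Tracking is nearest-centroid assignment with a per-frame displacement gate
(greedy by default, optionally globally optimal via the Hungarian
algorithm). A 1->2 object split is accepted as a mitosis only if the mother
shows the chromatin-condensation signature — a rise in mean H2B intensity
and a drop in nuclear area over the frames preceding the split — which
rejects over-segmentation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .segmentation import LabelMask


@dataclass(frozen=True)
class TrackingParams:
    max_displacement: float = 10.0  # px per frame
    method: str = "greedy"  # or "optimal"


@dataclass(frozen=True)
class MitosisParams:
    window: int = 3  # frames before the split examined for condensation
    intensity_fold: float = 1.3  # required mean-intensity rise (x)
    area_fold: float = 0.6  # required area shrinkage (<= x)
    search_radius: float = 18.0  # px, daughter-to-mother gate


@dataclass
class MitosisEvent:
    frame: int
    mother_track: int
    daughter_tracks: tuple[int, int]
    intensity_fold: float
    area_fold: float


@dataclass
class TrackGraph:
    """Identity/division graph over (frame, label) nodes.

    Node attributes: x, y, area, mean_intensity, track_id. Edge attribute
    ``kind`` is ``"identity"`` or ``"division"``; a division node has one
    outgoing division edge to each of exactly two daughters.
    """

    graph: nx.DiGraph
    frames: list[int]

    def tracks(self) -> dict[int, list[tuple[int, int]]]:
        """track_id -> list of (frame, label) nodes in frame order."""
        out: dict[int, list[tuple[int, int]]] = {}
        for node, data in self.graph.nodes(data=True):
            out.setdefault(data["track_id"], []).append(node)
        for nodes in out.values():
            nodes.sort()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (f, lbl), data in sorted(self.graph.nodes(data=True)):
            parent = -1
            for pred in self.graph.predecessors((f, lbl)):
                if self.graph.edges[pred, (f, lbl)]["kind"] == "division":
                    parent = self.graph.nodes[pred]["track_id"]
            rows.append(
                {"frame": f, "label": lbl, "track_id": data["track_id"],
                 "parent_track_id": parent, "x": data["x"], "y": data["y"]}
            )
        return pd.DataFrame(
            rows, columns=["frame", "label", "track_id", "parent_track_id", "x", "y"]
        )


def _assign(prev: pd.DataFrame, cur: pd.DataFrame, params: TrackingParams):
    """Match previous-frame regions to current-frame regions.

    Returns list of (prev_label, cur_label) pairs within the gate.
    """
    if prev.empty or cur.empty:
        return []
    d = cdist(prev[["x", "y"]].to_numpy(), cur[["x", "y"]].to_numpy())
    gate = params.max_displacement
    pairs = []
    if params.method == "optimal":
        cost = np.where(d <= gate, d, 1e6)
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if d[i, j] <= gate:
                pairs.append((int(prev["label"].iloc[i]), int(cur["label"].iloc[j])))
    elif params.method == "greedy":
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_p: set[int] = set()
        used_c: set[int] = set()
        for i, j in order:
            if d[i, j] > gate:
                break
            if i in used_p or j in used_c:
                continue
            used_p.add(i)
            used_c.add(j)
            pairs.append((int(prev["label"].iloc[i]), int(cur["label"].iloc[j])))
    else:
        raise ValueError(f"unknown tracking method {params.method!r}")
    return pairs


def track_cells(
    masks: list[LabelMask], params: TrackingParams | None = None
) -> TrackGraph:
    """Link per-frame label masks into identity tracks.

    Unmatched current-frame regions start new tracks; unmatched
    previous-frame regions terminate. Frame indices must be strictly
    increasing.
    """
    params = params or TrackingParams()
    if not masks:
        raise ValueError("need at least one frame")
    frames = [m.frame for m in masks]
    if any(b <= a for a, b in zip(frames, frames[1:])):
        raise ValueError("frame ordering must be strictly increasing")

    g = nx.DiGraph()
    for m in masks:
        for _, row in m.regions.iterrows():
            g.add_node(
                (m.frame, int(row["label"])),
                x=float(row["x"]),
                y=float(row["y"]),
                area=float(row["area"]),
                mean_intensity=float(row.get("mean_intensity", np.nan)),
            )
    for prev_m, cur_m in zip(masks, masks[1:]):
        for pl, cl in _assign(prev_m.regions, cur_m.regions, params):
            g.add_edge((prev_m.frame, pl), (cur_m.frame, cl), kind="identity")

    tg = TrackGraph(graph=g, frames=frames)
    _assign_track_ids(tg)
    return tg


def _assign_track_ids(tg: TrackGraph) -> None:
    """Track id = connected chain of identity edges; division edges start
    new tracks for both daughters."""
    g = tg.graph
    next_id = 0
    for node in sorted(g.nodes):
        preds = [
            p for p in g.predecessors(node) if g.edges[p, node]["kind"] == "identity"
        ]
        if preds:
            g.nodes[node]["track_id"] = g.nodes[preds[0]]["track_id"]
        else:
            g.nodes[node]["track_id"] = next_id
            next_id += 1


def _chain_back(g: nx.DiGraph, node, n_frames: int):
    """Walk the identity chain backwards up to n_frames steps."""
    cur = node
    for _ in range(n_frames):
        preds = [
            p for p in g.predecessors(cur) if g.edges[p, cur]["kind"] == "identity"
        ]
        if not preds:
            return None
        cur = preds[0]
    return cur


def detect_mitosis(
    graph: TrackGraph,
    masks: list[LabelMask] | None = None,
    params: MitosisParams | None = None,
) -> list[MitosisEvent]:
    """Find divisions: a new-born object adjacent to a condensing mother.

    A split is accepted only if, over the ``window`` frames before it, the
    mother's mean H2B intensity rose by at least ``intensity_fold`` and its
    area fell to at most ``area_fold`` of its earlier value. Accepted splits
    replace the mother's identity link with division edges to exactly two
    daughters (both starting new tracks); rejected splits leave the newborn
    as an unrelated track.
    """
    params = params or MitosisParams()
    g = graph.graph
    frame_nodes: dict[int, list] = {}
    for node in g.nodes:
        frame_nodes.setdefault(node[0], []).append(node)

    events_raw = []
    used_mothers: set = set()
    used_newborns: set = set()
    for f in sorted(frame_nodes):
        if f == min(frame_nodes):
            continue
        newborns = [
            n
            for n in frame_nodes[f]
            if not any(True for _ in g.predecessors(n)) and n not in used_newborns
        ]
        for nb in newborns:
            if nb in used_newborns:
                continue
            nbx, nby = g.nodes[nb]["x"], g.nodes[nb]["y"]
            best = None
            for m in frame_nodes.get(f - 1, []):
                if m in used_mothers:
                    continue
                dist = np.hypot(g.nodes[m]["x"] - nbx, g.nodes[m]["y"] - nby)
                if dist > params.search_radius:
                    continue
                succs = [
                    s for s in g.successors(m) if g.edges[m, s]["kind"] == "identity"
                ]
                sibling = succs[0] if succs else None
                if sibling is None:
                    # mother unmatched: look for a second newborn nearby
                    others = [
                        o
                        for o in newborns
                        if o is not nb
                        and o not in used_newborns
                        and np.hypot(g.nodes[m]["x"] - g.nodes[o]["x"],
                                     g.nodes[m]["y"] - g.nodes[o]["y"])
                        <= params.search_radius
                    ]
                    if not others:
                        continue
                    sibling = others[0]
                if best is None or dist < best[0]:
                    best = (dist, m, sibling)
            if best is None:
                continue
            _, mother, sibling = best
            anc = _chain_back(g, mother, params.window)
            if anc is None:
                continue
            i_fold = g.nodes[mother]["mean_intensity"] / g.nodes[anc]["mean_intensity"]
            a_fold = g.nodes[mother]["area"] / g.nodes[anc]["area"]
            if not (i_fold >= params.intensity_fold and a_fold <= params.area_fold):
                continue
            used_mothers.add(mother)
            used_newborns.add(nb)
            if sibling in newborns:
                used_newborns.add(sibling)
            if g.has_edge(mother, sibling):
                g.remove_edge(mother, sibling)
            g.add_edge(mother, nb, kind="division")
            g.add_edge(mother, sibling, kind="division")
            events_raw.append((f, mother, (sibling, nb), i_fold, a_fold))

    _assign_track_ids(graph)  # re-derive ids with division cuts
    events = [
        MitosisEvent(
            frame=f,
            mother_track=g.nodes[mother]["track_id"],
            daughter_tracks=(
                g.nodes[d1]["track_id"],
                g.nodes[d2]["track_id"],
            ),
            intensity_fold=float(i_fold),
            area_fold=float(a_fold),
        )
        for f, mother, (d1, d2), i_fold, a_fold in events_raw
    ]
    return events


def proliferation_curve(masks: list[LabelMask]) -> np.ndarray:
    """Per-frame cell count normalized to the first frame."""
    counts = np.array([m.n_labels for m in masks], dtype=float)
    if counts.size == 0 or counts[0] == 0:
        raise ValueError("first frame has no cells; normalization undefined")
    return counts / counts[0]
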