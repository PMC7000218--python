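"""Synthetic movies, trace ensembles, and fixed-cell images with ground truth.

The generator emulates the statistical structure of live-cell CDK2-reporter
experiments under three zinc regimes — zinc-deficient (ZD), minimal medium
(MM), and zinc-replete (ZR) — plus p21-null variants and a
schedule-conditioned experiment in which the chelator is added mid-movie.
Every output carries a ground-truth table so each downstream analysis stage
(segmentation, tracking, mitosis detection, reporter quantification, fate
classification, foci scoring, phase gating) can be verified.

Trace model
-----------
Each cell is followed as a single lineage on the acquisition time grid
(12-minute cadence by default). The mother's CDK2 ratio ramps up to a
maximal value at its division; at mitosis the ratio resets to a low
post-mitotic baseline. The post-mitosis trajectory follows the cell's fate:

* ``CDK2inc`` — the ratio crosses the commitment level within 4 h of birth
  (cells committing very early are born with already-elevated activity);
* ``CDK2emerge`` — the crossing occurs after a delay drawn uniform on
  (4 h, 20 h);
* ``CDK2low`` — the ratio stays at the quiescent baseline.

In zinc-deficient conditions, committed cells rise only to an intermediate
plateau (default ratio 1.2), hold it, and never divide again — the S-phase
stall phenotype. In replete conditions committed cells reach maximal
activity and keep cycling with lognormal inter-mitotic times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .traces import CellTrace, TraceEnsemble

FATES = ("CDK2inc", "CDK2emerge", "CDK2low")

#: Condition label that triggers the schedule-conditioned (chelator-timing)
#: generator path; requires ``perturbation_time`` and ``window_mixture``.
SCHEDULE_CONDITION = "schedule"

#: Default per-condition fate mixtures (p_inc, p_emerge, p_low). The ZD,
#: MM/ZR CDK2low, and p21-null CDK2low components are anchored to reported
#: population fractions; the remaining components are free parameters
#: normalised to sum to 1.
DEFAULT_FATE_MIXTURES: dict[str, tuple[float, float, float]] = {
    "ZD": (0.09, 0.50, 0.41),
    "MM": (0.56, 0.27, 0.17),
    "ZR": (0.60, 0.26, 0.14),
    "MM-p21KO": (0.65, 0.27, 0.08),
    "ZD-p21KO": (0.10, 0.48, 0.42),
}

#: Fate mixtures conditioned on when a cell's mitosis falls relative to the
#: perturbation (window start hour -> mixture). Windows are 4 h wide.
DEFAULT_WINDOW_MIXTURE: dict[float, tuple[float, float, float]] = {
    -4.0: (0.55, 0.30, 0.15),
    0.0: (0.43, 0.40, 0.17),
    4.0: (0.30, 0.47, 0.23),
    8.0: (0.17, 0.50, 0.33),
    12.0: (0.05, 0.50, 0.45),
}

#: Conditions in which committed cells stall at the intermediate plateau
#: instead of completing the cycle.
DEFAULT_STALL_CONDITIONS = frozenset({"ZD", "ZD-p21KO", SCHEDULE_CONDITION})


@dataclass(frozen=True)
class CycleLengthDist:
    """Right-skewed inter-mitotic time distribution.

    Lognormal parameterized by its mode (hours) and the log-scale dispersion
    sigma, so the histogram peak of sampled cycle lengths sits at the mode.
    """

    family: str = "lognormal"
    mode_hours: float = 13.0
    dispersion: float = 0.12

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family != "lognormal":
            raise ValueError(f"unknown cycle-length family {self.family!r}")
        # lognormal mode = exp(mu - sigma^2)
        mu = math.log(self.mode_hours) + self.dispersion**2
        return rng.lognormal(mean=mu, sigma=self.dispersion, size=size)


@dataclass(frozen=True)
class CommitShape:
    """Post-mitosis CDK2 trajectory template.

    baseline: quiescent/post-mitotic ratio; rise_rate: ratio units per hour
    once activity ramps; max_ratio: maximal activity reached before the next
    division; commit_level: the ratio at which the crossing time is anchored.
    """

    baseline: float = 0.5
    rise_rate: float = 0.35
    max_ratio: float = 1.9
    commit_level: float = 1.0


@dataclass
class SyntheticConfig:
    """Study-condition parameters for all synthetic generators."""

    seed: int = 0
    frame_interval: float = 0.2  # hours (12 min)
    duration: float = 60.0  # hours
    image_size: tuple[int, int] = (256, 256)
    n_cells_initial: int = 12
    noise_sd: float = 0.05  # ratio units, additive on traces
    image_noise_sd: float = 2.0  # intensity units, additive on rendered images
    fate_mixture: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FATE_MIXTURES)
    )
    window_mixture: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOW_MIXTURE)
    )
    cycle_length_dist: CycleLengthDist = field(default_factory=CycleLengthDist)
    stall_plateau: float = 1.2
    stall_conditions: frozenset[str] = DEFAULT_STALL_CONDITIONS
    commit_shape: CommitShape = field(default_factory=CommitShape)
    perturbation_time: float | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if self.noise_sd < 0 or self.image_noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cond, mix in self.fate_mixture.items():
            _validate_mixture(mix, f"fate_mixture[{cond!r}]")
        for w, mix in self.window_mixture.items():
            _validate_mixture(mix, f"window_mixture[{w}]")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    def snap(self, t: float) -> float:
        """Snap a time to the acquisition frame grid."""
        return round(t / self.frame_interval) * self.frame_interval


def _validate_mixture(mix, name: str) -> None:
    if len(mix) != 3:
        raise ValueError(f"{name} must have 3 components (inc, emerge, low)")
    if any(not (0.0 <= p <= 1.0) for p in mix):
        raise ValueError(f"{name} components must lie in [0, 1]")
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 within 1e-9")


@dataclass
class GroundTruth:
    """Planted truth for a synthetic dataset.

    ``cells`` always has one row per cell; ``divisions`` lists every true
    division time; ``foci`` and ``phases`` are populated by the fixed-cell
    generators only.
    """

    cells: pd.DataFrame
    divisions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_id", "t_hours"])
    )
    foci: pd.DataFrame | None = None

    @classmethod
    def empty(cls) -> "GroundTruth":
        return cls(
            cells=pd.DataFrame(
                columns=["cell_id", "condition", "fate", "commit_time", "stalled",
                         "plateau_ratio", "first_division"]
            )
        )


def _rng_for(config: SyntheticConfig, *tags) -> np.random.Generator:
    """Deterministic child generator for (config.seed, tags)."""
    entropy = [int(config.seed) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            entropy.extend(tag.encode())
        else:
            entropy.append(int(tag) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Trace ensembles
# ---------------------------------------------------------------------------


def _window_start(t_rel: float, window: float = 4.0) -> float:
    return math.floor(t_rel / window) * window


def _mixture_for(config: SyntheticConfig, condition: str, t_div: float):
    if condition == SCHEDULE_CONDITION:
        if config.perturbation_time is None:
            raise ValueError("schedule condition requires config.perturbation_time")
        rel = t_div - config.perturbation_time
        start = _window_start(rel)
        try:
            return config.window_mixture[start]
        except KeyError:
            raise ValueError(
                f"no window mixture defined for window starting at {start} h"
            ) from None
    try:
        return config.fate_mixture[condition]
    except KeyError:
        raise ValueError(f"unknown condition label {condition!r}") from None


def _post_mitosis_ratio(
    t: np.ndarray, t_birth: float, t_cross: float, shape: CommitShape, top: float
) -> np.ndarray:
    """Committed-cell ramp anchored so the ratio passes commit_level at
    ``t_birth + t_cross``; early committers are born already elevated."""
    ramp = shape.commit_level + shape.rise_rate * (t - t_birth - t_cross)
    return np.clip(ramp, shape.baseline, top)


def _pre_division_ratio(t: np.ndarray, t_div: float, shape: CommitShape) -> np.ndarray:
    """Mother-cell ramp reaching max_ratio at its division."""
    ramp = shape.max_ratio - shape.rise_rate * (t_div - t)
    return np.clip(ramp, shape.baseline, shape.max_ratio)


def generate_trace_ensemble(
    config: SyntheticConfig, condition: str, n_cells: int
) -> tuple[TraceEnsemble, GroundTruth]:
    """Generate ``n_cells`` single-lineage CDK2 traces for one condition.

    Returns the ensemble and a ground-truth table with one row per cell
    (true fate, commit time, stall status, plateau, division times).

    Cells are asynchronous at movie start: the first division falls uniform
    on (2 h, 20 h) — or, for the schedule-conditioned experiment, uniform
    across the binning range around the perturbation — and each cell's fate
    is drawn from the condition (or division-window) mixture.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    # validate the condition label eagerly, even for n_cells == 0
    if condition == SCHEDULE_CONDITION:
        if config.perturbation_time is None:
            raise ValueError("schedule condition requires config.perturbation_time")
    elif condition not in config.fate_mixture:
        raise ValueError(f"unknown condition label {condition!r}")

    if n_cells == 0:
        return TraceEnsemble([]), GroundTruth.empty()

    rng = _rng_for(config, "traces", condition)
    t = config.time_grid
    shape = config.commit_shape
    stalls_here = condition in config.stall_conditions

    traces: list[CellTrace] = []
    rows = []
    div_rows = []
    for cid in range(n_cells):
        if condition == SCHEDULE_CONDITION:
            lo = config.perturbation_time - 4.0
            hi = config.perturbation_time + 16.0
            t1 = config.snap(rng.uniform(lo, hi))
            # snapping must not push the division outside the binning range
            if t1 >= hi:
                t1 -= config.frame_interval
            if t1 < lo:
                t1 += config.frame_interval
        else:
            t1 = config.snap(rng.uniform(2.0, 20.0))
        mixture = _mixture_for(config, condition, t1)
        fate = FATES[rng.choice(3, p=np.asarray(mixture, dtype=float))]

        if fate == "CDK2inc":
            # commit within the 4 h decision window, with a margin so the
            # class is not defined by sampling jitter at the boundary
            t_cross = rng.uniform(0.5, 3.5)
        elif fate == "CDK2emerge":
            t_cross = rng.uniform(4.0, 20.0)
        else:
            t_cross = math.nan

        committed = fate in ("CDK2inc", "CDK2emerge")
        stalled = bool(committed and stalls_here)
        top = config.stall_plateau if stalled else shape.max_ratio

        divisions = [t1]
        ratio = np.empty_like(t)
        pre = t < t1
        ratio[pre] = _pre_division_ratio(t[pre], t1, shape)

        if fate == "CDK2low":
            ratio[~pre] = shape.baseline
        elif stalled:
            ratio[~pre] = _post_mitosis_ratio(t[~pre], t1, t_cross, shape, top)
        else:
            # cycling cell: first post-mitosis segment follows the fate
            # template, then the lineage keeps dividing with lognormal
            # cycle lengths until the movie ends
            t_commit_abs = t1 + t_cross
            rise_done = t_commit_abs + (shape.max_ratio - shape.commit_level) / shape.rise_rate
            t_next = max(t1 + config.cycle_length_dist.sample(rng), rise_done + 0.5)
            t_next = config.snap(t_next)
            seg = ~pre & (t < t_next)
            ratio[seg] = _post_mitosis_ratio(t[seg], t1, t_cross, shape, top)
            t_prev = t_next
            while t_prev <= config.duration:
                divisions.append(t_prev)
                t_after = config.snap(t_prev + config.cycle_length_dist.sample(rng))
                seg = (t >= t_prev) & (t < t_after)
                ratio[seg] = _pre_division_ratio(t[seg], t_after, shape)
                t_prev = t_after

        if config.noise_sd > 0:
            ratio = ratio + rng.normal(0.0, config.noise_sd, size=ratio.shape)
        ratio = np.clip(ratio, 0.0, None)

        divisions = [d for d in divisions if d <= config.duration]
        traces.append(
            CellTrace(
                cell_id=cid,
                t=t.copy(),
                ratio=ratio,
                division_times=divisions,
                condition=condition,
            )
        )
        rows.append(
            {
                "cell_id": cid,
                "condition": condition,
                "fate": fate,
                "commit_time": t_cross,
                "stalled": stalled,
                "plateau_ratio": config.stall_plateau if stalled else math.nan,
                "first_division": t1,
            }
        )
        div_rows.extend({"cell_id": cid, "t_hours": d} for d in divisions)

    truth = GroundTruth(
        cells=pd.DataFrame(rows),
        divisions=pd.DataFrame(div_rows, columns=["cell_id", "t_hours"]),
    )
    return TraceEnsemble(traces), truth


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


@dataclass
class Movie:
    """Two-channel rendered time-lapse with per-frame object truth.

    ``h2b`` and ``cdk2`` are (n_frames, H, W) float32 stacks. ``objects``
    has one row per rendered nucleus per frame: frame, cell_id, x, y,
    radius, true ratio, and whether a division happens at the next frame.
    """

    h2b: np.ndarray
    cdk2: np.ndarray
    objects: pd.DataFrame
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return int(self.h2b.shape[0])


_H2B_LEVEL = 100.0
_CDK2_NUC_LEVEL = 80.0
_CYTO_MARGIN = 6  # cytoplasm disc extends this many px beyond the nucleus
_CONDENSE_RADIUS = (1.0, 0.78, 0.58)  # 3 frames before split
_CONDENSE_TOTAL = (1.0, 1.2, 1.45)  # total-H2B fold over the same frames


def _paint_disc(
    img: np.ndarray, cx: float, cy: float, r: float, value: float,
    mode: str = "max",
) -> None:
    """Paint a filled disc; ``mode="set"`` overwrites (used for nuclei whose
    level must not be masked by a brighter surrounding cytoplasm)."""
    h, w = img.shape
    x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
    y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    region = img[y0:y1, x0:x1]
    if mode == "set":
        region[inside] = value
    else:
        region[inside] = np.maximum(region[inside], value)


def render_movie(ensemble: TraceEnsemble, config: SyntheticConfig) -> Movie:
    """Render an ensemble as a two-channel movie.

    H2B channel: each nucleus is a smoothed disc; over the 3 frames before
    a division its total intensity rises >=30% while its area falls >=40%
    (chromatin condensation), then it splits into two daughter blobs. The
    tracked lineage continues as one daughter; the other persists as an
    independent low-activity cell.

    CDK2 channel: nuclear level is constant and the perinuclear cytoplasm is
    painted at nuclear level x programmed ratio, so ring/nucleus
    quantification recovers the programmed trace.
    """
    t_grid = config.time_grid
    for tr in ensemble:
        if tr.n_samples != t_grid.size or not np.allclose(tr.t, t_grid):
            raise ValueError("all traces must share the config frame grid")

    h, w = config.image_size
    n_frames = t_grid.size
    rng = _rng_for(config, "render")

    # state per rendered object: position, radius, source trace or None
    objects = []  # dicts with mutable state
    margin = 22
    n0 = len(ensemble)
    if n0:
        cols = int(np.ceil(np.sqrt(n0)))
        pitch_x = (w - 2 * margin) / max(cols - 1, 1) if cols > 1 else 0
        rows_n = int(np.ceil(n0 / cols))
        pitch_y = (h - 2 * margin) / max(rows_n - 1, 1) if rows_n > 1 else 0
        min_pitch = 2 * (12 + _CYTO_MARGIN) + 6
        if n0 > 1 and (pitch_x and pitch_x < min_pitch or pitch_y and pitch_y < min_pitch):
            raise ValueError("too many cells for the field: programmed positions would collide")
    for i, tr in enumerate(ensemble):
        cx = margin + (i % cols) * pitch_x if n0 > 1 else w / 2
        cy = margin + (i // cols) * pitch_y if n0 > 1 else h / 2
        objects.append(
            {
                "trace": tr,
                "x": float(cx),
                "y": float(cy),
                "radius": float(rng.uniform(8.0, 12.0)),
                "divisions": sorted(
                    int(round(d / config.frame_interval)) for d in tr.division_times
                ),
                "born": 0,
                "baseline_obj": False,
            }
        )

    h2b = np.zeros((n_frames, h, w), dtype=np.float32)
    cdk2 = np.zeros((n_frames, h, w), dtype=np.float32)
    truth_rows = []
    min_sep = 2 * (12 + _CYTO_MARGIN)

    for f in range(n_frames):
        frame_h2b = np.zeros((h, w), dtype=float)
        frame_cdk2 = np.zeros((h, w), dtype=float)

        # random walk with collision rejection and reflecting bounds
        for obj in objects:
            if f <= obj["born"]:
                continue
            nx = obj["x"] + rng.normal(0, 1.0)
            ny = obj["y"] + rng.normal(0, 1.0)
            bm = obj["radius"] + _CYTO_MARGIN + 2
            nx = min(max(nx, bm), w - 1 - bm)
            ny = min(max(ny, bm), h - 1 - bm)
            ok = all(
                (nx - o["x"]) ** 2 + (ny - o["y"]) ** 2 >= min_sep**2
                for o in objects
                if o is not obj and o["born"] <= f
            )
            if ok:
                obj["x"], obj["y"] = nx, ny

        new_objects = []
        for obj in objects:
            if f < obj["born"]:
                continue
            tr = obj["trace"]
            r = obj["radius"]
            if obj["baseline_obj"]:
                ratio = obj["ratio"]
            else:
                ratio = float(tr.ratio[f])
            # condensation before an upcoming division
            r_scale, i_scale = 1.0, 1.0
            div_frame = None
            for df_ in obj["divisions"]:
                if f < df_ <= f + 3:
                    k = 3 - (df_ - f)  # 0,1,2 for frames -3,-2,-1
                    r_scale = _CONDENSE_RADIUS[k]
                    i_scale = _CONDENSE_TOTAL[k]
                if df_ == f:
                    div_frame = df_
            if div_frame is not None:
                # split: lineage continues in-place, sibling is a new object
                angle = rng.uniform(0, 2 * np.pi)
                rd = 0.75 * r
                off = rd + 2.0
                sx, sy = math.cos(angle) * off, math.sin(angle) * off
                bm = rd + _CYTO_MARGIN + 2
                obj["x"] = min(max(obj["x"] + sx, bm), w - 1 - bm)
                obj["y"] = min(max(obj["y"] + sy, bm), h - 1 - bm)
                obj["radius"] = rd
                sib = {
                    "trace": tr,
                    "x": min(max(obj["x"] - 2 * sx, bm), w - 1 - bm),
                    "y": min(max(obj["y"] - 2 * sy, bm), h - 1 - bm),
                    "radius": rd,
                    "divisions": [],
                    "born": f,
                    "baseline_obj": True,
                    "ratio": config.commit_shape.baseline,
                }
                new_objects.append(sib)
                r = rd
                r_scale, i_scale = 1.0, 1.0
                # paint the sibling this frame too
                _paint_disc(frame_cdk2, sib["x"], sib["y"], rd + _CYTO_MARGIN,
                            _CDK2_NUC_LEVEL * sib["ratio"])
                _paint_disc(frame_cdk2, sib["x"], sib["y"], rd, _CDK2_NUC_LEVEL,
                            mode="set")
                _paint_disc(frame_h2b, sib["x"], sib["y"], rd, _H2B_LEVEL)
                truth_rows.append(
                    {"frame": f, "cell_id": tr.cell_id, "sibling": True,
                     "x": sib["x"], "y": sib["y"], "radius": rd,
                     "ratio": sib["ratio"], "divides_next": False}
                )

            r_draw = r * r_scale
            level = _H2B_LEVEL * i_scale / (r_scale**2)
            _paint_disc(frame_cdk2, obj["x"], obj["y"], r + _CYTO_MARGIN,
                        _CDK2_NUC_LEVEL * max(ratio, 0.0))
            _paint_disc(frame_cdk2, obj["x"], obj["y"], r_draw, _CDK2_NUC_LEVEL,
                        mode="set")
            _paint_disc(frame_h2b, obj["x"], obj["y"], r_draw, level)
            truth_rows.append(
                {"frame": f, "cell_id": tr.cell_id, "sibling": obj["baseline_obj"],
                 "x": obj["x"], "y": obj["y"], "radius": r_draw, "ratio": ratio,
                 "divides_next": any(df_ == f + 1 for df_ in obj["divisions"])}
            )
        objects.extend(new_objects)

        frame_h2b = ndi.gaussian_filter(frame_h2b, 0.6)
        frame_cdk2 = ndi.gaussian_filter(frame_cdk2, 0.6)
        if config.image_noise_sd > 0:
            frame_h2b = frame_h2b + rng.normal(0, config.image_noise_sd, frame_h2b.shape)
            frame_cdk2 = frame_cdk2 + rng.normal(0, config.image_noise_sd, frame_cdk2.shape)
        h2b[f] = np.clip(frame_h2b, 0, None)
        cdk2[f] = np.clip(frame_cdk2, 0, None)

    return Movie(
        h2b=h2b,
        cdk2=cdk2,
        objects=pd.DataFrame(
            truth_rows,
            columns=["frame", "cell_id", "sibling", "x", "y", "radius", "ratio",
                     "divides_next"],
        ),
        frame_interval=config.frame_interval,
    )


# ---------------------------------------------------------------------------
# Fixed-cell images: nuclear foci + pRb
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FociPlantSpec:
    """Geometry ranges for planted nuclear foci.

    Areas are the above-half-maximum footprint of the rendered punctum in
    px^2; eccentricity is that of its moment ellipse.
    """

    area_range: tuple[float, float] = (30.0, 90.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.3)
    per_cell_range: tuple[int, int] = (1, 3)
    amplitude: float = 150.0


@dataclass
class FieldImages:
    """One multi-channel fixed-cell field."""

    nuclei: np.ndarray
    foci: np.ndarray | None = None
    prb: np.ndarray | None = None
    edu: np.ndarray | None = None
    pi: np.ndarray | None = None


_PRB_HYPO_MEAN = 50.0
_PRB_HYPER_MEAN = 400.0
_PRB_LOG_SD = 0.25


def generate_foci_image(
    n_cells: int,
    frac_positive: float | dict[str, float],
    foci_spec: FociPlantSpec | None = None,
    config: SyntheticConfig | None = None,
    *,
    filters=None,
    hyper_fraction: float = 0.4,
    field_size: int = 512,
    cells_per_field: int = 36,
) -> tuple[list[FieldImages], GroundTruth]:
    """Render fixed-cell fields with planted nuclear foci and a bimodal pRb
    channel.

    ``frac_positive`` may be a single proportion or a per-pRb-class map
    ``{"hypo": p, "hyper": p}``; exactly ``round(p * n)`` cells per stratum
    carry at least one planted focus whose area and eccentricity fall
    strictly inside the detection ``filters`` (defaults to
    :class:`zincycle.fixed.FociParams`).
    """
    from .fixed import FociParams  # local import to avoid a cycle

    config = config or SyntheticConfig()
    foci_spec = foci_spec or FociPlantSpec()
    filters = filters or FociParams()

    lo_a, hi_a = foci_spec.area_range
    if not (filters.area_range[0] < lo_a and hi_a < filters.area_range[1]):
        raise ValueError(
            "planted focus area range must lie strictly inside the detection filters"
        )
    if not (0 <= foci_spec.eccentricity_range[0]
            and foci_spec.eccentricity_range[1] < filters.eccentricity_max):
        raise ValueError(
            "planted eccentricity range must lie strictly inside the detection filters"
        )

    if isinstance(frac_positive, dict):
        frac_map = dict(frac_positive)
    else:
        frac_map = {"hypo": float(frac_positive), "hyper": float(frac_positive)}
    for k, p in frac_map.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"frac_positive[{k!r}] must lie in [0, 1]")

    rng = _rng_for(config, "foci")

    # assign pRb class and positivity: exact counts per stratum
    n_hyper = int(round(hyper_fraction * n_cells))
    prb_class = np.array(["hypo"] * n_cells, dtype=object)
    hyper_ids = rng.permutation(n_cells)[:n_hyper]
    prb_class[hyper_ids] = "hyper"
    positive = np.zeros(n_cells, dtype=bool)
    for cls in ("hypo", "hyper"):
        ids = np.flatnonzero(prb_class == cls)
        k = int(round(frac_map.get(cls, 0.0) * ids.size))
        positive[rng.permutation(ids)[:k]] = True

    fields: list[FieldImages] = []
    cell_rows = []
    foci_rows = []
    cid = 0
    n_fields = int(np.ceil(n_cells / cells_per_field)) if n_cells else 0
    for fi in range(n_fields):
        n_here = min(cells_per_field, n_cells - fi * cells_per_field)
        nuc_img = np.zeros((field_size, field_size), dtype=float)
        foci_img = np.zeros_like(nuc_img)
        prb_img = np.zeros_like(nuc_img)
        cols = int(np.ceil(np.sqrt(cells_per_field)))
        pitch = (field_size - 60) / (cols - 1)
        for j in range(n_here):
            gx = 30 + (j % cols) * pitch + rng.uniform(-8, 8)
            gy = 30 + (j // cols) * pitch + rng.uniform(-8, 8)
            r = rng.uniform(8.0, 12.0)
            _paint_disc(nuc_img, gx, gy, r, _H2B_LEVEL)
            mean_prb = _PRB_HYPER_MEAN if prb_class[cid] == "hyper" else _PRB_HYPO_MEAN
            _paint_disc(prb_img, gx, gy, r, rng.lognormal(math.log(mean_prb), _PRB_LOG_SD))
            n_foci = 0
            if positive[cid]:
                n_want = int(rng.integers(foci_spec.per_cell_range[0],
                                          foci_spec.per_cell_range[1] + 1))
                placed: list[tuple[float, float, float]] = []
                for _ in range(n_want):
                    area = rng.uniform(*foci_spec.area_range)
                    ecc = rng.uniform(*foci_spec.eccentricity_range)
                    res = _plant_punctum(
                        foci_img, rng, gx, gy, r, area, ecc,
                        foci_spec.amplitude, placed,
                    )
                    if res is None:
                        continue  # nucleus too crowded; plant fewer foci
                    fx, fy, a_eff, e_eff = res
                    foci_rows.append(
                        {"cell_id": cid, "field": fi, "x": fx, "y": fy,
                         "area": a_eff, "eccentricity": e_eff}
                    )
                    n_foci += 1
            cell_rows.append(
                {"cell_id": cid, "field": fi, "x": gx, "y": gy, "radius": r,
                 "prb_class": prb_class[cid], "n_foci": n_foci,
                 "damage_positive": bool(positive[cid])}
            )
            cid += 1
        for img in (nuc_img, foci_img, prb_img):
            img += rng.normal(0, config.image_noise_sd, img.shape)
            np.clip(img, 0, None, out=img)
        fields.append(FieldImages(nuclei=nuc_img, foci=foci_img, prb=prb_img))

    truth = GroundTruth(
        cells=pd.DataFrame(
            cell_rows,
            columns=["cell_id", "field", "x", "y", "radius", "prb_class",
                     "n_foci", "damage_positive"],
        ),
        foci=pd.DataFrame(
            foci_rows, columns=["cell_id", "field", "x", "y", "area", "eccentricity"]
        ),
    )
    return fields, truth


def _plant_punctum(img, rng, cx, cy, nuc_r, area, ecc, amplitude, placed=None):
    """Add an anisotropic Gaussian punctum inside the nucleus.

    The above-half-max footprint of an elliptical Gaussian with axis sigmas
    (sa, sb) has area pi * 2 ln 2 * sa * sb and eccentricity matching the
    sa/sb axis ratio. ``placed`` holds (x, y, sigma) of earlier puncta in
    the same nucleus; placement keeps puncta separated so their footprints
    stay resolvable, returning ``None`` when no admissible spot is found.
    """
    axis_ratio = math.sqrt(1.0 - ecc**2)  # b/a of the half-max ellipse
    sa = math.sqrt(area / (math.pi * 2.0 * math.log(2.0) * axis_ratio))
    sb = sa * axis_ratio
    theta = rng.uniform(0, math.pi)
    # keep the footprint well inside the nuclear disc
    max_off = max(nuc_r - 1.3 * sa - 1.0, 0.0)
    fx = fy = None
    for _ in range(25):
        ang = rng.uniform(0, 2 * math.pi)
        rad = math.sqrt(rng.uniform(0, 1)) * max_off
        px, py = cx + math.cos(ang) * rad, cy + math.sin(ang) * rad
        if placed and any(
            math.hypot(px - qx, py - qy) < 2.6 * (sa + qs) for qx, qy, qs in placed
        ):
            continue
        fx, fy = px, py
        break
    if fx is None:
        return None
    if placed is not None:
        placed.append((fx, fy, sa))

    size = int(math.ceil(3 * sa)) + 2
    x0, x1 = int(fx) - size, int(fx) + size + 1
    y0, y1 = int(fy) - size, int(fy) + size + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - fx) * ct + (yy - fy) * st
    v = -(xx - fx) * st + (yy - fy) * ct
    blob = amplitude * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))
    img[y0:y1, x0:x1] += blob
    return fx, fy, area, ecc


# ---------------------------------------------------------------------------
# Fixed-cell images: EdU / PI populations
# ---------------------------------------------------------------------------

_PI_2N_INTEGRATED = 2.0e4
_EDU_NEG_MEAN = 20.0
_EDU_NEG_SD = 4.0
_EDU_POS_MEAN = 150.0
_EDU_POS_SD = 15.0

PHASES = ("G0/G1", "S", "G2/M")


def generate_edu_pi_population(
    n_cells: int,
    phase_mixture: dict[str, float],
    background_gradient: float = 30.0,
    config: SyntheticConfig | None = None,
    *,
    field_size: int = 512,
    cells_per_field: int = 36,
) -> tuple[list[FieldImages], GroundTruth]:
    """Render EdU/PI fields with a planted phase mixture.

    Integrated PI intensity is bimodal at the 2N and 4N (=2x) centers;
    S-phase cells carry intermediate DNA content and elevated EdU. A smooth
    additive plane of the given amplitude is applied to the EdU channel to
    exercise block background subtraction.
    """
    config = config or SyntheticConfig()
    probs = np.array([phase_mixture.get(p, 0.0) for p in PHASES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("phase mixture over {G0/G1, S, G2/M} must sum to 1")
    multi = np.count_nonzero(probs) > 1
    if multi and n_cells < 50:
        raise ValueError("need >= 50 cells to estimate 2N/4N modes of a mixed population")

    rng = _rng_for(config, "edu")
    phases = np.array(PHASES, dtype=object)[rng.choice(3, size=n_cells, p=probs)]

    fields: list[FieldImages] = []
    rows = []
    cid = 0
    n_fields = int(np.ceil(n_cells / cells_per_field)) if n_cells else 0
    for fi in range(n_fields):
        n_here = min(cells_per_field, n_cells - fi * cells_per_field)
        nuc_img = np.zeros((field_size, field_size), dtype=float)
        pi_img = np.zeros_like(nuc_img)
        edu_img = np.zeros_like(nuc_img)
        cols = int(np.ceil(np.sqrt(cells_per_field)))
        pitch = (field_size - 60) / (cols - 1)
        for j in range(n_here):
            gx = 30 + (j % cols) * pitch + rng.uniform(-8, 8)
            gy = 30 + (j // cols) * pitch + rng.uniform(-8, 8)
            r = rng.uniform(8.0, 12.0)
            phase = phases[cid]
            if phase == "G0/G1":
                dna = rng.normal(_PI_2N_INTEGRATED, 0.05 * _PI_2N_INTEGRATED)
                dna_class = "2N"
                edu = rng.normal(_EDU_NEG_MEAN, _EDU_NEG_SD)
            elif phase == "G2/M":
                dna = rng.normal(2 * _PI_2N_INTEGRATED, 0.10 * _PI_2N_INTEGRATED)
                dna_class = "4N"
                edu = rng.normal(_EDU_NEG_MEAN, _EDU_NEG_SD)
            else:
                dna = rng.uniform(1.3 * _PI_2N_INTEGRATED, 1.7 * _PI_2N_INTEGRATED)
                dna_class = "intermediate"
                edu = rng.normal(_EDU_POS_MEAN, _EDU_POS_SD)
            edu = max(edu, 1.0)
            area = math.pi * r * r
            _paint_disc(nuc_img, gx, gy, r, _H2B_LEVEL)
            _paint_disc(pi_img, gx, gy, r, dna / area)
            _paint_disc(edu_img, gx, gy, r, edu)
            rows.append(
                {"cell_id": cid, "field": fi, "x": gx, "y": gy, "radius": r,
                 "phase": phase, "dna_class": dna_class,
                 "dna_integrated": dna, "edu_mean": edu}
            )
            cid += 1
        if background_gradient > 0:
            yy, xx = np.mgrid[0:field_size, 0:field_size].astype(float)
            plane = background_gradient * (
                0.6 * xx / field_size + 0.4 * yy / field_size
            )
            edu_img += plane
        for img in (nuc_img, pi_img, edu_img):
            img += rng.normal(0, config.image_noise_sd, img.shape)
            np.clip(img, 0, None, out=img)
        fields.append(FieldImages(nuclei=nuc_img, pi=pi_img, edu=edu_img))

    truth = GroundTruth(
        cells=pd.DataFrame(
            rows,
            columns=["cell_id", "field", "x", "y", "radius", "phase",
                     "dna_class", "dna_integrated", "edu_mean"],
        )
    )
    return fields, truth
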