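"""Fixed-cell image analysis: nuclear foci, pRb classing, EdU/DNA gating.

Implements the fixed-assay arm of the pipeline: per-cell crops for
DNA-damage foci detection (53BP1/RPA2 puncta filtered by size and shape),
hypo/hyper-pRb classification by a two-component mixture on log intensity,
per-block percentile background subtraction for EdU images, integrated
PI-based DNA content with 2N/4N gating, and cell-cycle phase calls from the
2D EdU-vs-DNA plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from skimage import measure
from sklearn.mixture import GaussianMixture

from .segmentation import LabelMask, SegmentationParams, segment_nuclei


@dataclass(frozen=True)
class FociParams:
    """Foci detection filters.

    crop_size: side of the square crop centered on each cell; area_range:
    accepted focus footprint in px^2 (RPA2: 10-100, 53BP1: 10-200);
    eccentricity_max: maximal moment-ellipse eccentricity (0 = circle);
    sensitivity: fraction of the nucleus peak-over-median excursion used as
    the adaptive threshold; noise_floor: minimal threshold in robust sigmas,
    keeping featureless nuclei focus-free.
    """

    crop_size: int = 140
    area_range: tuple[float, float] = (10.0, 200.0)
    eccentricity_max: float = 0.6
    sensitivity: float = 0.5
    noise_floor: float = 5.0

    def __post_init__(self) -> None:
        if not self.area_range[0] < self.area_range[1]:
            raise ValueError("area_range must be (min, max) with min < max")
        if not (0 <= self.eccentricity_max < 1):
            raise ValueError("eccentricity_max must lie in [0, 1)")


RPA2_PARAMS = FociParams(area_range=(10.0, 100.0))
BP53_PARAMS = FociParams(area_range=(10.0, 200.0))


@dataclass
class FixedCellRecord:
    """Per-cell fixed-assay measurements."""

    cell_id: int
    prb_mean: float = math.nan
    prb_class: str | None = None
    p21_mean: float = math.nan
    foci_count: int = 0
    damage_positive: bool = False
    edu_mean_corrected: float = math.nan
    dna_integrated: float = math.nan
    phase: str | None = None
    dna_class: str | None = None


def detect_foci(
    image: np.ndarray, mask: LabelMask, params: FociParams | None = None
) -> pd.DataFrame:
    """Detect nuclear puncta per cell.

    For each cell a ``crop_size`` square around its centroid is examined;
    candidate pixels exceed the nuclear median by the larger of
    ``sensitivity x (peak - median)`` and ``noise_floor`` robust sigmas.
    Connected components are kept if their area falls in ``area_range``,
    their eccentricity is below ``eccentricity_max``, and they overlap the
    cell's own nucleus. Returns one row per focus:
    (label, x, y, area, eccentricity).
    """
    params = params or FociParams()
    img = np.asarray(image, dtype=float)
    half = params.crop_size // 2
    h, w = img.shape
    rows = []
    for _, reg in mask.regions.iterrows():
        lbl = int(reg["label"])
        cx, cy = int(round(reg["x"])), int(round(reg["y"]))
        x0, x1 = max(0, cx - half), min(w, cx + half)
        y0, y1 = max(0, cy - half), min(h, cy + half)
        crop = img[y0:y1, x0:x1]
        nuc = mask.labels[y0:y1, x0:x1] == lbl
        if not nuc.any():
            continue
        nuc_px = crop[nuc]
        # background level/spread from the dim half of the nucleus, so that
        # bright puncta (which can cover a large nuclear fraction) do not
        # inflate the estimate
        bg_px = nuc_px[nuc_px <= np.percentile(nuc_px, 50)]
        bg = float(np.percentile(nuc_px, 20))
        sigma = 1.4826 * float(np.median(np.abs(bg_px - np.median(bg_px)))) or 1e-6
        peak = float(nuc_px.max())
        thr = bg + max(params.sensitivity * (peak - bg),
                       params.noise_floor * sigma)
        cand = measure.label(crop > thr, connectivity=2)
        for p in measure.regionprops(cand):
            if not (params.area_range[0] <= p.area <= params.area_range[1]):
                continue
            if p.eccentricity >= params.eccentricity_max:
                continue
            comp = cand == p.label
            if not np.any(comp & nuc):
                continue
            rows.append(
                {"label": lbl, "x": p.centroid[1] + x0, "y": p.centroid[0] + y0,
                 "area": float(p.area), "eccentricity": float(p.eccentricity)}
            )
    return pd.DataFrame(rows, columns=["label", "x", "y", "area", "eccentricity"])


def damage_fraction(
    records: pd.DataFrame, stratify_by: str = "prb_class"
) -> pd.DataFrame:
    """Fraction of cells positive for damage (>= 1 focus) per stratum."""
    if "damage_positive" not in records:
        records = records.assign(damage_positive=records["foci_count"] >= 1)
    out = []
    for stratum, grp in records.groupby(stratify_by, sort=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"empty stratum {stratum!r} omitted", stacklevel=2)
            continue
        out.append(
            {stratify_by: stratum, "fraction_positive": grp["damage_positive"].mean(),
             "n": n}
        )
    return pd.DataFrame(out, columns=[stratify_by, "fraction_positive", "n"])


def classify_prb(
    prb_mean: np.ndarray | pd.Series,
) -> tuple[np.ndarray, float | None]:
    """Split cells into hypo-/hyper-pRb on log intensity.

    A two-component Gaussian mixture is fit to log intensities; the boundary
    is the equal-posterior point between the component means. Unimodal
    populations produce a single-class result with a warning and a ``None``
    boundary. Returns (labels array of "hypo"/"hyper", boundary intensity).
    """
    vals = np.asarray(prb_mean, dtype=float)
    if vals.size < 20:
        raise ValueError("need at least 20 cells to estimate the pRb split")
    if np.any(vals <= 0):
        raise ValueError("pRb intensities must be positive")
    logv = np.log(vals).reshape(-1, 1)
    if np.ptp(logv) < 1e-12:
        warnings.warn("pRb intensities unimodal (constant); single class",
                      stacklevel=2)
        return np.array(["hypo"] * vals.size, dtype=object), None
    init = np.percentile(logv, [20, 80]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, means_init=init, random_state=0, n_init=1, reg_covar=1e-6
    ).fit(logv)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    lo_c, hi_c = int(np.argmin(mu)), int(np.argmax(mu))
    sep = abs(mu[hi_c] - mu[lo_c]) / max(float(np.mean(sd)), 1e-12)
    if sep < 2.0 or gm.weights_.min() < 0.02:
        warnings.warn("pRb intensity distribution not clearly bimodal; "
                      "single class returned", stacklevel=2)
        return np.array(["hypo"] * vals.size, dtype=object), None
    # equal-posterior boundary between the means
    grid = np.linspace(mu[lo_c], mu[hi_c], 2001).reshape(-1, 1)
    post = gm.predict_proba(grid)
    cross = np.argmin(np.abs(post[:, lo_c] - post[:, hi_c]))
    boundary_log = float(grid[cross, 0])
    labels = np.where(logv.ravel() > boundary_log, "hyper", "hypo").astype(object)
    return labels, float(np.exp(boundary_log))


def block_background_subtract(
    image: np.ndarray, grid: tuple[int, int] = (11, 11), percentile: float = 5.0
) -> np.ndarray:
    """Per-block percentile background subtraction.

    The image is tiled by a ``grid[0] x grid[1]`` array of equal blocks; the
    lowest ``percentile`` intensity of each block is subtracted from that
    block, and negatives are clipped to 0.
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] < grid[0] or img.shape[1] < grid[1]:
        raise ValueError("image smaller than the background grid")
    out = img.copy()
    row_edges = np.linspace(0, img.shape[0], grid[0] + 1).astype(int)
    col_edges = np.linspace(0, img.shape[1], grid[1] + 1).astype(int)
    for r0, r1 in zip(row_edges, row_edges[1:]):
        for c0, c1 in zip(col_edges, col_edges[1:]):
            block = out[r0:r1, c0:c1]
            block -= np.percentile(block, percentile)
    np.clip(out, 0.0, None, out=out)
    return out


@dataclass
class DnaGates:
    """2N/4N gate centers from the integrated-DNA histogram."""

    center_2n: float
    center_4n: float | None
    tolerance: float = 0.25
    single_mode: bool = False

    def classify(self, value: float) -> str:
        if value <= self.center_2n * (1 + self.tolerance):
            return "2N"
        if self.center_4n is not None and value >= self.center_4n * (1 - self.tolerance):
            return "4N"
        return "intermediate"


def integrated_dna(
    mask: LabelMask, pi_image: np.ndarray
) -> pd.DataFrame:
    """Integrated (summed) nuclear PI intensity per cell."""
    img = np.asarray(pi_image, dtype=float)
    sums = ndi.sum_labels(img, mask.labels, index=mask.regions["label"].astype(int))
    return pd.DataFrame(
        {"label": mask.regions["label"].astype(int).to_numpy(),
         "dna_integrated": np.asarray(sums, dtype=float)}
    )


def dna_gates(
    values: np.ndarray | pd.Series, tolerance: float = 0.25, n_bins: int = 64
) -> DnaGates:
    """Locate the 2N and 4N modes of the integrated-DNA histogram.

    The two most prominent peaks of a lightly smoothed histogram define the
    gate centers (the lower is 2N). A single-mode population yields a
    flagged result with an undefined 4N gate.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 50:
        raise ValueError("need at least 50 cells for DNA mode finding")
    hist, edges = np.histogram(vals, bins=n_bins)
    smooth = ndi.gaussian_filter1d(hist.astype(float), 1.5)
    peaks, props = find_peaks(smooth, prominence=max(smooth.max() * 0.05, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(smooth))])
        props = {"prominences": np.array([smooth.max()])}
    order = np.argsort(props["prominences"])[::-1]
    top = sorted(centers[peaks[order[:2]]])
    # a genuine 4N mode sits near twice the 2N mode; two peaks of one mode
    # (histogram wiggle) are rejected by a separation requirement
    if len(top) == 2 and top[1] < 1.4 * top[0]:
        top = [min(top)]
    if len(top) == 1:
        warnings.warn("single DNA mode; 4N gate undefined", stacklevel=2)
        return DnaGates(center_2n=float(top[0]), center_4n=None,
                        tolerance=tolerance, single_mode=True)
    return DnaGates(center_2n=float(top[0]), center_4n=float(top[1]),
                    tolerance=tolerance)


def estimate_edu_threshold(values: np.ndarray | pd.Series) -> float:
    """EdU positivity cut: mean + 3 sd of the EdU-negative mode.

    The negative mode is the peak of a smoothed histogram; its spread is
    estimated robustly from the deviations of values at or below the mode.
    """
    vals = np.asarray(values, dtype=float)
    hist, edges = np.histogram(vals, bins=64)
    smooth = ndi.gaussian_filter1d(hist.astype(float), 1.5)
    centers = (edges[:-1] + edges[1:]) / 2
    mode = float(centers[int(np.argmax(smooth))])
    below = vals[vals <= mode]
    if below.size == 0:
        sd = float(vals.std())
    else:
        sd = 1.4826 * float(np.median(np.abs(below - mode)))
    return mode + 3.0 * sd


def classify_phase(
    edu_corrected: np.ndarray | pd.Series,
    dna_class: np.ndarray | pd.Series,
    edu_threshold: float | None = None,
) -> np.ndarray:
    """Phase call from the 2D EdU-vs-DNA plane.

    EdU+ cells are S regardless of DNA content; EdU- cells are G0/G1 (2N)
    or G2/M (4N); EdU- cells with intermediate DNA are "unclassified".
    """
    edu = np.asarray(edu_corrected, dtype=float)
    dna = np.asarray(dna_class, dtype=object)
    if edu_threshold is None:
        edu_threshold = estimate_edu_threshold(edu)
    out = np.empty(edu.shape, dtype=object)
    pos = edu > edu_threshold
    out[pos] = "S"
    out[~pos & (dna == "2N")] = "G0/G1"
    out[~pos & (dna == "4N")] = "G2/M"
    out[~pos & (dna == "intermediate")] = "unclassified"
    return out


def p21_vs_cdk2(records: pd.DataFrame) -> tuple[pd.DataFrame, int, float | None]:
    """Per-cell (cdk2_ratio, p21_mean) pairs with rank correlation.

    Cells missing either measurement are dropped and counted. The Spearman
    correlation is ``None`` when undefined (fewer than 3 pairs or a constant
    column).
    """
    cols = ["cdk2_ratio", "p21_mean"]
    if records.empty:
        return pd.DataFrame(columns=["cell_id", *cols]), 0, None
    keep = records.dropna(subset=cols)
    dropped = len(records) - len(keep)
    table = keep[["cell_id", *cols]].reset_index(drop=True)
    rho = None
    if len(table) >= 3 and table[cols].nunique().min() > 1:
        rho = float(table[cols].corr(method="spearman").iloc[0, 1])
    return table, dropped, rho


# ---------------------------------------------------------------------------
# Field-level drivers
# ---------------------------------------------------------------------------


def analyze_foci_fields(
    fields,
    foci_params: FociParams | None = None,
    seg_params: SegmentationParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment nuclei per field, measure pRb, detect foci, and class cells.

    Returns (records, foci) tables; records carry field, label, centroid,
    prb_mean, prb_class, foci_count, damage_positive.
    """
    foci_params = foci_params or FociParams()
    rec_rows = []
    foci_tables = []
    for fi, fld in enumerate(fields):
        mask = segment_nuclei(fld.nuclei, seg_params, frame=fi)
        prb_means = ndi.mean(
            np.asarray(fld.prb, dtype=float), mask.labels,
            index=mask.regions["label"].astype(int),
        )
        foci = detect_foci(fld.foci, mask, foci_params)
        foci.insert(0, "field", fi)
        foci_tables.append(foci)
        counts = foci.groupby("label").size() if len(foci) else pd.Series(dtype=int)
        for (_, reg), prb in zip(mask.regions.iterrows(), np.atleast_1d(prb_means)):
            lbl = int(reg["label"])
            rec_rows.append(
                {"field": fi, "label": lbl, "x": reg["x"], "y": reg["y"],
                 "prb_mean": float(prb), "foci_count": int(counts.get(lbl, 0))}
            )
    records = pd.DataFrame(
        rec_rows, columns=["field", "label", "x", "y", "prb_mean", "foci_count"]
    )
    if len(records):
        labels, _ = classify_prb(records["prb_mean"])
        records["prb_class"] = labels
        records["damage_positive"] = records["foci_count"] >= 1
    foci_all = (
        pd.concat(foci_tables, ignore_index=True)
        if foci_tables
        else pd.DataFrame(columns=["field", "label", "x", "y", "area", "eccentricity"])
    )
    return records, foci_all


def analyze_edu_fields(
    fields,
    seg_params: SegmentationParams | None = None,
    edu_threshold: float | None = None,
    background_grid: tuple[int, int] = (11, 11),
) -> pd.DataFrame:
    """Segment nuclei, background-correct EdU, integrate DNA, gate phases."""
    rows = []
    for fi, fld in enumerate(fields):
        mask = segment_nuclei(fld.nuclei, seg_params, frame=fi)
        edu_corr = block_background_subtract(fld.edu, grid=background_grid)
        edu_means = ndi.mean(edu_corr, mask.labels,
                             index=mask.regions["label"].astype(int))
        dna = integrated_dna(mask, fld.pi)
        for (_, reg), edu_m, dna_i in zip(
            mask.regions.iterrows(), np.atleast_1d(edu_means),
            dna["dna_integrated"].to_numpy(),
        ):
            rows.append(
                {"field": fi, "label": int(reg["label"]), "x": reg["x"],
                 "y": reg["y"], "edu_mean_corrected": float(edu_m),
                 "dna_integrated": float(dna_i)}
            )
    records = pd.DataFrame(
        rows, columns=["field", "label", "x", "y", "edu_mean_corrected",
                       "dna_integrated"],
    )
    if len(records):
        gates = dna_gates(records["dna_integrated"])
        records["dna_class"] = [
            gates.classify(v) for v in records["dna_integrated"]
        ]
        records["phase"] = classify_phase(
            records["edu_mean_corrected"], records["dna_class"], edu_threshold
        )
    return records
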