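"""Reporter quantification: CDK2 translocation ratio and FRET Zn calibration.

CDK2 activity is read out as the cytoplasm/nucleus intensity ratio of a
translocation reporter; the cytoplasmic signal is measured in a 3-px-wide
perinuclear ring. Cytosolic Zn concentrations are derived from a FRET
sensor's resting ratio via a Hill-form binding model:

    FS   = (R_rest - R_min) / (R_max - R_min)
    DR   = R_max / R_min
    [Zn] = K_D * ((R_rest - R_min) / (R_max - R_rest))**(1/n)

with dissociation constant K_D in pM and Hill coefficient n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.segmentation import expand_labels

from .segmentation import LabelMask

RING_WIDTH_DEFAULT = 3


@dataclass
class RingMask:
    """Perinuclear rings for every labeled nucleus.

    ``rings`` is a label image in which pixel value i marks the ring of
    nucleus i; rings exclude all nuclei and pixels claimed by a closer
    neighboring nucleus. ``clipped`` lists labels whose nucleus touches the
    image border (their rings are partial but still returned).
    """

    rings: np.ndarray
    width: int
    clipped: frozenset[int]


def perinuclear_ring(mask: LabelMask, width: int = RING_WIDTH_DEFAULT) -> RingMask:
    """Build a ring of the given width immediately outside each nucleus.

    Each background pixel within ``width`` px of a nucleus joins that
    nucleus's ring unless a different nucleus is closer, so rings of
    adjacent cells never overlap or cover foreign nuclei.
    """
    if width < 1:
        raise ValueError("ring width must be >= 1")
    labels = mask.labels
    expanded = expand_labels(labels, distance=width)
    rings = np.where(labels == 0, expanded, 0).astype(labels.dtype)

    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    clipped = frozenset(int(v) for v in np.unique(labels[border]) if v != 0)
    return RingMask(rings=rings, width=width, clipped=clipped)


def cdk2_ratio(cyto_mean: float, nuc_mean: float) -> float:
    """Cytoplasmic / nuclear reporter intensity; the CDK2 activity readout."""
    if nuc_mean <= 0:
        raise ValueError("nuclear intensity must be positive for a defined ratio")
    return float(cyto_mean) / float(nuc_mean)


def fret_ratio(
    fret_cell: float, cfp_cell: float, fret_bg: float = 0.0, cfp_bg: float = 0.0
) -> float:
    """Background-subtracted FRET/CFP ratio for one cell."""
    cfp = cfp_cell - cfp_bg
    if cfp <= 0:
        raise ValueError("CFP signal at or below background; ratio undefined")
    return (fret_cell - fret_bg) / cfp


def estimate_background(image: np.ndarray, labels: np.ndarray,
                        percentile: float = 5.0) -> float:
    """Dark-region background estimate: mean of the lowest ``percentile`` of
    non-cell pixels (automated stand-in for a manually drawn dark ROI)."""
    outside = np.asarray(image, dtype=float)[labels == 0]
    if outside.size == 0:
        return 0.0
    cut = np.percentile(outside, percentile)
    dark = outside[outside <= cut]
    return float(dark.mean()) if dark.size else float(cut)


def quantify_frame(
    reporter_image: np.ndarray,
    mask: LabelMask,
    ring: RingMask | None = None,
    stat: str = "median",
) -> pd.DataFrame:
    """Per-cell nuclear and ring intensities plus the CDK2 ratio.

    The cytoplasmic statistic defaults to the ring median, which is robust
    to bleed-through from neighboring cells; set ``stat="mean"`` for the
    plain mean.
    """
    if ring is None:
        ring = perinuclear_ring(mask)
    img = np.asarray(reporter_image, dtype=float)
    agg = {"median": np.median, "mean": np.mean}[stat]
    rows = []
    for lbl in mask.regions["label"].astype(int):
        nuc_px = img[mask.labels == lbl]
        ring_px = img[ring.rings == lbl]
        nuc_val = float(agg(nuc_px)) if nuc_px.size else np.nan
        ring_val = float(agg(ring_px)) if ring_px.size else np.nan
        ratio = (
            cdk2_ratio(ring_val, nuc_val)
            if np.isfinite(ring_val) and np.isfinite(nuc_val) and nuc_val > 0
            else np.nan
        )
        rows.append(
            {"label": lbl, "nuc_value": nuc_val, "ring_value": ring_val,
             "cdk2_ratio": ratio, "ring_clipped": lbl in ring.clipped}
        )
    return pd.DataFrame(
        rows, columns=["label", "nuc_value", "ring_value", "cdk2_ratio", "ring_clipped"]
    )


def premitosis_average(trace, window: float = 1.0, event_index: int = 0) -> float:
    """Mean ratio over the window preceding a mitosis.

    Samples in ``[t_mitosis - window, t_mitosis)`` are averaged; the mitosis
    frame itself (post-division) is excluded.
    """
    if not trace.division_times:
        raise ValueError("trace has no recorded mitosis")
    try:
        t_m = sorted(trace.division_times)[event_index]
    except IndexError:
        raise ValueError(f"trace has no mitosis with index {event_index}") from None
    sel = (trace.t >= t_m - window) & (trace.t < t_m)
    if not np.any(sel):
        raise ValueError("no samples in the pre-mitosis window")
    return float(trace.ratio[sel].mean())


# ---------------------------------------------------------------------------
# FRET Zn calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationParams:
    """Zn-sensor calibration constants.

    R_rest/R_min/R_max: resting, chelated, and Zn-saturated FRET ratios;
    K_D in pM; n is the Hill coefficient.
    """

    r_rest: float
    r_min: float
    r_max: float
    k_d: float = 5300.0  # pM
    n: float = 0.29

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("R_min must be < R_max")
        if not (self.r_min <= self.r_rest <= self.r_max):
            raise ValueError("R_rest must lie in [R_min, R_max]")
        if self.k_d <= 0:
            raise ValueError("K_D must be positive")
        if not (0 < self.n <= 2):
            raise ValueError("Hill coefficient must lie in (0, 2]")


def dynamic_range(p: CalibrationParams) -> float:
    """Sensor dynamic range DR = R_max / R_min."""
    return p.r_max / p.r_min


def fractional_saturation(p: CalibrationParams) -> float:
    """Occupied sensor fraction FS = (R_rest - R_min)/(R_max - R_min)."""
    return (p.r_rest - p.r_min) / (p.r_max - p.r_min)


def zn_concentration(p: CalibrationParams) -> float:
    """Invert the Hill response: [Zn] = K_D ((R_rest-R_min)/(R_max-R_rest))^(1/n) in pM."""
    if p.r_rest >= p.r_max:
        raise ValueError("R_rest at R_max implies saturating (infinite) concentration")
    num = p.r_rest - p.r_min
    if num < 0:
        raise ValueError("R_rest below R_min; negative ratio argument")
    if num == 0:
        return 0.0
    return p.k_d * (num / (p.r_max - p.r_rest)) ** (1.0 / p.n)


def hill_response(zn_pm: float, p: CalibrationParams) -> float:
    """Forward Hill model: resting ratio produced by a given [Zn] in pM.

    Inverse of :func:`zn_concentration`; useful for round-trip validation.
    """
    if zn_pm < 0:
        raise ValueError("concentration must be non-negative")
    occ = (zn_pm / p.k_d) ** p.n
    fs = occ / (1.0 + occ)
    return p.r_min + fs * (p.r_max - p.r_min)
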