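"""Plate-level assay quantifications.

Covers the bulk readouts that accompany the single-cell work: CellTiter-Glo
viability normalisation (blank-subtracted, scaled to the unirradiated
control), colony counting from thresholded well images, CFDA-uptake flow
cytometry (scatter-based debris removal, unstained-reference positive gate,
MFI), sEV dosing arithmetic (particles per cell), and mitochondrial
stress-test metrics from 4-phase oxygen-consumption-rate traces.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .imgseg import label_objects, rolling_ball, threshold_mask
from skimage import measure

__all__ = [
    "AssayError",
    "TraceInvalidError",
    "ColonyConfig",
    "ColonyResult",
    "FlowGateConfig",
    "PositiveGateResult",
    "SeahorseMetrics",
    "normalize_viability",
    "quantify_colonies",
    "gate_singlets",
    "gate_positive",
    "subgate_divisions",
    "sev_dose",
    "seahorse_metrics",
]

#: Canonical mitochondrial stress-test phase order.
OCR_PHASES = ("basal", "oligomycin", "fccp", "rot_aa")


class AssayError(ValueError):
    """Raised when a plate assay's controls invalidate normalisation."""


class TraceInvalidError(ValueError):
    """Raised when an OCR trace violates the stress-test structure."""


def normalize_viability(lum_treated, lum_blank, lum_zero_dose) -> float:
    """Percent viability from luminescence readings.

    ``100 * (treated - blank) / (zero_dose - blank)``; replicate wells for
    any of the three readings are averaged before normalisation. The result
    is invariant to any affine rescaling of the luminometer (gain and
    offset cancel).
    """
    treated = float(np.mean(lum_treated))
    blank = float(np.mean(lum_blank))
    zero = float(np.mean(lum_zero_dose))
    if zero <= blank:
        raise AssayError(
            "assay failed: zero-dose control does not exceed the blank "
            f"(control {zero}, blank {blank})"
        )
    return 100.0 * (treated - blank) / (zero - blank)


@dataclass
class ColonyConfig:
    """Colony-scale segmentation parameters (coarser than single cells)."""

    rolling_ball_radius: float = 50.0
    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    min_area_px: int = 100
    merged_circularity: float = 0.8  # below this, flag as suspected merge
    noise_floor_k: float = 5.0  # robust floor under the automatic threshold
    pixel_size_um: float | None = None


@dataclass
class ColonyResult:
    count: int
    areas_px: np.ndarray
    areas_um2: np.ndarray | None
    table: pd.DataFrame  # colony_id, centroid, area_px, circularity, merged_suspect


def quantify_colonies(image: np.ndarray, config: ColonyConfig | None = None) -> ColonyResult:
    """Count colonies and measure their areas in a well image.

    Pipeline: rolling-ball background subtraction -> threshold (manual
    value or Otsu) -> 8-connected labeling with a colony-scale minimum
    area. Touching colonies are not split; objects with low circularity
    (4 pi A / P^2 below ``merged_circularity``) are flagged as suspected
    merges.
    """
    config = config or ColonyConfig()
    img = rolling_ball(np.asarray(image, dtype=float), config.rolling_ball_radius)
    if config.threshold_mode == "manual":
        mask = threshold_mask(img, "manual", config.threshold_value)
    else:
        # automatic threshold guarded by a robust noise floor, so an empty
        # well yields no colonies instead of thresholding inside the noise
        med = np.median(img)
        mad = np.median(np.abs(img - med))
        floor = med + config.noise_floor_k * 1.4826 * mad
        try:
            otsu_mask = threshold_mask(img, "otsu")
            thr = img[otsu_mask].min() if otsu_mask.any() else np.inf
        except ValueError:
            thr = np.inf
        mask = img >= max(thr, floor)
    objects = label_objects(mask, config.min_area_px)
    rows = []
    for prop in measure.regionprops(objects.label_image):
        perim = prop.perimeter if prop.perimeter > 0 else np.nan
        circ = 4 * np.pi * prop.area / perim**2 if np.isfinite(perim) else np.nan
        rows.append(
            {
                "colony_id": prop.label,
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "area_px": int(prop.area),
                "circularity": circ,
                "merged_suspect": bool(
                    np.isfinite(circ) and circ < config.merged_circularity
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "colony_id", "centroid_row", "centroid_col", "area_px",
            "circularity", "merged_suspect",
        ],
    )
    areas_px = table["area_px"].to_numpy(dtype=float)
    areas_um2 = (
        areas_px * config.pixel_size_um**2 if config.pixel_size_um else None
    )
    return ColonyResult(
        count=len(table), areas_px=areas_px, areas_um2=areas_um2, table=table
    )


@dataclass
class FlowGateConfig:
    """Rectangular scatter gate separating intact cells from debris.

    Defaults match the synthetic generator's populations (debris at roughly
    a tenth of the cell scatter); for real exports set the bounds from the
    instrument's scatter scale.
    """

    fsc_min: float = 15000.0
    ssc_min: float = 8000.0
    fsc_max: float = np.inf
    ssc_max: float = np.inf


def gate_singlets(events: pd.DataFrame, config: FlowGateConfig | None = None) -> pd.DataFrame:
    """Remove the low-FSC/low-SSC debris cluster with a rectangular gate."""
    if len(events) == 0:
        raise ValueError("empty event table")
    for col in ("FSC", "SSC"):
        if col not in events.columns:
            raise ValueError(f"missing column {col!r}")
    config = config or FlowGateConfig()
    keep = (
        (events["FSC"] >= config.fsc_min)
        & (events["FSC"] <= config.fsc_max)
        & (events["SSC"] >= config.ssc_min)
        & (events["SSC"] <= config.ssc_max)
    )
    return events.loc[keep].reset_index(drop=True)


@dataclass
class PositiveGateResult:
    gate: float
    positive_fraction: float
    mfi_all: float
    mfi_positive: float
    n_events: int
    n_positive: int


def gate_positive(
    events: pd.DataFrame,
    unstained_reference: pd.DataFrame,
    percentile: float = 99.0,
    fluorescence_col: str = "FL1",
    mfi: str = "arithmetic",
) -> PositiveGateResult:
    """Positive-uptake gating against an unstained reference sample.

    The gate is the given percentile of the unstained reference's
    fluorescence; events above it are positive. MFI is the arithmetic mean
    fluorescence by default (``mfi='geometric'`` for the log-scale
    convention), reported both for all events and for positives only. Both
    tables should already be singlet-gated.
    """
    if len(events) == 0 or len(unstained_reference) == 0:
        raise ValueError("both event tables must be non-empty")
    fl = events[fluorescence_col].to_numpy(dtype=float)
    ref = unstained_reference[fluorescence_col].to_numpy(dtype=float)
    gate = float(np.percentile(ref, percentile))
    positive = fl > gate

    def _mfi(x: np.ndarray) -> float:
        if x.size == 0:
            return np.nan
        if mfi == "geometric":
            return float(np.exp(np.mean(np.log(np.clip(x, 1e-12, None)))))
        return float(np.mean(x))

    return PositiveGateResult(
        gate=gate,
        positive_fraction=float(positive.mean()),
        mfi_all=_mfi(fl),
        mfi_positive=_mfi(fl[positive]),
        n_events=int(fl.size),
        n_positive=int(positive.sum()),
    )


def subgate_divisions(
    events: pd.DataFrame,
    gate: float,
    fluorescence_col: str = "FL1",
    max_generations: int = 6,
) -> pd.DataFrame:
    """Assign positive events to division generations by 2x dye dilution.

    Optional sub-gating of stained cells undergoing multiple divisions:
    peaks are sought in the histogram of log2 fluorescence above the gate,
    then each event is assigned to the nearest generation assuming one
    2-fold dilution per division from the brightest peak. Returns the
    positive events with ``generation`` (0 = undivided) appended.
    """
    pos = events.loc[events[fluorescence_col] > gate].copy()
    if len(pos) == 0:
        pos["generation"] = pd.Series(dtype=int)
        return pos
    log2f = np.log2(pos[fluorescence_col].to_numpy(dtype=float))
    hist, edges = np.histogram(log2f, bins=80)
    centers = (edges[:-1] + edges[1:]) / 2
    peaks, _ = find_peaks(hist, prominence=max(2, 0.05 * hist.max()))
    top = centers[peaks].max() if peaks.size else log2f.max()
    gen = np.clip(np.round(top - log2f), 0, max_generations).astype(int)
    pos["generation"] = gen
    return pos


def sev_dose(particle_concentration: float, volume: float, n_cells: float) -> float:
    """Particles per cell: concentration x volume / number of cells.

    Nanoparticle-tracking concentrations are per-volume; pass volume in the
    same units so the product is total particles.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if particle_concentration < 0 or volume < 0:
        raise ValueError("concentration and volume must be >= 0")
    return particle_concentration * volume / n_cells


@dataclass
class SeahorseMetrics:
    """Mitochondrial stress-test summary (units follow the input trace)."""

    nonmito: float
    basal_respiration: float
    maximal_respiration: float
    spare_capacity: float
    spare_capacity_pct: float

    def summary(self) -> str:
        return (
            f"non-mitochondrial OCR : {self.nonmito:.3g}\n"
            f"basal respiration     : {self.basal_respiration:.3g}\n"
            f"maximal respiration   : {self.maximal_respiration:.3g}\n"
            f"spare capacity        : {self.spare_capacity:.3g}"
            f" ({self.spare_capacity_pct:.1f}% of basal)"
        )


def seahorse_metrics(trace: pd.DataFrame) -> SeahorseMetrics:
    """Stress-test metrics from a 4-phase OCR trace.

    Non-mitochondrial OCR = mean of the rotenone/antimycin-A phase; basal
    respiration = last pre-injection (basal-phase) measurement minus
    non-mitochondrial; maximal respiration = FCCP-phase maximum minus
    non-mitochondrial; spare capacity = maximal - basal, also expressed as
    a percent of basal. Phases must appear in canonical order with at
    least one measurement each.
    """
    for col in ("ocr", "phase"):
        if col not in trace.columns:
            raise ValueError(f"trace missing column {col!r}")
    phases_present = list(dict.fromkeys(trace["phase"]))
    missing = [p for p in OCR_PHASES if p not in phases_present]
    if missing:
        raise TraceInvalidError(f"trace missing phases: {missing}")
    if phases_present != list(OCR_PHASES):
        raise TraceInvalidError(
            f"phases must appear in canonical order {OCR_PHASES}: got {phases_present}"
        )
    nonmito = float(trace.loc[trace["phase"] == "rot_aa", "ocr"].mean())
    basal_raw = float(trace.loc[trace["phase"] == "basal", "ocr"].iloc[-1])
    fccp_max = float(trace.loc[trace["phase"] == "fccp", "ocr"].max())
    basal = basal_raw - nonmito
    if basal <= 0:
        raise TraceInvalidError(
            "trace invalid: basal respiration non-positive after "
            "non-mitochondrial subtraction"
        )
    maximal = fccp_max - nonmito
    spare = maximal - basal
    return SeahorseMetrics(
        nonmito=nonmito,
        basal_respiration=basal,
        maximal_respiration=maximal,
        spare_capacity=spare,
        spare_capacity_pct=100.0 * spare / basal,
    )
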