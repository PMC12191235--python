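"""Synthetic-data generators with machine-readable ground truth.

Every downstream stage of the package (segmentation, tracking, fate calling,
foci counting, flow gating, mitochondrial-stress metrics) is testable against
data generated here, because no suitable public imaging dataset exists for
the assays the package quantifies.

The generators emulate the statistical structure the analysis assumes:

* **GEDI timelapse** — cells as isotropic Gaussian blobs with constant
  per-cell red (mApple) intensity; the green (GC150) channel follows
  ``green = red * r(t)`` where the ratio steps from ``r_live`` to ``r_dead``
  at an exponentially distributed death time (group-specific hazards encode
  dose-dependent radioprotection); dead cells detach and vanish from the
  field after a delay.
* **Foci stacks** — Poisson-distributed DNA-damage puncta per nucleus,
  rendered as PSF-shaped spots an order of magnitude brighter than the
  in-cell background, for 53BP1 (red) and gamma-H2AX (green) counting.
* **Colony images** — disk-shaped colonies above background.
* **Flow-cytometry events** — log-normal unstained population, a stained
  population shifted by a known factor (halved per cell division), and a
  low-FSC/SSC debris cluster.
* **OCR traces** — 4-phase mitochondrial stress test (basal, oligomycin,
  FCCP, rotenone/antimycin-A).

All randomness flows through :func:`numpy.random.default_rng` seeded from the
parameter objects; identical seed and parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FrameStack

__all__ = [
    "TimelapseParams",
    "GroundTruth",
    "gen_timelapse",
    "gen_foci_stack",
    "gen_colony_image",
    "gen_flow_events",
    "gen_ocr_trace",
    "sample_death_times",
    "tracks_from_truth",
]

#: Default observation schedule, hours post-irradiation.
DEFAULT_SCHEDULE = (0.0, 6.0, 12.0, 18.0)

#: Default group death hazards (events/hour): untreated control vs cells
#: pre-treated with a high dose of radioresistant-cell-derived sEVs.
#: The 3:1 ratio reproduces the dose-dependent radioprotection effect size
#: used throughout the test-bench.
DEFAULT_HAZARDS = {"control": 0.12, "sev_high": 0.04}


@dataclass
class GroundTruth:
    """Machine-readable truth emitted alongside every synthetic dataset.

    Only the fields relevant to the generating assay are populated.
    """

    cells: pd.DataFrame | None = None  # per-cell: id, group, row, col, radius, ...
    foci: pd.DataFrame | None = None  # per-cell true puncta counts
    foci_points: pd.DataFrame | None = None  # per-punctum positions
    colonies: pd.DataFrame | None = None  # per-colony geometry
    flow: pd.DataFrame | None = None  # per-event labels
    scalars: dict = field(default_factory=dict)  # assay-level truth values


@dataclass
class TimelapseParams:
    """Parameters of the GEDI timelapse generator.

    Attributes
    ----------
    n_cells
        Total number of cells, split as evenly as possible across the groups
        of ``hazard_per_group`` (insertion order).
    field_size
        Field of view in pixels, (rows, cols).
    cell_radius_px
        (mean, sd) of the per-cell Gaussian-blob radius; the blob sigma is
        radius / 2.
    red_intensity
        (mu, sigma) of the log-normal per-cell mApple amplitude, in log
        intensity units; exp(mu) is the median amplitude (a.u.).
    r_live, r_dead
        GEDI ratio (green/red) before and after apoptotic commitment.
    hazard_per_group
        Death hazard per condition, events/hour; exponential by default,
        Weibull when ``weibull_shape != 1``.
    weibull_shape
        Shape of the Weibull death-time distribution (1 = exponential).
    ramp_duration_h
        Duration of the live-to-dead ratio transition; 0 gives a step.
    detach_delay_h
        Hours between apoptotic commitment and detachment from the plate.
    detach_prob
        Fraction of dead cells that detach (disappear from the FOV).
    background_level
        Additive background (a.u.).
    noise_sigma
        Gaussian read-noise sigma (a.u.).
    poisson_noise
        Add Poisson shot noise on pixel means.
    timepoints_h
        Observation schedule, hours post-irradiation, strictly increasing.
    jitter_px
        Per-timepoint Gaussian jitter of cell centroids (small drift only).
    min_separation_factor
        Minimum centre-to-centre distance between cells, in units of the sum
        of their radii (default leaves cells non-overlapping).
    seed
        RNG seed.
    """

    n_cells: int = 400
    field_size: tuple[int, int] = (768, 768)
    cell_radius_px: tuple[float, float] = (6.0, 1.0)
    red_intensity: tuple[float, float] = (6.2, 0.25)
    r_live: float = 0.5
    r_dead: float = 1.5
    hazard_per_group: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARDS)
    )
    weibull_shape: float = 1.0
    ramp_duration_h: float = 0.0
    detach_delay_h: float = 6.0
    detach_prob: float = 0.8
    background_level: float = 100.0
    noise_sigma: float = 5.0
    poisson_noise: bool = False
    timepoints_h: Sequence[float] = DEFAULT_SCHEDULE
    jitter_px: float = 0.7
    min_separation_factor: float = 1.6
    seed: int = 0

    def validate(self) -> None:
        if not (self.r_dead > self.r_live > 0):
            raise ValueError("require r_dead > r_live > 0")
        if any(h < 0 for h in self.hazard_per_group.values()):
            raise ValueError("hazards must be >= 0")
        tp = np.asarray(self.timepoints_h, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 <= self.detach_prob <= 1:
            raise ValueError("detach_prob must be in [0, 1]")

    def asdict(self) -> dict:
        d = asdict(self)
        d["hazard_per_group"] = dict(self.hazard_per_group)
        d["timepoints_h"] = list(self.timepoints_h)
        return d


def sample_death_times(
    hazard: float, n: int, rng: np.random.Generator, shape: float = 1.0
) -> np.ndarray:
    """Draw death times (hours) from a Weibull hazard; shape 1 = exponential.

    A hazard of 0 yields +inf (the cell never dies).
    """
    if hazard < 0:
        raise ValueError("hazard must be >= 0")
    if n == 0:
        return np.empty(0)
    if hazard == 0:
        return np.full(n, np.inf)
    scale = 1.0 / hazard
    if shape == 1.0:
        return rng.exponential(scale, size=n)
    return scale * rng.weibull(shape, size=n)


def _split_groups(n_total: int, groups: Sequence[str]) -> list[str]:
    """Assign n_total cells to groups as evenly as possible, in group order."""
    per, extra = divmod(n_total, len(groups))
    out: list[str] = []
    for i, g in enumerate(groups):
        out.extend([g] * (per + (1 if i < extra else 0)))
    return out


def _place_centres(
    n: int,
    field: tuple[int, int],
    radii: np.ndarray,
    min_sep_factor: float,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Rejection-sample centres keeping cells separated; (row, col), 0-based."""
    rows, cols = field
    centres = np.empty((n, 2))
    for i in range(n):
        margin = radii[i] + 2
        for _ in range(max_tries):
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            if i == 0:
                break
            d = np.hypot(centres[:i, 0] - r, centres[:i, 1] - c)
            if np.all(d >= min_sep_factor * (radii[:i] + radii[i])):
                break
        centres[i] = (r, c)
    return centres


def _add_gaussian_blob(
    img: np.ndarray, row: float, col: float, sigma: float, amp: float
) -> None:
    """Accumulate an isotropic Gaussian blob in place (4-sigma support)."""
    half = int(np.ceil(4 * sigma))
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0c, r1c = max(r0, 0), min(r1, img.shape[0])
    c0c, c1c = max(c0, 0), min(c1, img.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None] - row
    cc = np.arange(c0c, c1c)[None, :] - col
    img[r0c:r1c, c0c:c1c] += amp * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _add_soft_disk(
    img: np.ndarray, row: float, col: float, radius: float, amp: float, edge: float = 1.5
) -> None:
    """Accumulate a flat disk with a soft (linear) edge in place.

    The edge ramp is centred on ``radius`` (half-amplitude at d == radius),
    so a half-maximum threshold recovers the nominal disk area.
    """
    half = int(np.ceil(radius + edge)) + 1
    r0c, r1c = max(int(row) - half, 0), min(int(row) + half + 1, img.shape[0])
    c0c, c1c = max(int(col) - half, 0), min(int(col) + half + 1, img.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None] - row
    cc = np.arange(c0c, c1c)[None, :] - col
    d = np.hypot(rr, cc)
    img[r0c:r1c, c0c:c1c] += amp * np.clip((radius + edge / 2 - d) / edge, 0.0, 1.0)


def _finish_image(
    img: np.ndarray,
    background: float,
    noise_sigma: float,
    poisson: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    img = img + background
    if poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, None).astype(np.float32)


def gen_timelapse(params: TimelapseParams) -> tuple[list[FrameStack], GroundTruth]:
    """Render a GEDI two-channel timelapse plus per-cell ground truth.

    Returns one :class:`FrameStack` per scheduled timepoint and a truth table
    with each cell's group, base centroid, radius, red amplitude, true death
    time (hours; inf if it never dies within the model) and true detachment
    time (NaN if the cell never detaches).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    timepoints = [float(t) for t in params.timepoints_h]
    groups = list(params.hazard_per_group)

    n = params.n_cells
    if n == 0:
        cells = pd.DataFrame(
            columns=[
                "cell_id", "group", "row", "col", "radius_px", "red_amp",
                "death_time_h", "detach_time_h",
            ]
        )
        frames = []
        for t in timepoints:
            zero = np.zeros(params.field_size)
            frames.append(
                FrameStack(
                    channels={
                        "red": _finish_image(
                            zero.copy(), params.background_level,
                            params.noise_sigma, params.poisson_noise, rng,
                        ),
                        "green": _finish_image(
                            zero.copy(), params.background_level,
                            params.noise_sigma, params.poisson_noise, rng,
                        ),
                    },
                    timepoint_h=t,
                )
            )
        return frames, GroundTruth(cells=cells)

    group_of = _split_groups(n, groups)
    radii = np.clip(
        rng.normal(params.cell_radius_px[0], params.cell_radius_px[1], size=n),
        2.0,
        None,
    )
    centres = _place_centres(
        n, params.field_size, radii, params.min_separation_factor, rng
    )
    red_amp = rng.lognormal(params.red_intensity[0], params.red_intensity[1], size=n)

    death = np.empty(n)
    for g in groups:
        idx = [i for i in range(n) if group_of[i] == g]
        death[idx] = sample_death_times(
            params.hazard_per_group[g], len(idx), rng, params.weibull_shape
        )

    detaches = rng.random(n) < params.detach_prob
    detach_time = np.where(detaches, death + params.detach_delay_h, np.inf)

    # per-timepoint centroid jitter (small drift; no migration model)
    jitter = rng.normal(0.0, params.jitter_px, size=(len(timepoints), n, 2))

    frames: list[FrameStack] = []
    for k, t in enumerate(timepoints):
        red = np.zeros(params.field_size)
        green = np.zeros(params.field_size)
        for i in range(n):
            if t >= detach_time[i]:
                continue  # detached: gone from the field of view
            if params.ramp_duration_h > 0 and death[i] < np.inf:
                frac = np.clip((t - death[i]) / params.ramp_duration_h, 0.0, 1.0)
                r_t = params.r_live + frac * (params.r_dead - params.r_live)
            else:
                r_t = params.r_dead if t >= death[i] else params.r_live
            row = centres[i, 0] + jitter[k, i, 0]
            col = centres[i, 1] + jitter[k, i, 1]
            sigma = radii[i] / 2.0
            _add_gaussian_blob(red, row, col, sigma, red_amp[i])
            _add_gaussian_blob(green, row, col, sigma, red_amp[i] * r_t)
        frames.append(
            FrameStack(
                channels={
                    "red": _finish_image(
                        red, params.background_level, params.noise_sigma,
                        params.poisson_noise, rng,
                    ),
                    "green": _finish_image(
                        green, params.background_level, params.noise_sigma,
                        params.poisson_noise, rng,
                    ),
                },
                timepoint_h=t,
            )
        )

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "group": group_of,
            "row": centres[:, 0],
            "col": centres[:, 1],
            "radius_px": radii,
            "red_amp": red_amp,
            "death_time_h": death,
            "detach_time_h": np.where(np.isinf(detach_time), np.nan, detach_time),
        }
    )
    return frames, GroundTruth(cells=cells)


def tracks_from_truth(
    truth: GroundTruth,
    timepoints_h: Sequence[float] = DEFAULT_SCHEDULE,
    r_live: float = 0.5,
    r_dead: float = 1.5,
    red_amp: float = 500.0,
):
    """Build idealised :class:`~radassay.gedifate.CellTrack` objects directly
    from a timelapse truth table, bypassing image rendering.

    Each cell is present until its true detachment time and carries ratio
    ``r_live`` before its true death time and ``r_dead`` after. Useful for
    exercising fate calling and survival statistics at cohort sizes where
    rendering every field would be wasteful.
    """
    from .gedifate import CellTrack  # deferred: avoid module cycle

    timepoints = np.asarray(timepoints_h, dtype=float)
    tracks = []
    for rec in truth.cells.itertuples():
        detach = rec.detach_time_h if np.isfinite(rec.detach_time_h) else np.inf
        present = timepoints < detach
        ratio = np.where(timepoints >= rec.death_time_h, r_dead, r_live)
        amp = rec.red_amp if hasattr(rec, "red_amp") else red_amp
        tracks.append(
            CellTrack(
                track_id=int(rec.cell_id),
                group=rec.group,
                timepoints_h=timepoints,
                present=present,
                mean_red=np.where(present, amp, np.nan),
                mean_green=np.where(present, amp * ratio, np.nan),
                first_seen_h=float(timepoints[0]),
            )
        )
    return tracks


def gen_foci_stack(
    n_cells: int = 60,
    lambda_per_group: float | Mapping[str, float] = 5.0,
    foci_intensity_factor: float = 20.0,
    psf_sigma_px: float = 1.0,
    field_size: tuple[int, int] = (512, 512),
    cell_radius_px: float = 14.0,
    background_level: float = 20.0,
    cell_level: float = 60.0,
    nucleus_level: float = 120.0,
    noise_sigma: float = 2.0,
    min_focus_sep_px: float = 4.0,
    seed: int = 0,
) -> tuple[FrameStack, GroundTruth]:
    """Render one fixed-timepoint foci field plus per-cell true counts.

    Channels: ``blue`` = nuclear (DAPI-like) disks; ``green`` = diffuse
    in-cell signal plus gamma-H2AX-like puncta; ``red`` = the same diffuse
    signal and puncta, standing in for the 53BP1trunc-mApple reporter (so
    the live-cell and fixed-cell counting paths can be compared on one
    field). Puncta are Gaussian PSF spots whose peak, before noise, is
    ``foci_intensity_factor`` times the in-cell background level.

    Per-cell counts are Poisson(lambda); a per-group mapping assigns cells
    to groups evenly and draws from group-specific means. Foci are kept
    ``min_focus_sep_px`` apart when possible so truth counts stay
    unambiguous.
    """
    if foci_intensity_factor <= 1:
        raise ValueError(
            "foci_intensity_factor must be > 1: dimmer puncta are undetectable "
            "under the order-of-magnitude contrast rule"
        )
    lam_map = (
        {"group0": float(lambda_per_group)}
        if np.isscalar(lambda_per_group)
        else dict(lambda_per_group)
    )
    if any(l < 0 for l in lam_map.values()):
        raise ValueError("lambda must be >= 0")

    rng = np.random.default_rng(seed)
    groups = list(lam_map)
    group_of = _split_groups(n_cells, groups) if n_cells else []
    radii = np.full(n_cells, float(cell_radius_px))
    centres = _place_centres(n_cells, field_size, radii, 1.25, rng)

    blue = np.zeros(field_size)
    cyto = np.zeros(field_size)  # diffuse reporter signal
    foci_img = np.zeros(field_size)

    cell_rows = []
    point_rows = []
    # peak so that (background + diffuse + peak) == factor * (background + diffuse)
    in_cell_bg = background_level + cell_level
    peak = (foci_intensity_factor - 1.0) * in_cell_bg
    for i in range(n_cells):
        row, col = centres[i]
        _add_soft_disk(blue, row, col, cell_radius_px, nucleus_level)
        _add_soft_disk(cyto, row, col, cell_radius_px, cell_level)
        count = int(rng.poisson(lam_map[group_of[i]]))
        placed: list[tuple[float, float]] = []
        for _ in range(count):
            for _try in range(200):
                rad = cell_radius_px * 0.6 * np.sqrt(rng.random())
                ang = rng.uniform(0, 2 * np.pi)
                fr, fc = row + rad * np.sin(ang), col + rad * np.cos(ang)
                if all(
                    np.hypot(fr - pr, fc - pc) >= min_focus_sep_px
                    for pr, pc in placed
                ):
                    break
            placed.append((fr, fc))
            _add_gaussian_blob(foci_img, fr, fc, psf_sigma_px, peak)
            point_rows.append(
                {"cell_id": i, "row": fr, "col": fc, "peak_amp": peak}
            )
        cell_rows.append(
            {
                "cell_id": i,
                "group": group_of[i],
                "row": row,
                "col": col,
                "radius_px": cell_radius_px,
                "true_count": count,
            }
        )

    frame = FrameStack(
        channels={
            "blue": _finish_image(blue, background_level, noise_sigma, False, rng),
            "green": _finish_image(
                cyto + foci_img, background_level, noise_sigma, False, rng
            ),
            "red": _finish_image(
                cyto + foci_img, background_level, noise_sigma, False, rng
            ),
        },
        timepoint_h=0.0,
    )
    truth = GroundTruth(
        foci=pd.DataFrame(
            cell_rows,
            columns=["cell_id", "group", "row", "col", "radius_px", "true_count"],
        ),
        foci_points=pd.DataFrame(
            point_rows, columns=["cell_id", "row", "col", "peak_amp"]
        ),
        scalars={
            "in_cell_background": in_cell_bg,
            "focus_peak_over_background": foci_intensity_factor,
        },
    )
    return frame, truth


def gen_colony_image(
    n_colonies: int = 12,
    radius_range: tuple[float, float] = (8.0, 20.0),
    intensity: float = 150.0,
    field_size: tuple[int, int] = (768, 768),
    background_level: float = 30.0,
    noise_sigma: float = 3.0,
    overlap_allowed: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a colony-assay image (soft-edged disks above background).

    Truth holds the colony count, per-colony centre, radius and ideal area
    (pi r^2), and — when overlap is allowed — a ``merged`` flag on colonies
    whose disks intersect another colony's.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    if radius_range[1] * 2 >= min(field_size):
        raise ValueError("colony radii exceed the field")
    rng = np.random.default_rng(seed)
    img = np.zeros(field_size)
    rows_ = []
    radii = rng.uniform(radius_range[0], radius_range[1], size=n_colonies)
    centres = np.empty((n_colonies, 2))
    for i in range(n_colonies):
        margin = radii[i] + 3
        for _ in range(2000):
            r = rng.uniform(margin, field_size[0] - margin)
            c = rng.uniform(margin, field_size[1] - margin)
            if overlap_allowed or i == 0:
                break
            d = np.hypot(centres[:i, 0] - r, centres[:i, 1] - c)
            if np.all(d > radii[:i] + radii[i] + 4):
                break
        centres[i] = (r, c)
    for i in range(n_colonies):
        _add_soft_disk(img, centres[i, 0], centres[i, 1], radii[i], intensity)
    merged = np.zeros(n_colonies, dtype=bool)
    for i in range(n_colonies):
        for j in range(i + 1, n_colonies):
            if np.hypot(*(centres[i] - centres[j])) < radii[i] + radii[j]:
                merged[i] = merged[j] = True
    for i in range(n_colonies):
        rows_.append(
            {
                "colony_id": i,
                "row": centres[i, 0],
                "col": centres[i, 1],
                "radius_px": radii[i],
                "area_px": np.pi * radii[i] ** 2,
                "merged": bool(merged[i]),
            }
        )
    img = _finish_image(img, background_level, noise_sigma, False, rng)
    truth = GroundTruth(
        colonies=pd.DataFrame(
            rows_, columns=["colony_id", "row", "col", "radius_px", "area_px", "merged"]
        ),
        scalars={"colony_count": n_colonies, "any_merged": bool(merged.any())},
    )
    return img, truth


def gen_flow_events(
    n_events: int = 10000,
    stained_fraction: float = 0.5,
    shift_factor: float = 100.0,
    division_peaks: int = 1,
    debris_fraction: float = 0.08,
    unstained_median: float = 100.0,
    unstained_cv_log: float = 0.35,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a CFDA-uptake flow-cytometry event table.

    Fluorescence: unstained events are log-normal around ``unstained_median``;
    stained events are shifted by ``shift_factor``, with ``division_peaks``
    sub-populations at shift, shift/2, shift/4, ... (2x dye dilution per cell
    division), split evenly. FSC/SSC place intact cells high and a debris
    cluster at roughly a tenth of the cell scatter. Truth labels every event.
    """
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    if not 0 <= stained_fraction <= 1:
        raise ValueError("stained_fraction must be in [0, 1]")
    if shift_factor <= 1:
        raise ValueError("shift_factor must be > 1")
    if division_peaks < 1:
        raise ValueError("division_peaks must be >= 1")
    rng = np.random.default_rng(seed)

    n_debris = int(round(n_events * debris_fraction))
    n_cells = n_events - n_debris
    n_stained = int(round(n_cells * stained_fraction))
    n_unstained = n_cells - n_stained

    mu = np.log(unstained_median)
    labels = ["debris"] * n_debris + ["unstained"] * n_unstained
    peak_idx = [-1] * (n_debris + n_unstained)
    fl = list(rng.lognormal(mu, unstained_cv_log, size=n_debris + n_unstained))
    for k, i_ev in enumerate(range(n_stained)):
        peak = k % division_peaks
        fl.append(
            rng.lognormal(mu, unstained_cv_log) * shift_factor / (2.0**peak)
        )
        labels.append("stained")
        peak_idx.append(peak)

    n_tot = len(fl)
    is_debris = np.array([lab == "debris" for lab in labels])
    fsc = np.where(
        is_debris,
        rng.normal(5000, 1200, size=n_tot),
        rng.normal(50000, 7000, size=n_tot),
    )
    ssc = np.where(
        is_debris,
        rng.normal(3000, 900, size=n_tot),
        rng.normal(30000, 6000, size=n_tot),
    )
    order = rng.permutation(n_tot)
    events = pd.DataFrame(
        {
            "FSC": np.clip(fsc, 1, None)[order],
            "SSC": np.clip(ssc, 1, None)[order],
            "FL1": np.asarray(fl)[order],
        }
    )
    flow_truth = pd.DataFrame(
        {
            "label": np.asarray(labels, dtype=object)[order],
            "division_peak": np.asarray(peak_idx)[order],
        }
    )
    truth = GroundTruth(
        flow=flow_truth,
        scalars={
            "stained_fraction": (n_stained / n_cells) if n_cells else 0.0,
            "n_debris": n_debris,
            "shift_factor": shift_factor,
        },
    )
    return events, truth


def gen_ocr_trace(
    basal_ocr: float = 100.0,
    nonmito_ocr: float = 20.0,
    fccp_max_ocr: float = 180.0,
    oligo_ocr: float = 40.0,
    n_measurements_per_phase: int = 3,
    noise_sigma: float = 2.0,
    measurement_interval_min: float = 6.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a 4-phase mitochondrial stress-test OCR trace.

    Phases in injection order: ``basal``, ``oligomycin`` (ATP-synthase
    inhibition), ``fccp`` (uncoupling, maximal respiration), ``rot_aa``
    (rotenone/antimycin-A, non-mitochondrial residual). Truth carries the
    noiseless basal/maximal/spare-capacity values in pmol O2/min (a.u.).
    """
    if not basal_ocr > nonmito_ocr >= 0:
        raise ValueError("require basal_ocr > nonmito_ocr >= 0")
    if fccp_max_ocr < basal_ocr:
        raise ValueError("require fccp_max_ocr >= basal_ocr")
    if n_measurements_per_phase < 1:
        raise ValueError("need at least 1 measurement per phase")
    rng = np.random.default_rng(seed)
    levels = {
        "basal": basal_ocr,
        "oligomycin": oligo_ocr,
        "fccp": fccp_max_ocr,
        "rot_aa": nonmito_ocr,
    }
    rows = []
    idx = 0
    for phase, level in levels.items():
        for _ in range(n_measurements_per_phase):
            rows.append(
                {
                    "measurement": idx,
                    "time_min": idx * measurement_interval_min,
                    "ocr": level + (rng.normal(0, noise_sigma) if noise_sigma else 0.0),
                    "phase": phase,
                }
            )
            idx += 1
    trace = pd.DataFrame(rows)
    basal_resp = basal_ocr - nonmito_ocr
    maximal = fccp_max_ocr - nonmito_ocr
    spare = maximal - basal_resp
    truth = GroundTruth(
        scalars={
            "nonmito": nonmito_ocr,
            "basal_respiration": basal_resp,
            "maximal_respiration": maximal,
            "spare_capacity": spare,
            "spare_capacity_pct": 100.0 * spare / basal_resp,
        }
    )
    return trace, truth
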