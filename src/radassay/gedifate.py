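"""Single-cell GEDI fate calling and survival analysis.

The GEDI (Genetically Encoded Death Indicator) biosensor couples a calcium
sensor (GC150, green) to a constitutive red marker (mApple). Apoptotic
commitment triggers an irreversible calcium influx, so the per-cell
green/red ratio R steps from a low live value to a high dead value. This
module turns per-object measurements into:

1. per-cell GEDI ratios (:func:`gedi_ratio`),
2. cell tracks across the scheduled imaging timepoints
   (:func:`track_cells`, greedy nearest-centroid linking),
3. a calibrated death threshold theta from baseline vs post-lethal-dose
   ratio samples (:func:`calibrate_threshold`; a lethal 25 Gy exposure at
   24 h is the standard calibration condition, and theta = 1 is the
   conventional fallback),
4. per-cell fate records (:func:`call_fates`): a cell dies at the earlier
   of its first ratio crossing and its first disappearance from the field
   of view; cells alive and present at the last timepoint are censored,
5. Kaplan-Meier survival curves and log-rank group comparisons
   (:func:`km_curve`, :func:`logrank`), computed with lifelines.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, logrank_test

__all__ = [
    "CellTrack",
    "SurvivalCurve",
    "CalibrationError",
    "CalibrationResult",
    "LogrankResult",
    "gedi_ratio",
    "track_cells",
    "calibrate_threshold",
    "call_fates",
    "km_curve",
    "logrank",
]


class CalibrationError(ValueError):
    """Raised when baseline and post-lethal ratio distributions are inseparable."""


@dataclass
class CellTrack:
    """One cell followed across the scheduled timepoints.

    ``present``, ``mean_red`` and ``mean_green`` are aligned with
    ``timepoints_h``; intensities are NaN where the cell is absent.
    ``first_seen_h`` is the first timepoint at which the cell was detected —
    tracks appearing after the first scheduled timepoint were not at risk at
    baseline and are excluded from survival analysis.
    """

    track_id: int
    group: str
    timepoints_h: np.ndarray
    present: np.ndarray
    mean_red: np.ndarray
    mean_green: np.ndarray
    first_seen_h: float
    centroid_row: np.ndarray | None = None
    centroid_col: np.ndarray | None = None

    def ratios(self, red_floor: float = 0.0) -> np.ndarray:
        """GEDI ratio per timepoint; NaN where absent or red is unmeasurable."""
        return gedi_ratio(self.mean_green, self.mean_red, red_floor)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the ordered distinct observation times (starting at 0),
    with survival probability S(t), at-risk count n(t) and event count d(t)
    at each.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CalibrationResult:
    """Calibrated GEDI death threshold and its training misclassification."""

    theta: float
    misclassification_rate: float
    n_baseline: int
    n_lethal: int


@dataclass
class LogrankResult:
    """Log-rank comparison of survival across groups.

    ``pairwise`` (dose comparisons, typically each treated arm against the
    control) reports unadjusted and Bonferroni-adjusted p-values side by
    side.
    """

    statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "Log-rank test",
            f"  chi2 = {self.statistic:.4g}  df = {self.df}  p = {self.p_value:.4g}",
        ]
        if self.pairwise is not None and len(self.pairwise):
            lines.append("  pairwise:")
            for rec in self.pairwise.itertuples():
                lines.append(
                    f"    {rec.group_a} vs {rec.group_b}: chi2 = {rec.statistic:.4g}"
                    f"  p = {rec.p_value:.4g}  p_bonferroni = {rec.p_bonferroni:.4g}"
                )
        return "\n".join(lines)


def gedi_ratio(mean_green, mean_red, red_floor: float = 0.0):
    """GEDI ratio = green / red mean intensity within the cell mask.

    Cells whose red signal does not exceed ``red_floor`` are unmeasurable at
    that timepoint: the ratio is NaN (the cell is excluded there, never
    assigned 0). Scalar in, scalar out; array in, array out.
    """
    green = np.asarray(mean_green, dtype=float)
    red = np.asarray(mean_red, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(red > red_floor, green / red, np.nan)
    if np.ndim(mean_green) == 0 and np.ndim(mean_red) == 0:
        return float(ratio)
    return ratio


def track_cells(
    object_tables: Mapping[float, pd.DataFrame],
    max_displacement_px: float = 24.0,
    group: str = "",
) -> list[CellTrack]:
    """Link objects across timepoints by greedy nearest-centroid matching.

    ``object_tables`` maps each scheduled timepoint (hours) to an object
    table with columns ``label``, ``centroid_row``, ``centroid_col``,
    ``mean_red``, ``mean_green`` (the imgseg CSV contract). Matches between
    consecutive timepoints are accepted in order of increasing displacement
    up to ``max_displacement_px``; an unmatched earlier object ends its
    track (disappearance), an unmatched later object opens a new track
    (flagged by ``first_seen_h``, excluded from survival downstream).

    Greedy linking is adequate for the sparse fields this package targets
    (no global assignment is attempted).
    """
    if len(object_tables) < 1:
        raise ValueError("need at least one timepoint")
    times = sorted(object_tables)
    for t in times:
        labels = object_tables[t]["label"]
        if labels.duplicated().any():
            raise ValueError(f"duplicate object ids at t={t}")

    timepoints = np.asarray(times, dtype=float)
    n_t = len(times)
    tracks_data: list[dict] = []  # per track: first_k, rows: list of row-or-None

    def new_track(k: int, row) -> None:
        tracks_data.append({"first_k": k, "rows": [None] * k + [row]})

    prev_assign: dict[int, int] = {}  # row index in previous table -> track index
    for k, t in enumerate(times):
        table = object_tables[t].reset_index(drop=True)
        cur_assign: dict[int, int] = {}
        if k == 0:
            for j in range(len(table)):
                new_track(0, table.iloc[j])
                cur_assign[j] = j
        else:
            prev_table = object_tables[times[k - 1]].reset_index(drop=True)
            matched_prev: set[int] = set()
            matched_cur: set[int] = set()
            if len(prev_table) and len(table):
                pc = prev_table[["centroid_row", "centroid_col"]].to_numpy()
                cc = table[["centroid_row", "centroid_col"]].to_numpy()
                d = np.hypot(
                    pc[:, None, 0] - cc[None, :, 0], pc[:, None, 1] - cc[None, :, 1]
                )
                order = np.argsort(d, axis=None)
                for flat in order:
                    i, j = divmod(flat, d.shape[1])
                    if d[i, j] > max_displacement_px:
                        break
                    if i in matched_prev or j in matched_cur:
                        continue
                    matched_prev.add(i)
                    matched_cur.add(j)
                    tr = prev_assign[i]
                    tracks_data[tr]["rows"].append(table.iloc[j])
                    cur_assign[j] = tr
            # pad tracks that found no match with an absence
            for tr in range(len(tracks_data)):
                if len(tracks_data[tr]["rows"]) == k:
                    tracks_data[tr]["rows"].append(None)
            # unmatched current objects open new (late-appearing) tracks
            for j in range(len(table)):
                if j not in cur_assign:
                    new_track(k, table.iloc[j])
                    cur_assign[j] = len(tracks_data) - 1
        prev_assign = cur_assign

    tracks: list[CellTrack] = []
    for tid, data in enumerate(tracks_data):
        rows = data["rows"] + [None] * (n_t - len(data["rows"]))
        present = np.array([r is not None for r in rows])
        mean_red = np.array([r["mean_red"] if r is not None else np.nan for r in rows])
        mean_green = np.array(
            [r["mean_green"] if r is not None else np.nan for r in rows]
        )
        crow = np.array(
            [r["centroid_row"] if r is not None else np.nan for r in rows]
        )
        ccol = np.array(
            [r["centroid_col"] if r is not None else np.nan for r in rows]
        )
        tracks.append(
            CellTrack(
                track_id=tid,
                group=group,
                timepoints_h=timepoints,
                present=present,
                mean_red=mean_red,
                mean_green=mean_green,
                first_seen_h=float(timepoints[data["first_k"]]),
                centroid_row=crow,
                centroid_col=ccol,
            )
        )
    return tracks


def calibrate_threshold(
    ratios_baseline: Iterable[float], ratios_post_lethal: Iterable[float]
) -> CalibrationResult:
    """Calibrate the GEDI death threshold from a lethal-dose experiment.

    Given ratio samples from cells at baseline and from cells after a
    lethal radiation dose (the standard is 25 Gy, measured at 24 h), theta
    is the cut minimising total misclassification between the two empirical
    distributions (a cell is called dead when R > theta). Ties are broken
    toward the midpoint of the tied cuts. If no cut beats 50%
    misclassification the distributions are inseparable and calibration
    fails.
    """
    base = np.sort(np.asarray(list(ratios_baseline), dtype=float))
    lethal = np.sort(np.asarray(list(ratios_post_lethal), dtype=float))
    if base.size == 0 or lethal.size == 0:
        raise ValueError("both ratio samples must be non-empty")
    pooled = np.unique(np.concatenate([base, lethal]))
    if pooled.size < 2:
        raise CalibrationError(
            "calibration failed: baseline and lethal ratios are indistinguishable"
        )
    cuts = (pooled[:-1] + pooled[1:]) / 2.0
    n = base.size + lethal.size
    # misclassified = baseline called dead (R > cut) + lethal called alive (R <= cut)
    fp = base.size - np.searchsorted(base, cuts, side="right")
    fn = np.searchsorted(lethal, cuts, side="right")
    err = (fp + fn) / n
    best = err.min()
    if best >= 0.5:
        raise CalibrationError(
            "calibration failed: distributions inseparable "
            f"(best achievable misclassification {best:.2f})"
        )
    tied = cuts[err == best]
    theta = float((tied.min() + tied.max()) / 2.0)
    return CalibrationResult(
        theta=theta,
        misclassification_rate=float(best),
        n_baseline=int(base.size),
        n_lethal=int(lethal.size),
    )


def call_fates(
    tracks: Iterable[CellTrack],
    theta: float = 1.0,
    schedule: Sequence[float] | None = None,
    red_floor: float = 0.0,
    events: str = "both",
) -> pd.DataFrame:
    """Classify each track's fate and assign an event or censor time.

    A cell's death time is the earlier of (a) the first scheduled timepoint
    at which its GEDI ratio exceeds ``theta`` (cause ``ratio_crossing``)
    and (b) the first scheduled timepoint at which a previously present
    cell is absent from the field of view (cause ``disappearance``;
    detachment of dead cells makes disappearance an operational death
    criterion). Cells still present with R <= theta at the final timepoint
    are censored there. Tracks first seen after baseline were not at risk
    at t=0 and are excluded; tracks with no measurable timepoint are
    excluded with a warning.

    ``events`` selects which causes count as death events ("both",
    "ratio_crossing" or "disappearance"; the other cause is then treated
    as informative for exclusion only in the sense that disappearance
    always ends observation).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if events not in ("both", "ratio_crossing", "disappearance"):
        raise ValueError(f"unknown events mode {events!r}")
    records = []
    for track in tracks:
        tp = np.asarray(track.timepoints_h, dtype=float)
        if schedule is not None:
            sched = np.asarray(schedule, dtype=float)
            keep = np.isin(tp, sched)
            tp = tp[keep]
        else:
            keep = np.ones(len(tp), dtype=bool)
        present = np.asarray(track.present)[keep]
        ratios = track.ratios(red_floor)[keep]
        if track.first_seen_h > tp[0]:
            continue  # not at risk at baseline
        measurable = present & np.isfinite(ratios)
        if not measurable.any():
            warnings.warn(
                f"track {track.track_id}: no measurable timepoints; excluded",
                stacklevel=2,
            )
            continue

        cross_k = next(
            (k for k in range(len(tp)) if measurable[k] and ratios[k] > theta), None
        )
        gone_k = None
        seen = False
        for k in range(len(tp)):
            if present[k]:
                seen = True
            elif seen:
                gone_k = k
                break
        candidates = []
        if cross_k is not None and events in ("both", "ratio_crossing"):
            candidates.append((cross_k, "ratio_crossing"))
        if gone_k is not None and events in ("both", "disappearance"):
            candidates.append((gone_k, "disappearance"))
        if candidates:
            k, cause = min(candidates, key=lambda c: c[0])
            records.append(
                {
                    "track_id": track.track_id,
                    "group": track.group,
                    "time_h": float(tp[k]),
                    "status": "event",
                    "cause": cause,
                }
            )
        else:
            # censored: last timepoint at which the cell was observed
            last_seen = int(np.flatnonzero(present)[-1])
            records.append(
                {
                    "track_id": track.track_id,
                    "group": track.group,
                    "time_h": float(tp[last_seen]),
                    "status": "censored",
                    "cause": "none",
                }
            )
    return pd.DataFrame(
        records, columns=["track_id", "group", "time_h", "status", "cause"]
    )


def km_curve(fates: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier product-limit survival estimate from fate records.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over event times; censored
    cells leave the risk set after their censor time.
    """
    if len(fates) < 1:
        raise ValueError("need at least one fate record")
    observed = (fates["status"] == "event").to_numpy().astype(int)
    kmf = KaplanMeierFitter()
    kmf.fit(fates["time_h"].to_numpy(), event_observed=observed)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
    )


def logrank(
    fates: pd.DataFrame,
    group_col: str = "group",
    control: str | None = None,
    pairwise: bool = True,
) -> LogrankResult:
    """Log-rank test of survival differences across groups.

    Computes the standard multi-group log-rank statistic (observed vs
    expected events over pooled event times, hypergeometric variance, ties
    pooled at identical times). With ``pairwise=True`` every treated arm is
    also compared against ``control`` (or all pairs when no control is
    named), with unadjusted and Bonferroni-adjusted p-values reported side
    by side.
    """
    groups = fates[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (fates["status"] == "event").sum() == 0:
        raise ValueError("no events; test undefined")
    observed = (fates["status"] == "event").astype(int)
    res = multivariate_logrank_test(fates["time_h"], fates[group_col], observed)
    pw = None
    if pairwise:
        if control is not None:
            pairs = [(control, g) for g in groups if g != control]
        else:
            pairs = list(itertools.combinations(sorted(groups), 2))
        rows = []
        for a, b in pairs:
            sub = fates[fates[group_col].isin([a, b])]
            obs = (sub["status"] == "event").astype(int)
            if obs.sum() == 0:
                stat, p = 0.0, 1.0
            else:
                r = logrank_test(
                    sub.loc[sub[group_col] == a, "time_h"],
                    sub.loc[sub[group_col] == b, "time_h"],
                    event_observed_A=obs[sub[group_col] == a],
                    event_observed_B=obs[sub[group_col] == b],
                )
                stat, p = float(r.test_statistic), float(r.p_value)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "statistic": stat,
                    "p_value": p,
                    "p_bonferroni": min(1.0, p * len(pairs)),
                }
            )
        pw = pd.DataFrame(rows)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
        pairwise=pw,
    )
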