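"""DNA-damage foci detection, per-cell counting and group comparison.

Two markers share one code path:

* **53BP1trunc-mApple** — live-cell reporter that forms puncta at
  double-strand breaks over a diffuse nuclear signal; compartments are
  red-channel cell masks.
* **gamma-H2AX** — immunofluorescent foci in fixed cells; compartments are
  DAPI nuclear masks.

A punctum must be at least an order of magnitude brighter than the in-cell
background (``contrast_factor``, default 10). Because reporter expression
varies from cell to cell, background is estimated per cell as a trimmed
median inside the compartment mask, so counts are invariant to overall gain
and to per-cell expression level.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.feature import peak_local_max
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .imgseg import LabeledObjects

__all__ = [
    "estimate_background",
    "detect_foci",
    "foci_timecourse",
    "compare_counts",
]


def estimate_background(
    image: np.ndarray, cell_masks: LabeledObjects | np.ndarray, trim_quantile: float = 0.95
) -> pd.Series:
    """Per-cell background: median of in-mask pixels, brightest 5% excluded.

    Trimming the top ``1 - trim_quantile`` fraction of in-mask pixels makes
    the estimate robust to the foci themselves, which occupy a small
    fraction of the compartment. Returns a Series indexed by object label.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    labels = (
        cell_masks.label_image
        if isinstance(cell_masks, LabeledObjects)
        else np.asarray(cell_masks)
    )
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("empty mask: no compartments to estimate background in")
    out = {}
    for lab in ids:
        vals = image[labels == lab]
        cut = np.quantile(vals, trim_quantile)
        trimmed = vals[vals <= cut]
        out[int(lab)] = float(np.median(trimmed if trimmed.size else vals))
    return pd.Series(out, name="background")


def detect_foci(
    image: np.ndarray,
    compartment_masks: LabeledObjects | np.ndarray,
    contrast_factor: float = 10.0,
    min_punctum_area_px: int = 2,
    max_punctum_area_px: int = 50,
    marker: str = "53BP1",
    timepoint_h: float = 0.0,
    group: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect puncta per compartment under the ratio-to-background rule.

    Candidate regions are 8-connected components of pixels at least
    ``contrast_factor`` times the compartment's background. Each region
    contributes one punctum per local intensity maximum it contains
    (adjacent maxima closer than 2 px are suppressed), so touching foci are
    still resolved and, because a maximum that clears a high threshold also
    clears every lower one, counts never decrease when the contrast factor
    is lowered. The area bounds reject hot pixels (region smaller than
    ``min_punctum_area_px``) and saturated compartments (region larger than
    ``max_punctum_area_px`` per contained punctum).

    Returns ``(counts, puncta)``: per-cell rows
    (cell_id, marker, timepoint_h, group, count) and per-punctum rows
    (cell_id, centroid_row, centroid_col, area_px, contrast).
    """
    if contrast_factor <= 1:
        raise ValueError("contrast_factor must be > 1")
    image = np.asarray(image, dtype=float)
    labels = (
        compartment_masks.label_image
        if isinstance(compartment_masks, LabeledObjects)
        else np.asarray(compartment_masks)
    )
    background = estimate_background(image, labels)

    counts = {int(lab): 0 for lab in background.index}
    puncta_rows = []
    for lab, bg in background.items():
        in_cell = labels == lab
        if bg <= 0:
            continue
        thr = contrast_factor * bg
        cand = in_cell & (image >= thr)
        comp = measure.label(cand, connectivity=2)
        if comp.max() == 0:
            continue
        peaks = peak_local_max(
            np.where(in_cell, image, 0.0), min_distance=2, threshold_abs=thr
        )
        peaks_per_comp: dict[int, list[np.ndarray]] = {}
        for pk in peaks:
            cid = int(comp[tuple(pk)])
            if cid > 0:
                peaks_per_comp.setdefault(cid, []).append(pk)
        props = {
            p.label: p for p in measure.regionprops(comp, intensity_image=image)
        }
        for cid, cid_peaks in peaks_per_comp.items():
            prop = props[cid]
            area = int(prop.area)
            n = len(cid_peaks)
            if float(prop.intensity_max - prop.intensity_min) == 0.0:
                # perfectly flat region: a single punctum if punctum-sized,
                # a saturated patch (rejected) otherwise
                if area > max_punctum_area_px:
                    continue
                n = 1
                cid_peaks = cid_peaks[:1]
            if area < min_punctum_area_px or area > max_punctum_area_px * n:
                continue
            counts[int(lab)] += n
            for pk in cid_peaks:
                puncta_rows.append(
                    {
                        "cell_id": int(lab),
                        "centroid_row": float(pk[0]),
                        "centroid_col": float(pk[1]),
                        "area_px": area // n,
                        "contrast": float(image[tuple(pk)] / bg),
                    }
                )
    count_df = pd.DataFrame(
        {
            "cell_id": list(counts),
            "marker": marker,
            "timepoint_h": timepoint_h,
            "group": group,
            "count": list(counts.values()),
        }
    )
    puncta_df = pd.DataFrame(
        puncta_rows,
        columns=["cell_id", "centroid_row", "centroid_col", "area_px", "contrast"],
    )
    return count_df, puncta_df


def foci_timecourse(
    records: pd.DataFrame, schedule: Sequence[float] | None = None
) -> pd.DataFrame:
    """Per-group, per-timepoint summary: mean puncta/cell, SEM and n.

    SEM is reported as NaN for n = 1 (undefined). Summarisation preserves
    counts: the group sums of per-cell counts are unchanged.
    """
    df = records.copy()
    if schedule is not None:
        sched = set(float(t) for t in schedule)
        missing = set(df["timepoint_h"].astype(float)) - sched
        if missing:
            raise ValueError(f"records contain timepoints outside the schedule: {missing}")
    grouped = df.groupby(["group", "timepoint_h"])["count"]
    out = grouped.agg(
        mean_count="mean",
        sem_count=lambda x: x.sem(ddof=1) if len(x) > 1 else np.nan,
        n="size",
        total_count="sum",
    ).reset_index()
    return out


def compare_counts(records: pd.DataFrame, design: str = "one_way") -> dict:
    """ANOVA group comparison of per-cell foci counts with Tukey HSD.

    ``one_way``: counts ~ group at one timepoint (pass a single-timepoint
    slice). ``two_way``: counts ~ group * timepoint for timecourses.
    Returns a dict with an ``anova`` table and a ``tukey`` pairwise table
    (Tukey-adjusted p-values across groups).
    """
    df = records.copy()
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = df.groupby("group")["count"].agg(["size", "var"])
    if ((sizes["size"] < 2)).any():
        raise ValueError("every group needs at least 2 cells")

    df["count"] = df["count"].astype(float)
    if design == "one_way":
        model = ols("count ~ C(group)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    elif design == "two_way":
        model = ols("count ~ C(group) * C(timepoint_h)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    else:
        raise ValueError(f"unknown design {design!r}")

    # degenerate case: an effect with (numerically) zero sum of squares has
    # no signal; 0/0 noise in the F ratio is reported as F=0, p=1
    anova = anova.copy()
    total_ss = max(float(anova["sum_sq"].sum()), 1.0)
    zero_ss = (anova["sum_sq"] / total_ss < 1e-12) & (anova.index != "Residual")
    anova.loc[zero_ss, "F"] = 0.0
    anova.loc[zero_ss, "PR(>F)"] = 1.0

    tukey_res = pairwise_tukeyhsd(df["count"], df["group"])
    tukey = pd.DataFrame(
        tukey_res.summary().data[1:], columns=tukey_res.summary().data[0]
    )
    return {"anova": anova, "tukey": tukey}
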