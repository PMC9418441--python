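"""Editing quantification from Sanger chromatogram peak heights.

Percent editing at a site is G/(A+G) x 100 from the two peak heights at the
edited adenosine; case values are normalised to a control condition as a
per-site ratio, averaged across biological replicates with SEM.  Input is a
peak-height table (heights measured from chromatograms); trace-file parsing
is out of scope.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd


def peak_editing(a_height: float, g_height: float) -> float:
    """Percent editing = G / (A + G) x 100 from peak heights."""
    if a_height < 0 or g_height < 0:
        raise ValueError("peak heights must be non-negative")
    total = a_height + g_height
    if total == 0:
        return float("nan")  # undefined: no signal at either peak
    return 100.0 * g_height / total


def relative_editing(case_percent: float, control_percent: float) -> float:
    """Case editing normalised to control (ratio of percents)."""
    if control_percent <= 0:
        raise ValueError("control percent must be > 0 for normalisation")
    return case_percent / control_percent


def summarize_ratios(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the mean of per-replicate ratios."""
    arr = np.asarray(ratios, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return mean, sem


def quantify_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Add a percent-editing column to a peak-height table.

    Expects columns ``A_height`` and ``G_height``; extra columns (site,
    sample, condition, replicate) pass through.
    """
    out = peaks.copy()
    out["percent_editing"] = [
        peak_editing(a, g) for a, g in zip(out["A_height"], out["G_height"])
    ]
    return out


def normalize_to_control(
    quantified: pd.DataFrame,
    case: str,
    control: str,
    condition_col: str = "condition",
    site_col: str = "site",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Per-site case/control editing ratios with replicate mean and SEM.

    Replicates are paired by ``replicate_col`` within each site; sites where
    the control percent is zero in any replicate are reported with NaN.
    """
    rows = []
    for site, sub in quantified.groupby(site_col):
        case_vals = sub[sub[condition_col] == case].set_index(replicate_col)[
            "percent_editing"]
        ctrl_vals = sub[sub[condition_col] == control].set_index(replicate_col)[
            "percent_editing"]
        common = case_vals.index.intersection(ctrl_vals.index)
        ratios = []
        for r in common:
            try:
                ratios.append(relative_editing(case_vals[r], ctrl_vals[r]))
            except ValueError:
                ratios.append(float("nan"))
        arr = [x for x in ratios if not math.isnan(x)]
        if arr:
            mean, sem = summarize_ratios(arr)
        else:
            mean, sem = float("nan"), float("nan")
        rows.append((site, len(common), mean, sem))
    return pd.DataFrame(
        rows, columns=[site_col, "n_replicates", "relative_editing_mean",
                       "relative_editing_sem"]
    )
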