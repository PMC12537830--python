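"""Peri-injection firing-rate response classification.

Each unit's activity is summarised as a 1 s rate histogram.  Relative to a
pre-injection baseline, the smoothed post-injection rate is scanned for
sustained supra-threshold excursions: one excursion is a monophasic positive
response (MONO), two or more are bi/multiphasic (MULTI); with no positive
excursion, a sustained dip below half the baseline rate is a suppression
(SUPP); otherwise the unit is non-responsive (NONE).  MONO/MULTI take
precedence over SUPP when a profile shows both.

All thresholds, window lengths and the smoothing scale are explicit
configuration and are echoed into every report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io_sessions import ValidationError

__all__ = [
    "ResponseConfig",
    "ResponseProfile",
    "RESPONSE_CLASSES",
    "rate_histogram",
    "classify_response",
    "class_summary",
]

RESPONSE_CLASSES = ("MONO", "MULTI", "SUPP", "NONE")


@dataclass(frozen=True)
class ResponseConfig:
    hist_bin_s: float = 1.0
    baseline_window_s: float = 600.0
    response_window_s: float = 3600.0
    smooth_sd_s: float = 30.0
    up_sd_mult: float = 2.0          # up threshold: baseline mean + this * baseline sd ...
    up_min_ratio: float = 1.5        # ... and at least this multiple of the baseline mean
    down_ratio: float = 0.5          # suppression threshold as a fraction of baseline mean
    min_excursion_s: float = 60.0
    min_gap_s: float = 120.0
    zero_baseline_floor_hz: float = 0.05  # absolute up threshold when baseline is silent

    def __post_init__(self) -> None:
        if min(self.hist_bin_s, self.baseline_window_s, self.response_window_s) <= 0:
            raise ValidationError("windows and bin width must be positive")
        if not 0 < self.down_ratio < 1 < self.up_min_ratio:
            raise ValidationError("thresholds must satisfy down < baseline < up")


@dataclass
class ResponseProfile:
    unit_id: str
    response_class: str
    n_excursions: int
    pre_mean_hz: float
    post_mean_hz: float
    percent_change: float
    flagged: str = ""

    def as_row(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "class": self.response_class,
            "n_excursions": self.n_excursions,
            "pre_hz": self.pre_mean_hz,
            "post_hz": self.post_mean_hz,
            "pct_change": self.percent_change,
            "flag": self.flagged,
        }


def rate_histogram(times: np.ndarray, duration_s: float, bin_s: float = 1.0) -> np.ndarray:
    """Firing rate (Hz) in consecutive bins spanning the whole session."""
    if bin_s <= 0:
        raise ValidationError("bin_s must be positive")
    times = np.asarray(times, float)
    n_bins = max(int(np.ceil(duration_s / bin_s)), 1)
    counts, _ = np.histogram(times, bins=n_bins, range=(0.0, n_bins * bin_s))
    return counts / bin_s


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def _excursions(mask: np.ndarray, min_len: int, min_gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by gaps shorter than min_gap, keep long ones."""
    runs = _runs(mask)
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return [(a, b) for a, b in merged if b - a >= min_len]


def classify_response(
    series_hz: np.ndarray,
    injection_time_s: float,
    config: ResponseConfig = ResponseConfig(),
    unit_id: str = "",
) -> ResponseProfile:
    """Classify one unit's peri-injection rate series.

    ``series_hz`` is a 1-bin rate histogram over the session
    (:func:`rate_histogram` with ``config.hist_bin_s``).  The baseline is the
    window immediately before the injection; thresholds derive from its
    unsmoothed mean and standard deviation, while the post-injection series
    is Gaussian-smoothed before the excursion scan so that brief rate flickers
    do not count as responses.
    """
    series_hz = np.asarray(series_hz, float)
    bin_s = config.hist_bin_s
    inj = int(round(injection_time_s / bin_s))
    base_lo = inj - int(round(config.baseline_window_s / bin_s))
    if base_lo < 0:
        raise ValidationError("baseline window does not fit before the injection")
    baseline = series_hz[base_lo:inj]
    post = series_hz[inj : inj + int(round(config.response_window_s / bin_s))]
    if post.size == 0:
        raise ValidationError("no post-injection samples")

    base_mean = float(baseline.mean())
    base_sd = float(baseline.std(ddof=1)) if baseline.size > 1 else 0.0
    flagged = ""
    if base_mean == 0.0:
        up = config.zero_baseline_floor_hz
        down = 0.0
        flagged = "zero-baseline"
    else:
        up = max(base_mean + config.up_sd_mult * base_sd, config.up_min_ratio * base_mean)
        down = config.down_ratio * base_mean

    smoothed = gaussian_filter1d(post, sigma=config.smooth_sd_s / bin_s, mode="nearest")
    min_len = int(round(config.min_excursion_s / bin_s))
    min_gap = int(round(config.min_gap_s / bin_s))
    ups = _excursions(smoothed > up, min_len, min_gap)

    if len(ups) == 1:
        cls = "MONO"
    elif len(ups) >= 2:
        cls = "MULTI"
    else:
        dips = _excursions(smoothed < down, min_len, min_gap) if down > 0 else []
        cls = "SUPP" if dips else "NONE"

    pre_mean = base_mean
    post_mean = float(post.mean())
    pct = 100.0 * (post_mean - pre_mean) / pre_mean if pre_mean > 0 else float("nan")
    return ResponseProfile(
        unit_id=unit_id,
        response_class=cls,
        n_excursions=len(ups),
        pre_mean_hz=pre_mean,
        post_mean_hz=post_mean,
        percent_change=pct,
        flagged=flagged,
    )


def class_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-region response-class proportions and magnitudes.

    ``profiles`` needs columns unit_id, region, recording_id, class, pre_hz,
    post_hz.  Proportions are computed per recording and averaged across
    recordings (mean ± SEM with recording-level degrees of freedom); class
    rate magnitudes are unit-level means.  Proportions sum to 1 per region
    within each recording by construction.
    """
    rows = []
    for region, rdf in profiles.groupby("region"):
        per_rec = (
            rdf.groupby("recording_id")["class"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=RESPONSE_CLASSES, fill_value=0.0)
        )
        n_rec = len(per_rec)
        for cls in RESPONSE_CLASSES:
            frac = per_rec[cls]
            cdf = rdf[rdf["class"] == cls]
            pre = float(cdf["pre_hz"].mean()) if len(cdf) else float("nan")
            post = float(cdf["post_hz"].mean()) if len(cdf) else float("nan")
            rows.append(
                {
                    "region": region,
                    "class": cls,
                    "fraction_mean": float(frac.mean()),
                    "fraction_sem": float(frac.std(ddof=1) / np.sqrt(n_rec))
                    if n_rec > 1
                    else float("nan"),
                    "n_recordings": n_rec,
                    "n_units": int(len(cdf)),
                    "pre_hz": pre,
                    "post_hz": post,
                    "pct_change": 100.0 * (post - pre) / pre if pre and pre > 0 else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "class",
            "fraction_mean",
            "fraction_sem",
            "n_recordings",
            "n_units",
            "pre_hz",
            "post_hz",
            "pct_change",
        ],
    )
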