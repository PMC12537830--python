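"""Quiet-epoch extraction and max-over-lag pairwise cross-correlation.

The synchrony statistic is the maximum, over integer bin lags within a
window, of the Pearson correlation between two units' binned spike counts,
restricted to quiet (movement-free) epochs.  Quiet epochs are the gaps
between annotated movements, shrunk by a safety margin (default 1 s) on each
movement-facing side.  Counts are binned per window (bins never span
windows); lags shift one series against the other *within* each window with
edge truncation — no wrap-around and no cross-window shifts.

Pair-level results are aggregated into the six region pair classes
L23–L23, L23–L5, L5–L5, L23–STR, L5–STR, STR–STR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_sessions import Region, Session, ValidationError

__all__ = [
    "EpochSet",
    "SynchronyConfig",
    "LagCorrelation",
    "CorrelationResult",
    "PAIR_CLASSES",
    "extract_quiet_windows",
    "bin_counts",
    "max_lag_correlation",
    "correlation_matrix",
    "pair_class_means",
]

_REGION_ORDER = {Region.L23: 0, Region.L5: 1, Region.STR: 2}
PAIR_CLASSES = (
    "L23-L23",
    "L23-L5",
    "L5-L5",
    "L23-STR",
    "L5-STR",
    "STR-STR",
)


def pair_class(region_a: str, region_b: str) -> str | None:
    """Name of the region pair class, or None if either region is excluded."""
    if region_a not in _REGION_ORDER or region_b not in _REGION_ORDER:
        return None
    a, b = sorted((region_a, region_b), key=_REGION_ORDER.get)
    return f"{a}-{b}"


@dataclass(frozen=True)
class EpochSet:
    """Disjoint, sorted time intervals with their total duration."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.intervals:
            if end <= start:
                raise ValidationError(f"epoch ({start}, {end}) empty or reversed")
            if start < prev_end:
                raise ValidationError("epochs overlap or are unsorted")
            prev_end = end

    @property
    def total_duration_s(self) -> float:
        return float(sum(end - start for start, end in self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class SynchronyConfig:
    margin_s: float = 1.0
    bin_width_s: float = 0.025
    max_lag_s: float = 0.1
    min_window_s: float | None = None  # default: 2 * bin width
    min_spikes_per_unit: int = 10

    def __post_init__(self) -> None:
        if self.margin_s < 0 or self.max_lag_s < 0 or self.bin_width_s <= 0:
            raise ValidationError("margin_s/max_lag_s must be >= 0 and bin_width_s > 0")

    @property
    def resolved_min_window_s(self) -> float:
        return 2.0 * self.bin_width_s if self.min_window_s is None else self.min_window_s

    @property
    def max_lag_bins(self) -> int:
        return int(round(self.max_lag_s / self.bin_width_s))


def extract_quiet_windows(
    movements: list[tuple[float, float]],
    span_s: float,
    margin_s: float = 1.0,
    min_window_s: float = 0.0,
) -> EpochSet:
    """Complement of the movement intervals, shrunk by the safety margin.

    The margin is applied only on window sides that face a movement: the
    leading window starts at 0 and the trailing one ends at ``span_s``.
    Windows shorter than ``min_window_s`` are dropped.
    """
    edges: list[tuple[float, float]] = []
    prev_end: float | None = None
    for onset, offset in movements:
        start = 0.0 if prev_end is None else prev_end + margin_s
        end = onset - margin_s
        edges.append((start, end))
        prev_end = offset
    edges.append((0.0 if prev_end is None else prev_end + margin_s, span_s))
    kept = tuple(
        (s, e) for s, e in edges if e - s > 0 and e - s >= min_window_s and s < span_s and e > 0
    )
    kept = tuple((max(s, 0.0), min(e, span_s)) for s, e in kept)
    kept = tuple((s, e) for s, e in kept if e - s > 0 and e - s >= min_window_s)
    return EpochSet(kept)


def bin_counts(
    times: np.ndarray, epochs: EpochSet, bin_width_s: float
) -> list[np.ndarray]:
    """Per-window spike-count vectors.

    Each window is tiled from its own start; a trailing partial bin is
    discarded, so bins never span windows.  Windows too short for one bin
    yield an empty vector.
    """
    times = np.asarray(times, float)
    out = []
    for start, end in epochs.intervals:
        n_bins = int(np.floor((end - start) / bin_width_s))
        if n_bins <= 0:
            out.append(np.zeros(0, dtype=np.int64))
            continue
        edges = start + bin_width_s * np.arange(n_bins + 1)
        counts, _ = np.histogram(times, bins=edges)
        out.append(counts.astype(np.int64))
    return out


@dataclass(frozen=True)
class LagCorrelation:
    r_max: float
    lag_bins: int
    defined: bool = True


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with the zero-variance convention r = 0."""
    if x.size < 2:
        return 0.0
    xs, ys = x.std(), y.std()
    if xs == 0.0 or ys == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _lag_slices(windows_x, windows_y, lag: int):
    """Aligned (head, tail) slices pooled over windows for one lag.

    Lag ``L`` pairs x[t] with y[t+L]; bins pushed past a window edge are
    dropped.
    """
    xs, ys = [], []
    for wx, wy in zip(windows_x, windows_y):
        n = wx.size
        if n <= abs(lag):
            continue
        if lag >= 0:
            xs.append(wx[: n - lag])
            ys.append(wy[lag:])
        else:
            xs.append(wx[-lag:])
            ys.append(wy[: n + lag])
    if not xs:
        return None, None
    return np.concatenate(xs), np.concatenate(ys)


def max_lag_correlation(
    counts_x: list[np.ndarray] | np.ndarray,
    counts_y: list[np.ndarray] | np.ndarray,
    max_lag_bins: int,
) -> LagCorrelation:
    """Signed maximum over integer lags of the pooled Pearson correlation.

    ``counts_x``/``counts_y`` are per-window count vectors from
    :func:`bin_counts` (a bare vector is treated as a single window).  Ties
    between lags prefer the smaller |lag|, then the negative lag.  If either
    series has zero variance at some lag, that lag contributes r = 0.  With
    no usable window the result is flagged undefined.
    """
    if isinstance(counts_x, np.ndarray):
        counts_x = [counts_x]
    if isinstance(counts_y, np.ndarray):
        counts_y = [counts_y]
    if len(counts_x) != len(counts_y) or any(
        wx.size != wy.size for wx, wy in zip(counts_x, counts_y)
    ):
        raise ValidationError("x and y must share the same windowed binning")
    lags = sorted(range(-max_lag_bins, max_lag_bins + 1), key=lambda l: (abs(l), l))
    best_r, best_lag, any_usable = -np.inf, 0, False
    for lag in lags:
        x, y = _lag_slices(counts_x, counts_y, lag)
        if x is None or x.size < 2:
            continue
        any_usable = True
        r = _pearson(x.astype(float), y.astype(float))
        if r > best_r:
            best_r, best_lag = r, lag
    if not any_usable:
        return LagCorrelation(float("nan"), 0, defined=False)
    return LagCorrelation(best_r, best_lag)


@dataclass
class CorrelationResult:
    """Symmetric unit x unit max-over-lag correlation matrix plus metadata."""

    unit_ids: list[str]
    regions: dict[str, str]
    matrix: np.ndarray
    lags: np.ndarray
    excluded_units: list[str] = field(default_factory=list)
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)
    config: SynchronyConfig = field(default_factory=SynchronyConfig)

    def pair_table(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.unit_ids)), 2):
            ui, uj = self.unit_ids[i], self.unit_ids[j]
            rows.append(
                {
                    "unit_i": ui,
                    "unit_j": uj,
                    "r_max": self.matrix[i, j],
                    "lag_s": self.lags[i, j] * self.config.bin_width_s,
                    "class": pair_class(self.regions[ui], self.regions[uj]),
                }
            )
        return pd.DataFrame(rows, columns=["unit_i", "unit_j", "r_max", "lag_s", "class"])


def correlation_matrix(
    session: Session,
    epochs: EpochSet,
    config: SynchronyConfig = SynchronyConfig(),
    units: list[str] | None = None,
) -> CorrelationResult:
    """Max-over-lag correlations for all unordered unit pairs in quiet time.

    Units with fewer than ``min_spikes_per_unit`` quiet-time spikes are
    excluded and listed.  The matrix is symmetric by construction with unit
    diagonal; undefined pairs (no usable window) hold NaN and are excluded
    from aggregation.
    """
    trains = [tr for tr in session.trains if units is None or tr.unit_id in set(units)]
    counts = {}
    excluded = []
    for tr in trains:
        c = bin_counts(tr.times, epochs, config.bin_width_s)
        if sum(int(w.sum()) for w in c) < config.min_spikes_per_unit:
            excluded.append(tr.unit_id)
        else:
            counts[tr.unit_id] = c
    ids = [tr.unit_id for tr in trains if tr.unit_id in counts]
    regions = {tr.unit_id: tr.region for tr in trains}
    n = len(ids)
    matrix = np.eye(n)
    lags = np.zeros((n, n), dtype=int)
    undefined = []
    for i, j in combinations(range(n), 2):
        res = max_lag_correlation(counts[ids[i]], counts[ids[j]], config.max_lag_bins)
        if not res.defined:
            undefined.append((ids[i], ids[j]))
            matrix[i, j] = matrix[j, i] = np.nan
        else:
            matrix[i, j] = matrix[j, i] = res.r_max
            lags[i, j] = res.lag_bins
            lags[j, i] = -res.lag_bins
    return CorrelationResult(
        unit_ids=ids,
        regions=regions,
        matrix=matrix,
        lags=lags,
        excluded_units=excluded,
        undefined_pairs=undefined,
        config=config,
    )


def pair_class_means(result: CorrelationResult) -> pd.DataFrame:
    """Mean correlation per region pair class.

    Pairs involving BORDERLINE/OUT units never enter; empty classes are
    reported as missing rows (not zeros).  Columns: class, mean, sem, n_pairs.
    """
    values: dict[str, list[float]] = {}
    ids = result.unit_ids
    for i, j in combinations(range(len(ids)), 2):
        cls = pair_class(result.regions[ids[i]], result.regions[ids[j]])
        if cls is None or np.isnan(result.matrix[i, j]):
            continue
        values.setdefault(cls, []).append(result.matrix[i, j])
    rows = []
    for cls in PAIR_CLASSES:
        if cls not in values:
            continue
        vals = np.asarray(values[cls])
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        rows.append({"class": cls, "mean": float(vals.mean()), "sem": sem, "n_pairs": vals.size})
    return pd.DataFrame(rows, columns=["class", "mean", "sem", "n_pairs"])
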