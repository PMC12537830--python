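"""Single-unit inclusion criteria.

A cluster is accepted as a single unit only if all five criteria pass:

1. curation label equals the accept label ("good", case-insensitive);
2. waveform stability — mean spike amplitude and half-width do not differ
   significantly between the first and last 20% of spikes;
3. refractory behaviour — the fraction of inter-spike intervals below 2 ms
   stays under a small tolerance;
4. the ISI distribution is a smooth exponential-like curve (log-density of
   the ISI histogram is well fit by a straight line);
5. the unit's waveform-feature cloud is statistically separated from every
   spatially neighbouring cluster (two-group multivariate test).

The stability test treats ``stability_alpha`` as the unit-level error rate
and splits it across the two measures (Bonferroni), so that on stationary
units the rejection rate calibrates to alpha.  Unit decisions are
deterministic and independent across units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_sessions import Region, Session

__all__ = [
    "QCConfig",
    "CriterionResult",
    "QCReport",
    "label_filter",
    "waveform_stability",
    "refractory_check",
    "isi_shape_check",
    "cluster_separation",
    "run_qc",
]


@dataclass(frozen=True)
class QCConfig:
    accept_label: str = "good"
    stability_alpha: float = 0.05
    split_fraction: float = 0.20
    min_spikes_per_segment: int = 10
    refractory_ms: float = 2.0
    max_refractory_violation_frac: float = 0.005
    zero_tolerance_refractory: bool = False
    isi_min_isis: int = 100
    isi_fit_min_r2: float = 0.8
    isi_n_bins: int = 16
    isi_min_count_per_bin: int = 5
    separation_alpha: float = 0.05
    separation_min_spikes: int = 20
    neighbor_radius_um: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 0.5:
            raise ValueError("split_fraction must be in (0, 0.5)")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        for a in (self.stability_alpha, self.separation_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha levels must be in (0, 1)")


@dataclass
class CriterionResult:
    passed: bool
    statistic: float = float("nan")
    detail: str = ""


@dataclass
class QCReport:
    """Per-unit criterion outcomes; ``accepted`` is the AND of all five."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def accepted_units(self) -> list[str]:
        if self.table.empty:
            return []
        return list(self.table.loc[self.table["accepted"], "unit_id"])


def label_filter(sorter_label: str, accept_label: str = "good") -> bool:
    """Curation-label criterion: case-insensitive equality with the accept label."""
    return str(sorter_label).strip().lower() == accept_label.strip().lower()


def _two_group_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-way two-group ANOVA p (== two-sample t, two-sided).

    Zero variance in both groups: p = 1 when means agree, 0 otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.f_oneway(a, b).pvalue)


def waveform_stability(
    amplitudes: np.ndarray,
    halfwidths: np.ndarray,
    split_fraction: float = 0.20,
    alpha: float = 0.05,
    min_spikes_per_segment: int = 10,
) -> CriterionResult:
    """Compare waveform summaries between the first and last spikes.

    Takes the initial and final ``split_fraction`` of spikes (time order) and
    tests amplitude and half-width separately (two-group ANOVA), each at
    alpha/2 so the unit-level false-rejection rate is ~alpha.  Fails when
    either measure drifted; units too short to split are untestable and fail.
    """
    amplitudes = np.asarray(amplitudes, float)
    halfwidths = np.asarray(halfwidths, float)
    n = amplitudes.size
    k = int(np.floor(n * split_fraction))
    if k < min_spikes_per_segment:
        return CriterionResult(False, detail="untestable: too few spikes per segment")
    p_amp = _two_group_p(amplitudes[:k], amplitudes[-k:])
    p_hw = _two_group_p(halfwidths[:k], halfwidths[-k:])
    p_min = min(p_amp, p_hw)
    passed = p_min >= alpha / 2.0
    return CriterionResult(passed, statistic=p_min, detail=f"p_amp={p_amp:.4g} p_hw={p_hw:.4g}")


def refractory_check(
    times: np.ndarray,
    refractory_ms: float = 2.0,
    max_violation_frac: float = 0.005,
    zero_tolerance: bool = False,
) -> CriterionResult:
    """Fraction of ISIs below the refractory period must stay under tolerance."""
    times = np.asarray(times, float)
    if times.size < 2:
        return CriterionResult(False, detail="untestable: fewer than 2 spikes")
    isis = np.diff(times)
    frac = float(np.mean(isis < refractory_ms / 1000.0))
    limit = 0.0 if zero_tolerance else max_violation_frac
    return CriterionResult(frac <= limit, statistic=frac)


def isi_shape_check(
    times: np.ndarray,
    min_r2: float = 0.8,
    refractory_ms: float = 2.0,
    n_bins: int = 16,
    min_count_per_bin: int = 5,
    min_isis: int = 100,
) -> CriterionResult:
    """Exponential-likeness of the ISI distribution.

    ISIs beyond the refractory period are histogrammed into log-spaced bins
    up to the 95th percentile; the log of the density estimate (count/width)
    is regressed linearly on the bin centre.  An exponential ISI density has
    a linear log-density, so R² >= ``min_r2`` passes.  Degenerate histograms
    (fewer than 5 usable bins, e.g. a strictly periodic train) score R² = 0.
    """
    times = np.asarray(times, float)
    isis = np.diff(times)
    isis = isis[isis >= refractory_ms / 1000.0]
    if isis.size < min_isis:
        return CriterionResult(False, statistic=float("nan"), detail="untestable: too few ISIs")
    hi = np.quantile(isis, 0.95)
    lo = refractory_ms / 1000.0
    if hi <= lo:
        return CriterionResult(False, statistic=0.0, detail="degenerate: mass below refractory scale")
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(isis, bins=edges)
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    usable = counts >= min_count_per_bin
    if usable.sum() < 5:
        return CriterionResult(False, statistic=0.0, detail="degenerate: <5 usable bins")
    y = np.log(counts[usable] / widths[usable])
    x = centers[usable]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CriterionResult(False, statistic=0.0, detail="degenerate: constant fit input")
    r = stats.pearsonr(x, y).statistic
    r2 = float(r * r)
    return CriterionResult(r2 >= min_r2, statistic=r2)


def _hotelling_t2_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-group multivariate location test (Hotelling T², Wilks-equivalent)."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    n1, p = a.shape
    n2 = b.shape[0]
    if b.shape[1] != p:
        raise ValueError("feature dimensions differ")
    if n1 + n2 - p - 1 <= 0:
        return float("nan")
    d = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False)) / (
        n1 + n2 - 2
    )
    s_pooled = np.atleast_2d(s_pooled)
    try:
        t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(s_pooled, d)
    except np.linalg.LinAlgError:
        return 0.0  # singular pooled covariance: clouds are degenerate/distinct
    f_stat = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * t2
    return float(stats.f.sf(f_stat, p, n1 + n2 - p - 1))


def cluster_separation(
    features_unit: np.ndarray,
    features_neighbors: Sequence[np.ndarray],
    alpha: float = 0.05,
    min_spikes: int = 20,
) -> CriterionResult:
    """Multivariate separation from each neighbouring cluster.

    Pass iff the two-group multivariate test rejects (p < alpha) against
    *every* neighbour, i.e. the unit's feature cloud is distinguishable from
    all of them.  With no neighbours the criterion passes vacuously (flagged).
    """
    features_unit = np.atleast_2d(np.asarray(features_unit, float))
    if not features_neighbors:
        return CriterionResult(True, detail="no-neighbor")
    if features_unit.shape[0] < min_spikes:
        return CriterionResult(False, detail="untestable: too few spikes")
    worst = 0.0
    for nb in features_neighbors:
        nb = np.atleast_2d(np.asarray(nb, float))
        if nb.shape[0] < min_spikes:
            continue
        p = _hotelling_t2_p(features_unit, nb)
        worst = max(worst, p)
        if not p < alpha:
            return CriterionResult(False, statistic=p, detail="not separated from a neighbor")
    return CriterionResult(True, statistic=worst)


def run_qc(session: Session, config: QCConfig = QCConfig()) -> tuple[QCReport, Session]:
    """Apply the five criteria to every unit and filter the session.

    The filtered session keeps units that pass all five criteria *and* sit in
    one of the analysed regions (L2/3, L5, striatum); borderline/out-of-range
    units are excluded from analysis but reported.
    """
    rows = []
    feats = {
        tr.unit_id: np.column_stack([tr.amplitudes_uv, tr.halfwidths_ms])
        if tr.amplitudes_uv is not None and tr.halfwidths_ms is not None
        else None
        for tr in session.trains
    }
    for tr in session.trains:
        res_label = CriterionResult(label_filter(tr.sorter_label, config.accept_label))
        if tr.amplitudes_uv is not None and tr.halfwidths_ms is not None:
            res_stab = waveform_stability(
                tr.amplitudes_uv,
                tr.halfwidths_ms,
                config.split_fraction,
                config.stability_alpha,
                config.min_spikes_per_segment,
            )
        else:
            res_stab = CriterionResult(False, detail="untestable: no waveform stats")
        res_refr = refractory_check(
            tr.times,
            config.refractory_ms,
            config.max_refractory_violation_frac,
            config.zero_tolerance_refractory,
        )
        res_isi = isi_shape_check(
            tr.times,
            config.isi_fit_min_r2,
            config.refractory_ms,
            config.isi_n_bins,
            config.isi_min_count_per_bin,
            config.isi_min_isis,
        )
        own = feats[tr.unit_id]
        neighbors = [
            feats[o.unit_id]
            for o in session.trains
            if o.unit_id != tr.unit_id
            and abs(o.depth_um - tr.depth_um) <= config.neighbor_radius_um
            and feats[o.unit_id] is not None
        ]
        if own is not None:
            res_sep = cluster_separation(
                own, neighbors, config.separation_alpha, config.separation_min_spikes
            )
        else:
            res_sep = CriterionResult(False, detail="untestable: no waveform stats")

        results = {
            "label": res_label,
            "stability": res_stab,
            "refractory": res_refr,
            "isi_shape": res_isi,
            "separation": res_sep,
        }
        accepted = all(r.passed for r in results.values())
        reason = ";".join(name for name, r in results.items() if not r.passed)
        rows.append(
            {
                "unit_id": tr.unit_id,
                "region": tr.region,
                "label_pass": res_label.passed,
                "stability_pass": res_stab.passed,
                "stability_p": res_stab.statistic,
                "refractory_pass": res_refr.passed,
                "refractory_violation_frac": res_refr.statistic,
                "isi_pass": res_isi.passed,
                "isi_r2": res_isi.statistic,
                "separation_pass": res_sep.passed,
                "separation_p": res_sep.statistic,
                "separation_flag": res_sep.detail,
                "accepted": accepted,
                "region_included": tr.region in Region.ANALYSIS,
                "reason": reason,
            }
        )
    report = QCReport(pd.DataFrame(rows))
    if report.table.empty:
        return report, session.subset([])
    keep = report.table.loc[
        report.table["accepted"] & report.table["region_included"], "unit_id"
    ]
    return report, session.subset(keep)
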