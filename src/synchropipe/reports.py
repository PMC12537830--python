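"""End-to-end orchestration: bundles in, result tables and a report out.

The analysis order is QC -> region filter -> quiet-window extraction ->
max-lag correlations and pair-class means -> peri-injection response
classification -> cross-state comparisons.  Every output table carries the
resolved configuration in its comment header, and the stage log accounts for
every unit (accepted + QC-rejected + borderline = total).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import state_stats
from .io_sessions import Session, merge_intervals, read_session_bundle, write_tables
from .response_class import ResponseConfig, class_summary, classify_response, rate_histogram
from .synchrony import SynchronyConfig, correlation_matrix, extract_quiet_windows, pair_class_means
from .unit_qc import QCConfig, run_qc

log = logging.getLogger("synchropipe")

__all__ = ["PipelineConfig", "analyze_bundle", "analyze_bundles", "render_report"]


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (TOML sections map 1:1 to fields)."""

    qc: QCConfig = field(default_factory=QCConfig)
    synchrony: SynchronyConfig = field(default_factory=SynchronyConfig)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_toml(cls, path: Path | str | None) -> "PipelineConfig":
        if path is None:
            return cls()
        raw = tomllib.loads(Path(path).read_text())
        return cls(
            qc=QCConfig(**raw.get("qc", {})),
            synchrony=SynchronyConfig(**raw.get("synchrony", {})),
            response=ResponseConfig(**raw.get("response", {})),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "results")),
        )

    def echo(self) -> dict:
        return {
            "qc": dataclasses.asdict(self.qc),
            "synchrony": dataclasses.asdict(self.synchrony),
            "response": dataclasses.asdict(self.response),
            "seed": self.seed,
        }


def analyze_bundle(
    bundle_dir: Path | str, config: PipelineConfig = PipelineConfig()
) -> dict[str, pd.DataFrame]:
    """Run the full analysis on one session bundle; returns named tables."""
    session = read_session_bundle(bundle_dir)
    return analyze_session(session, config)


def analyze_session(
    session: Session, config: PipelineConfig = PipelineConfig()
) -> dict[str, pd.DataFrame]:
    report, accepted = run_qc(session, config.qc)
    total = len(session.trains)
    if report.table.empty:
        n_rejected = n_borderline = n_accepted = 0
    else:
        n_rejected = int((~report.table["accepted"]).sum())
        n_borderline = int(
            (report.table["accepted"] & ~report.table["region_included"]).sum()
        )
        n_accepted = len(accepted.trains)
    log.info(
        "session %s: %d clusters -> %d accepted, %d QC-rejected, %d borderline/out",
        session.session_id,
        total,
        n_accepted,
        n_rejected,
        n_borderline,
    )
    assert n_accepted + n_rejected + n_borderline == total

    tables: dict[str, pd.DataFrame] = {"qc_report": report.table}
    unit_rows = [
        {
            "session_id": session.session_id,
            "mouse_id": session.mouse_id,
            "state": session.state,
            "unit_id": tr.unit_id,
            "region": tr.region,
            "depth_um": tr.depth_um,
            "n_spikes": tr.n_spikes,
            "rate_hz": tr.rate_hz(session.duration_s),
        }
        for tr in accepted.trains
    ]
    tables["unit_table"] = pd.DataFrame(
        unit_rows,
        columns=[
            "session_id",
            "mouse_id",
            "state",
            "unit_id",
            "region",
            "depth_um",
            "n_spikes",
            "rate_hz",
        ],
    )

    scfg = config.synchrony
    epochs = extract_quiet_windows(
        session.movements, session.duration_s, scfg.margin_s, scfg.resolved_min_window_s
    )
    # restrict synchrony to pre-injection quiet time so the drug response does
    # not masquerade as stationary correlation structure
    if session.injection_time_s is not None and session.injection_time_s < session.duration_s:
        blocked = merge_intervals(
            session.movements + [(session.injection_time_s, session.duration_s)]
        )
        epochs = extract_quiet_windows(
            blocked, session.duration_s, scfg.margin_s, scfg.resolved_min_window_s
        )
    if len(accepted.trains) >= 2 and len(epochs):
        corr = correlation_matrix(accepted, epochs, scfg)
        tables["correlations"] = corr.pair_table()
        tables["pair_class_summary"] = pair_class_means(corr)
        quiet_rates = []
        for tr in accepted.trains:
            n_quiet = int(
                sum(((tr.times >= a) & (tr.times < b)).sum() for a, b in epochs.intervals)
            )
            quiet_rates.append(
                {
                    "unit_id": tr.unit_id,
                    "region": tr.region,
                    "quiet_rate_hz": n_quiet / epochs.total_duration_s,
                }
            )
        tables["quiet_rates"] = pd.DataFrame(
            quiet_rates, columns=["unit_id", "region", "quiet_rate_hz"]
        )
    else:
        log.warning("session %s: synchrony skipped (units=%d, quiet windows=%d)",
                    session.session_id, len(accepted.trains), len(epochs))
        tables["correlations"] = pd.DataFrame(columns=["unit_i", "unit_j", "r_max", "lag_s", "class"])
        tables["pair_class_summary"] = pd.DataFrame(columns=["class", "mean", "sem", "n_pairs"])
        tables["quiet_rates"] = pd.DataFrame(columns=["unit_id", "region", "quiet_rate_hz"])

    rcfg = config.response
    if session.injection_time_s is not None and session.injection_time_s >= rcfg.baseline_window_s:
        rows = []
        for tr in accepted.trains:
            series = rate_histogram(tr.times, session.duration_s, rcfg.hist_bin_s)
            prof = classify_response(series, session.injection_time_s, rcfg, unit_id=tr.unit_id)
            row = prof.as_row()
            row["region"] = tr.region
            row["recording_id"] = session.session_id
            rows.append(row)
        tables["responses"] = pd.DataFrame(
            rows,
            columns=["unit_id", "region", "recording_id", "class", "n_excursions",
                     "pre_hz", "post_hz", "pct_change", "flag"],
        )
        tables["response_summary"] = (
            class_summary(tables["responses"]) if rows else pd.DataFrame()
        )
    else:
        log.info("session %s: response stage skipped (no usable injection)", session.session_id)

    return tables


def analyze_bundles(
    bundle_dirs: list[Path | str],
    config: PipelineConfig = PipelineConfig(),
    out_dir: Path | str | None = None,
) -> dict[str, pd.DataFrame]:
    """Analyze several bundles and add cross-state comparison tables."""
    per_session: dict[str, dict[str, pd.DataFrame]] = {}
    states: dict[str, str] = {}
    for bd in bundle_dirs:
        session = read_session_bundle(bd)
        per_session[session.session_id] = analyze_session(session, config)
        states[session.session_id] = session.state

    combined: dict[str, pd.DataFrame] = {}
    for name in ("unit_table", "correlations", "pair_class_summary", "responses",
                 "response_summary", "qc_report", "quiet_rates"):
        frames = []
        for sid, tabs in per_session.items():
            if name in tabs and len(tabs[name]):
                df = tabs[name].copy()
                df.insert(0, "session_id_", sid)
                df.insert(1, "state_", states[sid])
                frames.append(df)
        if frames:
            combined[name] = pd.concat(frames, ignore_index=True)

    comparisons = []
    if "pair_class_summary" in combined:
        pcs = combined["pair_class_summary"]
        for cls, cdf in pcs.groupby("class"):
            by_state = {st: sdf["mean"].to_numpy(float) for st, sdf in cdf.groupby("state_")}
            for sa, sb in (("PD", "LID"), ("WT", "WT_LDOPA")):
                if sa in by_state and sb in by_state and len(by_state[sa]) == len(by_state[sb]) >= 2:
                    comparisons.append(
                        state_stats.compare_states(
                            f"corr_{cls}", sa, by_state[sa], sb, by_state[sb],
                            alternative="greater" if (sa, sb) == ("PD", "LID") else "two-sided",
                        )
                    )
    if "quiet_rates" in combined:
        qr = combined["quiet_rates"]
        rates = (
            qr.groupby(["state_", "session_id_"])["quiet_rate_hz"].mean().reset_index()
        )
        by_state = {st: sdf["quiet_rate_hz"].to_numpy(float) for st, sdf in rates.groupby("state_")}
        for sa, sb in (("PD", "LID"), ("WT", "WT_LDOPA")):
            if sa in by_state and sb in by_state and len(by_state[sa]) == len(by_state[sb]) >= 2:
                comparisons.append(
                    state_stats.compare_states(
                        "quiet_rate_hz", sa, by_state[sa], sb, by_state[sb],
                        alternative="two-sided",
                    )
                )
    combined["state_comparisons"] = state_stats.comparison_table(comparisons)

    if out_dir is not None:
        write_tables(combined, out_dir, meta={"config": json.dumps(config.echo())})
    return combined


def render_report(tables: dict[str, pd.DataFrame], config: PipelineConfig) -> str:
    """Single markdown report: state comparisons plus the config echo."""
    lines = ["# synchropipe analysis report", ""]
    sc = tables.get("state_comparisons")
    if sc is not None and len(sc):
        lines += ["## State comparisons", "", sc.to_string(index=False), ""]
    else:
        lines += ["## State comparisons", "", "(single state: no comparisons)", ""]
    pcs = tables.get("pair_class_summary")
    if pcs is not None and len(pcs):
        lines += ["## Pair-class correlations", "", pcs.to_string(index=False), ""]
    rs = tables.get("response_summary")
    if rs is not None and len(rs):
        lines += ["## Response classes", "", rs.to_string(index=False), ""]
    lines += ["## Configuration", "", "```json", json.dumps(config.echo(), indent=1), "```", ""]
    return "\n".join(lines)
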