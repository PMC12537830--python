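"""Session data model and plain-text interchange formats.

A recording session is exchanged as a *session bundle*: a directory of
TSV/JSON files (``session.json``, ``spikes.tsv``, ``units.tsv``,
``events.tsv``, ``waveform_stats.tsv`` and optionally ``trajectory.tsv``
and ``ground_truth.json``).  A convenience adapter for Kilosort/phy-style
sorter output directories is provided as well; the bundle is the canonical
format because it is human-readable and diffable.

Depths are micrometres below the pial surface; all times are seconds from
recording start, stored as 64-bit floats.  Sample counts from sorter output
are converted to seconds at read time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "RegionBoundaries",
    "DEFAULT_BOUNDARIES",
    "SpikeTrain",
    "Session",
    "STATES",
    "FormatError",
    "ValidationError",
    "assign_region",
    "merge_intervals",
    "read_events",
    "read_session_bundle",
    "write_session_bundle",
    "read_sorter_dir",
    "read_tsv",
    "write_tsv",
    "write_tables",
    "sessions_equal",
]

SCHEMA_VERSION = "synchropipe-bundle/1"
STATES = ("WT", "WT_LDOPA", "PD", "LID")


class FormatError(RuntimeError):
    """A mandatory file is missing or malformed."""


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class Region:
    """Anatomical labels assigned from depth below the pia."""

    L23 = "L23"
    L5 = "L5"
    STR = "STR"
    BORDERLINE = "BORDERLINE"
    OUT = "OUT"

    ANALYSIS = (L23, L5, STR)
    ALL = (L23, L5, STR, BORDERLINE, OUT)


@dataclass(frozen=True)
class RegionBoundaries:
    """Closed depth bands (µm below pia) for the three analysed regions.

    Depths between bands are BORDERLINE, depths beyond the striatal band are
    OUT.  Ties at band edges go to the named region (closed intervals on both
    ends); pass different tuples to move an edge.
    """

    l23: tuple[float, float] = (0.0, 350.0)
    l5: tuple[float, float] = (450.0, 1000.0)
    striatum: tuple[float, float] = (1500.0, 3500.0)

    def __post_init__(self) -> None:
        bands = [self.l23, self.l5, self.striatum]
        for lo, hi in bands:
            if not lo <= hi:
                raise ValidationError(f"band {lo}..{hi} is reversed")
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            if hi >= lo:
                raise ValidationError("depth bands overlap or touch")


DEFAULT_BOUNDARIES = RegionBoundaries()


def assign_region(depth_um: float, boundaries: RegionBoundaries = DEFAULT_BOUNDARIES) -> str:
    """Map a depth below the pia to one of the five region labels.

    Total on [0, inf): L23 / L5 / STR inside the closed bands, BORDERLINE in
    the two gaps, OUT beyond the striatal band.
    """
    if depth_um < 0 or not np.isfinite(depth_um):
        raise ValidationError(f"depth must be finite and >= 0, got {depth_um}")
    for band, label in (
        (boundaries.l23, Region.L23),
        (boundaries.l5, Region.L5),
        (boundaries.striatum, Region.STR),
    ):
        if band[0] <= depth_um <= band[1]:
            return label
    if depth_um > boundaries.striatum[1]:
        return Region.OUT
    return Region.BORDERLINE


@dataclass
class SpikeTrain:
    """One sorted unit: event times plus depth, region and QC metadata.

    ``amplitudes_uv`` / ``halfwidths_ms`` are per-spike waveform summaries
    aligned with ``times`` (may be None when the source provides none).
    """

    unit_id: str
    times: np.ndarray
    depth_um: float
    region: str
    sorter_label: str = "good"
    amplitudes_uv: np.ndarray | None = None
    halfwidths_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"unit {self.unit_id}: times not strictly increasing")
        if self.depth_um < 0:
            raise ValidationError(f"unit {self.unit_id}: negative depth")
        for name in ("amplitudes_uv", "halfwidths_ms"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.times.shape:
                    raise ValidationError(
                        f"unit {self.unit_id}: {name} not aligned with times"
                    )
                setattr(self, name, arr)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def rate_hz(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else float("nan")


@dataclass
class Session:
    """One recording: spike trains, event tables, state label and duration."""

    mouse_id: str
    state: str
    duration_s: float
    trains: list[SpikeTrain] = field(default_factory=list)
    movements: list[tuple[float, float]] = field(default_factory=list)
    injection_time_s: float | None = None
    sample_rate_hz: float = 30000.0
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}; expected one of {STATES}")
        self.movements = merge_intervals(self.movements)
        for on, off in self.movements:
            if not (0.0 <= on < off <= self.duration_s):
                raise ValidationError(f"movement ({on}, {off}) outside [0, {self.duration_s}]")
        if self.injection_time_s is not None and not (
            0.0 <= self.injection_time_s <= self.duration_s
        ):
            raise ValidationError("injection time outside the session span")
        for tr in self.trains:
            if tr.times.size and (tr.times[0] < 0 or tr.times[-1] > self.duration_s):
                raise ValidationError(f"unit {tr.unit_id}: spikes outside [0, duration]")
        if not self.session_id:
            self.session_id = f"{self.mouse_id}_{self.state}"

    @property
    def units(self) -> list[str]:
        return [tr.unit_id for tr in self.trains]

    def train(self, unit_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)

    def subset(self, unit_ids: Iterable[str]) -> "Session":
        keep = set(unit_ids)
        return replace(self, trains=[tr for tr in self.trains if tr.unit_id in keep])


def merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sort intervals and merge overlapping or touching ones (idempotent)."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for a, b in ivs:
        if b <= a:
            raise ValidationError(f"interval ({a}, {b}) has offset <= onset")
    merged: list[tuple[float, float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# TSV helpers — all output tables carry '#' comment header lines.
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: Path | str, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {json.dumps(val) if not isinstance(val, str) else val}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_events(path: Path | str) -> tuple[list[tuple[float, float]], float | None]:
    """Read an events table into merged movement intervals + injection time.

    Expected columns: ``event_type`` in {movement, injection}, ``onset_s``,
    ``offset_s`` (empty for injection rows).  At most one injection row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"events file not found: {path}")
    df = read_tsv(path)
    required = {"event_type", "onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path.name}: missing columns {required - set(df.columns)}")
    movements = []
    injection: float | None = None
    for _, row in df.iterrows():
        kind = str(row["event_type"])
        if kind == "movement":
            on, off = float(row["onset_s"]), float(row["offset_s"])
            if not off > on:
                raise ValidationError(f"movement offset {off} <= onset {on}")
            movements.append((on, off))
        elif kind == "injection":
            if injection is not None:
                raise ValidationError("more than one injection row")
            injection = float(row["onset_s"])
        else:
            raise FormatError(f"unknown event_type {kind!r}")
    return merge_intervals(movements), injection


# ---------------------------------------------------------------------------
# Session bundle (canonical interchange format)
# ---------------------------------------------------------------------------

def write_session_bundle(
    session: Session,
    out_dir: Path | str,
    trajectory: pd.DataFrame | None = None,
    ground_truth: dict | None = None,
) -> Path:
    """Write a session to the plain-text bundle layout; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema": SCHEMA_VERSION,
        "session_id": session.session_id,
        "mouse_id": session.mouse_id,
        "state": session.state,
        "duration_s": session.duration_s,
        "sample_rate_hz": session.sample_rate_hz,
        "injection_time_s": session.injection_time_s,
    }
    (out / "session.json").write_text(json.dumps(meta, indent=1) + "\n")

    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(
                [np.repeat(tr.unit_id, tr.n_spikes) for tr in session.trains]
            )
            if session.trains
            else np.array([], dtype=str),
            "time_s": np.concatenate([tr.times for tr in session.trains])
            if session.trains
            else np.array([], dtype=float),
        }
    )
    write_tsv(spikes, out / "spikes.tsv")

    units = pd.DataFrame(
        [
            {"unit_id": tr.unit_id, "depth_um": tr.depth_um, "sorter_label": tr.sorter_label}
            for tr in session.trains
        ],
        columns=["unit_id", "depth_um", "sorter_label"],
    )
    write_tsv(units, out / "units.tsv")

    rows = []
    for tr in session.trains:
        if tr.amplitudes_uv is None:
            continue
        for i in range(tr.n_spikes):
            rows.append(
                {
                    "unit_id": tr.unit_id,
                    "spike_index": i,
                    "amplitude_uv": tr.amplitudes_uv[i],
                    "halfwidth_ms": tr.halfwidths_ms[i] if tr.halfwidths_ms is not None else np.nan,
                }
            )
    wf = pd.DataFrame(rows, columns=["unit_id", "spike_index", "amplitude_uv", "halfwidth_ms"])
    write_tsv(wf, out / "waveform_stats.tsv")

    ev_rows = [
        {"event_type": "movement", "onset_s": on, "offset_s": off}
        for on, off in session.movements
    ]
    if session.injection_time_s is not None:
        ev_rows.append(
            {"event_type": "injection", "onset_s": session.injection_time_s, "offset_s": ""}
        )
    events = pd.DataFrame(ev_rows, columns=["event_type", "onset_s", "offset_s"])
    write_tsv(events, out / "events.tsv")

    if trajectory is not None:
        write_tsv(trajectory, out / "trajectory.tsv")
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1) + "\n")
    return out


def read_session_bundle(path: Path | str) -> Session:
    """Read a session bundle directory back into a :class:`Session`.

    Lossless for every field the bundle writer emits.  Curation labels are
    kept as-is (no QC filtering happens at read time).
    """
    path = Path(path)
    meta_path = path / "session.json"
    for name in ("session.json", "spikes.tsv", "units.tsv", "events.tsv"):
        if not (path / name).exists():
            raise FormatError(f"bundle {path} is missing mandatory file {name}")
    meta = json.loads(meta_path.read_text())
    spikes = read_tsv(path / "spikes.tsv")
    units = read_tsv(path / "units.tsv")
    wf_path = path / "waveform_stats.tsv"
    wf = read_tsv(wf_path) if wf_path.exists() else pd.DataFrame(
        columns=["unit_id", "spike_index", "amplitude_uv", "halfwidth_ms"]
    )
    movements, injection = read_events(path / "events.tsv")

    trains = []
    spikes_by_unit = dict(iter(spikes.groupby("unit_id"))) if len(spikes) else {}
    wf_by_unit = dict(iter(wf.groupby("unit_id"))) if len(wf) else {}
    for _, urow in units.iterrows():
        uid = str(urow["unit_id"])
        grp = spikes_by_unit.get(uid)
        times = np.sort(grp["time_s"].to_numpy(float)) if grp is not None else np.array([])
        if grp is not None and np.any(np.diff(grp["time_s"].to_numpy(float)) <= 0):
            # sorted above, but duplicates indicate a malformed bundle
            if np.any(np.diff(times) <= 0):
                raise ValidationError(f"unit {uid}: non-monotone spike times in bundle")
        amps = hw = None
        wgrp = wf_by_unit.get(uid)
        if wgrp is not None and len(wgrp) == len(times):
            wgrp = wgrp.sort_values("spike_index")
            amps = wgrp["amplitude_uv"].to_numpy(float)
            hw = wgrp["halfwidth_ms"].to_numpy(float)
        depth = float(urow["depth_um"])
        trains.append(
            SpikeTrain(
                unit_id=uid,
                times=times,
                depth_um=depth,
                region=assign_region(depth),
                sorter_label=str(urow["sorter_label"]),
                amplitudes_uv=amps,
                halfwidths_ms=hw,
            )
        )
    inj = meta.get("injection_time_s")
    return Session(
        mouse_id=str(meta["mouse_id"]),
        state=str(meta["state"]),
        duration_s=float(meta["duration_s"]),
        trains=trains,
        movements=movements,
        injection_time_s=float(inj) if inj is not None else injection,
        sample_rate_hz=float(meta.get("sample_rate_hz", 30000.0)),
        session_id=str(meta.get("session_id", "")),
    )


def read_trajectory(path: Path | str) -> pd.DataFrame:
    """Read a bundle trajectory table (t_s, x, y, heading_rad)."""
    return read_tsv(Path(path) / "trajectory.tsv")


def sessions_equal(a: Session, b: Session, rtol: float = 0.0, atol: float = 1e-12) -> bool:
    """Field-wise equality of two sessions (numeric fields to tolerance)."""
    if (
        a.mouse_id != b.mouse_id
        or a.state != b.state
        or not np.isclose(a.duration_s, b.duration_s, rtol=rtol, atol=atol)
        or sorted(a.units) != sorted(b.units)
        or len(a.movements) != len(b.movements)
    ):
        return False
    if not all(
        np.isclose(x, y, rtol=rtol, atol=atol)
        for (x1, x2), (y1, y2) in zip(a.movements, b.movements)
        for x, y in ((x1, y1), (x2, y2))
    ):
        return False
    if (a.injection_time_s is None) != (b.injection_time_s is None):
        return False
    if a.injection_time_s is not None and not np.isclose(
        a.injection_time_s, b.injection_time_s, rtol=rtol, atol=atol
    ):
        return False
    for uid in a.units:
        ta, tb = a.train(uid), b.train(uid)
        if ta.n_spikes != tb.n_spikes or not np.allclose(ta.times, tb.times, rtol=rtol, atol=atol):
            return False
        if ta.sorter_label != tb.sorter_label or not np.isclose(ta.depth_um, tb.depth_um, atol=atol):
            return False
        for fa, fb in ((ta.amplitudes_uv, tb.amplitudes_uv), (ta.halfwidths_ms, tb.halfwidths_ms)):
            if (fa is None) != (fb is None):
                return False
            if fa is not None and not np.allclose(fa, fb, rtol=rtol, atol=atol, equal_nan=True):
                return False
    return True


# ---------------------------------------------------------------------------
# Kilosort/phy-style sorter directory adapter
# ---------------------------------------------------------------------------

def _read_params_py(path: Path) -> dict:
    params: dict = {}
    for line in path.read_text().splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        try:
            params[key.strip()] = eval(val.strip(), {"__builtins__": {}})  # noqa: S307
        except Exception:
            params[key.strip()] = val.strip().strip("'\"")
    return params


def read_sorter_dir(
    path: Path | str,
    sample_rate_hz: float | None = None,
    duration_s: float | None = None,
    mouse_id: str = "unknown",
    state: str = "WT",
    depth_source: str = "peak_channel",
) -> Session:
    """Ingest a Kilosort/phy-style output directory.

    Requires ``spike_times.npy`` (samples), ``spike_clusters.npy`` and
    ``cluster_group.tsv``.  Cluster depth comes from ``cluster_info.tsv``
    (``depth`` column) when present; otherwise, with
    ``depth_source='peak_channel'``, from the vertical coordinate of the
    channel with the largest mean template amplitude (``templates.npy`` +
    ``channel_positions.npy``).  The vertical coordinate is interpreted as
    micrometres below the pia.
    """
    path = Path(path)
    for name in ("spike_times.npy", "spike_clusters.npy", "cluster_group.tsv"):
        if not (path / name).exists():
            raise FormatError(f"sorter directory {path} is missing {name}")
    spike_samples = np.load(path / "spike_times.npy").ravel()
    clusters = np.load(path / "spike_clusters.npy").ravel()
    if spike_samples.shape != clusters.shape:
        raise FormatError("spike_times.npy and spike_clusters.npy disagree in length")
    groups = pd.read_csv(path / "cluster_group.tsv", sep="\t")
    label_col = "KSLabel" if "KSLabel" in groups.columns else "group"
    labels = {int(r["cluster_id"]): str(r[label_col]) for _, r in groups.iterrows()}

    if sample_rate_hz is None:
        params_path = path / "params.py"
        if not params_path.exists():
            raise FormatError("sample rate not given and params.py missing")
        sample_rate_hz = float(_read_params_py(params_path).get("sample_rate", 0.0))
        if sample_rate_hz <= 0:
            raise FormatError("could not resolve sample_rate from params.py")

    depths: dict[int, float] = {}
    info_path = path / "cluster_info.tsv"
    if info_path.exists():
        info = pd.read_csv(info_path, sep="\t")
        if "depth" in info.columns:
            depths = {int(r["cluster_id"]): float(r["depth"]) for _, r in info.iterrows()}
    if not depths and depth_source == "peak_channel":
        tpl_path, pos_path = path / "templates.npy", path / "channel_positions.npy"
        if not (tpl_path.exists() and pos_path.exists()):
            raise FormatError("no cluster_info.tsv depth and no templates/channel_positions")
        templates = np.load(tpl_path)  # (n_templates, n_samples, n_channels)
        positions = np.load(pos_path)  # (n_channels, 2), column 1 = vertical coord
        peak = np.argmax(np.ptp(templates, axis=1), axis=1)
        depths = {cid: float(positions[peak[cid], 1]) for cid in range(templates.shape[0])}

    times_s = spike_samples.astype(float) / sample_rate_hz
    if duration_s is None:
        duration_s = float(times_s.max()) + 1.0 if times_s.size else 1.0
    trains = []
    for cid in sorted(np.unique(clusters)):
        cid = int(cid)
        t = np.sort(times_s[clusters == cid])
        if np.any(np.diff(t) < 0):
            raise ValidationError(f"cluster {cid}: non-monotone spike times")
        t = np.unique(t)
        depth = depths.get(cid)
        if depth is None:
            raise FormatError(f"cluster {cid}: no depth available")
        trains.append(
            SpikeTrain(
                unit_id=str(cid),
                times=t,
                depth_um=depth,
                region=assign_region(depth),
                sorter_label=labels.get(cid, "unsorted"),
            )
        )
    events_path = path / "events.tsv"
    movements, injection = read_events(events_path) if events_path.exists() else ([], None)
    return Session(
        mouse_id=mouse_id,
        state=state,
        duration_s=duration_s,
        trains=trains,
        movements=movements,
        injection_time_s=injection,
        sample_rate_hz=sample_rate_hz,
    )


def write_tables(results: dict[str, pd.DataFrame], out_dir: Path | str, meta: dict | None = None) -> list[Path]:
    """Write analysis result tables as TSVs with a schema/config header.

    ``results`` maps table names (e.g. ``unit_table``, ``correlations``,
    ``pair_class_summary``, ``responses``, ``response_summary``,
    ``state_comparisons``) to DataFrames; empty frames yield header-only
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        written.append(write_tsv(df, out / f"{name}.tsv", meta=meta))
    return written
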