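"""Ground-truth session generator.

Every pipeline stage is testable without recordings: this module emits
session bundles whose spike trains, waveform series, movement schedules and
trajectories are sampled from known parameters, written alongside a
``ground_truth.json`` describing them.

Correlated populations use the multiple interaction process (MIP): a mother
Poisson process at rate ``rate/p`` is copied into each child train, keeping
each mother spike independently with probability ``p`` and jittering kept
spikes by a Gaussian of sd ``jitter_sd_s``.  The expected pairwise Pearson
correlation of binned counts has the closed form ``p * gamma(b, sigma)``,
where ``gamma`` is the probability that two independently jittered copies of
the same mother spike land in the same bin of width ``b`` — this closed form
is the oracle the correlation stage is validated against.

Defaults emulate quiet-epoch motor-cortex recordings: quiet rates around
0.1–4 Hz depending on state, injected pairwise correlations in the
0.04–0.12 range, movement bouts with movement-locked rate gains, and the
four peri-injection response shapes (monophasic bump, multiple bumps,
sustained suppression, flat).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_sessions import (
    Region,
    Session,
    SpikeTrain,
    ValidationError,
    assign_region,
    merge_intervals,
    write_session_bundle,
)

__all__ = [
    "PopulationSpec",
    "ResponseTemplates",
    "SynthConfig",
    "mip_expected_correlation",
    "mip_population",
    "response_rate_profile",
    "response_train",
    "movement_schedule",
    "synth_trajectory",
    "emit_session",
    "state_preset",
]

_DEPTH_RANGES = {Region.L23: (50.0, 330.0), Region.L5: (470.0, 980.0), Region.STR: (1600.0, 3400.0)}


# ---------------------------------------------------------------------------
# MIP populations
# ---------------------------------------------------------------------------

def mip_expected_correlation(copy_prob: float, jitter_sd_s: float, bin_width_s: float) -> float:
    """Closed-form expected pairwise binned-count correlation of MIP trains.

    r = p * gamma where gamma = E[(1 - |D|/b)+] with D ~ Normal(0, 2*sigma^2):
    the probability that the two jittered copies of a shared mother spike fall
    into the same bin (triangular bin-overlap kernel).  With no jitter
    gamma = 1 and r = p exactly.
    """
    if not 0.0 <= copy_prob <= 1.0:
        raise ValidationError("copy_prob must lie in [0, 1]")
    if copy_prob == 0.0:
        return 0.0
    if jitter_sd_s <= 0.0:
        return copy_prob
    s = np.sqrt(2.0) * jitter_sd_s
    b = bin_width_s
    gamma = (
        2.0 * stats.norm.cdf(b / s)
        - 1.0
        - (2.0 * s**2 / b) * (stats.norm.pdf(0.0, scale=s) - stats.norm.pdf(b, scale=s))
    )
    return float(copy_prob * gamma)


def mip_population(
    n_units: int,
    rate_hz: float,
    copy_prob: float,
    jitter_sd_s: float,
    duration_s: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Sample ``n_units`` correlated Poisson trains with expected rate ``rate_hz``.

    ``copy_prob = 0`` yields independent Poisson trains; ``copy_prob = 1``
    with zero jitter yields identical trains.  Jittered spikes falling outside
    [0, duration] are dropped.
    """
    if not 0.0 <= copy_prob <= 1.0:
        raise ValidationError("copy_prob must lie in [0, 1]")
    if rate_hz < 0:
        raise ValidationError("rate_hz must be >= 0")
    if copy_prob > 0 and rate_hz == 0:
        raise ValidationError("copy_prob > 0 requires a positive rate")
    trains = []
    if copy_prob == 0.0:
        for _ in range(n_units):
            n = rng.poisson(rate_hz * duration_s)
            trains.append(np.sort(rng.uniform(0.0, duration_s, size=n)))
        return trains
    mother_rate = rate_hz / copy_prob
    n_mother = rng.poisson(mother_rate * duration_s)
    mother = np.sort(rng.uniform(0.0, duration_s, size=n_mother))
    for _ in range(n_units):
        keep = rng.random(n_mother) < copy_prob
        t = mother[keep]
        if jitter_sd_s > 0:
            t = t + rng.normal(0.0, jitter_sd_s, size=t.size)
            t = t[(t >= 0.0) & (t <= duration_s)]
        trains.append(np.unique(t))
    return trains


# ---------------------------------------------------------------------------
# Peri-injection response templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseTemplates:
    """Rate-profile parameters for the four peri-injection response shapes.

    Gains are multiples of the baseline rate; times are seconds relative to
    the injection.  Defaults are chosen so each template is unambiguous under
    the default classifier thresholds at realistic low cortical baselines.
    """

    mono_peak_gain: float = 7.0
    mono_peak_time_s: float = 600.0
    mono_shape: float = 2.0  # gamma-bump sharpness
    multi_peak_gain: float = 8.0
    multi_centers_s: tuple[float, ...] = (600.0, 1800.0, 3000.0)
    multi_sd_s: float = 150.0
    supp_gain: float = 0.2
    supp_onset_s: float = 120.0
    supp_duration_s: float = 1500.0


def response_rate_profile(
    response_class: str,
    baseline_hz: float,
    injection_time_s: float,
    duration_s: float,
    templates: ResponseTemplates = ResponseTemplates(),
    n_bumps: int | None = None,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Ground-truth rate profile lambda(t) on a ``dt_s`` grid over the session."""
    t = np.arange(0.0, duration_s, dt_s)
    lam = np.full(t.shape, baseline_hz)
    rel = t - injection_time_s
    post = rel >= 0
    if response_class == "NONE":
        return lam
    if response_class == "MONO":
        tp, a = templates.mono_peak_time_s, templates.mono_shape
        x = np.where(post, rel / tp, 0.0)
        bump = np.where(post, np.power(x, a, where=post, out=np.zeros_like(x)) * np.exp(a * (1.0 - x)), 0.0)
        lam = baseline_hz * (1.0 + (templates.mono_peak_gain - 1.0) * bump)
    elif response_class == "MULTI":
        centers = templates.multi_centers_s[: (n_bumps or 2)]
        bump = np.zeros_like(t)
        for c in centers:
            bump += np.exp(-0.5 * ((rel - c) / templates.multi_sd_s) ** 2)
        lam = baseline_hz * (1.0 + (templates.multi_peak_gain - 1.0) * np.where(post, bump, 0.0))
    elif response_class == "SUPP":
        dip = (rel >= templates.supp_onset_s) & (
            rel < templates.supp_onset_s + templates.supp_duration_s
        )
        lam = np.where(dip, baseline_hz * templates.supp_gain, baseline_hz)
    else:
        raise ValidationError(f"unknown response class {response_class!r}")
    return lam


def _inhomogeneous_poisson(
    profile_hz: np.ndarray, duration_s: float, rng: np.random.Generator, dt_s: float = 1.0
) -> np.ndarray:
    """Thinning sampler for a piecewise-constant rate profile."""
    lam_max = float(profile_hz.max())
    if lam_max <= 0:
        return np.array([])
    n = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n))
    idx = np.minimum((cand / dt_s).astype(int), profile_hz.size - 1)
    keep = rng.random(n) < profile_hz[idx] / lam_max
    return cand[keep]


def response_train(
    response_class: str,
    baseline_hz: float,
    injection_time_s: float,
    duration_s: float,
    rng: np.random.Generator,
    templates: ResponseTemplates = ResponseTemplates(),
    n_bumps: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson train for one response class.

    Returns (spike times, ground-truth rate profile on a 1 s grid).
    """
    profile = response_rate_profile(
        response_class, baseline_hz, injection_time_s, duration_s, templates, n_bumps
    )
    return _inhomogeneous_poisson(profile, duration_s, rng), profile


# ---------------------------------------------------------------------------
# Movement schedules and trajectories
# ---------------------------------------------------------------------------

def movement_schedule(
    duration_s: float,
    bout_rate_hz: float,
    bout_duration_s: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Poisson-process movement bouts of fixed length, merged if overlapping."""
    if bout_rate_hz < 0 or bout_duration_s <= 0 or duration_s <= 0:
        raise ValidationError("schedule parameters must be positive")
    if bout_rate_hz == 0:
        return []
    n = rng.poisson(bout_rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n))
    intervals = [
        (float(on), float(min(on + bout_duration_s, duration_s)))
        for on in onsets
        if on < duration_s - 1e-9
    ]
    return merge_intervals([iv for iv in intervals if iv[1] > iv[0]])


def synth_trajectory(
    duration_s: float,
    rng: np.random.Generator,
    dt_s: float = 0.1,
    cw_turns: int = 0,
    ccw_turns: int = 0,
    speed: float = 1.0,
    heading_noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Open-field trajectory with a planted number of full turns.

    Heading drifts linearly by 2*pi*(ccw - cw) over the session (plus small
    noise, kept well below a quarter turn so the planted count is exact);
    positions integrate unit steps along the heading at ``speed``.
    """
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    net = 2.0 * np.pi * (ccw_turns - cw_turns)
    heading = net * (t / duration_s) + rng.normal(0.0, heading_noise_sd, size=t.size)
    heading[0] = 0.0
    step = speed * dt_s
    x = np.concatenate([[0.0], np.cumsum(step * np.cos(heading[:-1]))])
    y = np.concatenate([[0.0], np.cumsum(step * np.sin(heading[:-1]))])
    return pd.DataFrame({"t_s": t, "x": x, "y": y, "heading_rad": heading})


# ---------------------------------------------------------------------------
# Whole-session emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    region: str
    n_units: int
    quiet_rate_hz: float
    copy_prob: float
    jitter_sd_s: float = 0.003


@dataclass
class SynthConfig:
    """One synthetic recording session.

    Quiet rates and injected correlations default to the regime the pipeline
    targets (sub-hertz quiet cortical rates; intra-layer count correlations of
    a few hundredths).  ``drift_unit_ids`` get a linear amplitude decay of
    ``drift_fraction`` over the recording and should fail waveform-stability
    QC; everything else is constructed to pass all five criteria.
    """

    seed: int = 0
    mouse_id: str = "m01"
    state: str = "PD"
    duration_s: float = 1800.0
    sample_rate_hz: float = 30000.0
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec(Region.L23, 6, 1.0, 0.04),
        PopulationSpec(Region.L5, 8, 1.0, 0.04),
        PopulationSpec(Region.STR, 6, 1.5, 0.04),
    )
    bout_rate_hz: float = 1.0 / 60.0
    bout_duration_s: float = 3.0
    movement_gain: float = 3.0
    injection_time_s: float | None = None
    response_mix: tuple[float, float, float, float] = (0.4, 0.2, 0.13, 0.27)  # MONO/MULTI/SUPP/NONE
    templates: ResponseTemplates = field(default_factory=ResponseTemplates)
    amplitude_uv_range: tuple[float, float] = (60.0, 220.0)
    halfwidth_ms_range: tuple[float, float] = (0.15, 0.55)
    waveform_cv: float = 0.05
    drift_fraction: float = 0.0
    n_drift_units: int = 0
    refractory_deadtime_s: float = 0.0025
    trajectory_cw_turns: int = 0
    trajectory_ccw_turns: int = 0


def _enforce_deadtime(times: np.ndarray, deadtime_s: float) -> np.ndarray:
    """Greedily drop spikes closer than ``deadtime_s`` to the kept predecessor."""
    if times.size == 0 or deadtime_s <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= deadtime_s:
            kept.append(t)
    return np.asarray(kept)


def state_preset(state: str, seed: int = 0, mouse_id: str = "m01") -> SynthConfig:
    """Study-condition presets for the four recording states.

    PD and LID share identical quiet-time firing rates but differ in injected
    intra-layer correlation (0.04 vs 0.11) — the dissociation the synchrony
    analysis is designed to expose.  The WT pair shares its correlation level
    (l-dopa alone leaves synchrony unchanged) and carries an injection in the
    treated state; LID sessions also carry an injection so the response
    classifier has work to do.
    """
    quiet = {"WT": 0.9, "WT_LDOPA": 0.9, "PD": 0.6, "LID": 0.6}[state]
    p_intra = {"WT": 0.057, "WT_LDOPA": 0.057, "PD": 0.04, "LID": 0.11}[state]
    inj = 700.0 if state in ("WT_LDOPA", "LID") else None
    duration = 4300.0 if inj is not None else 1800.0
    return SynthConfig(
        seed=seed,
        mouse_id=mouse_id,
        state=state,
        duration_s=duration,
        populations=(
            PopulationSpec(Region.L23, 6, quiet, p_intra),
            PopulationSpec(Region.L5, 8, quiet, p_intra),
            PopulationSpec(Region.STR, 6, 1.5 * quiet, 0.04),
        ),
        injection_time_s=inj,
        trajectory_cw_turns={"PD": 9, "LID": 2}.get(state, 3),
        trajectory_ccw_turns={"PD": 1, "LID": 12}.get(state, 3),
    )


def emit_session(config: SynthConfig, out_dir: Path | str | None = None) -> tuple[Session, dict]:
    """Build one ground-truth session (optionally writing its bundle).

    Per-component random streams are spawned from the master seed so spikes,
    waveforms, schedule and trajectory can be regenerated independently; the
    emitted bundle is identical across runs for equal configs.
    """
    root = np.random.SeedSequence(config.seed)
    ss_spikes, ss_wave, ss_sched, ss_traj, ss_resp = root.spawn(5)
    rng_spikes = np.random.default_rng(ss_spikes)
    rng_wave = np.random.default_rng(ss_wave)
    rng_resp = np.random.default_rng(ss_resp)

    movements = movement_schedule(
        config.duration_s, config.bout_rate_hz, config.bout_duration_s, np.random.default_rng(ss_sched)
    )

    trains: list[SpikeTrain] = []
    gt_units = []
    drift_budget = config.n_drift_units
    unit_index = 0
    for pop in config.populations:
        base_trains = mip_population(
            pop.n_units, pop.quiet_rate_hz, pop.copy_prob, pop.jitter_sd_s, config.duration_s, rng_spikes
        )
        depth_lo, depth_hi = _DEPTH_RANGES[pop.region]
        depths = np.sort(rng_wave.uniform(depth_lo, depth_hi, size=pop.n_units))
        for k, base in enumerate(base_trains):
            uid = f"u{unit_index:03d}"
            unit_index += 1
            times = base
            # movement-locked multiplicative gain: extra independent spikes in bouts
            if config.movement_gain > 1.0 and movements:
                extra = []
                for on, off in movements:
                    lam = (config.movement_gain - 1.0) * pop.quiet_rate_hz * (off - on)
                    m = rng_spikes.poisson(lam)
                    extra.append(rng_spikes.uniform(on, off, size=m))
                times = np.concatenate([times] + extra)
            response_class = "NONE"
            pre_rate = post_rate = pop.quiet_rate_hz
            if config.injection_time_s is not None:
                response_class = rng_resp.choice(
                    ("MONO", "MULTI", "SUPP", "NONE"), p=np.asarray(config.response_mix)
                )
                if response_class != "NONE":
                    profile = response_rate_profile(
                        response_class,
                        pop.quiet_rate_hz,
                        config.injection_time_s,
                        config.duration_s,
                        config.templates,
                        n_bumps=int(rng_resp.integers(2, 4)) if response_class == "MULTI" else None,
                    )
                    # replace post-injection activity with the template train
                    gain = profile / pop.quiet_rate_hz
                    post_mask = times >= config.injection_time_s
                    post_times = times[post_mask]
                    idx = np.minimum(post_times.astype(int), profile.size - 1)
                    keep = rng_resp.random(post_times.size) < np.minimum(gain[idx], 1.0)
                    lam_extra = np.maximum(profile - pop.quiet_rate_hz, 0.0)
                    extra = _inhomogeneous_poisson(lam_extra, config.duration_s, rng_resp)
                    times = np.concatenate([times[~post_mask], post_times[keep], extra])
                    inj_bin = int(config.injection_time_s)
                    post_rate = float(profile[inj_bin:].mean())
            times = _enforce_deadtime(np.unique(np.sort(times)), config.refractory_deadtime_s)
            times = times[(times >= 0) & (times <= config.duration_s)]

            amp_mean = rng_wave.uniform(*config.amplitude_uv_range)
            hw_mean = rng_wave.uniform(*config.halfwidth_ms_range)
            amps = amp_mean * (1.0 + config.waveform_cv * rng_wave.standard_normal(times.size))
            hws = hw_mean * (1.0 + config.waveform_cv * rng_wave.standard_normal(times.size))
            is_drift = drift_budget > 0 and k == 0 and config.drift_fraction > 0
            if is_drift:
                drift_budget -= 1
                amps = amps * (1.0 - config.drift_fraction * times / config.duration_s)
            depth = float(depths[k])
            trains.append(
                SpikeTrain(
                    unit_id=uid,
                    times=times,
                    depth_um=depth,
                    region=assign_region(depth),
                    sorter_label="good",
                    amplitudes_uv=amps,
                    halfwidths_ms=hws,
                )
            )
            gt_units.append(
                {
                    "unit_id": uid,
                    "region": pop.region,
                    "depth_um": depth,
                    "quiet_rate_hz": pop.quiet_rate_hz,
                    "copy_prob": pop.copy_prob,
                    "response_class": response_class,
                    "pre_rate_hz": pre_rate,
                    "post_rate_hz": post_rate,
                    "drift": bool(is_drift),
                }
            )

    session = Session(
        mouse_id=config.mouse_id,
        state=config.state,
        duration_s=config.duration_s,
        trains=trains,
        movements=movements,
        injection_time_s=config.injection_time_s,
        sample_rate_hz=config.sample_rate_hz,
        session_id=f"{config.mouse_id}_{config.state}_s{config.seed}",
    )
    expected_means = {}
    for pop in config.populations:
        cls = f"{pop.region}-{pop.region}"
        expected_means[cls] = mip_expected_correlation(pop.copy_prob, pop.jitter_sd_s, 0.025)
    ground_truth = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("populations", "templates")},
            "populations": [asdict(p) for p in config.populations],
        },
        "units": gt_units,
        "movements": [list(iv) for iv in movements],
        "expected_pair_class_means_bin25ms": expected_means,
    }
    trajectory = synth_trajectory(
        min(config.duration_s, 600.0),
        np.random.default_rng(ss_traj),
        cw_turns=config.trajectory_cw_turns,
        ccw_turns=config.trajectory_ccw_turns,
    )
    if out_dir is not None:
        write_session_bundle(session, out_dir, trajectory=trajectory, ground_truth=ground_truth)
        (Path(out_dir) / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1) + "\n")
    return session, ground_truth
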