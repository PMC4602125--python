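"""Programmed electrical stimulation (PES) and reentry detection.

The induction protocol mirrors clinical EP-lab practice: a drive train of
S1 beats (default 6 at 600 ms cycle length) from one site, then a premature
S2 initially at 90% of the S1 cycle length, shortened in fixed decrements
until ventricular tachycardia is induced, capture fails (effective
refractory period) or the minimum coupling is reached.  If the S2 scan
fails, an S3 (then S4) extrastimulus is added, each scanned the same way
starting at the same fraction of the preceding coupling interval.

Induction is declared when sentinel probes register at least two
self-sustained activations later than one paced cycle after the last
stimulus; the VT cycle length is the median inter-activation interval.
Induced runs are continued to the configured VT duration (default 3 s).

The scan re-simulates only what changes: the S1 train is run once and its
final state snapshotted, every S2 trial restarts from that snapshot, and
S3/S4 scans restart from the shortest-capturing prefix.  Outcomes are
therefore bit-reproducible for a given grid and protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .monodomain import (
    TissueGrid, StimulusEvent, SimulationRecord, run_monodomain,
    CT_NORMAL, CT_GZ,
)


@dataclass(frozen=True)
class PacingProtocol:
    """S1-S4 programmed-stimulation settings (times in ms)."""

    n_s1: int = 6
    s1_cycle_length: float = 600.0
    s2_initial_fraction: float = 0.90
    coupling_decrement: float = 10.0
    min_coupling: float = 120.0
    max_extrastimuli: int = 3  # S2, S3, S4
    stimulus_amplitude: float = 60.0  # µA/µF
    stimulus_duration: float = 2.0
    stimulus_radius_mm: float = 1.2
    observation_window: float = 1300.0  # after each extrastimulus
    vt_duration: float = 3000.0  # simulated VT once induced
    vt_frame_interval: float = 2.0  # voltage-frame cadence during VT
    capture_window: float = 150.0  # ms for a stimulus to excite the sentinel
    dt: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.s2_initial_fraction < 1.0):
            raise ValueError("s2_initial_fraction must be in (0, 1)")
        if self.coupling_decrement <= 0:
            raise ValueError("coupling_decrement must be > 0")
        if self.n_s1 < 1:
            raise ValueError("at least one S1 beat is required")
        if self.max_extrastimuli < 0:
            raise ValueError("max_extrastimuli must be >= 0")

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PacingProtocol":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class InductionOutcome:
    """Result of PES at one site."""

    induced: bool
    site_mm: tuple[float, float, float]
    coupling_intervals_ms: list[float] = field(default_factory=list)
    tested_s2_couplings: list[float] = field(default_factory=list)
    vt_cycle_length_ms: float | None = None
    n_extrastimuli: int = 0
    record: SimulationRecord | None = None
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if self.induced and self.vt_cycle_length_ms is None:
            raise ValueError("induced outcomes must carry a VT cycle length")
        if not self.induced and self.vt_cycle_length_ms is not None:
            raise ValueError("cycle length only applies to induced outcomes")

    def summary(self) -> dict:
        return {
            "site_mm": tuple(np.round(self.site_mm, 3)),
            "induced": self.induced,
            "coupling_intervals_ms": list(self.coupling_intervals_ms),
            "vt_cycle_length_ms": self.vt_cycle_length_ms,
            "n_extrastimuli": self.n_extrastimuli,
            "failure_reason": self.failure_reason,
        }


def detect_reentry(record: SimulationRecord, last_stimulus_time: float,
                   window_ms: float, paced_cycle_ms: float = 600.0,
                   sentinel_indices=None) -> tuple[bool, float | None]:
    """Self-sustained-activation test on sentinel probes.

    Reentry is declared iff at least two activations occur at the sentinel
    node set later than ``last_stimulus_time + paced_cycle_ms``; the cycle
    length is the median inter-activation interval over the busiest
    sentinel.  The observation window must cover at least two paced cycles.
    """
    if window_ms < 2.0 * paced_cycle_ms:
        raise ValueError(
            f"observation window {window_ms} ms is shorter than two paced "
            f"cycles ({2 * paced_cycle_ms} ms)")
    if sentinel_indices is None:
        ct = record.grid.celltype.ravel()
        sentinel_indices = np.flatnonzero((ct == CT_NORMAL) | (ct == CT_GZ))
    t_free = last_stimulus_time + paced_cycle_ms
    best: np.ndarray | None = None
    for idx in np.atleast_1d(sentinel_indices):
        times = record.node_activations(int(idx))
        late = times[times > t_free]
        if best is None or late.size > best.size:
            best = late
    if best is None or best.size < 2:
        return False, None
    cl = float(np.median(np.diff(best))) if best.size >= 2 else None
    return True, cl


def _stimulus(protocol: PacingProtocol, onset: float, site) -> StimulusEvent:
    return StimulusEvent(onset_ms=onset, duration_ms=protocol.stimulus_duration,
                         amplitude=protocol.stimulus_amplitude,
                         center_mm=tuple(site),
                         radius_mm=protocol.stimulus_radius_mm)


def _captures(record: SimulationRecord, grid: TissueGrid, site,
              stim_onset: float, protocol: PacingProtocol) -> bool:
    """A stimulus captures if tissue just outside the electrode activates."""
    near = grid.nodes_in_ball(site, protocol.stimulus_radius_mm + 4.0)
    inside = grid.nodes_in_ball(site, protocol.stimulus_radius_mm)
    ring = np.setdiff1d(near, inside)
    if ring.size == 0:
        ring = near
    t0, t1 = stim_onset, stim_onset + protocol.capture_window
    for idx in ring:
        times = record.node_activations(int(idx))
        if np.any((times >= t0) & (times <= t1)):
            return True
    return False


def run_pes(grid: TissueGrid, protocol: PacingProtocol, site_mm,
            probes_mm=(), verbose=False) -> InductionOutcome:
    """Full S1-S(2..4) scan at one epicardial site.

    Returns the outcome with the induced VT record (continued to
    ``protocol.vt_duration`` after the last stimulus) or the last
    non-induced trial record.
    """
    site = tuple(float(v) for v in site_mm)
    p = protocol
    cl = p.s1_cycle_length

    # ---- S1 drive train, simulated once and snapshotted ------------------
    s1_onsets = [10.0 + b * cl for b in range(p.n_s1)]
    train_end = s1_onsets[-1]  # snapshot at delivery of the last S1
    s1_stims = [_stimulus(p, t, site) for t in s1_onsets]
    rec_s1 = run_monodomain(grid, s1_stims, train_end + p.stimulus_duration + p.dt,
                            dt=p.dt, probes_mm=probes_mm)
    if not _captures(rec_s1, grid, site, s1_onsets[0], p):
        raise RuntimeError(
            f"S1 never captured at site {site}: non-excitable stimulus site")
    snapshot = rec_s1.final_states
    snap_t = rec_s1.t_end

    def run_from(states, t0, stims, duration, frames=False):
        return run_monodomain(
            grid, stims, duration, dt=p.dt, probes_mm=probes_mm,
            initial_states=states, t_start=t0,
            stop_quiescent_after_ms=(stims[-1].onset_ms + 50.0) if stims else t0,
        )

    tested_s2 = []

    def scan(prefix_states, prefix_t, prefix_couplings, last_onset, level):
        """Scan one extrastimulus level; recurse to the next on failure.

        The quiet interval between the prefix snapshot and each candidate
        extrastimulus is identical across trials, so it is simulated once,
        checkpointed at every tested onset, and each trial restarts from
        its checkpoint (bit-identical to simulating the wait inline).
        Returns an InductionOutcome or None if this level exhausted.
        """
        base_interval = cl if level == 2 else prefix_couplings[-1]
        start = np.floor(p.s2_initial_fraction * base_interval
                         / p.coupling_decrement) * p.coupling_decrement
        couplings = np.arange(start, p.min_coupling - 1e-9,
                              -p.coupling_decrement)
        if couplings.size == 0:
            return None
        onsets = [last_onset + c for c in couplings]
        free = run_monodomain(grid, [], max(onsets) - prefix_t, dt=p.dt,
                              initial_states=prefix_states, t_start=prefix_t,
                              checkpoint_times_ms=onsets)
        shortest_captured = None
        for coupling in couplings:
            onset = last_onset + coupling
            stim = _stimulus(p, onset, site)
            obs_end = onset + p.stimulus_duration + p.observation_window
            start_states = free.checkpoints.get(float(onset))
            if start_states is None:  # free run ended early (quiescent)
                start_states, t_from = prefix_states, prefix_t
            else:
                t_from = float(onset)
            rec = run_from(start_states, t_from, [stim], obs_end - t_from)
            if level == 2:
                tested_s2.append(float(coupling))
            induced, cl_vt = detect_reentry(
                rec, onset, p.observation_window + p.stimulus_duration,
                paced_cycle_ms=cl)
            if induced:
                # continue the episode to the configured VT duration
                vt_end = onset + p.stimulus_duration + p.vt_duration
                rec_vt = run_monodomain(
                    grid, [], vt_end - rec.t_end, dt=p.dt, probes_mm=probes_mm,
                    initial_states=rec.final_states, t_start=rec.t_end,
                    frame_interval_ms=p.vt_frame_interval)
                full = _merge_records(rec, rec_vt)
                _, cl_vt = detect_reentry(full, onset,
                                          full.t_end - onset, paced_cycle_ms=cl)
                return InductionOutcome(
                    induced=True, site_mm=site,
                    coupling_intervals_ms=prefix_couplings + [float(coupling)],
                    tested_s2_couplings=tested_s2,
                    vt_cycle_length_ms=cl_vt, n_extrastimuli=level - 1,
                    record=full)
            if not _captures(rec, grid, site, onset, p):
                break  # effective refractory period reached
            shortest_captured = (float(coupling), onset)
            if verbose:
                print(f"  S{level} at {coupling:.0f} ms: captured, no reentry")
        if level - 1 < p.max_extrastimuli and shortest_captured is not None:
            c_cap, onset_cap = shortest_captured
            # replay the prefix + this extrastimulus, snapshot just after it
            start_states = free.checkpoints.get(float(onset_cap))
            t_from = float(onset_cap) if start_states is not None else prefix_t
            if start_states is None:
                start_states = prefix_states
            stim = _stimulus(p, onset_cap, site)
            rec_pref = run_monodomain(
                grid, [stim], onset_cap + p.stimulus_duration + p.dt - t_from,
                dt=p.dt, probes_mm=probes_mm,
                initial_states=start_states, t_start=t_from)
            return scan(rec_pref.final_states, rec_pref.t_end,
                        prefix_couplings + [c_cap], onset_cap, level + 1)
        return None

    if p.max_extrastimuli == 0:
        # drive train only: extend the record through the final cycle so the
        # last beat is fully captured
        tail = run_monodomain(grid, [], cl, dt=p.dt, probes_mm=probes_mm,
                              initial_states=snapshot, t_start=snap_t,
                              stop_quiescent_after_ms=snap_t + 50.0)
        return InductionOutcome(induced=False, site_mm=site,
                                coupling_intervals_ms=[],
                                tested_s2_couplings=[],
                                n_extrastimuli=0,
                                record=_merge_records(rec_s1, tail),
                                failure_reason="no extrastimuli configured")

    outcome = scan(snapshot, snap_t, [], train_end, 2)
    if outcome is not None:
        return outcome
    return InductionOutcome(
        induced=False, site_mm=site, coupling_intervals_ms=[],
        tested_s2_couplings=tested_s2, n_extrastimuli=min(p.max_extrastimuli, 3),
        record=None,
        failure_reason="scan exhausted: no sustained reentry at any coupling")


def _merge_records(a: SimulationRecord, b: SimulationRecord) -> SimulationRecord:
    """Concatenate a record and its continuation (shared grid and dt)."""
    act_times = a.act_times.copy()
    act_count = a.act_count.copy()
    for i in range(act_times.shape[0]):
        nb = b.act_count[i]
        if nb:
            na = act_count[i]
            take = min(nb, act_times.shape[1] - na)
            act_times[i, na:na + take] = b.act_times[i, :take]
            act_count[i] = na + take
    frames = a.frames
    frame_times = a.frame_times
    if b.frames is not None:
        frames = b.frames if frames is None else np.concatenate([frames, b.frames])
        frame_times = (b.frame_times if frame_times is None
                       else np.concatenate([frame_times, b.frame_times]))
    skip = 1 if (b.probe_times.size and a.probe_times.size
                 and abs(b.probe_times[0] - a.probe_times[-1]) < 1e-9) else 0
    return SimulationRecord(
        grid=a.grid, dt=a.dt, t_start=a.t_start, t_end=b.t_end,
        probe_indices=a.probe_indices,
        probe_times=np.concatenate([a.probe_times, b.probe_times[skip:]]),
        probe_traces=np.concatenate([a.probe_traces, b.probe_traces[:, skip:]],
                                    axis=1),
        act_times=act_times, act_count=act_count,
        frames=frames, frame_times=frame_times,
        final_states=b.final_states,
        stimuli=a.stimuli + b.stimuli, lat_mode=a.lat_mode)


def run_pes_multisite(grid: TissueGrid, protocol: PacingProtocol,
                      sites_mm, probes_mm=()) -> list[InductionOutcome]:
    """Independent PES per site, deterministic order; one failing site does
    not abort the others."""
    if len(sites_mm) == 0:
        raise ValueError("at least one stimulation site is required")
    outcomes = []
    for site in sites_mm:
        try:
            outcomes.append(run_pes(grid, protocol, site, probes_mm=probes_mm))
        except RuntimeError as exc:
            outcomes.append(InductionOutcome(
                induced=False, site_mm=tuple(float(v) for v in site),
                failure_reason=str(exc)))
    return outcomes


def inducibility_summary(outcomes) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        rows.append({
            "site_x_mm": o.site_mm[0], "site_y_mm": o.site_mm[1],
            "site_z_mm": o.site_mm[2], "induced": o.induced,
            "couplings_ms": ";".join(f"{c:.0f}" for c in o.coupling_intervals_ms),
            "vt_cycle_length_ms": o.vt_cycle_length_ms,
            "n_extrastimuli": o.n_extrastimuli,
            "failure_reason": o.failure_reason,
        })
    return pd.DataFrame(rows)


def save_outcomes(outcomes, json_path=None, csv_path=None) -> None:
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([o.summary() for o in outcomes], indent=2, default=str))
    if csv_path is not None:
        inducibility_summary(outcomes).to_csv(csv_path, index=False)
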