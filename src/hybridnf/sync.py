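"""Two-layer synchronization engine on a simulated clock.

Layer one anchors both acquisition streams to the first TTL pulse (time
reference t0) and watches for delays, jitter and drift between the nominal
TR grid and the recorded markers.  Layer two runs the feedback loop:
update ticks on the lattice t0 + BEGIN + k x update_period, with protocol
(block) transitions constrained to land exactly on update ticks.  The
engine is deliberately decoupled from the signal pipelines: the closed-loop
runner injects a ``compute_nfb`` callable, so every timing invariant is
testable with stubs.

A virtual clock (the caller advances ``clock_now``) replaces wall-clock
threads: the published processing-latency budget is modelled as constant
delays (EEG path ~200 ms, fMRI path ~150 ms), which makes data-causality
assertions exact instead of statistical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DesyncError, ProtocolError
from .protocol import ProtocolSpec, validate_protocol

REPORT_KINDS = ("BUFFER_OVERFLOW", "ACQ_DELAY", "DRIFT", "MISSED_TTL")


@dataclass
class SyncReport:
    kind: str
    magnitude: float
    tick: int
    label: str = ""
    resolved: bool = False

    def __post_init__(self):
        if self.kind not in REPORT_KINDS:
            raise ValueError(f"unknown report kind {self.kind!r}")


@dataclass(frozen=True)
class Latencies:
    """Constant processing-path delays (seconds) of the simulated platform."""

    eeg: float = 0.2
    fmri: float = 0.15
    display: float = 0.08
    marker: float = 0.039


@dataclass
class SchedulerState:
    t0: float = 0.0
    started: bool = False
    finished: bool = False
    aborted: bool = False
    tick: int = 0
    block_index: int = 0
    block_start_tick: int = 0
    eeg_cursor: int = 0
    fmri_cursor: int = 0
    desync_flags: set = field(default_factory=set)
    pending_desync: set = field(default_factory=set)
    reports: list = field(default_factory=list)
    event_log: list = field(default_factory=list)
    emitted: list = field(default_factory=list)

    def log(self, tick: int, t_rel: float, event: str, detail: str = "") -> None:
        self.event_log.append((tick, t_rel, event, detail))


class Scheduler:
    """Tick engine for one feedback session."""

    def __init__(
        self,
        protocol: ProtocolSpec,
        tr: float,
        fs_eeg: float = 250.0,
        latencies: Latencies | None = None,
        nfb_target: float = 1.0,
        watchdog_timeout: float = 30.0,
        buffer_capacity_s: float | None = None,
    ):
        self.protocol = validate_protocol(protocol)
        self.tr = float(tr)
        self.fs = float(fs_eeg)
        self.u = self.protocol.update_period
        self.begin = self.protocol.begin_duration
        self.blocks = self.protocol.repeated_blocks()
        self.lat = latencies or Latencies()
        self.nfb_target = nfb_target
        self.watchdog_timeout = watchdog_timeout
        self.buffer_capacity_s = buffer_capacity_s

    # -- session lifecycle --------------------------------------------------

    def start_session(self, first_ttl_time: float,
                      state: SchedulerState | None = None) -> SchedulerState:
        """Anchor the session clock to the first TTL pulse."""
        if state is not None and state.started and not state.finished:
            raise ProtocolError("session already live: cannot start again")
        st = SchedulerState(t0=float(first_ttl_time), started=True)
        st.log(-1, 0.0, "SESSION_START", f"t0={first_ttl_time:.6f}")
        if not self.blocks:
            st.finished = True
            st.log(-1, 0.0, "SESSION_END", "empty protocol")
        return st

    def check_watchdog(self, clock_now: float,
                       state: SchedulerState | None = None) -> None:
        """Raise if no TTL ever started the session within the timeout."""
        if (state is None or not state.started) and clock_now > self.watchdog_timeout:
            raise DesyncError(
                f"no TTL pulse within {self.watchdog_timeout} s: session never started"
            )

    def tick_time(self, state: SchedulerState, k: int) -> float:
        return state.t0 + self.begin + k * self.u

    def _block_ticks(self, block) -> tuple:
        """(min_ticks, max_ticks) of a block in update periods."""
        if block.duration is not None:
            n = int(round(block.duration / self.u))
            return n, n
        lo, hi = block.duration_range
        return max(1, math.ceil(lo / self.u - 1e-9)), int(round(hi / self.u))

    # -- main loop ----------------------------------------------------------

    def step(
        self,
        state: SchedulerState,
        clock_now: float,
        eeg_stream=None,
        volume_series=None,
        compute_nfb=None,
        on_tick=None,
        on_transition=None,
    ) -> list:
        """Process every update tick due by ``clock_now``.

        ``compute_nfb(state, tick, t, task_on)`` returns an NfbSample (or
        None during warm-up); ``on_transition(old_kind, new_kind, tick)``
        fires at every protocol callback (new_kind is None at session end).
        Returns the NfbSamples emitted during this call.
        """
        if not state.started:
            raise ProtocolError("step called before the session started")
        out = []
        while not (state.finished or state.aborted):
            k = state.tick
            t = self.tick_time(state, k)
            if t > clock_now + 1e-9:
                break
            self._due_fixed_transition(state, k, on_transition)
            if state.finished:
                break
            block = self.blocks[state.block_index]
            task_on = block.kind == "TASK"

            stale = self._absorb(state, k, t, eeg_stream, volume_series)
            nfb = None
            if not stale and compute_nfb is not None:
                nfb = compute_nfb(state, k, t, task_on)
            if nfb is not None:
                state.emitted.append(nfb)
                out.append(nfb)
                state.log(k, t - state.t0, "NFB_UPDATE",
                          "[" + ",".join(f"{v:.6f}" for v in nfb.values) + "]")
            elif stale:
                state.log(k, t - state.t0, "STALE", "feedback suppressed")
            if on_tick is not None:
                on_tick(state, k, t, task_on, nfb)
            self._flexible_transition(state, k, nfb, on_transition)
            state.tick += 1
        return out

    def _absorb(self, state, k, t, eeg_stream, volume_series) -> bool:
        """Advance acquisition cursors to the causality horizon; returns
        True when the EEG stream delivered nothing new (stale tick)."""
        stale = False
        if eeg_stream is not None:
            horizon = int(math.floor((t - self.lat.eeg - state.t0) * self.fs))
            avail = min(eeg_stream.n_samples, max(0, horizon))
            if avail < state.eeg_cursor:
                raise DesyncError("EEG cursor regression: time went backwards")
            if avail == state.eeg_cursor and k > 0:
                r = SyncReport("ACQ_DELAY", self.u, k, "no new EEG samples")
                state.reports.append(r)
                state.desync_flags.add("ACQ_DELAY")
                stale = True
            else:
                if (self.buffer_capacity_s is not None
                        and (avail - state.eeg_cursor) / self.fs
                        > self.buffer_capacity_s):
                    state.reports.append(SyncReport(
                        "BUFFER_OVERFLOW",
                        (avail - state.eeg_cursor) / self.fs, k,
                        "EEG backlog exceeded buffer capacity"))
                    state.desync_flags.add("BUFFER_OVERFLOW")
                state.eeg_cursor = avail
        if volume_series is not None:
            horizon_v = int(math.floor((t - self.lat.fmri - state.t0) / self.tr))
            avail_v = min(volume_series.n_volumes, max(0, horizon_v))
            if avail_v < state.fmri_cursor:
                raise DesyncError("fMRI cursor regression: time went backwards")
            state.fmri_cursor = avail_v
        return stale

    def _due_fixed_transition(self, state, k, on_transition) -> None:
        """Fixed blocks end exactly when their tick quota is spent; the
        boundary tick belongs to the next block."""
        while not state.finished:
            block = self.blocks[state.block_index]
            if block.duration is None:
                return
            n_min, _ = self._block_ticks(block)
            if k - state.block_start_tick < n_min:
                return
            self._advance_block(state, k, on_transition)

    def _flexible_transition(self, state, k, nfb, on_transition) -> None:
        if state.finished:
            return
        block = self.blocks[state.block_index]
        if block.duration_range is None:
            return
        n_min, n_max = self._block_ticks(block)
        elapsed = k - state.block_start_tick + 1
        hit = (nfb is not None and float(np.max(nfb.values)) >= self.nfb_target
               and nfb.normalized)
        if (hit and elapsed >= n_min) or elapsed >= n_max:
            reason = "target achieved" if hit and elapsed < n_max else "range maximum"
            self._advance_block(state, k, on_transition, start_next=k + 1,
                                detail=reason)

    def _advance_block(self, state, k, on_transition, start_next=None,
                       detail="") -> None:
        old = self.blocks[state.block_index]
        state.block_index += 1
        state.block_start_tick = k if start_next is None else start_next
        new_kind = (self.blocks[state.block_index].kind
                    if state.block_index < len(self.blocks) else None)
        t_rel = self.begin + k * self.u
        state.log(k, t_rel, "PROTOCOL",
                  f"{old.kind}->{new_kind or 'END'}"
                  + (f" ({detail})" if detail else ""))
        if on_transition is not None:
            on_transition(old.kind, new_kind, k)
        if new_kind is None:
            state.finished = True
            state.log(k, t_rel, "SESSION_END", "protocol complete")


# ---------------------------------------------------------------------------
# first-layer checks


def check_sync(
    ttl_times: np.ndarray,
    protocol_marker_times: np.ndarray,
    tr: float,
    update_period: float,
    begin: float = 0.0,
    tolerance: float = 0.1,
) -> list:
    """Compare recorded markers against the nominal timing grids.

    TTL gaps deviating from the TR by more than ``tolerance x TR`` flag
    acquisition jitter (a delayed-then-recovered pulse counts once); gaps
    near 2 TR flag a missed pulse.  A cumulative TTL offset that exceeds
    the tolerance while individual gaps stay clean flags clock drift.
    Protocol markers off the update-tick lattice are reported as
    second-layer drift.  Returns typed reports; never raises.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    reports = []
    ttl = np.asarray(ttl_times, dtype=float)
    if ttl.size >= 2:
        t0 = ttl[0]
        gaps = np.diff(ttl)
        tol = tolerance * tr
        i = 0
        flagged_gap = False
        while i < gaps.size:
            dev = gaps[i] - tr
            if gaps[i] > 1.5 * tr:
                reports.append(SyncReport("MISSED_TTL", float(gaps[i]), i + 1,
                                          f"gap {gaps[i]:.3f}s ~ {gaps[i]/tr:.1f} TR"))
                flagged_gap = True
            elif abs(dev) > tol:
                reports.append(SyncReport("ACQ_DELAY", float(abs(dev)), i + 1,
                                          f"TTL gap off by {dev:+.3f}s"))
                flagged_gap = True
                if (i + 1 < gaps.size
                        and abs(gaps[i] + gaps[i + 1] - 2 * tr) <= tol):
                    i += 1  # compensating gap: one delayed pulse, one report
            i += 1
        offsets = ttl - (t0 + np.arange(ttl.size) * tr)
        if not flagged_gap and abs(offsets[-1]) > tol:
            slope = float(np.polyfit(np.arange(ttl.size), offsets, 1)[0])
            reports.append(SyncReport(
                "DRIFT", float(abs(offsets[-1])), int(ttl.size - 1),
                f"cumulative TTL offset {offsets[-1]:+.3f}s "
                f"(~{slope:+.2e}s/TR)"))
    pm = np.asarray(protocol_marker_times, dtype=float)
    for j, p in enumerate(pm):
        r = (p - begin) / update_period
        if abs(r - round(r)) * update_period > 1e-6 + 1e-9 * abs(p):
            reports.append(SyncReport(
                "DRIFT", float(abs(r - round(r)) * update_period), j,
                "protocol marker off the update lattice"))
    return reports


def resync_or_abort(state: SchedulerState, reports: list,
                    flush=None) -> SchedulerState:
    """One re-synchronization attempt; a repeat offence stops the session.

    New report kinds re-anchor the cursors (one retry, reports marked
    resolved).  A kind already pending from the previous check aborts the
    session; ``flush`` (if given) is called so buffers and logs reach disk.
    An empty report list clears the pending set and is a no-op.
    """
    if not reports:
        state.pending_desync.clear()
        return state
    kinds = {r.kind for r in reports}
    state.reports.extend(r for r in reports if r not in state.reports)
    state.desync_flags |= kinds
    repeat = kinds & state.pending_desync
    t_rel = state.event_log[-1][1] if state.event_log else 0.0
    if repeat:
        state.aborted = True
        state.log(state.tick, t_rel, "SESSION_ABORT",
                  "resync failed: " + ",".join(sorted(repeat)))
        if flush is not None:
            flush(state)
        return state
    state.pending_desync = set(kinds)
    for r in reports:
        r.resolved = True
    state.log(state.tick, t_rel, "RESYNC",
              "re-anchored after " + ",".join(sorted(kinds)))
    return state
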