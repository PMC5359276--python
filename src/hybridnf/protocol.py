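"""Block-design protocol declarations and their validation.

A protocol is an ordered list of blocks (BEGIN / TASK / REST).  In *fixed*
mode every duration is known up front and must be an exact multiple of the
feedback update period, so block transitions always coincide with update
ticks.  In *flexible* mode a TASK block carries a duration range and ends at
the first update tick after the feedback target is achieved (REST blocks stay
fixed); the same tick-multiplicity law then holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import ProtocolError

BLOCK_KINDS = ("BEGIN", "TASK", "REST")


@dataclass(frozen=True)
class Block:
    kind: str
    duration: float | None = None
    duration_range: tuple | None = None

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ProtocolError(f"unknown block kind {self.kind!r}")
        if self.duration is None and self.duration_range is None:
            raise ProtocolError(f"{self.kind} block needs a duration or a range")
        if self.duration is not None and self.duration <= 0:
            raise ProtocolError("block duration must be positive")
        if self.duration_range is not None:
            lo, hi = self.duration_range
            if not 0 < lo < hi:
                raise ProtocolError(
                    f"flexible range must satisfy 0 < min < max, got ({lo}, {hi})"
                )


@dataclass
class ProtocolSpec:
    """Declarative block design.

    ``blocks`` may start with a single BEGIN block (run once); the remaining
    blocks are repeated ``repetitions`` times.  ``update_period`` is the
    feedback refresh period in seconds (default 0.5 s).
    """

    blocks: list
    mode: str = "fixed"
    update_period: float = 0.5
    repetitions: int = 1

    def __post_init__(self):
        if self.mode not in ("fixed", "flexible"):
            raise ProtocolError(f"unknown protocol mode {self.mode!r}")
        if self.update_period <= 0:
            raise ProtocolError("update period must be positive")
        if self.repetitions < 1:
            raise ProtocolError("repetitions must be >= 1")
        for i, b in enumerate(self.blocks):
            if b.kind == "BEGIN" and i != 0:
                raise ProtocolError("BEGIN block allowed only first")

    @property
    def begin_duration(self) -> float:
        if self.blocks and self.blocks[0].kind == "BEGIN":
            return float(self.blocks[0].duration)
        return 0.0

    def repeated_blocks(self) -> list:
        """The post-BEGIN block sequence expanded over repetitions."""
        body = [b for b in self.blocks if b.kind != "BEGIN"]
        return body * self.repetitions

    def expanded_blocks(self) -> list:
        """Full block sequence: BEGIN (once) then the repeated body."""
        head = [self.blocks[0]] if self.begin_duration > 0 else []
        return head + self.repeated_blocks()


def _is_multiple(duration: float, period: float, tol: float = 1e-9) -> bool:
    ratio = duration / period
    return abs(ratio - round(ratio)) <= tol * max(1.0, abs(ratio))


def validate_protocol(spec: ProtocolSpec) -> ProtocolSpec:
    """Check the tick-multiplicity law and flexible-range sanity.

    Fixed durations (including BEGIN) must be exact multiples of the update
    period so protocol transitions land on update ticks.  Flexible TASK
    blocks keep their range and are snapped to the tick lattice at run time.
    """
    u = spec.update_period
    for b in spec.blocks:
        if b.duration is not None and not _is_multiple(b.duration, u):
            raise ProtocolError(
                f"{b.kind} duration {b.duration} s is not a multiple of the "
                f"update period {u} s: protocol transitions must coincide "
                "with update ticks"
            )
        if b.duration_range is not None and spec.mode == "fixed":
            raise ProtocolError(
                "duration ranges are only allowed in flexible mode"
            )
    if spec.mode == "flexible" and not any(
        b.duration_range is not None for b in spec.blocks
    ):
        raise ProtocolError("flexible mode requires at least one ranged block")
    # normalized copy (floats coerced)
    return replace(
        spec,
        blocks=list(spec.blocks),
        update_period=float(u),
        repetitions=int(spec.repetitions),
    )


def standard_protocol(
    task: float = 20.0,
    rest: float = 20.0,
    repetitions: int = 4,
    begin: float = 0.0,
    update_period: float = 0.5,
) -> ProtocolSpec:
    """The 20 s Task / 20 s Rest alternating block design."""
    blocks = []
    if begin > 0:
        blocks.append(Block("BEGIN", begin))
    blocks += [Block("TASK", task), Block("REST", rest)]
    return validate_protocol(
        ProtocolSpec(blocks=blocks, update_period=update_period,
                     repetitions=repetitions)
    )
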