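"""Session protocol: the block layout of mental states within a recording.

A session interleaves three states — rest, self-boundary dissolution (SB−)
and self-boundary maintenance (SB+) — as contiguous segments of whole-second
duration. The default layout mimics the two-block meditation protocol in
which each block opens with 100 s of rest followed by five 60 s alternations
between SB− and SB+, with a third 100 s rest at the end, so every state
accumulates exactly 300 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REST = "rest"
SB_MINUS = "SBminus"
SB_PLUS = "SBplus"
STATES = (REST, SB_MINUS, SB_PLUS)


@dataclass(frozen=True)
class SessionProtocol:
    """Ordered state segments with durations in seconds, plus sampling rate.

    Parameters
    ----------
    block_layout
        Sequence of ``(state, duration_s)`` pairs; states must belong to
        :data:`STATES` and durations must be positive whole seconds.
    sampling_rate
        Sampling frequency in Hz.
    """

    block_layout: tuple[tuple[str, int], ...] = field(default_factory=tuple)
    sampling_rate: float = 300.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for state, dur in self.block_layout:
            if state not in STATES:
                raise ValueError(f"unknown state label {state!r}")
            if dur <= 0 or int(dur) != dur:
                raise ValueError(
                    f"segment durations must be positive whole seconds, got {dur!r}"
                )

    @property
    def total_duration_s(self) -> int:
        return sum(d for _, d in self.block_layout)

    def state_totals(self) -> dict[str, int]:
        """Total seconds per state over the whole layout."""
        totals = {s: 0 for s in STATES}
        for state, dur in self.block_layout:
            totals[state] += int(dur)
        return totals

    def segment_count(self, state: str) -> int:
        return sum(1 for s, _ in self.block_layout if s == state)


def default_protocol(sampling_rate: float = 300.0) -> SessionProtocol:
    """Two meditation blocks plus a closing rest, 300 s per state.

    Block 1: 100 s rest, then SB−/SB+/SB−/SB+/SB− (60 s each).
    Block 2: 100 s rest, then SB+/SB−/SB+/SB−/SB+ (60 s each).
    A final 100 s rest closes the session.  The alternation order is one
    consistent reading of "five alternations per block"; any layout with the
    same per-state totals can be passed explicitly instead.
    """
    block1 = [(REST, 100)] + [
        (SB_MINUS if i % 2 == 0 else SB_PLUS, 60) for i in range(5)
    ]
    block2 = [(REST, 100)] + [
        (SB_PLUS if i % 2 == 0 else SB_MINUS, 60) for i in range(5)
    ]
    layout = tuple(block1 + block2 + [(REST, 100)])
    return SessionProtocol(block_layout=layout, sampling_rate=sampling_rate)
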