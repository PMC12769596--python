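"""Multiple baseline factorial design (MBFD) layouts and randomization.

An MBFD schedules two interventions, A and B, on top of a standard-of-care
control. Every participant starts under control, switches to a single
intervention (A or B, depending on the randomized sequence) at a staggered
start period, and finally receives the sequential combination AB until trial
exit. The outcome is measured once at the end of every period.

The design is a grid of conditions indexed by (sequence, period). Sequences
come in two arms — A-first and B-first — with a minimum of three sequences
per arm so that within- and between-sequence comparisons are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "Design",
    "Allocation",
    "build_standard_design",
    "build_extended_design",
    "randomize",
]


class Condition(str, Enum):
    """Treatment condition of one (sequence, period) cell."""

    CONTROL = "C"
    A = "A"
    B = "B"
    AB = "AB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SINGLE = {Condition.A, Condition.B}
# phase order within any valid sequence; reverting is never allowed
_PHASE_RANK = {Condition.CONTROL: 0, Condition.A: 1, Condition.B: 1, Condition.AB: 2}


class DesignError(ValueError):
    """Raised when a design grid violates the MBFD structure."""


@dataclass(frozen=True)
class Design:
    """A validated MBFD layout.

    Parameters
    ----------
    grid : tuple of tuple of Condition
        One inner tuple per sequence, one entry per period. Sequences may
        have different lengths when participants exit at different times
        (fixed combined-phase duration); under a common exit all rows have
        equal length.
    """

    grid: tuple[tuple[Condition, ...], ...]
    first_intervention: tuple[Condition, ...] = field(init=False)
    start_period: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        first, starts = _validate_grid(self.grid)
        object.__setattr__(self, "first_intervention", first)
        object.__setattr__(self, "start_period", starts)

    @property
    def n_sequences(self) -> int:
        return len(self.grid)

    @property
    def n_periods(self) -> int:
        """Length of the longest sequence (J for common-exit designs)."""
        return max(len(row) for row in self.grid)

    def sequence_length(self, s: int) -> int:
        return len(self.grid[s])

    def condition(self, s: int, period: int) -> Condition:
        """Condition of sequence ``s`` in 1-based ``period``."""
        return self.grid[s][period - 1]

    # -- serialization ---------------------------------------------------
    def to_text(self) -> str:
        """Delimited grid, one sequence per row, cells in {C, A, B, AB}."""
        return "\n".join(",".join(c.value for c in row) for row in self.grid)

    @classmethod
    def from_text(cls, text: str) -> "Design":
        rows = []
        for line in text.strip().splitlines():
            cells = [c.strip() for c in line.split(",") if c.strip()]
            try:
                rows.append(tuple(Condition(c) for c in cells))
            except ValueError as exc:
                raise DesignError(f"unknown condition label in row {line!r}") from exc
        return cls(grid=tuple(rows))

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": [[c.value for c in row] for row in self.grid],
                "n_sequences": self.n_sequences,
                "n_periods": self.n_periods,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Design":
        payload = json.loads(text)
        return cls(
            grid=tuple(
                tuple(Condition(c) for c in row) for row in payload["grid"]
            )
        )


def _validate_grid(
    grid: tuple[tuple[Condition, ...], ...],
) -> tuple[tuple[Condition, ...], tuple[int, ...]]:
    """Strictly validate the MBFD invariants; return per-sequence metadata."""
    if not grid:
        raise DesignError("design has no sequences")
    first: list[Condition] = []
    starts: list[int] = []
    for s, row in enumerate(grid):
        if not row:
            raise DesignError(f"sequence {s} is empty")
        if row[0] is not Condition.CONTROL:
            raise DesignError(f"sequence {s} must begin with a control period")
        ranks = [_PHASE_RANK[c] for c in row]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise DesignError(f"sequence {s} reverts to an earlier phase")
        singles = {c for c in row if c in _SINGLE}
        if len(singles) != 1:
            raise DesignError(
                f"sequence {s} must deliver exactly one single intervention"
            )
        if Condition.AB not in row:
            raise DesignError(f"sequence {s} never reaches the combined phase")
        (single,) = singles
        first.append(single)
        starts.append(1 + row.index(single))  # 1-based period
    n_a = sum(c is Condition.A for c in first)
    n_b = sum(c is Condition.B for c in first)
    if n_a < 3 or n_b < 3:
        raise DesignError(
            f"need at least three sequences per intervention (got A-first={n_a}, "
            f"B-first={n_b})"
        )
    if max(len(row) for row in grid) < 5:
        raise DesignError("an MBFD requires at least five periods")
    return tuple(first), tuple(starts)


def _build_arm(
    first: Condition,
    n_sequences: int,
    single_phase_len: int,
    stagger_gap: int,
    tail_policy: str,
    ab_len: int,
) -> list[tuple[Condition, ...]]:
    rows = []
    last_start = 2 + (n_sequences - 1) * stagger_gap
    common_end = last_start + single_phase_len  # last sequence gets one AB period
    for k in range(n_sequences):
        start = 2 + k * stagger_gap
        row = [Condition.CONTROL] * (start - 1) + [first] * single_phase_len
        if tail_policy == "common_exit":
            n_ab = common_end - len(row)
        else:  # fixed_ab_len
            n_ab = ab_len
        row += [Condition.AB] * n_ab
        rows.append(tuple(row))
    return rows


def build_extended_design(
    n_sequences_per_arm: int = 3,
    single_phase_len: int = 1,
    stagger_gap: int = 1,
    tail_policy: str = "common_exit",
    ab_len: int = 1,
) -> Design:
    """Construct an MBFD with configurable phase lengths and stagger.

    Parameters
    ----------
    n_sequences_per_arm : int
        Sequences starting with A and with B, each; at least 3.
    single_phase_len : int
        Periods spent on the single intervention before the combination.
    stagger_gap : int
        Periods between the single-intervention start of adjacent sequences.
    tail_policy : {"common_exit", "fixed_ab_len"}
        ``common_exit`` pads the combined phase so every sequence ends at the
        same period (combined-phase duration then varies by sequence);
        ``fixed_ab_len`` gives every sequence ``ab_len`` combined periods, so
        later-starting sequences exit later.
    ab_len : int
        Combined-phase duration per sequence under ``fixed_ab_len``; ignored
        otherwise.
    """
    if n_sequences_per_arm < 3:
        raise DesignError("at least three sequences per intervention are required")
    if single_phase_len < 1 or stagger_gap < 1:
        raise DesignError("single_phase_len and stagger_gap must be >= 1")
    if tail_policy not in ("common_exit", "fixed_ab_len"):
        raise DesignError(f"unknown tail_policy {tail_policy!r}")
    if tail_policy == "fixed_ab_len" and ab_len < 1:
        raise DesignError("every sequence needs at least one combined period")
    rows = _build_arm(
        Condition.A, n_sequences_per_arm, single_phase_len, stagger_gap,
        tail_policy, ab_len,
    ) + _build_arm(
        Condition.B, n_sequences_per_arm, single_phase_len, stagger_gap,
        tail_policy, ab_len,
    )
    return Design(grid=tuple(rows))


def build_standard_design() -> Design:
    """The standard 6-sequence, 5-period MBFD.

    Three A-first and three B-first sequences; the single intervention starts
    at periods 2, 3 and 4 and lasts one period, after which the sequence
    stays on the combination until the common exit at period 5. Combined-
    phase durations are therefore 3, 2 and 1 periods.
    """
    return build_extended_design(3, 1, 1, "common_exit")


@dataclass(frozen=True)
class Allocation:
    """Randomized mapping of participants to design sequences."""

    sequence_of: np.ndarray  # shape (N,), values in [0, n_sequences)
    n_sequences: int

    @property
    def n_participants(self) -> int:
        return len(self.sequence_of)

    def counts(self) -> np.ndarray:
        return np.bincount(self.sequence_of, minlength=self.n_sequences)


def randomize(design: Design, n_participants: int, seed: int) -> Allocation:
    """Individually randomize participants to sequences, balanced.

    Group sizes are ``N // S`` or ``N // S + 1``; when S does not divide N the
    sequences receiving the extra participant are chosen uniformly at random.
    """
    S = design.n_sequences
    if n_participants < S:
        raise ValueError(
            f"cannot fill {S} sequences with {n_participants} participants"
        )
    rng = np.random.default_rng(seed)
    base, rem = divmod(n_participants, S)
    sizes = np.full(S, base, dtype=int)
    if rem:
        sizes[rng.choice(S, size=rem, replace=False)] += 1
    labels = np.repeat(np.arange(S), sizes)
    rng.shuffle(labels)
    return Allocation(sequence_of=labels, n_sequences=S)
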