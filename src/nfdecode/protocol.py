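"""Block-design experiment schedules and per-volume condition labels.

The motor-imagery neurofeedback protocol alternates 30-s rest and task
blocks within one continuous scan (a *run*).  The default run has nine
rest blocks bracketing eight task blocks — four imagined left-hand
gripping/opening (LGO) and four right-hand (RGO) — sampled at TR = 2.0 s,
for 255 volumes in total.  A :class:`BlockSchedule` is the single source
of truth for block boundaries, per-volume condition labels, and the cue
timeline that drives both classifier selection and feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Condition",
    "BlockSchedule",
    "build_schedule",
    "labels_for",
    "read_schedule_tsv",
    "write_schedule_tsv",
]


class Condition(str, Enum):
    """Experimental conditions within a run."""

    REST = "REST"
    LGO = "LGO"  # imagined left hand gripping and opening
    RGO = "RGO"  # imagined right hand gripping and opening

    def __str__(self) -> str:  # tidy TSV / repr output
        return self.value


TASK_CONDITIONS = (Condition.LGO, Condition.RGO)


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered block timeline of one run plus label bookkeeping.

    Parameters
    ----------
    tr_s:
        Repetition time — seconds per acquired volume.
    blocks:
        Ordered ``(condition, duration_s)`` pairs.  Every duration must be
        an integer multiple of ``tr_s``.
    label_shift_volumes:
        Non-negative delay (in volumes) applied to the per-volume label
        sequence to account for hemodynamic lag.  0 keeps labels aligned
        with the cue timeline, matching the literal task-volume counting
        used by the TPV metric.
    """

    tr_s: float
    blocks: tuple[tuple[Condition, float], ...]
    label_shift_volumes: int = 0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.label_shift_volumes < 0:
            raise ValueError("label_shift_volumes must be >= 0")
        for cond, dur in self.blocks:
            n = dur / self.tr_s
            if abs(n - round(n)) > 1e-9 or dur <= 0:
                raise ValueError(
                    f"block duration {dur} s is not a positive integer "
                    f"multiple of tr_s={self.tr_s} s"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n_volumes(self) -> int:
        return int(round(sum(d for _, d in self.blocks) / self.tr_s))

    @property
    def block_n_volumes(self) -> tuple[int, ...]:
        return tuple(int(round(d / self.tr_s)) for _, d in self.blocks)

    def block_of_volume(self) -> np.ndarray:
        """Index of the block covering each volume (half-open intervals)."""
        return np.repeat(np.arange(len(self.blocks)), self.block_n_volumes)

    def cue_labels(self) -> np.ndarray:
        """Unshifted per-volume conditions: the cue shown at each volume."""
        conds = np.array([c for c, _ in self.blocks], dtype=object)
        return conds[self.block_of_volume()]

    def labels(self) -> np.ndarray:
        """Per-volume condition labels with the hemodynamic-lag shift applied."""
        return labels_for(self)

    def is_block_end(self) -> np.ndarray:
        """Boolean flag per volume: True at the final volume of each block."""
        ends = np.cumsum(self.block_n_volumes) - 1
        flags = np.zeros(self.n_volumes, dtype=bool)
        flags[ends] = True
        return flags

    def with_shift(self, label_shift_volumes: int) -> "BlockSchedule":
        return replace(self, label_shift_volumes=label_shift_volumes)

    def condition_counts(self) -> dict[Condition, int]:
        labels = self.labels()
        return {c: int(np.sum(labels == c)) for c in Condition}


def build_schedule(
    n_rest: int,
    n_lgo: int,
    n_rgo: int,
    block_s: float = 30.0,
    tr_s: float = 2.0,
    order_rule: str = "alternate",
    seed: int = 0,
    label_shift_volumes: int = 0,
) -> BlockSchedule:
    """Build a rest-bracketed block schedule.

    Rest blocks bracket every task block, so ``n_rest`` must equal
    ``n_lgo + n_rgo + 1``.  ``order_rule="alternate"`` interleaves task
    conditions deterministically starting with LGO; ``"shuffled"``
    permutes the task-block conditions with a seeded generator (condition
    counts are preserved).

    The study default ``build_schedule(9, 4, 4, 30, 2.0)`` yields 255
    volumes: 135 rest, 60 LGO, 60 RGO.
    """
    if min(n_rest, n_lgo, n_rgo) < 0:
        raise ValueError("block counts must be non-negative")
    n_task = n_lgo + n_rgo
    if n_rest != n_task + 1:
        raise ValueError(
            f"rest blocks must bracket every task block: need "
            f"n_rest = n_lgo + n_rgo + 1, got n_rest={n_rest}, "
            f"n_lgo={n_lgo}, n_rgo={n_rgo}"
        )
    n_per_block = block_s / tr_s
    if abs(n_per_block - round(n_per_block)) > 1e-9 or block_s <= 0:
        raise ValueError(
            f"block_s={block_s} is not a positive integer multiple of "
            f"tr_s={tr_s}"
        )

    if order_rule == "alternate":
        tasks: list[Condition] = []
        remaining = {Condition.LGO: n_lgo, Condition.RGO: n_rgo}
        turn = Condition.LGO
        while len(tasks) < n_task:
            other = Condition.RGO if turn is Condition.LGO else Condition.LGO
            pick = turn if remaining[turn] > 0 else other
            tasks.append(pick)
            remaining[pick] -= 1
            turn = other
    elif order_rule == "shuffled":
        pool = [Condition.LGO] * n_lgo + [Condition.RGO] * n_rgo
        rng = np.random.default_rng(seed)
        tasks = [pool[i] for i in rng.permutation(n_task)]
    else:
        raise ValueError(f"unknown order_rule {order_rule!r}")

    blocks: list[tuple[Condition, float]] = [(Condition.REST, block_s)]
    for t in tasks:
        blocks.append((t, block_s))
        blocks.append((Condition.REST, block_s))
    return BlockSchedule(
        tr_s=tr_s,
        blocks=tuple(blocks),
        label_shift_volumes=label_shift_volumes,
    )


def labels_for(schedule: BlockSchedule) -> np.ndarray:
    """Per-volume condition labels, delayed by ``label_shift_volumes``.

    The base label of volume ``v`` is the condition of the block covering
    time ``v * tr_s`` (half-open intervals).  A shift of ``k`` delays the
    sequence by ``k`` positions — label ``v`` becomes the base label of
    volume ``v - k`` — with the leading positions filled by the first
    block's condition.  Length always equals the run's volume count.
    """
    base = schedule.cue_labels()
    k = schedule.label_shift_volumes
    if k == 0:
        return base
    idx = np.maximum(np.arange(schedule.n_volumes) - k, 0)
    return base[idx]


# -- TSV (BIDS-style events) serialisation ----------------------------------


def write_schedule_tsv(schedule: BlockSchedule, path: str | Path) -> None:
    """Write the block timeline as a 3-column TSV (onset_s, duration_s, condition)."""
    lines = ["onset_s\tduration_s\tcondition"]
    onset = 0.0
    for cond, dur in schedule.blocks:
        lines.append(f"{onset:g}\t{dur:g}\t{cond}")
        onset += dur
    Path(path).write_text("\n".join(lines) + "\n")


def read_schedule_tsv(
    path: str | Path, tr_s: float = 2.0, label_shift_volumes: int = 0
) -> BlockSchedule:
    """Read a block timeline from a 3-column TSV written by :func:`write_schedule_tsv`.

    Rows must be contiguous in time (onsets equal to the running sum of
    durations); gaps or overlaps are rejected.
    """
    rows = Path(path).read_text().strip().splitlines()
    blocks: list[tuple[Condition, float]] = []
    onset_expected = 0.0
    for row in rows[1:]:
        onset_s, duration_s, condition = row.split("\t")
        if abs(float(onset_s) - onset_expected) > 1e-9:
            raise ValueError(
                f"non-contiguous schedule: onset {onset_s} != {onset_expected:g}"
            )
        blocks.append((Condition(condition), float(duration_s)))
        onset_expected += float(duration_s)
    return BlockSchedule(
        tr_s=tr_s, blocks=tuple(blocks), label_shift_volumes=label_shift_volumes
    )
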