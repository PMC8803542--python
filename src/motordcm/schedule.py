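"""Block-design command-following task schedule.

The task alternates 'move' and 'rest' blocks of 20 s (8 of each, 320 s
total).  Each move block carries 7 auditory cues at jittered 2-3 s
inter-stimulus intervals; participants perform a discrete thumb
abduction-adduction movement in response to each cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BLOCKS_PER_TYPE = 8
BLOCK_DURATION = 20.0
CUES_PER_BLOCK = 7
CUE_ISI_RANGE = (2.0, 3.0)
#: earliest cue onset relative to its block onset; the cue train must fit
#: inside the 20 s block even at the maximal 3 s jitter (1.5 + 6*3 = 19.5 s)
FIRST_CUE_OFFSET_RANGE = (0.5, 1.5)


@dataclass(frozen=True)
class TaskSchedule:
    """Timing of a single command-following run.

    Attributes
    ----------
    block_onsets : (16,) array of block start times in seconds.
    block_types : list of 'move' / 'rest', aligned with ``block_onsets``.
    block_duration : block length in seconds (20 s).
    cue_onsets : (56,) array of auditory cue times, 7 per move block.
    total_duration : run length in seconds (320 s).
    """

    block_onsets: np.ndarray
    block_types: list
    cue_onsets: np.ndarray
    block_duration: float = BLOCK_DURATION
    total_duration: float = field(default=2 * N_BLOCKS_PER_TYPE * BLOCK_DURATION)

    def __post_init__(self):
        self.validate()

    @property
    def move_onsets(self) -> np.ndarray:
        return self.block_onsets[[t == "move" for t in self.block_types]]

    @property
    def rest_onsets(self) -> np.ndarray:
        return self.block_onsets[[t == "rest" for t in self.block_types]]

    def validate(self) -> None:
        onsets = np.asarray(self.block_onsets, float)
        types = list(self.block_types)
        if len(onsets) != len(types):
            raise ValueError("block_onsets and block_types length mismatch")
        if sum(t == "move" for t in types) != N_BLOCKS_PER_TYPE:
            raise ValueError(f"expected {N_BLOCKS_PER_TYPE} move blocks")
        if sum(t == "rest" for t in types) != N_BLOCKS_PER_TYPE:
            raise ValueError(f"expected {N_BLOCKS_PER_TYPE} rest blocks")
        for a, b in zip(types[:-1], types[1:]):
            if a == b:
                raise ValueError("blocks must alternate move/rest")
        cues = np.asarray(self.cue_onsets, float)
        if len(cues) != CUES_PER_BLOCK * N_BLOCKS_PER_TYPE:
            raise ValueError("expected 7 cues per move block")
        # every cue inside its move block, ISIs within [2, 3] s
        for onset in self.move_onsets:
            in_block = cues[(cues >= onset) & (cues < onset + self.block_duration)]
            if len(in_block) != CUES_PER_BLOCK:
                raise ValueError(f"move block at {onset} s does not contain 7 cues")
            isi = np.diff(np.sort(in_block))
            if np.any(isi < CUE_ISI_RANGE[0] - 1e-9) or np.any(isi > CUE_ISI_RANGE[1] + 1e-9):
                raise ValueError("cue inter-stimulus interval outside [2, 3] s")
        if not np.isclose(self.total_duration, 2 * N_BLOCKS_PER_TYPE * BLOCK_DURATION):
            raise ValueError("total duration must be 320 s")

    def to_events(self) -> pd.DataFrame:
        """Tab-separable events table (onset, duration, trial_type)."""
        rows = [
            {"onset": float(o), "duration": self.block_duration,
             "trial_type": f"{t}_block"}
            for o, t in zip(self.block_onsets, self.block_types)
        ]
        rows += [{"onset": float(c), "duration": 0.0, "trial_type": "cue"}
                 for c in self.cue_onsets]
        return pd.DataFrame(rows).sort_values("onset", ignore_index=True)

    def write_events(self, path) -> None:
        self.to_events().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_events(cls, path) -> "TaskSchedule":
        ev = pd.read_csv(path, sep="\t")
        blocks = ev[ev.trial_type.str.endswith("_block")]
        cues = ev[ev.trial_type == "cue"]
        return cls(
            block_onsets=blocks.onset.to_numpy(float),
            block_types=[t.removesuffix("_block") for t in blocks.trial_type],
            cue_onsets=cues.onset.to_numpy(float),
        )


def generate_schedule(seed: int, first_block: str = "move") -> TaskSchedule:
    """Draw a task schedule with jittered cue trains.

    Blocks are laid out deterministically (alternating, 20 s); only the cue
    onsets are random: the first cue in each move block falls 0.5-1.5 s
    after block onset and consecutive cues follow at uniform 2-3 s
    intervals, so the 7-cue train always ends before the block does.
    """
    rng = np.random.default_rng(seed)
    n = 2 * N_BLOCKS_PER_TYPE
    onsets = np.arange(n) * BLOCK_DURATION
    other = "rest" if first_block == "move" else "move"
    types = [first_block if i % 2 == 0 else other for i in range(n)]

    cue_onsets = []
    for onset, typ in zip(onsets, types):
        if typ != "move":
            continue
        t = onset + rng.uniform(*FIRST_CUE_OFFSET_RANGE)
        cue_onsets.append(t)
        for _ in range(CUES_PER_BLOCK - 1):
            t = t + rng.uniform(*CUE_ISI_RANGE)
            cue_onsets.append(t)
    return TaskSchedule(
        block_onsets=onsets,
        block_types=types,
        cue_onsets=np.asarray(cue_onsets),
    )
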