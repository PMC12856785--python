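"""Sternberg task design: balanced load sequences and trial tables.

The modified Sternberg task presents a fixation cross (2 s), a memory set
of 1/3/5 consonants (1 s), a 4 s retention interval, and a probe that
stays on screen until response. Twenty blocks of 15 trials give 300
trials, 100 per load, with the probe drawn from the memory set at 50%
probability. Times are expressed relative to probe onset (t = 0), so the
canonical epoch spans negative (pre-probe) to positive (post-probe) time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Task phase windows in seconds relative to probe onset, half-open.
DEFAULT_PHASE_TIMES: dict[str, tuple[float, float]] = {
    "fixation": (-7.0, -5.0),
    "encoding": (-5.0, -4.0),
    "retention": (-4.0, 0.0),
    "probe": (0.0, 1.0),
}

TRIAL_COLUMNS = ["block", "trial", "load", "probe_present"]


@dataclass(frozen=True)
class TaskDesign:
    """Static description of the task an experiment (or simulation) runs."""

    n_blocks: int = 20
    trials_per_block: int = 15
    loads: tuple[int, ...] = (1, 3, 5)
    probe_present_prob: float = 0.5
    phase_times: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_TIMES)
    )

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if self.trials_per_block % len(self.loads) != 0:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} is not divisible by "
                f"the number of loads ({len(self.loads)}); blocks cannot be balanced"
            )
        if not 0.0 < self.probe_present_prob < 1.0:
            raise ValueError("probe_present_prob must lie strictly in (0, 1)")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def make_task_design(
    n_blocks: int = 20,
    trials_per_block: int = 15,
    loads: tuple[int, ...] = (1, 3, 5),
    seed: int = 0,
) -> tuple[TaskDesign, pd.DataFrame]:
    """Build the task design and a randomized, balanced trial table.

    Each block contains an equal number of trials per load, shuffled
    within block; probe presence is Bernoulli(0.5) per trial. The same
    seed always yields the same table.
    """
    design = TaskDesign(n_blocks=n_blocks, trials_per_block=trials_per_block,
                        loads=tuple(sorted(loads)))
    rng = np.random.default_rng(seed)
    per_load = trials_per_block // len(design.loads)
    rows = []
    for block in range(n_blocks):
        block_loads = np.repeat(design.loads, per_load)
        rng.shuffle(block_loads)
        present = rng.random(trials_per_block) < design.probe_present_prob
        for i, (load, p) in enumerate(zip(block_loads, present)):
            rows.append((block, block * trials_per_block + i, int(load), bool(p)))
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return design, trials
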