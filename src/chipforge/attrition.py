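"""Attrition accounting shared by every filtering stage.

Each filter records (stage name, input count, output count); the ledger
asserts on demand that per-stage removals plus survivors reconcile exactly,
mirroring the bookkeeping a design pipeline must publish with its panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Ledger"]


@dataclass
class Ledger:
    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in or n_out < 0:
            raise ValueError(
                f"stage {stage!r}: output {n_out} not within [0, {n_in}]"
            )
        self.stages.append((stage, n_in, n_out))

    def removed(self, stage: str) -> int:
        for name, n_in, n_out in self.stages:
            if name == stage:
                return n_in - n_out
        raise KeyError(stage)

    def check(self) -> None:
        """Assert consecutive stages chain (out of one = in of the next) and
        total removals + final survivors = initial input."""
        if not self.stages:
            return
        for (_, _, prev_out), (name, n_in, _) in zip(self.stages, self.stages[1:]):
            if n_in != prev_out:
                raise AssertionError(
                    f"stage {name!r} input {n_in} != previous output {prev_out}"
                )
        total_removed = sum(n_in - n_out for _, n_in, n_out in self.stages)
        if self.stages[0][1] != total_removed + self.stages[-1][2]:
            raise AssertionError("attrition ledger does not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_in", "n_out"]
        ).assign(removed=lambda d: d.n_in - d.n_out)
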