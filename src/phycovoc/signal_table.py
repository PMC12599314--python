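"""The m/z-signal x sample matrix carried through the pipeline.

A :class:`SignalTable` wraps a pandas DataFrame (rows: m/z signal labels at
the 2-decimal convention; columns: sample ids) tagged with a processing
*level*. Levels may only be promoted in the fixed order
``counts -> ncps -> ppbv -> nM -> fmol_per_cell``; any other transition is a
programming error and raises.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

__all__ = ["LEVELS", "SignalTable", "LevelError"]

LEVELS = ("counts", "ncps", "ppbv", "nM", "fmol_per_cell")


class LevelError(ValueError):
    """Raised on an out-of-order level transition."""


class SignalTable:
    """Signal x sample matrix with a processing-level tag."""

    def __init__(self, data: pd.DataFrame, level: str):
        if level not in LEVELS:
            raise LevelError(f"unknown level {level!r}; expected one of {LEVELS}")
        if not data.map(lambda v: pd.notna(v)).all().all():
            raise ValueError("SignalTable values must be finite (no NaN)")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "signal"
        self.level = level

    # -- basic accessors -------------------------------------------------
    @property
    def signals(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "SignalTable":
        return SignalTable(self.data.copy(), self.level)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SignalTable(level={self.level!r}, "
            f"{self.data.shape[0]} signals x {self.data.shape[1]} samples)"
        )

    # -- level management ------------------------------------------------
    def promote(self, data: pd.DataFrame, level: str) -> "SignalTable":
        """Return a new table at ``level``, enforcing the documented order."""
        if level not in LEVELS:
            raise LevelError(f"unknown level {level!r}")
        if LEVELS.index(level) <= LEVELS.index(self.level):
            raise LevelError(
                f"cannot promote {self.level!r} -> {level!r}: levels only move "
                f"forward in the order {LEVELS}"
            )
        return SignalTable(data, level)

    def with_rows(self, data: pd.DataFrame) -> "SignalTable":
        """Same level, different rows (e.g. after exclusion filtering)."""
        return SignalTable(data, self.level)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# level: {self.level}\n")
            self.data.to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "SignalTable":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# level:"):
                raise ValueError(f"{path}: missing '# level:' header line")
            level = header.split(":", 1)[1].strip()
            data = pd.read_csv(fh, index_col="signal", dtype={"signal": str})
        data.index = data.index.astype(str)
        return cls(data, level)


def mz_label(mz: float) -> str:
    """Signal row label: m/z rendered at the 2-decimal convention."""
    return f"{mz:.2f}"


def label_mz(label: str) -> float:
    """Numeric m/z of a signal row label."""
    return float(label)


def subset_columns(table: SignalTable, samples: Iterable[str]) -> SignalTable:
    return SignalTable(table.data[list(samples)], table.level)
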