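"""Core containers for density-gradient fraction data.

A :class:`GradientRun` is one fractionated isopycnic CsCl gradient: an
ordered list of fractions (bottom of the tube first, so fraction 1 is the
heaviest), a taxon × fraction signal matrix, and optional per-fraction 16S
rRNA gene copy numbers from qPCR. Densities must strictly decrease with
fraction index; this is the fractionation convention of pulling 12 equal
fractions from the bottom of the tube upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: plausibility window for CsCl buoyant densities of DNA (g/ml)
DENSITY_SANITY = (1.60, 1.85)


@dataclass(frozen=True)
class GradientFraction:
    """One gradient fraction: 1-based index, buoyant density (g/ml),
    optional volume (ml)."""

    index: int
    density: float
    volume: float | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"fraction index must be >= 1, got {self.index}")
        lo, hi = DENSITY_SANITY
        if not (lo < self.density < hi):
            raise ValueError(
                f"fraction {self.index}: density {self.density} g/ml outside "
                f"the plausible CsCl window ({lo}, {hi})"
            )


@dataclass
class GradientRun:
    """One fractionated gradient with its abundance matrix.

    Attributes
    ----------
    run_id
        Unique identifier, conventionally ``{soil}_{treatment}_r{rep}_t{days}``.
    soil, treatment, replicate, timepoint_days
        Experimental metadata. ``treatment`` is one of ``"12C"``, ``"13C"``,
        ``"control"``.
    fractions
        Ordered fractions; densities strictly decreasing with index
        (fraction 1 = bottom = heaviest).
    abundance
        taxon × fraction DataFrame; columns are the 1-based fraction
        indices. Either raw read counts (``values_kind="counts"``) or
        per-fraction relative abundances summing to 1
        (``values_kind="relative"``).
    copies
        Per-fraction 16S rRNA gene copy numbers (qPCR), or None.
    """

    run_id: str
    soil: str
    treatment: str
    replicate: int
    timepoint_days: int
    fractions: list[GradientFraction]
    abundance: pd.DataFrame
    copies: np.ndarray | None = None
    values_kind: str = "relative"
    tail_mass: dict = field(default_factory=dict)

    VALID_TREATMENTS = ("12C", "13C", "control")

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.treatment not in self.VALID_TREATMENTS:
            raise ValueError(
                f"run {self.run_id}: treatment {self.treatment!r} not in "
                f"{self.VALID_TREATMENTS}"
            )
        if self.values_kind not in ("counts", "relative"):
            raise ValueError(
                f"run {self.run_id}: values_kind must be 'counts' or "
                f"'relative', got {self.values_kind!r}"
            )
        idx = [f.index for f in self.fractions]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(
                f"run {self.run_id}: fraction indices must be 1..n in order, got {idx}"
            )
        dens = self.densities
        if not np.all(np.diff(dens) < 0):
            raise ValueError(
                f"run {self.run_id}: densities must strictly decrease with "
                "fraction index (fraction 1 is the heaviest, bottom fraction)"
            )
        if list(self.abundance.columns) != idx:
            raise ValueError(
                f"run {self.run_id}: abundance columns {list(self.abundance.columns)} "
                f"do not match fraction indices {idx}"
            )
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError(f"run {self.run_id}: negative abundances")
        if self.copies is not None:
            self.copies = np.asarray(self.copies, dtype=float)
            if len(self.copies) != len(self.fractions):
                raise ValueError(
                    f"run {self.run_id}: {len(self.copies)} copy numbers for "
                    f"{len(self.fractions)} fractions"
                )
            if (self.copies < 0).any():
                raise ValueError(f"run {self.run_id}: negative 16S copy numbers")
        if self.values_kind == "relative":
            sums = self.abundance.to_numpy().sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(
                    f"run {self.run_id}: relative-abundance columns must sum "
                    f"to 1 (got sums {sums})"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    @property
    def densities(self) -> np.ndarray:
        """Fraction buoyant densities (g/ml), heaviest first."""
        return np.array([f.density for f in self.fractions], dtype=float)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.index)

    def normalized(self) -> "GradientRun":
        """Return a copy with per-fraction columns normalized to sum to 1."""
        if self.values_kind == "relative":
            return self
        mat = self.abundance.to_numpy(dtype=float)
        sums = mat.sum(axis=0)
        if (sums <= 0).any():
            empty = [f.index for f, s in zip(self.fractions, sums) if s <= 0]
            raise ValueError(
                f"run {self.run_id}: cannot normalize empty fraction(s) {empty}"
            )
        norm = pd.DataFrame(
            mat / sums, index=self.abundance.index, columns=self.abundance.columns
        )
        return replace(self, abundance=norm, values_kind="relative")


def check_same_design(runs: Sequence[GradientRun]) -> int:
    """Assert all runs share one fraction count; return it."""
    counts = {r.n_fractions for r in runs}
    if len(counts) != 1:
        raise ValueError(f"runs have mismatched fraction counts: {sorted(counts)}")
    return counts.pop()
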