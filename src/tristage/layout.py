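"""Hypercolumn layouts for modular (soft-WTA) and non-modular (kWTA) populations.

A hypercolumn is a group of rate units under normalizing lateral inhibition:
activity sums to one within each hypercolumn, so a unit's activity can be read
as the posterior probability of the feature the hypercolumn codes for.
Non-modular populations (the hippocampal stage) form a single group and are
normalized by a k-winner-take-all rule instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HypercolumnLayout:
    """Partition of ``n_units`` rate units into hypercolumns.

    Parameters
    ----------
    n_units:
        Total number of units N.
    hypercolumn_sizes:
        Sizes ``M_k`` of each hypercolumn; must sum to ``n_units``. For a
        non-modular layout this is the single group ``(n_units,)``.
    modular:
        Whether the layout carries soft-WTA hypercolumn structure. Non-modular
        layouts are normalized by kWTA.
    """

    n_units: int
    hypercolumn_sizes: tuple[int, ...]
    modular: bool = True

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        sizes = tuple(int(m) for m in self.hypercolumn_sizes)
        object.__setattr__(self, "hypercolumn_sizes", sizes)
        if any(m <= 0 for m in sizes):
            raise ValueError("hypercolumn sizes must be positive")
        if sum(sizes) != self.n_units:
            raise ValueError(
                f"hypercolumn sizes sum to {sum(sizes)}, expected {self.n_units}"
            )
        if not self.modular and len(sizes) != 1:
            raise ValueError("a non-modular layout is a single group of all units")

    @classmethod
    def uniform(cls, n_hypercolumns: int, size: int) -> "HypercolumnLayout":
        """Modular layout of ``n_hypercolumns`` equal hypercolumns of ``size`` units."""
        return cls(n_hypercolumns * size, (size,) * n_hypercolumns, modular=True)

    @classmethod
    def flat(cls, n_units: int) -> "HypercolumnLayout":
        """Non-modular (kWTA) layout: one group of all units."""
        return cls(n_units, (n_units,), modular=False)

    @property
    def n_hypercolumns(self) -> int:
        return len(self.hypercolumn_sizes)

    @property
    def uniform_size(self) -> int | None:
        """Common hypercolumn size M, or None if sizes differ."""
        sizes = set(self.hypercolumn_sizes)
        return sizes.pop() if len(sizes) == 1 else None

    @property
    def starts(self) -> np.ndarray:
        """Start offset of each hypercolumn (length H + 1, last = n_units)."""
        return np.concatenate(([0], np.cumsum(self.hypercolumn_sizes)))

    @property
    def membership(self) -> np.ndarray:
        """Map unit index -> hypercolumn index H(i)."""
        return np.repeat(
            np.arange(self.n_hypercolumns), self.hypercolumn_sizes
        )

    def slices(self) -> list[slice]:
        starts = self.starts
        return [slice(int(starts[k]), int(starts[k + 1])) for k in range(self.n_hypercolumns)]

    def group_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum ``values`` (units on the first axis) within each hypercolumn."""
        m = self.uniform_size
        if m is not None:
            shaped = values.reshape(self.n_hypercolumns, m, *values.shape[1:])
            return shaped.sum(axis=1)
        return np.add.reduceat(values, self.starts[:-1], axis=0)

    def uniform_activity(self) -> np.ndarray:
        """The maximum-entropy activity state (1/M_k per unit; kWTA: A per unit)."""
        if self.modular:
            return np.repeat(
                1.0 / np.asarray(self.hypercolumn_sizes, dtype=float),
                self.hypercolumn_sizes,
            )
        return np.full(self.n_units, 1.0 / self.n_units)
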