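"""Core in-memory containers for combination-screen data.

A :class:`CombinationBlock` is one drug-combination experiment: ``n`` drugs,
one sorted dose vector per drug (always starting at dose 0), and an
``n``-dimensional tensor of % inhibition indexed by dose position.
Single-agent responses live on the tensor axes (all other doses 0); the
all-zero-dose cell is the untreated control and is defined as 0 %inh.

Responses are % inhibition relative to control: 0 = control signal,
100 = complete inhibition.  Values outside [0, 100] (stimulation,
super-inhibition) are preserved; individual formulas clamp where required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import DataError


@dataclass
class WellRecord:
    """One measured well of a combination screen (long-format row)."""

    block_id: str
    drug_names: tuple[str, ...]
    concentrations: tuple[float, ...]
    response: Optional[float] = None
    raw_count: Optional[float] = None
    sample_id: Optional[str] = None
    replicate: Optional[int] = None
    conc_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.drug_names = tuple(self.drug_names)
        self.concentrations = tuple(float(c) for c in self.concentrations)
        if len(self.drug_names) < 2:
            raise DataError("a well record needs at least 2 drugs")
        if len(self.concentrations) != len(self.drug_names):
            raise DataError(
                "concentrations and drug_names must have the same length"
            )
        if any(c < 0 for c in self.concentrations):
            raise DataError("negative concentration")
        if (self.response is None) == (self.raw_count is None):
            raise DataError(
                "exactly one of response / raw_count must be populated"
            )
        if self.raw_count is not None and self.raw_count < 0:
            raise DataError("raw_count must be non-negative")


@dataclass
class CombinationBlock:
    """One combination experiment on a full factorial dose grid."""

    block_id: str
    drugs: tuple[str, ...]
    dose_grid: tuple[np.ndarray, ...]
    response: np.ndarray
    sample_id: Optional[str] = None
    replicate_tensor: Optional[np.ndarray] = None
    dose_units: tuple[str, ...] = ()
    replaced_cells: tuple[tuple[int, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.drugs = tuple(self.drugs)
        self.dose_grid = tuple(
            np.asarray(d, dtype=float) for d in self.dose_grid
        )
        self.response = np.asarray(self.response, dtype=float)
        if not self.dose_units:
            self.dose_units = tuple("" for _ in self.drugs)
        if len(self.dose_grid) != len(self.drugs):
            raise DataError("one dose vector per drug is required")
        for name, doses in zip(self.drugs, self.dose_grid):
            if doses.ndim != 1 or doses.size < 2:
                raise DataError(f"dose vector for {name!r} needs >= 2 doses")
            if doses[0] != 0.0:
                raise DataError(f"dose vector for {name!r} must start at 0")
            if np.any(np.diff(doses) <= 0):
                raise DataError(
                    f"dose vector for {name!r} must be strictly increasing"
                )
        if self.response.shape != self.shape:
            raise DataError(
                f"response tensor shape {self.response.shape} does not match "
                f"dose grid shape {self.shape}"
            )
        interior = self.response[self.interior_index]
        if not np.all(np.isfinite(interior)):
            raise DataError("combination cells must be finite")

    # -- geometry -----------------------------------------------------------

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.dose_grid)

    @property
    def interior_index(self) -> tuple[slice, ...]:
        """Index selecting the all-positive-dose subgrid."""
        return tuple(slice(1, None) for _ in self.drugs)

    @property
    def interior_doses(self) -> tuple[np.ndarray, ...]:
        return tuple(d[1:] for d in self.dose_grid)

    def axis_index(self, axis: int, pos: int) -> tuple[int, ...]:
        """Tensor index of the single-agent cell ``pos`` on drug ``axis``."""
        idx = [0] * self.n_drugs
        idx[axis] = pos
        return tuple(idx)

    def single_agent_responses(self, axis: int) -> np.ndarray:
        """Measured single-agent responses of drug ``axis`` over its doses.

        Index 0 is the control cell (0 by construction); missing axis
        measurements appear as NaN.
        """
        idx: list = [0] * self.n_drugs
        idx[axis] = slice(None)
        return np.array(self.response[tuple(idx)], dtype=float)

    def iter_interior_cells(self) -> Iterator[tuple[tuple[int, ...], tuple[float, ...]]]:
        """Yield (tensor index, dose tuple) for every all-positive-dose cell."""
        for idx in np.ndindex(*(s - 1 for s in self.shape)):
            full = tuple(i + 1 for i in idx)
            doses = tuple(self.dose_grid[k][i] for k, i in enumerate(full))
            yield full, doses

    def copy(self) -> "CombinationBlock":
        return replace(
            self,
            response=self.response.copy(),
            replicate_tensor=(
                None
                if self.replicate_tensor is None
                else self.replicate_tensor.copy()
            ),
        )

    @property
    def combination_key(self) -> tuple[str, ...]:
        """Order-invariant identity of the drug set."""
        return tuple(sorted(self.drugs))


def make_block(
    drugs: Sequence[str],
    dose_grid: Sequence[Sequence[float]],
    response: np.ndarray,
    block_id: str = "block1",
    sample_id: Optional[str] = None,
    **kwargs,
) -> CombinationBlock:
    """Convenience constructor used by tests and the simulator."""
    return CombinationBlock(
        block_id=block_id,
        drugs=tuple(drugs),
        dose_grid=tuple(np.asarray(d, dtype=float) for d in dose_grid),
        response=np.asarray(response, dtype=float),
        sample_id=sample_id,
        **kwargs,
    )
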