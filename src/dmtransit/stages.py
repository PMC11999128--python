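"""Four-stage disease-progression state space.

A patient with diabetes mellitus is classified each year along two axes:
whether the HbA1c level is within the personalized metabolic goal
(``ON`` / ``OUT``) and whether a chronic staging complication —
retinopathy, cerebrovascular disease, or chronic kidney disease — has
been diagnosed (``NOT`` / ``YES``). Complications are absorbing: once a
patient enters a ``YES`` stage they can never return to a ``NOT`` stage,
while movement between ``ON`` and ``OUT`` is bidirectional.

The fixed index order ``ON-NOT, OUT-NOT, ON-YES, OUT-YES`` is used for
every transition-matrix row and column in the package.
"""

from __future__ import annotations

import enum
from collections.abc import Sequence

import numpy as np


class Stage(str, enum.Enum):
    """One of the four metabolic-goal x complication stages."""

    ON_NOT = "ON-NOT"
    OUT_NOT = "OUT-NOT"
    ON_YES = "ON-YES"
    OUT_YES = "OUT-YES"

    @property
    def on_goal(self) -> bool:
        return self in (Stage.ON_NOT, Stage.ON_YES)

    @property
    def has_complication(self) -> bool:
        return self in (Stage.ON_YES, Stage.OUT_YES)

    @classmethod
    def from_flags(cls, on_goal: bool, has_complication: bool) -> "Stage":
        if has_complication:
            return cls.ON_YES if on_goal else cls.OUT_YES
        return cls.ON_NOT if on_goal else cls.OUT_NOT


#: Canonical row/column order for all transition matrices.
STAGE_ORDER: tuple[Stage, ...] = (
    Stage.ON_NOT,
    Stage.OUT_NOT,
    Stage.ON_YES,
    Stage.OUT_YES,
)
STAGE_INDEX: dict[Stage, int] = {s: i for i, s in enumerate(STAGE_ORDER)}
STAGE_NAMES: tuple[str, ...] = tuple(s.value for s in STAGE_ORDER)

# (row, column) cells that must be zero: a complication stage can never
# transition back to a no-complication stage.
STRUCTURAL_ZEROS: tuple[tuple[int, int], ...] = (
    (2, 0),
    (2, 1),
    (3, 0),
    (3, 1),
)


class InvalidTransitionMatrixError(ValueError):
    """A transition matrix violates row-stochasticity or a structural zero."""


def validate_transition_matrix(
    matrix: np.ndarray, *, atol: float = 1e-9, name: str = "transition matrix"
) -> np.ndarray:
    """Validate a 4x4 row-stochastic stage-transition matrix.

    Checks shape, non-negativity, unit row sums (within ``atol``) and the
    structural zeros implied by absorbing complications. Returns the
    matrix as a float array.

    Raises
    ------
    InvalidTransitionMatrixError
        Naming the offending row or cell.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise InvalidTransitionMatrixError(f"{name}: expected shape (4, 4), got {m.shape}")
    if (m < 0).any():
        r, c = np.argwhere(m < 0)[0]
        raise InvalidTransitionMatrixError(
            f"{name}: negative entry at row {STAGE_NAMES[r]}, column {STAGE_NAMES[c]}"
        )
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if abs(s - 1.0) > atol:
            raise InvalidTransitionMatrixError(
                f"{name}: row {STAGE_NAMES[i]} sums to {s!r}, expected 1"
            )
    for r, c in STRUCTURAL_ZEROS:
        if m[r, c] > atol:
            raise InvalidTransitionMatrixError(
                f"{name}: structural zero violated at row {STAGE_NAMES[r]}, "
                f"column {STAGE_NAMES[c]} (complications are absorbing)"
            )
    return m


def matrix_from_percentages(rows: Sequence[Sequence[float]]) -> np.ndarray:
    """Build a transition matrix from rows of printed percentages.

    Published tables round each cell to two decimals, so rows may sum to
    99.99% or 100.01%; each row is renormalized to sum exactly to 1.
    """
    m = np.asarray(rows, dtype=float) / 100.0
    m = m / m.sum(axis=1, keepdims=True)
    return validate_transition_matrix(m, name="percentage matrix")


# Observed 1-year stage-transition structure of the reference cohort
# (row = initial stage, column = stage one year later).
TRANSITIONS_1Y = matrix_from_percentages(
    [
        [47.75, 10.10, 34.62, 7.52],
        [16.11, 40.82, 11.97, 31.11],
        [0.00, 0.00, 81.84, 18.16],
        [0.00, 0.00, 26.94, 73.06],
    ]
)

# Observed 2-year structure. Not the square of the 1-year matrix: the
# empirical 2-year dynamics differ from chaining two 1-year draws, so
# both are kept and either can drive a simulation.
TRANSITIONS_2Y = matrix_from_percentages(
    [
        [26.86, 6.73, 52.04, 14.37],
        [11.57, 21.03, 22.33, 45.06],
        [0.00, 0.00, 80.99, 19.01],
        [0.00, 0.00, 32.98, 67.02],
    ]
)

# 2018 stage occupancy of the reference cohort (counts 8685 / 6858 /
# 4375 / 3884 of 23802 patients), used as the default initial
# distribution.
INITIAL_STAGE_COUNTS_2018 = np.array([8685, 6858, 4375, 3884], dtype=float)
INITIAL_STAGE_PROBS = INITIAL_STAGE_COUNTS_2018 / INITIAL_STAGE_COUNTS_2018.sum()
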