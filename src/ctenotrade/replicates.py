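"""Domain types for arena spawning replicates.

The experimental unit throughout is the *arena replicate*: one overnight
spawning trial in a two-litre arena holding either a single animal
(solitary), a free pair (no barrier), or a pair separated by a divider
that is either perforated (permeable: water, chemical cues and sperm pass,
eggs mostly do not) or watertight (sealed: the no-communication control).
Divided arenas yield one egg count per side; undivided arenas yield a
single combined count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Treatment(str, enum.Enum):
    SOLITARY = "solitary"
    NO_BARRIER = "no_barrier"
    PERMEABLE = "permeable"
    SEALED = "sealed"


#: Treatments whose arenas are divided and therefore produce paired counts.
PAIRED_TREATMENTS = frozenset({Treatment.PERMEABLE, Treatment.SEALED})


class UndefinedSplitError(ValueError):
    """Raised when a proportion split is requested for a zero-total pair.

    A 0/0 split is undefined; callers must exclude double-zero replicates
    explicitly (see :func:`ctenotrade.trading.filter_double_zero`) rather
    than rely on a silent imputation.
    """


class InsufficientDataError(ValueError):
    """Raised when a test is requested with too few observations."""


@dataclass(frozen=True)
class PairedSpawnReplicate:
    """One arena replicate with per-side egg counts.

    ``eggs_b`` is ``None`` for undivided arenas (solitary / no-barrier),
    which report a single combined count in ``eggs_a``.
    """

    replicate_id: str
    treatment: Treatment
    eggs_a: int
    eggs_b: int | None = None
    block_id: str | None = None

    def __post_init__(self) -> None:
        if self.eggs_a < 0 or (self.eggs_b is not None and self.eggs_b < 0):
            raise ValueError(
                f"replicate {self.replicate_id!r}: egg counts must be non-negative"
            )
        if not isinstance(self.treatment, Treatment):
            object.__setattr__(self, "treatment", Treatment(self.treatment))

    @property
    def total(self) -> int:
        return self.eggs_a + (self.eggs_b or 0)

    @property
    def is_paired(self) -> bool:
        return self.eggs_b is not None

    def swapped(self) -> "PairedSpawnReplicate":
        """The same replicate with the (arbitrary) side labels exchanged."""
        if self.eggs_b is None:
            return self
        return PairedSpawnReplicate(
            self.replicate_id, self.treatment, self.eggs_b, self.eggs_a, self.block_id
        )


@dataclass(frozen=True)
class ProportionSplit:
    """Each side's share of a pair's total egg output.

    Defined only for pairs with at least one egg; ``abs_diff`` is the
    per-replicate contribution to the absolute-difference-total statistic.
    """

    p_a: float
    p_b: float
    abs_diff: float


@dataclass(frozen=True)
class AbsoluteDifferenceTotal:
    """The test statistic: sum over replicates of |p_a - p_b|.

    Bounded by [0, n_replicates]; the maximum is attained only when every
    pair spawned entirely on one side, the minimum only at exact 50/50
    splits throughout.
    """

    value: float
    n_replicates: int
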