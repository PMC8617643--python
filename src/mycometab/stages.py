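"""Phenophase design of the two-treatment developmental time course.

*Medicago lupulina* plants inoculated with the arbuscular-mycorrhizal (AM)
fungus advance through the phenological stages one position ahead of the
non-inoculated controls from 21 days after sowing (DAS) onward.  This module
encodes that fixed (treatment, DAS) -> stage mapping and the stage order used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: phenophase labels in developmental order: first leaf development, second
#: leaf initiation, third leaf initiation, stooling initiation, stooling
#: (stem formation), shoot branching initiation, flowering initiation,
#: flowering development.
STAGE_ORDER = ("1L", "2LI", "3LI", "SI", "ST", "SBI", "FI", "FD")

#: the seven phenology observation days (DAS = DAI in this design)
DAS_POINTS = (14, 21, 24, 29, 38, 45, 52)

_MINUS_AM = {14: "1L", 21: "2LI", 24: "3LI", 29: "SI", 38: "ST", 45: "SBI", 52: "FI"}
_PLUS_AM = {14: "1L", 21: "3LI", 24: "SI", 29: "ST", 38: "SBI", 45: "FI", 52: "FD"}


@dataclass(frozen=True)
class StageDesign:
    """Ordered stage labels plus the (treatment, das) -> stage map."""

    stages: tuple[str, ...] = STAGE_ORDER
    map: dict = field(default_factory=lambda: {"minusAM": dict(_MINUS_AM), "plusAM": dict(_PLUS_AM)})

    def stage(self, treatment: str, das: int) -> str:
        try:
            by_das = self.map[treatment]
        except KeyError:
            raise KeyError(f"unknown treatment {treatment!r}") from None
        try:
            return by_das[int(das)]
        except KeyError:
            raise KeyError(
                f"das={das} outside the design domain {sorted(by_das)}"
            ) from None

    def index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise KeyError(f"unknown stage {stage!r}") from None

    def shift(self, stage: str, offset: int) -> str:
        """Stage ``offset`` positions away in the order, clamped at both ends."""
        i = min(max(self.index(stage) + offset, 0), len(self.stages) - 1)
        return self.stages[i]

    @property
    def das_points(self) -> tuple[int, ...]:
        return tuple(sorted(self.map["minusAM"]))


def make_stage_design() -> StageDesign:
    """The fixed developmental design of the study (both treatments, 7 DAS)."""
    return StageDesign()
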