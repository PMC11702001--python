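"""Measure definitions for weekly patient-reported outcomes.

The pipeline tracks one detection measure (the Liebowitz Social Anxiety
Scale, LSAS, 24 items, total score 0-144) and five process measures:
the Social Cognitions Questionnaire frequency and belief subscales
(22 items each; frequency summed over items 1-5 -> 22-110, belief summed
over items 0-100 -> 0-2200), two single-item self-focused-attention
ratings (0-8 each) and the PHQ-9 depression scale (0-27).  All are
"lower is better" severity scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class MeasureSpec:
    """Range and orientation of a weekly self-report measure."""

    name: str
    min_value: float
    max_value: float
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        if not self.min_value < self.max_value:
            raise ValueError(
                f"measure {self.name!r}: min_value {self.min_value} must be "
                f"below max_value {self.max_value}"
            )

    def in_range(self, value: float) -> bool:
        return self.min_value <= value <= self.max_value


LSAS = "lsas"
SCQ_FREQUENCY = "scq_frequency"
SCQ_BELIEF = "scq_belief"
SFA_GENERAL = "sfa_general"
SFA_DIFFICULT = "sfa_difficult"
PHQ9 = "phq9"

#: Measures analysed around the gain (the detection measure is included
#: so the symptom course itself can be tabulated alongside the processes).
PROCESS_MEASURES = (
    SCQ_BELIEF,
    SCQ_FREQUENCY,
    SFA_GENERAL,
    SFA_DIFFICULT,
    PHQ9,
    LSAS,
)


def default_registry() -> dict[str, MeasureSpec]:
    """Registry of the six standard measures with their scale ranges."""
    specs = [
        MeasureSpec(LSAS, 0, 144),
        MeasureSpec(SCQ_FREQUENCY, 22, 110),
        MeasureSpec(SCQ_BELIEF, 0, 2200),
        MeasureSpec(SFA_GENERAL, 0, 8),
        MeasureSpec(SFA_DIFFICULT, 0, 8),
        MeasureSpec(PHQ9, 0, 27),
    ]
    return {s.name: s for s in specs}


def registry_from_config(config: Mapping) -> dict[str, MeasureSpec]:
    """Build a measure registry from a parsed YAML/JSON mapping.

    Expected layout::

        measures:
          lsas: {min: 0, max: 144}
          ...
    """
    out: dict[str, MeasureSpec] = {}
    for name, spec in config.get("measures", {}).items():
        out[name] = MeasureSpec(
            name=name,
            min_value=float(spec["min"]),
            max_value=float(spec["max"]),
            lower_is_better=bool(spec.get("lower_is_better", True)),
        )
    if not out:
        return default_registry()
    return out
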