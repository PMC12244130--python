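"""Tissue-area normalization of the DSC signal and the low-signal filter.

The distal seed coat (DSC) covers a much larger tissue area than the
funiculus (FUN) or chalazal seed coat (CSC); dividing its raw signal by
the area ratio puts all three tissues on a comparable per-area scale.
Genes whose raw signal is below threshold in BOTH FUN and CSC are dropped
before any grouping to limit false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from gradientnet.errors import ConfigError
from gradientnet.expression_io import ExpressionProfile

__all__ = ["NormalizationConfig", "normalize_dsc", "filter_low_signal"]

#: DSC area relative to FUN (= CSC) area, measured from tissue-section images.
DEFAULT_AREA_RATIO = 26.8

#: Raw-signal floor: drop genes below this in both FUN and CSC.
DEFAULT_LOW_SIGNAL_THRESHOLD = 10.0


@dataclass(frozen=True)
class NormalizationConfig:
    area_ratio: float = DEFAULT_AREA_RATIO
    low_signal_threshold: float = DEFAULT_LOW_SIGNAL_THRESHOLD

    def __post_init__(self) -> None:
        if not (self.area_ratio > 0):
            raise ConfigError(f"area_ratio must be positive, got {self.area_ratio}")
        if self.low_signal_threshold < 0:
            raise ConfigError(
                f"low_signal_threshold must be non-negative, "
                f"got {self.low_signal_threshold}"
            )


def normalize_dsc(
    profiles: Sequence[ExpressionProfile],
    config: NormalizationConfig = NormalizationConfig(),
) -> list[ExpressionProfile]:
    """Set ``dsc_norm = dsc_raw / area_ratio`` on every profile.

    FUN and CSC signals are left untouched; the normalized DSC value is
    what enters every downstream 3-point correlation.
    """
    return [p.with_dsc_norm(p.dsc_raw / config.area_ratio) for p in profiles]


def filter_low_signal(
    profiles: Sequence[ExpressionProfile],
    config: NormalizationConfig = NormalizationConfig(),
) -> tuple[list[ExpressionProfile], list[ExpressionProfile]]:
    """Partition profiles into (kept, dropped) by the raw-signal floor.

    A gene is dropped iff its raw FUN and raw CSC signals are BOTH
    strictly below the threshold; the DSC signal is not consulted.
    """
    threshold = config.low_signal_threshold
    kept: list[ExpressionProfile] = []
    dropped: list[ExpressionProfile] = []
    for p in profiles:
        if p.fun < threshold and p.csc < threshold:
            dropped.append(p)
        else:
            kept.append(p)
    return kept, dropped
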