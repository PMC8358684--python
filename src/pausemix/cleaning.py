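"""Essay-level cleaning before mixture modeling.

Low-stakes writing assessments collect a contingent of low-effort
essays: the student types a few characters and submits, leaving almost
no pause events and earning zero scores.  With fewer than 30 pause
events an 8-parameter mixture is hopeless, and a zero score carries no
signal for the correlation stage, so such essays are excluded.

The exclusion rule is conjunctive: an essay is removed iff it has fewer
than 30 pause events AND its human scores are zero.  "Fewer than 30" is
strict (30 events is kept); by default both strand scores must be zero,
with an ``either`` switch for sensitivity analysis.

The characters-typed / pause-events ratio diagnoses whether the removed
essays are a random subsample: for engaged writers the two means track
each other (ratio near the characters-per-keystroke rate), while for
low-effort essays the pause-event mean collapses and the ratio blows up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import EssayRecord, ValidationError

MIN_PAUSE_EVENTS = 30


class DegenerateRatioError(ZeroDivisionError):
    """Mean pause count is zero; the ratio is undefined."""


@dataclass(frozen=True)
class CleaningConfig:
    min_pause_events: int = MIN_PAUSE_EVENTS
    #: "both" removes only when strand1 == strand3 == 0 (primary reading);
    #: "either" removes when either strand is 0 (sensitivity switch).
    zero_score_rule: str = "both"

    def __post_init__(self) -> None:
        if self.zero_score_rule not in ("both", "either"):
            raise ValidationError("zero_score_rule must be 'both' or 'either'")


def is_low_effort(essay: EssayRecord, config: CleaningConfig | None = None) -> bool:
    cfg = config or CleaningConfig()
    few_events = essay.n_pauses < cfg.min_pause_events
    if cfg.zero_score_rule == "both":
        zero_scores = essay.strand1 == 0 and essay.strand3 == 0
    else:
        zero_scores = essay.strand1 == 0 or essay.strand3 == 0
    return few_events and zero_scores


def char_pause_ratio(corpus: Sequence[EssayRecord]) -> float:
    """(mean characters typed) / (mean pause events) across essays.

    Raises :class:`DegenerateRatioError` when no essay produced a pause
    event (possible: zero-event essays are representable).
    """
    if not corpus:
        raise ValidationError("ratio undefined on an empty corpus")
    mean_chars = sum(e.n_chars_typed for e in corpus) / len(corpus)
    mean_pauses = sum(e.n_pauses for e in corpus) / len(corpus)
    if mean_pauses == 0:
        raise DegenerateRatioError("mean pause count is 0; char/pause ratio undefined")
    return mean_chars / mean_pauses


def filter_essays(
    corpus: Sequence[EssayRecord], config: CleaningConfig | None = None
) -> tuple[list[EssayRecord], list[EssayRecord], dict]:
    """Split a corpus into kept and removed essays and report the split.

    kept and removed partition the input (order preserved).  The report
    carries counts, the removed fraction, and the char/pause ratio of
    each side (None where undefined).
    """
    cfg = config or CleaningConfig()
    if not corpus:
        raise ValidationError("cannot clean an empty corpus")
    kept, removed = [], []
    for essay in corpus:
        (removed if is_low_effort(essay, cfg) else kept).append(essay)

    def _ratio(sub):
        try:
            return char_pause_ratio(sub) if sub else None
        except DegenerateRatioError:
            return None

    report = {
        "n_input": len(corpus),
        "n_kept": len(kept),
        "n_removed": len(removed),
        "removed_fraction": len(removed) / len(corpus),
        "kept_ratio": _ratio(kept),
        "removed_ratio": _ratio(removed),
        "min_pause_events": cfg.min_pause_events,
        "zero_score_rule": cfg.zero_score_rule,
    }
    return kept, removed, report
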