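"""Core data containers shared across the pipeline.

The unit of observation is a *pause event*: the latency, in milliseconds,
between two consecutive keystroke-log events, labeled with the linguistic
context at which the pause occurred (within a word, between words, between
sentences, around deletions, and so on).  An essay is a collection of pause
events plus the human scores assigned to the final writing product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

#: The eight linguistic contexts a pause can be attributed to.
CONTEXTS: tuple[str, ...] = (
    "WithinWord",
    "BackSpace",
    "BetweenWord",
    "BetweenSentence",
    "BetweenParagraph",
    "MultipleBackspace",
    "SingleBackspace",
    "Edit",
)

#: Keystroke-log actions.  ``press`` commits a key; the rest are editor
#: operations that precede an ``Edit`` pause.
ACTIONS: tuple[str, ...] = ("press", "cut", "paste", "replace", "cursor_move")
EDIT_ACTIONS: frozenset[str] = frozenset({"cut", "paste", "replace", "cursor_move"})

#: Named (non-printing) keys used in keystroke logs.
BACKSPACE = "BACKSPACE"
ENTER = "ENTER"
SPACE = "SPACE"


class PauseEvent(NamedTuple):
    """One latency observation with its linguistic context label."""

    context: str
    latency_ms: float


class KeystrokeEvent(NamedTuple):
    """One time-stamped editor event.

    ``timestamp_ms`` is milliseconds since session start (integer,
    non-decreasing within a stream).  ``key`` is a single character or one
    of the named keys ``BACKSPACE``/``ENTER``/``SPACE``; for non-press
    actions it names the operation target and is ignored by the classifier.
    """

    timestamp_ms: int
    action: str
    key: str


class ValidationError(ValueError):
    """An input violated a documented invariant."""


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of a K-component lognormal mixture.

    Components are Normal on the log-millisecond scale: component k has
    mean ``mu[k]`` and SD ``sigma[k]`` and is drawn with probability
    ``pi[k]``.  Equivalently the raw latencies are lognormal.
    """

    mu: np.ndarray
    sigma: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "pi"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        self.validate()

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    def validate(self) -> None:
        if not (self.mu.shape == self.sigma.shape == self.pi.shape) or self.mu.ndim != 1:
            raise ValidationError("mu, sigma, pi must be 1-d arrays of equal length")
        if self.K < 1:
            raise ValidationError("mixture needs at least one component")
        if np.any(self.sigma < 0) or not np.all(np.isfinite(self.sigma)):
            raise ValidationError("sigma must be finite and nonnegative")
        if not np.all(np.isfinite(self.mu)):
            raise ValidationError("mu must be finite")
        if np.any(self.pi < 0):
            raise ValidationError("pi must be nonnegative")
        if abs(float(self.pi.sum()) - 1.0) > 1e-10:
            raise ValidationError(f"pi must sum to 1 (got {float(self.pi.sum())!r})")

    @property
    def is_ordered(self) -> bool:
        return bool(np.all(np.diff(self.mu) >= 0))

    def ordered(self) -> "MixtureSpec":
        """Return the label-switching-resolved spec: components sorted by
        mean, ascending, ties broken by original index (stable sort)."""
        order = np.argsort(self.mu, kind="stable")
        return MixtureSpec(self.mu[order], self.sigma[order], self.pi[order])


@dataclass
class EssayRecord:
    """One essay: its pause events, character count and two strand scores.

    ``strand1`` is the sentence-level-control score, ``strand3`` the
    critical-thinking score, both small nonnegative integers assigned by
    human raters to the final writing product.
    """

    essay_id: str
    pauses: list[PauseEvent]
    n_chars_typed: int
    strand1: int
    strand3: int

    def __post_init__(self) -> None:
        if self.n_chars_typed < 0:
            raise ValidationError("n_chars_typed must be >= 0")
        if self.strand1 < 0 or self.strand3 < 0:
            raise ValidationError("strand scores must be >= 0")

    @property
    def n_pauses(self) -> int:
        return len(self.pauses)


def select_context(pauses: Sequence[PauseEvent], context: str) -> list[float]:
    """Latencies of the pauses in one linguistic context, order preserved.

    The analysis streams one context at a time (typically ``WithinWord``,
    the most frequent one); this is the filter behind that convention.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    return [p.latency_ms for p in pauses if p.context == context]


def context_counts(pauses: Iterable[PauseEvent]) -> dict[str, int]:
    """Number of pause events per context (all eight keys always present)."""
    counts = {c: 0 for c in CONTEXTS}
    for p in pauses:
        counts[p.context] += 1
    return counts
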