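"""Keystroke-log parsing: turn an event stream into labeled pause events.

A pause event is the positive latency between two consecutive editor
events.  Each pause is attributed to exactly one of the eight linguistic
contexts by a precedence state machine over the event pair and a small
amount of local text state (the tail of the committed text and the length
of the current backspace run):

1. ``Edit`` — the upcoming event is a cut/paste/replace/cursor-move
   operation.
2. ``SingleBackspace`` — the upcoming key is BACKSPACE and it starts a
   deletion run (the previous event was not a BACKSPACE).
3. ``MultipleBackspace`` — the upcoming key is BACKSPACE continuing a run.
4. ``BackSpace`` — the first keypress after a deletion run ends
   (resume-after-deletion).
5. ``BetweenParagraph`` — the interval spans an ENTER.
6. ``BetweenSentence`` — the committed text ends with ``. ! ?`` plus
   optional spaces.
7. ``BetweenWord`` — the interval spans a SPACE.
8. ``WithinWord`` — anything else before a printing character.

Zero-latency (same-timestamp) intervals are logging artifacts and are
dropped; every positive interval maps to exactly one context, so the
per-context counts partition the intervals.  Classification depends only
on event order, actions and keys — never on the timestamps themselves —
which is what makes an exact generator/parser round trip possible.
"""

from __future__ import annotations

import csv
from typing import Iterable, Iterator, Sequence

from .core import (
    BACKSPACE,
    EDIT_ACTIONS,
    ENTER,
    SPACE,
    ACTIONS,
    KeystrokeEvent,
    PauseEvent,
    ValidationError,
)

_SENTENCE_END = ".!?"


class ParseError(ValueError):
    """Malformed keystroke stream (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class ContextTracker:
    """Incremental classifier over a keystroke stream.

    Feed events in order with :meth:`step`; it returns the context label
    for the interval ending at that event (or ``None`` for the first
    event).  The tracker maintains the last committed-text suffix and the
    backspace run state.  Both the parser and the synthetic log generator
    run this same machine, which is what guarantees their round trip.
    """

    #: length of the committed-text suffix kept for sentence detection
    _TAIL = 16

    def __init__(self) -> None:
        self._prev: KeystrokeEvent | None = None
        self._tail: str = ""

    def _classify(self, prev: KeystrokeEvent, nxt: KeystrokeEvent) -> str:
        if nxt.action in EDIT_ACTIONS:
            return "Edit"
        if nxt.key == BACKSPACE:
            if prev.action == "press" and prev.key == BACKSPACE:
                return "MultipleBackspace"
            return "SingleBackspace"
        if prev.action == "press" and prev.key == BACKSPACE:
            return "BackSpace"
        if (prev.action == "press" and prev.key == ENTER) or nxt.key == ENTER:
            return "BetweenParagraph"
        if self._tail.rstrip(" ").endswith(tuple(_SENTENCE_END)):
            # committed text ends with sentence-final punctuation (+ spaces)
            return "BetweenSentence"
        if (prev.action == "press" and prev.key == SPACE) or nxt.key == SPACE:
            return "BetweenWord"
        return "WithinWord"

    def _commit(self, ev: KeystrokeEvent) -> None:
        if ev.action in EDIT_ACTIONS:
            # document position is unknown after an edit operation
            self._tail = ""
        elif ev.key == BACKSPACE:
            self._tail = self._tail[:-1]
        elif ev.key == SPACE:
            self._tail += " "
        elif ev.key == ENTER:
            self._tail = ""
        else:
            self._tail = (self._tail + ev.key)[-self._TAIL :]
        self._prev = ev

    def step(self, event: KeystrokeEvent) -> str | None:
        """Consume the next event; return the label of the interval that
        ends at it, or ``None`` if this is the first event."""
        label = None
        if self._prev is not None:
            label = self._classify(self._prev, event)
        self._commit(event)
        return label


def classify_context(
    prev_event: KeystrokeEvent, next_event: KeystrokeEvent, committed_tail: str = ""
) -> str:
    """Label the interval between two consecutive events.

    ``committed_tail`` is the trailing committed text before the interval
    (used only to detect sentence boundaries).  Total over valid inputs:
    always returns one of the eight labels.
    """
    tracker = ContextTracker()
    tracker._tail = committed_tail
    return tracker._classify(prev_event, next_event)


def extract_pauses(stream: Sequence[KeystrokeEvent] | Iterable[KeystrokeEvent]) -> list[PauseEvent]:
    """Convert an ordered keystroke stream into labeled pause events.

    One :class:`PauseEvent` per consecutive pair with strictly positive
    latency, in stream order.  Raises :class:`ParseError` naming the line
    number on a timestamp inversion.
    """
    tracker = ContextTracker()
    pauses: list[PauseEvent] = []
    prev_t: int | None = None
    for i, ev in enumerate(stream):
        if ev.action not in ACTIONS:
            raise ParseError(f"unknown action {ev.action!r}", line=i + 1)
        if ev.timestamp_ms < 0:
            raise ParseError("negative timestamp", line=i + 1)
        if prev_t is not None and ev.timestamp_ms < prev_t:
            raise ParseError(
                f"timestamps must be non-decreasing ({ev.timestamp_ms} < {prev_t})", line=i + 1
            )
        latency = None if prev_t is None else ev.timestamp_ms - prev_t
        label = tracker.step(ev)
        if label is not None and latency is not None and latency > 0:
            pauses.append(PauseEvent(label, float(latency)))
        prev_t = ev.timestamp_ms
    return pauses


# ---------------------------------------------------------------------------
# keystroke-log CSV dialect


def write_keystroke_csv(path, stream: Sequence[KeystrokeEvent]) -> None:
    """Write a stream as CSV with columns timestamp_ms, action, key."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp_ms", "action", "key"])
        for ev in stream:
            w.writerow([ev.timestamp_ms, ev.action, ev.key])


def read_keystroke_csv(path) -> list[KeystrokeEvent]:
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        out = []
        for i, row in enumerate(r):
            try:
                out.append(KeystrokeEvent(int(row["timestamp_ms"]), row["action"], row["key"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"malformed row: {exc}", line=i + 2) from exc
    return out
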