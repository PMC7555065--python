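"""Labeled 4-s analysis windows and binary speech vectors built from an annotation.

All intervals are half-open ``[onset, offset)`` in seconds; sample/frame
indexing is 0-based.  Binary frame labels are decided by frame-center
membership so that no boundary frame is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Interval",
    "Annotation",
    "Fragment",
    "FragmentSet",
    "extract_speech_fragments",
    "extract_nonspeech_fragments",
    "extract_noisy_fragments",
    "speech_onoff_vector",
]

FRAME_RATE = 100.0  # Hz; shared time base of all derived series


@dataclass(frozen=True)
class Interval:
    """Half-open time interval ``[onset, offset)`` with an optional label."""

    onset: float
    offset: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"ill-formed interval [{self.onset}, {self.offset})")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def intersects(self, onset: float, offset: float) -> bool:
        return self.onset < offset and onset < self.offset

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.offset


def _sorted(intervals: list[Interval]) -> list[Interval]:
    return sorted(intervals, key=lambda iv: (iv.onset, iv.offset))


@dataclass
class Annotation:
    """Word-level sound annotation with overlap / nonspeech / hand tiers.

    ``words`` holds individual word boundaries, ``overlap`` marks stretches
    where speech co-occurs with music or noise, ``nonspeech`` marks sound
    without any speech, and ``hand`` carries one interval per planned
    fragment window whose label is the hand covariate level ("0", "1", "2").
    """

    words: list[Interval] = field(default_factory=list)
    overlap: list[Interval] = field(default_factory=list)
    nonspeech: list[Interval] = field(default_factory=list)
    hand: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.words = _sorted(self.words)
        self.overlap = _sorted(self.overlap)
        self.nonspeech = _sorted(self.nonspeech)
        self.hand = _sorted(self.hand)

    @property
    def span(self) -> float:
        ends = [iv.offset for tier in (self.words, self.overlap, self.nonspeech, self.hand) for iv in tier]
        return max(ends) if ends else 0.0

    def hand_label_at(self, onset: float, offset: float) -> int | None:
        """Hand covariate of the fragment window that covers [onset, offset)."""
        for iv in self.hand:
            if iv.intersects(onset, offset):
                return int(iv.label)
        return None


@dataclass
class Fragment:
    """One analysis window of fixed duration with a condition label."""

    onset: float
    duration: float
    condition: str  # "speech" | "nonspeech" | "noisy"
    hand_label: int | None = None
    pauses: list[Interval] = field(default_factory=list)

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class FragmentSet:
    fragments: list[Fragment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def by_condition(self, condition: str) -> "FragmentSet":
        return FragmentSet([f for f in self.fragments if f.condition == condition])

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.fragments:
            out[f.condition] = out.get(f.condition, 0) + 1
        return out

    @property
    def total_duration(self) -> float:
        return float(sum(f.duration for f in self.fragments))

    def extend(self, other: "FragmentSet") -> "FragmentSet":
        return FragmentSet(self.fragments + other.fragments)


# ---------------------------------------------------------------------------
# window validity helpers

def _word_gaps_in_window(words: list[Interval], onset: float, offset: float):
    """Pauses between/around words inside [onset, offset).

    Returns (covered, pauses): ``covered`` is False when the window holds no
    word at all; ``pauses`` lists the silent stretches inside the window,
    including any leading/trailing silence.
    """
    inside = [w for w in words if w.intersects(onset, offset)]
    if not inside:
        return False, []
    pauses: list[Interval] = []
    cursor = onset
    for w in inside:
        start = max(w.onset, onset)
        if start - cursor > 1e-9:
            pauses.append(Interval(cursor, start))
        cursor = max(cursor, min(w.offset, offset))
    if offset - cursor > 1e-9:
        pauses.append(Interval(cursor, offset))
    return True, pauses


def _window_is_valid_speech(words, onset, offset, max_pause) -> tuple[bool, list[Interval]]:
    covered, pauses = _word_gaps_in_window(words, onset, offset)
    if not covered:
        return False, []
    ok = all(p.duration <= max_pause + 1e-9 for p in pauses)
    return ok, pauses


def _intersects_any(intervals: list[Interval], onset: float, offset: float) -> bool:
    return any(iv.intersects(onset, offset) for iv in intervals)


def extract_speech_fragments(
    ann: Annotation,
    n_max: int | None = None,
    duration: float = 4.0,
    max_pause: float = 0.5,
    allow_soft_overlap: bool = False,
) -> FragmentSet:
    """Greedy earliest-fit scan for clear-speech windows.

    A window is accepted when it starts at a speech point, every internal
    pause (including trailing silence) is at most ``max_pause`` and it does
    not intersect any overlap interval (unless ``allow_soft_overlap``).
    Accepted windows do not overlap; fewer than ``n_max`` may be returned.
    """
    out: list[Fragment] = []
    if n_max is not None and n_max <= 0:
        return FragmentSet(out)
    onsets = [w.onset for w in ann.words]
    span = ann.span
    max_iter = len(onsets) + int(span / duration) + 10
    cursor = 0.0
    for _ in range(max_iter):
        # candidate start: resume point if inside a word, else next word onset
        inside = next((w for w in ann.words if w.contains(cursor)), None)
        if inside is not None:
            start = cursor
        else:
            nxt = [o for o in onsets if o >= cursor - 1e-9]
            if not nxt:
                break
            start = nxt[0]
        end = start + duration
        ok, pauses = _window_is_valid_speech(ann.words, start, end, max_pause)
        if ok and not allow_soft_overlap and _intersects_any(ann.overlap, start, end):
            ok = False
        if ok:
            out.append(
                Fragment(start, duration, "speech", ann.hand_label_at(start, end), pauses)
            )
            cursor = end
            if n_max is not None and len(out) >= n_max:
                break
        else:
            later = [o for o in onsets if o > start + 1e-9]
            if not later:
                break
            cursor = later[0]
    return FragmentSet(out)


def extract_nonspeech_fragments(
    ann: Annotation, n_match: int | None = None, duration: float = 4.0
) -> FragmentSet:
    """Consecutive word-free windows drawn from the nonspeech sound intervals."""
    out: list[Fragment] = []
    if n_match is not None and n_match <= 0:
        return FragmentSet(out)
    for iv in ann.nonspeech:
        start = iv.onset
        while start + duration <= iv.offset + 1e-9:
            end = start + duration
            if not _intersects_any(ann.words, start, end):
                out.append(Fragment(start, duration, "nonspeech", ann.hand_label_at(start, end)))
                if n_match is not None and len(out) >= n_match:
                    return FragmentSet(out)
            start = end
    return FragmentSet(out)


def extract_noisy_fragments(
    ann: Annotation, duration: float = 4.0, max_pause: float = 0.5
) -> FragmentSet:
    """Speech windows whose words intersect the overlap tier (noisy speech).

    The pause rule is identical to the clear-speech scan; these windows may
    coincide with clear-speech windows in principle (they never do on the
    synthetic annotations, where overlap regions are kept separate).
    """
    out: list[Fragment] = []
    onsets = [w.onset for w in ann.words]
    span = ann.span
    max_iter = len(onsets) + int(span / duration) + 10
    cursor = 0.0
    for _ in range(max_iter):
        inside = next((w for w in ann.words if w.contains(cursor)), None)
        if inside is not None:
            start = cursor
        else:
            nxt = [o for o in onsets if o >= cursor - 1e-9]
            if not nxt:
                break
            start = nxt[0]
        end = start + duration
        ok, pauses = _window_is_valid_speech(ann.words, start, end, max_pause)
        words_in = [w for w in ann.words if w.intersects(start, end)]
        touches_overlap = any(
            _intersects_any(ann.overlap, w.onset, w.offset) for w in words_in
        )
        if ok and touches_overlap:
            out.append(Fragment(start, duration, "noisy", ann.hand_label_at(start, end), pauses))
            cursor = end
        else:
            later = [o for o in onsets if o > start + 1e-9]
            if not later:
                break
            cursor = later[0]
    return FragmentSet(out)


def speech_onoff_vector(
    fragment: Fragment, ann: Annotation, frame_rate: float = FRAME_RATE
) -> np.ndarray:
    """Binary 100 Hz vector: 1 iff the frame center falls inside a word."""
    n = int(round(fragment.duration * frame_rate))
    centers = fragment.onset + (np.arange(n) + 0.5) / frame_rate
    if not ann.words:
        return np.zeros(n, dtype=np.int8)
    onsets = np.array([w.onset for w in ann.words])
    offsets = np.array([w.offset for w in ann.words])
    idx = np.searchsorted(onsets, centers, side="right") - 1
    on = (idx >= 0) & (centers < offsets[np.clip(idx, 0, None)])
    return on.astype(np.int8)
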