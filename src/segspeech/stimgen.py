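"""Artificial-language stimulus construction for statistical-learning streams.

Builds the two four-word artificial languages (tri-syllabic CV pseudo-words,
350 ms per syllable), assigns flat (216 Hz) or melodic (one tone per syllable)
pitch, and generates the continuous learning and implicit-test streams in which
the only systematic word-boundary cue is the drop in transitional probability
(1.0 within words, 1/3 across boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

SYLLABLE_MS = 350.0
FLAT_PITCH_HZ = 216.0

# Printed word inventories of the two languages.
L1_WORDS = ("KUPOTE", "DOGUKI", "TAPIKO", "DAGOPE")
L2_WORDS = ("TUGODE", "PAGODI", "DUGAKE", "KATIPU")

# Melodic tone map of L1 (note names, scientific pitch).
L1_MELODIC_NOTES: dict[str, tuple[str, str, str]] = {
    "KUPOTE": ("D4", "C4", "G3"),
    "DOGUKI": ("Db4", "A3", "E3"),
    "TAPIKO": ("B3", "E4", "F4"),
    "DAGOPE": ("C3", "D3", "F3"),
}

# The L2 tone map is not printed anywhere; this package's convention keeps the
# printed syllabification (note that GO occurs in two L2 words and must carry
# the same tone), uses C-major tones only, and yields 2 rising + 2 falling
# contours, mirroring the L1 design.
L2_MELODIC_NOTES: dict[str, tuple[str, str, str]] = {
    "TUGODE": ("C3", "G3", "B3"),
    "PAGODI": ("E4", "G3", "D3"),
    "DUGAKE": ("C4", "D4", "F4"),
    "KATIPU": ("A4", "G4", "E3"),
}


class StimulusError(ValueError):
    """Raised for invalid language specifications or unsatisfiable streams."""


# ---------------------------------------------------------------------------
# Pitch utilities
# ---------------------------------------------------------------------------

_NOTE_SEMITONES = {"C": -9, "D": -7, "E": -5, "F": -4, "G": -2, "A": 0, "B": 2}


def note_to_hz(note: str, reference_a4: float = 440.0) -> float:
    """Convert scientific pitch notation (e.g. ``"Db4"``) to Hz.

    Equal temperament relative to A4 = `reference_a4`. Accidentals ``#``/``b``
    (also ``s``/``f``) are supported, possibly repeated.
    """
    s = note.strip()
    if not s:
        raise StimulusError("empty note name")
    letter = s[0].upper()
    if letter not in _NOTE_SEMITONES:
        raise StimulusError(f"unparseable note {note!r}")
    i = 1
    acc = 0
    while i < len(s) and s[i] in "#b sf♯♭":
        c = s[i]
        if c in "#s♯":
            acc += 1
        elif c in "bf♭":
            acc -= 1
        i += 1
    try:
        octave = int(s[i:])
    except ValueError as exc:
        raise StimulusError(f"unparseable note {note!r}") from exc
    semitones = _NOTE_SEMITONES[letter] + acc + 12 * (octave - 4)
    return reference_a4 * 2.0 ** (semitones / 12.0)


def semitone_interval(hz_from: float, hz_to: float) -> float:
    """Signed interval in equal-tempered semitones."""
    return 12.0 * math.log2(hz_to / hz_from)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Syllable:
    label: str
    duration_ms: float = SYLLABLE_MS
    pitch_hz: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise StimulusError("syllable label must be nonempty")
        if self.duration_ms <= 0:
            raise StimulusError("syllable duration must be positive")


@dataclass(frozen=True)
class PseudoWord:
    id: str
    syllables: tuple[str, str, str]
    legality: str = "legal"  # {"legal", "illegal"}
    source_word: str = ""

    def __post_init__(self) -> None:
        if len(self.syllables) != 3:
            raise StimulusError(f"word {self.id!r} must have exactly 3 syllables")
        if self.legality == "illegal" and not self.source_word:
            raise StimulusError("illegal word must name its source word")


@dataclass(frozen=True)
class Language:
    id: str
    words: tuple[PseudoWord, ...]
    pitch_map: Mapping[str, float] | None = None  # syllable label -> Hz
    note_map: Mapping[str, str] | None = None  # syllable label -> note name
    condition: str | None = None  # {"flat", "melodic"} once pitched

    @property
    def inventory(self) -> tuple[str, ...]:
        seen: list[str] = []
        for w in self.words:
            for s in w.syllables:
                if s not in seen:
                    seen.append(s)
        return tuple(seen)

    def word(self, word_id: str) -> PseudoWord:
        for w in self.words:
            if w.id == word_id:
                return w
        raise KeyError(word_id)


@dataclass(frozen=True)
class StreamEvent:
    onset_ms: float
    syllable: str
    pitch_hz: float
    word_token_index: int
    word_id: str
    position_in_word: int  # 1..3
    legality: str


@dataclass(frozen=True)
class Stream:
    events: tuple[StreamEvent, ...]
    condition: str
    phase: str  # {"learning", "test"}
    language_id: str

    @property
    def total_duration_ms(self) -> float:
        return len(self.events) * SYLLABLE_MS

    @property
    def n_word_tokens(self) -> int:
        return len(self.events) // 3

    def word_token_ids(self) -> list[str]:
        return [e.word_id for e in self.events if e.position_in_word == 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_ms": [e.onset_ms for e in self.events],
                "duration_ms": SYLLABLE_MS,
                "syllable": [e.syllable for e in self.events],
                "pitch_hz": [e.pitch_hz for e in self.events],
                "word_id": [e.word_id for e in self.events],
                "token_index": [e.word_token_index for e in self.events],
                "position": [e.position_in_word for e in self.events],
                "legality": [e.legality for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Language construction
# ---------------------------------------------------------------------------

def split_cv_word(word: str) -> tuple[str, str, str]:
    """Split a 6-letter word into its three CV syllables."""
    if len(word) != 6:
        raise StimulusError(f"cannot split {word!r} into 3 CV syllables")
    return (word[0:2], word[2:4], word[4:6])


def build_language(
    word_specs: Sequence[str] | Mapping[str, Sequence[str]] | None = None,
    id: str = "L1",
    strict: bool = True,
) -> Language:
    """Build a validated 4-word language.

    `word_specs` may be 6-letter strings (CV-split automatically) or a mapping
    of word id to its 3 syllables. With no specs, the printed default words of
    `id` (L1 or L2) are used. `strict` enforces that no syllable occurs in two
    words — true of L1, but the printed L2 reuses GO, so the default L2 is
    built with ``strict=False``.
    """
    if word_specs is None:
        if id == "L1":
            word_specs = L1_WORDS
        elif id == "L2":
            word_specs = L2_WORDS
            strict = False
        else:
            raise StimulusError(f"no default words for language {id!r}")
    if isinstance(word_specs, Mapping):
        items = [(wid, tuple(syls)) for wid, syls in word_specs.items()]
    else:
        items = [(w, split_cv_word(w)) for w in word_specs]
    if len(items) != 4:
        raise StimulusError(f"a language needs exactly 4 words, got {len(items)}")
    words = []
    for wid, syls in items:
        if len(syls) != 3:
            raise StimulusError(f"word {wid!r} must have 3 syllables")
        words.append(PseudoWord(id=wid, syllables=tuple(syls)))
    all_syls = [s for w in words for s in w.syllables]
    if strict and len(set(all_syls)) != len(all_syls):
        dupes = sorted({s for s in all_syls if all_syls.count(s) > 1})
        raise StimulusError(f"duplicate syllables across words: {dupes}")
    return Language(id=id, words=tuple(words))


def reverse_word(word: PseudoWord) -> PseudoWord:
    """Syllable-reversed (illegal) counterpart of a legal word: ABC -> CBA."""
    syls = (word.syllables[2], word.syllables[1], word.syllables[0])
    if word.legality == "illegal":
        # Involution: reversing an illegal item restores its source word.
        return PseudoWord(id=word.source_word, syllables=syls)
    return PseudoWord(id="".join(syls), syllables=syls, legality="illegal",
                      source_word=word.id)


def assign_pitches(language: Language, condition: str,
                   note_map: Mapping[str, Sequence[str]] | None = None) -> Language:
    """Return the language with its pitch map set.

    Flat: every syllable at 216 Hz. Melodic: one tone per syllable from the
    language's note map (printed for L1, this package's C-major convention for
    L2), or a user-supplied ``word id -> 3 note names`` mapping.
    """
    if condition == "flat":
        pm = {s: FLAT_PITCH_HZ for s in language.inventory}
        return replace(language, pitch_map=pm, note_map=None, condition="flat")
    if condition != "melodic":
        raise StimulusError(f"unknown condition {condition!r}")
    if note_map is None:
        if language.id == "L1":
            note_map = L1_MELODIC_NOTES
        elif language.id == "L2":
            note_map = L2_MELODIC_NOTES
        else:
            raise StimulusError(f"no default melodic map for {language.id!r}")
    syl_notes: dict[str, str] = {}
    for w in language.words:
        try:
            notes = note_map[w.id]
        except KeyError as exc:
            raise StimulusError(f"no notes for word {w.id!r}") from exc
        for syl, note in zip(w.syllables, notes):
            if syl in syl_notes and syl_notes[syl] != note:
                raise StimulusError(
                    f"syllable {syl!r} mapped to both {syl_notes[syl]!r} and {note!r}"
                )
            syl_notes[syl] = note
    pm = {s: note_to_hz(n) for s, n in syl_notes.items()}
    if len(set(round(v, 6) for v in pm.values())) != len(pm):
        raise StimulusError("melodic pitch map is not one tone per syllable")
    return replace(language, pitch_map=pm, note_map=syl_notes, condition="melodic")


def contour_of(word: PseudoWord, pitch_map: Mapping[str, float]) -> str:
    """Pitch contour of a word: rising / falling / flat / mixed."""
    f = [pitch_map[s] for s in word.syllables]
    d1, d2 = f[1] - f[0], f[2] - f[1]
    if d1 == 0 and d2 == 0:
        return "flat"
    if d1 > 0 and d2 > 0:
        return "rising"
    if d1 < 0 and d2 < 0:
        return "falling"
    return "mixed"


# ---------------------------------------------------------------------------
# Stream generation
# ---------------------------------------------------------------------------

def _constrained_word_sequence(word_ids: Sequence[str], reps: Mapping[str, int],
                               rng: np.random.Generator,
                               max_restarts: int = 1000) -> list[str]:
    """Random word-token sequence with exact counts, no item twice in a row.

    Next token drawn uniformly among words != previous with remaining count;
    dead ends restart the draw (rare for balanced counts).
    """
    total = sum(reps.values())
    if max(reps.values()) > total - max(reps.values()) + 1:
        raise StimulusError("impossible: one word outnumbers all others + 1")
    ids = list(word_ids)
    for _ in range(max_restarts):
        counts = dict(reps)
        seq: list[str] = []
        prev = None
        ok = True
        for _ in range(total):
            options = [w for w in ids if w != prev and counts[w] > 0]
            if not options:
                ok = False
                break
            w = options[rng.integers(len(options))]
            seq.append(w)
            counts[w] -= 1
            prev = w
        if ok:
            return seq
    raise StimulusError("could not satisfy no-repeat constraint (exhausted restarts)")


def _events_from_tokens(tokens: Sequence[PseudoWord], pitch_map: Mapping[str, float]
                        ) -> tuple[StreamEvent, ...]:
    events: list[StreamEvent] = []
    k = 0
    for ti, w in enumerate(tokens):
        for pos, syl in enumerate(w.syllables, start=1):
            events.append(StreamEvent(
                onset_ms=k * SYLLABLE_MS,
                syllable=syl,
                pitch_hz=float(pitch_map[syl]),
                word_token_index=ti,
                word_id=w.id,
                position_in_word=pos,
                legality=w.legality,
            ))
            k += 1
    return tuple(events)


def _require_pitched(language: Language) -> Language:
    if language.pitch_map is None:
        return assign_pitches(language, "flat")
    return language


def generate_learning_stream(language: Language, reps: int = 50,
                             seed: int | None = 0) -> Stream:
    """Continuous learning stream: `reps` tokens of each word, randomly
    concatenated with no immediate repetition; syllable onsets on the 350 ms
    grid. Defaults give 200 word tokens / 600 syllables / 210 s."""
    if reps < 1:
        raise StimulusError("reps must be >= 1")
    language = _require_pitched(language)
    rng = np.random.default_rng(seed)
    word_ids = [w.id for w in language.words]
    seq = _constrained_word_sequence(word_ids, {w: reps for w in word_ids}, rng)
    tokens = [language.word(wid) for wid in seq]
    return Stream(events=_events_from_tokens(tokens, language.pitch_map),
                  condition=language.condition or "flat", phase="learning",
                  language_id=language.id)


def generate_test_stream(language: Language, legal_reps: int = 66,
                         illegal_reps: int = 22, seed: int | None = 0,
                         max_tries: int = 100_000) -> Stream:
    """Implicit-test stream: legal words plus syllable-reversed illegal items.

    The legal backbone is generated like a learning stream; each illegal token
    is then inserted at a uniformly random position, re-drawing any insertion
    that would put an illegal item right after its source word or any item
    right after an identical one. Defaults (66/22 per word) give 352 tokens,
    25% illegal.
    """
    if legal_reps < 1 or illegal_reps < 0:
        raise StimulusError("repetition counts must be positive")
    language = _require_pitched(language)
    rng = np.random.default_rng(seed)
    word_ids = [w.id for w in language.words]
    seq = _constrained_word_sequence(word_ids, {w: legal_reps for w in word_ids}, rng)
    tokens: list[PseudoWord] = [language.word(wid) for wid in seq]

    illegal = [reverse_word(w) for w in language.words]
    pitch_map = dict(language.pitch_map)
    # Reversal introduces no new syllables, so the pitch map carries over.

    to_insert = [iw for iw in illegal for _ in range(illegal_reps)]
    order = rng.permutation(len(to_insert))
    tries = 0
    for idx in order:
        iw = to_insert[idx]
        while True:
            tries += 1
            if tries > max_tries:
                raise StimulusError(
                    f"unsatisfiable illegal-item insertion after {max_tries} tries "
                    f"(seed context: {seed!r})")
            pos = int(rng.integers(len(tokens) + 1))
            prev = tokens[pos - 1] if pos > 0 else None
            nxt = tokens[pos] if pos < len(tokens) else None
            if prev is not None and prev.id in (iw.id, iw.source_word):
                continue
            if nxt is not None and nxt.id == iw.id:
                continue
            tokens.insert(pos, iw)
            break
    return Stream(events=_events_from_tokens(tokens, pitch_map),
                  condition=language.condition or "flat", phase="test",
                  language_id=language.id)


# ---------------------------------------------------------------------------
# Stream statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """Empirical syllable-bigram transition probabilities of a stream."""
    probabilities: Mapping[tuple[str, str], float]
    counts: Mapping[tuple[str, str], int]

    def prob(self, a: str, b: str) -> float:
        return self.probabilities.get((a, b), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "n": self.counts[(a, b)], "p": p}
            for (a, b), p in sorted(self.probabilities.items())
        ]
        return pd.DataFrame(rows)


def transition_matrix(stream: Stream) -> TransitionMatrix:
    """Empirical conditional probability of each observed syllable bigram."""
    syls = [e.syllable for e in stream.events]
    if len(syls) < 2:
        raise StimulusError("need at least 2 events for transition probabilities")
    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for a, b in zip(syls[:-1], syls[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
        totals[a] = totals.get(a, 0) + 1
    probs = {(a, b): n / totals[a] for (a, b), n in counts.items()}
    return TransitionMatrix(probabilities=probs, counts=counts)


def within_word_bigrams(language: Language) -> list[tuple[str, str]]:
    out = []
    for w in language.words:
        out.append((w.syllables[0], w.syllables[1]))
        out.append((w.syllables[1], w.syllables[2]))
    return out


def boundary_tp_summary(stream: Stream, language: Language | None = None
                        ) -> pd.DataFrame:
    """Empirical TP of every word-boundary bigram in a stream (per word-final
    syllable, each observed successor)."""
    tm = transition_matrix(stream)
    within = set()
    finals = set()
    # Reconstruct word forms from the stream itself (covers illegal items).
    forms: dict[str, list[str]] = {}
    for e in stream.events:
        forms.setdefault(e.word_id, ["", "", ""])[e.position_in_word - 1] = e.syllable
    for wid, syls in forms.items():
        within.add((syls[0], syls[1]))
        within.add((syls[1], syls[2]))
        finals.add(syls[2])
    rows = []
    for (a, b), p in tm.probabilities.items():
        if a in finals and (a, b) not in within:
            rows.append({"from": a, "to": b, "n": tm.counts[(a, b)], "p": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IntervalStats:
    mean_abs_within: float
    mean_abs_between: float
    within_intervals: tuple[float, ...]
    between_intervals: tuple[float, ...]
    t: float
    p: float


def interval_stats(language: Language, stream: Stream | None = None,
                   all_pairs: bool = False) -> IntervalStats:
    """Within-word vs. between-word absolute pitch intervals (semitones).

    Within: the 8 adjacent-syllable steps inside the 4 words. Between: steps
    across word boundaries — either the boundary bigrams observed in `stream`
    (token-weighted) or, with ``all_pairs=True``, the 12 ordered word pairs.
    Flat languages have all-zero intervals; the comparison is then undefined.
    """
    if language.pitch_map is None:
        raise StimulusError("assign pitches before computing interval stats")
    pm = language.pitch_map
    within = []
    for w in language.words:
        f = [pm[s] for s in w.syllables]
        within.append(semitone_interval(f[0], f[1]))
        within.append(semitone_interval(f[1], f[2]))
    between: list[float] = []
    if all_pairs or stream is None:
        for w1 in language.words:
            for w2 in language.words:
                if w1.id == w2.id:
                    continue
                between.append(semitone_interval(pm[w1.syllables[2]],
                                                 pm[w2.syllables[0]]))
    else:
        toks = stream.word_token_ids()
        forms = {w.id: w.syllables for w in language.words}
        for a, b in zip(toks[:-1], toks[1:]):
            between.append(semitone_interval(pm[forms[a][2]], pm[forms[b][0]]))
    aw = np.abs(within)
    ab = np.abs(between)
    if np.allclose(aw, 0) and np.allclose(ab, 0):
        raise StimulusError("all intervals are zero (flat condition); "
                            "comparison undefined")
    t, p = _sps.ttest_ind(aw, ab, equal_var=False)
    return IntervalStats(
        mean_abs_within=float(aw.mean()),
        mean_abs_between=float(ab.mean()),
        within_intervals=tuple(float(x) for x in within),
        between_intervals=tuple(float(x) for x in between),
        t=float(t), p=float(p),
    )


# ---------------------------------------------------------------------------
# Optional demonstration rendering
# ---------------------------------------------------------------------------

def render_sine_wav(stream: Stream, path, sample_rate: int = 16000,
                    amplitude: float = 0.5) -> None:
    """Render a stream as 16-bit PCM sine tones (demonstration only)."""
    from scipy.io import wavfile

    n = int(round(stream.total_duration_ms / 1000.0 * sample_rate))
    out = np.zeros(n, dtype=np.float64)
    for e in stream.events:
        i0 = int(round(e.onset_ms / 1000.0 * sample_rate))
        i1 = min(n, i0 + int(round(SYLLABLE_MS / 1000.0 * sample_rate)))
        t = np.arange(i1 - i0) / sample_rate
        seg = np.sin(2 * np.pi * e.pitch_hz * t)
        ramp = min(80, len(seg) // 4)
        if ramp:
            w = np.linspace(0, 1, ramp)
            seg[:ramp] *= w
            seg[-ramp:] *= w[::-1]
        out[i0:i1] = seg
    wavfile.write(path, sample_rate, (amplitude * out * 32767).astype(np.int16))
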