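"""Synthetic lexicons and narratives with known emotion-dynamics structure.

The generator emulates a turn-structured multi-speaker narrative whose
valence-arousal path is a mean-reverting baseline around a home center
with injected displacement events of known amplitude and duration.  Each
event is a piecewise-linear bump: a linear rise over ``rise`` words, a
hold at full amplitude for ``hold`` words and a linear recovery over
``recovery`` words — ramps keep the injected rise/recovery word counts
exact integers, which makes rate-recovery tests sharp.

Words are emitted by nearest-neighbour lookup into a synthetic lexicon
laid out on a uniform lattice over [0.05, 0.95]^2, so the ground-truth
path is recoverable up to lattice quantization (error at most
spacing/sqrt(2)).  All randomness flows from the spec-level seed through
a named generator; the same seed yields byte-identical transcripts.

Default study conditions (one focal speaker): home center (0.5, 0.5),
baseline noise SD 0.03, 600 focal words, three amplitude-0.3 events
(about 10 baseline SDs) at 25% / 50% / 85% of the narrative with
rise = hold = recovery = 10 words and inter-event gaps of at least three
rolling windows.  The event directions sketch a story arc: a
positive-valence lift early, an arousal surge mid-story and a
negative-valence climax near 85%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .lexicons import CategoricalLexicon, DimensionalLexicon
from .transcripts import Turn

__all__ = [
    "DisplacementEvent",
    "NarrativeSpec",
    "GroundTruth",
    "make_lexicon",
    "make_narrative",
    "make_corpus",
    "default_spec",
]


@dataclass
class DisplacementEvent:
    """One injected excursion: deviation ramps 0 -> (dv, da) -> 0.

    ``start`` is the focal-word ordinal where the rise begins (deviation
    is still zero there); full amplitude is first reached at
    ``start + rise`` and last held at ``start + rise + hold``; the path is
    back at baseline at ``start + rise + hold + recovery``.
    """

    start: int
    dv: float
    da: float
    rise: int = 10
    hold: int = 10
    recovery: int = 10

    @property
    def peak(self) -> int:
        return self.start + self.rise

    @property
    def offset(self) -> int:
        return self.start + self.rise + self.hold + self.recovery

    @property
    def amplitude(self) -> float:
        return math.hypot(self.dv, self.da)


@dataclass
class NarrativeSpec:
    """Generative recipe for one focal speaker's narrative."""

    center: tuple[float, float] = (0.5, 0.5)
    sigma: float = 0.03  # baseline noise SD per word, per dimension
    n_words: int = 600  # focal-speaker word count
    events: list[DisplacementEvent] = field(default_factory=list)
    mean_turn_words: float = 8.0
    window: int = 10  # rolling window the events must be separated against
    seed: int = 0
    speaker: str = "S1"
    filler_speaker: str = "OTHER"
    movie_id: str = "m1"

    def validate(self) -> None:
        if self.n_words < 1:
            raise ValueError("n_words must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.mean_turn_words < 1:
            raise ValueError("mean_turn_words must be >= 1")
        events = sorted(self.events, key=lambda e: e.start)
        prev_end = None
        for ev in events:
            if min(ev.rise, ev.hold, ev.recovery) < 0 or ev.rise < 1 or ev.recovery < 1:
                raise ValueError("event rise/recovery must be >= 1, hold >= 0")
            if ev.start < 0 or ev.offset >= self.n_words:
                raise ValueError(f"event at {ev.start} extends past the narrative")
            for val in (
                self.center[0] + ev.dv,
                self.center[1] + ev.da,
                self.center[0],
                self.center[1],
            ):
                if not 0.0 <= val <= 1.0:
                    raise ValueError("event pushes the path outside [0, 1]^2")
            if prev_end is not None and ev.start - prev_end < 3 * self.window:
                raise ValueError(
                    f"events closer than 3x window ({ev.start - prev_end} < {3 * self.window})"
                )
            prev_end = ev.offset


@dataclass
class GroundTruth:
    """Noise-free target path and the injected event records."""

    speaker: str
    movie_id: str
    center: tuple[float, float]
    sigma: float
    path: np.ndarray  # (n_words, 2) noise-free (v, a) targets
    events: list[DisplacementEvent]

    def to_record(self) -> dict:
        return {
            "speaker": self.speaker,
            "movie_id": self.movie_id,
            "center": list(self.center),
            "sigma": self.sigma,
            "events": [
                {
                    "onset": e.start,
                    "peak": e.peak,
                    "offset": e.offset,
                    "dv": e.dv,
                    "da": e.da,
                    "rise": e.rise,
                    "hold": e.hold,
                    "recovery": e.recovery,
                }
                for e in self.events
            ],
        }


def default_spec(seed: int = 0, speaker: str = "S1", movie_id: str = "m1") -> NarrativeSpec:
    """The default study conditions (see module docstring)."""
    return NarrativeSpec(
        events=[
            DisplacementEvent(start=150, dv=0.3, da=0.0),
            DisplacementEvent(start=300, dv=0.0, da=0.3),
            DisplacementEvent(start=510, dv=-0.3, da=0.15),
        ],
        seed=seed,
        speaker=speaker,
        movie_id=movie_id,
    )


def make_lexicon(n_words: int = 2500, seed: int = 0) -> tuple[DimensionalLexicon, CategoricalLexicon]:
    """Synthetic lexicon pair on a uniform (v, a) lattice over [0.05, 0.95]^2.

    Emits the largest ``side x side`` lattice with ``side**2 <= n_words``
    (every score pair unique); ``n_words`` below 25 cannot cover a 5x5
    lattice and raises.  Categorical flags are deterministic thresholds:
    valence >= 0.7 -> positive + joy; valence <= 0.3 -> negative, plus
    anger + fear when arousal >= 0.7.  The layout is deterministic;
    ``seed`` is accepted for interface symmetry.
    """
    del seed  # lattice layout is fully deterministic
    side = math.isqrt(n_words)
    if side < 5:
        raise ValueError(f"n_words={n_words} too small to cover a 5x5 lattice")
    coords = np.linspace(0.05, 0.95, side)
    dim_entries: dict[str, tuple[float, float, float]] = {}
    cat_entries: dict[str, frozenset[str]] = {}
    i = 0
    for v in coords:
        for a in coords:
            word = f"w{i:05d}"
            dim_entries[word] = (float(v), float(a), 0.5)
            flags = set()
            if v >= 0.7:
                flags |= {"positive", "joy"}
            if v <= 0.3:
                flags.add("negative")
                if a >= 0.7:
                    flags |= {"anger", "fear"}
            cat_entries[word] = frozenset(flags)
            i += 1
    return (
        DimensionalLexicon(entries=dim_entries, source=f"synthetic-lattice-{side}x{side}"),
        CategoricalLexicon(entries=cat_entries, source=f"synthetic-lattice-{side}x{side}"),
    )


def _target_path(spec: NarrativeSpec) -> np.ndarray:
    """Noise-free piecewise-linear (v, a) path of a spec."""
    path = np.tile(np.asarray(spec.center, dtype=float), (spec.n_words, 1))
    for ev in sorted(spec.events, key=lambda e: e.start):
        amp = np.array([ev.dv, ev.da])
        for i in range(ev.start, min(ev.offset + 1, spec.n_words)):
            if i <= ev.peak:
                frac = (i - ev.start) / ev.rise
            elif i <= ev.peak + ev.hold:
                frac = 1.0
            else:
                frac = 1.0 - (i - ev.peak - ev.hold) / ev.recovery
            path[i] += amp * frac
    return path


class _Emitter:
    """Nearest-lexicon-word emission (lowest insertion index wins ties)."""

    def __init__(self, lexicon: DimensionalLexicon):
        self.words = list(lexicon.entries.keys())
        pts = np.array([[v, a] for v, a, _ in lexicon.entries.values()])
        self.tree = cKDTree(pts)

    def emit(self, targets: np.ndarray) -> list[str]:
        _, idx = self.tree.query(targets)
        return [self.words[i] for i in np.atleast_1d(idx)]


def _token_stream(
    spec: NarrativeSpec, lexicon: DimensionalLexicon, rng: np.random.Generator
) -> tuple[list[str], GroundTruth]:
    path = _target_path(spec)
    noisy = np.clip(path + rng.normal(0.0, spec.sigma, size=path.shape), 0.0, 1.0)
    tokens = _Emitter(lexicon).emit(noisy)
    truth = GroundTruth(
        speaker=spec.speaker,
        movie_id=spec.movie_id,
        center=spec.center,
        sigma=spec.sigma,
        path=path,
        events=sorted(spec.events, key=lambda e: e.start),
    )
    return tokens, truth


def _turn_lengths(n: int, mean: float, rng: np.random.Generator) -> list[int]:
    """Geometric (>=1) turn lengths consuming exactly n words."""
    lengths: list[int] = []
    left = n
    p = 1.0 / mean
    while left > 0:
        length = min(int(rng.geometric(p)), left)
        lengths.append(length)
        left -= length
    return lengths


def _interleave(
    streams: dict[str, list[str]],
    mean_turn_words: float,
    movie_id: str,
    rng: np.random.Generator,
) -> list[Turn]:
    """Interleave the speakers' token streams into alternating turns.

    The next turn always goes to the speaker who is proportionally
    furthest behind in their stream (ties by speaker order), so all
    speakers span the whole movie rather than one finishing early.
    """
    cursors = {s: 0 for s in streams}
    order = list(streams.keys())
    turns: list[Turn] = []
    while any(cursors[s] < len(streams[s]) for s in order):
        behind = [s for s in order if cursors[s] < len(streams[s])]
        speaker = min(behind, key=lambda s: (cursors[s] / len(streams[s]), order.index(s)))
        tokens = streams[speaker]
        i = cursors[speaker]
        length = min(int(rng.geometric(1.0 / mean_turn_words)), len(tokens) - i)
        chunk = tokens[i : i + length]
        cursors[speaker] = i + length
        turns.append(
            Turn(
                movie_id=movie_id,
                turn_index=len(turns),
                speaker=speaker,
                text=" ".join(chunk),
                tokens=list(chunk),
            )
        )
    return turns


def make_narrative(
    spec: NarrativeSpec, lexicon: DimensionalLexicon
) -> tuple[list[Turn], GroundTruth]:
    """Generate one movie: the focal speaker interleaved with a filler.

    The filler speaker hovers at the focal speaker's home center with the
    same baseline noise and no events, so the focal speaker's movie-global
    time axis is realistic but the filler carries no structure.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    focal_tokens, truth = _token_stream(spec, lexicon, rng)
    filler_spec = replace(
        spec, events=[], speaker=spec.filler_speaker, n_words=spec.n_words
    )
    filler_targets = np.clip(
        np.tile(np.asarray(spec.center), (filler_spec.n_words, 1))
        + rng.normal(0.0, spec.sigma, size=(filler_spec.n_words, 2)),
        0.0,
        1.0,
    )
    filler_tokens = _Emitter(lexicon).emit(filler_targets)
    turns = _interleave(
        {spec.speaker: focal_tokens, spec.filler_speaker: filler_tokens},
        spec.mean_turn_words,
        spec.movie_id,
        rng,
    )
    return turns, truth


def _spawn_spec(
    template: NarrativeSpec, rng: np.random.Generator, speaker: str, movie_id: str
) -> NarrativeSpec:
    """Independent per-speaker variation of a template spec.

    Event amplitude vectors are rotated by a small random angle
    (SD 15 degrees) and onsets jittered by up to half a window, keeping
    the template's story-arc structure while decorrelating speakers.
    """
    events = []
    for ev in sorted(template.events, key=lambda e: e.start):
        ang = rng.normal(0.0, np.deg2rad(15.0))
        c, s = np.cos(ang), np.sin(ang)
        dv = c * ev.dv - s * ev.da
        da = s * ev.dv + c * ev.da
        jitter = int(rng.integers(-template.window // 2, template.window // 2 + 1))
        events.append(replace(ev, start=ev.start + jitter, dv=float(dv), da=float(da)))
    return replace(
        template,
        events=events,
        seed=int(rng.integers(0, 2**31 - 1)),
        speaker=speaker,
        movie_id=movie_id,
    )


def make_corpus(
    n_speakers: int,
    template: NarrativeSpec | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> dict[str, Path]:
    """Write a synthetic corpus: one movie per pair of focal speakers.

    Each movie interleaves two focal speakers with independently drawn
    specs, so both span the whole movie and form an eligible pair for
    discordance.  Writes the transcript TSV dialect, both lexicon TSV
    dialects and a ground-truth JSON sidecar; returns their paths.
    """
    if n_speakers < 2 or n_speakers % 2:
        raise ValueError("n_speakers must be an even number >= 2")
    template = template if template is not None else default_spec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    vad_lex, emo_lex = make_lexicon()

    rows: list[str] = []
    truths: list[dict] = []
    for m in range(n_speakers // 2):
        movie_id = f"m{m + 1:03d}"
        speakers = (f"S{2 * m + 1:03d}", f"S{2 * m + 2:03d}")
        streams: dict[str, list[str]] = {}
        for speaker in speakers:
            sp = _spawn_spec(template, master, speaker, movie_id)
            sp.validate()
            tokens, truth = _token_stream(sp, vad_lex, np.random.default_rng(sp.seed))
            streams[speaker] = tokens
            truths.append(truth.to_record())
        turns = _interleave(streams, template.mean_turn_words, movie_id, master)
        for turn in turns:
            rows.append(f"{movie_id}\t{turn.turn_index}\t{turn.speaker}\t{turn.text}\n")

    paths = {
        "transcript": out_dir / "transcript.tsv",
        "vad_lexicon": out_dir / "vad_lexicon.tsv",
        "emotion_lexicon": out_dir / "emotion_lexicon.tsv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    with open(paths["transcript"], "w", encoding="utf-8") as fh:
        fh.writelines(rows)
    vad_lex.to_tsv(paths["vad_lexicon"])
    emo_lex.to_tsv(paths["emotion_lexicon"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump({"speakers": truths}, fh, indent=1)
    return paths
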