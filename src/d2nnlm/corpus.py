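"""Reading, tokenizing, and splitting labeled speech-transcript collections.

A *transcript* is one participant's picture-description speech: an ordered
list of sentences, each a sequence of lowercased word tokens, labeled either
``positive`` (the impaired group, e.g. MCI or AD-type dementia) or
``control``.  Two on-disk formats are read:

* ``plain`` — UTF-8 text, one sentence per line;
* ``chat_minimal`` — a minimal dialect of the TalkBank CHAT transcription
  format that keeps only speaker-prefixed utterance lines (``*PAR:`` by
  default), drops dependent tiers (``%mor:`` etc.) and bracketed annotation
  codes, and strips non-word symbols before tokenization.  Full CHAT is
  deliberately out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

POSITIVE = "positive"
CONTROL = "control"
LABELS = (POSITIVE, CONTROL)

Label = Literal["positive", "control"]

# a token is a maximal run of word characters, allowing internal apostrophes
# and hyphens ("don't", "mother-in-law")
_TOKEN_RE = re.compile(r"[\w]+(?:['\-][\w]+)*")

# CHAT bracketed codes like [: jar], [//], [+ exc]; non-nested
_CHAT_BRACKET_RE = re.compile(r"\[[^\]]*\]")
# CHAT angle-bracket retracing groups keep their words, only <> are dropped
_CHAT_ANGLE_RE = re.compile(r"[<>]")
# fillers / special-form markers: &uh, &=laughs, +..., xxx handled by token rule
_CHAT_SPECIAL_RE = re.compile(r"(?:&=?\S+|\+\S+)")


@dataclass
class Transcript:
    """One participant's labeled utterances as tokenized sentences."""

    id: str
    label: Label
    sentences: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        for sent in self.sentences:
            if len(sent) == 0:
                raise ValueError(f"transcript {self.id!r}: empty sentence")
            for tok in sent:
                if not tok or any(ch.isspace() for ch in tok):
                    raise ValueError(
                        f"transcript {self.id!r}: token {tok!r} contains whitespace"
                    )

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def to_plain(self) -> str:
        """Serialize to the plain one-sentence-per-line format."""
        return "".join(" ".join(s) + "\n" for s in self.sentences)


@dataclass(frozen=True)
class DatasetSplit:
    """A seeded, stratified partition of transcript ids into train/test/validation."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    proportions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.test_ids), set(self.validation_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split id sets are not disjoint")

    def subset(self, transcripts: Sequence[Transcript], part: str) -> list[Transcript]:
        ids = {"train": self.train_ids, "test": self.test_ids,
               "validation": self.validation_ids}[part]
        wanted = set(ids)
        return [t for t in transcripts if t.id in wanted]


def tokenize(text: str) -> list[str]:
    """Lowercase and split a sentence into word tokens.

    Leading/trailing punctuation is stripped; internal apostrophes and
    hyphens are preserved (``"don't stop"`` -> ``["don't", "stop"]``).
    May return an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def _clean_chat_utterance(line: str) -> str:
    """Strip CHAT annotation codes from one utterance body."""
    line = _CHAT_BRACKET_RE.sub(" ", line)
    line = _CHAT_SPECIAL_RE.sub(" ", line)
    line = _CHAT_ANGLE_RE.sub(" ", line)
    return line


def _parse_chat(text: str, speakers: tuple[str, ...]) -> list[list[str]]:
    """Extract tokenized utterances of the given speakers from CHAT text.

    Only ``*XXX:``-prefixed main tiers are read; ``%`` dependent tiers,
    ``@`` headers, and other speakers' turns are ignored.  CHAT continuation
    lines (indented) are joined to the preceding tier.
    """
    # re-join continuation lines onto their tier line
    tiers: list[str] = []
    for raw in text.splitlines():
        if raw.startswith(("\t", " ")) and tiers:
            tiers[-1] += " " + raw.strip()
        else:
            tiers.append(raw.rstrip())
    sentences = []
    for line in tiers:
        m = re.match(r"\*([A-Za-z0-9]+):\s*(.*)", line)
        if not m:
            continue
        if m.group(1).upper() not in speakers:
            continue
        toks = tokenize(_clean_chat_utterance(m.group(2)))
        toks = [t for t in toks if t not in ("xxx", "yyy", "www")]  # unintelligible
        if toks:
            sentences.append(toks)
    return sentences


def _parse_plain(text: str) -> list[list[str]]:
    sentences = []
    for line in text.splitlines():
        toks = tokenize(line)
        if toks:
            sentences.append(toks)
    return sentences


def load_transcripts(
    path: str | Path,
    format: str = "plain",
    label: Label = CONTROL,
    speakers: Iterable[str] = ("PAR",),
) -> list[Transcript]:
    """Load labeled transcripts from a file or a directory of files.

    Parameters
    ----------
    path:
        A single transcript file, or a directory whose files are each one
        participant's transcript.  Directory entries are read in sorted
        order so transcript ids are deterministic.
    format:
        ``"plain"`` (one sentence per line) or ``"chat_minimal"``.
    label:
        Class label assigned to every loaded transcript.
    speakers:
        For ``chat_minimal``, the speaker codes whose utterances are kept
        (default: participant only, interviewer turns dropped).

    Transcripts that are empty after cleaning are excluded with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format not in ("plain", "chat_minimal", "chat"):
        raise ValueError(f"unsupported format: {format!r}")
    files = sorted(p for p in path.iterdir() if p.is_file()) if path.is_dir() else [path]
    speakers = tuple(s.upper() for s in speakers)

    out: list[Transcript] = []
    for f in files:
        try:
            text = f.read_text(encoding="utf-8")
        except (OSError, UnicodeDecodeError) as exc:
            raise OSError(f"unreadable transcript file {f}: {exc}") from exc
        if format == "plain":
            sentences = _parse_plain(text)
        else:
            sentences = _parse_chat(text, speakers)
        if not sentences:
            logger.warning("transcript %s empty after cleaning; excluded", f.name)
            continue
        out.append(Transcript(id=f.stem, label=label, sentences=sentences))
    return out


def save_transcript(transcript: Transcript, path: str | Path) -> None:
    """Write a transcript in plain format (round-trips through ``load_transcripts``)."""
    Path(path).write_text(transcript.to_plain(), encoding="utf-8")


def _allocate(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items to the given fractions."""
    raw = [n * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # most-short first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def make_split(
    transcripts: Sequence[Transcript],
    proportions: Sequence[float] = (0.5, 0.25, 0.25),
    seed: int = 0,
    stratify: bool = True,
) -> DatasetSplit:
    """Partition transcripts into train/test/validation id sets.

    Deterministic for a fixed seed.  With ``stratify`` (default), the split
    is performed within each class so realized per-class fractions are
    within one transcript of those requested; each class must be non-empty.
    """
    proportions = tuple(float(p) for p in proportions)
    if len(proportions) != 3:
        raise ValueError("exactly three proportions required")
    if any(p < 0 for p in proportions) or abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must be nonnegative and sum to 1: {proportions}")
    if not transcripts:
        raise ValueError("no transcripts to split")
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")

    rng = np.random.default_rng(seed)
    groups: list[list[str]]
    if stratify:
        by_label: dict[str, list[str]] = {lab: [] for lab in LABELS}
        for t in transcripts:
            by_label[t.label].append(t.id)
        for lab, members in by_label.items():
            if not members:
                raise ValueError(f"stratified split impossible: class {lab!r} is empty")
        groups = [by_label[lab] for lab in LABELS]
    else:
        groups = [list(ids)]

    parts: list[list[str]] = [[], [], []]
    for members in groups:
        members = sorted(members)
        rng.shuffle(members)
        counts = _allocate(len(members), proportions)
        pos = 0
        for k, c in enumerate(counts):
            parts[k].extend(members[pos:pos + c])
            pos += c
    return DatasetSplit(
        train_ids=tuple(parts[0]),
        test_ids=tuple(parts[1]),
        validation_ids=tuple(parts[2]),
        proportions=proportions,
        seed=int(seed),
    )
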