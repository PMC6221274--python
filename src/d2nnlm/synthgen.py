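"""Synthetic two-group transcript corpora with controllable divergence.

Real picture-description corpora in this problem are tiny: tens of
transcripts per group, each a handful of short sentences over a small
shared vocabulary fixed by the objects in the picture.  The generator
emulates exactly that regime.  Sentences are first-order Markov walks over
a word vocabulary; the control group uses a base transition matrix and the
positive (impaired) group uses the mixture

    T_pos = (1 - delta) * base + delta * perturbation,

where the perturbation re-draws a fraction of the transition rows from a
Dirichlet and ``delta`` in [0, 1] is the divergence dial: at 0 the two
groups share one generating process exactly; at 1 the positive group fully
follows the perturbed rows.  Although generation is first-order, differing
transitions propagate into differing higher-order (4-/5-gram) statistics,
which is what the downstream models consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import CONTROL, POSITIVE, Transcript

# picture-description-flavored word stock; sliced to vocabulary_size
_WORDS = [
    "the", "a", "boy", "girl", "mother", "woman", "child", "children",
    "cookie", "cookies", "jar", "lid", "shelf", "cupboard", "stool", "chair",
    "kitchen", "sink", "water", "dish", "dishes", "plate", "cup", "curtain",
    "window", "floor", "counter", "garden", "outside", "is", "are", "was",
    "be", "being", "has", "have", "and", "or", "but", "while", "on", "in",
    "under", "over", "by", "to", "of", "with", "from", "reaching", "taking",
    "falling", "standing", "washing", "drying", "running", "spilling",
    "overflowing", "looking", "laughing",
]


def _word_list(size: int) -> list[str]:
    if size <= len(_WORDS):
        return _WORDS[:size]
    return _WORDS + [f"word{i}" for i in range(size - len(_WORDS))]


def _check_stochastic(mat: np.ndarray, name: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"{name} rows must be nonnegative and sum to 1")


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic corpus.

    Defaults mirror the smaller (MCI-arm) scale: 19 transcripts per group,
    8-15 sentences each of 4-12 words over a 60-word vocabulary, roughly
    two hundred sentences per group.
    """

    vocabulary_size: int = 60
    divergence: float = 0.5
    perturbed_fraction: float = 0.5
    successors_per_word: int = 4
    dirichlet_alpha: float = 0.7
    sentences_per_transcript: tuple[int, int] = (8, 15)
    sentence_length: tuple[int, int] = (4, 12)
    transcripts_per_group: int = 19
    seed: int = 0
    base_transition: np.ndarray | None = field(default=None, repr=False)
    perturbation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0.0 <= self.perturbed_fraction <= 1.0:
            raise ValueError("perturbed_fraction must lie in [0, 1]")
        for lo, hi in (self.sentences_per_transcript, self.sentence_length):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        if self.transcripts_per_group < 1:
            raise ValueError("transcripts_per_group must be >= 1")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("base_transition", "perturbation"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        Path(path).write_text(json.dumps(d, indent=1) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorSpec":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        for key in ("base_transition", "perturbation"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        for key in ("sentences_per_transcript", "sentence_length"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _dirichlet_row(V: int, support: int, alpha: float,
                   rng: np.random.Generator) -> np.ndarray:
    """A sparse-support stochastic row: Dirichlet weights on a few successors.

    Limiting each word to a handful of likely successors is what makes
    n-grams *recur* across transcripts — the defining feature of constrained
    picture-description speech — instead of nearly every 4-gram being unique.
    """
    row = np.zeros(V)
    idx = rng.choice(V, size=min(support, V), replace=False)
    row[idx] = rng.dirichlet(np.full(len(idx), alpha))
    return row


def _transition_matrices(spec: GeneratorSpec, rng: np.random.Generator):
    """Base and positive-group transition matrices plus the initial law."""
    V = spec.vocabulary_size
    if spec.base_transition is not None:
        base = np.asarray(spec.base_transition, dtype=float)
    else:
        base = np.vstack([
            _dirichlet_row(V, spec.successors_per_word, spec.dirichlet_alpha, rng)
            for _ in range(V)])
    _check_stochastic(base, "base_transition")
    if base.shape[0] != V:
        raise ValueError("base_transition size disagrees with vocabulary_size")

    if spec.perturbation is not None:
        pert = np.asarray(spec.perturbation, dtype=float)
    else:
        pert = base.copy()
        n_rows = int(round(spec.perturbed_fraction * V))
        rows = rng.choice(V, size=n_rows, replace=False)
        for r in rows:
            pert[r] = _dirichlet_row(V, spec.successors_per_word,
                                     spec.dirichlet_alpha, rng)
    _check_stochastic(pert, "perturbation")

    positive = (1.0 - spec.divergence) * base + spec.divergence * pert
    initial = rng.dirichlet(np.full(V, 1.0))
    return base, positive, initial


def _walk(transition: np.ndarray, initial: np.ndarray, length: int,
          rng: np.random.Generator) -> list[int]:
    states = [int(rng.choice(len(initial), p=initial))]
    for _ in range(length - 1):
        states.append(int(rng.choice(transition.shape[1], p=transition[states[-1]])))
    return states


def make_groups(spec: GeneratorSpec) -> list[Transcript]:
    """Generate the labeled two-group corpus; deterministic per spec.seed."""
    rng = np.random.default_rng(spec.seed)
    base, positive, initial = _transition_matrices(spec, rng)
    words = _word_list(spec.vocabulary_size)
    lo_s, hi_s = spec.sentences_per_transcript
    lo_w, hi_w = spec.sentence_length

    out: list[Transcript] = []
    for label, matrix in ((POSITIVE, positive), (CONTROL, base)):
        short = "pos" if label == POSITIVE else "ctl"
        for t in range(spec.transcripts_per_group):
            n_sent = int(rng.integers(lo_s, hi_s + 1))
            sentences = []
            for _ in range(n_sent):
                length = int(rng.integers(lo_w, hi_w + 1))
                sentences.append([words[i] for i in _walk(matrix, initial, length, rng)])
            out.append(Transcript(id=f"{short}{t:03d}", label=label,
                                  sentences=sentences))
    return out


def write_fixture(transcripts: list[Transcript], path: str | Path,
                  format: str = "plain") -> list[Path]:
    """Write one file per transcript plus a labels TSV.

    Transcripts go into per-class subdirectories (``positive/``,
    ``control/``) so each can be fed directly to
    ``corpus.load_transcripts``; a pooled ``labels.tsv`` sits at the root.
    """
    if format not in ("plain", "chat_minimal", "chat"):
        raise ValueError(f"unsupported format: {format!r}")
    root = Path(path)
    for lab in (POSITIVE, CONTROL):
        (root / lab).mkdir(parents=True, exist_ok=True)
    suffix = ".txt" if format == "plain" else ".cha"
    written = []
    for t in transcripts:
        f = root / t.label / f"{t.id}{suffix}"
        if format == "plain":
            f.write_text(t.to_plain(), encoding="utf-8")
        else:
            lines = ["@Begin", "@Participants:\tPAR Participant"]
            lines += ["*PAR:\t" + " ".join(s) + " ." for s in t.sentences]
            lines.append("@End")
            f.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(f)
    labels = root / "labels.tsv"
    labels.write_text(
        "id\tlabel\n" + "".join(f"{t.id}\t{t.label}\n" for t in transcripts),
        encoding="utf-8")
    return written
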