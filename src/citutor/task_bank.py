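"""Sound-asset pool, difficulty scoring, and single-choice task assembly.

Seven task types drive the training: sound perception (SP, "Did you hear
anything?"), sound categorization (SC, "Does the sound fit this category?"),
consonant/vowel differentiation (CD/VD, "Are the two sounds the same?"),
word differentiation (WD), word identification (WI, "Which word did you
hear?"), and sentence identification (SI).  SP–WD are yes/no tasks; WI and SI
offer four labelled options.

Each asset carries difficulty metadata: loudness, recurrence (familiarity),
concreteness — all in [0, 1] — plus a phonetic code used to score similarity
between a key and its distractors.  A fixture generator emulates the study's
pool of roughly a thousand annotated audio assets; its phonetic codes are
synthetic strings, no audio or grapheme-to-phoneme conversion is involved.
"""
from __future__ import annotations

import csv
import functools
import io
import json
import pathlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .errors import ContractError, PoolValidationError
from .network import TASK_TYPES

ASSET_TYPES = ("sound", "word", "sentence")

#: Asset type each task type draws from.
TASK_ASSET_TYPE = {
    "SP": "sound",
    "SC": "sound",
    "CD": "sound",
    "VD": "sound",
    "WD": "word",
    "WI": "word",
    "SI": "sentence",
}

#: Number of answer options per task type.
OPTION_COUNT = {"SP": 2, "SC": 2, "CD": 2, "VD": 2, "WD": 2, "WI": 4, "SI": 4}

#: Number of distractor assets per task type (different-trials for CD/VD/WD).
DISTRACTOR_COUNT = {"SP": 0, "SC": 0, "CD": 1, "VD": 1, "WD": 1, "WI": 3, "SI": 3}

#: Additive difficulty offset of the single default background noise.
NOISE_OFFSET = 0.15

#: Weights of the WI/SI difficulty blend: distractor similarity vs key rarity.
WI_SI_SIMILARITY_WEIGHT = 0.6

_CSV_COLUMNS = [
    "id",
    "asset_type",
    "label",
    "categories",
    "loudness",
    "recurrence",
    "concreteness",
    "length_syllables",
    "phonetic_code",
]

_CATEGORY_TAGS = ("animal", "nature", "music", "household", "traffic", "voices")


@dataclass(frozen=True)
class SoundAsset:
    """One training item with difficulty metadata."""

    id: str
    asset_type: str
    label: str
    categories: frozenset[str]
    loudness: float
    recurrence: float
    concreteness: float
    length_syllables: int
    phonetic_code: str

    def __post_init__(self) -> None:
        if self.asset_type not in ASSET_TYPES:
            raise PoolValidationError(f"asset {self.id!r}: unknown asset_type {self.asset_type!r}")
        for name in ("loudness", "recurrence", "concreteness"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PoolValidationError(f"asset {self.id!r}: {name}={v!r} outside [0, 1]")
        if self.length_syllables < 1:
            raise PoolValidationError(f"asset {self.id!r}: length_syllables must be >= 1")
        if not self.phonetic_code:
            raise PoolValidationError(f"asset {self.id!r}: empty phonetic_code")


class AssetPool:
    """Validated collection of assets, indexed by id and by asset type."""

    def __init__(self, assets: Iterable[SoundAsset]) -> None:
        self.assets: dict[str, SoundAsset] = {}
        for a in assets:
            if a.id in self.assets:
                raise PoolValidationError(f"duplicate asset id {a.id!r}")
            self.assets[a.id] = a
        self.by_type: dict[str, list[SoundAsset]] = {t: [] for t in ASSET_TYPES}
        for a in self.assets.values():
            self.by_type[a.asset_type].append(a)
        for t in ASSET_TYPES:
            self.by_type[t].sort(key=lambda a: a.id)

    def __len__(self) -> int:
        return len(self.assets)

    def __getitem__(self, asset_id: str) -> SoundAsset:
        return self.assets[asset_id]

    def __iter__(self):
        return iter(self.assets.values())


@dataclass(frozen=True)
class TaskSpec:
    """An assembled single-choice task.

    ``key_id`` always names the source asset; for SP *silence trials* the
    asset is withheld at presentation time (``silence=True``) and the correct
    answer becomes "No", while the difficulty stays that of the planned asset.
    """

    task_type: str
    key_id: str
    distractor_ids: tuple[str, ...]
    options: tuple[str, ...]
    correct_index: int
    noise: bool
    difficulty: float
    same_trial: bool = False
    category: str | None = None
    silence: bool = False

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ContractError(f"unknown task type {self.task_type!r}")
        if len(self.options) != OPTION_COUNT[self.task_type]:
            raise ContractError(
                f"{self.task_type} tasks carry {OPTION_COUNT[self.task_type]} options, "
                f"got {len(self.options)}"
            )
        if not (0 <= self.correct_index < len(self.options)):
            raise ContractError(f"correct_index {self.correct_index} out of range")
        if not (0.0 <= self.difficulty <= 1.0):
            raise ContractError(f"difficulty {self.difficulty!r} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "task_type": self.task_type,
            "key_id": self.key_id,
            "distractor_ids": list(self.distractor_ids),
            "options": list(self.options),
            "correct_index": self.correct_index,
            "noise": self.noise,
            "difficulty": self.difficulty,
            "same_trial": self.same_trial,
            "category": self.category,
            "silence": self.silence,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskSpec":
        return cls(
            task_type=d["task_type"],
            key_id=d["key_id"],
            distractor_ids=tuple(d["distractor_ids"]),
            options=tuple(d["options"]),
            correct_index=int(d["correct_index"]),
            noise=bool(d["noise"]),
            difficulty=float(d["difficulty"]),
            same_trial=bool(d.get("same_trial", False)),
            category=d.get("category"),
            silence=bool(d.get("silence", False)),
        )


# -- manifest I/O ----------------------------------------------------------

def load_pool(source) -> AssetPool:
    """Load and validate an asset manifest (CSV path/handle or JSON path).

    Errors name the offending manifest row.
    """
    if isinstance(source, (str, pathlib.Path)):
        path = pathlib.Path(source)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return _pool_from_records(json.loads(text))
        return _pool_from_csv(io.StringIO(text))
    return _pool_from_csv(source)


def _pool_from_csv(handle) -> AssetPool:
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        raise PoolValidationError("empty manifest")
    missing = [c for c in _CSV_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise PoolValidationError(f"manifest lacks required columns: {missing}")
    records = []
    for row in reader:
        rec = dict(row)
        rec["categories"] = [c for c in row["categories"].split(";") if c]
        records.append(rec)
    return _pool_from_records(records)


def _pool_from_records(records: Sequence[Mapping]) -> AssetPool:
    assets = []
    for i, rec in enumerate(records):
        rownum = i + 2  # header is row 1 in the CSV view
        try:
            assets.append(
                SoundAsset(
                    id=str(rec["id"]),
                    asset_type=str(rec["asset_type"]),
                    label=str(rec["label"]),
                    categories=frozenset(rec["categories"]),
                    loudness=float(rec["loudness"]),
                    recurrence=float(rec["recurrence"]),
                    concreteness=float(rec["concreteness"]),
                    length_syllables=int(rec["length_syllables"]),
                    phonetic_code=str(rec["phonetic_code"]),
                )
            )
        except KeyError as exc:
            raise PoolValidationError(f"manifest row {rownum}: missing field {exc}") from exc
        except (PoolValidationError, ValueError) as exc:
            raise PoolValidationError(f"manifest row {rownum}: {exc}") from exc
    try:
        return AssetPool(assets)
    except PoolValidationError as exc:
        raise PoolValidationError(f"manifest: {exc}") from exc


def write_pool(pool: AssetPool, path) -> None:
    """Write a pool back to a CSV manifest (round-trips through load_pool)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for a in sorted(pool, key=lambda a: a.id):
            writer.writerow(
                [
                    a.id,
                    a.asset_type,
                    a.label,
                    ";".join(sorted(a.categories)),
                    repr(a.loudness),
                    repr(a.recurrence),
                    repr(a.concreteness),
                    a.length_syllables,
                    a.phonetic_code,
                ]
            )


# -- fixture generation ----------------------------------------------------

_SYLLABLE_ONSETS = "bdfghklmnprstvw"
_SYLLABLE_VOWELS = ["a", "e", "i", "o", "u", "au", "ei", "eu"]
_SYLLABLE_CODAS = ["", "n", "r", "s", "t", "ch"]


def _random_word(rng: np.random.Generator, n_syllables: int) -> str:
    parts = []
    for _ in range(n_syllables):
        parts.append(
            rng.choice(list(_SYLLABLE_ONSETS))
            + rng.choice(_SYLLABLE_VOWELS)
            + rng.choice(_SYLLABLE_CODAS)
        )
    return "".join(parts)


def generate_fixture_pool(n: int, seed: int) -> AssetPool:
    """Deterministic synthetic asset pool emulating the study's pool.

    Mix: ~40% sounds, ~40% words, ~20% sentences.  Loudness, recurrence and
    concreteness are uniform on [0, 1]; syllable counts span 1–8; phonetic
    codes are built from a small syllable inventory so that pairwise
    similarity spans the full [0, 1] range; sounds carry category tags so
    that categorization tasks are constructible.
    """
    if n < 50:
        raise ContractError(f"fixture pool needs n >= 50, got {n}")
    rng = np.random.default_rng(seed)
    n_sound = round(0.4 * n)
    n_word = round(0.4 * n)
    n_sentence = n - n_sound - n_word
    assets: list[SoundAsset] = []

    def features() -> tuple[float, float, float]:
        loud, rec, conc = rng.uniform(0, 1, size=3)
        return float(loud), float(rec), float(conc)

    for i in range(n_sound):
        loud, rec, conc = features()
        syllables = int(rng.integers(1, 3))
        code = _random_word(rng, syllables)
        n_tags = int(rng.integers(1, 3))
        tags = rng.choice(_CATEGORY_TAGS, size=n_tags, replace=False)
        assets.append(
            SoundAsset(
                id=f"snd{i:04d}",
                asset_type="sound",
                label=f"[{code}]",
                categories=frozenset(tags.tolist()),
                loudness=loud,
                recurrence=rec,
                concreteness=conc,
                length_syllables=syllables,
                phonetic_code=code,
            )
        )
    for i in range(n_word):
        loud, rec, conc = features()
        syllables = int(rng.integers(1, 4))
        code = _random_word(rng, syllables)
        assets.append(
            SoundAsset(
                id=f"wrd{i:04d}",
                asset_type="word",
                label=code.capitalize(),
                categories=frozenset([str(rng.choice(_CATEGORY_TAGS))]),
                loudness=loud,
                recurrence=rec,
                concreteness=conc,
                length_syllables=syllables,
                phonetic_code=code,
            )
        )
    for i in range(n_sentence):
        loud, rec, conc = features()
        n_words = int(rng.integers(3, 7))
        words = [_random_word(rng, int(rng.integers(1, 3))) for _ in range(n_words)]
        code = " ".join(words)
        syllables = min(8, max(4, sum(1 for _ in words) + 1))
        assets.append(
            SoundAsset(
                id=f"sen{i:04d}",
                asset_type="sentence",
                label=" ".join(w.capitalize() for w in words) + ".",
                categories=frozenset([str(rng.choice(_CATEGORY_TAGS))]),
                loudness=loud,
                recurrence=rec,
                concreteness=conc,
                length_syllables=syllables,
                phonetic_code=code,
            )
        )
    pool = AssetPool(assets)
    if len(pool.by_type["sound"]) < 2 or len(pool.by_type["word"]) < 4 or len(
        pool.by_type["sentence"]
    ) < 4:
        raise ContractError("fixture pool too small to construct every task type")
    return pool


# -- similarity and difficulty --------------------------------------------

@functools.lru_cache(maxsize=200_000)
def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def similarity(a: SoundAsset, b: SoundAsset) -> float:
    """Phonetic similarity: 1 − edit distance / max code length, in [0, 1]."""
    if a.asset_type != b.asset_type:
        raise ContractError(
            f"similarity undefined across asset types ({a.asset_type} vs {b.asset_type})"
        )
    longest = max(len(a.phonetic_code), len(b.phonetic_code))
    return 1.0 - _edit_distance(a.phonetic_code, b.phonetic_code) / longest


def candidate_difficulty(
    task_type: str,
    key: SoundAsset,
    distractors: Sequence[SoundAsset] = (),
    same_trial: bool = False,
    noise: bool = False,
) -> float:
    """Difficulty score of a candidate key/distractor combination.

    SP/SC: quiet, rare, abstract sounds are hard — mean of (1−loudness,
    1−recurrence, 1−concreteness).  CD/VD/WD different-trials: similarity of
    the pair; same-trials: rarity of the key.  WI/SI: blend of mean distractor
    similarity and key rarity.  Background noise adds a fixed offset.
    """
    if task_type not in TASK_TYPES:
        raise ContractError(f"unknown task type {task_type!r}")
    expected = 0 if same_trial else DISTRACTOR_COUNT[task_type]
    if len(distractors) != expected:
        raise ContractError(
            f"{task_type} ({'same' if same_trial else 'different'}-trial) needs "
            f"{expected} distractors, got {len(distractors)}"
        )
    if task_type in ("SP", "SC"):
        score = float(np.mean([1 - key.loudness, 1 - key.recurrence, 1 - key.concreteness]))
    elif task_type in ("CD", "VD", "WD"):
        score = (1 - key.recurrence) if same_trial else similarity(key, distractors[0])
    else:  # WI / SI
        sims = [similarity(key, d) for d in distractors]
        score = WI_SI_SIMILARITY_WEIGHT * float(np.mean(sims)) + (
            1 - WI_SI_SIMILARITY_WEIGHT
        ) * (1 - key.recurrence)
    if noise:
        score += NOISE_OFFSET
    return float(min(max(score, 0.0), 1.0))


# -- task assembly ---------------------------------------------------------

_YES_NO = ("Yes", "No")


def build_task(
    task_type: str,
    key: SoundAsset,
    distractors: Sequence[SoundAsset] = (),
    same_trial: bool = False,
    noise: bool = False,
    seed: int | None = None,
    category: str | None = None,
    silence: bool = False,
) -> TaskSpec:
    """Assemble a TaskSpec with options laid out per the task-type blueprint.

    Yes/no types get (Yes, No); WI/SI get four labels with the key's position
    shuffled deterministically from ``seed``.  For SC the supplied ``category``
    decides the correct answer; for SP a silence trial makes "No" correct.
    """
    if task_type not in TASK_TYPES:
        raise ContractError(f"unknown task type {task_type!r}")
    if not same_trial:
        for d in distractors:
            if d.id == key.id:
                raise ContractError(
                    f"distractor {d.id!r} equals the key on a different-trial"
                )
    difficulty = candidate_difficulty(task_type, key, distractors, same_trial, noise)
    if task_type == "SP":
        correct = 1 if silence else 0
        return TaskSpec(task_type, key.id, (), _YES_NO, correct, noise, difficulty,
                        silence=silence)
    if task_type == "SC":
        if category is None:
            raise ContractError("SC tasks need a category tag")
        correct = 0 if category in key.categories else 1
        return TaskSpec(task_type, key.id, (), _YES_NO, correct, noise, difficulty,
                        category=category)
    if task_type in ("CD", "VD", "WD"):
        # "Are the two the same?" — Yes on same-trials, No on different-trials.
        correct = 0 if same_trial else 1
        ids = () if same_trial else (distractors[0].id,)
        return TaskSpec(task_type, key.id, ids, _YES_NO, correct, noise, difficulty,
                        same_trial=same_trial)
    # WI / SI: four labels, seeded shuffle of the correct position.
    labels = [key.label] + [d.label for d in distractors]
    order = np.random.default_rng(seed).permutation(len(labels))
    options = tuple(labels[i] for i in order)
    correct = int(np.where(order == 0)[0][0])
    return TaskSpec(task_type, key.id, tuple(d.id for d in distractors), options, correct,
                    noise, difficulty)
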