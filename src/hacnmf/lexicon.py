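"""Phone inventory, word pronunciations and carrier-sentence templates.

The corpus emulates a recorded infant-directed speech collection: 15 keywords
(animal, apple, banana, baby, bird, bottle, car, cat, cookie, daddy, dog,
mummy, telephone, toy, truck) embedded sentence-initially or -finally in
short carrier phrases, plus acoustically comparable foil words used only at
test. The lexicon ships as a JSON data file; phone strings are synthetic
(built from an 18-symbol inventory of formant/noise targets), not English
phonology.

Target words and their matched foils follow the behavioural design:
``cat`` vs {ball, cow, red}, ``mummy`` vs {woman, robin, airplane},
``banana`` vs {edible, robin, airplane}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "KEYWORDS",
    "TARGET_WORDS",
    "FOILS",
    "Phone",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
]

#: The 15 keywords the model learns, in canonical order. The index of a
#: keyword in this tuple is its slot in the meaning block of a HAC+M vector.
KEYWORDS = (
    "animal", "apple", "banana", "baby", "bird", "bottle", "car", "cat",
    "cookie", "daddy", "dog", "mummy", "telephone", "toy", "truck",
)

#: The three keywords singled out as test targets (one, two, three syllables).
TARGET_WORDS = ("cat", "mummy", "banana")

#: Matched foils per target word, presented only at test.
FOILS = {
    "cat": ("ball", "cow", "red"),
    "mummy": ("woman", "robin", "airplane"),
    "banana": ("edible", "robin", "airplane"),
}


class LexiconError(KeyError):
    """Raised when a word or phone is not in the lexicon."""


@dataclass(frozen=True)
class Phone:
    """One synthesis unit: a formant target (voiced) or a noise band."""

    symbol: str
    kind: str
    voiced: bool
    duration: float
    amplitude: float
    formants: tuple[float, float, float] | None = None
    band: tuple[float, float] | None = None
    closure: float = 0.0


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    phones: tuple[str, ...]
    syllables: int
    role: str  # keyword | foil | carrier


@dataclass(frozen=True)
class Carrier:
    """A carrier sentence template with a keyword slot at one edge."""

    carrier_id: str
    words: tuple[str, ...]
    position: str  # 'initial' or 'final' — where the keyword goes

    def sentence_words(self, keyword: str | None) -> tuple[str, ...]:
        if keyword is None:
            return self.words
        if self.position == "final":
            return self.words + (keyword,)
        return (keyword,) + self.words


class Lexicon:
    """Read-only view of the shipped lexicon data file."""

    def __init__(self, phones, words, carriers):
        self.phones: dict[str, Phone] = phones
        self.words: dict[str, LexiconEntry] = words
        self.carriers: dict[str, Carrier] = carriers

    def entry(self, word: str) -> LexiconEntry:
        try:
            return self.words[word]
        except KeyError:
            raise LexiconError(f"word not in lexicon: {word!r}") from None

    def phone(self, symbol: str) -> Phone:
        try:
            return self.phones[symbol]
        except KeyError:
            raise LexiconError(f"phone not in inventory: {symbol!r}") from None

    def phone_string(self, words) -> list[Phone]:
        """Flatten a word sequence into its phone objects."""
        out: list[Phone] = []
        for w in words:
            out.extend(self.phone(p) for p in self.entry(w).phones)
        return out

    @property
    def carrier_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.carriers))


@lru_cache(maxsize=1)
def load_lexicon() -> Lexicon:
    """Load the packaged lexicon; validates the keyword set on load."""
    raw = json.loads(
        resources.files("hacnmf").joinpath("data/lexicon.json").read_text()
    )
    phones = {}
    for sym, p in raw["phones"].items():
        phones[sym] = Phone(
            symbol=sym,
            kind=p["kind"],
            voiced=p["voiced"],
            duration=p["duration"],
            amplitude=p["amplitude"],
            formants=tuple(p["formants"]) if "formants" in p else None,
            band=tuple(p["band"]) if "band" in p else None,
            closure=p.get("closure", 0.0),
        )
    words = {}
    for w, e in raw["words"].items():
        if not e["phones"]:
            raise ValueError(f"lexicon entry {w!r} has an empty phone string")
        words[w] = LexiconEntry(w, tuple(e["phones"]), e["syllables"], e["role"])
    carriers = {
        cid: Carrier(cid, tuple(c["words"]), c["position"])
        for cid, c in raw["carriers"].items()
    }
    keyword_entries = {w for w, e in words.items() if e.role == "keyword"}
    if keyword_entries != set(KEYWORDS):
        raise ValueError("lexicon keyword set does not match the 15 keywords")
    return Lexicon(phones, words, carriers)
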