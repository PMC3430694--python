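"""Centre-embedded A^nB^n artificial-grammar syllable sequences.

The stimulus language consists of consonant–vowel syllables built from the six
plosives ``b d g p t k`` and the vowels ``e i o u``.  A syllable belongs to
category A when it ends in /e/ or /i/ and to category B when it ends in /o/ or
/u/.  Grammatical sequences follow the centre-embedded rule A^nB^n: ``n``
category-A syllables followed by ``n`` category-B syllables, with the consonant
of the i-th A syllable tied to the consonant of the mirror-positioned B
syllable through the voiced/voiceless plosive pairing b–p, d–t, g–k
(e.g. ``be di ge ko tu pu`` at n = 3).

Besides grammaticality, every sequence carries a second, orthogonal judgement:
whether the number of /e/-final syllables equals the number of /o/-final
syllables (the "count" task).  The generator can produce sequences with any
satisfiable combination of the two labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLOSIVES",
    "VOWELS",
    "PLOSIVE_PAIR",
    "Syllable",
    "SequenceSpec",
    "parse_sequence",
    "classify_syllable",
    "is_grammatical",
    "count_match",
    "generate_sequence",
]

#: The six plosive consonants the grammar draws from.
PLOSIVES = frozenset("bdgptk")
#: Legal syllable-final vowels.  /e/,/i/ mark category A; /o/,/u/ category B.
VOWELS = frozenset("eiou")
#: The fixed voiced/voiceless pairing used for mirrored dependencies.
PLOSIVE_PAIR = {"b": "p", "p": "b", "d": "t", "t": "d", "g": "k", "k": "g"}

_A_VOWELS = ("e", "i")
_B_VOWELS = ("o", "u")
_VOICED = ("b", "d", "g")


class MalformedSyllableError(ValueError):
    """Raised when a token is not a plosive+vowel syllable of this grammar."""


@dataclass(frozen=True)
class Syllable:
    """A consonant–vowel stimulus syllable.

    Parameters
    ----------
    consonant : str
        One of the six plosives ``b d g p t k``.
    vowel : str
        One of ``e i o u``.  The vowel alone determines the category.
    """

    consonant: str
    vowel: str

    def __post_init__(self) -> None:
        if self.consonant not in PLOSIVES:
            raise MalformedSyllableError(
                f"invalid consonant {self.consonant!r}: must be one of b,d,g,p,t,k"
            )
        if self.vowel not in VOWELS:
            raise MalformedSyllableError(
                f"invalid vowel {self.vowel!r}: must be one of e,i,o,u"
            )

    @property
    def category(self) -> str:
        """``"A"`` if the vowel is /e/ or /i/, ``"B"`` if /o/ or /u/."""
        return "A" if self.vowel in _A_VOWELS else "B"

    @classmethod
    def from_string(cls, token: str) -> "Syllable":
        if len(token) != 2:
            raise MalformedSyllableError(
                f"{token!r} is not a two-character consonant-vowel syllable"
            )
        return cls(token[0], token[1])

    def __str__(self) -> str:
        return self.consonant + self.vowel


def parse_sequence(text: str) -> list[Syllable]:
    """Parse a space-separated syllable string such as ``"be di ge ko tu pu"``."""
    tokens = text.split()
    if not tokens:
        raise MalformedSyllableError("empty sequence string")
    return [Syllable.from_string(t) for t in tokens]


@dataclass(frozen=True)
class SequenceSpec:
    """A labelled six-syllable (length 2n) stimulus.

    ``is_grammatical`` and ``count_match`` are the ground-truth answers to the
    grammar task and the count task; both are re-derivable from ``syllables``
    via :func:`is_grammatical` and :func:`count_match`.
    """

    syllables: tuple[Syllable, ...]
    is_grammatical: bool
    count_match: bool
    n: int = field(default=3)

    def __str__(self) -> str:
        return " ".join(str(s) for s in self.syllables)


def classify_syllable(s: Syllable | str) -> str:
    """Return the category, ``"A"`` or ``"B"``, of a syllable.

    Accepts either a :class:`Syllable` or a two-character string; malformed
    input raises :class:`MalformedSyllableError`.
    """
    if isinstance(s, str):
        s = Syllable.from_string(s)
    return s.category


def _coerce(seq) -> list[Syllable]:
    return [Syllable.from_string(s) if isinstance(s, str) else s for s in seq]


def is_grammatical(seq) -> bool:
    """Check the centre-embedded A^nB^n rule with mirrored plosive pairing.

    A sequence of length 2n is grammatical iff the first n syllables are
    category A, the last n category B, and for every i the consonant at
    position i is the plosive partner of the consonant at position 2n+1-i
    (bracket matching over the pairing involution).

    Raises
    ------
    ValueError
        If the sequence is empty or of odd length.
    """
    syls = _coerce(seq)
    if not syls:
        raise ValueError("empty sequence cannot be judged")
    if len(syls) % 2:
        raise ValueError(f"sequence length {len(syls)} is odd; A^nB^n requires 2n")
    n = len(syls) // 2
    if any(s.category != "A" for s in syls[:n]):
        return False
    if any(s.category != "B" for s in syls[n:]):
        return False
    return all(
        PLOSIVE_PAIR[syls[i].consonant] == syls[2 * n - 1 - i].consonant
        for i in range(n)
    )


def count_match(seq) -> bool:
    """True iff the sequence has as many /e/-final as /o/-final syllables."""
    syls = _coerce(seq)
    if not syls:
        raise ValueError("empty sequence cannot be judged")
    n_e = sum(s.vowel == "e" for s in syls)
    n_o = sum(s.vowel == "o" for s in syls)
    return n_e == n_o


def _vowel_assignments(n: int, want_match: bool) -> list[tuple[str, ...]]:
    """All vowel assignments (A slots from e/i, B slots from o/u) with the
    requested count-match label."""
    out = []
    for a_vowels in itertools.product(_A_VOWELS, repeat=n):
        n_e = a_vowels.count("e")
        for b_vowels in itertools.product(_B_VOWELS, repeat=n):
            if (n_e == b_vowels.count("o")) == want_match:
                out.append(a_vowels + b_vowels)
    return out


def generate_sequence(
    n: int,
    grammatical: bool,
    countmatch: bool,
    rng: np.random.Generator,
) -> SequenceSpec:
    """Draw one labelled A^nB^n-shaped stimulus.

    Construction follows the convention of the grammar's canonical example:
    category-A syllables take voiced plosives {b, d, g} and category-B
    syllables their voiceless partners {p, t, k}.  Ungrammatical sequences
    keep the n-A-then-n-B block shape and differ from a grammatical one only
    by a permutation of the B consonants that leaves at least one mirrored
    pair mismatched, so the category structure alone never betrays the label.
    Vowels are the free degrees of freedom used to realise the requested
    count-match label; the assignment is uniform among the satisfying ones.

    Raises
    ------
    ValueError
        If the label combination is unsatisfiable at depth ``n`` (at n = 1 no
        block-shaped consonant permutation can break grammaticality).
    """
    if n < 1:
        raise ValueError("embedding depth n must be >= 1")
    if n > 8:
        raise ValueError("embedding depth n > 8 not supported (vowel enumeration)")

    if grammatical:
        a_cons = list(rng.choice(_VOICED, size=n))
        b_cons = [PLOSIVE_PAIR[c] for c in reversed(a_cons)]
    else:
        if n == 1:
            raise ValueError(
                "ungrammatical sequences are unsatisfiable at n=1: a single "
                "B consonant admits no pair-breaking permutation"
            )
        # Need >=2 distinct B consonants for a mismatching rearrangement.
        while True:
            a_cons = list(rng.choice(_VOICED, size=n))
            if len(set(a_cons)) > 1:
                break
        mirror = [PLOSIVE_PAIR[c] for c in reversed(a_cons)]
        perms = {p for p in itertools.permutations(mirror) if list(p) != mirror}
        perms = sorted(perms)
        b_cons = list(perms[rng.integers(len(perms))])

    assignments = _vowel_assignments(n, countmatch)
    if not assignments:  # unreachable for n >= 1, kept as a guard
        raise ValueError(
            f"count_match={countmatch} unsatisfiable at depth n={n}"
        )
    vowels = assignments[rng.integers(len(assignments))]

    syls = tuple(
        Syllable(c, v) for c, v in zip(a_cons + b_cons, vowels, strict=True)
    )
    spec = SequenceSpec(
        syllables=syls,
        is_grammatical=is_grammatical(syls),
        count_match=count_match(syls),
        n=n,
    )
    assert spec.is_grammatical == grammatical and spec.count_match == countmatch
    return spec
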