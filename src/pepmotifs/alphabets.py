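"""Reduced amino-acid alphabets.

Grouping the 20 residues by shared physicochemical character (small
hydrophobic, polar uncharged, positively charged, negatively charged,
aromatic, structure-breaking, methionine) generalizes motifs: a sequence is
recoded group-wise and the motif engine runs unchanged on group symbols.
Three built-in partitions are provided — enc7, enc8 (serine/threonine split
from asparagine/glutamine) and enc10 (arginine, alanine and histidine/lysine
further isolated) — and custom partitions can be loaded from a plain-text
config (one group per line).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

from .motifs import STANDARD_AA

_BUILTIN = {
    "enc7": ("AVIL", "STNQ", "RHK", "DE", "FYW", "CGP", "M"),
    "enc8": ("AVIL", "ST", "NQ", "RHK", "DE", "FYW", "CGP", "M"),
    "enc10": ("VIL", "A", "ST", "NQ", "R", "HK", "DE", "FYW", "CGP", "M"),
}


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class ReducedAlphabet:
    """A partition of the 20 standard residues into disjoint groups.

    Each group gets a single lowercase symbol for internal recoding; the
    external rendering is the bracketed letter set in definition order
    (``[AVIL]``), or the bare letter for singleton groups.
    """

    name: str
    groups: tuple[str, ...]  # letter strings, rendered in the given order
    _letter_to_symbol: dict = field(default_factory=dict, repr=False)
    _symbol_to_group: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        seen = set()
        for g in self.groups:
            if not g:
                raise AlphabetError("empty residue group")
            for letter in g:
                if letter not in STANDARD_AA:
                    raise AlphabetError(f"non-standard letter {letter!r} in group {g!r}")
                if letter in seen:
                    raise AlphabetError(f"letter {letter!r} appears in two groups")
                seen.add(letter)
        if seen != set(STANDARD_AA):
            missing = "".join(sorted(set(STANDARD_AA) - seen))
            raise AlphabetError(f"groups must cover all 20 residues; missing {missing}")
        symbols = string.ascii_lowercase
        for i, g in enumerate(self.groups):
            sym = symbols[i]
            self._symbol_to_group[sym] = g
            for letter in g:
                self._letter_to_symbol[letter] = sym

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def recode(self, sequence: str) -> str:
        """Replace each residue by its group symbol (length-preserving)."""
        try:
            return "".join(self._letter_to_symbol[c] for c in sequence)
        except KeyError as exc:
            raise AlphabetError(f"residue {exc.args[0]!r} is in no group") from None

    def class_of(self, letters: str) -> frozenset:
        """The group (as a letter set) containing the given letters; the
        letters must all belong to one group and name it completely when
        more than one is given (bracketed notation)."""
        syms = {self._letter_to_symbol.get(c) for c in letters}
        if None in syms or len(syms) != 1:
            raise AlphabetError(f"{letters!r} does not name a single {self.name} group")
        group = self._symbol_to_group[syms.pop()]
        if len(letters) > 1 and set(letters) != set(group):
            raise AlphabetError(f"{letters!r} is not a complete {self.name} group ({group})")
        return frozenset(group)

    def class_of_symbol(self, symbol: str) -> frozenset:
        return frozenset(self._symbol_to_group[symbol])

    def symbol_of_class(self, cls: frozenset) -> str:
        for sym, g in self._symbol_to_group.items():
            if frozenset(g) == cls:
                return sym
        raise AlphabetError(f"{''.join(sorted(cls))!r} is not a {self.name} group")

    def render_symbol(self, symbol: str) -> str:
        g = self._symbol_to_group[symbol]
        return g if len(g) == 1 else f"[{g}]"


def builtin_alphabet(name: str) -> ReducedAlphabet:
    """One of the built-in reductions: enc7, enc8 or enc10."""
    if name not in _BUILTIN:
        raise AlphabetError(
            f"unknown alphabet {name!r}; valid names: {', '.join(sorted(_BUILTIN))}"
        )
    return ReducedAlphabet(name, _BUILTIN[name])


def load_alphabet(path: str | Path, name: str | None = None) -> ReducedAlphabet:
    """Load a custom partition: one group per line as concatenated letters."""
    path = Path(path)
    groups = tuple(
        line.strip().upper()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    return ReducedAlphabet(name or path.stem, groups)
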