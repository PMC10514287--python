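"""Gapped (discontinuous) motif shapes, matching and counting.

A motif is an ordered list of *residue classes* (singleton letters on the
full alphabet, bracketed letter groups on reduced alphabets) separated by
fixed numbers of unspecified positions (gaps), written with one ``_`` per
unspecified position: ``S_S`` is serine, any residue, serine.  Motif sizes
run from bigrams (two specified residues) to pentagrams (five), with gap
budgets chosen so the total footprint (span) never exceeds 10 positions:

* bigrams and trigrams: 0–3 unspecified residues per gap slot,
* tetragrams: 0–2 per slot,
* pentagrams: contiguous, or a single gap of exactly one position.

Coordinates are 0-based internally; report writers add 1 for display.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Literal, Sequence

import numpy as np
from scipy import sparse

if TYPE_CHECKING:  # pragma: no cover
    from .alphabets import ReducedAlphabet
    from .datasets import PeptideRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: per-slot gap bounds (inclusive) for each motif size; pentagrams are special-cased
GAP_MAX = {2: 3, 3: 3, 4: 2}
MAX_SPAN = 10
K_RANGE = (2, 3, 4, 5)


class MotifError(ValueError):
    """Raised for malformed motif strings or invalid shapes."""


def enumerate_shapes(k: int) -> list[tuple[int, ...]]:
    """All admissible gap-length tuples for motifs of ``k`` specified residues.

    Returns tuples of length ``k - 1`` in lexicographic order.  For k=5 the
    admissible shapes are the contiguous one plus those with exactly one gap
    of length 1.  Every returned shape has span ≤ 10.
    """
    if k not in (2, 3, 4, 5):
        raise MotifError(f"motif size must be in 2..5, got {k}")
    if k == 5:
        shapes = [(0, 0, 0, 0)]
        for i in range(4):
            g = [0, 0, 0, 0]
            g[i] = 1
            shapes.append(tuple(g))
        shapes.sort()
    else:
        gmax = GAP_MAX[k]
        shapes = [
            g
            for g in itertools.product(range(gmax + 1), repeat=k - 1)
            if k + sum(g) <= MAX_SPAN
        ]
    return shapes


def _offsets(gaps: Sequence[int]) -> tuple[int, ...]:
    offs = [0]
    for g in gaps:
        offs.append(offs[-1] + 1 + g)
    return tuple(offs)


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of residue classes with fixed inter-class gaps.

    ``classes[i]`` is the set of letters admitted at specified position i;
    ``gaps[i]`` is the number of unspecified positions between classes i and
    i+1 (``len(gaps) == len(classes) - 1``).
    """

    classes: tuple[frozenset, ...]
    gaps: tuple[int, ...]

    def __post_init__(self):
        k = len(self.classes)
        if not 2 <= k <= 5:
            raise MotifError(f"motif must have 2..5 specified residues, got {k}")
        if len(self.gaps) != k - 1:
            raise MotifError("need exactly one gap length per adjacent class pair")
        if any(g < 0 for g in self.gaps):
            raise MotifError("gap lengths must be non-negative")
        if any(not c for c in self.classes):
            raise MotifError("residue classes must be non-empty")
        if self.gaps not in set(enumerate_shapes(k)):
            raise MotifError(
                f"gap shape {self.gaps} not admissible for motif size {k}"
            )

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def span(self) -> int:
        return len(self.classes) + sum(self.gaps)

    @property
    def offsets(self) -> tuple[int, ...]:
        return _offsets(self.gaps)


@dataclass(frozen=True)
class MatchResult:
    """Occurrences of one motif in one sequence (0-based start positions)."""

    motif: MotifPattern
    count: int
    starts: tuple[int, ...]


_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|([A-Z])|(_)")


def parse_motif(text: str, alphabet: "ReducedAlphabet | None" = None) -> MotifPattern:
    """Parse a canonical motif string such as ``S_S`` or ``[AVIL]__[ST]``.

    Bracketed groups denote residue classes of a reduced alphabet; if
    ``alphabet`` is given, bare letters are expanded to their group, so
    reduced-alphabet motifs can also be written with representative letters.
    """
    if not text:
        raise MotifError("empty motif string")
    classes: list[frozenset] = []
    gaps: list[int] = []
    pending_gap = 0
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise MotifError(f"unexpected character at position {pos} in {text!r}")
        pos = m.end()
        if m.group(3):  # '_'
            if not classes:
                raise MotifError(f"motif {text!r} starts with an unspecified position")
            pending_gap += 1
        else:
            letters = m.group(1) or m.group(2)
            cls = frozenset(letters)
            if alphabet is not None:
                cls = alphabet.class_of(letters)
            if classes:
                gaps.append(pending_gap)
                pending_gap = 0
            classes.append(cls)
    if pos != len(text):
        raise MotifError(f"unexpected character at position {pos} in {text!r}")
    if pending_gap:
        raise MotifError(f"motif {text!r} ends with an unspecified position")
    return MotifPattern(tuple(classes), tuple(gaps))


def format_motif(pattern: MotifPattern, alphabet: "ReducedAlphabet | None" = None) -> str:
    """Canonical string rendering: bare letter for singleton classes,
    bracketed letters otherwise, one ``_`` per unspecified position.  With
    ``alphabet`` given, multi-letter classes render in the alphabet's group
    definition order (``[AVIL]``); otherwise alphabetically."""
    parts = []
    for i, cls in enumerate(pattern.classes):
        if i:
            parts.append("_" * pattern.gaps[i - 1])
        if len(cls) == 1:
            parts.append(next(iter(cls)))
        elif alphabet is not None:
            parts.append(alphabet.render_symbol(alphabet.symbol_of_class(cls)))
        else:
            parts.append(f"[{''.join(sorted(cls))}]")
    return "".join(parts)


def find_occurrences(sequence: str, pattern: MotifPattern) -> MatchResult:
    """All (overlapping) occurrences of ``pattern`` in ``sequence``.

    A start ``s`` matches iff ``sequence[s + offset_i]`` is in class i for
    every specified position; unspecified positions match any letter.
    """
    offs = pattern.offsets
    classes = pattern.classes
    starts = []
    for s in range(len(sequence) - pattern.span + 1):
        if all(sequence[s + o] in c for o, c in zip(offs, classes)):
            starts.append(s)
    return MatchResult(pattern, len(starts), tuple(starts))


# ---------------------------------------------------------------------------
# lazy count matrix


@dataclass
class CountMatrix:
    """Sparse motif × sequence matrix of presence flags or occurrence counts.

    Rows are exactly the motifs observed at least once somewhere (motifs
    absent from every sequence are never materialized).  Row order is
    deterministic: by motif size, then gap shape, then residue string.
    """

    matrix: sparse.csr_matrix
    motif_keys: list[tuple[int, tuple[int, ...], str]]  # (k, gaps, class chars)
    seq_ids: list[str]
    mode: Literal["presence", "count"]
    alphabet: "ReducedAlphabet | None" = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {key: i for i, key in enumerate(self.motif_keys)}

    @property
    def n_sequences(self) -> int:
        return len(self.seq_ids)

    def motif_string(self, key: tuple[int, tuple[int, ...], str]) -> str:
        k, gaps, chars = key
        if self.alphabet is None:
            classes = tuple(frozenset(c) for c in chars)
        else:
            classes = tuple(self.alphabet.class_of_symbol(c) for c in chars)
        return format_motif(MotifPattern(classes, gaps), self.alphabet)

    def motif_strings(self) -> list[str]:
        return [self.motif_string(key) for key in self.motif_keys]

    def row(self, key) -> np.ndarray:
        """Dense per-sequence vector for one motif (zeros included)."""
        i = self._index[key]
        return self.matrix[[i], :].toarray().ravel()

    def row_by_string(self, motif: str) -> np.ndarray:
        pat = parse_motif(motif, self.alphabet)
        key = _key_of(pat, self.alphabet)
        if key not in self._index:
            return np.zeros(self.n_sequences)
        return self.row(key)

    def presence_counts(self) -> np.ndarray:
        """Number of sequences containing each motif at least once."""
        return np.asarray((self.matrix > 0).sum(axis=1)).ravel()

    def to_frame(self):
        """Long-format DataFrame (motif, sequence_id, value); sparse triples."""
        import pandas as pd

        coo = self.matrix.tocoo()
        strings = self.motif_strings()
        return pd.DataFrame(
            {
                "motif": [strings[i] for i in coo.row],
                "sequence_id": [self.seq_ids[j] for j in coo.col],
                "value": coo.data,
            }
        )


def _key_of(pattern: MotifPattern, alphabet: "ReducedAlphabet | None"):
    if alphabet is None:
        chars = "".join(sorted(c)[0] if len(c) == 1 else "?" for c in pattern.classes)
        if "?" in chars:
            raise MotifError("full-alphabet count keys require singleton classes")
    else:
        chars = "".join(alphabet.symbol_of_class(c) for c in pattern.classes)
    return (pattern.k, pattern.gaps, chars)


def count_matrix(
    records: "Iterable[PeptideRecord | str]",
    k_range: Iterable[int] = K_RANGE,
    mode: Literal["presence", "count"] = "presence",
    alphabet: "ReducedAlphabet | None" = None,
) -> CountMatrix:
    """Extract every motif occurring in ``records`` for the given sizes.

    Motifs are instantiated lazily from the sequences themselves, never from
    Cartesian products of the alphabet.  With ``alphabet`` set, sequences are
    recoded group-wise first and motif classes are residue groups.
    """
    ks = sorted(set(k_range))
    if not set(ks) <= set(K_RANGE):
        raise MotifError(f"k_range must be within {K_RANGE}, got {ks}")
    shapes = [
        (k, gaps, _offsets(gaps)[1:]) for k in ks for gaps in enumerate_shapes(k)
    ]
    seq_ids: list[str] = []
    motif_ids: dict[tuple[int, tuple[int, ...], str], int] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for j, rec in enumerate(records):
        seq = rec if isinstance(rec, str) else rec.sequence
        seq_ids.append(f"seq{j}" if isinstance(rec, str) else rec.id)
        if alphabet is not None:
            seq = alphabet.recode(seq)
        counter: Counter = Counter()
        n = len(seq)
        for k, gaps, tail_offs in shapes:
            span = k + sum(gaps)
            for s in range(n - span + 1):
                chars = seq[s] + "".join(seq[s + o] for o in tail_offs)
                counter[(k, gaps, chars)] += 1
        for key, c in counter.items():
            i = motif_ids.setdefault(key, len(motif_ids))
            rows.append(i)
            cols.append(j)
            vals.append(1 if mode == "presence" else c)
    order = sorted(motif_ids, key=lambda key: (key[0], key[1], key[2]))
    remap = {motif_ids[key]: i for i, key in enumerate(order)}
    mat = sparse.csr_matrix(
        ([np.int64(v) for v in vals], ([remap[i] for i in rows], cols)),
        shape=(len(order), len(seq_ids)),
        dtype=np.int64,
    )
    return CountMatrix(mat, order, seq_ids, mode, alphabet)
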