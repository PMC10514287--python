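"""Presence-frequency tables and repeat (multiple-occurrence) statistics.

The central observable is the *presence frequency* of a motif: the fraction
of sequences in a set that contain it at least once.  The repeats analysis
looks instead at motifs occurring two or more times within a single
sequence, reporting the maximum repeat count and how common ≥2 and ≥3
occurrences are.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .motifs import CountMatrix, count_matrix

#: presentation-layer defaults per motif size; full tables are never thresholded
DEFAULT_THRESHOLDS: dict[int, float] = {2: 0.25, 3: 0.10, 4: 0.05, 5: 0.05}


def _shape_string(gaps: tuple[int, ...]) -> str:
    return "-".join(str(g) for g in gaps)


def frequency_table(cm: CountMatrix, n_sequences: int | None = None) -> pd.DataFrame:
    """Per-motif presence fractions for one sequence set.

    Returns a DataFrame with columns ``motif, k, shape, n_present, n,
    fraction, percent`` sorted by descending fraction (ties broken by the
    canonical motif string).  ``percent`` is the fraction rounded to one
    decimal on the 0–100 scale, matching the usual reporting style.
    """
    n = cm.n_sequences if n_sequences is None else n_sequences
    if n <= 0:
        raise ValueError("n_sequences must be positive")
    present = cm.presence_counts()
    table = pd.DataFrame(
        {
            "motif": cm.motif_strings(),
            "k": [key[0] for key in cm.motif_keys],
            "shape": [_shape_string(key[1]) for key in cm.motif_keys],
            "n_present": present,
            "n": n,
            "fraction": present / n,
        }
    )
    table["percent"] = (100 * table["fraction"]).round(1)
    table = table.sort_values(
        ["fraction", "motif"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.attrs["alphabet"] = cm.alphabet.name if cm.alphabet else "full"
    return table


def top_motifs(
    table: pd.DataFrame,
    thresholds: Mapping[int, float] | float | None = None,
) -> pd.DataFrame:
    """Motifs at or above the frequency cutoff for their size class.

    ``thresholds`` maps motif size k to a fraction cutoff (a bare float
    applies to all sizes); defaults are the shipped per-size cutoffs.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    if isinstance(thresholds, (int, float)):
        thresholds = {k: float(thresholds) for k in (2, 3, 4, 5)}
    cut = table["k"].map(lambda k: thresholds.get(k, 0.0))
    return table[table["fraction"] >= cut].reset_index(drop=True)


def repeat_analysis(
    records: Iterable,
    k_range: Iterable[int] = (2, 3, 4, 5),
    alphabet=None,
    cm: CountMatrix | None = None,
) -> pd.DataFrame:
    """Statistics over motifs found at least twice in one sequence.

    Returns a DataFrame with columns ``motif, k, shape, max_repeats,
    frac_ge2, frac_ge3`` restricted to motifs whose occurrence count reaches
    2 in at least one sequence; sorted by descending ``max_repeats``.
    """
    if cm is None:
        cm = count_matrix(records, k_range=k_range, mode="count", alphabet=alphabet)
    elif cm.mode != "count":
        raise ValueError("repeat analysis needs a count-mode matrix")
    mat = cm.matrix
    n = cm.n_sequences
    max_rep = np.asarray(mat.max(axis=1).todense()).ravel()
    ge2 = np.asarray((mat >= 2).sum(axis=1)).ravel()
    ge3 = np.asarray((mat >= 3).sum(axis=1)).ravel()
    keep = max_rep >= 2
    strings = cm.motif_strings()
    table = pd.DataFrame(
        {
            "motif": [s for s, m in zip(strings, keep) if m],
            "k": [key[0] for key, m in zip(cm.motif_keys, keep) if m],
            "shape": [_shape_string(key[1]) for key, m in zip(cm.motif_keys, keep) if m],
            "max_repeats": max_rep[keep].astype(int),
            "frac_ge2": ge2[keep] / n,
            "frac_ge3": ge3[keep] / n,
        }
    )
    return table.sort_values(
        ["max_repeats", "frac_ge2", "motif"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
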