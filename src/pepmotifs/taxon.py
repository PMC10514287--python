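"""Taxon-group comparison of motif occurrence.

Sequences are grouped by membership of a named taxon in their lineage;
per-motif occurrence vectors (zeros included for sequences lacking the
motif) are compared between two groups with a two-sided Mann–Whitney U
test, and p-values are Benjamini–Hochberg adjusted within each family of
motifs of one size and gap shape (a global family mode is available).
Motifs observed in one group and entirely absent from the other are flagged
*exclusive*; such calls bypass the test.

The per-sequence observable defaults to the occurrence count rather than
the 0/1 presence flag: on binary data the rank test degenerates toward a
two-proportion test with massive ties, while counts retain resolution.
Presence mode is available behind a flag.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import PeptideRecord
from .motifs import CountMatrix

logger = logging.getLogger(__name__)

#: below this per-group size the exact U distribution is used (no ties only)
EXACT_N = 8


def group_by_taxon(
    records: Sequence[PeptideRecord], taxon_names: Iterable[str]
) -> tuple[dict[str, list[PeptideRecord]], int]:
    """Partition records by lineage membership of the named taxa.

    Taxa compared at one level must be disjoint: a record matching two of
    them is an error (naming the record).  Records matching none are left
    out and tallied in the returned ``n_unassigned``.
    """
    names = list(taxon_names)
    groups: dict[str, list[PeptideRecord]] = {name: [] for name in names}
    n_unassigned = 0
    for rec in records:
        hits = [name for name in names if name in rec.lineage]
        if len(hits) > 1:
            raise ValueError(
                f"record {rec.id!r} belongs to overlapping groups {hits}; "
                "taxa compared at one level must be disjoint"
            )
        if hits:
            groups[hits[0]].append(rec)
        else:
            n_unassigned += 1
    return groups, n_unassigned


def _mwu_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Mann–Whitney U: exact when both sides are small
    and tie-free, tie-corrected normal approximation otherwise."""
    nA, nB = a.shape[1], b.shape[1]
    if a.shape[0] == 0:
        return np.empty(0), np.empty(0)
    # rows constant across both groups carry no rank information: U is its
    # null mean and p = 1 (the tie-corrected variance degenerates to 0 there)
    both = np.concatenate([a, b], axis=1)
    constant = both.max(axis=1) == both.min(axis=1)
    U = np.full(a.shape[0], nA * nB / 2.0)
    p = np.ones(a.shape[0])
    small = max(nA, nB) <= EXACT_N
    if not constant.all():
        idx = np.flatnonzero(~constant)
        if not small:
            # no continuity correction: identical groups give exactly p = 1
            res = stats.mannwhitneyu(
                a[idx], b[idx], alternative="two-sided", method="asymptotic",
                use_continuity=False, axis=1,
            )
            U[idx] = np.atleast_1d(res.statistic)
            p[idx] = np.atleast_1d(res.pvalue)
        else:
            for i in idx:
                x, y = a[i], b[i]
                has_ties = len(np.unique(both[i])) < nA + nB
                res = stats.mannwhitneyu(
                    x, y, alternative="two-sided",
                    method="asymptotic" if has_ties else "exact",
                    use_continuity=False,
                )
                U[i], p[i] = res.statistic, res.pvalue
    return U, p


def mann_whitney_bh(
    cm: CountMatrix,
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    family: Literal["shape", "global"] = "shape",
    observable: Literal["count", "presence"] = "count",
) -> pd.DataFrame:
    """Compare motif occurrence between two groups of sequences.

    ``groups`` maps exactly two group names to sequence-id collections
    (columns of ``cm``).  Motifs tested are the union of motifs observed in
    either group.  Returns a DataFrame with columns ``motif, k, shape,
    group_a, group_b, n_a, n_b, frac_a, frac_b, U, p, p_adj, significant,
    exclusive``, ordered deterministically (by k, shape, motif).  A group
    with fewer than two sequences skips the comparison (empty result,
    logged).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups per comparison")
    (name_a, ids_a), (name_b, ids_b) = groups.items()
    col = {sid: j for j, sid in enumerate(cm.seq_ids)}
    idx_a = [col[s] for s in ids_a]
    idx_b = [col[s] for s in ids_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        logger.warning(
            "skipping comparison %s vs %s: a group has fewer than 2 sequences",
            name_a,
            name_b,
        )
        return _empty_comparison()

    dense = cm.matrix[:, idx_a + idx_b].toarray()
    a, b = dense[:, : len(idx_a)], dense[:, len(idx_a):]
    observed = (a.sum(axis=1) > 0) | (b.sum(axis=1) > 0)
    keys = [key for key, keep in zip(cm.motif_keys, observed) if keep]
    a, b = a[observed], b[observed]
    if observable == "presence" or cm.mode == "presence":
        a, b = (a > 0).astype(int), (b > 0).astype(int)

    frac_a = (a > 0).mean(axis=1)
    frac_b = (b > 0).mean(axis=1)
    U, p = _mwu_rows(a, b)

    table = pd.DataFrame(
        {
            "motif": [cm.motif_string(key) for key in keys],
            "k": [key[0] for key in keys],
            "shape": ["-".join(map(str, key[1])) for key in keys],
            "group_a": name_a,
            "group_b": name_b,
            "n_a": len(idx_a),
            "n_b": len(idx_b),
            "frac_a": frac_a,
            "frac_b": frac_b,
            "U": U,
            "p": p,
        }
    )
    if family == "global" or table.empty:
        fam_keys = pd.Series(0, index=table.index)
    else:
        fam_keys = table["k"].astype(str) + ":" + table["shape"]
    p_adj = np.empty(len(table))
    for _, idx in table.groupby(fam_keys).groups.items():
        p_adj[np.asarray(idx)] = multipletests(
            table.loc[idx, "p"].to_numpy(), method="fdr_bh"
        )[1]
    table["p_adj"] = p_adj
    table["significant"] = table["p_adj"] <= alpha
    table["exclusive"] = ((frac_a == 0) & (frac_b > 0)) | (
        (frac_b == 0) & (frac_a > 0)
    )
    return table.sort_values(["k", "shape", "motif"], kind="mergesort").reset_index(
        drop=True
    )


def _empty_comparison() -> pd.DataFrame:
    cols = [
        "motif", "k", "shape", "group_a", "group_b", "n_a", "n_b",
        "frac_a", "frac_b", "U", "p", "p_adj", "significant", "exclusive",
    ]
    return pd.DataFrame(columns=cols)


def taxon_specific_motifs(
    comparisons: pd.DataFrame, min_fraction: float = 0.0
) -> pd.DataFrame:
    """Motifs to report as taxon-specific: significant with at least
    ``min_fraction`` presence in the enriched group, plus exclusive motifs
    (absent from one group, present in the other), which bypass the test.
    Adds columns ``enriched_group`` and ``call`` (significant | exclusive).
    """
    if comparisons.empty:
        out = comparisons.copy()
        out["enriched_group"] = []
        out["call"] = []
        return out
    enriched_frac = comparisons[["frac_a", "frac_b"]].max(axis=1)
    enriched_group = np.where(
        comparisons["frac_a"] >= comparisons["frac_b"],
        comparisons["group_a"],
        comparisons["group_b"],
    )
    keep_sig = comparisons["significant"] & (enriched_frac >= min_fraction)
    keep_exc = comparisons["exclusive"] & (enriched_frac > 0)
    out = comparisons[keep_sig | keep_exc].copy()
    out["enriched_group"] = enriched_group[(keep_sig | keep_exc).to_numpy()]
    out["call"] = np.where(out["exclusive"], "exclusive", "significant")
    return out.reset_index(drop=True)
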