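"""Taxon grouping, Mann–Whitney comparisons and BH adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from pepmotifs.datasets import PeptideRecord
from pepmotifs.motifs import count_matrix
from pepmotifs.simulate import GeneratorSpec, PlantedMotif, TaxonSpec, generate, preset
from pepmotifs.taxon import group_by_taxon, mann_whitney_bh, taxon_specific_motifs

from .conftest import bh_stepup, make_records


def _rec(i, lineage):
    return PeptideRecord(f"t{i}", "ASLKASLKAS", "cTP", lineage)


class TestGroupByTaxon:
    def test_disjoint_subsets(self):
        records = [
            _rec(0, ("Eukaryota", "Streptophyta")),
            _rec(1, ("Eukaryota", "Chlorophyta")),
            _rec(2, ("Eukaryota", "Streptophyta")),
        ]
        groups, n_un = group_by_taxon(records, ["Streptophyta", "Chlorophyta"])
        assert [r.id for r in groups["Streptophyta"]] == ["t0", "t2"]
        assert [r.id for r in groups["Chlorophyta"]] == ["t1"]
        assert n_un == 0

    def test_empty_lineage_unassigned(self):
        groups, n_un = group_by_taxon([_rec(0, ())], ["Streptophyta"])
        assert n_un == 1 and groups["Streptophyta"] == []

    def test_overlap_errors_naming_record(self):
        rec = _rec(7, ("Viridiplantae", "Streptophyta"))
        with pytest.raises(ValueError, match="t7"):
            group_by_taxon([rec], ["Viridiplantae", "Streptophyta"])

    def test_membership_case_sensitive_exact(self):
        groups, n_un = group_by_taxon([_rec(0, ("streptophyta",))], ["Streptophyta"])
        assert n_un == 1

    def test_planted_group_sizes(self):
        spec = GeneratorSpec(
            n=90,
            taxa=(
                TaxonSpec("A", ("rootA", "A"), weight=1),
                TaxonSpec("B", ("rootB", "B"), weight=1),
                TaxonSpec("C", ("rootC", "C"), weight=1),
            ),
            seed=2,
        )
        records, _ = generate(spec)
        groups, _ = group_by_taxon(records, ["A", "B", "C"])
        assert {k: len(v) for k, v in groups.items()} == {"A": 30, "B": 30, "C": 30}


class TestBH:
    def test_hand_computed_case(self):
        assert np.allclose(bh_stepup([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
        assert np.allclose(
            multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1], [0.03, 0.03, 0.04]
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_stepup_matches_reference_implementation(self, pvals):
        assert np.allclose(
            bh_stepup(pvals), multipletests(pvals, method="fdr_bh")[1], atol=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_monotone_in_rank(self, pvals):
        p = np.asarray(pvals)
        adj = bh_stepup(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1 + 1e-15).all()


class TestMannWhitneyBH:
    def _demo_matrix(self, n_per=30, seed=0, plant_a=0.7, plant_b=0.1):
        spec = GeneratorSpec(
            n=2 * n_per,
            taxa=(
                TaxonSpec("A", ("root", "A"), planted=(PlantedMotif("WW", plant_a),)),
                TaxonSpec("B", ("root", "B"), planted=(PlantedMotif("WW", plant_b),)),
            ),
            seed=seed,
        )
        records, _ = generate(spec)
        groups, _ = group_by_taxon(records, ["A", "B"])
        cm = count_matrix(records, k_range=(2,), mode="count")
        ids = {name: [r.id for r in recs] for name, recs in groups.items()}
        return cm, ids

    def test_identical_groups_null(self):
        """A = B as multisets gives raw p = 1 everywhere, nothing significant."""
        seqs = ["ASLKASLKAS", "KKLLSSAALL", "ASKLSAKLSA"]
        records = make_records(seqs + seqs, lineage=())
        cm = count_matrix(records, k_range=(2,), mode="count")
        ids_a = [r.id for r in records[:3]]
        ids_b = [r.id for r in records[3:]]
        table = mann_whitney_bh(cm, {"A": ids_a, "B": ids_b})
        assert np.allclose(table.p, 1.0, atol=1e-10)
        assert not table.significant.any()

    def test_adjusted_dominates_raw(self):
        cm, ids = self._demo_matrix()
        table = mann_whitney_bh(cm, ids)
        assert (table.p_adj >= table.p - 1e-12).all()
        assert (table.p_adj <= 1 + 1e-12).all()
        assert (table.significant == (table.p_adj <= 0.05)).all()

    def test_bh_family_is_per_shape(self):
        cm, ids = self._demo_matrix()
        table = mann_whitney_bh(cm, ids, family="shape")
        for (_, _), grp in table.groupby(["k", "shape"]):
            assert np.allclose(
                grp.p_adj.to_numpy(), bh_stepup(grp.p.to_numpy()), atol=1e-9
            )

    def test_label_swap_preserves_pvalues(self):
        cm, ids = self._demo_matrix()
        t1 = mann_whitney_bh(cm, ids)
        t2 = mann_whitney_bh(cm, dict(reversed(list(ids.items()))))
        m1 = t1.set_index("motif")
        m2 = t2.set_index("motif")
        assert np.allclose(m1.p, m2.loc[m1.index].p, atol=1e-12)
        assert np.allclose(m1.frac_a, m2.loc[m1.index].frac_b)

    def test_planted_differential_detected(self):
        cm, ids = self._demo_matrix(n_per=60, seed=3, plant_a=0.8, plant_b=0.05)
        table = mann_whitney_bh(cm, ids).set_index("motif")
        row = table.loc["WW"]
        assert row.significant and row.frac_a > row.frac_b

    def test_small_group_skipped(self, caplog):
        cm, ids = self._demo_matrix(n_per=30)
        table = mann_whitney_bh(cm, {"A": ids["A"][:1], "B": ids["B"]})
        assert table.empty

    def test_two_groups_required(self):
        cm, ids = self._demo_matrix()
        with pytest.raises(ValueError):
            mann_whitney_bh(cm, {"A": ids["A"]})


class TestTaxonSpecific:
    def test_exclusive_call(self):
        seqs_a = ["WWASLKASLK", "ASLKWWASLK"]
        seqs_b = ["ASLKASLKAS", "KLSAKLSAKL", "SSAALLKKAA"]
        records = make_records(seqs_a, prefix="a") + make_records(seqs_b, prefix="b")
        cm = count_matrix(records, k_range=(2,), mode="count")
        table = mann_whitney_bh(
            cm,
            {"A": [f"a{i}" for i in range(2)], "B": [f"b{i}" for i in range(3)]},
        )
        calls = taxon_specific_motifs(table).set_index("motif")
        assert calls.loc["WW", "call"] == "exclusive"
        assert calls.loc["WW", "enriched_group"] == "A"

    def test_min_fraction_excludes(self):
        cm, ids = TestMannWhitneyBH()._demo_matrix(n_per=60, seed=3, plant_a=0.3, plant_b=0.0)
        table = mann_whitney_bh(cm, ids)
        strict = taxon_specific_motifs(table, min_fraction=0.99)
        assert (strict.call == "exclusive").all()  # significant ones filtered out

    def test_recovers_planted_exclusive_in_preset(self):
        records, _ = generate(preset("two-taxon-demo", n=160, seed=8))
        groups, _ = group_by_taxon(records, ["Streptophyta", "Chlorophyta"])
        cm = count_matrix(records, k_range=(3,), mode="count")
        table = mann_whitney_bh(
            cm,
            {name: [r.id for r in recs] for name, recs in groups.items()},
        )
        calls = taxon_specific_motifs(table)
        exc = calls[calls.call == "exclusive"].set_index("motif")
        assert "WCW" in exc.index
        assert exc.loc["WCW", "enriched_group"] == "Streptophyta"
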