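"""Distances, neighbor joining, bootstrap and subclass assignment."""

import numpy as np
import pytest

from hsfkit.phylogeny_classify import (
    DistanceMatrix, assign_subclasses, bipartitions, bootstrap_support,
    build_anchored_alignment, build_nj_tree, distance_matrix,
    extract_n_terminal_region, pdistance, poisson_correct,
)
from hsfkit.sequence_io import ProteinRecord


class TestPDistance:
    def test_identical_rows(self):
        assert pdistance("AAAA", "AAAA") == 0.0

    def test_one_in_four(self):
        assert pdistance("AAAA", "AAAT") == 0.25

    def test_pairwise_deletion_excludes_gapped_sites(self):
        assert pdistance("A-AA", "AAAA") == 0.0
        assert pdistance("A-AT", "AAAA") == pytest.approx(1 / 3)

    def test_all_gaps_is_an_error(self):
        with pytest.raises(ValueError, match="zero comparable"):
            pdistance("--", "AA")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pdistance("AA", "AAA")


class TestPoissonCorrection:
    @pytest.mark.parametrize("p,d", [(0.0, 0.0), (0.1, 0.105361),
                                     (0.5, 0.693147)])
    def test_closed_form(self, p, d):
        assert poisson_correct(p) == pytest.approx(d, abs=1e-6)

    def test_saturated_rejected(self):
        with pytest.raises(ValueError):
            poisson_correct(1.0)

    def test_increasing_and_dominates_p(self):
        grid = np.linspace(0, 0.99, 100)
        vals = [poisson_correct(p) for p in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(v >= p for v, p in zip(vals, grid))


# ---------------------------------------------------------------------------
# random additive trees as the NJ oracle

def random_additive_tree(n_taxa, rng):
    """Random topology + branch lengths; returns (distance matrix, splits)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    # grow an unrooted tree by sequential leaf attachment; represent as
    # an edge-weighted graph, then distances = path lengths
    import itertools

    import networkx as nx

    g = nx.Graph()
    g.add_edge(taxa[0], taxa[1], weight=rng.uniform(0.05, 1.0))
    internal = 0
    for leaf in taxa[2:]:
        u, v = list(g.edges())[int(rng.integers(0, g.number_of_edges()))]
        w = g[u][v]["weight"]
        internal += 1
        mid = f"x{internal}"
        split = rng.uniform(0.2, 0.8) * w
        g.remove_edge(u, v)
        g.add_edge(u, mid, weight=split)
        g.add_edge(mid, v, weight=w - split)
        g.add_edge(mid, leaf, weight=rng.uniform(0.05, 1.0))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    m = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        m[i, j] = m[j, i] = dist[taxa[i]][taxa[j]]
    # splits: for each internal edge, the leaf set on one side
    splits = set()
    all_taxa = frozenset(taxa)
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(t for t in taxa if nx.has_path(h, t, u))
        if 1 < len(side) < n_taxa - 1:
            other = all_taxa - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return DistanceMatrix(tuple(taxa), m), splits, g


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]),
        )
        tree = build_nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 0.1, "b": 0.3, "c": 0.5})

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(5)
        dm, splits, _ = random_additive_tree(4, rng)
        tree = build_nj_tree(dm)
        assert bipartitions(tree) == splits

    def test_recovers_random_additive_trees_with_lengths(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            dm, splits, g = random_additive_tree(n, rng)
            tree = build_nj_tree(dm)
            assert bipartitions(tree) == splits
            # pendant + internal lengths reproduce all pairwise distances
            import itertools
            for i, j in itertools.combinations(range(n), 2):
                a, b = dm.taxa[i], dm.taxa[j]
                d = tree.find(a).distance(tree.find(b))
                assert d == pytest.approx(dm.values[i, j], abs=1e-9)

    def test_equal_distances_tie_break_is_deterministic(self):
        m = np.full((5, 5), 1.0)
        np.fill_diagonal(m, 0.0)
        dm = DistanceMatrix(tuple("abcde"), m)
        t1 = build_nj_tree(dm)
        t2 = build_nj_tree(dm)
        assert str(t1) == str(t2)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_matches_scikit_bio_topology(self):
        """Independent cross-check of NJ against scikit-bio's implementation."""
        import skbio

        rng = np.random.default_rng(12)
        for _ in range(5):
            dm, _, _ = random_additive_tree(7, rng)
            ours = build_nj_tree(dm)
            theirs = skbio.tree.nj(
                skbio.DistanceMatrix(dm.values, ids=dm.taxa))
            assert bipartitions(ours) == bipartitions(theirs)


class TestBootstrap:
    def make_alignment(self):
        return {
            "a": "AAAAAAAAAACCCCCCCCCC",
            "b": "AAAAAAAAAACCCCCCCCCC",
            "c": "AAAATTTTTTCCCGGGGGGG",
            "d": "AAAATTTTTTCCCGGGGGAA",
        }

    def test_identical_pair_gets_full_support(self):
        sup = bootstrap_support(self.make_alignment(), n_replicates=50, seed=1)
        cherry = frozenset({"a", "b"})
        assert sup[cherry] == pytest.approx(100.0)

    def test_single_replicate_gives_zero_or_hundred(self):
        sup = bootstrap_support(self.make_alignment(), n_replicates=1, seed=2)
        assert set(sup.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces(self):
        aln = self.make_alignment()
        s1 = bootstrap_support(aln, n_replicates=25, seed=3)
        s2 = bootstrap_support(aln, n_replicates=25, seed=3)
        assert s1 == s2

    def test_invariant_to_taxon_input_order(self):
        aln = self.make_alignment()
        rev = dict(reversed(list(aln.items())))
        assert bootstrap_support(aln, 25, seed=4) == \
            bootstrap_support(rev, 25, seed=4)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.make_alignment(), n_replicates=0)


class TestNTerminalRegion:
    def test_span_arithmetic(self):
        prot = ProteinRecord("p", "M" * 200)
        region = extract_n_terminal_region(prot, (10, 105), (150, 180))
        assert len(region) == 171  # residues 10..180 inclusive

    def test_end_beyond_length_rejected(self):
        prot = ProteinRecord("p", "M" * 100)
        with pytest.raises(ValueError):
            extract_n_terminal_region(prot, (10, 50), (90, 120))

    def test_missing_domain_rejected(self):
        prot = ProteinRecord("p", "M" * 100)
        with pytest.raises(ValueError):
            extract_n_terminal_region(prot, None, (90, 95))


class TestSubclassAssignment:
    def _setup(self, clean_family, dbd_profile):
        from hsfkit.pipeline import annotate_candidate

        seqs, spans, insert_cls = {}, {}, {}
        for rec in clean_family.members + clean_family.references:
            c = annotate_candidate(rec, dbd_profile)
            seqs[rec.id] = rec.sequence
            spans[rec.id] = (c.dbd.span, c.hrab.hr_a_span, c.hrab.hr_b_span)
            insert_cls[rec.id] = c.classification.hsf_class
        aln = build_anchored_alignment(seqs, spans)
        tree = build_nj_tree(distance_matrix(aln))
        sup = bootstrap_support(aln, n_replicates=50, seed=9)
        return aln, tree, sup, insert_cls

    def test_recovers_generator_truth(self, clean_family, dbd_profile):
        aln, tree, sup, insert_cls = self._setup(clean_family, dbd_profile)
        queries = [r.id for r in clean_family.members]
        out = assign_subclasses(
            tree, queries, clean_family.reference_subclasses, aln,
            supports=sup, insert_classes=insert_cls)
        for a in out:
            assert a.subclass == clean_family.truth[a.gene_id].subclass

    def test_reference_free_clade_gets_next_class_index(self, dbd_profile):
        from hsfkit.pipeline import annotate_candidate
        from hsfkit.synthetic_data import FamilySpec, generate_family

        fam = generate_family(FamilySpec(
            counts={"C1": 2, "C2": 2, "C3": 3}, reference_free=("C3",),
            decoy_count=0, seed=31))
        seqs, spans, insert_cls = {}, {}, {}
        for rec in fam.members + fam.references:
            c = annotate_candidate(rec, dbd_profile)
            seqs[rec.id] = rec.sequence
            spans[rec.id] = (c.dbd.span, c.hrab.hr_a_span, c.hrab.hr_b_span)
            insert_cls[rec.id] = c.classification.hsf_class
        aln = build_anchored_alignment(seqs, spans)
        tree = build_nj_tree(distance_matrix(aln))
        sup = bootstrap_support(aln, n_replicates=50, seed=10)
        out = assign_subclasses(
            tree, [r.id for r in fam.members], fam.reference_subclasses,
            aln, supports=sup, insert_classes=insert_cls)
        c3 = [a for a in out if fam.truth[a.gene_id].subclass == "C3"]
        assert c3 and all(a.subclass == "C3" and a.conflict == "novel"
                          for a in c3)

    def test_unsupported_clades_leave_query_unresolved(
            self, clean_family, dbd_profile):
        aln, tree, sup, insert_cls = self._setup(clean_family, dbd_profile)
        zero = {k: 0.0 for k in sup}
        out = assign_subclasses(
            tree, [clean_family.members[0].id],
            clean_family.reference_subclasses, aln, supports=zero,
            insert_classes=insert_cls)
        assert out[0].subclass == "unresolved"

    def test_query_absent_from_tree_rejected(self, clean_family, dbd_profile):
        aln, tree, sup, insert_cls = self._setup(clean_family, dbd_profile)
        with pytest.raises(ValueError, match="absent"):
            assign_subclasses(tree, ["ghost"],
                              clean_family.reference_subclasses, aln)
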