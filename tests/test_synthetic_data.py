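"""Generator determinism, truth-table consistency and design contracts."""

import numpy as np
import pytest

from hsfkit.expression_analysis import call_responses
from hsfkit.sequence_io import parse_gene_name, write_fasta
from hsfkit.synthetic_data import (
    FamilySpec, expected_call, generate_allohexaploid, generate_expression,
    generate_family, generate_gene_models,
)


class TestFamilySpec:
    def test_contradictory_motif_plan_rejected(self):
        with pytest.raises(ValueError, match="class A"):
            FamilySpec(motif_plan={"B": ("AHA",)})
        with pytest.raises(ValueError, match="class B"):
            FamilySpec(motif_plan={"C": ("LFGV",)})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec(counts={"A1": -1})


class TestGenerateFamily:
    def test_fixed_seed_reproduces_fasta_bytes(self, tmp_path):
        spec = FamilySpec(counts={"A1": 2, "B1": 2}, decoy_count=5, seed=5)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(generate_family(spec).proteome, p1)
        write_fasta(generate_family(spec).proteome, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truth_spans_and_motifs_match_sequences(self, clean_family):
        for rec in clean_family.members:
            t = clean_family.truth[rec.id]
            assert parse_gene_name(rec.id).subclass == t.subclass
            s, e = t.hra_span
            hra = rec.sequence[s - 1:e]
            assert all(c in "LIVFMA" for c in hra[0::7])  # a anchors
            assert t.insert_length == t.hrb_span[0] - t.hra_span[1] - 1
            for m in t.motifs:
                assert rec.sequence[
                    m.position - 1:m.position - 1 + len(m.matched)
                ] == m.matched

    def test_class_layout_follows_insert_defaults(self, clean_family):
        for t in clean_family.truth.values():
            assert t.insert_length == {"A": 21, "B": 0, "C": 7}[t.hsf_class]

    def test_motif_exclusivity(self, clean_family):
        for t in clean_family.truth.values():
            kinds = {m.kind for m in t.motifs}
            if t.hsf_class == "A":
                assert "AHA" in kinds and "LFGV" not in kinds
            if t.hsf_class == "B":
                assert "LFGV" in kinds and "AHA" not in kinds
            if t.hsf_class == "C":
                assert kinds.isdisjoint({"AHA", "LFGV"})


class TestAllohexaploid:
    def test_triads_pairs_singletons_accounting(self):
        spec = FamilySpec(counts={"A1": 4, "C1": 3}, decoy_count=0, seed=8)
        fam = generate_allohexaploid(spec, n_singleton_groups=2,
                                     n_pair_groups=1)
        triads = {t.triad_id for t in fam.truth.values() if t.triad_id}
        assert len(triads) == 4  # 7 groups - 2 singletons - 1 pair
        assert len(fam.members) == 2 * 1 + 1 * 2 + 4 * 3

    def test_triad_chromosomes_share_group_number(self):
        spec = FamilySpec(counts={"A1": 2, "B1": 2}, decoy_count=0, seed=9)
        fam = generate_allohexaploid(spec)
        by_triad = {}
        for t in fam.truth.values():
            by_triad.setdefault(t.triad_id, []).append(t.chromosome)
        for tid, chroms in by_triad.items():
            assert sorted(c[1] for c in chroms) == ["A", "B", "D"]
            assert len({c[0] for c in chroms}) == 1

    def test_triad_identity_near_target(self):
        spec = FamilySpec(counts={"A1": 2}, decoy_count=0, seed=10,
                          triad_identity=0.97)
        fam = generate_allohexaploid(spec)
        groups = {}
        for rec in fam.members:
            groups.setdefault(fam.truth[rec.id].triad_id, []).append(rec)
        for recs in groups.values():
            a, b = recs[0].sequence, recs[1].sequence
            ident = np.mean([x == y for x, y in zip(a, b)])
            assert 0.93 <= ident <= 1.0


class TestGeneModels:
    def test_intron_lengths_within_stated_range(self):
        spec = FamilySpec(counts={"A1": 3, "B1": 3}, decoy_count=0, seed=12)
        fam = generate_family(spec)
        models = generate_gene_models(fam)
        for gid, d in models.items():
            t = fam.truth[gid]
            assert t.intron_in_dbd
            ilen = len(d["genomic"]) - len(d["cdna"])
            assert 80 <= ilen <= 5836
            intron = d["genomic"][t.exons[0][1]:t.exons[1][0] - 1]
            assert intron.startswith("GT") and intron.endswith("AG")

    def test_designated_subclass_is_intronless(self):
        spec = FamilySpec(counts={"C3": 3}, reference_free=("C3",),
                          decoy_count=0, seed=13)
        fam = generate_family(spec)
        models = generate_gene_models(fam)
        for gid, d in models.items():
            assert d["cdna"] == d["genomic"]
            assert not fam.truth[gid].intron_in_dbd

    def test_cdna_translates_back_to_protein(self):
        from Bio.Seq import Seq

        spec = FamilySpec(counts={"A1": 1}, decoy_count=0, seed=14)
        fam = generate_family(spec)
        models = generate_gene_models(fam)
        gid, d = next(iter(models.items()))
        assert str(Seq(d["cdna"]).translate()) == \
            fam.members[0].sequence + "*"


class TestExpressionGenerator:
    def test_noiseless_design_reproduced_exactly(self, clean_family):
        m = generate_expression(clean_family, sigma=0.0)
        for c in call_responses(m):
            t = clean_family.truth[c.gene]
            assert c.call == expected_call(t, c.organ, c.treatment)

    def test_root_specific_gene_not_expressed_in_leaf(self, clean_family):
        gid = clean_family.members[0].id
        m = generate_expression(clean_family, sigma=0.0,
                                root_specific=(gid,))
        leaf_calls = [c for c in call_responses(m)
                      if c.gene == gid and c.organ == "leaf"]
        assert all(c.call == "not_expressed" for c in leaf_calls)
        clean_family.truth[gid].root_specific = False  # restore fixture

    def test_fixed_seed_reproduces_matrix(self, clean_family):
        m1 = generate_expression(clean_family, sigma=0.3, seed=3)
        m2 = generate_expression(clean_family, sigma=0.3, seed=3)
        assert m1.data.equals(m2.data)

    def test_tsv_round_trip(self, clean_family, tmp_path):
        from hsfkit.expression_analysis import ExpressionMatrix

        m = generate_expression(clean_family, sigma=0.1, seed=4)
        p = tmp_path / "expr.tsv"
        m.to_tsv(p)
        back = ExpressionMatrix.from_tsv(p)
        assert np.allclose(back.data.to_numpy(), m.data.to_numpy())
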