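"""Motif scanners against regex oracles; MW and pI calculators."""

import re

import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight
from hypothesis import given, settings
from hypothesis import strategies as st

from hsfkit.motif_annotation import (
    DEFAULT_ER_LEXICON, compute_mw, compute_pi, net_charge, scan_aha,
    scan_c_terminal_signals, scan_nes, scan_nls,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# regex oracles (independent of the positional-logic implementations)

AHA_RE = re.compile(r"FW..[FL]")
NES_RE = re.compile(r"[LIVFM].{0,5}[LIVFM].{0,4}[LIVFM].{0,2}[LIVFM]")


def oracle_aha(s):
    return [(m.start() + 1, m.group()) for m in AHA_RE.finditer(s)]


def oracle_nes(s):
    hits, covered = [], -1
    for i in range(len(s)):
        m = NES_RE.match(s, i)
        if m and m.end() > covered:
            hits.append((i + 1, m.group()))
            covered = m.end()
    return hits


def oracle_nls(s):
    basic = lambda frag: len(re.findall("[KR]", frag))
    mono_pos = [i for i in range(len(s) - 3) if basic(s[i:i + 4]) >= 3]
    mono, i = [], 0
    while i < len(mono_pos):
        start = mono_pos[i]
        end = start + 4
        while i + 1 < len(mono_pos) and mono_pos[i + 1] <= end:
            i += 1
            end = mono_pos[i] + 4
        mono.append((start + 1, s[start:end]))
        i += 1
    bi = []
    for i in range(len(s) - 2):
        if basic(s[i:i + 3]) < 2:
            continue
        for spacer in range(6, 15):
            j = i + 3 + spacer
            if j + 5 > len(s):
                break
            if basic(s[j:j + 5]) >= 3:
                bi.append((i + 1, s[i:j + 5]))
                break
    return mono, bi


class TestAha:
    def test_published_class_a_motifs(self):
        hits = scan_aha("DSFWEQFLCA")
        assert [(h.position, h.matched) for h in hits] == [(3, "FWEQF")]
        hits = scan_aha("DDFWEDLLHE")
        assert [(h.position, h.matched) for h in hits] == [(3, "FWEDL")]

    def test_poly_alanine_has_no_hits(self):
        assert scan_aha("A" * 50) == []

    def test_strict_mode_requires_trailing_hydrophobic(self):
        assert scan_aha("DDFWEQFDDD", trailing_optional=False) == []
        assert scan_aha("DDFWEQFLDD", trailing_optional=False) != []


class TestNls:
    def test_published_monopartite(self):
        hits = scan_nls("AAEEKKRRDDS")
        mono = [h for h in hits if h.kind == "NLS_mono"]
        assert len(mono) == 1 and "KKRR" in mono[0].matched

    def test_published_bipartite(self):
        hits = scan_nls("KRKELEDAISNKRRRRID")
        assert any(h.kind == "NLS_bipartite" for h in hits)

    def test_sparse_basic_residues_give_no_hits(self):
        assert scan_nls("KADRKAADRK") == []


class TestNes:
    @pytest.mark.parametrize("seq", ["LDVRQLDLRLLM", "LKRDRQLLM"])
    def test_published_nes_motifs_match(self, seq):
        assert scan_nes(seq) != []

    def test_poly_glycine_has_no_hits(self):
        assert scan_nes("G" * 40) == []


@pytest.fixture(scope="module")
def random_seqs():
    rng = np.random.default_rng(17)
    return [
        "".join(rng.choice(list(AA), size=int(rng.integers(10, 201))))
        for _ in range(300)
    ]


class TestOracleEquivalence:
    """Scanner outputs equal the regex oracles on random sequences."""

    def test_aha(self, random_seqs):
        for s in random_seqs:
            got = [(h.position, h.matched) for h in scan_aha(s)]
            assert got == oracle_aha(s)

    def test_nes(self, random_seqs):
        for s in random_seqs:
            got = [(h.position, h.matched) for h in scan_nes(s)]
            assert got == oracle_nes(s)

    def test_nls(self, random_seqs):
        for s in random_seqs:
            mono, bi = oracle_nls(s)
            got_mono = [(h.position, h.matched) for h in scan_nls(s)
                        if h.kind == "NLS_mono"]
            got_bi = [(h.position, h.matched) for h in scan_nls(s)
                      if h.kind == "NLS_bipartite"]
            assert got_mono == mono
            assert got_bi == bi


class TestCTerminalSignals:
    def test_er_tetrapeptide_at_terminus(self):
        s = "M" + "S" * 100 + "AEKL"
        hits = scan_c_terminal_signals(s)
        er = [h for h in hits if h.kind == "ER"]
        assert er and er[0].position == len(s) - 3 and er[0].matched == "AEKL"

    def test_er_lexicon_is_configurable(self):
        s = "M" + "S" * 50 + "QQQQ"
        assert scan_c_terminal_signals(s) == []
        hits = scan_c_terminal_signals(s, er_lexicon=("QQQQ",))
        assert hits[0].kind == "ER"

    def test_lfgv_in_c_terminal_half_only(self):
        n = 100
        mid = ("S" * 60) + "LFGV" + ("S" * 36)
        hits = scan_c_terminal_signals(mid)
        assert any(h.kind == "LFGV" and h.position == 61 for h in hits)
        early = "LFGV" + "S" * 96
        assert all(h.kind != "LFGV" for h in scan_c_terminal_signals(early))
        assert len(mid) == len(early) == n

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_c_terminal_signals("MKL")

    def test_default_lexicon_covers_published_signals(self):
        for sig in ("AEKL", "AQKM", "DRVL", "SAQK", "SAEK", "EQLK", "GNMK"):
            assert sig in DEFAULT_ER_LEXICON


class TestMolecularWeight:
    def test_diglycine_exact(self):
        assert compute_mw("GG") == pytest.approx(132.1191, abs=1e-4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_mw("")

    def test_matches_expasy_convention_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            s = "".join(rng.choice(list(AA), size=209))
            expected = molecular_weight(s, seq_type="protein",
                                        monoisotopic=False)
            assert abs(compute_mw(s) - expected) < 20.0  # ±0.02 kDa

    @given(st.text(alphabet=AA, min_size=1, max_size=30),
           st.text(alphabet=AA, min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_additivity(self, s1, s2):
        assert compute_mw(s1 + s2) == pytest.approx(
            compute_mw(s1) + compute_mw(s2) - 18.0153, abs=1e-6)


class TestIsoelectricPoint:
    def test_net_charge_vanishes_at_pi(self):
        for s in ("MKWVTFISLLFLFSSAYS", "DDDDDDDDDD", "KKKKKKKKKK"):
            assert abs(net_charge(s, compute_pi(s))) < 1e-3

    def test_acidic_peptide_below_4(self):
        assert compute_pi("D" * 10) < 4.0

    def test_basic_peptide_above_9(self):
        assert compute_pi("K" * 10) > 9.0

    def test_charge_strictly_decreasing_in_ph(self):
        s = "ACDEFGHIKLMNPQRSTVWY"
        charges = [net_charge(s, ph) for ph in np.linspace(0.5, 13.5, 40)]
        assert all(a > b for a, b in zip(charges, charges[1:]))
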