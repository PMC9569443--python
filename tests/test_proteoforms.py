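"""Proteoform derivation, tryptic digestion and surrogate selection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import parser as ptparser

from laminprm.proteoforms import (
    FARN_PRELAMIN,
    MATURE,
    OBSERVABLE_PROTEOFORMS,
    PRELAMIN,
    PROGERIN,
    SurrogatePolicy,
    assign_signatures,
    build_proteoforms,
    bundled_sequence,
    digest_proteoform,
    select_surrogates,
    tryptic_digest,
)
from conftest import TOY_DELETION, TOY_PRELAMIN
from reference_values import HUMAN_PANEL_PEPTIDES, MOUSE_PANEL_PEPTIDES


class TestBuildProteoforms:
    def test_toy_lengths(self, toy_prelamin):
        pfs = build_proteoforms(toy_prelamin, TOY_DELETION)
        n = len(toy_prelamin)
        assert len(pfs[MATURE].sequence) == n - 18
        assert len(pfs[FARN_PRELAMIN].sequence) == n - 3
        d = TOY_DELETION[1] - TOY_DELETION[0] + 1
        assert len(pfs[PROGERIN].sequence) == n - d - 3

    def test_farnesylated_terminus(self, toy_prelamin):
        pfs = build_proteoforms(toy_prelamin, TOY_DELETION)
        for name in (FARN_PRELAMIN, PROGERIN):
            pf = pfs[name]
            assert pf.sequence.endswith("C")
            assert {m.name for m in pf.terminal_mods} == {"farnesyl", "o_methyl"}
        assert pfs[MATURE].terminal_mods == ()
        assert pfs[PRELAMIN].sequence == toy_prelamin

    def test_missing_caax_rejected(self):
        with pytest.raises(ValueError, match="CAAX"):
            build_proteoforms("AGELKSSQTRSVAGKLNDTRSQSSQNGSIM")

    def test_deletion_without_cleavage_site_warns(self, toy_prelamin):
        with pytest.warns(UserWarning, match="Zmpste24"):
            build_proteoforms(toy_prelamin, (2, 5))
        with pytest.raises(ValueError, match="Zmpste24"):
            build_proteoforms(toy_prelamin, (2, 5), strict_deletion=True)

    def test_bundled_deletion_length_is_50(self):
        for acc in ("P02545", "P48678"):
            _, (start, end) = bundled_sequence(acc)
            assert end - start + 1 == 50


class TestTrypticDigest:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAAKGGR", ["AAAK", "GGR"]),
            ("AAKPGG", ["AAKPGG"]),  # no cleavage before proline
            ("KGR", ["K", "GR"]),
        ],
    )
    def test_cleavage_rule(self, seq, expected):
        assert [p.sequence for p in tryptic_digest(seq)] == expected

    def test_coordinates_are_one_based_inclusive(self):
        peps = tryptic_digest("AAAKGGR")
        assert [(p.start, p.end) for p in peps] == [(1, 4), (5, 7)]

    def test_missed_cleavages(self):
        seqs = {p.sequence for p in tryptic_digest("AAAKGGRCCK", missed=1)}
        assert seqs == {"AAAK", "GGR", "CCK", "AAAKGGR", "GGRCCK"}

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.text(alphabet="ACDGKLPRSTVY", min_size=1, max_size=60))
    def test_concatenation_reconstructs_sequence(self, seq):
        peps = tryptic_digest(seq)
        assert "".join(p.sequence for p in peps) == seq
        assert all(seq[p.start - 1 : p.end] == p.sequence for p in peps)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.text(alphabet="ACDGKLPRSTVY", min_size=1, max_size=60))
    def test_matches_pyteomics_cleave(self, seq):
        ours = {p.sequence for p in tryptic_digest(seq)}
        theirs = ptparser.cleave(seq, r"[KR](?!P)", missed_cleavages=0)
        assert ours == set(theirs)


class TestSignatures:
    def test_progerin_digest_ends_in_signature_peptide(self):
        for acc, tail in (("P02545", "ASASGSGAQSPQNC"), ("P48678", "AAGGAGAQSSQNC")):
            seq, deletion = bundled_sequence(acc)
            pfs = build_proteoforms(seq, deletion)
            peps = digest_proteoform(pfs[PROGERIN])
            assert peps[-1].sequence == tail
            assert {m.name for m in peps[-1].terminal_mods} == {"farnesyl", "o_methyl"}

    def test_la_peptide_lies_in_deletion_interval(self):
        for acc in ("P02545", "P48678"):
            seq, (dstart, dend) = bundled_sequence(acc)
            pfs = build_proteoforms(seq, (dstart, dend))
            peps = digest_proteoform(pfs[PRELAMIN])
            (la,) = [p for p in peps if p.sequence == "SVGGSGGGSFGDNLVTR"]
            assert dstart <= la.start and la.end <= dend

    def test_peptides_overlapping_deletion_absent_from_progerin(self):
        seq, deletion = bundled_sequence("P48678")
        pfs = build_proteoforms(seq, deletion)
        assignments = assign_signatures(pfs)
        by_seq = {a.peptide.sequence: a for a in assignments if not a.peptide.mods}
        assert PROGERIN not in by_seq["SVGGSGGGSFGDNLVTR"].found_in
        assert PROGERIN not in by_seq["SYLLGNSSPR"].found_in

    def test_order_invariance(self):
        seq, deletion = bundled_sequence("P48678")
        pfs = build_proteoforms(seq, deletion)
        forward = assign_signatures({k: pfs[k] for k in sorted(pfs)})
        backward = assign_signatures({k: pfs[k] for k in sorted(pfs, reverse=True)})
        assert forward == backward

    def test_identical_proteoforms_all_shared(self, toy_prelamin):
        pfs = build_proteoforms(toy_prelamin)
        twins = {"a": pfs[PRELAMIN], "b": pfs[PRELAMIN]}
        twins = {
            "a": pfs[PRELAMIN].__class__("a", toy_prelamin),
            "b": pfs[PRELAMIN].__class__("b", toy_prelamin),
        }
        assert all(a.status == "shared_all" for a in assign_signatures(twins))

    def test_terminal_mods_distinguish_identical_sequences(self, toy_prelamin):
        # toy zFP (SQSSQNC + farnesyl/O-methyl) never merges with an
        # unmodified SQSSQNC tryptic product of full prelamin A
        pfs = build_proteoforms(toy_prelamin)
        assignments = assign_signatures(pfs)
        keys = {
            (a.peptide.sequence, tuple(m.name for _, m in a.peptide.mods))
            for a in assignments
        }
        assert ("SQSSQNC", ("farnesyl", "o_methyl")) in keys
        assert ("SQSSQNCSIM", ()) in keys

    def test_requires_two_proteoforms(self, toy_prelamin):
        pfs = build_proteoforms(toy_prelamin)
        with pytest.raises(ValueError):
            assign_signatures({PRELAMIN: pfs[PRELAMIN]})


@pytest.fixture(scope="module")
def mouse_selection():
    seq, deletion = bundled_sequence("P48678")
    pfs = build_proteoforms(seq, deletion)
    observable = {n: pfs[n] for n in OBSERVABLE_PROTEOFORMS}
    assignments = assign_signatures(observable)
    policy = SurrogatePolicy((MATURE, FARN_PRELAMIN, PROGERIN))
    return select_surrogates(assignments, policy)


class TestSurrogateSelection:
    def test_mouse_panel_is_the_five_named_peptides(self, mouse_selection):
        picked = {
            (a.peptide.sequence, bool(a.peptide.mods))
            for group in mouse_selection.values()
            for a in group
        }
        assert picked == set(MOUSE_PANEL_PEPTIDES.values())

    def test_mouse_roles(self, mouse_selection):
        assert [a.peptide.sequence for a in mouse_selection["control"]] == [
            "TVLCGTCGQPADK"
        ]
        assert [a.peptide.sequence for a in mouse_selection[MATURE]] == [
            "SVGGSGGGSFGDNLVTR"
        ]
        farn = {a.peptide.sequence for a in mouse_selection[FARN_PRELAMIN]}
        assert farn == {"SYLLGNSSPR", "SQSSQNC"}
        assert [a.peptide.sequence for a in mouse_selection[PROGERIN]] == [
            "AAGGAGAQSSQNC"
        ]

    def test_prela_unique_to_farnesylated_prelamin(self, mouse_selection):
        (prela,) = [
            a
            for a in mouse_selection[FARN_PRELAMIN]
            if a.peptide.sequence == "SYLLGNSSPR"
        ]
        assert prela.status == "unique" and prela.found_in == {FARN_PRELAMIN}

    def test_human_panel(self):
        seq, deletion = bundled_sequence("P02545")
        pfs = build_proteoforms(seq, deletion)
        observable = {n: pfs[n] for n in OBSERVABLE_PROTEOFORMS}
        selection = select_surrogates(
            assign_signatures(observable), SurrogatePolicy((MATURE, PROGERIN))
        )
        picked = {
            (a.peptide.sequence, bool(a.peptide.mods))
            for group in selection.values()
            for a in group
        }
        assert picked == set(HUMAN_PANEL_PEPTIDES.values())

    def test_no_interest_returns_control_only(self, mouse_selection):
        seq, deletion = bundled_sequence("P48678")
        pfs = build_proteoforms(seq, deletion)
        assignments = assign_signatures({n: pfs[n] for n in OBSERVABLE_PROTEOFORMS})
        out = select_surrogates(assignments, SurrogatePolicy(()))
        assert list(out) == ["control"] and len(out["control"]) == 1

    def test_proteoform_without_unique_peptide_gets_empty_entry(self, toy_prelamin):
        pfs = build_proteoforms(toy_prelamin)
        # two sequence-identical proteoforms: nothing discriminates them
        twins = {
            "a": pfs[PRELAMIN].__class__("a", toy_prelamin),
            "b": pfs[PRELAMIN].__class__("b", toy_prelamin),
        }
        out = select_surrogates(
            assign_signatures(twins), SurrogatePolicy(("a",), allow_fallback=False)
        )
        assert out["a"] == []

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValueError):
            select_surrogates([], SurrogatePolicy(()))
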