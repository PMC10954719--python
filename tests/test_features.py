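"""Structural annotation, feature extraction, motifs and group tests."""

import numpy as np
import pandas as pd
import pytest

from droshascan import features as FT
from droshascan import folding, stemloop, synthetic
from droshascan.stemloop import TerminusStack, reconstruct_stemloop


def _label(db, s_idx, e_idx):
    table = folding.parse_dotbracket(db)
    cats, loops, split = FT._label_structure(table, s_idx, e_idx)
    return cats


# ---------------------------------------------------------------------------
# category labelling (hand-checked structures)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "db,expected",
    [
        ("..((((...))))..", "FFPPPPTTTPPPPFF"),
        ("((.((...)).))", "PPIPPTTTPPIPP"),  # 1x1 symmetric internal loop
        ("((..((...))))", "PPBBPPTTTPPPP"),  # 2x0 bulge is asymmetric
    ],
)
def test_hand_annotated_structures(db, expected):
    assert _label(db, db.index("("), len(db) - 1 - db[::-1].index(")")) == expected


def test_annotation_is_exhaustive_and_exclusive(designed_hairpin):
    call = _design_call(designed_hairpin)
    genome = {"chrS": designed_hairpin.sequence.replace("U", "T")}
    ann = FT.annotate_positions(call, genome)
    assert len(ann.categories) == len(ann.sequence)
    assert set(ann.categories) <= set(FT.CATEGORIES)


def test_constrained_refold_keeps_called_pairs(designed_hairpin):
    """Every pair of the 15-nt-flank structure survives the 25-nt refold."""
    call = _design_call(designed_hairpin)
    genome = {"chrS": designed_hairpin.sequence.replace("U", "T")}
    ann = FT.annotate_positions(call, genome)
    assert ann.constrained
    shift = ann.s_idx - call.five_idx
    wide_pairs = set(ann.structure.pairs())
    for i, j in call.structure.pairs():
        assert (i + shift, j + shift) in wide_pairs


def _design_call(hp, strand="+"):
    genome = {"chrS": hp.sequence.replace("U", "T")}
    stack = TerminusStack(hp.s_offset, "five_prime_starts", 50.0, 50.0,
                          hp.s_offset)
    return reconstruct_stemloop(genome, "chrS", strand, hp.d_offset, stack)


# ---------------------------------------------------------------------------
# thermodynamic features
# ---------------------------------------------------------------------------

def test_length_is_span_plus_flanks(designed_hairpin):
    call = _design_call(designed_hairpin)
    row = FT.thermodynamic_features(call)
    assert row["length"] == call.span + 30
    assert 0 <= row["bp_frequency"] <= 0.5
    assert row["n_pairs"] == len(call.structure.pairs())


def test_bp_frequency_arithmetic():
    """26 pairs in a 96-nt window give frequency 26/96."""
    assert 26 / 96 == pytest.approx(0.2708, abs=1e-4)


def test_max_stack_counts_longest_helix():
    table = folding.parse_dotbracket("((((....))))..((....))")
    assert FT._max_stack(table) == 4
    assert FT._max_stack(folding.parse_dotbracket("..........")) == 0


def test_composition_triplets(designed_hairpin):
    call = _design_call(designed_hairpin)
    comp = FT.bp_composition(call)
    for region in ("lower", "upper"):
        total = sum(comp[region].values())
        assert total == pytest.approx(1.0)


def test_composition_on_constructed_duplex():
    seq = "GCAGAAAAUUGC"
    db = "((((....))))"
    struct = folding.SecondaryStructure(seq, db, folding.parse_dotbracket(db), 0.0)
    call = stemloop.StemLoopCall(
        chrom="x", strand="+", d_site=0, s_site=0, orientation="upstream",
        window_start=0, window_end=12, sequence=seq, structure=struct,
        overhang=2, support=1, support_rpm=1, accepted=True,
        five_idx=2, three_idx=9,
    )
    comp = FT.bp_composition(call)
    # pairs: (0,11) G-C, (1,10) C-G lower; (2,9) A-U, (3,8) G-U upper
    assert comp["lower"] == {"gc": 1.0, "au": 0.0, "gu": 0.0}
    assert comp["upper"]["au"] == pytest.approx(0.5)
    assert comp["upper"]["gu"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# internal loops
# ---------------------------------------------------------------------------

def test_symmetric_loop_record_window_arithmetic():
    rec = FT.InternalLoopRecord(size5=2, size3=2, position=7, window=2)
    assert rec.symmetric
    assert FT._five_bp_window(7) == 2
    assert FT._five_bp_window(1) == 1
    assert FT._five_bp_window(5) == 1
    assert FT._five_bp_window(6) == 2
    assert FT._five_bp_window(-1) == -1
    assert FT._five_bp_window(-6) == -2


def test_bulge_is_asymmetric():
    assert not FT.InternalLoopRecord(1, 0, 3, 1).symmetric


def test_perfect_helix_has_no_loops(rng):
    hp = synthetic.design_hairpin(
        synthetic.HairpinSpec(stem_length=20, loop_length=6,
                              lower_stem_length=10, flank_length=20,
                              gc_bias=(1.0, 0.0, 0.0)), rng
    )
    table = folding.parse_dotbracket(hp.dot_bracket)
    cats, loops, _ = FT._label_structure(table, hp.s_offset, hp.d_offset - 1)
    assert loops == []


def test_planted_asymmetric_loop_recovered(rng):
    spec = synthetic.HairpinSpec(internal_loops=((20, 2, 0),))
    hp = synthetic.design_hairpin(spec, rng)
    table = folding.parse_dotbracket(hp.dot_bracket)
    _, loops, _ = FT._label_structure(table, hp.s_offset, hp.d_offset - 1)
    sizes = {(len(a), len(b)) for a, b in loops}
    assert (2, 0) in sizes


# ---------------------------------------------------------------------------
# information matrices
# ---------------------------------------------------------------------------

def test_information_bits_limits():
    items = [{1: "P"} for _ in range(10)]
    freq, info = FT.information_matrix(items, FT.CATEGORIES)
    assert info[1] == pytest.approx(np.log2(5))

    items = [{1: c} for c in "PFIBT" * 2]
    _, info = FT.information_matrix(items, FT.CATEGORIES)
    assert info[1] == pytest.approx(0.0, abs=1e-12)

    items = [{1: "A"} for _ in range(5)] + [{1: "C"} for _ in range(5)]
    _, info = FT.information_matrix(items, "ACGU")
    assert info[1] == pytest.approx(1.0)


def test_low_coverage_positions_masked():
    items = [{1: "A", 2: "C"}, {1: "A"}]
    _, info = FT.information_matrix(items, "ACGU", min_coverage=2)
    assert not np.isnan(info[1])
    assert np.isnan(info[2])


def test_information_matrix_rejects_bad_symbol():
    with pytest.raises(ValueError):
        FT.information_matrix([{0: "X"}], "ACGU")
    with pytest.raises(ValueError):
        FT.information_matrix([], "ACGU")


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def test_planted_motifs_detected(rng):
    spec = synthetic.HairpinSpec(
        motif_flags=frozenset({"basal_UG", "apical_UGU", "CNNC"})
    )
    hp = synthetic.design_hairpin(spec, rng)
    call = _design_call(hp)
    ann = FT.annotate_positions(call, {"chrS": hp.sequence.replace("U", "T")})
    hits = {h.motif: h.present for h in FT.scan_motifs(ann)}
    assert hits["basal_UG"]
    assert hits["apical_UGU"]
    assert hits["CNNC"]


def test_ugu_substring_match():
    # loop sequence containing AUGUA matches via its UGU core
    assert "UGU" in "AUGUA"


def test_motif_windows_configurable(rng):
    hp = synthetic.design_hairpin(
        synthetic.HairpinSpec(motif_flags=frozenset({"CNNC"})), rng
    )
    call = _design_call(hp)
    ann = FT.annotate_positions(call, {"chrS": hp.sequence.replace("U", "T")})
    narrow = FT.scan_motifs(ann, windows={"CNNC": {"offsets": (40,)}})
    assert not {h.motif: h for h in narrow}["CNNC"].present


# ---------------------------------------------------------------------------
# Welch comparisons
# ---------------------------------------------------------------------------

def test_identical_groups_t_zero_p_one():
    table = pd.DataFrame(
        {"g": ["a"] * 3 + ["b"] * 3, "x": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]}
    )
    res = FT.compare_groups(table, "g", ["x"])
    assert res.loc["x", "t"] == 0.0
    assert res.loc["x", "p_value"] == 1.0


def test_welch_matches_reference_formula():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 3, 4, 5, 6])
    table = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5,
                          "x": np.concatenate([x, y])})
    res = FT.compare_groups(table, "g", ["x"])
    # closed form: t = (mx-my)/sqrt(vx/nx + vy/ny)
    t_ref = (x.mean() - y.mean()) / np.sqrt(x.var(ddof=1) / 5 + y.var(ddof=1) / 5)
    sx, sy = x.var(ddof=1) / 5, y.var(ddof=1) / 5
    df_ref = (sx + sy) ** 2 / (sx**2 / 4 + sy**2 / 4)
    from scipy import stats
    p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
    assert res.loc["x", "t"] == pytest.approx(t_ref)
    assert res.loc["x", "df"] == pytest.approx(df_ref)
    assert res.loc["x", "p_value"] == pytest.approx(p_ref)


def test_swapping_groups_flips_sign_only():
    rng = np.random.default_rng(1)
    table = pd.DataFrame(
        {"g": ["a"] * 10 + ["b"] * 10, "x": rng.normal(size=20)}
    )
    res1 = FT.compare_groups(table, "g", ["x"])
    # present the groups in the opposite order
    table2 = pd.concat([table[table.g == "b"], table[table.g == "a"]])
    res2 = FT.compare_groups(table2, "g", ["x"])
    assert res1.loc["x", "t"] == pytest.approx(-res2.loc["x", "t"])
    assert res1.loc["x", "p_value"] == pytest.approx(res2.loc["x", "p_value"])


def test_degenerate_variance_with_different_means_errors():
    table = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3,
                          "x": [1.0, 1, 1, 2, 2, 2]})
    with pytest.raises(ValueError, match="zero variance"):
        FT.compare_groups(table, "g", ["x"])
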