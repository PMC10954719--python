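"""Synthetic-data generator: geometry, determinism, count statistics."""

import numpy as np
import pandas as pd
import pytest

from droshascan import folding, stemloop, synthetic
from droshascan.synthetic import HairpinSpec, HairpinDesignError, LibraryModel


# ---------------------------------------------------------------------------
# hairpin design
# ---------------------------------------------------------------------------

def test_canonical_design_geometry(rng):
    hp = synthetic.design_hairpin(
        HairpinSpec(stem_length=35, loop_length=10, internal_loops=()), rng
    )
    db = hp.dot_bracket
    assert db.count("(") == db.count(")") == 35
    inner = db[db.rindex("(") + 1 : db.index(")")]
    assert inner == "." * 10
    # S and D bound the planted duplex with the planted overhang
    table = folding.parse_dotbracket(db)
    assert (hp.d_offset - 1) - table[hp.s_offset] == 2
    assert 25 <= hp.span <= 100


def test_blunt_duplex_partner_symmetry(rng):
    hp = synthetic.design_hairpin(
        HairpinSpec(stem_length=16, loop_length=4, lower_stem_length=4,
                    overhang=0), rng
    )
    table = folding.parse_dotbracket(hp.dot_bracket)
    assert table[hp.s_offset] == hp.d_offset - 1


def test_internal_loop_removes_pairs(rng):
    spec = HairpinSpec(internal_loops=((20, 2, 2),))
    hp = synthetic.design_hairpin(spec, rng)
    assert hp.dot_bracket.count("(") == spec.stem_length - 2
    assert spec.n_pairs == spec.stem_length - 2


@pytest.mark.parametrize(
    "kwargs",
    [
        {"loop_length": 2},
        {"stem_length": 10, "lower_stem_length": 13},
        {"overhang": -1},
        {"internal_loops": ((2, 40, 40),)},
        {"internal_loops": ((14, 2, 2),)},  # touches the cleavage-site pair
    ],
)
def test_infeasible_specs_rejected(kwargs):
    with pytest.raises(HairpinDesignError):
        HairpinSpec(**kwargs)


def test_planted_structure_verified_at_generation(designed_hairpin):
    """Discoverability: the designed window folds with the planted overhang."""
    hp = designed_hairpin
    window = hp.sequence[hp.s_offset - 15 : hp.d_offset + 15]
    struct = folding.fold_mfe(window)
    ovh = stemloop.compute_overhang(struct, 15, hp.d_offset - 1 - (hp.s_offset - 15))
    assert ovh == hp.spec.overhang


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def test_empty_genome():
    fasta, truth = synthetic.build_genome(0, 0, 10_000, np.random.default_rng(0))
    assert truth.empty
    assert fasta.startswith(">chrS")


def test_seeded_determinism():
    a = synthetic.build_genome(3, 3, 15_000, np.random.default_rng(1))
    b = synthetic.build_genome(3, 3, 15_000, np.random.default_rng(1))
    assert a[0] == b[0]
    pd.testing.assert_frame_equal(a[1], b[1])


def test_locus_spacing(small_genome):
    _, truth = small_genome
    starts = truth["region_start"].to_numpy()
    ends = truth["region_end"].to_numpy()
    gaps = starts[1:] - ends[:-1]
    assert (gaps >= 200).all()


def test_insufficient_space_errors():
    with pytest.raises(ValueError, match="at least"):
        synthetic.build_genome(10, 10, 2_000, np.random.default_rng(0))


def test_truth_span_within_scan_window(small_genome):
    _, truth = small_genome
    span = (truth["three_prime_pileup"] - truth["five_prime_cleavage"]).abs()
    assert span.between(25, 100).all()


# ---------------------------------------------------------------------------
# degradome simulation
# ---------------------------------------------------------------------------

def _one_locus_truth():
    return pd.DataFrame(
        [{
            "locus_id": "hp0", "chrom": "chrS", "strand": "+",
            "five_prime_cleavage": 500, "three_prime_pileup": 556,
            "region_start": 450, "region_end": 600, "dot_bracket": "",
            "class_label": "miRNA-like", "drosha_dependent": True,
            "depletion_factor": 0.1, "overhang": 2,
        }]
    )


def test_signal_counts_match_nb_mean():
    truth = _one_locus_truth()
    rng = np.random.default_rng(5)
    models = [
        LibraryModel("control", i, signal_depth=100.0, background_rate=0.0,
                     jitter=0.0, library_id=f"lib{i}")
        for i in range(400)
    ]
    beds = synthetic.simulate_degradome(truth, models, 2_000, rng)
    counts = np.array([len(b) for b in beds.values()])
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 100.0) < 3 * se + 1e-9


def test_knockout_depletion_ratio():
    truth = _one_locus_truth()
    rng = np.random.default_rng(6)
    ctrl = [LibraryModel("control", i, background_rate=0.0, library_id=f"c{i}")
            for i in range(200)]
    ko = [LibraryModel("knockout", i, background_rate=0.0, library_id=f"k{i}")
          for i in range(200)]
    nc = np.mean([len(b) for b in
                  synthetic.simulate_degradome(truth, ctrl, 2_000, rng).values()])
    nk = np.mean([len(b) for b in
                  synthetic.simulate_degradome(truth, ko, 2_000, rng).values()])
    assert nk / nc == pytest.approx(0.1, rel=0.25)


def test_zero_jitter_reads_start_exactly_at_pileup():
    truth = _one_locus_truth()
    model = LibraryModel("control", 1, background_rate=0.0, jitter=0.0)
    bed = synthetic.simulate_degradome(
        truth, [model], 2_000, np.random.default_rng(7)
    )[model.library_id]
    assert (bed["start"] == 556).all()  # + strand 5' start = BED start


def test_conservation_of_read_counts():
    truth = _one_locus_truth()
    model = LibraryModel("control", 1, background_rate=0.05)
    bed = synthetic.simulate_degradome(
        truth, [model], 2_000, np.random.default_rng(8)
    )[model.library_id]
    from droshascan import pileup
    track = pileup.count_read_starts(bed)
    total = sum(sum(b.values()) for b in track.counts.values())
    assert total == len(bed) == track.library_size


# ---------------------------------------------------------------------------
# sRNA simulation
# ---------------------------------------------------------------------------

def test_srna_without_morna_all_reads_at_cleavage_sites():
    truth = _one_locus_truth()
    model = LibraryModel("control", 1, srna_morna_depth=0.0)
    bed = synthetic.simulate_srna(
        truth, [model], 2_000, np.random.default_rng(9)
    )[model.library_id]
    # 5'-arm products start at S; 3'-arm products end at D-1
    ok = (bed["start"] == 500) | (bed["end"] == 556)
    assert ok.all()


def test_srna_rpm_with_forced_library_total():
    truth = _one_locus_truth()
    model = LibraryModel("control", 1, srna_mirna_depth=50.0,
                         srna_morna_depth=0.0)
    rng = np.random.default_rng(10)
    beds = synthetic.simulate_srna(truth, [model], 2_000, rng,
                                   library_size=1_000_000)
    from droshascan import pileup
    bed = beds[model.library_id]
    starts, _ = pileup.count_read_termini(bed, use_score=True)
    starts.library_size = bed.attrs["library_size"]
    assert starts.rpm("chrS", "+", 500) == pytest.approx(50.0, rel=0.5)


def test_srna_seeded_determinism():
    truth = _one_locus_truth()
    model = LibraryModel("control", 1)
    a = synthetic.simulate_srna(truth, [model], 2_000, np.random.default_rng(3))
    b = synthetic.simulate_srna(truth, [model], 2_000, np.random.default_rng(3))
    pd.testing.assert_frame_equal(a[model.library_id], b[model.library_id])
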