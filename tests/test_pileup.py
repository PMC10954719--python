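"""Pile-up detection: start counting, counting vectors, classifier logic."""

import numpy as np
import pandas as pd
import pytest

from droshascan import pileup
from droshascan.pileup import (
    MalformedBedError,
    UndefinedMetricError,
    classifier_metrics,
    count_read_starts,
    count_read_termini,
    counting_vector,
)


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


# ---------------------------------------------------------------------------
# start counting and RPM
# ---------------------------------------------------------------------------

def test_plus_strand_rpm_arithmetic():
    bed = _bed(
        [("chr1", 100, 150, f"r{i}", 1, "+") for i in range(3)]
        + [("chr1", 105, 155, "r3", 1, "+")]
    )
    track = count_read_starts(bed)
    assert track.library_size == 4
    assert track.rpm("chr1", "+", 100) == pytest.approx(750_000)
    assert track.rpm("chr1", "+", 105) == pytest.approx(250_000)


def test_minus_strand_start_is_bed_end_minus_one():
    track = count_read_starts(_bed([("chr1", 200, 220, "r0", 1, "-")]))
    assert track.count("chr1", "-", 219) == 1
    assert track.count("chr1", "-", 200) == 0


def test_three_prime_end_track_convention():
    starts, ends = count_read_termini(
        _bed([("chr1", 100, 120, "r", 1, "+"), ("chr1", 200, 220, "q", 1, "-")])
    )
    assert ends.count("chr1", "+", 119) == 1
    assert ends.count("chr1", "-", 200) == 1


def test_score_weighted_counting():
    starts, _ = count_read_termini(
        _bed([("chr1", 50, 70, "u0", 7, "+")]), use_score=True
    )
    assert starts.count("chr1", "+", 50) == 7
    assert starts.library_size == 7


def test_empty_library_rpm_errors():
    track = count_read_starts(_bed([]))
    with pytest.raises(UndefinedMetricError):
        track.rpm("chr1", "+", 0)


def test_malformed_bed_reports_row():
    with pytest.raises(MalformedBedError, match="row 1"):
        count_read_starts(
            _bed([("chr1", 0, 10, "a", 1, "+"), ("chr1", 10, 10, "b", 1, "+")])
        )


# ---------------------------------------------------------------------------
# counting vectors
# ---------------------------------------------------------------------------

def test_delta_track_vector():
    track = pileup.StartCountTrack(library_size=10)
    track.add("chr1", "+", 500, 10)
    vec = counting_vector(track, "chr1", "+", 500)
    assert vec[10] == pytest.approx(1e6)
    assert vec.sum() == pytest.approx(1e6)


def test_edge_positions_zero_padded():
    track = pileup.StartCountTrack(library_size=1)
    track.add("chr1", "+", 3, 1)
    vec = counting_vector(track, "chr1", "+", 3)
    assert np.all(vec[:10] == np.r_[np.zeros(10)]) or vec[10] > 0
    # only the centre is nonzero; negative coordinates contribute nothing
    assert np.flatnonzero(vec).tolist() == [10]


def test_rpm_linearity_in_library_size():
    t1 = pileup.StartCountTrack(library_size=100)
    t1.add("chr1", "+", 50, 5)
    t2 = pileup.StartCountTrack(library_size=200)
    t2.add("chr1", "+", 50, 5)
    v1 = counting_vector(t1, "chr1", "+", 50)
    v2 = counting_vector(t2, "chr1", "+", 50)
    np.testing.assert_allclose(v1, 2 * v2)


def test_minus_strand_vector_follows_transcript_orientation():
    track = pileup.StartCountTrack(library_size=1)
    track.add("chr1", "-", 499, 1)  # one position transcript-downstream of 500
    vec = counting_vector(track, "chr1", "-", 500)
    assert vec[11] > 0  # offset +1


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_sensitivity_specificity_formulas():
    truth = [True] * 10 + [False] * 100
    pred = [True] * 9 + [False] + [True] * 5 + [False] * 95
    sens, spec = classifier_metrics(truth, pred)
    assert sens == pytest.approx(0.9)
    assert spec == pytest.approx(0.95)


def test_metrics_undefined_without_positives():
    with pytest.raises(UndefinedMetricError):
        classifier_metrics([False, False], [True, False])


def test_trained_ok_rule():
    model = pileup.ClassifierModel(
        coefficients=np.zeros(21), intercept=0.0, C=1.0, l1_ratio=1.0,
        cv_folds=10, sensitivity=0.95, specificity=0.95, auc=0.99,
    )
    assert model.trained_ok
    model.auc = 0.9
    assert not model.trained_ok  # strict inequality


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _spiked_track(rng, n_pos, genome_len=50_000, depth=100):
    track = pileup.StartCountTrack(library_size=0)
    positives = []
    for k in range(n_pos):
        pos = 100 + k * (genome_len - 200) // n_pos
        track.add("chrS", "+", pos, depth)
        positives.append(("chrS", "+", pos))
    # diffuse background
    for pos in rng.integers(0, genome_len, size=2000):
        track.add("chrS", "+", int(pos), 1)
    track.library_size = sum(sum(b.values()) for b in track.counts.values())
    return track, positives


def test_separable_training_reaches_perfect_metrics(rng):
    track, positives = _spiked_track(rng, 50)
    model = pileup.train_and_validate(
        track, positives, {"chrS": 50_000}, rng, n_negatives=300
    )
    assert model.sensitivity == pytest.approx(1.0)
    assert model.specificity >= 0.99
    assert model.auc >= 0.99
    assert model.trained_ok


def test_permuted_labels_give_chance_auc(rng):
    """Training on labels decoupled from the signal yields AUC near 0.5."""
    track = pileup.StartCountTrack(library_size=0)
    loci = []
    for k in range(400):
        pos = 10 + 40 * k
        track.add("chrS", "+", pos, 1 + int(rng.integers(0, 3)))
        loci.append(("chrS", "+", pos))
    track.library_size = sum(sum(b.values()) for b in track.counts.values())
    X = pileup._design_matrix(track, loci)
    y = rng.permutation([1] * 200 + [0] * 200)
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import cross_val_predict
    est = pileup._make_estimator(1.0, 1.0, True, 0)
    proba = cross_val_predict(est, X, y, cv=10, method="predict_proba")[:, 1]
    assert abs(roc_auc_score(y, proba) - 0.5) < 0.1


def test_too_few_positives_rejected(rng):
    track, positives = _spiked_track(rng, 5)
    with pytest.raises(ValueError, match="20"):
        pileup.train_and_validate(track, positives, {"chrS": 50_000}, rng)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_requires_every_replicate():
    """A site voted in only one replicate is rejected (both-replicates rule),
    and raising the acceptance fraction never adds sites."""
    rng = np.random.default_rng(3)
    track1, positives = _spiked_track(rng, 40)
    track2, _ = _spiked_track(rng, 40)
    # an extra locus stacked in replicate 1 only
    lone = ("chrS", "+", 49_900)
    track1.add(*lone, 100)
    tracks = {"rep1": track1, "rep2": track2}
    sites, models = pileup.consensus_classify(
        tracks, positives, {"chrS": 50_000}, rng,
        n_iterations=10, n_negatives=200,
    )
    by_locus = sites.set_index(["chrom", "strand", "position"])
    assert by_locus.loc[lone, "votes_rep1"] > 8
    assert by_locus.loc[lone, "votes_rep2"] == 0
    assert not by_locus.loc[lone, "accepted"]
    planted_accept = by_locus.loc[positives, "accepted"]
    assert planted_accept.mean() >= 0.9

    # vote monotonicity: tighter acceptance keeps a subset
    loose = by_locus["votes_rep1"].gt(0.5 * 10) & by_locus["votes_rep2"].gt(0.5 * 10)
    tight = by_locus["votes_rep1"].gt(0.95 * 10) & by_locus["votes_rep2"].gt(0.95 * 10)
    assert (tight <= loose).all()


def test_strand_symmetry_of_counting_vectors():
    """Mirroring the genome (flipping strand and coordinates) mirrors the
    counting vectors exactly."""
    genome_len = 1000
    track_fwd = pileup.StartCountTrack(library_size=100)
    track_rev = pileup.StartCountTrack(library_size=100)
    rng = np.random.default_rng(0)
    for pos, c in zip(rng.integers(0, genome_len, 50), rng.integers(1, 5, 50)):
        track_fwd.add("chr", "+", int(pos), int(c))
        track_rev.add("chr", "-", genome_len - 1 - int(pos), int(c))
    center = 500
    v_fwd = counting_vector(track_fwd, "chr", "+", center)
    v_rev = counting_vector(track_rev, "chr", "-", genome_len - 1 - center)
    np.testing.assert_allclose(v_fwd, v_rev)
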