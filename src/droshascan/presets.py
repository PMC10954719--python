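"""Desk-scale study presets used by validation and the acceptance script.

The desk preset is the package's reference synthetic condition: a 100 kb
genome with 200 planted cleavage sites (100 canonical miRNA-like and 100
non-canonical mRNA-like hairpins), two control and two knockout Degradome
replicates at the generator defaults, and 100 consensus-resampling
iterations.  All quantities reported by ``scripts/acceptance.py`` are
recomputed from scratch under these conditions.
"""

from __future__ import annotations

import numpy as np

from . import folding, pileup, stemloop, synthetic
from .pipeline import RunConfig

__all__ = [
    "desk_config",
    "desk_classifier_metrics",
    "perfect_hairpin_overhang",
]

DESK_N_MIRNA = 100
DESK_N_MRNA = 100
DESK_GENOME_LENGTH = 100_000
DESK_N_ITERATIONS = 100


def desk_config(outdir: str, seed: int) -> RunConfig:
    return RunConfig(
        outdir=outdir, seed=seed,
        n_mirna_like=DESK_N_MIRNA, n_mrna_like=DESK_N_MRNA,
        genome_length=DESK_GENOME_LENGTH, n_iterations=DESK_N_ITERATIONS,
    )


def desk_classifier_metrics(seed: int) -> dict[str, float]:
    """Held-out classifier metrics on the desk-preset Degradome dataset.

    Generates the preset genome and two control replicates, trains the
    21-feature regularised logistic classifier per replicate (10-fold CV,
    1000 resampled negative loci) and returns the minimum held-out
    sensitivity, specificity and AUC across replicates, plus the training
    problem size.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    _, truth = synthetic.build_genome(
        DESK_N_MIRNA, DESK_N_MRNA, DESK_GENOME_LENGTH, rng
    )
    models = [synthetic.LibraryModel("control", rep) for rep in (1, 2)]
    beds = synthetic.simulate_degradome(truth, models, DESK_GENOME_LENGTH, rng)
    positives = [
        (r.chrom, r.strand, int(r.three_prime_pileup))
        for r in truth.itertuples()
    ]
    chrom_sizes = {"chrS": DESK_GENOME_LENGTH}
    metrics = {"sensitivity": [], "specificity": [], "auc": []}
    n_train = 0
    for model in models:
        track = pileup.count_read_starts(beds[model.library_id])
        fit = pileup.train_and_validate(
            track, positives, chrom_sizes, rng, n_negatives=1000, cv_folds=10
        )
        metrics["sensitivity"].append(fit.sensitivity)
        metrics["specificity"].append(fit.specificity)
        metrics["auc"].append(fit.auc)
        n_train = len(positives) + 1000
    return {
        "sensitivity": min(metrics["sensitivity"]),
        "specificity": min(metrics["specificity"]),
        "auc": min(metrics["auc"]),
        "n": n_train,
    }


def perfect_hairpin_overhang(seed: int) -> dict[str, int]:
    """The computed 3' overhang on a canonical perfect hairpin.

    Designs a 30-bp stem / 6-nt loop hairpin with canonical RNase III
    duplex-end geometry, folds the cleavage window with the built-in model
    and measures the overhang between the planted 5'-arm site and the
    pile-up site.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    spec = synthetic.HairpinSpec(
        stem_length=30, loop_length=6, lower_stem_length=13, overhang=2,
        internal_loops=(),
    )
    hp = synthetic.design_hairpin(spec, rng)
    window = hp.sequence[hp.s_offset - 15 : hp.d_offset + 15]
    struct = folding.fold_mfe(window)
    ovh = stemloop.compute_overhang(
        struct, 15, (hp.d_offset - 1) - (hp.s_offset - 15)
    )
    return {"overhang": int(ovh), "n": len(window)}
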