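"""End-to-end orchestration: simulate -> pile-up -> differential -> stem-loops
-> features, with seeded determinism and persisted intermediates.

A single global seed fans out into independent per-stage streams (via
``numpy.random.SeedSequence.spawn``) so any stage can be rerun in isolation
and reproduce identical output.  Every stage writes its table under the
run's output directory; the run report summarises counts, classifier
metrics and per-group feature statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, features, folding, pileup, stemloop, synthetic

__all__ = ["RunConfig", "run_pipeline", "classify_calls", "read_gff3",
           "truth_to_gff3", "CONTEXT_PRIORITY"]

CONTEXT_PRIORITY = [
    "miRNA", "CDS", "five_prime_UTR", "three_prime_UTR", "intron",
    "lncRNA_exon",
]
_MIRNA_TYPES = {"miRNA", "miRNA_primary_transcript", "pre_miRNA"}


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys are rejected on load."""

    outdir: str = "run"
    seed: int = 1
    backend: str = "toy"  # toy | vienna

    # simulation (desk preset)
    simulate: bool = True
    n_mirna_like: int = 100
    n_mrna_like: int = 100
    genome_length: int = 100_000
    chrom: str = "chrS"
    depletion_factor: float = 0.1
    signal_depth: float = 100.0
    background_rate: float = 0.2
    jitter: float = 0.02
    srna_mirna_depth: float = 50.0
    srna_morna_depth: float = 20.0
    n_replicates: int = 2

    # real-data inputs (used when simulate is off)
    genome_fasta: str | None = None
    degradome_beds: dict | None = None  # library id -> path; ids carry
    # "control"/"knockout" and replicate index
    srna_beds: list | None = None
    annotation_gff: str | None = None

    # pile-up classification
    n_iterations: int = 100
    accept_fraction: float = 0.9
    n_negatives: int = 1000
    cv_folds: int = 10
    l1_ratio: float = 1.0
    standardize: bool = True

    # differential gate
    prior_df: float = 10.0
    lfc_cut: float = -1.5
    fdr_cut: float = 0.05
    two_sided_gate: bool = False

    # stem-loop reconstruction
    rpm_min: float = 1.0
    flank: int = 15
    max_shift: int = 2

    # features
    annotate_flank: int = 25

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def _fold_fn(config: RunConfig, params):
    if config.backend == "vienna":
        from .vienna import fold_mfe_vienna

        return lambda seq: fold_mfe_vienna(seq)
    if config.backend != "toy":
        raise ValueError(f"unknown folding backend {config.backend!r}")
    return lambda seq: folding.fold_mfe(seq, params=params)


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    params = folding.DEFAULT_PARAMS
    fold_fn = _fold_fn(config, params)
    streams = np.random.SeedSequence(config.seed).spawn(5)
    report: dict = {"seed": config.seed, "stages": {}}

    # ---- stage 1: simulate (or load) -------------------------------------
    if config.simulate:
        rng = np.random.default_rng(streams[0])
        fasta, truth = synthetic.build_genome(
            config.n_mirna_like, config.n_mrna_like, config.genome_length,
            rng, chrom=config.chrom, depletion_factor=config.depletion_factor,
            params=params,
        )
        models = [
            synthetic.LibraryModel(
                condition=cond, replicate=rep,
                signal_depth=config.signal_depth,
                background_rate=config.background_rate,
                jitter=config.jitter,
                srna_mirna_depth=config.srna_mirna_depth,
                srna_morna_depth=config.srna_morna_depth,
            )
            for cond in ("control", "knockout")
            for rep in range(1, config.n_replicates + 1)
        ]
        deg = synthetic.simulate_degradome(
            truth, models, config.genome_length, rng, chrom=config.chrom
        )
        srna_models = [m for m in models if m.condition == "control"]
        srna = synthetic.simulate_srna(
            truth, srna_models, config.genome_length, rng, chrom=config.chrom
        )
        (out / "genome.fa").write_text(fasta)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "annotation.gff3").write_text(truth_to_gff3(truth))
        for lib, bed in deg.items():
            (out / f"degradome_{lib}.bed").write_text(synthetic.write_bed(bed))
        for lib, bed in srna.items():
            (out / f"srna_{lib}.bed").write_text(synthetic.write_bed(bed))
        genome = {config.chrom: fasta_to_dict(fasta)[config.chrom]}
        gff = read_gff3(truth_to_gff3(truth))
        positives = [
            (r.chrom, r.strand, int(r.three_prime_pileup))
            for r in truth.itertuples()
        ]
        conditions = {m.library_id: m.condition for m in models}
    else:
        if not (config.genome_fasta and config.degradome_beds and config.srna_beds):
            raise ValueError(
                "simulate is off but genome_fasta / degradome_beds / "
                "srna_beds are not all provided"
            )
        import pyfaidx

        fa = pyfaidx.Fasta(config.genome_fasta)
        genome = {name: fa[name] for name in fa.keys()}
        deg = {
            lib: read_bed(path) for lib, path in config.degradome_beds.items()
        }
        srna = {f"srna{i}": read_bed(p) for i, p in enumerate(config.srna_beds)}
        truth = None
        gff = read_gff3(Path(config.annotation_gff).read_text())
        positives = _positives_from_gff(gff)
        conditions = {
            lib: ("knockout" if "knockout" in lib else "control") for lib in deg
        }

    chrom_sizes = {name: len(seq) for name, seq in genome.items()}
    report["stages"]["simulate"] = {
        "libraries": sorted(deg),
        "n_planted": 0 if truth is None else int(len(truth)),
    }

    # ---- stage 2: pile-up consensus --------------------------------------
    tracks = {
        lib: pileup.count_read_starts(bed, lib) for lib, bed in deg.items()
    }
    control_tracks = {
        lib: t for lib, t in tracks.items() if conditions[lib] == "control"
    }
    rng = np.random.default_rng(streams[1])
    sites, models_fit = pileup.consensus_classify(
        control_tracks, positives, chrom_sizes, rng,
        n_iterations=config.n_iterations,
        accept_fraction=config.accept_fraction,
        n_negatives=config.n_negatives, cv_folds=config.cv_folds,
        l1_ratio=config.l1_ratio, standardize=config.standardize,
    )
    sites.to_csv(out / "pileup_sites.tsv", sep="\t", index=False)
    accepted = sites[sites["accepted"]].reset_index(drop=True)
    report["stages"]["pileup"] = {
        "candidate_loci": int(len(sites)),
        "accepted_sites": int(len(accepted)),
        "classifier": {
            rep: {
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "auc": m.auc,
                "trained_ok": m.trained_ok,
            }
            for rep, m in models_fit.items()
        },
    }

    # ---- stage 3: differential -------------------------------------------
    loci = [tuple(x) for x in sites[["chrom", "strand", "position"]]
            .itertuples(index=False)]
    counts = pd.DataFrame(
        {
            lib: np.rint(
                pileup._design_matrix(tracks[lib], loci)[:, pileup.VECTOR_RADIUS]
                * tracks[lib].library_size / 1e6
            ).astype(int)
            for lib in tracks
        },
        index=pd.MultiIndex.from_tuples(loci, names=["chrom", "strand", "position"]),
    )
    lib_sizes = pd.Series({lib: tracks[lib].library_size for lib in tracks})
    factors = differential.tmm_factors(counts, lib_sizes)
    results = differential.fit_and_test(
        counts, factors, conditions, lib_sizes,
        prior_df=config.prior_df, two_sided_gate=config.two_sided_gate,
    )
    results.to_csv(out / "differential.tsv", sep="\t")
    acc_idx = pd.MultiIndex.from_frame(
        accepted[["chrom", "strand", "position"]]
    )
    dependent = results.loc[results.index.intersection(acc_idx)]
    dependent = dependent[dependent["dependent"]]
    report["stages"]["differential"] = {
        "tested_loci": int(len(results)),
        "dependent_sites": int(len(dependent)),
        "common_dispersion": float(results.attrs["common_dispersion"]),
    }

    # ---- stage 4: stem-loop reconstruction -------------------------------
    srna_start_tracks, srna_end_tracks = [], []
    for lib, bed in srna.items():
        s, e = pileup.count_read_termini(bed, lib, use_score=True)
        size = bed.attrs.get("library_size", s.library_size)
        s.library_size = e.library_size = size
        srna_start_tracks.append(s)
        srna_end_tracks.append(e)
    srna_starts = pileup.merge_tracks(srna_start_tracks)
    srna_ends = pileup.merge_tracks(srna_end_tracks)

    dep_sites = dependent.reset_index()[["chrom", "strand", "position"]]
    calls = stemloop.call_stemloops(
        dep_sites, srna_starts, srna_ends, genome,
        rpm_min=config.rpm_min, flank=config.flank,
        max_shift=config.max_shift, params=params, fold_fn=fold_fn,
    )
    calls_frame = stemloop.calls_to_frame(calls)
    calls_frame.to_csv(out / "stemloops.tsv", sep="\t", index=False)
    with open(out / "stemloops.dbn", "w") as fh:
        for c in calls:
            if c.accepted:
                fh.write(f">{c.chrom}:{c.d_site}:{c.strand}\n"
                         f"{c.sequence}\n{c.structure.dot_bracket}\n")
    resolved = [c for c in calls if c.accepted]
    report["stages"]["stemloop"] = {
        "anchors": int(len(calls)),
        "resolved": int(len(resolved)),
        "unresolved": int(len(calls) - len(resolved)),
    }

    # ---- stage 5: features ------------------------------------------------
    labels = classify_calls(resolved, gff)
    rows, ann5, ann3, seq5, seq3 = [], [], [], [], []
    for call, (cls, context) in zip(resolved, labels):
        row = features.thermodynamic_features(call, params=params,
                                              class_label=cls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ann = features.annotate_positions(
                call, genome, flank=config.annotate_flank, params=params
            )
        loops = features.catalog_internal_loops(ann)
        row.update(
            {
                "chrom": call.chrom, "strand": call.strand,
                "d_site": call.d_site, "s_site": call.s_site,
                "context": context,
                "n_internal_loops": len(loops),
                "n_asym_loops": sum(1 for l in loops if not l.symmetric),
            }
        )
        for hit in features.scan_motifs(ann):
            row[f"motif_{hit.motif}"] = hit.present
        rows.append(row)
        ann5.append(ann.arm_categories("5p"))
        ann3.append(ann.arm_categories("3p"))
        seq5.append(ann.arm_sequences("5p"))
        seq3.append(ann.arm_sequences("3p"))
    table = pd.DataFrame(rows)
    table.to_csv(out / "features.tsv", sep="\t", index=False)

    matrices = {}
    if rows:
        for name, items, alphabet in (
            ("structure_5p", ann5, features.CATEGORIES),
            ("structure_3p", ann3, features.CATEGORIES),
            ("sequence_5p", seq5, "ACGU"),
            ("sequence_3p", seq3, "ACGU"),
        ):
            freq, info = features.information_matrix(items, alphabet)
            freq.to_csv(out / f"freq_{name}.tsv", sep="\t")
            info.to_csv(out / f"info_{name}.tsv", sep="\t")
            matrices[name] = float(np.nanmax(info.to_numpy())) if len(info) else 0.0

    group_stats = {}
    if rows and table["class_label"].nunique() == 2:
        welch = features.compare_groups(
            table, "class_label",
            ["mfe", "length", "bp_frequency", "max_stack",
             "ensemble_diversity", "n_asym_loops"],
        )
        welch.to_csv(out / "group_comparison.tsv", sep="\t")
        group_stats = welch["p_value"].to_dict()
    report["stages"]["features"] = {
        "feature_rows": int(len(table)),
        "class_counts": {} if not rows else
        table["class_label"].value_counts().to_dict(),
        "welch_p": group_stats,
        "max_information_bits": matrices,
    }

    # ---- recovery vs truth (synthetic mode) ------------------------------
    if truth is not None and rows:
        truth_pairs = {
            (r.chrom, r.strand, int(r.three_prime_pileup)):
            int(r.five_prime_cleavage)
            for r in truth.itertuples()
        }
        exact = sum(
            1 for c in resolved
            if truth_pairs.get((c.chrom, c.strand, c.d_site)) == c.s_site
        )
        report["recovery"] = {
            "planted": len(truth_pairs),
            "exact_pairs_in_feature_table": exact,
            "fraction": exact / max(len(truth_pairs), 1),
        }

    manifest = {
        "config": dataclasses.asdict(config),
        "checksums": {
            p.name: _checksum(p) for p in sorted(out.iterdir()) if p.is_file()
        },
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# annotation handling
# ---------------------------------------------------------------------------

def fasta_to_dict(text: str) -> dict[str, str]:
    records: dict[str, list[str]] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            records[name] = []
        elif name is not None:
            records[name].append(line.strip())
    return {k: "".join(v) for k, v in records.items()}


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=synthetic.BED_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int, "score": float,
               "strand": str},
    )


def read_gff3(text_or_path) -> pd.DataFrame:
    import io as _io

    text = str(text_or_path)
    if "\t" not in text and Path(text).exists():
        text = Path(text).read_text()
    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    frame = pd.read_csv(
        _io.StringIO(text), sep="\t", comment="#", header=None, names=cols,
        dtype={"chrom": str},
    )
    return frame


def truth_to_gff3(truth: pd.DataFrame) -> str:
    """Synthetic annotation: planted miRNA-like cassettes become
    miRNA_primary_transcript features, mRNA-like cassettes CDS features."""
    lines = ["##gff-version 3"]
    for r in truth.itertuples():
        ftype = (
            "miRNA_primary_transcript"
            if r.class_label == "miRNA-like" else "CDS"
        )
        lines.append(
            "\t".join(
                [
                    r.chrom, "droshascan_synthetic", ftype,
                    str(int(r.region_start) + 1), str(int(r.region_end)),
                    ".", r.strand, ".", f"ID={r.locus_id}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _positives_from_gff(gff: pd.DataFrame) -> list:
    """Known cleavage loci from annotated miRNA arms: the locus just
    upstream of the 5p arm 5' end and just downstream of the 3p arm 3' end."""
    out = []
    arms = gff[gff["type"].isin({"miRNA"})]
    for r in arms.itertuples():
        attrs = r.attributes or ""
        start0, end0 = int(r.start) - 1, int(r.end)  # to 0-based half-open
        is_5p = "5p" in attrs
        is_3p = "3p" in attrs
        if r.strand == "+":
            if is_5p:
                out.append((r.chrom, r.strand, start0 - 1))
            if is_3p:
                out.append((r.chrom, r.strand, end0))
        else:
            if is_5p:
                out.append((r.chrom, r.strand, end0))
            if is_3p:
                out.append((r.chrom, r.strand, start0 - 1))
    return out


def classify_calls(calls, gff: pd.DataFrame) -> list[tuple[str, str]]:
    """(class, context) per call from a GFF3 annotation frame.

    A call is miRNA-class when its product span overlaps an annotated
    miRNA hairpin feature on the same strand.  Genomic context is the
    highest-priority overlapping same-strand feature type, else
    "intergenic".
    """
    from intervaltree import IntervalTree

    trees: dict[tuple, IntervalTree] = {}
    for r in gff.itertuples():
        key = (r.chrom, r.strand, r.type)
        trees.setdefault(key, IntervalTree()).addi(
            int(r.start) - 1, int(r.end), r.type
        )
    gff_chroms = set(gff["chrom"])
    call_chroms = {c.chrom for c in calls}
    unmatched = call_chroms - gff_chroms
    if calls and gff_chroms and unmatched:
        raise ValueError(
            f"contigs absent from the annotation: {sorted(unmatched)}"
        )
    out = []
    for c in calls:
        lo = min(c.s_site, c.d_site)
        hi = max(c.s_site, c.d_site)
        overlapping = set()
        for (chrom, strand, ftype), tree in trees.items():
            if chrom == c.chrom and strand == c.strand and tree.overlap(lo, hi):
                overlapping.add(ftype)
        is_mirna = bool(overlapping & _MIRNA_TYPES)
        context = "intergenic"
        if is_mirna:
            context = "miRNA"
        else:
            for ftype in CONTEXT_PRIORITY[1:]:
                if ftype in overlapping:
                    context = ftype
                    break
        out.append(("miRNA" if is_mirna else "non-miRNA", context))
    return out
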