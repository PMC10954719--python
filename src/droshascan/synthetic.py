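"""Synthetic genomes with planted Drosha-substrate hairpins and read simulators.

The generator produces the study conditions the downstream pipeline assumes:

* a toy genome in which stem-loop cassettes with known cleavage geometry are
  planted on either strand,
* Degradome-seq-like libraries whose read 5' starts stack at the planted
  3'-arm cleavage site ``D`` over a homogeneous Poisson background, with a
  condition-dependent (control vs knockout) depletion of the stack,
* collapsed small-RNA-seq-like libraries whose proximal read termini mark
  the cleavage sites on both arms while distal termini are exonucleolytically
  ragged,
* a machine-readable truth table for every planted locus.

Geometry of a planted hairpin (transcript orientation)::

      5' flank | lower stem | upper 5' arm | loop | upper 3' arm | ovh | lower 3' arm | 3' flank
                            ^S                                        ^D

``S`` is the first nucleotide of the excised product (5'-arm cleavage
site); ``D`` is the first nucleotide of the downstream polyA-bearing
fragment, i.e. the Degradome pile-up site, offset so that the product ends
``overhang`` nucleotides 3' of the pairing partner of ``S`` (the RNase III
3' overhang).  Every planted hairpin is checked at generation time to fold,
under the built-in model, with the planted overhang, and to satisfy the
25-100 nt ``S``/``D`` spacing used by the downstream scan.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import folding
from .folding import ModelParams

__all__ = [
    "HairpinSpec",
    "LibraryModel",
    "DesignedHairpin",
    "design_hairpin",
    "build_genome",
    "simulate_degradome",
    "simulate_srna",
    "mirna_like_spec",
    "mrna_like_spec",
    "write_fasta",
    "write_bed",
    "TRUTH_COLUMNS",
]

DEGRADOME_READ_LENGTH = 50  # only 5' starts are consumed downstream
MIN_LOCUS_SPACING = 200

TRUTH_COLUMNS = [
    "locus_id",
    "chrom",
    "strand",
    "five_prime_cleavage",
    "three_prime_pileup",
    "region_start",
    "region_end",
    "dot_bracket",
    "class_label",
    "drosha_dependent",
    "depletion_factor",
    "overhang",
]


class HairpinDesignError(ValueError):
    """Infeasible hairpin specification."""


@dataclass(frozen=True)
class HairpinSpec:
    """Blueprint for one planted stem-loop.

    ``internal_loops`` entries are ``(pair_index_on_5'_arm, size5, size3)``
    with pair indices counted 1-based from the basal end of the stem; the
    loop replaces ``max(size5, size3)`` consecutive pairs with ``size5``
    unpaired nucleotides on the 5' arm and ``size3`` on the 3' arm.
    ``gc_bias`` gives the probabilities that a planted pair is G-C, A-U or
    G-U.  ``motif_flags`` may contain ``basal_UG``, ``apical_UGU`` and
    ``CNNC``.
    """

    stem_length: int = 35
    loop_length: int = 10
    lower_stem_length: int = 13
    internal_loops: tuple = ()
    overhang: int = 2
    motif_flags: frozenset = frozenset()
    gc_bias: tuple = (0.5, 0.4, 0.1)
    flank_length: int = 30

    def __post_init__(self):
        if self.loop_length < 3:
            raise HairpinDesignError(f"loop_length {self.loop_length} < 3")
        if not self.stem_length >= self.lower_stem_length >= 0:
            raise HairpinDesignError(
                f"need stem_length >= lower_stem_length >= 0, got "
                f"{self.stem_length} / {self.lower_stem_length}"
            )
        if self.overhang < 0:
            raise HairpinDesignError("overhang must be >= 0")
        if self.overhang > self.lower_stem_length:
            raise HairpinDesignError("overhang exceeds lower stem")
        if abs(sum(self.gc_bias) - 1.0) > 1e-9:
            raise HairpinDesignError("gc_bias must sum to 1")
        protected = {1, self.lower_stem_length + 1, self.stem_length}
        protected.update(
            range(self.lower_stem_length - self.overhang + 1, self.lower_stem_length + 1)
        )
        covered: set[int] = set()
        for pos, s5, s3 in self.internal_loops:
            width = max(s5, s3)
            if width < 1 or min(s5, s3) < 0:
                raise HairpinDesignError(f"bad internal loop sizes ({s5},{s3})")
            span = set(range(pos, pos + width))
            if span & protected:
                raise HairpinDesignError(
                    f"internal loop at pair {pos} touches a protected stem pair"
                )
            if not span <= set(range(2, self.stem_length)):
                raise HairpinDesignError(
                    f"internal loop at pair {pos} larger than the stem"
                )
            if span & covered:
                raise HairpinDesignError("internal loops overlap")
            covered |= span

    @property
    def n_pairs(self) -> int:
        return self.stem_length - sum(
            max(s5, s3) for _, s5, s3 in self.internal_loops
        )


@dataclass(frozen=True)
class LibraryModel:
    """Statistical model of one sequencing library."""

    condition: str = "control"  # control | knockout
    replicate: int = 1
    signal_depth: float = 100.0
    signal_dispersion: float = 0.05
    # Degradome libraries are dominated by diffuse exonucleolytic decay
    # fragments; a compositional majority of background reads is what the
    # TMM step anchors on between conditions
    background_rate: float = 0.2
    srna_mirna_depth: float = 50.0
    srna_morna_depth: float = 20.0
    jitter: float = 0.02
    library_id: str | None = None

    def __post_init__(self):
        if self.condition not in ("control", "knockout"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.jitter <= 0.5:
            raise ValueError("jitter must be in [0, 0.5]")
        for depth in (
            self.signal_depth,
            self.background_rate,
            self.srna_mirna_depth,
            self.srna_morna_depth,
        ):
            if depth < 0:
                raise ValueError("depths and rates must be >= 0")
        if self.library_id is None:
            object.__setattr__(
                self, "library_id", f"{self.condition}_rep{self.replicate}"
            )


@dataclass
class DesignedHairpin:
    """A designed cassette in local (transcript) coordinates."""

    sequence: str  # flank5 + stem-loop + flank3, RNA alphabet
    dot_bracket: str
    s_offset: int  # first nt of the excised product
    d_offset: int  # first nt of the downstream fragment
    spec: HairpinSpec
    ugu_span: tuple | None = None  # absolute positions of a planted UGU

    @property
    def span(self) -> int:
        return self.d_offset - self.s_offset


_PAIR_CHOICES = {
    "gc": (("G", "C"), ("C", "G")),
    "au": (("A", "U"), ("U", "A")),
    "gu": (("G", "U"), ("U", "G")),
}


def _draw_pair(spec: HairpinSpec, rng: np.random.Generator) -> tuple[str, str]:
    kind = ("gc", "au", "gu")[rng.choice(3, p=list(spec.gc_bias))]
    return _PAIR_CHOICES[kind][rng.integers(2)]


def design_hairpin(
    spec: HairpinSpec,
    rng: np.random.Generator,
    params: ModelParams | None = None,
    max_tries: int = 50,
) -> DesignedHairpin:
    """Design a sequence realising ``spec`` and verify its cleavage geometry.

    Random draws (pair identities, loop and flank bases) are repeated until
    the designed window folds, under the built-in model, such that the
    computed 3' overhang between ``S`` and ``D`` equals the planted one.
    Unpaired loop bases are drawn from {A, C} to suppress competing helices;
    flanks are uniform over ACGU apart from planted motif bases.
    """
    params = params or folding.DEFAULT_PARAMS
    last_err = None
    for _ in range(max_tries):
        hp = _design_once(spec, rng)
        ok, err = _check_geometry(hp, params)
        if ok:
            return hp
        last_err = err
    raise HairpinDesignError(
        f"could not realise hairpin spec after {max_tries} tries: {last_err}"
    )


def _design_once(spec: HairpinSpec, rng: np.random.Generator) -> DesignedHairpin:
    loops = {pos: (s5, s3) for pos, s5, s3 in spec.internal_loops}
    arm5: list[tuple[str, str]] = []  # (base, '(' | '.')
    arm3: list[tuple[str, str]] = []  # built basal->apical, reversed later
    s_index_in_arm5 = None
    k = 1
    while k <= spec.stem_length:
        if k == spec.lower_stem_length + 1:
            s_index_in_arm5 = len(arm5)
        if k in loops:
            s5, s3 = loops[k]
            for _ in range(s5):
                arm5.append((_unpaired_base(rng), "."))
            for _ in range(s3):
                arm3.append((_unpaired_base(rng), "."))
            k += max(s5, s3)
            continue
        b5, b3 = _draw_pair(spec, rng)
        arm5.append((b5, "("))
        arm3.append((b3, ")"))
        k += 1
    if s_index_in_arm5 is None:  # lower_stem_length == stem_length edge
        s_index_in_arm5 = len(arm5)

    ugu_in_loop = None
    if "apical_UGU" in spec.motif_flags:
        # C filler cannot form two adjacent pairs with U/G; the geometry
        # check additionally verifies the motif stays unpaired in the fold
        loop_bases = ["C"] * spec.loop_length
        loop_bases[:3] = list("UGU")
        ugu_in_loop = (0, 1, 2)
    else:
        loop_bases = [_unpaired_base(rng) for _ in range(spec.loop_length)]

    flank5 = [_random_base(rng) for _ in range(spec.flank_length)]
    flank3 = [_random_base(rng) for _ in range(spec.flank_length)]

    # assemble transcript: flank5, 5' arm, loop, reversed 3' arm, flank3
    arm3_seq = [b for b, _ in reversed(arm3)]
    arm3_db = [c for _, c in reversed(arm3)]
    seq = (
        flank5
        + [b for b, _ in arm5]
        + loop_bases
        + arm3_seq
        + flank3
    )
    db = (
        ["."] * spec.flank_length
        + [c for _, c in arm5]
        + ["."] * spec.loop_length
        + arm3_db
        + ["."] * spec.flank_length
    )

    s_offset = spec.flank_length + s_index_in_arm5
    # partner of S = 3'-arm nucleotide of pair lower_stem+1; locate via table
    table = folding.parse_dotbracket("".join(db))
    partner_s = int(table[s_offset])
    if partner_s < 0:
        raise HairpinDesignError("internal error: S not paired in planted structure")
    d_offset = partner_s + spec.overhang + 1

    if "basal_UG" in spec.motif_flags:
        # U at anchored -14, G at -13 relative to S (positions S-14, S-13)
        if s_offset >= 14:
            seq[s_offset - 14] = "U"
            _set_base(seq, table, s_offset - 13, "G")
    if "CNNC" in spec.motif_flags:
        # CNNC with the first C 17 nt 3' of D (inside the scanned 16-18 window)
        if d_offset + 20 <= len(seq):
            for off, base in ((17, "C"), (20, "C")):
                _set_base(seq, table, d_offset + off, base)

    ugu_span = None
    if ugu_in_loop is not None:
        loop_start = spec.flank_length + len(arm5)
        ugu_span = tuple(loop_start + k for k in ugu_in_loop)
    return DesignedHairpin(
        sequence="".join(seq),
        dot_bracket="".join(db),
        s_offset=s_offset,
        d_offset=d_offset,
        spec=spec,
        ugu_span=ugu_span,
    )


def _set_base(seq: list, table: np.ndarray, pos: int, base: str) -> None:
    """Set a base, keeping its partner complementary if the position pairs."""
    seq[pos] = base
    mate = int(table[pos]) if pos < len(table) else -1
    if mate >= 0:
        seq[mate] = {"G": "C", "C": "G", "A": "U", "U": "A"}[base]


def _unpaired_base(rng) -> str:
    return "AC"[rng.integers(2)]


def _random_base(rng) -> str:
    return "ACGU"[rng.integers(4)]


def _check_geometry(hp: DesignedHairpin, params: ModelParams) -> tuple[bool, str]:
    """Fold the [S-15, D+15) window and verify the planted overhang."""
    from .stemloop import compute_overhang, NoDuplexError

    lo, hi = hp.s_offset - 15, hp.d_offset + 15
    if lo < 0 or hi > len(hp.sequence):
        return False, "window outside designed region"
    if not 25 <= hp.span <= 100:
        return False, f"S/D span {hp.span} outside [25, 100]"
    window = hp.sequence[lo:hi]
    struct = folding.fold_mfe(window, params=params)
    try:
        ovh = compute_overhang(struct, 15, hp.d_offset - 1 - lo)
    except NoDuplexError as exc:
        return False, str(exc)
    if ovh != hp.spec.overhang:
        return False, f"folded overhang {ovh} != planted {hp.spec.overhang}"
    if hp.ugu_span is not None:
        for pos in hp.ugu_span:
            w = pos - lo
            if 0 <= w < len(window) and struct.pair_table[w] >= 0:
                return False, "planted apical UGU recruited into a helix"
    return True, ""


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

def mirna_like_spec(rng: np.random.Generator) -> HairpinSpec:
    """Canonical substrate: ~35 +- 1 bp stem, roomy loop, processing motifs."""
    return HairpinSpec(
        stem_length=int(rng.integers(34, 37)),
        loop_length=int(rng.integers(10, 15)),
        lower_stem_length=13,
        internal_loops=(),
        overhang=2,
        motif_flags=frozenset({"basal_UG", "apical_UGU", "CNNC"}),
        gc_bias=(0.5, 0.4, 0.1),
    )


def mrna_like_spec(rng: np.random.Generator) -> HairpinSpec:
    """Non-canonical substrate: ~26 bp stem, asymmetric loops, no motifs."""
    stem = int(rng.integers(24, 29))
    pos = int(rng.integers(16, stem - 3))
    loops = ((pos, int(rng.integers(1, 4)), 0),)
    return HairpinSpec(
        stem_length=stem,
        loop_length=int(rng.integers(6, 16)),
        lower_stem_length=13,
        internal_loops=loops,
        overhang=2,
        motif_flags=frozenset(),
        gc_bias=(0.7, 0.2, 0.1),
    )


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def build_genome(
    n_mirna_like: int,
    n_mrna_like: int,
    genome_length: int,
    rng: np.random.Generator,
    chrom: str = "chrS",
    depletion_factor: float = 0.1,
    spacing: int = MIN_LOCUS_SPACING,
    params: ModelParams | None = None,
) -> tuple[str, pd.DataFrame]:
    """Plant hairpin cassettes in a uniform-background genome.

    Returns the genome as FASTA text (DNA alphabet) and the truth table.
    Loci are placed non-overlapping with at least ``spacing`` nt between
    cassettes, strands drawn at random.
    """
    n_total = n_mirna_like + n_mrna_like
    designs = []
    for idx in range(n_total):
        spec_fn = mirna_like_spec if idx < n_mirna_like else mrna_like_spec
        label = "miRNA-like" if idx < n_mirna_like else "mRNA-like"
        designs.append((label, design_hairpin(spec_fn(rng), rng, params)))

    slot = max((len(hp.sequence) for _, hp in designs), default=0) + spacing
    required = n_total * slot + spacing
    if genome_length < required:
        raise ValueError(
            f"genome_length {genome_length} too small for {n_total} loci; "
            f"need at least {required}"
        )

    genome = rng.choice(list("ACGT"), genome_length)
    # evenly strided slots with random offsets keep placement trivial and
    # guarantee the spacing invariant
    starts = []
    for idx in range(n_total):
        base = spacing + idx * slot
        wiggle = slot - spacing - (len(designs[idx][1].sequence))
        starts.append(base + int(rng.integers(0, max(wiggle, 1))))

    rows = []
    for idx, ((label, hp), start) in enumerate(zip(designs, starts)):
        strand = "+" if rng.random() < 0.5 else "-"
        region = hp.sequence.replace("U", "T")
        db = hp.dot_bracket
        if strand == "-":
            region = _revcomp_dna(region)
        end = start + len(region)
        genome[start:end] = list(region)
        if strand == "+":
            s_gen = start + hp.s_offset
            d_gen = start + hp.d_offset
        else:
            # transcript position t maps to genomic end-1-t
            s_gen = end - 1 - hp.s_offset
            d_gen = end - 1 - hp.d_offset
        rows.append(
            {
                "locus_id": f"hp{idx:04d}",
                "chrom": chrom,
                "strand": strand,
                "five_prime_cleavage": s_gen,
                "three_prime_pileup": d_gen,
                "region_start": start,
                "region_end": end,
                "dot_bracket": db,
                "class_label": label,
                "drosha_dependent": True,
                "depletion_factor": depletion_factor,
                "overhang": hp.spec.overhang,
            }
        )

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    fasta = write_fasta({chrom: "".join(genome)})
    return fasta, truth


def _revcomp_dna(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def write_fasta(records: dict[str, str], width: int = 60) -> str:
    out = io.StringIO()
    for name, seq in records.items():
        out.write(f">{name}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# read simulators
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _nb_counts(mean, dispersion, size, rng):
    """Negative binomial draws parametrised by mean and dispersion alpha
    (variance = mu + alpha * mu^2), via the gamma-Poisson mixture."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _jittered_positions(center, count, jitter, rng):
    offsets = rng.choice(
        [-1, 0, 1], size=count, p=[jitter, 1.0 - 2.0 * jitter, jitter]
    )
    return center + offsets


def simulate_degradome(
    truth: pd.DataFrame,
    models: list[LibraryModel],
    genome_length: int,
    rng: np.random.Generator,
    read_length: int = DEGRADOME_READ_LENGTH,
    chrom: str = "chrS",
) -> dict[str, pd.DataFrame]:
    """Simulate Degradome-seq libraries as BED6 frames keyed by library id.

    Reads are fixed-length intervals on the locus strand whose biological 5'
    end sits at the planted pile-up site ``D`` (with +-1 jitter); background
    read starts are homogeneous Poisson per position and strand.
    """
    out = {}
    for model in models:
        rows = []
        read_id = 0
        for _, locus in truth.iterrows():
            if not locus["drosha_dependent"] and model.condition == "knockout":
                factor = 1.0
            else:
                factor = (
                    locus["depletion_factor"]
                    if model.condition == "knockout"
                    else 1.0
                )
            mean = model.signal_depth * factor
            count = int(_nb_counts(mean, model.signal_dispersion, 1, rng)[0])
            positions = _jittered_positions(
                int(locus["three_prime_pileup"]), count, model.jitter, rng
            )
            strand = locus["strand"]
            for pos in positions:
                rows.append(_degradome_read(chrom, int(pos), strand, read_length,
                                            model.library_id, read_id))
                read_id += 1
        n_bg = rng.poisson(model.background_rate * genome_length * 2)
        bg_pos = rng.integers(0, genome_length, size=n_bg)
        bg_strand = rng.integers(0, 2, size=n_bg)
        for pos, s in zip(bg_pos, bg_strand):
            strand = "+-"[s]
            rows.append(_degradome_read(chrom, int(pos), strand, read_length,
                                        model.library_id, read_id))
            read_id += 1
        bed = pd.DataFrame(rows, columns=BED_COLUMNS)
        bed = bed[(bed["start"] >= 0) & (bed["end"] <= genome_length)]
        out[model.library_id] = bed.reset_index(drop=True)
    return out


def _degradome_read(chrom, five_prime, strand, read_length, library_id, read_id):
    if strand == "+":
        start, end = five_prime, five_prime + read_length
    else:
        start, end = five_prime - read_length + 1, five_prime + 1
    return {
        "chrom": chrom,
        "start": start,
        "end": end,
        "name": f"{library_id}:{read_id}",
        "score": 1,
        "strand": strand,
    }


def simulate_srna(
    truth: pd.DataFrame,
    models: list[LibraryModel],
    genome_length: int,
    rng: np.random.Generator,
    chrom: str = "chrS",
    library_size: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate collapsed sRNA-seq libraries (multiplicity in the BED score).

    Per locus and arm: product-like ("miRNA-like") reads carry the cleavage
    site as their proximal terminus with lengths 20-24 nt; offset-RNA-like
    ("moRNA-like") reads abut the cleavage site on the flanking side with
    geometrically ragged distal termini.  ``library_size`` optionally forces
    the nominal total used for RPM normalisation.
    """
    out = {}
    for model in models:
        reads: list[tuple[int, int, str]] = []  # (start, end, strand)
        for _, locus in truth.iterrows():
            factor = (
                locus["depletion_factor"] if model.condition == "knockout" else 1.0
            )
            strand = locus["strand"]
            s_pos = int(locus["five_prime_cleavage"])
            d_pos = int(locus["three_prime_pileup"])
            n_mi = int(_nb_counts(model.srna_mirna_depth * factor, 0.1, 1, rng)[0])
            n_mo = int(_nb_counts(model.srna_morna_depth * factor, 0.1, 1, rng)[0])
            # 5' arm: products start at S, moRNAs end at S-1
            for _ in range(n_mi):
                length = int(rng.integers(20, 25))
                reads.append(_tx_read(s_pos, "start", length, strand))
            for _ in range(n_mo):
                length = 10 + int(rng.geometric(0.2))
                reads.append(_tx_read(s_pos - 1 if strand == "+" else s_pos + 1,
                                      "end", length, strand))
            # 3' arm: products end at D-1, moRNAs start at D
            for _ in range(n_mi):
                length = int(rng.integers(20, 25))
                reads.append(_tx_read(d_pos - 1 if strand == "+" else d_pos + 1,
                                      "end", length, strand))
            for _ in range(n_mo):
                length = 10 + int(rng.geometric(0.2))
                reads.append(_tx_read(d_pos, "start", length, strand))
        frame = pd.DataFrame(reads, columns=["start", "end", "strand"])
        frame = frame[(frame["start"] >= 0) & (frame["end"] <= genome_length)]
        collapsed = (
            frame.groupby(["start", "end", "strand"], as_index=False)
            .size()
            .rename(columns={"size": "score"})
        )
        collapsed["chrom"] = chrom
        collapsed["name"] = [
            f"{model.library_id}:u{i}" for i in range(len(collapsed))
        ]
        bed = collapsed[BED_COLUMNS].sort_values(["start", "end", "strand"])
        bed.attrs["library_size"] = (
            int(library_size) if library_size is not None else int(len(frame))
        )
        out[model.library_id] = bed.reset_index(drop=True)
    return out


def _tx_read(terminus: int, which: str, length: int, strand: str):
    """Build a genomic interval from a biological terminus.

    ``which`` names the biological end sitting at ``terminus``: for a +
    strand read, 'start' means the 5' end (BED start), 'end' the 3' end
    (BED end-1); on the - strand the mapping is mirrored.
    """
    if strand == "+":
        if which == "start":
            start = terminus
        else:
            start = terminus - length + 1
    else:
        if which == "start":
            start = terminus - length + 1
        else:
            start = terminus
    return (start, start + length, strand)


def write_bed(bed: pd.DataFrame) -> str:
    return bed.to_csv(sep="\t", header=False, index=False)
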