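"""Per-stem-loop features distinguishing miRNA from non-miRNA substrates.

All positional quantities are reported in cleavage-anchored coordinates:
position +1 is the first nucleotide of the excised product on each arm
(the upper stem), the cut falls between -1 and +1, and negative positions
run into the lower stem and flanking single-stranded RNA.  Structural
categories per nucleotide are

* ``P`` paired,
* ``F`` flanking ssRNA outside the outermost stem pair,
* ``T`` terminal loop (unpaired, enclosed by the innermost pair),
* ``I`` symmetric internal loop,
* ``B`` asymmetric internal loop / bulge.

Annotation refolds the call window with 25-nt flanks under the constraint
that every pair of the 15-nt-flank structure stays paired, so the longer
context can only extend -- never rearrange -- the called duplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import folding
from .folding import FoldConstraint, ModelParams
from .stemloop import StemLoopCall, fetch_transcript

__all__ = [
    "AnchoredAnnotation",
    "InternalLoopRecord",
    "MotifHit",
    "annotate_positions",
    "thermodynamic_features",
    "bp_composition",
    "catalog_internal_loops",
    "information_matrix",
    "scan_motifs",
    "compare_groups",
    "DEFAULT_MOTIF_WINDOWS",
]

CATEGORIES = "PFIBT"


@dataclass(frozen=True)
class InternalLoopRecord:
    """One internal loop: unpaired run sizes on each arm plus its anchored
    position (first unpaired 5'-arm nt closest to the cleavage site) and
    5-bp window index."""

    size5: int
    size3: int
    position: int  # anchored, 5' arm
    window: int  # 1-based 5-bp bin, sign matching the anchored position

    @property
    def symmetric(self) -> bool:
        return self.size5 == self.size3


@dataclass(frozen=True)
class MotifHit:
    motif: str
    window: str
    present: bool
    offset: int | None = None


@dataclass
class AnchoredAnnotation:
    """Per-position structural categories for one call, with arm-anchored
    coordinate lookups."""

    sequence: str
    categories: str
    structure: folding.SecondaryStructure
    s_idx: int  # product 5' nt (5'-arm anchored +1) in window coordinates
    e_idx: int  # product 3' nt (3'-arm anchored +1) in window coordinates
    arm_split: int  # first window index belonging to the 3' arm
    loops: list = field(default_factory=list)
    constrained: bool = True

    def anchored5(self, window_pos: int) -> int:
        a = window_pos - self.s_idx
        return a + 1 if a >= 0 else a

    def anchored3(self, window_pos: int) -> int:
        a = self.e_idx - window_pos
        return a + 1 if a >= 0 else a

    def arm_categories(self, arm: str) -> dict[int, str]:
        """anchored position -> category for one arm ('5p' or '3p')."""
        out = {}
        idx = range(0, self.arm_split) if arm == "5p" else range(
            self.arm_split, len(self.categories)
        )
        conv = self.anchored5 if arm == "5p" else self.anchored3
        for p in idx:
            out[conv(p)] = self.categories[p]
        return out

    def arm_sequences(self, arm: str) -> dict[int, str]:
        out = {}
        idx = range(0, self.arm_split) if arm == "5p" else range(
            self.arm_split, len(self.sequence)
        )
        conv = self.anchored5 if arm == "5p" else self.anchored3
        for p in idx:
            out[conv(p)] = self.sequence[p]
        return out


def _helix_children(table: np.ndarray, i: int, j: int) -> list[tuple[int, int]]:
    """Top-level pairs strictly inside (i, j)."""
    children = []
    p = i + 1
    while p < j:
        q = int(table[p])
        if q > p:
            children.append((p, q))
            p = q + 1
        else:
            p += 1
    return children


def _top_level_pairs(table: np.ndarray) -> list[tuple[int, int]]:
    return _helix_children(table, -1, len(table))


def annotate_positions(
    call: StemLoopCall,
    genome,
    flank: int = 25,
    params: ModelParams | None = None,
) -> AnchoredAnnotation:
    """Constrained refold with ``flank``-nt flanks and P/F/I/B/T labelling.

    Every pair of the call's 15-nt-flank structure is forced to remain
    paired in the wider window; if that constraint is infeasible the window
    is refolded unconstrained with a warning.
    """
    if not call.accepted or call.structure is None:
        raise ValueError("annotation requires an accepted call with a structure")
    params = params or folding.DEFAULT_PARAMS
    ext = max(flank - 15, 0)
    chrom_len = len(genome[call.chrom])
    if call.strand == "+":
        g_lo = max(call.window_start - ext, 0)
        g_hi = min(call.window_end + ext, chrom_len)
        ext5 = call.window_start - g_lo
    else:
        g_lo = max(call.window_start - ext, 0)
        g_hi = min(call.window_end + ext, chrom_len)
        ext5 = g_hi - call.window_end
    seq = fetch_transcript(genome, call.chrom, g_lo, g_hi, call.strand)

    shift = ext5
    forced = frozenset(
        (i + shift, j + shift) for i, j in call.structure.pairs()
    )
    constrained = True
    try:
        struct = folding.fold_mfe(
            seq, constraint=FoldConstraint(forced_pairs=forced), params=params
        )
    except folding.ConstraintError:
        warnings.warn(
            "constraint infeasible at wider flank; refolding unconstrained"
        )
        constrained = False
        struct = folding.fold_mfe(seq, params=params)

    s_idx = call.five_idx + shift
    e_idx = call.three_idx + shift
    categories, loops, arm_split = _label_structure(struct.pair_table, s_idx, e_idx)
    ann = AnchoredAnnotation(
        sequence=seq,
        categories=categories,
        structure=struct,
        s_idx=s_idx,
        e_idx=e_idx,
        arm_split=arm_split,
        constrained=constrained,
    )
    ann.loops = [_loop_record(run5, run3, ann) for run5, run3 in loops]
    return ann


def _label_structure(table: np.ndarray, s_idx: int, e_idx: int):
    """Walk the hairpin from its outermost pair inward.

    Returns the category string, the internal-loop runs as pairs of
    (5'-arm run, 3'-arm run) position lists, and the window index where the
    3' arm starts (the middle of the terminal loop).
    """
    n = len(table)
    cats = ["F"] * n
    loops: list[tuple[list[int], list[int]]] = []
    top = _top_level_pairs(table)
    if not top:
        return "".join(cats), loops, n // 2
    # the stem of interest is the top-level helix containing the product
    root = None
    for i, j in top:
        if i <= s_idx <= j or i <= e_idx <= j:
            root = (i, j)
            break
    if root is None:
        root = max(top, key=lambda ij: ij[1] - ij[0])

    t_mid = None
    i, j = root
    cats[i] = cats[j] = "P"
    while True:
        children = _helix_children(table, i, j)
        if not children:
            for p in range(i + 1, j):
                cats[p] = "T"
            t_mid = (i + j + 1) // 2
            break
        if len(children) > 1:
            warnings.warn(
                "multibranch loop inside a stem-loop window; unpaired "
                "positions classified as asymmetric (B)"
            )
            for p in range(i + 1, j):
                if table[p] < 0:
                    cats[p] = "B"
                elif cats[p] == "F":
                    cats[p] = "P"
            # descend into the child on the product side
            child = children[0]
            for a, b in children:
                if a <= s_idx <= b or a <= e_idx <= b:
                    child = (a, b)
            i, j = child
            cats[i] = cats[j] = "P"
            continue
        (a, b) = children[0]
        cats[a] = cats[b] = "P"
        run5 = list(range(i + 1, a))
        run3 = list(range(b + 1, j))
        if run5 or run3:
            label = "I" if len(run5) == len(run3) else "B"
            for p in run5 + run3:
                cats[p] = label
            loops.append((run5, run3))
        i, j = a, b
    arm_split = t_mid if t_mid is not None else (s_idx + e_idx + 1) // 2
    return "".join(cats), loops, arm_split


def _loop_record(run5: list[int], run3: list[int], ann: AnchoredAnnotation):
    """Anchored internal-loop record; position is the 5'-arm unpaired nt
    closest to the cleavage site (for 3'-arm-only bulges, the enclosing
    5'-arm nucleotide just apical of the junction)."""
    if run5:
        anchored = [ann.anchored5(p) for p in run5]
        # closest to the cut: smallest positive, else largest negative
        pos = min(anchored, key=lambda a: (a < 0, abs(a)))
    else:
        # 3'-arm-only bulge: anchor at the 5'-arm partner of the pair just
        # apical of the bulged run
        pos = ann.anchored5(_partner_on_5arm(ann, run3))
    window = _five_bp_window(pos)
    return InternalLoopRecord(
        size5=len(run5), size3=len(run3), position=int(pos), window=int(window)
    )


def _partner_on_5arm(ann: AnchoredAnnotation, run3: list[int]) -> int:
    table = ann.structure.pair_table
    inner_pair_3 = run3[0] - 1  # position of the pair just apical of the run
    mate = int(table[inner_pair_3]) if inner_pair_3 >= 0 else -1
    return mate if mate >= 0 else ann.s_idx


def _five_bp_window(pos: int) -> int:
    if pos >= 1:
        return (pos - 1) // 5 + 1
    return -((-pos - 1) // 5 + 1)


# ---------------------------------------------------------------------------
# thermodynamic and composition features
# ---------------------------------------------------------------------------

def thermodynamic_features(
    call: StemLoopCall,
    params: ModelParams | None = None,
    class_label: str = "",
) -> dict:
    """Summary features of the 15-nt-flank stem-loop window.

    Length is the cleavage-site span plus both flanks; base-pair frequency
    and maximum stack run are normalised to that length.  Ensemble
    diversity and mean positional entropy come from the partition function
    over the same window.
    """
    if not call.accepted or call.structure is None:
        raise ValueError("features require an accepted call")
    params = params or folding.DEFAULT_PARAMS
    struct = call.structure
    n = len(struct.sequence)
    pairs = struct.pairs()
    length = call.span + 30
    ens = folding.ensemble_statistics(struct.sequence, params=params)
    comp = bp_composition(call)
    row = {
        "class_label": class_label,
        "mfe": struct.mfe,
        "length": length,
        "n_pairs": len(pairs),
        "bp_frequency": len(pairs) / length,
        "max_stack": _max_stack(struct.pair_table) / length,
        "ensemble_diversity": ens.ensemble_diversity,
        "mean_entropy": float(np.mean(ens.positional_entropy)),
    }
    for region in ("lower", "upper"):
        for kind in ("gc", "au", "gu"):
            row[f"{region}_{kind}"] = comp[region][kind]
    return row


def _max_stack(table: np.ndarray) -> int:
    """Longest run of consecutively stacked pairs (i,j),(i+1,j-1),..."""
    best = run = 0
    prev = None
    for i, j in ((i, int(j)) for i, j in enumerate(table) if j > i):
        if prev is not None and (i, j) == (prev[0] + 1, prev[1] - 1):
            run += 1
        else:
            run = 1
        best = max(best, run)
        prev = (i, j)
    return best


def bp_composition(call: StemLoopCall) -> dict:
    """G-C / A-U / G-U fractions for the lower and upper stem separately.

    A pair belongs to the upper stem when its 5'-arm nucleotide sits at or
    apical of the product start (anchored >= +1), to the lower stem
    otherwise; fractions are normalised within each stem and NaN when the
    stem has no pairs.
    """
    struct = call.structure
    seq = struct.sequence
    counts = {"lower": {"gc": 0, "au": 0, "gu": 0},
              "upper": {"gc": 0, "au": 0, "gu": 0}}
    for i, j in struct.pairs():
        duo = frozenset((seq[i], seq[j]))
        kind = {frozenset("GC"): "gc", frozenset("AU"): "au",
                frozenset("GU"): "gu"}.get(duo)
        if kind is None:
            continue
        region = "upper" if i >= call.five_idx else "lower"
        counts[region][kind] += 1
    out = {}
    for region, c in counts.items():
        total = sum(c.values())
        out[region] = {
            k: (v / total if total else float("nan")) for k, v in c.items()
        }
    return out


def catalog_internal_loops(annotation: AnchoredAnnotation) -> list[InternalLoopRecord]:
    """Internal loops of the annotated stem, one record per loop."""
    return list(annotation.loops)


# ---------------------------------------------------------------------------
# information matrices
# ---------------------------------------------------------------------------

def information_matrix(
    items: list[dict[int, str]],
    alphabet: str,
    min_coverage: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-position symbol frequencies and information content in bits.

    ``items`` are mappings from anchored position to symbol (one per
    stem-loop, aligned on the cleavage anchor).  Information is
    ``log2 |alphabet| + sum_c f_c log2 f_c``; positions covered by fewer
    than ``min_coverage`` items are masked (NaN).
    """
    if not items:
        raise ValueError("no items to align")
    positions = sorted({p for item in items for p in item})
    freq = pd.DataFrame(0.0, index=positions, columns=list(alphabet))
    coverage = pd.Series(0, index=positions, dtype=int)
    for item in items:
        for pos, sym in item.items():
            if sym not in freq.columns:
                raise ValueError(f"symbol {sym!r} not in alphabet {alphabet!r}")
            freq.at[pos, sym] += 1
            coverage[pos] += 1
    freq = freq.div(coverage, axis=0)
    f = freq.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    info = pd.Series(
        np.log2(len(alphabet)) + plogp.sum(axis=1), index=positions, name="bits"
    )
    info[coverage < min_coverage] = np.nan
    return freq, info


# ---------------------------------------------------------------------------
# sequence motifs
# ---------------------------------------------------------------------------

# anchored-coordinate search windows; the canonical positions from the
# pri-miRNA processing literature, all configurable
DEFAULT_MOTIF_WINDOWS = {
    "basal_UG": {"center": -14, "slack": 1},
    "apical_UGU": {},  # searched within the terminal loop
    "CNNC": {"offsets": (16, 17, 18)},  # nt 3' of the 3'-arm cleavage site
    "mGHG": {"positions": (-7, -6, -5)},  # 3'-strand anchored positions
}


def scan_motifs(
    annotation: AnchoredAnnotation,
    windows: dict | None = None,
) -> list[MotifHit]:
    """Scan the canonical processing motifs in anchored coordinates.

    * ``basal_UG``: literal UG with the U at 5'-arm anchored -14 (+-1).
    * ``apical_UGU``: UGU or GUG within the terminal-loop sequence.
    * ``CNNC``: C-N-N-C starting 16-18 nt 3' of the 3'-arm cleavage site.
    * ``mGHG``: G-H-G (H in A/C/U) on the 3' strand across anchored
      -7..-5 with the central position unpaired (the mismatch).
    """
    windows = {**DEFAULT_MOTIF_WINDOWS, **(windows or {})}
    seq = annotation.sequence
    n = len(seq)
    hits = []

    cfg = windows["basal_UG"]
    present, offset = False, None
    for d in range(-cfg["slack"], cfg["slack"] + 1):
        p = annotation.s_idx + (cfg["center"] + d)  # anchored -14 -> S-14
        if 0 <= p and p + 1 < n and seq[p : p + 2] == "UG":
            present, offset = True, cfg["center"] + d
            break
    hits.append(MotifHit("basal_UG", f"5'-arm {cfg['center']}+-{cfg['slack']}",
                         present, offset))

    loop_positions = [i for i, c in enumerate(annotation.categories) if c == "T"]
    loop_seq = "".join(seq[i] for i in loop_positions)
    found = None
    for pat in ("UGU", "GUG"):
        k = loop_seq.find(pat)
        if k >= 0:
            found = k
            break
    hits.append(MotifHit("apical_UGU", "terminal loop", found is not None, found))

    cfg = windows["CNNC"]
    present, offset = False, None
    # 3'-arm anchored -k lies k-1 nt 3' of the product end in transcript space
    for off in cfg["offsets"]:
        p = annotation.e_idx + off
        if p + 3 < n and seq[p] == "C" and seq[p + 3] == "C":
            present, offset = True, off
            break
    hits.append(MotifHit("CNNC", f"3' flank +{cfg['offsets'][0]}..{cfg['offsets'][-1]}",
                         present, offset))

    cfg = windows["mGHG"]
    table = annotation.structure.pair_table
    pos = [annotation.e_idx - a for a in cfg["positions"]]  # anchored -> window
    present = False
    if all(0 <= p < n for p in pos):
        # transcript order on the 3' strand: most basal (lowest anchored) last
        ordered = sorted(pos)
        triplet = "".join(seq[p] for p in ordered)
        central = ordered[1]
        if (
            triplet[0] == "G"
            and triplet[2] == "G"
            and triplet[1] in "ACU"
            and table[central] < 0
        ):
            present = True
    hits.append(MotifHit("mGHG", f"3' strand {cfg['positions']}", present, None))
    return hits


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    table: pd.DataFrame,
    grouping: str | pd.Series,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Welch's unequal-variance two-tailed t-test per feature.

    Returns t, the Welch-Satterthwaite degrees of freedom, the two-tailed
    p-value and the group means.  No multiplicity correction is applied
    (features are reported individually).
    """
    labels = table[grouping] if isinstance(grouping, str) else grouping
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = table[labels == groups[0]]
    b = table[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if features is None:
        features = [
            c for c in table.columns
            if c != grouping and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for feat in features:
        x = a[feat].dropna().to_numpy(float)
        y = b[feat].dropna().to_numpy(float)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0.0 and vy == 0.0:
            if np.isclose(x.mean(), y.mean()):
                t, p, df = 0.0, 1.0, len(x) + len(y) - 2
            else:
                raise ValueError(
                    f"feature {feat!r}: zero variance in both groups with "
                    f"different means"
                )
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            sx, sy = vx / len(x), vy / len(y)
            df = (sx + sy) ** 2 / (
                sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1)
            )
        rows.append(
            {
                "feature": feat,
                f"mean_{groups[0]}": float(x.mean()),
                f"mean_{groups[1]}": float(y.mean()),
                "t": float(t),
                "df": float(df),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
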