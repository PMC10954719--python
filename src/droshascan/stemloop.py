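"""Pairing Degradome pile-up sites with sRNA terminus stacks into stem-loops.

A Degradome pile-up site ``D`` marks one cleavage position of an RNase III
duplex cut (the 5' end of the downstream polyA-bearing fragment).  The
cleavage site on the opposite arm is inferred from small-RNA read termini:
product-like reads carry it as their proximal terminus, offset-RNA-like
reads abut it from the flanking side.  Candidate sites ``S`` are terminus
stacks deeper than 1 RPM whose implied cleavage position lies 25-100 nt
from ``D`` (in either transcript direction; the downstream direction covers
hairpins whose only Degradome-visible cut is on the 5' arm).  The window
spanning both sites with 15-nt flanks is folded, and a candidate is
accepted when the two sites bound a duplex end with a 3' overhang of
2 +- 2 nt -- the RNase III signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import folding
from .folding import ModelParams, SecondaryStructure

__all__ = [
    "NoDuplexError",
    "TerminusStack",
    "StemLoopCall",
    "compute_overhang",
    "find_terminus_stacks",
    "reconstruct_stemloop",
    "call_stemloops",
    "fetch_transcript",
]

WINDOW_MIN = 25
WINDOW_MAX = 100
ACCEPT_OVERHANG = (0, 4)  # 2 +- 2 nt


class NoDuplexError(ValueError):
    """The product 5' end is unpaired beyond the allowed inward shift."""


@dataclass(frozen=True)
class TerminusStack:
    """A stacked sRNA read terminus near an anchor pile-up site."""

    position: int  # genomic position of the terminus itself
    side: str  # "five_prime_starts" | "three_prime_ends"
    count: float
    rpm: float
    implied_site: int  # genomic position of the implied cleavage site


@dataclass
class StemLoopCall:
    """One candidate (S, D) cleavage-site pairing with its folded window."""

    chrom: str
    strand: str
    d_site: int
    s_site: int
    orientation: str  # "upstream" (canonical) | "downstream"
    window_start: int  # genomic start of folded window (0-based half-open)
    window_end: int
    sequence: str
    structure: SecondaryStructure | None
    overhang: int | None
    support: float  # supporting sRNA stack depth (count)
    support_rpm: float
    accepted: bool
    five_idx: int = -1  # product 5' nt in window coordinates
    three_idx: int = -1  # product 3' nt in window coordinates
    reject_reason: str = ""

    @property
    def span(self) -> int:
        """Transcript-space distance between the paired cleavage sites."""
        return abs(self.s_site - self.d_site)


def fetch_transcript(genome, chrom: str, start: int, end: int, strand: str) -> str:
    """Extract [start, end) from a chrom->sequence mapping in transcript
    orientation (reverse complement on the minus strand), RNA alphabet."""
    seq = str(genome[chrom][start:end]).upper()
    if strand == "-":
        seq = seq.translate(str.maketrans("ACGTU", "TGCAA"))[::-1]
    return seq.replace("T", "U")


def compute_overhang(
    structure: SecondaryStructure,
    five_idx: int,
    three_end_idx: int,
    max_shift: int = 2,
) -> int:
    """Signed 3' overhang between a duplex 5' start and a 3' end.

    ``five_idx`` is the product's 5'-most nucleotide and ``three_end_idx``
    its 3'-most, in window coordinates.  If ``five_idx`` is unpaired the
    duplex end is located by sliding up to ``max_shift`` nt inward with
    compensation.  An RNase III cut leaves overhang 2; callers apply the
    2 +- 2 acceptance gate.
    """
    table = structure.pair_table
    n = len(table)
    if not (0 <= five_idx < n and 0 <= three_end_idx < n):
        raise IndexError("cleavage indices outside the folded window")
    for k in range(0, max_shift + 1):
        idx = five_idx + k
        if idx >= n:
            break
        partner = int(table[idx])
        if partner >= 0:
            return (three_end_idx - partner) - k
    raise NoDuplexError(
        f"no paired position within {max_shift} nt inward of the product 5' end"
    )


def find_terminus_stacks(
    srna_starts,
    srna_ends,
    chrom: str,
    strand: str,
    d_site: int,
    rpm_min: float = 1.0,
    window: tuple[int, int] = (WINDOW_MIN, WINDOW_MAX),
) -> list[TerminusStack]:
    """Scan both 25-100 nt windows around ``D`` for qualifying stacks.

    ``srna_starts``/``srna_ends`` are count tracks of biological read 5'
    starts and 3' ends (see :func:`droshascan.pileup.count_read_termini`).
    A 5'-start stack implies cleavage at its own position; a 3'-end stack
    implies cleavage at the next transcript position.
    """
    lo, hi = window
    sign = 1 if strand == "+" else -1
    stacks = []
    for side, track in (("five_prime_starts", srna_starts),
                        ("three_prime_ends", srna_ends)):
        positions = track.positions(chrom, strand)
        for pos in positions:
            if side == "five_prime_starts":
                implied = pos
            else:
                implied = pos + sign  # cut lies just 3' of a 3' end
            dist = (implied - d_site) * sign
            if not lo <= abs(dist) <= hi:
                continue
            count = track.count(chrom, strand, pos)
            rpm = track.rpm(chrom, strand, pos)
            if rpm > rpm_min:
                stacks.append(
                    TerminusStack(
                        position=int(pos),
                        side=side,
                        count=float(count),
                        rpm=float(rpm),
                        implied_site=int(implied),
                    )
                )
    return stacks


def reconstruct_stemloop(
    genome,
    chrom: str,
    strand: str,
    d_site: int,
    stack: TerminusStack,
    flank: int = 15,
    max_shift: int = 2,
    params: ModelParams | None = None,
    fold_fn=None,
) -> StemLoopCall:
    """Fold the window spanned by ``D`` and a terminus stack, test the overhang.

    Canonical ("upstream") orientation: the hairpin lies transcript-5' of
    ``D``; the product runs from ``S`` to ``D``-1 and ``D`` anchors the
    3'-arm cut.  "Downstream" orientation covers a single 5'-arm cut:
    ``D`` is the product's 5' end and the stack marks its 3' end.
    """
    params = params or folding.DEFAULT_PARAMS
    fold = fold_fn or (lambda seq: folding.fold_mfe(seq, params=params))
    sign = 1 if strand == "+" else -1
    s_site = stack.implied_site
    dist = (s_site - d_site) * sign
    orientation = "upstream" if dist < 0 else "downstream"

    if orientation == "upstream":
        span = -dist
        win_first = s_site - sign * flank
        win_last = d_site + sign * (flank - 1)
        five_idx = flank
        three_idx = flank + span - 1
    else:
        span = dist
        win_first = d_site - sign * flank
        win_last = (s_site - sign) + sign * flank  # product 3' end + flank
        five_idx = flank
        three_idx = flank + span - 1

    g_lo = min(win_first, win_last)
    g_hi = max(win_first, win_last) + 1
    chrom_len = len(genome[chrom])
    truncated_left = max(0, -g_lo)
    g_lo = max(g_lo, 0)
    g_hi = min(g_hi, chrom_len)
    seq = fetch_transcript(genome, chrom, g_lo, g_hi, strand)
    # truncation shifts indices only when the transcript 5' side was cut
    if strand == "+":
        cut5 = truncated_left
    else:
        cut5 = max(0, (max(win_first, win_last) + 1) - chrom_len)
    five_idx -= cut5
    three_idx -= cut5

    base = dict(
        chrom=chrom, strand=strand, d_site=int(d_site), s_site=int(s_site),
        orientation=orientation, window_start=int(g_lo), window_end=int(g_hi),
        sequence=seq, support=stack.count, support_rpm=stack.rpm,
        five_idx=int(five_idx), three_idx=int(three_idx),
    )
    if five_idx < 0 or three_idx >= len(seq):
        return StemLoopCall(**base, structure=None, overhang=None,
                            accepted=False, reject_reason="window truncated")
    struct = fold(seq)
    try:
        ovh = compute_overhang(struct, five_idx, three_idx, max_shift=max_shift)
    except NoDuplexError as exc:
        return StemLoopCall(**base, structure=struct, overhang=None,
                            accepted=False, reject_reason=str(exc))
    accepted = ACCEPT_OVERHANG[0] <= ovh <= ACCEPT_OVERHANG[1]
    return StemLoopCall(
        **base, structure=struct, overhang=int(ovh), accepted=accepted,
        reject_reason="" if accepted else f"overhang {ovh} outside 2 +- 2",
    )


def call_stemloops(
    pileup_sites: pd.DataFrame,
    srna_starts,
    srna_ends,
    genome,
    rpm_min: float = 1.0,
    flank: int = 15,
    max_shift: int = 2,
    params: ModelParams | None = None,
    fold_fn=None,
) -> list[StemLoopCall]:
    """One best stem-loop call per accepted pile-up site.

    Every qualifying stack in both orientations is evaluated; among
    accepted candidates the one with the deepest supporting sRNA stack is
    retained, ties broken by |overhang - 2|, then smaller |S - D|, then
    the transcript-5'-most S.  Anchors with no accepted candidate are
    returned as unresolved calls.
    """
    params = params or folding.DEFAULT_PARAMS
    calls: list[StemLoopCall] = []
    for _, site in pileup_sites.iterrows():
        chrom, strand, d_site = site["chrom"], site["strand"], int(site["position"])
        sign = 1 if strand == "+" else -1
        stacks = find_terminus_stacks(
            srna_starts, srna_ends, chrom, strand, d_site, rpm_min=rpm_min
        )
        candidates = [
            reconstruct_stemloop(
                genome, chrom, strand, d_site, stack, flank=flank,
                max_shift=max_shift, params=params, fold_fn=fold_fn,
            )
            for stack in stacks
        ]
        accepted = [c for c in candidates if c.accepted]
        if accepted:
            accepted.sort(
                key=lambda c: (
                    -c.support,
                    abs(c.overhang - 2),
                    c.span,
                    sign * c.s_site,
                )
            )
            calls.append(accepted[0])
        else:
            calls.append(
                StemLoopCall(
                    chrom=chrom, strand=strand, d_site=d_site, s_site=-1,
                    orientation="unresolved", window_start=-1, window_end=-1,
                    sequence="", structure=None, overhang=None, support=0.0,
                    support_rpm=0.0, accepted=False,
                    reject_reason="no accepted candidate"
                    if candidates else "no qualifying terminus stack",
                )
            )
    return calls


def calls_to_frame(calls: list[StemLoopCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom,
                "strand": c.strand,
                "d_site": c.d_site,
                "s_site": c.s_site,
                "orientation": c.orientation,
                "overhang": c.overhang if c.overhang is not None else np.nan,
                "support": c.support,
                "support_rpm": c.support_rpm,
                "accepted": c.accepted,
                "dot_bracket": c.structure.dot_bracket if c.structure else "",
                "mfe": c.structure.mfe if c.structure else np.nan,
                "window_start": c.window_start,
                "window_end": c.window_end,
                "reject_reason": c.reject_reason,
            }
        )
    return pd.DataFrame(rows)
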