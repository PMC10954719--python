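"""RNA secondary-structure services on a small, exactly solvable energy model.

The package needs folding in three places: deciding whether a candidate
cleavage-site pair closes a duplex with the RNase III 3' overhang, computing
thermodynamic summaries (MFE, base-pair probabilities, positional entropy,
ensemble diversity), and constrained refolding for cleavage-anchored
structure annotation.  All of these run on a deliberately simple stacking
model -- the energy of a structure is the sum of contributions of adjacent
base-pair stacks -- so that every quantity can be cross-checked against
exhaustive enumeration of structures on short sequences.  A production
thermodynamic backend (ViennaRNA) can be swapped in through
:mod:`droshascan.vienna`; everything downstream consumes only dot-brackets
and probability matrices and is backend-agnostic.

Model
-----
Allowed pairs are Watson-Crick (A-U, G-C) plus the G-U wobble.  A stack of
two adjacent pairs (i,j), (i+1,j-1) contributes

* ``-3`` if both pairs are G-C,
* ``-2`` if exactly one is G-C,
* ``-1`` otherwise,

in model units.  Unpaired bases are free.  Hairpin loops must contain at
least ``min_loop`` (default 3) unpaired bases, and by default lonely pairs
(helices of length one) are disallowed, mirroring the ``--noLP`` convention
of production folders.

Boltzmann weights use ``exp(-E / temperature_scale)`` with
``temperature_scale`` in the same model units (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "FoldConstraint",
    "SecondaryStructure",
    "DotBracketError",
    "ConstraintError",
    "parse_dotbracket",
    "pairs_from_dotbracket",
    "to_dotbracket",
    "fold_mfe",
    "ensemble_statistics",
    "enumerate_structures",
    "structure_energy",
]

RNA_ALPHABET = frozenset("ACGU")
_PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
_GC = frozenset({("G", "C"), ("C", "G")})

INF = float("inf")


class DotBracketError(ValueError):
    """Malformed dot-bracket string (unbalanced or illegal character)."""


class ConstraintError(ValueError):
    """Infeasible or ill-formed folding constraint."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the built-in stacking model."""

    stack_gc: float = -3.0
    stack_mixed: float = -2.0
    stack_other: float = -1.0
    min_loop: int = 3
    no_lonely_pairs: bool = True
    temperature_scale: float = 1.0

    def stack_energy(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        n_gc = (outer in _GC) + (inner in _GC)
        if n_gc == 2:
            return self.stack_gc
        if n_gc == 1:
            return self.stack_mixed
        return self.stack_other


DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class FoldConstraint:
    """Hard constraints: specific forced pairs and forced-unpaired positions."""

    forced_pairs: frozenset = frozenset()
    forbidden_positions: frozenset = frozenset()

    def __post_init__(self):
        pairs = sorted((min(i, j), max(i, j)) for i, j in self.forced_pairs)
        object.__setattr__(self, "forced_pairs", frozenset(pairs))
        seen: dict[int, tuple[int, int]] = {}
        for i, j in pairs:
            if i == j:
                raise ConstraintError(f"self-pair ({i},{j})")
            for x in (i, j):
                if x in seen:
                    raise ConstraintError(f"position {x} in two forced pairs")
                seen[x] = (i, j)
                if x in self.forbidden_positions:
                    raise ConstraintError(
                        f"forced pair ({i},{j}) hits forbidden position {x}"
                    )
        # forced pairs must nest
        for a, b in pairs:
            for c, d in pairs:
                if a < c < b < d:
                    raise ConstraintError(f"forced pairs ({a},{b}) and ({c},{d}) cross")

    @property
    def partner_of(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.forced_pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class SecondaryStructure:
    """A folded sequence with optional ensemble summaries.

    ``pair_table`` maps each position to its partner, ``-1`` meaning
    unpaired.  ``bp_prob`` is the symmetric base-pair probability matrix,
    ``positional_entropy`` the per-position pairing entropy (natural log)
    and ``ensemble_diversity`` the expected base-pair distance between two
    independent draws from the Boltzmann ensemble.
    """

    sequence: str
    dot_bracket: str
    pair_table: np.ndarray
    mfe: float
    bp_prob: np.ndarray | None = None
    positional_entropy: np.ndarray | None = None
    ensemble_diversity: float | None = None
    backend_id: str = "toy-stack"

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, int(j)) for i, j in enumerate(self.pair_table) if 0 <= j and i < j]


# ---------------------------------------------------------------------------
# dot-bracket handling
# ---------------------------------------------------------------------------

def parse_dotbracket(db: str) -> np.ndarray:
    """Parse a dot-bracket string into a partner table (-1 = unpaired)."""
    table = np.full(len(db), -1, dtype=np.int64)
    stack: list[int] = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at index {idx}")
            j = stack.pop()
            table[j] = idx
            table[idx] = j
        elif ch != ".":
            raise DotBracketError(f"illegal character {ch!r} at index {idx}")
    if stack:
        raise DotBracketError(f"unmatched '(' at index {stack[-1]}")
    return table


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    table = parse_dotbracket(db)
    return [(i, int(j)) for i, j in enumerate(table) if j >= 0 and i < j]


def to_dotbracket(pair_table: Sequence[int]) -> str:
    chars = []
    for i, j in enumerate(pair_table):
        if j < 0:
            chars.append(".")
        elif j > i:
            chars.append("(")
        else:
            chars.append(")")
    return "".join(chars)


# ---------------------------------------------------------------------------
# shared pre-computation
# ---------------------------------------------------------------------------

def _check_sequence(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return seq


def _pair_matrices(seq: str, params: ModelParams, constraint: FoldConstraint | None):
    """Boolean pair-allowed matrix, per-position must-pair flags and stack energies.

    ``stackE[i, j]`` is the energy of stacking pair (i, j) on inner pair
    (i+1, j-1), defined wherever both are allowed.
    """
    n = len(seq)
    allowed = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            allowed[i, j] = (seq[i], seq[j]) in _PAIRABLE
    must_pair = np.zeros(n, dtype=bool)
    if constraint is not None:
        partner = constraint.partner_of
        for pos in constraint.forbidden_positions:
            if not 0 <= pos < n:
                raise ConstraintError(f"forbidden position {pos} outside sequence")
            allowed[pos, :] = False
            allowed[:, pos] = False
        for i, j in constraint.forced_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ConstraintError(f"forced pair ({i},{j}) outside sequence")
            if not allowed[i, j]:
                raise ConstraintError(
                    f"forced pair ({i},{j}) not pairable ({seq[i]}-{seq[j]})"
                )
        for pos, mate in partner.items():
            keep = allowed[pos, mate] if pos < mate else allowed[mate, pos]
            allowed[pos, :] = False
            allowed[:, pos] = False
            if pos < mate:
                allowed[pos, mate] = keep
            else:
                allowed[mate, pos] = keep
            must_pair[pos] = True
    stackE = np.zeros((n, n))
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            if allowed[i, j] and i + 1 < j - 1 and allowed[i + 1, j - 1]:
                stackE[i, j] = params.stack_energy(
                    (seq[i], seq[j]), (seq[i + 1], seq[j - 1])
                )
    return allowed, must_pair, stackE


# ---------------------------------------------------------------------------
# MFE dynamic programme
# ---------------------------------------------------------------------------

def _mfe_tables(seq, params, allowed, must_pair, stackE):
    """Fill the minimum-energy tables.

    ``EW[i, j+1]`` is the minimum energy of the open region i..j (top-level
    pairs must be extensible helices when no_lonely_pairs); ``Eany[i, j]``
    is the minimum with (i, j) paired and supported by an enclosing stack;
    ``Ens[i, j]`` additionally requires (i, j) to stack inward (the
    unsupported case).  Without the lonely-pair ban Ens == Eany.
    """
    n = len(seq)
    ml = params.min_loop
    EW = np.zeros((n + 1, n + 1))
    Eany = np.full((n, n), INF)
    Ens = np.full((n, n), INF)

    # single pass by increasing span: pair states need EW of the interior
    # (span - 2), the open region needs Ens of pairs up to the same span
    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            if span >= ml + 1 and allowed[i, j]:
                best = EW[i + 1, j]  # interior i+1..j-1 left open
                if i + 1 < j - 1 and Eany[i + 1, j - 1] < INF:
                    best = min(best, stackE[i, j] + Eany[i + 1, j - 1])
                Eany[i, j] = best
                if params.no_lonely_pairs:
                    if i + 1 < j - 1 and Eany[i + 1, j - 1] < INF:
                        Ens[i, j] = stackE[i, j] + Eany[i + 1, j - 1]
                else:
                    Ens[i, j] = best
            if span < ml + 1:
                # too short for any pair; feasible only if no must-pair inside
                EW[i, j + 1] = INF if must_pair[i : j + 1].any() else 0.0
                continue
            best = INF if must_pair[j] else EW[i, j]
            ks = np.arange(i, j - ml)
            if len(ks):
                cand = EW[i, ks] + Ens[ks, j]
                m = cand.min()
                if m < best:
                    best = m
            EW[i, j + 1] = best
    return EW, Eany, Ens


def _traceback(seq, params, allowed, must_pair, stackE, EW, Eany, Ens):
    n = len(seq)
    ml = params.min_loop
    table = np.full(n, -1, dtype=np.int64)
    eps = 1e-9

    def trace_W(i, j):
        if j < i:
            return
        if j - i < ml + 1:
            return
        target = EW[i, j + 1]
        ks = range(i, j - ml)
        for k in ks:
            if EW[i, k] + Ens[k, j] <= target + eps:
                trace_pair(k, j, supported=False)
                trace_W(i, k - 1)
                return
        # j unpaired
        trace_W(i, j - 1)

    def trace_pair(i, j, supported):
        table[i] = j
        table[j] = i
        target = Ens[i, j] if not supported and params.no_lonely_pairs else Eany[i, j]
        if (
            i + 1 < j - 1
            and Eany[i + 1, j - 1] < INF
            and stackE[i, j] + Eany[i + 1, j - 1] <= target + eps
        ):
            trace_pair(i + 1, j - 1, supported=True)
        else:
            trace_W(i + 1, j - 1)

    trace_W(0, n - 1)
    return table


def fold_mfe(
    seq: str,
    constraint: FoldConstraint | None = None,
    params: ModelParams | None = None,
) -> SecondaryStructure:
    """Minimum free energy structure under the built-in stacking model.

    Ties between co-optimal structures are broken deterministically by the
    traceback branch order (outermost pair first, stacking preferred).
    """
    params = params or DEFAULT_PARAMS
    seq = _check_sequence(seq)
    allowed, must_pair, stackE = _pair_matrices(seq, params, constraint)
    EW, Eany, Ens = _mfe_tables(seq, params, allowed, must_pair, stackE)
    n = len(seq)
    mfe = EW[0, n]
    if not np.isfinite(mfe):
        raise ConstraintError("constraints admit no valid structure")
    table = _traceback(seq, params, allowed, must_pair, stackE, EW, Eany, Ens)
    return SecondaryStructure(
        sequence=seq,
        dot_bracket=to_dotbracket(table),
        pair_table=table,
        mfe=float(mfe),
    )


# ---------------------------------------------------------------------------
# partition function (inside-outside)
# ---------------------------------------------------------------------------

def ensemble_statistics(
    seq: str,
    constraint: FoldConstraint | None = None,
    params: ModelParams | None = None,
) -> SecondaryStructure:
    """Boltzmann-ensemble base-pair probabilities, entropy and diversity.

    Uses an unambiguous decomposition of the structure space so that every
    structure contributes its weight exactly once:

    * ``Q[i, j]``: all structures of the open region i..j; a pair closing
      the region top level is "unsupported" and must stack inward when
      lonely pairs are banned.
    * ``Zns[i, j]`` / ``Zany[i, j]``: (i, j) paired, unsupported /
      supported by an enclosing stack.

    Pair probabilities come from the matching outside pass.  Positional
    entropy is ``H_i = -sum_j p_ij ln p_ij - q_i ln q_i`` with
    ``q_i = 1 - sum_j p_ij``; ensemble diversity is
    ``sum_{i<j} 2 p_ij (1 - p_ij)``.
    """
    params = params or DEFAULT_PARAMS
    seq = _check_sequence(seq)
    allowed, must_pair, stackE = _pair_matrices(seq, params, constraint)
    n = len(seq)
    ml = params.min_loop
    kT = params.temperature_scale
    wstack = np.exp(-stackE / kT)

    Zany = np.zeros((n, n))
    Zns = np.zeros((n, n))
    # Q[i, j+1] = partition function of open region i..j; Q[i, i] = 1 (empty)
    Q = np.zeros((n + 1, n + 1))

    # inside pass, by increasing span
    for i in range(n + 1):
        Q[i, i] = 1.0
    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            # pair states first (they only need shorter spans)
            if span >= ml + 1 and allowed[i, j]:
                inner_open = Q[i + 1, j] if j - 1 >= i + 1 else 1.0
                inner_ns = Zns[i + 1, j - 1] if i + 1 < j - 1 else 0.0
                stacked = (
                    wstack[i, j] * Zany[i + 1, j - 1] if i + 1 < j - 1 else 0.0
                )
                Zany[i, j] = stacked + (inner_open - inner_ns)
                Zns[i, j] = stacked if params.no_lonely_pairs else Zany[i, j]
            # open region
            if span < ml + 1:
                Q[i, j + 1] = 0.0 if must_pair[i : j + 1].any() else 1.0
                continue
            total = 0.0 if must_pair[j] else Q[i, j]
            ks = np.arange(i, j - ml)
            if len(ks):
                total += float(Q[i, ks] @ Zns[ks, j])
            Q[i, j + 1] = total

    Z = Q[0, n]
    if Z <= 0.0:
        raise ConstraintError("constraints admit no valid structure")

    # outside pass
    OQ = np.zeros((n + 1, n + 1))  # OQ[i, j+1] multiplies Q[i, j+1]
    Oany = np.zeros((n, n))
    Ons = np.zeros((n, n))
    OQ[0, n] = 1.0
    for span in range(n - 1, -1, -1):
        for i in range(0, n - span):
            j = i + span
            # contributions from Q(i, j) as parent
            oq = OQ[i, j + 1]
            if oq != 0.0 and span >= ml + 1:
                if not must_pair[j]:
                    OQ[i, j] += oq
                ks = np.arange(i, j - ml)
                if len(ks):
                    OQ[i, ks] += oq * Zns[ks, j]
                    Ons[ks, j] += oq * Q[i, ks]
            # contributions from pair states as parents
            if span >= ml + 1 and allowed[i, j]:
                oany, ons = Oany[i, j], Ons[i, j]
                if oany != 0.0 or ons != 0.0:
                    if i + 1 < j - 1:
                        Oany[i + 1, j - 1] += (oany + ons) * wstack[i, j]
                    # the (Q - Zns) open-interior branch belongs to Zany
                    # only when lonely pairs are banned; otherwise Zns
                    # expands identically and shares it
                    o_open = oany if params.no_lonely_pairs else oany + ons
                    if o_open != 0.0:
                        OQ[i + 1, j] += o_open
                        if i + 1 < j - 1:
                            Ons[i + 1, j - 1] -= o_open

    with np.errstate(invalid="ignore"):
        P = (Oany * Zany + Ons * Zns) / Z
    P = np.clip(np.nan_to_num(P), 0.0, 1.0)
    P = P + P.T

    q_unpaired = np.clip(1.0 - P.sum(axis=1), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_pairs = np.where(P > 0.0, -P * np.log(P), 0.0).sum(axis=1)
        h_un = np.where(q_unpaired > 0.0, -q_unpaired * np.log(q_unpaired), 0.0)
    entropy = h_pairs + h_un
    upper = np.triu(P, k=1)
    diversity = float((2.0 * upper * (1.0 - upper)).sum())

    mfe_struct = fold_mfe(seq, constraint=constraint, params=params)
    return SecondaryStructure(
        sequence=seq,
        dot_bracket=mfe_struct.dot_bracket,
        pair_table=mfe_struct.pair_table,
        mfe=mfe_struct.mfe,
        bp_prob=P,
        positional_entropy=entropy,
        ensemble_diversity=diversity,
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration (test oracle)
# ---------------------------------------------------------------------------

def structure_energy(seq: str, db: str, params: ModelParams | None = None) -> float:
    """Energy of a given structure: sum over adjacent stacked pairs."""
    params = params or DEFAULT_PARAMS
    seq = _check_sequence(seq)
    table = parse_dotbracket(db)
    energy = 0.0
    for i, j in ((i, int(j)) for i, j in enumerate(table) if j > i):
        if i + 1 < j - 1 and table[i + 1] == j - 1:
            energy += params.stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
    return energy


def enumerate_structures(
    seq: str,
    params: ModelParams | None = None,
    constraint: FoldConstraint | None = None,
    max_len: int = 20,
) -> list[tuple[str, float]]:
    """All nested structures with their exact energies (independent oracle).

    Generates every nested matching respecting ``min_loop``, then filters
    for the lonely-pair ban and constraints on the complete pair set; the
    logic is intentionally independent of the dynamic programmes above.
    """
    params = params or DEFAULT_PARAMS
    seq = _check_sequence(seq)
    n = len(seq)
    if n > max_len:
        raise ValueError(f"enumeration limited to length {max_len}, got {n}")
    ml = params.min_loop

    def gen(i: int, j: int) -> list[frozenset]:
        # all pair sets over region i..j
        if j - i < ml + 1:
            return [frozenset()]
        out = []
        for rest in gen(i + 1, j):  # i unpaired
            out.append(rest)
        for k in range(i + ml + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRABLE:
                for inner in gen(i + 1, k - 1):
                    for right in gen(k + 1, j):
                        out.append(inner | right | {(i, k)})
        return out

    results = []
    forced = set(constraint.forced_pairs) if constraint else set()
    forbidden = set(constraint.forbidden_positions) if constraint else set()
    for pairset in gen(0, n - 1):
        if params.no_lonely_pairs and any(
            (i + 1, j - 1) not in pairset and (i - 1, j + 1) not in pairset
            for i, j in pairset
        ):
            continue
        if forced and not forced <= pairset:
            continue
        if forbidden and any(i in forbidden or j in forbidden for i, j in pairset):
            continue
        table = np.full(n, -1, dtype=np.int64)
        for i, j in pairset:
            table[i] = j
            table[j] = i
        db = to_dotbracket(table)
        results.append((db, structure_energy(seq, db, params)))
    results.sort(key=lambda t: (t[1], t[0]))
    return results


def ensemble_statistics_by_enumeration(
    seq: str,
    params: ModelParams | None = None,
    constraint: FoldConstraint | None = None,
):
    """Oracle counterpart of :func:`ensemble_statistics` via enumeration."""
    params = params or DEFAULT_PARAMS
    seq = _check_sequence(seq)
    n = len(seq)
    structures = enumerate_structures(seq, params, constraint)
    weights = np.array([np.exp(-e / params.temperature_scale) for _, e in structures])
    Z = weights.sum()
    P = np.zeros((n, n))
    for (db, _), w in zip(structures, weights):
        for i, j in pairs_from_dotbracket(db):
            P[i, j] += w
            P[j, i] += w
    P /= Z
    q = 1.0 - P.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(P > 0, -P * np.log(P), 0.0).sum(axis=1)
        h += np.where(q > 1e-15, -q * np.log(q), 0.0)
    upper = np.triu(P, k=1)
    diversity = float((2 * upper * (1 - upper)).sum())
    mfe = min(e for _, e in structures)
    return {
        "Z": float(Z),
        "bp_prob": P,
        "positional_entropy": h,
        "ensemble_diversity": diversity,
        "mfe": float(mfe),
        "n_structures": len(structures),
    }
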