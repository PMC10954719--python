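"""Optional production folding backend (ViennaRNA).

The built-in stacking model in :mod:`droshascan.folding` is the default
because every statistic it produces is verifiable by enumeration.  For
realistic thermodynamics this adapter folds with the ViennaRNA programs
(``-p -d2 --noLP`` semantics: partition function, dangles model 2, no
lonely pairs) and returns the same :class:`SecondaryStructure` container,
so all downstream geometry and feature code is backend-agnostic.

Requires the ``RNA`` python bindings; import errors surface only when the
backend is actually selected.
"""

from __future__ import annotations

import numpy as np

from .folding import FoldConstraint, SecondaryStructure, parse_dotbracket

__all__ = ["fold_mfe_vienna", "ensemble_statistics_vienna"]


def _fold_compound(seq: str, constraint: FoldConstraint | None):
    import RNA

    md = RNA.md()
    md.noLP = 1
    md.dangles = 2
    fc = RNA.fold_compound(seq, md)
    if constraint is not None:
        for i, j in constraint.forced_pairs:
            fc.hc_add_bp(i + 1, j + 1, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS
                         | RNA.CONSTRAINT_CONTEXT_ENFORCE)
        for i in constraint.forbidden_positions:
            fc.hc_add_up(i + 1)
    return fc


def fold_mfe_vienna(
    seq: str, constraint: FoldConstraint | None = None
) -> SecondaryStructure:
    """Minimum free energy structure from RNAfold (kcal/mol)."""
    seq = seq.upper().replace("T", "U")
    fc = _fold_compound(seq, constraint)
    db, mfe = fc.mfe()
    return SecondaryStructure(
        sequence=seq,
        dot_bracket=db,
        pair_table=parse_dotbracket(db),
        mfe=float(mfe),
        backend_id="viennarna",
    )


def ensemble_statistics_vienna(
    seq: str, constraint: FoldConstraint | None = None
) -> SecondaryStructure:
    """Base-pair probabilities, positional entropy and ensemble diversity
    from the ViennaRNA partition function (same definitions as the
    built-in model: natural-log entropy, expected base-pair distance)."""
    seq = seq.upper().replace("T", "U")
    struct = fold_mfe_vienna(seq, constraint)
    fc = _fold_compound(seq, constraint)
    fc.pf()
    n = len(seq)
    P = np.zeros((n, n))
    bpp = fc.bpp()  # 1-based upper-triangular
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            P[i - 1, j - 1] = bpp[i][j]
    P = P + P.T
    q = np.clip(1.0 - P.sum(axis=1), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(P > 0, -P * np.log(P), 0.0).sum(axis=1)
        h += np.where(q > 0, -q * np.log(q), 0.0)
    upper = np.triu(P, k=1)
    diversity = float((2.0 * upper * (1.0 - upper)).sum())
    struct.bp_prob = P
    struct.positional_entropy = h
    struct.ensemble_diversity = diversity
    return struct
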