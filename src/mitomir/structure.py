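"""RNA secondary-structure thermodynamics: MFE, AMFE, MFEI, GC content.

The minimum free energy (MFE, kcal/mol) of an RNA's optimal nested secondary
structure measures its thermodynamic stability: the lower the MFE, the more
stable the fold.  Because MFE scales with sequence length, two normalized
quantities are used to compare miRNAs as a group:

* AMFE  = (-MFE / length) x 100      (per-100-nt adjusted MFE)
* MFEI  = AMFE / (G+C)%              (MFE index)

Energy model
------------
The built-in engine is a reduced nearest-neighbor model chosen for
self-containedness rather than full Turner parity: Watson-Crick and G·U
wobble pairs; no pseudoknots; hairpin loops of at least 3 nt.  A structure's
energy is the sum of

* a stacking term for every pair lying directly inside another
  (constant per combination of the two pair classes GC/AU/GU), and
* a linear hairpin-loop penalty ``3.0 + 0.3 (L - 3)`` kcal/mol for every
  pair whose interior is completely unpaired (loop length L >= 3).

Bulge, internal and multibranch loops carry no penalty.  The open chain has
energy 0, so MFE <= 0 always.  Energies computed externally with a full
Turner-model folder (e.g. RNAfold) can be supplied per miRNA to
:func:`feature_table` and override the built-in engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldResult",
    "fold_mfe",
    "structure_energy",
    "amfe",
    "mfei",
    "gc_content",
    "feature_table",
    "STACK_ENERGY",
    "hairpin_penalty",
]

_PAIRABLE = {"AU", "UA", "GC", "CG", "GU", "UG"}
_PAIR_CLASS = {"AU": "AU", "UA": "AU", "GC": "GC", "CG": "GC", "GU": "GU", "UG": "GU"}

#: stacking free energies (kcal/mol) by unordered pair of pair classes
STACK_ENERGY = {
    frozenset(["GC"]): -3.3,
    frozenset(["GC", "AU"]): -2.4,
    frozenset(["GC", "GU"]): -1.5,
    frozenset(["AU"]): -1.1,
    frozenset(["AU", "GU"]): -1.0,
    frozenset(["GU"]): -0.5,
}

MIN_HAIRPIN_LOOP = 3
_INF = float("inf")


def hairpin_penalty(loop_len: int) -> float:
    """Linear hairpin-loop penalty (kcal/mol), defined for loop_len >= 3."""
    if loop_len < MIN_HAIRPIN_LOOP:
        raise ValueError(f"hairpin loop must be >= {MIN_HAIRPIN_LOOP}")
    return 3.0 + 0.3 * (loop_len - MIN_HAIRPIN_LOOP)


def _normalize_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in "ACGU":
            raise ValueError(f"invalid RNA character {ch!r} at position {pos}")
    return seq


def _pairable(a: str, b: str) -> bool:
    return a + b in _PAIRABLE


def _stack(seq: str, i: int, j: int, k: int, l: int) -> float:
    outer = _PAIR_CLASS[seq[i] + seq[j]]
    inner = _PAIR_CLASS[seq[k] + seq[l]]
    return STACK_ENERGY[frozenset([outer, inner])]


def structure_energy(sequence: str, pairs: set[tuple[int, int]]) -> float:
    """Model energy of an explicit (nested, valid) set of 0-based pairs.

    This is the definition the dynamic program optimizes; it is also usable
    to score structures produced elsewhere.  Raises on invalid structures
    (crossing, unpairable bases, hairpin loop < 3).
    """
    seq = _normalize_rna(sequence)
    pairs = {(min(i, j), max(i, j)) for i, j in pairs}
    partner: dict[int, int] = {}
    for i, j in pairs:
        if i == j or not (0 <= i < j < len(seq)):
            raise ValueError(f"bad pair ({i}, {j})")
        if i in partner or j in partner:
            raise ValueError("base paired twice")
        if not _pairable(seq[i], seq[j]):
            raise ValueError(f"unpairable bases {seq[i]}{seq[j]} at ({i}, {j})")
        partner[i] = j
        partner[j] = i
    for i, j in pairs:  # nestedness
        for k, l in pairs:
            if i < k < j < l:
                raise ValueError("crossing pairs (pseudoknot)")
    energy = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pairs:
            energy += _stack(seq, i, j, i + 1, j - 1)
        if not any(i < k < j for k in partner):  # hairpin-closing pair
            loop = j - i - 1
            if loop < MIN_HAIRPIN_LOOP:
                raise ValueError(f"hairpin loop of {loop} < {MIN_HAIRPIN_LOOP}")
            energy += hairpin_penalty(loop)
    return energy


@dataclass(frozen=True)
class FoldResult:
    """Optimal nested structure in dot-bracket notation with its energy."""

    sequence: str
    structure: str
    mfe: float
    model: str = "reduced-stacking-v1"

    @property
    def pairs(self) -> set[tuple[int, int]]:
        stack: list[int] = []
        out: set[tuple[int, int]] = set()
        for idx, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                out.add((stack.pop(), idx))
        return out


def fold_mfe(sequence: str) -> FoldResult:
    """Minimum-energy nested secondary structure under the reduced model.

    Dynamic program over intervals: ``V[i][j]`` is the optimum with (i, j)
    paired (hairpin closing / stacking on (i+1, j-1) / closing an interior
    containing pairs); ``W1[i][j]`` the optimum containing at least one pair;
    the MFE is ``min(0, W1[0][n-1])``.  Ties break by a fixed branch
    preference (pair the leftmost base, smallest partner, stacking first),
    which favors '(' early in the dot-bracket and is deterministic.
    """
    seq = _normalize_rna(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if n < MIN_HAIRPIN_LOOP + 2:
        return FoldResult(seq, "." * n, 0.0)

    V = [[_INF] * n for _ in range(n)]
    W1 = [[_INF] * n for _ in range(n)]

    def w(i: int, j: int) -> float:  # min(0, W1)
        if i > j:
            return 0.0
        return min(0.0, W1[i][j])

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _pairable(seq[i], seq[j]):
                best = hairpin_penalty(span - 1) if span - 1 >= MIN_HAIRPIN_LOOP else _INF
                if (
                    span >= MIN_HAIRPIN_LOOP + 3
                    and _pairable(seq[i + 1], seq[j - 1])
                    and V[i + 1][j - 1] < _INF
                ):
                    best = min(best, V[i + 1][j - 1] + _stack(seq, i, j, i + 1, j - 1))
                if j - 1 >= i + 1 and W1[i + 1][j - 1] < _INF:
                    best = min(best, W1[i + 1][j - 1])
                V[i][j] = best
            best1 = W1[i + 1][j] if i + 1 <= j else _INF
            for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if V[i][l] < _INF:
                    best1 = min(best1, V[i][l] + w(l + 1, j))
            W1[i][j] = best1

    mfe = min(0.0, W1[0][n - 1])
    structure = ["."] * n
    _EPS = 1e-9

    def trace_w1(i: int, j: int) -> None:
        target = W1[i][j]
        for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if V[i][l] < _INF and abs(V[i][l] + w(l + 1, j) - target) <= _EPS:
                trace_v(i, l)
                if l + 1 <= j and W1[l + 1][j] <= _EPS:
                    trace_w1(l + 1, j)
                return
        trace_w1(i + 1, j)

    def trace_v(i: int, j: int) -> None:
        structure[i], structure[j] = "(", ")"
        target = V[i][j]
        span = j - i
        if (
            span >= MIN_HAIRPIN_LOOP + 3
            and _pairable(seq[i + 1], seq[j - 1])
            and V[i + 1][j - 1] < _INF
            and abs(V[i + 1][j - 1] + _stack(seq, i, j, i + 1, j - 1) - target) <= _EPS
        ):
            trace_v(i + 1, j - 1)
            return
        if j - 1 >= i + 1 and W1[i + 1][j - 1] < _INF and abs(W1[i + 1][j - 1] - target) <= _EPS:
            trace_w1(i + 1, j - 1)
            return
        # hairpin: interior stays unpaired

    # take the paired structure whenever it is at least as good as the open
    # chain (ties included: '(' sorts before '.' in dot-bracket)
    if W1[0][n - 1] <= _EPS:
        trace_w1(0, n - 1)
    return FoldResult(seq, "".join(structure), float(mfe))


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: (-MFE / length) x 100 (per 100 nt)."""
    if length <= 0:
        raise ValueError("length must be > 0")
    return (-mfe / length) * 100.0


def mfei(amfe_value: float, gc_pct: float) -> float:
    """MFE index: AMFE / (G+C)% — undefined for gc_pct = 0."""
    if gc_pct <= 0:
        raise ValueError("MFEI undefined for (G+C)% <= 0")
    return amfe_value / gc_pct


def gc_content(sequence: str) -> float:
    """(G+C) percentage of a sequence (T/U agnostic)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def feature_table(
    mature: dict[str, str],
    precursor: dict[str, str],
    external_mfe: dict[str, float] | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-miRNA feature records: lengths, GC%, MFE, AMFE, MFEI.

    ``mature`` and ``precursor`` map miRNA id -> sequence (the precursor is
    the folded unit; GC%, MFE, AMFE, MFEI refer to it).  ``external_mfe``
    values (e.g. from a Turner-model folder) override the built-in engine
    and are flagged in the ``mfe_source`` column; ids in the external file
    that do not appear in ``precursor`` raise.  ``groups`` labels each row
    (e.g. ``mitomiR`` vs ``control``).
    """
    external_mfe = external_mfe or {}
    unknown = sorted(set(external_mfe) - set(precursor))
    if unknown:
        raise KeyError(f"external MFE ids not in precursor set: {unknown}")
    rows = []
    for mid, pre_seq in precursor.items():
        pre = _normalize_rna(pre_seq)
        if mid in external_mfe:
            mfe_val, source = float(external_mfe[mid]), "external"
        else:
            mfe_val, source = fold_mfe(pre).mfe, "internal"
        gc = gc_content(pre)
        a = amfe(mfe_val, len(pre))
        rows.append(
            {
                "mirna_id": mid,
                "mature_length": len(mature[mid]) if mid in mature else np.nan,
                "pre_length": len(pre),
                "gc_pct": gc,
                "mfe": mfe_val,
                "mfe_source": source,
                "amfe": a,
                "mfei": mfei(a, gc) if gc > 0 else np.nan,
                "group": (groups or {}).get(mid, ""),
            }
        )
    return pd.DataFrame(rows)
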