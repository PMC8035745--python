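"""Simplified cofold MFE scoring and the secondary-structure correlation.

Two transcripts are scored by concatenating them (mRNA transcript first)
across a short unpairable linker and running a weighted Nussinov dynamic
program: non-crossing base pairs, pair energies GC = -3, AU = -2,
GU = -1 (model units), a minimum of 3 unpaired positions inside any
loop.  This is a deliberately transparent base-pair-counting stand-in
for a full thermodynamic cofolding engine; the ``mfe_fn`` hook on
:func:`structure_score` accepts any callable with the same signature
(e.g. a true RNAcofold wrapper, in which case energies are kcal/mol).

The per-gene-pair score E(m,l) averages MFE / (len_s + len_t) over all
transcript pairs; E_ML is then min-max normalized to [0, 1] for fusion
with the expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "FoldingModel",
    "cofold_mfe",
    "structure_score",
    "structure_score_matrix",
    "normalize_structure",
]

_VALID = set("ACGUN")


@dataclass(frozen=True)
class FoldingModel:
    """Base-pair energy model for the simplified cofold DP."""

    pair_energies: dict = field(
        default_factory=lambda: {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}
    )
    min_loop: int = 3  # unpaired positions required inside a hairpin loop
    linker: int = 3  # unpairable positions inserted between the two strands

    def energy(self, a: str, b: str) -> float:
        e = self.pair_energies
        return e.get((a, b)) or e.get((b, a)) or 0.0

    def pairable(self, a: str, b: str) -> bool:
        return (a, b) in self.pair_energies or (b, a) in self.pair_energies


DEFAULT_MODEL = FoldingModel()


def _clean(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if not set(s) <= _VALID:
        raise ValueError(f"invalid characters in sequence: {set(s) - _VALID}")
    return s


def cofold_mfe(s: str, t: str, model: FoldingModel = DEFAULT_MODEL) -> float:
    """Minimum total pair energy of cofolding ``s`` (mRNA) with ``t`` (lncRNA).

    Nussinov-style O(n^3) DP on s + linker + t; linker positions cannot
    pair; any pair (i, j) requires j - i > min_loop.  The empty structure
    scores 0, so the result is always <= 0.
    """
    s, t = _clean(s), _clean(t)
    if not s or not t:
        raise ValueError("sequences must be non-empty")
    seq = s + "N" * model.linker + t
    n = len(seq)
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int8)
    for idx, b in enumerate("ACGUN"):
        lut[ord(b)] = idx
    c = lut[code]
    etab = np.zeros((5, 5))
    for (a, b), e in model.pair_energies.items():
        ia, ib = "ACGUN".index(a), "ACGUN".index(b)
        etab[ia, ib] = etab[ib, ia] = e
    emat = etab[c[:, None], c[None, :]]  # pair energy, 0 if unpairable

    gap = model.min_loop + 1  # any pair (i, k) needs k - i >= gap + 0? k-i > min_loop
    w = np.zeros((n + 1, n + 1))
    # w[i][j]: MFE of positions i..j-1 (half-open); pair (i,k) needs k-i > min_loop
    for span in range(model.min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # exclusive
            best = w[i + 1, j]  # i left unpaired
            k0 = i + gap
            if k0 < j:
                erow = emat[i, k0:j]
                pairable = erow < 0
                if pairable.any():
                    cand = erow + w[i + 1, k0:j] + w[k0 + 1 : j + 1, j]
                    m = cand[pairable].min()
                    if m < best:
                        best = m
            w[i, j] = best
    return float(w[0, n])


def _windows(seq: str, window: int, step: int):
    if len(seq) <= window:
        return [seq]
    return [seq[i : i + window] for i in range(0, len(seq) - window + 1, step)] or [seq]


def cofold_mfe_windowed(
    s: str,
    t: str,
    model: FoldingModel = DEFAULT_MODEL,
    window: int = 300,
    step: int | None = None,
) -> float:
    """Windowed cofold for long transcripts: minimum over window pairs.

    Bounds the cubic DP cost; exact (single window) whenever both
    sequences fit inside ``window``.
    """
    step = step or window
    best = 0.0
    for ws, wt in product(_windows(s, window, step), _windows(t, window, step)):
        best = min(best, cofold_mfe(ws, wt, model))
    return best


def structure_score(
    m_transcripts: dict,
    l_transcripts: dict,
    model: FoldingModel = DEFAULT_MODEL,
    mfe_fn=None,
) -> float:
    """Length-normalized mean cofold energy E(m,l) over all transcript pairs.

    E = mean over the u(m)*v(l) pairs of MFE_st / (LEN_M_s + LEN_L_t).
    """
    if not m_transcripts or not l_transcripts:
        raise ValueError("empty transcript set")
    fn = mfe_fn or (lambda a, b: cofold_mfe_windowed(a, b, model))
    total = 0.0
    for s_seq in m_transcripts.values():
        for t_seq in l_transcripts.values():
            total += fn(s_seq, t_seq) / (len(s_seq) + len(t_seq))
    return total / (len(m_transcripts) * len(l_transcripts))


def structure_score_matrix(
    transcripts: dict,
    row_ids,
    col_ids,
    model: FoldingModel = DEFAULT_MODEL,
    mfe_fn=None,
) -> pd.DataFrame:
    """E_ML matrix for all (mRNA, lncRNA) id pairs.

    ``transcripts`` maps feature id -> {transcript id -> sequence}.
    """
    rows = pd.Index(row_ids)
    cols = pd.Index(col_ids)
    e = np.zeros((len(rows), len(cols)))
    for a, m in enumerate(rows):
        for b, l in enumerate(cols):
            e[a, b] = structure_score(transcripts[m], transcripts[l], model, mfe_fn)
    return pd.DataFrame(e, index=rows, columns=cols)


def normalize_structure(e: pd.DataFrame, invert: bool = False) -> pd.DataFrame:
    """Min-max normalize E_ML to [0, 1].

    The literal normalization maps the least negative (least stable) score
    to 1; ``invert=True`` flips the scale so the most stable duplex maps
    to 1 instead.  A constant matrix maps to all zeros, degenerating the
    downstream fusion to |C|.
    """
    x = e.to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    lo, hi = x.min(), x.max()
    if hi == lo:
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
        if invert:
            out = 1.0 - out
    return pd.DataFrame(out, index=e.index, columns=e.columns)
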