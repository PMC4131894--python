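"""Secondary-structure and duplex-energy engine.

A self-contained minimum-free-energy folder: a Zuker-style dynamic program
scored with a nearest-neighbor stacking table (Turner-like values shipped as
package data, kcal/mol) plus simple hairpin / bulge / internal-loop /
multiloop penalties.  It is deliberately simpler than a full thermodynamic
folder (no dangles, no terminal-AU penalty, no tetraloop bonuses, 37 °C
only) but is deterministic, dependency-free and fast enough to fold
thousands of precursor windows.  An external folding engine can be plugged
in through the ``engine`` argument of :func:`fold`; every built-in analysis
and test runs on this engine.

An oracle mode (``mode="maxpair"``) scores −1 per pair with all penalties
zero and unrestricted loop sizes; in that mode the DP reduces exactly to
Nussinov maximum pairing, which the test-suite checks against brute-force
enumeration on short sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from numba import njit

from .seqio import to_rna, revcomp

INF = 1e9
MIN_HAIRPIN = 3  # minimum unpaired nucleotides closed by a pair

# pair-type encoding: index into the 6x6 stack table
PAIR_TYPES = ["AU", "UA", "CG", "GC", "GU", "UG"]
_PT = {("A", "U"): 0, ("U", "A"): 1, ("C", "G"): 2,
       ("G", "C"): 3, ("G", "U"): 4, ("U", "G"): 5}


def _load_stack_table() -> np.ndarray:
    table = np.full((6, 6), INF)
    data = resources.files("mulmir.data").joinpath("stack_energies.tsv").read_text()
    for line in data.strip().splitlines()[1:]:
        p5, p3, dg = line.split("\t")
        table[PAIR_TYPES.index(p5), PAIR_TYPES.index(p3)] = float(dg)
    # a stack viewed from the opposite strand must have the same energy
    rot = [1, 0, 3, 2, 5, 4]  # AU<->UA, CG<->GC, GU<->UG
    for i in range(6):
        for j in range(6):
            if not math.isclose(table[i, j], table[rot[j], rot[i]]):
                raise AssertionError("stack table breaks strand symmetry")
    return table


STACK = _load_stack_table()

# loop penalties, kcal/mol (simplified Jacobson-Stockmayer-style)
_HAIRPIN_BASE, _HAIRPIN_SLOPE = 4.5, 1.8
_BULGE_BASE, _BULGE_SLOPE = 3.3, 1.3
_IL_BASE, _IL_NT, _IL_ASYM = 1.6, 0.35, 0.45
_MULTI_A, _MULTI_B, _MULTI_C = 3.4, 0.4, 0.0
MAXLOOP = 30


def _loop_vectors(n: int, oracle: bool) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.arange(n + 2, dtype=np.float64)
    if oracle:
        return np.zeros(n + 2), np.zeros(n + 2)
    with np.errstate(divide="ignore"):
        hairpin = _HAIRPIN_BASE + _HAIRPIN_SLOPE * np.log(
            np.maximum(sizes, MIN_HAIRPIN) / MIN_HAIRPIN
        )
        bulge = _BULGE_BASE + _BULGE_SLOPE * np.log(np.maximum(sizes, 1.0))
    return hairpin, bulge


@njit(cache=True)
def _fill(ptype, stack, hairpin, bulge, il_base, il_nt, il_asym,
          multi_a, multi_b, multi_c, pair_bonus, maxloop):  # pragma: no cover
    n = ptype.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if ptype[i, j] >= 0:
                best = hairpin[j - i - 1]
                # interior pair (stack / bulge / internal loop)
                kmax = min(i + 1 + maxloop, j - 1)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (maxloop - n1))
                    for l in range(lmin, j):
                        if ptype[k, l] < 0 or V[k, l] >= INF:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            cost = stack[ptype[i, j], ptype[k, l]]
                        elif n1 == 0 or n2 == 0:
                            cost = bulge[n1 + n2]
                        else:
                            cost = (il_base + il_nt * (n1 + n2)
                                    + il_asym * abs(n1 - n2))
                        if cost + V[k, l] < best:
                            best = cost + V[k, l]
                # multiloop: >= 2 branches inside
                for m in range(i + 2, j - 2):
                    if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                        cand = multi_a + WM[i + 1, m] + WM[m + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best + pair_bonus
            # WM
            best = INF
            if V[i, j] < INF:
                best = V[i, j] + multi_b
            if WM[i + 1, j] + multi_c < best:
                best = WM[i + 1, j] + multi_c
            if WM[i, j - 1] + multi_c < best:
                best = WM[i, j - 1] + multi_c
            for m in range(i + 1, j):
                if WM[i, m] < INF and WM[m + 1, j] < INF:
                    if WM[i, m] + WM[m + 1, j] < best:
                        best = WM[i, m] + WM[m + 1, j]
            WM[i, j] = best
    # exterior loop
    W = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j):
            if V[i, j - 1] < INF and W[i] + V[i, j - 1] < best:
                best = W[i] + V[i, j - 1]
        W[j] = best
    return V, WM, W


@dataclass
class FoldResult:
    """A minimum-free-energy structure.

    ``structure`` is dot-bracket over the input length; ``mfe`` in kcal/mol
    (0.0 for a structure with no pairs); ``pairs[i]`` is the partner index
    of position i or -1.
    """

    structure: str
    mfe: float
    pairs: list


def _ptype_matrix(seq_rna: str) -> np.ndarray:
    n = len(seq_rna)
    pt = np.full((n, n), -1, dtype=np.int8)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            pt[i, j] = _PT.get((seq_rna[i], seq_rna[j]), -1)
    return pt


def fold(seq: str, mode: str = "turner", engine=None) -> FoldResult:
    """Fold a single sequence to its minimum-free-energy structure.

    Parameters
    ----------
    seq : str
        20-1000 nt, A/C/G/T/U only (T is treated as U).
    mode : str
        "turner" (default nearest-neighbor scoring) or "maxpair"
        (-1 per pair, no penalties: Nussinov oracle mode).
    engine : callable, optional
        Drop-in replacement ``engine(rna_seq) -> (structure, mfe)``; used
        verbatim when given.
    """
    seq_rna = to_rna(seq)
    if not (4 <= len(seq_rna) <= 1000):
        raise ValueError(f"sequence length {len(seq_rna)} outside foldable range")
    if engine is not None:
        structure, mfe = engine(seq_rna)
        return FoldResult(structure=structure, mfe=float(mfe),
                          pairs=pairs_from_structure(structure))
    oracle = mode == "maxpair"
    if not oracle and mode != "turner":
        raise ValueError(f"unknown fold mode {mode!r}")
    bad = set(seq_rna) - set("ACGU")
    if bad:
        raise ValueError(f"cannot fold sequence with characters {sorted(bad)}")
    n = len(seq_rna)
    ptype = _ptype_matrix(seq_rna)
    hairpin, bulge = _loop_vectors(n, oracle)
    if oracle:
        stack = np.zeros((6, 6))
        params = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -1.0, n)
    else:
        stack = STACK
        params = (_IL_BASE, _IL_NT, _IL_ASYM, _MULTI_A, _MULTI_B, _MULTI_C,
                  0.0, MAXLOOP)
    V, WM, W = _fill(ptype, stack, hairpin, bulge, *params)
    mfe = min(0.0, W[n])
    pairs = [-1] * n
    if mfe < 0.0:
        _traceback_exterior(0, n, seq_rna, ptype, V, WM, W, hairpin, bulge,
                            params, pairs)
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(pairs)
    )
    return FoldResult(structure=structure, mfe=round(float(mfe), 2), pairs=pairs)


def _close(a: float, b: float) -> bool:
    return abs(a - b) < 1e-6


def _traceback_exterior(lo, hi, seq, ptype, V, WM, W, hairpin, bulge, params,
                        pairs) -> None:
    j = hi
    while j > lo:
        if _close(W[j], W[j - 1]):
            j -= 1
            continue
        for i in range(lo, j):
            if V[i, j - 1] < INF and _close(W[j], W[i] + V[i, j - 1]):
                _traceback_v(i, j - 1, seq, ptype, V, WM, hairpin, bulge,
                             params, pairs)
                j = i
                break
        else:  # numerical safety: treat as unpaired
            j -= 1


def _traceback_v(i, j, seq, ptype, V, WM, hairpin, bulge, params, pairs) -> None:
    il_base, il_nt, il_asym, multi_a, _b, _c, pair_bonus, maxloop = params
    stack_tab = STACK if pair_bonus == 0.0 else np.zeros((6, 6))
    pairs[i], pairs[j] = j, i
    target = V[i, j] - pair_bonus
    if _close(target, hairpin[j - i - 1]):
        return
    kmax = min(i + 1 + maxloop, j - 1)
    for k in range(i + 1, kmax + 1):
        n1 = k - i - 1
        lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (maxloop - n1))
        for l in range(lmin, j):
            if ptype[k, l] < 0 or V[k, l] >= INF:
                continue
            n2 = j - l - 1
            if n1 == 0 and n2 == 0:
                cost = stack_tab[ptype[i, j], ptype[k, l]]
            elif n1 == 0 or n2 == 0:
                cost = bulge[n1 + n2]
            else:
                cost = il_base + il_nt * (n1 + n2) + il_asym * abs(n1 - n2)
            if _close(target, cost + V[k, l]):
                _traceback_v(k, l, seq, ptype, V, WM, hairpin, bulge, params,
                             pairs)
                return
    for m in range(i + 2, j - 2):
        if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF and _close(
            target, multi_a + WM[i + 1, m] + WM[m + 1, j - 1]
        ):
            _traceback_wm(i + 1, m, seq, ptype, V, WM, hairpin, bulge, params,
                          pairs)
            _traceback_wm(m + 1, j - 1, seq, ptype, V, WM, hairpin, bulge,
                          params, pairs)
            return
    raise AssertionError("fold traceback failed")  # pragma: no cover


def _traceback_wm(i, j, seq, ptype, V, WM, hairpin, bulge, params, pairs) -> None:
    _ib, _in, _ia, _a, multi_b, multi_c, _pb, _ml = params
    if V[i, j] < INF and _close(WM[i, j], V[i, j] + multi_b):
        _traceback_v(i, j, seq, ptype, V, WM, hairpin, bulge, params, pairs)
        return
    if _close(WM[i, j], WM[i + 1, j] + multi_c):
        _traceback_wm(i + 1, j, seq, ptype, V, WM, hairpin, bulge, params, pairs)
        return
    if _close(WM[i, j], WM[i, j - 1] + multi_c):
        _traceback_wm(i, j - 1, seq, ptype, V, WM, hairpin, bulge, params, pairs)
        return
    for m in range(i + 1, j):
        if WM[i, m] < INF and WM[m + 1, j] < INF and _close(
            WM[i, j], WM[i, m] + WM[m + 1, j]
        ):
            _traceback_wm(i, m, seq, ptype, V, WM, hairpin, bulge, params, pairs)
            _traceback_wm(m + 1, j, seq, ptype, V, WM, hairpin, bulge, params,
                          pairs)
            return
    raise AssertionError("WM traceback failed")  # pragma: no cover


def pairs_from_structure(structure: str) -> list:
    pairs = [-1] * len(structure)
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def amfe(seq: str, mfe: float) -> float:
    """Adjusted MFE: |MFE| per 100 nt."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return abs(mfe) / len(seq) * 100.0


def gc_percent(seq: str) -> float:
    s = to_rna(seq)
    return 100.0 * sum(c in "GC" for c in s) / len(s)


def mfei(seq: str, mfe: float) -> float:
    """Minimal folding free energy index: AMFE / GC-percentage.

    High MFEI separates miRNA precursors from other structured RNAs; the
    discovery filter requires MFEI >= 0.85.
    """
    gc = gc_percent(seq)
    if gc == 0:
        raise ValueError("MFEI undefined for GC-free sequence")
    return amfe(seq, mfe) / gc


@dataclass
class DuplexAlignment:
    """Ungapped antiparallel pairing of a miRNA against a same-length site.

    Position i (0-based, from the miRNA 5' end) is paired with site
    position L-1-i.  ``classes[i]`` is "WC", "GU" or "MM";
    ``weighted_mismatches`` counts full mismatches as 1 and G:U wobbles as
    0.5; ``energy`` sums nearest-neighbor stacks over consecutive paired
    positions (kcal/mol, <= 0).
    """

    classes: list
    weighted_mismatches: float
    energy: float

    @property
    def n_pairs(self) -> int:
        return sum(c != "MM" for c in self.classes)

    def alignment_string(self) -> str:
        """| for WC, o for G:U, . for mismatch (5'->3' of the miRNA)."""
        return "".join(
            {"WC": "|", "GU": "o", "MM": "."}[c] for c in self.classes
        )


def duplex(mirna: str, site: str) -> DuplexAlignment:
    """Score the ungapped duplex of ``mirna`` against target ``site``.

    Both are given 5'->3'; the site is the target-strand window, so miRNA
    position i faces site position L-1-i.
    """
    a = to_rna(mirna)
    b = to_rna(site)
    if len(a) != len(b):
        raise ValueError(
            f"ungapped duplex requires equal lengths ({len(a)} vs {len(b)})"
        )
    L = len(a)
    classes = []
    ptypes = []
    wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    for i in range(L):
        pair = (a[i], b[L - 1 - i])
        if pair in wc:
            classes.append("WC")
        elif pair in (("G", "U"), ("U", "G")):
            classes.append("GU")
        else:
            classes.append("MM")
        ptypes.append(_PT.get(pair, -1))
    energy = 0.0
    for i in range(L - 1):
        if ptypes[i] >= 0 and ptypes[i + 1] >= 0:
            energy += STACK[ptypes[i], ptypes[i + 1]]
    energy = min(energy, 0.0)
    mm = sum(c == "MM" for c in classes) + 0.5 * sum(c == "GU" for c in classes)
    return DuplexAlignment(classes=classes, weighted_mismatches=mm,
                           energy=round(energy, 2))


def perfect_complement_energy(mirna: str) -> float:
    """Duplex energy of a miRNA bound to its exact reverse complement."""
    return duplex(mirna, revcomp(mirna)).energy
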