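"""Minimum-free-energy RNA secondary-structure prediction.

A Zuker-style dynamic program over a simplified nearest-neighbour model:
stacking energies for the six canonical pair types (Watson-Crick plus
G:U wobble), hairpin/bulge/internal-loop initiation penalties by size,
an asymmetry penalty for internal loops, and a linear multibranch-loop
score.  Dangling ends and coaxial stacking are omitted.  Parameters live
in editable TSV files shipped with the package; energies are handled as
integer centi-kcal/mol so that ties are exact.

Tie-breaking is deterministic: minimum energy first, then the structure
with more base pairs, then a fixed traceback preference order.

The same energy function is exposed as :func:`structure_energy` (a loop
decomposition over an explicit pair set), which powers the exhaustive
:func:`enumerate_structures` oracle used to verify the DP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "HairpinMetrics",
    "fold_mfe",
    "max_pairs",
    "structure_energy",
    "enumerate_structures",
    "extract_hairpin",
    "excise_precursor",
    "write_ct",
]

MIN_LOOP_DEFAULT = 3
MAXLOOP = 30            # interior-loop size cap in the DP search
MAX_FOLD_LEN = 500
_ENUM_GUARD = 18

_BASE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIRS = ("AU", "CG", "GC", "GU", "UA", "UG")
# pair-type index by (base_i, base_j); -1 = not pairable
_PIDX = -np.ones((4, 4), dtype=np.int64)
for _k, _p in enumerate(_PAIRS):
    _PIDX[_BASE[_p[0]], _BASE[_p[1]]] = _k

_INF = 1 << 40
_SCALE = 4096           # combined key: energy*SCALE - n_pairs (lexicographic min)


class EnergyModel:
    """Nearest-neighbour parameter set in integer centi-kcal/mol."""

    def __init__(self, stack: np.ndarray, hairpin: dict, bulge: dict,
                 internal: dict, ml_init: int, ml_branch: int,
                 ml_unpaired: int, asym_coeff: int, asym_max: int):
        self.stack = stack              # (6,6) int64
        self._hairpin = hairpin
        self._bulge = bulge
        self._internal = internal
        self.ml_init = ml_init
        self.ml_branch = ml_branch
        self.ml_unpaired = ml_unpaired
        self.asym_coeff = asym_coeff
        self.asym_max = asym_max

    @classmethod
    def from_files(cls, stack_path=None, loop_path=None) -> "EnergyModel":
        data = resources.files("mirest") / "data"
        sp = Path(stack_path or data / "stack_energies.tsv")
        lp = Path(loop_path or data / "loop_energies.tsv")
        sdf = pd.read_csv(sp, sep="\t")
        stack = np.zeros((6, 6), dtype=np.int64)
        pidx = {p: i for i, p in enumerate(_PAIRS)}
        for _, r in sdf.iterrows():
            stack[pidx[r["outer"]], pidx[r["inner"]]] = round(r["dg_kcal_mol"] * 100)
        ldf = pd.read_csv(lp, sep="\t")
        tabs = {"hairpin": {}, "bulge": {}, "internal": {}}
        consts = {}
        for _, r in ldf.iterrows():
            if r["kind"] in tabs:
                tabs[r["kind"]][int(r["size"])] = round(r["dg_kcal_mol"] * 100)
            else:
                consts[r["kind"]] = round(r["dg_kcal_mol"] * 100)
        return cls(stack, tabs["hairpin"], tabs["bulge"], tabs["internal"],
                   consts["ml_init"], consts["ml_branch"], consts["ml_unpaired"],
                   consts["asym_coeff"], consts["asym_max"])

    def _extrap(self, table: dict, n: int) -> int:
        m = max(table)
        if n <= m:
            return table[n]
        # Jacobson-Stockmayer-style logarithmic extrapolation
        return table[m] + round(108 * math.log(n / m))

    def hairpin_e(self, n: int) -> int:
        return self._extrap(self._hairpin, n) if n >= 1 else _INF

    def bulge_e(self, n: int) -> int:
        return self._extrap(self._bulge, n)

    def internal_e(self, n1: int, n2: int) -> int:
        init = self._extrap(self._internal, n1 + n2)
        asym = min(self.asym_coeff * abs(n1 - n2), self.asym_max)
        return init + asym

    def loop_table(self, n: int, kind: str) -> np.ndarray:
        """Initiation energies for sizes 0..n as an array (for the DP kernel)."""
        tab = {"hairpin": self._hairpin, "bulge": self._bulge,
               "internal": self._internal}[kind]
        out = np.full(n + 1, _INF, dtype=np.int64)
        for s in range(1, n + 1):
            if s >= min(tab):
                out[s] = self._extrap(tab, s)
        return out


_DEFAULT_MODEL = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel.from_files()
    return _DEFAULT_MODEL


@dataclass
class SecondaryStructure:
    """A nested secondary structure with its model energy."""

    sequence: str
    pairing: str                 # dot-bracket
    energy: float                # kcal/mol
    pair_table: list             # 1-based; pair_table[i] = partner of i, 0 if unpaired

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_table[1:], 1) if j > i)

    @property
    def pairs(self) -> list:
        return [(i, j) for i, j in enumerate(self.pair_table[1:], 1) if j > i]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE[c] for c in seq], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-RNA character {e} in sequence") from None


def _pairs_to_structure(seq: str, pairs: list, energy_cc: int) -> SecondaryStructure:
    n = len(seq)
    pt = [0] * (n + 1)
    db = ["."] * n
    for i, j in pairs:
        pt[i], pt[j] = j, i
        db[i - 1], db[j - 1] = "(", ")"
    return SecondaryStructure(seq, "".join(db), energy_cc / 100.0, pt)


# --------------------------------------------------------------------------
# energy of an explicit structure (loop decomposition)
# --------------------------------------------------------------------------

def structure_energy(seq: str, pairs: list, model: EnergyModel | None = None) -> float:
    """Energy (kcal/mol) of the nested structure given by 1-based *pairs*."""
    model = model or default_model()
    enc = _encode(seq)
    n = len(seq)
    pt = [0] * (n + 1)
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise ValueError(f"pair {(i, j)} out of bounds")
        pt[i], pt[j] = j, i

    def ptype(i, j):
        k = _PIDX[enc[i - 1], enc[j - 1]]
        if k < 0:
            raise ValueError(f"non-canonical pair {seq[i-1]}:{seq[j-1]} at {(i, j)}")
        return k

    total = 0
    for i, j in pairs:
        # children = pairs directly nested under (i, j)
        children, unpaired = [], 0
        k = i + 1
        while k < j:
            if pt[k] > k:
                children.append((k, pt[k]))
                k = pt[k] + 1
            elif pt[k] == 0:
                unpaired += 1
                k += 1
            else:
                raise ValueError("pseudoknotted or ill-nested pair set")
        if not children:
            total += model.hairpin_e(j - i - 1)
        elif len(children) == 1:
            (k1, l1) = children[0]
            n1, n2 = k1 - i - 1, j - l1 - 1
            if n1 == 0 and n2 == 0:
                total += model.stack[ptype(i, j), ptype(k1, l1)]
            elif n1 == 0 or n2 == 0:
                total += model.bulge_e(n1 + n2)
            else:
                total += model.internal_e(n1, n2)
        else:
            total += (model.ml_init + model.ml_branch * (len(children) + 1)
                      + model.ml_unpaired * unpaired)
    return total / 100.0


# --------------------------------------------------------------------------
# the DP kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _fill(enc, pidx, stack, hp_tab, bl_tab, il_tab, ml_init, ml_branch,
          ml_unpaired, asym_coeff, asym_max, min_loop, maxloop, INF, SCALE):
    n = enc.shape[0]
    V = np.full((n + 2, n + 2), INF, dtype=np.int64)
    WM = np.full((n + 2, n + 2), INF, dtype=np.int64)
    W = np.zeros(n + 1, dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            pt_ij = pidx[enc[i - 1], enc[j - 1]]
            if pt_ij >= 0:
                best = hp_tab[j - i - 1] * SCALE - 1
                # interior (stack / bulge / internal) to inner pair (k, l)
                for k in range(i + 1, j - min_loop):
                    n1 = k - i - 1
                    if n1 > maxloop:
                        break
                    lmin = k + min_loop + 1
                    for l in range(j - 1, lmin - 1, -1):
                        n2 = j - l - 1
                        if n1 + n2 > maxloop:
                            break
                        if V[k, l] >= INF:
                            continue
                        pt_kl = pidx[enc[k - 1], enc[l - 1]]
                        if pt_kl < 0:
                            continue
                        if n1 == 0 and n2 == 0:
                            cost = stack[pt_ij, pt_kl]
                        elif n1 == 0 or n2 == 0:
                            cost = bl_tab[n1 + n2]
                        else:
                            asym = asym_coeff * (n1 - n2 if n1 > n2 else n2 - n1)
                            if asym > asym_max:
                                asym = asym_max
                            cost = il_tab[n1 + n2] + asym
                        cand = cost * SCALE - 1 + V[k, l]
                        if cand < best:
                            best = cand
                # multibranch: >= 2 branches inside
                if j - i - 1 >= 2 * (min_loop + 2):
                    for k in range(i + 1, j - 1):
                        if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                            cand = ((ml_init + ml_branch) * SCALE - 1
                                    + WM[i + 1, k] + WM[k + 1, j - 1])
                            if cand < best:
                                best = cand
                V[i, j] = best
            # WM: >= 1 multiloop branches spanning exactly region i..j
            best = INF
            if WM[i + 1, j] < INF:
                best = WM[i + 1, j] + ml_unpaired * SCALE
            if WM[i, j - 1] < INF and WM[i, j - 1] + ml_unpaired * SCALE < best:
                best = WM[i, j - 1] + ml_unpaired * SCALE
            if V[i, j] < INF and V[i, j] + ml_branch * SCALE < best:
                best = V[i, j] + ml_branch * SCALE
            for k in range(i, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    cand = WM[i, k] + WM[k + 1, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(1, j):
            if V[i, j] < INF:
                cand = W[i - 1] + V[i, j]
                if cand < best:
                    best = cand
        W[j] = best
    return V, WM, W


def _traceback(seq, enc, model, V, WM, W, min_loop):
    """Recover one optimal pair set from the filled DP matrices."""
    n = len(seq)
    pairs = []
    stack_jobs = []
    # exterior: walk j from n downward
    j = n
    while j > 0:
        if W[j] == W[j - 1]:
            j -= 1
            continue
        for i in range(1, j):
            if V[i, j] < _INF and W[i - 1] + V[i, j] == W[j]:
                stack_jobs.append(("V", i, j))
                j = i - 1
                break
        else:  # pragma: no cover - DP consistency
            raise AssertionError("exterior traceback failed")
    while stack_jobs:
        kind, i, j = stack_jobs.pop()
        if kind == "V":
            pairs.append((i, j))
            target = V[i, j]
            pt_ij = _PIDX[enc[i - 1], enc[j - 1]]
            if model.hairpin_e(j - i - 1) * _SCALE - 1 == target:
                continue
            found = False
            for k in range(i + 1, j - min_loop):
                n1 = k - i - 1
                if n1 > MAXLOOP or found:
                    break
                for l in range(j - 1, k + min_loop, -1):
                    n2 = j - l - 1
                    if n1 + n2 > MAXLOOP:
                        break
                    if V[k, l] >= _INF:
                        continue
                    pt_kl = _PIDX[enc[k - 1], enc[l - 1]]
                    if pt_kl < 0:
                        continue
                    if n1 == 0 and n2 == 0:
                        cost = model.stack[pt_ij, pt_kl]
                    elif n1 == 0 or n2 == 0:
                        cost = model.bulge_e(n1 + n2)
                    else:
                        cost = model.internal_e(n1, n2)
                    if cost * _SCALE - 1 + V[k, l] == target:
                        stack_jobs.append(("V", k, l))
                        found = True
                        break
            if found:
                continue
            for k in range(i + 1, j - 1):
                if (WM[i + 1, k] < _INF and WM[k + 1, j - 1] < _INF
                        and (model.ml_init + model.ml_branch) * _SCALE - 1
                        + WM[i + 1, k] + WM[k + 1, j - 1] == target):
                    stack_jobs.append(("WM", i + 1, k))
                    stack_jobs.append(("WM", k + 1, j - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - DP consistency
                raise AssertionError(f"V traceback failed at {(i, j)}")
        else:  # WM
            target = WM[i, j]
            if V[i, j] < _INF and V[i, j] + model.ml_branch * _SCALE == target:
                stack_jobs.append(("V", i, j))
            elif WM[i + 1, j] < _INF and WM[i + 1, j] + model.ml_unpaired * _SCALE == target:
                stack_jobs.append(("WM", i + 1, j))
            elif WM[i, j - 1] < _INF and WM[i, j - 1] + model.ml_unpaired * _SCALE == target:
                stack_jobs.append(("WM", i, j - 1))
            else:
                for k in range(i, j):
                    if (WM[i, k] < _INF and WM[k + 1, j] < _INF
                            and WM[i, k] + WM[k + 1, j] == target):
                        stack_jobs.append(("WM", i, k))
                        stack_jobs.append(("WM", k + 1, j))
                        break
                else:  # pragma: no cover - DP consistency
                    raise AssertionError(f"WM traceback failed at {(i, j)}")
    return sorted(pairs)


def fold_mfe(seq: str, model: EnergyModel | None = None,
             min_loop: int = MIN_LOOP_DEFAULT) -> SecondaryStructure:
    """Fold *seq* (RNA, uppercase) into its minimum-energy nested structure.

    The returned energy is never positive: the open chain (energy 0) is
    always an admissible structure.
    """
    n = len(seq)
    if n < 15 and n < MIN_LOOP_DEFAULT + 2:
        raise ValueError(f"sequence of length {n} too short to fold")
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence of length {n} exceeds fold limit {MAX_FOLD_LEN}")
    model = model or default_model()
    enc = _encode(seq)
    V, WM, W = _fill(enc, _PIDX, model.stack, model.loop_table(n, "hairpin"),
                     model.loop_table(n, "bulge"), model.loop_table(n, "internal"),
                     model.ml_init, model.ml_branch, model.ml_unpaired,
                     model.asym_coeff, model.asym_max, min_loop, MAXLOOP,
                     _INF, _SCALE)
    pairs = _traceback(seq, enc, model, V, WM, W, min_loop)
    energy_cc = round(structure_energy(seq, pairs, model) * 100)
    return _pairs_to_structure(seq, pairs, energy_cc)


def max_pairs(seq: str, min_loop: int = MIN_LOOP_DEFAULT) -> int:
    """Nussinov-style maximum count of nested canonical pairs."""
    if len(seq) < MIN_LOOP_DEFAULT + 2:
        return 0
    enc = _encode(seq)
    n = len(seq)
    M = np.zeros((n + 2, n + 2), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = M[i, j - 1]
            for k in range(i, j - min_loop):
                if _PIDX[enc[k - 1], enc[j - 1]] >= 0:
                    cand = M[i, k - 1] + 1 + M[k + 1, j - 1]
                    if cand > best:
                        best = cand
            M[i, j] = best
    return int(M[1, n])


def enumerate_structures(seq: str, min_loop: int = MIN_LOOP_DEFAULT,
                         model: EnergyModel | None = None) -> list:
    """All nested structures of *seq* with their energies (test oracle).

    Refuses sequences longer than 18 nt (combinatorial guard).  Returns a
    list of ``(pairs, energy)`` sorted by (energy, -n_pairs, dot-bracket).
    """
    n = len(seq)
    if n > _ENUM_GUARD:
        raise ValueError(f"enumeration limited to {_ENUM_GUARD} nt, got {n}")
    model = model or default_model()
    enc = _encode(seq)

    def regions(i, j):
        """All pair sets within positions i..j (inclusive, 1-based)."""
        if i >= j:
            return [[]]
        out = []
        # position i unpaired
        out.extend(regions(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if _PIDX[enc[i - 1], enc[k - 1]] >= 0:
                for inner in regions(i + 1, k - 1):
                    for outer in regions(k + 1, j):
                        out.append([(i, k)] + inner + outer)
        return out

    results = []
    for pairs in regions(1, n):
        e = structure_energy(seq, sorted(pairs), model)
        db = ["."] * n
        for a, b in pairs:
            db[a - 1], db[b - 1] = "(", ")"
        results.append((sorted(pairs), e, "".join(db)))
    results.sort(key=lambda t: (round(t[1] * 100), -len(t[0]), t[2]))
    return [(p, e) for p, e, _ in results]


# --------------------------------------------------------------------------
# hairpin metrics
# --------------------------------------------------------------------------

@dataclass
class HairpinMetrics:
    """Placement of a mature miRNA within a folded precursor."""

    arm: str                     # "5'", "3'", "loop", or "split"
    mature_span: tuple
    star_span: tuple | None
    mature_star_pairs: int
    largest_asymmetry: int
    in_stem: bool


def extract_hairpin(structure: SecondaryStructure, mature_span: tuple) -> HairpinMetrics:
    """Locate the mature span on the hairpin and count mature:star pairs.

    The arm is 5' when every partner of the mature lies downstream of it
    (the terminal loop sits between mature and star), 3' when upstream,
    "loop" when partners fall on both sides, and "split" when the mature
    pairs with nothing outside itself.
    """
    a, b = mature_span
    n = len(structure.sequence)
    if not (1 <= a <= b <= n):
        raise ValueError(f"mature span {mature_span} outside 1..{n}")
    pt = structure.pair_table
    all_partners = [pt[i] for i in range(a, b + 1)
                    if pt[i] and not a <= pt[i] <= b]
    # pairs to a single opposite arm have strictly decreasing partners as
    # the mature position increases (nestedness); stray pairs into padding
    # or other branches break that run and are not mature:star pairs
    partners = _longest_decreasing_subsequence(all_partners)
    mature_star_pairs = len(partners)
    if not partners:
        return HairpinMetrics("split", mature_span, None, 0,
                              _largest_unpaired_run(pt, a, b), False)
    lo, hi = min(partners), max(partners)
    if lo > b:
        arm = "5'"
    elif hi < a:
        arm = "3'"
    else:
        arm = "loop"
    in_stem = arm in ("5'", "3'")
    return HairpinMetrics(arm, mature_span, (lo, hi), mature_star_pairs,
                          _largest_unpaired_run(pt, a, b), in_stem)


def _longest_decreasing_subsequence(xs: list) -> list:
    if not xs:
        return []
    best = [1] * len(xs)
    prev = [-1] * len(xs)
    for i in range(len(xs)):
        for j in range(i):
            if xs[j] > xs[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    k = max(range(len(xs)), key=lambda i: best[i])
    out = []
    while k >= 0:
        out.append(xs[k])
        k = prev[k]
    return out[::-1]


def _largest_unpaired_run(pt: list, a: int, b: int) -> int:
    """Longest run of consecutive unpaired positions within span a..b —
    a proxy for the largest bulge/internal loop interrupting the mature."""
    best = run = 0
    for i in range(a, b + 1):
        run = run + 1 if pt[i] == 0 else 0
        best = max(best, run)
    return best


def excise_precursor(est_seq: str, hit_span: tuple,
                     model: EnergyModel | None = None, max_extension: int = 250,
                     step: int = 25):
    """Choose the precursor window around a homology hit.

    Candidate windows extend the hit by 0..*max_extension* nt on each side
    in *step*-nt increments; the window whose fold maximizes the
    mature:star pair count subject to the mature sitting in a stem wins,
    ties going to the shortest window.

    Returns ``(window_span, structure, metrics)`` with the span 1-based
    on the EST; the mature span inside the window is
    ``hit_span`` shifted accordingly.
    """
    model = model or default_model()
    n = len(est_seq)
    a, b = hit_span
    best = None
    exts = range(0, max_extension + 1, step)
    for left in exts:
        for right in exts:
            lo, hi = max(1, a - left), min(n, b + right)
            if hi - lo + 1 < 15 or hi - lo + 1 > MAX_FOLD_LEN:
                continue
            window = est_seq[lo - 1:hi]
            try:
                st = fold_mfe(window, model)
            except ValueError:
                continue
            m = extract_hairpin(st, (a - lo + 1, b - lo + 1))
            score = (m.mature_star_pairs if m.in_stem else -1,
                     -(hi - lo + 1))
            if best is None or score > best[0]:
                best = (score, (lo, hi), st, m)
    if best is None:
        raise ValueError("no foldable window around hit")
    return best[1], best[2], best[3]


def write_ct(structure: SecondaryStructure, path, title: str = "structure") -> None:
    """Write a connectivity-table (.ct) file for interoperability."""
    n = len(structure.sequence)
    lines = [f"{n}\t{title}\tdG = {structure.energy:.2f}"]
    for i, c in enumerate(structure.sequence, 1):
        lines.append(f"{i}\t{c}\t{i-1}\t{(i+1) % (n+1)}\t{structure.pair_table[i]}\t{i}")
    Path(path).write_text("\n".join(lines) + "\n")
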