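"""Minimum-free-energy RNA secondary structure for short sequences.

The built-in engine is a simplified Zuker-style dynamic program: helix
stability comes from a packaged nearest-neighbor stacking table, every loop
(hairpin / internal-or-bulge / multiloop) costs a fixed constant, hairpin
loops hold at least 3 unpaired bases, internal loops are capped at 30
unpaired bases, and pseudoknots are excluded.  That is deliberately not a
full thermodynamic model — the free energy is used as a *ranking* covariate
(more negative = more structured), for which stacking dominance suffices.
Users wanting published parameter sets can register an external engine
(e.g. an RNAfold subprocess) behind the same contract.

Energies are in kcal/mol; an unpaired sequence scores 0, so ``delta_g <= 0``
always holds for the built-in engine.
"""

from __future__ import annotations

import importlib.resources
import subprocess
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

try:  # compiled kernel when numba is available; identical pure-Python otherwise
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

_INF = 1e9
MAX_LOOP = 30  # max unpaired bases in an internal/bulge loop
MIN_HAIRPIN = 3

# base codes: A=0 C=1 G=2 U=3 (T folded onto U), N=4
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
_PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
# pair-type lookup: 5x5 matrix of pair ids, -1 = not pairable
_PAIR_ID = -np.ones((5, 5), dtype=np.int64)
for _pid, _name in enumerate(_PAIR_NAMES):
    _PAIR_ID[_CODE[_name[0]], _CODE[_name[1]]] = _pid


@dataclass(frozen=True)
class FoldParams:
    stack: np.ndarray  # (6, 6) stacking energies, outer pair x inner pair
    hairpin: float
    internal: float
    multi: float


def load_params() -> FoldParams:
    """Load the packaged plain-text parameter table."""
    text = (
        importlib.resources.files("intronseek")
        .joinpath("data/fold_params.txt")
        .read_text()
    )
    stack = np.full((6, 6), _INF)
    loops = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "stack":
            outer, inner, val = parts[1], parts[2], float(parts[3])
            stack[_PAIR_NAMES.index(outer), _PAIR_NAMES.index(inner)] = val
        else:
            loops[parts[0]] = float(parts[1])
    return FoldParams(stack=stack, hairpin=loops["hairpin"],
                      internal=loops["internal"], multi=loops["multi"])


_PARAMS: FoldParams | None = None


def _params() -> FoldParams:
    global _PARAMS
    if _PARAMS is None:
        _PARAMS = load_params()
    return _PARAMS


def encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGTUN base in sequence: {exc}") from exc


@njit(cache=True)
def _fill(codes, pair_id, stack, hairpin_p, internal_p, multi_p,
          max_loop, min_hairpin):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_id[codes[i], codes[j]]
            if pt >= 0:
                best = hairpin_p
                # stack on the immediately enclosed pair
                if j - 1 - (i + 1) > min_hairpin:
                    inner = pair_id[codes[i + 1], codes[j - 1]]
                    if inner >= 0 and V[i + 1, j - 1] < _INF:
                        e = stack[pt, inner] + V[i + 1, j - 1]
                        if e < best:
                            best = e
                # internal / bulge loops (>= 1 unpaired, capped size)
                for k in range(i + 1, j - 1):
                    gap5 = k - i - 1
                    if gap5 > max_loop:
                        break
                    for l in range(j - 1, k, -1):
                        gap3 = j - l - 1
                        if gap5 + gap3 == 0:
                            continue
                        if gap5 + gap3 > max_loop:
                            break
                        if V[k, l] < _INF:
                            e = internal_p + V[k, l]
                            if e < best:
                                best = e
                # multiloop: >= 2 branches
                for d in range(i + 2, j - 2):
                    if WM[i + 1, d] < _INF and WM[d + 1, j - 1] < _INF:
                        e = multi_p + WM[i + 1, d] + WM[d + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: >= 1 branch in [i, j], unpaired bases free
            best_m = _INF
            if V[i, j] < best_m:
                best_m = V[i, j]
            if WM[i + 1, j] < best_m:
                best_m = WM[i + 1, j]
            if WM[i, j - 1] < best_m:
                best_m = WM[i, j - 1]
            for d in range(i + 1, j):
                if WM[i, d] < _INF and WM[d + 1, j] < _INF:
                    e = WM[i, d] + WM[d + 1, j]
                    if e < best_m:
                        best_m = e
            if best_m < WM[i, j]:
                WM[i, j] = best_m
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for k in range(0, j):
            if V[k, j] < _INF:
                left = W[k - 1] if k > 0 else 0.0
                e = left + V[k, j]
                if e < best:
                    best = e
        W[j] = best
    return V, WM, W


def _traceback(codes, V, WM, W, params) -> list[tuple[int, int]]:
    """Recover one optimal pair set from the filled matrices."""
    n = codes.shape[0]
    eps = 1e-9
    pairs: list[tuple[int, int]] = []
    stack_tasks: list[tuple] = [("W", n - 1)]
    pid = _PAIR_ID

    while stack_tasks:
        task = stack_tasks.pop()
        if task[0] == "W":
            j = task[1]
            if j < 0 or W[j] > -eps:
                continue
            prev = W[j - 1] if j > 0 else 0.0
            if abs(W[j] - prev) <= eps:
                stack_tasks.append(("W", j - 1))
                continue
            for k in range(0, j):
                if V[k, j] < _INF:
                    left = W[k - 1] if k > 0 else 0.0
                    if abs(W[j] - (left + V[k, j])) <= eps:
                        stack_tasks.append(("V", k, j))
                        stack_tasks.append(("W", k - 1))
                        break
        elif task[0] == "V":
            i, j = task[1], task[2]
            pairs.append((i, j))
            e = V[i, j]
            if abs(e - params.hairpin) <= eps:
                continue
            pt = pid[codes[i], codes[j]]
            inner = pid[codes[i + 1], codes[j - 1]] if j - i >= 2 else -1
            if (
                inner >= 0
                and V[i + 1, j - 1] < _INF
                and abs(e - (params.stack[pt, inner] + V[i + 1, j - 1])) <= eps
            ):
                stack_tasks.append(("V", i + 1, j - 1))
                continue
            found = False
            for k in range(i + 1, j - 1):
                if found or k - i - 1 > MAX_LOOP:
                    break
                for l in range(j - 1, k, -1):
                    gap = (k - i - 1) + (j - l - 1)
                    if gap == 0 or gap > MAX_LOOP:
                        continue
                    if V[k, l] < _INF and abs(e - (params.internal + V[k, l])) <= eps:
                        stack_tasks.append(("V", k, l))
                        found = True
                        break
            if found:
                continue
            for d in range(i + 2, j - 2):
                if (
                    WM[i + 1, d] < _INF
                    and WM[d + 1, j - 1] < _INF
                    and abs(e - (params.multi + WM[i + 1, d] + WM[d + 1, j - 1])) <= eps
                ):
                    stack_tasks.append(("WM", i + 1, d))
                    stack_tasks.append(("WM", d + 1, j - 1))
                    break
        else:  # WM
            i, j = task[1], task[2]
            e = WM[i, j]
            if V[i, j] < _INF and abs(e - V[i, j]) <= eps:
                stack_tasks.append(("V", i, j))
                continue
            if i + 1 <= j and WM[i + 1, j] < _INF and abs(e - WM[i + 1, j]) <= eps:
                stack_tasks.append(("WM", i + 1, j))
                continue
            if j - 1 >= i and WM[i, j - 1] < _INF and abs(e - WM[i, j - 1]) <= eps:
                stack_tasks.append(("WM", i, j - 1))
                continue
            for d in range(i + 1, j):
                if (
                    WM[i, d] < _INF
                    and WM[d + 1, j] < _INF
                    and abs(e - (WM[i, d] + WM[d + 1, j])) <= eps
                ):
                    stack_tasks.append(("WM", i, d))
                    stack_tasks.append(("WM", d + 1, j))
                    break
    return pairs


def structure_energy(seq: str, pairs: Iterable[tuple[int, int]],
                     params: FoldParams | None = None) -> float:
    """Energy of a given pseudoknot-free pair set under the packaged model.

    Loop decomposition is derived directly from the pair nesting: a pair
    whose only child is immediately inside it contributes a stacking term,
    a childless pair closes a hairpin, one non-adjacent child an internal or
    bulge loop, and two or more children a multiloop.
    """
    params = params or _params()
    codes = encode(seq)
    pairs = sorted(pairs)
    total = 0.0
    for i, j in pairs:
        pt = _PAIR_ID[codes[i], codes[j]]
        if pt < 0:
            raise ValueError(f"unpairable bases at ({i}, {j})")
        inside = [(k, l) for k, l in pairs if i < k and l < j]
        top = [
            (k, l) for k, l in inside
            if not any(k2 < k and l < l2 for k2, l2 in inside)
        ]
        if not top:
            total += params.hairpin
        elif len(top) == 1 and top[0] == (i + 1, j - 1):
            inner = _PAIR_ID[codes[i + 1], codes[j - 1]]
            total += params.stack[pt, inner]
        elif len(top) == 1:
            total += params.internal
        else:
            total += params.multi
    return total


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    delta_g: float
    structure: str | None
    engine: str


def _fold_builtin(seq: str) -> FoldResult:
    params = _params()
    codes = encode(seq)
    n = len(codes)
    if n < 2:
        return FoldResult(seq, 0.0, "." * n, "builtin")
    V, WM, W = _fill(codes, _PAIR_ID, params.stack, params.hairpin,
                     params.internal, params.multi, MAX_LOOP, MIN_HAIRPIN)
    mfe = float(min(0.0, W[n - 1]))
    if mfe == 0.0:
        return FoldResult(seq, 0.0, "." * n, "builtin")
    pairs = _traceback(codes, V, WM, W, params)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult(seq, mfe, "".join(db), "builtin")


def _fold_rnafold(seq: str) -> FoldResult:  # pragma: no cover - external tool
    """Adapter for the ViennaRNA RNAfold executable (if on PATH)."""
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=seq + "\n", text=True,
        capture_output=True, check=True,
    )
    line = proc.stdout.strip().splitlines()[-1]
    structure, _, energy = line.partition(" ")
    return FoldResult(seq, float(energy.strip().strip("()")), structure, "rnafold")


_ENGINES: dict[str, Callable[[str], FoldResult]] = {
    "builtin": _fold_builtin,
    "rnafold": _fold_rnafold,
}


def register_engine(name: str, fn: Callable[[str], FoldResult]) -> None:
    _ENGINES[name] = fn


def fold_sequence(seq: str, engine: str = "builtin") -> FoldResult:
    """Minimum free energy (kcal/mol) of a DNA/RNA sequence (T read as U)."""
    if engine not in _ENGINES:
        raise ValueError(f"unknown folding engine {engine!r}")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    n_count = seq.upper().count("N")
    if n_count > len(seq) / 2:
        raise ValueError("more than 50% N bases; refusing to fold")
    return _ENGINES[engine](seq)


def fold_intron_pool(records, engine: str = "builtin") -> int:
    """Fold each record's flanked sequence; set ``delta_g`` in place.

    Returns the number of records successfully folded; failures leave
    ``delta_g`` as None.
    """
    n_ok = 0
    for rec in records:
        try:
            rec.delta_g = fold_sequence(rec.flanked_seq, engine=engine).delta_g
            n_ok += 1
        except (ValueError, subprocess.SubprocessError):
            rec.delta_g = None
    return n_ok
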