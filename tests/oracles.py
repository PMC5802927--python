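"""Independent brute-force oracles used by the test suite and the
acceptance script.  Everything here is computed directly from definitions
(string scanning, exhaustive search, full dynamic programming) without
touching the package's own algorithms."""

from __future__ import annotations

import numpy as np

ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def brute_suffix_array(s: str) -> list[int]:
    return sorted(range(len(s)), key=lambda i: s[i:])


def brute_lcp(s: str, sa: list[int]) -> list[int]:
    out = [0] * len(sa)
    for k in range(1, len(sa)):
        a, b = s[sa[k - 1]:], s[sa[k]:]
        n = 0
        while n < min(len(a), len(b)) and a[n] == b[n]:
            n += 1
        out[k] = n
    return out


def _lce_matrix(a: np.ndarray, b: np.ndarray,
                a_ok: np.ndarray, b_ok: np.ndarray) -> np.ndarray:
    """L[i, j] = length of the longest common extension of a[i:] and b[j:]
    counting only ACGT-valid positions (an invalid base matches nothing)."""
    L = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int32)
    for i in range(len(a) - 1, -1, -1):
        eq = (a[i] == b) & a_ok[i] & b_ok
        L[i, :-1] = np.where(eq, L[i + 1, 1:] + 1, 0)
    return L


def seed_oracle(S: str, Q: str, min_len: int, mode: str) -> set[tuple[int, int, int]]:
    """Every maximal exact match (1-based ref start, 1-based qry start,
    length) of length >= min_len, filtered by uniqueness ``mode`` in
    {'all', 'ref', 'both'}.  Direct definition: full LCE matrices plus
    occurrence counting."""
    s = np.frombuffer(S.encode(), dtype=np.uint8)
    q = np.frombuffer(Q.encode(), dtype=np.uint8)
    s_ok = np.isin(s, ACGT)
    q_ok = np.isin(q, ACGT)
    Lsq = _lce_matrix(s, q, s_ok, q_ok)
    Lss = _lce_matrix(s, s, s_ok, s_ok) if mode != "all" else None
    Lqq = _lce_matrix(q, q, q_ok, q_ok) if mode == "both" else None
    out: set[tuple[int, int, int]] = set()
    for i in range(len(s)):
        for j in range(len(q)):
            l = int(Lsq[i, j])
            if l < min_len:
                continue
            if (
                i > 0 and j > 0
                and s[i - 1] == q[j - 1] and s_ok[i - 1] and q_ok[j - 1]
            ):
                continue  # left-extendable
            if mode != "all" and int(np.sum(Lss[: len(s), i] >= l)) != 1:
                continue
            if mode == "both" and int(np.sum(Lqq[: len(q), j] >= l)) != 1:
                continue
            out.add((i + 1, j + 1, l))
    return out


def full_nw(a: str, b: str, match: int = 3, mismatch: int = -3,
            gap: int = -4) -> tuple[int, int]:
    """Unbanded global alignment by plain dictionary dynamic programming.
    Returns (optimal score, error count of the optimal transcript under a
    diagonal > up > left move preference)."""
    la, lb = len(a), len(b)
    score = [[0] * (lb + 1) for _ in range(la + 1)]
    ptr = [[0] * (lb + 1) for _ in range(la + 1)]
    for j in range(1, lb + 1):
        score[0][j] = gap * j
        ptr[0][j] = 2
    for i in range(1, la + 1):
        score[i][0] = gap * i
        ptr[i][0] = 1
        row, prev = score[i], score[i - 1]
        for j in range(1, lb + 1):
            d = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = prev[j] + gap
            l = row[j - 1] + gap
            best = max(d, u, l)
            row[j] = best
            ptr[i][j] = 0 if best == d else (1 if best == u else 2)
    i, j, errors = la, lb, 0
    while i > 0 or j > 0:
        p = ptr[i][j]
        if p == 0:
            errors += a[i - 1] != b[j - 1]
            i -= 1
            j -= 1
        elif p == 1:
            errors += 1
            i -= 1
        else:
            errors += 1
            j -= 1
    return score[la][lb], errors


def chain_oracle(matches, max_gap: int, diag_frac: float) -> int:
    """Exhaustive best strictly-colinear chain score by depth-first search
    over every chain ordered by reference start.  ``matches`` is a list of
    (ref_start, qry_start, length) triples."""
    ms = sorted(matches)
    n = len(ms)

    def ok(a, b) -> bool:
        ar, aq, al = a
        br, bq, _ = b
        if br <= ar or bq <= aq:
            return False
        gr = br - (ar + al - 1) - 1
        gq = bq - (aq + al - 1) - 1
        if gr > max_gap or gq > max_gap:
            return False
        return abs((br - bq) - (ar - aq)) <= diag_frac * max(gr, gq, 1)

    best = 0

    def dfs(last_idx: int, score: int) -> None:
        nonlocal best
        best = max(best, score)
        for k in range(last_idx + 1, n):
            if last_idx >= 0 and not ok(ms[last_idx], ms[k]):
                continue
            dfs(k, score + ms[k][2])

    dfs(-1, 0)
    return best


def replay_alignment(ref_slice: str, qry_slice: str, indels: list[int]) -> tuple[int, int]:
    """Replay MUMmer indel offsets against the actual aligned substrings
    (query already strand-adjusted).  Returns (columns, mismatch+gap count)
    computed by direct walking, independent of the package decoder."""
    i = j = cols = errs = 0
    for off in indels:
        run = abs(off) - 1
        for _ in range(run):
            errs += ref_slice[i] != qry_slice[j]
            i += 1
            j += 1
            cols += 1
        if off > 0:
            i += 1
        else:
            j += 1
        errs += 1
        cols += 1
    while i < len(ref_slice) and j < len(qry_slice):
        errs += ref_slice[i] != qry_slice[j]
        i += 1
        j += 1
        cols += 1
    if i != len(ref_slice) or j != len(qry_slice):
        raise AssertionError("indel offsets inconsistent with spans")
    return cols, errs


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(ACGT, size=n).tobytes().decode()
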