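"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or exact
arithmetic, independently of the implementation path it checks.
"""

from __future__ import annotations

import math
from decimal import Decimal, getcontext
from itertools import combinations

import numpy as np

getcontext().prec = 60


def naive_combine(profiles_at_site: list[tuple[float, float, float]]) -> tuple[float, float]:
    """Eq.-style weighted mean at one site: inputs (total_aligned, r, mr)."""
    num_r = num_mr = den = 0.0
    for total, r, mr in profiles_at_site:
        w = 1.0 / total
        num_r += w * r
        num_mr += w * mr
        den += w
    return num_r / den, num_mr / den


def enumerate_runs(pos: np.ndarray, meth: np.ndarray, predicate,
                   n_cpg_cutoff: int, max_gap_bp: int,
                   verify_maximality: bool = False) -> list[tuple[int, int, int]]:
    """Maximal qualifying runs as (start, end, n_cpg) via group splitting.

    Independent route: break indices wherever the predicate fails or the
    inter-CpG gap exceeds the limit, then keep groups of sufficient size.
    Optionally cross-check maximality by exhaustive window enumeration
    (cubic; only for small profiles).
    """
    n = len(pos)
    ok = np.array([bool(predicate(m)) for m in meth])
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    for k in range(1, n):
        breaks[k] = (not ok[k - 1]) or (pos[k] - pos[k - 1] > max_gap_bp)
    group = np.cumsum(breaks) - 1 if n else np.array([], dtype=int)
    runs = []
    for g in np.unique(group):
        idx = np.nonzero((group == g) & ok)[0]
        # a group may start with failing sites; qualifying indices within a
        # group are contiguous only if ok throughout — re-split on ok
        if not len(idx):
            continue
        sub_break = np.nonzero(np.diff(idx) > 1)[0]
        pieces = np.split(idx, sub_break + 1)
        for piece in pieces:
            if len(piece) >= n_cpg_cutoff:
                runs.append((int(pos[piece[0]]), int(pos[piece[-1]]) + 2, len(piece)))
    runs.sort()
    if verify_maximality:
        for a in range(n):
            for b in range(a + n_cpg_cutoff - 1, n):
                window_ok = all(ok[a : b + 1]) and all(
                    pos[k + 1] - pos[k] <= max_gap_bp for k in range(a, b))
                if window_ok:
                    assert any(s <= pos[a] and pos[b] + 2 <= e for s, e, _ in runs), \
                        "qualifying window not covered by a maximal run"
    return runs


def exact_binom_upper_tail(n_kc: int, n_c: int, p: float) -> float:
    """Strict upper tail Pr(X > n_kc) by exact big-integer/Decimal summation."""
    if p == 0:
        return 0.0
    if p == 1:
        return 0.0 if n_kc >= n_c else 1.0
    dp = Decimal(p)
    dq = Decimal(1) - dp
    # iterative term recurrence keeps the exact summation fast at large n
    term = dq**n_c
    total = term
    for i in range(1, n_kc + 1):
        term = term * Decimal(n_c - i + 1) / Decimal(i) * dp / dq
        total += term
    return float(Decimal(1) - total)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins (point-probability rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # hypergeometric P(X = x) with margins fixed
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def all_pairs_nearest(regions: list[tuple[str, int, int]]) -> dict[int, float]:
    """Edge-to-edge nearest same-set neighbor distance per region index."""
    out = {}
    for i, (ci, si, ei) in enumerate(regions):
        best = math.inf
        for j, (cj, sj, ej) in enumerate(regions):
            if i == j or ci != cj:
                continue
            best = min(best, max(sj - ei, si - ej, 0))
        if math.isfinite(best):
            out[i] = best
    return out


def all_pairs_cross(queries, targets) -> dict[int, float]:
    out = {}
    for i, (ci, si, ei) in enumerate(queries):
        best = math.inf
        for cj, sj, ej in targets:
            if ci != cj:
                continue
            best = min(best, max(sj - ei, si - ej, 0))
        if math.isfinite(best):
            out[i] = best
    return out


def per_base_overlap(start: int, end: int, intervals: list[tuple[int, int]]) -> int:
    """Covered base pairs of [start, end) by counting positions one by one."""
    covered = 0
    for p in range(start, end):
        if any(s <= p < e for s, e in intervals):
            covered += 1
    return covered


def rescan_all_windows(pwm, sequence: str) -> set[tuple[int, str]]:
    """Exhaustive per-window rescoring: every offset and strand whose
    discretized score reaches the motif's calibrated threshold."""
    from dremap.tfbs import _CODE, reverse_complement

    thr = pwm.int_threshold(1e-4)
    w = pwm.width
    hits = set()
    for strand in "+-":
        seq = sequence.upper() if strand == "+" else reverse_complement(sequence).upper()
        for off in range(len(seq) - w + 1):
            window = seq[off : off + w]
            if any(b not in _CODE for b in window):
                continue
            score = sum(int(pwm.int_scores[k, _CODE[b]]) for k, b in enumerate(window))
            if score >= thr:
                fwd_off = off if strand == "+" else len(sequence) - w - off
                hits.add((fwd_off, strand))
    return hits


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str = "less") -> float:
    """Exact one-sided rank-sum p by enumerating every assignment of the
    pooled sample into the two groups (feasible for small samples)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    idx = range(len(pooled))

    def u_stat(x_idx) -> float:
        xs = pooled[list(x_idx)]
        ys = np.delete(pooled, list(x_idx))
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    u_obs = u_stat(range(n))
    count = total = 0
    for comb in combinations(idx, n):
        u = u_stat(comb)
        if alternative == "less":
            count += u <= u_obs + 1e-9
        else:
            count += u >= u_obs - 1e-9
        total += 1
    return count / total
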