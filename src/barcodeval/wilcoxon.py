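"""Wilcoxon signed-rank comparison of interspecific distances across markers.

Paired units are interspecific sample pairs (i, j) present and valid in both
markers, matched by sample-pair identity (the ``matched`` mode).  Because the
original pairing rule behind published tables of this kind is typically not
stated, a ``sorted`` mode is available for sensitivity analysis: each
marker's interspecific distances over the shared samples are sorted and
paired by rank.

The test itself follows Wilcoxon's conventions: zero differences are
dropped (and counted), absolute differences are mid-ranked, and the
two-sided p-value is exact (full enumeration of sign assignments via dynamic
programming) for n <= 25 without ties, otherwise a normal approximation with
tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import PairingError, TestError
from .distances import DistanceMatrix

EXACT_LIMIT = 25


@dataclass
class WilcoxonResult:
    w_plus: float
    w_minus: float
    n: int  # non-zero paired differences
    n_zeros: int
    p_value: float
    method: str  # "exact" | "normal-approximation"
    direction: str  # "greater" | "less" | "equal"  (first vs second vector)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def pair_marker_distances(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    labels: Mapping[str, str],
    mode: str = "matched",
):
    """Aligned interspecific-distance vectors for two markers.

    Returns ``(x, y, pairs)`` where ``pairs`` are the (id, id) sample pairs
    (``matched`` mode) or ``None`` placeholders (``sorted`` mode).
    """
    shared = sorted(set(dm_a.sample_ids) & set(dm_b.sample_ids))
    if mode == "matched":
        x, y, pairs = [], [], []
        for ia, a in enumerate(shared):
            for b in shared[ia + 1 :]:
                if labels[a] == labels[b]:
                    continue
                da, ok_a = dm_a.get(a, b)
                db, ok_b = dm_b.get(a, b)
                if ok_a and ok_b:
                    x.append(da)
                    y.append(db)
                    pairs.append((a, b))
        if not pairs:
            raise PairingError("no shared valid interspecific pairs")
        return np.asarray(x), np.asarray(y), pairs
    if mode == "sorted":
        def inter(dm):
            vals = []
            for ia, a in enumerate(shared):
                for b in shared[ia + 1 :]:
                    if labels[a] == labels[b]:
                        continue
                    d, ok = dm.get(a, b)
                    if ok:
                        vals.append(d)
            return sorted(vals)

        va, vb = inter(dm_a), inter(dm_b)
        n = min(len(va), len(vb))
        if n == 0:
            raise PairingError("no shared valid interspecific pairs")
        return np.asarray(va[:n]), np.asarray(vb[:n]), [None] * n
    raise ValueError(f"unknown pairing mode {mode!r}")


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact p by DP over the 2^n equiprobable sign assignments.

    Valid for integer rank vectors (no ties).  counts[s] = number of subsets
    of the ranks summing to s; the null distribution of W+ is counts / 2^n.
    """
    ranks_int = ranks.astype(int)
    total = int(ranks_int.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks_int:
        counts[r:] += counts[: total + 1 - r]
    denom = float(2 ** len(ranks_int))
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum() / denom
    p_ge = counts[w:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    # grouping on midrank values is equivalent to grouping on tied |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_counts = tie_counts.astype(float)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts) / 48.0).sum()
    )
    if var <= 0:
        raise TestError("zero variance: all differences tied")
    z = w_plus - mean
    z -= 0.5 * np.sign(z)  # continuity correction
    z /= np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    x, y, method: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of paired vectors ``x`` vs ``y``.

    ``method`` is ``auto`` (exact when n <= 25 and |d| are tie-free, else
    normal approximation), ``exact`` or ``approx``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise TestError("paired vectors must have equal length")
    d = x - y
    nonzero = d != 0.0
    n_zeros = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        raise TestError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n

    if method == "auto":
        use_exact = n <= EXACT_LIMIT and not has_ties
    elif method == "exact":
        if has_ties:
            raise TestError("exact method requires tie-free |differences|")
        use_exact = True
    elif method == "approx":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if use_exact:
        p = _exact_two_sided_p(ranks, w_plus)
        used = "exact"
    else:
        p = _approx_two_sided_p(ranks, w_plus)
        used = "normal-approximation"

    if w_plus > w_minus:
        direction = "greater"
    elif w_plus < w_minus:
        direction = "less"
    else:
        direction = "equal"
    return WilcoxonResult(
        w_plus=w_plus,
        w_minus=w_minus,
        n=n,
        n_zeros=n_zeros,
        p_value=p,
        method=used,
        direction=direction,
    )


def compare_markers(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    labels: Mapping[str, str],
    name_a: str,
    name_b: str,
    mode: str = "matched",
) -> dict:
    """Convenience wrapper: pairing + test + verdict string."""
    x, y, _ = pair_marker_distances(dm_a, dm_b, labels, mode=mode)
    res = wilcoxon_signed_rank(x, y)
    if res.direction == "greater":
        verdict = f"{name_a} > {name_b}"
    elif res.direction == "less":
        verdict = f"{name_a} < {name_b}"
    else:
        verdict = f"{name_a} = {name_b}"
    return {
        "marker_a": name_a,
        "marker_b": name_b,
        "w_plus": res.w_plus,
        "w_minus": res.w_minus,
        "n": res.n,
        "n_zeros": res.n_zeros,
        "p_value": res.p_value,
        "method": res.method,
        "pairing": mode,
        "verdict": verdict,
    }
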