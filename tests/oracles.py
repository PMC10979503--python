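"""Independent oracles used by the spectral tests.

The exhaustive matcher enumerates every one-to-one assignment over the
direct/shifted candidate pairs (feasible for spectra of <= ~8 peaks) and is
deliberately independent of the greedy implementation it checks.
"""

from __future__ import annotations

import math


def exhaustive_modified_cosine(a, b, tol: float):
    """Maximum-weight one-to-one assignment score and the number of optimal
    assignments (for uniqueness checks)."""
    shift = a.precursor_mz - b.precursor_mz
    pa, pb = list(a.peaks), list(b.peaks)
    compat = [
        [j for j, q in enumerate(pb)
         if abs(p.mz - q.mz) <= tol or abs((p.mz - q.mz) - shift) <= tol]
        for p in pa
    ]
    best = {"total": 0.0, "count": 1, "pairs": 0}

    def rec(i: int, used: frozenset, total: float, n_pairs: int) -> None:
        if i == len(pa):
            if total > best["total"] + 1e-15:
                best.update(total=total, count=1, pairs=n_pairs)
            elif abs(total - best["total"]) <= 1e-15 and total > 0:
                best["count"] += 1
            return
        rec(i + 1, used, total, n_pairs)
        for j in compat[i]:
            if j not in used:
                rec(i + 1, used | {j}, total + pa[i].intensity * pb[j].intensity,
                    n_pairs + 1)

    rec(0, frozenset(), 0.0, 0)
    norm = (math.sqrt(sum(p.intensity ** 2 for p in pa))
            * math.sqrt(sum(p.intensity ** 2 for p in pb)))
    score = best["total"] / norm if norm else 0.0
    return min(score, 1.0), best["count"], best["pairs"]
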