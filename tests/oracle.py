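"""Independent brute-force reference implementation of the score updates.

Pure-dict arithmetic, written separately from the array-based production
code so the two can be compared on small instances.
"""

from __future__ import annotations


def brute_init(bitscores: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    totals: dict[str, float] = {}
    for (q, _s), b in bitscores.items():
        totals[q] = totals.get(q, 0.0) + b
    return {(q, s): b / totals[q] for (q, s), b in bitscores.items()}


def brute_reweight(scores: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    weights: dict[str, float] = {}
    for (_q, s), v in scores.items():
        weights[s] = weights.get(s, 0.0) + v
    raw = {(q, s): v * weights[s] for (q, s), v in scores.items()}
    totals: dict[str, float] = {}
    for (q, _s), v in raw.items():
        totals[q] = totals.get(q, 0.0) + v
    return {(q, s): v / totals[q] for (q, s), v in raw.items()}


def brute_prune(
    scores: dict[tuple[str, str], float], ratio: float
) -> tuple[dict[tuple[str, str], float], int]:
    maxima: dict[str, float] = {}
    for (q, _s), v in scores.items():
        maxima[q] = max(maxima.get(q, 0.0), v)
    kept = {
        (q, s): v for (q, s), v in scores.items() if v >= ratio * maxima[q]
    }
    n_pruned = len(scores) - len(kept)
    totals: dict[str, float] = {}
    for (q, _s), v in kept.items():
        totals[q] = totals.get(q, 0.0) + v
    return {(q, s): v / totals[q] for (q, s), v in kept.items()}, n_pruned


def brute_iterate(
    bitscores: dict[tuple[str, str], float],
    ratio: float = 0.5,
    max_iterations: int = 10,
) -> list[dict[tuple[str, str], float]]:
    """Score trajectory: [initial, after iter 1, after iter 2, ...]."""
    scores = brute_init(bitscores)
    trajectory = [scores]
    for _ in range(max_iterations):
        scores = brute_reweight(scores)
        scores, n_pruned = brute_prune(scores, ratio)
        trajectory.append(scores)
        if n_pruned == 0:
            break
    return trajectory
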