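"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (exhaustive enumeration, O(n^3)
re-averaging) and shares no code with the package's implementations.
"""

from __future__ import annotations

import math

import numpy as np

from confeax.sequence_io import AMINO_ACIDS, LETTER_INDEX


def enumerate_paths(hmm, seq: str) -> tuple[float, float]:
    """Brute-force (viterbi_bits, forward_bits) by enumerating every legal
    local path: enter at any match state (prob 1/L), traverse match /
    insert / delete states, exit from any match state (prob 1/L).  Match
    emissions contribute e/bg odds, inserts contribute 1, deletes are silent.
    """
    codes = [LETTER_INDEX[c] for c in seq]
    L = hmm.length
    n = len(codes)
    odds = hmm.match_emissions / hmm.background[None, :]
    weights: list[float] = []

    def rec(state: str, j: int, i: int, w: float) -> None:
        if state == "M":
            weights.append(w / L)  # exit here
        if state == "M" and j < L - 1:
            if i < n:
                rec("M", j + 1, i + 1, w * hmm.t_mm[j] * odds[j + 1, codes[i]])
                rec("I", j, i + 1, w * hmm.t_mi[j])
            rec("D", j + 1, i, w * hmm.t_md[j])
        elif state == "I":
            if i < n:
                rec("M", j + 1, i + 1, w * hmm.t_im[j] * odds[j + 1, codes[i]])
                rec("I", j, i + 1, w * hmm.t_ii[j])
        elif state == "D" and j < L - 1:
            if i < n:
                rec("M", j + 1, i + 1, w * hmm.t_dm[j] * odds[j + 1, codes[i]])
            rec("D", j + 1, i, w * hmm.t_dd[j])

    for start in range(n):
        for k in range(L):
            rec("M", k, start + 1, odds[k, codes[start]] / L)
    return math.log2(max(weights)), math.log2(sum(weights))


def naive_upgma(d: np.ndarray, labels: list[str]
                ) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
    """Reference average-linkage agglomerator.

    Recomputes every inter-cluster average from the original matrix at each
    step (no Lance-Williams update).  Same tie-break contract as the
    implementation: lexicographically smallest sorted member tuple.
    Heights are average distance / 2.
    """
    d = np.asarray(d, dtype=float)
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pairs = [d[idx[x], idx[y]] for x in clusters[a]
                         for y in clusters[b]]
                avg = sum(pairs) / len(pairs)
                key = (avg, tuple(sorted(clusters[a] + clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (avg, _), a, b = best
        merges.append((clusters[a], clusters[b], avg / 2.0))
        merged = tuple(sorted(clusters[a] + clusters[b]))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def random_profile_hmm(L: int, rng: np.random.Generator):
    """A random valid model for oracle comparisons."""
    from confeax.profile_hmm import ProfileHMM

    bg = np.ones(21) / 21.0
    em = np.zeros((L, 21))
    em[:, :20] = rng.dirichlet(np.ones(20), size=L) * (1 - bg[20])
    em[:, 20] = bg[20]
    t3 = rng.dirichlet(np.ones(3), size=L - 1)
    ti = rng.dirichlet(np.ones(2), size=L - 1)
    td = rng.dirichlet(np.ones(2), size=L - 1)
    return ProfileHMM(match_emissions=em, background=bg,
                      t_mm=t3[:, 0], t_mi=t3[:, 1], t_md=t3[:, 2],
                      t_im=ti[:, 0], t_ii=ti[:, 1],
                      t_dm=td[:, 0], t_dd=td[:, 1])


def random_sequence(rng: np.random.Generator, length: int,
                    alphabet: str = "ACDE") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def brute_force_pwm_score(pwm, window: str) -> float:
    """Per-column log-odds sum by explicit loop; X contributes 0."""
    total = 0.0
    for j, ch in enumerate(window):
        a = LETTER_INDEX[ch]
        if ch == "X":
            continue
        total += math.log2(pwm.probs[j, a] / pwm.background[a])
    return total
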