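"""Profile hidden Markov models: build from instance alignments, score by
Viterbi/forward in bits, calibrate empirical E-values, search a family, and
iterate align -> model -> search to convergence.

Model class and scoring contract
--------------------------------
A model of length L has match states M_1..M_L with 21-letter emission rows,
insert states I_1..I_{L-1} emitting background (so inserts score 0 bits),
and silent delete states D_1..D_L.  Core transitions {M->M, M->I, M->D,
I->M, I->I, D->M, D->D} are estimated per node with Henikoff position-based
sequence weights and Laplace +1 pseudocounts; every state's outgoing
distribution sums to 1.

Search is local (Smith-Waterman style): a scoring path enters at any match
state with uniform probability 1/L, traverses core states, and exits from
any match state with probability 1/L.  Unaligned flanking residues emit
background in both the model and the null, so they cancel; the score of a
path is its log2 odds ratio (emission log-odds of match residues, zero for
inserts, plus log2 of the entry, core-transition and exit probabilities).
Viterbi reports the best path, forward the log-sum over all paths, so
forward >= viterbi always.

E-values come from an empirical Gumbel fit to Viterbi scores of
composition-matched random sequences: E(S) = n_targets * exp(-lambda (S -
mu)), clipped to [0, n_targets].
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy import stats

from .alignment_refinement import (
    InstanceAlignment,
    align_instances,
    extend_hits,
    instances_from_hits,
)
from .motif_discovery import MotifModel
from .sequence_io import (
    ALPHABET,
    N_LETTERS,
    X_INDEX,
    FeatureHit,
    SequenceRecord,
    background_frequencies,
)

logger = logging.getLogger("confeax")

LN2 = math.log(2.0)

MATCH_THRESHOLD = 0.5     # column occupancy for match-state assignment
N_CALIBRATE = 200
# Permissive search thresholds.  One expected false hit per family round trip
# keeps marginal true instances in the training alignment without flooding it
# with background windows (which dilutes match emissions and suppresses the
# weak sites the iteration exists to recover).
ITER_EVALUE = 1.0
FINAL_EVALUE = 1.0
MAX_ITER = 20
JACCARD_NEAR = 0.99


@dataclass
class ProfileHMM:
    """Profile HMM over the 21-letter alphabet; see module docstring."""

    match_emissions: np.ndarray   # (L, 21)
    background: np.ndarray        # (21,)
    t_mm: np.ndarray              # (L-1,) node j -> j+1 transitions
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    calibration: tuple[float, float] | None = None  # (mu, lambda)
    feature_id: str = "feature"

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.length < 2:
            raise ValueError("profile HMM needs at least 2 match states")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        for name, row_sum in (
            ("match", self.t_mm + self.t_mi + self.t_md),
            ("insert", self.t_im + self.t_ii),
            ("delete", self.t_dm + self.t_dd),
        ):
            if not np.allclose(row_sum, 1.0, atol=1e-9):
                raise ValueError(f"{name}-state transitions must sum to 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def match_log_odds(self) -> np.ndarray:
        lo = np.log2(self.match_emissions / self.background[None, :])
        lo[:, X_INDEX] = 0.0
        return lo

    def to_json(self) -> str:
        obj = {
            "schema": "confeax-hmm-1",
            "feature_id": self.feature_id,
            "alphabet": ALPHABET,
            "length": self.length,
            "match_emissions": [[repr(float(v)) for v in row]
                                for row in self.match_emissions],
            "background": [repr(float(v)) for v in self.background],
            "transitions": {name: [repr(float(v)) for v in getattr(self, name)]
                            for name in ("t_mm", "t_mi", "t_md", "t_im",
                                          "t_ii", "t_dm", "t_dd")},
            "calibration": (None if self.calibration is None
                            else [repr(float(self.calibration[0])),
                                  repr(float(self.calibration[1]))]),
        }
        return json.dumps(obj, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        obj = json.loads(text)
        t = {k: np.array([float(v) for v in vs])
             for k, vs in obj["transitions"].items()}
        calib = obj.get("calibration")
        return cls(
            match_emissions=np.array([[float(v) for v in row]
                                      for row in obj["match_emissions"]]),
            background=np.array([float(v) for v in obj["background"]]),
            calibration=None if calib is None else (float(calib[0]),
                                                    float(calib[1])),
            feature_id=obj.get("feature_id", "feature"), **t)

    def save(self, dest: str | Path) -> None:
        Path(dest).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, source: str | Path) -> "ProfileHMM":
        return cls.from_json(Path(source).read_text())


@dataclass
class ConvergenceRecord:
    iteration: int
    jaccard: float
    n_hits: int
    converged: bool


# --- model construction ------------------------------------------------------

def henikoff_weights(strings: list[str]) -> np.ndarray:
    """Position-based sequence weights, normalized to mean 1.

    Each column distributes weight 1/(r*s) to every sequence, where r is the
    number of distinct residues in the column and s the multiplicity of that
    sequence's residue; gap cells contribute nothing.
    """
    n = len(strings)
    w = np.zeros(n)
    n_cols = len(strings[0])
    for j in range(n_cols):
        col = [s[j] for s in strings]
        residues = [c for c in col if c != "-"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c != "-":
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def build_hmm(aln: InstanceAlignment,
              background: np.ndarray | None = None,
              match_threshold: float = MATCH_THRESHOLD,
              feature_id: str | None = None) -> ProfileHMM:
    """Build a profile HMM from an instance alignment.

    Columns with occupancy >= match_threshold become match states; the rest
    become insert columns attached to the preceding match node.  Emissions
    and transitions use Henikoff weights and Laplace +1 pseudocounts.
    """
    from .sequence_io import LETTER_INDEX

    if aln.n_rows < 2:
        raise ValueError("need at least 2 alignment rows")
    strings = aln.aligned_strings()
    n_rows, n_cols = len(strings), aln.n_cols
    occupancy = np.array([
        sum(1 for s in strings if s[j] != "-") / n_rows for j in range(n_cols)])
    match_cols = [j for j in range(n_cols)
                  if occupancy[j] >= match_threshold - 1e-12]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no columns reach the match-state occupancy threshold")
    if L < 2:
        raise ValueError("profile HMM needs at least 2 match states")
    if background is None:
        # uniform over the canonical residues: deriving the null from the
        # instances themselves would assign near-zero background to letters
        # the motif lacks, making every such letter score positive
        background = np.full(N_LETTERS, 1.0 / 20.0)
        background[X_INDEX] = 1e-6
        background = background / background.sum()
    weights = henikoff_weights(strings)

    em_counts = np.zeros((L, X_INDEX))
    # transition counts per source node (0-based node index j = M_{j+1})
    c_mm = np.zeros(L - 1); c_mi = np.zeros(L - 1); c_md = np.zeros(L - 1)
    c_im = np.zeros(L - 1); c_ii = np.zeros(L - 1)
    c_dm = np.zeros(L - 1); c_dd = np.zeros(L - 1)
    match_set = set(match_cols)
    for i, s in enumerate(strings):
        w = weights[i]
        # row state path over nodes
        events: list[tuple[str, int]] = []  # (state, node index 0-based)
        node = -1
        for j in range(n_cols):
            if j in match_set:
                node += 1
                events.append(("M" if s[j] != "-" else "D", node))
                if s[j] != "-":
                    a = LETTER_INDEX[s[j]]
                    if a != X_INDEX:
                        em_counts[node, a] += w
            else:
                if s[j] != "-" and 0 <= node < L - 1:
                    events.append(("I", node))
        prev = None
        for ev in events:
            if prev is not None:
                (s1, n1), (s2, n2) = prev, ev
                if s1 == "M" and n1 < L - 1:
                    if s2 == "M":
                        c_mm[n1] += w
                    elif s2 == "I":
                        c_mi[n1] += w
                    else:
                        c_md[n1] += w
                elif s1 == "I":
                    if s2 == "I":
                        c_ii[n1] += w
                    else:  # M or D->? inserts return to next match or delete
                        c_im[n1] += w
                elif s1 == "D" and n1 < L - 1:
                    if s2 == "M":
                        c_dm[n1] += w
                    elif s2 == "D":
                        c_dd[n1] += w
                    elif s2 == "I":
                        c_dm[n1] += w  # rare D->I collapsed into D->M route
            prev = ev

    bg_x = background[X_INDEX]
    em = np.empty((L, N_LETTERS))
    c = em_counts + 1.0  # Laplace
    em[:, :X_INDEX] = c / c.sum(axis=1, keepdims=True) * (1.0 - bg_x)
    em[:, X_INDEX] = bg_x

    def _norm(*rows):
        total = sum(r + 1.0 for r in rows)
        return tuple((r + 1.0) / total for r in rows)

    t_mm, t_mi, t_md = _norm(c_mm, c_mi, c_md)
    t_im, t_ii = _norm(c_im, c_ii)
    t_dm, t_dd = _norm(c_dm, c_dd)
    return ProfileHMM(match_emissions=em, background=np.asarray(background),
                      t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
                      t_dm=t_dm, t_dd=t_dd,
                      feature_id=feature_id or aln.feature_id)


# --- DP kernels --------------------------------------------------------------

@njit(cache=True)
def _viterbi_kernel(lm, a_mm, a_mi, a_md, a_im, a_ii, a_dm, a_dd, entry, exit_):
    n, L = lm.shape
    NEG = -1e30
    vm = np.full((n + 1, L), NEG)
    vi = np.full((n + 1, L), NEG)
    vd = np.full((n + 1, L), NEG)
    pm = np.zeros((n + 1, L), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    pi = np.zeros((n + 1, L), dtype=np.int8)
    pd_ = np.zeros((n + 1, L), dtype=np.int8)
    best = NEG
    best_i = -1
    best_j = -1
    for i in range(1, n + 1):
        for j in range(L):
            # match
            cand = entry
            ptr = 0
            if j > 0:
                v = vm[i - 1, j - 1] + a_mm[j - 1]
                if v > cand:
                    cand = v; ptr = 1
                v = vi[i - 1, j - 1] + a_im[j - 1]
                if v > cand:
                    cand = v; ptr = 2
                v = vd[i - 1, j - 1] + a_dm[j - 1]
                if v > cand:
                    cand = v; ptr = 3
            vm[i, j] = cand + lm[i - 1, j]
            pm[i, j] = ptr
            # insert (exists for nodes 0..L-2)
            if j < L - 1:
                v1 = vm[i - 1, j] + a_mi[j]
                v2 = vi[i - 1, j] + a_ii[j]
                if v1 >= v2:
                    vi[i, j] = v1; pi[i, j] = 1
                else:
                    vi[i, j] = v2; pi[i, j] = 2
            # delete
            if j > 0:
                v1 = vm[i, j - 1] + a_md[j - 1]
                v2 = vd[i, j - 1] + a_dd[j - 1]
                if v1 >= v2:
                    vd[i, j] = v1; pd_[i, j] = 1
                else:
                    vd[i, j] = v2; pd_[i, j] = 3
            sc = vm[i, j] + exit_
            if sc > best:
                best = sc; best_i = i; best_j = j
    return best, best_i, best_j, pm, pi, pd_


@njit(cache=True)
def _forward_kernel(lm, a_mm, a_mi, a_md, a_im, a_ii, a_dm, a_dd, entry, exit_):
    n, L = lm.shape
    NEG = -1e30
    fm = np.full((n + 1, L), NEG)
    fi = np.full((n + 1, L), NEG)
    fd = np.full((n + 1, L), NEG)
    total = NEG
    for i in range(1, n + 1):
        for j in range(L):
            acc = entry
            if j > 0:
                acc = np.logaddexp(acc, fm[i - 1, j - 1] + a_mm[j - 1])
                acc = np.logaddexp(acc, fi[i - 1, j - 1] + a_im[j - 1])
                acc = np.logaddexp(acc, fd[i - 1, j - 1] + a_dm[j - 1])
            fm[i, j] = acc + lm[i - 1, j]
            if j < L - 1:
                fi[i, j] = np.logaddexp(fm[i - 1, j] + a_mi[j],
                                        fi[i - 1, j] + a_ii[j])
            if j > 0:
                fd[i, j] = np.logaddexp(fm[i, j - 1] + a_md[j - 1],
                                        fd[i, j - 1] + a_dd[j - 1])
            total = np.logaddexp(total, fm[i, j] + exit_)
    return total


def _log_arrays(hmm: ProfileHMM, base: str) -> tuple:
    """Transition log arrays in bits ('2') or nats ('e')."""
    log = np.log2 if base == "2" else np.log
    return tuple(log(getattr(hmm, name))
                 for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii",
                              "t_dm", "t_dd"))


def _match_lo(hmm: ProfileHMM, codes: np.ndarray, base: str) -> np.ndarray:
    lo = hmm.match_log_odds()  # bits
    if base == "e":
        lo = lo * LN2
    return lo.T[codes]  # (n, L): row i = log-odds of residue i at each node


def viterbi(hmm: ProfileHMM, seq: str | SequenceRecord
            ) -> tuple[float, list[tuple[int, int, str]]]:
    """Best local-alignment log-odds score (bits) and its aligned path.

    The path is a list of (residue_index, model_node, state) triples with
    state in {'M','I'}; delete states are silent and omitted.
    """
    record = seq if isinstance(seq, SequenceRecord) else \
        SequenceRecord(id="query", residues=seq)
    if len(record.residues) == 0:
        raise ValueError("empty sequence")
    codes = record.encoded().astype(np.int64)
    L = hmm.length
    lm = _match_lo(hmm, codes, "2")
    trans = _log_arrays(hmm, "2")
    entry = math.log2(1.0 / L)
    exit_ = math.log2(1.0 / L)
    score, ei, ej, pm, pi, pd_ = _viterbi_kernel(lm, *trans, entry, exit_)
    # traceback from (ei, ej) in state M
    path: list[tuple[int, int, str]] = []
    i, j, state = ei, ej, "M"
    while True:
        if state == "M":
            path.append((i - 1, j, "M"))
            ptr = pm[i, j]
            if ptr == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(ptr)]
            i, j = i - 1, j - 1
        elif state == "I":
            path.append((i - 1, j, "I"))
            state = "M" if pi[i, j] == 1 else "I"
            i = i - 1
        else:  # D, silent
            state = "M" if pd_[i, j] == 1 else "D"
            j = j - 1
    path.reverse()
    return float(score), path


def forward(hmm: ProfileHMM, seq: str | SequenceRecord) -> float:
    """Log-sum score (bits) over all local alignment paths."""
    record = seq if isinstance(seq, SequenceRecord) else \
        SequenceRecord(id="query", residues=seq)
    if len(record.residues) == 0:
        raise ValueError("empty sequence")
    codes = record.encoded().astype(np.int64)
    L = hmm.length
    lm = _match_lo(hmm, codes, "e")
    trans = _log_arrays(hmm, "e")
    entry = math.log(1.0 / L)
    total = _forward_kernel(lm, *trans, entry, entry)
    return float(total / LN2)


# --- calibration and search --------------------------------------------------

def calibrate(hmm: ProfileHMM, n_random: int = N_CALIBRATE,
              len_dist: list[int] | int = 400,
              seed: int = 0) -> tuple[float, float]:
    """Fit a Gumbel (mu, lambda) to Viterbi scores of random sequences.

    Sequences are drawn i.i.d. from the model's background composition with
    lengths sampled from *len_dist* (an int for a fixed length, or a list to
    resample from).  Maximum-likelihood fit via scipy's gumbel_r.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    rng = np.random.default_rng(seed)
    bg20 = hmm.background[:X_INDEX] / hmm.background[:X_INDEX].sum()
    lengths = [len_dist] * n_random if isinstance(len_dist, int) else \
        list(rng.choice(len_dist, size=n_random, replace=True))
    scores = np.empty(n_random)
    from .sequence_io import AMINO_ACIDS
    for k in range(n_random):
        codes = rng.choice(X_INDEX, size=int(lengths[k]), p=bg20)
        seq = "".join(AMINO_ACIDS[c] for c in codes)
        scores[k], _ = viterbi(hmm, seq)
    if np.std(scores) < 1e-9:
        raise ValueError("degenerate score variance during calibration")
    loc, scale = stats.gumbel_r.fit(scores)
    mu, lam = float(loc), float(1.0 / scale)
    hmm.calibration = (mu, lam)
    return mu, lam


def evalue(hmm: ProfileHMM, score_bits: float, n_targets: int) -> float:
    """Expected number of false hits at this score among n_targets sequences."""
    if hmm.calibration is None:
        raise ValueError("model is not calibrated")
    mu, lam = hmm.calibration
    e = n_targets * math.exp(-lam * (score_bits - mu))
    return float(min(max(e, 0.0), n_targets))


def _best_hit_recursive(hmm: ProfileHMM, record: SequenceRecord, lo: int,
                        hi: int, accept, out: list[FeatureHit],
                        iteration: int, n_targets: int) -> None:
    if hi - lo < 1:
        return
    segment = record.residues[lo:hi]
    score, path = viterbi(hmm, segment)
    emitting = [i for i, _, st in path if st in ("M", "I")]
    start, end = lo + emitting[0], lo + emitting[-1] + 1
    ev = evalue(hmm, score, n_targets) if hmm.calibration else float("nan")
    if not accept(score, ev):
        return
    out.append(FeatureHit(feature_id=hmm.feature_id, seq_id=record.id,
                          start=start, end=end, score_bits=score,
                          evalue=ev, iteration=iteration))
    _best_hit_recursive(hmm, record, lo, start, accept, out, iteration,
                        n_targets)
    _best_hit_recursive(hmm, record, end, hi, accept, out, iteration,
                        n_targets)


def search(hmm: ProfileHMM, seqs: list[SequenceRecord],
           threshold_evalue: float | None = None,
           threshold_bits: float | None = None,
           iteration: int = 0) -> list[FeatureHit]:
    """All non-overlapping local hits above threshold, best-hit-then-mask.

    Exactly one of the two thresholds must be given; an E-value threshold
    requires a calibrated model.
    """
    if (threshold_evalue is None) == (threshold_bits is None):
        raise ValueError("give exactly one of threshold_evalue/threshold_bits")
    if threshold_evalue is not None and hmm.calibration is None:
        raise ValueError("E-value threshold requires a calibrated model")

    def accept(score: float, ev: float) -> bool:
        if threshold_evalue is not None:
            return ev <= threshold_evalue
        return score >= threshold_bits

    hits: list[FeatureHit] = []
    for rec in seqs:
        per_seq: list[FeatureHit] = []
        _best_hit_recursive(hmm, rec, 0, len(rec.residues), accept, per_seq,
                            iteration, len(seqs))
        per_seq.sort(key=lambda h: h.start)
        hits.extend(per_seq)
    return hits


# --- the ConFeaX iteration ---------------------------------------------------

def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def confeax_iterate(seed_motif: MotifModel, seqs: list[SequenceRecord],
                    flank: int = 5,
                    iter_evalue: float = ITER_EVALUE,
                    final_evalue: float = FINAL_EVALUE,
                    max_iter: int = MAX_ITER,
                    match_threshold: float = MATCH_THRESHOLD,
                    n_calibrate: int = N_CALIBRATE,
                    extend_each_iteration: bool = False,
                    seed: int = 0
                    ) -> tuple[ProfileHMM, list[FeatureHit],
                               list[ConvergenceRecord]]:
    """Iterate {extend -> align -> model -> calibrate -> search} to convergence.

    Convergence: the hit set (intervals) is identical to the previous
    iteration (Jaccard 1), Jaccard >= 0.99 on two consecutive iterations, or
    the hit set equals one seen on an earlier iteration (the update is a
    deterministic map, so a revisit proves a limit cycle that will never
    settle further); hard cap *max_iter*.  Flank extension is applied to the
    seed hits; re-extending every round would grow the model by two flanks
    per iteration without bound (``extend_each_iteration=True`` restores
    that behaviour).  The returned hits are the converged search output
    filtered at *final_evalue*; the full iteration trace is returned as
    :class:`ConvergenceRecord` objects.  Deterministic given *seed*.
    """
    if len(seed_motif.hits) < 2:
        raise ValueError("seed motif needs at least 2 hits")
    background = background_frequencies(seqs)
    lengths = [len(r.residues) for r in seqs]
    ss = np.random.SeedSequence(seed)
    # one calibration seed for the whole iteration: recalibrating with fresh
    # random sequences every round makes borderline hits flicker in and out
    # of the permissive threshold and stalls convergence
    cal_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    hits = list(seed_motif.hits)
    prev_keys = {(h.seq_id, h.start, h.end) for h in hits}
    seen_sets: set[frozenset] = {frozenset(prev_keys)}
    prev_jaccard = 0.0
    records: list[ConvergenceRecord] = []
    hmm: ProfileHMM | None = None
    for it in range(1, max_iter + 1):
        extended = extend_hits(hits, seqs, flank=flank) if extend_each_iteration \
            or it == 1 else hits
        instances = instances_from_hits(extended, seqs)
        aln = align_instances(instances, feature_id=seed_motif.motif_id)
        hmm = build_hmm(aln, background=background,
                        match_threshold=match_threshold,
                        feature_id=seed_motif.motif_id)
        calibrate(hmm, n_random=n_calibrate, len_dist=lengths, seed=cal_seed)
        hits = search(hmm, seqs, threshold_evalue=iter_evalue, iteration=it)
        if len(hits) < 2:
            raise ValueError("feature lost during iteration")
        keys = {(h.seq_id, h.start, h.end) for h in hits}
        j = _jaccard(keys, prev_keys)
        converged = (j == 1.0
                     or (j >= JACCARD_NEAR and prev_jaccard >= JACCARD_NEAR)
                     or frozenset(keys) in seen_sets)
        records.append(ConvergenceRecord(iteration=it, jaccard=j,
                                         n_hits=len(hits), converged=converged))
        if converged:
            break
        seen_sets.add(frozenset(keys))
        prev_keys, prev_jaccard = keys, j
    final_hits = [h for h in hits if h.evalue <= final_evalue]
    return hmm, final_hits, records
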