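"""De novo gapless motif discovery by expectation-maximization on PWMs.

The site model is "repeats allowed": every window position in every sequence
independently either starts a motif occurrence (probability ``site_prior``)
or is background.  This is the classic two-component mixture over sliding
windows, so any number of occurrences per sequence is possible, including
zero.  EM alternates posterior site probabilities (E) with weighted counts
(M); the observed-data log likelihood of this window mixture is guaranteed
non-decreasing.

Significance of a trained motif is empirical: the fraction of per-sequence
residue-shuffled datasets (composition preserved) on which a same-width EM
refinement reaches a training log-likelihood-ratio at least as large as the
observed one.  Smaller is more significant; a motif is accepted when its
significance is strictly below ``sig_threshold``.

Discovery is iterative with masking: the accepted sites of each reported
motif are masked out before the search for the next one, so training sites
of successive motifs never overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import (
    ALPHABET,
    N_LETTERS,
    X_INDEX,
    FeatureHit,
    SequenceRecord,
    background_frequencies,
    decode,
)

LN2 = math.log(2.0)

# EM defaults (all overridable through function arguments)
PSEUDOCOUNT = 0.01          # per letter per column at estimation
EM_TOL = 1e-6               # |delta loglik| convergence
EM_MAX_ITER = 200
N_REFINE = 50               # seeds refined to convergence
MAX_SEED_CANDIDATES = 1000  # distinct windows screened with one EM step
SIG_THRESHOLD = 0.05        # accept motif iff significance strictly below
N_SHUFFLES = 20
POSTERIOR_THRESHOLD = 0.5   # site acceptance within a motif
# A short feature occupies a small fraction of a multidomain protein, so the
# per-position site prior is capped well below 1/width.  The cap also blocks
# a degenerate EM mode in which the prior inflates until half of all windows
# count as weak "sites" (inflating the summed training LLR on shuffled data),
# and it keeps accepted-site log-odds non-negative.
MAX_SITE_PRIOR = 0.05


@dataclass
class PositionWeightMatrix:
    """Column-stochastic motif model over the 21-letter alphabet.

    The ``X`` column always equals the background frequency of ``X`` so that
    ``X`` scores exactly zero bits everywhere; the 20 canonical entries of
    each column share the remaining mass.
    """

    probs: np.ndarray       # (width, 21)
    background: np.ndarray  # (21,)
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not (4 <= self.width <= 30):
            raise ValueError(f"PWM width must be in [4, 30], got {self.width}")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.all(self.probs > 0):
            raise ValueError("PWM entries must be positive")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 21) log2(p/bg); the X column is exactly zero."""
        lo = np.log2(self.probs / self.background[None, :])
        lo[:, X_INDEX] = 0.0
        return lo

    def consensus(self) -> str:
        return decode(np.argmax(self.probs[:, :X_INDEX], axis=1))


@dataclass
class MotifModel:
    """A discovered motif: PWM plus its training-site statistics."""

    motif_id: str
    pwm: PositionWeightMatrix
    site_prior: float
    llr: float                         # total log-odds (bits) of training sites, >= 0
    sig: float = float("nan")          # empirical significance, smaller = stronger
    hits: list[FeatureHit] = field(default_factory=list)

    def to_json(self) -> str:
        obj = {
            "motif_id": self.motif_id,
            "width": self.pwm.width,
            "alphabet": ALPHABET,
            "probs": [[repr(float(v)) for v in row] for row in self.pwm.probs],
            "background": [repr(float(v)) for v in self.pwm.background],
            "pseudocount": self.pwm.pseudocount,
            "site_prior": repr(float(self.site_prior)),
            "llr": repr(float(self.llr)),
            "sig": repr(float(self.sig)),
            "hits": [[h.feature_id, h.seq_id, h.start, h.end,
                      repr(float(h.score_bits)), repr(float(h.evalue)), h.iteration]
                     for h in self.hits],
        }
        return json.dumps(obj, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MotifModel":
        obj = json.loads(text)
        pwm = PositionWeightMatrix(
            probs=np.array([[float(v) for v in row] for row in obj["probs"]]),
            background=np.array([float(v) for v in obj["background"]]),
            pseudocount=obj["pseudocount"],
        )
        hits = [FeatureHit(f, s, int(a), int(b), float(sc), float(ev), int(it))
                for f, s, a, b, sc, ev, it in obj["hits"]]
        return cls(motif_id=obj["motif_id"], pwm=pwm,
                   site_prior=float(obj["site_prior"]),
                   llr=float(obj["llr"]), sig=float(obj["sig"]), hits=hits)


def save_motifs(motifs: list[MotifModel], dest: str | Path) -> None:
    payload = "[\n" + ",\n".join(m.to_json() for m in motifs) + "\n]\n"
    Path(dest).write_text(payload)


def load_motifs(source: str | Path) -> list[MotifModel]:
    arr = json.loads(Path(source).read_text())
    return [MotifModel.from_json(json.dumps(o)) for o in arr]


# --- window dataset ----------------------------------------------------------

@dataclass
class _WindowSet:
    """All width-w windows of a sequence set, as an index matrix."""

    windows: np.ndarray    # (n, w) int codes
    seq_index: np.ndarray  # (n,) which sequence
    positions: np.ndarray  # (n,) start offset within that sequence
    bg_loglik: float       # sum over windows of log P(window | background), nats


def _build_windows(encoded: list[np.ndarray], width: int,
                   background: np.ndarray,
                   masked: list[np.ndarray] | None = None) -> _WindowSet | None:
    rows, seq_idx, pos = [], [], []
    for s, codes in enumerate(encoded):
        n = len(codes) - width + 1
        if n <= 0:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, width)
        keep = np.ones(n, dtype=bool)
        if masked is not None and masked[s].any():
            # a window is unusable if any of its positions is masked
            hit_any = np.convolve(masked[s].astype(int), np.ones(width, int))[width - 1:len(codes)]
            keep = hit_any == 0
        if keep.any():
            rows.append(win[keep])
            seq_idx.append(np.full(keep.sum(), s))
            pos.append(np.nonzero(keep)[0])
    if not rows:
        return None
    windows = np.concatenate(rows).astype(np.int64)
    log_bg = np.log(background)
    bg_ll = float(log_bg[windows].sum())
    return _WindowSet(windows=windows,
                      seq_index=np.concatenate(seq_idx),
                      positions=np.concatenate(pos),
                      bg_loglik=bg_ll)


def _window_log_odds(pwm_probs: np.ndarray, background: np.ndarray,
                     windows: np.ndarray) -> np.ndarray:
    """Per-window log-odds (nats) under pwm vs background; X scores 0."""
    lr = np.log(pwm_probs / background[None, :])
    lr[:, X_INDEX] = 0.0
    s = np.zeros(len(windows))
    for j in range(pwm_probs.shape[0]):
        s += lr[j][windows[:, j]]
    return s


def _make_probs(counts20: np.ndarray, background: np.ndarray,
                pseudocount: float) -> np.ndarray:
    """Column-normalize canonical counts; X column pinned to its background."""
    bg_x = background[X_INDEX]
    c = counts20 + pseudocount
    probs = np.empty((counts20.shape[0], N_LETTERS))
    probs[:, :X_INDEX] = c / c.sum(axis=1, keepdims=True) * (1.0 - bg_x)
    probs[:, X_INDEX] = bg_x
    return probs


def _em_step_arrays(probs: np.ndarray, site_prior: float, ws: _WindowSet,
                    background: np.ndarray, pseudocount: float
                    ) -> tuple[np.ndarray, float, float, np.ndarray]:
    """One EM step on a window set.

    Returns (new probs, new site_prior, objective of the *input* parameters,
    posterior site probabilities of the input parameters).  The objective is
    the window-mixture log likelihood plus the Dirichlet-pseudocount penalty
    the M-step maximizes (MAP-EM), so it is guaranteed non-decreasing across
    successive steps; the clamp on site_prior is a constrained M-step and
    preserves the guarantee.
    """
    s = _window_log_odds(probs, background, ws.windows)
    logit = math.log(site_prior) - math.log1p(-site_prior)
    z = 1.0 / (1.0 + np.exp(-(s + logit)))
    penalty = pseudocount * float(np.log(probs[:, :X_INDEX]).sum())
    loglik = float(np.logaddexp(math.log(site_prior) + s,
                                math.log1p(-site_prior)).sum()
                   + ws.bg_loglik + penalty)
    w = probs.shape[0]
    counts = np.zeros((w, X_INDEX))
    for j in range(w):
        col = np.bincount(ws.windows[:, j], weights=z, minlength=N_LETTERS)
        counts[j] = col[:X_INDEX]  # X observations carry no letter information
    new_probs = _make_probs(counts, background, pseudocount)
    new_prior = float(np.clip(z.mean(), 1e-8, MAX_SITE_PRIOR))
    return new_probs, new_prior, loglik, z


def em_step(pwm: PositionWeightMatrix, site_prior: float,
            seqs: list[SequenceRecord]
            ) -> tuple[PositionWeightMatrix, float, float]:
    """One public EM step over a sequence set.

    The returned objective (window-mixture log likelihood plus the
    pseudocount penalty, evaluated at the input parameters) is non-decreasing
    across successive calls — the MAP-EM guarantee.
    """
    encoded = [s.encoded() for s in seqs]
    ws = _build_windows(encoded, pwm.width, pwm.background)
    if ws is None:
        raise ValueError("all sequences shorter than motif width")
    probs, prior, ll, _ = _em_step_arrays(pwm.probs, site_prior, ws,
                                          pwm.background, pwm.pseudocount)
    return (PositionWeightMatrix(probs, pwm.background, pwm.pseudocount),
            prior, ll)


def _refine(probs: np.ndarray, site_prior: float, ws: _WindowSet,
            background: np.ndarray, pseudocount: float,
            tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
            ) -> tuple[np.ndarray, float, float, np.ndarray]:
    """EM to convergence; returns (probs, prior, final loglik, posteriors)."""
    prev_ll = -np.inf
    for _ in range(max_iter):
        new_probs, new_prior, ll, z = _em_step_arrays(
            probs, site_prior, ws, background, pseudocount)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            return probs, site_prior, ll, z
        probs, site_prior, prev_ll = new_probs, new_prior, ll
    # final evaluation at the last parameters
    _, _, ll, z = _em_step_arrays(probs, site_prior, ws, background, pseudocount)
    return probs, site_prior, ll, z


def _greedy_sites(ws: _WindowSet, z: np.ndarray, s_bits: np.ndarray,
                  width: int, threshold: float = POSTERIOR_THRESHOLD
                  ) -> list[tuple[int, int, float]]:
    """Greedy non-overlapping site selection by descending posterior.

    Returns (seq_index, position, score_bits) triples.  Ties in posterior are
    broken toward the leftmost start.
    """
    cand = np.nonzero(z >= threshold)[0]
    if len(cand) == 0:
        return []
    order = cand[np.lexsort((ws.positions[cand], ws.seq_index[cand], -z[cand]))]
    taken: dict[int, list[tuple[int, int]]] = {}
    out = []
    for i in order:
        s, p = int(ws.seq_index[i]), int(ws.positions[i])
        intervals = taken.setdefault(s, [])
        if any(p < e and p + width > b for b, e in intervals):
            continue
        intervals.append((p, p + width))
        out.append((s, p, float(s_bits[i])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def score_window(pwm: PositionWeightMatrix, window: str) -> float:
    """Log-odds score (bits) of one window; ``X`` contributes exactly 0."""
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}")
    from .sequence_io import LETTER_INDEX
    lo = pwm.log_odds()
    total = 0.0
    for j, ch in enumerate(window.upper()):
        total += lo[j, LETTER_INDEX[ch]]
    return float(total)


# --- discovery ---------------------------------------------------------------

def _seed_probs(window: np.ndarray, background: np.ndarray,
                weight: float = 0.7) -> np.ndarray:
    """Starting PWM from one window: 0.7 on the observed letter, rest uniform."""
    w = len(window)
    bg_x = background[X_INDEX]
    probs = np.full((w, N_LETTERS), (1.0 - weight) / 19.0 * (1.0 - bg_x))
    for j, a in enumerate(window):
        if a == X_INDEX:
            probs[j, :X_INDEX] = (1.0 - bg_x) / 20.0
        else:
            probs[j, a] = weight * (1.0 - bg_x)
    probs[:, X_INDEX] = bg_x
    probs[:, :X_INDEX] *= ((1.0 - bg_x) / probs[:, :X_INDEX].sum(axis=1))[:, None]
    return probs


def _candidate_seeds(ws: _WindowSet, max_candidates: int) -> np.ndarray:
    uniq = np.unique(ws.windows, axis=0)
    if len(uniq) > max_candidates:
        # deterministic even subsample of the sorted distinct windows
        idx = np.linspace(0, len(uniq) - 1, max_candidates).astype(int)
        uniq = uniq[idx]
    return uniq


def _discover_width(ws: _WindowSet, background: np.ndarray, mean_len: float,
                    pseudocount: float = PSEUDOCOUNT,
                    max_candidates: int = MAX_SEED_CANDIDATES,
                    n_refine: int = N_REFINE,
                    max_iter: int = EM_MAX_ITER
                    ) -> tuple[np.ndarray, float, float, np.ndarray] | None:
    """Best EM solution at one width: seed screen, then refinement.

    Returns (probs, site_prior, loglik, posteriors) or None if no windows.
    """
    if ws is None or len(ws.windows) == 0:
        return None
    prior0 = min(1.0 / mean_len, MAX_SITE_PRIOR)
    seeds = _candidate_seeds(ws, max_candidates)
    scores = np.empty(len(seeds))
    stepped = []
    for k, win in enumerate(seeds):
        probs = _seed_probs(win, background)
        new_probs, new_prior, _, _ = _em_step_arrays(
            probs, prior0, ws, background, pseudocount)
        # rank by the loglik of the once-updated parameters
        _, _, ll, _ = _em_step_arrays(new_probs, new_prior, ws, background,
                                      pseudocount)
        scores[k] = ll
        stepped.append((new_probs, new_prior))
    best = None
    for k in np.argsort(-scores)[:n_refine]:
        probs, prior = stepped[int(k)]
        probs, prior, ll, z = _refine(probs, prior, ws, background,
                                      pseudocount, max_iter=max_iter)
        if best is None or ll > best[2]:
            best = (probs, prior, ll, z)
    return best


def _training_llr(ws: _WindowSet, z: np.ndarray, probs: np.ndarray,
                  background: np.ndarray, width: int) -> tuple[float, list]:
    s_nats = _window_log_odds(probs, background, ws.windows)
    sites = _greedy_sites(ws, z, s_nats / LN2, width)
    return sum(b for _, _, b in sites), sites


def _dataset_llr(ws: _WindowSet, probs: np.ndarray, site_prior: float,
                 background: np.ndarray) -> float:
    """Dataset-level log likelihood ratio (nats): mixture vs background-only.

    This is the classic likelihood-ratio statistic for "a motif is present".
    Unlike the summed training-site LLR it charges every claimed occurrence
    the prior's log(1/site_prior) toll, so a diffuse overfit of many weak
    sites cannot out-score one genuinely conserved motif.
    """
    s = _window_log_odds(probs, background, ws.windows)
    return float(np.logaddexp(math.log(site_prior) + s,
                              math.log1p(-site_prior)).sum())


def _shuffle_records(encoded: list[np.ndarray], rng: np.random.Generator
                     ) -> list[np.ndarray]:
    return [rng.permutation(codes) for codes in encoded]


def _null_llr(encoded: list[np.ndarray], width: int, background: np.ndarray,
              mean_len: float, rng: np.random.Generator,
              max_candidates: int, n_refine: int) -> float:
    """Best dataset-level LLR an EM refinement finds on one shuffled dataset."""
    shuffled = _shuffle_records(encoded, rng)
    ws = _build_windows(shuffled, width, background)
    if ws is None:
        return 0.0
    best = _discover_width(ws, background, mean_len,
                           max_candidates=max_candidates, n_refine=n_refine)
    if best is None:
        return 0.0
    probs, prior, _, _ = best
    return _dataset_llr(ws, probs, prior, background)


def motif_significance(motif: MotifModel, seqs: list[SequenceRecord],
                       n_shuffles: int = N_SHUFFLES, seed: int = 0,
                       max_seed_candidates: int = MAX_SEED_CANDIDATES,
                       n_refine: int = N_REFINE) -> float:
    """Empirical significance of a trained motif.

    Fraction of per-sequence-shuffled (composition-preserving) datasets whose
    best same-width EM refinement attains a dataset-level log likelihood
    ratio at least as large as the trained motif's on the real data.  The
    shuffled datasets are searched with exactly the same seeding/refinement
    protocol that produced the motif, so observed and null statistics are
    exchangeable when the data are pure background.  Smaller is more
    significant; deterministic given *seed*.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    encoded = [s.encoded() for s in seqs]
    mean_len = float(np.mean([len(c) for c in encoded]))
    ws = _build_windows(encoded, motif.pwm.width, motif.pwm.background)
    observed = _dataset_llr(ws, motif.pwm.probs, motif.site_prior,
                            motif.pwm.background)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        null = _null_llr(encoded, motif.pwm.width, motif.pwm.background,
                         mean_len, rng, max_seed_candidates, n_refine)
        if null >= observed:
            exceed += 1
    return exceed / n_shuffles


def discover_motifs(seqs: list[SequenceRecord],
                    max_motifs: int = 50,
                    width_range: tuple[int, int] | list[int] = (6, 14),
                    seed: int = 0,
                    sig_threshold: float | None = SIG_THRESHOLD,
                    n_shuffles: int = N_SHUFFLES,
                    uniform_background: bool = False,
                    max_seed_candidates: int = MAX_SEED_CANDIDATES,
                    n_refine: int = N_REFINE) -> list[MotifModel]:
    """Iterative masked motif discovery over a protein family.

    ``width_range`` is either an inclusive (lo, hi) pair or an explicit list
    of widths; for each motif the width with the best (significance, LLR) is
    kept.  Discovery stops at the first non-significant candidate or after
    ``max_motifs`` accepted motifs.  ``sig_threshold=None`` disables the
    empirical significance gate entirely (candidates are accepted by LLR;
    their ``sig`` stays NaN) — useful when a downstream stage does its own
    vetting.  Runs are deterministic given *seed*.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if isinstance(width_range, tuple):
        widths = list(range(width_range[0], width_range[1] + 1))
    else:
        widths = list(width_range)
    if any(w < 4 or w > 30 for w in widths):
        raise ValueError("widths must lie within [4, 30]")
    encoded = [s.encoded() for s in seqs]
    if all(len(c) < min(widths) for c in encoded):
        raise ValueError("all sequences shorter than the minimum motif width")
    background = background_frequencies(seqs, uniform=uniform_background)
    mean_len = float(np.mean([len(c) for c in encoded]))
    masked = [np.zeros(len(c), dtype=bool) for c in encoded]
    ss = np.random.SeedSequence(seed)
    motifs: list[MotifModel] = []
    for m in range(max_motifs):
        candidates = []
        for w in widths:
            ws = _build_windows(encoded, w, background, masked)
            best = _discover_width(ws, background, mean_len,
                                   max_candidates=max_seed_candidates,
                                   n_refine=n_refine)
            if best is None:
                continue
            probs, prior, ll, z = best
            llr, sites = _training_llr(ws, z, probs, background, w)
            if not sites:
                continue
            motif = MotifModel(
                motif_id=f"m{m + 1}",
                pwm=PositionWeightMatrix(probs, background),
                site_prior=prior, llr=llr)
            if sig_threshold is not None:
                sig_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                motif.sig = motif_significance(
                    motif, _masked_records(seqs, masked), n_shuffles=n_shuffles,
                    seed=sig_seed, max_seed_candidates=max_seed_candidates,
                    n_refine=n_refine)
                rank_sig = motif.sig
            else:
                rank_sig = 0.0
            candidates.append((rank_sig, -llr, w, motif, sites))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        sig, _, w, motif, sites = candidates[0]
        if sig_threshold is not None and sig >= sig_threshold:
            break
        motif.hits = [
            FeatureHit(feature_id=motif.motif_id, seq_id=seqs[s].id,
                       start=p, end=p + w, score_bits=bits, iteration=0)
            for s, p, bits in sites]
        for h, (s, p, _) in zip(motif.hits, sites):
            masked[s][p:p + w] = True
        motifs.append(motif)
    return motifs


def _masked_records(seqs: list[SequenceRecord],
                    masked: list[np.ndarray]) -> list[SequenceRecord]:
    """Copies of the records with already-claimed sites replaced by X."""
    out = []
    for rec, m in zip(seqs, masked):
        if m.any():
            res = "".join("X" if f else c for c, f in zip(rec.residues, m))
            out.append(SequenceRecord(id=rec.id, residues=res,
                                      description=rec.description,
                                      paralogue_label=rec.paralogue_label,
                                      clade_label=rec.clade_label))
        else:
            out.append(rec)
    return out
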