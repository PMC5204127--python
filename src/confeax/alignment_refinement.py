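"""Hit extension, progressive alignment of motif instances, column filtering
and sequence-logo matrices.

Motif hits from the gapless EM stage treat alignment information strictly:
a hit covers exactly the motif window.  To recover conserved context lost to
that strictness, each significant hit is extended by a fixed flank (default
5 residues) on both sides before the instances are aligned.  The instance
aligner is progressive: all pairwise global alignments (BLOSUM62, affine
gap open 11 / extend 1) give percent-identity distances, an average-linkage
guide tree orders the merges, and clusters are merged by profile-profile
alignment under the same scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .coevolution import average_linkage_cluster
from .sequence_io import (
    ALPHABET,
    LETTER_INDEX,
    N_LETTERS,
    FeatureHit,
    SequenceRecord,
)

logger = logging.getLogger("confeax")

GAP_OPEN = 11.0
GAP_EXTEND = 1.0
MAX_IC = math.log2(20.0)


def _blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 21x21 array over this package's alphabet order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((N_LETTERS, N_LETTERS))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a, b]
    return out


_B62 = _blosum62()


@dataclass
class InstanceAlignment:
    """Gapped alignment of feature instances.

    Each row records where its instance came from, so ungapping row i must
    reproduce ``residues[start:end]`` of the source sequence exactly.  That
    invariant holds for aligner output; column-filtered alignments (see
    :func:`occupancy_filter`) retain coordinates for provenance only.
    """

    feature_id: str
    rows: list[tuple[str, int, int, str]]  # (seq_id, start, end, aligned)
    n_cols: int

    def __post_init__(self) -> None:
        for seq_id, start, end, aligned in self.rows:
            if len(aligned) != self.n_cols:
                raise ValueError(
                    f"row {seq_id!r} has {len(aligned)} columns, expected {self.n_cols}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def aligned_strings(self) -> list[str]:
        return [aligned for _, _, _, aligned in self.rows]

    def row_names(self) -> list[str]:
        return [f"{seq_id}/{start}-{end}" for seq_id, start, end, _ in self.rows]


def extend_hits(hits: list[FeatureHit], seqs: list[SequenceRecord],
                flank: int = 5) -> list[FeatureHit]:
    """Extend each hit by *flank* residues on both sides, clamped to the sequence."""
    lengths = {rec.id: len(rec.residues) for rec in seqs}
    out = []
    for h in hits:
        if h.seq_id not in lengths:
            raise ValueError(f"hit references unknown sequence {h.seq_id!r}")
        L = lengths[h.seq_id]
        out.append(FeatureHit(
            feature_id=h.feature_id, seq_id=h.seq_id,
            start=max(0, h.start - flank), end=min(L, h.end + flank),
            score_bits=h.score_bits, evalue=h.evalue, iteration=h.iteration))
    return out


def instances_from_hits(hits: list[FeatureHit], seqs: list[SequenceRecord]
                        ) -> list[tuple[str, int, int, str]]:
    by_id = {rec.id: rec for rec in seqs}
    return [(h.seq_id, h.start, h.end, by_id[h.seq_id].residues[h.start:h.end])
            for h in hits]


# --- progressive aligner -----------------------------------------------------

def _pairwise_identity_distance(a: str, b: str, aligner: Align.PairwiseAligner
                                ) -> float:
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    ncols = aln.length
    return 1.0 - (counts.identities / ncols if ncols else 0.0)


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(n_cols, 21) per-column residue frequencies, gaps counted as zero mass."""
    n_rows, n_cols = len(rows), len(rows[0])
    freqs = np.zeros((n_cols, N_LETTERS))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                freqs[j, LETTER_INDEX[ch]] += 1.0
    return freqs / n_rows


def _profile_align(rows_a: list[str], rows_b: list[str]
                   ) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) profile-profile alignment.

    Column pairs score the expected BLOSUM62 substitution under the two
    column frequency profiles; gap costs are the pairwise ones.  Returns the
    two row sets padded with '-' to a common set of merged columns.
    """
    fa, fb = _profile_freqs(rows_a), _profile_freqs(rows_b)
    na, nb = fa.shape[0], fb.shape[0]
    s = fa @ _B62 @ fb.T  # (na, nb) expected column-pair score
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    Ix = np.full((na + 1, nb + 1), NEG)  # gap in B (A column vs '-')
    Iy = np.full((na + 1, nb + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        Ix[i, 0] = -GAP_OPEN - (i - 1) * GAP_EXTEND
    for j in range(1, nb + 1):
        Iy[0, j] = -GAP_OPEN - (j - 1) * GAP_EXTEND
    ptr_m = np.zeros((na + 1, nb + 1), dtype=np.int8)
    ptr_x = np.zeros((na + 1, nb + 1), dtype=np.int8)
    ptr_y = np.zeros((na + 1, nb + 1), dtype=np.int8)
    ptr_x[2:, 0] = 1  # border gap runs continue as extensions
    ptr_y[0, 2:] = 1
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            opts = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + s[i - 1, j - 1]
            ptr_m[i, j] = k
            ox = (M[i - 1, j] - GAP_OPEN, Ix[i - 1, j] - GAP_EXTEND)
            kx = int(np.argmax(ox))
            Ix[i, j] = ox[kx]
            ptr_x[i, j] = kx
            oy = (M[i, j - 1] - GAP_OPEN, Iy[i, j - 1] - GAP_EXTEND)
            ky = int(np.argmax(oy))
            Iy[i, j] = oy[ky]
            ptr_y[i, j] = ky
    # also allow leading-gap-only paths ending in M at borders
    end_scores = (M[na, nb], Ix[na, nb], Iy[na, nb])
    state = int(np.argmax(end_scores))
    i, j = na, nb
    ops: list[str] = []  # 'M', 'X' (A col vs gap), 'Y' (gap vs B col)
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:  # only possible at origin
                break
            ops.append("M")
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("X")
            prev = int(ptr_x[i, j])
            state = 0 if prev == 0 else 1
            i -= 1
        else:
            ops.append("Y")
            prev = int(ptr_y[i, j])
            state = 0 if prev == 0 else 2
            j -= 1
    ops.reverse()
    out_a, out_b = [], []
    for row in rows_a:
        it = iter(row)
        out_a.append("".join(next(it) if op in ("M", "X") else "-" for op in ops))
    for row in rows_b:
        it = iter(row)
        out_b.append("".join(next(it) if op in ("M", "Y") else "-" for op in ops))
    return out_a, out_b


def align_instances(instances: list[tuple[str, int, int, str]] | list[str],
                    feature_id: str = "feature") -> InstanceAlignment:
    """Progressively align extended instance strings.

    *instances* is either a list of raw residue strings or of
    (seq_id, start, end, residues) tuples.  A single instance is returned
    trivially ungapped (with a warning).
    """
    if instances and isinstance(instances[0], str):
        instances = [(f"inst{i + 1}", 0, len(s), s)
                     for i, s in enumerate(instances)]
    if not instances:
        raise ValueError("no instances to align")
    if len(instances) == 1:
        logger.warning("single instance for %s; alignment is trivial", feature_id)
        seq_id, start, end, res = instances[0]
        return InstanceAlignment(feature_id=feature_id,
                                 rows=[(seq_id, start, end, res)],
                                 n_cols=len(res))
    strings = [res for _, _, _, res in instances]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    n = len(strings)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _pairwise_identity_distance(
                strings[i], strings[j], aligner)
    labels = [str(i) for i in range(n)]
    dendro = average_linkage_cluster(dist, labels)
    # progressive merge following the guide-tree merge order
    clusters: dict[frozenset, tuple[list[int], list[str]]] = {
        frozenset([lab]): ([int(lab)], [strings[int(lab)]]) for lab in labels}
    for mem_a, mem_b, _ in dendro.merges:
        sa, sb = frozenset(mem_a), frozenset(mem_b)
        ids_a, rows_a = clusters.pop(sa)
        ids_b, rows_b = clusters.pop(sb)
        new_a, new_b = _profile_align(rows_a, rows_b)
        clusters[sa | sb] = (ids_a + ids_b, new_a + new_b)
    ids, rows = next(iter(clusters.values()))
    ordered = sorted(zip(ids, rows))
    out_rows = []
    for idx, aligned in ordered:
        seq_id, start, end, res = instances[idx]
        if aligned.replace("-", "") != res:
            raise AssertionError("aligned row does not ungap to its source")
        out_rows.append((seq_id, start, end, aligned))
    return InstanceAlignment(feature_id=feature_id, rows=out_rows,
                             n_cols=len(out_rows[0][3]))


def occupancy_filter(aln: InstanceAlignment,
                     min_occupancy: float = 0.8) -> InstanceAlignment:
    """Keep columns whose non-gap fraction is >= min_occupancy (inclusive)."""
    if not (0.0 < min_occupancy <= 1.0):
        raise ValueError("min_occupancy must be in (0, 1]")
    strings = aln.aligned_strings()
    n_rows = len(strings)
    keep = []
    for j in range(aln.n_cols):
        non_gap = sum(1 for row in strings if row[j] != "-")
        if non_gap / n_rows >= min_occupancy - 1e-12:
            keep.append(j)
    if not keep:
        raise ValueError("no columns survive occupancy filter")
    rows = [(sid, s, e, "".join(aligned[j] for j in keep))
            for sid, s, e, aligned in aln.rows]
    return InstanceAlignment(feature_id=aln.feature_id, rows=rows,
                             n_cols=len(keep))


@dataclass
class LogoMatrix:
    """Per-column letter frequencies and information content of an alignment."""

    freqs: np.ndarray       # (n_cols, 21), rows sum to 1 (or 0 for all-gap)
    ic: np.ndarray          # bits, in [0, log2 20]
    n_seqs_per_column: np.ndarray

    def write_tsv(self, dest) -> None:
        import pandas as pd
        df = pd.DataFrame(self.freqs, columns=list(ALPHABET))
        df.insert(0, "column", np.arange(len(self.ic)))
        df["ic_bits"] = self.ic
        df["n_seqs"] = self.n_seqs_per_column
        df.to_csv(dest, sep="\t", index=False)


def logo_matrix(aln: InstanceAlignment, pseudocount: float = 0.0) -> LogoMatrix:
    """Column frequencies over non-gap residues and IC = log2(20) - H (bits).

    Gaps reduce the column's sequence count but never appear as letters.
    All-gap columns get IC 0 and an all-zero frequency row.
    """
    strings = aln.aligned_strings()
    if not strings:
        raise ValueError("empty alignment")
    n_cols = aln.n_cols
    freqs = np.zeros((n_cols, N_LETTERS))
    n_seqs = np.zeros(n_cols, dtype=int)
    ic = np.zeros(n_cols)
    for j in range(n_cols):
        counts = np.zeros(N_LETTERS)
        for row in strings:
            ch = row[j]
            if ch != "-":
                counts[LETTER_INDEX[ch]] += 1.0
        n_seqs[j] = int(counts.sum())
        if n_seqs[j] == 0:
            continue  # all-gap column: flagged by zero row, IC 0
        counts += pseudocount
        f = counts / counts.sum()
        freqs[j] = f
        nz = f[f > 0]
        h = float(-(nz * np.log2(nz)).sum())
        ic[j] = min(max(MAX_IC - h, 0.0), MAX_IC)
    return LogoMatrix(freqs=freqs, ic=ic, n_seqs_per_column=n_seqs)
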