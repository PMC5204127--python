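"""On-disk artifact I/O: FASTA, aligned FASTA / Stockholm, hits and label TSVs, newick.

All sequence coordinates in this package are 0-based half-open, so
``end - start`` is always the hit length.  The amino-acid alphabet is the 20
canonical residues plus ``X`` (unknown); ``X`` emits background frequency in
every scoring routine downstream.  Gap characters ``-`` and ``.`` are legal
only in alignment files (``.`` marks an insert-column gap in the Stockholm
dialect written here).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("confeax")

#: canonical residues, fixed order; index 20 is the ambiguity letter.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
N_LETTERS = len(ALPHABET)  # 21
X_INDEX = 20
LETTER_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

GAP_CHARS = frozenset("-.")

#: columns of the hits TSV, in order
HITS_COLUMNS = ["feature_id", "seq_id", "start", "end", "score_bits", "evalue", "iteration"]


class SequenceParseError(ValueError):
    """Raised when a sequence or sidecar file violates its format contract."""


@dataclass
class SequenceRecord:
    """One protein sequence with optional paralogue/clade annotation."""

    id: str
    residues: str
    description: str = ""
    paralogue_label: str | None = None
    clade_label: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as int codes into :data:`ALPHABET`."""
        return encode(self.residues)


@dataclass
class FeatureHit:
    """A located occurrence of a feature on a sequence.

    ``evalue`` is NaN for hits produced before a model has been calibrated
    (e.g. raw EM training sites).
    """

    feature_id: str
    seq_id: str
    start: int
    end: int
    score_bits: float
    evalue: float = float("nan")
    iteration: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"hit start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"hit end must exceed start, got [{self.start}, {self.end})")
        if not np.isfinite(self.score_bits):
            raise ValueError("hit score must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, str, int, int]:
        return (self.feature_id, self.seq_id, self.start, self.end)


def encode(residues: str) -> np.ndarray:
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = LETTER_INDEX[ch]
    return out


def decode(codes: Iterable[int]) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _validate_residues(seq_id: str, residues: str) -> str:
    if not residues:
        raise SequenceParseError(f"sequence {seq_id!r} is empty")
    residues = residues.upper()
    for offset, ch in enumerate(residues):
        if ch not in LETTER_INDEX:
            raise SequenceParseError(
                f"illegal residue {ch!r} in sequence {seq_id!r} at offset {offset}"
            )
    return residues


def read_fasta(source: str | Path | io.TextIOBase) -> list[SequenceRecord]:
    """Read unaligned protein FASTA into :class:`SequenceRecord` objects.

    Residues are uppercased; order is preserved; duplicate ids and residues
    outside the 21-letter alphabet are rejected with the offending id (and
    offset, for residues).
    """
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        records: list[SequenceRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise SequenceParseError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            residues = _validate_residues(rec.id, str(rec.seq))
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if not records:
        raise SequenceParseError("no sequences in input")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: str | Path | io.TextIOBase,
                width: int = 60) -> None:
    handle = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i:i + width] + "\n")
    finally:
        if isinstance(dest, (str, Path)):
            handle.close()


def read_labels(source: str | Path,
                known_ids: Iterable[str] | None = None,
                header: bool = False) -> dict[str, tuple[str | None, str | None]]:
    """Read a 2-3 column TSV mapping seq_id -> (paralogue_label, clade_label).

    Ids absent from *known_ids* are reported as warnings but retained.
    Malformed rows (fewer than 2 columns) raise with the line number.
    """
    known = set(known_ids) if known_ids is not None else None
    mapping: dict[str, tuple[str | None, str | None]] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceParseError(
                    f"malformed label row at line {lineno}: expected >=2 columns"
                )
            seq_id = parts[0].strip()
            par = parts[1].strip() or None
            clade = parts[2].strip() or None if len(parts) > 2 else None
            if known is not None and seq_id not in known:
                logger.warning("label file references unknown sequence id %r", seq_id)
            mapping[seq_id] = (par, clade)
    return mapping


def write_labels(labels: Mapping[str, tuple[str | None, str | None]],
                 dest: str | Path) -> None:
    with open(dest, "w") as fh:
        for seq_id, (par, clade) in labels.items():
            fh.write(f"{seq_id}\t{par or ''}\t{clade or ''}\n")


def apply_labels(records: list[SequenceRecord],
                 labels: Mapping[str, tuple[str | None, str | None]]) -> None:
    for rec in records:
        if rec.id in labels:
            rec.paralogue_label, rec.clade_label = labels[rec.id]


def write_hits(hits: Iterable[FeatureHit], dest: str | Path) -> None:
    rows = [[h.feature_id, h.seq_id, h.start, h.end, h.score_bits, h.evalue, h.iteration]
            for h in hits]
    df = pd.DataFrame(rows, columns=HITS_COLUMNS)
    df.to_csv(dest, sep="\t", index=False)


def read_hits(source: str | Path) -> list[FeatureHit]:
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in HITS_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceParseError(f"hits table missing columns: {missing}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(FeatureHit(
            feature_id=str(row.feature_id), seq_id=str(row.seq_id),
            start=int(row.start), end=int(row.end),
            score_bits=float(row.score_bits), evalue=float(row.evalue),
            iteration=int(row.iteration),
        ))
    return hits


# --- alignment I/O -----------------------------------------------------------

def write_aligned_fasta(rows: Iterable[tuple[str, str]], dest: str | Path,
                        width: int = 60) -> None:
    """Write (name, gapped string) rows as aligned FASTA."""
    with open(dest, "w") as fh:
        for name, aligned in rows:
            fh.write(f">{name}\n")
            for i in range(0, len(aligned), width):
                fh.write(aligned[i:i + width] + "\n")


def read_aligned_fasta(source: str | Path) -> list[tuple[str, str]]:
    rows = []
    with open(source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            aligned = str(rec.seq).upper()
            for offset, ch in enumerate(aligned):
                if ch not in LETTER_INDEX and ch not in GAP_CHARS:
                    raise SequenceParseError(
                        f"illegal alignment character {ch!r} in row {rec.id!r} "
                        f"at offset {offset}"
                    )
            rows.append((rec.id, aligned))
    if not rows:
        raise SequenceParseError("no sequences in input")
    lengths = {len(a) for _, a in rows}
    if len(lengths) > 1:
        raise SequenceParseError("alignment rows have unequal lengths")
    return rows


def write_stockholm(rows: Iterable[tuple[str, str]], dest: str | Path) -> None:
    """Minimal single-block Stockholm writer ('.' and '-' both accepted as gaps)."""
    rows = list(rows)
    with open(dest, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        name_w = max((len(n) for n, _ in rows), default=0)
        for name, aligned in rows:
            fh.write(f"{name:<{name_w}}  {aligned}\n")
        fh.write("//\n")


def read_stockholm(source: str | Path) -> list[tuple[str, str]]:
    rows: dict[str, str] = {}
    order: list[str] = []
    with open(source) as fh:
        first = fh.readline()
        if not first.startswith("# STOCKHOLM"):
            raise SequenceParseError("not a Stockholm file")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("//"):
                break
            parts = line.split()
            if len(parts) != 2:
                raise SequenceParseError(f"malformed Stockholm row: {line!r}")
            name, chunk = parts
            if name not in rows:
                rows[name] = ""
                order.append(name)
            rows[name] += chunk.upper()
    out = [(n, rows[n].replace(".", "-")) for n in order]
    if not out:
        raise SequenceParseError("no sequences in input")
    lengths = {len(a) for _, a in out}
    if len(lengths) > 1:
        raise SequenceParseError("alignment rows have unequal lengths")
    return out


def background_frequencies(records: Iterable[SequenceRecord],
                           uniform: bool = False) -> np.ndarray:
    """Length-21 background letter frequencies of a sequence set.

    The default is the empirical composition of the input (with a small
    pseudocount so no letter has zero probability); ``uniform=True`` gives
    1/20 on each canonical residue.  ``X`` always receives a tiny floor so
    scores stay finite.
    """
    freqs = np.zeros(N_LETTERS)
    if uniform:
        freqs[:X_INDEX] = 1.0 / 20.0
    else:
        counts = np.full(N_LETTERS, 0.1)
        for rec in records:
            counts += np.bincount(rec.encoded(), minlength=N_LETTERS)
        freqs = counts / counts.sum()
    freqs[X_INDEX] = max(freqs[X_INDEX], 1e-6)
    return freqs / freqs.sum()
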