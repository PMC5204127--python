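"""Synthetic gene families with duplications, planted motifs and
paralogue-specific feature retention, with full ground truth.

The generator emulates the evolutionary scenario this package analyses: a
family of homologous multidomain proteins across species, a subset of which
carry a lineage-specific gene duplication producing a MAD-like and a
BUB-like copy.  Short conserved features (motifs) are planted on an i.i.d.
random background at tunable per-column conservation; after duplication each
feature is retained according to a designed retention scheme (MAD / BUB /
both), optionally corrupted by independent retention-bit flips.

Sequences are generated independently per protein — there is no shared
mutational history beyond the retention scheme and the shared consensus, and
no indels inside planted sites.  That is deliberately simpler than real
molecular evolution; it is sufficient to exercise motif/HMM recovery and the
coevolution readout with exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coevolution import FeatureProfileMatrix
from .sequence_io import AMINO_ACIDS, FeatureHit, SequenceRecord

#: a mildly non-uniform default background over the 20 canonical residues
DEFAULT_COMPOSITION = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0966, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}


@dataclass
class FeatureSpec:
    """One plantable feature: consensus, conservation and copy number."""

    feature_id: str
    consensus: str
    conservation: float = 1.0       # probability of the consensus letter per column
    copies_per_protein: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.conservation <= 1.0):
            raise ValueError("conservation must be in [0, 1]")
        if len(self.consensus) < 4:
            raise ValueError("feature width must be >= 4")


@dataclass
class FamilySimConfig:
    """Study conditions for one synthetic family."""

    n_species: int = 24
    n_duplicated: int = 16          # species carrying a MAD/BUB duplication
    length_range: tuple[int, int] = (300, 1200)
    features: list[FeatureSpec] = field(default_factory=list)
    retention: dict[str, str] = field(default_factory=dict)  # feature -> MAD|BUB|both
    flip_noise: float = 0.0
    composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.n_duplicated > self.n_species:
            raise ValueError("more duplicated clades than species")


@dataclass
class TruthTable:
    """Ground truth of one simulated family."""

    sites: list[tuple[str, str, int, int]]      # (seq_id, feature_id, start, end)
    presence: FeatureProfileMatrix              # designed presence after noise
    bipartition: dict[str, int]                 # designed feature clusters (0=MAD, 1=BUB)


def _composition_arrays(comp: dict[str, float]) -> np.ndarray:
    p = np.array([comp.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    if p.sum() <= 0:
        raise ValueError("empty background composition")
    return p / p.sum()


def _plant(rng: np.random.Generator, seq: np.ndarray, feat: FeatureSpec,
           bg: np.ndarray, occupied: list[tuple[int, int]]) -> tuple[int, int]:
    """Choose a free interval, write conservation-sampled residues, return it."""
    w = len(feat.consensus)
    L = len(seq)
    free = [p for p in range(L - w + 1)
            if not any(p < e and p + w > b for b, e in occupied)]
    if not free:
        raise ValueError("sequence too short for feature load")
    p = int(rng.choice(free))
    cons_idx = [AMINO_ACIDS.index(c) for c in feat.consensus]
    for j, ci in enumerate(cons_idx):
        if rng.random() < feat.conservation:
            seq[p + j] = ci
        else:
            # remainder proportional to background over the other letters
            probs = bg.copy()
            probs[ci] = 0.0
            probs /= probs.sum()
            seq[p + j] = int(rng.choice(20, p=probs))
    occupied.append((p, p + w))
    return p, p + w


def simulate_family(config: FamilySimConfig
                    ) -> tuple[list[SequenceRecord],
                               dict[str, tuple[str | None, str | None]],
                               TruthTable]:
    """Generate one family with labels and ground truth; deterministic per seed.

    Unduplicated species contribute one ``MADBUB`` protein carrying every
    feature whose (possibly flipped) retention bit is on; duplicated species
    contribute a MAD and a BUB copy, each retaining the features assigned to
    its paralogue class (or to both).
    """
    rng = np.random.default_rng(config.seed)
    bg = _composition_arrays(config.composition)
    retention = {f.feature_id: config.retention.get(f.feature_id, "both")
                 for f in config.features}
    for fid, r in retention.items():
        if r not in ("MAD", "BUB", "both"):
            raise ValueError(f"unknown retention class {r!r} for {fid!r}")

    proteins: list[tuple[str, str, str]] = []  # (seq_id, paralogue, clade)
    for s in range(config.n_species):
        species = f"sp{s + 1:02d}"
        if s < config.n_duplicated:
            proteins.append((f"{species}_MAD", "MAD", species))
            proteins.append((f"{species}_BUB", "BUB", species))
        else:
            proteins.append((f"{species}_MADBUB", "MADBUB", species))

    def designed_present(paralogue: str, fid: str) -> bool:
        r = retention[fid]
        return r == "both" or paralogue == "MADBUB" or paralogue == r

    records: list[SequenceRecord] = []
    labels: dict[str, tuple[str | None, str | None]] = {}
    sites: list[tuple[str, str, int, int]] = []
    feature_ids = [f.feature_id for f in config.features]
    presence = np.zeros((len(proteins), len(feature_ids)), dtype=int)

    for i, (seq_id, paralogue, clade) in enumerate(proteins):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = rng.choice(20, size=L, p=bg).astype(np.int8)
        occupied: list[tuple[int, int]] = []
        for j, feat in enumerate(config.features):
            present = designed_present(paralogue, feat.feature_id)
            if config.flip_noise > 0 and rng.random() < config.flip_noise:
                present = not present
            if not present:
                continue
            presence[i, j] = 1
            for _ in range(feat.copies_per_protein):
                b, e = _plant(rng, seq, feat, bg, occupied)
                sites.append((seq_id, feat.feature_id, b, e))
        residues = "".join(AMINO_ACIDS[c] for c in seq)
        records.append(SequenceRecord(id=seq_id, residues=residues,
                                      paralogue_label=paralogue,
                                      clade_label=clade))
        labels[seq_id] = (paralogue, clade)

    profile = FeatureProfileMatrix(
        matrix=presence, copy_ids=[p[0] for p in proteins],
        feature_ids=feature_ids,
        paralogue_labels=[p[1] for p in proteins],
        clade_labels=[p[2] for p in proteins])
    bipartition = {fid: (0 if retention[fid] in ("MAD", "both") else 1)
                   for fid in feature_ids}
    truth = TruthTable(sites=sites, presence=profile, bipartition=bipartition)
    return records, labels, truth


# --- named study configurations ---------------------------------------------

def planted_motif_config(seed: int = 0, conservation: float = 1.0,
                         carrier_fraction: float = 0.8,
                         width: int = 10, n_proteins: int = 40,
                         length_range: tuple[int, int] = (250, 350)
                         ) -> FamilySimConfig:
    """A 40-protein unduplicated family with one planted motif.

    The motif is present in ``carrier_fraction`` of the proteins, realised
    through the retention-flip channel (retention "both", flip probability
    1 - carrier_fraction).
    """
    consensus = ("WKHDEMNFRY" * 3)[:width]
    return FamilySimConfig(
        n_species=n_proteins, n_duplicated=0, length_range=length_range,
        features=[FeatureSpec("planted", consensus, conservation)],
        retention={"planted": "both"},
        flip_noise=round(1.0 - carrier_fraction, 6), seed=seed)


def subfunctionalization_config(seed: int = 0, flip_noise: float = 0.05,
                                n_duplicated: int = 16) -> FamilySimConfig:
    """Duplicated pairs with a designed MAD-set/BUB-set feature retention."""
    mad_feats = [FeatureSpec(f"mad_f{i}", c) for i, c in enumerate(
        ["KENWHDMF", "WKENQRLY", "DEFWHKMN", "RYWQHEDK", "MNKYWFDE"], start=1)]
    bub_feats = [FeatureSpec(f"bub_f{i}", c) for i, c in enumerate(
        ["EHWKYQMD", "FDNWKEHR", "YQMKWHED", "KRFWYEND", "HWDEKYMQ"], start=1)]
    retention = {f.feature_id: "MAD" for f in mad_feats}
    retention.update({f.feature_id: "BUB" for f in bub_feats})
    return FamilySimConfig(
        n_species=n_duplicated, n_duplicated=n_duplicated,
        length_range=(300, 600), features=mad_feats + bub_feats,
        retention=retention, flip_noise=flip_noise, seed=seed)


def default_benchmark_config(seed: int = 0) -> FamilySimConfig:
    """The full benchmark family: ~40 proteins, 10 features with a cassette.

    Includes a symmetric three-feature cassette (two flanking features always
    co-retained with a central one, all MAD-retained) plus kinetochore-style
    BUB-retained features and one feature kept in both copies.
    """
    features = [
        FeatureSpec("abba1", "FEPYDE", 0.9),
        FeatureSpec("ken2", "KENWHDMF", 0.9),
        FeatureSpec("abba2", "FDPYEE", 0.9),
        FeatureSpec("ken1", "WKENQRLY", 0.9),
        FeatureSpec("dbox", "RDELNNHK", 0.85),
        FeatureSpec("glebs", "EEMNWQKYRF", 0.9),
        FeatureSpec("cmi", "WDEQHKYM", 0.85),
        FeatureSpec("kard", "SITDWEKYHN", 0.85),
        FeatureSpec("cdii", "YHWMQEDKRF", 0.9),
        FeatureSpec("tprlike", "LHEQWYNKDRFM", 0.9),
    ]
    retention = {"abba1": "MAD", "ken2": "MAD", "abba2": "MAD", "ken1": "MAD",
                 "dbox": "MAD", "glebs": "BUB", "cmi": "BUB", "kard": "BUB",
                 "cdii": "BUB", "tprlike": "both"}
    return FamilySimConfig(n_species=24, n_duplicated=16,
                           length_range=(300, 1200), features=features,
                           retention=retention, flip_noise=0.02, seed=seed)


# --- recovery metrics --------------------------------------------------------

@dataclass
class RecoveryMetrics:
    site_recall: float
    site_precision: float | None       # None when there are no hits
    presence_accuracy: float | None
    bipartition_ari: float | None


def _overlap_ge_half(a: tuple[int, int], b: tuple[int, int]) -> bool:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    shorter = min(a[1] - a[0], b[1] - b[0])
    return inter >= 0.5 * shorter


def match_feature_ids(truth: TruthTable, hits: list[FeatureHit]
                      ) -> dict[str, str]:
    """Map each discovered feature id to the truth feature it overlaps most."""
    truth_by_seq: dict[str, list[tuple[str, int, int]]] = {}
    for seq_id, fid, b, e in truth.sites:
        truth_by_seq.setdefault(seq_id, []).append((fid, b, e))
    votes: dict[str, dict[str, int]] = {}
    for h in hits:
        for fid, b, e in truth_by_seq.get(h.seq_id, []):
            if _overlap_ge_half((h.start, h.end), (b, e)):
                votes.setdefault(h.feature_id, {}).setdefault(fid, 0)
                votes[h.feature_id][fid] += 1
    return {dfid: max(v.items(), key=lambda kv: (kv[1], kv[0]))[0]
            for dfid, v in votes.items()}


def evaluate_recovery(truth: TruthTable, hits: list[FeatureHit],
                      presence: FeatureProfileMatrix | None = None,
                      feature_map: dict[str, str] | None = None,
                      auto_map: bool = False,
                      assignments: dict[str, int] | None = None
                      ) -> RecoveryMetrics:
    """Site-level precision/recall, presence accuracy and bipartition ARI.

    A hit is a true positive iff it overlaps a planted site of the same
    feature by at least 50% of the shorter interval.  ``feature_map``
    renames discovered feature ids to truth ids (``auto_map=True`` derives it
    by majority overlap).  Metrics are invariant under sequence reordering.
    """
    if auto_map and feature_map is None:
        feature_map = match_feature_ids(truth, hits)
    mapped = [FeatureHit(feature_map.get(h.feature_id, h.feature_id), h.seq_id,
                         h.start, h.end, h.score_bits, h.evalue, h.iteration)
              for h in hits] if feature_map else list(hits)

    truth_sites = [(sid, fid, b, e) for sid, fid, b, e in truth.sites]
    recovered = 0
    for sid, fid, b, e in truth_sites:
        if any(h.seq_id == sid and h.feature_id == fid
               and _overlap_ge_half((h.start, h.end), (b, e)) for h in mapped):
            recovered += 1
    recall = recovered / len(truth_sites) if truth_sites else 1.0
    if mapped:
        tp = sum(1 for h in mapped
                 if any(sid == h.seq_id and fid == h.feature_id
                        and _overlap_ge_half((h.start, h.end), (b, e))
                        for sid, fid, b, e in truth_sites))
        precision = tp / len(mapped)
    else:
        precision = None

    pres_acc = None
    if presence is not None:
        t = truth.presence
        shared_rows = [r for r in t.copy_ids if r in presence.copy_ids]
        shared_cols = [f for f in t.feature_ids if f in presence.feature_ids]
        if shared_rows and shared_cols:
            ti = np.ix_([t.copy_ids.index(r) for r in shared_rows],
                        [t.feature_ids.index(f) for f in shared_cols])
            pi = np.ix_([presence.copy_ids.index(r) for r in shared_rows],
                        [presence.feature_ids.index(f) for f in shared_cols])
            pres_acc = float((t.matrix[ti] == presence.matrix[pi]).mean())

    ari = bipartition_ari(truth, assignments) if assignments else None
    return RecoveryMetrics(site_recall=recall, site_precision=precision,
                           presence_accuracy=pres_acc, bipartition_ari=ari)


def bipartition_ari(truth: TruthTable, assignments: dict[str, int]) -> float:
    """Adjusted Rand index between a feature clustering and the designed one."""
    from sklearn.metrics import adjusted_rand_score
    shared = [f for f in truth.bipartition if f in assignments]
    if not shared:
        raise ValueError("no shared features between truth and clustering")
    a = [truth.bipartition[f] for f in shared]
    b = [assignments[f] for f in shared]
    return float(adjusted_rand_score(a, b))
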