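"""End-to-end pipeline: discover -> refine -> search -> profile -> cluster,
with a run manifest for exact reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .alignment_refinement import (
    align_instances,
    extend_hits,
    instances_from_hits,
    logo_matrix,
    occupancy_filter,
)
from .coevolution import (
    FeatureProfileMatrix,
    build_profiles,
    coevolution_analysis,
    cosegregation_report,
    write_matrix_tsv,
)
from .config import PipelineConfig
from .motif_discovery import discover_motifs, save_motifs
from .profile_hmm import confeax_iterate
from .sequence_io import (
    SequenceRecord,
    apply_labels,
    read_fasta,
    read_labels,
    write_aligned_fasta,
    write_hits,
    write_stockholm,
)

logger = logging.getLogger("confeax")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(fasta: str | Path, labels: str | Path | None,
                 config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages in order and write every artifact plus a manifest.

    Output files: motifs.json, hits TSVs per stage, instance alignments
    (aligned FASTA + Stockholm), HMM JSONs, logo TSVs, profile matrix TSV,
    correlation/distance TSVs, dendrogram newick, report JSON, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_times: dict[str, float] = {}
    outputs: list[Path] = []

    def _stage(name: str):
        class _Timer:
            def __enter__(self_):
                self_.start = time.time()
                logger.info("stage %s ...", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                stage_times[name] = round(time.time() - self_.start, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc
        return _Timer()

    with _stage("load"):
        seqs = read_fasta(fasta)
        if labels is not None:
            apply_labels(seqs, read_labels(labels, known_ids=[s.id for s in seqs]))

    with _stage("discover"):
        motifs = discover_motifs(
            seqs, max_motifs=config.max_motifs,
            width_range=(config.min_width, config.max_width),
            seed=config.seed, sig_threshold=config.sig_threshold,
            n_shuffles=config.n_shuffles,
            max_seed_candidates=config.max_seed_candidates,
            n_refine=config.n_refine,
            uniform_background=config.uniform_background)
        if not motifs:
            raise ValueError("no significant motifs discovered")
        save_motifs(motifs, out / "motifs.json")
        outputs.append(out / "motifs.json")
        em_hits = [h for m in motifs for h in m.hits]
        write_hits(em_hits, out / "em_hits.tsv")
        outputs.append(out / "em_hits.tsv")

    all_hits = []
    traces = {}
    with _stage("refine"):
        ss = np.random.SeedSequence(config.seed)
        for m in motifs:
            it_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            hmm, hits, records = confeax_iterate(
                m, seqs, flank=config.flank,
                iter_evalue=config.iter_evalue,
                final_evalue=config.final_evalue,
                max_iter=config.max_iter,
                match_threshold=config.match_threshold,
                n_calibrate=config.n_calibrate,
                extend_each_iteration=config.extend_each_iteration,
                seed=it_seed)
            hmm.save(out / f"{m.motif_id}.hmm.json")
            outputs.append(out / f"{m.motif_id}.hmm.json")
            all_hits.extend(hits)
            traces[m.motif_id] = [vars(r) for r in records]
            extended = extend_hits(hits, seqs, flank=config.flank)
            aln = align_instances(instances_from_hits(extended, seqs),
                                  feature_id=m.motif_id)
            rows = list(zip(aln.row_names(), aln.aligned_strings()))
            write_aligned_fasta(rows, out / f"{m.motif_id}.aln.fasta")
            write_stockholm(rows, out / f"{m.motif_id}.sto")
            outputs += [out / f"{m.motif_id}.aln.fasta", out / f"{m.motif_id}.sto"]
            filtered = occupancy_filter(aln, config.occupancy)
            logo_matrix(filtered).write_tsv(out / f"{m.motif_id}.logo.tsv")
            outputs.append(out / f"{m.motif_id}.logo.tsv")
        write_hits(all_hits, out / "hits.tsv")
        outputs.append(out / "hits.tsv")

    with _stage("profile"):
        if config.include_unduplicated:
            copies = seqs
        else:
            copies = [s for s in seqs if s.paralogue_label in ("MAD", "BUB")]
        if len(copies) < 2:
            copies = seqs  # no duplication labels: keep all copies
        copy_ids = {s.id for s in copies}
        profile_hits = [h for h in all_hits if h.seq_id in copy_ids]
        profiles = build_profiles(profile_hits, copies,
                                  [m.motif_id for m in motifs],
                                  min_hits=config.min_hits)
        profiles.write_tsv(out / "profiles.tsv")
        outputs.append(out / "profiles.tsv")

    with _stage("cluster"):
        result = coevolution_analysis(profiles, k=config.k_clusters)
        write_matrix_tsv(result.r, result.feature_ids, out / "correlation.tsv")
        write_matrix_tsv(result.d, result.feature_ids, out / "distance.tsv")
        (out / "dendrogram.nwk").write_text(result.dendrogram.newick + "\n")
        report = cosegregation_report(profiles, result, k=config.k_clusters)
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        outputs += [out / "correlation.tsv", out / "distance.tsv",
                    out / "dendrogram.nwk", out / "report.json"]

    manifest = {
        "tool": "confeax",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {str(fasta): _checksum(Path(fasta)),
                   **({str(labels): _checksum(Path(labels))} if labels else {})},
        "outputs": {p.name: _checksum(p) for p in outputs},
        "iteration_traces": traces,
        "stage_seconds": stage_times,
        "total_seconds": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
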