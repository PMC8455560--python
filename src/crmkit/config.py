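"""Run configuration and the reproducible end-to-end synthetic pipeline.

A :class:`RunConfig` mirrors every stage default of the package; unknown
keys are rejected so that a typo in a config file cannot silently fall
back to a default. :func:`run_pipeline` executes the stages in
dependency order on synthetic inputs derived from one seed, writes every
artefact in a plain-text genomic format, and records a JSON-lines
manifest with a SHA-256 checksum per output — rerunning with the same
config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fourc, motifs, orthology, qpcr, simulate
from .io import IntervalRecord, format_region, write_bed, write_bedgraph, write_fasta, write_fastq

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    # synthetic genome / 4C
    genome_length: int = 120_000
    gc_fraction: float = 0.42
    primary_motif: str = "GATC"
    secondary_motif: str = "CATG"
    min_frag_len: int = 20
    window: int = 5
    exclusion_radius: int = 2_000
    n_reads: int = 50_000
    decay_alpha: float = 1.0
    decoy_fraction: float = 0.05
    primer: str = "ACGTACGTACGTACG"
    # orthology
    evalue_max: float = 1e-5
    word_size: int = 11
    substitution_rate: float = 0.1
    crm_length: int = 600
    # conservation
    conservation_window: int = 100
    identity_threshold: float = 70.0
    # motifs
    pvalue_cutoff: float = 0.01
    pseudocount: float = 0.1
    # qPCR
    cq_noise_sd: float = 0.2
    group_sizes: dict[str, int] = field(default_factory=lambda: {"wt": 7, "mutant": 7})
    fold_changes: dict[str, float] = field(default_factory=lambda: {"wt": 1.0, "mutant": 0.5})
    control_group: str = "wt"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path, log=None) -> Path:
    """Execute every stage on synthetic data and write the artefacts.

    Returns the output directory; a ``manifest.jsonl`` inside lists each
    artefact with its checksum, and ``config.json`` records the resolved
    configuration next to the outputs.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SimConfig(
        seed=config.seed,
        genome_length=config.genome_length,
        gc_fraction=config.gc_fraction,
        n_reads=config.n_reads,
        decay_alpha=config.decay_alpha,
        substitution_rate=config.substitution_rate,
        cq_noise_sd=config.cq_noise_sd,
        group_sizes=tuple(config.group_sizes.values()),
    )
    artefacts: list[Path] = []

    def emit(path: Path):
        artefacts.append(path)
        log(f"wrote {path}")

    # --- stage 1: genome, digestion -------------------------------------
    genome_seq = simulate.make_genome(config.genome_length, config.gc_fraction, cfg.rng(1))
    genome = {"chrS": genome_seq}
    write_fasta(outdir / "genome.fa", genome)
    emit(outdir / "genome.fa")

    library = fourc.digest(genome, config.primary_motif, config.secondary_motif,
                           config.min_frag_len)
    write_bed(outdir / "fragments.bed", library.to_intervals())
    emit(outdir / "fragments.bed")

    # --- stage 2: 4C simulation, counting, profiles ----------------------
    viewpoint = fourc.ViewpointSpec(
        "chrS", config.genome_length // 2, config.primer,
        exclusion_radius=config.exclusion_radius,
    )
    reads, truth_4c = simulate.simulate_4c_reads(
        library, genome, viewpoint, config.decay_alpha, config.n_reads,
        cfg.rng(2), decoy_fraction=config.decoy_fraction,
    )
    write_fastq(outdir / "reads.fastq", reads)
    emit(outdir / "reads.fastq")
    (outdir / "ground_truth.tsv").write_text(truth_4c.to_manifest())
    emit(outdir / "ground_truth.tsv")

    kept, n_bad, n_short = fourc.filter_primer_reads(reads, config.primer)
    log(f"primer filter: kept {len(kept)}, discarded {n_bad}, too short {n_short}")
    counts, n_unassigned, n_ambig = fourc.assign_reads(kept, genome, library, "chrS")
    profile = fourc.count_profile(counts, library, viewpoint, config.window)

    frags = library.fragments["chrS"]
    prof_records = [
        (f.chrom, f.start, f.end, profile.rpm[f.index])
        for f in frags if profile.informative[f.index]
    ]
    write_bedgraph(outdir / "profile.bedgraph", prof_records, "4C RPM")
    emit(outdir / "profile.bedgraph")

    reads_b, _ = simulate.simulate_4c_reads(
        library, genome, viewpoint, config.decay_alpha, config.n_reads,
        cfg.rng(3), decoy_fraction=config.decoy_fraction,
    )
    kept_b, _, _ = fourc.filter_primer_reads(reads_b, config.primer)
    counts_b, _, _ = fourc.assign_reads(kept_b, genome, library, "chrS")
    profile_b = fourc.count_profile(counts_b, library, viewpoint, config.window)
    diff = fourc.subtract_profiles(profile, profile_b)
    diff_records = [
        (f.chrom, f.start, f.end, diff[f.index])
        for f in frags if profile.informative[f.index]
    ]
    write_bedgraph(outdir / "subtraction.bedgraph", diff_records, "4C subtraction")
    emit(outdir / "subtraction.bedgraph")

    # --- stage 3: orthology and conservation ------------------------------
    source, target, crm_iv, truth_orth = simulate.simulate_ortholog_pair(
        config.crm_length, min(config.genome_length, 50_000),
        config.substitution_rate, config.gc_fraction, cfg.rng(4),
    )
    params = orthology.SearchParams(evalue_max=config.evalue_max, word_size=config.word_size)
    result = orthology.bbh_detect(("source",) + crm_iv, source, target, params)
    with open(outdir / "orthology.tsv", "w") as fh:
        fh.write("crm\tgenome\tstatus\tforward_hit\treciprocal_hit\toverlap_bp\n")
        fwd = result.forward_hit
        rec = result.reciprocal_hit
        fh.write(
            f"{result.crm_id}\t{result.genome_id}\t{result.status}\t"
            f"{format_region(fwd.target_chrom, fwd.target_start, fwd.target_end) if fwd else '.'}\t"
            f"{format_region(rec.target_chrom, rec.target_start, rec.target_end) if rec else '.'}\t"
            f"{result.overlap_bp}\n"
        )
    emit(outdir / "orthology.tsv")

    crm_seq = source["source"][crm_iv[0]:crm_iv[1]]
    if truth_orth.planted_ortholog_intervals:
        _, ps, pe = truth_orth.planted_ortholog_intervals[0]
        aligned_a, aligned_b, _ = orthology.global_align(crm_seq, target["target"][ps:pe])
        track = orthology.conservation_windows(
            {"source": aligned_a, "target": aligned_b},
            window_length=min(config.conservation_window, config.crm_length),
            threshold=config.identity_threshold,
        )
        write_bedgraph(
            outdir / "conservation.bedgraph",
            [("crm", i, i + 1, v) for i, v in enumerate(track.identity)],
            "windowed identity",
        )
        emit(outdir / "conservation.bedgraph")
        write_bed(
            outdir / "conserved_calls.bed",
            [IntervalRecord("crm", s, e, "conserved", 0.0, ".") for s, e in track.calls],
        )
        emit(outdir / "conserved_calls.bed")

    # --- stage 4: motif scan and mutagenesis ------------------------------
    pwms = [simulate.gli_like_pwm(), simulate.hox13_like_pwm()]
    motif_seq, truth_motif = simulate.simulate_motif_sequence(
        600, pwms, n_sites_each=2, seed=cfg.rng(5), gc=config.gc_fraction,
    )
    hits = [h for p in pwms for h in scan_with(p, motif_seq, config.pvalue_cutoff)]
    write_bed(
        outdir / "motif_hits.bed",
        [IntervalRecord("motif_seq", h.start, h.end, h.pwm_id,
                        -np.log10(h.pvalue), h.strand) for h in hits],
    )
    emit(outdir / "motif_hits.bed")
    plan = motifs.design_mutations(motif_seq, hits, pwms, config.pvalue_cutoff)
    with open(outdir / "mutagenesis_plan.tsv", "w") as fh:
        fh.write("offset\tref\talt\n")
        for offset, ref, alt in plan.edits:
            fh.write(f"{offset}\t{ref}\t{alt}\n")
    emit(outdir / "mutagenesis_plan.tsv")
    (outdir / "verification.txt").write_text(
        f"clean: {plan.report.clean}\n"
        f"residual hits: {len(plan.report.residual_hits)}\n"
        f"de novo hits: {len(plan.report.de_novo_hits)}\n"
    )
    emit(outdir / "verification.txt")

    # --- stage 5: qPCR fold changes ---------------------------------------
    cq = simulate.simulate_cq(
        config.group_sizes, config.fold_changes, config.cq_noise_sd, cfg.rng(6),
    )
    cq.to_csv(outdir / "cq_table.tsv", sep="\t", index=False)
    emit(outdir / "cq_table.tsv")
    fc = qpcr.ddcq_fold_change(cq, "Grem1", "Rpl19", config.control_group)
    fc.summary.to_csv(outdir / "qpcr_summary.tsv", sep="\t", index=False)
    emit(outdir / "qpcr_summary.tsv")

    # --- manifest ----------------------------------------------------------
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    with open(outdir / "manifest.jsonl", "w") as fh:
        for path in artefacts:
            fh.write(json.dumps({"artefact": path.name, "sha256": _sha256(path)}) + "\n")
    log(f"manifest written with {len(artefacts)} artefacts")
    return outdir


def scan_with(pwm: motifs.Pwm, sequence: str, p_threshold: float):
    return motifs.scan(sequence, pwm, p_threshold, sequence_id="motif_seq")
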