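"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic under its seed and emits artefacts that
exercise a specific downstream computation:

* random genomes with realistic GATC/CATG site spacing (i.i.d. bases at a
  chosen GC content give a 4-cutter site roughly every 256 bp);
* enhancer (CRM) ortholog families diverged along a rooted tree by
  Jukes-Cantor per-site substitution, for reciprocal-best-hit detection;
* 4C reads drawn from a distance-decaying capture distribution over
  informative restriction fragments, each read carrying the viewpoint
  primer followed by sequence anchored at a DpnII fragment boundary;
* qPCR Cq tables with specified per-group fold changes and Gaussian
  cycle noise.

The read model is deliberately fragment-end based — reads begin exactly
at a primary-enzyme boundary, which is how the counting stage assigns
them — and does not model ligation-junction chimeras, sequencing error
or PCR duplicates.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo

from .fourc import FragmentLibrary, ViewpointSpec, informative_mask, revcomp

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_genome",
    "evolve_crm",
    "simulate_4c_reads",
    "simulate_cq",
    "plant",
    "simulate_ortholog_pair",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Bundle of simulation parameters; one seed fixes all outputs."""

    seed: int = 0
    genome_length: int = 100_000
    gc_fraction: float = 0.42
    n_reads: int = 100_000
    decay_alpha: float = 1.0
    substitution_rate: float = 0.1
    cq_noise_sd: float = 0.2
    group_sizes: tuple[int, ...] = (7, 7)

    def __post_init__(self):
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.decay_alpha <= 0:
            raise ValueError("decay_alpha must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stage generator split from the global seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """What the generators actually planted, for downstream verification."""

    planted_ortholog_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    planted_motif_positions: list[tuple[str, int, str]] = field(default_factory=list)
    true_fold_changes: dict[str, float] = field(default_factory=dict)
    fragment_capture_probs: dict[int, float] = field(default_factory=dict)

    def to_manifest(self) -> str:
        lines = []
        for gid, start, end in self.planted_ortholog_intervals:
            lines.append(f"ortholog\t{gid}\t{start}\t{end}")
        for sid, offset, strand in self.planted_motif_positions:
            lines.append(f"motif\t{sid}\t{offset}\t{strand}")
        for group, fold in self.true_fold_changes.items():
            lines.append(f"fold_change\t{group}\t{fold}")
        for idx, prob in sorted(self.fragment_capture_probs.items()):
            lines.append(f"capture_prob\t{idx}\t{prob:.12g}")
        return "\n".join(lines) + "\n"


def make_genome(length: int, gc: float = 0.42, seed: int | np.random.Generator = 0) -> str:
    """I.i.d. random genome with P(G) + P(C) = gc."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


# ---------------------------------------------------------------------------
# CRM ortholog families
# ---------------------------------------------------------------------------

def _jc_mutate(seq: str, distance: float, rng: np.random.Generator) -> str:
    """Jukes-Cantor substitution at expected ``distance`` subs/site.

    The probability that a site differs from its ancestor after distance
    d is (3/4)(1 - exp(-4d/3)); substituted sites pick uniformly among
    the three alternative bases.
    """
    if distance < 0:
        raise ValueError("branch length must be >= 0")
    if distance == 0:
        return seq
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = rng.random(len(arr)) < p_diff
    if hit.any():
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        codes = np.array([idx[b] for b in arr[hit]])
        shifts = rng.integers(1, 4, size=hit.sum())
        arr[hit] = _BASES[(codes + shifts) % 4]
    return "".join(arr)


def evolve_crm(
    ancestor: str,
    tree: str,
    rate: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Evolve one descendant per leaf of a rooted newick tree.

    Branch lengths are in expected substitutions per site and are scaled
    by ``rate``; substitution is Jukes-Cantor without indels, so the
    expected pairwise divergence between leaves is an analytic function
    of their path length.
    """
    if not ancestor:
        raise ValueError("ancestor sequence must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phylo = Phylo.read(_stdio.StringIO(tree), "newick")
    leaves: dict[str, str] = {}

    def walk(clade, seq: str):
        for child in clade.clades:
            bl = child.branch_length or 0.0
            child_seq = _jc_mutate(seq, rate * bl, rng)
            if child.clades:
                walk(child, child_seq)
            else:
                name = child.name or f"leaf{len(leaves)}"
                leaves[name] = child_seq

    root = phylo.root
    if not root.clades:  # single-node tree
        leaves[root.name or "leaf0"] = _jc_mutate(ancestor, rate * (root.branch_length or 0.0), rng)
    else:
        walk(root, ancestor)
    return leaves


def plant(genome: str, insert: str, offset: int) -> str:
    """Overwrite ``genome`` with ``insert`` at ``offset`` (same length out)."""
    if offset < 0 or offset + len(insert) > len(genome):
        raise ValueError("insert does not fit inside the genome")
    return genome[:offset] + insert + genome[offset + len(insert):]


def simulate_ortholog_pair(
    crm_length: int = 600,
    genome_length: int = 50_000,
    rate: float = 0.1,
    gc: float = 0.42,
    seed: int | np.random.Generator = 0,
    planted: bool = True,
) -> tuple[dict[str, str], dict[str, str], tuple[int, int], GroundTruth]:
    """Source genome carrying a CRM plus a target genome with its ortholog.

    The ancestral CRM sits mid-source; its descendant (diverged by
    ``rate`` substitutions/site along each of two branches of length
    rate/2, i.e. total path ``rate``) is planted at a random position in
    an independent target genome. With ``planted=False`` the target is
    left empty of any ortholog (negative control).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    source = make_genome(genome_length, gc, rng)
    target = make_genome(genome_length, gc, rng)
    crm_start = genome_length // 2
    crm = source[crm_start : crm_start + crm_length]
    truth = GroundTruth()
    if planted:
        descendants = evolve_crm(crm, f"(target:{rate});", rate=1.0, seed=rng)
        insert_at = int(rng.integers(0, genome_length - crm_length))
        target = plant(target, descendants["target"], insert_at)
        truth.planted_ortholog_intervals.append(("target", insert_at, insert_at + crm_length))
    return (
        {"source": source},
        {"target": target},
        (crm_start, crm_start + crm_length),
        truth,
    )


# ---------------------------------------------------------------------------
# 4C reads
# ---------------------------------------------------------------------------

def capture_probabilities(
    library: FragmentLibrary,
    viewpoint: ViewpointSpec,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-decaying capture distribution over informative fragments.

    P(fragment) is proportional to (1 + |d|)^-alpha with d the distance
    from the fragment midpoint to the viewpoint; probabilities sum to 1
    over the informative mask. Returns (informative indices, probs).
    """
    if alpha <= 0:
        raise ValueError("decay exponent alpha must be positive")
    mask = informative_mask(library, viewpoint)
    idx = np.flatnonzero(mask)
    if len(idx) < 10:
        raise ValueError("need at least 10 informative fragments to simulate")
    frags = library.fragments[viewpoint.chrom]
    mids = np.array([(frags[i].start + frags[i].end) / 2 for i in idx])
    weights = (1.0 + np.abs(mids - viewpoint.position)) ** (-alpha)
    return idx, weights / weights.sum()


def simulate_4c_reads(
    library: FragmentLibrary,
    genome: dict[str, str],
    viewpoint: ViewpointSpec,
    alpha: float = 1.0,
    n_reads: int = 100_000,
    seed: int | np.random.Generator = 0,
    read_length: int = 30,
    decoy_fraction: float = 0.0,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Draw 4C reads from the capture distribution.

    Each genuine read is primer + ``read_length`` bases anchored at a
    DpnII boundary of the captured fragment (either end, the 3' end read
    back on the reverse strand). A ``decoy_fraction`` of reads carries a
    scrambled primer and fails the primer filter downstream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx, probs = capture_probabilities(library, viewpoint, alpha)
    seq = genome[viewpoint.chrom].upper()
    frags = library.fragments[viewpoint.chrom]

    draws = rng.choice(len(idx), size=n_reads, p=probs)
    use_end = rng.random(n_reads) < 0.5
    is_decoy = rng.random(n_reads) < decoy_fraction
    bad_primer = _scramble_primer(viewpoint.primer, rng)

    reads: list[tuple[str, str]] = []
    for r in range(n_reads):
        frag = frags[idx[draws[r]]]
        if use_end[r] and frag.end - read_length >= frag.start:
            body = revcomp(seq[frag.end - read_length : frag.end])
        else:
            body = seq[frag.start : frag.start + read_length]
        primer = bad_primer if is_decoy[r] else viewpoint.primer
        reads.append((f"read{r}", primer + body))

    truth = GroundTruth(
        fragment_capture_probs={int(i): float(p) for i, p in zip(idx, probs)}
    )
    return reads, truth


def _scramble_primer(primer: str, rng: np.random.Generator) -> str:
    """A primer-length sequence guaranteed to mismatch at every position."""
    shift = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}
    return "".join(shift[b] for b in primer)


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def consensus_pwm(consensus: str, pwm_id: str, strength: float = 20.0, off: float = 1.0):
    """Synthetic high-information PWM built from a consensus string.

    A stand-in for experimentally derived matrices: the consensus base
    of each column gets ``strength`` counts, the others ``off``.
    """
    from .motifs import Pwm

    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.full((4, len(consensus)), off)
    for j, base in enumerate(consensus):
        counts[idx[base], j] = strength
    return Pwm(counts, pwm_id=pwm_id)


def gli_like_pwm():
    """Synthetic Gli-class matrix (GACCACCCA-type consensus)."""
    return consensus_pwm("GACCACCCA", "gli_like")


def hox13_like_pwm():
    """Synthetic Hox13-class matrix (AT-rich TAAT-core consensus)."""
    return consensus_pwm("CTAATAAAA", "hox13_like")


def simulate_motif_sequence(
    length: int,
    pwms,
    n_sites_each: int = 1,
    seed: int | np.random.Generator = 0,
    gc: float = 0.42,
) -> tuple[str, GroundTruth]:
    """Random sequence with motif consensus instances planted at known,
    non-overlapping positions (random strand per site)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = make_genome(length, gc, rng)
    truth = GroundTruth()
    occupied: list[tuple[int, int]] = []
    for pwm in pwms:
        consensus = pwm.consensus
        w = len(consensus)
        for _ in range(n_sites_each):
            for _attempt in range(200):
                pos = int(rng.integers(0, length - w))
                if all(pos + w <= s or pos >= e for s, e in occupied):
                    break
            else:
                raise ValueError("could not place motif sites without overlap")
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else revcomp(consensus)
            seq = plant(seq, insert, pos)
            occupied.append((pos, pos + w))
            truth.planted_motif_positions.append((pwm.id, pos, strand))
    return seq, truth


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------

def simulate_cq(
    group_sizes: dict[str, int],
    fold_changes: dict[str, float],
    noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
    target_gene: str = "Grem1",
    reference_gene: str = "Rpl19",
    target_baseline: float = 22.0,
    reference_baseline: float = 18.0,
) -> pd.DataFrame:
    """Replicate-level Cq table for a target and a reference gene.

    Target Cq = baseline - log2(fold change of the group) + noise;
    reference-gene Cq is drawn independently of group. Returns a tidy
    table with columns sample, group, gene, Cq, replicate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for group, n in group_sizes.items():
        if n < 1:
            raise ValueError(f"group {group!r} has non-positive size {n}")
        fold = fold_changes.get(group, 1.0)
        if fold <= 0:
            raise ValueError(f"fold change for group {group!r} must be positive")
        for rep in range(n):
            sample = f"{group}_{rep + 1}"
            cq_target = target_baseline - np.log2(fold) + rng.normal(0.0, noise_sd)
            cq_ref = reference_baseline + rng.normal(0.0, noise_sd)
            rows.append((sample, group, target_gene, cq_target, rep + 1))
            rows.append((sample, group, reference_gene, cq_ref, rep + 1))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "Cq", "replicate"])
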