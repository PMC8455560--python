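"""Enhancer orthology by reciprocal best local hits, plus conservation calling.

Cis-regulatory modules (CRMs) evolve too fast for whole-gene orthology
pipelines, so presence of an orthologous enhancer in another genome is
decided by a bidirectional-best-hit (BBH) scheme on local sequence
similarity: the CRM sequence is searched against the target genome; the
best local hit is extracted together with flanks covering the unaligned
query portions (extended by 20 nt to absorb indels) and searched back
against the source genome; the CRM is scored *detected* only when the
best reciprocal hit overlaps the original CRM interval by at least one
base pair. Hits on either side must clear an E-value cap of 1e-5.

The local search engine is pluggable: any callable with the
:func:`local_search` signature can stand in for the built-in
seed-and-extend implementation (exact word seeds, ungapped X-drop
extension, Karlin-Altschul E-values).

The module also provides Gblocks-style alignment column trimming (drop
columns above a gap-fraction cap, then drop surviving runs shorter than
a minimum block length) and VISTA-style windowed percent-identity
conservation calling on pairwise alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .fourc import revcomp

__all__ = [
    "SearchParams",
    "LocalHit",
    "OrthologyResult",
    "TrimmedMsa",
    "ConservationTrack",
    "karlin_lambda",
    "local_search",
    "bbh_detect",
    "trim_msa",
    "conservation_windows",
    "global_align",
]


def karlin_lambda(match: float, mismatch: float, background: Sequence[float] | None = None) -> float:
    """Karlin-Altschul lambda for a match/mismatch scheme.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0. With a
    uniform background this reduces to
    (1/4) e^(lambda*match) + (3/4) e^(lambda*mismatch) = 1.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("require match > 0 and mismatch < 0")
    p_match = 0.25 if background is None else float(np.sum(np.square(background)))

    def f(lam: float) -> float:
        return p_match * np.exp(lam * match) + (1 - p_match) * np.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the built-in seed-and-extend local search."""

    evalue_max: float = 1e-5
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: float = -5.0
    gap_extend: float = -2.0
    xdrop: int = 30
    karlin_k: float = 0.35
    karlin_lam: float | None = None

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.karlin_lam is None:
            object.__setattr__(self, "karlin_lam", karlin_lambda(self.match, self.mismatch))


@dataclass(frozen=True)
class LocalHit:
    """One local alignment hit; all coordinates 0-based half-open, forward frame."""

    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    score: float
    evalue: float

    def overlap_bp(self, start: int, end: int) -> int:
        return max(0, min(self.target_end, end) - max(self.target_start, start))


@dataclass(frozen=True)
class OrthologyResult:
    """Detected / not-detected call for one CRM in one target genome."""

    crm_id: str
    genome_id: str
    status: str                       # "detected" | "not_detected"
    forward_hit: LocalHit | None = None
    extract_interval: tuple[str, int, int] | None = None
    reciprocal_hit: LocalHit | None = None
    overlap_bp: int = 0

    def __post_init__(self):
        if (self.status == "detected") != (self.overlap_bp >= 1):
            raise ValueError("status must be 'detected' iff overlap_bp >= 1")


# ---------------------------------------------------------------------------
# Seed-and-extend local search
# ---------------------------------------------------------------------------

def _word_index(seq: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - w + 1):
        index.setdefault(seq[j : j + w], []).append(j)
    return index


def _extend_seed(q: str, t: str, qi: int, tj: int, w: int, params: SearchParams):
    """Ungapped X-drop extension of an exact word seed; returns the
    best-scoring segment as (q_start, q_end, t_start, t_end, score)."""
    match, mismatch, xdrop = params.match, params.mismatch, params.xdrop
    score = w * match

    best = score
    best_left = 0
    i, j, run = qi - 1, tj - 1, score
    steps = 0
    while i >= 0 and j >= 0:
        run += match if q[i] == t[j] else mismatch
        steps += 1
        if run > best:
            best, best_left = run, steps
        if run < best - xdrop:
            break
        i -= 1
        j -= 1

    total_best = best
    best_right = 0
    i, j, run = qi + w, tj + w, best
    steps = 0
    while i < len(q) and j < len(t):
        run += match if q[i] == t[j] else mismatch
        steps += 1
        if run > total_best:
            total_best, best_right = run, steps
        if run < total_best - xdrop:
            break
        i += 1
        j += 1

    return (
        qi - best_left,
        qi + w + best_right,
        tj - best_left,
        tj + w + best_right,
        total_best,
    )


def _search_one_strand(q: str, t: str, params: SearchParams):
    """All distinct extended segments of q against t (forward frames)."""
    w = params.word_size
    index = _word_index(t, w)
    segments: dict[tuple[int, int, int], float] = {}
    extended: dict[int, list[tuple[int, int]]] = {}
    for i in range(len(q) - w + 1):
        positions = index.get(q[i : i + w])
        if not positions:
            continue
        for j in positions:
            diag = j - i
            spans = extended.get(diag)
            if spans and any(a <= i < b for a, b in spans):
                continue
            qs, qe, ts, te, score = _extend_seed(q, t, i, j, w, params)
            extended.setdefault(diag, []).append((qs, qe))
            key = (diag, ts, te)
            if score > segments.get(key, -np.inf):
                segments[key] = score
    return segments


def local_search(
    query: str,
    target_genome: dict[str, str],
    params: SearchParams | None = None,
) -> list[LocalHit]:
    """Local similarity search of ``query`` against a genome, both strands.

    Exact ``word_size``-mers seed ungapped X-drop extensions; segment
    E-values follow E = K * m * n * exp(-lambda * S). Hits with
    E < ``evalue_max`` are returned sorted by ascending E-value (ties
    broken by coordinates for determinism).
    """
    params = params or SearchParams()
    if not query or len(query) < 2 * params.word_size:
        raise ValueError("query must be at least twice the word size")
    if not target_genome or any(not s for s in target_genome.values()):
        raise ValueError("target genome is empty")
    m = len(query)
    hits: list[LocalHit] = []
    for chrom, tseq in target_genome.items():
        tseq = tseq.upper()
        n = len(tseq)
        for strand, q in (("+", query.upper()), ("-", revcomp(query.upper()))):
            if len(q) < params.word_size:
                continue
            segments = _search_one_strand(q, tseq, params)
            for (diag, ts, te), score in segments.items():
                evalue = params.karlin_k * m * n * np.exp(-params.karlin_lam * score)
                if evalue >= params.evalue_max:
                    continue
                qs, qe = ts - diag, te - diag
                if strand == "-":
                    qs, qe = m - qe, m - qs
                hits.append(LocalHit(qs, qe, chrom, ts, te, strand, float(score), float(evalue)))
    hits.sort(key=lambda h: (h.evalue, -h.score, h.target_chrom, h.target_start, h.strand))
    return hits


SearchEngine = Callable[[str, dict[str, str], SearchParams], list[LocalHit]]


def bbh_detect(
    crm_interval: tuple[str, int, int],
    source_genome: dict[str, str],
    target_genome: dict[str, str],
    params: SearchParams | None = None,
    crm_id: str = "crm",
    genome_id: str = "target",
    flank_extension: int = 20,
    engine: SearchEngine = None,
) -> OrthologyResult:
    """Bidirectional-best-hit orthology call for one CRM in one genome.

    Forward: search the CRM sequence in the target and take the
    top-scoring hit under the E-value cap. Extract the hit interval plus
    flanks sized by the unaligned query portions, extended by
    ``flank_extension`` nt per side to absorb indels. Reciprocal: search
    the extract back against the source; *detected* iff the best
    reciprocal hit overlaps the original CRM interval by >= 1 bp.
    Absence of hits on either side yields *not_detected*.
    """
    params = params or SearchParams()
    search = engine or local_search
    chrom, crm_start, crm_end = crm_interval
    crm_seq = source_genome[chrom][crm_start:crm_end].upper()
    if not crm_seq:
        raise ValueError("empty CRM interval")

    forward = search(crm_seq, target_genome, params)
    if not forward:
        return OrthologyResult(crm_id, genome_id, "not_detected")
    best = forward[0]

    left_unaligned = best.query_start
    right_unaligned = len(crm_seq) - best.query_end
    if best.strand == "-":
        left_unaligned, right_unaligned = right_unaligned, left_unaligned
    t_len = len(target_genome[best.target_chrom])
    ext_start = max(0, best.target_start - left_unaligned - flank_extension)
    ext_end = min(t_len, best.target_end + right_unaligned + flank_extension)
    extract = target_genome[best.target_chrom][ext_start:ext_end].upper()
    extract_iv = (best.target_chrom, ext_start, ext_end)

    reciprocal = search(extract, source_genome, params)
    if not reciprocal:
        return OrthologyResult(crm_id, genome_id, "not_detected",
                               forward_hit=best, extract_interval=extract_iv)
    # only the genome-wide best reciprocal hit is examined; a paralog
    # elsewhere in the source that outscores the true locus defeats detection
    top = reciprocal[0]
    overlap = top.overlap_bp(crm_start, crm_end) if top.target_chrom == chrom else 0
    status = "detected" if overlap >= 1 else "not_detected"
    return OrthologyResult(crm_id, genome_id, status, forward_hit=best,
                           extract_interval=extract_iv, reciprocal_hit=top,
                           overlap_bp=overlap)


# ---------------------------------------------------------------------------
# Alignment trimming (Gblocks-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimmedMsa:
    """Column-trimmed alignment with the map back to input columns."""

    alignment: dict[str, str]
    kept_columns: tuple[int, ...]
    max_gap_fraction: float
    min_block_length: int

    @property
    def trimmed(self) -> dict[str, str]:
        return {
            name: "".join(row[c] for c in self.kept_columns)
            for name, row in self.alignment.items()
        }


def trim_msa(
    alignment: dict[str, str],
    max_gap_fraction: float = 0.5,
    min_block_length: int = 10,
) -> TrimmedMsa:
    """Drop gappy columns, then drop surviving runs shorter than a block.

    A column survives when its gap fraction is <= ``max_gap_fraction``;
    surviving columns are partitioned into maximal runs of consecutive
    input columns and runs shorter than ``min_block_length`` are removed
    entirely. Zero surviving columns is a legal (empty) result.
    """
    rows = list(alignment.values())
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("aligned sequences must have equal length")
    nseq = len(rows)
    survivors = [
        c for c in range(ncol)
        if sum(r[c] == "-" for r in rows) / nseq <= max_gap_fraction
    ]
    kept: list[int] = []
    run: list[int] = []
    for c in survivors + [None]:
        if run and (c is None or c != run[-1] + 1):
            if len(run) >= min_block_length:
                kept.extend(run)
            run = []
        if c is not None:
            run.append(c)
    return TrimmedMsa(dict(alignment), tuple(kept), max_gap_fraction, min_block_length)


# ---------------------------------------------------------------------------
# VISTA-style conservation windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationTrack:
    """Windowed percent identity along the reference, with region calls."""

    reference: str
    identity: np.ndarray              # percent, one value per reference position
    window_length: int
    threshold: float
    calls: tuple[tuple[int, int], ...]  # 0-based half-open reference intervals


def conservation_windows(
    alignment: dict[str, str],
    reference: str | None = None,
    window_length: int = 100,
    threshold: float = 70.0,
    min_call_length: int | None = None,
) -> ConservationTrack:
    """Sliding-window identity of a pairwise alignment versus a reference.

    The window covers ``window_length`` reference (non-gap) positions;
    within its alignment-column span, columns where the reference
    carries a gap count as mismatches. At the sequence edges the window
    is clamped so it always holds the full ``window_length`` positions.
    Positions at or above ``threshold`` percent identity merge into
    calls; calls shorter than ``min_call_length`` (default: the window
    length) are dropped.
    """
    if len(alignment) != 2:
        raise ValueError("conservation_windows requires a pairwise alignment")
    names = list(alignment)
    reference = reference or names[0]
    other = names[1] if names[0] == reference else names[0]
    ref_row, oth_row = alignment[reference], alignment[other]
    if len(ref_row) != len(oth_row):
        raise ValueError("aligned sequences must have equal length")
    min_call_length = window_length if min_call_length is None else min_call_length

    ref_cols = [c for c, ch in enumerate(ref_row) if ch != "-"]
    n_ref = len(ref_cols)
    if window_length > n_ref:
        raise ValueError("window longer than the ungapped reference")

    match = np.array(
        [1 if (a != "-" and a == b) else 0 for a, b in zip(ref_row, oth_row)],
        dtype=np.int64,
    )
    cum = np.concatenate([[0], np.cumsum(match)])

    half = window_length // 2
    identity = np.empty(n_ref)
    for i in range(n_ref):
        wstart = min(max(i - half, 0), n_ref - window_length)
        wend = wstart + window_length - 1
        col_lo, col_hi = ref_cols[wstart], ref_cols[wend]
        matches = cum[col_hi + 1] - cum[col_lo]
        identity[i] = 100.0 * matches / (col_hi - col_lo + 1)

    calls: list[tuple[int, int]] = []
    start = None
    for i in range(n_ref + 1):
        above = i < n_ref and identity[i] >= threshold
        if above and start is None:
            start = i
        elif not above and start is not None:
            if i - start >= min_call_length:
                calls.append((start, i))
            start = None
    return ConservationTrack(reference, identity, window_length, threshold, tuple(calls))


# ---------------------------------------------------------------------------
# Global alignment (desk-scale stand-in for whole-locus aligners)
# ---------------------------------------------------------------------------

def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global pairwise alignment under affine-gap scoring.

    Returns (gapped a, gapped b, score). Intended for region-scale
    sequences (tens of kb at most); deterministic alignment choice.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1]), float(aln.score)
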