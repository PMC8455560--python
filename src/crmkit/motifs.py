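"""PWM binding-site identification, conservation marks and mutagenesis design.

Transcription-factor binding sites (here Gli- and Hox13-class motifs)
are modelled as position weight matrices: per-position base counts
converted, with a pseudocount, into log-odds scores against a background
base composition. A window of sequence is a *hit* when the probability
that a random background sequence of motif length scores at least as
high — the exact p-value of the score — falls below a cutoff (0.01 by
default).

P-values are exact: the score distribution is built by dynamic
programming over motif columns, merging equal partial sums, which for
motif lengths up to ~12 reproduces exhaustive k-mer enumeration
bit-for-bit (partial sums are accumulated left to right exactly as an
enumeration would). Longer motifs fall back to a discretised grid.

Mutagenesis design disrupts a set of target sites by greedily editing
the most informative motif position to the worst-scoring base, then
rescans the whole mutant with every matrix and repairs residual or
de-novo sites until a full rescan is clean. A plan is accepted only if
its verification rescan finds no hit at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fourc import revcomp

__all__ = [
    "Pwm",
    "MotifHit",
    "MutagenesisPlan",
    "VerificationReport",
    "MutagenesisError",
    "score_to_pvalue",
    "scan",
    "overlap_sites",
    "conserved_columns",
    "design_mutations",
    "verify_mutagenesis",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])

EXACT_DP_MAX_LENGTH = 12


class MutagenesisError(RuntimeError):
    """Raised when mutagenesis design fails to converge; carries the hits."""

    def __init__(self, message: str, hits: list["MotifHit"]):
        super().__init__(message)
        self.hits = hits


class Pwm:
    """Position weight matrix with exact score-distribution p-values.

    Parameters
    ----------
    counts : array (4, L)
        Base counts in A, C, G, T row order; every column needs at least
        one positive entry.
    background : array (4,), optional
        Background base frequencies (default uniform).
    pseudocount : float
        Added to counts (distributed by background) before log-odds.
    """

    def __init__(
        self,
        counts,
        pwm_id: str = "pwm",
        background: Sequence[float] | None = None,
        pseudocount: float = 0.1,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, L) in ACGT order")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("degenerate PWM column with no positive count")
        self.id = pwm_id
        self.counts = counts
        self.pseudocount = float(pseudocount)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        self.background = bg
        freqs = (counts + self.pseudocount * bg[:, None]) / (
            counts.sum(axis=0) + self.pseudocount
        )
        self.log_odds = np.log2(freqs / bg[:, None])
        self._distribution: tuple[np.ndarray, np.ndarray] | None = None

    # -- basic properties ---------------------------------------------------

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[b] for b in self.counts.argmax(axis=0))

    def information_content(self) -> np.ndarray:
        """Per-column information content (bits) relative to background."""
        freqs = (self.counts + self.pseudocount * self.background[:, None]) / (
            self.counts.sum(axis=0) + self.pseudocount
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(freqs > 0, freqs * np.log2(freqs / self.background[:, None]), 0.0)
        return terms.sum(axis=0)

    def score(self, window: str) -> float:
        """Log-odds score of one window (left-to-right accumulation)."""
        if len(window) != self.length:
            raise ValueError("window length must equal motif length")
        s = 0.0
        for j, ch in enumerate(window):
            s = s + self.log_odds[_BASE_INDEX[ch], j]
        return s

    # -- exact score distribution -------------------------------------------

    def score_distribution(self, grid: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
        """Attainable scores (ascending) and P(S >= score) tail probabilities.

        Exact partial-sum DP up to length 12 (bit-compatible with
        exhaustive enumeration); discretised-grid DP beyond.
        """
        if self._distribution is None:
            if self.length <= EXACT_DP_MAX_LENGTH:
                dist: dict[float, float] = {0.0: 1.0}
                for j in range(self.length):
                    nxt: dict[float, float] = {}
                    col = self.log_odds[:, j]
                    for s, p in dist.items():
                        for b in range(4):
                            s2 = s + col[b]
                            nxt[s2] = nxt.get(s2, 0.0) + p * self.background[b]
                    dist = nxt
                scores = np.array(sorted(dist))
                probs = np.array([dist[s] for s in scores])
            else:
                lo = np.round(self.log_odds / grid).astype(np.int64)
                offset = -lo.min(axis=0)
                width = int((lo + offset[None, :]).max(axis=0).sum()) + 1
                pmf = np.zeros(width)
                pmf[0] = 1.0
                pos = 0
                for j in range(self.length):
                    nxt = np.zeros(width)
                    for b in range(4):
                        shift = int(lo[b, j] + offset[j])
                        nxt[shift:] += self.background[b] * pmf[: width - shift]
                    pmf = nxt
                    pos += offset[j]
                support = np.flatnonzero(pmf)
                scores = (support.astype(float) - pos) * grid
                probs = pmf[support]
            tails = np.cumsum(probs[::-1])[::-1]
            self._distribution = (scores, tails)
        return self._distribution

    def pvalue(self, score: float) -> float:
        """P(random background window scores >= ``score``); exact."""
        scores, tails = self.score_distribution()
        if score < scores[0] - 1e-9 or score > scores[-1] + 1e-9:
            raise ValueError(
                f"score {score} outside achievable range "
                f"[{scores[0]:.4f}, {scores[-1]:.4f}]"
            )
        i = int(np.searchsorted(scores, score, side="left"))
        if i == len(scores):
            return float(tails[-1])
        return float(tails[i])

    def score_threshold(self, p_threshold: float) -> float | None:
        """Smallest attainable score with p-value < ``p_threshold``."""
        scores, tails = self.score_distribution()
        idx = np.flatnonzero(tails < p_threshold)
        return float(scores[idx[0]]) if len(idx) else None

    # -- construction helpers -----------------------------------------------

    @classmethod
    def from_jaspar(cls, path, background=None, pseudocount: float = 0.1) -> list["Pwm"]:
        from .io import read_jaspar

        return [
            cls(counts, pwm_id=ident, background=background, pseudocount=pseudocount)
            for ident, counts in read_jaspar(path)
        ]


@dataclass(frozen=True)
class MotifHit:
    """One binding-site hit, coordinates on the forward frame."""

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    pwm_id: str

    def overlaps(self, other: "MotifHit") -> bool:
        return min(self.end, other.end) > max(self.start, other.start)


def score_to_pvalue(pwm: Pwm, score: float) -> float:
    """Exact p-value of a log-odds score under the background model."""
    return pwm.pvalue(score)


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    codes = np.full(len(arr), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _scan_forward(codes: np.ndarray, pwm: Pwm, p_threshold: float):
    """(window start, score) pairs with p-value below threshold."""
    L = pwm.length
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return []
    cutoff = pwm.score_threshold(p_threshold)
    if cutoff is None:
        return []
    acc = np.zeros(n_win)
    for j in range(L):
        acc = acc + pwm.log_odds[:, j][codes[j : j + n_win]]
    starts = np.flatnonzero(acc >= cutoff)
    return [(int(i), float(acc[i])) for i in starts]


def scan(
    sequence: str,
    pwm: Pwm,
    p_threshold: float = 0.01,
    strands: str = "both",
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All windows with exact p-value < ``p_threshold`` on the requested
    strands, reported on the forward coordinate frame."""
    sequence = sequence.upper()
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than the motif")
    if strands not in {"both", "+", "-"}:
        raise ValueError("strands must be 'both', '+' or '-'")
    hits: list[MotifHit] = []
    n = len(sequence)
    if strands in {"both", "+"}:
        for start, score in _scan_forward(_encode(sequence), pwm, p_threshold):
            hits.append(MotifHit(sequence_id, start, start + pwm.length, "+",
                                 score, pwm.pvalue(score), pwm.id))
    if strands in {"both", "-"}:
        rc = revcomp(sequence)
        for start_rc, score in _scan_forward(_encode(rc), pwm, p_threshold):
            start = n - start_rc - pwm.length
            hits.append(MotifHit(sequence_id, start, start + pwm.length, "-",
                                 score, pwm.pvalue(score), pwm.id))
    hits.sort(key=lambda h: (h.start, h.strand, h.pwm_id))
    return hits


def overlap_sites(
    hits_a: Iterable[MotifHit], hits_b: Iterable[MotifHit]
) -> list[tuple[int, int]]:
    """Maximal regions where hits from the two sets overlap by >= 1 bp.

    Each overlapping (a, b) pair spans the union of the two intervals;
    overlapping pair spans are then merged into maximal regions.
    """
    spans = [
        (min(a.start, b.start), max(a.end, b.end))
        for a in hits_a
        for b in hits_b
        if min(a.end, b.end) > max(a.start, b.start)
    ]
    spans.sort()
    merged: list[tuple[int, int]] = []
    for start, end in spans:
        if merged and start < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def conserved_columns(msa: dict[str, str]) -> list[int]:
    """Alignment columns with 100% base-pair conservation.

    A column qualifies only if every sequence carries the same base and
    none carries a gap.
    """
    rows = list(msa.values())
    if not rows or not rows[0]:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("aligned sequences must have equal length")
    out = []
    for c in range(ncol):
        chars = {r[c] for r in rows}
        if len(chars) == 1 and "-" not in chars:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Mutagenesis design and verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerificationReport:
    """Full-rescan outcome for a mutant sequence."""

    residual_hits: tuple[MotifHit, ...]
    de_novo_hits: tuple[MotifHit, ...]

    @property
    def clean(self) -> bool:
        return not self.residual_hits and not self.de_novo_hits


@dataclass(frozen=True)
class MutagenesisPlan:
    """Edits that disrupt all target sites without creating new ones."""

    original: str
    edits: tuple[tuple[int, str, str], ...]   # (offset, ref base, alt base)
    mutant: str
    report: VerificationReport

    @property
    def accepted(self) -> bool:
        return self.report.clean

    def __post_init__(self):
        seq = list(self.original)
        for offset, ref, alt in self.edits:
            if seq[offset] != ref:
                raise ValueError(f"edit ref base mismatch at offset {offset}")
            seq[offset] = alt
        if "".join(seq) != self.mutant:
            raise ValueError("edits applied to original do not yield mutant")


def verify_mutagenesis(
    mutant: str,
    pwms: Sequence[Pwm],
    p_threshold: float = 0.01,
    target_sites: Iterable[MotifHit] = (),
) -> VerificationReport:
    """Rescan a mutant with every matrix on both strands.

    Hits overlapping any of the original target sites are *residual*,
    all others *de novo*; the mutant is clean iff both lists are empty.
    """
    targets = list(target_sites)
    residual: list[MotifHit] = []
    de_novo: list[MotifHit] = []
    for pwm in pwms:
        for hit in scan(mutant, pwm, p_threshold):
            if any(hit.overlaps(t) for t in targets):
                residual.append(hit)
            else:
                de_novo.append(hit)
    return VerificationReport(tuple(residual), tuple(de_novo))


def _candidate_edits(sequence: str, hit: MotifHit, pwm: Pwm, frozen: set[int]):
    """Score-lowering edits for one hit, in greedy preference order:
    highest-information column first (ties: leftmost), then lowest
    log-odds base (ties: alphabetical). Minus-strand hits are edited as
    the complement on the forward frame. Offsets already edited by the
    plan are frozen and skipped; only strictly score-lowering
    substitutions are yielded."""
    ic = pwm.information_content()
    columns = sorted(range(pwm.length), key=lambda j: (-ic[j], j))
    for j in columns:
        col = pwm.log_odds[:, j]
        if hit.strand == "+":
            offset = hit.start + j
            current = _BASE_INDEX[sequence[offset]]
        else:
            offset = hit.start + (pwm.length - 1 - j)
            current = _COMPLEMENT_IDX[_BASE_INDEX[sequence[offset]]]
        if offset in frozen:
            continue
        for b in sorted(range(4), key=lambda b: (col[b], _BASES[b])):
            if col[b] < col[current] - 1e-12:
                alt = _BASES[b] if hit.strand == "+" else _BASES[_COMPLEMENT_IDX[b]]
                yield offset, alt


def _disrupting_edit(
    sequence: str,
    hit: MotifHit,
    pwm: Pwm,
    pwms: Sequence[Pwm] = (),
    p_threshold: float = 0.01,
    frozen: set[int] | None = None,
) -> tuple[int, str]:
    """Pick the edit for one hit.

    Candidates are tried in greedy preference order; the first that
    disrupts the hit without creating any new hit in the local
    neighbourhood (the hit extended by one motif length per side) wins.
    Where no candidate is that clean — edits on dense sites can always
    complete some overlapping window — the candidate introducing the
    fewest new local hits is applied and the outer repair loop deals
    with the rest. Previously edited offsets are never touched again,
    which rules out oscillation between mutually recreating sites.
    """
    pwms = pwms or (pwm,)
    frozen = frozen if frozen is not None else set()
    max_len = max(p.length for p in pwms)
    lo = max(0, hit.start - max_len + 1)
    hi = min(len(sequence), hit.end + max_len - 1)

    def local_hits(seq: str) -> set[tuple[int, str, str]]:
        return {
            (h.start + lo, h.strand, h.pwm_id)
            for p in pwms if hi - lo >= p.length
            for h in scan(seq[lo:hi], p, p_threshold)
        }

    before = local_hits(sequence)
    this_hit = (hit.start, hit.strand, hit.pwm_id)
    fallback: tuple[tuple[int, int], tuple[int, str]] | None = None
    for offset, alt in _candidate_edits(sequence, hit, pwm, frozen):
        trial = sequence[:offset] + alt + sequence[offset + 1:]
        after = local_hits(trial)
        if this_hit not in after and after <= before:
            return offset, alt
        badness = (len(after - before), int(this_hit in after))
        if fallback is None or badness < fallback[0]:
            fallback = (badness, (offset, alt))
    if fallback is None:
        raise MutagenesisError(
            "no editable position remains for this site", [hit]
        )
    return fallback[1]


def design_mutations(
    sequence: str,
    target_sites: Sequence[MotifHit],
    pwms: Sequence[Pwm],
    p_threshold: float = 0.01,
    max_rounds: int = 10,
) -> MutagenesisPlan:
    """Design substitutions that abolish every target site.

    Greedy loop: disrupt each outstanding hit at its most informative
    position, rescan the full mutant with every matrix, and repair any
    residual or de-novo hit the same way; terminates when a rescan finds
    zero hits. Raises :class:`MutagenesisError` listing the offending
    hits if ``max_rounds`` is exhausted.
    """
    sequence = sequence.upper()
    by_id = {p.id: p for p in pwms}
    current = sequence
    outstanding = list(target_sites)
    frozen: set[int] = set()
    rounds = 0
    while outstanding:
        if rounds >= max_rounds:
            raise MutagenesisError(
                f"mutagenesis did not converge within {max_rounds} rounds", outstanding
            )
        for hit in outstanding:
            pwm = by_id[hit.pwm_id]
            window = current[hit.start:hit.end]
            if hit.strand == "-":
                window = revcomp(window)
            if pwm.pvalue(pwm.score(window)) >= p_threshold:
                continue  # an earlier edit this round already disrupted it
            offset, alt = _disrupting_edit(current, hit, pwm, pwms, p_threshold, frozen)
            current = current[:offset] + alt + current[offset + 1:]
            frozen.add(offset)
        outstanding = [h for pwm in pwms for h in scan(current, pwm, p_threshold)]
        rounds += 1

    edits = tuple(
        (i, ref, alt) for i, (ref, alt) in enumerate(zip(sequence, current)) if ref != alt
    )
    report = verify_mutagenesis(current, pwms, p_threshold, target_sites)
    return MutagenesisPlan(sequence, edits, current, report)
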