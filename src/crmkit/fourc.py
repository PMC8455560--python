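"""4C-seq viewpoint analysis on an in-silico restriction fragment library.

Circular chromosome conformation capture (4C-seq) measures how often one
anchor locus — the viewpoint, here typically a gene promoter — contacts
the rest of its chromosomal neighbourhood. The computational backbone is
a double digestion of the genome: a 4-cutter primary enzyme (DpnII,
``GATC``) defines the fragments on which reads are counted, and a
secondary enzyme (NlaIII, ``CATG``) determines which fragments could have
been re-circularised and are therefore informative. Fragments without a
secondary site, or shorter than a minimum length, are removed from
quantification.

Counts on the remaining ("valid") fragments are normalised to reads per
million (RPM) over a sliding window of informative fragments, after
excluding the viewpoint fragment itself, its undigested neighbours and a
fixed exclusion radius around the viewpoint where self-ligation artefacts
dominate. Genotype comparisons subtract one normalised profile from
another, so that positive values mark gained contacts.

A small ATAC-seq helper bins fragment 5'-ends and converts them to RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RestrictionFragment",
    "FragmentLibrary",
    "ViewpointSpec",
    "ViewpointProfile",
    "BinnedTrack",
    "digest",
    "find_motif_starts",
    "filter_primer_reads",
    "assign_reads",
    "informative_mask",
    "count_profile",
    "smooth_rpm",
    "subtract_profiles",
    "atac_rpkm",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionFragment:
    """One primary-enzyme fragment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    has_secondary_site: bool
    valid: bool
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentLibrary:
    """Ordered restriction fragments per chromosome.

    Fragments tile each chromosome exactly: fragment k ends where
    fragment k+1 starts, the first starts at 0 and the last ends at the
    chromosome length.
    """

    fragments: dict[str, list[RestrictionFragment]]
    primary_motif: str = "GATC"
    secondary_motif: str = "CATG"
    min_length: int = 20

    def chrom_length(self, chrom: str) -> int:
        return self.fragments[chrom][-1].end

    def fragment_at(self, chrom: str, position: int) -> RestrictionFragment:
        """Fragment containing ``position`` (binary search over starts)."""
        frags = self.fragments[chrom]
        if not 0 <= position < frags[-1].end:
            raise ValueError(f"position {position} outside {chrom} [0, {frags[-1].end})")
        starts = [f.start for f in frags]
        idx = int(np.searchsorted(starts, position, side="right")) - 1
        return frags[idx]

    def n_fragments(self, chrom: str) -> int:
        return len(self.fragments[chrom])

    def to_intervals(self):
        from .io import IntervalRecord

        out = []
        for chrom, frags in self.fragments.items():
            for f in frags:
                out.append(
                    IntervalRecord(chrom, f.start, f.end, f"frag_{f.index}", float(f.valid), ".")
                )
        return out


@dataclass(frozen=True)
class ViewpointSpec:
    """Anchor locus of a 4C experiment.

    ``exclusion_radius`` removes fragments within the stated distance of
    the viewpoint (self-ligation zone); ``analysis_interval`` restricts
    quantification to the profiled region, as 0-based half-open
    (chrom, start, end).
    """

    chrom: str
    position: int
    primer: str
    exclusion_radius: int = 10_000
    analysis_interval: tuple[str, int, int] | None = None

    def __post_init__(self):
        if len(self.primer) < 10:
            raise ValueError("viewpoint primer must be at least 10 nt")
        if self.analysis_interval is not None:
            chrom, start, end = self.analysis_interval
            if chrom != self.chrom:
                raise ValueError("analysis interval must be on the viewpoint chromosome")
            if not start <= self.position < end:
                raise ValueError("viewpoint position must lie inside the analysis interval")


@dataclass
class ViewpointProfile:
    """Per-fragment raw counts plus smoothed RPM values for one viewpoint."""

    library: FragmentLibrary
    viewpoint: ViewpointSpec
    counts: np.ndarray          # raw counts, every fragment of the viewpoint chromosome
    informative: np.ndarray     # boolean mask, same length
    rpm: np.ndarray | None = None   # smoothed RPM; NaN off the informative mask
    window_width: int = 5

    @property
    def total_mapped(self) -> int:
        return int(self.counts[self.informative].sum())


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def find_motif_starts(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of ``motif``.

    GATC and CATG are palindromic, so a forward-strand scan covers both
    strands.
    """
    starts = []
    pos = sequence.find(motif)
    while pos != -1:
        starts.append(pos)
        pos = sequence.find(motif, pos + 1)
    return starts


def digest(
    genome: dict[str, str] | str,
    primary_motif: str = "GATC",
    secondary_motif: str = "CATG",
    min_length: int = 20,
) -> FragmentLibrary:
    """In-silico double digestion of a genome.

    Fragment boundaries sit at every occurrence start of the primary
    motif (DpnII cuts ^GATC, leaving the site at the fragment 5' end). A
    fragment is valid when it contains at least one secondary-motif site
    and is at least ``min_length`` bp long.
    """
    if isinstance(genome, str):
        genome = {"chr": genome}
    for motif in (primary_motif, secondary_motif):
        if not motif or set(motif) - set("ACGT"):
            raise ValueError(f"motif {motif!r} must be non-empty uppercase ACGT")
    fragments: dict[str, list[RestrictionFragment]] = {}
    for chrom, seq in genome.items():
        if not seq:
            raise ValueError(f"empty sequence for chromosome {chrom!r}")
        seq = seq.upper()
        cuts = find_motif_starts(seq, primary_motif)
        boundaries = [0] + [c for c in cuts if c != 0] + [len(seq)]
        frags = []
        for idx, (start, end) in enumerate(zip(boundaries[:-1], boundaries[1:])):
            piece = seq[start:end]
            has_secondary = secondary_motif in piece
            valid = has_secondary and (end - start) >= min_length
            frags.append(RestrictionFragment(chrom, start, end, has_secondary, valid, idx))
        fragments[chrom] = frags
    return FragmentLibrary(fragments, primary_motif, secondary_motif, min_length)


# ---------------------------------------------------------------------------
# Read filtering and counting
# ---------------------------------------------------------------------------

def filter_primer_reads(
    reads: Iterable[tuple[str, str]],
    primer: str,
    max_mismatch: int = 0,
) -> tuple[list[tuple[str, str]], int, int]:
    """Keep reads whose prefix matches the viewpoint primer.

    The primer is trimmed from kept reads. Returns (kept reads,
    mismatch-discard count, too-short-discard count).
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    kept: list[tuple[str, str]] = []
    n_discarded = 0
    n_too_short = 0
    plen = len(primer)
    for name, seq in reads:
        if len(seq) < plen:
            n_too_short += 1
            continue
        prefix = seq[:plen]
        if prefix == primer:
            mismatches = 0
        else:
            mismatches = sum(a != b for a, b in zip(prefix, primer))
        if mismatches <= max_mismatch:
            kept.append((name, seq[plen:]))
        else:
            n_discarded += 1
    return kept, n_discarded, n_too_short


def _boundary_index(
    genome: dict[str, str], library: FragmentLibrary, chrom: str, key_length: int
) -> dict[str, list[int]]:
    """Map boundary-anchored sequence keys to fragment indices.

    Every valid fragment exposes two capture points: its 5' boundary read
    rightward on the forward strand, and its 3' boundary read leftward
    (i.e. the reverse complement ending at the boundary). A read whose
    first ``key_length`` bases equal one of these keys is assigned to the
    corresponding fragment.
    """
    seq = genome[chrom].upper()
    index: dict[str, list[int]] = {}
    for frag in library.fragments[chrom]:
        if not frag.valid:
            continue
        fwd = seq[frag.start : frag.start + key_length]
        rev = revcomp(seq[max(frag.end - key_length, frag.start) : frag.end])
        for key in (fwd, rev):
            if len(key) == key_length:
                index.setdefault(key, []).append(frag.index)
    return index


def assign_reads(
    reads: Iterable[tuple[str, str]],
    genome: dict[str, str],
    library: FragmentLibrary,
    chrom: str,
    key_length: int = 20,
) -> tuple[np.ndarray, int, int]:
    """Assign primer-trimmed reads to valid fragments by exact boundary match.

    Returns (per-fragment counts over the whole chromosome, unassigned
    count, ambiguous count). Reads matching no boundary, or only
    boundaries of invalid fragments, are unassigned; reads matching
    boundaries of more than one fragment are ambiguous and dropped.
    """
    index = _boundary_index(genome, library, chrom, key_length)
    counts = np.zeros(library.n_fragments(chrom), dtype=np.int64)
    n_unassigned = 0
    n_ambiguous = 0
    for _, seq in reads:
        key = seq[:key_length]
        hits = index.get(key)
        if hits is None or len(seq) < key_length:
            n_unassigned += 1
        elif len(set(hits)) > 1:
            n_ambiguous += 1
        else:
            counts[hits[0]] += 1
    return counts, n_unassigned, n_ambiguous


# ---------------------------------------------------------------------------
# Informative mask and RPM smoothing
# ---------------------------------------------------------------------------

def informative_mask(
    library: FragmentLibrary,
    viewpoint: ViewpointSpec,
    flanking_fragments: int = 1,
) -> np.ndarray:
    """Boolean mask of informative fragments on the viewpoint chromosome.

    Excluded are: invalid fragments; the viewpoint fragment and
    ``flanking_fragments`` undigested neighbours per side; any fragment
    overlapping viewpoint +/- exclusion_radius; and fragments outside the
    analysis interval.
    """
    frags = library.fragments[viewpoint.chrom]
    n = len(frags)
    mask = np.array([f.valid for f in frags], dtype=bool)

    vp_frag = library.fragment_at(viewpoint.chrom, viewpoint.position)
    lo = max(vp_frag.index - flanking_fragments, 0)
    hi = min(vp_frag.index + flanking_fragments, n - 1)
    mask[lo : hi + 1] = False

    if viewpoint.exclusion_radius > 0:
        zone_lo = viewpoint.position - viewpoint.exclusion_radius
        zone_hi = viewpoint.position + viewpoint.exclusion_radius
        for f in frags:
            if f.start < zone_hi and f.end > zone_lo:
                mask[f.index] = False

    if viewpoint.analysis_interval is not None:
        _, a_start, a_end = viewpoint.analysis_interval
        for f in frags:
            if f.end <= a_start or f.start >= a_end:
                mask[f.index] = False

    if not mask.any():
        raise ValueError("no informative fragments remain after exclusion")
    return mask


def count_profile(
    counts: np.ndarray,
    library: FragmentLibrary,
    viewpoint: ViewpointSpec,
    window_width: int = 5,
    flanking_fragments: int = 1,
) -> ViewpointProfile:
    """Bundle raw counts with the informative mask and smoothed RPM."""
    mask = informative_mask(library, viewpoint, flanking_fragments)
    profile = ViewpointProfile(library, viewpoint, np.asarray(counts), mask,
                               window_width=window_width)
    profile.rpm = smooth_rpm(profile, window_width)
    return profile


def smooth_rpm(profile: ViewpointProfile, window_width: int | None = None) -> np.ndarray:
    """Sliding-window mean over informative fragments, scaled to RPM.

    The window holds ``window_width`` informative fragments centred on
    each informative fragment and shrinks symmetrically at the edges.
    The RPM denominator is the total of raw counts on informative
    fragments (the profiled region), not the sequencing library size.
    """
    w = profile.window_width if window_width is None else window_width
    if w < 1 or w % 2 == 0:
        raise ValueError("window width must be odd and >= 1")
    total = profile.total_mapped
    if total == 0:
        raise ValueError("no mapped reads on informative fragments")
    idx = np.flatnonzero(profile.informative)
    vals = profile.counts[idx].astype(float)
    half = w // 2
    smoothed = np.empty_like(vals)
    n = len(vals)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        smoothed[i] = vals[i - h : i + h + 1].mean()
    rpm = np.full(len(profile.counts), np.nan)
    rpm[idx] = smoothed * 1e6 / total
    return rpm


def subtract_profiles(a: ViewpointProfile, b: ViewpointProfile) -> np.ndarray:
    """Per-fragment RPM difference a - b (positive = gain in a).

    Both profiles must be built on the same fragment library and share
    the informative mask.
    """
    if a.library is not b.library and a.library.fragments.keys() != b.library.fragments.keys():
        raise ValueError("profiles built on different fragment libraries")
    if a.counts.shape != b.counts.shape or not np.array_equal(a.informative, b.informative):
        raise ValueError("profiles have mismatched fragment grids or masks")
    if a.rpm is None or b.rpm is None:
        raise ValueError("profiles must be smoothed before subtraction")
    diff = np.full_like(a.rpm, np.nan)
    m = a.informative
    diff[m] = a.rpm[m] - b.rpm[m]
    return diff


# ---------------------------------------------------------------------------
# ATAC-style binned RPKM track
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """Fixed-width bins of fragment 5'-end counts with per-bin RPKM.

    RPKM_bin = count / (library_size * bin_size) * 1e9.
    """

    bin_size: int
    counts: np.ndarray
    rpkm: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        lib = self.library_size
        if lib == 0:
            raise ValueError("empty track: no fragment ends counted")
        self.rpkm = self.counts / (lib * self.bin_size) * 1e9

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())


def atac_rpkm(
    fragment_intervals: Sequence[tuple[int, int]],
    bin_size: int = 10,
    n_bins: int | None = None,
) -> BinnedTrack:
    """Bin both 5'-ends of each sequenced fragment and normalise to RPKM.

    Each (start, end) fragment contributes its two outermost positions
    (start, and end - 1) to the bins that contain them.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    if not fragment_intervals:
        raise ValueError("no fragments supplied")
    ends: list[int] = []
    for start, end in fragment_intervals:
        if end <= start:
            raise ValueError(f"invalid fragment interval ({start}, {end})")
        ends.extend((start, end - 1))
    ends_arr = np.asarray(ends, dtype=np.int64)
    bins = ends_arr // bin_size
    if n_bins is None:
        n_bins = int(bins.max()) + 1
    counts = np.bincount(bins, minlength=n_bins)
    return BinnedTrack(bin_size, counts)
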