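"""4C primer-pair design on a TE family consensus.

A viewpoint ("bait") on a repeat consensus needs two restriction-fragment
features: at least ``min_primary`` bases between consecutive primary-enzyme
sites (so the captured fragment is long enough to map), and at least
``min_secondary`` bases between the primary site and the nearest secondary
site inside the fragment (so the circle can be trimmed).  The reading primer
is the 20-mer ending with the primary site, reading into the fragment; the
second primer is chosen from the stretch between the two sites by
exhaustive scoring against a 60 degC melting-temperature target.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import RestrictionEnzyme, revcomp

MIN_PRIMARY_SPACING = 300
MIN_SECONDARY_SPACING = 150
READING_PRIMER_LEN = 20
SECOND_PRIMER_LEN_RANGE = (18, 27)
SECOND_PRIMER_GC_RANGE = (0.20, 0.80)
TM_TARGET = 60.0


@dataclass(frozen=True)
class ConsensusSequence:
    family: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty consensus sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError("consensus contains characters outside {A,C,G,T,N}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class BaitCandidate:
    """A qualifying pair of adjacent primary sites with its secondary site."""

    primary_site_pos: int
    partner_primary_site_pos: int
    secondary_site_pos: int
    primary_spacing: int
    primary_to_secondary: int


@dataclass(frozen=True)
class BaitPrimerPair:
    reading_primer: str
    second_primer: str
    reading_pos: int  # start offset of the reading primer on the consensus
    second_pos: int  # start offset of the second-primer window on the consensus
    orientation: tuple[str, str]  # strand each primer matches ("+", "-")
    gc: tuple[float, float]
    tm: tuple[float, float]


def scan_restriction_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Sorted start offsets of exact site occurrences on the forward strand.

    Palindromic sites need no reverse scan; sites spanning an N never match.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    hits = []
    i = seq.find(enzyme.site)
    while i != -1:
        hits.append(i)
        i = seq.find(enzyme.site, i + 1)
    return hits


def enumerate_bait_candidates(
    consensus: ConsensusSequence,
    primary: RestrictionEnzyme,
    secondary: RestrictionEnzyme,
    min_primary: int = MIN_PRIMARY_SPACING,
    min_secondary: int = MIN_SECONDARY_SPACING,
) -> list[BaitCandidate]:
    """All adjacent primary-site pairs meeting both spacing minima.

    The spacing criteria are treated as minimum distances.  One candidate is
    produced per adjacent pair, anchored at the left (upstream) primary site
    and reading rightward; the recorded secondary site is the nearest one at
    least ``min_secondary`` bases into the fragment.
    """
    if primary == secondary:
        raise ValueError("primary and secondary enzymes must differ")
    p_sites = scan_restriction_sites(consensus.sequence, primary)
    s_sites = scan_restriction_sites(consensus.sequence, secondary)
    out = []
    for left, right in zip(p_sites[:-1], p_sites[1:]):
        spacing = right - left
        if spacing < min_primary:
            continue
        candidates = [
            s for s in s_sites if left + min_secondary <= s and s + len(secondary.site) <= right
        ]
        if not candidates:
            continue
        sec = min(candidates)  # nearest qualifying secondary site
        out.append(BaitCandidate(left, right, sec, spacing, sec - left))
    return out


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """Deterministic Tm estimate: Wallace rule up to 14 nt, GC/length above."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if len(seq) <= 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def design_primer_pair(
    candidate: BaitCandidate,
    consensus: ConsensusSequence,
    primary: RestrictionEnzyme | None = None,
) -> BaitPrimerPair:
    """Primer pair for one candidate; deterministic for identical inputs.

    The reading primer is the 20-mer whose 3' terminus is the end of the
    primary site (site included, reading into the fragment, '+' strand).
    The second primer is picked from between the end of the primary site and
    the start of the secondary site: every window of length 18-27 with GC in
    [0.20, 0.80] and no N is scored by |Tm - 60|; ties prefer the shorter
    window, then the leftmost.  It is reported as the reverse complement of
    the winning window ('-' strand), pointing back toward the reading primer.
    """
    seq = consensus.sequence
    site_len = len(primary.site) if primary is not None else 4
    site_end = candidate.primary_site_pos + site_len
    read_start = site_end - READING_PRIMER_LEN
    if read_start < 0:
        raise ValueError(
            f"candidate at {candidate.primary_site_pos}: too close to the "
            "consensus start to place the reading primer"
        )
    reading = seq[read_start:site_end]
    if "N" in reading:
        raise ValueError(
            f"candidate at {candidate.primary_site_pos}: reading primer window contains N"
        )

    region_start = site_end
    region_end = candidate.secondary_site_pos
    lo, hi = SECOND_PRIMER_LEN_RANGE
    best = None  # (|Tm-60|, length, start)
    for length in range(lo, hi + 1):
        for start in range(region_start, region_end - length + 1):
            window = seq[start : start + length]
            if "N" in window:
                continue
            gc = _gc_fraction(window)
            if not (SECOND_PRIMER_GC_RANGE[0] <= gc <= SECOND_PRIMER_GC_RANGE[1]):
                continue
            key = (abs(melting_temperature(window) - TM_TARGET), length, start)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError(
            f"candidate at {candidate.primary_site_pos}: fragment too short to "
            "place both primers"
        )
    _, length, start = best
    window = seq[start : start + length]
    second = revcomp(window)
    return BaitPrimerPair(
        reading_primer=reading,
        second_primer=second,
        reading_pos=read_start,
        second_pos=start,
        orientation=("+", "-"),
        gc=(_gc_fraction(reading), _gc_fraction(window)),
        tm=(melting_temperature(reading), melting_temperature(window)),
    )


def write_primer_report(
    pairs: list[tuple[str, BaitCandidate, BaitPrimerPair]], path
) -> None:
    """TSV report: family, positions, sequences, scores."""
    with open(path, "w") as fh:
        fh.write(
            "family\tprimary_site\tsecondary_site\treading_pos\tsecond_pos\t"
            "reading_primer\tsecond_primer\treading_gc\tsecond_gc\treading_tm\tsecond_tm\n"
        )
        for family, cand, pp in pairs:
            fh.write(
                f"{family}\t{cand.primary_site_pos}\t{cand.secondary_site_pos}\t"
                f"{pp.reading_pos}\t{pp.second_pos}\t{pp.reading_primer}\t"
                f"{pp.second_primer}\t{pp.gc[0]:.3f}\t{pp.gc[1]:.3f}\t"
                f"{pp.tm[0]:.2f}\t{pp.tm[1]:.2f}\n"
            )
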