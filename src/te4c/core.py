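"""Genome, annotation, and restriction-fragment data model.

Coordinates are 0-based, half-open (BED convention) everywhere in memory;
1-based formats are converted at the I/O boundary only.  Enzymes are plain
data (recognition site + cut offset), not code: DpnII is ``GATC`` cut at
offset 0 (blunt, 5' of the site), Csp6I is ``GTAC`` cut at offset 1.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default flank length of the mappable reduced genome, in bp
DEFAULT_FLANK = 25


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval; strand is '+', '-' or '.' (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TEAnnotation:
    """One annotated transposable-element copy.

    ``consensus_span`` records which part of the family consensus the copy
    retains, as a half-open (lo, hi) offset pair on the consensus.
    """

    interval: GenomicInterval
    family: str
    copy_id: str = ""
    consensus_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("TE annotation requires a non-empty family")
        if self.consensus_span is not None:
            lo, hi = self.consensus_span
            if not (0 <= lo < hi):
                raise ValueError(f"invalid consensus span {self.consensus_span}")


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    site: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise ValueError("recognition site must be at least 4 bp")
        if set(self.site) - set("ACGT"):
            raise ValueError(
                f"ambiguity codes not supported in site {self.site!r}"
            )
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError("cut offset outside the recognition site")


DPNII = RestrictionEnzyme("DpnII", "GATC", 0)
CSP6I = RestrictionEnzyme("Csp6I", "GTAC", 1)


class Genome(Mapping):
    """A set of named chromosome sequences over {A,C,G,T,N}.

    Sequences are upper-cased on construction and validated against the
    alphabet; chromosome names must be unique and sequences non-empty.
    """

    def __init__(self, sequences: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = sequences.items() if isinstance(sequences, Mapping) else sequences
        self._seqs: dict[str, str] = {}
        for name, seq in items:
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"invalid characters {bad} in chromosome {name!r}")
            self._seqs[name] = seq

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self._seqs[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"{iv} extends past chromosome end ({len(seq)})")
        return seq[iv.start : iv.end]


@dataclass
class RestrictionMap:
    """Genome-wide fragment tiling for one enzyme.

    ``boundaries[chrom]`` is the sorted array of fragment boundaries
    including 0 and the chromosome length, so fragment ``i`` on a chromosome
    is ``[boundaries[i], boundaries[i+1])``.  Fragment indices are
    per-chromosome ranks, strictly increasing with coordinate.
    """

    enzyme: RestrictionEnzyme
    boundaries: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]

    def n_fragments(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    def fragment(self, chrom: str, index: int) -> GenomicInterval:
        b = self.boundaries[chrom]
        if not (0 <= index < len(b) - 1):
            raise IndexError(f"fragment index {index} out of range on {chrom}")
        return GenomicInterval(chrom, int(b[index]), int(b[index + 1]))

    def fragments(self, chrom: str) -> list[GenomicInterval]:
        b = self.boundaries[chrom]
        return [
            GenomicInterval(chrom, int(s), int(e)) for s, e in zip(b[:-1], b[1:])
        ]

    def fragment_index(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """Index of the fragment containing each position (vectorized)."""
        b = self.boundaries[chrom]
        pos = np.asarray(pos)
        if np.any(pos < 0) or np.any(pos >= b[-1]):
            raise ValueError(f"position outside chromosome {chrom}")
        return np.searchsorted(b, pos, side="right") - 1

    def iter_chroms(self) -> Iterator[str]:
        return iter(self.boundaries)


@dataclass(frozen=True)
class ReducedFragment:
    """One fixed-length flank adjacent to a cut boundary.

    The reduced genome — the set of flanks whose sequence is unique in the
    genome (both strands) — is the mappable target space for 4C reads.
    """

    interval: GenomicInterval
    side: str  # "upstream" or "downstream" of the cut
    parent_fragment_index: int
    unique: bool


# ---------------------------------------------------------------------------
# digestion and reduced genome
# ---------------------------------------------------------------------------


def find_site_occurrences(seq: str, site: str) -> list[int]:
    """Sorted start offsets of every exact occurrence of ``site`` in ``seq``.

    Sites spanning an N never match (exact string comparison).  Palindromic
    sites (DpnII GATC) need only the forward scan.
    """
    hits = []
    i = seq.find(site)
    while i != -1:
        hits.append(i)
        i = seq.find(site, i + 1)
    return hits


def digest_genome(genome: Genome, enzyme: RestrictionEnzyme) -> RestrictionMap:
    """Fragment map of the genome under one enzyme.

    Fragment boundaries fall at ``site_start + cut_offset`` for every site
    occurrence; fragments tile each chromosome exactly (empty leading or
    trailing fragments are suppressed).
    """
    if len(genome) == 0:
        raise ValueError("cannot digest an empty genome")
    boundaries: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        cuts = [h + enzyme.cut_offset for h in find_site_occurrences(seq, enzyme.site)]
        b = np.unique(np.array([0, *cuts, len(seq)], dtype=np.int64))
        b = b[(b >= 0) & (b <= len(seq))]
        boundaries[chrom] = b
    return RestrictionMap(enzyme, boundaries, genome.chrom_sizes())


def _encode(seq: str) -> np.ndarray:
    """Sequence to uint8 codes: A,C,G,T -> 0..3, anything else 255."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in zip(b"ACGT", range(4)):
        codes[arr == base] = code
    return codes


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer integers for every position, plus a validity mask."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    acc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        acc = (acc << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    bad = (codes > 3).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return acc, valid


def _revcomp_kmer(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mers (vectorized)."""
    out = np.zeros_like(kmers)
    x = kmers.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (x & np.uint64(3)))
        x >>= np.uint64(2)
    return out


def build_reduced_genome(
    rmap: RestrictionMap, genome: Genome, flank: int = DEFAULT_FLANK
) -> list[ReducedFragment]:
    """Flanks of length ``flank`` on both sides of every internal cut.

    A flank is emitted only when at least ``flank`` bases exist on its side
    of the cut.  ``unique`` is exact-sequence uniqueness over the whole
    genome counting both strands (a flank whose sequence, or its reverse
    complement, occurs anywhere else is flagged non-unique); flanks
    containing N are never unique.  Only unique flanks form the mappable
    reduced genome, but all emitted flanks are returned with their flag.
    """
    if flank < 10:
        raise ValueError("flank length must be >= 10")
    # genome-wide k-mer census (forward strand; minus-strand occurrences of a
    # flank are forward occurrences of its reverse complement)
    all_kmers = []
    codes_by_chrom: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        codes = _encode(seq)
        codes_by_chrom[chrom] = codes
        kmers, valid = _kmer_codes(codes, flank)
        all_kmers.append(kmers[valid])
    census_keys, census_counts = (
        np.unique(np.concatenate(all_kmers), return_counts=True)
        if all_kmers
        else (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    )

    def occurrence_counts(kmers: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(census_keys, kmers)
        found = (idx < len(census_keys)) & (
            census_keys[np.minimum(idx, len(census_keys) - 1)] == kmers
        )
        counts = np.zeros(len(kmers), dtype=np.int64)
        counts[found] = census_counts[idx[found]]
        return counts

    out: list[ReducedFragment] = []
    for chrom in rmap.iter_chroms():
        b = rmap.boundaries[chrom]
        length = rmap.chrom_sizes[chrom]
        kmers, valid = _kmer_codes(codes_by_chrom[chrom], flank)
        cuts = b[1:-1].astype(np.int64)  # internal boundaries only
        if len(cuts) == 0:
            continue
        # one upstream and one downstream flank per cut, where they fit
        starts = np.concatenate([cuts - flank, cuts])
        sides = np.array(["upstream"] * len(cuts) + ["downstream"] * len(cuts))
        parents = np.concatenate(
            [
                np.searchsorted(b, cuts - 1, side="right") - 1,
                np.searchsorted(b, cuts, side="right") - 1,
            ]
        )
        fits = (starts >= 0) & (starts + flank <= length)
        starts, sides, parents = starts[fits], sides[fits], parents[fits]
        ok = valid[starts]
        km = kmers[starts]
        rc = _revcomp_kmer(km, flank)
        n = occurrence_counts(km)
        extra = occurrence_counts(rc)
        n = np.where(rc == km, n, n + extra)
        unique = ok & (n == 1)
        order = np.argsort(starts, kind="stable")
        for i in order:
            iv = GenomicInterval(chrom, int(starts[i]), int(starts[i]) + flank)
            out.append(
                ReducedFragment(iv, str(sides[i]), int(parents[i]), bool(unique[i]))
            )
    return out


# ---------------------------------------------------------------------------
# FASTA / BED / bedGraph / BEDPE I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Multi-record wrapped FASTA to an ordered name->sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """BED3/BED6 (extra columns ignored) to intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """BED6 (name '.' when empty, score 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_te_annotations(path: str | os.PathLike) -> list[TEAnnotation]:
    """RepeatMasker-style BED6+: col 7 = family, cols 8,9 = consensus span."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else ".", f[3])
            family = f[6] if len(f) > 6 else f[3]
            span = (int(f[7]), int(f[8])) if len(f) > 8 else None
            out.append(TEAnnotation(iv, family, copy_id=f[3], consensus_span=span))
    return out


def write_te_annotations(tes: Iterable[TEAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.copy_id or '.'}\t0\t{iv.strand}\t{te.family}")
            if te.consensus_span is not None:
                fh.write(f"\t{te.consensus_span[0]}\t{te.consensus_span[1]}")
            fh.write("\n")


def write_restriction_map(rmap: RestrictionMap, path: str | os.PathLike) -> None:
    """BED with the per-chromosome fragment index in the name column."""
    with open(path, "w") as fh:
        for chrom in rmap.iter_chroms():
            b = rmap.boundaries[chrom]
            for i, (s, e) in enumerate(zip(b[:-1], b[1:])):
                fh.write(f"{chrom}\t{s}\t{e}\t{i}\n")


def write_reduced_fragments(
    frags: Iterable[ReducedFragment], path: str | os.PathLike
) -> None:
    """BED6: name = side, score = 1 if unique else 0."""
    with open(path, "w") as fh:
        for f in frags:
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.side}\t{1 if f.unique else 0}\t.\n"
            )


def _format_value(v: float) -> str:
    """Round-trip-safe numeric formatting: integers without a decimal point."""
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{_format_value(value)}\n")


def read_bedgraph(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")
            out.append((c, int(s), int(e), float(v)))
    return out


def read_bedpe(path: str | os.PathLike) -> list[tuple]:
    """BEDPE rows as tuples (chrom1,start1,end1,chrom2,start2,end2,name,score,strand1,strand2)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"malformed BEDPE line {ln}: {line!r}")
            name = f[6] if len(f) > 6 else "."
            score = float(f[7]) if len(f) > 7 else 0.0
            s1 = f[8] if len(f) > 8 else "."
            s2 = f[9] if len(f) > 9 else "."
            out.append(
                (f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), name, score, s1, s2)
            )
    return out


def write_bedpe(rows: Iterable[tuple], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in rows:
            c1, s1, e1, c2, s2, e2, name, score, st1, st2 = r
            fh.write(
                f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{name}\t{_format_value(score)}\t{st1}\t{st2}\n"
            )


# ---------------------------------------------------------------------------
# interval overlap helpers (sorted-array queries used across modules)
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, merging pairs separated by at most ``gap`` bases."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e <= gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


class IntervalIndex:
    """Overlap queries against a merged, sorted interval set."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[attr-defined]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[attr-defined]
        for chrom in self._starts:
            self._starts[chrom] = np.asarray(self._starts[chrom], dtype=np.int64)
            self._ends[chrom] = np.asarray(self._ends[chrom], dtype=np.int64)

    def overlaps_any(
        self, chrom: str, starts: np.ndarray | int, ends: np.ndarray | int
    ) -> np.ndarray:
        """Boolean: does [start, end) overlap any indexed interval (vectorized)."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=bool)
        fs, fe = self._starts[chrom], self._ends[chrom]
        # candidate = first indexed interval ending after the query start
        idx = np.searchsorted(fe, starts, side="right")
        ok = idx < len(fs)
        res = np.zeros(starts.shape, dtype=bool)
        res[ok] = fs[idx[ok]] < ends[ok]
        return res

    def overlap_interval(self, iv: GenomicInterval) -> bool:
        return bool(self.overlaps_any(iv.chrom, iv.start, iv.end)[0])
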