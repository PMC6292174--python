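"""In-silico PCR: genome-wide primer-site search and amplicon prediction.

A primer binds where its 3'-terminal block (default 15 nt, the lowest
stringency of the classic UCSC tool) matches the genome exactly and the
remaining 5' bases carry at most a small number of mismatches (default 2).
An amplicon is any inward-facing +/- match pair on one chromosome whose
product is no longer than ``max_product``.  Predicted viewpoint locations
("predicted baits") are amplicons cross-referenced with TE annotations:
on-target means the amplicon overlaps the target family and no other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Genome, GenomicInterval, TEAnnotation, revcomp

MIN_PERFECT_3PRIME = 15
MAX_MISMATCH_5PRIME = 2
MAX_PRODUCT = 4000


@dataclass(frozen=True)
class PrimerMatch:
    primer_id: str
    interval: GenomicInterval
    strand: str
    mismatches_5prime: int


@dataclass(frozen=True)
class PredictedBait:
    amplicon: GenomicInterval
    forward_match: PrimerMatch
    reverse_match: PrimerMatch
    product_size: int
    on_target: bool
    overlapping_families: frozenset[str]


def _count_mismatches(a: str, b: str) -> int:
    # N in the genome or primer always counts as a mismatch
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def find_primer_sites(
    genome: Genome,
    primer: str,
    primer_id: str = "primer",
    min_perfect_3prime: int = MIN_PERFECT_3PRIME,
    max_mismatch_5prime: int = MAX_MISMATCH_5PRIME,
) -> list[PrimerMatch]:
    """All binding sites of one primer on both strands, sorted by coordinate.

    The exact 3'-terminal ``min_perfect_3prime``-mer is used as the search
    seed (an exact-block index, not a heuristic: every qualifying site must
    contain it), then the 5' remainder is checked for mismatches.
    """
    primer = primer.upper()
    if len(primer) < min_perfect_3prime:
        raise ValueError(
            f"primer ({len(primer)} nt) shorter than the protected 3' block "
            f"({min_perfect_3prime} nt)"
        )
    k = min_perfect_3prime
    tail = primer[-k:]  # 3' block as it appears on the + strand
    head = primer[:-k]
    rc = revcomp(primer)
    rc_head = rc[k:]  # 5' remainder of the primer, in - orientation
    rc_tail = rc[:k]
    matches = []
    for chrom, seq in genome.items():
        # + strand: primer read left-to-right, 3' block at the right end
        i = seq.find(tail)
        while i != -1:
            start = i - len(head)
            if start >= 0:
                mm = _count_mismatches(seq[start:i], head)
                if mm <= max_mismatch_5prime:
                    matches.append(
                        PrimerMatch(
                            primer_id,
                            GenomicInterval(chrom, start, i + k),
                            "+",
                            mm,
                        )
                    )
            i = seq.find(tail, i + 1)
        # - strand: the primer's reverse complement appears on the forward
        # sequence with the protected block at its left end
        i = seq.find(rc_tail)
        while i != -1:
            end = i + k + len(rc_head)
            if end <= len(seq):
                mm = _count_mismatches(seq[i + k : end], rc_head)
                if mm <= max_mismatch_5prime:
                    matches.append(
                        PrimerMatch(
                            primer_id,
                            GenomicInterval(chrom, i, end),
                            "-",
                            mm,
                        )
                    )
            i = seq.find(rc_tail, i + 1)
    matches.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.strand))
    return matches


def predict_baits(
    fwd: list[PrimerMatch],
    rev: list[PrimerMatch],
    max_product: int = MAX_PRODUCT,
    te: list[TEAnnotation] | None = None,
    target_family: str | None = None,
) -> list[PredictedBait]:
    """Amplicons from inward-facing match pairs, annotated with TE overlap.

    ``fwd`` and ``rev`` are match lists (any strand mixture); an amplicon is
    formed by a '+' match upstream of a '-' match on the same chromosome with
    product size (minus.end - plus.start) in (0, max_product].  All pairs
    from clustered matches are reported; the caller deduplicates if desired.
    """
    te = te or []
    plus = [m for m in list(fwd) + list(rev) if m.strand == "+"]
    minus = [m for m in list(fwd) + list(rev) if m.strand == "-"]
    by_chrom_minus: dict[str, list[PrimerMatch]] = {}
    for m in minus:
        by_chrom_minus.setdefault(m.interval.chrom, []).append(m)
    for ms in by_chrom_minus.values():
        ms.sort(key=lambda m: m.interval.end)

    te_by_chrom: dict[str, list[TEAnnotation]] = {}
    for t in te:
        te_by_chrom.setdefault(t.interval.chrom, []).append(t)

    out = []
    for p in plus:
        chrom = p.interval.chrom
        ms = by_chrom_minus.get(chrom, [])
        ends = np.array([m.interval.end for m in ms])
        lo = np.searchsorted(ends, p.interval.start, side="right")
        hi = np.searchsorted(ends, p.interval.start + max_product, side="right")
        for m in ms[lo:hi]:
            size = m.interval.end - p.interval.start
            if size <= 0 or size > max_product:
                continue
            amp = GenomicInterval(chrom, p.interval.start, m.interval.end)
            fams = frozenset(
                t.family for t in te_by_chrom.get(chrom, []) if t.interval.overlaps(amp)
            )
            on_target = (
                target_family is not None
                and fams == frozenset([target_family])
            )
            out.append(PredictedBait(amp, p, m, size, on_target, fams))
    out.sort(key=lambda b: (b.amplicon.chrom, b.amplicon.start, b.amplicon.end))
    return out


def write_predicted_baits(baits: list[PredictedBait], path) -> None:
    """BED6+ with product size, on-target flag and overlapping families."""
    with open(path, "w") as fh:
        for b in baits:
            a = b.amplicon
            fams = ",".join(sorted(b.overlapping_families)) or "."
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\tamplicon\t0\t.\t"
                f"{b.product_size}\t{1 if b.on_target else 0}\t{fams}\n"
            )


def write_primer_matches(matches: list[PrimerMatch], path) -> None:
    with open(path, "w") as fh:
        for m in matches:
            iv = m.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.primer_id}\t"
                f"{m.mismatches_5prime}\t{m.strand}\n"
            )
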