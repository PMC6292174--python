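"""Seeded synthetic data: genomes with planted TE insertions, 4C reads, pairs.

The generator emulates the study system: a multi-chromosome genome carrying
non-overlapping ERV-like insertions of one family consensus, with the
characteristic truncation structure (full-length copies, solo LTRs, and
5'-truncated copies that retain the 3' end), per-base divergence from the
consensus, and two strains sharing a configurable fraction of insertions.
4C reads decay from each primer-retaining insertion with a power-law
contact-decay surrogate (1 + d/s)^(-alpha) over the mappable reduced
genome, on top of a uniform background; capture read pairs mix anchor-decay
pairs, planted loops, and uniform background, with natural duplicates
preserved (deduplication is the pipeline's job).

Insertions replace an equal-length stretch of background sequence, so
coordinates are identical across strains and each planted sequence is
retrievable from the emitted genome at its recorded interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baits import ConsensusSequence
from .core import Genome, GenomicInterval, ReducedFragment, RestrictionMap, TEAnnotation
from .capture import PAIR_COLUMNS
from .profile import FragmentCounts

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiments.

    ``decay_alpha`` / ``decay_scale`` parametrize the bait-centric contact
    decay (unitless exponent; scale in bp); ``background_rate`` is the
    probability a read or pair is uniform background rather than signal.
    """

    seed: int
    chrom_count: int = 4
    chrom_length: int = 5_000_000
    n_insertions: int = 15
    fraction_full_length: float = 0.3
    fraction_solo_ltr: float = 0.4
    fraction_5prime_truncated: float = 0.3
    mutation_rate: float = 0.02
    strain_shared_fraction: float = 0.7
    decay_alpha: float = 1.5
    decay_scale: float = 20_000.0
    background_rate: float = 0.2
    n_reads: int = 200_000
    n_pairs: int = 200_000
    min_spacing: int = 200_000
    ltr_length: int = 350
    loop_fraction: float = 0.3

    def __post_init__(self) -> None:
        fr = (
            self.fraction_full_length
            + self.fraction_solo_ltr
            + self.fraction_5prime_truncated
        )
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("truncation-class fractions must sum to 1")
        for name in ("mutation_rate", "strain_shared_fraction", "background_rate",
                     "loop_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass(frozen=True)
class InsertionTruth:
    copy_id: str
    interval: GenomicInterval
    consensus_span: tuple[int, int]
    retains_primers: bool
    strains: frozenset[str]
    family: str = ""


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hit):
        # substitute with one of the three other bases
        cur = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=len(hit))
        out[hit] = _BASES[(cur + shift) % 4]
    return out


def simulate_te_genome(
    cfg: SimConfig,
    consensus: ConsensusSequence,
    primer_segments: list[tuple[int, int]] | None = None,
) -> tuple[dict[str, Genome], list[InsertionTruth]]:
    """Two strain genomes with planted insertions, plus the truth table.

    Insertions are spread round-robin across chromosomes and placed with at
    least ``min_spacing`` bases between insertion intervals (integer
    arithmetic, deterministic under the seed).  Each insertion draws a
    truncation class (full length; solo LTR = 3'-terminal ``ltr_length``
    span; 5'-truncated = uniform truncation point, 3' end retained), is
    mutated once at ``mutation_rate``, and is present in both strains with
    probability ``strain_shared_fraction``, otherwise in exactly one.

    ``retains_primers`` records whether the retained consensus span covers
    every interval in ``primer_segments`` (when None, whether the copy is
    full length).
    """
    rng = np.random.default_rng(cfg.seed)
    clen = len(consensus.sequence)
    cons_arr = np.frombuffer(consensus.sequence.encode("ascii"), dtype=np.uint8)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.chrom_count)]
    backgrounds = {c: _random_sequence(rng, cfg.chrom_length) for c in chrom_names}

    per_chrom = [cfg.n_insertions // cfg.chrom_count] * cfg.chrom_count
    for i in range(cfg.n_insertions % cfg.chrom_count):
        per_chrom[i] += 1

    # positions with guaranteed spacing via the order-statistics transform
    slot = cfg.min_spacing + clen
    placements: list[tuple[str, int]] = []
    for chrom, k in zip(chrom_names, per_chrom):
        if k == 0:
            continue
        margin = cfg.chrom_length - k * slot - clen
        if margin <= 0:
            raise ValueError(
                f"cannot place {k} insertions with {cfg.min_spacing} bp spacing "
                f"on a {cfg.chrom_length} bp chromosome"
            )
        u = np.sort(rng.integers(0, margin, size=k))
        starts = u + np.arange(k) * slot
        placements.extend((chrom, int(s)) for s in starts)

    class_p = [
        cfg.fraction_full_length,
        cfg.fraction_solo_ltr,
        cfg.fraction_5prime_truncated,
    ]
    strain_seqs = {s: {c: backgrounds[c].copy() for c in chrom_names} for s in "AB"}
    truth: list[InsertionTruth] = []
    for n, (chrom, pos) in enumerate(placements):
        cls = rng.choice(3, p=class_p)
        if cls == 0:
            span = (0, clen)
        elif cls == 1:
            span = (clen - cfg.ltr_length, clen)
        else:
            t = int(rng.integers(1, max(clen - cfg.ltr_length, 2)))
            span = (t, clen)
        ins = _mutate(rng, cons_arr[span[0] : span[1]], cfg.mutation_rate)
        if rng.random() < cfg.strain_shared_fraction:
            strains = frozenset("AB")
        else:
            strains = frozenset([str(rng.choice(["A", "B"]))])
        for s in strains:
            strain_seqs[s][chrom][pos : pos + len(ins)] = ins
        if primer_segments is None:
            retains = span == (0, clen)
        else:
            retains = all(span[0] <= lo and hi <= span[1] for lo, hi in primer_segments)
        truth.append(
            InsertionTruth(
                copy_id=f"{consensus.family}_{n:03d}",
                interval=GenomicInterval(chrom, pos, pos + len(ins)),
                consensus_span=span,
                retains_primers=retains,
                strains=strains,
                family=consensus.family,
            )
        )
    genomes = {
        s: Genome({c: arr.tobytes().decode("ascii") for c, arr in seqs.items()})
        for s, seqs in strain_seqs.items()
    }
    return genomes, truth


def truth_for_strain(truth: list[InsertionTruth], strain: str) -> list[InsertionTruth]:
    return [t for t in truth if strain in t.strains]


def truth_to_te_annotations(
    truth: list[InsertionTruth], strain: str | None = None
) -> list[TEAnnotation]:
    rows = truth if strain is None else truth_for_strain(truth, strain)
    return [
        TEAnnotation(t.interval, t.family or "TE", t.copy_id, t.consensus_span)
        for t in rows
    ]


# ---------------------------------------------------------------------------
# 4C reads
# ---------------------------------------------------------------------------


def simulate_4c_reads(
    truth: list[InsertionTruth],
    fragments: list[ReducedFragment],
    cfg: SimConfig,
    n_replicates: int = 2,
    sample_prefix: str = "rep",
) -> list[FragmentCounts]:
    """Per-replicate fragment counts with bait-centric decay plus background.

    Baits are the primer-retaining truth rows.  A read is background with
    probability ``background_rate`` (uniform over mappable fragments);
    otherwise it picks a bait uniformly and lands on a fragment of the
    bait's chromosome with probability proportional to
    (1 + d / decay_scale)^(-decay_alpha), d being the fragment-midpoint
    distance to the insertion midpoint (cis only).  Replicates differ only
    by the seed stream.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mappable = [f for f in fragments if f.unique]
    if not mappable:
        raise ValueError("no mappable reduced fragments")
    chroms = np.array([f.interval.chrom for f in mappable])
    mids = np.array([f.interval.midpoint for f in mappable], dtype=np.float64)
    n_frag = len(mappable)

    baits = [t for t in truth if t.retains_primers]
    bait_probs = []
    for b in baits:
        on_chrom = chroms == b.interval.chrom
        d = np.abs(mids - b.interval.midpoint)
        w = np.where(on_chrom, (1.0 + d / cfg.decay_scale) ** (-cfg.decay_alpha), 0.0)
        total = w.sum()
        if total == 0:
            raise ValueError(f"bait {b.copy_id} has no mappable cis fragment")
        bait_probs.append(w / total)

    out = []
    for r in range(n_replicates):
        counts = np.zeros(n_frag, dtype=np.int64)
        n_bg = rng.binomial(cfg.n_reads, cfg.background_rate) if baits else cfg.n_reads
        counts += rng.multinomial(n_bg, np.full(n_frag, 1.0 / n_frag))
        n_signal = cfg.n_reads - n_bg
        if baits and n_signal:
            per_bait = rng.multinomial(n_signal, np.full(len(baits), 1.0 / len(baits)))
            for nb, p in zip(per_bait, bait_probs):
                if nb:
                    counts += rng.multinomial(nb, p)
        out.append(
            FragmentCounts.from_reduced_fragments(
                f"{sample_prefix}{r + 1}", mappable, counts, mappable_only=True
            )
        )
    return out


# ---------------------------------------------------------------------------
# capture read pairs
# ---------------------------------------------------------------------------


def simulate_capture_experiment(
    genome_sizes: dict[str, int],
    anchors: list[GenomicInterval],
    loops: list[tuple[int, GenomicInterval, float]],
    rmap: RestrictionMap,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Read-pair table mixing anchor decay, planted loops, and background.

    ``loops`` entries are (anchor index, target interval, strength); loop
    mass within an anchor is proportional to strength.  Background pairs
    draw both ends uniformly over restriction fragments.  Duplicates arise
    naturally and are preserved.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    chrom_names = list(rmap.iter_chroms())
    frag_chrom, frag_start, frag_end = [], [], []
    for chrom in chrom_names:
        b = rmap.boundaries[chrom]
        frag_chrom.extend([chrom] * (len(b) - 1))
        frag_start.extend(b[:-1].tolist())
        frag_end.extend(b[1:].tolist())
    frag_chrom = np.array(frag_chrom)
    frag_start = np.array(frag_start, dtype=np.int64)
    frag_end = np.array(frag_end, dtype=np.int64)
    n_frag = len(frag_chrom)
    frag_mid = (frag_start + frag_end) // 2

    def positions_in(frag_idx: np.ndarray) -> np.ndarray:
        s, e = frag_start[frag_idx], frag_end[frag_idx]
        return s + (rng.random(len(frag_idx)) * (e - s)).astype(np.int64)

    anchor_frag_idx = []
    for a in anchors:
        # the fragment containing the anchor midpoint
        mask = (frag_chrom == a.chrom) & (frag_start <= a.midpoint) & (a.midpoint < frag_end)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"anchor {a} overlaps no restriction fragment")
        anchor_frag_idx.append(int(idx[0]))

    loops_by_anchor: dict[int, list[tuple[int, float]]] = {}
    for ai, target, strength in loops:
        tmask = (
            (frag_chrom == target.chrom)
            & (frag_start < target.end)
            & (frag_end > target.start)
        )
        tidx = np.flatnonzero(tmask)
        if len(tidx) == 0:
            raise ValueError(f"loop target {target} overlaps no fragment")
        loops_by_anchor.setdefault(ai, []).append((int(tidx[0]), float(strength)))

    n_bg = rng.binomial(cfg.n_pairs, cfg.background_rate) if anchors else cfg.n_pairs
    n_signal = cfg.n_pairs - n_bg

    end1_frag = [rng.integers(0, n_frag, size=n_bg)]
    end2_frag = [rng.integers(0, n_frag, size=n_bg)]

    if anchors and n_signal:
        per_anchor = rng.multinomial(n_signal, np.full(len(anchors), 1.0 / len(anchors)))
        for ai, n_a in enumerate(per_anchor):
            if n_a == 0:
                continue
            afi = anchor_frag_idx[ai]
            achrom = frag_chrom[afi]
            amid = frag_mid[afi]
            my_loops = loops_by_anchor.get(ai, [])
            n_loop = rng.binomial(n_a, cfg.loop_fraction) if my_loops else 0
            n_decay = n_a - n_loop
            if n_loop:
                strengths = np.array([s for _t, s in my_loops])
                p = strengths / strengths.sum()
                per_loop = rng.multinomial(n_loop, p)
                for (tfi, _s), nl in zip(my_loops, per_loop):
                    if nl:
                        end1_frag.append(np.full(nl, afi))
                        end2_frag.append(np.full(nl, tfi))
            if n_decay:
                on_chrom = frag_chrom == achrom
                d = np.abs(frag_mid - amid).astype(np.float64)
                w = np.where(
                    on_chrom, (1.0 + d / cfg.decay_scale) ** (-cfg.decay_alpha), 0.0
                )
                w /= w.sum()
                other = rng.choice(n_frag, size=n_decay, p=w)
                end1_frag.append(np.full(n_decay, afi))
                end2_frag.append(other)

    f1 = np.concatenate(end1_frag)
    f2 = np.concatenate(end2_frag)
    strands = np.array(["+", "-"])
    pairs = pd.DataFrame(
        {
            "chrom1": frag_chrom[f1],
            "pos1": positions_in(f1),
            "strand1": strands[rng.integers(0, 2, size=len(f1))],
            "chrom2": frag_chrom[f2],
            "pos2": positions_in(f2),
            "strand2": strands[rng.integers(0, 2, size=len(f2))],
        },
        columns=PAIR_COLUMNS,
    )
    return pairs


def write_truth_tsv(truth: list[InsertionTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "copy_id\tchrom\tstart\tend\tspan_lo\tspan_hi\tretains_primers\tstrains\tfamily\n"
        )
        for t in truth:
            fh.write(
                f"{t.copy_id}\t{t.interval.chrom}\t{t.interval.start}\t"
                f"{t.interval.end}\t{t.consensus_span[0]}\t{t.consensus_span[1]}\t"
                f"{int(t.retains_primers)}\t{''.join(sorted(t.strains))}\t{t.family}\n"
            )
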