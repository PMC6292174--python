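"""Capture-based viewpoint analysis: probe targets, anchors, interactions.

Read pairs from a capture Hi-C style experiment are assigned to restriction
fragments; cis pairs closer than 100 fragments (self-ligation / undigested
products) are removed and exact duplicates collapsed.  Fragments in the
extreme upper tail of unique-read counts (top 0.0005 quantile) that overlap
the target TE family are the capture anchors.  Scored interaction calls
(CHiCAGO-style) are an import format, filtered at their score cut-off;
per-anchor signal tracks are binned at 1 kb / 500 bp in a 1 MB region and
normalized across samples with median-of-ratios size factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .core import (
    Genome,
    GenomicInterval,
    IntervalIndex,
    RestrictionMap,
    TEAnnotation,
    merge_intervals,
    revcomp,
)
from .profile import WindowTrack

MIN_FRAGMENT_SEPARATION = 100
ANCHOR_TOP_QUANTILE = 0.0005
SCORE_CUTOFF = 7.5
REGION_HALF_WIDTH = 500_000
SIGNAL_BIN = 1000
SIGNAL_STEP = 500

#: thresholds the paper-level differential step would use downstream; the
#: differential test itself is external (count matrices are exported for it)
DIFFERENTIAL_METADATA = {"padj_cutoff": 0.01, "log2fc_cutoff": 2.0}

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


@dataclass(frozen=True)
class AnchorFragment:
    fragment: GenomicInterval
    index: int  # per-chromosome fragment rank
    unique_read_count: int
    predicted: bool
    te_overlap: frozenset[str]


@dataclass(frozen=True)
class Interaction:
    anchor: GenomicInterval
    other_end: GenomicInterval
    score: float
    condition: str = ""
    read_counts: tuple[int, ...] = ()

    def is_cis(self) -> bool:
        return self.anchor.chrom == self.other_end.chrom

    def distance(self) -> int | None:
        if not self.is_cis():
            return None
        return abs(self.anchor.midpoint - self.other_end.midpoint)


# ---------------------------------------------------------------------------
# probe-target prediction (local alignment)
# ---------------------------------------------------------------------------


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def _alignment_stats(alignment) -> tuple[int, int, tuple[int, int]]:
    """(alignment columns incl. gaps, identities, genome span) of one local alignment.

    Gap columns count against identity, otherwise a gapped chain of short
    exact matches in random sequence would masquerade as a high-identity hit.
    """
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    span = (int(alignment.coordinates[0][0]), int(alignment.coordinates[0][-1]))
    return columns, counts.identities, span


def predict_probe_targets(
    genome: Genome,
    probe: str,
    min_identity: float = 0.80,
    min_aligned: int = 60,
    window: int = 2000,
) -> list[GenomicInterval]:
    """Genome loci where the capture probe aligns locally above threshold.

    Both strands are searched.  The genome is scanned in overlapping windows
    (overlap twice the probe length, so any qualifying hit lies wholly
    inside at least one window) and the best local alignment per window is
    kept when it reaches ``min_identity`` over at least ``min_aligned``
    aligned bases; overlapping hits are merged.  Exact for hit loci
    separated by more than one window.
    """
    probe = probe.upper()
    if len(probe) < min_aligned:
        raise ValueError("probe shorter than the minimum aligned length")
    aligner = _local_aligner()
    queries = (probe, revcomp(probe))
    overlap = 2 * len(probe)
    step = max(window - overlap, 1)
    hits: list[GenomicInterval] = []
    for chrom, seq in genome.items():
        for w_start in range(0, max(len(seq) - overlap, 1), step):
            chunk = seq[w_start : w_start + window]
            if len(chunk) < min_aligned:
                continue
            for q in queries:
                alns = aligner.align(chunk.replace("N", "X"), q)
                if alns.score <= 0:
                    continue
                aligned, ident, (s, e) = _alignment_stats(alns[0])
                if aligned >= min_aligned and ident / aligned >= min_identity:
                    hits.append(GenomicInterval(chrom, w_start + s, w_start + e))
    return merge_intervals(hits)


# ---------------------------------------------------------------------------
# read pairs
# ---------------------------------------------------------------------------


def pairs_from_bedpe(rows: list[tuple]) -> pd.DataFrame:
    """BEDPE rows to the canonical pair table (5' positions = interval starts)."""
    return pd.DataFrame(
        [(r[0], r[1], r[8], r[3], r[4], r[9]) for r in rows], columns=PAIR_COLUMNS
    )


def pairs_to_bedpe(pairs: pd.DataFrame, read_length: int = 1) -> list[tuple]:
    return [
        (
            r.chrom1, int(r.pos1), int(r.pos1) + read_length,
            r.chrom2, int(r.pos2), int(r.pos2) + read_length,
            ".", 0, r.strand1, r.strand2,
        )
        for r in pairs.itertuples()
    ]


def _canonical_order(pairs: pd.DataFrame) -> pd.DataFrame:
    """Swap ends so (chrom1, pos1) <= (chrom2, pos2) lexicographically."""
    p = pairs.copy()
    swap = (p["chrom1"] > p["chrom2"]) | (
        (p["chrom1"] == p["chrom2"]) & (p["pos1"] > p["pos2"])
    )
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        tmp = p.loc[swap, a].copy()
        p.loc[swap, a] = p.loc[swap, b]
        p.loc[swap, b] = tmp
    return p


def pairs_to_fragments(
    pairs: pd.DataFrame,
    rmap: RestrictionMap,
    min_fragment_separation: int = MIN_FRAGMENT_SEPARATION,
) -> pd.DataFrame:
    """Fragment assignment, proximity filtering, and duplicate collapse.

    Each end gets the per-chromosome index of the fragment containing its 5'
    position.  Same-chromosome pairs with index difference strictly below
    ``min_fragment_separation`` are removed (trans pairs are never
    proximity-filtered); exact duplicates — same canonical coordinate and
    strand tuple of both ends — are collapsed to one.  Idempotent.
    """
    p = _canonical_order(pairs)
    frag1 = np.empty(len(p), dtype=np.int64)
    frag2 = np.empty(len(p), dtype=np.int64)
    for col, frag in (("1", frag1), ("2", frag2)):
        for chrom, sub in p.groupby(f"chrom{col}", sort=False):
            if chrom not in rmap.boundaries:
                raise ValueError(f"pair end on unknown chromosome {chrom!r}")
            frag[sub.index.to_numpy()] = rmap.fragment_index(
                chrom, sub[f"pos{col}"].to_numpy()
            )
    p["frag1"], p["frag2"] = frag1, frag2
    cis = p["chrom1"].to_numpy() == p["chrom2"].to_numpy()
    close = np.abs(frag1 - frag2) < min_fragment_separation
    p = p.loc[~(cis & close)]
    p = p.drop_duplicates(subset=PAIR_COLUMNS, keep="first").reset_index(drop=True)
    return p


def fragment_read_counts(pairs: pd.DataFrame, rmap: RestrictionMap) -> pd.DataFrame:
    """Unique-read count per fragment: each pair adds 1 to each of its ends.

    Returns one row per fragment in the map (zeros included):
    chrom, index, start, end, count.
    """
    rows = []
    for chrom in rmap.iter_chroms():
        b = rmap.boundaries[chrom]
        n = len(b) - 1
        counts = np.zeros(n, dtype=np.int64)
        for col in ("1", "2"):
            sub = pairs[pairs[f"chrom{col}"] == chrom]
            if len(sub):
                np.add.at(counts, sub[f"frag{col}"].to_numpy(), 1)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "index": np.arange(n),
                    "start": b[:-1],
                    "end": b[1:],
                    "count": counts,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def select_anchors(
    pairs: pd.DataFrame,
    rmap: RestrictionMap,
    top_quantile: float = ANCHOR_TOP_QUANTILE,
    predicted: list[GenomicInterval] | None = None,
    te: list[TEAnnotation] | None = None,
    target_family: str | None = None,
) -> tuple[list[AnchorFragment], int]:
    """Capture anchors: fragments in the extreme upper count tail.

    Fragments with unique-read count strictly above the (1 - top_quantile)
    empirical quantile of all fragment counts are selected (a flat count
    vector therefore yields none), flagged by probe-target overlap, and
    restricted to those overlapping the target TE family; the number removed
    by that restriction is returned alongside.
    """
    if not (0 < top_quantile < 0.5):
        raise ValueError("top_quantile must be in (0, 0.5)")
    if len(pairs) == 0:
        return [], 0
    counts = fragment_read_counts(pairs, rmap)
    thr = float(np.quantile(counts["count"].to_numpy(), 1.0 - top_quantile))
    sel = counts[counts["count"] > thr]
    pred_idx = IntervalIndex(predicted) if predicted else None
    te_list = te or []
    te_by_chrom: dict[str, list[TEAnnotation]] = {}
    for t in te_list:
        te_by_chrom.setdefault(t.interval.chrom, []).append(t)

    anchors, removed = [], 0
    for r in sel.itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
        fams = frozenset(
            t.family for t in te_by_chrom.get(r.chrom, []) if t.interval.overlaps(iv)
        )
        if target_family is not None and target_family not in fams:
            removed += 1
            continue
        is_pred = bool(pred_idx.overlap_interval(iv)) if pred_idx else False
        anchors.append(
            AnchorFragment(iv, int(r.index), int(r.count), is_pred, fams)
        )
    return anchors, removed


# ---------------------------------------------------------------------------
# interaction import
# ---------------------------------------------------------------------------

_IBED_HEADER = [
    "bait_chr", "bait_start", "bait_end", "bait_name",
    "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_name",
    "N_reads", "score",
]


def load_interactions(path, score_cutoff: float = SCORE_CUTOFF) -> list[Interaction]:
    """Scored interaction calls from BEDPE (score in column 8) or ibed.

    Records with score strictly below ``score_cutoff`` are dropped (a score
    exactly at the cut-off is kept).  The ibed dialect is recognized by its
    header line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    out: list[Interaction] = []
    if lines and lines[0].split("\t")[0] == "bait_chr":
        for ln, line in enumerate(lines[1:], 2):
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"malformed ibed line {ln}: {line!r}")
            try:
                rec = Interaction(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[3]),
                    GenomicInterval(f[4], int(f[5]), int(f[6]), name=f[7]),
                    float(f[9]),
                    read_counts=(int(f[8]),),
                )
            except ValueError as exc:
                raise ValueError(f"malformed ibed line {ln}: {exc}") from exc
            out.append(rec)
    else:
        for ln, line in enumerate(lines, 1):
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(
                    f"malformed interaction line {ln} (need BEDPE with score "
                    f"in column 8 or an ibed header): {line!r}"
                )
            try:
                rec = Interaction(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[6]),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                    float(f[7]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed BEDPE line {ln}: {exc}") from exc
            out.append(rec)
    return [i for i in out if i.score >= score_cutoff]


def write_interactions_bedpe(ints: list[Interaction], path) -> None:
    from .core import write_bedpe

    rows = [
        (
            i.anchor.chrom, i.anchor.start, i.anchor.end,
            i.other_end.chrom, i.other_end.start, i.other_end.end,
            i.anchor.name or ".", i.score, ".", ".",
        )
        for i in ints
    ]
    write_bedpe(rows, path)


def write_interactions_ibed(ints: list[Interaction], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_IBED_HEADER) + "\n")
        for i in ints:
            n = i.read_counts[0] if i.read_counts else 0
            from .core import _format_value

            fh.write(
                f"{i.anchor.chrom}\t{i.anchor.start}\t{i.anchor.end}\t"
                f"{i.anchor.name or '.'}\t{i.other_end.chrom}\t{i.other_end.start}\t"
                f"{i.other_end.end}\t{i.other_end.name or '.'}\t{n}\t"
                f"{_format_value(i.score)}\n"
            )


def export_interaction_counts(
    ints: list[Interaction], samples: list[str], path
) -> None:
    """Per-interaction count matrix (TSV) for external differential testing."""
    with open(path, "w") as fh:
        fh.write("anchor\tother_end\t" + "\t".join(samples) + "\n")
        for i in ints:
            counts = list(i.read_counts) + [0] * (len(samples) - len(i.read_counts))
            fh.write(
                f"{i.anchor.chrom}:{i.anchor.start}-{i.anchor.end}\t"
                f"{i.other_end.chrom}:{i.other_end.start}-{i.other_end.end}\t"
                + "\t".join(str(c) for c in counts[: len(samples)])
                + "\n"
            )


# ---------------------------------------------------------------------------
# per-anchor signal tracks and normalization
# ---------------------------------------------------------------------------


def anchor_signal_track(
    pairs: pd.DataFrame,
    anchor: AnchorFragment,
    region_half_width: int = REGION_HALF_WIDTH,
    bin_size: int = SIGNAL_BIN,
    step: int = SIGNAL_STEP,
) -> WindowTrack:
    """Sliding-window pair counts around one anchor.

    For the region of 2 x ``region_half_width`` centered on the anchor
    fragment midpoint, each bin counts retained pairs with one end in the
    anchor fragment and the other end's 5' position inside the bin (a
    position in the overlap of two bins counts in both).
    """
    chrom = anchor.fragment.chrom
    mid = anchor.fragment.midpoint
    region_start = mid - region_half_width
    region_end = mid + region_half_width

    other_pos = []
    for a, b in (("1", "2"), ("2", "1")):
        end_in_anchor = (
            (pairs[f"chrom{a}"] == chrom)
            & (pairs[f"frag{a}"] == anchor.index)
        )
        sub = pairs.loc[end_in_anchor]
        same = sub[sub[f"chrom{b}"] == chrom]
        other_pos.append(same[f"pos{b}"].to_numpy())
    pos = np.sort(np.concatenate(other_pos)) if other_pos else np.empty(0)

    starts = np.arange(region_start, region_end - bin_size + 1, step, dtype=np.int64)
    ends = starts + bin_size
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "value": (hi - lo).astype(np.float64),
            "n_frag": 1,
        }
    )
    return WindowTrack(bin_size, step, table)


def size_factor_normalize(
    tracks: dict[str, WindowTrack],
) -> tuple[dict[str, float], dict[str, WindowTrack]]:
    """Median-of-ratios size factors over bins nonzero in every sample."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 samples")
    names = list(tracks)
    mat = np.stack([tracks[n].table["value"].to_numpy(dtype=np.float64) for n in names])
    if mat.shape[1] == 0 or len({mat.shape[1]}) != 1:
        raise ValueError("tracks must share identical binning")
    common = np.all(mat > 0, axis=0)
    if not common.any():
        raise ValueError("no bin is nonzero in all samples")
    sub = mat[:, common]
    log_geomean = np.mean(np.log(sub), axis=0)
    factors = {}
    normalized = {}
    for i, n in enumerate(names):
        f = float(np.exp(np.median(np.log(sub[i]) - log_geomean)))
        factors[n] = f
        t = tracks[n]
        tab = t.table.copy()
        tab["value"] = tab["value"] / f
        normalized[n] = WindowTrack(t.window_size, t.step, tab)
    return factors, normalized
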