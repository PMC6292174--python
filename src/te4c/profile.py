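"""Fragment-level 4C counts to tracks and statistically called viewpoints.

The pipeline mirrors classical repeat-viewpoint 4C analysis: reads mapped to
the unique reduced genome give per-fragment counts; blacklist fragments and
the extreme upper tail (self-ligation / undigested products, above the 99.9%
quantile of nonzero counts) are removed; counts are summed in sliding
windows for visualization (100 kb / 25 kb, capped at the 75% quantile) and
in non-overlapping windows for detection.  A window z-score against the
genome-wide mean and SD yields a one-sided upper-tail normal p (with a
Benjamini-Hochberg q computed alongside); windows passing the 0.05
threshold are merged when separated by at most 100 kb, and regions
supported in every replicate become "observed baits".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    GenomicInterval,
    IntervalIndex,
    ReducedFragment,
    merge_intervals,
    write_bedgraph,
)

SELF_LIGATION_QUANTILE = 0.999
VIS_WINDOW = 100_000
VIS_STEP = 25_000
VIS_CAP_QUANTILE = 0.75
DETECT_WINDOW = 100_000
DETECT_ALPHA = 0.05
MERGE_GAP = 100_000


@dataclass
class FragmentCounts:
    """Per-reduced-fragment read counts for one sample.

    ``table`` columns: chrom, start, end, fragment_id, count.  Every
    mappable reduced fragment appears, including zero-count ones, so that
    downstream windowing knows which windows are informative.
    """

    sample_id: str
    table: pd.DataFrame

    COLUMNS = ["chrom", "start", "end", "fragment_id", "count"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"fragment count table missing columns {missing}")
        if (self.table["count"] < 0).any():
            raise ValueError("negative read counts")

    @classmethod
    def from_reduced_fragments(
        cls,
        sample_id: str,
        fragments: list[ReducedFragment],
        counts: np.ndarray | None = None,
        mappable_only: bool = True,
    ) -> "FragmentCounts":
        if mappable_only:
            keep = [i for i, f in enumerate(fragments) if f.unique]
        else:
            keep = list(range(len(fragments)))
        if counts is None:
            counts = np.zeros(len(fragments), dtype=np.int64)
        tab = pd.DataFrame(
            {
                "chrom": [fragments[i].interval.chrom for i in keep],
                "start": [fragments[i].interval.start for i in keep],
                "end": [fragments[i].interval.end for i in keep],
                "fragment_id": [
                    f"{fragments[i].interval.chrom}:{fragments[i].interval.start}"
                    for i in keep
                ],
                "count": np.asarray(counts)[keep],
            }
        )
        return cls(sample_id, tab)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, sample_id: str, path) -> "FragmentCounts":
        tab = pd.read_csv(path, sep="\t", header=None, names=cls.COLUMNS)
        return cls(sample_id, tab)


@dataclass
class WindowTrack:
    """Binned genomic values: sorted constant-size windows (last truncated).

    ``table`` columns: chrom, start, end, value, n_frag (number of mappable
    fragments whose midpoint falls in the window; 0 marks uninformative
    windows excluded from the normal fit).
    """

    window_size: int
    step: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window size")

    def to_bedgraph(self, path) -> None:
        write_bedgraph(
            self.table[["chrom", "start", "end", "value"]].itertuples(index=False),
            path,
        )


@dataclass(frozen=True)
class ObservedBait:
    region: GenomicInterval
    peak_z: float
    p_value: float
    q_value: float
    replicate_support: int


# ---------------------------------------------------------------------------


def preprocess_counts(
    counts: FragmentCounts,
    blacklist: list[GenomicInterval] | None = None,
    upper_quantile: float = SELF_LIGATION_QUANTILE,
) -> FragmentCounts:
    """Blacklist removal and self-ligation filtering.

    Fragments overlapping any blacklist interval are dropped regardless of
    count.  The self-ligation filter drops fragments whose count is strictly
    above the ``upper_quantile`` empirical quantile of the nonzero-count
    distribution; ties at the threshold are retained, so a flat count vector
    loses nothing.
    """
    if not (0 < upper_quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    tab = counts.table
    if blacklist:
        idx = IntervalIndex(blacklist)
        keep = np.ones(len(tab), dtype=bool)
        for chrom, sub in tab.groupby("chrom", sort=False):
            hit = idx.overlaps_any(
                chrom, sub["start"].to_numpy(), sub["end"].to_numpy()
            )
            keep[sub.index.to_numpy()] = ~hit
        tab = tab.loc[keep].reset_index(drop=True)
    nz = tab.loc[tab["count"] > 0, "count"].to_numpy()
    if len(nz):
        thr = float(np.quantile(nz, upper_quantile))
        tab = tab.loc[tab["count"] <= thr].reset_index(drop=True)
    return FragmentCounts(counts.sample_id, tab)


def window_counts(
    counts: FragmentCounts,
    chrom_sizes: dict[str, int],
    window_size: int = VIS_WINDOW,
    step: int | None = None,
    cap_quantile: float | None = None,
) -> WindowTrack:
    """Sum of fragment counts per sliding window (midpoint assignment).

    A fragment contributes to every window containing its midpoint.  With
    ``cap_quantile`` set, window values above that empirical quantile of all
    window values are reduced to it (PCR-artifact dampening).
    """
    step = window_size if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    rows = []
    tab = counts.table
    for chrom, length in chrom_sizes.items():
        sub = tab[tab["chrom"] == chrom]
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        order = np.argsort(mids)
        mids = mids[order]
        vals = sub["count"].to_numpy()[order].astype(np.float64)
        cumw = np.concatenate([[0.0], np.cumsum(vals)])
        cumn = np.arange(len(mids) + 1, dtype=np.int64)
        starts = np.arange(0, length, step, dtype=np.int64)
        starts = starts[starts < length]
        ends = np.minimum(starts + window_size, length)
        lo = np.searchsorted(mids, starts, side="left")
        hi = np.searchsorted(mids, ends, side="left")
        values = cumw[hi] - cumw[lo]
        nfrag = cumn[hi] - cumn[lo]
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": values,
                 "n_frag": nfrag}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    if cap_quantile is not None:
        cap = float(np.quantile(table["value"].to_numpy(), cap_quantile))
        table["value"] = np.minimum(table["value"], cap)
    return WindowTrack(window_size, step, table)


def window_zscores(track: WindowTrack) -> pd.DataFrame:
    """Per-window z, one-sided upper-tail p, and BH q over informative windows."""
    tab = track.table.copy()
    informative = tab["n_frag"].to_numpy() > 0
    vals = tab.loc[informative, "value"].to_numpy(dtype=np.float64)
    mean = vals.mean()
    sd = vals.std(ddof=0)
    z = np.full(len(tab), np.nan)
    p = np.full(len(tab), np.nan)
    q = np.full(len(tab), np.nan)
    if sd > 0:
        zi = (vals - mean) / sd
        pi = stats.norm.sf(zi)
        qi = multipletests(pi, method="fdr_bh")[1]
        z[informative] = zi
        p[informative] = pi
        q[informative] = qi
    tab["z"], tab["p"], tab["q"] = z, p, q
    return tab


def detect_observed_baits(
    tracks: list[WindowTrack],
    alpha: float = DETECT_ALPHA,
    merge_gap: int = MERGE_GAP,
    threshold_on: str = "p",
) -> list[ObservedBait]:
    """Replicate-supported enriched regions from non-overlapping windows.

    Per replicate: z against the genome-wide mean/SD of informative windows,
    one-sided normal p, BH q; windows with p < alpha (``threshold_on="p"``,
    the default) or q < alpha (``threshold_on="q"``) are kept and merged
    when separated by at most ``merge_gap``.  Final regions are those
    overlapping a kept region in every replicate; the reported region is
    the union hull of the supporting regions, peak_z the maximum window z
    inside it, and p/q the smallest supporting window values.

    The raw-p default reflects that viewpoint windows themselves inflate
    the genome-wide SD: background windows then sit far below the z = 1.645
    line, so the nominal threshold is self-guarding, while BH adjustment
    (computed and reported either way) can push boundary-straddling
    viewpoints whose signal splits across two windows below significance.
    """
    if threshold_on not in ("p", "q"):
        raise ValueError("threshold_on must be 'p' or 'q'")
    if not tracks:
        raise ValueError("at least one replicate track required")
    ref = tracks[0]
    for t in tracks[1:]:
        if t.window_size != ref.window_size or t.step != ref.step or len(t.table) != len(ref.table):
            raise ValueError("replicates must share identical windowing")
    per_rep_regions: list[list[GenomicInterval]] = []
    scored_tables = []
    for t in tracks:
        tab = window_zscores(t)
        scored_tables.append(tab)
        if np.all(np.isnan(tab["z"].to_numpy())):
            warnings.warn(
                "flat genome-wide signal (sd = 0): no windows can be called",
                stacklevel=2,
            )
            per_rep_regions.append([])
            continue
        sig = tab[tab[threshold_on] < alpha]
        wins = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sig.itertuples()
        ]
        per_rep_regions.append(merge_intervals(wins, gap=merge_gap))
    if any(len(r) == 0 for r in per_rep_regions):
        return []

    # replicate intersection by any-overlap; report the union hull
    out = []
    others = [IntervalIndex(r) for r in per_rep_regions[1:]]
    for region in per_rep_regions[0]:
        supported = all(ix.overlap_interval(region) for ix in others)
        if not supported:
            continue
        lo, hi = region.start, region.end
        for regions in per_rep_regions[1:]:
            for r in regions:
                if r.overlaps(GenomicInterval(region.chrom, lo, hi)):
                    lo, hi = min(lo, r.start), max(hi, r.end)
        hull = GenomicInterval(region.chrom, lo, hi)
        peak_z, p_val, q_val = -np.inf, 1.0, 1.0
        for tab in scored_tables:
            sub = tab[
                (tab["chrom"] == hull.chrom)
                & (tab["end"] > hull.start)
                & (tab["start"] < hull.end)
                & tab["z"].notna()
            ]
            if len(sub):
                peak_z = max(peak_z, float(sub["z"].max()))
                p_val = min(p_val, float(sub["p"].min()))
                q_val = min(q_val, float(sub["q"].min()))
        out.append(ObservedBait(hull, peak_z, p_val, q_val, len(tracks)))
    return out


@dataclass
class BaitSetComparison:
    """Any-overlap Venn partition of two region sets."""

    shared_a: list[GenomicInterval]
    shared_b: list[GenomicInterval]
    a_only: list[GenomicInterval]
    b_only: list[GenomicInterval]

    @property
    def shared(self) -> int:
        # counts agree between sides whenever the overlap graph is one-to-one
        return len(self.shared_a)

    @property
    def n_a_only(self) -> int:
        return len(self.a_only)

    @property
    def n_b_only(self) -> int:
        return len(self.b_only)


def _regions_of(items) -> list[GenomicInterval]:
    regions = []
    for x in items:
        if isinstance(x, GenomicInterval):
            regions.append(x)
        elif hasattr(x, "region"):
            regions.append(x.region)
        elif hasattr(x, "amplicon"):
            regions.append(x.amplicon)
        else:
            raise TypeError(f"cannot extract a region from {type(x).__name__}")
    return regions


def compare_bait_sets(a, b) -> BaitSetComparison:
    """Partition two bait sets (observed or predicted) by any-overlap."""
    ra, rb = _regions_of(a), _regions_of(b)
    ib = IntervalIndex(rb)
    ia = IntervalIndex(ra)
    shared_a = [r for r in ra if ib.overlap_interval(r)]
    a_only = [r for r in ra if not ib.overlap_interval(r)]
    shared_b = [r for r in rb if ia.overlap_interval(r)]
    b_only = [r for r in rb if not ia.overlap_interval(r)]
    return BaitSetComparison(shared_a, shared_b, a_only, b_only)


def write_observed_baits(baits: list[ObservedBait], path) -> None:
    """BED6+ with z, p, q and replicate support in extra columns."""
    with open(path, "w") as fh:
        for b in baits:
            r = b.region
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tobserved_bait\t0\t.\t"
                f"{b.peak_z:.6g}\t{b.p_value:.6g}\t{b.q_value:.6g}\t{b.replicate_support}\n"
            )
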