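"""Compartment and TAD context for TE-anchored interactions.

A/B compartments are read from the first principal component of the
distance-normalized Hi-C correlation matrix, per chromosome: observed /
expected (per-diagonal mean, no smoothing), Pearson correlation across bin
profiles, leading eigenvector, sign oriented against a user-supplied
reference track (e.g. gene density) so that positive scores mean the active
A compartment.  TAD membership of an interaction is decided by both end
midpoints falling inside one TAD interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval
from .capture import Interaction


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact matrix must be nonnegative")
        self.matrix = m

    @classmethod
    def from_dense_tsv(cls, chrom: str, bin_size: int, path) -> "ContactMatrix":
        return cls(chrom, bin_size, np.loadtxt(path, delimiter="\t"))

    @classmethod
    def from_coo_tsv(cls, chrom: str, bin_size: int, path) -> "ContactMatrix":
        """3-column (bin_i, bin_j, value) triplets; symmetrized."""
        tab = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "v"])
        n = int(max(tab["i"].max(), tab["j"].max())) + 1
        m = np.zeros((n, n))
        m[tab["i"], tab["j"]] = tab["v"]
        m[tab["j"], tab["i"]] = tab["v"]
        return cls(chrom, bin_size, m)

    def to_dense_tsv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter="\t", fmt="%.10g")


@dataclass
class CompartmentTrack:
    """Per-bin PC score and A/B label; masked bins carry NaN and no label."""

    chrom: str
    bin_size: int
    scores: np.ndarray  # NaN where masked

    @property
    def labels(self) -> np.ndarray:
        out = np.full(len(self.scores), "", dtype=object)
        defined = ~np.isnan(self.scores)
        out[defined & (self.scores > 0)] = "A"
        out[defined & (self.scores <= 0)] = "B"
        return out

    def bins(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, i * self.bin_size, (i + 1) * self.bin_size)
            for i in range(len(self.scores))
        ]

    def to_bedgraph(self, path) -> None:
        from .core import write_bedgraph

        rows = [
            (self.chrom, i * self.bin_size, (i + 1) * self.bin_size, float(s))
            for i, s in enumerate(self.scores)
            if not np.isnan(s)
        ]
        write_bedgraph(rows, path)


def observed_over_expected(matrix: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-diagonal mean normalization restricted to unmasked bins."""
    n = matrix.shape[0]
    oe = np.zeros_like(matrix)
    valid = np.outer(mask, mask)
    for d in range(n):
        idx = (np.arange(n - d), np.arange(d, n))
        vals = matrix[idx]
        ok = valid[idx]
        if ok.any():
            exp = vals[ok].mean()
            if exp > 0:
                oe[idx] = np.where(ok, vals / exp, 0.0)
                if d:
                    oe[(idx[1], idx[0])] = oe[idx]
    return oe


def compartment_scores(
    m: ContactMatrix, reference_track: np.ndarray
) -> CompartmentTrack:
    """First principal component of the O/E correlation matrix, per bin.

    ``reference_track`` supplies one value per bin; the component sign is
    flipped if needed so it correlates positively with the reference.
    Zero-coverage bins are masked (NaN score, excluded from labels).
    """
    mat = m.matrix
    n = mat.shape[0]
    reference_track = np.asarray(reference_track, dtype=np.float64)
    if len(reference_track) != n:
        raise ValueError("reference track must cover every bin")
    mask = mat.sum(axis=1) > 0
    if not mask.any():
        raise ValueError("all-zero contact matrix")
    if mask.sum() < 10:
        raise ValueError("fewer than 10 informative bins")
    oe = observed_over_expected(mat, mask)
    sub = oe[np.ix_(mask, mask)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    w, v = np.linalg.eigh(corr)
    pc1 = v[:, -1]
    ref = reference_track[mask]
    if np.std(ref) > 0 and np.corrcoef(pc1, ref)[0, 1] < 0:
        pc1 = -pc1
    scores = np.full(n, np.nan)
    scores[mask] = pc1
    return CompartmentTrack(m.chrom, m.bin_size, scores)


def pc_of_regions(
    regions: list[GenomicInterval], track: CompartmentTrack
) -> tuple[list[float | None], float | None]:
    """Coverage-weighted mean PC score per region, and the fraction positive.

    A region overlapping no informative bin gets None and is excluded from
    the fraction denominator; with no evaluable region the fraction is None.
    """
    values: list[float | None] = []
    bs = track.bin_size
    for r in regions:
        if r.chrom != track.chrom:
            raise ValueError(f"region {r} not on track chromosome {track.chrom}")
        first = r.start // bs
        last = (r.end - 1) // bs
        wsum = 0.0
        vsum = 0.0
        for b in range(first, last + 1):
            if b >= len(track.scores) or np.isnan(track.scores[b]):
                continue
            ov = min(r.end, (b + 1) * bs) - max(r.start, b * bs)
            wsum += ov
            vsum += ov * track.scores[b]
        values.append(vsum / wsum if wsum > 0 else None)
    defined = [v for v in values if v is not None]
    frac = (sum(1 for v in defined if v > 0) / len(defined)) if defined else None
    return values, frac


def classify_interactions_by_tad(
    ints: list[Interaction], tads: list[GenomicInterval]
) -> dict:
    """Partition interactions into trans / cis same-TAD / cis different-TAD.

    An interaction is same-TAD iff the midpoints of both ends fall inside
    one TAD interval (midpoint rule: border-straddling fragments classify
    deterministically).  TADs must be non-overlapping per chromosome.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in sorted(tads, key=lambda x: (x.chrom, x.start)):
        lst = by_chrom.setdefault(t.chrom, [])
        if lst and t.start < lst[-1].end:
            raise ValueError(f"overlapping TADs on {t.chrom}")
        lst.append(t)

    def tad_of(chrom: str, pos: int) -> int | None:
        lst = by_chrom.get(chrom, [])
        starts = [t.start for t in lst]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < lst[i].end:
            return i
        return None

    trans = cis_same = cis_diff = 0
    for i in ints:
        if not i.is_cis():
            trans += 1
            continue
        a = tad_of(i.anchor.chrom, i.anchor.midpoint)
        b = tad_of(i.other_end.chrom, i.other_end.midpoint)
        if a is not None and a == b:
            cis_same += 1
        else:
            cis_diff += 1
    n_cis = cis_same + cis_diff
    return {
        "trans": trans,
        "cis_same_tad": cis_same,
        "cis_diff_tad": cis_diff,
        "same_tad_fraction_of_cis": (cis_same / n_cis) if n_cis else None,
    }


def interaction_distance_stats(
    ints: list[Interaction],
) -> tuple[list[int], float | None]:
    """Anchor-to-other-end midpoint distances for cis interactions, + median."""
    distances = [d for i in ints if (d := i.distance()) is not None]
    median = float(np.median(distances)) if distances else None
    return distances, median
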