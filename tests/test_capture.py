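"""Probe targets, pair filtering, anchor selection, interaction import."""

import numpy as np
import pandas as pd
import pytest

import te4c
from te4c import DPNII, Genome, GenomicInterval, TEAnnotation
from te4c.capture import (
    PAIR_COLUMNS,
    fragment_read_counts,
    pairs_from_bedpe,
    pairs_to_bedpe,
    write_interactions_bedpe,
    write_interactions_ibed,
)


def smith_waterman(a: str, b: str):
    """Quadratic local-alignment oracle (match 1 / mismatch -1 / open -2 / ext -1)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (deletion from b)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - 2, E[i][j - 1] - 1)
            F[i][j] = max(H[i - 1][j] - 2, F[i - 1][j] - 1)
            s = 1 if a[i - 1] == b[j - 1] else -1
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_dna(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


def make_pairs(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


@pytest.fixture(scope="module")
def probe():
    return random_dna(10, 120)


class TestProbeTargets:
    def test_verbatim_probe_single_hit(self, probe):
        seq = random_dna(11, 20_000)
        seq = seq[:8000] + probe + seq[8120:]
        hits = te4c.predict_probe_targets(Genome({"c": seq}), probe)
        assert len(hits) == 1
        assert hits[0].start <= 8000 and hits[0].end >= 8120 - 5

    def test_diverged_copy_found_and_score_matches_dp_oracle(self, probe):
        rng = np.random.default_rng(12)
        copy = list(probe)
        for i in rng.choice(120, size=18, replace=False):  # 15% divergence
            copy[i] = rng.choice([b for b in "ACGT" if b != copy[i]])
        copy = "".join(copy)
        seq = random_dna(13, 10_000)
        seq = seq[:5000] + copy + seq[5120:]
        hits = te4c.predict_probe_targets(Genome({"c": seq}), probe)
        assert len(hits) == 1
        # best local score in the hit region equals the full DP oracle
        window = seq[4500:5700]
        from te4c.capture import _local_aligner

        score = _local_aligner().align(window, probe).score
        assert score == smith_waterman(window, probe)

    def test_reverse_strand_copy_found(self, probe):
        seq = random_dna(14, 10_000)
        seq = seq[:4000] + te4c.revcomp(probe) + seq[4120:]
        hits = te4c.predict_probe_targets(Genome({"c": seq}), probe)
        assert len(hits) == 1

    def test_shuffled_probe_control_no_hits(self, probe):
        rng = np.random.default_rng(15)
        shuffled = "".join(rng.permutation(list(probe)))
        seq = random_dna(16, 30_000)
        hits = te4c.predict_probe_targets(Genome({"c": seq}), shuffled)
        assert hits == []


class TestPairsToFragments:
    @pytest.fixture()
    def rmap(self):
        # chromosome with a cut every 200 bp -> many small fragments
        seq = ("A" * 196 + "GATC") * 500
        return te4c.digest_genome(Genome({"c": seq, "d": seq}), DPNII)

    def test_close_cis_pair_removed_far_retained(self, rmap):
        pairs = make_pairs(
            [
                ("c", 10 * 200 + 5, "+", "c", 60 * 200 + 5, "-"),   # sep 50
                ("c", 10 * 200 + 5, "+", "c", 200 * 200 + 5, "-"),  # sep 190
            ]
        )
        out = te4c.pairs_to_fragments(pairs, rmap)
        assert len(out) == 1
        assert abs(out.iloc[0]["frag2"] - out.iloc[0]["frag1"]) == 190

    def test_trans_pair_retained_duplicates_collapsed(self, rmap):
        row = ("c", 1000, "+", "d", 50_000, "-")
        pairs = make_pairs([row, row, ("d", 50_000, "-", "c", 1000, "+")])
        out = te4c.pairs_to_fragments(pairs, rmap)
        assert len(out) == 1  # byte-identical + orientation-swapped collapse

    def test_idempotent_and_never_grows(self, rmap):
        rng = np.random.default_rng(20)
        rows = [
            (
                rng.choice(["c", "d"]), int(rng.integers(0, 99_999)), "+",
                rng.choice(["c", "d"]), int(rng.integers(0, 99_999)), "-",
            )
            for _ in range(500)
        ]
        pairs = make_pairs(rows)
        once = te4c.pairs_to_fragments(pairs, rmap)
        twice = te4c.pairs_to_fragments(once[PAIR_COLUMNS], rmap)
        assert len(once) <= len(pairs)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_position_outside_fragments_errors(self, rmap):
        pairs = make_pairs([("c", 10**9, "+", "c", 0, "-")])
        with pytest.raises(ValueError):
            te4c.pairs_to_fragments(pairs, rmap)


class TestSelectAnchors:
    def _setup(self, seed=0, n_frag=10_000, n_anchors=5, anchor_count=400):
        # one chromosome, fragment every 100 bp
        seq = ("A" * 96 + "GATC") * n_frag
        genome = Genome({"c": seq})
        rmap = te4c.digest_genome(genome, DPNII)
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2, size=rmap.n_fragments("c"))
        anchor_idx = rng.choice(rmap.n_fragments("c"), size=n_anchors, replace=False)
        counts[anchor_idx] = anchor_count
        # synthesize pairs touching each fragment `count` times, every pair
        # with a distinct partner position so nothing collapses as duplicate
        chrom_len = len(genome["c"])
        rows = []
        for fi, c in enumerate(counts):
            pos = int(rmap.boundaries["c"][fi]) + 1
            for k in range(c):
                partner = (fi * 7919 + k * 104729) % (chrom_len - 10)
                rows.append(("c", pos, "+", "c", partner, "-"))
        pairs = make_pairs(rows)
        pairs = te4c.pairs_to_fragments(pairs, rmap, min_fragment_separation=0)
        return genome, rmap, pairs, set(anchor_idx.tolist()), counts

    def test_top_count_fragments_selected(self):
        genome, rmap, pairs, anchor_idx, counts = self._setup()
        te = [TEAnnotation(GenomicInterval("c", 0, len(genome["c"])), "fam")]
        anchors, removed = te4c.select_anchors(
            pairs, rmap, 0.0005, None, te, "fam"
        )
        got = {a.index for a in anchors}
        assert anchor_idx <= got
        # sort-based oracle: strictly above the (1 - q) quantile
        fr = fragment_read_counts(pairs, rmap)
        thr = np.quantile(fr["count"], 1 - 0.0005)
        expected = set(fr.loc[fr["count"] > thr, "index"])
        assert got == expected

    def test_flat_counts_yield_no_anchors(self):
        seq = ("A" * 96 + "GATC") * 1000
        genome = Genome({"c": seq})
        rmap = te4c.digest_genome(genome, DPNII)
        rows = [("c", int(rmap.boundaries["c"][i]) + 1, "+",
                 "c", int(rmap.boundaries["c"][i + 500]) + 1, "-")
                for i in range(400)]
        pairs = te4c.pairs_to_fragments(make_pairs(rows), rmap, 0)
        anchors, _ = te4c.select_anchors(pairs, rmap, 0.0005)
        counts = fragment_read_counts(pairs, rmap)["count"]
        if counts.nunique() == 1:
            assert anchors == []

    def test_family_filter_removes_and_tallies(self):
        genome, rmap, pairs, anchor_idx, counts = self._setup()
        # annotate only some anchors with the target family
        keep = sorted(anchor_idx)[:2]
        te = [
            TEAnnotation(
                GenomicInterval(
                    "c",
                    int(rmap.boundaries["c"][i]),
                    int(rmap.boundaries["c"][i + 1]),
                ),
                "fam",
            )
            for i in keep
        ]
        anchors, removed = te4c.select_anchors(pairs, rmap, 0.0005, None, te, "fam")
        assert {a.index for a in anchors} == set(keep)
        assert removed >= len(anchor_idx) - len(keep)

    def test_empty_pairs(self):
        seq = ("A" * 96 + "GATC") * 10
        rmap = te4c.digest_genome(Genome({"c": seq}), DPNII)
        assert te4c.select_anchors(make_pairs([]), rmap) == ([], 0)


class TestInteractionIO:
    def _ints(self):
        return [
            te4c.Interaction(
                GenomicInterval("chr1", 1000, 1500, name=f"a{k}"),
                GenomicInterval("chr1" if k % 2 else "chr2", 5000 + 100 * k, 5100 + 100 * k),
                7.5 + k,
            )
            for k in range(10)
        ]

    def test_score_cutoff_boundary(self, tmp_path):
        p = tmp_path / "i.bedpe"
        rows = [
            ("c", 0, 10, "c", 100, 110, "x", 7.4, ".", "."),
            ("c", 0, 10, "c", 200, 210, "y", 7.5, ".", "."),
        ]
        te4c.write_bedpe(rows, p)
        ints = te4c.load_interactions(p)
        assert len(ints) == 1 and ints[0].score == 7.5

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bedpe"
        p.write_text("")
        assert te4c.load_interactions(p) == []

    def test_bedpe_and_ibed_parse_identically(self, tmp_path):
        ints = self._ints()
        p1, p2 = tmp_path / "a.bedpe", tmp_path / "a.ibed"
        write_interactions_bedpe(ints, p1)
        write_interactions_ibed(ints, p2)
        from_bedpe = te4c.load_interactions(p1)
        from_ibed = te4c.load_interactions(p2)
        key = lambda i: (i.anchor.chrom, i.anchor.start, i.anchor.end,
                         i.other_end.chrom, i.other_end.start, i.other_end.end,
                         i.score)
        assert sorted(map(key, from_bedpe)) == sorted(map(key, from_ibed))

    def test_ibed_roundtrip_byte_identical(self, tmp_path):
        ints = te4c.load_interactions.__wrapped__ if False else None
        p1, p2 = tmp_path / "a.ibed", tmp_path / "b.ibed"
        write_interactions_ibed(self._ints(), p1)
        write_interactions_ibed(te4c.load_interactions(p1, score_cutoff=0), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("c\t0\t10\tc\t100\n")
        with pytest.raises(ValueError, match="line 1"):
            te4c.load_interactions(p)

    def test_pair_bedpe_roundtrip(self, tmp_path):
        rows = [("c", 5, "+", "d", 9, "-"), ("c", 7, "-", "c", 1000, "+")]
        pairs = make_pairs(rows)
        back = pairs_from_bedpe(pairs_to_bedpe(pairs))
        pd.testing.assert_frame_equal(pairs, back)


class TestSignalTracks:
    @pytest.fixture()
    def setup(self):
        seq = ("A" * 996 + "GATC") * 2000  # 1 kb fragments, 2 Mb chrom
        genome = Genome({"c": seq})
        rmap = te4c.digest_genome(genome, DPNII)
        anchor_fi = 1000
        anchor = te4c.AnchorFragment(
            rmap.fragment("c", anchor_fi), anchor_fi, 10, True, frozenset()
        )
        return rmap, anchor

    def test_bin_count_in_one_mb_region(self, setup):
        rmap, anchor = setup
        rows = [("c", int(rmap.boundaries["c"][1000]) + 5, "+",
                 "c", 1_200_000 + 10 * k, "-") for k in range(30)]
        pairs = te4c.pairs_to_fragments(make_pairs(rows), rmap, 0)
        tr = te4c.anchor_signal_track(pairs, anchor)
        assert len(tr.table) == 1999

    def test_other_end_in_bin_overlap_counted_twice(self, setup):
        rmap, anchor = setup
        # other end at a position covered by two overlapping 1 kb bins
        pos = anchor.fragment.midpoint + 10_750
        rows = [("c", int(rmap.boundaries["c"][1000]) + 5, "+", "c", pos, "-")]
        pairs = te4c.pairs_to_fragments(make_pairs(rows), rmap, 0)
        tr = te4c.anchor_signal_track(pairs, anchor)
        covering = tr.table[(tr.table.start <= pos) & (pos < tr.table.end)]
        assert len(covering) == 2
        assert (covering["value"] == 1).all()
        assert tr.table["value"].sum() == 2

    def test_pair_outside_region_ignored(self, setup):
        rmap, anchor = setup
        far = anchor.fragment.midpoint + 700_000
        rows = [("c", int(rmap.boundaries["c"][1000]) + 5, "+", "c", far, "-")]
        pairs = te4c.pairs_to_fragments(make_pairs(rows), rmap, 0)
        tr = te4c.anchor_signal_track(pairs, anchor)
        assert tr.table["value"].sum() == 0


class TestSizeFactors:
    def _track(self, values):
        from te4c.profile import WindowTrack

        n = len(values)
        tab = pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "value": np.asarray(values, dtype=float),
                "n_frag": 1,
            }
        )
        return WindowTrack(1000, 1000, tab)

    def test_identical_samples_unit_factors(self):
        vals = np.random.default_rng(0).poisson(10, 200) + 1.0
        f, norm = te4c.size_factor_normalize(
            {"a": self._track(vals), "b": self._track(vals)}
        )
        assert f["a"] == pytest.approx(1.0) and f["b"] == pytest.approx(1.0)

    def test_doubled_sample_factor_ratio_two(self):
        vals = np.random.default_rng(1).poisson(10, 200) + 1.0
        f, norm = te4c.size_factor_normalize(
            {"a": self._track(vals), "b": self._track(2 * vals)}
        )
        assert f["b"] / f["a"] == pytest.approx(2.0, rel=1e-12)
        a = norm["a"].table["value"].to_numpy()
        b = norm["b"].table["value"].to_numpy()
        assert np.allclose(a, b, rtol=1e-9)

    def test_zero_bins_excluded_from_median(self):
        vals = np.arange(1.0, 101.0)
        v2 = 3 * vals.copy()
        v2[:50] = 0.0  # common-nonzero bins are the upper half only
        f, _ = te4c.size_factor_normalize(
            {"a": self._track(vals), "b": self._track(v2)}
        )
        assert f["b"] / f["a"] == pytest.approx(3.0, rel=1e-12)

    def test_no_common_nonzero_bin_errors(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            te4c.size_factor_normalize({"a": self._track(a), "b": self._track(b)})
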