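"""Read counting, overhang filtering, normalization, PSI and the EM."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from splicedose.gene_model import ExonicPart, Junction
from splicedose.quantify import (
    AlignedRead,
    CountMatrix,
    count_exonic_parts,
    count_introns,
    estimate_psi,
    extract_junction_counts,
    normalize,
    quantify_transcripts_em,
    rpkm,
    rpm,
    splice_site_activity,
)
from splicedose.synthetic_data import emit_junction_reads


def brute_force_junction_counts(reads, min_overhang):
    """Independent per-read recount of gap observations."""
    tallies = {}
    for read in reads:
        blocks = list(read.blocks)
        for i in range(len(blocks) - 1):
            left = blocks[i][1] - blocks[i][0]
            right = blocks[i + 1][1] - blocks[i + 1][0]
            if left >= min_overhang and right >= min_overhang:
                key = (blocks[i][1], blocks[i + 1][0])
                tallies[key] = tallies.get(key, 0) + 1
    return tallies


class TestJunctionCounting:
    def test_exact_six_nt_overhang_counts(self):
        reads = {"s": [AlignedRead(((94, 100), (200, 206)))]}
        cm = extract_junction_counts(reads, min_overhang=6)
        assert cm.counts.loc["chr:100-200:+", "s"] == 1

    def test_five_nt_overhang_filtered(self):
        reads = {"s": [AlignedRead(((95, 100), (200, 210)))]}
        cm = extract_junction_counts(reads, min_overhang=6)
        assert cm.counts.empty or cm.counts["s"].sum() == 0

    def test_unspliced_reads_contribute_nothing(self):
        cm = extract_junction_counts({"s": [AlignedRead(((0, 50),))]})
        assert cm.counts.empty or cm.counts["s"].sum() == 0
        assert cm.library_sizes["s"] == 1

    def test_multi_gap_read_counts_each_junction(self):
        read = AlignedRead(((0, 10), (20, 30), (40, 50)))
        cm = extract_junction_counts({"s": [read]}, min_overhang=6)
        assert cm.counts["s"].sum() == 2

    def test_simulated_reads_match_brute_force(self):
        reads = emit_junction_reads(0.7, 1000, seed=5)
        cm = extract_junction_counts({"s": reads}, min_overhang=6,
                                     chrom="chr19")
        oracle = brute_force_junction_counts(reads, 6)
        assert cm.counts["s"].sum() == sum(oracle.values())
        for (donor, acceptor), n in oracle.items():
            assert cm.counts.loc[f"chr19:{donor}-{acceptor}:+", "s"] == n

    def test_overhang_filter_monotone(self):
        reads = emit_junction_reads(0.5, 500, seed=11)
        loose = extract_junction_counts({"s": reads}, min_overhang=1,
                                        chrom="chr19").counts
        strict = extract_junction_counts({"s": reads}, min_overhang=6,
                                         chrom="chr19").counts
        strict = strict.reindex(loose.index).fillna(0)
        assert (loose["s"] >= strict["s"]).all()

    def test_min_overhang_must_be_positive(self):
        with pytest.raises(ValueError):
            extract_junction_counts({"s": []}, min_overhang=0)


class TestOverlapCounting:
    def test_read_within_part(self):
        parts = [ExonicPart("p1", (0, 100), frozenset({"T"}))]
        cm = count_exonic_parts({"s": [AlignedRead(((0, 50),))]}, parts)
        assert cm.counts.loc["p1", "s"] == 1

    def test_spliced_read_hits_both_parts_once_each(self):
        parts = [
            ExonicPart("p1", (0, 100), frozenset({"T"})),
            ExonicPart("p2", (200, 300), frozenset({"T"})),
        ]
        read = AlignedRead(((90, 100), (200, 210)))
        cm = count_exonic_parts({"s": [read]}, parts)
        assert cm.counts["s"].tolist() == [1, 1]

    def test_retained_intron_read_counts(self):
        cm = count_introns(
            {"s": [AlignedRead(((150, 160),))]}, {"intron:1": (100, 200)}
        )
        assert cm.counts.loc["intron:1", "s"] == 1

    def test_junction_spanning_read_skips_intron(self):
        cm = count_introns(
            {"s": [AlignedRead(((94, 100), (200, 206)))]},
            {"intron:1": (100, 200)},
        )
        assert cm.counts.loc["intron:1", "s"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_reads_match_all_pairs_oracle(self, seed):
        rng = random.Random(seed)
        features = {}
        pos = 0
        for i in range(8):
            start = pos + rng.randint(1, 10)
            end = start + rng.randint(5, 40)
            features[f"f{i}"] = (start, end)
            pos = end
        reads = []
        for _ in range(200):
            blocks = []
            start = rng.randint(0, pos)
            n_blocks = rng.randint(1, 3)
            for _ in range(n_blocks):
                end = start + rng.randint(1, 30)
                blocks.append((start, end))
                start = end + rng.randint(1, 40)
            reads.append(AlignedRead(tuple(blocks)))
        cm = count_introns({"s": reads}, features)
        for fid, (fs, fe) in features.items():
            expected = sum(
                1
                for r in reads
                if any(bs < fe and fs < be for bs, be in r.blocks)
            )
            assert cm.counts.loc[fid, "s"] == expected


class TestSpliceSiteActivity:
    def _junction_map(self):
        j78 = Junction("c", 100, 200)
        j89 = Junction("c", 300, 400)
        j79 = Junction("c", 100, 400)
        return {"j78": j78, "j89": j89, "j79": j79}

    def _counts(self, c78, c89, c79):
        frame = pd.DataFrame({"s": [c78, c89, c79]},
                             index=["j78", "j89", "j79"])
        return CountMatrix(frame)

    def test_shared_donor_adds(self):
        jm = self._junction_map()
        cm = self._counts(30, 0, 10)
        act = splice_site_activity(cm, jm)
        assert act.counts.loc["donor:c:100:+", "s"] == 40

    def test_cassette_sites(self):
        jm = self._junction_map()
        act = splice_site_activity(self._counts(30, 30, 10), jm)
        assert act.counts.loc["acceptor:c:200:+", "s"] == 30
        assert act.counts.loc["donor:c:300:+", "s"] == 30

    def test_conservation_identity_random_tables(self):
        rng = np.random.default_rng(3)
        jm = self._junction_map()
        for _ in range(20):
            c = rng.integers(0, 100, size=3)
            act = splice_site_activity(self._counts(*c), jm)
            donors = act.counts[act.counts.index.str.startswith("donor")]
            acceptors = act.counts[act.counts.index.str.startswith("acceptor")]
            assert donors["s"].sum() == acceptors["s"].sum() == c.sum()

    def test_unknown_junction_key_rejected(self):
        with pytest.raises(KeyError):
            splice_site_activity(self._counts(1, 1, 1), {"j78": Junction("c", 100, 200)})


class TestNormalization:
    def test_rpkm_definitional(self):
        assert rpkm(10, 1e6, 1000) == pytest.approx(10.0)
        assert rpkm(0, 1e6, 500) == 0.0

    def test_rpm_definitional(self):
        assert rpm(5, 1e6) == pytest.approx(5.0)
        assert rpm(0, 1e6) == 0.0

    def test_rpkm_scale_invariance(self):
        base = rpkm(13, 2.5e6, 742)
        assert rpkm(13 * 7, 2.5e6 * 7, 742) == pytest.approx(base, abs=1e-12)

    def test_rpm_linear_in_count(self):
        assert rpm(3 * 11, 9e5) == pytest.approx(3 * rpm(11, 9e5), abs=1e-12)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpm(1, 0)
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_normalize_matrix_matches_scalar(self):
        cm = CountMatrix(
            pd.DataFrame({"s1": [10, 20], "s2": [5, 0]}, index=["a", "b"]),
            pd.Series({"s1": 1e6, "s2": 2e6}),
        )
        nm = normalize(cm, "RPKM", {"a": 1000, "b": 250})
        assert nm.values.loc["a", "s1"] == pytest.approx(rpkm(10, 1e6, 1000))
        assert nm.values.loc["b", "s2"] == pytest.approx(rpkm(0, 2e6, 250))
        nm2 = normalize(cm, "RPM")
        assert nm2.values.loc["b", "s1"] == pytest.approx(rpm(20, 1e6))


class TestPsi:
    def test_inclusion_ratio(self):
        est = estimate_psi(30, 30, 10)
        assert est.psi == pytest.approx(0.75)

    def test_pure_skipping(self):
        assert estimate_psi(0, 0, 50).psi == 0.0

    def test_all_zero_flagged_not_zero(self):
        est = estimate_psi(0, 0, 0)
        assert not est.defined
        assert math.isnan(est.psi)

    def test_monte_carlo_mean_near_truth(self):
        rng = np.random.default_rng(42)
        truth, depth = 0.9, 200
        estimates = []
        for _ in range(500):
            c78 = rng.poisson(depth * truth)
            c89 = rng.poisson(depth * truth)
            c79 = rng.poisson(depth * (1 - truth))
            estimates.append(estimate_psi(c78, c89, c79).psi)
        assert abs(np.mean(estimates) - truth) < 0.02


class TestTranscriptEM:
    def test_two_class_closed_form(self):
        em = quantify_transcripts_em(
            {("full",): 90, ("skip",): 10}, {"full": 2, "skip": 1}
        )
        assert em.theta["full"] == pytest.approx(45 / 55, abs=1e-9)
        assert em.converged

    def test_single_isoform(self):
        em = quantify_transcripts_em({("only",): 50}, {"only": 3})
        assert em.theta["only"] == pytest.approx(1.0)

    def test_symmetry(self):
        em = quantify_transcripts_em(
            {("a",): 40, ("b",): 40}, {"a": 2, "b": 2}
        )
        assert em.theta["a"] == pytest.approx(0.5)

    def test_loglik_monotone_and_order_invariant(self):
        classes = {("a",): 55, ("b",): 20, ("a", "b"): 25}
        em = quantify_transcripts_em(classes, {"a": 3, "b": 1})
        diffs = np.diff(em.log_likelihood)
        assert (diffs >= -1e-10).all()
        flipped = {("a", "b"): 25, ("b",): 20, ("a",): 55}
        em2 = quantify_transcripts_em(flipped, {"a": 3, "b": 1})
        assert em.theta["a"] == pytest.approx(em2.theta["a"], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_grid_search_oracle(self, seed):
        """On two-isoform problems the EM optimum matches a 1e-3 grid
        maximization of the class-multinomial log-likelihood."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 100, size=3)
        classes = {("a",): int(counts[0]), ("b",): int(counts[1]),
                   ("a", "b"): int(counts[2])}
        J = {"a": int(rng.integers(1, 5)), "b": int(rng.integers(1, 5))}

        def loglik(theta_a):
            mass_a, mass_b = theta_a * J["a"], (1 - theta_a) * J["b"]
            z = mass_a + mass_b
            return (
                counts[0] * math.log(mass_a / z)
                + counts[1] * math.log(mass_b / z)
                + counts[2] * math.log(1.0)
            )

        grid = np.arange(1e-3, 1.0, 1e-3)
        best = grid[np.argmax([loglik(t) for t in grid])]
        em = quantify_transcripts_em(classes, J)
        assert em.theta["a"] == pytest.approx(best, abs=1.5e-3)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            quantify_transcripts_em({}, {"a": 1})
        with pytest.raises(ValueError):
            quantify_transcripts_em({("a",): 5}, {"a": 0})
        with pytest.raises(KeyError):
            quantify_transcripts_em({("ghost",): 5}, {"a": 1})
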