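"""Regulatory potential, rank products and direction tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methregen.integration import (
    DirectionTestResult,
    RegulatoryPotentialParams,
    _d_plus,
    direction_test,
    overlap_sets,
    peaks_from_dm,
    rank_product_integration,
    regulatory_potential,
    score_genes,
)
from methregen.io import GeneModel, MethylationPeak, ValidationError

DEFAULTS = RegulatoryPotentialParams()


def _gene(tss=1_000_000, strand="+", chrom="chr1", gid="g"):
    if strand == "+":
        start, end = tss - 1, tss - 1 + 10_000
    else:
        start, end = tss - 10_000, tss
    return GeneModel(gid, gid, chrom, strand, tss, start, end)


def _peak(pos, chrom="chr1", pid="cg", direction="hypo"):
    return MethylationPeak(chrom, pos, pid, direction)


class TestPeaksFromDM:
    def _dm(self, n_sig, n_ns, effects=None):
        n = n_sig + n_ns
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "effect": effects if effects is not None else [-0.2] * n,
                "q": [0.01] * n_sig + [0.5] * n_ns,
                "chrom": "chr1",
                "pos": np.arange(1, n + 1) * 100,
            }
        )

    def test_no_significant_probes_empty(self):
        assert peaks_from_dm(self._dm(0, 5)) == []

    def test_direction_filter_semantics(self):
        dm = self._dm(3, 0, effects=[-0.2, -0.1, 0.3])
        assert len(peaks_from_dm(dm, direction_filter="hypo_only")) == 2
        assert len(peaks_from_dm(dm, direction_filter="hyper_only")) == 1
        assert len(peaks_from_dm(dm, direction_filter="both")) == 3

    def test_count_conservation_on_random_tables(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            dm = pd.DataFrame(
                {
                    "probe_id": [f"cg{i}" for i in range(n)],
                    "effect": rng.normal(size=n),
                    "q": rng.random(n),
                    "chrom": rng.choice(["chr1", "chr2"], n),
                    "pos": rng.integers(1, 10**6, n),
                }
            )
            peaks = peaks_from_dm(dm, direction_filter="both")
            assert len(peaks) == ((dm["q"] < 0.05) & (dm["effect"] != 0)).sum()

    def test_missing_manifest_position_errors(self):
        dm = pd.DataFrame({"probe_id": ["cgX"], "effect": [-0.1], "q": [0.01]})
        manifest = pd.DataFrame(
            {"probe_id": ["other"], "chrom": ["chr1"], "pos": [10]}
        )
        with pytest.raises(ValidationError, match="cgX"):
            peaks_from_dm(dm, manifest)

    def test_sorted_by_position(self, rng):
        dm = self._dm(20, 0)
        dm["pos"] = rng.permutation(dm["pos"].to_numpy())
        peaks = peaks_from_dm(dm)
        assert peaks == sorted(peaks, key=lambda p: (p.chrom, p.pos, p.probe_id))


class TestRegulatoryPotential:
    def test_peak_at_tss_closed_form(self):
        rp = regulatory_potential(_gene(), [_peak(1_000_000)], DEFAULTS)
        assert rp == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_no_peaks_in_window_zero(self):
        rp = regulatory_potential(_gene(), [_peak(1_000_000 + 100_001)], DEFAULTS)
        assert rp == 0.0

    def test_two_peak_closed_form(self):
        peaks = [_peak(1_000_000), _peak(1_100_000)]
        rp = regulatory_potential(_gene(), peaks, DEFAULTS)
        assert rp == pytest.approx(math.exp(-0.5) + math.exp(-4.5), abs=1e-12)

    def test_randomized_properties(self, rng):
        """Additivity, distance monotonicity, order and strand-mirror
        invariance over randomized gene/peak configurations."""
        for _ in range(200):
            tss = int(rng.integers(200_000, 5_000_000))
            gene_plus = _gene(tss=tss, strand="+")
            n = int(rng.integers(1, 8))
            offsets = rng.integers(-100_000, 100_000, n)
            peaks = [_peak(int(tss + o), pid=f"cg{i}") for i, o in enumerate(offsets)]
            rp = regulatory_potential(gene_plus, peaks, DEFAULTS)
            # additivity over single peaks
            parts = sum(regulatory_potential(gene_plus, [p], DEFAULTS) for p in peaks)
            assert rp == pytest.approx(parts, rel=1e-12)
            # order invariance
            shuffled = [peaks[i] for i in rng.permutation(n)]
            assert regulatory_potential(gene_plus, shuffled, DEFAULTS) == pytest.approx(rp)
            # strand mirror: reflect peak offsets around the TSS of a minus-strand gene
            gene_minus = _gene(tss=tss, strand="-")
            mirrored = [_peak(int(tss - o), pid=f"m{i}") for i, o in enumerate(offsets)]
            assert regulatory_potential(gene_minus, mirrored, DEFAULTS) == pytest.approx(rp)

    def test_strictly_decreasing_in_distance(self):
        rps = [
            regulatory_potential(_gene(), [_peak(1_000_000 + d)], DEFAULTS)
            for d in (0, 10, 1_000, 50_000, 100_000)
        ]
        assert all(a > b for a, b in zip(rps, rps[1:]))

    def test_score_genes_matches_scalar_function(self, rng):
        genes = [_gene(tss=int(t), gid=f"g{i}") for i, t in
                 enumerate(rng.integers(200_000, 2_000_000, 20))]
        peaks = sorted(
            (_peak(int(p), pid=f"cg{i}") for i, p in
             enumerate(rng.integers(150_000, 2_050_000, 100))),
            key=lambda pk: pk.pos,
        )
        table = score_genes(genes, peaks, DEFAULTS)
        for g in genes:
            assert table.loc[g.gene_id, "rp"] == pytest.approx(
                regulatory_potential(g, peaks, DEFAULTS), rel=1e-12
            )


class TestRankProduct:
    def _rp(self, d):
        return pd.DataFrame(
            {"rp": list(d.values()), "n_peaks": [1 if v > 0 else 0 for v in d.values()]},
            index=list(d.keys()),
        )

    def test_single_gene(self):
        de = pd.DataFrame(
            {"gene_id": ["g1"], "log2_fold_change": [2.0], "p": [0.001], "adj_p": [0.01]}
        )
        out = rank_product_integration(self._rp({"g1": 0.5}), de, rank_product_cutoff=1.0)
        assert out.loc[0, "rank_product"] == 1.0
        assert bool(out.loc[0, "predicted"])
        out2 = rank_product_integration(self._rp({"g1": 0.5}), de, rank_product_cutoff=0.25)
        assert not bool(out2.loc[0, "predicted"])

    def test_zero_rp_ranks_last_and_never_predicted(self):
        de = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "log2_fold_change": [1.0, 1.0, 1.0],
                "p": [0.001, 0.002, 0.003],
                "adj_p": [0.01, 0.01, 0.01],
            }
        )
        out = rank_product_integration(
            self._rp({"g1": 0.9, "g2": 0.0, "g3": 0.4}), de, rank_product_cutoff=1.0
        ).set_index("gene_id")
        assert out.loc["g2", "rank_rp"] == 3
        assert not bool(out.loc["g2", "predicted"])

    def test_hand_computed_three_gene_example(self):
        # rp ranks (1,2,3), DE ranks (2,1,3) -> rank products (2/9, 2/9, 1)
        de = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2_fold_change": [1.0, 1.0, 1.0],
                "p": [0.02, 0.01, 0.03],
                "adj_p": [0.04, 0.04, 0.04],
            }
        )
        out = rank_product_integration(
            self._rp({"a": 0.9, "b": 0.5, "c": 0.1}), de
        ).set_index("gene_id")
        np.testing.assert_allclose(
            out.loc[["a", "b", "c"], "rank_product"], [2 / 9, 2 / 9, 1.0]
        )

    def test_gene_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rp = pd.DataFrame(
            {"rp": rng.random(30), "n_peaks": rng.integers(0, 3, 30)}, index=genes
        )
        de = pd.DataFrame(
            {
                "gene_id": genes,
                "log2_fold_change": rng.normal(size=30),
                "p": rng.random(30),
                "adj_p": rng.random(30) * 0.04,
            }
        )
        a = rank_product_integration(rp, de).sort_values("gene_id").reset_index(drop=True)
        perm = rng.permutation(30)
        b = rank_product_integration(
            rp.iloc[perm], de.iloc[perm].reset_index(drop=True)
        ).sort_values("gene_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_rank_products_in_unit_interval(self, rng):
        genes = [f"g{i}" for i in range(50)]
        rp = pd.DataFrame({"rp": rng.random(50), "n_peaks": 1}, index=genes)
        de = pd.DataFrame(
            {
                "gene_id": genes,
                "log2_fold_change": rng.normal(size=50),
                "p": rng.random(50),
                "adj_p": rng.random(50),
            }
        )
        out = rank_product_integration(rp, de)
        assert ((out["rank_product"] > 0) & (out["rank_product"] <= 1)).all()


def _de_frame(set_genes, bg_genes, label="up"):
    lfc = 1.0 if label == "up" else -1.0
    return pd.DataFrame(
        {
            "gene_id": list(set_genes) + list(bg_genes),
            "log2_fold_change": [lfc] * len(set_genes) + [0.0] * len(bg_genes),
            "p": 0.01,
            "adj_p": [0.01] * len(set_genes) + [0.9] * len(bg_genes),
        }
    )


def _rp_frame(values: dict):
    return pd.DataFrame(
        {"rp": list(values.values()), "n_peaks": 1}, index=list(values.keys())
    )


class TestDirectionTest:
    def test_extreme_separation_hits_permutation_floor(self):
        set_genes = {f"u{i}": 10.0 + i for i in range(20)}
        bg_genes = {f"b{i}": float(i) / 20 for i in range(20)}
        res = direction_test(
            _rp_frame({**set_genes, **bg_genes}),
            _de_frame(set_genes, bg_genes),
            "up",
            method="permutation",
            n_permutations=999,
            seed=3,
        )
        assert res.p == pytest.approx(1 / 1000)
        assert res.d_plus == pytest.approx(1.0)

    def test_permutation_matches_exhaustive_enumeration(self, rng):
        """6-vs-6 toy: sampled permutation p equals the exhaustive
        label-assignment p within Monte-Carlo error."""
        x = rng.normal(1.0, 1.0, 6)
        y = rng.normal(0.0, 1.0, 6)
        d_obs = _d_plus(x, y)
        pooled = np.concatenate([x, y])
        idx = set(range(12))
        count = 0
        combos = list(itertools.combinations(range(12), 6))
        for combo in combos:
            rest = sorted(idx - set(combo))
            if _d_plus(pooled[list(combo)], pooled[rest]) >= d_obs - 1e-12:
                count += 1
        exact_p = count / len(combos)
        set_genes = {f"u{i}": v for i, v in enumerate(x)}
        bg_genes = {f"b{i}": v for i, v in enumerate(y)}
        B = 4999
        res = direction_test(
            _rp_frame({**set_genes, **bg_genes}),
            _de_frame(set_genes, bg_genes),
            "up",
            method="permutation",
            n_permutations=B,
            seed=7,
        )
        se = math.sqrt(exact_p * (1 - exact_p) / B)
        assert abs(res.p - exact_p) < max(4 * se, 0.01)

    def test_d_plus_agrees_with_scipy(self, rng):
        x = rng.normal(0.3, 1.0, 40)
        y = rng.normal(0.0, 1.0, 60)
        ours = _d_plus(x, y)
        # scipy's 'less' statistic is max(F_bg - F_set) for ks_2samp(set, bg)
        ks = stats.ks_2samp(x, y, alternative="less", method="asymp")
        assert ours == pytest.approx(ks.statistic, abs=1e-12)
        assert math.exp(-2 * ours**2 * 40 * 60 / 100) == pytest.approx(
            ks.pvalue, rel=0.05
        )

    def test_asymptotic_and_permutation_agree_at_scale(self, rng):
        x = rng.normal(0.15, 1.0, 200)
        y = rng.normal(0.0, 1.0, 200)
        set_genes = {f"u{i}": v for i, v in enumerate(x)}
        bg_genes = {f"b{i}": v for i, v in enumerate(y)}
        rp, de = _rp_frame({**set_genes, **bg_genes}), _de_frame(set_genes, bg_genes)
        asym = direction_test(rp, de, "up", method="asymptotic")
        perm = direction_test(rp, de, "up", method="permutation", n_permutations=1999, seed=5)
        assert abs(asym.p - perm.p) < 0.02

    def test_null_calibration_small_sample_permutation(self):
        """Same-distribution draws: fraction of p < 0.05 near nominal."""
        hits = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(10_000 + i)
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            set_genes = {f"u{k}": v for k, v in enumerate(x)}
            bg_genes = {f"b{k}": v for k, v in enumerate(y)}
            res = direction_test(
                _rp_frame({**set_genes, **bg_genes}),
                _de_frame(set_genes, bg_genes),
                "up",
                method="permutation",
                n_permutations=399,
                seed=i,
            )
            hits += res.p < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_overlapping_set_and_background_rejected(self):
        set_genes = {f"u{i}": 1.0 for i in range(5)}
        bg_genes = {f"b{i}": 0.5 for i in range(5)}
        de = _de_frame(set_genes, bg_genes)
        rp = _rp_frame({**set_genes, **bg_genes})
        with pytest.raises(ValidationError, match="overlap"):
            direction_test(rp, de, "up", background_min_adj_p=0.001)


class TestOverlapSets:
    def test_disjoint(self):
        out = overlap_sets({"a"}, {"b"})
        assert out["n_shared"] == 0 and out["n_a_only"] == 1 and out["n_b_only"] == 1

    def test_identical(self):
        out = overlap_sets({"a", "b"}, {"a", "b"})
        assert out == {"n_a_only": 0, "n_b_only": 0, "n_shared": 2, "shared": ["a", "b"]}

    def test_partition_conservation(self, rng):
        universe = [f"g{i}" for i in range(200)]
        a = set(rng.choice(universe, 80, replace=False))
        b = set(rng.choice(universe, 120, replace=False))
        out = overlap_sets(a, b)
        assert out["n_a_only"] + out["n_b_only"] + out["n_shared"] == len(a | b)
        assert out["n_a_only"] + out["n_shared"] == len(a)
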