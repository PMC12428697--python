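"""SNP filtering, Weir–Cockerham FST, CLR scan, interval selection."""

import numpy as np
import pandas as pd
import pytest

from panpav import popgen, simdata
from panpav.containers import MISSING
from panpav.simdata import SimPopConfig, SweepRegion

from conftest import make_panel


# ---------------------------------------------------------------------------
# Independent oracle: a literal transcription of the 1984 variance-component
# formulas for two populations, evaluated per site from raw genotype vectors.


def wc_oracle(geno_pop1, geno_pop2):
    comps = []
    for g1, g2 in zip(np.atleast_2d(geno_pop1), np.atleast_2d(geno_pop2)):
        stats = []
        for g in (g1, g2):
            g = g[g != MISSING]
            n_i = len(g)
            p_i = g.sum() / (2 * n_i)
            h_i = (g == 1).sum() / n_i
            stats.append((n_i, p_i, h_i))
        (n1, p1, h1), (n2, p2, h2) = stats
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        comps.append((a, b, c))
    return np.array(comps)


class TestFilterVariants:
    def test_toy_panel_tally(self):
        # five sites: multi-allelic, qual == 10, call rate 0.5, MAF 0.04, passing
        g = np.array(
            [
                [1, 0, 0, 0, 0, 0, 0, 0, 0, 0] + [0] * 40,
                [1, 1, 0, 0, 0, 0, 0, 0, 0, 0] + [1] * 40,
                [1, 1, 1, 1, 1] + [MISSING] * 45,
                [1, 1, 1, 1, 0, 0, 0, 0, 0, 0] + [0] * 40,  # MAF 4/100
                [2, 2, 2, 1, 1, 0, 0, 0, 0, 0] + [1] * 40,
            ],
            dtype=np.int8,
        )
        panel = make_panel(
            g,
            quals=[50, 10, 50, 50, 50],
            alts=["C,T", "C", "C", "C", "C"],
        )
        kept, tally = popgen.filter_variants(panel)
        assert kept.n_sites == 1
        assert kept.sites["pos"].iloc[0] == 50
        assert tally == {
            "multi_allelic": 1, "low_qual": 1, "low_call_rate": 1, "low_maf": 1
        }

    def test_empty_panel(self):
        panel = make_panel(np.empty((0, 4), dtype=np.int8))
        kept, tally = popgen.filter_variants(panel)
        assert kept.n_sites == 0 and sum(tally.values()) == 0

    def test_all_passing_identity(self, two_pop_panel):
        panel, _ = two_pop_panel
        kept, _ = popgen.filter_variants(panel, min_qual=0, min_call_rate=0, min_maf=-1)
        assert kept.n_sites == panel.n_sites
        assert np.array_equal(kept.genotypes, panel.genotypes)


class TestWcFst:
    def test_fixed_difference_theta_one(self):
        """Opposite fixation with 10 diploids per pop: a=0.5, b=c=0, theta=1."""
        g = np.array([[2] * 10 + [0] * 10], dtype=np.int8)
        panel = make_panel(g, pops=["p1"] * 10 + ["p2"] * 10)
        out = popgen.wc_fst_sites(panel, ("p1", "p2"))
        assert out["a"].iloc[0] == pytest.approx(0.5)
        assert out["b"].iloc[0] == pytest.approx(0.0)
        assert out["c"].iloc[0] == pytest.approx(0.0)
        assert out["theta"].iloc[0] == pytest.approx(1.0)

    def test_all_heterozygous_matches_oracle(self):
        g = np.array([[1] * 20], dtype=np.int8)
        panel = make_panel(g, pops=["p1"] * 10 + ["p2"] * 10)
        out = popgen.wc_fst_sites(panel, ("p1", "p2"))
        (a, b, c), = wc_oracle(g[:, :10], g[:, 10:])
        assert out["a"].iloc[0] == pytest.approx(a, abs=1e-12)
        assert out["theta"].iloc[0] == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_monomorphic_site_undefined(self):
        g = np.array([[0] * 20, [2] * 20], dtype=np.int8)
        panel = make_panel(g, pops=["p1"] * 10 + ["p2"] * 10)
        out = popgen.wc_fst_sites(panel, ("p1", "p2"))
        assert out["theta"].isna().all()

    def test_thousand_random_sites_match_oracle(self):
        """Implementation equals the independent transcription to 1e-12."""
        rng = np.random.default_rng(99)
        g = rng.integers(0, 3, size=(1000, 30)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        # guarantee every site has called genotypes in both pops
        g[:, 0] = np.abs(g[:, 0])
        g[:, 15] = np.abs(g[:, 15])
        g[g[:, 0] == MISSING, 0] = 1
        g[g[:, 15] == MISSING, 15] = 1
        panel = make_panel(g, pops=["p1"] * 15 + ["p2"] * 15)
        out = popgen.wc_fst_sites(panel, ("p1", "p2"))
        oracle = wc_oracle(g[:, :15], g[:, 15:])
        np.testing.assert_allclose(out[["a", "b", "c"]].to_numpy(), oracle, atol=1e-12)
        denom = oracle.sum(axis=1)
        defined = denom != 0
        np.testing.assert_allclose(
            out.loc[defined, "theta"], oracle[defined, 0] / denom[defined], atol=1e-12
        )
        assert (out["theta"].dropna() <= 1 + 1e-12).all()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_zero_drift_limit_gives_zero_fst(self, seed):
        """F -> 0: genome-wide mean per-site theta is 0 within Monte-Carlo error."""
        cfg = SimPopConfig(
            n_pops=2, samples_per_pop=(20, 20), n_sites=5000,
            drift=1e-6, chrom_length=5_000_000, seed=seed,
        )
        panel, _ = simdata.sim_genotypes(cfg)
        out = popgen.wc_fst_sites(panel, ("pop1", "pop2"))
        assert abs(out["theta"].mean()) < 0.01

    def test_drift_mean_matches_moment_oracle(self):
        """Ratio-of-sums FST agrees with the parametric moment estimate
        computed directly from the simulated population frequencies."""
        means, oracles = [], []
        for seed in (11, 12, 13):
            cfg = SimPopConfig(
                n_pops=2, samples_per_pop=(25, 25), n_sites=5000,
                drift=0.2, chrom_length=5_000_000, seed=seed,
            )
            panel, truth = simdata.sim_genotypes(cfg)
            out = popgen.wc_fst_sites(panel, ("pop1", "pop2"))
            means.append(out["a"].sum() / (out["a"] + out["b"] + out["c"]).sum())
            p1, p2 = truth.pop_freqs
            pbar = (p1 + p2) / 2
            s2 = (p1 - pbar) ** 2 + (p2 - pbar) ** 2  # r-1 = 1, equal weights
            oracles.append(s2.sum() / (pbar * (1 - pbar) + s2 / 2).sum())
        assert np.mean(means) == pytest.approx(np.mean(oracles), abs=0.02)


class TestWindowAggregate:
    def fst_frame(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "a", "b", "c"])
        df["theta"] = df["a"] / (df["a"] + df["b"] + df["c"])
        return df

    def test_single_site_window(self):
        rows = [("chr1", p, 0.5, 0.0, 0.0) for p in (10, 20, 30, 40, 50)]
        track = popgen.window_aggregate(self.fst_frame(rows), window_size=100)
        assert len(track) == 1
        assert track["score"].iloc[0] == pytest.approx(1.0)

    def test_ratio_of_sums_hand_example(self):
        # components (1,0,1) and (0,0,2): window FST = (1+0)/(2+2) = 0.25
        rows = [("chr1", 10, 1.0, 0.0, 1.0), ("chr1", 20, 0.0, 0.0, 2.0)]
        track = popgen.window_aggregate(self.fst_frame(rows), window_size=100, min_sites=2)
        assert track["score"].iloc[0] == pytest.approx(0.25)

    def test_sparse_windows_dropped(self):
        rows = [("chr1", 10, 0.5, 0.0, 0.5)]
        track = popgen.window_aggregate(self.fst_frame(rows), window_size=100)
        assert track.empty

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(0)
        rows = [
            ("chr1", int(p), float(a), float(b), float(c))
            for p, a, b, c in zip(
                rng.choice(10_000, 200, replace=False),
                rng.random(200), rng.random(200), rng.random(200),
            )
        ]
        t1 = popgen.window_aggregate(self.fst_frame(rows), window_size=1000)
        t2 = popgen.window_aggregate(self.fst_frame(rows[::-1]), window_size=1000)
        pd.testing.assert_frame_equal(
            t1.sort_values("start").reset_index(drop=True),
            t2.sort_values("start").reset_index(drop=True),
        )


class TestClrScan:
    def test_null_scores_near_zero_and_nonnegative(self, two_pop_panel):
        panel, _ = two_pop_panel
        track = popgen.clr_scan(panel, "pop1", "pop2", window_size=200_000)
        assert (track["score"] >= 0).all()

    def test_deterministic(self, two_pop_panel):
        panel, _ = two_pop_panel
        t1 = popgen.clr_scan(panel, "pop1", "pop2", window_size=200_000)
        t2 = popgen.clr_scan(panel, "pop1", "pop2", window_size=200_000)
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_few_informative_sites_rejected(self):
        g = np.tile([2] * 5 + [0] * 5, (30, 1)).astype(np.int8)
        panel = make_panel(g, pops=["p1"] * 5 + ["p2"] * 5)
        with pytest.raises(ValueError, match="informative"):
            popgen.clr_scan(panel, "p1", "p2")

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_sweep_windows_rank_in_top_decile(self, seed):
        sweep = SweepRegion("chr1", 2_000_000, 2_500_000, "pop1", 0.8)
        cfg = SimPopConfig(
            n_pops=2, samples_per_pop=(20, 20), n_sites=8000,
            chrom_length=10_000_000, sweeps=(sweep,), seed=seed,
        )
        panel, _ = simdata.sim_genotypes(cfg)
        track = popgen.clr_scan(panel, "pop1", "pop2")
        overlapping = track[(track["start"] < sweep.end) & (sweep.start < track["end"])]
        cutoff = np.ceil(0.1 * len(track))
        assert (overlapping["rank"] <= cutoff).any()


class TestSelectIntervals:
    def track(self, scores, chrom="chr1", size=100):
        return popgen._rank_windows(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(len(scores)) * size,
                    "end": (np.arange(len(scores)) + 1) * size,
                    "score": scores,
                    "n_sites": 10,
                }
            )
        )

    def test_identical_tracks_return_top_windows(self):
        t = self.track([5.0, 1.0, 4.0, 0.5, 0.2, 0.1, 0.3, 0.2, 0.1, 0.05])
        iv = popgen.select_intervals(t, t, top_fraction=0.2)
        assert [(r.start, r.end) for r in iv.itertuples()] == [(0, 100), (200, 300)]

    def test_disjoint_top_sets_empty(self):
        t1 = self.track([9.0, 8.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        t2 = self.track([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 9.0, 8.0])
        assert popgen.select_intervals(t1, t2, 0.2).empty

    def test_abutting_top_windows_merge(self):
        t = self.track([5.0, 4.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        iv = popgen.select_intervals(t, t, 0.2)
        assert [(r.start, r.end) for r in iv.itertuples()] == [(0, 200)]

    def test_invariant_to_window_order(self):
        rng = np.random.default_rng(5)
        t1 = self.track(list(rng.random(30)))
        t2 = self.track(list(rng.random(30)))
        iv = popgen.select_intervals(t1, t2)
        shuffled = popgen.select_intervals(
            t1.sample(frac=1, random_state=1), t2.sample(frac=1, random_state=2)
        )
        pd.testing.assert_frame_equal(
            iv[["chrom", "start", "end"]], shuffled[["chrom", "start", "end"]]
        )

    def test_empty_track_warns_and_returns_empty(self):
        t = self.track([1.0] * 10)
        empty = t.iloc[0:0]
        assert popgen.select_intervals(t, empty).empty


class TestGenesInIntervals:
    GENES = pd.DataFrame(
        {
            "gene": ["gA", "gB", "gC", "gD"],
            "chrom": ["chr1", "chr1", "chr1", "contig7"],
            "start": [100, 250, 900, 10],
            "end": [200, 350, 1000, 80],
        }
    )

    def test_toy_overlap_count(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [300]})
        genes, tally = popgen.genes_in_intervals(iv, self.GENES)
        assert list(genes["gene"]) == ["gA", "gB"]

    def test_abutting_gene_excluded(self):
        # interval ends exactly where the gene starts (half-open: no overlap)
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [800], "end": [900]})
        genes, _ = popgen.genes_in_intervals(iv, self.GENES)
        assert genes.empty

    def test_origin_tally_and_unknown_sequence(self):
        iv = pd.DataFrame(
            {"chrom": ["chr1", "contig7"], "start": [100, 0], "end": [1000, 100]}
        )
        genes, tally = popgen.genes_in_intervals(
            iv, self.GENES, origin_classifier={"chr1": "reference"}
        )
        assert tally == {"reference": 3, "non_reference": 1}

    def test_shared_genes_between_interval_lists(self):
        iv1 = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [400]})
        iv2 = pd.DataFrame({"chrom": ["chr1"], "start": [300], "end": [1000]})
        g1, _ = popgen.genes_in_intervals(iv1, self.GENES)
        g2, _ = popgen.genes_in_intervals(iv2, self.GENES)
        assert set(g1["gene"]) & set(g2["gene"]) == {"gB"}


@pytest.mark.parametrize("seed", [31, 32, 33])
def test_windowed_fst_elevated_inside_sweep(seed):
    """At F=0.2 with a 0.8-intensity sweep, sweep windows exceed the genome mean."""
    sweep = SweepRegion("chr1", 3_000_000, 3_600_000, "pop1", 0.8)
    cfg = SimPopConfig(
        n_pops=2, samples_per_pop=(20, 20), n_sites=8000,
        chrom_length=10_000_000, sweeps=(sweep,), seed=seed,
    )
    panel, _ = simdata.sim_genotypes(cfg)
    sites = popgen.wc_fst_sites(panel, ("pop1", "pop2"))
    track = popgen.window_aggregate(sites)
    inside = track[(track["start"] < sweep.end) & (sweep.start < track["end"])]
    assert inside["score"].mean() > track["score"].mean()
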