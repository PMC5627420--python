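"""High-quality site selection, windowed MAF curves, arm calls and LOH counts."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from lynchtrio import (
    Arm,
    ArmCallConfig,
    SimulationConfig,
    SiteFilterConfig,
    WindowConfig,
    call_arm_events,
    count_loh_sites,
    genome_scna_scan,
    select_hq_sites,
    simulate_germline_sites,
    simulate_reference,
    window_maf_curve,
)
from lynchtrio.errors import DataIntegrityError
from lynchtrio.variantio import site_maf


def _sites_frame(rng, n=300, samples=("blood", "rpc")):
    frame = {
        "chrom": "1",
        "pos": np.arange(1, n + 1),
        "ref": "A",
        "alt": "C",
        "is_dbsnp": rng.random(n) < 0.8,
    }
    for s in samples:
        depth = rng.integers(5, 60, size=n)
        frame[f"depth_{s}"] = depth
        frame[f"alt_{s}"] = rng.binomial(depth, 0.5)
        frame[f"gt_{s}"] = rng.choice(["het", "hom_ref"], size=n, p=[0.9, 0.1])
    return pd.DataFrame(frame)


class TestSelectHqSites:
    def test_coverage_boundary_is_strict(self):
        base = {"chrom": ["1"] * 2, "pos": [1, 2], "ref": "A", "alt": "C", "is_dbsnp": True}
        table = pd.DataFrame(
            {**base,
             "depth_blood": [20, 21], "alt_blood": [10, 10], "gt_blood": "het",
             "depth_rpc": [40, 40], "alt_rpc": [20, 20], "gt_rpc": "het"}
        )
        kept = select_hq_sites(table, "blood")
        assert kept["pos"].tolist() == [2]  # depth 20 in one sample -> dropped

    def test_normal_maf_boundary_inclusive(self):
        table = pd.DataFrame(
            {"chrom": ["1"] * 2, "pos": [1, 2], "ref": "A", "alt": "C", "is_dbsnp": True,
             "depth_blood": [40, 40], "alt_blood": [10, 9], "gt_blood": "het"}
        )
        kept = select_hq_sites(table, "blood")
        assert kept["pos"].tolist() == [1]  # maf 0.25 retained, 0.225 dropped

    def test_matches_brute_force_predicate(self, rng):
        table = _sites_frame(rng)
        cfg = SiteFilterConfig()
        kept = select_hq_sites(table, "blood", cfg)
        expected = []
        for _, row in table.iterrows():
            depths_ok = all(row[f"depth_{s}"] > cfg.min_coverage for s in ("blood", "rpc"))
            vaf = row["alt_blood"] / row["depth_blood"]
            ok = (
                depths_ok
                and bool(row["is_dbsnp"])
                and row["gt_blood"] == "het"
                and min(vaf, 1 - vaf) >= cfg.min_normal_maf
            )
            if ok:
                expected.append(row["pos"])
        assert kept["pos"].tolist() == expected

    def test_missing_normal_sample_rejected(self, rng):
        with pytest.raises(DataIntegrityError):
            select_hq_sites(_sites_frame(rng), "marrow")


class TestWindowMafCurve:
    @pytest.mark.parametrize("n,expected", [(2500, 4), (1000, 1), (999, 0), (2000, 3)])
    def test_window_counts(self, n, expected):
        curve = window_maf_curve(np.full(n, 0.5))
        assert curve.size == expected

    def test_constant_input_constant_summary(self):
        curve = window_maf_curve(np.full(2500, 0.5))
        assert np.all(curve == 0.5)

    @given(st.integers(0, 5000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_count_formula(self, n):
        curve = window_maf_curve(np.zeros(n), WindowConfig(window_size=1000, step=500))
        assert curve.size == (0 if n < 1000 else (n - 1000) // 500 + 1)

    def test_permutation_invariant_within_window_and_bounded(self, rng):
        values = rng.uniform(0, 0.5, size=1000)
        cfg = WindowConfig(window_size=1000, step=500)
        a = window_maf_curve(values, cfg)
        b = window_maf_curve(rng.permutation(values), cfg)
        assert a == pytest.approx(b)
        assert 0.0 <= a[0] <= 0.5


class TestCallArmEvents:
    def test_identical_diploid_curves_neutral(self):
        curve = np.full(4, 0.5)
        assert call_arm_events(curve, curve) == "neutral"

    def test_simulated_purity_point_six_loss(self):
        # tumor at the closed-form (1-0.6)/(2-0.6) ~ 0.286, normal near 0.5
        assert call_arm_events(np.full(4, 0.48), np.full(4, 0.28)) == "loss"

    def test_too_few_windows_insufficient(self):
        cfg = ArmCallConfig(min_windows=3)
        assert call_arm_events(np.full(2, 0.5), np.full(2, 0.2), cfg) == "insufficient_data"

    def test_curve_length_mismatch_rejected(self):
        with pytest.raises(DataIntegrityError):
            call_arm_events(np.full(3, 0.5), np.full(4, 0.5))


class TestCountLohSites:
    def test_diploid_tumor_yields_zero(self):
        table = pd.DataFrame(
            {"chrom": "1", "pos": [1, 2], "ref": "A", "alt": "C", "is_dbsnp": True,
             "depth_rpc": [40, 40], "alt_rpc": [20, 20], "gt_rpc": ["het", "het"]}
        )
        assert count_loh_sites(table, "rpc") == 0

    def test_pure_tumor_loss_counts_every_site(self):
        config = SimulationConfig(
            seed=13, n_chromosomes=1, arm_length=50_000, het_sites_per_arm=1000,
            mean_depth=40.0, tumor_purity=1.0, tumor_samples=("rpc",),
            lost_arms=(("rpc", "1p"),), n_somatic=0,
        )
        reference, arms = simulate_reference(config)
        sites, _ = simulate_germline_sites(config, reference, arms)
        on_p = sites[sites["pos"] - 1 < config.arm_length]
        assert count_loh_sites(on_p, "rpc") == len(on_p)

    def test_count_matches_binomial_closed_form(self):
        """rho=0.8: LOH count within Monte-Carlo CI of n * P(Bin(N, 1/6)/N < 0.1)."""
        rho, depth, n = 0.8, 40.0, 2000
        config = SimulationConfig(
            seed=17, n_chromosomes=1, arm_length=50_000, het_sites_per_arm=n,
            mean_depth=depth, tumor_purity=rho, tumor_samples=("rpc",),
            lost_arms=(("rpc", "1p"),), n_somatic=0,
        )
        reference, arms = simulate_reference(config)
        sites, _ = simulate_germline_sites(config, reference, arms)
        on_p = sites[sites["pos"] - 1 < config.arm_length]
        observed = count_loh_sites(on_p, "rpc")
        # oracle: mix the binomial over the (truncated) Poisson depth
        p_site = 0.0
        p_del = (1 - rho) / (2 - rho)
        norm = 1 - scipy.stats.poisson.pmf(0, depth)
        for nd in range(1, 120):
            w = scipy.stats.poisson.pmf(nd, depth) / norm
            kmax = int(np.ceil(0.1 * nd)) - 1  # X/n < 0.1 strictly
            if kmax >= 0:
                p_site += w * scipy.stats.binom.cdf(kmax, nd, p_del)
        se = np.sqrt(n * p_site * (1 - p_site))
        assert abs(observed - n * p_site) < 5 * se

    def test_monotone_in_threshold(self, rng):
        table = _sites_frame(rng, n=200)
        counts = [
            count_loh_sites(table, "rpc", ArmCallConfig(loh_site_max_maf=t))
            for t in (0.05, 0.10, 0.20, 0.40)
        ]
        assert counts == sorted(counts)


class TestGenomeScan:
    def test_planted_arms_recovered_exactly(self):
        config = SimulationConfig(
            seed=23, n_chromosomes=3, arm_length=100_000, het_sites_per_arm=2000,
            mean_depth=40.0, tumor_purity=0.6,
            lost_arms=(("rpc", "2p"), ("sic", "3p"), ("sic", "3q")), n_somatic=0,
        )
        reference, arms = simulate_reference(config)
        sites, _ = simulate_germline_sites(config, reference, arms)
        reports = genome_scna_scan(sites, arms, "blood", ["rpc", "sic"])
        losses = {(r.tumor_sample, r.arm) for r in reports if r.status == "loss"}
        assert losses == {("rpc", "2p"), ("sic", "3p"), ("sic", "3q")}
        assert all(
            r.status == "neutral" for r in reports if (r.tumor_sample, r.arm) not in losses
        )

    def test_no_losses_all_neutral(self):
        config = SimulationConfig(
            seed=29, n_chromosomes=2, arm_length=100_000, het_sites_per_arm=2000,
            mean_depth=40.0, lost_arms=(), n_somatic=0,
        )
        reference, arms = simulate_reference(config)
        sites, _ = simulate_germline_sites(config, reference, arms)
        reports = genome_scna_scan(sites, arms, "blood", ["rpc", "sic"])
        assert all(r.status == "neutral" for r in reports)

    def test_detection_monotone_in_purity(self):
        """Across a purity grid, the detection rate never decreases with purity."""
        purities = (0.2, 0.4, 0.6, 0.8, 1.0)
        n_seeds = 5
        rates = []
        for rho in purities:
            hits = 0
            for s in range(n_seeds):
                config = SimulationConfig(
                    seed=1000 + s, n_chromosomes=1, arm_length=120_000,
                    het_sites_per_arm=2200, mean_depth=40.0, tumor_purity=rho,
                    tumor_samples=("rpc",), lost_arms=(("rpc", "1p"),), n_somatic=0,
                )
                reference, arms = simulate_reference(config)
                sites, _ = simulate_germline_sites(config, reference, arms)
                reports = genome_scna_scan(sites, arms, "blood", ["rpc"])
                hits += any(r.status == "loss" and r.arm == "1p" for r in reports)
            rates.append(hits / n_seeds)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 1.0

    def test_window_counts_respect_invariant(self):
        config = SimulationConfig(
            seed=37, n_chromosomes=1, arm_length=100_000, het_sites_per_arm=1700,
            lost_arms=(), n_somatic=0,
        )
        reference, arms = simulate_reference(config)
        sites, _ = simulate_germline_sites(config, reference, arms)
        reports = genome_scna_scan(sites, arms, "blood", ["rpc"])
        for r in reports:
            n = r.n_hq_sites
            expected = 0 if n < 1000 else (n - 1000) // 500 + 1
            assert len(r.windows) == expected
            if len(r.windows):
                assert r.windows["normal_maf"].between(0, 0.5).all()
        assert r.n_loh_sites <= r.n_hq_sites
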