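"""Recovery experiments and independent oracles used for validation.

Each function here either re-runs a pipeline stage on freshly simulated data
with known ground truth and measures recovery, or checks a stage against an
independent brute-force oracle (exhaustive enumeration, closed forms).  The
oracles are deliberately written without reusing the code paths they check.
"""

from __future__ import annotations

from math import comb

import numpy as np

from .compare import ContingencyTable2x2, fisher_test
from .filtering import ConsensusConfig, consensus_merge
from .scna import genome_scna_scan, SiteFilterConfig, WindowConfig, ArmCallConfig
from .simulate import (
    ContextIndex,
    SimulationConfig,
    simulate_germline_sites,
    simulate_reference,
    simulate_somatic_calls,
)
from .spectrum import build_spectrum, cosine_match, default_catalog
from .variantio import VariantCall


# ---------------------------------------------------------------------------
# Signature recovery (spectrum path)
# ---------------------------------------------------------------------------

def signature_recovery_experiment(
    n_seeds: int = 100,
    n_somatic: int = 300,
    base_seed: int = 0,
    genome_mb: float = 5.0,
) -> dict:
    """Plant a defective-MMR-like signature, rebuild spectra, re-identify it.

    One toy reference (``genome_mb`` megabases) is shared across seeds; only
    the somatic stream varies.  Returns the fraction of seeds in which
    cosine matching picks the planted signature over the decoys, and the
    mean best cosine.
    """
    catalog = default_catalog()
    ref_config = SimulationConfig(
        seed=base_seed,
        n_chromosomes=1,
        arm_length=int(genome_mb * 1e6 / 2),
        het_sites_per_arm=0,
        n_somatic=n_somatic,
        indel_fraction=0.0,
        n_callers=1,
        caller_sensitivity=1.0,
        private_fp_rate=0.0,
        common_snp_fraction=0.0,
        tumor_samples=("rpc",),
        lost_arms=(),
    )
    reference, _arms = simulate_reference(ref_config)
    index = ContextIndex(reference)
    hits = 0
    cosines = []
    for i in range(n_seeds):
        config = SimulationConfig(**{**ref_config.__dict__, "seed": base_seed + i})
        _callsets, _ann, truth = simulate_somatic_calls(
            config, reference, catalog=catalog, context_index=index
        )
        sample = config.tumor_samples[0]
        variants = [
            VariantCall(chrom=c, pos=p, ref=r, alt=a, sample=sample)
            for (c, p, r, a, _ctx) in truth.somatic_truth[sample]
        ]
        spec = build_spectrum(variants, reference, sample)
        match = cosine_match(spec, catalog)
        planted = truth.planted_signature
        if match.best == planted:
            hits += 1
        cosines.append(match.similarities[planted])
    return {
        "n_seeds": n_seeds,
        "recovery_rate": hits / n_seeds,
        "n_recovered": hits,
        "mean_planted_cosine": float(np.mean(cosines)),
    }


# ---------------------------------------------------------------------------
# Arm-loss recovery (SCNA path)
# ---------------------------------------------------------------------------

def _arm_scan_config(
    seed: int, purity: float, depth: float, sites_per_arm: int, lost_arms: tuple
) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_chromosomes=3,
        arm_length=100_000,
        het_sites_per_arm=sites_per_arm,
        mean_depth=depth,
        tumor_purity=purity,
        lost_arms=lost_arms,
        n_somatic=0,
        indel_fraction=0.0,
    )


def arm_loss_recovery_experiment(
    n_seeds: int = 100,
    purity: float = 0.6,
    depth: float = 40.0,
    sites_per_arm: int = 2000,
    base_seed: int = 0,
) -> dict:
    """Plant one arm loss per tumor; scan; require the exact loss map back.

    Also runs fully neutral simulations (no losses) and counts false-positive
    loss calls.  A seed counts as recovered only when every planted (arm,
    tumor) pair is called loss and every other pair neutral.
    """
    lost = (("rpc", "2p"), ("sic", "3p"))
    exact = 0
    fp_calls = 0
    for i in range(n_seeds):
        config = _arm_scan_config(base_seed + i, purity, depth, sites_per_arm, lost)
        reference, arms = simulate_reference(config)
        sites, _truth = simulate_germline_sites(config, reference, arms)
        reports = genome_scna_scan(
            sites, arms, config.normal_sample, list(config.tumor_samples)
        )
        wanted = {(s, a) for s, a in lost}
        got = {(r.tumor_sample, r.arm) for r in reports if r.status == "loss"}
        others_neutral = all(
            r.status == "neutral"
            for r in reports
            if (r.tumor_sample, r.arm) not in wanted
        )
        if got == wanted and others_neutral:
            exact += 1
        # neutral companion simulation: same conditions, nothing lost
        neutral_config = _arm_scan_config(base_seed + n_seeds + i, purity, depth, sites_per_arm, ())
        n_reference, n_arms = simulate_reference(neutral_config)
        n_sites, _ = simulate_germline_sites(neutral_config, n_reference, n_arms)
        n_reports = genome_scna_scan(
            n_sites, n_arms, neutral_config.normal_sample, list(neutral_config.tumor_samples)
        )
        fp_calls += sum(1 for r in n_reports if r.status == "loss")
    return {
        "n_seeds": n_seeds,
        "exact_recovery_rate": exact / n_seeds,
        "n_exact": exact,
        "neutral_false_positive_calls": fp_calls,
    }


# ---------------------------------------------------------------------------
# Closed-form minor-allele fraction under one-copy loss
# ---------------------------------------------------------------------------

def maf_closed_form_experiment(
    purities: tuple = (0.2, 0.4, 0.6, 0.8, 1.0),
    n_sites: int = 10_000,
    depth: float = 40.0,
    base_seed: int = 0,
) -> dict:
    """Mean deleted-allele read fraction on a lost arm vs (1-rho)/(2-rho).

    The deleted allele is known from ground truth, so its read fraction is
    measured directly (the folded MAF min(f, 1-f) is biased low at finite
    depth when the expectation approaches 0.5).  Each purity must agree with
    the closed form within 5 standard errors (Monte-Carlo binomial CI).
    """
    rows = []
    max_dev = 0.0
    all_within = True
    for j, rho in enumerate(purities):
        config = SimulationConfig(
            seed=base_seed + j,
            n_chromosomes=1,
            arm_length=20 * n_sites,
            het_sites_per_arm=n_sites,
            mean_depth=depth,
            tumor_purity=rho,
            tumor_samples=("rpc",),
            lost_arms=(("rpc", "1p"),),
            n_somatic=0,
            indel_fraction=0.0,
        )
        reference, arms = simulate_reference(config)
        sites, truth = simulate_germline_sites(config, reference, arms)
        arm_mask = (sites["pos"] - 1 < config.arm_length).to_numpy()
        depth_t = sites["depth_rpc"].to_numpy(dtype=float)[arm_mask]
        alt_t = sites["alt_rpc"].to_numpy(dtype=float)[arm_mask]
        del_alt = truth.deleted_is_alt["rpc"][arm_mask]
        frac = np.where(del_alt, alt_t / depth_t, 1.0 - alt_t / depth_t)
        expected = (1.0 - rho) / (2.0 - rho)
        dev = abs(float(frac.mean()) - expected)
        se = float(frac.std(ddof=1) / np.sqrt(frac.size))
        within = dev <= max(5.0 * se, 1e-9)
        all_within &= within
        max_dev = max(max_dev, dev)
        rows.append({"purity": rho, "mean_fraction": float(frac.mean()), "expected": expected,
                     "deviation": dev, "se": se, "within_ci": within})
    return {"per_purity": rows, "max_abs_deviation": max_dev, "all_within_ci": bool(all_within)}


# ---------------------------------------------------------------------------
# Consensus brute-force oracle
# ---------------------------------------------------------------------------

def random_caller_fixture(
    rng: np.random.Generator, n_keys: int = 200, n_callers: int = 4, p_support: float = 0.45
) -> dict:
    """Random per-caller call sets over ``n_keys`` variant keys (one sample)."""
    callsets: dict[str, list] = {f"caller{i+1}": [] for i in range(n_callers)}
    for k in range(n_keys):
        key = ("1", k + 1, "A", "C")
        support = rng.random(n_callers) < p_support
        for i, caller in enumerate(callsets):
            if support[i]:
                callsets[caller].append(
                    VariantCall(chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                                sample="s", callers={caller})
                )
    return callsets


def consensus_oracle_check(
    rng: np.random.Generator, n_keys: int = 200, min_callers: int = 2
) -> dict:
    """Compare consensus_merge against naive support counting over all keys."""
    callsets = random_caller_fixture(rng, n_keys=n_keys)
    merged = consensus_merge(callsets, ConsensusConfig(min_callers=min_callers))
    got = {v.key for v in merged}
    support: dict[tuple, int] = {}
    for calls in callsets.values():
        for v in calls:
            support[v.key] = support.get(v.key, 0) + 1
    expected = {k for k, n in support.items() if n >= min_callers}
    return {"agrees": got == expected, "n_expected": len(expected), "n_got": len(got)}


def noiseless_consensus_check(base_seed: int = 0, n_somatic: int = 150) -> dict:
    """With perfect callers and no false positives, consensus equals truth."""
    config = SimulationConfig(
        seed=base_seed,
        n_chromosomes=2,
        arm_length=100_000,
        het_sites_per_arm=200,
        n_somatic=n_somatic,
        indel_fraction=0.0,
        caller_sensitivity=1.0,
        private_fp_rate=0.0,
        common_snp_fraction=0.0,
    )
    reference, arms = simulate_reference(config)
    _sites, truth = simulate_germline_sites(config, reference, arms)
    callsets, _ann, truth = simulate_somatic_calls(config, reference, truth=truth)
    ok = True
    for sample in config.tumor_samples:
        merged = consensus_merge(callsets[sample])
        got = {(v.chrom, v.pos, v.ref, v.alt) for v in merged}
        expected = {(c, p, r, a) for (c, p, r, a, _ctx) in truth.somatic_truth[sample]}
        ok &= got == expected
    return {"matches_truth": bool(ok), "n_somatic": n_somatic}


# ---------------------------------------------------------------------------
# Fisher exact vs exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration of the margin-fixed tables.

    Sums hypergeometric weights C(r1, x) * C(r2, c1 - x) over all x whose
    weight does not exceed the observed table's weight (ties included
    exactly, thanks to integer arithmetic).
    """
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    acc = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        total += w
        if w <= w_obs:
            acc += w
    return acc / total


def fisher_oracle_check(max_total: int = 40) -> dict:
    """Max relative error of the implemented Fisher p over all small tables."""
    worst = 0.0
    worst_table = None
    n_tables = 0
    for a in range(max_total + 1):
        for b in range(max_total - a + 1):
            for c in range(max_total - a - b + 1):
                for d in range(max_total - a - b - c + 1):
                    if a + b + c + d == 0:
                        continue
                    n_tables += 1
                    p_impl = fisher_test(
                        ContingencyTable2x2(a, b, c, d), compute_chi2=False
                    ).p_value
                    p_oracle = fisher_enumeration_p(a, b, c, d)
                    rel = abs(p_impl - p_oracle) / p_oracle
                    if rel > worst:
                        worst, worst_table = rel, (a, b, c, d)
    return {"n_tables": n_tables, "max_rel_error": worst, "worst_table": worst_table}
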