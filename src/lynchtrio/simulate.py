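"""Synthetic tumor–normal trios with known ground truth.

The generator emulates the inputs of a whole-genome trio study of a
mismatch-repair-deficient patient: a matched normal plus two tumors, with

* germline heterozygous SNVs whose allele depths are binomially sampled at
  Poisson coverage;
* planted one-copy arm losses diluted by tumor purity rho — at a lost-arm
  het site the expected read fraction of the retained allele is 1/(2-rho)
  and of the deleted allele (1-rho)/(2-rho), the deleted allele chosen
  uniformly per site;
* hypermutated somatic SNV sets whose trinucleotide contexts are drawn from
  a signature-catalog profile (defective-MMR-like by default) and placed at
  reference positions that actually carry the sampled context;
* several pseudo-callers that each see every true variant with probability
  ``caller_sensitivity`` and add private (unshared) false positives;
* an annotation table in which a minority of calls carry population
  frequency above 1%.

All randomness flows from one root seed through named substreams (reference,
germline, somatic, callers) so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .spectrum import default_catalog, revcomp
from .variantio import (
    Arm,
    SignatureCatalog,
    VariantCall,
    write_annotation,
    write_arm_bed,
    write_fasta,
    write_sites_tsv,
    write_vcf,
)

_STREAMS = {"reference": 0, "germline": 1, "somatic": 2, "callers": 3, "annotation": 4}

#: Consequence distribution for simulated somatic SNVs (annotation ground truth).
SNV_CONSEQUENCE_PROBS = {
    "noncoding": 0.45,
    "synonymous": 0.15,
    "missense": 0.25,
    "nonsense": 0.08,
    "splicing": 0.05,
    "nonstop": 0.02,
}
INDEL_CONSEQUENCE_PROBS = {"frameshift_indel": 0.8, "inframe_indel": 0.2}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated trio.

    Defaults follow the emulated study: ~37x mean coverage, two tumors with
    one arm-level one-copy loss each (one losing a single arm, the other a
    whole chromosome), a defective-MMR-like mutational signature, and four
    somatic callers merged by consensus.
    """

    seed: int = 0
    n_chromosomes: int = 3
    arm_length: int = 400_000
    het_sites_per_arm: int = 2000
    mean_depth: float = 37.0
    tumor_purity: float = 0.6
    normal_sample: str = "blood"
    tumor_samples: tuple = ("rpc", "sic")
    lost_arms: tuple = (("rpc", "2p"), ("sic", "3p"), ("sic", "3q"))
    n_somatic: int = 300
    signature_name: str = "MMR_deficient"
    signature_mixture: dict | None = None
    n_callers: int = 4
    caller_sensitivity: float = 0.95
    private_fp_rate: float = 10.0
    common_snp_fraction: float = 0.1
    dbsnp_fraction: float = 0.95
    indel_fraction: float = 0.05
    somatic_vaf: float | None = None  # default purity/2 (clonal het in a diploid tumor)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_purity <= 1.0:
            raise ConfigurationError(f"tumor_purity must be in [0,1], got {self.tumor_purity}")
        if not 0.0 < self.caller_sensitivity <= 1.0:
            raise ConfigurationError("caller_sensitivity must be in (0,1]")
        if self.arm_length <= 0:
            raise ConfigurationError("arm_length must be positive")
        for count_field in ("n_chromosomes", "het_sites_per_arm", "n_somatic", "n_callers"):
            if getattr(self, count_field) < 0:
                raise ConfigurationError(f"{count_field} must be >= 0")
        if self.private_fp_rate < 0 or not 0.0 <= self.common_snp_fraction <= 1.0:
            raise ConfigurationError("invalid caller-noise parameters")
        if not 0.0 <= self.indel_fraction < 1.0:
            raise ConfigurationError("indel_fraction must be in [0,1)")
        if self.signature_mixture is not None:
            total = sum(self.signature_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"signature_mixture sums to {total}, not 1")
        known = {self.normal_sample, *self.tumor_samples}
        for sample, _arm in self.lost_arms:
            if sample not in known:
                raise ConfigurationError(f"lost arm assigned to unknown sample {sample!r}")

    @property
    def samples(self) -> list[str]:
        return [self.normal_sample, *self.tumor_samples]

    @property
    def caller_names(self) -> list[str]:
        return [f"caller{i + 1}" for i in range(self.n_callers)]

    def lost_arms_of(self, sample: str) -> set:
        return {arm for s, arm in self.lost_arms if s == sample}

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator derived from the root seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class GroundTruth:
    """The answer key for recovery tests."""

    germline_sites: list  # (chrom, pos) identifiers
    lost_arms: dict  # sample -> set of arm names
    somatic_truth: dict  # sample -> set of (chrom, pos, ref, alt, context)
    planted_signature: str
    deleted_is_alt: dict = field(default_factory=dict)  # sample -> bool array over sites rows (lost arms only)


@dataclass
class SimulatedTrio:
    config: SimulationConfig
    reference: dict  # chrom -> sequence
    arms: list  # list[Arm]
    sites: pd.DataFrame  # germline sites table
    callsets: dict  # sample -> caller -> list[VariantCall]
    annotation: dict  # (chrom,pos,ref,alt) -> (gene, consequence, pop_freq)
    truth: GroundTruth

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.reference.values())


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig) -> tuple[dict, list]:
    """Deterministic toy reference: each chromosome is two arms of uniform bases."""
    rng = config.rng("reference")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reference: dict[str, str] = {}
    arms: list[Arm] = []
    for i in range(1, config.n_chromosomes + 1):
        chrom = str(i)
        length = 2 * config.arm_length
        codes = rng.integers(0, 4, size=length)
        reference[chrom] = bytes(bases[codes]).decode()
        arms.append(Arm(chrom=chrom, arm_label="p", start=0, end=config.arm_length))
        arms.append(Arm(chrom=chrom, arm_label="q", start=config.arm_length, end=length))
    return reference, arms


# ---------------------------------------------------------------------------
# Germline sites
# ---------------------------------------------------------------------------

def lost_arm_alt_fraction(purity: float, deleted_is_alt: np.ndarray) -> np.ndarray:
    """Expected alt-read fraction at a het site under one-copy loss.

    A fraction ``purity`` of cells carry one copy (the retained allele), the
    rest carry both; average copy number is 2 - purity, so the retained
    allele is read at 1/(2-purity) and the deleted one at
    (1-purity)/(2-purity).
    """
    retained = 1.0 / (2.0 - purity)
    deleted = (1.0 - purity) / (2.0 - purity)
    return np.where(deleted_is_alt, deleted, retained)


def simulate_germline_sites(
    config: SimulationConfig, reference: Mapping[str, str], arms: Sequence[Arm]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Germline het SNVs with binomial allele depths; planted losses shift tumors.

    Returns the sites table plus a partial GroundTruth (germline identifiers,
    lost arms, per-tumor deleted-allele masks; somatic fields empty).
    """
    rng = config.rng("germline")
    rho = config.tumor_purity
    frames = []
    deleted_is_alt: dict[str, list] = {t: [] for t in config.tumor_samples}
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    for arm in arms:
        n = config.het_sites_per_arm
        lo = max(arm.start, 2)  # keep a full trinucleotide inside the chromosome
        hi = min(arm.end, len(reference[arm.chrom]) - 2)
        offsets = rng.choice(hi - lo, size=n, replace=False)
        pos = np.sort(offsets) + lo + 1  # 1-based
        seq = np.frombuffer(reference[arm.chrom].encode(), dtype=np.uint8)
        ref_codes = np.searchsorted(base_arr, seq[pos - 1])
        alt_codes = (ref_codes + rng.integers(1, 4, size=n)) % 4
        frame = {
            "chrom": arm.chrom,
            "pos": pos,
            "ref": [chr(base_arr[c]) for c in ref_codes],
            "alt": [chr(base_arr[c]) for c in alt_codes],
            "is_dbsnp": rng.random(n) < config.dbsnp_fraction,
        }
        for sample in config.samples:
            depth = np.maximum(1, rng.poisson(config.mean_depth, size=n))
            if sample in config.tumor_samples and arm.name in config.lost_arms_of(sample):
                del_alt = rng.random(n) < 0.5
                p_alt = lost_arm_alt_fraction(rho, del_alt)
                deleted_is_alt[sample].append(del_alt)
            else:
                p_alt = np.full(n, 0.5)
                if sample in config.tumor_samples:
                    deleted_is_alt[sample].append(np.zeros(n, dtype=bool))
            alt_reads = rng.binomial(depth, p_alt)
            frame[f"depth_{sample}"] = depth
            frame[f"alt_{sample}"] = alt_reads
            frame[f"gt_{sample}"] = "het"
        frames.append(pd.DataFrame(frame))
    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    truth = GroundTruth(
        germline_sites=list(zip(sites["chrom"], sites["pos"])) if len(sites) else [],
        lost_arms={t: config.lost_arms_of(t) for t in config.tumor_samples},
        somatic_truth={t: set() for t in config.tumor_samples},
        planted_signature=config.signature_name,
        deleted_is_alt={t: np.concatenate(v) if v else np.zeros(0, dtype=bool) for t, v in deleted_is_alt.items()},
    )
    return sites, truth


# ---------------------------------------------------------------------------
# Somatic calls
# ---------------------------------------------------------------------------

class ContextIndex:
    """Positions of every trinucleotide in a reference, for context placement."""

    def __init__(self, reference: Mapping[str, str]):
        self._positions: dict[str, list] = {}
        for chrom, seq in reference.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            code = np.full(arr.size, -1, dtype=np.int64)
            for i, b in enumerate(b"ACGT"):
                code[arr == b] = i
            ok = (code[:-2] >= 0) & (code[1:-1] >= 0) & (code[2:] >= 0)
            tri = code[:-2] * 16 + code[1:-1] * 4 + code[2:]
            for t in np.unique(tri[ok]):
                name = "ACGT"[t // 16] + "ACGT"[(t // 4) % 4] + "ACGT"[t % 4]
                centers = np.where(ok & (tri == t))[0] + 2  # 1-based center position
                self._positions.setdefault(name, []).append((chrom, centers))

    def sample_for_label(self, rng: np.random.Generator, label: str, used: set) -> tuple[str, int, str, str] | None:
        """Random unused (chrom, pos, ref, alt) whose context classifies as ``label``.

        The label names a pyrimidine-strand substitution; a position matches
        on the forward strand (center C/T) or via its reverse complement
        (center G/A), in which case alleles are complemented.
        """
        five, sub, three = label[0], label[2:5], label[6]
        ref_py, alt_py = sub[0], sub[2]
        fwd = five + ref_py + three
        rev = revcomp(fwd)
        pools = []
        for trinuc, strand in ((fwd, "+"), (rev, "-")):
            for chrom, centers in self._positions.get(trinuc, []):
                pools.append((chrom, centers, strand))
        total = sum(len(c) for _, c, _ in pools)
        if total == 0:
            return None
        for _ in range(200):  # rejection sampling against collisions
            k = rng.integers(total)
            for chrom, centers, strand in pools:
                if k < len(centers):
                    pos = int(centers[k])
                    if (chrom, pos) in used:
                        break
                    if strand == "+":
                        return chrom, pos, ref_py, alt_py
                    comp = str.maketrans("ACGT", "TGCA")
                    return chrom, pos, ref_py.translate(comp), alt_py.translate(comp)
                k -= len(centers)
        return None


def _draw_categorical(rng: np.random.Generator, probs: dict, size: int) -> list:
    names = list(probs)
    p = np.array([probs[n] for n in names], dtype=float)
    return [names[i] for i in rng.choice(len(names), size=size, p=p / p.sum())]


def simulate_somatic_calls(
    config: SimulationConfig,
    reference: Mapping[str, str],
    catalog: SignatureCatalog | None = None,
    truth: GroundTruth | None = None,
    context_index: ContextIndex | None = None,
) -> tuple[dict, dict, GroundTruth]:
    """Per-caller somatic call sets plus annotation and ground truth.

    True SNVs are placed at positions matching contexts drawn from the
    planted signature (or mixture).  Each caller sees each true variant with
    probability ``caller_sensitivity`` and adds Poisson(``private_fp_rate``)
    false positives private to itself.  ``common_snp_fraction`` of all call
    keys receive population frequency above 1% in the annotation table.
    """
    catalog = catalog or default_catalog()
    rng = config.rng("somatic")
    caller_rng = config.rng("callers")
    ann_rng = config.rng("annotation")
    if config.signature_mixture:
        for name in config.signature_mixture:
            if name not in catalog:
                raise KeyError(f"signature {name!r} not in catalog")
        probs = np.zeros(96)
        for name, w in config.signature_mixture.items():
            probs += w * catalog[name]
    else:
        if config.signature_name not in catalog:
            raise KeyError(f"signature {config.signature_name!r} not in catalog")
        probs = catalog[config.signature_name]
    probs = probs / probs.sum()
    index = context_index or ContextIndex(reference)
    from .variantio import CONTEXT_LABELS

    if truth is None:
        truth = GroundTruth(
            germline_sites=[],
            lost_arms={t: config.lost_arms_of(t) for t in config.tumor_samples},
            somatic_truth={t: set() for t in config.tumor_samples},
            planted_signature=config.signature_name,
        )
    used: set = set(truth.germline_sites)
    vaf = config.somatic_vaf if config.somatic_vaf is not None else max(config.tumor_purity / 2.0, 0.05)
    callsets: dict[str, dict[str, list[VariantCall]]] = {}
    annotation: dict[tuple, tuple] = {}
    genes = [f"GENE{i:04d}" for i in range(1, 400)]

    for sample in config.tumor_samples:
        true_variants: list[VariantCall] = []
        n_indel = int(round(config.indel_fraction * config.n_somatic))
        n_snv = config.n_somatic - n_indel
        label_draws = rng.choice(96, size=n_snv, p=probs)
        for li in label_draws:
            label = CONTEXT_LABELS[li]
            placed = index.sample_for_label(rng, label, used)
            while placed is None:  # resample a fresh context if this one is exhausted
                placed = index.sample_for_label(rng, CONTEXT_LABELS[rng.choice(96, p=probs)], used)
            chrom, pos, ref, alt = placed
            used.add((chrom, pos))
            depth = max(1, int(rng.poisson(config.mean_depth)))
            alt_depth = int(rng.binomial(depth, vaf))
            true_variants.append(
                VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, sample=sample,
                            depth=depth, alt_depth=alt_depth)
            )
            truth.somatic_truth[sample].add((chrom, pos, ref, alt, label))
        for _ in range(n_indel):
            chrom, pos, ref, alt = _random_indel(rng, reference, used)
            used.add((chrom, pos))
            depth = max(1, int(rng.poisson(config.mean_depth)))
            alt_depth = int(rng.binomial(depth, vaf))
            true_variants.append(
                VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, sample=sample,
                            depth=depth, alt_depth=alt_depth)
            )
            truth.somatic_truth[sample].add((chrom, pos, ref, alt, None))

        # annotation ground truth for true variants
        snv_cons = _draw_categorical(ann_rng, SNV_CONSEQUENCE_PROBS, n_snv)
        indel_cons = _draw_categorical(ann_rng, INDEL_CONSEQUENCE_PROBS, n_indel)
        for v, cons in zip(true_variants, snv_cons + indel_cons):
            annotation[v.site_key] = (genes[ann_rng.integers(len(genes))], cons, None)

        # noisy caller views
        callsets[sample] = {}
        for caller in config.caller_names:
            seen = caller_rng.random(len(true_variants)) < config.caller_sensitivity
            calls = [v.copy() for v, s in zip(true_variants, seen) if s]
            for c in calls:
                c.callers = {caller}
            n_fp = caller_rng.poisson(config.private_fp_rate)
            for _ in range(n_fp):
                chrom, pos, ref, alt = _random_snv(caller_rng, reference, used)
                used.add((chrom, pos))  # privacy: no other caller may reuse this locus
                depth = max(1, int(caller_rng.poisson(config.mean_depth)))
                alt_depth = int(caller_rng.binomial(depth, 0.1))
                calls.append(
                    VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, sample=sample,
                                callers={caller}, depth=depth, alt_depth=alt_depth)
                )
                annotation[(chrom, pos, ref, alt)] = (
                    genes[ann_rng.integers(len(genes))],
                    _draw_categorical(ann_rng, SNV_CONSEQUENCE_PROBS, 1)[0],
                    None,
                )
            callsets[sample][caller] = calls

    # population frequencies: a minority of keys are common (> 1%)
    keys = sorted(annotation)
    common = ann_rng.random(len(keys)) < config.common_snp_fraction
    for key, is_common in zip(keys, common):
        gene, cons, _ = annotation[key]
        if is_common:
            freq = float(ann_rng.uniform(0.011, 0.5))
        else:
            freq = None if ann_rng.random() < 0.5 else float(ann_rng.uniform(0.0, 0.009))
        annotation[key] = (gene, cons, freq)

    return callsets, annotation, truth


def _random_snv(rng: np.random.Generator, reference: Mapping[str, str], used: set) -> tuple:
    chroms = list(reference)
    while True:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(3, len(reference[chrom]) - 1))  # 1-based, flanks inside
        if (chrom, pos) in used:
            continue
        ref = reference[chrom][pos - 1]
        alt = "ACGT"[("ACGT".index(ref) + rng.integers(1, 4)) % 4]
        return chrom, pos, ref, alt


def _random_indel(rng: np.random.Generator, reference: Mapping[str, str], used: set) -> tuple:
    chroms = list(reference)
    while True:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(3, len(reference[chrom]) - 2))
        if (chrom, pos) in used:
            continue
        anchor = reference[chrom][pos - 1]
        if rng.random() < 0.5:  # insertion
            ins = "ACGT"[rng.integers(4)]
            return chrom, pos, anchor, anchor + ins
        return chrom, pos, anchor + reference[chrom][pos], anchor  # 1-base deletion


# ---------------------------------------------------------------------------
# Whole-trio convenience and disk output
# ---------------------------------------------------------------------------

def simulate_trio(config: SimulationConfig, catalog: SignatureCatalog | None = None) -> SimulatedTrio:
    """Run the full generator: reference, germline sites, somatic callsets."""
    reference, arms = simulate_reference(config)
    sites, truth = simulate_germline_sites(config, reference, arms)
    callsets, annotation, truth = simulate_somatic_calls(
        config, reference, catalog=catalog, truth=truth
    )
    return SimulatedTrio(
        config=config,
        reference=reference,
        arms=arms,
        sites=sites,
        callsets=callsets,
        annotation=annotation,
        truth=truth,
    )


def write_trio(trio: SimulatedTrio, outdir: str | Path) -> None:
    """Write the simulated inputs and truth tables as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(trio.reference, outdir / "reference.fa")
    write_arm_bed(trio.arms, outdir / "arms.bed")
    write_sites_tsv(trio.sites, outdir / "germline_sites.tsv")
    write_annotation(outdir / "annotation.tsv", trio.annotation)
    lengths = {c: len(s) for c, s in trio.reference.items()}
    for sample, by_caller in trio.callsets.items():
        for caller, calls in by_caller.items():
            write_vcf(outdir / f"{sample}.{caller}.vcf", calls, contig_lengths=lengths)
    truth_rows = [
        {"sample": s, "chrom": t[0], "pos": t[1], "ref": t[2], "alt": t[3], "context": t[4]}
        for s, entries in trio.truth.somatic_truth.items()
        for t in sorted(entries)
    ]
    pd.DataFrame(truth_rows, columns=["sample", "chrom", "pos", "ref", "alt", "context"]).to_csv(
        outdir / "truth_somatic.tsv", sep="\t", index=False
    )
    arm_rows = [{"sample": s, "arm": a} for s, arms_ in sorted(trio.truth.lost_arms.items()) for a in sorted(arms_)]
    pd.DataFrame(arm_rows, columns=["sample", "arm"]).to_csv(
        outdir / "truth_lost_arms.tsv", sep="\t", index=False
    )
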