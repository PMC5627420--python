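"""Shared variant data model and readers/writers for the formats the pipeline touches.

The VCF dialect is deliberately minimal: columns CHROM POS ID REF ALT QUAL
FILTER INFO with INFO keys DP (total depth), AD (alt-supporting depth, one
value per ALT allele), AF (alt fraction) and CALLER (emitting caller).  It is
valid VCF 4.2 and readable by standard tooling; reading goes through
:mod:`pysam`.

Chromosome names are normalized internally by stripping any ``chr`` prefix;
writers restore it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import DataIntegrityError, ParseError

logger = logging.getLogger(__name__)

#: Controlled consequence vocabulary.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "nonstop",
        "splicing",
        "frameshift_indel",
        "inframe_indel",
        "synonymous",
        "noncoding",
    }
)


def norm_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix ('chr2' and '2' are the same chromosome)."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def vcf_chrom(chrom: str) -> str:
    """Restore the ``chr`` prefix used on write."""
    return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"


@dataclass
class VariantCall:
    """One called variant in one sample.

    ``pos`` is 1-based.  ``callers`` is the set of programs supporting the
    call; consensus merging unions it across per-caller files.  Annotation
    fields (``gene``, ``consequence``, ``pop_freq``, ``protein_pos``) are
    absent until an annotation table is applied.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    callers: set = field(default_factory=set)
    depth: int | None = None
    alt_depth: int | None = None
    pop_freq: float | None = None
    gene: str | None = None
    consequence: str | None = None
    protein_pos: int | None = None

    def __post_init__(self) -> None:
        self.chrom = norm_chrom(self.chrom)
        if self.pos < 1:
            raise DataIntegrityError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataIntegrityError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.depth is not None and self.alt_depth is not None and self.alt_depth > self.depth:
            raise DataIntegrityError(
                f"alt_depth {self.alt_depth} > depth {self.depth} at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float | None:
        """Alternate-allele read fraction, recomputed from depths."""
        if self.depth in (None, 0) or self.alt_depth is None:
            return None
        return self.alt_depth / self.depth

    @property
    def key(self) -> tuple:
        """Caller-independent variant identity: (chrom, pos, ref, alt, sample)."""
        return (self.chrom, self.pos, self.ref, self.alt, self.sample)

    @property
    def site_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def copy(self) -> "VariantCall":
        c = replace(self)
        c.callers = set(self.callers)
        return c


@dataclass
class Arm:
    """A chromosome arm as a 0-based half-open interval."""

    chrom: str
    arm_label: str  # "p" or "q"
    start: int
    end: int

    def __post_init__(self) -> None:
        self.chrom = norm_chrom(self.chrom)
        if not self.start < self.end:
            raise DataIntegrityError(f"arm {self.name}: start {self.start} >= end {self.end}")

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm_label}"

    def contains(self, pos: int) -> bool:
        """Membership of a 1-based variant position: start <= pos-1 < end."""
        return self.start <= pos - 1 < self.end


@dataclass
class GermlineSite:
    """A germline SNV with per-sample allele depths; the unit of SCNA analysis."""

    chrom: str
    pos: int
    ref: str
    alt: str
    is_dbsnp: bool
    genotype: dict  # sample -> {"het", "hom_ref", "hom_alt"}
    depth: dict  # sample -> int
    alt_depth: dict  # sample -> int

    def __post_init__(self) -> None:
        self.chrom = norm_chrom(self.chrom)
        for s, d in self.depth.items():
            if self.alt_depth[s] > d:
                raise DataIntegrityError(f"alt_depth > depth for sample {s} at {self.chrom}:{self.pos}")

    def vaf(self, sample: str) -> float:
        d = self.depth[sample]
        return self.alt_depth[sample] / d if d else 0.0

    def maf(self, sample: str) -> float:
        """Minor-allele fraction min(vaf, 1-vaf), in [0, 0.5]."""
        v = self.vaf(sample)
        return min(v, 1.0 - v)


# ---------------------------------------------------------------------------
# Germline sites table <-> records
# ---------------------------------------------------------------------------

def sites_to_table(sites: Sequence[GermlineSite], samples: Sequence[str]) -> pd.DataFrame:
    """Tidy table with one row per site and depth_/alt_/gt_ columns per sample."""
    rows = []
    for s in sites:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt, "is_dbsnp": s.is_dbsnp}
        for sm in samples:
            row[f"depth_{sm}"] = s.depth[sm]
            row[f"alt_{sm}"] = s.alt_depth[sm]
            row[f"gt_{sm}"] = s.genotype[sm]
        rows.append(row)
    return pd.DataFrame(rows)


def table_to_sites(table: pd.DataFrame) -> list[GermlineSite]:
    samples = table_samples(table)
    out = []
    for row in table.itertuples(index=False):
        r = row._asdict()
        out.append(
            GermlineSite(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref=r["ref"],
                alt=r["alt"],
                is_dbsnp=bool(r["is_dbsnp"]),
                genotype={s: r[f"gt_{s}"] for s in samples},
                depth={s: int(r[f"depth_{s}"]) for s in samples},
                alt_depth={s: int(r[f"alt_{s}"]) for s in samples},
            )
        )
    return out


def table_samples(table: pd.DataFrame) -> list[str]:
    """Sample names encoded in a sites table's depth_ columns."""
    return [c[len("depth_"):] for c in table.columns if c.startswith("depth_")]


def site_maf(table: pd.DataFrame, sample: str) -> np.ndarray:
    """Vectorized minor-allele fraction for one sample over a sites table."""
    depth = table[f"depth_{sample}"].to_numpy(dtype=float)
    alt = table[f"alt_{sample}"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / depth, 0.0)
    return np.minimum(vaf, 1.0 - vaf)


def write_sites_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "chrom" not in table.columns:
        raise ParseError(f"{path}: missing 'chrom' column")
    return table


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    "##source=lynchtrio",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=AD,Number=A,Type=Integer,Description="Alt-supporting read depth">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele read fraction">',
    '##INFO=<ID=CALLER,Number=.,Type=String,Description="Calling program(s)">',
]


def write_vcf(
    path: str | Path,
    variants: Iterable[VariantCall],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write calls in the minimal dialect, sorted by (chrom, pos, ref, alt)."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    contigs: dict[str, int | None] = {}
    if contig_lengths:
        contigs.update({norm_chrom(c): length for c, length in contig_lengths.items()})
    for v in variants:
        contigs.setdefault(v.chrom, None)
    with open(path, "w") as fh:
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        for chrom, length in contigs.items():
            if length is None:
                fh.write(f"##contig=<ID={vcf_chrom(chrom)}>\n")
            else:
                fh.write(f"##contig=<ID={vcf_chrom(chrom)},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = []
            if v.depth is not None:
                info.append(f"DP={v.depth}")
            if v.alt_depth is not None:
                info.append(f"AD={v.alt_depth}")
            if v.vaf is not None:
                info.append(f"AF={v.vaf:.6g}")
            if v.callers:
                info.append("CALLER=" + ",".join(sorted(v.callers)))
            fh.write(
                "\t".join(
                    [
                        vcf_chrom(v.chrom),
                        str(v.pos),
                        ".",
                        v.ref,
                        v.alt,
                        ".",
                        "PASS",
                        ";".join(info) if info else ".",
                    ]
                )
                + "\n"
            )


def read_caller_vcf(path: str | Path, caller_name: str, sample: str) -> list[VariantCall]:
    """Read one caller's VCF into VariantCalls with ``callers={caller_name}``.

    Multi-allelic records are split into one call per ALT allele.  Records
    without depth fields are retained with depths absent (logged).
    """
    out: list[VariantCall] = []
    record_no = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    def info_get(rec, key):
        # .get raises on keys absent from the header; treat both as missing
        try:
            return rec.info.get(key)
        except (KeyError, ValueError):
            return None

    with vf:
        try:
            for rec in vf:
                record_no += 1
                depth = info_get(rec, "DP")
                ads = info_get(rec, "AD")
                if depth is None:
                    logger.warning("%s record %d: missing DP; depths left absent", path, record_no)
                if ads is not None and not isinstance(ads, tuple):
                    ads = (ads,)
                for i, alt in enumerate(rec.alts or ()):
                    alt_depth = None
                    if ads is not None and i < len(ads):
                        alt_depth = ads[i]
                    out.append(
                        VariantCall(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            sample=sample,
                            callers={caller_name},
                            depth=None if depth is None else int(depth),
                            alt_depth=None if alt_depth is None else int(alt_depth),
                        )
                    )
        except (ValueError, OSError) as exc:
            raise ParseError(f"{path}: malformed record #{record_no + 1}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence", "pop_freq"]


def read_annotation(path: str | Path) -> dict[tuple, tuple]:
    """Map (chrom, pos, ref, alt) -> (gene, consequence, pop_freq).

    Unknown consequence strings map to ``noncoding`` with a warning; a missing
    pop_freq cell maps to None (treated as rare downstream).  Duplicate keys
    with conflicting values are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    out: dict[tuple, tuple] = {}
    for row in df.itertuples(index=False):
        key = (norm_chrom(str(row.chrom)), int(row.pos), row.ref, row.alt)
        gene = None if pd.isna(row.gene) else str(row.gene)
        cons = None if pd.isna(row.consequence) else str(row.consequence)
        if cons is not None and cons not in CONSEQUENCES:
            logger.warning("%s: unknown consequence %r mapped to noncoding", path, cons)
            cons = "noncoding"
        pf = None if pd.isna(row.pop_freq) else float(row.pop_freq)
        value = (gene, cons, pf)
        if key in out and out[key] != value:
            raise ParseError(f"{path}: conflicting duplicate annotation for {key}")
        out[key] = value
    return out


def write_annotation(path: str | Path, entries: Mapping[tuple, tuple]) -> None:
    rows = [
        {
            "chrom": k[0],
            "pos": k[1],
            "ref": k[2],
            "alt": k[3],
            "gene": v[0],
            "consequence": v[1],
            # repr round-trips the float exactly; the column is object-typed
            "pop_freq": "" if v[2] is None else repr(float(v[2])),
        }
        for k, v in sorted(entries.items())
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def annotate_calls(variants: Iterable[VariantCall], annotation: Mapping[tuple, tuple]) -> list[VariantCall]:
    """Attach gene/consequence/pop_freq to calls (in place); returns the list."""
    variants = list(variants)
    for v in variants:
        entry = annotation.get((v.chrom, v.pos, v.ref, v.alt))
        if entry is not None:
            v.gene, v.consequence, v.pop_freq = entry
    return variants


# ---------------------------------------------------------------------------
# Signature catalog
# ---------------------------------------------------------------------------

#: Pyrimidine-collapsed substitution classes in catalog order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical 96 context labels: substitution-major, then 5' and 3' flank.
CONTEXT_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)

_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


@dataclass
class SignatureCatalog:
    """Named probability vectors over the 96 trinucleotide contexts."""

    signatures: dict  # name -> np.ndarray of shape (96,)
    context_labels: tuple = CONTEXT_LABELS

    def __post_init__(self) -> None:
        if len(self.context_labels) != 96 or len(set(self.context_labels)) != 96:
            raise ParseError("catalog must define exactly 96 unique context labels")
        for name, vec in self.signatures.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (96,):
                raise ParseError(f"signature {name}: expected 96 entries, got {vec.shape}")
            if (vec < 0).any():
                raise ParseError(f"signature {name}: negative entries")
            total = vec.sum()
            if total <= 0:
                raise ParseError(f"signature {name}: all-zero column cannot be normalized")
            if abs(total - 1.0) > 1e-6:
                raise ParseError(f"signature {name}: sums to {total}, not 1")
            self.signatures[name] = vec / total

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def matrix(self) -> np.ndarray:
        """(96, K) matrix in catalog order."""
        return np.column_stack([self.signatures[n] for n in self.names])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signatures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.signatures


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-style TSV: first column context label, one column per signature."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != 96:
        raise ParseError(f"{path}: expected 96 context rows, got {len(df)}")
    labels = df.iloc[:, 0].astype(str).tolist()
    if set(labels) != set(CONTEXT_LABELS):
        unknown = sorted(set(labels) - set(CONTEXT_LABELS))[:3]
        raise ParseError(f"{path}: context labels do not match the 96-context scheme (e.g. {unknown})")
    order = np.argsort([_LABEL_INDEX[lab] for lab in labels])
    sigs = {}
    for col in df.columns[1:]:
        vec = df[col].to_numpy(dtype=float)[order]
        sigs[str(col)] = vec
    return SignatureCatalog(signatures=sigs)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame({"Context": list(catalog.context_labels)})
    for name in catalog.names:
        df[name] = catalog[name]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Arm BED
# ---------------------------------------------------------------------------

def read_arm_bed(path: str | Path) -> list[Arm]:
    """BED file of chromosome arms: chrom, start, end, arm name (e.g. ``2p``)."""
    arms = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path} line {ln}: expected 4 BED columns")
            chrom = norm_chrom(parts[0])
            name = norm_chrom(parts[3])
            if not name.endswith(("p", "q")):
                raise ParseError(f"{path} line {ln}: arm name {name!r} must end in p or q")
            arms.append(Arm(chrom=chrom, arm_label=name[-1], start=int(parts[1]), end=int(parts[2])))
    _check_arm_overlap(arms)
    return arms


def write_arm_bed(arms: Sequence[Arm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in sorted(arms, key=lambda a: (a.chrom, a.start)):
            fh.write(f"{vcf_chrom(a.chrom)}\t{a.start}\t{a.end}\t{a.name}\n")


def _check_arm_overlap(arms: Sequence[Arm]) -> None:
    by_chrom: dict[str, list[Arm]] = {}
    for a in arms:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda a: a.start)
        for prev, nxt in zip(group, group[1:]):
            if nxt.start < prev.end:
                raise DataIntegrityError(f"arms {prev.name} and {nxt.name} overlap on chromosome {chrom}")


def arm_of(arms: Sequence[Arm], chrom: str, pos: int) -> Arm | None:
    """Arm containing a 1-based position, or None."""
    chrom = norm_chrom(chrom)
    for a in arms:
        if a.chrom == chrom and a.contains(pos):
            return a
    return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{vcf_chrom(name)}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small, toy-scale) reference into memory, chrom names normalized."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {norm_chrom(name): str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def read_gene_lists(path: str | Path) -> dict[str, set]:
    """Two-column TSV (list_name, gene) -> map list_name -> gene set."""
    df = pd.read_csv(path, sep="\t")
    if not {"list_name", "gene"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns list_name, gene")
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.list_name), set()).add(str(row.gene))
    return out
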