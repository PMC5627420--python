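"""96-context mutation spectra and signature matching.

Single-base substitutions are classified into the 6 pyrimidine-collapsed
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 5' and
3' reference flanks — 96 trinucleotide contexts, COSMIC convention.  When the
reference base is a purine, alleles and flanks are reverse-complemented
before labeling, so a variant and its reverse-complement representation map
to the same bin.

Spectra are matched against a signature catalog by cosine similarity, and
decomposed into non-negative signature exposures by constrained least
squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .errors import DataIntegrityError
from .variantio import (
    CONTEXT_LABELS,
    SUBSTITUTION_CLASSES,
    SignatureCatalog,
    VariantCall,
    norm_chrom,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _triplet(reference, chrom: str, pos: int) -> str | None:
    """Reference trinucleotide centred on a 1-based position, or None at an edge.

    ``reference`` may be a mapping chrom -> sequence string or a pyfaidx.Fasta.
    """
    chrom = norm_chrom(chrom)
    try:
        seq = reference[chrom]
    except KeyError:
        for key in getattr(reference, "keys", lambda: [])():
            if norm_chrom(key) == chrom:
                seq = reference[key]
                break
        else:
            raise DataIntegrityError(f"chromosome {chrom!r} not in reference")
    if pos < 2 or pos + 1 > len(seq):
        return None
    trip = seq[pos - 2 : pos + 1]
    trip = str(getattr(trip, "seq", trip))
    return trip.upper()


def classify_context(variant: VariantCall, reference) -> str | None:
    """Label an SNV as one of the 96 contexts, or None if unclassifiable.

    Raises DataIntegrityError if the variant is not an SNV or its REF allele
    disagrees with the reference sequence.  A flank containing a non-ACGT
    base (or a chromosome-edge position) is unclassifiable.
    """
    if not variant.is_snv:
        raise DataIntegrityError(f"not an SNV: {variant.ref}>{variant.alt}")
    trip = _triplet(reference, variant.chrom, variant.pos)
    if trip is None:
        return None
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if trip[1] != ref:
        raise DataIntegrityError(
            f"reference base {trip[1]} at {variant.chrom}:{variant.pos} != REF allele {ref}"
        )
    if any(b not in "ACGT" for b in trip) or alt not in "ACGT":
        return None
    if ref in "AG":  # purine: collapse to the pyrimidine strand
        trip = revcomp(trip)
        ref = trip[1]
        alt = alt.translate(_COMPLEMENT)
    return f"{trip[0]}[{ref}>{alt}]{trip[2]}"


@dataclass
class MutationSpectrum:
    """96-bin count vector over pyrimidine-collapsed trinucleotide contexts."""

    sample: str
    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=int))
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,) or (self.counts < 0).any():
            raise ValueError("spectrum requires 96 non-negative counts")

    @property
    def n_snv(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, label: str) -> int:
        return int(self.counts[_LABEL_INDEX[label]])

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("all-zero spectrum has no direction")
        return self.counts / total

    def class_counts(self) -> dict[str, int]:
        """Counts aggregated to the 6 substitution classes."""
        by_class = self.counts.reshape(6, 16).sum(axis=1)
        return dict(zip(SUBSTITUTION_CLASSES, by_class.tolist()))


def build_spectrum(variants, reference, sample: str) -> MutationSpectrum:
    """Count one sample's SNVs into the 96 bins.

    Non-SNV inputs (indels) are skipped with a warning — they have no
    trinucleotide substitution class.  ``n_snv + n_skipped`` equals the number
    of SNV inputs (unclassifiable flanks are skipped, not counted).
    """
    counts = np.zeros(96, dtype=int)
    n_skipped = 0
    for v in variants:
        if not v.is_snv:
            logger.warning("skipping non-SNV %s:%d %s>%s", v.chrom, v.pos, v.ref, v.alt)
            continue
        label = classify_context(v, reference)
        if label is None:
            n_skipped += 1
        else:
            counts[_LABEL_INDEX[label]] += 1
    return MutationSpectrum(sample=sample, counts=counts, n_skipped=n_skipped)


@dataclass
class SignatureMatch:
    """Cosine similarities of one spectrum against every catalog signature."""

    sample: str
    similarities: dict  # name -> cosine
    best: str
    best_similarity: float


def cosine_match(spectrum: MutationSpectrum, catalog: SignatureCatalog) -> SignatureMatch:
    """Best-matching signature by cosine similarity; ties broken by catalog order."""
    u = spectrum.normalized()  # raises on all-zero
    sims: dict[str, float] = {}
    for name in catalog.names:
        s = catalog[name]
        denom = np.linalg.norm(u) * np.linalg.norm(s)
        sims[name] = float(u @ s / denom) if denom > 0 else 0.0
    best = max(catalog.names, key=lambda n: sims[n])  # max is stable: first of ties
    top = sims[best]
    ties = [n for n in catalog.names if sims[n] == top]
    if len(ties) > 1:
        logger.info("cosine tie among %s; keeping catalog order (%s)", ties, best)
    return SignatureMatch(sample=spectrum.sample, similarities=sims, best=best, best_similarity=top)


@dataclass
class MixtureFit:
    weights: dict  # name -> exposure in [0,1]
    residual: float  # Euclidean distance between spectrum and fitted mixture


def mixture_refit(spectrum: MutationSpectrum, catalog: SignatureCatalog) -> MixtureFit:
    """Non-negative signature exposures summing to 1.

    Minimizes || S w - u ||_2 over the probability simplex, where u is the
    normalized spectrum and S the (96, K) catalog matrix.
    """
    u = spectrum.normalized()
    S = catalog.matrix()
    k = S.shape[1]
    if k == 1:
        w = np.array([1.0])
    else:
        # unit-sum via a heavily weighted penalty row, solved by exact NNLS,
        # then renormalized; deterministic and accurate to machine precision
        lam = 1e4
        A = np.vstack([S, lam * np.ones((1, k))])
        b = np.concatenate([u, [lam]])
        w, _ = scipy.optimize.nnls(A, b)
        total = w.sum()
        if total == 0:
            w = np.full(k, 1.0 / k)
        else:
            w = w / total
    residual = float(np.linalg.norm(S @ w - u))
    return MixtureFit(weights=dict(zip(catalog.names, w.tolist())), residual=residual)


# ---------------------------------------------------------------------------
# Built-in fixture catalog
# ---------------------------------------------------------------------------

def default_catalog() -> SignatureCatalog:
    """Small built-in catalog: a defective-MMR-like profile plus four decoys.

    ``MMR_deficient`` concentrates mass on C>T at NCG contexts (the hallmark
    of defective mismatch repair, as in COSMIC signature 6) over a small flat
    background.  The decoys occupy well-separated supports: C>A-heavy
    (tobacco-like), T>C-heavy, C>G-heavy and a flat background.  This is a
    synthetic stand-in catalog shipped for tests and simulations; a real
    COSMIC catalog file loads through the same reader.
    """

    def _profile(weights: dict[str, float], background: float = 0.02) -> np.ndarray:
        vec = np.full(96, background / 96)
        for label, w in weights.items():
            vec[_LABEL_INDEX[label]] += w
        return vec / vec.sum()

    ncg = {f"{five}[C>T]G": 0.85 / 4 for five in "ACGT"}
    # mild secondary C>T mass at non-G 3' flanks, as in MMR-deficient tumors
    other_ct = {f"{five}[C>T]{three}": 0.13 / 12 for five in "ACGT" for three in "ACT"}
    mmr = _profile({**ncg, **other_ct})

    c_to_a = _profile({f"{f}[C>A]{t}": 0.9 / 16 for f in "ACGT" for t in "ACGT"})
    t_to_c = _profile({f"{f}[T>C]{t}": 0.9 / 16 for f in "ACGT" for t in "ACGT"})
    c_to_g = _profile({f"{f}[C>G]{t}": 0.9 / 16 for f in "ACGT" for t in "ACGT"})
    flat = np.full(96, 1.0 / 96)

    return SignatureCatalog(
        signatures={
            "MMR_deficient": mmr,
            "decoy_CtoA": c_to_a,
            "decoy_TtoC": t_to_c,
            "decoy_CtoG": c_to_g,
            "decoy_flat": flat,
        }
    )
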