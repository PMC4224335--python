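"""PCR-RFLP genotype calling and mtDNA haplogroup clustering.

The nuclear NDUFC2 L46V variant (rs8875) is genotyped by restriction
digestion of a 326-bp exon-1 amplicon with HpyCH4IV, which recognises
the palindromic ACGT motif present only on the rare (cut) allele.  A
homozygote for the common allele leaves the amplicon intact; a cut-allele
homozygote yields the 215 + 111 bp fragments; a heterozygote shows all
three bands.  Fine mtDNA haplogroup labels are merged into the four
phylogenetic clusters used throughout the analysis: HV (H, V), UK (U, K),
JT (J, T) and IW (I, W, X, N1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "DigestSpec",
    "BandPattern",
    "AlleleModel",
    "HPYCH4IV",
    "RS8875_MODEL",
    "DEFAULT_CLUSTER_MAP",
    "CLUSTERS",
    "digest",
    "genotype_from_bands",
    "cluster_haplogroup",
]

logger = logging.getLogger(__name__)

_DNA_ALPHABET = frozenset("ACGT")

#: The four merged haplogroup clusters used by the association analysis.
CLUSTERS = ("HV", "UK", "JT", "IW")


@dataclass(frozen=True)
class DigestSpec:
    """A restriction enzyme's recognition motif and cut position.

    ``cut_offset`` is the 0-based index within the motif *after* which the
    enzyme cuts (offset 0 means the cut falls between the first and second
    motif bases).
    """

    recognition_motif: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        if not self.recognition_motif:
            raise ValueError("recognition motif must be non-empty")
        bad = set(self.recognition_motif) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"motif contains non-DNA characters: {sorted(bad)}")
        if not 0 <= self.cut_offset < len(self.recognition_motif):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside motif of length "
                f"{len(self.recognition_motif)}"
            )


#: HpyCH4IV: recognises ACGT, cuts after the first base (A^CGT).
HPYCH4IV = DigestSpec("ACGT", cut_offset=0)


@dataclass(frozen=True)
class BandPattern:
    """Observed gel bands (fragment lengths in bp, sorted descending)."""

    fragment_lengths: tuple[int, ...]
    tolerance_bp: int = 5

    def __post_init__(self) -> None:
        lengths = tuple(sorted(self.fragment_lengths, reverse=True))
        if not lengths or any(l <= 0 for l in lengths):
            raise ValueError("fragment lengths must be positive and non-empty")
        if self.tolerance_bp < 0:
            raise ValueError("tolerance_bp must be non-negative")
        object.__setattr__(self, "fragment_lengths", lengths)


@dataclass(frozen=True)
class AlleleModel:
    """Expected band patterns for the two alleles of a biallelic RFLP assay."""

    uncut_allele: str
    cut_allele: str
    amplicon_length: int
    cut_fragments: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.uncut_allele == self.cut_allele:
            raise ValueError("alleles must be distinct")
        frags = tuple(sorted(self.cut_fragments, reverse=True))
        if sum(frags) != self.amplicon_length:
            raise ValueError(
                f"cut fragments {frags} do not sum to amplicon length "
                f"{self.amplicon_length}"
            )
        object.__setattr__(self, "cut_fragments", frags)


#: rs8875 assay: C allele uncut (326 bp), G allele cut into 215 + 111 bp.
RS8875_MODEL = AlleleModel("C", "G", 326, (215, 111))


def digest(sequence: str, spec: DigestSpec = HPYCH4IV) -> list[int]:
    """In-silico restriction digestion; returns fragment lengths left to right.

    Motif occurrences are found by a greedy non-overlapping scan from the
    left; the cut falls after ``spec.cut_offset`` within each occurrence.
    Fragment lengths always partition the sequence.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")

    motif = spec.recognition_motif
    cuts: list[int] = []
    pos = seq.find(motif)
    while pos != -1:
        cuts.append(pos + spec.cut_offset + 1)
        pos = seq.find(motif, pos + len(motif))

    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _bands_match(observed: tuple[int, ...], expected: tuple[int, ...], tol: int) -> bool:
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tol for o, e in zip(sorted(observed), sorted(expected)))


def genotype_from_bands(pattern: BandPattern, model: AlleleModel = RS8875_MODEL) -> str | None:
    """Call a diploid genotype from a gel band pattern.

    Returns the two allele labels sorted (e.g. ``"CG"``), or ``None`` when
    the pattern matches none of the three expected configurations within
    ``pattern.tolerance_bp`` per band — an ungenotypeable sample, not an
    error.
    """
    uncut = (model.amplicon_length,)
    cut = model.cut_fragments
    het = tuple(sorted((*uncut, *cut), reverse=True))
    tol = pattern.tolerance_bp
    obs = pattern.fragment_lengths

    if _bands_match(obs, uncut, tol):
        alleles = (model.uncut_allele, model.uncut_allele)
    elif _bands_match(obs, cut, tol):
        alleles = (model.cut_allele, model.cut_allele)
    elif _bands_match(obs, het, tol):
        alleles = (model.uncut_allele, model.cut_allele)
    else:
        logger.warning("unrecognised band pattern %s: no genotype call", obs)
        return None
    return "".join(sorted(alleles))


#: Top-level haplogroup -> cluster assignments.
DEFAULT_CLUSTER_MAP: dict[str, str] = {
    "H": "HV",
    "V": "HV",
    "U": "UK",
    "K": "UK",
    "J": "JT",
    "T": "JT",
    "I": "IW",
    "W": "IW",
    "X": "IW",
    "N1": "IW",
}


def cluster_haplogroup(
    haplogroup: str, mapping: dict[str, str] | None = None
) -> str | None:
    """Map a (possibly fine-grained) haplogroup label to its cluster.

    Sub-haplogroups resolve by longest-prefix match against the mapped
    top-level labels, so ``"H1a"`` -> ``"HV"`` and ``"N1b"`` -> ``"IW"``
    (via ``N1``, not a bare ``N``).  Unmapped haplogroups (e.g. ``L3``,
    ``M``) return ``None`` with a logged warning.
    """
    mapping = DEFAULT_CLUSTER_MAP if mapping is None else mapping
    label = haplogroup.strip().upper()
    best: str | None = None
    best_len = 0
    for prefix, cluster in mapping.items():
        if label.startswith(prefix) and len(prefix) > best_len:
            best, best_len = cluster, len(prefix)
    if best is None:
        logger.warning("haplogroup %r maps to no cluster", haplogroup)
    return best
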