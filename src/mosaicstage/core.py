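"""Shared domain types and sequence-level constants.

Coordinates are 0-based half-open internally; VCF emission converts to
1-based. Substitution channels follow the conventional pyrimidine-reference
96-channel layout (6 substitution types x 16 flanking contexts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable as _CodonTable

BASES = "ACGT"
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the six pyrimidine-reference substitution types, catalog order
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _build_channels() -> tuple[str, ...]:
    chans = []
    for sub in SUBSTITUTION_TYPES:
        ref, alt = sub[0], sub[2]
        for up in BASES:
            for down in BASES:
                chans.append(f"{up}[{ref}>{alt}]{down}")
    return tuple(chans)


#: canonical labels of the 96 single-base-substitution channels
CHANNELS_96: tuple[str, ...] = _build_channels()
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS_96)}

_standard = _CodonTable.unambiguous_dna_by_id[1]
#: codon -> single-letter amino acid, '*' for stop (standard table)
CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TABLE[_stop] = "*"


def channel_of(context: str, alt: str) -> int:
    """Index of the 96-channel for a trinucleotide ``context`` mutated to ``alt``.

    Purine-reference substitutions are folded onto the reverse complement so
    the reference base of the reported channel is always a pyrimidine.
    """
    if len(context) != 3:
        raise ValueError(f"context must be a trinucleotide, got {context!r}")
    ref = context[1]
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = context[1]
        alt = COMPLEMENT[alt]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    try:
        return CHANNEL_INDEX[label]
    except KeyError:
        raise ValueError(f"not a substitution: {context!r} -> {alt!r}") from None


@dataclass(frozen=True, order=True)
class Site:
    """A genomic substitution site (0-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass(frozen=True)
class SiteAnnotation:
    """Static annotation attached to a site by the generator or a user table."""

    context: str  # trinucleotide centred on the site, genome '+' strand
    strand: Optional[str] = None  # strand of overlapping transcript, or None
    gene: Optional[str] = None


@dataclass
class VariantObservation:
    """Read support for one candidate site in one tissue."""

    site: Site
    tissue_id: str
    depth: int
    alt_count: int
    alt_f1r2: int
    alt_f2r1: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )
        if self.alt_f1r2 + self.alt_f2r1 != self.alt_count:
            raise ValueError("orientation counts must sum to alt_count")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class TissueSample:
    """One tissue of one individual with its per-site read counts."""

    individual: str
    tissue_id: str
    organ: str
    age: float
    is_tumor: bool = False
    disease: Optional[str] = None
    observations: dict[Site, VariantObservation] = field(default_factory=dict)

    def sites(self) -> list[Site]:
        return sorted(self.observations)


class ConfigError(ValueError):
    """Invalid configuration of the simulator or a pipeline stage."""
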