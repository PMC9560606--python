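"""Synthetic multi-tissue cohort generator.

Produces per-individual tissue sets with planted early (multi-organ shared),
late (organ-restricted) and tumor mutations, per-site read counts with
orientation splits, oxoG-like and blacklist-region artifacts, plus the side
tables the downstream stages consume (gene models, pLI scores, reference
signatures, BED blacklists).

Early mutations share one clone VAF across every tissue of the individual;
late mutations are confined to a single organ, with the blood rate rising
linearly with age; tumor mutations live only in the tumor specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .core import (
    BASES,
    CHANNELS_96,
    CODON_TABLE,
    COMPLEMENT,
    ConfigError,
    PYRIMIDINES,
    Site,
    SiteAnnotation,
    TissueSample,
    VariantObservation,
    revcomp,
)

KNOWN_ORGANS = ("brain", "blood", "heart", "liver", "other")
BLACKLIST_TRACKS = (
    "common_snp",
    "segdup",
    "simple_repeat",
    "low_mappability",
    "off_target",
    "utr",
)

#: read orientation on which an oxoG artifact concentrates, per substitution
OXOG_PRONE_ORIENTATION = {("C", "A"): "F2R1", ("G", "T"): "F1R2"}


# ---------------------------------------------------------------------------
# Generator spectra (96-channel mixtures used to plant contexts per stage).
# Shapes are generator parameters, not claims: a CpG-focused C>T spectrum,
# a broad clock-like spectrum, a T>C-skewed spectrum for the early stage and
# an oxidative C>A-heavy spectrum for tumors.
# ---------------------------------------------------------------------------

def _spectrum(weights: dict[str, float], background: float = 0.0) -> np.ndarray:
    v = np.full(96, background, dtype=float)
    for i, chan in enumerate(CHANNELS_96):
        sub = chan[2] + ">" + chan[4]
        up, down = chan[0], chan[6]
        for key, w in weights.items():
            if key == sub or key == f"{sub}@{down}" or key == f"{up}@{sub}":
                v[i] += w
    s = v.sum()
    if s <= 0:
        raise ValueError("degenerate spectrum")
    return v / s


def build_generator_spectra() -> dict[str, np.ndarray]:
    return {
        "clocklike_cpg": _spectrum({"C>T@G": 10.0, "C>T": 0.5}, background=0.02),
        "flat_clock": _spectrum({"C>T": 1.0, "T>C": 1.0, "C>A": 0.4}, background=0.5),
        "tc_skew": _spectrum({"T>C": 8.0, "T>A": 0.5}, background=0.05),
        "oxidative": _spectrum({"C>A": 8.0, "C>G": 0.5}, background=0.05),
    }


GENERATOR_SPECTRA = build_generator_spectra()

_DEFAULT_SIGNATURE_MIX = {
    "early": {"clocklike_cpg": 0.40, "flat_clock": 0.25, "tc_skew": 0.35},
    "late": {"clocklike_cpg": 0.55, "flat_clock": 0.45},
    "tumor": {"clocklike_cpg": 0.20, "flat_clock": 0.30, "oxidative": 0.50},
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    VAF distributions are truncated normals on ``(vaf_floor, 1]``; mutation
    counts are Poisson with stage/organ-specific means. The blood late-clone
    rate is ``blood_rate_intercept + blood_rate_slope * age``.
    """

    n_individuals: int = 20
    organs_per_individual: tuple[str, ...] = ("brain", "blood", "heart", "liver")
    age_range: tuple[float, float] = (0.0, 90.0)
    depth_mean: float = 500.0
    seq_error_rate: float = 1e-3
    early_rate: float = 2.0
    late_rate_by_organ: dict[str, float] = field(
        default_factory=lambda: {"brain": 0.67, "heart": 1.5, "liver": 1.5, "other": 1.5}
    )
    blood_rate_intercept: float = 0.5
    blood_rate_slope: float = 0.08
    tumor_fraction: float = 0.1
    tumor_rate: float = 8.12
    vaf_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "early": (0.0617, 0.0332),
            "late": (0.0150, 0.0329),
            "tumor": (0.15, 0.05),
        }
    )
    vaf_floor: float = 0.002
    signature_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SIGNATURE_MIX.items()}
    )
    oxog_rate: float = 0.3
    blacklist_artifact_rate: float = 0.5
    artifact_vaf: float = 0.02
    oxog_orientation_bias: float = 0.97
    coding_fraction: float = 0.25
    contig: str = "chr1"
    contig_length: int = 10_000_000
    gene_region_end: int = 1_000_000
    n_genes: int = 12
    fraction_blacklisted: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.organs_per_individual:
            raise ConfigError("at least one organ per individual is required")
        for organ in self.organs_per_individual:
            if organ not in KNOWN_ORGANS:
                raise ConfigError(f"unknown organ label: {organ!r}")
        rates = [self.early_rate, self.tumor_rate, self.oxog_rate,
                 self.blood_rate_intercept, self.blacklist_artifact_rate,
                 *self.late_rate_by_organ.values()]
        if any(r < 0 for r in rates):
            raise ConfigError("all rates must be >= 0")
        if not 0 <= self.tumor_fraction <= 1:
            raise ConfigError("tumor_fraction must lie in [0, 1]")
        if not 0 < self.vaf_floor < 1:
            raise ConfigError("vaf_floor must lie in (0, 1)")
        for stage, (mean, sd) in self.vaf_params.items():
            if not 0 < mean <= 1 or sd < 0:
                raise ConfigError(f"bad VAF parameters for stage {stage!r}")
        for stage, mix in self.signature_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"signature mix for {stage!r} sums to {total}")
            for name in mix:
                if name not in GENERATOR_SPECTRA:
                    raise ConfigError(f"unknown generator spectrum {name!r}")
        if self.contig_length <= self.gene_region_end:
            raise ConfigError("contig_length must exceed gene_region_end")


@dataclass
class TruthRecord:
    """Ground truth for one planted site of one individual."""

    individual: str
    site: Site
    annotation: SiteAnnotation
    stage: str  # early | late | tumor | artifact
    clone_vaf_by_tissue: dict[str, float]
    artifact: bool = False
    artifact_kind: Optional[str] = None  # "oxog" or a blacklist track name
    artifact_tissue: Optional[str] = None
    apparent_vaf: float = 0.0

    @property
    def carrier_tissues(self) -> list[str]:
        return sorted(t for t, v in self.clone_vaf_by_tissue.items() if v > 0)


@dataclass
class GeneModel:
    """A synthetic transcript: sense-strand CDS with one-base flanks."""

    gene: str
    contig: str
    strand: str  # '+' or '-'
    cds_intervals: list[tuple[int, int]]  # 0-based half-open, genomic order
    cds_seq: str  # sense strand, length divisible by 3
    flank5: str  # one sense-strand base upstream of the CDS
    flank3: str  # one sense-strand base downstream
    protein: str

    def genomic_positions(self) -> list[int]:
        pos = [p for s, e in self.cds_intervals for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


@dataclass
class SyntheticCohort:
    """Everything a desk-scale run needs, generated from one seed."""

    config: CohortConfig
    tissues: list[TissueSample]
    truth: list[TruthRecord]
    annotations: dict[Site, SiteAnnotation]
    gene_models: list[GeneModel]
    pli: dict[str, float]
    reference_signatures: dict[str, np.ndarray]
    blacklists: dict[str, list[tuple[str, int, int]]]

    def tissues_of(self, individual: str) -> list[TissueSample]:
        return [t for t in self.tissues if t.individual == individual]

    def individuals(self) -> list[str]:
        return sorted({t.individual for t in self.tissues})


# ---------------------------------------------------------------------------
# Side tables
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


def generate_gene_models(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[GeneModel], dict[str, float], dict[str, np.ndarray]]:
    """Synthetic transcripts, a gene->pLI table and reference signatures.

    Transcripts tile the low-coordinate end of the contig (kept clear of
    blacklist intervals); every CDS length is a multiple of 3 and the stored
    protein tag is the straight translation of the sense CDS.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    genes: list[GeneModel] = []
    pli: dict[str, float] = {}
    cursor = 10_000
    for i in range(config.n_genes):
        n_codons = int(rng.integers(100, 300))
        codons = rng.choice(_NON_STOP_CODONS, size=n_codons)
        seq = "".join(codons)
        strand = "+" if rng.random() < 0.5 else "-"
        # one or two CDS intervals covering len(seq) genomic bases
        length = len(seq)
        if rng.random() < 0.5:
            intervals = [(cursor, cursor + length)]
        else:
            cut = int(rng.integers(30, length - 30))
            intron = int(rng.integers(50, 200))
            intervals = [(cursor, cursor + cut), (cursor + cut + intron, cursor + length + intron)]
        gm = GeneModel(
            gene=f"GENE{i:03d}",
            contig=config.contig,
            strand=strand,
            cds_intervals=intervals,
            cds_seq=seq,
            flank5=str(rng.choice(list(BASES))),
            flank3=str(rng.choice(list(BASES))),
            protein="".join(CODON_TABLE[seq[j : j + 3]] for j in range(0, length, 3)),
        )
        genes.append(gm)
        pli[gm.gene] = float(np.round(rng.random(), 4))
        cursor = intervals[-1][1] + int(rng.integers(500, 2_000))
        if cursor >= config.gene_region_end - 2_000:
            break
    refs = {name: spec.copy() for name, spec in GENERATOR_SPECTRA.items()}
    return genes, pli, refs


def generate_blacklists(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, list[tuple[str, int, int]]]:
    """Disjoint BED-style interval tracks over the non-genic contig tail.

    Total blacklisted bases hit ``fraction_blacklisted * contig_length``
    exactly (the last interval is trimmed); tracks never overlap.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    tracks: dict[str, list[tuple[str, int, int]]] = {t: [] for t in BLACKLIST_TRACKS}
    target = int(round(config.fraction_blacklisted * config.contig_length))
    if target == 0:
        return tracks
    cursor = config.gene_region_end
    covered = 0
    i = 0
    while covered < target and cursor < config.contig_length - 10:
        cursor += int(rng.integers(200, 5_000))  # gap
        length = int(rng.integers(100, 2_000))
        length = min(length, target - covered, config.contig_length - cursor)
        if length <= 0:
            break
        track = BLACKLIST_TRACKS[int(rng.integers(len(BLACKLIST_TRACKS)))]
        tracks[track].append((config.contig, cursor, cursor + length))
        cursor += length
        covered += length
        i += 1
    return tracks


# ---------------------------------------------------------------------------
# Context / VAF sampling helpers
# ---------------------------------------------------------------------------

def _stage_spectrum(config: CohortConfig, stage: str) -> np.ndarray:
    mix = config.signature_mix[stage]
    v = np.zeros(96)
    for name, w in mix.items():
        v += w * GENERATOR_SPECTRA[name]
    return v / v.sum()


def _channel_to_genomic(channel: str, rng: np.random.Generator) -> tuple[str, str]:
    """Pick a genome-strand representation (context, alt) for a 96-channel."""
    context = channel[0] + channel[2] + channel[6]
    alt = channel[4]
    if rng.random() < 0.5:  # present the purine-strand representation
        return revcomp(context), COMPLEMENT[alt]
    return context, alt


def draw_vaf(config: CohortConfig, stage: str, rng: np.random.Generator) -> float:
    mean, sd = config.vaf_params[stage]
    if sd == 0:
        return float(np.clip(mean, config.vaf_floor, 1.0))
    a = (config.vaf_floor - mean) / sd
    b = (1.0 - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _interval_lookup(blacklists: dict[str, list[tuple[str, int, int]]]):
    flat = [(c, s, e) for ivs in blacklists.values() for (c, s, e) in ivs]

    def contains(contig: str, pos: int) -> bool:
        return any(c == contig and s <= pos < e for c, s, e in flat)

    return contains


# ---------------------------------------------------------------------------
# Read-count simulation
# ---------------------------------------------------------------------------

def simulate_read_counts(
    truth: TruthRecord,
    tissue: TissueSample,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> VariantObservation:
    """Draw one tissue's read support at a truth site.

    Carrier tissues see ``Binomial(depth, clone_vaf + error)`` alt reads with
    a 50/50 orientation split; non-carriers see pure error; oxoG artifacts
    concentrate >= 90%% of their alt reads on the artifact-prone orientation.
    """
    rng = rng or np.random.default_rng(config.seed)
    depth = max(1, int(rng.poisson(config.depth_mean)))
    clone_vaf = truth.clone_vaf_by_tissue.get(tissue.tissue_id, 0.0)
    is_artifact_here = truth.artifact and truth.artifact_tissue == tissue.tissue_id
    p = clone_vaf + (config.artifact_vaf if is_artifact_here else 0.0)
    p = min(p + config.seq_error_rate, 1.0)
    alt = int(rng.binomial(depth, p))
    prone = OXOG_PRONE_ORIENTATION.get((truth.site.ref, truth.site.alt))
    if is_artifact_here and truth.artifact_kind == "oxog" and prone is not None:
        on_prone = int(rng.binomial(alt, config.oxog_orientation_bias))
        f1r2, f2r1 = (
            (on_prone, alt - on_prone) if prone == "F1R2" else (alt - on_prone, on_prone)
        )
    else:
        f1r2 = int(rng.binomial(alt, 0.5))
        f2r1 = alt - f1r2
    return VariantObservation(
        site=truth.site,
        tissue_id=tissue.tissue_id,
        depth=depth,
        alt_count=alt,
        alt_f1r2=f1r2,
        alt_f2r1=f2r1,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _sample_noncoding_site(
    config: CohortConfig,
    stage: str,
    spectrum: np.ndarray,
    rng: np.random.Generator,
    in_blacklist,
    used: set[int],
) -> tuple[Site, SiteAnnotation]:
    while True:
        pos = int(rng.integers(config.gene_region_end, config.contig_length - 1))
        if pos in used or in_blacklist(config.contig, pos):
            continue
        channel = CHANNELS_96[int(rng.choice(96, p=spectrum))]
        context, alt = _channel_to_genomic(channel, rng)
        used.add(pos)
        site = Site(config.contig, pos, context[1], alt)
        return site, SiteAnnotation(context=context, strand=None, gene=None)


def _sample_coding_site(
    config: CohortConfig,
    genes: list[GeneModel],
    gene_weights: np.ndarray,
    rng: np.random.Generator,
    used: set[int],
) -> tuple[Site, SiteAnnotation]:
    for _ in range(200):
        gm = genes[int(rng.choice(len(genes), p=gene_weights))]
        idx = int(rng.integers(gm.cds_length))
        pos = gm.genomic_positions()[idx]
        if pos in used:
            continue
        used.add(pos)
        padded = gm.flank5 + gm.cds_seq + gm.flank3
        sense_context = padded[idx : idx + 3]
        sense_ref = gm.cds_seq[idx]
        sense_alt = str(rng.choice([b for b in BASES if b != sense_ref]))
        if gm.strand == "+":
            context, ref, alt = sense_context, sense_ref, sense_alt
        else:
            context = revcomp(sense_context)
            ref, alt = COMPLEMENT[sense_ref], COMPLEMENT[sense_alt]
        site = Site(gm.contig, pos, ref, alt)
        return site, SiteAnnotation(context=context, strand=gm.strand, gene=gm.gene)
    raise RuntimeError("could not place a coding site without collision")


def _plant_artifact_site(
    config: CohortConfig,
    blacklists: dict[str, list[tuple[str, int, int]]],
    spectrum: np.ndarray,
    rng: np.random.Generator,
    used: set[int],
) -> Optional[tuple[Site, SiteAnnotation, str]]:
    tracks = [t for t, ivs in blacklists.items() if ivs]
    if not tracks:
        return None
    track = tracks[int(rng.integers(len(tracks)))]
    contig, s, e = blacklists[track][int(rng.integers(len(blacklists[track])))]
    for _ in range(50):
        pos = int(rng.integers(s, e))
        if pos not in used:
            break
    else:
        return None
    used.add(pos)
    channel = CHANNELS_96[int(rng.choice(96, p=spectrum))]
    context, alt = _channel_to_genomic(channel, rng)
    site = Site(contig, pos, context[1], alt)
    return site, SiteAnnotation(context=context, strand=None, gene=None), track


def _sample_oxog_site(
    config: CohortConfig, rng: np.random.Generator, in_blacklist, used: set[int]
) -> tuple[Site, SiteAnnotation]:
    while True:
        pos = int(rng.integers(config.gene_region_end, config.contig_length - 1))
        if pos in used or in_blacklist(config.contig, pos):
            continue
        used.add(pos)
        ref, alt = ("C", "A") if rng.random() < 0.5 else ("G", "T")
        up, down = rng.choice(list(BASES)), rng.choice(list(BASES))
        site = Site(config.contig, pos, ref, alt)
        return site, SiteAnnotation(context=f"{up}{ref}{down}", strand=None, gene=None)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort deterministically from the seed.

    One child random stream per individual keeps cohorts stable when the
    individual list is re-ordered or truncated.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    gm_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    bl_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    genes, pli, refs = generate_gene_models(config, gm_rng)
    blacklists = generate_blacklists(config, bl_rng)
    in_blacklist = _interval_lookup(blacklists)
    gene_weights = np.array([g.cds_length for g in genes], dtype=float)
    gene_weights /= gene_weights.sum()

    spectra = {stage: _stage_spectrum(config, stage) for stage in ("early", "late", "tumor")}

    tissues: list[TissueSample] = []
    truth: list[TruthRecord] = []
    annotations: dict[Site, SiteAnnotation] = {}
    used_positions: set[int] = set()

    child_seeds = root.spawn(config.n_individuals)
    for i in range(config.n_individuals):
        rng = np.random.default_rng(child_seeds[i])
        indiv = f"IND{i:04d}"
        age = float(rng.uniform(*config.age_range))
        has_tumor = rng.random() < config.tumor_fraction
        my_tissues = [
            TissueSample(
                individual=indiv,
                tissue_id=f"{indiv}_{organ}",
                organ=organ,
                age=age,
            )
            for organ in config.organs_per_individual
        ]
        if has_tumor:
            my_tissues.append(
                TissueSample(
                    individual=indiv,
                    tissue_id=f"{indiv}_tumor",
                    organ=config.organs_per_individual[0],
                    age=age,
                    is_tumor=True,
                )
            )
        my_truth: list[TruthRecord] = []

        def _new_site(stage: str) -> tuple[Site, SiteAnnotation]:
            if genes and rng.random() < config.coding_fraction:
                return _sample_coding_site(config, genes, gene_weights, rng, used_positions)
            return _sample_noncoding_site(
                config, stage, spectra[stage], rng, in_blacklist, used_positions
            )

        # early: shared across every tissue, one clone VAF
        for _ in range(rng.poisson(config.early_rate)):
            site, ann = _new_site("early")
            vaf = draw_vaf(config, "early", rng)
            my_truth.append(
                TruthRecord(
                    individual=indiv,
                    site=site,
                    annotation=ann,
                    stage="early",
                    clone_vaf_by_tissue={t.tissue_id: vaf for t in my_tissues},
                )
            )

        # late: confined to one organ; blood rate rises with age
        for tissue in my_tissues:
            if tissue.is_tumor:
                continue
            if tissue.organ == "blood":
                rate = config.blood_rate_intercept + config.blood_rate_slope * age
            else:
                rate = config.late_rate_by_organ.get(tissue.organ, 0.0)
            for _ in range(rng.poisson(rate)):
                site, ann = _new_site("late")
                vaf = draw_vaf(config, "late", rng)
                my_truth.append(
                    TruthRecord(
                        individual=indiv,
                        site=site,
                        annotation=ann,
                        stage="late",
                        clone_vaf_by_tissue={tissue.tissue_id: vaf},
                    )
                )

        # tumor: only in the tumor specimen
        if has_tumor:
            tumor_tissue = my_tissues[-1]
            for _ in range(rng.poisson(config.tumor_rate)):
                site, ann = _new_site("tumor")
                vaf = draw_vaf(config, "tumor", rng)
                my_truth.append(
                    TruthRecord(
                        individual=indiv,
                        site=site,
                        annotation=ann,
                        stage="tumor",
                        clone_vaf_by_tissue={tumor_tissue.tissue_id: vaf},
                    )
                )

        # oxoG artifacts: clone VAF zero everywhere, biased orientation
        for tissue in my_tissues:
            for _ in range(rng.poisson(config.oxog_rate)):
                site, ann = _sample_oxog_site(config, rng, in_blacklist, used_positions)
                my_truth.append(
                    TruthRecord(
                        individual=indiv,
                        site=site,
                        annotation=ann,
                        stage="artifact",
                        clone_vaf_by_tissue={},
                        artifact=True,
                        artifact_kind="oxog",
                        artifact_tissue=tissue.tissue_id,
                        apparent_vaf=config.artifact_vaf,
                    )
                )

        # artifacts planted inside blacklist intervals (to be region-filtered)
        for _ in range(rng.poisson(config.blacklist_artifact_rate)):
            planted = _plant_artifact_site(
                config, blacklists, spectra["late"], rng, used_positions
            )
            if planted is None:
                continue
            site, ann, track = planted
            tissue = my_tissues[int(rng.integers(len(my_tissues)))]
            my_truth.append(
                TruthRecord(
                    individual=indiv,
                    site=site,
                    annotation=ann,
                    stage="artifact",
                    clone_vaf_by_tissue={},
                    artifact=True,
                    artifact_kind=track,
                    artifact_tissue=tissue.tissue_id,
                    apparent_vaf=config.artifact_vaf,
                )
            )

        # read counts: every tissue of the individual observes every truth site
        for rec in my_truth:
            annotations[rec.site] = rec.annotation
            for tissue in my_tissues:
                tissue.observations[rec.site] = simulate_read_counts(
                    rec, tissue, config, rng
                )

        tissues.extend(my_tissues)
        truth.extend(my_truth)

    return SyntheticCohort(
        config=config,
        tissues=tissues,
        truth=truth,
        annotations=annotations,
        gene_models=genes,
        pli=pli,
        reference_signatures=refs,
        blacklists=blacklists,
    )


def expected_filtered_manifest(
    truth: list[TruthRecord], blacklists: dict[str, list[tuple[str, int, int]]]
) -> list[TruthRecord]:
    """Truth records whose site lies inside any blacklist interval."""
    contains = _interval_lookup(blacklists)
    return [r for r in truth if contains(r.site.contig, r.site.pos)]
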