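"""End-to-end driver, descriptive summaries and the truth-table validation
harness."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import io as msio
from .calling import CallParams, all_pairs_call
from .classify import (
    ClassifiedVariant,
    ClassifyParams,
    IntervalTrack,
    classify_stage,
    normalize_counts,
)
from .core import Site, SiteAnnotation, TissueSample
from .selection import (
    CodingModel,
    atypical_mutability,
    dnds_mle,
    pli_profile,
)
from .signatures import (
    build_catalog,
    cluster_exposures,
    extract_signatures_nmf,
    refit_exposures,
    strand_asymmetry,
)
from .synthetic import (
    GENERATOR_SPECTRA,
    CohortConfig,
    SyntheticCohort,
    TruthRecord,
    simulate_cohort,
)

STAGES = ("early", "late", "tumor")


def precision(n_confirmed: int, n_tested: int) -> float:
    """Validation precision: confirmed / tested."""
    if n_tested <= 0:
        raise ValueError("precision undefined with zero tested variants")
    if not 0 <= n_confirmed <= n_tested:
        raise ValueError("confirmed count outside [0, tested]")
    return n_confirmed / n_tested


def precision_percent(n_confirmed: int, n_tested: int, digits: int = 2) -> float:
    return round(100.0 * precision(n_confirmed, n_tested), digits)


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    group: str
    n_variants: int
    per_individual_mean: float
    per_individual_normalized: float
    vaf_mean: float
    vaf_sd: float
    age_count_r: Optional[float]
    age_count_p: Optional[float]
    age_vaf_r: Optional[float]
    age_vaf_p: Optional[float]


def _safe_pearson(x, y) -> tuple[Optional[float], Optional[float]]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    r, p = pearsonr(x, y)
    return float(r), float(p)


def summarize_groups(
    classified: list[ClassifiedVariant], tissues: list[TissueSample]
) -> list[GroupSummary]:
    """Per-stage burden / VAF summaries with age correlations."""
    age_by_individual = {}
    tissues_by_individual: dict[str, int] = {}
    for t in tissues:
        age_by_individual[t.individual] = t.age
        tissues_by_individual[t.individual] = tissues_by_individual.get(t.individual, 0) + 1
    individuals = sorted(age_by_individual)
    summaries = []
    for stage in STAGES:
        stage_variants = [cv for cv in classified if cv.stage == stage]
        counts = {i: 0 for i in individuals}
        for cv in stage_variants:
            counts[cv.individual] += 1
        ages = [age_by_individual[i] for i in individuals]
        count_vec = [counts[i] for i in individuals]
        norm_vec = [
            normalize_counts(counts[i], tissues_by_individual[i]) for i in individuals
        ]
        vafs = [cv.mean_vaf for cv in stage_variants]
        vaf_by_ind = {}
        for cv in stage_variants:
            vaf_by_ind.setdefault(cv.individual, []).append(cv.mean_vaf)
        ind_with = sorted(vaf_by_ind)
        r_count, p_count = _safe_pearson(ages, count_vec)
        r_vaf, p_vaf = _safe_pearson(
            [age_by_individual[i] for i in ind_with],
            [float(np.mean(vaf_by_ind[i])) for i in ind_with],
        )
        summaries.append(
            GroupSummary(
                group=stage,
                n_variants=len(stage_variants),
                per_individual_mean=float(np.mean(count_vec)) if individuals else 0.0,
                per_individual_normalized=float(np.mean(norm_vec)) if individuals else 0.0,
                vaf_mean=float(np.mean(vafs)) if vafs else float("nan"),
                vaf_sd=float(np.std(vafs, ddof=1)) if len(vafs) > 1 else float("nan"),
                age_count_r=r_count,
                age_count_p=p_count,
                age_vaf_r=r_vaf,
                age_vaf_p=p_vaf,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Validation against the truth table
# ---------------------------------------------------------------------------

@dataclass
class StageValidation:
    n_tested: int
    n_confirmed: int
    precision: Optional[float]
    n_truth: int
    n_recovered: int
    recall: Optional[float]


@dataclass
class ValidationReport:
    by_stage: dict[str, StageValidation]
    vaf_concordance_r: Optional[float]
    paired_tissue_r: Optional[float]

    def precision_percent(self, stage: str, digits: int = 2) -> float:
        entry = self.by_stage[stage]
        return precision_percent(entry.n_confirmed, entry.n_tested, digits)


def validate_against_truth(
    classified: list[ClassifiedVariant], truth: list[TruthRecord]
) -> ValidationReport:
    """Join calls to truth on (individual, site); per-stage precision/recall
    plus VAF concordance."""
    truth_by_key = {(r.individual, r.site): r for r in truth}
    by_stage: dict[str, StageValidation] = {}
    called_vafs, true_vafs = [], []
    pair_a, pair_b = [], []
    confirmed_keys: dict[str, set] = {s: set() for s in STAGES}
    tested: dict[str, int] = {s: 0 for s in STAGES}
    confirmed: dict[str, int] = {s: 0 for s in STAGES}
    for cv in classified:
        if cv.stage not in tested:
            continue
        tested[cv.stage] += 1
        rec = truth_by_key.get((cv.individual, cv.site))
        if rec is not None and rec.stage == cv.stage:
            confirmed[cv.stage] += 1
            confirmed_keys[cv.stage].add((cv.individual, cv.site))
        if rec is not None and not rec.artifact:
            called_vafs.append(cv.mean_vaf)
            true_vafs.append(float(np.mean(list(rec.clone_vaf_by_tissue.values()))))
            present = cv.presence_tissues
            if len(present) >= 2:
                pair_a.append(cv.observations[present[0]].vaf)
                pair_b.append(cv.observations[present[1]].vaf)
    for stage in STAGES:
        n_truth = sum(1 for r in truth if r.stage == stage)
        n_rec = len(confirmed_keys[stage])
        by_stage[stage] = StageValidation(
            n_tested=tested[stage],
            n_confirmed=confirmed[stage],
            precision=(confirmed[stage] / tested[stage]) if tested[stage] else None,
            n_truth=n_truth,
            n_recovered=n_rec,
            recall=(n_rec / n_truth) if n_truth else None,
        )
    r_conc, _ = _safe_pearson(called_vafs, true_vafs)
    r_pair, _ = _safe_pearson(pair_a, pair_b)
    return ValidationReport(
        by_stage=by_stage, vaf_concordance_r=r_conc, paired_tissue_r=r_pair
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    classified: list[ClassifiedVariant]
    summaries: list[GroupSummary]
    validation: ValidationReport
    signature_output: dict = field(default_factory=dict)
    selection_output: dict = field(default_factory=dict)


def _variant_records(
    classified: list[ClassifiedVariant], annotations: dict[Site, SiteAnnotation]
) -> dict[str, list[SimpleNamespace]]:
    by_stage: dict[str, list[SimpleNamespace]] = {s: [] for s in STAGES}
    for cv in classified:
        ann = annotations.get(cv.site)
        if ann is None:
            continue
        by_stage[cv.stage].append(
            SimpleNamespace(
                site=cv.site,
                context=ann.context,
                alt=cv.site.alt,
                strand=ann.strand,
                gene=ann.gene,
            )
        )
    return by_stage


def classify_cohort(
    cohort: SyntheticCohort,
    call_params: Optional[CallParams] = None,
    classify_params: Optional[ClassifyParams] = None,
) -> list[ClassifiedVariant]:
    """All-pairs calling plus stage classification for every individual."""
    call_params = call_params or CallParams(error_rate=cohort.config.seq_error_rate)
    classify_params = classify_params or ClassifyParams()
    tracks = {
        name: IntervalTrack(ivs) for name, ivs in cohort.blacklists.items()
    }
    classified: list[ClassifiedVariant] = []
    for individual in cohort.individuals():
        tissues = cohort.tissues_of(individual)
        if len(tissues) < 2:
            raise ValueError(
                f"{individual}: all-pairs mode needs >= 2 tissues; "
                "use tumor-vs-normal mode"
            )
        matrix = all_pairs_call(tissues, call_params)
        classified.extend(
            classify_stage(tissues, matrix, tracks, call_params, classify_params)
        )
    return classified


def run_pipeline(
    config: CohortConfig,
    outdir: Optional[Path] = None,
    call_params: Optional[CallParams] = None,
    classify_params: Optional[ClassifyParams] = None,
    nmf_rank: int = 3,
    nmf_restarts: int = 10,
) -> PipelineResult:
    """simulate -> call -> filter/classify -> signatures -> selection -> report."""
    cohort = simulate_cohort(config)
    classified = classify_cohort(cohort, call_params, classify_params)
    summaries = summarize_groups(classified, cohort.tissues)
    validation = validate_against_truth(classified, cohort.truth)

    by_stage = _variant_records(classified, cohort.annotations)
    catalogs = {s: build_catalog(v, label=s) for s, v in by_stage.items()}
    signature_output: dict = {
        "catalogs": {s: c.counts.tolist() for s, c in catalogs.items()}
    }
    nonempty = [catalogs[s] for s in STAGES if catalogs[s].total > 0]
    if len(nonempty) >= nmf_rank and all(c.total >= 10 for c in nonempty):
        sigset = extract_signatures_nmf(
            nonempty, rank=min(nmf_rank, len(nonempty)), n_restarts=nmf_restarts,
            seed=config.seed,
        )
        signature_output["nmf"] = {
            "signatures": sigset.signatures.tolist(),
            "exposures": sigset.exposures.tolist(),
            "groups": sigset.group_labels,
            "reconstruction_error": sigset.reconstruction_error,
        }
    refits = {}
    for stage, cat in catalogs.items():
        if cat.total > 0:
            refit = refit_exposures(cat, cohort.reference_signatures)
            refits[stage] = dict(
                zip(refit.signature_names, refit.contributions.tolist())
            )
    signature_output["refit_contributions"] = refits
    if len(refits) >= 2:
        clustering = cluster_exposures(
            {s: np.array(list(c.values())) for s, c in refits.items()}
        )
        signature_output["exposure_leaf_order"] = clustering.leaf_order
    stranded = [v for vs in by_stage.values() for v in vs if v.strand in ("+", "-")]
    if stranded:
        sc = strand_asymmetry(stranded)
        signature_output["strand_asymmetry"] = {
            "transcribed": sc.transcribed,
            "untranscribed": sc.untranscribed,
            "p_value": sc.p_value,
        }

    model = CodingModel(cohort.gene_models)
    background = np.mean([GENERATOR_SPECTRA[k] for k in GENERATOR_SPECTRA], axis=0)
    selection_output: dict = {}
    for stage, variants in by_stage.items():
        if not variants:
            continue
        res = dnds_mle(variants, model, label=stage)
        entry = {
            "n_syn": res.n_syn,
            "n_nonsyn": res.n_nonsyn,
            "omega": res.omega,
            "ci": res.ci,
            "undefined": res.undefined,
            "atypical_fraction": atypical_mutability(variants, background),
        }
        selection_output[stage] = entry
    groups_with_genes = {
        s: [v for v in vs if v.gene] for s, vs in by_stage.items() if vs
    }
    if any(groups_with_genes.values()):
        profile = pli_profile(groups_with_genes, cohort.pli)
        selection_output["pli"] = {
            "medians": profile.median_by_group,
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in profile.pairwise_p.items()},
        }

    result = PipelineResult(
        cohort=cohort,
        classified=classified,
        summaries=summaries,
        validation=validation,
        signature_output=signature_output,
        selection_output=selection_output,
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = result.cohort
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for tissue in cohort.tissues:
        msio.write_tissue_vcf(
            vcf_dir / f"{tissue.tissue_id}.vcf",
            tissue,
            cohort.annotations,
            contig_length=cohort.config.contig_length,
        )
    bed_dir = outdir / "blacklists"
    bed_dir.mkdir(exist_ok=True)
    for track, intervals in cohort.blacklists.items():
        msio.write_bed(bed_dir / f"{track}.bed", intervals)
    msio.truth_to_frame(cohort.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    msio.classified_to_frame(result.classified).to_csv(
        outdir / "classified.tsv", sep="\t", index=False
    )
    msio.write_gene_models(outdir / "gene_models.tsv", cohort.gene_models)
    pd.DataFrame(
        sorted(cohort.pli.items()), columns=["gene", "pli"]
    ).to_csv(outdir / "pli.tsv", sep="\t", index=False)
    msio.write_signature_matrix(
        outdir / "reference_signatures.tsv", cohort.reference_signatures
    )
    pd.DataFrame([vars(s) for s in result.summaries]).to_csv(
        outdir / "group_summary.tsv", sep="\t", index=False
    )
    msio.write_json(
        outdir / "validation.json",
        {
            stage: vars(entry)
            for stage, entry in result.validation.by_stage.items()
        }
        | {
            "vaf_concordance_r": result.validation.vaf_concordance_r,
            "paired_tissue_r": result.validation.paired_tissue_r,
        },
    )
    msio.write_json(outdir / "signatures.json", result.signature_output)
    msio.write_json(outdir / "selection.json", result.selection_output)
    config_repr = json.dumps(
        {k: str(v) for k, v in vars(cohort.config).items()}, sort_keys=True
    )
    msio.write_json(
        outdir / "run_log.json",
        {
            "seed": cohort.config.seed,
            "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
            "n_tissues": len(cohort.tissues),
            "n_truth": len(cohort.truth),
            "n_classified": len(result.classified),
        },
    )
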