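"""Post-call filter cascade and early/late/tumor stage assignment.

A variant's stage is decided from the set of organs with statistically
supported presence: >= 2 distinct non-tumor organs -> early, exactly one ->
late, tumor specimen only -> tumor. Shared variants invisible to the
case/control contrast are rescued through a VAF-concordance test against
the best-supported tissue.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import binomtest

from .calling import (
    CallParams,
    CandidateMatrix,
    all_pairs_call,
    bh_adjust,
    presence_test,
    strand_balance_ok,
)
from .core import Site, TissueSample, VariantObservation

REGION_TRACKS = (
    "common_snp",
    "segdup",
    "simple_repeat",
    "low_mappability",
    "off_target",
    "utr",
)

OXOG_CLASSES = {("C", "A"), ("G", "T")}


@dataclass(frozen=True)
class ClassifyParams:
    alpha_presence: float = 0.05  # BH level for per-tissue presence
    alpha_concordance: float = 0.05  # two-sided VAF concordance, uncorrected
    oxog_orientation_cut: float = 0.9
    oxog_max_alt: int = 20


# ---------------------------------------------------------------------------
# oxoG artifact filter
# ---------------------------------------------------------------------------

def oxog_filter(
    obs: VariantObservation,
    orientation_cut: float = 0.9,
    max_alt: int = 20,
) -> bool:
    """True when the observation is kept (i.e. does not look oxoG-induced).

    Applies only to C>A / G>T substitutions: the observation fails when the
    fraction of alt reads on the artifact-prone orientation reaches
    ``orientation_cut`` with at most ``max_alt`` supporting reads. All other
    substitution classes always pass.
    """
    key = (obs.site.ref, obs.site.alt)
    if key not in OXOG_CLASSES or obs.alt_count == 0:
        return True
    prone = obs.alt_f2r1 if key == ("C", "A") else obs.alt_f1r2
    fraction = prone / obs.alt_count
    return not (fraction >= orientation_cut and obs.alt_count <= max_alt)


# ---------------------------------------------------------------------------
# Region blacklist filters
# ---------------------------------------------------------------------------

class IntervalTrack:
    """Sorted half-open 0-based intervals of one contig-keyed BED track."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        self._by_contig: dict[str, tuple[list[int], list[int]]] = {}
        per: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if end < start:
                raise ValueError(f"interval end {end} before start {start}")
            per.setdefault(contig, []).append((start, end))
        for contig, ivs in per.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:  # overlapping inputs are merged for the lookup
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._by_contig[contig] = (
                [s for s, _ in merged],
                [e for _, e in merged],
            )

    def contains(self, contig: str, pos: int) -> bool:
        entry = self._by_contig.get(contig)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]


@dataclass
class FilterVerdict:
    """Per-track boolean outcomes; True means the site passes that filter."""

    site: Site
    oxog: bool = True
    common_snp: bool = True
    segdup: bool = True
    simple_repeat: bool = True
    low_mappability: bool = True
    off_target: bool = True
    utr: bool = True

    @property
    def keep(self) -> bool:
        return all(
            getattr(self, name) for name in ("oxog",) + REGION_TRACKS
        )


def region_filters(site: Site, blacklists: dict[str, IntervalTrack]) -> FilterVerdict:
    """Evaluate every region track independently for one site."""
    verdict = FilterVerdict(site=site)
    for track in REGION_TRACKS:
        intervals = blacklists.get(track)
        if intervals is not None and intervals.contains(site.contig, site.pos):
            setattr(verdict, track, False)
    return verdict


# ---------------------------------------------------------------------------
# Shared-variant concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceDecision:
    concordant: bool
    p_concordance: float
    p_presence: float


def shared_concordance_test(
    obs_b: VariantObservation,
    vaf_a: float,
    alpha: float = 0.05,
    error_rate: float = 1e-3,
    alpha_presence: float = 0.05,
) -> ConcordanceDecision:
    """Is tissue B's support consistent with the partner tissue's VAF?

    Exact two-sided binomial test of ``obs_b`` against the null proportion
    ``vaf_a``; concordant iff that test does NOT reject at ``alpha`` while
    the one-sided presence test against the background error rejects at
    ``alpha_presence``.
    """
    if not 0.0 < vaf_a < 1.0:
        raise ValueError("partner VAF must lie strictly inside (0, 1)")
    p_conc = binomtest(obs_b.alt_count, obs_b.depth, vaf_a).pvalue
    p_pres = presence_test(obs_b.alt_count, obs_b.depth, error_rate)
    return ConcordanceDecision(
        concordant=bool(p_conc >= alpha and p_pres < alpha_presence),
        p_concordance=float(p_conc),
        p_presence=float(p_pres),
    )


# ---------------------------------------------------------------------------
# Stage classification
# ---------------------------------------------------------------------------

@dataclass
class PresenceDecision:
    present: bool
    p_value: float
    q_value: float
    concordant_with_anchor: Optional[bool] = None


@dataclass
class ClassifiedVariant:
    site: Site
    individual: str
    observations: dict[str, VariantObservation]
    presence: dict[str, PresenceDecision]
    organs: set[str]
    stage: str  # early | late | tumor
    mean_vaf: float
    filter_verdict: FilterVerdict
    anchor_tissue: str
    pass_primary: bool = True
    pass_secondary: bool = True

    @property
    def presence_tissues(self) -> list[str]:
        return sorted(t for t, d in self.presence.items() if d.present)


def _presence_qvalues(
    tissue: TissueSample, params: CallParams
) -> dict[Site, tuple[float, float]]:
    sites = tissue.sites()
    if not sites:
        return {}
    p = np.array(
        [
            presence_test(
                tissue.observations[s].alt_count,
                tissue.observations[s].depth,
                params.error_rate,
            )
            for s in sites
        ]
    )
    q = bh_adjust(p)
    return {s: (float(pv), float(qv)) for s, pv, qv in zip(sites, p, q)}


def classify_stage(
    tissues: list[TissueSample],
    matrix: Optional[CandidateMatrix] = None,
    blacklists: Optional[dict[str, IntervalTrack]] = None,
    call_params: Optional[CallParams] = None,
    params: Optional[ClassifyParams] = None,
) -> list[ClassifiedVariant]:
    """Assign a stage to every surviving candidate of one individual.

    Presence per tissue requires a BH-corrected presence test plus the
    alt-count / VAF support floor; tissues other than the best-supported
    anchor additionally need VAF concordance with the anchor before their
    organ counts toward the multi-organ (early) definition. The two ensemble
    pass flags must both hold at the anchor. Tumor specimens never count
    toward the organ set: presence in a tumor plus exactly one organ is
    late; presence in the tumor alone is tumor.
    """
    call_params = call_params or CallParams()
    params = params or ClassifyParams()
    if not tissues:
        return []
    for t in tissues:
        if t.organ is None or t.organ == "":
            raise ValueError(f"tissue {t.tissue_id} has no organ label")
    if matrix is None:
        matrix = all_pairs_call(tissues, call_params)
    by_id = {t.tissue_id: t for t in tissues}
    individual = tissues[0].individual

    pq = {t.tissue_id: _presence_qvalues(t, call_params) for t in tissues}
    candidate_sites: set[Site] = set(matrix.all_sites())
    # shared-candidate rescue: sites whose presence test survives BH in >= 1
    # tissue even without a case/control contrast (fully shared variants)
    for t in tissues:
        for site, (p, q) in pq[t.tissue_id].items():
            obs = t.observations[site]
            if (
                q < params.alpha_presence
                and obs.alt_count >= call_params.alt_min
                and obs.vaf >= call_params.vaf_min
            ):
                candidate_sites.add(site)

    results: list[ClassifiedVariant] = []
    for site in sorted(candidate_sites):
        observations = {
            t.tissue_id: t.observations[site]
            for t in tissues
            if site in t.observations
        }
        presence: dict[str, PresenceDecision] = {}
        for tid, obs in observations.items():
            p, q = pq[tid].get(site, (1.0, 1.0))
            present = (
                q < params.alpha_presence
                and obs.alt_count >= call_params.alt_min
                and obs.vaf >= call_params.vaf_min
            )
            presence[tid] = PresenceDecision(present=present, p_value=p, q_value=q)
        supported = [tid for tid, d in presence.items() if d.present]
        if not supported:
            continue
        anchor = max(supported, key=lambda tid: observations[tid].alt_count)
        anchor_obs = observations[anchor]
        # concordance gate: other tissues join the presence set only when
        # their VAF is consistent with the anchor clone
        if 0.0 < anchor_obs.vaf < 1.0:
            for tid in supported:
                if tid == anchor:
                    continue
                decision = shared_concordance_test(
                    observations[tid],
                    anchor_obs.vaf,
                    alpha=params.alpha_concordance,
                    error_rate=call_params.error_rate,
                    alpha_presence=params.alpha_presence,
                )
                presence[tid].concordant_with_anchor = decision.concordant
                if not decision.concordant:
                    presence[tid].present = False
        present_ids = [tid for tid, d in presence.items() if d.present]

        pass_primary = pq[anchor].get(site, (1.0, 1.0))[1] < params.alpha_presence
        pass_secondary = (
            anchor_obs.alt_count >= call_params.alt_min
            and anchor_obs.vaf >= call_params.vaf_min
            and strand_balance_ok(anchor_obs)
        )
        if not (pass_primary and pass_secondary):
            continue

        verdict = (
            region_filters(site, blacklists)
            if blacklists is not None
            else FilterVerdict(site=site)
        )
        pooled = _pool_observations([observations[tid] for tid in present_ids])
        verdict.oxog = oxog_filter(
            pooled, params.oxog_orientation_cut, params.oxog_max_alt
        )
        if not verdict.keep:
            continue

        organs = {by_id[tid].organ for tid in present_ids if not by_id[tid].is_tumor}
        if len(organs) >= 2:
            stage = "early"
        elif len(organs) == 1:
            stage = "late"
        else:
            stage = "tumor"
        mean_vaf = float(np.mean([observations[tid].vaf for tid in present_ids]))
        results.append(
            ClassifiedVariant(
                site=site,
                individual=individual,
                observations=observations,
                presence=presence,
                organs=organs,
                stage=stage,
                mean_vaf=mean_vaf,
                filter_verdict=verdict,
                anchor_tissue=anchor,
                pass_primary=pass_primary,
                pass_secondary=pass_secondary,
            )
        )
    return results


def _pool_observations(observations: list[VariantObservation]) -> VariantObservation:
    first = observations[0]
    return VariantObservation(
        site=first.site,
        tissue_id="pooled",
        depth=sum(o.depth for o in observations),
        alt_count=sum(o.alt_count for o in observations),
        alt_f1r2=sum(o.alt_f1r2 for o in observations),
        alt_f2r1=sum(o.alt_f2r1 for o in observations),
    )


def normalize_counts(n_mutations: float, n_tissues: int) -> float:
    """Tissue-count-normalized mutation burden."""
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    return n_mutations / n_tissues
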