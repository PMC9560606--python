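"""Functional-impact statistics per mutation group.

A reduced global-omega trinucleotide dN/dS model: context-specific
mutation rates are estimated from synonymous observations over a
strand-specific 192-class opportunity tensor enumerated from the packaged
transcripts, and omega compares observed-to-expected nonsynonymous against
synonymous rates with a profile-likelihood confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, mannwhitneyu

from .core import BASES, CODON_TABLE, COMPLEMENT, Site, revcomp
from .synthetic import GeneModel

_B = {b: i for i, b in enumerate(BASES)}
N_CLASSES = 192  # 64 sense-strand trinucleotide contexts x 3 alternate bases


def class_index(context: str, alt: str) -> int:
    """Index of a strand-specific (trinucleotide, alt) substitution class."""
    up, ref, down = context
    alts = [b for b in BASES if b != ref]
    return (_B[up] * 16 + _B[ref] * 4 + _B[down]) * 3 + alts.index(alt)


CONSEQUENCES = ("synonymous", "missense", "nonsense", "noncoding")


@dataclass
class _CodingSite:
    gene: str
    cds_index: int
    sense_context: str
    sense_ref: str
    strand: str
    codon_start: int


class CodingModel:
    """Transcript set with a brute-force-checkable opportunity tensor.

    ``opportunity_syn`` / ``opportunity_nonsyn`` count, per 192-class, the
    number of possible CDS changes of that class that are synonymous or
    nonsynonymous (missense + nonsense) across every packaged transcript.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._by_pos: dict[tuple[str, int], _CodingSite] = {}
        self.opportunity_syn = np.zeros(N_CLASSES)
        self.opportunity_nonsyn = np.zeros(N_CLASSES)
        self._all_changes: list[tuple[Site, int, str]] = []
        #: (contig, pos, genomic alt) -> (class index, consequence)
        self._by_change: dict[tuple[str, int, str], tuple[int, str]] = {}
        for gm in self.genes:
            if gm.cds_length % 3 != 0:
                raise ValueError(f"{gm.gene}: CDS length not divisible by 3")
            padded = gm.flank5 + gm.cds_seq + gm.flank3
            positions = gm.genomic_positions()
            for i in range(gm.cds_length):
                ctx = padded[i : i + 3]
                ref = gm.cds_seq[i]
                cs = _CodingSite(
                    gene=gm.gene,
                    cds_index=i,
                    sense_context=ctx,
                    sense_ref=ref,
                    strand=gm.strand,
                    codon_start=(i // 3) * 3,
                )
                self._by_pos[(gm.contig, positions[i])] = cs
                codon = gm.cds_seq[cs.codon_start : cs.codon_start + 3]
                aa = CODON_TABLE[codon]
                for alt in BASES:
                    if alt == ref:
                        continue
                    new_codon = list(codon)
                    new_codon[i % 3] = alt
                    new_aa = CODON_TABLE["".join(new_codon)]
                    k = class_index(ctx, alt)
                    if new_aa == aa:
                        self.opportunity_syn[k] += 1
                        cons = "synonymous"
                    else:
                        self.opportunity_nonsyn[k] += 1
                        cons = "nonsense" if new_aa == "*" else "missense"
                    if gm.strand == "+":
                        g_ref, g_alt = ref, alt
                    else:
                        g_ref, g_alt = COMPLEMENT[ref], COMPLEMENT[alt]
                    self._all_changes.append(
                        (Site(gm.contig, positions[i], g_ref, g_alt), k, cons)
                    )
                    self._by_change[(gm.contig, positions[i], g_alt)] = (k, cons)

    def lookup(self, contig: str, pos: int) -> Optional[_CodingSite]:
        return self._by_pos.get((contig, pos))


def annotate_consequence(site: Site, model: CodingModel) -> str:
    """Coding consequence of a genomic SNV under the standard codon table."""
    cs = model.lookup(site.contig, site.pos)
    if cs is None:
        return "noncoding"
    sense_ref = site.ref if cs.strand == "+" else COMPLEMENT[site.ref]
    if sense_ref != cs.sense_ref:
        raise ValueError(
            f"reference mismatch at {site.contig}:{site.pos}: "
            f"{sense_ref} vs transcript {cs.sense_ref}"
        )
    return model._by_change[(site.contig, site.pos, site.alt)][1]


def _variant_class(site: Site, cs: _CodingSite) -> int:
    alt = site.alt if cs.strand == "+" else COMPLEMENT[site.alt]
    return class_index(cs.sense_context, alt)


# ---------------------------------------------------------------------------
# dN/dS maximum likelihood
# ---------------------------------------------------------------------------

def omega_point(n_syn: int, n_nonsyn: int, e_syn: float, e_nonsyn: float) -> float:
    """Point estimate (n_N / E_N) / (n_S / E_S)."""
    if n_syn <= 0 or e_syn <= 0 or e_nonsyn <= 0:
        raise ValueError("omega requires positive synonymous count and expectations")
    if n_nonsyn == 0:
        return 0.0
    return (n_nonsyn / e_nonsyn) / (n_syn / e_syn)


@dataclass
class SelectionResult:
    label: str
    n_syn: int
    n_nonsyn: int
    e_syn: float
    e_nonsyn: float
    omega: Optional[float]
    ci: Optional[tuple[float, float]] = None
    atypical_fraction: Optional[float] = None
    pli_values: list[float] = field(default_factory=list)
    undefined: bool = False


def dnds_mle(
    variants: Sequence,
    model: CodingModel,
    label: str = "",
    pseudocount: float = 0.01,
    ci_level: float = 0.95,
) -> SelectionResult:
    """Global dN/dS with context-specific rates learned from synonymous hits.

    Per-class rates are Poisson MLEs (with a small pseudocount) of the
    synonymous count over the synonymous opportunity; omega is the ratio of
    nonsynonymous to synonymous observed/expected rates, with a
    profile-likelihood CI treating both counts as Poisson.
    """
    syn_by_class = np.zeros(N_CLASSES)
    n_syn = n_non = 0
    for v in variants:
        entry = model._by_change.get((v.site.contig, v.site.pos, v.site.alt))
        if entry is None:
            continue
        k, cons = entry
        if cons == "synonymous":
            syn_by_class[k] += 1
            n_syn += 1
        else:
            n_non += 1
    if n_syn == 0:
        return SelectionResult(
            label=label, n_syn=0, n_nonsyn=n_non, e_syn=0.0, e_nonsyn=0.0,
            omega=None, undefined=True,
        )
    o_syn, o_non = model.opportunity_syn, model.opportunity_nonsyn
    total_rate = (syn_by_class.sum() + pseudocount * N_CLASSES) / max(o_syn.sum(), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(
            o_syn > 0, (syn_by_class + pseudocount) / np.maximum(o_syn, 1e-300),
            total_rate,
        )
    e_syn = float(np.sum(rates * o_syn))
    e_non = float(np.sum(rates * o_non))
    omega = omega_point(n_syn, n_non, e_syn, e_non)
    ci = _profile_ci(n_syn, n_non, e_syn, e_non, ci_level)
    return SelectionResult(
        label=label, n_syn=n_syn, n_nonsyn=n_non, e_syn=e_syn, e_nonsyn=e_non,
        omega=float(omega), ci=ci,
    )


def _profile_loglik(omega: float, n_s: int, n_n: int, e_s: float, e_n: float) -> float:
    mu = (n_s + n_n) / (e_s + omega * e_n)
    ll = n_s * np.log(mu * e_s) - mu * e_s
    lam = omega * mu * e_n
    if n_n > 0:
        ll += n_n * np.log(lam)
    ll -= lam
    return float(ll)


def _profile_ci(
    n_s: int, n_n: int, e_s: float, e_n: float, level: float
) -> tuple[float, float]:
    omega_hat = (n_n / e_n) / (n_s / e_s) if n_n > 0 else 0.0
    crit = chi2.ppf(level, df=1) / 2.0
    ll_hat = _profile_loglik(max(omega_hat, 1e-12), n_s, n_n, e_s, e_n)

    def deficit(omega: float) -> float:
        return ll_hat - _profile_loglik(omega, n_s, n_n, e_s, e_n) - crit

    if n_n == 0:
        lo = 0.0
    else:
        a = omega_hat
        b = omega_hat / 2
        while deficit(b) < 0 and b > 1e-12:
            b /= 2
        lo = brentq(deficit, b, a) if deficit(b) >= 0 else 0.0
    a = max(omega_hat, 1e-6)
    b = a * 2
    while deficit(b) < 0 and b < 1e6:
        b *= 2
    hi = brentq(deficit, a, b) if deficit(b) >= 0 else float("inf")
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Neutral / suppressed coding-mutation generator (for calibration)
# ---------------------------------------------------------------------------

@dataclass
class CodingVariant:
    site: Site
    gene: str
    consequence: str


def simulate_coding_mutations(
    model: CodingModel,
    n: int,
    rng: np.random.Generator,
    suppression: float = 1.0,
) -> list[CodingVariant]:
    """Sample coding SNVs uniformly over the opportunity tensor.

    With ``suppression`` f < 1 nonsynonymous draws are rejected with
    probability 1 - f, planting negative selection of known strength.
    """
    changes = model._all_changes
    out: list[CodingVariant] = []
    n_changes = len(changes)
    while len(out) < n:
        idx = rng.integers(n_changes, size=n - len(out))
        u = rng.random(size=idx.size)
        for j, uj in zip(idx, u):
            site, _, cons = changes[j]
            if cons != "synonymous" and uj > suppression:
                continue
            cs = model.lookup(site.contig, site.pos)
            out.append(CodingVariant(site=site, gene=cs.gene, consequence=cons))
            if len(out) == n:
                break
    return out


# ---------------------------------------------------------------------------
# Atypical mutability
# ---------------------------------------------------------------------------

def atypical_mutability(
    variants: Sequence,
    background: np.ndarray,
    threshold_quantile: float = 0.10,
) -> float:
    """Fraction of variants whose context mutability is atypically low.

    ``background`` scores the 96 channels; a variant is atypical when its
    channel score falls strictly below the ``threshold_quantile`` quantile
    of the background score distribution.
    """
    from .core import channel_of

    background = np.asarray(background, dtype=float)
    if background.shape != (96,):
        raise ValueError("background model must score 96 channels")
    variants = list(variants)
    if not variants:
        raise ValueError("atypical fraction undefined for an empty group")
    threshold = float(np.quantile(background, threshold_quantile))
    flags = [
        background[channel_of(v.context, v.alt)] < threshold for v in variants
    ]
    return float(np.mean(flags))


# ---------------------------------------------------------------------------
# pLI profiles
# ---------------------------------------------------------------------------

@dataclass
class PliProfile:
    values_by_group: dict[str, list[float]]
    n_missing_by_group: dict[str, int]
    median_by_group: dict[str, float]
    #: (group_a, group_b) -> two-sided rank-sum p-value
    pairwise_p: dict[tuple[str, str], float]


def pli_profile(
    variants_by_group: dict[str, Sequence], pli_table: dict[str, float]
) -> PliProfile:
    """Per-group pLI score multisets with pairwise rank-sum comparisons.

    Variants must expose ``gene``; genes absent from the table are excluded
    and counted.
    """
    values: dict[str, list[float]] = {}
    missing: dict[str, int] = {}
    for group, variants in variants_by_group.items():
        vals, miss = [], 0
        for v in variants:
            gene = getattr(v, "gene", None)
            if gene is None or gene not in pli_table:
                miss += 1
            else:
                vals.append(float(pli_table[gene]))
        values[group] = vals
        missing[group] = miss
    medians = {
        g: float(np.median(v)) if v else float("nan") for g, v in values.items()
    }
    pairwise: dict[tuple[str, str], float] = {}
    groups = sorted(values)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if values[a] and values[b]:
                stat = mannwhitneyu(values[a], values[b], alternative="two-sided")
                pairwise[(a, b)] = float(stat.pvalue)
            else:
                pairwise[(a, b)] = float("nan")
    return PliProfile(
        values_by_group=values,
        n_missing_by_group=missing,
        median_by_group=medians,
        pairwise_p=pairwise,
    )
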