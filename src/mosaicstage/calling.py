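"""Reciprocal all-pairs somatic candidate detection from read counts.

Every ordered tissue pair of an individual is tested case-vs-control; a
site becomes a candidate in a tissue if at least one control supports it.
Two independent pass flags stand in for the published two-caller PASS
conjunction: an exact binomial presence test with per-tissue BH correction
(primary) and a strand-balance / minimum-support heuristic (secondary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import binom

from .core import Site, TissueSample, VariantObservation


@dataclass(frozen=True)
class CallParams:
    error_rate: float = 1e-3
    alpha_call: float = 0.05  # BH level for presence in the case tissue
    alpha_ctrl: float = 0.05  # raw level above which the control is "absent"
    vaf_min: float = 0.005
    alt_min: int = 3


def presence_test(
    alt_count: int, depth: int, error_rate: float, alternative: str = "greater"
) -> float:
    """Exact one-sample binomial proportion test against the error rate.

    Returns ``P(X >= alt_count | X ~ Binomial(depth, error_rate))`` for the
    default "greater" alternative — an exact tail sum, no normal
    approximation. "less" gives the lower tail; "two-sided" doubles the
    smaller tail (capped at 1).
    """
    if depth <= 0:
        raise ValueError("presence_test is undefined at depth 0")
    if not 0 <= alt_count <= depth:
        raise ValueError("alt_count must lie in [0, depth]")
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must lie in (0, 1)")
    if alternative == "greater":
        return float(binom.sf(alt_count - 1, depth, error_rate))
    if alternative == "less":
        return float(binom.cdf(alt_count, depth, error_rate))
    if alternative == "two-sided":
        upper = binom.sf(alt_count - 1, depth, error_rate)
        lower = binom.cdf(alt_count, depth, error_rate)
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError(f"unknown alternative {alternative!r}")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class CandidateCall:
    site: Site
    case_tissue: str
    control_tissue: str
    case_obs: VariantObservation
    control_obs: VariantObservation
    p_case: float
    p_control: float
    pass_primary: bool
    pass_secondary: bool


def strand_balance_ok(obs: VariantObservation) -> bool:
    """Secondary-caller stand-in: reject fully one-sided orientation splits
    once there is enough alt support to judge (>= 6 alt reads)."""
    if obs.alt_count < 6:
        return True
    return min(obs.alt_f1r2, obs.alt_f2r1) > 0


def call_pair(
    case: TissueSample, control: TissueSample, params: Optional[CallParams] = None
) -> list[CandidateCall]:
    """Candidates present in ``case`` and consistent with absence in ``control``.

    Presence p-values are BH-corrected across all sites of the case tissue;
    a site is emitted when the corrected presence test rejects, the control
    presence test does NOT reject at ``alpha_ctrl``, and the case passes the
    VAF / alt-count floor.
    """
    params = params or CallParams()
    if case.individual != control.individual:
        raise ValueError(
            f"case and control belong to different individuals: "
            f"{case.individual} vs {control.individual}"
        )
    sites = case.sites()
    if not sites:
        return []
    p_case = np.array(
        [
            presence_test(
                case.observations[s].alt_count,
                case.observations[s].depth,
                params.error_rate,
            )
            for s in sites
        ]
    )
    q_case = bh_adjust(p_case)
    calls: list[CandidateCall] = []
    for site, p, q in zip(sites, p_case, q_case):
        obs = case.observations[site]
        ctrl_obs = control.observations.get(site)
        if ctrl_obs is None:
            continue
        p_ctrl = presence_test(ctrl_obs.alt_count, ctrl_obs.depth, params.error_rate)
        control_absent = p_ctrl >= params.alpha_ctrl
        support_ok = obs.alt_count >= params.alt_min and obs.vaf >= params.vaf_min
        pass_primary = bool(q < params.alpha_call and control_absent)
        pass_secondary = bool(support_ok and strand_balance_ok(obs))
        if pass_primary and support_ok:
            calls.append(
                CandidateCall(
                    site=site,
                    case_tissue=case.tissue_id,
                    control_tissue=control.tissue_id,
                    case_obs=obs,
                    control_obs=ctrl_obs,
                    p_case=float(p),
                    p_control=float(p_ctrl),
                    pass_primary=pass_primary,
                    pass_secondary=pass_secondary,
                )
            )
    return calls


@dataclass
class CandidateMatrix:
    """Per-site, per-tissue record of which controls supported a call."""

    individual: str
    #: site -> case tissue -> set of control tissue ids
    controls: dict[Site, dict[str, set[str]]] = field(default_factory=dict)
    #: (site, case tissue) -> best (lowest p_case) CandidateCall
    calls: dict[tuple[Site, str], CandidateCall] = field(default_factory=dict)

    def candidate_sites(self, tissue_id: str) -> set[Site]:
        return {s for s, by_case in self.controls.items() if tissue_id in by_case}

    def all_sites(self) -> set[Site]:
        return set(self.controls)


def all_pairs_call(
    tissues: list[TissueSample], params: Optional[CallParams] = None
) -> CandidateMatrix:
    """Run ``call_pair`` over every ordered tissue pair of one individual.

    A tissue's candidate set is the union over all controls under which it
    was called.
    """
    params = params or CallParams()
    if len(tissues) < 2:
        raise ValueError(
            "all-pairs calling needs >= 2 tissues; use tumor-vs-normal mode "
            "for single-tissue individuals"
        )
    individuals = {t.individual for t in tissues}
    if len(individuals) != 1:
        raise ValueError(f"tissues span multiple individuals: {sorted(individuals)}")
    matrix = CandidateMatrix(individual=tissues[0].individual)
    for case in tissues:
        for control in tissues:
            if control.tissue_id == case.tissue_id:
                continue
            for call in call_pair(case, control, params):
                matrix.controls.setdefault(call.site, {}).setdefault(
                    call.case_tissue, set()
                ).add(call.control_tissue)
                key = (call.site, call.case_tissue)
                best = matrix.calls.get(key)
                if best is None or call.p_case < best.p_case:
                    matrix.calls[key] = call
    return matrix
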