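"""Mutation-context catalogs, NMF signature extraction and refitting.

Catalogs use the conventional 96-channel pyrimidine-reference layout.
De novo extraction is multiplicative-update NMF under generalized
Kullback-Leibler divergence (200 iterations, best of several restarts);
refitting against a fixed reference set is non-negative least squares with
deconstructSigs-style pruning of minor contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist
from scipy.stats import binomtest

from .core import CHANNELS_96, PYRIMIDINES, SUBSTITUTION_TYPES, channel_of

_EPS = 1e-12


@dataclass
class Catalog96:
    """96-channel substitution counts for one mutation group."""

    label: str
    counts: np.ndarray  # shape (96,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("a catalog must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def build_catalog(variants: Sequence, label: str = "") -> Catalog96:
    """Count SNVs into the 96 channels.

    Each variant must expose ``context`` (genome-strand trinucleotide whose
    middle base is the reference allele) and ``alt``; purine-reference
    substitutions are folded onto the reverse complement. Counts are
    conserved: the catalog total equals the number of contributing SNVs.
    """
    counts = np.zeros(96)
    for v in variants:
        counts[channel_of(v.context, v.alt)] += 1
    return Catalog96(label=label, counts=counts)


# ---------------------------------------------------------------------------
# De novo NMF
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    signatures: np.ndarray  # (96, k), columns sum to 1
    exposures: np.ndarray  # (k, n_groups), non-negative
    reconstruction_error: float
    restart_errors: list[float] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)


def _gkl(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(div)


def _nmf_once(
    V: np.ndarray,
    rank: int,
    n_iter: int,
    rng: np.random.Generator,
    trace: Optional[list[float]] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    m, n = V.shape
    scale = np.sqrt(V.mean() / max(rank, 1))
    W = rng.uniform(0.5, 1.5, size=(m, rank)) * scale
    H = rng.uniform(0.5, 1.5, size=(rank, n)) * scale
    ones = np.ones_like(V)
    for _ in range(n_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.T @ ones, _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(ones @ H.T, _EPS)
        if trace is not None:
            trace.append(_gkl(V, np.maximum(W @ H, _EPS)))
    return W, H, _gkl(V, np.maximum(W @ H, _EPS))


def nmf_objective_trace(
    V: np.ndarray, rank: int, n_iter: int = 200, seed: int = 0
) -> list[float]:
    """Per-iteration generalized KL divergence of one multiplicative-update run."""
    trace: list[float] = []
    _nmf_once(np.asarray(V, dtype=float), rank, n_iter, np.random.default_rng(seed), trace)
    return trace


def extract_signatures_nmf(
    catalogs: Sequence[Catalog96],
    rank: int,
    n_iter: int = 200,
    n_restarts: int = 50,
    seed: int = 0,
) -> SignatureSet:
    """Multiplicative-update NMF on a channel x group count matrix.

    Minimizes generalized KL divergence; keeps the best of ``n_restarts``
    random initializations by reconstruction error. Signature columns are
    normalized to sum to 1 with the compensating scale absorbed into the
    exposures.
    """
    V = np.stack([c.counts for c in catalogs], axis=1)
    if rank < 1 or rank > min(V.shape):
        raise ValueError(f"rank {rank} outside [1, {min(V.shape)}]")
    rng_master = np.random.default_rng(seed)
    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    errors: list[float] = []
    for _ in range(n_restarts):
        W, H, err = _nmf_once(V, rank, n_iter, rng_master)
        errors.append(err)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, err = best
    col = W.sum(axis=0)
    col = np.where(col <= 0, 1.0, col)
    W = W / col
    H = H * col[:, None]
    return SignatureSet(
        signatures=W,
        exposures=H,
        reconstruction_error=err,
        restart_errors=errors,
        group_labels=[c.label for c in catalogs],
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def match_signatures(
    extracted: np.ndarray, references: np.ndarray
) -> list[tuple[int, int, float]]:
    """Greedy cosine assignment of extracted signature columns to references."""
    pairs = []
    used_e: set[int] = set()
    used_r: set[int] = set()
    sims = [
        (cosine_similarity(extracted[:, i], references[:, j]), i, j)
        for i in range(extracted.shape[1])
        for j in range(references.shape[1])
    ]
    for sim, i, j in sorted(sims, reverse=True):
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        pairs.append((i, j, sim))
    return pairs


# ---------------------------------------------------------------------------
# Reference refitting (NNLS, deconstructSigs-style pruning)
# ---------------------------------------------------------------------------

@dataclass
class RefitResult:
    exposures: np.ndarray  # mutation counts attributed to each reference
    contributions: np.ndarray  # relative, summing to 1 over retained refs
    signature_names: list[str]
    degenerate: bool = False  # all-zero catalog


def refit_exposures(
    catalog: Catalog96,
    references: dict[str, np.ndarray],
    prune_threshold: float = 0.06,
) -> RefitResult:
    """Non-negative least-squares fit of a catalog onto reference signatures.

    References with relative contribution below ``prune_threshold`` are
    zeroed and the remaining set refit, iterating until stable.
    """
    names = list(references)
    R = np.stack([np.asarray(references[n], dtype=float) for n in names], axis=1)
    if not np.allclose(R.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("reference signature columns must sum to 1")
    y = catalog.counts
    if y.sum() == 0:
        return RefitResult(
            exposures=np.zeros(len(names)),
            contributions=np.zeros(len(names)),
            signature_names=names,
            degenerate=True,
        )
    active = list(range(len(names)))
    exposures = np.zeros(len(names))
    while True:
        x, _ = nnls(R[:, active], y)
        total = x.sum()
        if total == 0:
            exposures[:] = 0
            break
        rel = x / total
        keep = [a for a, r in zip(active, rel) if r >= prune_threshold]
        if len(keep) == len(active) or not keep:
            exposures[:] = 0
            exposures[active] = x
            break
        active = keep
    total = exposures.sum()
    contributions = exposures / total if total > 0 else np.zeros(len(names))
    return RefitResult(
        exposures=exposures, contributions=contributions, signature_names=names
    )


# ---------------------------------------------------------------------------
# Reduced indel catalog
# ---------------------------------------------------------------------------

INDEL_CHANNELS = (
    "ins1_short",  # 1 bp insertion, homopolymer run <= 4
    "ins1_long",  # 1 bp insertion, run >= 5
    "del1_short",
    "del1_long",
    "ins2plus",
    "del2plus",
)


def classify_indel(ref: str, alt: str, homopolymer_run: int = 0) -> str:
    """Reduced indel channel for a normalized (left-aligned) allele pair."""
    dlen = len(alt) - len(ref)
    if dlen == 0:
        raise ValueError("not an indel")
    if dlen >= 2:
        return "ins2plus"
    if dlen <= -2:
        return "del2plus"
    kind = "ins1" if dlen == 1 else "del1"
    return f"{kind}_{'long' if homopolymer_run >= 5 else 'short'}"


def build_indel_catalog(indels: Sequence) -> dict[str, int]:
    """Count indels into the reduced channel set; totals are conserved.

    Each indel must expose ``ref``, ``alt`` and ``homopolymer_run`` (length
    of the homopolymer run context at the site).
    """
    counts = {c: 0 for c in INDEL_CHANNELS}
    for ind in indels:
        counts[classify_indel(ind.ref, ind.alt, ind.homopolymer_run)] += 1
    return counts


# ---------------------------------------------------------------------------
# Transcriptional strand asymmetry
# ---------------------------------------------------------------------------

@dataclass
class StrandCatalog:
    """Per substitution type: pyrimidine-on-transcribed vs untranscribed."""

    transcribed: dict[str, int]
    untranscribed: dict[str, int]
    ratio: dict[str, float]
    p_value: dict[str, float]
    n_excluded: int = 0


def strand_asymmetry(variants: Sequence) -> StrandCatalog:
    """Count substitutions by the strand carrying the pyrimidine of the pair.

    Variants must expose ``context``, ``alt`` and ``strand`` (transcript
    strand, or None outside transcripts — those are excluded). A pyrimidine
    reference on the genome '+' strand of a '+' transcript sits on the
    coding (untranscribed) strand. Equality is tested per type with an
    exact two-sided binomial test at p = 1/2.
    """
    transcribed = {s: 0 for s in SUBSTITUTION_TYPES}
    untranscribed = {s: 0 for s in SUBSTITUTION_TYPES}
    excluded = 0
    for v in variants:
        if v.strand not in ("+", "-"):
            excluded += 1
            continue
        idx = channel_of(v.context, v.alt)
        sub = SUBSTITUTION_TYPES[idx // 16]
        pyr_on_plus = v.context[1] in PYRIMIDINES
        # pyrimidine on the transcribed (template) strand iff it sits on
        # the strand opposite the transcript's coding strand
        on_transcribed = (v.strand == "+") != pyr_on_plus
        (transcribed if on_transcribed else untranscribed)[sub] += 1
    ratio = {}
    pval = {}
    for sub in SUBSTITUTION_TYPES:
        t, u = transcribed[sub], untranscribed[sub]
        ratio[sub] = t / u if u else float("inf") if t else float("nan")
        pval[sub] = binomtest(t, t + u, 0.5).pvalue if t + u else float("nan")
    return StrandCatalog(
        transcribed=transcribed,
        untranscribed=untranscribed,
        ratio=ratio,
        p_value=pval,
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Exposure clustering
# ---------------------------------------------------------------------------

@dataclass
class ExposureClustering:
    labels: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]


def cluster_exposures(
    exposures: dict[str, np.ndarray]
) -> ExposureClustering:
    """Average-linkage agglomerative clustering on cosine distances.

    Group labels are pre-sorted so ties resolve deterministically.
    """
    labels = sorted(exposures)
    if len(labels) < 2:
        if not labels:
            raise ValueError("need at least one exposure profile")
        return ExposureClustering(
            labels=labels, linkage_matrix=np.empty((0, 4)), leaf_order=labels
        )
    X = np.stack([np.asarray(exposures[l], dtype=float) for l in labels])
    D = pdist(X, metric="cosine")
    D = np.clip(D, 0.0, None)  # numerical noise can dip below zero
    Z = linkage(D, method="average")
    order = [labels[i] for i in leaves_list(Z)]
    return ExposureClustering(labels=labels, linkage_matrix=Z, leaf_order=order)
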