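import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicstage.core import CHANNELS_96, COMPLEMENT
from mosaicstage.signatures import (
    Catalog96,
    build_catalog,
    build_indel_catalog,
    classify_indel,
    cluster_exposures,
    cosine_similarity,
    extract_signatures_nmf,
    match_signatures,
    nmf_objective_trace,
    refit_exposures,
    strand_asymmetry,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_channel(context, alt):
    """Test-local reimplementation of channel folding (independent oracle)."""
    if context[1] in "AG":
        context = "".join(_COMP[b] for b in reversed(context))
        alt = _COMP[alt]
    return f"{context[0]}[{context[1]}>{alt}]{context[2]}"


def _variant(context, alt, strand=None):
    return SimpleNamespace(context=context, alt=alt, strand=strand)


class TestBuildCatalog:
    def test_purine_reference_reverse_complemented(self):
        cat = build_catalog([_variant("AAA", "G")])
        assert cat.counts[CHANNELS_96.index("T[T>C]T")] == 1
        assert cat.total == 1

    def test_empty_input_is_zero_vector(self):
        cat = build_catalog([])
        assert cat.total == 0
        assert (cat.counts == 0).all()

    def test_matches_naive_recount(self, rng):
        bases = "ACGT"
        variants = []
        for _ in range(500):
            ctx = "".join(rng.choice(list(bases), size=3))
            alt = rng.choice([b for b in bases if b != ctx[1]])
            variants.append(_variant(ctx, str(alt)))
        cat = build_catalog(variants)
        naive = {c: 0 for c in CHANNELS_96}
        for v in variants:
            naive[naive_channel(v.context, v.alt)] += 1
        for chan, count in naive.items():
            assert cat.counts[CHANNELS_96.index(chan)] == count

    @given(
        st.lists(
            st.tuples(
                st.text("ACGT", min_size=3, max_size=3),
                st.sampled_from("ACGT"),
            ).filter(lambda t: t[0][1] != t[1]),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, pairs):
        variants = [_variant(ctx, alt) for ctx, alt in pairs]
        assert build_catalog(variants).total == len(variants)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Catalog96(label="x", counts=-np.ones(96))


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_one_hot(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # (1,1,0)·(1,0,1) / (sqrt2 * sqrt2) = 1/2
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


def _planted_signatures(rng, k=3):
    """Well-separated signatures: disjoint channel blocks plus light noise."""
    W = np.zeros((96, k))
    for j in range(k):
        block = slice(32 * j, 32 * (j + 1))
        W[block, j] = rng.uniform(0.5, 1.5, size=32)
    W /= W.sum(axis=0)
    return W


def _planted_exposures(rng, k, n_groups):
    """Exposures with one anchor group per signature (keeps the noiseless
    factorization identifiable up to permutation/scale)."""
    H = rng.uniform(5, 30, size=(k, n_groups))
    for j in range(k):
        H[:, j] = 0.0
        H[j, j] = rng.uniform(200, 400)
    return H


class TestNMF:
    def test_rank_one_recovery(self, rng):
        s = rng.uniform(0.1, 1.0, size=96)
        s /= s.sum()
        exposures = np.array([200.0, 500.0, 800.0])
        V = np.outer(s, exposures)
        catalogs = [Catalog96(label=f"g{i}", counts=V[:, i]) for i in range(3)]
        sigset = extract_signatures_nmf(catalogs, rank=1, n_restarts=3, seed=0)
        assert cosine_similarity(sigset.signatures[:, 0], s) >= 0.999

    def test_three_planted_signatures_recovered(self, rng):
        W = _planted_signatures(rng)
        H = _planted_exposures(rng, 3, 8)
        V = W @ H
        catalogs = [Catalog96(label=f"g{i}", counts=V[:, i]) for i in range(8)]
        sigset = extract_signatures_nmf(catalogs, rank=3, n_restarts=10, seed=1)
        matches = match_signatures(sigset.signatures, W)
        assert len(matches) == 3
        for _, _, sim in matches:
            assert sim >= 0.95

    def test_column_permutation_symmetry(self, rng):
        W = _planted_signatures(rng)
        H = _planted_exposures(rng, 3, 6)
        V = W @ H
        catalogs = [Catalog96(label=f"g{i}", counts=V[:, i]) for i in range(6)]
        a = extract_signatures_nmf(catalogs, rank=3, n_restarts=5, seed=2)
        b = extract_signatures_nmf(catalogs[::-1], rank=3, n_restarts=5, seed=2)
        # same signature subspace: every signature of a matches one of b
        for _, _, sim in match_signatures(a.signatures, b.signatures):
            assert sim >= 0.99

    def test_objective_non_increasing(self, rng):
        W = _planted_signatures(rng)
        V = W @ rng.uniform(50, 300, size=(3, 5)) + rng.uniform(0, 5, size=(96, 5))
        trace = nmf_objective_trace(V, rank=3, n_iter=100, seed=0)
        diffs = np.diff(trace)
        assert (diffs <= 1e-8).all()

    def test_signature_columns_normalized(self, rng):
        W = _planted_signatures(rng)
        V = W @ rng.uniform(50, 300, size=(3, 4))
        catalogs = [Catalog96(label=f"g{i}", counts=V[:, i]) for i in range(4)]
        sigset = extract_signatures_nmf(catalogs, rank=2, n_restarts=2, seed=0)
        np.testing.assert_allclose(sigset.signatures.sum(axis=0), 1.0, atol=1e-9)
        assert (sigset.exposures >= 0).all()

    def test_excessive_rank_rejected(self):
        catalogs = [Catalog96(label="g", counts=np.ones(96))]
        with pytest.raises(ValueError):
            extract_signatures_nmf(catalogs, rank=2)


class TestRefit:
    def _refs(self, rng, k=3):
        R = rng.uniform(0.05, 1.0, size=(96, k))
        R /= R.sum(axis=0)
        return {f"S{i}": R[:, i] for i in range(k)}

    def test_pure_signature_recovered(self, rng):
        refs = self._refs(rng)
        cat = Catalog96(label="x", counts=100 * refs["S0"])
        res = refit_exposures(cat, refs)
        assert res.contributions[res.signature_names.index("S0")] == pytest.approx(1.0)
        assert res.exposures[res.signature_names.index("S0")] == pytest.approx(100.0, rel=1e-6)

    def test_noiseless_60_40_mixture(self, rng):
        refs = self._refs(rng)
        cat = Catalog96(label="x", counts=600 * refs["S0"] + 400 * refs["S1"])
        res = refit_exposures(cat, refs)
        by = dict(zip(res.signature_names, res.contributions))
        assert by["S0"] == pytest.approx(0.6, abs=1e-6)
        assert by["S1"] == pytest.approx(0.4, abs=1e-6)

    def test_zero_catalog_flagged(self, rng):
        refs = self._refs(rng)
        res = refit_exposures(Catalog96(label="x", counts=np.zeros(96)), refs)
        assert res.degenerate is True
        assert (res.exposures == 0).all()

    def test_minor_contribution_pruned(self, rng):
        refs = self._refs(rng)
        cat = Catalog96(label="x", counts=980 * refs["S0"] + 20 * refs["S1"])
        res = refit_exposures(cat, refs, prune_threshold=0.06)
        by = dict(zip(res.signature_names, res.contributions))
        assert by["S1"] == 0.0
        assert by["S0"] == pytest.approx(1.0)

    def test_noiseless_recovery_l1_error(self, rng):
        refs = self._refs(rng, k=4)
        weights = np.array([0.3, 0.3, 0.2, 0.2])
        counts = 1000 * sum(w * refs[f"S{i}"] for i, w in enumerate(weights))
        res = refit_exposures(Catalog96(label="x", counts=counts), refs)
        assert np.abs(res.contributions - weights).sum() < 1e-4

    def test_unnormalized_references_rejected(self, rng):
        refs = self._refs(rng)
        refs["S0"] = refs["S0"] * 2
        with pytest.raises(ValueError):
            refit_exposures(Catalog96(label="x", counts=np.ones(96)), refs)


class TestIndelCatalog:
    def test_one_bp_insertion_in_long_run(self):
        assert classify_indel("T", "TT", homopolymer_run=6) == "ins1_long"

    def test_three_bp_deletion(self):
        assert classify_indel("TACG", "T", homopolymer_run=1) == "del2plus"

    def test_one_bp_deletion_short_run(self):
        assert classify_indel("TA", "T", homopolymer_run=2) == "del1_short"

    def test_conservation(self):
        indels = [
            SimpleNamespace(ref="T", alt="TT", homopolymer_run=6),
            SimpleNamespace(ref="TA", alt="T", homopolymer_run=1),
            SimpleNamespace(ref="C", alt="CAGG", homopolymer_run=0),
        ]
        catalog = build_indel_catalog(indels)
        assert sum(catalog.values()) == len(indels)

    def test_snv_rejected(self):
        with pytest.raises(ValueError):
            classify_indel("A", "T")


def two_sided_binom_oracle(k, n):
    """Exact two-sided binomial p at p0=1/2 by pmf summation."""
    pmf = [math.comb(n, x) * 0.5**n for x in range(n + 1)]
    cutoff = pmf[k] * (1 + 1e-12)
    return sum(p for p in pmf if p <= cutoff)


class TestStrandAsymmetry:
    def test_balanced_counts(self):
        variants = [_variant("ACA", "T", "+") for _ in range(10)] + [
            _variant("ACA", "T", "-") for _ in range(10)
        ]
        sc = strand_asymmetry(variants)
        assert sc.transcribed["C>T"] == 10
        assert sc.untranscribed["C>T"] == 10
        assert sc.ratio["C>T"] == pytest.approx(1.0)
        assert sc.p_value["C>T"] == pytest.approx(1.0)

    def test_16_vs_4_matches_exact_binomial(self):
        variants = [_variant("ATA", "C", "-") for _ in range(16)] + [
            _variant("ATA", "C", "+") for _ in range(4)
        ]
        sc = strand_asymmetry(variants)
        assert sc.transcribed["T>C"] == 16
        oracle = two_sided_binom_oracle(16, 20)
        assert oracle == pytest.approx(0.01181793212890625, rel=1e-9)
        assert sc.p_value["T>C"] == pytest.approx(oracle, rel=1e-6)

    def test_intergenic_variants_excluded(self):
        sc = strand_asymmetry([_variant("ACA", "T", None)])
        assert sc.n_excluded == 1
        assert sum(sc.transcribed.values()) + sum(sc.untranscribed.values()) == 0

    def test_swap_symmetry(self):
        a = [_variant("ACA", "T", "+")] * 13 + [_variant("ACA", "T", "-")] * 5
        b = [_variant("ACA", "T", "-")] * 13 + [_variant("ACA", "T", "+")] * 5
        sa, sb = strand_asymmetry(a), strand_asymmetry(b)
        assert sa.p_value["C>T"] == pytest.approx(sb.p_value["C>T"])
        assert sa.transcribed["C>T"] == sb.untranscribed["C>T"]

    def test_purine_context_strand_assignment(self):
        # G>A on a '+' transcript: pyrimidine (C) sits on the minus strand,
        # which is the template -> transcribed
        sc = strand_asymmetry([_variant("AGA", "A", "+")])
        assert sc.transcribed["C>T"] == 1


class TestClusterExposures:
    def test_identical_profiles_merge_first_at_zero(self):
        clustering = cluster_exposures(
            {"a": np.array([1.0, 0.0]), "b": np.array([1.0, 0.0]),
             "c": np.array([0.0, 1.0])}
        )
        Z = clustering.linkage_matrix
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # a and b (sorted labels)

    def test_nearest_profile_pairs_first(self):
        clustering = cluster_exposures(
            {"x": np.array([1.0, 0.0]), "y": np.array([0.0, 1.0]),
             "z": np.array([0.9, 0.1])}
        )
        Z = clustering.linkage_matrix
        labels = clustering.labels  # sorted: x, y, z
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {labels.index("x"), labels.index("z")}

    def test_singleton(self):
        clustering = cluster_exposures({"only": np.array([1.0, 2.0])})
        assert clustering.leaf_order == ["only"]

    def test_deterministic_leaf_order(self):
        profiles = {
            "a": np.array([1.0, 0.1]), "b": np.array([0.1, 1.0]),
            "c": np.array([0.8, 0.3]),
        }
        o1 = cluster_exposures(profiles).leaf_order
        o2 = cluster_exposures(dict(reversed(list(profiles.items())))).leaf_order
        assert o1 == o2
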