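"""Signature extraction, NNLS refitting, naming, and dominant-signature
assignment, checked against closed forms, grid-search oracles, and the
generator's truth."""

import numpy as np
import pandas as pd
import pytest

from hrdpipe.catalog import CONTEXT_96, TrinucleotideCatalog
from hrdpipe.errors import DataError, UnstableExtractionError
from hrdpipe.signatures import (
    ExposureTable, SignatureMatrix, assign_first_signature, cosine_similarity,
    extract_signatures, flag_singleton_signature, match_to_cosmic,
    refit_exposures,
)


def make_catalog(rows, samples=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"S{i}" for i in range(rows.shape[0])]
    return TrinucleotideCatalog(
        pd.DataFrame(rows, index=pd.Index(samples, name="sample"), columns=list(CONTEXT_96))
    )


class TestCosineSimilarity:
    def test_identity_is_one(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_are_orthogonal(self):
        u = np.zeros(96)
        v = np.zeros(96)
        u[:48] = 1.0
        v[48:] = 1.0
        assert cosine_similarity(u, v) == 0.0

    def test_hand_computed_value(self):
        u = np.zeros(96)
        v = np.zeros(96)
        u[:3] = (1, 2, 2)
        v[:3] = (2, 1, 2)
        assert cosine_similarity(u, v) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(DataError):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestSignatureMatrixContract:
    def test_rows_must_normalize(self):
        with pytest.raises(DataError):
            SignatureMatrix(names=["a"], profiles=np.full((1, 96), 0.5))

    def test_negative_rejected(self):
        p = np.full((1, 96), 1 / 96)
        p[0, 0] = -p[0, 0]
        with pytest.raises(DataError):
            SignatureMatrix(names=["a"], profiles=p)

    def test_tsv_round_trip(self, tmp_path, reference_sigs):
        path = tmp_path / "sigs.tsv"
        reference_sigs.to_tsv(path)
        back = SignatureMatrix.from_tsv(path)
        assert back.names == reference_sigs.names
        np.testing.assert_allclose(back.profiles, reference_sigs.profiles, atol=1e-9)


class TestRefitExposures:
    def test_exact_member_recovered(self, truth_profiles):
        ref = SignatureMatrix(names=["A", "B"], profiles=truth_profiles[:2])
        counts = np.round(truth_profiles[0] * 100000)
        exp = refit_exposures(make_catalog(counts), ref, floor=0.0)
        assert exp.normalized.iloc[0]["A"] == pytest.approx(1.0, abs=1e-3)
        assert exp.normalized.iloc[0]["B"] == pytest.approx(0.0, abs=1e-3)

    def test_orthogonal_mixture_matches_grid_search_oracle(self):
        # two disjoint-support signatures, noise-free 60/40 mixture
        p1 = np.zeros(96)
        p2 = np.zeros(96)
        p1[:48] = 1 / 48
        p2[48:] = 1 / 48
        ref = SignatureMatrix(names=["A", "B"], profiles=np.vstack([p1, p2]))
        counts = 0.6 * p1 * 10000 + 0.4 * p2 * 10000
        exp = refit_exposures(make_catalog(counts), ref, floor=0.0)
        est = exp.normalized.iloc[0].to_numpy()
        np.testing.assert_allclose(est, [0.6, 0.4], atol=1e-6)
        # dense grid-search oracle over the simplex
        b = counts / counts.sum()
        grid = np.linspace(0, 1, 2001)
        resid = [
            np.sum((w * p1 + (1 - w) * p2 - b) ** 2) for w in grid
        ]
        w_star = grid[int(np.argmin(resid))]
        assert abs(est[0] - w_star) + abs(est[1] - (1 - w_star)) < 1e-3

    def test_multinomial_mixture_recovery(self, truth_profiles, mixture_catalog_factory):
        cat = mixture_catalog_factory(
            np.tile([0.7, 0.3, 0.0, 0.0], (100, 1)), 2000, truth_profiles, seed=42
        )
        ref = SignatureMatrix(names=["A", "B"], profiles=truth_profiles[:2])
        exp = refit_exposures(cat, ref, floor=0.0)
        err = np.abs(exp.normalized.to_numpy() - np.array([0.7, 0.3])).sum(axis=1)
        assert err.mean() / 2 < 0.03  # mean absolute exposure error

    def test_scale_invariance(self, truth_profiles):
        ref = SignatureMatrix(names=["A", "B"], profiles=truth_profiles[:2])
        counts = np.round(
            (0.5 * truth_profiles[0] + 0.5 * truth_profiles[1]) * 5000
        )
        e1 = refit_exposures(make_catalog(counts), ref)
        e2 = refit_exposures(make_catalog(counts * 10), ref)
        np.testing.assert_allclose(
            e1.normalized.to_numpy(), e2.normalized.to_numpy(), atol=1e-9
        )

    def test_reconstruction_not_worse_than_any_single_reference(self, truth_profiles):
        rng = np.random.default_rng(3)
        ref = SignatureMatrix(
            names=["A", "B", "C", "D"], profiles=truth_profiles
        )
        w = rng.dirichlet(np.ones(4))
        counts = rng.multinomial(3000, w @ truth_profiles)
        exp = refit_exposures(make_catalog(counts), ref, floor=0.0)
        recon = float(exp.reconstruction_cosine.iloc[0])
        freq = counts / counts.sum()
        singles = [cosine_similarity(freq, p) for p in truth_profiles]
        assert recon >= max(singles) - 1e-9

    def test_zero_mutation_sample_gets_zero_row(self, truth_profiles):
        ref = SignatureMatrix(names=["A"], profiles=truth_profiles[:1])
        exp = refit_exposures(make_catalog(np.zeros(96)), ref)
        assert exp.normalized.iloc[0].sum() == 0.0

    def test_floor_zeroes_small_contributions_and_renormalizes(self, truth_profiles):
        p1, p2 = truth_profiles[0], truth_profiles[1]
        counts = (0.97 * p1 + 0.03 * p2) * 100000
        ref = SignatureMatrix(names=["A", "B"], profiles=truth_profiles[:2])
        exp = refit_exposures(make_catalog(counts), ref, floor=0.06)
        assert exp.normalized.iloc[0]["B"] == 0.0
        assert exp.normalized.iloc[0].sum() == pytest.approx(1.0)


class TestExtraction:
    def test_rank_one_catalog_recovers_single_profile(self, truth_profiles):
        profile = truth_profiles[1]
        loads = np.array([500.0, 1000.0, 2000.0, 800.0, 1200.0])
        X = np.outer(loads, profile)
        rep = extract_signatures(make_catalog(X), n_restarts=8, k_max=5, seed=0)
        assert rep.chosen_k == 1
        assert cosine_similarity(rep.consensus.profiles[0], profile) > 0.9999

    def test_four_separated_signatures_recovered(self, truth_profiles, mixture_catalog_factory):
        rng = np.random.default_rng(5)
        weights = rng.dirichlet(np.full(4, 0.8), size=150)
        cat = mixture_catalog_factory(weights, 1500, truth_profiles, seed=6)
        rep = extract_signatures(cat, n_restarts=10, k_max=8, seed=1)
        assert rep.chosen_k == 4
        sims = np.array(
            [
                [cosine_similarity(c, t) for t in truth_profiles]
                for c in rep.consensus.profiles
            ]
        )
        # each consensus profile matches a distinct truth signature
        assert sorted(sims.argmax(axis=1)) == [0, 1, 2, 3]
        assert (sims.max(axis=1) >= 0.95).all()

    def test_sample_order_invariance_of_consensus(self, truth_profiles, mixture_catalog_factory):
        rng = np.random.default_rng(9)
        weights = rng.dirichlet(np.full(4, 0.8), size=60)
        cat = mixture_catalog_factory(weights, 800, truth_profiles, seed=2)
        perm = rng.permutation(len(cat.samples))
        cat_perm = TrinucleotideCatalog(cat.counts.iloc[perm])
        r1 = extract_signatures(cat, n_restarts=6, k_max=6, seed=3)
        r2 = extract_signatures(cat_perm, n_restarts=6, k_max=6, seed=3)
        assert r1.chosen_k == r2.chosen_k
        sims = np.array(
            [
                [cosine_similarity(a, b) for b in r2.consensus.profiles]
                for a in r1.consensus.profiles
            ]
        )
        assert (sims.max(axis=1) > 0.98).all()

    def test_unreachable_quorum_raises_with_vote_table(self, truth_profiles, mixture_catalog_factory):
        cat = mixture_catalog_factory(
            np.tile([0.25, 0.25, 0.25, 0.25], (20, 1)), 300, truth_profiles, seed=0
        )
        with pytest.raises(UnstableExtractionError) as exc:
            extract_signatures(cat, n_restarts=4, k_max=6, seed=0, quorum=1.1)
        assert sum(exc.value.votes.values()) == 4

    def test_empty_catalog_rejected(self):
        with pytest.raises(DataError):
            extract_signatures(make_catalog(np.zeros(96)), n_restarts=2, seed=0)


class TestSingletonFlag:
    @staticmethod
    def _exposures(activity_matrix, samples, sigs):
        act = pd.DataFrame(activity_matrix, index=samples, columns=sigs)
        norm = act.div(act.sum(axis=1).replace(0, 1), axis=0)
        return ExposureTable(activities=act, normalized=norm)

    def test_dominant_sample_flagged(self):
        act = np.array([[69.0, 10], [11.0, 10], [20.0, 10]])
        exp = self._exposures(act, ["A", "B", "C"], ["W1", "W2"])
        flags = flag_singleton_signature(exp, threshold_fraction=0.5)
        assert flags == [("W1", "A", pytest.approx(0.69))]

    def test_uniform_contributions_not_flagged(self):
        act = np.full((10, 1), 5.0)
        exp = self._exposures(act, [f"S{i}" for i in range(10)], ["W1"])
        assert flag_singleton_signature(exp) == []

    def test_threshold_boundary_is_inclusive(self):
        act = np.array([[69.0], [31.0]])
        exp = self._exposures(act, ["A", "B"], ["W1"])
        assert flag_singleton_signature(exp, threshold_fraction=0.69) != []


class TestMatchToCosmic:
    def test_exact_reference_member(self, reference_sigs):
        extracted = SignatureMatrix(
            names=["W1"], profiles=reference_sigs.profiles[:1].copy()
        )
        (m,) = match_to_cosmic(extracted, reference_sigs)
        assert m.best_ids == ["COSMIC 1"]
        assert m.cosine_similarities["COSMIC 1"] == pytest.approx(1.0)
        assert "CpG" in m.assigned_label

    def test_apobec_pair_merged(self, reference_sigs):
        i2 = reference_sigs.names.index("COSMIC 2")
        i13 = reference_sigs.names.index("COSMIC 13")
        mean = (reference_sigs.profiles[i2] + reference_sigs.profiles[i13]) / 2
        extracted = SignatureMatrix(names=["W1"], profiles=mean[None, :] / mean.sum())
        (m,) = match_to_cosmic(extracted, reference_sigs)
        assert set(m.best_ids) == {"COSMIC 2", "COSMIC 13"}
        assert "APOBEC" in m.assigned_label
        direct2 = cosine_similarity(mean, reference_sigs.profiles[i2])
        assert m.cosine_similarities["COSMIC 2"] == pytest.approx(direct2)

    def test_no_label_promotion_below_floor(self, reference_sigs):
        flat = np.full((1, 96), 1 / 96)
        (m,) = match_to_cosmic(
            SignatureMatrix(names=["W1"], profiles=flat), reference_sigs,
            report_floor=0.999,
        )
        assert m.assigned_label == m.best_ids[0]  # plain id, no alias


class TestAssignFirstSignature:
    @staticmethod
    def _exposures(norm_rows, sigs):
        norm = pd.DataFrame(norm_rows, columns=sigs, index=[f"S{i}" for i in range(len(norm_rows))])
        return ExposureTable(activities=norm.copy(), normalized=norm)

    def test_argmax_label(self):
        exp = self._exposures([[0.7, 0.2, 0.1]], ["W1", "W2", "W3"])
        assert assign_first_signature(exp).iloc[0] == "W1"

    def test_exact_tie_goes_to_lexicographically_first(self, caplog):
        exp = self._exposures([[0.5, 0.5]], ["W2", "W1"])
        with caplog.at_level("WARNING"):
            label = assign_first_signature(exp).iloc[0]
        assert label == "W1"
        assert any("tie" in r.message for r in caplog.records)

    def test_zero_row_unassigned(self):
        exp = self._exposures([[0.0, 0.0]], ["W1", "W2"])
        assert assign_first_signature(exp).iloc[0] == "unassigned"

    def test_syndata_dominant_signature_agreement(self, small_cohort, truth_profiles, reference_sigs):
        ids = list(small_cohort.truth["signature_ids"])
        ref = SignatureMatrix(
            names=ids,
            profiles=np.vstack(
                [reference_sigs.profiles[reference_sigs.names.index(s)] for s in ids]
            ),
        )
        exp = refit_exposures(small_cohort.catalog, ref, floor=0.0)
        labels = assign_first_signature(exp)
        truth = small_cohort.truth["first_signature"]
        agree = np.mean([labels[s] == truth[s] for s in small_cohort.samples])
        assert agree >= 0.95
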