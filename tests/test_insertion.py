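"""Correlation-filter profiling, acceptance, and tree augmentation."""

import numpy as np
import pytest

from proteodendro import pipeline
from proteodendro.insertion import augment_tree, correlate, profile_new_taxon
from proteodendro.profiles import BinaryProfile, ProfileMatrix
from proteodendro.sequence_io import Proteome, ProteinRecord

from .oracles import rf_distance


def renamed(proteome, new_taxon):
    return Proteome(
        new_taxon,
        tuple(
            ProteinRecord(r.protein_id, new_taxon, r.sequence) for r in proteome
        ),
    )


class TestProfileNewTaxon:
    def test_copy_of_library_taxon_reproduces_its_row(self, fixture_set, build_result):
        """Profiling a taxon's own proteome against the built clusters must
        reproduce its library row exactly (within-cluster scores are far
        above the 0.2 membership cutoff)."""
        for original in fixture_set.proteomes[:3]:
            copy = renamed(original, "NEW")
            profile = profile_new_taxon(copy, build_result.clusters)
            expected = build_result.matrix.row(original.taxon_id)
            assert np.array_equal(profile.bits, expected.bits)

    def test_unrelated_proteome_has_zero_profile(self, alien_set, build_result):
        alien = alien_set.proteomes[0]
        profile = profile_new_taxon(alien, build_result.clusters)
        assert not profile.bits.any()

    def test_chimeric_protein_sets_both_bits(self, fixture_set, build_result):
        """A protein fusing members of two families scores >0.2 against both
        clusters."""
        membership = build_result.clusters.membership()
        seqs = build_result.clusters.sequences
        # fuse members of two different clusters with comparable lengths, so
        # each half keeps score > 0.2 despite the doubled denominator
        items = sorted(membership.items())
        pick = None
        for key_a, cid_a in items:
            for key_b, cid_b in items:
                if cid_b != cid_a and (
                    0.75 <= len(seqs[key_a]) / len(seqs[key_b]) <= 1.33
                ):
                    pick = (key_a, cid_a, key_b, cid_b)
                    break
            if pick:
                break
        assert pick, "no length-matched cluster pair in fixture"
        key_a, cid_a, key_b, cid_b = pick
        chimera = seqs[key_a] + seqs[key_b]
        p = Proteome("CHIM", (ProteinRecord("fusion", "CHIM", chimera),))
        profile = profile_new_taxon(p, build_result.clusters)
        assert profile.bits[cid_a] == 1 and profile.bits[cid_b] == 1

    def test_empty_proteome_rejected(self, build_result):
        with pytest.raises(ValueError):
            profile_new_taxon(
                Proteome("E", ()), build_result.clusters
            )


class TestCorrelate:
    @staticmethod
    def library():
        return ProfileMatrix(
            taxa=("A", "B", "C"),
            values=np.array(
                [[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 1]], dtype=np.uint8
            ),
        )

    def test_identical_profile_scores_one(self):
        lib = self.library()
        rep = correlate(BinaryProfile("N", lib.values[0]), lib)
        assert rep.coefficients["A"] == pytest.approx(1.0)
        assert rep.best_match == "A"
        assert rep.accepted

    def test_complement_scores_minus_one(self):
        lib = self.library()
        rep = correlate(BinaryProfile("N", 1 - lib.values[0]), lib)
        assert rep.coefficients["A"] == pytest.approx(-1.0)

    def test_half_overlap_scores_zero(self):
        lib = ProfileMatrix(taxa=("A",), values=np.array([[1, 0, 1, 0]], dtype=np.uint8))
        rep = correlate(BinaryProfile("N", np.array([1, 1, 0, 0])), lib)
        assert rep.coefficients["A"] == pytest.approx(0.0)
        assert not rep.accepted

    def test_zero_variance_profile_reports_zero(self, caplog):
        lib = self.library()
        with caplog.at_level("WARNING"):
            rep = correlate(BinaryProfile("N", np.zeros(4, dtype=np.uint8)), lib)
        assert (rep.coefficients == 0).all()
        assert not rep.accepted
        assert any("zero variance" in m for m in caplog.messages)

    def test_length_mismatch_names_both_lengths(self):
        with pytest.raises(ValueError, match="3.*4|4.*3"):
            correlate(BinaryProfile("N", np.array([1, 0, 1])), self.library())

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 2, 20).astype(np.uint8)
            y = rng.integers(0, 2, 20).astype(np.uint8)
            lib_y = ProfileMatrix(taxa=("Y",), values=y[None, :])
            lib_x = ProfileMatrix(taxa=("X",), values=x[None, :])
            rxy = correlate(BinaryProfile("x", x), lib_y).coefficients["Y"]
            ryx = correlate(BinaryProfile("y", y), lib_x).coefficients["X"]
            assert -1.0 <= rxy <= 1.0
            assert rxy == pytest.approx(ryx)


class TestAugmentTree:
    def test_duplicate_taxon_accepted_and_placed_as_sister(
        self, fixture_set, build_result
    ):
        original = fixture_set.proteomes[0]
        copy = renamed(original, "NEWCOPY")
        tree, reports = pipeline.insert_taxa(
            build_result.clusters, build_result.matrix, [copy]
        )
        (rep,) = reports
        assert rep.accepted
        assert rep.best_value == pytest.approx(1.0)
        assert rep.best_match == original.taxon_id
        assert "NEWCOPY" in tree.leaf_names()
        nearest, dist = tree.nearest_leaf("NEWCOPY")
        assert nearest == original.taxon_id
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_low_correlation_profile_rejected(self, build_result):
        """A profile whose best library correlation is below 0.5 is reported
        but never inserted (chance-level bit overlap usually qualifies, but
        with few clusters a random draw can fluke past 0.5, so draw until
        the premise holds)."""
        lib = build_result.matrix
        rng = np.random.default_rng(1)
        profile = None
        for _ in range(100):
            candidate = BinaryProfile("RAND", rng.integers(0, 2, lib.n_clusters))
            if correlate(candidate, lib).best_value < 0.5:
                profile = candidate
                break
        assert profile is not None
        tree, reports = augment_tree(lib, [profile])
        assert not reports[0].accepted
        assert "RAND" not in tree.leaf_names()

    def test_no_acceptance_leaves_tree_unchanged(self, build_result):
        zero = BinaryProfile("Z", np.zeros(build_result.matrix.n_clusters, dtype=np.uint8))
        tree, reports = augment_tree(build_result.matrix, [zero])
        assert not reports[0].accepted
        assert rf_distance(tree.to_newick(), build_result.tree.to_newick()) == 0

    def test_related_batch_forms_clade(self, fixture_set, build_result):
        """A batch of taxa sharing a library taxon's gene content minus a
        little is accepted together and clusters together in the tree."""
        base = build_result.matrix.row(build_result.matrix.taxa[0]).bits
        profiles = []
        rng = np.random.default_rng(2)
        for i in range(3):
            bits = base.copy()
            on = np.flatnonzero(bits)
            if len(on) > 1:
                bits[on[rng.integers(len(on))]] = 0  # drop one family
            profiles.append(BinaryProfile(f"NEW{i}", bits))
        tree, reports = augment_tree(build_result.matrix, profiles)
        assert all(r.accepted for r in reports)
        leaves = tree.leaf_names()
        assert {"NEW0", "NEW1", "NEW2"} <= set(leaves)
        # the batch plus its template are mutually nearest neighbors
        dm = tree.leaf_distances()
        group = {"NEW0", "NEW1", "NEW2", build_result.matrix.taxa[0]}
        for a in ("NEW0", "NEW1", "NEW2"):
            others = [(dm[a, b], b) for b in leaves if b != a]
            assert min(others)[1] in group

    def test_taxon_id_collision_rejected(self, build_result):
        clash = BinaryProfile(
            build_result.matrix.taxa[0],
            build_result.matrix.values[0],
        )
        with pytest.raises(ValueError, match="collides"):
            augment_tree(build_result.matrix, [clash])
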