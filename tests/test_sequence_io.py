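"""FASTA reading, Newick writing, and library persistence."""

import json

import numpy as np
import pytest

from proteodendro import pipeline
from proteodendro.nj_tree import Clade, Dendrogram
from proteodendro.sequence_io import (
    Proteome,
    ProteinRecord,
    load_library,
    read_proteome,
    sanitize_label,
    save_library,
    write_newick,
    write_proteome,
)


def write_fasta(path, entries):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))


class TestReadProteome:
    def test_entry_count_and_content_preserved(self, tmp_path):
        fasta = tmp_path / "t.faa"
        write_fasta(fasta, [("p1", "MKV"), ("p2", "ACDEF"), ("p3", "WYW")])
        p = read_proteome(fasta, "T1")
        assert len(p) == 3
        assert [r.sequence for r in p] == ["MKV", "ACDEF", "WYW"]
        assert all(r.taxon_id == "T1" for r in p)

    def test_case_normalized(self, tmp_path):
        fasta = tmp_path / "t.faa"
        write_fasta(fasta, [("p1", "mkv")])
        assert read_proteome(fasta, "T").records[0].sequence == "MKV"

    def test_trailing_stop_stripped_internal_stop_rejected(self, tmp_path):
        ok = tmp_path / "ok.faa"
        write_fasta(ok, [("p1", "MKV*")])
        assert read_proteome(ok, "T").records[0].sequence == "MKV"
        bad = tmp_path / "bad.faa"
        write_fasta(bad, [("p9", "MK*V")])
        with pytest.raises(ValueError, match="p9"):
            read_proteome(bad, "T")

    def test_ambiguity_codes_mapped_to_x(self, tmp_path, caplog):
        fasta = tmp_path / "t.faa"
        write_fasta(fasta, [("p1", "MKBZUOV")])
        with caplog.at_level("WARNING"):
            p = read_proteome(fasta, "T")
        assert p.records[0].sequence == "MKXXXXV"
        assert any("non-standard" in m for m in caplog.messages)

    def test_empty_file_rejected(self, tmp_path):
        fasta = tmp_path / "empty.faa"
        fasta.write_text("")
        with pytest.raises(ValueError):
            read_proteome(fasta, "T")

    def test_empty_sequence_names_header(self, tmp_path):
        fasta = tmp_path / "t.faa"
        fasta.write_text(">good\nMKV\n>hollow\n*\n")
        with pytest.raises(ValueError, match="hollow"):
            read_proteome(fasta, "T")

    def test_roundtrip_through_write(self, tmp_path):
        p = Proteome("T", (ProteinRecord("p1", "T", "MKV" * 30),))
        out = tmp_path / "o.faa"
        write_proteome(p, out)
        assert read_proteome(out, "T").records[0].sequence == "MKV" * 30


class TestProteomeInvariants:
    def test_duplicate_protein_ids_rejected(self):
        recs = (ProteinRecord("p", "T", "MKV"), ProteinRecord("p", "T", "ACD"))
        with pytest.raises(ValueError):
            Proteome("T", recs)

    def test_taxon_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Proteome("T", (ProteinRecord("p", "U", "MKV"),))


class TestWriteNewick:
    def test_two_leaf_tree(self, tmp_path):
        tree = Dendrogram(
            root=Clade(children=[Clade("A", 0.1), Clade("B", 0.2)])
        )
        out = tmp_path / "t.nwk"
        write_newick(tree, out)
        assert out.read_text().strip() == "(A:0.100000,B:0.200000);"

    def test_roundtrip_preserves_topology_and_lengths(self, build_result, tmp_path):
        from skbio import TreeNode

        out = tmp_path / "t.nwk"
        write_newick(build_result.tree, out)
        parsed = TreeNode.read(str(out))
        assert sorted(t.name for t in parsed.tips()) == sorted(
            build_result.tree.leaf_names()
        )
        # root trifurcation of the unrooted NJ tree survives serialization
        assert len(parsed.children) == 3
        ours = build_result.tree.leaf_distances()
        for a in ours.ids[:3]:
            for b in ours.ids[3:]:
                got = parsed.find(a).distance(parsed.find(b))
                assert got == pytest.approx(ours[a, b], abs=1e-5)

    def test_unsafe_labels_sanitized(self):
        assert sanitize_label("pAKD 16;x") == "pAKD_16_x"


class TestLibraryPersistence:
    def test_roundtrip_and_byte_stability(self, build_result, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_library(build_result.clusters, build_result.matrix, p1)
        save_library(build_result.clusters, build_result.matrix, p2)
        assert p1.read_bytes() == p2.read_bytes()
        clusters, matrix = load_library(p1)
        assert matrix.taxa == build_result.matrix.taxa
        assert np.array_equal(matrix.values, build_result.matrix.values)
        assert [c.members for c in clusters.clusters] == [
            c.members for c in build_result.clusters.clusters
        ]
        assert clusters.sequences == build_result.clusters.sequences
        assert matrix.values.shape[1] == len(clusters.clusters)

    def test_truncated_file_rejected(self, build_result, tmp_path):
        path = tmp_path / "lib.json"
        save_library(build_result.clusters, build_result.matrix, path)
        path.write_bytes(path.read_bytes()[:50])
        with pytest.raises(ValueError, match="corrupt|truncated"):
            load_library(path)

    def test_version_mismatch_rejected(self, build_result, tmp_path):
        path = tmp_path / "lib.json"
        save_library(build_result.clusters, build_result.matrix, path)
        doc = json.loads(path.read_text())
        doc["version"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            load_library(path)

    def test_empty_matrix_rejected(self, build_result, tmp_path):
        from proteodendro.profiles import ProfileMatrix

        empty = ProfileMatrix(taxa=(), values=np.zeros((0, 0), dtype=np.uint8))
        with pytest.raises(ValueError):
            save_library(build_result.clusters, empty, tmp_path / "x.json")
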