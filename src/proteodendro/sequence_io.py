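"""Reading proteome FASTA files; writing Newick trees; library persistence.

A *proteome* here is the complete set of putative protein sequences of one
taxon (e.g. one plasmid). Input is plain amino-acid FASTA, one file per
taxon. The persisted *library* bundles the homolog clusters (with member
sequences) and the binary profile matrix so that new taxa can be profiled
and inserted later without redoing the all-against-all clustering.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .clustering import ClusterSet
    from .nj_tree import Dendrogram
    from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus X (unknown/ambiguous).
ACCEPTED_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

LIBRARY_FORMAT = "proteodendro-library"
LIBRARY_VERSION = 1

_NEWICK_SAFE = re.compile(r"[^A-Za-z0-9_.-]")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence of a proteome.

    ``(taxon_id, protein_id)`` is the globally unique key used throughout
    the pipeline to refer to a protein.
    """

    protein_id: str
    taxon_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be nonempty")
        if not self.sequence:
            raise ValueError(
                f"protein {self.taxon_id}/{self.protein_id} has an empty sequence"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.taxon_id, self.protein_id)


@dataclass(frozen=True)
class Proteome:
    """Ordered collection of the proteins of one taxon."""

    taxon_id: str
    records: tuple[ProteinRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.taxon_id != self.taxon_id:
                raise ValueError(
                    f"record {rec.protein_id} has taxon {rec.taxon_id!r}, "
                    f"expected {self.taxon_id!r}"
                )
            if rec.protein_id in seen:
                raise ValueError(
                    f"duplicate protein_id {rec.protein_id!r} in proteome "
                    f"{self.taxon_id!r}"
                )
            seen.add(rec.protein_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)


def _clean_sequence(raw: str, header: str, path: Path) -> str:
    """Upper-case, strip one trailing stop, map odd letters to X."""
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise ValueError(
            f"{path}: entry {header!r} contains an internal stop character '*'"
        )
    if not seq:
        raise ValueError(f"{path}: entry {header!r} has an empty sequence")
    bad = set(seq) - ACCEPTED_ALPHABET
    if bad:
        logger.warning(
            "%s: entry %r: mapping non-standard residue(s) %s to X",
            path, header, "".join(sorted(bad)),
        )
        seq = "".join(c if c in ACCEPTED_ALPHABET else "X" for c in seq)
    return seq


def read_proteome(path: str | Path, taxon_id: str) -> Proteome:
    """Read one amino-acid FASTA file as the proteome of ``taxon_id``.

    Sequences are upper-cased; a single trailing ``*`` (stop) is stripped;
    characters outside the 20 standard residues (including the ambiguity
    codes B, Z, U, O) are mapped to ``X`` with a logged warning. An internal
    ``*`` or an empty sequence is an error naming the offending header.
    """
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(entry.seq), entry.id, path)
        records.append(ProteinRecord(protein_id=entry.id, taxon_id=taxon_id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return Proteome(taxon_id=taxon_id, records=tuple(records))


def write_proteome(proteome: Proteome, path: str | Path) -> None:
    """Write a proteome back out as FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def sanitize_label(label: str) -> str:
    """Replace characters unsafe in unquoted Newick labels with ``_``."""
    return _NEWICK_SAFE.sub("_", label)


def write_newick(tree: "Dendrogram", path: str | Path) -> None:
    """Serialize a dendrogram to a ``.nwk`` file.

    Labels are restricted to ``[A-Za-z0-9_.-]``; any other character is
    replaced by ``_`` and the substitution is logged, for compatibility
    with downstream tree viewers. Branch lengths are written with six
    decimal places.
    """
    mapped = {
        name: sanitize_label(name)
        for name in tree.leaf_names()
        if sanitize_label(name) != name
    }
    for original, safe in mapped.items():
        logger.warning("newick label %r written as %r", original, safe)
    with open(path, "w") as fh:
        fh.write(tree.to_newick(decimals=6, label_fn=sanitize_label) + "\n")


def save_library(clusters: "ClusterSet", matrix: "ProfileMatrix", path: str | Path) -> None:
    """Persist the correlation-filter library (clusters + profile matrix).

    The file is a versioned JSON document; member sequences are included so
    that new proteomes can be profiled against the clusters later. Saving
    the same objects twice yields byte-identical files.
    """
    if len(matrix.taxa) == 0:
        raise ValueError("cannot save a library with no taxa")
    if matrix.values.shape[1] != len(clusters.clusters):
        raise ValueError(
            f"profile matrix has {matrix.values.shape[1]} columns but the "
            f"cluster set has {len(clusters.clusters)} clusters"
        )
    doc = {
        "format": LIBRARY_FORMAT,
        "version": LIBRARY_VERSION,
        "taxa": list(matrix.taxa),
        "matrix": matrix.values.astype(int).tolist(),
        "clusters": [
            {"cluster_id": c.cluster_id, "members": sorted(list(m) for m in c.members)}
            for c in clusters.clusters
        ],
        "sequences": {
            f"{taxon}\t{pid}": seq
            for (taxon, pid), seq in sorted(clusters.sequences.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_library(path: str | Path) -> tuple["ClusterSet", "ProfileMatrix"]:
    """Load a library written by :func:`save_library`."""
    from .clustering import ClusterSet, ProteinCluster
    from .profiles import ProfileMatrix
    import numpy as np

    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: corrupt or truncated library file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != LIBRARY_FORMAT:
        raise ValueError(f"{path}: not a {LIBRARY_FORMAT} file")
    if doc.get("version") != LIBRARY_VERSION:
        raise ValueError(
            f"{path}: library version {doc.get('version')!r} is not supported "
            f"(expected {LIBRARY_VERSION})"
        )
    sequences = {}
    for key, seq in doc["sequences"].items():
        taxon, pid = key.split("\t")
        sequences[(taxon, pid)] = seq
    clusters = ClusterSet(
        clusters=tuple(
            ProteinCluster(
                cluster_id=c["cluster_id"],
                members=frozenset((t, p) for t, p in c["members"]),
            )
            for c in doc["clusters"]
        ),
        sequences=sequences,
    )
    matrix = ProfileMatrix(
        taxa=tuple(doc["taxa"]),
        values=np.asarray(doc["matrix"], dtype=np.uint8).reshape(
            len(doc["taxa"]), len(doc["clusters"])
        ),
    )
    return clusters, matrix


def read_proteomes(paths: Iterable[str | Path]) -> list[Proteome]:
    """Read several FASTA files, deriving each taxon_id from the file stem."""
    return [read_proteome(p, Path(p).stem) for p in paths]
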