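"""Synthetic multi-taxon proteomes with planted homolog families.

The generator emulates the structure the pipeline is built to recover: a
pool of ancestral protein families shared across taxa (each present copy
carrying independent point mutations), taxon-private proteins with no
homolog anywhere, and occasional within-taxon duplicates (near-exact
copies of a family member, guaranteed to reach the 0.45 duplicate score).
Alongside the FASTA-ready proteomes it emits the ground truth — family
labels, duplicate groups, and the expected cluster incidence matrix — so
every pipeline stage can be checked exactly. The same seed always yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import Proteome, ProteinRecord, write_proteome

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

MIN_FAMILY_LENGTH = 80
MAX_FAMILY_LENGTH = 300


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic proteome set.

    Defaults describe the benchmark regime used throughout the test suite:
    six taxa drawing from ten families, each family present in a taxon with
    probability 0.8, family copies diverged by 5% per-residue substitution
    (pairwise identity ~90%, far above the 40% homology cutoff and far
    below duplicate similarity), three private proteins per taxon, and a
    0.3 chance that a present family copy is duplicated within its taxon.
    """

    n_taxa: int = 6
    n_families: int = 10
    family_presence_prob: float = 0.8
    mutation_rate: float = 0.05
    n_private: int = 3
    dup_prob: float = 0.3
    seed: int = 0
    taxon_prefix: str = "T"

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("family_presence_prob", "mutation_rate", "dup_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_private < 0:
            raise ValueError("n_private must be >= 0")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth emitted alongside the synthetic proteomes."""

    #: family index for every family-derived protein (duplicates included)
    family_of: dict[tuple[str, str], int]
    #: groups of within-taxon duplicate keys (original listed first)
    duplicate_groups: tuple[tuple[tuple[str, str], ...], ...]
    #: keys expected to survive dedup (originals and private proteins)
    expected_retained: frozenset[tuple[str, str]]
    #: taxa x families presence (before restricting to clusterable families)
    presence: pd.DataFrame

    def clusterable_families(self) -> list[int]:
        """Families present in >= 2 taxa: exactly those that can become
        clusters once duplicates are removed."""
        counts = self.presence.sum(axis=0)
        return [int(f) for f in self.presence.columns if counts[f] >= 2]

    def expected_incidence(self) -> pd.DataFrame:
        """Expected profile matrix, taxa x clusterable families."""
        return self.presence[self.clusterable_families()]

    def expected_partition(self) -> dict[tuple[str, str], int]:
        """Family label for each retained, clusterable protein."""
        clusterable = set(self.clusterable_families())
        return {
            key: fam
            for key, fam in self.family_of.items()
            if key in self.expected_retained and fam in clusterable
        }


@dataclass(frozen=True)
class FixtureSet:
    spec: FixtureSpec
    proteomes: tuple[Proteome, ...]
    truth: FixtureTruth

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write one FASTA per taxon plus truth tables; returns FASTA paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for proteome in self.proteomes:
            path = out_dir / f"{proteome.taxon_id}.faa"
            write_proteome(proteome, path)
            paths.append(path)
        family_rows = [
            (taxon, pid, fam) for (taxon, pid), fam in sorted(self.truth.family_of.items())
        ]
        pd.DataFrame(family_rows, columns=["taxon_id", "protein_id", "family"]).to_csv(
            out_dir / "truth_families.tsv", sep="\t", index=False
        )
        self.truth.presence.to_csv(out_dir / "truth_presence.tsv", sep="\t")
        dup_rows = [
            (gi, taxon, pid)
            for gi, group in enumerate(self.truth.duplicate_groups)
            for taxon, pid in group
        ]
        pd.DataFrame(dup_rows, columns=["group", "taxon_id", "protein_id"]).to_csv(
            out_dir / "truth_duplicates.tsv", sep="\t", index=False
        )
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate == 0.0:
        return sequence
    chars = np.array(list(sequence))
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        choices = AMINO_ACIDS[AMINO_ACIDS != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


def generate(spec: FixtureSpec) -> FixtureSet:
    """Generate synthetic proteomes plus ground truth from a spec.

    Family ancestors are random sequences of length 80-300 (comfortably
    above the 20-column minimum alignment length); duplicates carry at most
    one extra substitution, which keeps their similarity score >= 0.45 at
    these lengths.
    """
    rng = np.random.default_rng(spec.seed)
    ancestors = [
        _random_sequence(rng, int(rng.integers(MIN_FAMILY_LENGTH, MAX_FAMILY_LENGTH + 1)))
        for _ in range(spec.n_families)
    ]
    taxa = [f"{spec.taxon_prefix}{i:02d}" for i in range(spec.n_taxa)]
    family_of: dict[tuple[str, str], int] = {}
    duplicate_groups: list[tuple[tuple[str, str], ...]] = []
    retained: set[tuple[str, str]] = set()
    presence = np.zeros((spec.n_taxa, spec.n_families), dtype=np.uint8)
    proteomes = []
    for ti, taxon in enumerate(taxa):
        records: list[ProteinRecord] = []
        for fam in range(spec.n_families):
            if rng.random() >= spec.family_presence_prob:
                continue
            presence[ti, fam] = 1
            copy = _mutate(rng, ancestors[fam], spec.mutation_rate)
            pid = f"fam{fam:02d}"
            key = (taxon, pid)
            records.append(ProteinRecord(pid, taxon, copy))
            family_of[key] = fam
            retained.add(key)
            if rng.random() < spec.dup_prob:
                # near-exact copy: at most one substitution
                dup_seq = copy
                if rng.random() < 0.5:
                    pos = int(rng.integers(len(copy)))
                    dup_seq = copy[:pos] + str(rng.choice(AMINO_ACIDS)) + copy[pos + 1 :]
                dup_pid = f"fam{fam:02d}.dup"
                records.append(ProteinRecord(dup_pid, taxon, dup_seq))
                family_of[(taxon, dup_pid)] = fam
                duplicate_groups.append((key, (taxon, dup_pid)))
        for pi in range(spec.n_private):
            length = int(rng.integers(MIN_FAMILY_LENGTH, MAX_FAMILY_LENGTH + 1))
            pid = f"priv{pi:02d}"
            records.append(ProteinRecord(pid, taxon, _random_sequence(rng, length)))
            retained.add((taxon, pid))
        proteomes.append(Proteome(taxon_id=taxon, records=tuple(records)))
    truth = FixtureTruth(
        family_of=family_of,
        duplicate_groups=tuple(duplicate_groups),
        expected_retained=frozenset(retained),
        presence=pd.DataFrame(presence, index=taxa, columns=list(range(spec.n_families))),
    )
    return FixtureSet(spec=spec, proteomes=tuple(proteomes), truth=truth)


def generate_pair(
    spec: FixtureSpec, alien_seed_offset: int = 10_000
) -> tuple[FixtureSet, FixtureSet]:
    """Two fixture sets drawing from disjoint family pools.

    The second set reuses the spec with a shifted seed and a different
    taxon prefix, giving families unrelated to the first pool — the
    synthetic analogue of proteomes from an unrelated clade.
    """
    first = generate(spec)
    second = generate(
        replace(spec, seed=spec.seed + alien_seed_offset, taxon_prefix="U")
    )
    return first, second
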