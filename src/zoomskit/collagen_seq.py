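"""Collagen type I chain sequences: containers, coverage, distances, trees.

Teleost fish carry three distinct collagen type I chains (COL1a1a, COL1a2,
COL1a1b), each a Gly-X-Y triplet-repeat protein. Peptide positions throughout
the package are numbered against the *mature* chain (propeptides removed),
with 1-based inclusive coordinates. Mature-region bounds are supplied as
explicit annotations because propeptide cleavage sites are not computed here.

A p-distance/neighbor-joining tree with column-resampling bootstrap is
provided as a sanity check on inter-species collagen variation; it is not a
substitute for model-based maximum-likelihood phylogenetics.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix as _SkDistanceMatrix
from skbio import TreeNode as _SkTreeNode
from skbio.tree import nj as _sk_nj

logger = logging.getLogger(__name__)

CHAIN_IDS = ("COL1a1a", "COL1a2", "COL1a1b")

#: 20 amino-acid letters plus 'X' for unresolved positions
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class CollagenChain:
    """One collagen type I chain of one species, with mature-region bounds."""

    species_id: str
    chain_id: str
    residues: str
    mature_start: int
    mature_end: int

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.species_id}/{self.chain_id}: residues outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )
        if not (1 <= self.mature_start <= self.mature_end <= len(self.residues)):
            raise ValueError(
                f"{self.species_id}/{self.chain_id}: invalid mature bounds "
                f"{self.mature_start}..{self.mature_end} for length "
                f"{len(self.residues)}"
            )

    @property
    def mature_length(self) -> int:
        return self.mature_end - self.mature_start + 1


@dataclass(frozen=True)
class SpeciesProfile:
    """The collagen type I chain set of one species."""

    species_id: str
    chains: tuple[CollagenChain, ...]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.species_id}: duplicate chain_ids {ids}")
        for c in self.chains:
            if c.species_id != self.species_id:
                raise ValueError(
                    f"chain {c.chain_id} belongs to {c.species_id}, "
                    f"not {self.species_id}"
                )

    def chain(self, chain_id: str) -> CollagenChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.species_id} has no chain {chain_id}")

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c.chain_id for c in self.chains)


def mature_sequence(chain: CollagenChain) -> str:
    """The mature-chain substring (1-based inclusive bounds)."""
    return chain.residues[chain.mature_start - 1 : chain.mature_end]


def read_bounds(path) -> dict[tuple[str, str], tuple[int, int]]:
    """Read a mature-bounds annotation TSV: species, chain, start, end."""
    out: dict[tuple[str, str], tuple[int, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "species":
                continue
            if len(row) < 4:
                raise ValueError(f"malformed bounds row: {row!r}")
            species, chain, start, end = row[0], row[1], int(row[2]), int(row[3])
            out[(species, chain)] = (start, end)
    return out


def read_profiles(
    fasta_path,
    bounds: dict[tuple[str, str], tuple[int, int]] | str | None = None,
    header_sep: str = "|",
    known_chains: tuple[str, ...] = CHAIN_IDS,
) -> list[SpeciesProfile]:
    """Read species collagen profiles from FASTA plus a mature-bounds table.

    FASTA headers follow the dialect ``>SPECIES|CHAIN`` (separator
    configurable). ``bounds`` maps (species, chain) to 1-based inclusive
    mature bounds, or is a path to a TSV of them; chains without an annotation
    are taken as entirely mature. Species with missing chains are reported via
    a logged warning but still returned.
    """
    if isinstance(bounds, (str, bytes)) or hasattr(bounds, "__fspath__"):
        bounds = read_bounds(bounds)
    bounds = bounds or {}
    by_species: dict[str, list[CollagenChain]] = {}
    n_records = 0
    for rec in SeqIO.parse(fasta_path, "fasta"):
        n_records += 1
        if header_sep not in rec.id:
            raise ValueError(
                f"FASTA header {rec.id!r} lacks a chain tag "
                f"(expected 'SPECIES{header_sep}CHAIN')"
            )
        species, chain_id = rec.id.split(header_sep, 1)
        if chain_id not in known_chains:
            raise ValueError(
                f"record {rec.id!r}: unknown chain_id {chain_id!r} "
                f"(known: {known_chains})"
            )
        residues = str(rec.seq).upper()
        start, end = bounds.get((species, chain_id), (1, len(residues)))
        by_species.setdefault(species, []).append(
            CollagenChain(species, chain_id, residues, start, end)
        )
    if n_records == 0:
        logger.warning("no FASTA records in %s", fasta_path)
        return []
    profiles = []
    for species, chains in by_species.items():
        missing = set(known_chains) - {c.chain_id for c in chains}
        if missing:
            logger.warning("%s is missing chain(s) %s", species, sorted(missing))
        profiles.append(SpeciesProfile(species, tuple(chains)))
    return profiles


def coverage_pct(
    chain: CollagenChain,
    peptides,
    min_support: int = 2,
    scope: str = "mature",
) -> float:
    """Percentage of chain positions covered by >= ``min_support`` peptides.

    Mirrors the sequence-reconstruction quality rule: a position counts as
    recovered only if it lies in at least ``min_support`` distinct peptides.
    Peptide positions are 1-based within the mature chain.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if scope not in ("mature", "total"):
        raise ValueError("scope must be 'mature' or 'total'")
    mature_len = chain.mature_length
    support = np.zeros(mature_len, dtype=int)
    for p in peptides:
        start, end = p.span if hasattr(p, "span") else (p[0], p[1])
        if not (1 <= start <= end <= mature_len):
            raise ValueError(
                f"peptide span {start}..{end} outside mature chain "
                f"(length {mature_len})"
            )
        support[start - 1 : end] += 1
    covered = int((support >= min_support).sum())
    denom = mature_len if scope == "mature" else len(chain.residues)
    return 100.0 * covered / denom


def p_distance(a: str, b: str) -> float:
    """Proportion of differing positions, ignoring 'X' in either sequence."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    compared = diff = 0
    for x, y in zip(a, b):
        if x == "X" or y == "X":
            continue
        compared += 1
        if x != y:
            diff += 1
    if compared == 0:
        raise ValueError("no comparable positions (all masked by 'X')")
    return diff / compared


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over ordered taxa."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not fit {n} taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")


def concatenated_mature(profile: SpeciesProfile, chain_ids=CHAIN_IDS) -> str:
    """Concatenated mature sequences in fixed chain order."""
    return "".join(mature_sequence(profile.chain(cid)) for cid in chain_ids)


def _aligned_rows(profiles, chain_ids=CHAIN_IDS) -> tuple[list[str], np.ndarray]:
    """Stack concatenated mature sequences; end-pad with 'X' if lengths differ."""
    taxa = [p.species_id for p in profiles]
    seqs = [concatenated_mature(p, chain_ids) for p in profiles]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        warnings.warn(
            "chain lengths differ across species; end-padding with 'X' "
            "(collagen chains are assumed gap-free and near length-matched)",
            stacklevel=2,
        )
        L = max(lengths)
        seqs = [s + "X" * (L - len(s)) for s in seqs]
    arr = np.array([list(s) for s in seqs], dtype="U1")
    return taxa, arr


def _pdist_matrix(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    valid = arr != "X"
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError("no comparable positions between a taxon pair")
            d[i, j] = d[j, i] = int((arr[i][both] != arr[j][both]).sum()) / m
    return d


def profile_distance_matrix(profiles, chain_ids=CHAIN_IDS) -> DistanceMatrix:
    """Pairwise p-distances over concatenated mature chains."""
    taxa, arr = _aligned_rows(profiles, chain_ids)
    return DistanceMatrix(tuple(taxa), _pdist_matrix(arr))


class PhyloTree:
    """Unrooted tree over taxa with branch lengths and optional split support.

    Thin wrapper over a scikit-bio ``TreeNode``; bootstrap supports (percent,
    0-100) are stored as internal node names so they survive newick
    round-trips.
    """

    def __init__(self, tree: _SkTreeNode, taxa: tuple[str, ...]):
        self.tree = tree
        self.taxa = tuple(taxa)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = _SkTreeNode.read(io.StringIO(text), format="newick")
        taxa = tuple(sorted(t.name for t in tree.tips()))
        return cls(tree, taxa)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the side not holding taxa[0]."""
        ref = sorted(self.taxa)[0]
        full = set(self.taxa)
        out: set[frozenset[str]] = set()
        for node in self.tree.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            if ref in side:
                side = full - side
            if 1 < len(side) < len(full) - 1:
                out.add(frozenset(side))
        return out

    def support(self) -> dict[frozenset[str], float]:
        """Split -> bootstrap support in [0, 100], where annotated."""
        ref = sorted(self.taxa)[0]
        full = set(self.taxa)
        out: dict[frozenset[str], float] = {}
        for node in self.tree.non_tips(include_self=False):
            if node.name is None:
                continue
            side = {t.name for t in node.tips()}
            if ref in side:
                side = full - side
            if 1 < len(side) < len(full) - 1:
                out[frozenset(side)] = float(node.name)
        return out


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree; negative branch-length estimates clamp to 0."""
    if len(m.taxa) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    skdm = _SkDistanceMatrix(m.d, ids=list(m.taxa))
    tree = _sk_nj(skdm, neg_as_zero=True)
    return PhyloTree(tree, m.taxa)


def bootstrap_support(
    profiles,
    B: int = 100,
    seed: int | None = None,
    chain_ids=CHAIN_IDS,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports.

    Resamples alignment columns of the concatenated mature chains ``B`` times,
    rebuilds the NJ tree each time, and annotates each split of the full-data
    tree with the percentage of replicates containing it. Deterministic for a
    fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    taxa, arr = _aligned_rows(profiles, chain_ids)
    base = nj_tree(DistanceMatrix(tuple(taxa), _pdist_matrix(arr)))
    counts: dict[frozenset[str], int] = {s: 0 for s in base.splits()}
    rng = np.random.default_rng(seed)
    L = arr.shape[1]
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(DistanceMatrix(tuple(taxa), _pdist_matrix(arr[:, cols])))
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    full = set(base.taxa)
    ref = sorted(base.taxa)[0]
    for node in base.tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = full - side
        key = frozenset(side)
        if key in counts:
            node.name = f"{100.0 * counts[key] / B:g}"
    return base
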