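"""De novo RAD tag assembly: within-individual stacks, cross-individual catalog.

Reads are fixed-length (82 nt) and indel-free by construction of the library,
so homology is decided purely by Hamming distance.  Within an individual,
unique sequences are clustered greedily around abundance-ranked seeds with a
2-mismatch radius (ustacks-style); across individuals, stack consensuses are
merged by single linkage at the same radius to form catalog loci.

Stacks retain per-column base counts.  This matters for heterozygotes: the
two alleles of a het differ at 1-2 positions, i.e. they fall within the
clustering radius and are absorbed into one stack — the allelic signal
survives only in the column counts, which is where genotyping reads it.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .simulate import TAG_LENGTH

_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)  # row order = lexicographic
_CODE_TO_ROW = np.full(256, -1, dtype=np.int64)
for _row, _c in enumerate(_CODES):
    _CODE_TO_ROW[_c] = _row


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _encode(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, TAG_LENGTH), dtype=np.uint8)
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _decode(row: np.ndarray) -> str:
    return row.tobytes().decode()


@dataclass
class TagStack:
    """One within-individual cluster of 82-nt reads."""

    individual_id: str
    consensus: str
    depth: int
    members: int  # distinct read sequences absorbed
    #: 4 x 82 read counts per base (rows A,C,G,T) over all member reads
    column_counts: np.ndarray = field(repr=False, default=None)


@dataclass
class CatalogLocus:
    """Cross-individual homologous tag locus."""

    locus_id: str
    reference_consensus: str
    #: individual_id -> that individual's stacks merged into this locus
    alleles: dict[str, list[TagStack]]
    variant_positions: list[int]  # 1-based, position 1 = leading A of AATTC
    repetitive: bool = False

    def allele_summary(self) -> dict[str, list[tuple[str, int]]]:
        return {
            ind: [(s.consensus, s.depth) for s in stacks]
            for ind, stacks in self.alleles.items()
        }

    def individual_column_counts(self, individual_id: str) -> np.ndarray | None:
        """Aggregate 4x82 base counts over the individual's member stacks."""
        stacks = self.alleles.get(individual_id)
        if not stacks:
            return None
        return np.sum([s.column_counts for s in stacks], axis=0)


def _consensus_from_counts(counts: np.ndarray, seed_rows: np.ndarray | None = None) -> str:
    """Per-column majority; ties go to the seed base if given, else to the
    lexicographically smallest base (argmax picks the first maximal row)."""
    best = counts.argmax(axis=0)
    if seed_rows is not None:
        maxv = counts.max(axis=0)
        seed_hits = counts[seed_rows, np.arange(counts.shape[1])] == maxv
        best = np.where(seed_hits, seed_rows, best)
    return _CODES[best].tobytes().decode()


def build_stacks(
    reads: list[str],
    min_stack_depth: int = 3,
    max_mismatch: int = 2,
) -> tuple[list[TagStack], list[tuple[str, int]]]:
    """Greedy star clustering of one individual's reads.

    Unique sequences are ranked by (descending count, lexicographic); each
    still-unassigned sequence within ``max_mismatch`` of the current seed
    joins its stack.  Stacks below ``min_stack_depth`` total reads are
    returned as the residual (sequence, count) list instead.
    """
    for r in reads:
        if len(r) != TAG_LENGTH:
            raise ValueError(f"read of length {len(r)} != {TAG_LENGTH}")
    if not reads:
        return [], []

    tally = Counter(reads)
    uniq = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    seqs = [s for s, _ in uniq]
    counts = np.array([c for _, c in uniq], dtype=np.int64)
    mat = _encode(seqs)
    n = len(seqs)

    assigned = np.zeros(n, dtype=bool)
    kept: list[TagStack] = []
    residual: list[tuple[str, int]] = []

    for i in range(n):
        if assigned[i]:
            continue
        dist = (mat != mat[i]).sum(axis=1)
        member_idx = np.flatnonzero(~assigned & (dist <= max_mismatch))
        assigned[member_idx] = True

        sub = mat[member_idx]
        w = counts[member_idx]
        cc = np.zeros((4, TAG_LENGTH), dtype=np.int64)
        rows = _CODE_TO_ROW[sub]
        for k in range(4):
            cc[k] = ((rows == k) * w[:, None]).sum(axis=0)
        seed_rows = _CODE_TO_ROW[mat[i]]
        consensus = _consensus_from_counts(cc, seed_rows)
        depth = int(w.sum())
        if depth >= min_stack_depth:
            kept.append(
                TagStack(
                    individual_id="",
                    consensus=consensus,
                    depth=depth,
                    members=len(member_idx),
                    column_counts=cc,
                )
            )
        else:
            residual.extend((seqs[j], int(counts[j])) for j in member_idx)
    return kept, residual


def build_stacks_for(
    individual_id: str,
    reads: list[str],
    min_stack_depth: int = 3,
    max_mismatch: int = 2,
) -> tuple[list[TagStack], list[tuple[str, int]]]:
    stacks, residual = build_stacks(reads, min_stack_depth, max_mismatch)
    for s in stacks:
        s.individual_id = individual_id
    return stacks, residual


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_catalog(
    stacks_by_individual: dict[str, list[TagStack]],
    catalog_mismatch: int = 2,
    parent_ids: tuple[str, ...] = ("mother", "father"),
    min_variant_depth: int = 2,
    min_variant_ratio: float = 0.1,
) -> list[CatalogLocus]:
    """Single-linkage merge of all individuals' stacks into catalog loci.

    The reference consensus is the column-majority over parent-derived stacks
    when any parent contributes, else over all stacks.  A locus where any
    individual contributes more than two distinct stack consensuses is
    flagged repetitive (putative paralog collapse) and carries no variant
    positions.  Variant positions are the 1-based columns at which either
    individuals' major bases disagree or some individual carries a credible
    second base (count >= min_variant_depth and >= min_variant_ratio of its
    major base) — the latter catches heterozygotes whose alleles were
    absorbed into a single stack.
    """
    flat: list[TagStack] = []
    for ind in sorted(stacks_by_individual):
        flat.extend(stacks_by_individual[ind])
    if not flat:
        return []
    mat = _encode([s.consensus for s in flat])
    n = len(flat)

    uf = _UnionFind(n)
    for i in range(n - 1):
        dist = (mat[i + 1:] != mat[i]).sum(axis=1)
        for j in np.flatnonzero(dist <= catalog_mismatch):
            uf.union(i, int(i + 1 + j))

    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        comps[uf.find(i)].append(i)
    ordered = sorted(comps.values(), key=lambda idxs: min(flat[i].consensus for i in idxs))

    loci: list[CatalogLocus] = []
    for k, idxs in enumerate(ordered):
        members = [flat[i] for i in idxs]
        alleles: dict[str, list[TagStack]] = defaultdict(list)
        for s in members:
            alleles[s.individual_id].append(s)
        repetitive = any(
            len({s.consensus for s in stacks}) > 2 for stacks in alleles.values()
        )

        parent_stacks = [s for s in members if s.individual_id in parent_ids]
        basis = parent_stacks if parent_stacks else members
        ref_counts = np.sum([s.column_counts for s in basis], axis=0)
        reference = _consensus_from_counts(ref_counts)

        positions: list[int] = []
        if not repetitive:
            per_ind = {
                ind: np.sum([s.column_counts for s in stacks], axis=0)
                for ind, stacks in alleles.items()
            }
            for col in range(TAG_LENGTH):
                seen: set[int] = set()
                for cc in per_ind.values():
                    col_counts = cc[:, col]
                    major = int(col_counts.argmax())
                    if col_counts[major] == 0:
                        continue
                    seen.add(major)
                    for row in range(4):
                        if row == major:
                            continue
                        c = int(col_counts[row])
                        if (
                            c >= min_variant_depth
                            and c / col_counts[major] >= min_variant_ratio
                        ):
                            seen.add(row)
                if len(seen) >= 2:
                    positions.append(col + 1)

        loci.append(
            CatalogLocus(
                locus_id=f"L{k + 1:05d}",
                reference_consensus=reference,
                alleles=dict(alleles),
                variant_positions=positions,
                repetitive=repetitive,
            )
        )
    return loci
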