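"""Stringent greedy overlap-layout-consensus assembly of cleaned EST reads.

Candidate overlaps are found by shared k-mers, placed on their best
diagonal, and scored by gapless identity (reads carry substitution errors
only, so overlaps are unbanded); up to ``clip_range`` bases may be trimmed
from each overlap end when reconciling a read with an overlap.  Reads merge
only when the overlap is at least ``min_overlap`` bases long at
``overlap_identity`` or better; merging is greedy, highest-scoring overlap
first, with deterministic tie-breaking.  The consensus is a per-column
quality-weighted majority.  Reverse-complement overlaps are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaning import QualityRead, revcomp


@dataclass(frozen=True)
class AssemblyParams:
    """Assembly stringency settings (the printed -p / -y values, plus the
    assembler's conventional minimum overlap length)."""

    overlap_identity: float = 0.90
    clip_range: int = 30
    min_overlap: int = 40
    kmer_size: int = 16
    kmer_stride: int = 8      # index every stride-th k-mer of each read
    min_shared_kmers: int = 2
    max_kmer_occ: int = 200   # skip repetitive seeds

    def __post_init__(self) -> None:
        if not 0 < self.overlap_identity <= 1:
            raise ValueError("overlap_identity must be in (0, 1]")


@dataclass
class Unigene:
    """An assembled contig or a singleton read.

    ``members`` holds (read_id, offset, strand) placements in consensus
    coordinates; read count is the expression proxy.
    """

    id: str
    consensus: str
    members: list[tuple[str, int, str]]
    kind: str  # "contig" | "singleton"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class _UnionFind:
    """Union-find tracking each read's signed-affine placement x -> s*x + o
    relative to its component root."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.sign = [1] * n
        self.off = [0] * n
        self.size = [1] * n

    def find(self, i: int) -> tuple[int, int, int]:
        if self.parent[i] == i:
            return i, self.sign[i], self.off[i]
        root, s, o = self.find(self.parent[i])
        # compose: x ->(this) sign*x+off ->(parent chain) s*(.)+o
        self.sign[i] = s * self.sign[i]
        self.off[i] = s * self.off[i] + o
        self.parent[i] = root
        return root, self.sign[i], self.off[i]

    def union(self, i: int, j: int, s_ij: int, o_ij: int) -> bool:
        """Link j to i with placement x_j -> s_ij * x_j + o_ij in i's coords."""
        ri, si, oi = self.find(i)
        rj, sj, oj = self.find(j)
        if ri == rj:
            return False
        # placement of rj in ri coordinates:
        #   x_ri = si * x_i + oi ; x_i = s_ij * x_j + o_ij
        #   x_rj = sj * x_j + oj  =>  x_j = sj * (x_rj - oj)
        s = si * s_ij * sj
        o = si * (o_ij - s_ij * sj * oj) + oi
        if self.size[ri] < self.size[rj]:
            # attach ri under rj: invert the transform
            s_inv, o_inv = s, -s * o
            self.parent[ri] = rj
            self.sign[ri], self.off[ri] = s_inv, o_inv
            self.size[rj] += self.size[ri]
        else:
            self.parent[rj] = ri
            self.sign[rj], self.off[rj] = s, o
            self.size[ri] += self.size[rj]
        return True


def _overlap_score(
    a: np.ndarray, b: np.ndarray, d: int, params: AssemblyParams
) -> tuple[int, float, int] | None:
    """Score b aligned on a at offset d (a-coord = b-coord + d).

    Returns (matches, identity, length) of the best overlap after trimming
    up to clip_range from each end, or None if no acceptable overlap.
    """
    s = max(0, d)
    e = min(len(a), d + len(b))
    L0 = e - s
    if L0 < params.min_overlap:
        return None
    m = (a[s:e] == b[s - d : e - d]).astype(np.int32)
    total = int(m.sum())
    if total / L0 >= params.overlap_identity:
        return total, total / L0, L0
    y = params.clip_range
    max_trim = min(y, L0 - params.min_overlap)
    if max_trim <= 0:
        return None
    cum = np.concatenate([[0], np.cumsum(m)])
    ta = np.arange(0, max_trim + 1)
    tb = np.arange(0, max_trim + 1)
    lengths = L0 - np.add.outer(ta, tb)
    matches = cum[L0 - tb][None, :] - cum[ta][:, None]
    with np.errstate(invalid="ignore"):
        ident = matches / lengths
    ok = (ident >= params.overlap_identity) & (lengths >= params.min_overlap)
    if not ok.any():
        return None
    best = np.where(ok, matches, -1)
    idx = int(best.argmax())
    i, j = divmod(idx, best.shape[1])
    return int(matches[i, j]), float(ident[i, j]), int(lengths[i, j])


def find_overlaps(
    reads: list[QualityRead], params: AssemblyParams
) -> list[tuple[int, int, int, int, str]]:
    """All acceptable pairwise overlaps as (matches, length, i, j, strand:d).

    Returned tuples are (matches, i, j, strand_sign, d) sorted for greedy
    merging: descending match count, then lexicographic read-id pair.
    """
    seqs = [r.seq.upper() for r in reads]
    fwd = [_encode(s) for s in seqs]
    rev = [_encode(revcomp(s)) for s in seqs]
    k, stride = params.kmer_size, params.kmer_stride
    index: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(seqs):
        for p in range(0, len(s) - k + 1, stride):
            kmer = s[p : p + k]
            if "N" in kmer or "X" in kmer:
                continue
            index.setdefault(kmer, []).append((i, p))
    for kmer in list(index):
        if len(index[kmer]) > params.max_kmer_occ:
            del index[kmer]

    overlaps = []
    for j, s in enumerate(seqs):
        for strand, query in (("+", s), ("-", revcomp(s))):
            votes: dict[tuple[int, int], int] = {}
            for p in range(len(query) - k + 1):
                kmer = query[p : p + k]
                for i, q in index.get(kmer, ()):
                    if i >= j:
                        continue
                    key = (i, q - p)
                    votes[key] = votes.get(key, 0) + 1
            by_read: dict[int, tuple[int, int]] = {}
            for (i, d), n in votes.items():
                prev = by_read.get(i)
                # best-supported diagonal, deterministic tie-break on d
                if prev is None or (n, -d) > (prev[0], -prev[1]):
                    by_read[i] = (n, d)
            b = fwd[j] if strand == "+" else rev[j]
            for i in sorted(by_read):
                n, d = by_read[i]
                if n < params.min_shared_kmers:
                    continue
                res = _overlap_score(fwd[i], b, d, params)
                if res is None:
                    continue
                matches, _ident, _length = res
                overlaps.append((matches, i, j, 1 if strand == "+" else -1, d))
    overlaps.sort(key=lambda t: (-t[0], reads[t[1]].id, reads[t[2]].id, t[3], t[4]))
    return overlaps


def _merge_consistent(
    uf: _UnionFind,
    comp_a: list[int],
    comp_b: list[int],
    i: int,
    j: int,
    s_ij: int,
    o_ij: int,
    fwd: list[np.ndarray],
    rev: list[np.ndarray],
    params: AssemblyParams,
) -> bool:
    """Check every implied read-pair overlap of a candidate component merge.

    Placing component B against component A via the (i, j) overlap implies a
    relative placement for every read pair across the two components; the
    merge is accepted only if every pair co-spanning at least ``min_overlap``
    bases still aligns at ``overlap_identity`` or better.  This is what
    keeps 85%-identity paralogs from coalescing through one lucky short
    overlap.
    """
    _ri, si, oi = uf.find(i)
    _rj, sj, oj = uf.find(j)
    S = si * s_ij * sj
    O = si * (o_ij - s_ij * sj * oj) + oi
    placements_a = []
    for a in comp_a:
        _r, sa, oa = uf.find(a)
        placements_a.append((a, sa, oa))
    for b in comp_b:
        _r, sb, ob = uf.find(b)
        s_b_in_ri = S * sb
        o_b_in_ri = S * ob + O
        len_b = len(fwd[b])
        b_lo = o_b_in_ri if s_b_in_ri == 1 else o_b_in_ri - (len_b - 1)
        for a, sa, oa in placements_a:
            len_a = len(fwd[a])
            a_lo = oa if sa == 1 else oa - (len_a - 1)
            span = min(a_lo + len_a, b_lo + len_b) - max(a_lo, b_lo)
            if span < params.min_overlap:
                continue
            s_ab = sa * s_b_in_ri
            c = sa * (o_b_in_ri - oa)
            if s_ab == 1:
                if _overlap_score(fwd[a], fwd[b], c, params) is None:
                    return False
            else:
                if _overlap_score(fwd[a], rev[b], c - len_b + 1, params) is None:
                    return False
    return True


def assemble(
    reads: list[QualityRead], params: AssemblyParams = AssemblyParams()
) -> list[Unigene]:
    """Assemble cleaned reads into unigenes (contigs + singletons).

    Every input read appears in exactly one unigene.  Empty input yields an
    empty list.
    """
    if not reads:
        return []
    overlaps = find_overlaps(reads, params)
    uf = _UnionFind(len(reads))
    members: dict[int, list[int]] = {i: [i] for i in range(len(reads))}
    fwd = [_encode(r.seq.upper()) for r in reads]
    rev = [_encode(revcomp(r.seq.upper())) for r in reads]
    for _matches, i, j, sign, d in overlaps:
        if sign == 1:
            s_ij, o_ij = 1, d  # a-coord = b-coord + d
        else:
            s_ij, o_ij = -1, d + len(reads[j].seq) - 1
        ri, *_ = uf.find(i)
        rj, *_ = uf.find(j)
        if ri == rj:
            continue
        if not _merge_consistent(
            uf, members[ri], members[rj], i, j, s_ij, o_ij, fwd, rev, params
        ):
            continue
        uf.union(i, j, s_ij, o_ij)
        new_root, *_ = uf.find(i)
        old = rj if new_root == ri else ri
        members[new_root].extend(members.pop(old))

    components: dict[int, list[int]] = {}
    placements: dict[int, tuple[int, int]] = {}
    for i in range(len(reads)):
        root, s, o = uf.find(i)
        components.setdefault(root, []).append(i)
        placements[i] = (s, o)

    unigenes: list[Unigene] = []
    raw = []
    for root, members in components.items():
        members.sort(key=lambda i: reads[i].id)
        # canonical orientation: first (lexicographic) member on + strand
        flip = placements[members[0]][0] == -1
        placed = []
        for i in members:
            s, o = placements[i]
            if flip:
                s, o = -s, -o
            n = len(reads[i].seq)
            start = o if s == 1 else o - (n - 1)
            placed.append((i, s, start))
        lo = min(p[2] for p in placed)
        placed = [(i, s, start - lo) for i, s, start in placed]
        length = max(start + len(reads[i].seq) for i, _s, start in placed)
        cons = _consensus(reads, placed, length)
        raw.append((placed, cons))

    raw.sort(key=lambda t: (-len(t[0]), reads[t[0][0][0]].id))
    for idx, (placed, cons) in enumerate(raw):
        member_list = [
            (reads[i].id, start, "+" if s == 1 else "-") for i, s, start in placed
        ]
        unigenes.append(
            Unigene(
                id=f"u{idx:05d}",
                consensus=cons,
                members=member_list,
                kind="contig" if len(placed) > 1 else "singleton",
            )
        )
    return unigenes


_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


def _consensus(
    reads: list[QualityRead], placed: list[tuple[int, int, int]], length: int
) -> str:
    """Per-column quality-weighted majority; ties resolve alphabetically."""
    weights = np.zeros((4, length), dtype=np.int64)
    for i, s, start in placed:
        seq = reads[i].seq.upper() if s == 1 else revcomp(reads[i].seq.upper())
        qual = reads[i].qual if s == 1 else reads[i].qual[::-1]
        codes = _BASE_IDX[_encode(seq)]
        valid = codes >= 0
        pos = np.arange(len(seq))[valid] + start
        np.add.at(weights, (codes[valid], pos), qual[valid])
    covered = weights.sum(axis=0) > 0
    best = weights.argmax(axis=0)
    out = np.array(list("ACGT"))[best]
    out[~covered] = "N"
    return "".join(out)


def expression_proxy(unigenes: list[Unigene]) -> pd.Series:
    """Read count per unigene — the study's expression proxy."""
    return pd.Series(
        {u.id: len(u.members) for u in unigenes}, name="read_count", dtype=int
    ).sort_index()


def assembly_stats(unigenes: list[Unigene]) -> dict:
    """Summary: contig/singleton counts, contig mean length, member stats."""
    contigs = [u for u in unigenes if u.kind == "contig"]
    singletons = [u for u in unigenes if u.kind == "singleton"]
    sizes = [len(u.members) for u in contigs]
    return {
        "n_unigenes": len(unigenes),
        "n_contigs": len(contigs),
        "n_singletons": len(singletons),
        "contig_mean_length": (
            float(np.mean([len(u.consensus) for u in contigs])) if contigs else None
        ),
        "mean_members": float(np.mean(sizes)) if sizes else None,
        "median_members": float(np.median(sizes)) if sizes else None,
        "size_distribution": dict(
            pd.Series(sizes, dtype=int).value_counts().sort_index()
        ) if sizes else {},
    }
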