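"""Sanger-style EST read cleaning.

Implements the pre-assembly filtering applied to single-pass cDNA reads:

* sliding-window quality clipping (window mean phred above a threshold,
  scanned from both read ends),
* vector masking by seeded ungapped matching against a vector library,
* terminal poly(A)/poly(T) masking with an m-of-n window rule,
* final disposition (kept / too_short / empty_vector).

Coordinates are 0-based half-open throughout; human-readable reports use
1-based inclusive positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MASK_VECTOR = "vector"
MASK_POLYA = "polyA"
MASK_POLYT = "polyT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class QualityRead:
    """A read with per-base phred scores, a clip interval and mask intervals.

    ``clip`` is the high-quality region [start, end); ``masks`` is a list of
    ``(start, end, label)`` half-open intervals with label one of
    ``vector`` / ``polyA`` / ``polyT``.
    """

    id: str
    seq: str
    qual: np.ndarray
    clip: tuple[int, int] | None = None
    masks: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id}: qual length {len(self.qual)} != "
                f"seq length {len(self.seq)}"
            )

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)

    def copy(self) -> "QualityRead":
        return dataclasses.replace(
            self, qual=self.qual.copy(), masks=list(self.masks)
        )

    # -- derived views ----------------------------------------------------
    def masked_positions(self, labels: tuple[str, ...] | None = None) -> np.ndarray:
        """Boolean array, True where the base is covered by a mask."""
        covered = np.zeros(len(self.seq), dtype=bool)
        for start, end, label in self.masks:
            if labels is None or label in labels:
                covered[start:end] = True
        return covered

    def display_seq(self) -> str:
        """Sequence with masked bases lowercased (coordinates preserved)."""
        chars = list(self.seq)
        for start, end, _ in self.masks:
            for i in range(start, end):
                chars[i] = chars[i].lower()
        return "".join(chars)


def _merge_intervals(
    intervals: list[tuple[int, int, str]],
) -> list[tuple[int, int, str]]:
    """Merge overlapping/adjacent intervals that share a label."""
    out: list[tuple[int, int, str]] = []
    for iv in sorted(intervals):
        if out and iv[2] == out[-1][2] and iv[0] <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], iv[1]), iv[2])
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# quality clipping
# ---------------------------------------------------------------------------

def quality_clip(
    read: QualityRead, window: int = 20, threshold: float = 13.0
) -> tuple[int, int]:
    """Clip interval from a sliding-window scan of the phred values.

    A window of ``window`` bases is slid in from both read ends; the left
    clip is the start of the first window (left-to-right) whose mean phred
    exceeds ``threshold``, and the right clip is the end of the first such
    window right-to-left.  Reads shorter than the window are evaluated as a
    single window.  Returns the empty interval ``(0, 0)`` when no window
    qualifies.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    n = len(read.qual)
    if n == 0:
        return (0, 0)
    if n < window:
        return (0, n) if float(read.qual.mean()) > threshold else (0, 0)
    # mean of every window in one pass
    csum = np.concatenate([[0], np.cumsum(read.qual, dtype=np.int64)])
    means = (csum[window:] - csum[:-window]) / window
    ok = means > threshold
    if not ok.any():
        return (0, 0)
    left = int(np.argmax(ok))
    right = int(len(ok) - 1 - np.argmax(ok[::-1])) + window
    return (left, right)


# ---------------------------------------------------------------------------
# vector masking
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer or "X" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_segments(
    read_seq: str, vec_seq: str, vec_index: dict[str, list[int]], k: int
) -> list[tuple[int, int]]:
    """Maximal exact read/vector matches from chained k-mer seeds.

    Seeds on the same diagonal are grouped and each group is extended to its
    maximal exact match; returns read-coordinate intervals.
    """
    diagonals: dict[int, list[int]] = {}
    for i in range(len(read_seq) - k + 1):
        kmer = read_seq[i : i + k]
        for j in vec_index.get(kmer, ()):
            diagonals.setdefault(i - j, []).append(i)
    segments: list[tuple[int, int]] = []
    n, m = len(read_seq), len(vec_seq)
    for diag, starts in diagonals.items():
        starts.sort()
        i = 0
        while i < len(starts):
            s = starts[i]
            e = s + k
            # absorb overlapping/contiguous seeds on this diagonal
            while i + 1 < len(starts) and starts[i + 1] <= e:
                e = starts[i + 1] + k
                i += 1
            # exact extension both directions
            while s > 0 and s - diag > 0 and read_seq[s - 1] == vec_seq[s - diag - 1]:
                s -= 1
            while e < n and e - diag < m and read_seq[e] == vec_seq[e - diag]:
                e += 1
            segments.append((s, e))
            i += 1
    return segments


def _chain_segments(
    segments: list[tuple[int, int]], max_mismatch_rate: float
) -> list[tuple[int, int]]:
    """Bridge nearby same-strand segments when the merged mismatch rate stays
    below ``max_mismatch_rate`` (gap bases counted as mismatches)."""
    if not segments:
        return []
    segments = sorted(set(segments))
    merged = [segments[0]]
    for s, e in segments[1:]:
        ps, pe = merged[-1]
        if s <= pe:
            merged[-1] = (ps, max(pe, e))
            continue
        gap = s - pe
        span = max(e, pe) - ps
        if span > 0 and gap / span <= max_mismatch_rate:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def mask_vector(
    read: QualityRead,
    vectors: list[tuple[str, str]],
    min_match: int = 20,
    max_mismatch_rate: float = 0.05,
    k: int = 12,
) -> QualityRead:
    """Mask read segments matching any vector sequence on either strand.

    ``vectors`` is a list of ``(id, sequence)`` records.  Matching is a
    cross_match-style stand-in: exact 12-mer seeds chained on their diagonal
    and extended without gaps; segments of length >= ``min_match`` whose
    mismatch rate is <= ``max_mismatch_rate`` are masked.  Returns the read
    with ``vector`` mask intervals added (no vectors -> no-op).
    """
    if not vectors:
        return read
    for vid, vseq in vectors:
        if 0 < len(vseq) < k:
            raise ValueError(
                f"vector {vid} shorter than seed size {k}: cannot mask"
            )
    new_masks = list(read.masks)
    seq = read.seq.upper()
    for _vid, vseq in vectors:
        vseq = vseq.upper()
        for strand_seq in (vseq, revcomp(vseq)):
            index = _kmer_positions(strand_seq, k)
            segments = _seed_segments(seq, strand_seq, index, k)
            for s, e in _chain_segments(segments, max_mismatch_rate):
                if e - s >= min_match:
                    new_masks.append((s, e, MASK_VECTOR))
    read.masks = _merge_intervals(new_masks)
    return read


# ---------------------------------------------------------------------------
# poly(A)/poly(T) boundary masking
# ---------------------------------------------------------------------------

def _terminal_tail(
    seq: str, letter: str, end: str, hits_required: int, window: int
) -> tuple[int, int] | None:
    """Maximal terminal region of windows holding >= hits_required ``letter``.

    ``end`` is '5p' or '3p'.  The chain of qualifying windows must be
    anchored at the read end (boundary rule: internal homopolymer runs are
    never masked).  The inner edge is trimmed back to the outermost base of
    ``letter`` so that a pure tail is recovered exactly.
    """
    n = len(seq)
    w = min(window, n)
    if w == 0:
        return None
    is_letter = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(letter)
    counts = np.convolve(is_letter, np.ones(w, dtype=np.int32), mode="valid")
    need = min(hits_required, w)
    ok = counts >= need
    if end == "3p":
        # windows anchored at the right end, walking left while qualifying
        i = len(ok) - 1
        if not ok[i]:
            return None
        while i > 0 and ok[i - 1]:
            i -= 1
        # inner boundary: the contiguous terminal run of the letter
        s, e = i, n
        run = s
        for q in range(s, e):
            if seq[q] != letter:
                run = q + 1
        return (run, e) if e > run else None
    else:
        i = 0
        if not ok[i]:
            return None
        while i < len(ok) - 1 and ok[i + 1]:
            i += 1
        s, e = 0, i + w
        run = e
        for q in range(e - 1, s - 1, -1):
            if seq[q] != letter:
                run = q
        return (s, run) if run > s else None


def mask_poly_tails(
    read: QualityRead, hits_required: int = 20, window: int = 25
) -> QualityRead:
    """Mask terminal poly(A)/poly(T) runs with an m-of-n sliding window.

    Scanning inward from each read end, every window of ``window`` bases
    containing at least ``hits_required`` A (or T) extends the tail region;
    the maximal such terminal region is masked (label ``polyA``/``polyT``).
    Both letters are searched at both ends, covering sense and antisense
    reads.  Internal runs flanked by non-tail sequence are left alone.
    """
    if hits_required > window:
        raise ValueError("hits_required cannot exceed window size")
    seq = read.seq.upper()
    new_masks = list(read.masks)
    for end in ("5p", "3p"):
        best: tuple[int, int, str] | None = None
        for letter, label in (("A", MASK_POLYA), ("T", MASK_POLYT)):
            tail = _terminal_tail(seq, letter, end, hits_required, window)
            if tail and (best is None or tail[1] - tail[0] > best[1] - best[0]):
                best = (tail[0], tail[1], label)
        if best:
            new_masks.append(best)
    read.masks = _merge_intervals(new_masks)
    return read


# ---------------------------------------------------------------------------
# disposition
# ---------------------------------------------------------------------------

KEPT = "kept"
TOO_SHORT = "too_short"
EMPTY_VECTOR = "empty_vector"


def finalize(read: QualityRead, min_len: int = 100) -> str:
    """Disposition of a clipped, masked read.

    ``kept`` iff the clipped region minus all masks is at least ``min_len``
    bases; ``empty_vector`` when vector masking alone leaves nothing inside
    the clip; ``too_short`` otherwise.
    """
    if read.clip is None:
        raise ValueError(f"read {read.id}: finalize before quality_clip")
    lo, hi = read.clip
    span = np.zeros(len(read.seq), dtype=bool)
    span[lo:hi] = True
    vector_free = span & ~read.masked_positions((MASK_VECTOR,))
    effective = span & ~read.masked_positions()
    if int(effective.sum()) >= min_len:
        return KEPT
    if int(vector_free.sum()) == 0 and hi > lo:
        return EMPTY_VECTOR
    return TOO_SHORT


@dataclass
class CleaningReport:
    """Summary of a cleaning run over a read collection."""

    n_input: int
    n_clean: int
    dispositions: pd.DataFrame  # columns: read_id, disposition, clip_start, clip_end, has_polya
    polya_fraction: float


def _trimmed_read(read: QualityRead) -> QualityRead:
    """Clip region with terminal masks removed and internal masks X'd out."""
    lo, hi = read.clip
    covered = read.masked_positions()
    while lo < hi and covered[lo]:
        lo += 1
    while hi > lo and covered[hi - 1]:
        hi -= 1
    seq = "".join(
        "X" if covered[i] else read.seq[i] for i in range(lo, hi)
    )
    return QualityRead(id=read.id, seq=seq, qual=read.qual[lo:hi].copy())


def clean_reads(
    reads: list[QualityRead],
    vectors: list[tuple[str, str]] | None = None,
    window: int = 20,
    threshold: float = 13.0,
    min_len: int = 100,
    polya_hits: int = 20,
    polya_window: int = 25,
    vector_min_match: int = 20,
    vector_max_mismatch_rate: float = 0.05,
) -> tuple[list[QualityRead], CleaningReport]:
    """Run the full cleaning pass: clip, mask, filter.

    Returns the kept reads (trimmed to the clipped, unmasked core; internal
    masked bases replaced by ``X``) and a :class:`CleaningReport`.
    """
    kept: list[QualityRead] = []
    rows = []
    n_polya = 0
    for read in reads:
        read = read.copy()
        read.clip = quality_clip(read, window=window, threshold=threshold)
        if vectors:
            mask_vector(
                read,
                vectors,
                min_match=vector_min_match,
                max_mismatch_rate=vector_max_mismatch_rate,
            )
        mask_poly_tails(read, hits_required=polya_hits, window=polya_window)
        disposition = finalize(read, min_len=min_len)
        has_polya = any(m[2] in (MASK_POLYA, MASK_POLYT) for m in read.masks)
        rows.append(
            {
                "read_id": read.id,
                "disposition": disposition,
                "clip_start": read.clip[0],
                "clip_end": read.clip[1],
                "has_polya": has_polya,
            }
        )
        if disposition == KEPT:
            if has_polya:
                n_polya += 1
            kept.append(_trimmed_read(read))
    report = CleaningReport(
        n_input=len(reads),
        n_clean=len(kept),
        dispositions=pd.DataFrame(
            rows,
            columns=["read_id", "disposition", "clip_start", "clip_end", "has_polya"],
        ),
        polya_fraction=n_polya / len(kept) if kept else float("nan"),
    )
    return kept, report
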