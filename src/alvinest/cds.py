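"""Coding-region determination on unigenes.

Two independent tracks, mirroring the study design:

* homology: the frame is taken from the best protein alignment (E <= 1e-05)
  and the matching region is extended in-frame in both directions — 3' to
  the first stop codon (included) or the sequence end, 5' to the first
  in-frame stop and then forward to the first ATG after that stop;
* ab initio: a codon-phased hexamer log-odds model (order-5 Markov,
  coding vs background) scored over all six frames, accepted above a score
  cutoff optimized on the with/without-homology score distributions.

Completeness requires a start codon, a stop codon and (for homology-derived
CDS) coverage of at least 80% of the best hit.  Frameshifts between hit
segments in different frames are masked with 'X' in the protein.

For hits on the reverse strand (negative frame) all coordinates — hit query
interval and resulting CDS interval — are expressed on the reverse
complement of the unigene sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .cleaning import revcomp

EVALUE_CUTOFF = 1e-5
STOPS = {"TAA", "TAG", "TGA"}

COMPLETE = "complete"
PARTIAL_5P = "partial_5p"
PARTIAL_3P = "partial_3p"
PARTIAL_BOTH = "partial_both"


@dataclass(frozen=True)
class HomologyHit:
    """A protein-homology alignment on a unigene (BLASTX-like best hit)."""

    query_id: str
    subject_id: str
    evalue: float
    query_interval: tuple[int, int]   # nt, half-open, on the stated strand
    subject_interval: tuple[int, int]  # residues, half-open
    frame: int                         # +1..+3 forward, -1..-3 reverse
    subject_length: int                # residues

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.frame == 0 or abs(self.frame) > 3:
            raise ValueError(f"invalid frame {self.frame}")


@dataclass
class CdsAnnotation:
    """A coding region on a unigene, with provenance and completeness."""

    unigene_id: str
    interval: tuple[int, int]  # nt, half-open, on the stated strand
    frame: int
    protein: str               # 'X' runs where frameshifts were masked
    completeness: str
    source: str                # "homology" | "ab_initio"
    coverage_of_best_hit: float = float("nan")
    secondary_evidence: str | None = None

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def oriented_seq(self, unigene_seq: str) -> str:
        """The unigene sequence on this annotation's strand."""
        return unigene_seq if self.frame > 0 else revcomp(unigene_seq)

    def regions(self, unigene_seq: str) -> tuple[str, str, str]:
        """(utr5, cds, utr3) tiling of the unigene on the CDS strand."""
        w = self.oriented_seq(unigene_seq)
        s, e = self.interval
        return w[:s], w[s:e], w[e:]


# ---------------------------------------------------------------------------
# homology track
# ---------------------------------------------------------------------------

def cds_from_homology(
    unigene_id: str, unigene_seq: str, best_hit: HomologyHit
) -> CdsAnnotation:
    """Extend the best-hit matching region to a CDS.

    3' extension runs in frame to (and including) the first stop codon or
    the sequence end; 5' extension runs back to the first in-frame stop,
    then forward to the first ATG after that stop.  Completeness follows the
    start+stop rule and the 80%-of-best-hit coverage rule.
    """
    if best_hit.evalue > EVALUE_CUTOFF:
        raise ValueError(
            f"hit E-value {best_hit.evalue} above cutoff {EVALUE_CUTOFF}"
        )
    w = unigene_seq.upper() if best_hit.frame > 0 else revcomp(unigene_seq.upper())
    f = abs(best_hit.frame) - 1
    hs, he = best_hit.query_interval
    if hs % 3 != f or (he - hs) % 3 != 0:
        raise ValueError(
            f"hit interval {best_hit.query_interval} inconsistent with "
            f"frame {best_hit.frame}"
        )
    n = len(w)
    # 3' extension: in frame from the hit end to the first stop (included)
    # or the last full codon before the sequence end
    stop_found = False
    pos = he
    end = he
    while pos + 3 <= n:
        codon = w[pos : pos + 3]
        pos += 3
        end = pos
        if codon in STOPS:
            stop_found = True
            break
    # 5' extension
    start_found = False
    start = hs
    pos = hs - 3
    stop5 = None
    while pos >= 0:
        if w[pos : pos + 3] in STOPS:
            stop5 = pos
            break
        pos -= 3
    if stop5 is not None:
        pos = stop5 + 3
        while pos + 3 <= min(end, n):
            if w[pos : pos + 3] == "ATG":
                start = pos
                start_found = True
                break
            pos += 3
        if not start_found:
            start = stop5 + 3
    else:
        start = f  # first in-frame position; 5'-partial
    cds_start, cds_end = start, end
    coverage = (
        (best_hit.subject_interval[1] - best_hit.subject_interval[0])
        / best_hit.subject_length
        if best_hit.subject_length
        else float("nan")
    )
    if start_found and stop_found:
        completeness = COMPLETE if coverage >= 0.8 else PARTIAL_BOTH
    elif start_found:
        completeness = PARTIAL_3P
    elif stop_found:
        completeness = PARTIAL_5P
    else:
        completeness = PARTIAL_BOTH
    coding = w[cds_start : cds_end - 3] if stop_found else w[cds_start:cds_end]
    protein = str(Seq(coding).translate())
    return CdsAnnotation(
        unigene_id=unigene_id,
        interval=(cds_start, cds_end),
        frame=best_hit.frame,
        protein=protein,
        completeness=completeness,
        source="homology",
        coverage_of_best_hit=coverage,
    )


def best_hit(hits: list[HomologyHit]) -> HomologyHit | None:
    """Best hit: lowest E-value, ties by alignment-length x 1 proxy (longer
    query interval wins), then subject id — deterministic."""
    usable = [h for h in hits if h.evalue <= EVALUE_CUTOFF]
    if not usable:
        return None
    return min(
        usable,
        key=lambda h: (
            h.evalue,
            -(h.query_interval[1] - h.query_interval[0]),
            h.subject_id,
        ),
    )


def mask_frameshift(unigene_seq: str, segments: list[HomologyHit]) -> str:
    """Protein translation across frameshifted hit segments.

    Segments (>= 2 local alignments to the same subject in different frames,
    same orientation) are translated in their own frames; the junction
    between adjacent segments in different frames is replaced by one 'X' per
    (started) codon of the intervening nucleotides, at least one.
    Overlapping same-frame segments are merged (no frameshift).
    """
    if not segments:
        raise ValueError("no segments")
    signs = {1 if s.frame > 0 else -1 for s in segments}
    if len(signs) > 1:
        raise ValueError("segments have inconsistent orientation")
    subjects = {s.subject_id for s in segments}
    if len(subjects) > 1:
        raise ValueError("segments hit different subjects")
    w = (
        unigene_seq.upper()
        if segments[0].frame > 0
        else revcomp(unigene_seq.upper())
    )
    segs = sorted(segments, key=lambda s: s.query_interval[0])
    # merge overlapping/adjacent same-frame segments
    merged: list[tuple[int, int, int]] = []
    for s in segs:
        a, b = s.query_interval
        if merged and s.frame == merged[-1][2] and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(b, merged[-1][1]), merged[-1][2])
        else:
            merged.append((a, b, s.frame))
    parts = []
    for idx, (a, b, frame) in enumerate(merged):
        f = abs(frame) - 1
        a += (f - a) % 3
        span = b - a - (b - a) % 3
        parts.append(str(Seq(w[a : a + span]).translate()))
        if idx + 1 < len(merged):
            na, _nb, nframe = merged[idx + 1]
            gap = max(0, na - b)
            if nframe != frame:
                # one X per full codon of the junction (the extra shifted
                # base belongs to no codon); at least one X marks the break
                parts.append("X" * max(1, gap // 3))
            # same frame with a gap: translate through the gap
            elif gap:
                parts.append(str(Seq(w[b : b + gap - gap % 3]).translate()))
    return "".join(parts)


# ---------------------------------------------------------------------------
# ab initio track: codon-phased hexamer log-odds model
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _hexamer_indices(seq: str, phase: int) -> np.ndarray:
    """Indices (0..4095) of hexamers starting at phase, phase+3, ...; -1
    where the window contains a non-ACGT base."""
    codes = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = len(codes)
    starts = np.arange(phase, n - 5, 3)
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64)
    win = codes[starts[:, None] + np.arange(6)[None, :]]
    bad = (win < 0).any(axis=1)
    idx = (win.clip(0) * (4 ** np.arange(5, -1, -1))).sum(axis=1)
    idx[bad] = -1
    return idx


@dataclass
class CodingModel:
    """Hexamer log-odds table (coding vs background), order-5 Markov."""

    log_odds: np.ndarray                 # shape (4096,)
    coding_counts: np.ndarray = field(repr=False, default=None)
    background_counts: np.ndarray = field(repr=False, default=None)
    trained_on: str = ""

    @classmethod
    def train(
        cls,
        coding_seqs: list[str],
        background_seqs: list[str],
        pseudocount: float = 1.0,
        trained_on: str = "",
    ) -> "CodingModel":
        def counts(seqs):
            c = np.zeros(4096, dtype=np.float64)
            for s in seqs:
                idx = _hexamer_indices(s, 0)
                idx = idx[idx >= 0]
                np.add.at(c, idx, 1)
            return c

        cc = counts(coding_seqs)
        bc = counts(background_seqs)
        lp_c = np.log(cc + pseudocount) - np.log(cc.sum() + 4096 * pseudocount)
        lp_b = np.log(bc + pseudocount) - np.log(bc.sum() + 4096 * pseudocount)
        return cls(
            log_odds=lp_c - lp_b,
            coding_counts=cc,
            background_counts=bc,
            trained_on=trained_on,
        )

    def _conditional(self, which: str) -> np.ndarray:
        counts = (
            self.coding_counts if which == "coding" else self.background_counts
        )
        table = (counts + 1.0).reshape(1024, 4)
        return table / table.sum(axis=1, keepdims=True)

    def sample(
        self, length: int, rng: np.random.Generator, which: str = "coding"
    ) -> str:
        """Sample a sequence from the order-5 Markov chain of this model."""
        cond = self._conditional(which)
        counts = (
            self.coding_counts if which == "coding" else self.background_counts
        )
        marg = (counts + 1.0).reshape(1024, 4).sum(axis=1)
        marg = marg / marg.sum()
        prefix = int(rng.choice(1024, p=marg))
        out = []
        state = prefix
        for i in range(5):
            out.append((prefix >> (2 * (4 - i))) & 3)
        for _ in range(length - 5):
            b = int(rng.choice(4, p=cond[state]))
            out.append(b)
            state = ((state << 2) | b) & 0x3FF
        return "".join("ACGT"[b] for b in out[:length])


def frame_scores(seq: str, model: CodingModel) -> dict[int, float]:
    """Summed hexamer log-odds for each of the six frames.

    Frames +1..+3 read the forward sequence at phases 0..2; frames -1..-3
    read the reverse complement likewise.
    """
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer: score undefined")
    scores: dict[int, float] = {}
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for phase in range(3):
            idx = _hexamer_indices(s, phase)
            idx = idx[idx >= 0]
            scores[strand * (phase + 1)] = float(model.log_odds[idx].sum())
    return scores


def coding_score(seq: str, model: CodingModel) -> tuple[float, int]:
    """Best-of-six-frames coding score and the winning frame."""
    scores = frame_scores(seq, model)
    frame = max(sorted(scores), key=lambda f: scores[f])
    return scores[frame], frame


# ---------------------------------------------------------------------------
# score-cutoff optimization
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    cutoff: float
    sensitivity: float
    specificity: float
    table: pd.DataFrame  # cutoff, sensitivity, specificity, youden_j


def optimize_cutoff(scores, labels) -> RocResult:
    """Cutoff maximizing Youden's J on has-homology labels.

    sensitivity(c) = fraction of labelled-coding with score >= c;
    specificity(c) = fraction of labelled-noncoding with score < c.
    Returns the full table so any operating point can be read off.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both label classes are required")
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    cutoffs = np.unique(scores)
    sens = 1.0 - np.searchsorted(pos, cutoffs, side="left") / len(pos)
    spec = np.searchsorted(neg, cutoffs, side="left") / len(neg)
    j = sens + spec - 1.0
    table = pd.DataFrame(
        {"cutoff": cutoffs, "sensitivity": sens, "specificity": spec, "youden_j": j}
    )
    k = int(np.argmax(j))  # first maximum -> lowest such cutoff
    return RocResult(
        cutoff=float(cutoffs[k]),
        sensitivity=float(sens[k]),
        specificity=float(spec[k]),
        table=table,
    )


# ---------------------------------------------------------------------------
# ab initio annotation + reconciliation
# ---------------------------------------------------------------------------

def cds_ab_initio(
    unigene_id: str, unigene_seq: str, model: CodingModel, cutoff: float
) -> CdsAnnotation | None:
    """ORF in the best-scoring frame, accepted only at or above ``cutoff``.

    The ORF is the longest stop-bounded open stretch in the winning frame;
    the start is the first ATG inside it when present.
    """
    score, frame = coding_score(unigene_seq, model)
    if score < cutoff:
        return None
    w = unigene_seq.upper() if frame > 0 else revcomp(unigene_seq.upper())
    f = abs(frame) - 1
    codon_starts = range(f, len(w) - 2, 3)
    best_iv: tuple[int, int, bool] | None = None
    open_start = f
    prev_end = f
    for p in list(codon_starts) + [None]:
        at_end = p is None
        if at_end or w[p : p + 3] in STOPS:
            end = (p + 3) if not at_end else prev_end
            if best_iv is None or end - open_start > best_iv[1] - best_iv[0]:
                best_iv = (open_start, end, not at_end)
            open_start = p + 3 if not at_end else open_start
        if p is not None:
            prev_end = p + 3
    s, e, stop_found = best_iv
    # prefer an ATG start inside the ORF
    start_found = False
    p = s
    while p + 3 <= e:
        if w[p : p + 3] == "ATG":
            s, start_found = p, True
            break
        p += 3
    if e - s < 6:
        return None
    coding = w[s : e - 3] if stop_found else w[s:e]
    if start_found and stop_found:
        completeness = COMPLETE
    elif start_found:
        completeness = PARTIAL_3P
    elif stop_found:
        completeness = PARTIAL_5P
    else:
        completeness = PARTIAL_BOTH
    return CdsAnnotation(
        unigene_id=unigene_id,
        interval=(s, e),
        frame=frame,
        protein=str(Seq(coding).translate()),
        completeness=completeness,
        source="ab_initio",
    )


def reconcile(
    homology_cds: CdsAnnotation | None,
    ab_initio_cds: CdsAnnotation | None,
    ab_initio_score: float | None = None,
    cutoff: float | None = None,
) -> CdsAnnotation | None:
    """Combine the two tracks: homology wins when present; the ab initio
    call is accepted alone only when its score reaches the cutoff."""
    if homology_cds is not None:
        if ab_initio_cds is not None:
            homology_cds.secondary_evidence = "ab_initio"
        return homology_cds
    if ab_initio_cds is None:
        return None
    if cutoff is not None and ab_initio_score is not None:
        if ab_initio_score < cutoff:
            return None
    return ab_initio_cds
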