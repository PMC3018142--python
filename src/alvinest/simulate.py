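"""Synthetic data with planted ground truth for the whole EST pipeline.

The generators emulate the statistical structure the analysis assumes:

* transcripts with distinct CDS/UTR GC composition and an expression-
  dependent GC3 that saturates with copy number,
* Sanger-style reads (~674 bp) with logistic quality decay at the ends,
  optional vector contamination and 3' poly(A) tails at library-dependent
  rates, and substitution errors,
* a planted-partition interactome with scored edges,
* taxon-labelled homology-hit profiles for specificity classification,
* equal-length ortholog families for amino-acid composition and identity
  statistics.

Every generator takes an integer seed and is byte-deterministic; every
emitted read/edge/hit is accounted for exactly once in the returned truth
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cleaning import QualityRead, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gc3ExpressionModel:
    """Saturating GC3-vs-expression curve: gc3(c) = plateau - (plateau - base) * c**(-k).

    ``base`` is the GC3 of a single-copy gene, ``plateau`` the asymptote
    reached by highly expressed genes, ``k`` the saturation rate.  Defaults
    follow the observed annelid ribosomal-protein behaviour: GC3 rising from
    ~0.42 to an asymptote near 0.55, most of the rise complete by ~25-30
    copies.
    """

    base: float = 0.42
    plateau: float = 0.55
    k: float = 0.85

    def __call__(self, copy_number) -> np.ndarray:
        c = np.asarray(copy_number, dtype=float)
        return self.plateau - (self.plateau - self.base) * c ** (-self.k)


@dataclass
class TranscriptModel:
    """A reference mRNA with known CDS/UTR structure and expression level."""

    id: str
    cds_seq: str
    utr5_seq: str
    utr3_seq: str
    copy_number: int
    gc3_target: float
    taxon_profile_id: str

    @property
    def mrna(self) -> str:
        return self.utr5_seq + self.cds_seq + self.utr3_seq

    @property
    def cds_interval(self) -> tuple[int, int]:
        """CDS coordinates on the mRNA (0-based half-open)."""
        start = len(self.utr5_seq)
        return (start, start + len(self.cds_seq))


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)]) if n else ""


def _cds_with_gc3(rng: np.random.Generator, n_codons: int, gc3: float, gc12: float = 0.40) -> str:
    """ATG + internal codons + stop, with exact third-position GC count.

    Third-position G/C is assigned to exactly ``round(gc3 * (n_codons - 1))``
    of the non-stop codons (ATG's G included), so the realized GC3 equals
    the target up to rounding.  In-frame stops are avoided by resampling the
    first two codon positions.
    """
    if n_codons < 3:
        raise ValueError("CDS needs at least start + 1 codon + stop")
    n_internal = n_codons - 2
    n_nonstop = n_internal + 1  # internal codons + ATG
    n_gc = int(round(gc3 * n_nonstop))
    n_gc_internal = min(max(n_gc - 1, 0), n_internal)  # ATG contributes one G
    third_gc = np.zeros(n_internal, dtype=bool)
    third_gc[rng.permutation(n_internal)[:n_gc_internal]] = True
    codons = ["ATG"]
    p12 = np.array([(1 - gc12) / 2, gc12 / 2, gc12 / 2, (1 - gc12) / 2])
    for i in range(n_internal):
        third = "GC"[rng.integers(2)] if third_gc[i] else "AT"[rng.integers(2)]
        while True:
            b1, b2 = _BASES[rng.choice(4, size=2, p=p12)]
            codon = b1 + b2 + third
            if codon not in STOP_CODONS:
                break
        codons.append(codon)
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def generate_transcriptome(
    n_genes: int,
    gc3_model: Gc3ExpressionModel = Gc3ExpressionModel(),
    seed: int = 0,
    noise_sd: float = 0.02,
    copy_range: tuple[int, int] = (1, 200),
    cds_codon_range: tuple[int, int] = (80, 400),
    utr5_len_range: tuple[int, int] = (40, 200),
    utr3_len_range: tuple[int, int] = (80, 300),
    utr5_gc: float = 0.457,
    utr3_gc: float = 0.397,
    copy_numbers: Sequence[int] | None = None,
    n_taxon_profiles: int = 8,
) -> list[TranscriptModel]:
    """Generate transcripts whose GC3 follows the saturating expression model.

    Copy numbers are drawn log-uniformly over ``copy_range`` (both endpoints
    forced to occur when n_genes >= 2) unless given explicitly; each gene's
    GC3 target is the model value at its copy number plus Gaussian noise of
    sd ``noise_sd``, and the realized CDS GC3 equals the target up to
    rounding.  UTR GC contents default to the observed 5'/3' means (45.7% /
    39.7%).
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    rng = np.random.default_rng(seed)
    cmin, cmax = copy_range
    if copy_numbers is not None:
        copies = np.asarray(copy_numbers, dtype=int)
        if len(copies) != n_genes:
            raise ValueError("copy_numbers length must equal n_genes")
    else:
        copies = np.exp(
            rng.uniform(math.log(cmin), math.log(cmax), size=n_genes)
        ).round().astype(int)
        copies = np.clip(copies, cmin, cmax)
        if n_genes >= 2:
            copies[0], copies[1] = cmin, cmax
    targets = gc3_model(copies)
    if noise_sd > 0:
        targets = targets + rng.normal(0.0, noise_sd, size=n_genes)
    targets = np.clip(targets, 0.05, 0.95)
    transcripts = []
    for i in range(n_genes):
        n_codons = int(rng.integers(cds_codon_range[0], cds_codon_range[1] + 1))
        cds = _cds_with_gc3(rng, n_codons, float(targets[i]))
        utr5 = _random_dna(rng, int(rng.integers(*utr5_len_range)), utr5_gc)
        # an in-frame stop directly upstream of the start codon, so the
        # homology-extension rule can identify the true initiation site
        utr5 = utr5[:-3] + STOP_CODONS[rng.integers(3)]
        utr3 = _random_dna(rng, int(rng.integers(*utr3_len_range)), utr3_gc)
        transcripts.append(
            TranscriptModel(
                id=f"t{i:05d}",
                cds_seq=cds,
                utr5_seq=utr5,
                utr3_seq=utr3,
                copy_number=int(copies[i]),
                gc3_target=float(targets[i]),
                taxon_profile_id=f"scenario{i % n_taxon_profiles:02d}",
            )
        )
    return transcripts


def realized_gc3(cds_seq: str) -> float:
    """GC fraction at third codon positions, stop codon excluded."""
    thirds = cds_seq[2:-3:3]
    counted = [b for b in thirds if b in "ACGT"]
    if not counted:
        return float("nan")
    return sum(b in "GC" for b in counted) / len(counted)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def default_quality_profile(positions: np.ndarray, length: int) -> np.ndarray:
    """Logistic decay from phred ~45 mid-read to ~8 in the last ~30 bases of
    each end, emulating Sanger trace quality."""
    d5 = positions
    d3 = length - 1 - positions
    f = lambda d: 1.0 / (1.0 + np.exp(-(d - 15.0) / 4.0))
    return 8.0 + 37.0 * np.minimum(f(d5), f(d3))


def make_default_vector(length: int = 600, seed: int = 905) -> str:
    """A fixed synthetic cloning-vector sequence (deterministic)."""
    return _random_dna(np.random.default_rng(seed), length, 0.5)


@dataclass
class ReadSimParams:
    """Parameters of the Sanger-style read simulator."""

    mean_read_len: float = 674.0
    len_sd: float = 80.0
    error_rate: float = 0.005
    quality_profile: Callable[[np.ndarray, int], np.ndarray] = default_quality_profile
    vector_seq: str = field(default_factory=make_default_vector)
    vector_rate: float = 0.0
    polya_rate: float = 0.15
    polya_len_range: tuple[int, int] = (20, 60)
    reads_per_copy: int = 1
    empty_vector_rate: float = 0.0
    qual_noise_sd: float = 2.0
    min_read_len: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "vector_rate", "polya_rate", "empty_vector_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.vector_rate > 0 and len(self.vector_seq) < 12:
            raise ValueError("vector_seq shorter than 12 nt with vector_rate > 0")


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        if arr[i] not in "ACGT":
            continue
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def generate_reads(
    transcripts: Sequence[TranscriptModel], params: ReadSimParams
) -> tuple[list[QualityRead], pd.DataFrame]:
    """Simulate reads from transcripts; returns (reads, truth table).

    Reads per transcript = copy_number * reads_per_copy.  A fraction
    ``polya_rate`` of reads is anchored at the mRNA 3' end and carries a
    poly(A) tail; a fraction ``vector_rate`` carries vector sequence at the
    5' and/or 3' end (5'-end fragments are vector suffixes and 3'-end
    fragments vector prefixes, so the planted span is the maximal exact
    match).  Truth intervals for tails are extended over the transcript's
    own trailing adenines; the truth table is exact.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    rng = np.random.default_rng(params.seed)
    vec = params.vector_seq.upper()
    reads: list[QualityRead] = []
    rows: list[dict] = []

    def _finish(read_id, seq, tid, mstart, mend, pa, vecs, empty):
        seq = _apply_errors(rng, seq, params.error_rate)
        n = len(seq)
        q = params.quality_profile(np.arange(n), n)
        if params.qual_noise_sd > 0:
            q = q + rng.normal(0.0, params.qual_noise_sd, size=n)
        qual = np.clip(np.rint(q), 2, 60).astype(np.int16)
        reads.append(QualityRead(id=read_id, seq=seq, qual=qual))
        rows.append(
            {
                "read_id": read_id,
                "transcript_id": tid,
                "mrna_start": mstart,
                "mrna_end": mend,
                "polya_start": pa[0] if pa else -1,
                "polya_end": pa[1] if pa else -1,
                "vector_intervals": ";".join(f"{s}-{e}" for s, e in vecs),
                "empty_vector": empty,
            }
        )

    for t in transcripts:
        mrna = t.mrna
        n_reads = t.copy_number * params.reads_per_copy
        for j in range(n_reads):
            rid = f"{t.id}_r{j:04d}"
            total_len = int(
                np.clip(
                    rng.normal(params.mean_read_len, params.len_sd),
                    params.min_read_len,
                    max(params.min_read_len, len(mrna) + params.polya_len_range[1]),
                )
            )
            has_polya = rng.random() < params.polya_rate
            if has_polya:
                tail_len = int(rng.integers(*params.polya_len_range))
                insert_len = max(40, min(total_len - tail_len, len(mrna)))
                start = len(mrna) - insert_len
                core = mrna[start:] + "A" * tail_len
                pa_start = insert_len
                # truth span includes the transcript's own trailing A's
                while pa_start > 0 and core[pa_start - 1] == "A":
                    pa_start -= 1
                polya = (pa_start, len(core))
                mstart, mend = start, len(mrna)
            else:
                insert_len = min(total_len, len(mrna))
                start = int(rng.integers(0, len(mrna) - insert_len + 1))
                core = mrna[start : start + insert_len]
                polya = None
                mstart, mend = start, start + insert_len
            vec_ivs: list[tuple[int, int]] = []
            if params.vector_rate > 0 and rng.random() < params.vector_rate:
                which = rng.random()
                at5 = which < 0.45 or which >= 0.9
                at3 = which >= 0.45
                if has_polya:
                    # vector after the tail would bury the tail internally;
                    # contaminated poly(A) reads carry 5' vector only
                    at5, at3 = True, False
                if at5:
                    lv = int(rng.integers(20, 61))
                    core = vec[-lv:] + core
                    vec_ivs.append((0, lv))
                    if polya:
                        polya = (polya[0] + lv, polya[1] + lv)
                    mstart_off = lv
                else:
                    mstart_off = 0
                if at3:
                    lv = int(rng.integers(20, 61))
                    vec_ivs.append((len(core), len(core) + lv))
                    core = core + vec[:lv]
            _finish(rid, core, t.id, mstart, mend, polya, vec_ivs, False)

    if params.empty_vector_rate > 0:
        n_empty = int(round(params.empty_vector_rate * len(reads)))
        for j in range(n_empty):
            ln = int(
                np.clip(rng.normal(params.mean_read_len, params.len_sd), 60, len(vec))
            )
            start = int(rng.integers(0, len(vec) - ln + 1))
            _finish(
                f"empty_r{j:04d}", vec[start : start + ln], "", -1, -1, None,
                [(0, ln)], True,
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "transcript_id", "mrna_start", "mrna_end",
            "polya_start", "polya_end", "vector_intervals", "empty_vector",
        ],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# planted-partition interactome
# ---------------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """An undirected scored graph with known module structure."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    module_assignment: dict[str, int]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["node_a", "node_b", "combined_score"])


def generate_ppi(
    n_modules: int,
    module_size: int,
    p_in: float,
    p_out: float,
    intra_score_range: tuple[float, float] = (0.9, 1.0),
    inter_score_range: tuple[float, float] = (0.5, 0.95),
    seed: int = 0,
) -> PlantedNetwork:
    """Planted-partition graph: intra-module edges with probability ``p_in``,
    inter-module with ``p_out``.

    Combined scores emulate evidence-integrated interaction confidence:
    intra-module (true) edges draw from ``intra_score_range``, inter-module
    (spurious) edges from the lower ``inter_score_range``, so a stringent
    score cutoff prunes most — not all — of the noise.
    """
    if n_modules < 1 or module_size < 1:
        raise ValueError("n_modules and module_size must be >= 1")
    if not p_in > p_out:
        raise ValueError(
            f"p_in ({p_in}) must exceed p_out ({p_out}): modules not recoverable"
        )
    rng = np.random.default_rng(seed)
    nodes = [
        f"m{m:02d}n{i:03d}" for m in range(n_modules) for i in range(module_size)
    ]
    module = {
        node: m for m in range(n_modules) for node in
        nodes[m * module_size : (m + 1) * module_size]
    }
    edges = []
    for a_idx in range(len(nodes)):
        for b_idx in range(a_idx + 1, len(nodes)):
            a, b = nodes[a_idx], nodes[b_idx]
            intra = module[a] == module[b]
            if rng.random() < (p_in if intra else p_out):
                rng_range = intra_score_range if intra else inter_score_range
                edges.append((a, b, round(float(rng.uniform(*rng_range)), 6)))
    return PlantedNetwork(nodes=nodes, edges=edges, module_assignment=module)


# ---------------------------------------------------------------------------
# homology-hit profiles
# ---------------------------------------------------------------------------

def generate_hit_profiles(
    proteins: Sequence[str],
    scenario_table: Mapping[str, Iterable[str]],
    evalue_log10_range: tuple[float, float] = (-50.0, -5.0),
    max_hits_per_taxon: int = 3,
    seed: int = 0,
):
    """Hit profiles realizing a protein -> taxa scenario exactly.

    Every requested (protein, taxon) pair yields 1..max_hits_per_taxon hits
    with E-value <= 1e-05; no hits outside the scenario.  Taxa are checked
    against the controlled vocabulary.
    """
    from .taxonomy import TAXON_VOCABULARY, HitProfile

    vocab = set(TAXON_VOCABULARY)
    rng = np.random.default_rng(seed)
    profiles = []
    for pid in proteins:
        taxa = sorted(scenario_table.get(pid, ()))
        hits = []
        for taxon in taxa:
            if taxon not in vocab:
                raise ValueError(f"unknown taxon label: {taxon!r}")
            for h in range(int(rng.integers(1, max_hits_per_taxon + 1))):
                expo = rng.uniform(*evalue_log10_range)
                hits.append(
                    (f"{taxon.replace(' ', '_')}_subj{h}", taxon, float(10 ** expo))
                )
        profiles.append(HitProfile(query_id=pid, hits=hits))
    return profiles


def write_scenario_table(
    scenario_table: Mapping[str, Iterable[str]], path
) -> None:
    """Write a protein -> taxa scenario mapping as YAML."""
    import yaml

    data = {pid: sorted(taxa) for pid, taxa in sorted(scenario_table.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_scenario_table(path) -> dict[str, list[str]]:
    """Read a protein -> taxa scenario mapping from YAML."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return {pid: list(taxa or []) for pid, taxa in data.items()}


# ---------------------------------------------------------------------------
# ortholog families (composition / identity inputs)
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# roughly uniform-ish background with realistic rank order
_AA_BG = np.array(
    [0.08, 0.02, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05, 0.06, 0.09,
     0.02, 0.04, 0.05, 0.04, 0.05, 0.07, 0.06, 0.07, 0.01, 0.03]
)
_AA_BG = _AA_BG / _AA_BG.sum()


def generate_ortholog_families(
    taxa: Sequence[str],
    n_families: int = 60,
    mean_len: int = 150,
    divergence: Mapping[str, float] | None = None,
    charged_bias: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[dict[str, str]]:
    """Equal-length (pre-aligned, gap-free) ortholog families.

    Each family derives from a common ancestor protein; each taxon's member
    carries substitutions at its ``divergence`` rate.  ``charged_bias``
    multiplies the substitution weight of D/E/K/R for that taxon, emulating
    a charge-enriched proteome.
    """
    rng = np.random.default_rng(seed)
    divergence = dict(divergence or {})
    charged_idx = np.isin(_AA, list("DEKR"))
    families = []
    for f in range(n_families):
        n = int(rng.integers(int(mean_len * 0.6), int(mean_len * 1.4)))
        ancestor = _AA[rng.choice(20, size=n, p=_AA_BG)]
        fam = {}
        for taxon in taxa:
            rate = divergence.get(taxon, 0.15)
            p = _AA_BG.copy()
            bias = (charged_bias or {}).get(taxon, 1.0)
            p[charged_idx] *= bias
            p = p / p.sum()
            seq = ancestor.copy()
            hit = rng.random(n) < rate
            seq[hit] = _AA[rng.choice(20, size=int(hit.sum()), p=p)]
            fam[taxon] = "".join(seq)
        families.append(fam)
    return families


# ---------------------------------------------------------------------------
# planting homology hits on assembled unigenes
# ---------------------------------------------------------------------------

def plant_hits_on_unigenes(
    unigenes,
    transcripts: Sequence[TranscriptModel],
    read_to_transcript: Mapping[str, str],
    margin_codons: int = 10,
    k: int = 21,
):
    """Simulated protein-homology hits for assembled unigenes.

    For each unigene the source transcript is taken by member majority; the
    transcript mRNA is located on the consensus by k-mer diagonal voting
    (either strand) and the known CDS is projected onto the consensus.  The
    emitted hit covers the projected CDS interior, shrunk by
    ``margin_codons`` codons on each side, in the correct frame — emulating
    a best protein alignment that does not reach the CDS boundaries.

    Returns (hits, truth) where hits is a list of
    :class:`alvinest.cds.HomologyHit` and truth maps unigene id to the
    projected true CDS interval/strand (only unigenes whose consensus
    contains the full CDS are listed).
    """
    from collections import Counter

    from .cds import HomologyHit

    tx = {t.id: t for t in transcripts}
    hits = []
    truth: dict[str, dict] = {}
    for u in unigenes:
        members = [m[0] for m in u.members]
        src_counts = Counter(
            read_to_transcript[r] for r in members if r in read_to_transcript
        )
        if not src_counts:
            continue
        tid = src_counts.most_common(1)[0][0]
        if tid not in tx:
            continue
        t = tx[tid]
        mrna = t.mrna
        cons = u.consensus
        offset_strand = _locate(mrna, cons, k)
        if offset_strand is None:
            continue
        offset, strand = offset_strand
        # w is the consensus on the hit's stated strand; it aligns to the
        # mRNA starting at `offset`, so CDS coordinates project directly.
        w_len = len(cons)
        cs, ce = t.cds_interval
        ps, pe = cs - offset, ce - offset
        full = 0 <= ps and pe <= w_len
        hs = ps + 3 * margin_codons
        he = pe - 3 * (margin_codons + 1)  # stay clear of the stop codon
        if he - hs < 60 or hs < 0 or he > w_len:
            continue  # hit must lie inside the consensus
        frame = (hs % 3 + 1) if strand == "+" else -(hs % 3 + 1)
        n_res = len(t.cds_seq) // 3 - 1  # residues, stop excluded
        sub_start = (hs - ps) // 3
        sub_end = sub_start + (he - hs) // 3
        hits.append(
            HomologyHit(
                query_id=u.id,
                subject_id=f"prot_{tid}",
                evalue=1e-30,
                query_interval=(hs, he),
                subject_interval=(sub_start, sub_end),
                frame=frame,
                subject_length=n_res,
            )
        )
        if full:
            truth[u.id] = {
                "transcript_id": tid,
                "cds_interval": (ps, pe),
                "strand": strand,
            }
    return hits, truth


def _locate(mrna: str, cons: str, k: int) -> tuple[int, str] | None:
    """Offset of ``cons`` on ``mrna`` (majority k-mer diagonal), either strand."""
    from collections import Counter

    index: dict[str, list[int]] = {}
    for i in range(0, len(mrna) - k + 1, 3):
        index.setdefault(mrna[i : i + k], []).append(i)
    for strand, seq in (("+", cons), ("-", revcomp(cons))):
        votes: Counter = Counter()
        for j in range(len(seq) - k + 1):
            for i in index.get(seq[j : j + k], ()):
                votes[i - j] += 1
        if votes:
            offset, n = votes.most_common(1)[0]
            if n >= 3:
                return offset, strand
    return None
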