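"""Sequence-composition statistics.

Covers the study's compositional analyses: GC content by mRNA region and at
third codon positions (GC3), per-gene codon usage with RSCU, correspondence
analysis of the gene x codon table with optimal-codon detection at the
first-axis extremes, regression of GC3 against expression (linear, power,
exponential, logarithmic and saturating forms), amino-acid composition and
charge/hydrophobicity profiles across taxa with chi-square / G homogeneity
tests, and mean percent identity over gapless alignment columns of
concatenated ortholog families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cds import STOPS

# ---------------------------------------------------------------------------
# GC by region
# ---------------------------------------------------------------------------


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N and other letters excluded entirely; NaN if no
    counted bases."""
    seq = seq.upper()
    counted = sum(seq.count(b) for b in "ACGT")
    if counted == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / counted


def gc3(cds_seq: str) -> float:
    """GC fraction at third codon positions, stop codon excluded."""
    cds_seq = cds_seq.upper()
    thirds = cds_seq[2::3]
    if len(cds_seq) >= 3 and cds_seq[-3:] in STOPS:
        thirds = thirds[:-1]
    return gc_fraction(thirds)


@dataclass
class RegionGC:
    unigene_id: str
    gc_cds: float
    gc3: float
    gc_utr5: float
    gc_utr3: float
    copy_number: int


def region_gc(
    unigene_id: str,
    utr5: str,
    cds: str,
    utr3: str,
    copy_number: int = 1,
    polya_trimmed: bool = True,
) -> RegionGC:
    """Per-region GC for one annotated unigene.

    The 3' UTR is expected with the poly(A) tail already masked/removed;
    when ``polya_trimmed`` is False a terminal adenine run of 10+ bases is
    stripped here.
    """
    if not polya_trimmed:
        utr3 = utr3.rstrip("aA") if len(utr3) - len(utr3.rstrip("aA")) >= 10 else utr3
    return RegionGC(
        unigene_id=unigene_id,
        gc_cds=gc_fraction(cds),
        gc3=gc3(cds),
        gc_utr5=gc_fraction(utr5),
        gc_utr3=gc_fraction(utr3),
        copy_number=copy_number,
    )


# ---------------------------------------------------------------------------
# codon usage / RSCU
# ---------------------------------------------------------------------------

from Bio.Data.CodonTable import standard_dna_table

ALL_CODONS = ["".join(c) for c in product("TCAG", repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOPS]
_AA_OF = dict(standard_dna_table.forward_table)
_SYN_FAMILY: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _SYN_FAMILY.setdefault(_AA_OF[_c], []).append(_c)


def codon_counts(cds_seq: str) -> pd.Series:
    """Counts of all 64 codons in a frame-0 CDS; codons containing X/N are
    skipped (frameshift-masked segments)."""
    cds_seq = cds_seq.upper()
    counts = dict.fromkeys(ALL_CODONS, 0)
    for i in range(0, len(cds_seq) - len(cds_seq) % 3, 3):
        codon = cds_seq[i : i + 3]
        if codon in counts:
            counts[codon] += 1
    return pd.Series(counts, dtype=int)


def rscu(counts: pd.Series) -> pd.Series:
    """Relative synonymous codon usage: observed / expected under uniform
    synonymous usage.  NA for codons of unexpressed amino acids; stop codons
    NA (tallied separately)."""
    out = pd.Series(np.nan, index=ALL_CODONS)
    for aa, family in _SYN_FAMILY.items():
        total = counts[family].sum()
        if total > 0:
            out[family] = counts[family] * len(family) / total
    return out


def codon_usage(cds_by_gene: dict[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene and pooled codon usage.

    Returns (per_gene, pooled): per_gene has one row per gene with 64 count
    columns; pooled is a one-row frame of summed counts with RSCU attached
    as a second row labelled 'rscu'.
    """
    per_gene = pd.DataFrame(
        {gid: codon_counts(seq) for gid, seq in cds_by_gene.items()}
    ).T
    per_gene.index.name = "gene"
    pooled_counts = per_gene.sum(axis=0)
    pooled = pd.DataFrame(
        {"count": pooled_counts, "rscu": rscu(pooled_counts)}
    )
    return per_gene, pooled


def most_frequent_codons(pooled_counts: pd.Series) -> pd.Series:
    """The most used codon per amino acid (ties alphabetical)."""
    return pd.Series(
        {
            aa: min(
                fam, key=lambda c: (-pooled_counts[c], c)
            )
            for aa, fam in sorted(_SYN_FAMILY.items())
        }
    )


# ---------------------------------------------------------------------------
# correspondence analysis
# ---------------------------------------------------------------------------

@dataclass
class CoaResult:
    row_coords: pd.DataFrame     # genes x axes (principal coordinates)
    col_coords: pd.DataFrame     # codons x axes
    inertia: np.ndarray          # fraction of total inertia per axis
    total_inertia: float


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int | None = None) -> CoaResult:
    """Standard CA of a non-negative contingency table.

    The standardized (Pearson) residuals of the relative-frequency matrix
    are decomposed by SVD; axes are ordered by inertia and the sign of each
    axis is fixed by making its largest-magnitude column loading positive.
    All-zero rows/columns must be filtered out beforehand.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    total = X.sum()
    if total == 0:
        raise ValueError("rank-0 matrix: nothing to decompose")
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise ValueError("all-zero rows/columns must be removed first")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    rank = min(X.shape) - 1
    if n_axes is None:
        n_axes = rank
    n_axes = max(1, min(n_axes, max(rank, 1)))
    U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes]
    # sign convention: largest-|loading| column coordinate positive
    col_std = Vt.T / np.sqrt(c)[:, None]
    for a in range(n_axes):
        pivot = int(np.argmax(np.abs(col_std[:, a])))
        if col_std[pivot, a] < 0:
            U[:, a] *= -1
            Vt[a] *= -1
            col_std[:, a] *= -1
    row_coords = (U / np.sqrt(r)[:, None]) * sv[None, :]
    col_coords = col_std * sv[None, :]
    eig = sv**2
    total_inertia = float((S**2).sum())
    axes = [f"axis{a + 1}" for a in range(n_axes)]
    return CoaResult(
        row_coords=pd.DataFrame(row_coords, index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=matrix.columns, columns=axes),
        inertia=eig / total_inertia if total_inertia > 0 else eig,
        total_inertia=total_inertia,
    )


@dataclass
class OptimalCodonReport:
    low_pole_codons: list[str]
    high_pole_codons: list[str]
    low_expression_pole: str       # "negative" | "positive"
    rho: float
    p_value: float


def optimal_codons(
    coa: CoaResult, expression: pd.Series, tail_fraction: float = 0.1
) -> OptimalCodonReport:
    """Codon sets at the axis-1 extremes plus the expression association.

    The rank correlation between gene axis-1 coordinates and expression
    orients the axis: the pole where low-expression genes sit is reported,
    with ``floor(tail_fraction * n_codons)`` codons taken at each extreme.
    """
    coords = coa.col_coords["axis1"]
    genes = coa.row_coords["axis1"]
    expr = expression.reindex(genes.index)
    rho, p = stats.spearmanr(genes.to_numpy(), expr.to_numpy())
    n_tail = int(np.floor(tail_fraction * len(coords)))
    order = coords.sort_values(kind="mergesort")
    low = list(order.index[:n_tail]) if n_tail else []
    high = list(order.index[-n_tail:]) if n_tail else []
    # genes with negative axis-1 coordinate are low-expression iff rho > 0
    low_pole = "negative" if rho > 0 else "positive"
    low_codons, high_codons = (low, high) if low_pole == "negative" else (high, low)
    return OptimalCodonReport(
        low_pole_codons=sorted(low_codons),
        high_pole_codons=sorted(high_codons),
        low_expression_pole=low_pole,
        rho=float(rho),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# expression-GC regression
# ---------------------------------------------------------------------------

@dataclass
class PowerFit:
    model: str
    params: dict[str, float]
    rss: float
    f_stat: float
    p_value: float

    def predict(self, x) -> np.ndarray:
        return _MODEL_FUNCS[self.model](np.asarray(x, dtype=float), **self.params)


def _f_linear(x, a, b):
    return a * x + b


def _f_power(x, a, b):
    return a * x**b


def _f_exponential(x, a, b):
    return a * np.exp(b * x)


def _f_logarithmic(x, a, b):
    return a * np.log(x) + b


def _f_saturating(x, plateau, base, k):
    return plateau - (plateau - base) * x ** (-k)


_MODEL_FUNCS = {
    "linear": _f_linear,
    "power": _f_power,
    "exponential": _f_exponential,
    "logarithmic": _f_logarithmic,
    "saturating": _f_saturating,
}


def fit_expression_gc(x, y, model: str = "saturating") -> PowerFit:
    """Least-squares fit of GC (or GC3) against expression.

    The F statistic compares the fitted model with the intercept-only model.
    Power/exponential fits are initialized from the log-linear closed form;
    the saturating form is the plateau model plateau - (plateau-base)*x^-k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if model in ("power", "logarithmic", "saturating") and (x <= 0).any():
        raise ValueError(f"{model} model requires positive x")
    func = _MODEL_FUNCS[model]
    if model == "linear":
        b1, b0 = np.polyfit(x, y, 1)
        params = {"a": float(b1), "b": float(b0)}
    elif model == "logarithmic":
        b1, b0 = np.polyfit(np.log(x), y, 1)
        params = {"a": float(b1), "b": float(b0)}
    elif model == "power":
        pos = y > 0
        if pos.sum() >= 2:
            b1, b0 = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
            p0 = (float(np.exp(b0)), float(b1))
        else:
            p0 = (1.0, 0.5)
        popt, _ = optimize.curve_fit(func, x, y, p0=p0, maxfev=20000)
        params = {"a": float(popt[0]), "b": float(popt[1])}
    elif model == "exponential":
        pos = y > 0
        if pos.sum() >= 2:
            b1, b0 = np.polyfit(x[pos], np.log(y[pos]), 1)
            p0 = (float(np.exp(b0)), float(b1))
        else:
            p0 = (1.0, 0.01)
        popt, _ = optimize.curve_fit(func, x, y, p0=p0, maxfev=20000)
        params = {"a": float(popt[0]), "b": float(popt[1])}
    elif model == "saturating":
        p0 = (float(np.max(y)), float(np.min(y)), 1.0)
        popt, _ = optimize.curve_fit(
            func, x, y, p0=p0, maxfev=20000,
            bounds=([0.0, 0.0, 1e-3], [1.0, 1.0, 20.0]),
        )
        params = {"plateau": float(popt[0]), "base": float(popt[1]), "k": float(popt[2])}
    else:
        raise ValueError(f"unknown model {model!r}")
    resid = y - func(x, **params)
    rss = float(resid @ resid)
    ss0 = float(((y - y.mean()) ** 2).sum())
    p_n = len(params)
    df1, df2 = p_n - 1, len(x) - p_n
    if df2 <= 0 or rss <= 0:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = max(0.0, (ss0 - rss) / max(df1, 1) / (rss / df2))
        p_value = float(stats.f.sf(f_stat, max(df1, 1), df2))
    return PowerFit(model=model, params=params, rss=rss, f_stat=float(f_stat), p_value=p_value)


def compare_models(x, y, models: tuple[str, ...] = ("linear", "power", "exponential", "logarithmic", "saturating")) -> pd.DataFrame:
    """Fit all requested model forms and rank them by residual sum of squares."""
    rows = []
    for m in models:
        try:
            fit = fit_expression_gc(x, y, model=m)
        except (ValueError, RuntimeError) as exc:
            rows.append({"model": m, "rss": np.nan, "f_stat": np.nan,
                         "p_value": np.nan, "error": str(exc)})
            continue
        rows.append({"model": m, "rss": fit.rss, "f_stat": fit.f_stat,
                     "p_value": fit.p_value, "error": ""})
    return pd.DataFrame(rows).sort_values("rss", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# amino-acid composition across taxa
# ---------------------------------------------------------------------------

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")

# Optimal matching hydrophobicity (Sweet & Eisenberg 1983), per residue
OMH_SCALE = {
    "A": -0.40, "R": -0.59, "N": -0.92, "D": -1.31, "C": 0.17,
    "Q": -0.91, "E": -1.22, "G": -0.67, "H": -0.64, "I": 1.25,
    "L": 1.22, "K": -0.67, "M": 1.02, "F": 1.92, "P": -0.49,
    "S": -0.55, "T": -0.28, "W": 0.50, "Y": 1.67, "V": 0.91,
}

CHARGED = set("DEKR")
POSITIVE = set("KR")


@dataclass
class AaCompositionProfile:
    taxon: str
    frequencies: pd.Series
    charged_fraction: float
    positive_fraction: float
    omh_index: float


def aa_composition(
    proteomes: dict[str, list[str]], include_histidine: bool = False
) -> tuple[list[AaCompositionProfile], dict]:
    """Amino-acid composition per taxon plus homogeneity statistics.

    Charged residues default to D/E/K/R (histidine optionally included);
    positive = K/R.  The chi-square and G statistics test homogeneity of
    the taxon x amino-acid count table.
    """
    charged = CHARGED | ({"H"} if include_histidine else set())
    counts = {}
    for taxon, proteins in proteomes.items():
        tally = dict.fromkeys(AMINO_ACIDS, 0)
        for p in proteins:
            for ch in p.upper():
                if ch in tally:
                    tally[ch] += 1
        if sum(tally.values()) == 0:
            raise ValueError(f"empty proteome for taxon {taxon!r}")
        counts[taxon] = pd.Series(tally, dtype=float)
    table = pd.DataFrame(counts).T  # taxa x amino acids
    profiles = []
    for taxon, row in table.iterrows():
        freq = row / row.sum()
        profiles.append(
            AaCompositionProfile(
                taxon=taxon,
                frequencies=freq,
                charged_fraction=float(freq[sorted(charged)].sum()),
                positive_fraction=float(freq[sorted(POSITIVE)].sum()),
                omh_index=float(sum(freq[a] * OMH_SCALE[a] for a in AMINO_ACIDS)),
            )
        )
    used = table.loc[:, table.sum(axis=0) > 0]
    if len(table) > 1:
        chi2, chi2_p, dof, _ = stats.chi2_contingency(used, correction=False)
        g, g_p, _, _ = stats.chi2_contingency(
            used, correction=False, lambda_="log-likelihood"
        )
    else:
        chi2 = chi2_p = g = g_p = dof = float("nan")
    homogeneity = {
        "chi2": float(chi2), "chi2_p": float(chi2_p),
        "g": float(g), "g_p": float(g_p), "dof": dof,
    }
    return profiles, homogeneity


# ---------------------------------------------------------------------------
# mean percent identity over gapless columns
# ---------------------------------------------------------------------------

@dataclass
class IdentityMatrix:
    matrix: pd.DataFrame  # taxa x taxa, percent
    n_columns: int


def mean_identity(
    families: list[dict[str, str]], taxa: list[str]
) -> IdentityMatrix:
    """Mean pairwise percent identity over gapless alignment columns.

    Each family is a taxon -> aligned-sequence mapping; families missing a
    requested taxon are skipped with a warning.  Columns containing a gap in
    any included sequence are discarded for all pairs, then families are
    concatenated; identity = matches / retained columns x 100.
    """
    blocks = {t: [] for t in taxa}
    n_cols = 0
    for i, fam in enumerate(families):
        if any(t not in fam for t in taxa):
            missing = [t for t in taxa if t not in fam]
            warnings.warn(f"family {i} skipped: missing taxa {missing}")
            continue
        seqs = {t: fam[t].upper() for t in taxa}
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"family {i}: aligned sequences differ in length")
        arr = np.array([list(seqs[t]) for t in taxa])
        gapless = ~((arr == "-") | (arr == ".") | (arr == "X")).any(axis=0)
        for j, t in enumerate(taxa):
            blocks[t].append(arr[j][gapless])
        n_cols += int(gapless.sum())
    if n_cols == 0:
        raise ValueError("no gapless columns available")
    concat = {t: np.concatenate(blocks[t]) for t in taxa}
    mat = pd.DataFrame(100.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            ident = float((concat[a] == concat[b]).mean() * 100.0)
            mat.loc[a, b] = mat.loc[b, a] = ident
    return IdentityMatrix(matrix=mat, n_columns=n_cols)
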