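"""Composition statistics over the annotated unigenes and ortholog families.

Computes GC by mRNA region and GC3, fits the GC3-vs-expression model menu,
runs the codon-usage correspondence analysis with optimal-codon detection,
and profiles amino-acid composition, charge and hydrophobicity across
synthetic ortholog families together with the mean-identity matrix.
Outputs under results/composition/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from alvinest import composition, io, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--assembly", default="results/assembly")
    ap.add_argument("--cds", default="results/cds")
    ap.add_argument("--out", default="results/composition")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    # region GC from the completeness report + unigene sequences
    seqs = dict(
        io.read_fasta(Path(args.assembly) / "contigs.fasta")
        + io.read_fasta(Path(args.assembly) / "singletons.fasta")
    )
    report = pd.read_csv(Path(args.cds) / "completeness_report.tsv", sep="\t")
    layout = pd.read_csv(Path(args.assembly) / "layout.tsv", sep="\t")
    expr = layout.groupby("unigene_id")["read_id"].count()
    from alvinest.cleaning import revcomp

    rows, cds_by_gene = [], {}
    for row in report.itertuples():
        seq = seqs[row.unigene_id]
        w = seq if row.frame > 0 else revcomp(seq)
        utr5, cseq, utr3 = w[: row.start], w[row.start : row.end], w[row.end :]
        rg = composition.region_gc(
            row.unigene_id, utr5, cseq, utr3,
            copy_number=int(expr.get(row.unigene_id, 1)),
        )
        rows.append(rg.__dict__)
        if row.source == "homology" and "X" not in cseq and "N" not in cseq:
            cds_by_gene[row.unigene_id] = cseq
    region_df = pd.DataFrame(rows)
    region_df.to_csv(out / "region_gc.tsv", sep="\t", index=False)
    means = region_df[["gc_cds", "gc3", "gc_utr5", "gc_utr3"]].mean()
    print("mean GC: CDS {:.1%}  GC3 {:.1%}  5'UTR {:.1%}  3'UTR {:.1%}".format(
        means["gc_cds"], means["gc3"], means["gc_utr5"], means["gc_utr3"]))

    ok = region_df.dropna(subset=["gc3"])
    ranking = composition.compare_models(ok["copy_number"], ok["gc3"])
    ranking.to_csv(out / "gc3_model_comparison.tsv", sep="\t", index=False)
    fit = composition.fit_expression_gc(ok["copy_number"], ok["gc3"], "saturating")
    print("GC3 vs expression ({} genes): best model by RSS = {}".format(
        len(ok), ranking.iloc[0]["model"]))
    print("  saturating fit: plateau {plateau:.3f}, base {base:.3f}, k {k:.2f}".format(
        **fit.params), f" (F = {fit.f_stat:.2f}, p = {fit.p_value:.2g})")

    per_gene, pooled = composition.codon_usage(cds_by_gene)
    pooled.to_csv(out / "codon_usage_pooled.tsv", sep="\t")
    rscu_rows = per_gene.apply(composition.rscu, axis=1)
    multi = [
        c for c in composition.SENSE_CODONS
        if len(composition._SYN_FAMILY[composition._AA_OF[c]]) > 1
    ]
    present = rscu_rows[multi].notna().mean(axis=0)
    keep = [c for c in multi if present[c] >= 0.95]
    mat = rscu_rows[keep].dropna()
    coa = composition.correspondence_analysis(mat, n_axes=4)
    coa.row_coords.round(8).to_csv(out / "coa_gene_coords.tsv", sep="\t")
    coa.col_coords.round(8).to_csv(out / "coa_codon_coords.tsv", sep="\t")
    opt = composition.optimal_codons(coa, expr.reindex(mat.index))
    print(f"CA first-axis inertia {100 * coa.inertia[0]:.1f}%; "
          f"rank corr. with expression rho = {opt.rho:.2f} (p = {opt.p_value:.2g})")
    print("  low-expression pole codons:", ", ".join(opt.low_pole_codons))

    taxa = ["Alvinella", "Homo", "Nematostella", "Drosophila",
            "Caenorhabditis", "Schistosoma"]
    families = simulate.generate_ortholog_families(
        taxa, n_families=60,
        divergence={"Alvinella": 0.12, "Homo": 0.12, "Nematostella": 0.14,
                    "Drosophila": 0.22, "Caenorhabditis": 0.30, "Schistosoma": 0.32},
        charged_bias={"Alvinella": 1.8, "Nematostella": 1.7},
        seed=args.seed + 3,
    )
    proteomes = {t: [f[t] for f in families] for t in taxa}
    profiles, homogeneity = composition.aa_composition(proteomes)
    pd.DataFrame({p.taxon: p.frequencies for p in profiles}).T.round(6).to_csv(
        out / "aa_frequencies.tsv", sep="\t"
    )
    charge = pd.DataFrame(
        [
            {"taxon": p.taxon, "charged": p.charged_fraction,
             "positive": p.positive_fraction, "omh": p.omh_index}
            for p in profiles
        ]
    )
    charge.to_csv(out / "aa_charge_profile.tsv", sep="\t", index=False)
    (out / "aa_homogeneity.json").write_text(json.dumps(homogeneity, indent=2) + "\n")
    top = charge.sort_values("charged", ascending=False).iloc[0]
    print(f"amino-acid homogeneity: chi2 = {homogeneity['chi2']:.1f} "
          f"(p = {homogeneity['chi2_p']:.2g}), G = {homogeneity['g']:.1f}")
    print(f"highest charged fraction: {top['taxon']} "
          f"({100 * top['charged']:.1f}%, K+R {100 * top['positive']:.1f}%)")

    ident = composition.mean_identity(families, taxa)
    ident.matrix.round(3).to_csv(out / "identity_matrix.tsv", sep="\t")
    print(f"mean identity over {ident.n_columns} gapless positions; "
          "Alvinella-Homo {:.1f}%, Alvinella-Caenorhabditis {:.1f}%".format(
              ident.matrix.loc["Alvinella", "Homo"],
              ident.matrix.loc["Alvinella", "Caenorhabditis"]))


if __name__ == "__main__":
    main()
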