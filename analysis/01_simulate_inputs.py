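"""Generate every pipeline input with planted ground truth.

Writes, under results/data/: the synthetic transcriptome (sequences and a
per-gene table), Sanger-style reads as FASTA+QUAL with an exact truth
table, the cloning-vector sequence, a scored interactome edge list with its
planted module assignment, and a taxon-labelled homology hit table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from alvinest import io, simulate
from alvinest.pipeline import SCENARIOS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-transcripts", type=int, default=150)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    transcripts = simulate.generate_transcriptome(args.n_transcripts, seed=args.seed)
    pd.DataFrame(
        [
            {
                "id": t.id, "utr5_seq": t.utr5_seq, "cds_seq": t.cds_seq,
                "utr3_seq": t.utr3_seq, "copy_number": t.copy_number,
                "gc3_target": round(t.gc3_target, 6),
                "taxon_profile_id": t.taxon_profile_id,
            }
            for t in transcripts
        ]
    ).to_csv(out / "transcripts.tsv", sep="\t", index=False)
    io.write_fasta(((t.id, t.mrna) for t in transcripts), out / "transcripts.fasta")

    params = simulate.ReadSimParams(
        seed=args.seed + 1, polya_rate=0.15, vector_rate=0.08,
        error_rate=0.005, empty_vector_rate=0.005,
    )
    reads, truth = simulate.generate_reads(transcripts, params)
    io.write_fasta_qual(reads, out / "reads.fasta", out / "reads.qual")
    truth.to_csv(out / "read_truth.tsv", sep="\t", index=False)
    io.write_fasta([("synthetic_vector", params.vector_seq)], out / "vector.fasta")

    planted = simulate.generate_ppi(8, 12, p_in=0.9, p_out=0.01, seed=args.seed + 4)
    io.write_edge_list(planted.edge_frame(), out / "ppi_edges.tsv")
    pd.DataFrame(
        sorted(planted.module_assignment.items()), columns=["node", "module"]
    ).to_csv(out / "ppi_modules.tsv", sep="\t", index=False)

    scenario_of = {f"prot_{t.id}": SCENARIOS[t.taxon_profile_id] for t in transcripts}
    simulate.write_scenario_table(scenario_of, out / "scenarios.yaml")
    profiles = simulate.generate_hit_profiles(
        sorted(scenario_of), scenario_of, seed=args.seed + 5
    )
    pd.DataFrame(
        [
            {"query": p.query_id, "subject": s, "taxon": t, "evalue": e}
            for p in profiles
            for s, t, e in p.hits
        ],
        columns=["query", "subject", "taxon", "evalue"],
    ).to_csv(out / "homology_hits.tsv", sep="\t", index=False)
    # the full query list: proteins without any hit are still classified
    pd.DataFrame({"query": sorted(scenario_of)}).to_csv(
        out / "queries.tsv", sep="\t", index=False
    )

    stats = {
        "n_transcripts": len(transcripts),
        "n_reads": len(reads),
        "mean_read_length": round(sum(len(r.seq) for r in reads) / len(reads), 1),
        "polya_reads": int((truth["polya_start"] >= 0).sum()),
        "vector_reads": int((truth["vector_intervals"] != "").sum()),
        "ppi_nodes": len(planted.nodes),
        "ppi_edges": len(planted.edges),
    }
    (out / "simulation_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
    print(f"wrote {stats['n_reads']} reads from {stats['n_transcripts']} transcripts")
    print(f"mean read length {stats['mean_read_length']} nt, "
          f"{stats['polya_reads']} poly(A) reads, {stats['vector_reads']} with vector")
    print(f"interactome: {stats['ppi_nodes']} nodes, {stats['ppi_edges']} edges")


if __name__ == "__main__":
    main()
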