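"""Classify proteins by the taxonomic distribution of their homology hits
and assemble the differential-gene-repertoire sets.

Reads the hit table from results/data/, applies the E-value cutoff and the
Annelid/Mollusc ignore rule, and writes per-query calls, set memberships
and counts under results/taxonomy/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from alvinest import io, taxonomy


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/taxonomy")
    ap.add_argument("--evalue", type=float, default=1e-5)
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    hits = io.read_hit_table(data / "homology_hits.tsv")
    profiles: dict[str, taxonomy.HitProfile] = {}
    for row in hits.itertuples():
        profiles.setdefault(
            row.query, taxonomy.HitProfile(query_id=row.query, hits=[])
        ).hits.append((row.subject, row.taxon, float(row.evalue)))
    # queries absent from the hit table still get a (no-homolog) call
    queries_path = data / "queries.tsv"
    if queries_path.exists():
        all_queries = list(pd.read_csv(queries_path, sep="\t")["query"])
    else:
        all_queries = sorted(set(hits["query"]))
    calls = [
        taxonomy.classify(
            profiles.get(q, taxonomy.HitProfile(query_id=q, hits=[])),
            evalue_cutoff=args.evalue,
        )
        for q in all_queries
    ]
    sets, membership = taxonomy.build_sets(calls)
    membership.to_csv(out / "set_membership.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"query": c.query_id, "call": c.call, "taxon": c.taxon or "",
             "effective_taxa": ";".join(sorted(c.effective_taxa))}
            for c in calls
        ]
    ).to_csv(out / "calls.tsv", sep="\t", index=False)
    counts = {name: len(members) for name, members in sets.items()}
    (out / "set_counts.json").write_text(json.dumps(counts, indent=2) + "\n")

    print(f"classified {len(calls)} proteins:")
    for name, n in sorted(counts.items()):
        print(f"  {name:26s}{n}")


if __name__ == "__main__":
    main()
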