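"""Determine coding regions on the unigenes by the two tracks.

Homology: hits planted on the assembled unigenes from the simulation truth
drive frame-aware extension to stop/start codons.  Ab initio: a hexamer
log-odds coding model trained on the synthetic transcriptome, thresholded
at the cutoff optimized on with/without-homology score distributions.
Writes GFF3, protein FASTA, the completeness report and the ROC table
under results/cds/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from alvinest import assembly, cds, io, simulate
from alvinest.pipeline import _write_annotations


def load_transcripts(path: Path) -> list[simulate.TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        simulate.TranscriptModel(
            id=row.id, cds_seq=row.cds_seq, utr5_seq=row.utr5_seq,
            utr3_seq=row.utr3_seq, copy_number=int(row.copy_number),
            gc3_target=float(row.gc3_target),
            taxon_profile_id=row.taxon_profile_id,
        )
        for row in df.itertuples()
    ]


def load_unigenes(assembly_dir: Path) -> list[assembly.Unigene]:
    layout = pd.read_csv(assembly_dir / "layout.tsv", sep="\t")
    members: dict[str, list] = {}
    for row in layout.itertuples():
        members.setdefault(row.unigene_id, []).append(
            (row.read_id, int(row.offset), row.strand)
        )
    unigenes = []
    for name in ("contigs.fasta", "singletons.fasta"):
        for uid, seq in io.read_fasta(assembly_dir / name):
            unigenes.append(
                assembly.Unigene(
                    id=uid, consensus=seq, members=members[uid],
                    kind="contig" if name.startswith("contigs") else "singleton",
                )
            )
    return sorted(unigenes, key=lambda u: u.id)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--assembly", default="results/assembly")
    ap.add_argument("--out", default="results/cds")
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    transcripts = load_transcripts(data / "transcripts.tsv")
    unigenes = load_unigenes(Path(args.assembly))
    truth = pd.read_csv(data / "read_truth.tsv", sep="\t")
    read_to_tx = dict(zip(truth["read_id"], truth["transcript_id"]))

    hits, cds_truth = simulate.plant_hits_on_unigenes(unigenes, transcripts, read_to_tx)
    hits_by_unigene: dict[str, list] = {}
    for h in hits:
        hits_by_unigene.setdefault(h.query_id, []).append(h)

    model = cds.CodingModel.train(
        [t.cds_seq for t in transcripts],
        [t.utr5_seq + t.utr3_seq for t in transcripts],
        trained_on="synthetic transcriptome",
    )
    seqs = {u.id: u.consensus for u in unigenes}
    scores = {
        uid: cds.coding_score(seq, model)[0]
        for uid, seq in sorted(seqs.items())
        if len(seq) >= 6
    }
    decoy_rng = np.random.default_rng(args.seed + 2)
    roc_scores, roc_labels = [], []
    for uid in sorted(scores):
        if uid in hits_by_unigene:
            roc_scores.append(scores[uid])
            roc_labels.append(True)
        shuffled = "".join(decoy_rng.permutation(list(seqs[uid])))
        roc_scores.append(cds.coding_score(shuffled, model)[0])
        roc_labels.append(False)
    roc = cds.optimize_cutoff(roc_scores, roc_labels)
    roc.table.to_csv(out / "coding_score_roc.tsv", sep="\t", index=False)

    annotations = {}
    n_exact = n_eval = 0
    for uid in sorted(seqs):
        bh = cds.best_hit(hits_by_unigene.get(uid, []))
        hom = cds.cds_from_homology(uid, seqs[uid], bh) if bh else None
        ab = None
        if uid in scores and scores[uid] >= roc.cutoff:
            ab = cds.cds_ab_initio(uid, seqs[uid], model, roc.cutoff)
        final = cds.reconcile(hom, ab, scores.get(uid), roc.cutoff)
        if final is not None:
            annotations[uid] = final
        if uid in cds_truth and hom is not None:
            n_eval += 1
            n_exact += tuple(hom.interval) == tuple(cds_truth[uid]["cds_interval"])
    _write_annotations(annotations, seqs, out)

    n_complete = sum(1 for a in annotations.values() if a.completeness == cds.COMPLETE)
    print(f"coding regions: {len(annotations)} on {len(unigenes)} unigenes "
          f"({n_complete} complete)")
    print(f"score cutoff {roc.cutoff:.1f}: sensitivity {100 * roc.sensitivity:.0f}%, "
          f"specificity {100 * roc.specificity:.0f}%")
    print(f"planted CDS intervals recovered exactly: {n_exact}/{n_eval}")


if __name__ == "__main__":
    main()
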