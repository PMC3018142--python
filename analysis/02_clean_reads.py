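"""Clean the simulated reads: quality clip, vector + poly-tail masks, filter.

Reads results/data/, writes cleaned FASTA+QUAL and the per-read disposition
report under results/cleaning/, and prints the Table-1-style summary
(clean-sequence fraction, poly(A) percentage, mean length).
"""

import argparse
from pathlib import Path

from alvinest import cleaning, io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/cleaning")
    ap.add_argument("--window", type=int, default=20)
    ap.add_argument("--qthresh", type=float, default=13.0)
    ap.add_argument("--minlen", type=int, default=100)
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    reads = io.read_fasta_qual(data / "reads.fasta", data / "reads.qual")
    vectors = io.read_fasta(data / "vector.fasta")
    kept, report = cleaning.clean_reads(
        reads, vectors=vectors,
        window=args.window, threshold=args.qthresh, min_len=args.minlen,
    )
    io.write_fasta_qual(kept, out / "clean.fasta", out / "clean.qual")
    report.dispositions.to_csv(out / "dispositions.tsv", sep="\t", index=False)

    counts = report.dispositions["disposition"].value_counts()
    mean_len = sum(len(r.seq) for r in kept) / max(len(kept), 1)
    print(f"input reads:      {report.n_input}")
    print(f"clean sequences:  {report.n_clean} "
          f"({100 * report.n_clean / report.n_input:.0f}%)")
    for disposition in ("too_short", "empty_vector"):
        print(f"  {disposition:14s}{int(counts.get(disposition, 0))}")
    print(f"3' poly(A):       {100 * report.polya_fraction:.0f}% of clean reads")
    print(f"mean clean length {mean_len:.0f} nt")


if __name__ == "__main__":
    main()
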