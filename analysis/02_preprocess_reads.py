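#!/usr/bin/env python
"""Quality-filter the simulated reads and length-filter the transcripts.

Applies the read screen (discard a read with more than 40 bases at Phred
quality <= 7 or more than 20% N) to the FASTQ pairs from step 01, then the
150 bp minimum-length contig filter to the transcripts, and writes the
discard log and a summary table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from vitephylo import preprocess as pp


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    kept_total = dropped_total = 0
    log_rows = []
    for mate in ("reads_1.fastq", "reads_2.fastq"):
        reads = list(pp.read_fastq(args.data / mate))
        kept, log = pp.filter_reads(reads)
        kept_total += len(kept)
        dropped_total += len(log)
        log_rows += [(mate, rid, reason) for rid, reason in log]
    pd.DataFrame(log_rows, columns=["file", "read_id", "reason"]).to_csv(
        args.out / "read_discard_log.tsv", sep="\t", index=False)

    n_contigs = n_kept = 0
    for fa in sorted(args.data.glob("*_transcripts.fasta")):
        taxon = fa.name.split("_")[0]
        ts = [pp.Transcript(r.id, taxon, str(r.seq))
              for r in SeqIO.parse(str(fa), "fasta")]
        kept = pp.filter_contigs(ts, min_length=150)
        n_contigs += len(ts)
        n_kept += len(kept)

    print(f"reads kept {kept_total}, discarded {dropped_total}")
    print(f"contigs >= 150 bp: {n_kept}/{n_contigs}")
    print(f"discard log: {args.out / 'read_discard_log.tsv'}")


if __name__ == "__main__":
    main()
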