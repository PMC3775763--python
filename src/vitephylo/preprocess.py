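"""Read- and transcript-level filters and CDS extraction.

Mirrors the pre-assembly / annotation screening of a transcriptome
phylogenomics run: FASTQ quality and N-content filtering, minimum contig
length, collapse of near-identical (alternatively spliced) transcripts,
and definition of coding regions by six-frame translation plus local
alignment against a reference proteome.

Quality thresholds are expressed as Phred integers with the encoding kept
explicit (phred33 or phred64): a "score of 71 or lower" in legacy
Phred+64 ASCII terms is quality <= 7, which is the default threshold here.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import SeqIO

from . import similarity
from ._codons import translate_codon

try:
    import edlib
    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

__all__ = [
    "ReadRecord", "Transcript", "CodingSequence", "read_fastq",
    "filter_reads", "filter_contigs", "collapse_redundant", "extract_cds",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ReadRecord:
    id: str
    bases: str
    qualities: list  # per-base Phred integers

    def validate(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id!r}: bases/qualities length mismatch "
                             f"({len(self.bases)} vs {len(self.qualities)})")


@dataclass
class Transcript:
    id: str
    taxon: str
    sequence: str


@dataclass
class CodingSequence:
    gene_id: str
    taxon: str
    cds: str
    protein: str
    frame: int          # 0, 1, 2 within the chosen strand
    strand: str         # '+' or '-'
    transcript_id: str
    score: float = 0.0
    reference_id: Optional[str] = None

    def validate(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if "*" in self.protein:
            raise ValueError(f"{self.gene_id}: internal stop in translation")
        if len(self.protein) != len(self.cds) // 3:
            raise ValueError(f"{self.gene_id}: protein/CDS length mismatch")


def read_fastq(path, encoding: str = "phred33") -> Iterable[ReadRecord]:
    """Stream a FASTQ file (gz transparent), yielding ReadRecords."""
    fmt = {"phred33": "fastq", "phred64": "fastq-illumina"}[encoding]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield ReadRecord(rec.id, str(rec.seq),
                             rec.letter_annotations["phred_quality"])


def filter_reads(reads: Iterable[ReadRecord], quality_threshold: int = 7,
                 max_low_quality_bases: int = 40,
                 max_n_fraction: float = 0.20):
    """Discard reads with too many low-quality bases or too many Ns.

    A read is discarded iff (number of bases with quality <=
    ``quality_threshold``) > ``max_low_quality_bases`` OR (N count /
    length) > ``max_n_fraction`` (both thresholds strict, so a read with
    exactly 40 low-quality bases or exactly 20% N is kept).

    Returns ``(kept, discard_log)`` where the log rows are (read_id, reason).
    """
    if not (0 <= max_n_fraction <= 1):
        raise ValueError("max_n_fraction must be in [0, 1]")
    kept, log = [], []
    for r in reads:
        r.validate()
        n_low = sum(1 for q in r.qualities if q <= quality_threshold)
        if n_low > max_low_quality_bases:
            log.append((r.id, f"low_quality_bases={n_low}"))
            continue
        n_frac = r.bases.count("N") / len(r.bases) if r.bases else 0.0
        if n_frac > max_n_fraction:
            log.append((r.id, f"n_fraction={n_frac:.3f}"))
            continue
        kept.append(r)
    return kept, log


def filter_contigs(transcripts: Iterable[Transcript],
                   min_length: int = 150) -> list[Transcript]:
    """Keep contigs of length >= min_length (inclusive), input order preserved."""
    return [t for t in transcripts if len(t.sequence) >= min_length]


def _infix_identity(query: str, target: str) -> float:
    """Identity of the best infix alignment of query inside target."""
    if not _HAVE_EDLIB:  # pragma: no cover - edlib is a hard dependency in practice
        raise RuntimeError("edlib is required for collapse_redundant")
    res = edlib.align(query, target, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return 1.0 - d / len(query)


def collapse_redundant(transcripts: list[Transcript],
                       identity_threshold: float = 0.95,
                       min_self_coverage: float = 0.8) -> list[Transcript]:
    """Greedy longest-first collapse of near-identical transcripts.

    A transcript is dropped when it aligns to an already-kept (longer)
    representative at >= ``identity_threshold`` identity over >=
    ``min_self_coverage`` of its own length, on either strand — the usual
    screen for alternative splice forms / redundant assembly contigs.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(transcripts, key=lambda t: (-len(t.sequence), t.id))
    kept: list[Transcript] = []
    for t in order:
        redundant = False
        w = max(1, int(round(min_self_coverage * len(t.sequence))))
        probes = [t.sequence, t.sequence[:w], t.sequence[-w:]]
        probes += [p.translate(_COMP)[::-1] for p in probes[:1]]
        for rep in kept:
            if rep.taxon != t.taxon:
                continue
            for probe in probes:
                if _infix_identity(probe, rep.sequence) >= identity_threshold:
                    redundant = True
                    break
            if redundant:
                break
        if not redundant:
            kept.append(t)
    # restore input order among the kept
    kept_ids = {t.id for t in kept}
    return [t for t in transcripts if t.id in kept_ids]


def _orfs_in_frame(seq: str, frame: int):
    """Yield (protein, nt_start, nt_end) for stop-free stretches in a frame."""
    aa = []
    start = frame
    pos = frame
    while pos + 3 <= len(seq):
        codon = seq[pos:pos + 3]
        r = translate_codon(codon)
        if r == "*":
            if aa:
                yield "".join(aa), start, pos
            aa = []
            start = pos + 3
        else:
            aa.append(r)
        pos += 3
    if aa:
        yield "".join(aa), start, pos


def extract_cds(transcript: Transcript, reference_proteins: dict,
                min_score: float = 60.0, min_orf_aa: int = 20,
                matrix: Optional[dict] = None) -> Optional[CodingSequence]:
    """Define the coding region of a transcript against a reference proteome.

    All six reading frames are translated; stop-free ORFs are locally
    aligned to every reference protein and the highest-scoring (ORF,
    reference) pair at or above ``min_score`` defines the CDS.  Returns
    ``None`` when nothing reaches the threshold (or the transcript is
    shorter than one codon).
    """
    if not reference_proteins:
        raise ValueError("reference proteome is empty")
    if len(transcript.sequence) < 3:
        return None
    matrix = matrix or similarity._matrix()
    best = None
    for strand in "+-":
        seq = transcript.sequence if strand == "+" else \
            transcript.sequence.translate(_COMP)[::-1]
        for frame in range(3):
            for prot, nt_start, nt_end in _orfs_in_frame(seq, frame):
                if len(prot) < min_orf_aa:
                    continue
                clean = prot.replace("X", "")
                if not clean:
                    continue
                for rid, ref in reference_proteins.items():
                    h = similarity.local_align_protein(
                        prot.replace("X", "A") if "X" in prot else prot,
                        ref, matrix)
                    if h.raw_score >= min_score and (
                            best is None or h.raw_score > best[0]):
                        best = (h.raw_score, strand, frame, nt_start, nt_end,
                                prot, seq, rid)
    if best is None:
        return None
    score, strand, frame, nt_start, nt_end, prot, seq, rid = best
    cds = seq[nt_start:nt_end]
    out = CodingSequence(
        gene_id=f"{transcript.id}.cds", taxon=transcript.taxon, cds=cds,
        protein=prot, frame=frame, strand=strand,
        transcript_id=transcript.id, score=score, reference_id=rid)
    out.validate()
    return out
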