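"""Paired-end amplicon read processing: FASTQ to per-sample allele read counts.

The chain mirrors a standard microsatellite amplicon workflow on
demultiplexed, adapter-free reads: sliding-window quality trimming, merging
of overlapping pairs, locus assignment by exact forward-primer prefix,
exact-identity read collapsing, and a reference-prefix filter that demands
90% identity over the first 40 bases of the locus reference (built from the
most common allele) to reject primer artifacts and paralogues while keeping
repeat-number variants and flank SNPs.

Alleles discovered here are identified by their merged contig sequence
itself, which makes allele identity trivially stable across samples and
runs; callers may relabel via a panel's allele catalogue.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AmpliconRead",
    "LocusDef",
    "LocusPanel",
    "quality_trim",
    "merge_pairs",
    "assign_locus",
    "collapse_reads",
    "reference_filter",
    "fastq_to_counts",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconRead:
    id: str
    bases: str
    quals: tuple

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases and qualities differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class LocusDef:
    """One panel locus: primers, repeat motif, reference prefix, allele catalogue."""

    locus: str
    fwd_primer: str
    rev_primer: str
    reference_prefix: str
    motif: str = ""
    alleles: Mapping[str, str] = dc_field(default_factory=dict)  # allele id -> amplicon

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.fwd_primer), ("reverse", self.rev_primer)):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{name} primer of {self.locus} must be nonempty ACGT")
        if len(self.reference_prefix) < 40:
            raise ValueError(f"reference prefix of {self.locus} shorter than 40 bases")


@dataclass(frozen=True)
class LocusPanel:
    loci: Mapping[str, LocusDef]

    def __post_init__(self) -> None:
        primers = {loc: d.fwd_primer for loc, d in self.loci.items()}
        for a, pa in primers.items():
            for b, pb in primers.items():
                if a < b and (pa.startswith(pb) or pb.startswith(pa)):
                    raise ValueError(
                        f"forward primers of {a} and {b} are mutually prefixing"
                    )

    def __iter__(self):
        return iter(self.loci.values())

    def sequence_labels(self) -> dict[tuple[str, str], str]:
        """(locus, amplicon sequence) -> allele id, for relabelling counts."""
        return {
            (d.locus, seq): allele
            for d in self.loci.values()
            for allele, seq in d.alleles.items()
        }


def quality_trim(
    read: AmpliconRead, q_min: int = 20, window: int = 4, min_len: int = 20
) -> AmpliconRead | None:
    """Trim the 3' tail at the first sliding window whose mean Phred < ``q_min``.

    Returns ``None`` (discard) when the surviving read is shorter than
    ``min_len`` (callers pass the panel's longest forward primer).
    """
    quals = read.quals
    cut = len(quals)
    for i in range(len(quals)):
        win = quals[i : i + window]
        if sum(win) / len(win) < q_min:
            cut = i
            break
    if cut < min_len:
        return None
    if cut == len(quals):
        return read
    return AmpliconRead(read.id, read.bases[:cut], read.quals[:cut])


def merge_pairs(
    fwd: AmpliconRead,
    rev: AmpliconRead,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.05,
) -> AmpliconRead | None:
    """Merge a pair into one contig; ``rev`` is the raw reverse-orientation read.

    Overlaps are scanned from longest to shortest; the first (maximal) one
    with at least ``min_overlap`` bases and a mismatch rate strictly below
    ``max_mismatch_rate`` wins.  Disagreeing overlap bases take the call
    with the higher Phred quality.  Returns ``None`` when no acceptable
    overlap exists.
    """
    r_bases = revcomp(rev.bases)
    r_quals = rev.quals[::-1]
    f_bases, f_quals = fwd.bases, fwd.quals
    for olap in range(min(len(f_bases), len(r_bases)), min_overlap - 1, -1):
        f_tail = f_bases[len(f_bases) - olap :]
        r_head = r_bases[:olap]
        mismatches = sum(a != b for a, b in zip(f_tail, r_head))
        if mismatches / olap >= max_mismatch_rate:
            continue
        bases = list(f_bases + r_bases[olap:])
        quals = list(f_quals + r_quals[olap:])
        off = len(f_bases) - olap
        for j in range(olap):
            fq, rq = f_quals[off + j], r_quals[j]
            if f_tail[j] != r_head[j] and rq > fq:
                bases[off + j] = r_head[j]
            quals[off + j] = max(fq, rq)
        return AmpliconRead(fwd.id, "".join(bases), tuple(quals))
    return None


def assign_locus(
    contig: AmpliconRead | str, panel: LocusPanel, max_primer_mismatches: int = 0
) -> str | None:
    """Locus whose forward primer matches the contig prefix; None if 0 or >1 match."""
    seq = contig.bases if isinstance(contig, AmpliconRead) else contig
    hits = []
    for d in panel:
        primer = d.fwd_primer
        if len(seq) < len(primer):
            continue
        mm = sum(a != b for a, b in zip(seq, primer))
        if mm <= max_primer_mismatches:
            hits.append(d.locus)
    return hits[0] if len(hits) == 1 else None


def collapse_reads(
    contigs: Iterable[tuple[str, str, str]]
) -> pd.DataFrame:
    """Collapse (sample, locus, sequence) records to exact-identity counts.

    Identical sequences share an allele identity across samples by
    construction (the sequence is the identifier).
    """
    counts = Counter(contigs)
    rows = [
        {"sample": s, "locus": l, "allele": seq, "reads": c}
        for (s, l, seq), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "locus", "allele", "reads"])


def reference_filter(
    sequence: str, reference_prefix: str, min_identity: float = 0.90, span: int = 40
) -> bool:
    """Keep iff ungapped identity over the first ``span`` bases >= ``min_identity``."""
    if len(sequence) < span:
        return False
    matches = sum(a == b for a, b in zip(sequence[:span], reference_prefix[:span]))
    return matches / span >= min_identity


def _read_fastq(path) -> list[AmpliconRead]:
    try:
        return [
            AmpliconRead(rec.id, str(rec.seq).upper(),
                         tuple(rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(str(path), "fastq")
        ]
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def fastq_to_counts(
    fastq_pairs: Mapping[str, tuple],
    panel: LocusPanel,
    *,
    q_min: int = 20,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.05,
    max_primer_mismatches: int = 0,
    min_identity: float = 0.90,
    span: int = 40,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full chain on per-sample FASTQ pairs.

    ``fastq_pairs`` maps sample id -> (forward path, reverse path).  Returns
    the read count table (sample, locus, allele=sequence, reads) and a
    per-sample attrition table whose stages partition the input pairs
    exactly: ``input = quality_discarded + merge_failed + unassigned +
    reference_filtered + counted``.
    """
    min_len = max(len(d.fwd_primer) for d in panel)
    all_contigs: list[tuple[str, str, str]] = []
    stats_rows = []
    for sample, (fwd_path, rev_path) in fastq_pairs.items():
        fwd_reads = _read_fastq(fwd_path)
        rev_reads = _read_fastq(rev_path)
        if len(fwd_reads) != len(rev_reads):
            raise ValueError(f"sample {sample}: unpaired FASTQ files")
        tally = Counter()
        tally["input"] = len(fwd_reads)
        for f, r in zip(fwd_reads, rev_reads):
            ft = quality_trim(f, q_min, min_len=min_len)
            rt = quality_trim(r, q_min, min_len=min_len)
            if ft is None or rt is None:
                tally["quality_discarded"] += 1
                continue
            merged = merge_pairs(ft, rt, min_overlap, max_mismatch_rate)
            if merged is None:
                tally["merge_failed"] += 1
                continue
            locus = assign_locus(merged, panel, max_primer_mismatches)
            if locus is None:
                tally["unassigned"] += 1
                continue
            if not reference_filter(
                merged.bases, panel.loci[locus].reference_prefix, min_identity, span
            ):
                tally["reference_filtered"] += 1
                continue
            tally["counted"] += 1
            all_contigs.append((sample, locus, merged.bases))
        stats_rows.append({"sample": sample, **tally})
    stage_cols = [
        "sample", "input", "quality_discarded", "merge_failed",
        "unassigned", "reference_filtered", "counted",
    ]
    stats = pd.DataFrame(stats_rows).reindex(columns=stage_cols).fillna(0)
    for c in stage_cols[1:]:
        stats[c] = stats[c].astype(int)
    return collapse_reads(all_contigs), stats
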