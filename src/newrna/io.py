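"""Conversion counting from aligned reads, table I/O and sample QC.

The counting entry point is :func:`count_conversions`, which walks a
SAM/BAM of (stitched) reads carrying MD tags and a per-read gene tag and
records, per read, the number ``n`` of covered convertible reference
positions and the number ``k`` of those read as the specific mismatch:
T positions read as C for plus-strand genes, A positions read as G for
minus-strand genes.  A :class:`MismatchProfile` accumulating all twelve
mismatch types (stratified by gene strand) is built alongside and feeds
the error-rate estimators.

Everything here uses 0-based half-open coordinates internally; the BED
reader keeps BED's native convention and the GTF reader converts from
1-based inclusive at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

BASES = "ACGT"
MISMATCH_TYPES = [(r, a) for r in BASES for a in BASES if r != a]

RECORD_COLUMNS = ["sample_id", "gene_id", "read_id", "n", "k"]


class MalformedLineError(ValueError):
    """A text input line that could not be parsed (carries line number)."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


@dataclass
class MismatchProfile:
    """Per-sample mismatch counts and reference-base coverage by gene strand.

    ``mismatches[strand][(ref, alt)]`` counts quality-passing positions
    where a read over a gene on ``strand`` showed ``alt`` against
    reference ``ref``; ``coverage[strand][ref]`` counts all
    quality-passing positions with that reference base.
    """

    sample_id: str = "sample"
    mismatches: dict = field(
        default_factory=lambda: {
            s: {mt: 0 for mt in MISMATCH_TYPES} for s in "+-"
        }
    )
    coverage: dict = field(
        default_factory=lambda: {s: {b: 0 for b in BASES} for s in "+-"}
    )

    def add(self, strand: str, ref: str, alt: str) -> None:
        self.coverage[strand][ref] += 1
        if alt != ref:
            self.mismatches[strand][(ref, alt)] += 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strand in "+-":
            for (ref, alt), count in self.mismatches[strand].items():
                rows.append((self.sample_id, strand, ref, alt, count, self.coverage[strand][ref]))
        return pd.DataFrame(
            rows, columns=["sample_id", "strand", "ref", "alt", "count", "coverage"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MismatchProfile":
        prof = cls(sample_id=str(df["sample_id"].iloc[0]) if len(df) else "sample")
        for row in df.itertuples(index=False):
            prof.mismatches[row.strand][(row.ref, row.alt)] = int(row.count)
            prof.coverage[row.strand][row.ref] = int(row.coverage)
        return prof

    def rate(self, ref: str, alt: str, strand: str | None = None) -> float:
        """Mismatch rate ref->alt, pooled over strands unless one is given."""
        strands = [strand] if strand else ["+", "-"]
        mm = sum(self.mismatches[s][(ref, alt)] for s in strands)
        cov = sum(self.coverage[s][ref] for s in strands)
        if cov == 0:
            raise ValueError(f"no coverage of reference base {ref}")
        return mm / cov


@dataclass
class SampleQCReport:
    sample_id: str
    total_reads: int | None = None
    exonic_fraction: float | None = None
    snr: float | None = None
    median_ci_width: float | None = None
    passed: bool = True
    reasons: list = field(default_factory=list)


def count_conversions(
    alignments: str | Path | pysam.AlignmentFile,
    gene_strand: Mapping[str, str],
    sample_id: str = "sample",
    gene_tag: str = "GE",
    min_base_quality: int = 20,
    position_blacklist: set[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, MismatchProfile, dict]:
    """Count convertible positions and specific mismatches per read.

    Parameters
    ----------
    alignments
        SAM/BAM path (or open AlignmentFile) whose reads carry MD tags
        and a per-read gene tag.  Gene assignment is taken from the tag;
        alignment and assignment are upstream concerns.
    gene_strand
        Mapping gene_id -> "+" or "-".
    min_base_quality
        Bases below this quality are excluded from both ``n`` and ``k``.
    position_blacklist
        Optional set of (chrom, 0-based position) to exclude (e.g. SNPs).

    Returns ``(records, profile, skipped)`` where ``records`` has columns
    sample_id, gene_id, read_id, n, k and ``skipped`` counts reads
    dropped for a missing MD tag or an unknown gene.
    """
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    profile = MismatchProfile(sample_id=sample_id)
    skipped = {"missing_md": 0, "unknown_gene": 0, "no_gene_tag": 0, "unmapped": 0}
    rows = []
    try:
        for read in alignments.fetch(until_eof=True):
            if read.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if not read.has_tag(gene_tag):
                skipped["no_gene_tag"] += 1
                continue
            gene = read.get_tag(gene_tag)
            if gene not in gene_strand:
                skipped["unknown_gene"] += 1
                continue
            if not read.has_tag("MD"):
                skipped["missing_md"] += 1
                continue
            strand = gene_strand[gene]
            conv_ref = "T" if strand == "+" else "A"
            conv_alt = "C" if strand == "+" else "G"
            quals = read.query_qualities
            seq = read.query_sequence
            chrom = read.reference_name
            n = k = 0
            for qpos, rpos, ref_base in read.get_aligned_pairs(with_seq=True):
                if qpos is None or rpos is None or ref_base is None:
                    continue  # insertion / deletion / soft-clip
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                if position_blacklist and (chrom, rpos) in position_blacklist:
                    continue
                ref = ref_base.upper()
                alt = seq[qpos].upper()
                if ref not in BASES or alt not in BASES:
                    continue
                profile.add(strand, ref, alt)
                if ref == conv_ref:
                    n += 1
                    if alt == conv_alt:
                        k += 1
            rows.append((sample_id, gene, read.query_name, n, k))
    finally:
        if close:
            alignments.close()
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, profile, skipped


# --------------------------------------------------------------------------
# synthetic SAM fixture writer
# --------------------------------------------------------------------------

def write_synthetic_sam(
    records: pd.DataFrame,
    gene_strand: Mapping[str, str],
    path: str | Path,
    gene_tag: str = "GE",
    base_quality: int = 37,
    contig: str = "chrS",
) -> None:
    """Write a synthetic SAM realizing given per-read ``(n, k)`` counts.

    Each read covers exactly ``n`` convertible reference positions for
    its gene's strand ('T' for '+', 'A' for '-'), of which the first
    ``k`` (evenly spread) are written as the converted base; the MD tag
    encodes the implied reference.  Intended for round-trip testing of
    :func:`count_conversions`.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": contig, "LN": 100_000_000}],
    }
    pos = 1
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in records.itertuples(index=False):
            strand = gene_strand[row.gene_id]
            ref_base = "T" if strand == "+" else "A"
            alt_base = "C" if strand == "+" else "G"
            n, k = int(row.n), int(row.k)
            length = max(n, 1)
            ref = [ref_base] * length
            seq = list(ref)
            if n > 0 and k > 0:
                idx = np.linspace(0, n - 1, k).round().astype(int)
                for i in idx:
                    seq[i] = alt_base
            md_parts: list[str] = []
            run = 0
            for r, s in zip(ref, seq):
                if r == s:
                    run += 1
                else:
                    md_parts.append(str(run))
                    md_parts.append(r)
                    run = 0
            md_parts.append(str(run))
            a = pysam.AlignedSegment()
            a.query_name = str(row.read_id)
            a.query_sequence = "".join(seq)
            a.flag = 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 255
            a.cigarstring = f"{length}M"
            a.query_qualities = pysam.qualitystring_to_array(
                chr(base_quality + 33) * length
            )
            a.set_tag("MD", "".join(md_parts))
            a.set_tag(gene_tag, str(row.gene_id))
            out.write(a)
            pos += length + 10


# --------------------------------------------------------------------------
# sample QC
# --------------------------------------------------------------------------

MINIBULK_MIN_READS = 200_000
MINIBULK_MIN_EXONIC = 0.45
MINIBULK_MIN_SNR = 10.0
MCF7_MIN_READS = 1_000_000
MCF7_MIN_EXONIC = 0.45
MCF7_MAX_CI_WIDTH = 0.4
MCF7_MIN_REPLICATES = 3


def minibulk_qc(
    sample_id: str,
    total_reads: int,
    exonic_fraction: float,
    p_c: float,
    p_e: float,
) -> SampleQCReport:
    """Mini-bulk sample QC: >= 200,000 reads, >= 45% exonic, SNR > 10.

    SNR is p_c/p_e; a zero error rate gives infinite SNR, which passes.
    """
    snr = math.inf if p_e == 0 else p_c / p_e
    reasons = []
    if total_reads < MINIBULK_MIN_READS:
        reasons.append(f"reads < {MINIBULK_MIN_READS:,}")
    if exonic_fraction < MINIBULK_MIN_EXONIC:
        reasons.append(f"exonic < {MINIBULK_MIN_EXONIC:.0%}")
    if not snr > MINIBULK_MIN_SNR:
        reasons.append(f"snr <= {MINIBULK_MIN_SNR:g}")
    return SampleQCReport(
        sample_id=sample_id,
        total_reads=total_reads,
        exonic_fraction=exonic_fraction,
        snr=snr,
        passed=not reasons,
        reasons=reasons,
    )


def mcf7_qc(
    metrics: pd.DataFrame,
    pi_table: pd.DataFrame,
    replicate_map: Mapping[str, str],
) -> tuple[list[SampleQCReport], set]:
    """MCF7 drug-panel QC.

    A sample fails if its exonic fraction is below 45%, its total read
    count below one million, or the median width of its per-gene credible
    intervals is 0.4 or greater.  Drugs with fewer than three surviving
    replicates are dropped entirely.

    ``metrics`` needs columns sample_id, total_reads, exonic_fraction;
    ``pi_table`` needs sample_id plus either ci_width or ci_low/ci_high.

    Returns (per-sample reports, set of surviving drug ids).
    """
    pi = pi_table.copy()
    if "ci_width" not in pi.columns:
        pi["ci_width"] = pi["ci_high"] - pi["ci_low"]
    widths = pi.groupby("sample_id")["ci_width"].median()
    reports = []
    for row in metrics.itertuples(index=False):
        reasons = []
        if row.exonic_fraction < MCF7_MIN_EXONIC:
            reasons.append(f"exonic < {MCF7_MIN_EXONIC:.0%}")
        if row.total_reads < MCF7_MIN_READS:
            reasons.append(f"reads < {MCF7_MIN_READS:,}")
        w = widths.get(row.sample_id, np.nan)
        if not np.isnan(w) and w >= MCF7_MAX_CI_WIDTH:
            reasons.append(f"median CI width >= {MCF7_MAX_CI_WIDTH}")
        reports.append(
            SampleQCReport(
                sample_id=row.sample_id,
                total_reads=row.total_reads,
                exonic_fraction=row.exonic_fraction,
                median_ci_width=None if np.isnan(w) else float(w),
                passed=not reasons,
                reasons=reasons,
            )
        )
    passing = {r.sample_id for r in reports if r.passed}
    surviving: dict[str, int] = {}
    for sample, drug in replicate_map.items():
        if sample in passing:
            surviving[drug] = surviving.get(drug, 0) + 1
    kept = {d for d, c in surviving.items() if c >= MCF7_MIN_REPLICATES}
    return reports, kept


# --------------------------------------------------------------------------
# tabular readers / writers
# --------------------------------------------------------------------------

def write_records_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "n", "k") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: records table missing columns {missing}")
    return df


def write_rates_tsv(rates: pd.DataFrame, path: str | Path) -> None:
    rates.to_csv(path, sep="\t", index=False)


def read_rates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pi_table(pi_table: pd.DataFrame, path: str | Path) -> None:
    pi_table.to_csv(path, sep="\t", index=False)


def read_pi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end/name."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedLineError(path, lineno, "fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MalformedLineError(path, lineno, f"non-integer coordinate: {exc}")
            if end < start:
                raise MalformedLineError(path, lineno, f"end < start ({end} < {start})")
            name = fields[3] if len(fields) > 3 else "."
            rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, chrom, tss
    (1-based), strand and optionally tes (1-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    return df


def write_tss_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def tss_from_gtf(path: str | Path) -> pd.DataFrame:
    """Extract one TSS (and TES) per gene from a GTF.

    GTF coordinates are 1-based inclusive.  When a gene has several
    transcripts the most upstream start in transcription direction is
    taken (min start on '+', max end on '-'), mirrored for the TES.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    spans: dict[str, list] = {}
    feature_types = set(db.featuretypes())
    ftype = "transcript" if "transcript" in feature_types else "gene"
    for feat in db.features_of_type(ftype):
        gene = feat.attributes.get("gene_id", [feat.id])[0]
        entry = spans.setdefault(gene, [feat.seqid, feat.strand, feat.start, feat.end])
        entry[2] = min(entry[2], feat.start)
        entry[3] = max(entry[3], feat.end)
    rows = []
    for gene, (chrom, strand, start, end) in spans.items():
        tss, tes = (start, end) if strand == "+" else (end, start)
        rows.append((gene, chrom, tss, tes, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "tes", "strand"])


def read_gene2go(path: str | Path) -> pd.DataFrame:
    """Read a gene -> GO term TSV (columns gene_id, go_id)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "go_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene2go table missing columns {sorted(missing)}")
    return df


def read_obo(path: str | Path) -> pd.DataFrame:
    """Read an OBO ontology into (term_id, name, is_obsolete).

    Only names and obsolete flags are used downstream: obsolete terms are
    excluded from the GO universe.
    """
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    rows = [
        (
            term,
            data.get("name", ""),
            str(data.get("is_obsolete", "false")).lower() == "true",
        )
        for term, data in graph.nodes(data=True)
    ]
    return pd.DataFrame(rows, columns=["term_id", "name", "is_obsolete"])
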