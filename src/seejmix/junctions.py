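"""Junction-read tables: parsing, filtering, and per-locus organization.

A *junction* is the genomic interval of an excised intron, observed through
reads that span the exon-exon boundary it creates.  All coordinates are
0-based, half-open ``[start, end)``; BED input is already in this convention.
Each read/junction incidence is one count token, so the per-sample row sum of
a :class:`JunctionReadTable` is the number of junction-read tokens ``J_i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default intron-length filters (bp)
MIN_INTRON = 50
MAX_INTRON = 500_000


@dataclass(frozen=True, order=True)
class Junction:
    """An excised-intron interval on a chromosome/strand.

    ``start``/``end`` are the intron's first base and one-past-last base.
    Strand ``"."`` means unknown and compares distinct from ``"+"``/``"-"``
    (conservative: never merges junctions across strands).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"junction end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneLocus:
    """A maximal union of overlapping gene intervals (half-open)."""

    chrom: str
    start: int
    end: int
    names: tuple[str, ...] = ()

    def contains(self, j: Junction) -> bool:
        return j.chrom == self.chrom and self.start <= j.start and j.end <= self.end


@dataclass
class JunctionReadTable:
    """Per-locus junction counts: ``counts[i, v]`` tokens for sample i, junction v."""

    locus_id: str
    junctions: list[Junction]
    counts: np.ndarray  # (n_samples, n_junctions) nonnegative ints
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.junctions):
            raise ValueError("counts must be (n_samples, n_junctions)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(set(self.junctions)) != len(self.junctions):
            raise ValueError("duplicate junctions in table")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(self.counts.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_junctions(self) -> int:
        return self.counts.shape[1]

    @property
    def tokens_per_sample(self) -> np.ndarray:
        """J_i: junction-read tokens per sample."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{j.chrom}:{j.start}-{j.end}({j.strand})" for j in self.junctions]
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=cols)


class JunctionParseError(ValueError):
    """Raised for malformed junction records; carries the offending line number."""


def _parse_tsv_line(fields: list[str], lineno: int) -> tuple[Junction, int]:
    if len(fields) < 5:
        raise JunctionParseError(f"line {lineno}: expected 5 fields, got {len(fields)}")
    chrom, start, end, strand, count = fields[:5]
    try:
        j = Junction(chrom, int(start), int(end), strand)
        n = int(count)
    except ValueError as exc:
        raise JunctionParseError(f"line {lineno}: {exc}") from exc
    return j, n


def _parse_regtools_bed_line(fields: list[str], lineno: int) -> tuple[Junction, int]:
    # BED12 junction records: the thick interval spans the two anchor blocks;
    # the intron is what remains after trimming the anchor block lengths.
    if len(fields) < 12:
        raise JunctionParseError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        count = int(fields[4])
        strand = fields[5] if fields[5] in ("+", "-", ".") else "."
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise JunctionParseError(f"line {lineno}: {exc}") from exc
    if len(block_sizes) != 2 or len(block_starts) != 2:
        raise JunctionParseError(
            f"line {lineno}: junction BED12 record must have exactly 2 blocks"
        )
    intron_start = chrom_start + block_starts[0] + block_sizes[0]
    intron_end = chrom_start + block_starts[1]
    if intron_end <= intron_start:
        raise JunctionParseError(
            f"line {lineno}: non-positive intron length "
            f"[{intron_start}, {intron_end})"
        )
    return Junction(chrom, intron_start, intron_end, strand), count


def parse_junction_table(path, dialect: str = "tsv", sample_id: str | None = None):
    """Parse one sample's junction counts from a file.

    Parameters
    ----------
    path : str or Path
        Input file. ``tsv`` dialect: chrom, start, end, strand, count.
        ``regtools-bed`` dialect: BED12 junction records whose two blocks are
        the alignment anchors; intron coordinates are recovered by trimming
        the anchor block lengths from the thick interval. The BED score
        column carries the read count.
    dialect : {"tsv", "regtools-bed"}

    Returns
    -------
    dict[Junction, int]
        Counts per junction (summed over duplicate records). Records with a
        non-positive intron length are rejected with a warning.
    """
    parse = {"tsv": _parse_tsv_line, "regtools-bed": _parse_regtools_bed_line}[dialect]
    counts: dict[Junction, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                j, n = parse(fields, lineno)
            except JunctionParseError as exc:
                if "non-positive intron" in str(exc) or "end must exceed" in str(exc):
                    logger.warning("rejected record: %s", exc)
                    continue
                raise
            if n < 1:
                logger.warning("line %d: count %d < 1, record skipped", lineno, n)
                continue
            counts[j] = counts.get(j, 0) + n
    return counts


def write_junction_table(path, counts: dict[Junction, int]) -> None:
    """Write counts in the TSV dialect (round-trips with :func:`parse_junction_table`)."""
    with open(path, "w") as fh:
        for j in sorted(counts):
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{counts[j]}\n")


def filter_junctions(
    table: JunctionReadTable,
    min_intron: int = MIN_INTRON,
    max_intron: int = MAX_INTRON,
    blacklist: set[Junction] | frozenset[Junction] | None = None,
) -> JunctionReadTable:
    """Drop short introns (< min_intron), long introns (> max_intron), and
    blacklisted junctions, together with their count columns.

    Idempotent; survivor order is preserved. The blacklist hook accepts
    externally identified false-positive junctions (e.g. a Portcullis call
    set) -- this package does not re-derive such calls.
    """
    blacklist = blacklist or set()
    keep = [
        v
        for v, j in enumerate(table.junctions)
        if min_intron <= j.length <= max_intron and j not in blacklist
    ]
    return JunctionReadTable(
        locus_id=table.locus_id,
        junctions=[table.junctions[v] for v in keep],
        counts=table.counts[:, keep],
        sample_ids=list(table.sample_ids),
    )


def build_loci(gene_intervals) -> list[GeneLocus]:
    """Merge overlapping gene intervals into pairwise non-overlapping loci.

    Each locus is a connected component under (half-open) interval overlap
    and spans the union of its members. Intervals are (chrom, start, end,
    name) tuples.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in gene_intervals:
        if end <= start:
            raise ValueError(f"invalid gene interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end, name))
    loci: list[GeneLocus] = []
    for chrom, ivals in sorted(by_chrom.items()):
        ivals.sort()
        cur_start, cur_end, names = ivals[0][0], ivals[0][1], [ivals[0][2]]
        for start, end, name in ivals[1:]:
            if start < cur_end:  # strict: touching half-open intervals don't merge
                cur_end = max(cur_end, end)
                names.append(name)
            else:
                loci.append(GeneLocus(chrom, cur_start, cur_end, tuple(names)))
                cur_start, cur_end, names = start, end, [name]
        loci.append(GeneLocus(chrom, cur_start, cur_end, tuple(names)))
    return loci


def assign_to_loci(
    counts: dict[Junction, dict[str, int]] | list[tuple[str, dict[Junction, int]]],
    loci: list[GeneLocus],
) -> tuple[list[JunctionReadTable], int]:
    """Split multi-sample junction counts into per-locus tables.

    Parameters
    ----------
    counts
        Either ``{junction: {sample_id: count}}`` or a list of
        ``(sample_id, {junction: count})`` pairs.
    loci
        Pairwise non-overlapping loci (from :func:`build_loci`).

    Returns
    -------
    (tables, n_dropped)
        One table per locus that received at least one junction, plus the
        total token count of junctions contained in no locus (dropped and
        logged; includes junctions straddling a locus boundary).
    """
    if isinstance(counts, list):
        merged: dict[Junction, dict[str, int]] = {}
        sample_order = [sid for sid, _ in counts]
        for sid, cmap in counts:
            for j, n in cmap.items():
                merged.setdefault(j, {})[sid] = merged.get(j, {}).get(sid, 0) + n
        counts = merged
    else:
        sample_order = sorted({sid for cmap in counts.values() for sid in cmap})

    locus_junctions: dict[int, list[Junction]] = {i: [] for i in range(len(loci))}
    n_dropped = 0
    for j in counts:
        hit = None
        for i, locus in enumerate(loci):
            if locus.contains(j):
                hit = i
                break
        if hit is None:
            n_dropped += sum(counts[j].values())
        else:
            locus_junctions[hit].append(j)
    if n_dropped:
        logger.warning("%d junction-read tokens fell outside all loci and were dropped",
                       n_dropped)

    tables = []
    for i, locus in enumerate(loci):
        juncs = sorted(locus_junctions[i])
        if not juncs:
            continue
        mat = np.zeros((len(sample_order), len(juncs)), dtype=np.int64)
        for v, j in enumerate(juncs):
            for si, sid in enumerate(sample_order):
                mat[si, v] = counts[j].get(sid, 0)
        locus_id = f"{locus.chrom}:{locus.start}-{locus.end}"
        tables.append(
            JunctionReadTable(locus_id, juncs, mat, list(sample_order))
        )
    return tables, n_dropped


def table_from_counts(counts_by_sample: list[tuple[str, dict[Junction, int]]],
                      locus_id: str = "locus") -> JunctionReadTable:
    """Build a single table from per-sample count dicts (no locus splitting)."""
    juncs = sorted({j for _, cmap in counts_by_sample for j in cmap})
    mat = np.zeros((len(counts_by_sample), len(juncs)), dtype=np.int64)
    index = {j: v for v, j in enumerate(juncs)}
    sids = []
    for i, (sid, cmap) in enumerate(counts_by_sample):
        sids.append(sid)
        for j, n in cmap.items():
            mat[i, index[j]] = n
    return JunctionReadTable(locus_id, juncs, mat, sids)


def read_gene_intervals_gtf(path) -> list[tuple[str, int, int, str]]:
    """Extract (chrom, start, end, gene_name) gene intervals from a GTF/GFF file.

    Uses ``gene`` features when present, otherwise the span of each gene_id's
    exons. GTF coordinates (1-based inclusive) are converted to 0-based
    half-open.
    """
    genes: dict[str, list] = {}
    have_gene_feature = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feature, start, end = f[0], f[1], f[2], int(f[3]) - 1, int(f[4])
            attrs = f[8]
            gid = _gtf_attr(attrs, "gene_id") or _gtf_attr(attrs, "ID") or "?"
            if feature == "gene":
                have_gene_feature = True
                genes[gid] = [chrom, start, end]
            elif feature == "exon" and not have_gene_feature:
                if gid in genes:
                    genes[gid][1] = min(genes[gid][1], start)
                    genes[gid][2] = max(genes[gid][2], end)
                else:
                    genes[gid] = [chrom, start, end]
    return [(chrom, s, e, gid) for gid, (chrom, s, e) in genes.items()]


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            val = part[len(key):].strip().strip("=").strip()
            return val.strip('"')
    return None
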