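"""Readers and writers for the interval formats the pipeline touches.

Everything inside the package uses a single coordinate convention:
0-based, half-open ``[start, end)`` intervals, the BED convention.  GTF
input (1-based, closed) is converted at the boundary and never seen
downstream.  Chromosome names are compared by exact string match;
``"chr1"`` and ``"1"`` are different chromosomes unless the caller
supplies an alias map.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval; the atom of all interval math.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).  Empty
    intervals are invalid: ``start < end`` is enforced on construction.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene with its body, exons, UTRs and strand-aware TSS/TTS.

    The TSS is the 5' end of the gene body in transcriptional
    orientation: ``start`` for a + gene, ``end - 1`` for a - gene.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"exon {ex.chrom}:{ex.start}-{ex.end} outside gene body of "
                    f"{self.gene_id}"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass
class FragmentSet:
    """One sequencing library reduced to fragment intervals.

    ``role`` is ``"IP"`` or ``"INPUT"``; ``total_mapped`` is the library
    size used for RPKM and always equals ``len(fragments)``.
    """

    library_id: str
    role: str
    mark: str
    condition: str
    fragments: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.role not in ("IP", "INPUT"):
            raise ValueError(f"role must be IP or INPUT, got {self.role!r}")

    @property
    def total_mapped(self) -> int:
        return len(self.fragments)


def _apply_alias(chrom: str, alias: Optional[Mapping[str, str]]) -> str:
    if alias is not None and chrom in alias:
        return alias[chrom]
    return chrom


def read_bed(
    path: str | os.PathLike,
    chrom_alias: Optional[Mapping[str, str]] = None,
) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak into a list of intervals, in file order.

    Columns 4-6 populate name/score/strand when present; columns beyond 6
    (narrowPeak) are ignored.  Malformed lines raise ``ValueError`` naming
    the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=_apply_alias(fields[0], chrom_alias),
                        start=start,
                        end=end,
                        strand=strand,
                        name=name,
                        score=score,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED6 (name/score default to ``.``/``0``)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            score = 0.0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score:g}\t{iv.strand}\n"
            )


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(
    path: str | os.PathLike,
    chrom_alias: Optional[Mapping[str, str]] = None,
) -> list[GeneModel]:
    """Parse GTF-style annotation into :class:`GeneModel` records.

    GTF coordinates (1-based, closed) are converted to the internal
    0-based half-open convention.  ``gene`` features define gene bodies;
    ``exon``, ``five_prime_utr``/``5UTR`` and ``three_prime_utr``/``3UTR``
    features are grouped under their ``gene_id``.  A feature whose
    ``gene_id`` never receives a ``gene`` record gets a synthesized gene
    body spanning its features (with a warning).  A missing strand is an
    error: gene models anchor strand-aware promoter logic.
    """
    bodies: dict[str, GenomicInterval] = {}
    features: dict[str, dict[str, list[GenomicInterval]]] = {}
    order: list[str] = []

    kind_map = {
        "exon": "exons",
        "five_prime_utr": "utr5",
        "5UTR": "utr5",
        "three_prime_utr": "utr3",
        "3UTR": "utr3",
    }

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: fewer than 9 columns")
            chrom, _source, ftype, start1, end1, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if ftype not in ("gene", *kind_map):
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: gene feature requires explicit strand, "
                    f"got {strand!r}"
                )
            attr_map = _parse_gtf_attributes(attrs)
            gene_id = attr_map.get("gene_id")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(
                chrom=_apply_alias(chrom, chrom_alias),
                start=start,
                end=end,
                strand=strand,
            )
            if gene_id not in features:
                features[gene_id] = {"exons": [], "utr5": [], "utr3": []}
                order.append(gene_id)
            if ftype == "gene":
                bodies[gene_id] = iv
            else:
                features[gene_id][kind_map[ftype]].append(iv)

    genes: list[GeneModel] = []
    for gene_id in order:
        parts = features[gene_id]
        body = bodies.get(gene_id)
        if body is None:
            members = parts["exons"] + parts["utr5"] + parts["utr3"]
            if not members:
                continue
            body = GenomicInterval(
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                strand=members[0].strand,
            )
            logger.warning(
                "gene %s has no gene record; synthesized body %s:%d-%d",
                gene_id,
                body.chrom,
                body.start,
                body.end,
            )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=body,
                exons=parts["exons"],
                utr5=parts["utr5"],
                utr3=parts["utr3"],
            )
        )
    return genes


def write_gene_models_gtf(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models back out as GTF (1-based closed coordinates)."""
    type_map = [("exons", "exon"), ("utr5", "five_prime_utr"), ("utr3", "three_prime_utr")]
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\thistofold\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for attr_name, ftype in type_map:
                for iv in getattr(g, attr_name):
                    fh.write(
                        f"{iv.chrom}\thistofold\t{ftype}\t{iv.start + 1}\t"
                        f"{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                    )


def read_fragments(
    path: str | os.PathLike,
    library_id: str,
    role: str,
    mark: str = "none",
    condition: str = "",
) -> FragmentSet:
    """Read a fragment BED (>= 3 columns) into a :class:`FragmentSet`.

    Uses a vectorized parser suited to million-line fragment files;
    strand/name/score columns are ignored (fragment counting is
    strand-blind).  Invalid coordinates raise with the count of bad rows.
    """
    import pandas as pd

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} fragments with invalid coordinates "
            f"(first at data row {int(bad.idxmax()) + 1})"
        )
    fragments = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    return FragmentSet(
        library_id=library_id,
        role=role,
        mark=mark,
        condition=condition,
        fragments=fragments,
    )


# ---------------------------------------------------------------------------
# Region-signal tables

REGIONS_TSV_FIXED = ["chrom", "start", "end", "mark", "n_sources"]
REGIONS_TSV_PERCOND = ["ip_count", "input_count", "ip_rpkm", "input_rpkm", "signal"]
REGIONS_TSV_TAIL = ["fold_change", "change_class"]


def write_regions_tsv(regions: Sequence, path: str | os.PathLike) -> None:
    """Persist quantified regions, sorted by (chrom, start), 6-decimal floats.

    One row per region: coordinates, per-condition IP/INPUT counts and
    RPKM, input-subtracted signal, fold change and change class.  The
    condition labels are embedded in the column names, so the file is
    self-describing and round-trips through :func:`read_regions_tsv`.
    """
    regions = sorted(regions, key=lambda r: (r.region.chrom, r.region.start))
    if regions:
        conditions = regions[0].conditions
    else:
        conditions = ("c1", "c2")
    header = list(REGIONS_TSV_FIXED)
    for cond in conditions:
        header.extend(f"{col}_{cond}" for col in REGIONS_TSV_PERCOND)
    header.extend(REGIONS_TSV_TAIL)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for r in regions:
            row = [
                r.region.chrom,
                str(r.region.start),
                str(r.region.end),
                r.mark,
                str(r.n_sources),
            ]
            for cond in conditions:
                row.extend(
                    [
                        str(r.ip_count[cond]),
                        str(r.input_count[cond]),
                        f"{r.ip_rpkm[cond]:.6f}",
                        f"{r.input_rpkm[cond]:.6f}",
                        f"{r.signal[cond]:.6f}",
                    ]
                )
            row.extend([f"{r.fold_change:.6f}", r.change_class])
            fh.write("\t".join(row) + "\n")


def read_regions_tsv(path: str | os.PathLike) -> list:
    """Read a table written by :func:`write_regions_tsv`."""
    from .diff_regions import RegionSignal  # local import: avoid cycle

    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        # condition labels are recovered from the ip_count_<cond> columns
        conditions = tuple(
            col[len("ip_count_"):] for col in header if col.startswith("ip_count_")
        )
        out: list[RegionSignal] = []
        for line in fh:
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                RegionSignal(
                    region=GenomicInterval(
                        chrom=fields["chrom"],
                        start=int(fields["start"]),
                        end=int(fields["end"]),
                    ),
                    mark=fields["mark"],
                    conditions=conditions,
                    n_sources=int(fields["n_sources"]),
                    ip_count={c: int(fields[f"ip_count_{c}"]) for c in conditions},
                    input_count={
                        c: int(fields[f"input_count_{c}"]) for c in conditions
                    },
                    ip_rpkm={c: float(fields[f"ip_rpkm_{c}"]) for c in conditions},
                    input_rpkm={
                        c: float(fields[f"input_rpkm_{c}"]) for c in conditions
                    },
                    signal={c: float(fields[f"signal_{c}"]) for c in conditions},
                    fold_change=float(fields["fold_change"]),
                    change_class=fields["change_class"],
                )
            )
    return out
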