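"""Readers, writers and domain containers for genomic data.

All coordinates are normalised to 0-based half-open intervals internally,
regardless of the source dialect.  MAF ``start``/``size`` pairs are converted
on read; BED-family formats already use this convention and pass through
unchanged.  Converters to and from 1-based inclusive coordinates are provided
for interoperability.

Every reader transparently accepts gzip-compressed input (detected by the
``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PHYLO_GROUPS = (
    "Boreoeutheria",
    "Atlantogenata",
    "MonotremesMarsupials",
    "SauropsidsAmphibians",
    "Teleosts",
)
#: phylo_group label reserved for the reference species itself
REFERENCE_GROUP = "Reference"


class MafParseError(ValueError):
    """Raised when a MAF file violates the format contract."""


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_one_based_inclusive(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def from_one_based_inclusive(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpeciesMeta:
    """Per-species genome metadata.

    ``coverage_factor`` (C_e) down-weights absence evidence from low-coverage
    assemblies: a documented default maps finished / high-coverage genomes to
    1.0 and ~2x drafts to 0.5, and any value in [0, 1] may be supplied.
    ``synteny_level`` (R_e) is the fraction of reference-adjacent gene pairs
    preserved as direct neighbours in this species; it is filled in by the
    linkage module.  Over-fragmented assemblies are flagged ``excluded`` and
    skipped by the scoring, mirroring the removal of assemblies too
    fragmented for a meaningful gene-order comparison.
    """

    species_id: str
    phylo_group: str
    genome_size: int
    coverage_factor: float = 1.0
    synteny_level: float | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.phylo_group not in PHYLO_GROUPS + (REFERENCE_GROUP,):
            raise ValueError(f"unknown phylo_group {self.phylo_group!r}")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if not 0.0 <= self.coverage_factor <= 1.0:
            raise ValueError("coverage_factor must lie in [0, 1]")
        if self.synteny_level is not None and not 0.0 <= self.synteny_level <= 1.0:
            raise ValueError("synteny_level must lie in [0, 1]")


@dataclass
class MafRow:
    """One species row of an alignment block (native coordinates)."""

    species_id: str
    chrom: str
    start: int          # 0-based on the strand given
    size: int           # ungapped length
    strand: str         # '+' or '-'
    src_size: int
    text: str           # gapped sequence

    @property
    def end(self) -> int:
        return self.start + self.size


@dataclass
class AlignmentBlock:
    """One multi-species alignment slice.

    ``rows`` maps species_id to its row; the reference row must be present.
    All gapped sequences have equal length (the number of columns).
    """

    rows: dict[str, MafRow]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.rows:
            raise ValueError(f"reference row {self.reference!r} missing from block")
        widths = {len(r.text) for r in self.rows.values()}
        if len(widths) != 1:
            raise ValueError(f"gapped sequences differ in length: {sorted(widths)}")

    @property
    def n_columns(self) -> int:
        return len(self.reference_row.text)

    @property
    def reference_row(self) -> MafRow:
        return self.rows[self.reference]

    def reference_positions(self) -> list[int | None]:
        """Reference coordinate of every column (None for reference gaps)."""
        pos = self.reference_row.start
        out: list[int | None] = []
        for ch in self.reference_row.text:
            if ch == "-":
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return out


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "Interval") -> int | None:
        """Closest-edge gap in bp; 0 if overlapping; None on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class ValuedInterval:
    chrom: str
    start: int
    end: int
    value: float
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.value < 0:
            raise ValueError("signal value must be >= 0")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.name)


@dataclass(frozen=True)
class InteractionPair:
    """A chromatin-interaction pair with the promoter-anchored gene id."""

    anchor1: Interval
    anchor2: Interval
    gene_id: str


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    species_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.gene_id, self.strand)


@dataclass
class OrthologFamily:
    """One gene family: per-species placements of a reference gene's orthologs.

    An empty per-species list means the gene is absent (or mis-annotated) in
    that species; more than one record means paralogs.
    """

    family_id: str
    reference_gene_id: str
    members: dict[str, list[GeneRecord]] = field(default_factory=dict)

    def records(self, species_id: str) -> list[GeneRecord]:
        return self.members.get(species_id, [])


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _open(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _split_src(src: str) -> tuple[str, str]:
    """Split a MAF src field ``species.chrom`` (chrom may contain dots)."""
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


def read_maf(path: str | Path, reference: str | None = None) -> Iterator[AlignmentBlock]:
    """Stream alignment blocks from a MAF file.

    ``a``/``s`` lines are parsed; ``e``, ``i``, ``q`` and track lines are
    tolerated and ignored.  The reference species defaults to the first row of
    the first block.  Malformed rows raise :class:`MafParseError` naming the
    offending line number.
    """
    with _open(path) as fh:
        rows: list[MafRow] = []
        in_block = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#") or line.startswith(("i ", "e ", "q ", "track")):
                continue
            if not line.strip():
                if in_block:
                    yield _finish_block(rows, reference, lineno)
                    rows, in_block = [], False
                continue
            if line.startswith("a"):
                if in_block:
                    yield _finish_block(rows, reference, lineno)
                    rows = []
                in_block = True
                continue
            if line.startswith("s "):
                parts = line.split()
                if len(parts) != 7:
                    raise MafParseError(f"line {lineno}: expected 7 fields on 's' line, got {len(parts)}")
                _, src, start, size, strand, src_size, text = parts
                sp, chrom = _split_src(src)
                row = MafRow(sp, chrom, int(start), int(size), strand, int(src_size), text)
                if len(text.replace("-", "")) != row.size:
                    raise MafParseError(
                        f"line {lineno}: row {src} declares size {row.size} but "
                        f"ungapped sequence has {len(text.replace('-', ''))} bases"
                    )
                rows.append(row)
                continue
            raise MafParseError(f"line {lineno}: unrecognised line {line[:40]!r}")
        if in_block:
            yield _finish_block(rows, reference, lineno)


def _finish_block(rows: list[MafRow], reference: str | None, lineno: int) -> AlignmentBlock:
    if not rows:
        raise MafParseError(f"line {lineno}: alignment block with no 's' rows")
    ref = reference if reference is not None else rows[0].species_id
    try:
        return AlignmentBlock({r.species_id: r for r in rows}, ref)
    except ValueError as exc:
        raise MafParseError(f"block ending at line {lineno}: {exc}") from exc


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    """Write alignment blocks in MAF format (reference row first)."""
    with _open(path, "wt") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            ordered = [block.reference_row] + [
                r for sp, r in block.rows.items() if sp != block.reference
            ]
            for r in ordered:
                fh.write(
                    f"s {r.species_id}.{r.chrom} {r.start} {r.size} "
                    f"{r.strand} {r.src_size} {r.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# interval formats
# ---------------------------------------------------------------------------

_INTERVAL_FORMATS = ("bed", "bedgraph", "broadpeak", "bedpe")


def read_intervals(path: str | Path, format: str) -> list[Interval] | list[ValuedInterval] | list[InteractionPair]:
    """Read BED / bedGraph / broadPeak / BEDPE records.

    Records with ``start >= end`` are rejected with a warning and counted in
    the module log rather than raising.  BEDPE rows yield
    :class:`InteractionPair` objects whose gene id is the name column.
    """
    if format not in _INTERVAL_FORMATS:
        raise ValueError(f"format must be one of {_INTERVAL_FORMATS}, got {format!r}")
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    out: list = []
    n_rejected = 0
    for idx, row in enumerate(df.itertuples(index=False, name=None)):
        try:
            if format == "bed":
                chrom, start, end = row[0], int(row[1]), int(row[2])
                name = row[3] if len(row) > 3 and pd.notna(row[3]) else None
                strand = row[5] if len(row) > 5 and pd.notna(row[5]) else None
                out.append(Interval(chrom, start, end, name, strand))
            elif format == "bedgraph":
                chrom, start, end = row[0], int(row[1]), int(row[2])
                if len(row) >= 5 and pd.notna(row[4]):
                    # 5-column dialect: name then value
                    out.append(ValuedInterval(chrom, start, end, float(row[4]), name=row[3]))
                else:
                    out.append(ValuedInterval(chrom, start, end, float(row[3])))
            elif format == "broadpeak":
                # chrom start end name score strand signalValue ...
                chrom, start, end = row[0], int(row[1]), int(row[2])
                value = float(row[6]) if len(row) > 6 and pd.notna(row[6]) else float(row[4])
                name = row[3] if pd.notna(row[3]) else None
                out.append(ValuedInterval(chrom, start, end, value, name=name))
            else:  # bedpe
                a1 = Interval(row[0], int(row[1]), int(row[2]))
                a2 = Interval(row[3], int(row[4]), int(row[5]))
                gene = row[6] if len(row) > 6 and pd.notna(row[6]) else ""
                out.append(InteractionPair(a1, a2, str(gene)))
        except ValueError:
            n_rejected += 1
            warnings.warn(f"{path}: rejected malformed record on data row {idx}")
    if n_rejected:
        logger.warning("%s: rejected %d malformed records", path, n_rejected)
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path,
              scores: Sequence[float] | None = None) -> None:
    with _open(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or scores is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if scores is not None:
                fields.append(f"{scores[i]:g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

ORTHOLOG_COLUMNS = ["family_id", "species_id", "gene_id", "chrom", "start", "end", "strand"]
SPECIES_COLUMNS = ["species_id", "phylo_group", "genome_size", "coverage_factor", "excluded"]


def read_ortholog_table(path: str | Path, species: Sequence[SpeciesMeta] | None = None) -> list[OrthologFamily]:
    """Read the ortholog family table (TSV with documented header).

    Every family must carry a row for the reference species (its reference
    gene).  Species without a row for a family map to an empty list (status
    "absent").  Duplicate (family, species, gene) rows are deduplicated with a
    warning; unknown species ids (when ``species`` metadata is given) raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "species_id": str, "gene_id": str})
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if species is not None:
        known = {s.species_id for s in species}
        offenders = sorted(set(df["species_id"]) - known)
        if offenders:
            raise ValueError(f"{path}: unknown species ids {offenders}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["family_id", "species_id", "gene_id"])
    if len(df) < n0:
        warnings.warn(f"{path}: dropped {n0 - len(df)} duplicate ortholog rows")
    known_species = [s.species_id for s in species] if species is not None else sorted(df["species_id"].unique())
    families: dict[str, OrthologFamily] = {}
    for row in df.itertuples(index=False):
        fam = families.get(row.family_id)
        if fam is None:
            fam = OrthologFamily(row.family_id, reference_gene_id="", members={sp: [] for sp in known_species})
            families[row.family_id] = fam
        rec = GeneRecord(row.gene_id, row.species_id, row.chrom, int(row.start), int(row.end), row.strand)
        fam.members.setdefault(row.species_id, []).append(rec)
    return list(families.values())


def resolve_reference_genes(families: Iterable[OrthologFamily], reference: str) -> None:
    """Fill each family's reference_gene_id from its reference-species row."""
    for fam in families:
        recs = fam.records(reference)
        if not recs:
            raise ValueError(f"family {fam.family_id} has no gene in reference species {reference}")
        fam.reference_gene_id = recs[0].gene_id


def write_ortholog_table(families: Iterable[OrthologFamily], path: str | Path) -> None:
    rows = []
    for fam in families:
        for sp, recs in fam.members.items():
            for r in recs:
                rows.append((fam.family_id, sp, r.gene_id, r.chrom, r.start, r.end, r.strand))
    pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS).to_csv(path, sep="\t", index=False)


#: default coverage factors by assembly class
COVERAGE_DEFAULTS = {"finished": 1.0, "high": 1.0, "draft2x": 0.5}


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    """Read species metadata TSV (species_id, phylo_group, genome_size,
    coverage_factor, excluded).  ``coverage_factor`` may be a number or one of
    the class labels in :data:`COVERAGE_DEFAULTS`."""
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "phylo_group": str})
    missing = set(SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        cov = row.coverage_factor
        if isinstance(cov, str) and cov in COVERAGE_DEFAULTS:
            cov = COVERAGE_DEFAULTS[cov]
        out.append(SpeciesMeta(
            species_id=row.species_id,
            phylo_group=row.phylo_group,
            genome_size=int(row.genome_size),
            coverage_factor=float(cov),
            excluded=bool(row.excluded),
        ))
    refs = [s for s in out if s.phylo_group == REFERENCE_GROUP]
    if len(refs) != 1:
        raise ValueError(f"{path}: expected exactly one Reference species, found {len(refs)}")
    return out


def write_species_meta(species: Iterable[SpeciesMeta], path: str | Path) -> None:
    rows = [(s.species_id, s.phylo_group, s.genome_size, s.coverage_factor, s.excluded)
            for s in species]
    pd.DataFrame(rows, columns=SPECIES_COLUMNS).to_csv(path, sep="\t", index=False)


def reference_species(species: Sequence[SpeciesMeta]) -> SpeciesMeta:
    return next(s for s in species if s.phylo_group == REFERENCE_GROUP)
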