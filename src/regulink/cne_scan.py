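"""Conserved noncoding element (CNE) calling from multi-species alignments.

The scanner works in alignment-column space, one block at a time (multiZ
blocks are syntenic units, so elements are never stitched across block
boundaries):

1. columns falling in exon or repeat masks — or in a reference gap — are
   masked out;
2. each remaining column is classified conserved or not: a column is
   conserved iff at least ``min_species_beyond_ref`` non-reference species
   are aligned (non-gap) there and the number of species differing from the
   reference base is at most ``ceil(column_mismatch_fraction * n)``, with
   ``n`` the number of aligned rows including the reference (at the minimum
   of seven species beyond the reference this allows one substitution);
3. core windows of ``core_window`` columns containing at least 90% conserved
   columns seed candidate elements; overlapping cores are unioned;
4. seeds are extended outward while runs of non-conserved columns stay at or
   below ``max_nonconserved_run``, stopping at a longer run, a masked column
   or the block edge, then trimmed so the element ends on conserved columns;
5. elements conserved in the same species subset, separated by fewer than
   ``fuse_max_gap`` bp on the reference and consecutive in every shared
   species are fused.

Each element is scored by summing, over the five phylogenetic groups
(Boreoeutheria, Atlantogenata, Monotremes/Marsupials, Sauropsids/Amphibians,
Teleosts), the maximum percent identity to the reference among the group's
aligned species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import (
    AlignmentBlock,
    Interval,
    SpeciesMeta,
    PHYLO_GROUPS,
    REFERENCE_GROUP,
)


@dataclass
class ScanParams:
    """Tunable thresholds of the scanner (defaults follow the method)."""

    min_species_beyond_ref: int = 7
    column_mismatch_fraction: float = 0.12
    core_window: int = 10
    core_min_conserved_fraction: float = 0.90
    max_nonconserved_run: int = 3
    fuse_max_gap: int = 100
    # optional global post-filters (off by default; the core/extension rules
    # already bound length and identity)
    min_length: int | None = None
    min_mean_identity: float | None = None
    #: fraction of element columns a species must align to count in species_set
    species_min_aligned_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_species_beyond_ref < 1 or self.core_window < 1:
            raise ValueError("thresholds must be positive")
        for f in (self.column_mismatch_fraction, self.core_min_conserved_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if self.max_nonconserved_run < 0 or self.fuse_max_gap <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def core_min_conserved(self) -> int:
        return int(np.ceil(self.core_min_conserved_fraction * self.core_window))

    def allowed_mismatches(self, n_aligned: int) -> int:
        """Maximum substitutions tolerated in a column of ``n_aligned`` rows
        (reference included): ceil(fraction * n), which allows exactly one
        substitution in the minimal 8-row case."""
        return int(np.ceil(self.column_mismatch_fraction * n_aligned))


@dataclass(eq=False)
class CNE:
    """A called conserved noncoding element on the reference genome.

    Instances compare by identity (an element is one call, not a value)."""

    cne_id: str
    interval: Interval                     # reference coordinates
    species_set: frozenset[str]            # species (beyond ref) aligned over the element
    locations: dict[str, Interval]         # per-species orthologous location (native frame)
    conservation_score: float = 0.0
    column_mask: np.ndarray | None = None  # conserved-column mask over the element
    source: str = "scan"                   # "scan" or "external"

    @property
    def length(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# column classification
# ---------------------------------------------------------------------------

def mask_columns(block: AlignmentBlock,
                 exon_intervals: Sequence[Interval] = (),
                 repeat_intervals: Sequence[Interval] = ()) -> np.ndarray:
    """Boolean mask over block columns: True = masked (excluded).

    A column is masked iff its reference base falls inside any exon or repeat
    interval, or the reference row has a gap there.
    """
    positions = block.reference_positions()
    chrom = block.reference_row.chrom
    masked = np.array([p is None for p in positions], dtype=bool)
    spans = [(iv.start, iv.end) for iv in list(exon_intervals) + list(repeat_intervals)
             if iv.chrom == chrom]
    if spans:
        pos = np.array([-1 if p is None else p for p in positions])
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        hit = ((pos[:, None] >= starts[None, :]) & (pos[:, None] < ends[None, :])).any(axis=1)
        masked |= hit & (pos >= 0)
    return masked


def _block_arrays(block: AlignmentBlock) -> tuple[np.ndarray, list[str]]:
    """Uppercase byte matrix (rows x columns) with the reference first."""
    order = [block.reference] + sorted(sp for sp in block.rows if sp != block.reference)
    mat = np.array([list(block.rows[sp].text.upper()) for sp in order], dtype="U1")
    return mat, order


def conserved_columns(block: AlignmentBlock, params: ScanParams) -> np.ndarray:
    """Vectorised per-column conservation classification."""
    mat, order = _block_arrays(block)
    ref = mat[0]
    aligned = mat != "-"
    n_aligned = aligned.sum(axis=0)
    n_nonref_aligned = aligned[1:].sum(axis=0)
    mismatch = (mat[1:] != ref[None, :]) & aligned[1:] & (ref[None, :] != "-")
    n_mismatch = mismatch.sum(axis=0)
    allowed = np.ceil(params.column_mismatch_fraction * n_aligned).astype(int)
    ok = (n_nonref_aligned >= params.min_species_beyond_ref) & (n_mismatch <= allowed)
    ok &= ref != "-"
    return ok


def column_conserved(column: Mapping[str, str], reference: str, params: ScanParams) -> bool:
    """Classify a single alignment column.

    ``column`` maps species_id to its character ('-' for a gap); the
    reference species' base must be present and non-gap.
    """
    ref_base = column[reference].upper()
    if ref_base == "-":
        return False
    aligned = {sp: b.upper() for sp, b in column.items() if b != "-"}
    n_nonref = len([sp for sp in aligned if sp != reference])
    if n_nonref < params.min_species_beyond_ref:
        return False
    n_mismatch = sum(1 for sp, b in aligned.items() if sp != reference and b != ref_base)
    return n_mismatch <= params.allowed_mismatches(len(aligned))


# ---------------------------------------------------------------------------
# cores, extension
# ---------------------------------------------------------------------------

def find_cores(conserved: np.ndarray, params: ScanParams,
               masked: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Seed intervals: unions of overlapping qualifying core windows.

    A window of ``core_window`` columns qualifies if it contains at least
    ``core_min_conserved`` conserved columns and no masked column.
    """
    n = len(conserved)
    w = params.core_window
    if masked is None:
        masked = np.zeros(n, dtype=bool)
    if n < w:
        return []
    cons = np.convolve(conserved.astype(int), np.ones(w, dtype=int), mode="valid")
    bad = np.convolve(masked.astype(int), np.ones(w, dtype=int), mode="valid")
    ok = (cons >= params.core_min_conserved) & (bad == 0)
    seeds: list[tuple[int, int]] = []
    for i in np.flatnonzero(ok):
        if seeds and i < seeds[-1][1]:
            seeds[-1] = (seeds[-1][0], i + w)
        else:
            seeds.append((i, i + w))
    return seeds


def extend_seed(seed: tuple[int, int], conserved: np.ndarray,
                params: ScanParams, masked: np.ndarray | None = None) -> tuple[int, int]:
    """Extend a seed outward across runs of up to ``max_nonconserved_run``
    non-conserved columns, stop at a longer run / masked column / block edge,
    and trim so both ends are conserved columns."""
    n = len(conserved)
    if masked is None:
        masked = np.zeros(n, dtype=bool)
    lo, hi = seed
    run = 0
    j = hi
    while j < n and not masked[j]:
        if conserved[j]:
            run = 0
        else:
            run += 1
            if run > params.max_nonconserved_run:
                break
        j += 1
    hi = j
    run = 0
    i = lo - 1
    while i >= 0 and not masked[i]:
        if conserved[i]:
            run = 0
        else:
            run += 1
            if run > params.max_nonconserved_run:
                break
        i -= 1
    lo = i + 1
    # trim to conserved ends
    while lo < hi and not conserved[lo]:
        lo += 1
    while hi > lo and not conserved[hi - 1]:
        hi -= 1
    return lo, hi


# ---------------------------------------------------------------------------
# element assembly
# ---------------------------------------------------------------------------

def _species_location(block: AlignmentBlock, species: str, lo: int, hi: int) -> Interval | None:
    """Native-frame interval spanned by a species row over columns [lo, hi)."""
    row = block.rows[species]
    text = row.text
    before = len(text[:lo].replace("-", ""))
    inside = len(text[lo:hi].replace("-", ""))
    if inside == 0:
        return None
    return Interval(row.chrom, row.start + before, row.start + before + inside,
                    strand=row.strand)


def _element_from_columns(block: AlignmentBlock, lo: int, hi: int,
                          params: ScanParams, conserved: np.ndarray,
                          idx: int) -> CNE | None:
    positions = block.reference_positions()
    ref_pos = [positions[c] for c in range(lo, hi) if positions[c] is not None]
    if not ref_pos:
        return None
    ref_iv = Interval(block.reference_row.chrom, ref_pos[0], ref_pos[-1] + 1)
    mat, order = _block_arrays(block)
    aligned = mat != "-"
    cols = slice(lo, hi)
    species_set = set()
    locations: dict[str, Interval] = {}
    for r, sp in enumerate(order):
        if sp == block.reference:
            continue
        frac = aligned[r, cols].mean()
        if frac >= params.species_min_aligned_fraction:
            loc = _species_location(block, sp, lo, hi)
            if loc is not None:
                species_set.add(sp)
                locations[sp] = loc
    if len(species_set) < params.min_species_beyond_ref:
        return None
    return CNE(
        cne_id=f"cne{idx:06d}",
        interval=ref_iv,
        species_set=frozenset(species_set),
        locations=locations,
        column_mask=conserved[lo:hi].copy(),
    )


def _contains_core(conserved: np.ndarray, masked: np.ndarray,
                   lo: int, hi: int, params: ScanParams) -> bool:
    w = params.core_window
    if hi - lo < w:
        return False
    sub = conserved[lo:hi]
    msk = masked[lo:hi]
    cons = np.convolve(sub.astype(int), np.ones(w, dtype=int), mode="valid")
    bad = np.convolve(msk.astype(int), np.ones(w, dtype=int), mode="valid")
    return bool(((cons >= params.core_min_conserved) & (bad == 0)).any())


def scan_block(block: AlignmentBlock, params: ScanParams,
               exon_intervals: Sequence[Interval] = (),
               repeat_intervals: Sequence[Interval] = (),
               start_idx: int = 0) -> list[CNE]:
    """Call CNEs within one alignment block."""
    masked = mask_columns(block, exon_intervals, repeat_intervals)
    conserved = conserved_columns(block, params) & ~masked
    seeds = find_cores(conserved, params, masked)
    seen: set[tuple[int, int]] = set()
    out: list[CNE] = []
    for seed in seeds:
        lo, hi = extend_seed(seed, conserved, params, masked)
        if (lo, hi) in seen or hi <= lo:
            continue
        seen.add((lo, hi))
        if not _contains_core(conserved, masked, lo, hi, params):
            continue
        cne = _element_from_columns(block, lo, hi, params, conserved, start_idx + len(out))
        if cne is None:
            continue
        if params.min_length is not None and cne.length < params.min_length:
            continue
        out.append(cne)
    return out


def call_cnes(blocks: Iterable[AlignmentBlock], params: ScanParams | None = None,
              exon_intervals: Sequence[Interval] = (),
              repeat_intervals: Sequence[Interval] = ()) -> list[CNE]:
    """Scan a stream of blocks; elements live entirely inside one block."""
    params = params or ScanParams()
    out: list[CNE] = []
    for block in blocks:
        out.extend(scan_block(block, params, exon_intervals, repeat_intervals,
                              start_idx=len(out)))
    return out


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def _adjacent_in_all_species(a: CNE, b: CNE, by_species: dict[str, list[CNE]]) -> bool:
    """True iff a and b are consecutive (no intervening called element) in the
    genomic order of every shared species."""
    for sp in a.species_set:
        order = by_species[sp]
        ia, ib = order.index(a), order.index(b)
        if abs(ia - ib) != 1:
            return False
    return True


def fuse_cnes(cnes: Sequence[CNE], params: ScanParams | None = None) -> list[CNE]:
    """Fuse elements conserved in the same species subset, < ``fuse_max_gap``
    bp apart on the reference, and consecutive in every shared species.

    Fusion is applied transitively along the reference order and is
    idempotent.
    """
    params = params or ScanParams()
    cnes = sorted(cnes, key=lambda c: (c.interval.chrom, c.interval.start))
    by_species: dict[str, list[CNE]] = {}
    for c in cnes:
        for sp in c.species_set:
            by_species.setdefault(sp, []).append(c)
    for sp in by_species:
        by_species[sp].sort(key=lambda c: (c.locations[sp].chrom, c.locations[sp].start))

    fused: list[CNE] = []
    group: list[CNE] = []

    def flush() -> None:
        if not group:
            return
        if len(group) == 1:
            fused.append(group[0])
        else:
            fused.append(_merge_group(group))

    for c in cnes:
        if group and _fusable(group[-1], c, params, by_species):
            group.append(c)
        else:
            flush()
            group = [c]
    flush()
    return fused


def _fusable(a: CNE, b: CNE, params: ScanParams, by_species: dict[str, list[CNE]]) -> bool:
    if a.species_set != b.species_set:
        return False
    if a.interval.chrom != b.interval.chrom:
        return False
    gap = b.interval.start - a.interval.end
    if gap < 0 or gap >= params.fuse_max_gap:
        return False
    return _adjacent_in_all_species(a, b, by_species)


def _merge_group(group: list[CNE]) -> CNE:
    first, last = group[0], group[-1]
    iv = Interval(first.interval.chrom, first.interval.start, last.interval.end)
    locations: dict[str, Interval] = {}
    for sp in first.species_set:
        locs = [c.locations[sp] for c in group if sp in c.locations]
        locations[sp] = Interval(locs[0].chrom, min(l.start for l in locs),
                                 max(l.end for l in locs), strand=locs[0].strand)
    mask = None
    if all(c.column_mask is not None for c in group):
        parts = []
        for i, c in enumerate(group):
            parts.append(c.column_mask)
            if i + 1 < len(group):
                gap = group[i + 1].interval.start - c.interval.end
                parts.append(np.zeros(gap, dtype=bool))
        mask = np.concatenate(parts)
    return CNE(cne_id=first.cne_id, interval=iv, species_set=first.species_set,
               locations=locations, column_mask=mask)


# ---------------------------------------------------------------------------
# conservation score
# ---------------------------------------------------------------------------

def percent_identity(ref_seq: str, sp_seq: str) -> float | None:
    """Percent identity over columns where both sequences are non-gap,
    rounded to the nearest integer; None if no such column exists."""
    pairs = [(a, b) for a, b in zip(ref_seq.upper(), sp_seq.upper())
             if a != "-" and b != "-"]
    if not pairs:
        return None
    matches = sum(1 for a, b in pairs if a == b)
    return float(round(100.0 * matches / len(pairs)))


def conservation_score(group_identities: Mapping[str, float]) -> float:
    """Sum of per-phylogenetic-group maximum percent identities.

    ``group_identities`` maps each represented group to the maximum percent
    identity among its species; absent groups contribute 0.  The worked
    behaviour: maxima {97, 68, 62, 54, 49} over the five groups give 330.
    """
    return float(sum(group_identities.get(g, 0.0) for g in PHYLO_GROUPS))


def score_cne(cne: CNE, block: AlignmentBlock, lo: int, hi: int,
              species_meta: Mapping[str, SpeciesMeta]) -> float:
    """Compute a CNE's conservation score from its block columns."""
    ref_seq = block.reference_row.text[lo:hi]
    per_group: dict[str, float] = {}
    for sp in cne.species_set:
        meta = species_meta.get(sp)
        if meta is None or meta.phylo_group == REFERENCE_GROUP:
            continue
        pid = percent_identity(ref_seq, block.rows[sp].text[lo:hi])
        if pid is None:
            continue
        g = meta.phylo_group
        per_group[g] = max(per_group.get(g, 0.0), pid)
    return conservation_score(per_group)


def score_cnes_in_blocks(cnes: Sequence[CNE], blocks: Sequence[AlignmentBlock],
                         species_meta: Mapping[str, SpeciesMeta]) -> list[CNE]:
    """Attach conservation scores, matching each (possibly fused) element to
    the block columns it spans.  Scoring is applied post-fusion."""
    out = []
    for cne in cnes:
        block = _containing_block(cne, blocks)
        if block is None:
            out.append(cne)
            continue
        lo, hi = _column_span(block, cne.interval)
        out.append(replace(cne, conservation_score=score_cne(cne, block, lo, hi, species_meta)))
    return out


def _containing_block(cne: CNE, blocks: Sequence[AlignmentBlock]) -> AlignmentBlock | None:
    for b in blocks:
        r = b.reference_row
        if r.chrom == cne.interval.chrom and r.start <= cne.interval.start and cne.interval.end <= r.end:
            return b
    return None


def _column_span(block: AlignmentBlock, iv: Interval) -> tuple[int, int]:
    positions = block.reference_positions()
    lo = next(c for c, p in enumerate(positions) if p is not None and p >= iv.start)
    hi = max(c for c, p in enumerate(positions) if p is not None and p < iv.end) + 1
    return lo, hi


# ---------------------------------------------------------------------------
# merging with an external element set
# ---------------------------------------------------------------------------

def merge_external(cnes: Sequence[CNE], external: Sequence[Interval]) -> list[CNE]:
    """Union the scanner's elements with an externally derived element set.

    Overlapping intervals (native or external) collapse into one element per
    maximal union interval; purely external elements carry an empty
    species_set (no per-species data)."""
    items: list[tuple[Interval, CNE | None]] = [(c.interval, c) for c in cnes]
    items += [(iv, None) for iv in external]
    items.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[CNE] = []
    cur: list[tuple[Interval, CNE | None]] = []
    cur_end = None
    cur_chrom = None

    def flush() -> None:
        if not cur:
            return
        ivs = [iv for iv, _ in cur]
        natives = [c for _, c in cur if c is not None]
        merged = Interval(ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs))
        if natives:
            base = natives[0]
            out.append(replace(base, interval=merged))
        else:
            out.append(CNE(cne_id=f"ext{len(out):06d}", interval=merged,
                           species_set=frozenset(), locations={}, source="external"))

    for iv, c in items:
        # book-ended intervals merge: the union is over base positions
        if cur and iv.chrom == cur_chrom and iv.start <= cur_end:
            cur.append((iv, c))
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cur = [(iv, c)]
            cur_chrom, cur_end = iv.chrom, iv.end
    flush()
    return out
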