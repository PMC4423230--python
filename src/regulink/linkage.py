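"""Evolutionary linkage scoring between CNEs and candidate target genes.

For a CNE aligned in a set of species, each candidate gene family (reference
gene within the search radius) receives a per-species status:

* ``S1`` — an ortholog lies within the scaled distance ``d_e`` of the
  orthologous CNE location;
* ``S2`` — an ortholog shares the chromosome but lies beyond ``d_e``;
* ``S3`` — orthologs exist only on other chromosomes or scaffolds;
* ``S0`` — the family has no annotated gene in that species.

The search radius (1 Mb on the reference by default) is scaled per species by
relative genome size: a genome 80% the size of the reference is searched with
d = 0.8 Mb.  Statuses are combined into a raw score in which preserved
linkage in a highly rearranged genome is strong positive evidence, and
absence or broken linkage is penalised in proportion to how much the
assembly can be trusted:

    raw = sum over species e of  w(status_e)
    w(S1) = +(1 - R_e)      w(S2) = -0.5 * C_e
    w(S3) = -1.0 * C_e      w(S0) = -0.25 * C_e

where R_e is the species' synteny level (fraction of reference-adjacent gene
pairs preserved as direct neighbours; 1 for the reference against itself, so
a reference-like genome carries no evidence) and C_e the sequencing-coverage
factor.  The weights are configurable; the defaults satisfy the contract
that improving any species' status along S3 -> S2 -> S1 strictly increases
the raw score (for C_e > 0).

Raw scores are mapped to the absolute linkage score S_A in (0, 1) with a
sigmoid 1/(1 + exp(-k (raw - m))), k = 1 and m = the median raw score of the
run by default.  Per CNE, all families attaining the maximal S_A are kept as
targets (ties retained), and the relative score is the gap between the best
and second-best distinct S_A.  Finally, consecutive CNEs with identical
target sets separated by <100 bp are fused into regulatory elements
("RegHsa"-style elements).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cne_scan import CNE
from .genome_io import GeneRecord, Interval, OrthologFamily, SpeciesMeta


class Status(enum.IntEnum):
    S0 = 0  # absent / mis-annotated
    S1 = 1  # linked within d_e
    S2 = 2  # same chromosome, beyond d_e
    S3 = 3  # different chromosome or scaffold


@dataclass
class LinkageWeights:
    """Coefficients of the raw-score terms (config-overridable)."""

    s1_synteny_gain: float = 1.0     # multiplies (1 - R_e)
    s2_penalty: float = -0.5         # multiplies C_e
    s3_penalty: float = -1.0         # multiplies C_e
    s0_penalty: float = -0.25        # multiplies C_e
    sigmoid_k: float = 1.0
    sigmoid_midpoint: float | None = None  # None -> median of the run

    def weight(self, status: Status, meta: SpeciesMeta) -> float:
        r = meta.synteny_level if meta.synteny_level is not None else 1.0
        c = meta.coverage_factor
        if status is Status.S1:
            return self.s1_synteny_gain * (1.0 - r)
        if status is Status.S2:
            return self.s2_penalty * c
        if status is Status.S3:
            return self.s3_penalty * c
        return self.s0_penalty * c


@dataclass
class StatusTrail:
    """Per-species status of one (CNE, family) pair."""

    statuses: dict[str, Status] = field(default_factory=dict)
    scaled_distances: dict[str, float] = field(default_factory=dict)


@dataclass
class LinkageAssignment:
    cne_id: str
    family_id: str
    raw_score: float
    s_a: float | None = None
    relative_score: float | None = None
    trail: StatusTrail | None = None


@dataclass(eq=False)
class RegElement:
    """A fused cluster of co-targeting CNEs ("RegHsa"-style element)."""

    element_id: str
    interval: Interval
    cne_ids: list[str]
    target_families: frozenset[str]
    max_s_a: float | None


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def scaled_radius(d_ref: float, genome_size_e: int, genome_size_ref: int) -> float:
    """Search radius in species e: d_ref scaled by relative genome size."""
    if genome_size_e <= 0 or genome_size_ref <= 0:
        raise ValueError("genome sizes must be positive")
    return d_ref * genome_size_e / genome_size_ref


def candidate_families(cne: CNE, families: Sequence[OrthologFamily],
                       reference: str, d_ref: float = 1_000_000.0) -> list[OrthologFamily]:
    """Families whose reference gene lies within ``d_ref`` of the CNE
    (closest-edge gap; 0 if overlapping).  Empty if no gene is close enough
    (an unassociated element)."""
    out = []
    for fam in families:
        for rec in fam.records(reference):
            gap = cne.interval.gap_to(rec.interval)
            if gap is not None and gap < d_ref:
                out.append(fam)
                break
    return out


def classify_status(cne: CNE, family: OrthologFamily, species_id: str,
                    d_e: float) -> Status:
    """Status of a family's ortholog(s) relative to the orthologous CNE in
    one species.  With paralogs the most favourable status (S1 > S2 > S3)
    applies.  The species must have the CNE aligned."""
    if species_id not in cne.locations:
        raise ValueError(f"CNE {cne.cne_id} is not aligned in species {species_id}")
    recs = family.records(species_id)
    if not recs:
        return Status.S0
    loc = cne.locations[species_id]
    best = Status.S3
    for rec in recs:
        gap = loc.gap_to(rec.interval)
        if gap is None:
            continue
        if gap < d_e:
            return Status.S1
        best = Status.S2
    return best


# ---------------------------------------------------------------------------
# synteny level R_e
# ---------------------------------------------------------------------------

def synteny_level(reference_order: Sequence[GeneRecord],
                  families: Sequence[OrthologFamily],
                  species_id: str) -> float:
    """R_e = P_e / H: fraction of reference-adjacent gene pairs whose
    orthologs are direct neighbours (same chromosome, adjacent in gene order,
    orientation ignored) in species e.

    ``reference_order`` is the reference gene list; adjacency is taken within
    chromosomes.  H = 0 raises.
    """
    by_gene = {f.reference_gene_id: f for f in families}
    ordered = sorted(reference_order, key=lambda g: (g.chrom, g.start))
    pairs = [(a, b) for a, b in zip(ordered, ordered[1:]) if a.chrom == b.chrom]
    if not pairs:
        raise ValueError("no adjacent reference gene pairs (H = 0)")

    # species gene order: all ortholog placements of the reference genes
    placements: list[tuple[str, int, str]] = []  # (chrom, start, family_id)
    for fam in families:
        for rec in fam.records(species_id):
            placements.append((rec.chrom, rec.start, fam.family_id))
    placements.sort()
    neighbour_pairs = set()
    for (c1, _, f1), (c2, _, f2) in zip(placements, placements[1:]):
        if c1 == c2:
            neighbour_pairs.add(frozenset((f1, f2)))

    preserved = 0
    for a, b in pairs:
        fa, fb = by_gene.get(a.gene_id), by_gene.get(b.gene_id)
        if fa is None or fb is None or fa is fb:
            continue
        if frozenset((fa.family_id, fb.family_id)) in neighbour_pairs:
            preserved += 1
    return preserved / len(pairs)


def fill_synteny_levels(species: Sequence[SpeciesMeta],
                        reference_order: Sequence[GeneRecord],
                        families: Sequence[OrthologFamily],
                        reference: str) -> None:
    """Compute and store R_e for every species (reference gets 1)."""
    for meta in species:
        if meta.species_id == reference:
            meta.synteny_level = 1.0
        else:
            meta.synteny_level = synteny_level(reference_order, families, meta.species_id)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def build_trail(cne: CNE, family: OrthologFamily,
                meta: Mapping[str, SpeciesMeta], d_ref: float) -> StatusTrail:
    trail = StatusTrail()
    ref_size = next(m.genome_size for m in meta.values() if m.species_id == _reference_id(meta))
    for sp in sorted(cne.species_set):
        m = meta.get(sp)
        if m is None:
            raise KeyError(f"species {sp} in CNE trail has no metadata")
        if m.excluded:
            continue
        d_e = scaled_radius(d_ref, m.genome_size, ref_size)
        trail.scaled_distances[sp] = d_e
        trail.statuses[sp] = classify_status(cne, family, sp, d_e)
    return trail


def _reference_id(meta: Mapping[str, SpeciesMeta]) -> str:
    from .genome_io import REFERENCE_GROUP
    return next(m.species_id for m in meta.values() if m.phylo_group == REFERENCE_GROUP)


def raw_linkage(trail: StatusTrail, meta: Mapping[str, SpeciesMeta],
                weights: LinkageWeights | None = None) -> float:
    """Sum of per-species status weights (excluded species never appear)."""
    weights = weights or LinkageWeights()
    total = 0.0
    for sp, status in trail.statuses.items():
        m = meta.get(sp)
        if m is None:
            raise KeyError(f"species {sp} in trail has no metadata")
        total += weights.weight(status, m)
    return total


def normalize_scores(raw_scores: Sequence[float],
                     weights: LinkageWeights | None = None) -> np.ndarray:
    """Sigmoid normalisation of raw scores into (0, 1); strictly monotone."""
    weights = weights or LinkageWeights()
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        return raw
    m = weights.sigmoid_midpoint
    if m is None:
        m = float(np.median(raw))
    out = 1.0 / (1.0 + np.exp(-weights.sigmoid_k * (raw - m)))
    # keep the open-interval contract under floating-point saturation
    tiny = np.finfo(float).tiny
    return np.clip(out, tiny, 1.0 - np.finfo(float).epsneg)


def rank_and_select(assignments: Sequence[LinkageAssignment]
                    ) -> tuple[frozenset[str], float | None]:
    """Target set (all families at the maximal S_A; ties kept) and relative
    score (best minus second-best *distinct* S_A; None with < 2 candidates).

    An empty assignment list yields an empty target set (unassociated
    element)."""
    if not assignments:
        return frozenset(), None
    scores = sorted({a.s_a for a in assignments}, reverse=True)
    best = scores[0]
    targets = frozenset(a.family_id for a in assignments if a.s_a == best)
    relative = None
    if len(assignments) >= 2 and len(scores) >= 2:
        relative = best - scores[1]
    elif len(assignments) >= 2:
        relative = 0.0  # several candidates, all tied
    return targets, relative


def score_all(cnes: Sequence[CNE], families: Sequence[OrthologFamily],
              meta: Mapping[str, SpeciesMeta], reference: str,
              d_ref: float = 1_000_000.0,
              weights: LinkageWeights | None = None
              ) -> dict[str, list[LinkageAssignment]]:
    """Score every (CNE, candidate family) pair; returns assignments grouped
    by cne_id with S_A and relative scores filled in."""
    weights = weights or LinkageWeights()
    all_assignments: list[LinkageAssignment] = []
    per_cne: dict[str, list[LinkageAssignment]] = {}
    for cne in cnes:
        cands = candidate_families(cne, families, reference, d_ref)
        per_cne[cne.cne_id] = []
        for fam in cands:
            trail = build_trail(cne, fam, meta, d_ref)
            raw = raw_linkage(trail, meta, weights)
            a = LinkageAssignment(cne.cne_id, fam.family_id, raw, trail=trail)
            per_cne[cne.cne_id].append(a)
            all_assignments.append(a)
    if all_assignments:
        s_a = normalize_scores([a.raw_score for a in all_assignments], weights)
        for a, s in zip(all_assignments, s_a):
            a.s_a = float(s)
    for cne_id, assigns in per_cne.items():
        targets, relative = rank_and_select(assigns)
        for a in assigns:
            if a.s_a is not None and a.family_id in targets:
                a.relative_score = relative
    return per_cne


# ---------------------------------------------------------------------------
# regulatory-element fusion
# ---------------------------------------------------------------------------

def fuse_reg_elements(cnes: Sequence[CNE],
                      per_cne: Mapping[str, Sequence[LinkageAssignment]],
                      max_gap: int = 100) -> list[RegElement]:
    """Chain-fuse consecutive CNEs with set-identical targets and an
    inter-element gap < ``max_gap`` bp; idempotent; the element interval
    spans its constituents."""
    info = {}
    for cne in cnes:
        targets, _ = rank_and_select(list(per_cne.get(cne.cne_id, [])))
        best = max((a.s_a for a in per_cne.get(cne.cne_id, []) if a.s_a is not None),
                   default=None)
        info[cne.cne_id] = (targets, best)
    ordered = sorted(cnes, key=lambda c: (c.interval.chrom, c.interval.start))
    elements: list[RegElement] = []
    group: list[CNE] = []

    def flush() -> None:
        if not group:
            return
        targets, _ = info[group[0].cne_id]
        best = max((info[c.cne_id][1] for c in group if info[c.cne_id][1] is not None),
                   default=None)
        iv = Interval(group[0].interval.chrom, group[0].interval.start,
                      group[-1].interval.end)
        elements.append(RegElement(
            element_id=f"Reg{len(elements):06d}",
            interval=iv, cne_ids=[c.cne_id for c in group],
            target_families=targets, max_s_a=best))

    for c in ordered:
        if group:
            prev = group[-1]
            gap = c.interval.start - prev.interval.end
            same_chrom = c.interval.chrom == prev.interval.chrom
            same_targets = info[c.cne_id][0] == info[prev.cne_id][0]
            nonempty = len(info[c.cne_id][0]) > 0
            if same_chrom and 0 <= gap < max_gap and same_targets and nonempty:
                group.append(c)
                continue
        flush()
        group = [c]
    flush()
    return elements
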