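"""End-to-end orchestration: scan -> score -> fuse -> annotate.

These helpers wire the modules together the way the command-line interface
and the examples use them; each step remains individually importable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import cne_scan, genome_io, linkage
from .cne_scan import CNE, ScanParams
from .genome_io import AlignmentBlock, Interval, SpeciesMeta
from .linkage import LinkageAssignment, LinkageWeights, RegElement


@dataclass
class ScanResult:
    cnes: list[CNE]
    blocks: list[AlignmentBlock]


@dataclass
class ScoreResult:
    assignments: dict[str, list[LinkageAssignment]]
    elements: list[RegElement]

    def best_targets(self, cne_id: str) -> frozenset[str]:
        targets, _ = linkage.rank_and_select(self.assignments.get(cne_id, []))
        return targets


def scan_maf(maf_path, species_meta: Sequence[SpeciesMeta],
             exons: Sequence[Interval] = (), repeats: Sequence[Interval] = (),
             params: ScanParams | None = None) -> ScanResult:
    """Read a MAF, call, fuse and score CNEs."""
    params = params or ScanParams()
    reference = genome_io.reference_species(species_meta).species_id
    blocks = list(genome_io.read_maf(maf_path, reference=reference))
    cnes = cne_scan.call_cnes(blocks, params, exons, repeats)
    cnes = cne_scan.fuse_cnes(cnes, params)
    meta = {m.species_id: m for m in species_meta}
    cnes = cne_scan.score_cnes_in_blocks(cnes, blocks, meta)
    return ScanResult(cnes, blocks)


def score_cnes(cnes: Sequence[CNE], families, species_meta: Sequence[SpeciesMeta],
               d_ref: float = 1_000_000.0,
               weights: LinkageWeights | None = None) -> ScoreResult:
    """Fill synteny levels, score every (CNE, family) pair, select targets
    and fuse co-targeting CNEs into regulatory elements."""
    reference = genome_io.reference_species(species_meta).species_id
    genome_io.resolve_reference_genes(families, reference)
    ref_order = sorted((f.records(reference)[0] for f in families),
                       key=lambda g: (g.chrom, g.start))
    linkage.fill_synteny_levels(species_meta, ref_order, families, reference)
    meta = {m.species_id: m for m in species_meta}
    assignments = linkage.score_all(cnes, families, meta, reference,
                                    d_ref=d_ref, weights=weights)
    elements = linkage.fuse_reg_elements(cnes, assignments)
    return ScoreResult(assignments, elements)


def match_to_planted(cnes: Sequence[CNE],
                     planted_intervals: Mapping[str, tuple[int, int]]
                     ) -> dict[str, CNE]:
    """Map planted element ids to the called CNE overlapping them (if any)."""
    out: dict[str, CNE] = {}
    for pid, (start, end) in planted_intervals.items():
        for c in cnes:
            if c.interval.start < end and c.interval.end > start:
                out[pid] = c
                break
    return out


def recovery_rate(bundle, score: ScoreResult, called: Mapping[str, CNE]) -> float:
    """Fraction of planted enhancers whose true target attains the maximal
    linkage score (ties count as recovered)."""
    hits = total = 0
    for pid, target in bundle.truth.cne_targets.items():
        if target is None:
            continue
        total += 1
        cne = called.get(pid)
        if cne is None:
            continue
        if target in score.best_targets(cne.cne_id):
            hits += 1
    return hits / total if total else 0.0
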