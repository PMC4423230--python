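"""Synthetic rearranged-genome bundles with known ground truth.

The generator emulates the statistical structure the linkage score relies
on: an ancestral (reference) gene order carrying planted CNEs, of which a
configurable fraction are true enhancers tied to a target gene; descendant
genomes that accumulate inversions and translocations at a configurable
breakpoint rate, *except* that intervals spanning a true enhancer-target
pair are shielded from breakpoints (enhancers under negative selection keep
their target in range) in all but a configurable violation fraction of
species; coverage-dependent gene annotation dropout; per-clade sequence
divergence inside the planted elements (with near-random flanks) so the
scanner can recover them; and signal peaks planted preferentially on true
enhancers.

Geometry is exact by construction: all reference coordinates and lengths
sit on a 20-bp grid and per-species genome-size factors on a 0.05 grid, so
scaled coordinates are integers and a gene within the reference radius is
within the scaled radius of every unrearranged species.

Same seed, same bundle — byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cne_scan import CNE
from .genome_io import (
    AlignmentBlock,
    GeneRecord,
    InteractionPair,
    Interval,
    MafRow,
    OrthologFamily,
    SpeciesMeta,
    ValuedInterval,
    PHYLO_GROUPS,
    REFERENCE_GROUP,
    write_bed,
    write_maf,
    write_ortholog_table,
    write_species_meta,
)

REF_CHROM = "chrX"
BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions of a simulated bundle (seed mandatory)."""

    seed: int
    n_species_per_group: dict[str, int] = field(default_factory=lambda: {
        "Boreoeutheria": 8, "Atlantogenata": 3, "MonotremesMarsupials": 3,
        "SauropsidsAmphibians": 3, "Teleosts": 3})
    n_genes: int = 60
    n_cnes: int = 80
    fraction_enhancers: float = 0.5
    rearrangement_rate: float = 6.0          # breakpoint events per Mb per species
    violation_fraction: float = 0.01         # per-species chance a true pair loses protection
    gene_loss_base: float = 0.002
    gene_loss_coverage_scale: float = 0.04   # loss prob = base + scale * (1 - C_e)
    n_draft_species: int = 3                 # species with C_e = 0.5
    group_identity: dict[str, float] = field(default_factory=lambda: {
        "Boreoeutheria": 0.98, "Atlantogenata": 0.95, "MonotremesMarsupials": 0.92,
        "SauropsidsAmphibians": 0.88, "Teleosts": 0.82})
    flank_identity: float = 0.55             # outside planted elements
    gap_rate: float = 0.01                   # deletion rate in species rows
    peak_true_prob: float = 0.9
    peak_background_prob: float = 0.05
    interaction_prob: float = 0.6
    gene_spacing: int = 200_000
    gene_length: int = 5_000
    flank: int = 40                          # alignment flank around each element
    radius: float = 1_000_000.0
    target_max_distance_fraction: float = 0.4  # true target within this fraction of radius

    def __post_init__(self) -> None:
        for p in (self.fraction_enhancers, self.violation_fraction, self.gene_loss_base,
                  self.gap_rate, self.peak_true_prob, self.peak_background_prob,
                  self.interaction_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        min_span = self.n_genes * (self.gene_length + 4000) + self.n_cnes * 500
        if min_span > (self.n_genes + 1) * self.gene_spacing:
            raise ValueError("infeasible config: more loci than the genome can space out")

    @property
    def genome_length(self) -> int:
        return (self.n_genes + 1) * self.gene_spacing


@dataclass
class Locus:
    kind: str      # "gene" | "cne"
    locus_id: str
    start: int     # reference coordinates
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class GroundTruth:
    """Planted structure, re-derivable from the emitted files."""

    seed: int
    n_genes: int
    n_cnes: int
    cne_targets: dict[str, str | None]          # planted cne id -> family id or None
    cne_intervals: dict[str, tuple[int, int]]
    peak_labels: dict[str, bool]
    breakpoints: dict[str, int]                 # species -> applied breakpoint events
    preserved_pairs: dict[str, int]             # species -> P_e
    n_reference_pairs: int                      # H
    violated_pairs: dict[str, list[str]]        # species -> cne ids with broken protection
    lost_genes: dict[str, list[str]]            # species -> families absent there

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["cne_intervals"] = {k: tuple(v) for k, v in d["cne_intervals"].items()}
        return cls(**d)


@dataclass
class Bundle:
    config: SimConfig
    species_meta: list[SpeciesMeta]
    reference: str
    reference_genes: list[GeneRecord]
    families: list[OrthologFamily]
    planted_cnes: list[CNE]
    blocks: list[AlignmentBlock]
    exons: list[Interval]
    repeats: list[Interval]
    peaks: list[ValuedInterval]
    interactions: list[InteractionPair]
    truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def meta_by_id(self) -> dict[str, SpeciesMeta]:
        return {m.species_id: m for m in self.species_meta}


# ---------------------------------------------------------------------------
# genome arrangement
# ---------------------------------------------------------------------------

def _grid(x: float, step: int = 20) -> int:
    return int(round(x / step)) * step


def _species_list(cfg: SimConfig) -> list[tuple[str, str]]:
    out = []
    for group in PHYLO_GROUPS:
        for i in range(cfg.n_species_per_group.get(group, 0)):
            out.append((f"{group[:3].lower()}{i}", group))
    return out


class _Arrangement:
    """Mutable per-species genome: chromosomes as ordered locus-id lists."""

    def __init__(self, locus_order: list[str]):
        self.chroms: dict[str, list[str]] = {"chr1": list(locus_order)}
        self._n_scaf = 0

    def locate(self, locus_id: str) -> tuple[str, int]:
        for name, ids in self.chroms.items():
            if locus_id in ids:
                return name, ids.index(locus_id)
        raise KeyError(locus_id)

    def new_scaffold_name(self) -> str:
        self._n_scaf += 1
        return f"scaf{self._n_scaf}"


def _pairs_linked(arr: _Arrangement, protected: list[tuple[str, str]],
                  loci: dict[str, Locus], ref_gaps: dict[frozenset[str], int],
                  radius: float) -> bool:
    """True iff every protected (CNE, gene) pair shares a chromosome and lies
    within ``radius`` in the reference-scale layout (species coordinates are
    an exact scaling of it, so checking at factor 1 is exact)."""
    if not protected:
        return True
    layout = _layout_species(arr, loci, ref_gaps, 1.0)
    for a, b in protected:
        ca, sa, la = layout[a]
        cb, sb, lb = layout[b]
        if ca != cb:
            return False
        if max(0, max(sa, sb) - min(sa + la, sb + lb)) >= radius:
            return False
    return True


def _apply_rearrangements(arr: _Arrangement, n_events: int,
                          protected: list[tuple[str, str]],
                          loci: dict[str, Locus],
                          ref_gaps: dict[frozenset[str], int],
                          radius: float,
                          rng: np.random.Generator) -> int:
    """Inversions and translocations; an event is undone (and retried) if it
    would break a protected enhancer-target pair."""
    applied = 0
    for _ in range(n_events):
        for _try in range(20):
            op = rng.choice(["inv", "scaf", "move"], p=[0.6, 0.2, 0.2])
            names = [n for n, ids in arr.chroms.items() if len(ids) >= 2]
            if not names:
                break
            name = names[rng.integers(len(names))]
            ids = arr.chroms[name]
            i, j = sorted(rng.integers(0, len(ids) + 1, size=2))
            if i == j:
                continue
            snapshot = {n: list(v) for n, v in arr.chroms.items()}
            if op == "inv":
                ids[i:j] = ids[i:j][::-1]
            elif op == "scaf":
                seg = ids[i:j]
                if len(seg) == len(ids):
                    continue
                del ids[i:j]
                arr.chroms[arr.new_scaffold_name()] = seg
            else:  # move within / between chromosomes
                seg = ids[i:j]
                if len(seg) == len(ids):
                    continue
                del ids[i:j]
                tnames = sorted(arr.chroms)
                tname = tnames[rng.integers(len(tnames))]
                tids = arr.chroms[tname]
                k = int(rng.integers(0, len(tids) + 1))
                tids[k:k] = seg
            if _pairs_linked(arr, protected, loci, ref_gaps, radius):
                applied += 1
                break
            arr.chroms = snapshot
    return applied


def _layout_species(arr: _Arrangement, loci: dict[str, Locus],
                    ref_gaps: dict[frozenset[str], int], factor: float,
                    novel_gap: int = 2000) -> dict[str, tuple[str, int, int]]:
    """Assign species coordinates: (chrom, start, length) per locus.

    Gaps between loci that were reference-adjacent keep their reference gap;
    novel junctions get a fixed gap; everything scales by the genome-size
    factor (exact on the grid)."""
    out: dict[str, tuple[str, int, int]] = {}
    for chrom in sorted(arr.chroms):
        ids = arr.chroms[chrom]
        cursor = int(round(factor * 1000))
        prev: str | None = None
        for lid in ids:
            if prev is not None:
                gap = ref_gaps.get(frozenset((prev, lid)), novel_gap)
                cursor += int(round(factor * gap))
            length = int(round(factor * loci[lid].length))
            out[lid] = (chrom, cursor, length)
            cursor += length
            prev = lid
    return out


# ---------------------------------------------------------------------------
# sequence emission
# ---------------------------------------------------------------------------

def _mutate(ref: np.ndarray, identity: float, gap_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    n = len(ref)
    out = ref.copy()
    sub = rng.random(n) > identity
    if sub.any():
        shift = rng.integers(1, 4, size=int(sub.sum()))
        idx = (np.searchsorted(BASES, ref[sub]) + shift) % 4
        out[sub] = BASES[idx]
    if gap_rate > 0:
        gaps = rng.random(n) < gap_rate
        out[gaps] = "-"
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, out_dir: str | Path | None = None) -> Bundle:
    """Generate the full bundle; optionally write all files to ``out_dir``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    reference = "ref"

    # --- species and coverage ------------------------------------------------
    sp_list = _species_list(cfg)
    factors = {}
    cov = {}
    draft_idx = set(rng.choice(len(sp_list), size=min(cfg.n_draft_species, len(sp_list)),
                               replace=False).tolist())
    for i, (sp, _group) in enumerate(sp_list):
        factors[sp] = 0.80 + 0.05 * int(rng.integers(0, 5))   # 0.80 .. 1.00
        cov[sp] = 0.5 if i in draft_idx else 1.0
    L = cfg.genome_length
    species_meta = [SpeciesMeta(reference, REFERENCE_GROUP, L, 1.0, synteny_level=1.0)]
    for sp, group in sp_list:
        species_meta.append(SpeciesMeta(sp, group, int(factors[sp] * L), cov[sp]))

    # --- reference layout ----------------------------------------------------
    loci: dict[str, Locus] = {}
    gene_ids = []
    for g in range(cfg.n_genes):
        gid = f"G{g:03d}"
        loci[gid] = Locus("gene", gid, (g + 1) * cfg.gene_spacing, cfg.gene_length)
        gene_ids.append(gid)
    cne_ids = []
    occupied = [(l.start - 2000, l.end + 2000) for l in loci.values()]
    attempts = 0
    while len(cne_ids) < cfg.n_cnes:
        attempts += 1
        if attempts > cfg.n_cnes * 200:
            raise ValueError("infeasible config: could not place all CNEs")
        start = _grid(rng.integers(2000, L - 2000))
        length = 20 * int(rng.integers(3, 8))   # 60..140 bp
        if any(s - 400 < start < e + 400 for s, e in occupied):
            continue
        cid = f"pcne{len(cne_ids):04d}"
        loci[cid] = Locus("cne", cid, start, length)
        occupied.append((start, start + length))
        cne_ids.append(cid)
    order = sorted(loci, key=lambda lid: loci[lid].start)
    cne_ids = [lid for lid in order if loci[lid].kind == "cne"]
    ref_gaps = {frozenset((a, b)): loci[b].start - loci[a].end
                for a, b in zip(order, order[1:])}

    # --- targets and protection ---------------------------------------------
    n_enh = int(round(cfg.fraction_enhancers * cfg.n_cnes))
    enhancer_ids = sorted(rng.choice(cne_ids, size=n_enh, replace=False).tolist())
    targets: dict[str, str | None] = {cid: None for cid in cne_ids}
    for cid in enhancer_ids:
        c = loci[cid]
        near = [gid for gid in gene_ids
                if _edge_gap(c, loci[gid]) < cfg.target_max_distance_fraction * cfg.radius]
        if near:
            targets[cid] = near[int(rng.integers(len(near)))]
    protected_pairs = [(cid, g) for cid, g in targets.items() if g is not None]

    # --- per-species genomes -------------------------------------------------
    arrangements: dict[str, _Arrangement] = {}
    layouts: dict[str, dict[str, tuple[str, int, int]]] = {}
    breakpoints: dict[str, int] = {}
    violated: dict[str, list[str]] = {}
    for sp, _group in sp_list:
        srng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, _stable(sp)]))
        viol = [cid for cid, _ in protected_pairs
                if srng.random() < cfg.violation_fraction]
        prot = [(cid, g) for cid, g in protected_pairs if cid not in viol]
        arr = _Arrangement(order)
        n_events = int(srng.poisson(cfg.rearrangement_rate * L / 1e6))
        applied = _apply_rearrangements(arr, n_events, prot, loci, ref_gaps,
                                        cfg.radius, srng)
        arrangements[sp] = arr
        layouts[sp] = _layout_species(arr, loci, ref_gaps, factors[sp])
        breakpoints[sp] = applied
        violated[sp] = viol

    # --- gene loss and ortholog families ------------------------------------
    ref_genes = [GeneRecord(gid, reference, REF_CHROM, loci[gid].start, loci[gid].end)
                 for gid in gene_ids]
    families = []
    lost: dict[str, set[str]] = {sp: set() for sp, _ in sp_list}
    for sp, _group in sp_list:
        lrng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, _stable(sp)]))
        p_loss = cfg.gene_loss_base + cfg.gene_loss_coverage_scale * (1 - cov[sp])
        for gid in gene_ids:
            if lrng.random() < p_loss:
                lost[sp].add(gid)
    for gid in gene_ids:
        members: dict[str, list[GeneRecord]] = {reference: [
            GeneRecord(gid, reference, REF_CHROM, loci[gid].start, loci[gid].end)]}
        for sp, _group in sp_list:
            if gid in lost[sp]:
                members[sp] = []
            else:
                chrom, start, length = layouts[sp][gid]
                members[sp] = [GeneRecord(f"{sp}_{gid}", sp, chrom, start, start + length)]
        families.append(OrthologFamily(gid, gid, members))

    # --- planted CNE objects -------------------------------------------------
    planted: list[CNE] = []
    for cid in cne_ids:
        c = loci[cid]
        locations = {}
        for sp, _group in sp_list:
            chrom, start, length = layouts[sp][cid]
            locations[sp] = Interval(chrom, start, start + length)
        planted.append(CNE(
            cne_id=cid, interval=Interval(REF_CHROM, c.start, c.end),
            species_set=frozenset(sp for sp, _ in sp_list),
            locations=locations))

    # --- synteny bookkeeping (from arrangements, not from the tables) -------
    ref_pairs = [(a, b) for a, b in zip(gene_ids, gene_ids[1:])]
    preserved: dict[str, int] = {}
    for sp, _group in sp_list:
        arr = arrangements[sp]
        neigh = set()
        for ids in arr.chroms.values():
            genes_here = [lid for lid in ids
                          if loci[lid].kind == "gene" and lid not in lost[sp]]
            for a, b in zip(genes_here, genes_here[1:]):
                neigh.add(frozenset((a, b)))
        preserved[sp] = sum(1 for a, b in ref_pairs if frozenset((a, b)) in neigh)

    # --- alignment blocks ----------------------------------------------------
    blocks = []
    group_of = dict(sp_list)
    for cid in cne_ids:
        c = loci[cid]
        n_cols = c.length + 2 * cfg.flank
        brng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, _stable(cid)]))
        ref_seq = BASES[brng.integers(0, 4, size=n_cols)]
        rows = {reference: MafRow(reference, REF_CHROM, c.start - cfg.flank, n_cols,
                                  "+", L, "".join(ref_seq))}
        for sp, _group in sp_list:
            ident = cfg.group_identity[group_of[sp]]
            left = _mutate(ref_seq[:cfg.flank], cfg.flank_identity, cfg.gap_rate, brng)
            mid = _mutate(ref_seq[cfg.flank:cfg.flank + c.length], ident, cfg.gap_rate, brng)
            right = _mutate(ref_seq[cfg.flank + c.length:], cfg.flank_identity,
                            cfg.gap_rate, brng)
            text = "".join(np.concatenate([left, mid, right]))
            chrom, sp_start, _length = layouts[sp][cid]
            n_left = int((left != "-").sum())
            size = len(text.replace("-", ""))
            rows[sp] = MafRow(sp, chrom, sp_start - n_left, size, "+",
                              int(factors[sp] * L), text)
        blocks.append(AlignmentBlock(rows, reference))

    # --- masks ---------------------------------------------------------------
    exons = [Interval(REF_CHROM, loci[g].start, loci[g].end, name=g) for g in gene_ids]
    repeats = []
    for r in range(5):
        start = _grid(rng.integers(2000, L - 3000))
        if not any(abs(start - loci[cid].start) < 1000 for cid in cne_ids):
            repeats.append(Interval(REF_CHROM, start, start + 600, name=f"rep{r}"))

    # --- peaks and interactions ----------------------------------------------
    peaks = []
    peak_labels: dict[str, bool] = {}
    interactions = []
    for cid in cne_ids:
        c = loci[cid]
        is_enh = targets[cid] is not None
        p = cfg.peak_true_prob if is_enh else cfg.peak_background_prob
        has_peak = bool(rng.random() < p)
        peak_labels[cid] = has_peak
        if has_peak:
            cover = int(rng.integers(max(1, c.length // 2), c.length + 1))
            offset = int(rng.integers(0, c.length - cover + 1))
            value = float(np.round(rng.uniform(2.0, 20.0), 2))
            peaks.append(ValuedInterval(REF_CHROM, c.start + offset,
                                        c.start + offset + cover, value, name=cid))
        if is_enh and rng.random() < cfg.interaction_prob:
            gid = targets[cid]
            g = loci[gid]
            interactions.append(InteractionPair(
                Interval(REF_CHROM, max(0, c.start - 200), c.end + 200),
                Interval(REF_CHROM, max(0, g.start - 1000), g.start + 1000),
                gid))

    truth = GroundTruth(
        seed=cfg.seed, n_genes=cfg.n_genes, n_cnes=cfg.n_cnes,
        cne_targets=targets,
        cne_intervals={cid: (loci[cid].start, loci[cid].end) for cid in cne_ids},
        peak_labels=peak_labels, breakpoints=breakpoints,
        preserved_pairs=preserved, n_reference_pairs=len(ref_pairs),
        violated_pairs=violated,
        lost_genes={sp: sorted(lost[sp]) for sp, _ in sp_list})

    bundle = Bundle(cfg, species_meta, reference, ref_genes, families, planted,
                    blocks, exons, repeats, peaks, interactions, truth)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _edge_gap(a: Locus, b: Locus) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _stable(s: str) -> int:
    import zlib
    return zlib.crc32(s.encode())


# ---------------------------------------------------------------------------
# file emission and audit
# ---------------------------------------------------------------------------

def _write_bundle(bundle: Bundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    p = bundle.paths
    p["maf"] = out / "alignment.maf"
    write_maf(bundle.blocks, p["maf"])
    p["orthologs"] = out / "orthologs.tsv"
    write_ortholog_table(bundle.families, p["orthologs"])
    p["species"] = out / "species.tsv"
    write_species_meta(bundle.species_meta, p["species"])
    p["exons"] = out / "exons.bed"
    write_bed(bundle.exons, p["exons"])
    p["repeats"] = out / "repeats.bed"
    write_bed(bundle.repeats, p["repeats"])
    p["peaks"] = out / "peaks.bedgraph"
    with open(p["peaks"], "w") as fh:
        for pk in bundle.peaks:
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.value:g}\n")
    p["interactions"] = out / "interactions.bedpe"
    with open(p["interactions"], "w") as fh:
        for it in bundle.interactions:
            fh.write(f"{it.anchor1.chrom}\t{it.anchor1.start}\t{it.anchor1.end}"
                     f"\t{it.anchor2.chrom}\t{it.anchor2.start}\t{it.anchor2.end}"
                     f"\t{it.gene_id}\n")
    p["truth"] = out / "ground_truth.json"
    p["truth"].write_text(bundle.truth.to_json())


@dataclass
class AuditReport:
    mismatches: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def audit(out_dir: str | Path) -> AuditReport:
    """Re-derive ground-truth summaries from the emitted files and compare.

    Checks: family count vs planted genes; synteny level recomputed from the
    ortholog table vs the generator's adjacency bookkeeping; alignment block
    count and reference coordinates vs planted elements; peak labels vs
    actual peak overlap.
    """
    from . import genome_io, linkage, functional

    out = Path(out_dir)
    mism: list[str] = []
    truth = GroundTruth.from_json((out / "ground_truth.json").read_text())
    species = genome_io.read_species_meta(out / "species.tsv")
    families = genome_io.read_ortholog_table(out / "orthologs.tsv", species)
    reference = genome_io.reference_species(species).species_id
    genome_io.resolve_reference_genes(families, reference)

    if len(families) != truth.n_genes:
        mism.append(f"family count {len(families)} != planted {truth.n_genes}")

    ref_order = sorted((f.records(reference)[0] for f in families),
                       key=lambda g: (g.chrom, g.start))
    for meta in species:
        if meta.species_id == reference:
            continue
        absent = sorted(f.family_id for f in families
                        if not f.records(meta.species_id))
        if absent != truth.lost_genes[meta.species_id]:
            mism.append(f"{meta.species_id}: absent families {absent} != "
                        f"planted losses {truth.lost_genes[meta.species_id]}")
        r_files = linkage.synteny_level(ref_order, families, meta.species_id)
        r_truth = truth.preserved_pairs[meta.species_id] / truth.n_reference_pairs
        if abs(r_files - r_truth) > 1e-12:
            mism.append(f"{meta.species_id}: R_e from files {r_files:.4f} "
                        f"!= bookkeeping {r_truth:.4f}")

    blocks = list(genome_io.read_maf(out / "alignment.maf", reference=reference))
    if len(blocks) != truth.n_cnes:
        mism.append(f"block count {len(blocks)} != planted {truth.n_cnes}")

    peaks = genome_io.read_intervals(out / "peaks.bedgraph", "bedgraph")
    for cid, (start, end) in sorted(truth.cne_intervals.items()):
        iv = genome_io.Interval(REF_CHROM, start, end)
        fs = functional.weighted_overlap(iv, peaks, cid)
        if (fs.score > 0) != truth.peak_labels[cid]:
            mism.append(f"{cid}: peak label {truth.peak_labels[cid]} but "
                        f"overlap score {fs.score:.2f}")
    return AuditReport(mism)
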