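"""Coverage-weighted functional-signal annotation of elements.

A CNE overlapping a signal peak by at least 1 bp receives a functional score
equal to the peak value weighted by the fraction of the CNE covered: a
100-bp element overlapped over 40 bp by a peak of value 12 scores
12 * (40/100) = 4.8.  Scores are additive over distinct peaks.  Fused
regulatory elements overlap a track iff any constituent CNE scores > 0, and
enrichment is summarised as the proportion of elements with score > 0 per
bin of increasing linkage score S_A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .cne_scan import CNE
from .genome_io import Interval, ValuedInterval
from .linkage import RegElement


@dataclass
class FunctionalScore:
    element_id: str
    track_name: str
    score: float
    covered_fraction: float


@dataclass
class EnrichmentCurve:
    """Per-S_A-bin proportion of elements with a positive functional score."""

    bin_edges: np.ndarray
    proportions: list[float | None]   # None for empty bins
    counts: list[int]
    track_name: str = ""

    def fold_change(self) -> float | None:
        """Ratio of the top bin's proportion to the bottom bin's; None if the
        bottom proportion is 0 or either bin is empty."""
        bottom, top = self.proportions[0], self.proportions[-1]
        if bottom is None or top is None or bottom == 0:
            return None
        return top / bottom


def _peak_tree(peaks: Sequence[ValuedInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.value)
    return trees


def weighted_overlap(element: Interval, peaks: Sequence[ValuedInterval],
                     element_id: str = "", track_name: str = "",
                     trees: Mapping[str, IntervalTree] | None = None) -> FunctionalScore:
    """Coverage-weighted, additive signal score of one element.

    score = sum over peaks of value * (overlap_bp / element_length); any
    overlap of >= 1 bp counts.
    """
    if trees is None:
        trees = _peak_tree(peaks)
    tree = trees.get(element.chrom)
    score = 0.0
    covered = np.zeros(element.length, dtype=bool)
    if tree is not None:
        for hit in tree.overlap(element.start, element.end):
            ov_start = max(element.start, hit.begin)
            ov_end = min(element.end, hit.end)
            ov = ov_end - ov_start
            if ov <= 0:
                continue
            score += hit.data * ov / element.length
            covered[ov_start - element.start:ov_end - element.start] = True
    return FunctionalScore(element_id, track_name, score, float(covered.mean()))


def score_cnes(cnes: Sequence[CNE], peaks: Sequence[ValuedInterval],
               track_name: str = "") -> dict[str, FunctionalScore]:
    trees = _peak_tree(peaks)
    return {c.cne_id: weighted_overlap(c.interval, peaks, c.cne_id, track_name, trees)
            for c in cnes}


def element_score_from_cnes(element: RegElement,
                            per_cne: Mapping[str, FunctionalScore]
                            ) -> tuple[bool, float]:
    """(overlaps, score) of a fused element: it overlaps the track iff any
    constituent CNE has score > 0; the element score sums constituents."""
    scores = [per_cne[cid].score for cid in element.cne_ids if cid in per_cne]
    total = float(sum(scores))
    return total > 0, total


def enrichment_by_score(elements: Sequence[RegElement],
                        element_overlaps: Mapping[str, bool],
                        n_bins: int = 10,
                        track_name: str = "",
                        strata: Mapping[str, int] | None = None,
                        stratum: int | None = None) -> EnrichmentCurve:
    """Proportion of elements with a positive score per quantile bin of S_A.

    Bins are equal-count quantile bins of max S_A (elements without a score
    are skipped).  ``strata``/``stratum`` restrict the curve to one
    conservation stratum so enrichment can be examined controlling for
    conservation.
    """
    usable = [e for e in elements if e.max_s_a is not None]
    if strata is not None and stratum is not None:
        usable = [e for e in usable if strata.get(e.element_id) == stratum]
    if not usable:
        raise ValueError("no scored elements to bin")
    s = np.array([e.max_s_a for e in usable])
    edges = np.unique(np.quantile(s, np.linspace(0, 1, n_bins + 1)))
    # assign to bins [edge_i, edge_{i+1}), last bin closed
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
    proportions: list[float | None] = []
    counts: list[int] = []
    for b in range(len(edges) - 1):
        members = [e for e, i in zip(usable, idx) if i == b]
        counts.append(len(members))
        if not members:
            proportions.append(None)
        else:
            pos = sum(1 for e in members if element_overlaps.get(e.element_id, False))
            proportions.append(pos / len(members))
    return EnrichmentCurve(edges, proportions, counts, track_name)


def fold_change(curve: EnrichmentCurve) -> float | None:
    return curve.fold_change()


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Plain Fisher exact test on a 2x2 table (odds ratio, p-value)."""
    return stats.fisher_exact([[a, b], [c, d]])
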