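"""Call conserved noncoding elements from a multi-species alignment.

The scanner classifies alignment columns as conserved (at least 7 species
beyond the reference, substitutions under 12% per column), seeds elements
from 10-bp cores that are >= 90% conserved, extends across runs of up to 3
non-conserved columns, fuses same-pattern neighbours under 100 bp apart,
and scores each element by summing the per-phylogenetic-group maximum
percent identities.
"""

from regulink import pipeline
from regulink.simulate import SimConfig, simulate

bundle = simulate(SimConfig(seed=1), "example_bundle")
result = pipeline.scan_maf(bundle.paths["maf"], bundle.species_meta,
                           bundle.exons, bundle.repeats)

print(f"called {len(result.cnes)} CNEs from {len(result.blocks)} blocks")
c = result.cnes[0]
print(f"first element: {c.interval.chrom}:{c.interval.start}-{c.interval.end} "
      f"({c.length} bp), aligned in {len(c.species_set)} species, "
      f"conservation score {c.conservation_score:.0f}")
# The conservation score sums one maximum percent identity per phylogenetic
# group, so five groups at high identity put it in the ~400-500 range here.
matched = pipeline.match_to_planted(result.cnes, bundle.truth.cne_intervals)
print(f"planted elements recovered: {len(matched)}/{bundle.config.n_cnes}")
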