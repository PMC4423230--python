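"""Deliberately simple scalar reference implementations used as independent
oracles for the vectorised production code."""

import math

import numpy as np


def oracle_scan(texts: dict[str, str], reference: str, params,
                mask_spans: list[tuple[int, int]], ref_start: int
                ) -> list[tuple[int, int, frozenset]]:
    """Brute-force CNE calling on one alignment: per-column counting,
    exhaustive window enumeration, step-by-step extension."""
    ref = texts[reference]
    n = len(ref)
    masked = []
    pos = ref_start
    for ch in ref:
        if ch == "-":
            masked.append(True)
        else:
            masked.append(any(s <= pos < e for s, e in mask_spans))
            pos += 1
    cons = []
    for c in range(n):
        rb = ref[c].upper()
        if rb == "-":
            cons.append(False)
            continue
        aligned = [sp for sp, t in texts.items() if t[c] != "-"]
        nonref = [sp for sp in aligned if sp != reference]
        if len(nonref) < params.min_species_beyond_ref:
            cons.append(False)
            continue
        mism = sum(1 for sp in nonref if texts[sp][c].upper() != rb)
        cons.append(mism <= math.ceil(params.column_mismatch_fraction * len(aligned)))
    cons = [c and not m for c, m in zip(cons, masked)]
    w = params.core_window
    need = math.ceil(params.core_min_conserved_fraction * w)

    def window_ok(i):
        return not any(masked[i:i + w]) and sum(cons[i:i + w]) >= need

    seeds = []
    for i in range(n - w + 1):
        if window_ok(i):
            if seeds and i < seeds[-1][1]:
                seeds[-1] = (seeds[-1][0], i + w)
            else:
                seeds.append((i, i + w))
    out = []
    for lo, hi in seeds:
        run, j = 0, hi
        while j < n and not masked[j]:
            if cons[j]:
                run = 0
            else:
                run += 1
                if run > params.max_nonconserved_run:
                    break
            j += 1
        hi2 = j
        run, i = 0, lo - 1
        while i >= 0 and not masked[i]:
            if cons[i]:
                run = 0
            else:
                run += 1
                if run > params.max_nonconserved_run:
                    break
            i -= 1
        lo2 = i + 1
        while lo2 < hi2 and not cons[lo2]:
            lo2 += 1
        while hi2 > lo2 and not cons[hi2 - 1]:
            hi2 -= 1
        if not any(window_ok(i) for i in range(lo2, hi2 - w + 1)):
            continue
        sps = set()
        for sp, t in texts.items():
            if sp == reference:
                continue
            nongap = sum(1 for ch in t[lo2:hi2] if ch != "-")
            if nongap >= params.species_min_aligned_fraction * (hi2 - lo2):
                sps.add(sp)
        if len(sps) < params.min_species_beyond_ref:
            continue
        refpos, p = [], ref_start
        for ch in ref:
            refpos.append(p if ch != "-" else None)
            if ch != "-":
                p += 1
        inpos = [refpos[c] for c in range(lo2, hi2) if refpos[c] is not None]
        if not inpos:
            continue
        item = (inpos[0], inpos[-1] + 1, frozenset(sps))
        if item not in out:
            out.append(item)
    return out


def random_alignment(rng: np.random.Generator):
    """A random alignment with patchy conservation plus random masks."""
    ncols = int(rng.integers(100, 400))
    nsp = int(rng.integers(8, 15))
    ref = "".join(rng.choice(list("ACGT"), size=ncols))
    pcons = np.empty(ncols)
    c = 0
    while c < ncols:
        seg = int(rng.integers(10, 60))
        pcons[c:c + seg] = rng.choice([0.97, 0.8, 0.5])
        c += seg
    texts = {"ref": ref}
    for s in range(nsp):
        chars = []
        for c in range(ncols):
            if rng.random() < 0.08:
                chars.append("-")
            elif rng.random() < pcons[c]:
                chars.append(ref[c])
            else:
                chars.append(str(rng.choice(list("ACGT"))))
        texts[f"sp{s}"] = "".join(chars)
    spans = []
    for _ in range(int(rng.integers(0, 3))):
        a = int(rng.integers(0, ncols))
        spans.append((100 + a, 100 + a + int(rng.integers(5, 40))))
    return texts, spans


def interval_union(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sweep-line union of half-open intervals."""
    out = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
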