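"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths (and numpy/scipy
statistics): plain-Python two-pass means and SDs, exhaustive filtering and
sorting, and a hypergeometric enumeration for Fisher's exact test built on
``math.comb``.
"""

from math import comb
from typing import List, Tuple

from rhizocore import AbundanceTable, natural_key


def group_samples(table: AbundanceTable, group: str) -> List[str]:
    return [s for s in table.sample_ids if table.groups[s] == group]


def brute_summaries(table: AbundanceTable, group: str, ddof: int = 1):
    """Per-OTU (mean_ra, sd_ra, prevalence) on the percent scale, two-pass."""
    samples = group_samples(table, group)
    out = {}
    for otu in table.otu_ids:
        vals = [float(table.data.at[otu, s]) for s in samples]
        n = len(vals)
        mean = sum(vals) / n
        if n - ddof > 0:
            var = sum((v - mean) ** 2 for v in vals) / (n - ddof)
        else:
            var = 0.0
        prev = sum(1 for v in vals if v > 0) / n
        out[otu] = (100.0 * mean, 100.0 * var**0.5, prev)
    return out

def brute_membership(table: AbundanceTable, group: str, top_n: int) -> List[str]:
    s = brute_summaries(table, group)
    cand = [(o, m) for o, (m, _, p) in s.items() if p == 1.0]
    cand.sort(key=lambda t: (-t[1], natural_key(t[0])))
    return [o for o, _ in cand[:top_n]]


def brute_composition(
    table: AbundanceTable, group: str, sd_threshold_pct: float
) -> List[str]:
    s = brute_summaries(table, group)
    cand = [(o, m, sd) for o, (m, sd, p) in s.items() if p == 1.0]
    kept = [(o, m) for o, m, sd in cand if sd < sd_threshold_pct]
    kept.sort(key=lambda t: (-t[1], natural_key(t[0])))
    return [o for o, _ in kept]


def fisher_enumeration(n_a: int, total_a: int, n_b: int, total_b: int) -> float:
    """Two-sided Fisher p by summing all tables no more likely than observed."""
    k = n_a + n_b
    denom = comb(total_a + total_b, k)
    lo, hi = max(0, k - total_b), min(k, total_a)
    pmfs = {x: comb(total_a, x) * comb(total_b, k - x) / denom for x in range(lo, hi + 1)}
    p_obs = pmfs[n_a]
    return sum(p for p in pmfs.values() if p <= p_obs * (1 + 1e-9))
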