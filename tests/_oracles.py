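"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles with explicit
per-pair loops and plain arithmetic, deliberately sharing no code with the
package implementation they check.
"""

from __future__ import annotations

import math


def brute_force_classify(tss_pos, tss_strand, cgi_list):
    """Classify one TSS against every CGI directly.

    ``cgi_list`` is a list of (start, end) on the TSS's chromosome.
    Returns (relation, bin_index, cgi_index) with relation one of
    'inside', 'upstream_flank', 'downstream_flank', 'unassociated'.
    """
    candidates = []
    for idx, (s, e) in enumerate(cgi_list):
        length = e - s
        win_lo = s - length // 2  # may be negative (virtual)
        win_hi = e + (length - (length // 2))  # ceil half
        if max(0, win_lo) <= tss_pos < win_hi:
            mid = (s + e) / 2.0
            candidates.append((abs(tss_pos - mid), s, idx, win_lo, win_hi))
    if not candidates:
        return "unassociated", None, None
    candidates.sort()
    _, _, idx, win_lo, win_hi = candidates[0]
    win_len = win_hi - win_lo
    if tss_strand == "+":
        rel = (tss_pos - win_lo) / win_len
    else:
        rel = (win_hi - 1 - tss_pos) / win_len
    if rel < 0.25:
        relation = "upstream_flank"
    elif rel < 0.75:
        relation = "inside"
    else:
        relation = "downstream_flank"
    bin_index = min(int(rel * 100), 99)
    return relation, bin_index, idx


def brute_force_profile(tss_records, cgi_list):
    """(bins, n_associated, relation counts) by direct pairwise testing.

    ``tss_records``: list of (pos, strand) tuples; ``cgi_list``: list of
    (start, end) tuples, all on one chromosome.
    """
    bins = [0] * 100
    counts = {"inside": 0, "upstream_flank": 0, "downstream_flank": 0,
              "unassociated": 0}
    for pos, strand in tss_records:
        relation, bin_index, _ = brute_force_classify(pos, strand, cgi_list)
        counts[relation] += 1
        if bin_index is not None:
            bins[bin_index] += 1
    n_assoc = sum(v for k, v in counts.items() if k != "unassociated")
    return bins, n_assoc, counts


def chi2_by_hand(observed, weights):
    """Pearson chi-square via the textbook sum, nothing else."""
    total = sum(observed)
    wsum = sum(weights)
    expected = [total * w / wsum for w in weights]
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))


def binom_ci99_halfwidth(p, n):
    """Half-width of a normal-approximation 99% binomial CI for a proportion."""
    return 2.5758 * math.sqrt(p * (1.0 - p) / n)
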