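"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written with plain loops, dicts and
term-by-term summation — no shared code paths with the package under test.
"""

from __future__ import annotations

import math


def poisson_upper_tail_brute(x: int, lam: float) -> float:
    """P(X >= x) by direct pmf summation from k = x upward."""
    if x == 0:
        return 1.0
    if lam == 0:
        return 0.0
    # first term in log space, then iterate multiplicatively
    log_term = -lam + x * math.log(lam) - math.lgamma(x + 1)
    term = math.exp(log_term)
    total = 0.0
    k = x
    while True:
        total += term
        k += 1
        term *= lam / k
        if term < total * 1e-18 and k > lam + x:
            break
        if k > x + 10000:
            break
    return total


def poisson_lower_tail_brute(y: int, lam: float) -> float:
    """P(Y <= y) by direct pmf summation from k = 0 to y."""
    if lam == 0:
        return 1.0
    terms = []
    term = math.exp(-lam)
    for k in range(0, y + 1):
        terms.append(term)
        term *= lam / (k + 1)
    return min(1.0, math.fsum(terms))


def _round_half_away(value: float) -> int:
    return int(math.floor(value + 0.5))


def naive_call_peaks(profile, params):
    """Enumerate every window explicitly; returns [(chrom, start, end, strand, total, summit)].

    Mirrors the published procedure step by step with dict arithmetic only.
    """
    results = []
    for chrom in sorted(profile.chrom_lengths):
        length = profile.chrom_lengths[chrom]
        for strand in ("+", "-"):
            pos_arr, cnt_arr, _ = profile.arrays(chrom, strand)
            counts = {int(p): int(c) for p, c in zip(pos_arr, cnt_arr)}
            if not counts:
                continue

            def window_count(a: int, b: int) -> int:
                return sum(c for p, c in counts.items() if a <= p < b)

            significant = []
            start = 0
            while start < length:
                end = min(start + params.w, length)
                c = window_count(start, end)
                if c >= params.min_reads:
                    lf_a, lf_b = max(0, start - params.flank_width), start
                    rf_a, rf_b = end, min(length, end + params.flank_width)
                    width = end - start
                    passed = []
                    for fa, fb in ((lf_a, lf_b), (rf_a, rf_b)):
                        fw = fb - fa
                        lam = _round_half_away(window_count(fa, fb) * width / fw) if fw > 0 else 0
                        passed.append(
                            poisson_upper_tail_brute(c, lam) < params.p_threshold
                        )
                    ok = all(passed) if params.require_both else any(passed)
                    if ok:
                        significant.append((start, end))
                start += params.step

            # trim each window to its nonzero span
            trimmed = []
            for a, b in significant:
                inside = sorted(p for p in counts if a <= p < b)
                if inside:
                    trimmed.append((inside[0], inside[-1] + 1))

            # merge transitively when separated by < merge_gap, then re-trim
            trimmed.sort()
            merged = []
            for a, b in trimmed:
                if merged and a - merged[-1][1] < params.merge_gap:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            for a, b in merged:
                inside = sorted(p for p in counts if a <= p < b)
                a, b = inside[0], inside[-1] + 1
                total = sum(counts[p] for p in inside)
                best = max(counts[p] for p in inside)
                tied = [p for p in inside if counts[p] == best]
                summit = min(tied) if strand == "+" else max(tied)
                results.append((chrom, a, b, strand, total, summit))
    results.sort(key=lambda r: (r[0], r[1], r[3]))
    return results


def kurtosis_brute(observations) -> float:
    """Pearson kurtosis m4/m2^2 on an explicit observation list."""
    n = len(observations)
    mean = math.fsum(observations) / n
    m2 = math.fsum((o - mean) ** 2 for o in observations) / n
    m4 = math.fsum((o - mean) ** 4 for o in observations) / n
    return m4 / m2**2
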