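"""Independent brute-force oracles used by the unit and acceptance tests."""

import itertools

import numpy as np

from starrmap.strength import _prefix_sums, _segment_costs


def brute_force_segmentation(x, max_changepoints, penalty, min_segment=2):
    """Exhaustive search over all changepoint combinations (<= max_changepoints).

    Enumerates every admissible set of changepoint indices directly with
    itertools — independent of the dynamic programmes under test — and
    returns the set minimising total Gaussian mean+variance cost plus
    penalty per changepoint.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    p1, p2 = _prefix_sums(x)
    # precompute every segment cost once; combinations then just add lookups
    C = np.full((n + 1, n + 1), np.inf)
    for a in range(n):
        bs = np.arange(a + min_segment, n + 1)
        if not bs.size:
            continue
        m = bs - a
        mean = (p1[bs] - p1[a]) / m
        var = np.maximum((p2[bs] - p2[a]) / m - mean * mean, 1e-8)
        C[a, bs] = m * (np.log(2 * np.pi) + np.log(var) + 1.0)

    best_cost, best_cps = C[0, n], []
    for k in range(1, max_changepoints + 1):
        for cps in itertools.combinations(range(min_segment - 1, n - min_segment), k):
            bounds = [0] + [c + 1 for c in cps] + [n]
            cost = penalty * k
            ok = True
            for a, b in zip(bounds, bounds[1:]):
                if b - a < min_segment:
                    ok = False
                    break
                cost += C[a, b]
            if ok and cost < best_cost - 1e-9:
                best_cost, best_cps = cost, list(cps)
    return best_cps


def enumerate_pwm_tail(pwm):
    """Exact tail P(S >= s) by enumerating all 4^w words.

    Returns (sorted integer scores, tail probabilities) computed directly
    from per-word products, independent of the DP convolution.
    """
    import itertools as it

    scores: dict[int, float] = {}
    for word in it.product(range(4), repeat=pwm.width):
        s = int(sum(pwm.int_scores[j, b] for j, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + p
    ss = np.array(sorted(scores))
    pmf = np.array([scores[s] for s in ss])
    tail = np.cumsum(pmf[::-1])[::-1]
    return ss, tail
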