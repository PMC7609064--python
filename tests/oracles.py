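"""Independent brute-force oracles, kept free of the package's internals."""

from itertools import product


def brute_force_bouts(minutes, min_bout=5):
    """Naive O(n) run scanner: (start, length) of zero runs >= min_bout."""
    bouts = []
    start = None
    for i, c in enumerate(list(minutes) + [1]):  # sentinel terminates last run
        if c == 0:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_bout:
                bouts.append((start, i - start))
            start = None
    return bouts


def brute_force_scored_minutes(minutes, min_bout=5):
    return sum(l for _, l in brute_force_bouts(minutes, min_bout))


def enumerate_expected_scored_sleep(p_fall, p_wake, init_p_sleep=0.0, min_bout=5):
    """Exact E[scored sleep] by summing over all 2^n state sequences.

    States: 1 = sleep.  Transition into minute t uses p_fall[t]/p_wake[t];
    minute 0 is asleep with probability ``init_p_sleep``.
    """
    n = len(p_fall)
    total = 0.0
    for seq in product((0, 1), repeat=n):
        p = init_p_sleep if seq[0] else 1.0 - init_p_sleep
        for t in range(1, n):
            if seq[t - 1] == 0:
                p *= p_fall[t] if seq[t] else 1.0 - p_fall[t]
            else:
                p *= 1.0 - p_wake[t] if seq[t] else p_wake[t]
        if p == 0.0:
            continue
        counts = [0 if s else 1 for s in seq]
        total += p * brute_force_scored_minutes(counts, min_bout)
    return total
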