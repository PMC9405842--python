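"""Independent brute-force segment enumeration used to cross-check the
run-based detector.  Deliberately written with plain Python scans and a
different decomposition (interval-by-interval run scan; zero-cut stretches
then sign grouping) so it shares no code path with the library."""

from __future__ import annotations


def _sign(v: float) -> int:
    return 0 if v == 0 else (1 if v > 0 else -1)


def brute_force_segments(rec, min_samples: int = 3):
    """All disconjugacy segments of a gap-free recording, by enumeration.

    Returns (start_sample, end_sample) inclusive index pairs, ordered.
    """
    t, xl, xr = rec.t, rec.left_x, rec.right_x
    n = len(t)
    d = [xl[i] - xr[i] for i in range(n)]
    dv = [
        ((xl[i + 1] - xl[i]) / (t[i + 1] - t[i]))
        * ((xr[i + 1] - xr[i]) / (t[i + 1] - t[i]))
        for i in range(n - 1)
    ]

    # maximal runs of negative velocity product, by linear scan
    runs = []
    i = 0
    while i < n - 1:
        if dv[i] < 0:
            j = i
            while j + 1 < n - 1 and dv[j + 1] < 0:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    segments = []
    for p, q in runs:
        s, l = p, q + 1  # run sample span
        signs = [_sign(d[k]) for k in range(n)]
        # cut at interior zeros of D (the zero sample is shared by both sides)
        zeros = [k for k in range(s + 1, l) if signs[k] == 0]
        stretches = list(zip([s] + zeros, zeros + [l]))
        for a0, b0 in stretches:
            nonzero = [(k, signs[k]) for k in range(a0, b0 + 1) if signs[k] != 0]
            if not nonzero:
                segments.append((a0, b0))
                continue
            start = a0
            prev = nonzero[0][1]
            for k, sk in nonzero[1:]:
                if sk != prev:
                    segments.append((start, k - 1))
                    start = k
                    prev = sk
            segments.append((start, b0))

    return [(a, b) for a, b in segments if b - a + 1 >= min_samples]
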