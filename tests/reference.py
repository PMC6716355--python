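"""Brute-force reference implementations, independent of the package code.

Plain dict/loop arithmetic only; used as oracles in tests.
"""

from __future__ import annotations


def reference_decontam(
    counts: dict[str, dict[str, int]],
    controls: set[str],
    ratio: float = 10.0,
    min_relabund: float = 0.001,
    max_filtered: float = 0.75,
):
    """Straight-line application of the four-step procedure.

    ``counts``: {sample: {sequence: count}}.  Returns (final counts in the
    same shape, iteration log).  Written with explicit loops, no shared code
    with the package.
    """
    current = {s: dict(col) for s, col in counts.items()}
    starting = {s: sum(col.values()) for s, col in counts.items()}
    log = []
    while True:
        seqs = sorted({u for col in current.values() for u in col if col[u] > 0})
        exp = [s for s in current if s not in controls]
        ctl = [s for s in current if s in controls]
        sizes = {s: sum(current[s].values()) for s in current}

        def rel(s, u):
            return current[s].get(u, 0) / sizes[s] if sizes[s] > 0 else 0.0

        # step 1
        removed1 = []
        for u in seqs:
            max_ctl = max((rel(s, u) for s in ctl), default=0.0)
            ok = False
            for s in exp:
                if sizes[s] > 0 and current[s].get(u, 0) > 0 and rel(s, u) >= ratio * max_ctl:
                    ok = True
            if not ok:
                removed1.append(u)
        for u in removed1:
            for s in current:
                current[s].pop(u, None)

        # step 2 (current, post-step-1 sizes)
        sizes = {s: sum(current[s].values()) for s in current}
        seqs2 = sorted({u for col in current.values() for u in col if col[u] > 0})
        removed2 = []
        for u in seqs2:
            best = max((rel(s, u) for s in exp if sizes[s] > 0), default=0.0)
            if best < min_relabund:
                removed2.append(u)
        for u in removed2:
            for s in current:
                current[s].pop(u, None)

        # step 3 against starting sizes
        sizes = {s: sum(current[s].values()) for s in current}
        removed_samples = []
        for s in list(current):
            if starting[s] <= 0 or sizes[s] / starting[s] < 1.0 - max_filtered:
                removed_samples.append(s)
        for s in removed_samples:
            del current[s]

        log.append((sorted(removed1), sorted(removed2), sorted(removed_samples)))
        exp_left = [s for s in current if s not in controls]
        if not exp_left:
            break
        if not removed1 and not removed2 and not removed_samples:
            break
    final = {s: {u: c for u, c in col.items() if c > 0} for s, col in current.items()}
    return final, log


def reference_shannon(counts):
    import math

    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def reference_spearman_rho(x, y):
    """Spearman rho via midranks and Pearson on ranks, explicit loops."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den
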