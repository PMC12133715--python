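"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pure Python, exact Fraction arithmetic,
risk sets recomputed by scanning all subjects) kept structurally unrelated
to the vectorised estimators they validate.
"""

from __future__ import annotations

from fractions import Fraction

CAUSES = ("recurrence", "second_primary", "death")


def aj_bruteforce(times, causes, entries=None):
    """Exact product-limit evaluation of survival and per-cause CIFs.

    Returns (event_times, surv, cif) with surv a list of Fractions and cif a
    dict cause -> list of Fractions, one value per distinct event time.
    """
    n = len(times)
    entries = [0] * n if entries is None else list(entries)
    event_times = sorted({t for t, c in zip(times, causes) if c != "censored"})
    surv_prev = Fraction(1)
    surv_out, cif_out = [], {k: [] for k in CAUSES}
    cif = {k: Fraction(0) for k in CAUSES}
    for t in event_times:
        at_risk = sum(1 for e, tt in zip(entries, times) if e < t <= tt)
        d_total = 0
        for tt, c in zip(times, causes):
            if tt == t and c != "censored":
                d_total += 1
                cif[c] += surv_prev * Fraction(1, at_risk)
        surv_prev *= 1 - Fraction(d_total, at_risk)
        surv_out.append(surv_prev)
        for k in CAUSES:
            cif_out[k].append(cif[k])
    return event_times, surv_out, cif_out


def random_competing_dataset(rng, n, with_entries=False):
    """A small random competing-risks dataset with ties and censoring."""
    times = rng.integers(1, 12, size=n).tolist()
    labels = [
        ("censored", "recurrence", "second_primary", "death")[i]
        for i in rng.integers(0, 4, size=n)
    ]
    if with_entries:
        entries = [int(rng.integers(0, t)) for t in times]
    else:
        entries = [0] * n
    return [float(t) for t in times], labels, [float(e) for e in entries]


def earliest_indicator_bruteforce(claims, prefix_table, start_date):
    """Exhaustive search over all (claim, class) pairs.

    ``claims`` are (date, codes) tuples, ``prefix_table`` maps class number
    to dot-stripped prefixes.  Returns (date, class) of the minimum over all
    qualifying pairs under (date, class) order, or None.
    """
    hits = []
    for when, codes in claims:
        if when < start_date:
            continue
        for cls, prefixes in prefix_table.items():
            for code in codes:
                stripped = str(code).replace(".", "").upper()
                if any(stripped.startswith(p) for p in prefixes):
                    hits.append((when, cls))
    return min(hits) if hits else None
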