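"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately share no code with the implementation paths they check.
"""

from __future__ import annotations

import functools


def optimal_tiling_tokens(lemmas, phrase_set) -> int:
    """Maximum total matched tokens over all non-overlapping phrase tilings.

    Exhaustive dynamic program over every phrase occurrence; independent of
    the greedy longest-match tagger.
    """
    n = len(lemmas)
    matches_at = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n + 1):
            if tuple(lemmas[i:j]) in phrase_set:
                matches_at[i].append(j)

    @functools.lru_cache(maxsize=None)
    def best(i: int) -> int:
        if i >= n:
            return 0
        options = [best(i + 1)]
        for j in matches_at[i]:
            options.append((j - i) + best(j))
        return max(options)

    result = best(0)
    best.cache_clear()
    return result


def brute_force_constraint_check(structured: dict, constraints: dict, policy: str) -> bool:
    """Re-evaluate a trial's structured constraints from raw dicts.

    ``structured`` is StructuredEntries.model_dump(); ``constraints`` is
    StructuredConstraints.model_dump(exclude_none=True). Written directly
    from the conventions ([lo, hi) intervals, membership sets, required =
    non-empty intersection, forbidden = empty intersection, unknowns pass
    only under the lenient policy).
    """
    unknowns = 0
    for name, spec in constraints.items():
        if name == "vitals":
            for vital, interval in spec.items():
                value = structured.get("vitals", {}).get(vital)
                if value is None:
                    unknowns += 1
                    continue
                if interval.get("min") is not None and value < interval["min"]:
                    return False
                if interval.get("max") is not None and value >= interval["max"]:
                    return False
            continue
        if name in ("medication_codes", "procedure_codes"):
            codes = set(structured.get(name, []))
            if spec.get("required") and not codes & set(spec["required"]):
                return False
            if spec.get("forbidden") and codes & set(spec["forbidden"]):
                return False
            continue
        value = structured.get(name)
        if name == "sex" and value == "U":
            value = None
        if name in ("race", "language") and value == "unknown":
            value = None
        if value is None:
            unknowns += 1
            continue
        if name == "age":
            if spec.get("min") is not None and value < spec["min"]:
                return False
            if spec.get("max") is not None and value >= spec["max"]:
                return False
        elif name == "guardian_present":
            if bool(value) != spec:
                return False
        else:  # membership constraint
            if value not in spec:
                return False
    return policy == "lenient" or unknowns == 0


def brute_force_rank_order(entries):
    """Full sort of (patient_id, arrival_time, score) under the dashboard
    comparator: score desc, then arrival asc, then patient_id asc."""
    return [
        pid for pid, arrival, score in
        sorted(entries, key=lambda e: (-e[2], e[1], e[0]))
    ]


def pooled_f1(counts) -> float:
    """Micro F from (tp, fp, fn) tuples pooled across trials; one-liner oracle."""
    tp = sum(c[0] for c in counts)
    fp = sum(c[1] for c in counts)
    fn = sum(c[2] for c in counts)
    return 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
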