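"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected behaviour from the documented
rule semantics with straightforward enumeration, independent of the
package's implementation paths.
"""

from __future__ import annotations

from pdacsym.symptoms import DVT_SYMPTOMS, PAIN_SYMPTOMS


def levenshtein(a: str, b: str) -> int:
    """Plain dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _placements(forms, phrase):
    n = len(phrase)
    return [(i, i + n) for i in range(len(forms) - n + 1)
            if tuple(forms[i:i + n]) == tuple(phrase)]


def _all_occurrences(forms, terms):
    occs = set()
    for t in terms:
        occs.update(_placements(forms, t))
    return sorted(occs)


def oracle_phrase_spans(forms, lex) -> set[tuple[int, int]]:
    """Maximal trigger spans: every placement of every trigger phrase,
    minus spans properly contained in another placement."""
    hits = set()
    for phrase in lex.trigger_phrases:
        hits.update(_placements(forms, phrase))
    return {h for h in hits
            if not any(o != h and o[0] <= h[0] and h[1] <= o[1]
                       for o in hits)}


def oracle_governed(forms, window=3) -> dict[int, str]:
    """Token indices governed by 'radiating to/from' constructions."""
    governed = {}
    verbs = {"radiating", "radiates", "radiated", "radiate"}
    for i, f in enumerate(forms):
        if f not in verbs:
            continue
        direction = None
        for j in (i + 1, i + 2):
            if j < len(forms) and forms[j] in (
                    "to", "into", "toward", "towards"):
                direction = "to"
                break
            if j < len(forms) and forms[j] == "from":
                direction = "from"
                break
        if direction is None:
            continue
        for k in range(i + 1, min(len(forms), i + window + 2)):
            governed.setdefault(k, direction)
    return governed


def oracle_mentions(forms, lexicons, require_laterality=False,
                    window=3) -> set[tuple[str, str]]:
    """Expected (symptom_id, match_kind) pairs after merging and
    radiation filtering, by exhaustive enumeration."""
    forms = list(forms)
    governed = oracle_governed(forms, window)
    out: set[tuple[str, str]] = set()
    phrase_spans: dict[str, set[tuple[int, int]]] = {}
    for sid, lex in lexicons.items():
        spans = oracle_phrase_spans(forms, lex)
        phrase_spans[sid] = spans
        for s, e in spans:
            if sid in PAIN_SYMPTOMS:
                loc_idx = [s + off for off, w in enumerate(forms[s:e])
                           if (w,) in lex.pain_location_terms]
                if any(governed.get(k) == "to" for k in loc_idx):
                    continue
            out.add((sid, "phrase"))
    for sid in sorted(DVT_SYMPTOMS):
        lex = lexicons.get(sid)
        if lex is None:
            continue
        locs = _all_occurrences(forms, lex.dvt_location_terms)
        feels = [f for f in _all_occurrences(forms, lex.dvt_feeling_terms)
                 if f not in locs]
        lats = _all_occurrences(forms, lex.dvt_laterality_terms)
        if not locs or not feels:
            continue
        if require_laterality and not lats:
            continue
        if governed.get(locs[0][0]) == "to":
            continue
        out.add((sid, "dvt_composite"))
    for sid in sorted(PAIN_SYMPTOMS):
        lex = lexicons.get(sid)
        if lex is None or not lex.pain_location_terms or not lex.pain_terms:
            continue
        locs = _all_occurrences(forms, lex.pain_location_terms)
        pains = _all_occurrences(forms, lex.pain_terms)
        pairs = [(abs(lo[0] - pa[0]), min(lo[0], pa[0]), lo, pa)
                 for lo in locs for pa in pains
                 if lo != pa and abs(lo[0] - pa[0]) <= lex.max_pain_distance]
        if not pairs:
            continue
        _, _, lo, pa = min(pairs, key=lambda t: (t[0], t[1]))
        overlaps_phrase = any(
            ps < e and s < pe
            for s, e in phrase_spans.get(sid, set())
            for ps, pe in (lo, pa))
        if overlaps_phrase:
            continue
        if governed.get(lo[0]) == "to":
            continue
        out.add((sid, "pain_proximity"))
    return out


def oracle_kappa(a, b) -> float | None:
    """Closed-form Cohen's kappa via contingency counting."""
    n = len(a)
    assert n == len(b)
    labels = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((sum(x == lab for x in a) / n)
              * (sum(y == lab for y in b) / n) for lab in labels)
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1 - p_e)
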