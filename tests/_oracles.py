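"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's matcher machinery: candidates are
found by exhaustive enumeration of every synonym at every position, then
resolved with the same leftmost-longest rule.
"""

from __future__ import annotations


def brute_force_extract(
    tokens: list[str], synonym_index: dict[str, frozenset[str]]
) -> set[str]:
    """All concept ids matched in ``tokens``, leftmost-longest.

    Enumerates every (synonym, start) pair; at each position the longest
    matching synonym wins and consumes its tokens.
    """
    candidates: dict[int, list[tuple[int, frozenset[str]]]] = {}
    for syn, ids in synonym_index.items():
        syn_toks = syn.split(" ")
        k = len(syn_toks)
        for start in range(0, len(tokens) - k + 1):
            if tokens[start : start + k] == syn_toks:
                candidates.setdefault(start, []).append((k, ids))

    found: set[str] = set()
    pos = 0
    while pos < len(tokens):
        here = candidates.get(pos)
        if here:
            length, _ = max(here, key=lambda item: item[0])
            for k, ids in here:
                if k == length:
                    found.update(ids)
            pos += length
        else:
            pos += 1
    return found
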