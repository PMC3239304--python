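"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected behaviour from first principles —
exhaustive expansion and enumeration — without going through the
package's compiled-regex matching or its greedy lookup loop.
"""

from __future__ import annotations

GAP_MAX = 6


def expand_template(template: str) -> list[list[str]]:
    """Expand a pattern template into all alternative token sequences.

    Items are literal words, the slot markers "E1"/"E2" (category
    constraints stripped), or "..." gap markers.  Optional groups expand
    both ways; alternations expand per branch.
    """
    seqs, i = _expand_seq(template, 0)
    assert i == len(template), template
    return seqs


def _expand_seq(s: str, i: int) -> tuple[list[list[str]], int]:
    outs: list[list[str]] = [[]]
    n = len(s)
    while i < n and s[i] not in ")|":
        if s[i].isspace():
            i += 1
            continue
        if s[i] == "(":
            alts: list[list[str]] = []
            seqs, i = _expand_seq(s, i + 1)
            alts.extend(seqs)
            while i < n and s[i] == "|":
                seqs, i = _expand_seq(s, i + 1)
                alts.extend(seqs)
            assert i < n and s[i] == ")", s
            i += 1
            if i < n and s[i] == "?":
                i += 1
                alts = alts + [[]]
            outs = [o + a for o in outs for a in alts]
        else:
            j = i
            while j < n and not s[j].isspace() and s[j] not in "()|":
                j += 1
            word = s[i:j]
            if word.startswith(("E1[", "E2[")) and word.endswith("]"):
                word = word[:2]
            outs = [o + [word] for o in outs]
            i = j
    return outs, i


def oracle_match(template: str, elements: list[str], gap_max: int = GAP_MAX) -> bool:
    """Exhaustive template matching against an element sequence.

    ``elements`` is the sentence token sequence with the two mention
    (groups) replaced by the markers "E1" and "E2".  A gap consumes 0 to
    ``gap_max`` non-marker elements; matching may start anywhere.
    """
    low = [e if e in ("E1", "E2") else e.lower() for e in elements]

    def align(seq: list[str], k: int) -> bool:
        if not seq:
            return True
        head, rest = seq[0], seq[1:]
        if head == "...":
            for take in range(0, gap_max + 1):
                if k + take > len(low):
                    break
                if any(low[k + t] in ("E1", "E2") for t in range(take)):
                    break
                if align(rest, k + take):
                    return True
            return False
        if k >= len(low):
            return False
        want = head if head in ("E1", "E2") else head.lower()
        return low[k] == want and align(rest, k + 1)

    for seq in expand_template(template):
        for start in range(len(low) + 1):
            if align(seq, start):
                return True
    return False


def enumerate_term_hits(terms: set[str], words: list[str]) -> list[tuple[int, int]]:
    """All (start, end) token windows whose joined text is a known term."""
    hits = []
    for i in range(len(words)):
        for j in range(i + 1, len(words) + 1):
            if " ".join(words[i:j]).lower() in terms:
                hits.append((i, j))
    return hits


def greedy_longest_tiling(terms: set[str], words: list[str]) -> list[tuple[int, int]]:
    """Left-to-right greedy longest-match tiling, derived from raw hits."""
    hits = enumerate_term_hits(terms, words)
    out = []
    i = 0
    while i < len(words):
        at_i = [h for h in hits if h[0] == i]
        if at_i:
            best = max(at_i, key=lambda h: h[1])
            out.append(best)
            i = best[1]
        else:
            i += 1
    return out
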