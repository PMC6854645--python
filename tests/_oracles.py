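"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives a result from first principles by exhaustive
enumeration, deliberately sharing no logic with the module it checks.
"""

from __future__ import annotations

from itertools import combinations


# ---------------------------------------------------------------------------
# Collapse: O(n^2) all-pairs mergeability + transitive closure


def collapse_partition_oracle(
    seqs: dict[str, str], trim_len: int = 150, containment: bool = True
) -> dict[frozenset[str], str]:
    """Expected collapse blocks by brute force.

    Two transcripts are mergeable if (stage 1) one equals the other or is
    a full-length substring of it, or (stage 2) a one-end trim of either
    (longer than trim_len) is an exact substring of the other / contains
    the other. Blocks are the transitive closure; the retained id is the
    longest member (ties: smallest id). Returns {block: retained_id}.
    """

    def variants(s: str) -> list[str]:
        out = []
        if len(s) - trim_len > trim_len:
            out = [s[trim_len:], s[:-trim_len]]
        return out

    def mergeable(a: str, b: str) -> bool:
        if a == b:
            return True
        if containment and (a in b or b in a):
            return True
        for v in variants(a):
            if v in b or b in v:
                return True
        for v in variants(b):
            if v in a or a in v:
                return True
        return False

    ids = sorted(seqs)
    adj = {i: set() for i in ids}
    for a, b in combinations(ids, 2):
        if mergeable(seqs[a], seqs[b]):
            adj[a].add(b)
            adj[b].add(a)
    seen: set[str] = set()
    blocks: dict[frozenset[str], str] = {}
    for i in ids:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        retained = min(comp, key=lambda x: (-len(seqs[x]), x))
        blocks[frozenset(comp)] = retained
    return blocks


# ---------------------------------------------------------------------------
# ORFs: per-position rescan


def orf_scan_oracle(seq: str, min_codons: int = 30) -> list[tuple[int, int]]:
    """Every ATG scanned forward codon-by-codon to its first in-frame stop."""
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops:
                if (j + 3 - i) >= min_codons * 3:
                    out.append((i, j + 3))
                break
            j += 3
    return sorted(out)


# ---------------------------------------------------------------------------
# miRNA: all-windows rescan with independent penalty arithmetic

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def duplex_penalty_oracle(mirna: str, site: str) -> float:
    """Penalty summed over the site read 3'->5' against the miRNA 5'->3'."""
    mirna = mirna.upper().replace("U", "T")
    site_rev = site.upper().replace("U", "T")[::-1]  # 3'->5' along the site
    total = 0.0
    for idx, (m, t) in enumerate(zip(mirna, site_rev), start=1):
        if _COMP[m] == t:
            pen = 0.0
        elif (m == "G" and t == "T") or (m == "T" and t == "G"):
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= idx <= 13:
            pen *= 2
        total += pen
    return total


def window_scan_oracle(mirna: str, transcript: str, cutoff: float) -> list[tuple[int, float]]:
    L = len(mirna)
    hits = []
    for start in range(len(transcript) - L + 1):
        e = duplex_penalty_oracle(mirna, transcript[start : start + L])
        if e <= cutoff:
            hits.append((start, e))
    return hits


# ---------------------------------------------------------------------------
# Duplication timing: bipartition-based rules, no rooting machinery

def _clades(node, outgroup="at"):
    """Tip-sets of all clades of the tree once rooted on the outgroup:
    exactly the node tip-sets (or complements) that exclude the outgroup."""
    all_tips = frozenset(t.tip_id for t in node.tips())
    sides = set()
    for n in node.walk():
        side = frozenset(t.tip_id for t in n.tips())
        sides.add(side)
        sides.add(all_tips - side)
    return {s for s in sides if s and outgroup not in s}


def classify_oracle(topology, query=("g1", "g2"), sisters=("h1", "h2"), outgroup="at") -> str:
    """Hand-derived rules for the 2-query/2-sister/1-outgroup tip set.

    LINEAGE when the two query tips form a clade (their joint sister in
    the outgroup-rooted tree is then necessarily sister-species-bearing);
    otherwise ASTERACEAE when at least one query tip's sister clade
    consists purely of sister-species tips; otherwise UNRESOLVED.
    """
    clades = _clades(topology, outgroup)
    q = frozenset(query)
    h = frozenset(sisters)
    if q in clades:
        return "LINEAGE"
    for g in query:
        for hsub in (frozenset({x}) for x in sisters):
            if frozenset({g}) | hsub in clades:
                return "ASTERACEAE"
        if (frozenset({g}) | h in clades) and h in clades:
            return "ASTERACEAE"
    return "UNRESOLVED"
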