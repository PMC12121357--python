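"""Independent brute-force oracles used to validate the package.

Deliberately naive re-implementations with different logic from the
package: the overlap matcher scans every alignment shift instead of
substring/suffix checks, clustering uses networkx connected components
over the full pairwise match matrix, and the classification oracle
evaluates the latitudinal rules with exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx


def naive_overlap_match(a: str, b: str, min_overlap: int) -> bool:
    """All-shifts matcher: align b at every offset against a; the pair
    matches if some alignment has zero mismatches in the overlap region
    and the overlap is either a full containment or >= min_overlap."""
    la, lb = len(a), len(b)
    for shift in range(-(lb - 1), la):
        lo_a, hi_a = max(0, shift), min(la, shift + lb)
        ov = hi_a - lo_a
        if ov <= 0:
            continue
        if a[lo_a:hi_a] != b[lo_a - shift:hi_a - shift]:
            continue
        contained = ov == la or ov == lb
        if contained or ov >= min_overlap:
            return True
    return False


def naive_cluster(entries, min_overlap):
    """Reference clusters by connected components of the naive match
    graph; study ASVs then join the matching cluster with the greatest
    summed study reads (tie: smallest cluster id), or found singletons."""
    refs = [e for e in entries if e.origin == "reference"]
    studies = [e for e in entries if e.origin == "study"]

    g = nx.Graph()
    g.add_nodes_from(r.id for r in refs)
    for i, r1 in enumerate(refs):
        for r2 in refs[i + 1:]:
            if naive_overlap_match(r1.sequence, r2.sequence, min_overlap):
                g.add_edge(r1.id, r2.id)
    cluster_id = {}
    for comp in nx.connected_components(g):
        cid = min(comp)
        for rid in comp:
            cluster_id[rid] = cid

    matches = {}  # study id -> set of cluster ids
    for s in studies:
        matches[s.id] = {
            cluster_id[r.id] for r in refs
            if naive_overlap_match(s.sequence, r.sequence, min_overlap)}
    reads = {}
    for s in studies:
        for cid in matches[s.id]:
            reads[cid] = reads.get(cid, 0) + s.total_reads

    study_to_casv = {}
    members = {cid: set() for cid in set(cluster_id.values())}
    for rid, cid in cluster_id.items():
        members[cid].add(rid)
    for s in studies:
        cands = matches[s.id]
        cid = s.id if not cands else min(cands, key=lambda c: (-reads[c], c))
        study_to_casv[s.id] = cid
        members.setdefault(cid, set()).add(s.id)
    return study_to_casv, {c: sorted(m) for c, m in members.items()}


def rule_classify(p: int, t: int, r: int, min_samples: int = 5) -> str:
    """Literal latitudinal-rule evaluator with exact rational arithmetic.

    Order: occurrence floor; single-zone 90% rules; two-zone 90% rules;
    cosmopolitan (all zones occupied); otherwise unallocated.
    """
    total = p + t + r
    if total < min_samples:
        return "unallocated"
    f = {z: Fraction(x, total) for z, x in
         (("p", p), ("t", t), ("r", r))}
    nine = Fraction(9, 10)
    if f["p"] >= nine:
        return "polar"
    if f["t"] >= nine:
        return "temperate"
    if f["r"] >= nine:
        return "tropical"
    if f["p"] + f["t"] >= nine:
        return "polar-temperate"
    if f["t"] + f["r"] >= nine:
        return "temperate-tropical"
    if p and t and r:
        return "cosmopolitan"
    return "unallocated"


def minimal_prefix(totals: dict[str, int], coverage: float) -> list[str]:
    """Brute-force smallest read-ranked prefix reaching the coverage."""
    order = sorted(totals, key=lambda k: (-totals[k], k))
    grand = sum(totals.values())
    for n in range(1, len(order) + 1):
        if sum(totals[k] for k in order[:n]) >= coverage * grand:
            return order[:n]
    return order


def random_instance(rng, n_min=30, n_max=200, seq_len=(40, 60),
                    min_overlap=20):
    """A random clustering instance mixing unrelated sequences with
    copies, truncations, extensions and point mutants of earlier ones."""
    from icebloom.sequence_clustering import SeqEntry

    n = int(rng.integers(n_min, n_max + 1))
    bases = "ACGT"
    entries = []
    seqs = []
    for i in range(n):
        kind = rng.random()
        if i < 5 or kind < 0.45 or not seqs:
            L = int(rng.integers(*seq_len))
            s = "".join(rng.choice(list(bases), size=L))
        else:
            src = seqs[int(rng.integers(len(seqs)))]
            op = rng.random()
            if op < 0.3:                       # exact copy
                s = src
            elif op < 0.55 and len(src) > min_overlap + 6:  # truncation
                t1 = int(rng.integers(0, 4))
                t2 = int(rng.integers(1, 4))
                s = src[t1:len(src) - t2]
            elif op < 0.8:                     # extension
                ext = "".join(rng.choice(list(bases),
                                         size=int(rng.integers(1, 6))))
                s = src + ext if rng.random() < 0.5 else ext + src
            else:                              # point mutant
                pos = int(rng.integers(len(src)))
                alt = bases[(bases.index(src[pos]) + 1) % 4]
                s = src[:pos] + alt + src[pos + 1:]
        seqs.append(s)
        origin = "study" if rng.random() < 0.5 else "reference"
        reads = int(rng.integers(1, 5000)) if origin == "study" else 0
        entries.append(SeqEntry(f"E{i:03d}", s, origin, reads))
    return entries
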