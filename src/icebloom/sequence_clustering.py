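"""Exact-overlap clustering of study ASVs with reference ASVs (cASVs).

Two amplicon sequence variants are merged only if they are 100% identical
over their overlapping region — one is a substring of the other, or a
suffix of one equals a prefix of the other over at least ``min_overlap``
nucleotides with zero mismatches.  Gapless by construction: ASVs of the
same locus differ by primer trimming, not indels.  Reference ASVs are
merged transitively (connected components); each study ASV then joins the
matching reference cluster, and a study ASV matching none founds its own
singleton cASV.  Study ASVs never merge with each other directly, so
single-base-pair ecotypes remain distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SeqEntry", "CasvAssignment", "overlap_match", "cluster_asvs",
           "entries_from_tables"]

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class SeqEntry:
    """One sequence to cluster: a study ASV (with reads) or a reference ASV."""

    id: str
    sequence: str
    origin: str  # "study" | "reference"
    total_reads: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")
        if not set(self.sequence) <= _ALPHABET:
            raise ValueError(f"sequence of {self.id!r} has non-ACGT characters")
        if self.origin not in ("study", "reference"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class CasvAssignment:
    """Study ASV → cASV mapping plus full cASV membership."""

    study_to_casv: dict[str, str] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    def mapping_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.study_to_casv.items()),
            columns=["study_asv_id", "casv_id"],
        )

    def members_frame(self) -> pd.DataFrame:
        rows = [(c, m) for c in sorted(self.members) for m in self.members[c]]
        return pd.DataFrame(rows, columns=["casv_id", "member_id"])


def overlap_match(a: str, b: str, min_overlap: int = 100) -> bool:
    """True iff ``a`` and ``b`` are identical over their overlap region.

    Either one sequence is an exact substring of the other, or a suffix of
    one equals a prefix of the other with overlap length >= ``min_overlap``.
    Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("overlap_match requires nonempty sequences")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if a in b or b in a:
        return True
    top = min(len(a), len(b))  # equal-full-length overlap is the substring case
    for ov in range(min_overlap, top):
        if a[-ov:] == b[:ov] or b[-ov:] == a[:ov]:
            return True
    return False


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id wins as root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _candidate_pairs(entries: list[SeqEntry], min_overlap: int):
    """Pairs that could possibly overlap-match, via a k-gram prefilter.

    Any match (substring or suffix/prefix overlap >= k) implies that the
    first min(k, len) nucleotides of one sequence occur verbatim somewhere
    in the other, so indexing every k-gram of every sequence and probing
    with each sequence's prefix gram finds a superset of matching pairs.
    """
    gram_index: dict[str, set[int]] = {}
    for idx, e in enumerate(entries):
        s = e.sequence
        k = min(min_overlap, len(s))
        for start in range(len(s) - k + 1):
            gram_index.setdefault(s[start:start + k], set()).add(idx)
    seen: set[tuple[int, int]] = set()
    for idx, e in enumerate(entries):
        s = e.sequence
        k = min(min_overlap, len(s))
        for j in gram_index.get(s[:k], ()):  # prefix gram of e occurs in j
            if j != idx:
                seen.add((min(idx, j), max(idx, j)))
    return sorted(seen)


def cluster_asvs(entries: list[SeqEntry], min_overlap: int = 100) -> CasvAssignment:
    """Cluster study and reference ASVs into cASVs.

    Reference entries are merged by connected components under
    :func:`overlap_match`.  Each study ASV joins the reference cluster it
    matches; when it matches several, it joins the one whose matching
    study ASVs carry the greatest summed reads (computed over the full
    match relation, so the result is independent of input order), with
    ties broken by lexicographically smallest cASV id.  Unmatched study
    ASVs become singleton cASVs named after themselves.
    """
    ids = [e.id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate entry ids: {dupes}")

    refs = [e for e in entries if e.origin == "reference"]
    studies = [e for e in entries if e.origin == "study"]

    # reference-reference connected components
    uf = _UnionFind([r.id for r in refs])
    ref_matches: dict[str, list[str]] = {}
    by_id = {e.id: e for e in entries}
    for i, j in _candidate_pairs(entries, min_overlap):
        a, b = entries[i], entries[j]
        if not overlap_match(a.sequence, b.sequence, min_overlap):
            continue
        if a.origin == "reference" and b.origin == "reference":
            uf.union(a.id, b.id)
        elif a.origin != b.origin:
            s, r = (a, b) if a.origin == "study" else (b, a)
            ref_matches.setdefault(s.id, []).append(r.id)

    cluster_of_ref = {r.id: uf.find(r.id) for r in refs}
    comp_members: dict[str, list[str]] = {}
    for rid, root in cluster_of_ref.items():
        comp_members.setdefault(root, []).append(rid)
    casv_of_root = {root: min(mem) for root, mem in comp_members.items()}

    # candidate clusters per study ASV, and summed study reads per cluster
    candidates: dict[str, set[str]] = {}
    cluster_reads: dict[str, int] = {}
    for sid, rids in ref_matches.items():
        cands = {casv_of_root[cluster_of_ref[r]] for r in rids}
        candidates[sid] = cands
        for c in cands:
            cluster_reads[c] = cluster_reads.get(c, 0) + by_id[sid].total_reads

    assign = CasvAssignment()
    members: dict[str, set[str]] = {
        casv_of_root[root]: set(mem) for root, mem in comp_members.items()
    }
    for s in studies:
        cands = candidates.get(s.id)
        if not cands:
            casv = s.id
            members.setdefault(casv, set())
        else:
            casv = min(cands, key=lambda c: (-cluster_reads[c], c))
        assign.study_to_casv[s.id] = casv
        members.setdefault(casv, set()).add(s.id)
    assign.members = {c: sorted(m) for c, m in sorted(members.items()) if m}
    # reference clusters no study ASV joined are still real cASVs
    for root, mem in comp_members.items():
        assign.members.setdefault(casv_of_root[root], sorted(mem))
    return assign


def entries_from_tables(asv_table: pd.DataFrame,
                        ref_seqs: pd.DataFrame) -> list[SeqEntry]:
    """Build SeqEntry list from a study ASV table and reference sequences."""
    from .synthetic_data import count_matrix

    counts = count_matrix(asv_table).sum(axis=1)
    out = [SeqEntry(str(i), str(r["sequence"]), "study", int(counts[i]))
           for i, r in asv_table.iterrows()]
    out += [SeqEntry(str(i), str(r["sequence"]), "reference", 0)
            for i, r in ref_seqs.iterrows()]
    return out
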