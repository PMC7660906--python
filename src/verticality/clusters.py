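"""Eukaryote-prokaryote cluster (EPC) merging and cluster annotation.

Gene families are clustered separately per provenance (eukaryotic,
archaeal, bacterial) upstream; here a eukaryotic cluster is merged with a
prokaryotic cluster when at least half of each side's sequences have their
best reciprocal alignment hit inside the other cluster (reciprocal best
cluster rule).  Ambiguous pairings (plurality ties, or non-mutual best
partners) are flagged and discarded from downstream EPC analyses.

Two lightweight annotation schemes travel with the clusters: choosing the
sequence header whose words are most common across the cluster, and a
majority rule over externally supplied per-gene function labels.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ClusterTable",
    "EPCMerge",
    "merge_epc",
    "annotate_cluster_headers",
    "majority_annotation",
]


@dataclass
class ClusterTable:
    """cluster_id -> set of sequence ids, with a provenance tag."""

    clusters: dict[str, set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cid, members in self.clusters.items():
            for seq in members:
                if seq in seen:
                    raise ValueError(
                        f"sequence {seq!r} in clusters {seen[seq]!r} and {cid!r}"
                    )
                seen[seq] = cid
        self._cluster_of = seen

    def cluster_of(self, seq_id: str) -> str | None:
        return self._cluster_of.get(seq_id)

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "ClusterTable":
        clusters: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cid, seq = line.split("\t")[:2]
                clusters.setdefault(cid, set()).add(seq)
        return cls(clusters=clusters, provenance=provenance)


@dataclass
class EPCMerge:
    euk_cluster_id: str
    prok_cluster_id: str | None
    frac_euk_supporting: float
    frac_prok_supporting: float
    status: str  # "merged" | "ambiguous" | "unmerged"


def _best_partners(hits: pd.DataFrame) -> dict[str, str]:
    """Best reciprocal partner per sequence: minimal e-value, ties broken
    by highest identity, then by partner name."""
    best: dict[str, tuple[float, float, str]] = {}
    for q, s, e, ident in hits[
        ["qseqid", "sseqid", "evalue", "pident"]
    ].itertuples(index=False):
        for a, b in ((q, s), (s, q)):
            key = (float(e), -float(ident), b)
            if a not in best or key < best[a]:
                best[a] = key
    return {a: key[2] for a, key in best.items()}


def merge_epc(
    euk_clusters: ClusterTable,
    prok_clusters: ClusterTable,
    hits: pd.DataFrame,
    evalue_max: float = 1e-10,
    identity_min: float = 30.0,
) -> list[EPCMerge]:
    """Reciprocal-best-cluster merging of eukaryotic with prokaryotic
    clusters.

    ``hits`` is a tabular alignment-hit table with columns qseqid, sseqid,
    evalue, pident, holding reciprocal best hit pairs between the two
    datasets.  After filtering by the e-value and local-identity cut-offs,
    a eukaryotic cluster E merges with a prokaryotic cluster P iff at least
    50% of E's sequences have their best partner in P, at least 50% of P's
    in E, and neither side's plurality vote is tied or points elsewhere.
    Sequences without a retained hit stay in the denominators.
    """
    kept = hits[
        (hits["evalue"] <= evalue_max) & (hits["pident"] >= identity_min)
    ]
    partner = _best_partners(kept)

    def plurality(members: set[str], other: ClusterTable):
        votes = Counter()
        for seq in members:
            p = partner.get(seq)
            if p is None:
                continue
            target = other.cluster_of(p)
            if target is not None:
                votes[target] += 1
        if not votes:
            return None, 0.0, False
        ranked = votes.most_common()
        tied = len(ranked) > 1 and ranked[0][1] == ranked[1][1]
        top, n = ranked[0]
        return top, n / len(members), tied

    prok_vote: dict[str, tuple] = {
        pid: plurality(members, euk_clusters)
        for pid, members in prok_clusters.clusters.items()
    }

    merges: list[EPCMerge] = []
    for eid in sorted(euk_clusters.clusters):
        members = euk_clusters.clusters[eid]
        target, frac_e, tie_e = plurality(members, prok_clusters)
        if target is None:
            merges.append(EPCMerge(eid, None, 0.0, 0.0, "unmerged"))
            continue
        back, frac_p, tie_p = prok_vote[target]
        if tie_e or tie_p:
            merges.append(EPCMerge(eid, target, frac_e, frac_p, "ambiguous"))
        elif back == eid and frac_e >= 0.5 and frac_p >= 0.5:
            merges.append(EPCMerge(eid, target, frac_e, frac_p, "merged"))
        else:
            merges.append(EPCMerge(eid, target, frac_e, frac_p, "unmerged"))
    return merges


_ACCESSION_LIKE = re.compile(r"(?=.*[0-9])(?=.*[A-Za-z])")
_PUNCT = re.compile(r"[^\w\s-]")


def _tokenize(header: str, stopwords: frozenset[str]) -> list[str]:
    words = []
    for token in _PUNCT.sub(" ", header.lower()).split():
        if _ACCESSION_LIKE.match(token):  # mixed letters+digits: accession
            continue
        if token in stopwords:
            continue
        words.append(token)
    return words


def annotate_cluster_headers(
    headers: list[str], stopwords: frozenset[str] = frozenset()
) -> str:
    """Choose the representative header of a cluster by word scoring.

    Every word's score is its occurrence count across all headers; each
    header scores the sum of its words' scores and the highest-scoring
    header wins (ties: first in input order).
    """
    if not headers or all(not h.strip() for h in headers):
        raise ValueError("no non-empty headers to annotate")
    tokenized = [_tokenize(h, stopwords) for h in headers]
    word_counts = Counter(w for words in tokenized for w in words)
    scores = [sum(word_counts[w] for w in words) for words in tokenized]
    return headers[max(range(len(headers)), key=lambda i: scores[i])]


def majority_annotation(labels: list[str | None]) -> str:
    """Modal function label of a cluster; ties break to the
    lexicographically smallest label, null labels are ignored, and a fully
    unannotated cluster is 'Poorly characterized'."""
    kept = [l for l in labels if l]
    if not kept:
        return "Poorly characterized"
    counts = Counter(kept)
    top = max(counts.values())
    return min(l for l, n in counts.items() if n == top)
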