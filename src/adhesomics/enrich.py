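"""Over-representation annotation of differential sets and network clusters.

Gene sets are tested against a query with the upper-tail hypergeometric
test restricted to a declared universe, corrected by Benjamini-Hochberg;
sets passing q < 0.05 with enrichment ratio >= 1 are reported. Network
communities are annotated with their two most significant categories
(or "unannotated" when nothing passes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from .communities import Partition
from .stats_core import EnrichmentRecord, bh_adjust, hypergeom_ora

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "annotate_sets",
    "annotate_clusters",
]


@dataclass
class GeneSetCollection:
    """Mapping set_id -> (display name, member identifiers)."""

    sets: dict[str, tuple[str, frozenset]]

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set_id <tab> description <tab> member...)."""
    sets: dict[str, tuple[str, frozenset]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sid, desc, members = fields[0], fields[1], frozenset(f for f in fields[2:] if f)
        if sid in sets:
            raise ValueError(f"duplicate set id {sid!r}")
        sets[sid] = (desc, members)
    return GeneSetCollection(sets)


def annotate_sets(
    query: set,
    universe: set,
    gsc: GeneSetCollection,
    q_thr: float = 0.05,
    min_ratio: float = 1.0,
) -> list[EnrichmentRecord]:
    """Hypergeometric ORA of every set with members in the universe.

    Returns records with q < ``q_thr`` and enrichment ratio >=
    ``min_ratio``, sorted by q ascending (ties by set id).
    """
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query identifiers outside the universe: {offenders}")
    N, n = len(universe), len(query)
    records = []
    for sid in sorted(gsc.sets):
        members = gsc.sets[sid][1] & universe
        K = len(members)
        if K == 0:
            continue
        x = len(members & query)
        rec = hypergeom_ora(x, K, n, N)
        records.append(replace(rec, set_id=sid))
    if not records:
        return []
    qs = bh_adjust([r.p for r in records])
    records = [replace(r, q=float(q)) for r, q in zip(records, qs)]
    kept = [
        r
        for r in records
        if r.q < q_thr and r.enrichment_ratio >= min_ratio
    ]
    kept.sort(key=lambda r: (r.q, r.set_id))
    return kept


def annotate_clusters(
    part: Partition | dict,
    universe: set,
    gsc: GeneSetCollection,
    top_k: int = 2,
    q_thr: float = 0.05,
) -> dict[int, list[str]]:
    """Annotate each community with its ``top_k`` most significant set names.

    BH correction runs within each community's scan separately, mirroring
    per-cluster annotation. Communities with no significant set receive
    the placeholder ["unannotated"].
    """
    membership = part.community_of_node if isinstance(part, Partition) else part
    by_comm: dict[int, set] = {}
    for node, c in membership.items():
        by_comm.setdefault(c, set()).add(node)
    out: dict[int, list[str]] = {}
    for c in sorted(by_comm):
        members = by_comm[c] & universe
        recs = annotate_sets(members, universe, gsc, q_thr=q_thr) if members else []
        if recs:
            out[c] = [gsc.sets[r.set_id][0] or r.set_id for r in recs[:top_k]]
        else:
            out[c] = ["unannotated"]
    return out
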