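"""Gene/lncRNA annotation: mapping features onto TADs, unifying catalog IDs.

A feature belongs to a TAD when their intervals overlap by at least one base
on the same chromosome (strand ignored for membership; a feature spanning a
TAD boundary belongs to every TAD it touches). lncRNA records from different
catalogs describing the same transcript are unified by transitive closure of
same-chromosome, same-strand, >= 1 bp overlap; each unified record carries
the full alias set (source, id). Strand must match for unification because
overlapping transcripts on opposite strands are distinct lncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError
from .types import GenomicInterval

FEATURE_CLASSES = ("coding_gene", "lncRNA")


@dataclass
class FeatureRecord:
    interval: GenomicInterval
    source: str
    feature_class: str
    aliases: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise DomainError(
                f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}"
            )
        self.aliases = set(self.aliases)
        self.aliases.add((self.source, self.interval.id))


def map_features_to_tads(
    features: list[FeatureRecord], tads: list[GenomicInterval]
) -> pd.DataFrame:
    """Membership table: one row per (feature, TAD) overlap.

    Unmatched features get a single row with tad_id = None (zero
    memberships, but still reported).
    """
    rows = []
    for f in features:
        hits = [t for t in tads if f.interval.overlaps(t)]
        if hits:
            for t in hits:
                rows.append(
                    {
                        "source": f.source,
                        "feature_id": f.interval.id,
                        "feature_class": f.feature_class,
                        "tad_id": t.id,
                    }
                )
        else:
            rows.append(
                {
                    "source": f.source,
                    "feature_id": f.interval.id,
                    "feature_class": f.feature_class,
                    "tad_id": None,
                }
            )
    return pd.DataFrame(
        rows, columns=["source", "feature_id", "feature_class", "tad_id"]
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def unify_feature_ids(catalogs: list[list[FeatureRecord]]) -> list[FeatureRecord]:
    """Merge records across catalogs into alias groups.

    Records from different catalogs overlapping by >= 1 bp on the same
    chromosome and strand fall into one group (transitive closure). One
    representative record per group is returned (the earliest by catalog
    order then file order) carrying the union of the group's aliases.
    """
    if len(catalogs) < 2:
        raise DomainError("need at least 2 catalogs to unify")
    flat: list[tuple[int, FeatureRecord]] = []
    for ci, catalog in enumerate(catalogs):
        for rec in catalog:
            flat.append((ci, rec))
    uf = _UnionFind(len(flat))
    for i in range(len(flat)):
        ci, ri = flat[i]
        for j in range(i + 1, len(flat)):
            cj, rj = flat[j]
            if ci == cj:
                continue
            a, b = ri.interval, rj.interval
            if a.strand == b.strand and a.overlaps(b):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(flat)):
        groups.setdefault(uf.find(i), []).append(i)
    out: list[FeatureRecord] = []
    for root in sorted(groups):
        idxs = groups[root]
        rep_ci, rep = flat[min(idxs)]
        aliases: set[tuple[str, str]] = set()
        for i in idxs:
            aliases |= flat[i][1].aliases
        out.append(
            FeatureRecord(
                interval=rep.interval,
                source=rep.source,
                feature_class=rep.feature_class,
                aliases=aliases,
            )
        )
    return out


def count_features_per_tad(membership: pd.DataFrame) -> pd.DataFrame:
    """Counts per (tad_id, feature_class); alias groups counted once.

    ``membership`` should come from :func:`map_features_to_tads` run on
    unified records (one record per alias group); duplicate
    (feature, class, tad) rows are collapsed defensively regardless.
    """
    hits = membership.dropna(subset=["tad_id"]).drop_duplicates(
        subset=["feature_id", "feature_class", "tad_id"]
    )
    counts = (
        hits.groupby(["tad_id", "feature_class"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return counts
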