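"""Trophospecies aggregation.

Food webs differ widely in taxonomic resolution, which biases structural
metrics (fraction of top species, chain lengths, link counts).  To control
for that, taxa are collapsed into *trophospecies*: equivalence classes of
taxa that are structurally redundant, i.e. have exactly the same resource
set and the same consumer set.  References within a candidate pair are
canonicalized (a link to the partner counts as a link to "partner", a link
to oneself as "self") so that, e.g., two mutually-feeding or two
cannibalistic taxa with otherwise identical diets can still merge.
"""

from __future__ import annotations

from dataclasses import dataclass

from .webio import FoodWeb

_SELF = object()
_PARTNER = object()


@dataclass(frozen=True)
class TrophoPartition:
    """A partition of a web's taxa into trophospecies groups.

    ``groups`` are disjoint, non-empty frozensets covering all taxa;
    ``representative`` maps each group to its lexicographically smallest
    member, used as the node label of the aggregated web.
    """

    web_id: str
    groups: tuple[frozenset[str], ...]
    representative: dict[frozenset[str], str]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _canonical_sets(
    taxon: str, partner: str, resources: set[str], consumers: set[str]
) -> tuple[frozenset, frozenset]:
    """Resource/consumer sets of ``taxon`` with self- and partner-references
    replaced by role tokens, for comparison against ``partner``."""

    def canon(s: set[str]) -> frozenset:
        out: set = set()
        for t in s:
            if t == taxon:
                out.add(_SELF)
            elif t == partner:
                out.add(_PARTNER)
            else:
                out.add(t)
        return frozenset(out)

    return canon(resources), canon(consumers)


def trophospecies_partition(web: FoodWeb) -> TrophoPartition:
    """Group taxa into trophospecies.

    Two taxa share a group iff their resource sets and consumer sets are
    identical after within-pair canonicalization.  Groups are built by
    union-find over all equivalent pairs; the representative is the
    lexicographically smallest label in each group.
    """
    resources = {t: web.resources_of(t) for t in web.taxa}
    consumers = {t: web.consumers_of(t) for t in web.taxa}

    parent = {t: t for t in web.taxa}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # candidate pairs must at least share degree signatures; cheap pre-bucket
    buckets: dict[tuple[int, int], list[str]] = {}
    for t in web.taxa:
        buckets.setdefault((len(resources[t]), len(consumers[t])), []).append(t)

    for bucket in buckets.values():
        for i, a in enumerate(bucket):
            for b in bucket[i + 1 :]:
                ra, ca = _canonical_sets(a, b, resources[a], consumers[a])
                rb, cb = _canonical_sets(b, a, resources[b], consumers[b])
                if ra == rb and ca == cb:
                    union(a, b)

    by_root: dict[str, set[str]] = {}
    for t in web.taxa:
        by_root.setdefault(find(t), set()).add(t)
    groups = tuple(
        frozenset(g) for g in sorted(by_root.values(), key=lambda g: min(g))
    )
    representative = {g: min(g) for g in groups}
    return TrophoPartition(web_id=web.web_id, groups=groups, representative=representative)


def aggregate_web(
    web: FoodWeb, partition: TrophoPartition | None = None, concat_names: bool = False
) -> FoodWeb:
    """Collapse ``web`` onto its trophospecies partition.

    One node per group, labelled by the group representative (or by the
    '+'-joined member names when ``concat_names``).  A link G1 -> G2 exists
    iff any member of G1 consumes any member of G2; within-group feeding
    becomes a self-loop.
    """
    if partition is None:
        partition = trophospecies_partition(web)
    if partition.web_id != web.web_id or set().union(*partition.groups) != set(web.taxa):
        raise ValueError(
            f"partition for {partition.web_id!r} does not match web {web.web_id!r}"
        )
    group_of: dict[str, frozenset[str]] = {}
    for g in partition.groups:
        for t in g:
            group_of[t] = g

    def label(g: frozenset[str]) -> str:
        return "+".join(sorted(g)) if concat_names else partition.representative[g]

    taxa = tuple(label(g) for g in partition.groups)
    links = frozenset(
        (label(group_of[c]), label(group_of[r])) for c, r in web.links
    )
    return FoodWeb(web_id=web.web_id, taxa=taxa, links=links)
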