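"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's fast paths: entropies are computed by
explicit sums over joint-frequency dictionaries, components by union-find.
"""

from __future__ import annotations

import math
from collections import Counter


def entropy_brute(values) -> float:
    n = len(values)
    return sum(-c / n * math.log2(c / n) for c in Counter(values).values())


def conditional_entropy_brute(labels, genotypes) -> float:
    """H(C|A) = sum_{a,c} p(a,c) log2(1 / p(c|a))."""
    n = len(labels)
    joint = Counter(zip(genotypes, labels))
    marg_a = Counter(genotypes)
    h = 0.0
    for (a, c), cnt in joint.items():
        p_ac = cnt / n
        p_c_given_a = cnt / marg_a[a]
        h += p_ac * math.log2(1.0 / p_c_given_a)
    return h


def mutual_information_brute(genotypes, labels) -> float:
    """I(A;C) = sum p(a,c) log2(p(a,c) / (p(a) p(c)))."""
    n = len(labels)
    joint = Counter(zip(genotypes, labels))
    pa = Counter(genotypes)
    pc = Counter(labels)
    mi = 0.0
    for (a, c), cnt in joint.items():
        mi += cnt / n * math.log2((cnt / n) / ((pa[a] / n) * (pc[c] / n)))
    return mi


def joint_mutual_information_brute(ga, gb, labels) -> float:
    composite = list(zip(ga, gb))
    return mutual_information_brute(composite, labels)


def information_gain_brute(ga, gb, labels) -> float:
    return (
        joint_mutual_information_brute(ga, gb, labels)
        - mutual_information_brute(ga, labels)
        - mutual_information_brute(gb, labels)
    )


class UnionFind:
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
            self.parent[ra] = rb


def components_brute(edges) -> list[set]:
    nodes = {u for e in edges for u in e}
    uf = UnionFind(nodes)
    for u, v in edges:
        uf.union(u, v)
    groups: dict = {}
    for x in nodes:
        groups.setdefault(uf.find(x), set()).add(x)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))
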