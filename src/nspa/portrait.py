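"""Subject portraits: per-edge class statistics, edge signs, delta degrees.

For each edge (u, v) of the comprehensive network, a 3x3x2 table of
within-class genotype-pair proportions is fitted on training subjects:
P(a_u, a_v, l) is the proportion of class-l training subjects carrying the
genotype pair (a_u, a_v). A subject's network signs each edge through the
chi function:

    chi(a_u, a_v) = '+'  if P(a_u, a_v, case) >= P(a_u, a_v, control)
                    '-'  otherwise

so '+' marks a genotype pair enriched among cases (risk) and '-' one
enriched among controls (protective). Comparing within-class proportions is
algebraically identical to comparing raw counts after multiplying control
counts by n_case/n_control (the class-balance weight); both modes are
provided and agree exactly.

A genotype pair never observed in training (zero count in both classes)
carries no evidence; by default its edges are treated as absent rather than
risk edges. The literal reading of the tie rule (0 >= 0 giving '+') is
available via ``zero_evidence="plus"``.

The transformed value of variant n for subject i is the delta degree

    d_delta(n) = d_minus(n) - d_plus(n),

the number of incident '-' edges minus incident '+' edges in subject i's
signed network. Large positive values mean the variant's interactions look
protective for this subject; large negative values mean they look risky.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import MISSING, Dataset, GenotypeMatrix
from .network import EpistasisNetwork

__all__ = [
    "PairClassProportions",
    "TransformedMatrix",
    "fit_pair_statistics",
    "edge_sign",
    "build_subject_network",
    "delta_degree_transform",
    "class_balance_weight",
]

SIGN_CHARS = {1: "+", -1: "-", 0: "absent"}


def class_balance_weight(n_case: int, n_control: int) -> float:
    """Multiplier applied to raw control counts in count-mode sign comparison.

    With n_case cases and n_control controls, comparing within-class
    proportions is equivalent to comparing case counts against control counts
    scaled by n_case / n_control (e.g. 10/9 for a 10-case / 9-control cohort).
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("both classes must be non-empty")
    return n_case / n_control


@dataclasses.dataclass
class PairClassProportions:
    """Per-edge class-conditional genotype-pair tables fitted on training data.

    Attributes
    ----------
    edges
        Sorted (u, v) tuples, u < v, matching the network's edge set.
    counts
        edge -> (3, 3, 2) integer array of training genotype-pair counts;
        last axis indexes class (0=control, 1=case).
    n_case, n_control
        Training class sizes.
    training_subject_ids
        The ids of the subjects the tables were fitted on (audit trail for
        leakage checks).
    zero_evidence
        "absent" (default) or "plus"; how unobserved genotype pairs sign.
    """

    edges: list[tuple[str, str]]
    counts: dict
    n_case: int
    n_control: int
    training_subject_ids: list[str]
    zero_evidence: str = "absent"

    def proportions(self, edge: tuple[str, str]) -> np.ndarray:
        """(3, 3, 2) within-class proportion table for one edge.

        Each class's nine cells sum to 1 when that class has at least one
        complete-data training subject for the pair; an unobserved class
        yields all-zero proportions.
        """
        c = self.counts[edge].astype(float)
        totals = c.sum(axis=(0, 1), keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, c / np.maximum(totals, 1), 0.0)
        return p

    def sign_table(self, edge: tuple[str, str], mode: str = "proportion") -> np.ndarray:
        """(3, 3) table of signs (+1 / -1 / 0=absent) for an edge.

        mode="proportion" compares within-class proportions; mode="count"
        compares raw counts with control counts scaled by the class-balance
        weight. The two are the same comparison and always agree.
        """
        c = self.counts[edge].astype(float)
        t_ctl, t_case = c[:, :, 0].sum(), c[:, :, 1].sum()
        if mode == "count" and t_ctl > 0 and t_case > 0:
            # count_case >= (t_case/t_ctl) * count_ctl, cross-multiplied to
            # avoid division; the weight is the per-edge class-balance ratio
            plus = c[:, :, 1] * t_ctl >= c[:, :, 0] * t_case
        elif mode in ("proportion", "count"):
            p = self.proportions(edge)
            plus = p[:, :, 1] >= p[:, :, 0]
        else:
            raise ValueError(f"unknown sign mode {mode!r}")
        signs = np.where(plus, 1, -1)
        if self.zero_evidence == "absent":
            unseen = c.sum(axis=2) == 0
            signs = np.where(unseen, 0, signs)
        elif self.zero_evidence != "plus":
            raise ValueError(f"unknown zero_evidence policy {self.zero_evidence!r}")
        return signs


def fit_pair_statistics(
    training: Dataset,
    network: EpistasisNetwork,
    zero_evidence: str = "absent",
) -> PairClassProportions:
    """Count genotype pairs per edge and class over the training subjects.

    Subjects missing either genotype of a pair are excluded from that pair's
    table only. Both classes must be non-empty.
    """
    training.phenotype.require_both_classes()
    codes = training.genotypes.codes
    y = training.phenotype.labels
    col = {v: j for j, v in enumerate(training.variant_ids)}
    counts: dict = {}
    edges = sorted((min(u, v), max(u, v)) for u, v, _ in network.edges())
    for u, v in edges:
        if u not in col or v not in col:
            raise KeyError(f"network variant missing from training data: {u if u not in col else v}")
        a, b = codes[:, col[u]], codes[:, col[v]]
        ok = (a != MISSING) & (b != MISSING)
        table = np.zeros((3, 3, 2), dtype=np.int64)
        flat = np.bincount((a[ok] * 3 + b[ok]) * 2 + y[ok], minlength=18)
        counts[(u, v)] = table + flat.reshape(3, 3, 2)
    return PairClassProportions(
        edges=edges,
        counts=counts,
        n_case=training.phenotype.n_cases,
        n_control=training.phenotype.n_controls,
        training_subject_ids=list(training.subject_ids),
        zero_evidence=zero_evidence,
    )


def edge_sign(
    stats: PairClassProportions,
    edge: tuple[str, str],
    a_u: int,
    a_v: int,
    mode: str = "proportion",
) -> str:
    """Sign of one edge for one genotype pair: '+', '-' or 'absent'.

    The edge is looked up in canonical (u < v) orientation; passing it
    reversed flips the genotype pair accordingly. A missing genotype at
    either endpoint gives 'absent'.
    """
    u, v = edge
    if (u, v) not in stats.counts:
        if (v, u) in stats.counts:
            u, v, a_u, a_v = v, u, a_v, a_u
        else:
            raise KeyError(f"unknown edge {edge!r}")
    if a_u == MISSING or a_v == MISSING:
        return "absent"
    if a_u not in (0, 1, 2) or a_v not in (0, 1, 2):
        raise ValueError(f"genotype codes must be in {{0,1,2}}, got ({a_u}, {a_v})")
    return SIGN_CHARS[int(stats.sign_table((u, v), mode=mode)[a_u, a_v])]


def build_subject_network(
    subject_genotypes: dict,
    network: EpistasisNetwork,
    stats: PairClassProportions,
    mode: str = "proportion",
) -> list[tuple[str, str, str]]:
    """Signed edge list for one subject: [(u, v, '+'/'-'/'absent'), ...].

    ``subject_genotypes`` maps variant id -> code; every network variant must
    be present (missing codes allowed).
    """
    out = []
    for u, v in stats.edges:
        if u not in subject_genotypes or v not in subject_genotypes:
            raise KeyError(f"subject genotypes do not cover network variant {u!r}/{v!r}")
        out.append((u, v, edge_sign(stats, (u, v), subject_genotypes[u], subject_genotypes[v], mode)))
    return out


@dataclasses.dataclass
class TransformedMatrix:
    """Subjects x connected-variants integer matrix of delta degrees."""

    subject_ids: list[str]
    variant_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.variant_ids)


def delta_degree_transform(
    dataset: Dataset,
    network: EpistasisNetwork,
    stats: PairClassProportions,
    mode: str = "proportion",
) -> TransformedMatrix:
    """Delta degree d_minus - d_plus for every subject and connected variant.

    'absent' edges (unseen genotype pair, or missing genotype at either
    endpoint) contribute 0. Columns are the network's connected variants in
    sorted order; each value lies in [-deg(n), +deg(n)].
    """
    nodes = network.nodes
    col_out = {v: j for j, v in enumerate(nodes)}
    col_in = {v: j for j, v in enumerate(dataset.variant_ids)}
    n = dataset.n_subjects
    delta = np.zeros((n, len(nodes)), dtype=np.int64)
    for u, v in stats.edges:
        if u not in col_in or v not in col_in:
            raise KeyError(f"dataset does not cover network variant {u if u not in col_in else v}")
        a = dataset.genotypes.codes[:, col_in[u]]
        b = dataset.genotypes.codes[:, col_in[v]]
        table = stats.sign_table((u, v), mode=mode)
        ok = (a != MISSING) & (b != MISSING)
        signs = np.zeros(n, dtype=np.int64)
        signs[ok] = table[a[ok], b[ok]]
        # a '+' edge lowers delta degree at both endpoints, a '-' edge raises it
        delta[:, col_out[u]] -= signs
        delta[:, col_out[v]] -= signs
    return TransformedMatrix(list(dataset.subject_ids), nodes, delta)
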