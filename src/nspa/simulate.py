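"""Synthetic case-control genotype data with planted epistatic interactions.

The generator mirrors the structure of GAMETES-style benchmark data and of a
post-QC case-control GWAS panel: every locus is drawn independently under
Hardy-Weinberg equilibrium at its allele frequency (alternate-allele count ~
Binomial(2, maf), linkage equilibrium across loci), a small number of loci
participate in planted penetrance-table models, and the remaining "noise"
loci are independent of the phenotype.

Penetrance models assign P(disease | genotype combination) through a table
indexed by the allele-count codes of their loci. Two families are built in:

* :func:`xor_model` - a two-locus parity model (penetrance = base + lift when
  exactly one locus carries an odd allele count). At maf 0.5 the single-locus
  marginal penetrances are flat: pure epistasis, no main effects.
* :func:`threeway_model` - a three-locus parity model whose two-locus
  marginals are flat, so no variant pair carries pairwise synergy; only the
  full triple is informative.

With several models, a subject's disease probability combines independent
causal routes: P(disease) = 1 - prod_j (1 - pen_j(g_j)). Case/control counts
are met exactly by per-class rejection sampling, emulating a case-control
(not cohort) design.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .data import Dataset, GenotypeMatrix, PhenotypeVector

__all__ = [
    "PenetranceModel",
    "ModelSummary",
    "xor_model",
    "threeway_model",
    "model_summary",
    "simulate_dataset",
    "simulate_population",
    "read_pmlb",
]


@dataclasses.dataclass
class PenetranceModel:
    """Penetrance table over one or more loci under HWE genotype frequencies.

    ``table`` has shape (3,)*n_loci; entry [g1, ..., gk] is the disease
    probability for that genotype combination. ``mafs`` are the alternate
    (minor) allele frequencies of the loci, each in (0, 0.5].
    """

    table: np.ndarray
    mafs: tuple[float, ...]

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        self.mafs = tuple(float(m) for m in self.mafs)
        if self.table.shape != (3,) * self.n_loci:
            raise ValueError("table shape must be (3,)*n_loci")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")
        for m in self.mafs:
            if not (0 < m <= 0.5):
                raise ValueError("allele frequencies must lie in (0, 0.5]")

    @property
    def n_loci(self) -> int:
        return len(self.mafs)

    @property
    def maf_a(self) -> float:
        return self.mafs[0]

    @property
    def maf_b(self) -> float:
        return self.mafs[1]

    def genotype_frequencies(self) -> np.ndarray:
        """Joint HWE genotype frequencies, shape (3,)*n_loci, summing to 1."""
        out = np.ones(())
        for q in self.mafs:
            f = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
            out = np.multiply.outer(out, f)
        return out


@dataclasses.dataclass
class ModelSummary:
    """Population-level expectations of a penetrance model under HWE."""

    prevalence: float
    heritability: float
    marginal_penetrance: list[np.ndarray]  # per locus, length-3
    main_effect: list[float]  # per locus, max |marginal - prevalence|


def xor_model(maf: float, base: float, lift: float) -> PenetranceModel:
    """Two-locus parity model: penetrance = base + lift when (a mod 2) xor (b mod 2)."""
    if not (0 <= base <= 1 and 0 <= base + lift <= 1):
        raise ValueError("base and base+lift must lie in [0, 1]")
    a, b = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    table = np.where((a % 2) ^ (b % 2) == 1, base + lift, base)
    return PenetranceModel(table, (maf, maf))


def threeway_model(maf: float, base: float = 0.1, lift: float = 0.8) -> PenetranceModel:
    """Three-locus parity model with flat pairwise marginals.

    Penetrance = base + lift when (a + b + c) is odd. Conditioning on any two
    loci leaves the third's parity at exactly 1/2 under maf 0.5, so every
    locus pair is uninformative about the phenotype; the interaction is
    visible only at third order.
    """
    if not (0 <= base <= 1 and 0 <= base + lift <= 1):
        raise ValueError("base and base+lift must lie in [0, 1]")
    g = np.indices((3, 3, 3)).sum(axis=0)
    table = np.where(g % 2 == 1, base + lift, base)
    return PenetranceModel(table, (maf, maf, maf))


def pure_epistasis_model(
    maf: float, prevalence: float, heritability: float
) -> PenetranceModel:
    """Two-locus penetrance table with exactly zero marginal effects.

    The table is K + c * outer(u, u) where u = (1, x, 1) is chosen orthogonal
    to the HWE genotype frequencies (sum_g f(g) u(g) = 0) and c is scaled so
    Var_g(pen) = heritability * K * (1 - K). By the product structure, every
    single-locus marginal penetrance equals the prevalence K exactly, at any
    allele frequency: the pair carries only epistatic signal, as in
    GAMETES-designed benchmark tables.

    Raises if the requested (maf, prevalence, heritability) would push a
    penetrance outside [0, 1].
    """
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0, 1)")
    if heritability < 0:
        raise ValueError("heritability must be non-negative")
    q = float(maf)
    f = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    # u = (1, x, 1) with f . u = 0
    x = -(f[0] + f[2]) / f[1]
    u = np.array([1.0, x, 1.0])
    su2 = float((f * u**2).sum())
    var_target = heritability * prevalence * (1 - prevalence)
    c = np.sqrt(var_target) / su2
    table = prevalence + c * np.outer(u, u)
    if ((table < 0) | (table > 1)).any():
        raise ValueError(
            "requested prevalence/heritability are not representable at this maf"
        )
    return PenetranceModel(table, (q, q))


def model_summary(model: PenetranceModel) -> ModelSummary:
    """Exact prevalence, broad-sense heritability and per-locus marginals."""
    freqs = model.genotype_frequencies()
    k = float((freqs * model.table).sum())
    var_g = float((freqs * (model.table - k) ** 2).sum())
    if k in (0.0, 1.0):
        h2 = 0.0
    else:
        h2 = var_g / (k * (1 - k))
    marginals = []
    effects = []
    for axis in range(model.n_loci):
        other = tuple(i for i in range(model.n_loci) if i != axis)
        joint = (freqs * model.table).sum(axis=other)
        weight = freqs.sum(axis=other)
        with np.errstate(invalid="ignore", divide="ignore"):
            marg = np.where(weight > 0, joint / np.maximum(weight, 1e-300), k)
        marginals.append(marg)
        effects.append(float(np.abs(marg - k).max()))
    return ModelSummary(k, h2, marginals, effects)


def _draw_genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray) -> np.ndarray:
    """n x len(mafs) HWE genotypes: alternate-allele count ~ Binomial(2, maf)."""
    return rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int64)


def disease_probability(models: list[PenetranceModel], planted: np.ndarray) -> np.ndarray:
    """P(disease) per subject via independent causal routes.

    ``planted`` columns are the models' loci concatenated in order.
    """
    n = planted.shape[0]
    p_healthy = np.ones(n)
    start = 0
    for m in models:
        g = planted[:, start : start + m.n_loci]
        pen = m.table[tuple(g[:, i] for i in range(m.n_loci))]
        p_healthy *= 1.0 - pen
        start += m.n_loci
    return 1.0 - p_healthy


def _planted_ids(models: list[PenetranceModel]) -> tuple[list[str], list[list[str]]]:
    ids: list[str] = []
    groups: list[list[str]] = []
    for j, m in enumerate(models):
        group = [f"rs_sig{j}{chr(ord('a') + k)}" for k in range(m.n_loci)]
        ids.extend(group)
        groups.append(group)
    return ids, groups


def _assemble(
    rng: np.random.Generator,
    planted: np.ndarray,
    labels: np.ndarray,
    models: list[PenetranceModel],
    n_noise_variants: int,
    noise_maf_range: tuple[float, float],
    seed,
    shuffle: bool = True,
) -> Dataset:
    n = planted.shape[0]
    planted_ids, groups = _planted_ids(models)
    lo, hi = noise_maf_range
    noise_mafs = rng.uniform(lo, hi, size=n_noise_variants)
    noise = _draw_genotypes(rng, n, noise_mafs)
    codes = np.hstack([planted, noise]) if n_noise_variants else planted
    variant_ids = planted_ids + [f"rs_noise{i}" for i in range(n_noise_variants)]
    order = rng.permutation(n) if shuffle else np.arange(n)
    meta = {
        "planted_groups": groups,
        "noise_variants": variant_ids[len(planted_ids) :],
        "noise_mafs": noise_mafs.tolist(),
        "seed": seed,
    }
    return Dataset(
        GenotypeMatrix([f"S{i}" for i in range(n)], variant_ids, codes[order]),
        PhenotypeVector(labels[order]),
        meta,
    )


def simulate_dataset(
    models: list[PenetranceModel],
    n_cases: int,
    n_controls: int,
    n_noise_variants: int = 0,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> Dataset:
    """Case-control dataset with exact class counts via rejection sampling.

    Planted loci (models' loci, in order) come first in the variant list,
    followed by noise variants with allele frequencies drawn uniformly from
    ``noise_maf_range``. Subject order is shuffled. Planted variant ids are
    recorded in ``Dataset.metadata["planted_groups"]``.
    """
    if not models and n_noise_variants == 0:
        raise ValueError("need at least one model or noise variant")
    if n_cases < 0 or n_controls < 0:
        raise ValueError("class counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_cases + n_controls
    n_planted = sum(m.n_loci for m in models)

    if not models:
        labels = np.concatenate([np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)])
        return _assemble(rng, np.empty((n, 0), dtype=np.int64), labels, models,
                         n_noise_variants, noise_maf_range, seed)

    mafs = np.array([m for model in models for m in model.mafs])
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    got_cases = got_controls = 0
    chunk = max(4 * n, 1024)
    for _ in range(max_attempts):
        g = _draw_genotypes(rng, chunk, mafs)
        p = disease_probability(models, g)
        sick = rng.random(chunk) < p
        if got_cases < n_cases:
            case_rows.append(g[sick])
            got_cases += int(sick.sum())
        if got_controls < n_controls:
            control_rows.append(g[~sick])
            got_controls += int((~sick).sum())
        if got_cases >= n_cases and got_controls >= n_controls:
            break
    else:
        raise RuntimeError(
            "could not reach the requested case/control counts; "
            "check that the penetrance model makes both classes reachable"
        )
    planted = np.vstack(
        [np.vstack(case_rows)[:n_cases] if case_rows else np.empty((0, n_planted), dtype=np.int64),
         np.vstack(control_rows)[:n_controls] if control_rows else np.empty((0, n_planted), dtype=np.int64)]
    )
    labels = np.concatenate([np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)])
    return _assemble(rng, planted, labels, models, n_noise_variants, noise_maf_range, seed)


def simulate_population(
    models: list[PenetranceModel],
    n_subjects: int,
    n_noise_variants: int = 0,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
) -> Dataset:
    """Unconstrained cohort sampling: labels drawn from the penetrance model.

    The empirical case fraction converges to the models' combined prevalence;
    useful for checking :func:`model_summary` and for cohort-style studies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.array([m for model in models for m in model.mafs])
    g = _draw_genotypes(rng, n_subjects, mafs)
    p = disease_probability(models, g)
    labels = (rng.random(n_subjects) < p).astype(np.int64)
    return _assemble(rng, g, labels, models, n_noise_variants, noise_maf_range, seed, shuffle=False)


def read_pmlb(path, class_column: str = "class") -> Dataset:
    """Read a PMLB-format GAMETES table (TSV: attribute columns + class).

    Predictive attributes follow the GAMETES naming convention (ids starting
    with 'M'); they are recorded as a single planted group in metadata.
    """
    df = pd.read_csv(path, sep="\t")
    if class_column not in df.columns:
        raise ValueError(f"{path}: missing class column {class_column!r}")
    y = df[class_column].astype(np.int64).to_numpy()
    geno = df.drop(columns=[class_column])
    codes = geno.to_numpy(dtype=np.int64)
    variant_ids = [str(c) for c in geno.columns]
    planted = [v for v in variant_ids if v.upper().startswith("M")]
    ds = Dataset(
        GenotypeMatrix([f"S{i}" for i in range(len(df))], variant_ids, codes),
        PhenotypeVector(y),
        {"planted_groups": [planted] if planted else []},
    )
    return ds
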