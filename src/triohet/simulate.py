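"""Synthetic trio RNA-seq with planted ground truth.

Emulates a two-parent/one-hybrid field study sampled in two environments
and at two timepoints with replicated libraries (3 genotypes x 2
environments x 2 timepoints x 3 replicates = 36 libraries by default).
Counts are negative binomial around a multiplicative (log2-scale) mean
structure: for a gene with baseline m, additive effect a and dominance
effect d,

    P1 = m + a,   P2 = m - a,   F1 = m + d        (log2 scale)

so the mid-parent log2 mean is m and the planted potency ratio d/a fixes
the gene's true inheritance class.  The generator can additionally plant

* timepoint shifts shared by all three genotypes (temporal SDGs) or
  restricted to the hybrid (hybrid-specific SDGs, the SDG_hp truth),
* correlated co-expression blocks driven by latent per-sample factors,
* an annotation term enriched for an arbitrary target set,

and returns a per-gene truth table so every downstream stage can be scored
against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .inheritance import MODES, classify_mode, potency_ratio
from .enrichment import AnnotationMap

__all__ = [
    "TrioSimConfig",
    "TraitSpec",
    "generate_trio_counts",
    "generate_phenotypes",
    "generate_annotation",
]

# |Hp| knots delimiting the four inheritance classes; planted ratios are
# drawn from a continuous piecewise-linear density over these intervals
_HP_KNOTS = (0.0, 0.2, 0.8, 1.2, 3.0)
_HP_CLASSES = ("additive", "partial_dominance", "dominance", "over_dominance")


def _hp_density_nodes(proportions: dict) -> np.ndarray:
    """Node heights of a continuous piecewise-linear |Hp| density.

    Real potency ratios follow a smooth distribution over the line rather
    than per-class uniform blocks, so the generator plants |Hp| from a
    piecewise-linear density that is continuous at the class boundaries
    while the area over each class interval equals its configured
    proportion.  Solved back-to-front with the density pinned to 0 at the
    outer knot; a proportion mix that would force a negative density is
    rejected.
    """
    k = _HP_KNOTS
    f = np.zeros(5)
    f[4] = 0.0
    for i in (3, 2, 1, 0):
        mass = proportions.get(_HP_CLASSES[i], 0.0)
        width = k[i + 1] - k[i]
        f[i] = 2.0 * mass / width - f[i + 1]
        if f[i] < 0:
            raise ValueError(
                "class_proportions incompatible with a continuous planted Hp density"
            )
    return f


def _sample_hp_magnitude(rng: np.random.Generator, cls: str, size: int, nodes: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of |Hp| within one class interval of the density."""
    i = _HP_CLASSES.index(cls)
    lo, hi = _HP_KNOTS[i], _HP_KNOTS[i + 1]
    f0, f1 = nodes[i], nodes[i + 1]
    # keep draws strictly interior so signed ratios never land on a boundary
    u = rng.uniform(1e-9, 1.0 - 1e-9, size)
    w = hi - lo
    if abs(f1 - f0) < 1e-12 * max(f0, f1, 1.0):
        return lo + u * w
    # solve u = (f0 t + (f1-f0) t^2 / 2) / (f0 + (f1-f0)/2) for t in [0,1]
    a2 = (f1 - f0) / 2.0
    total = f0 + a2
    disc = f0**2 + 4.0 * a2 * u * total
    t = (-f0 + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a2)
    return lo + np.clip(t, 0.0, 1.0) * w


@dataclass
class TrioSimConfig:
    """Study design and effect architecture for one simulated trio dataset.

    Defaults mirror the field-trial design the package targets: 3
    biological replicates, two environments, two timepoints, 20M-read
    libraries, NB dispersion 0.1, effects of magnitude 1 on the log2 scale
    (4-fold parental difference), and inheritance-class proportions echoing
    a typical hybrid-rice flag-leaf breakdown.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    environments: tuple = ("E1", "E2")
    timepoints: tuple = ("T1", "T2")
    library_size: int = 20_000_000
    dispersion: float = 0.1
    class_proportions: dict = field(
        default_factory=lambda: {
            "additive": 0.22,
            "partial_dominance": 0.42,
            "dominance": 0.11,
            "over_dominance": 0.25,
        }
    )
    effect_scale: float = 1.0
    module_spec: tuple = ()  # (module_size, within-module correlation) pairs
    n_sdg_parent_shared: int = 0  # timepoint shift in all three genotypes
    n_sdg_hybrid_specific: int = 0  # timepoint shift in the F1 only
    sdg_shift: float = 2.0  # log2 shift at the later timepoint (>= 2-fold)
    sdg_environments: tuple | None = None  # default: every environment
    base_log2_range: tuple = (3.0, 10.0)
    gene_length_range: tuple = (200, 10_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1 or self.library_size < 1:
            raise ValueError("all sizes must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if set(self.class_proportions) - set(MODES):
            raise ValueError(f"unknown class in proportions: {set(self.class_proportions) - set(MODES)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1 (got {total})")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be positive")
        n_planted = self.n_sdg_parent_shared + self.n_sdg_hybrid_specific
        if n_planted > self.n_genes:
            raise ValueError("more SDG genes requested than genes simulated")
        if sum(size for size, _ in self.module_spec) > self.n_genes:
            raise ValueError("module_spec allocates more genes than simulated")


def _allocate_classes(proportions: dict, n: int) -> list[str]:
    """Deterministic largest-remainder allocation of class counts."""
    classes = [c for c in MODES if proportions.get(c, 0) > 0]
    raw = np.array([proportions[c] * n for c in classes])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    for i in np.argsort(-(raw - np.floor(raw)), kind="stable")[:rem]:
        counts[i] += 1
    out = []
    for c, k in zip(classes, counts):
        out.extend([c] * k)
    return out


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def generate_trio_counts(
    config: TrioSimConfig, *, return_means: bool = False
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the full trio count matrix with its design and truth table.

    Returns ``(CountMatrix, SampleDesign, TruthTable)``.  SampleDesign is a
    DataFrame with columns sample_id/genotype/environment/timepoint/
    replicate; TruthTable is per-gene with the planted class, a, d, Hp,
    module id, and per-environment SDG / SDG_hp flags.  With
    ``return_means=True`` a fourth element carries the expected (scaled)
    mean-count matrix.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    # planted effect architecture ------------------------------------------
    classes = np.array(_allocate_classes(config.class_proportions, n))
    rng.shuffle(classes)
    sign_a = rng.choice([-1.0, 1.0], size=n)
    a = config.effect_scale * sign_a
    try:
        nodes = _hp_density_nodes(config.class_proportions)
    except ValueError:
        nodes = None  # degenerate mix (e.g. a single class): per-class uniform
    hp = np.empty(n)
    for i, cls in enumerate(_HP_CLASSES):
        mask = classes == cls
        m = int(mask.sum())
        if m == 0:
            continue
        if nodes is not None:
            mag = _sample_hp_magnitude(rng, cls, m, nodes)
        else:
            lo, hi = _HP_KNOTS[i], _HP_KNOTS[i + 1]
            mag = rng.uniform(lo + 1e-9, hi, size=m)
        hp[mask] = rng.choice([-1.0, 1.0], size=m) * mag
    d = hp * a
    base = rng.uniform(*config.base_log2_range, size=n)

    # planted SDG structure -------------------------------------------------
    envs_sdg = tuple(config.sdg_environments or config.environments)
    perm = rng.permutation(n)
    shared_idx = perm[: config.n_sdg_parent_shared]
    hyb_idx = perm[config.n_sdg_parent_shared : config.n_sdg_parent_shared + config.n_sdg_hybrid_specific]
    shift_sign = rng.choice([-1.0, 1.0], size=n)
    is_shared = np.zeros(n, dtype=bool)
    is_shared[shared_idx] = True
    is_hyb = np.zeros(n, dtype=bool)
    is_hyb[hyb_idx] = True

    # planted co-expression blocks ------------------------------------------
    module_id = np.array(["none"] * n, dtype=object)
    mod_perm = rng.permutation(np.setdiff1d(np.arange(n), np.concatenate([shared_idx, hyb_idx])))
    loadings = np.zeros(n)
    offset = 0
    for j, (size, r) in enumerate(config.module_spec):
        idx = mod_perm[offset : offset + size]
        offset += size
        module_id[idx] = f"module_{j + 1}"
        # amplitude mapping correlation -> latent factor weight, against a
        # nominal 0.5 log2-units of count-level noise
        loadings[idx] = 0.5 * np.sqrt(r / (1.0 - r)) if r < 1 else 5.0

    # sample sheet -----------------------------------------------------------
    rows = []
    for env in config.environments:
        for tp in config.timepoints:
            for geno in ("P1", "P2", "F1"):
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {"sample_id": f"{geno}_{env}_{tp}_R{rep}", "genotype": geno,
                         "environment": env, "timepoint": tp, "replicate": rep}
                    )
    design = pd.DataFrame(rows)
    n_samples = len(design)

    geno_eff = {"P1": a, "P2": -a, "F1": d}
    later_tp = config.timepoints[-1]
    factors = {
        (j, s): rng.normal() for j in range(len(config.module_spec)) for s in range(n_samples)
    }

    logm = np.empty((n, n_samples))
    for s, row in enumerate(design.itertuples()):
        col = base + geno_eff[row.genotype]
        if row.timepoint == later_tp and row.environment in envs_sdg:
            shift = np.zeros(n)
            shift[is_shared] = 1.0
            if row.genotype == "F1":
                shift[is_hyb] = 1.0
            col = col + shift_sign * config.sdg_shift * shift
        for j in range(len(config.module_spec)):
            mask = module_id == f"module_{j + 1}"
            col = np.where(mask, col + loadings * factors[(j, s)], col)
        logm[:, s] = col

    mu = np.exp2(logm)
    mu *= config.library_size / mu.sum(axis=0, keepdims=True)
    counts = _draw_counts(rng, mu, config.dispersion)
    lengths = pd.Series(rng.integers(*config.gene_length_range, size=n), index=genes, name="length")
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=design["sample_id"].tolist()),
        lengths=lengths,
    )

    truth = pd.DataFrame(
        {
            "class": classes,
            "a_true": a,
            "d_true": d,
            "hp_true": hp,
            "base_log2": base,
            "module": module_id,
        },
        index=genes,
    )
    for env in config.environments:
        planted = env in envs_sdg
        truth[f"sdg_shared_{env}"] = is_shared & planted
        truth[f"sdg_hp_{env}"] = is_hyb & planted
    truth["ssdg_hp"] = np.logical_and.reduce(
        [truth[f"sdg_hp_{env}"].to_numpy() for env in config.environments]
    )
    # consistency guard: the planted label must agree with the classifier
    assert (classify_mode(truth["hp_true"].to_numpy()) == truth["class"].to_numpy()).all()

    if return_means:
        means = pd.DataFrame(mu, index=genes, columns=design["sample_id"].tolist())
        return cm, design, truth, means
    return cm, design, truth


@dataclass
class TraitSpec:
    """Replicate-level phenotype generator for one trait in one condition."""

    trait: str
    genotype_means: dict
    sds: dict | float = 0.0
    n_replicates: int = 3
    environment: str = "E1"
    timepoint: str = "T1"
    seed: int = 0

    def sd_for(self, genotype: str) -> float:
        sd = self.sds.get(genotype, 0.0) if isinstance(self.sds, dict) else float(self.sds)
        if sd < 0:
            raise ValueError(f"negative sd for {genotype} in trait {self.trait!r}")
        return sd


def generate_phenotypes(trait_specs: list[TraitSpec]) -> pd.DataFrame:
    """Long-format replicate-level phenotype table from trait specs.

    With sd = 0 every replicate equals its genotype mean, so a spec built
    from a published trait-mean table reproduces those means exactly.
    """
    rows = []
    for spec in trait_specs:
        rng = np.random.default_rng(spec.seed)
        for geno, mean in spec.genotype_means.items():
            sd = spec.sd_for(geno)
            vals = mean + sd * rng.standard_normal(spec.n_replicates)
            for i, v in enumerate(vals, start=1):
                rows.append(
                    {"trait": spec.trait, "environment": spec.environment,
                     "timepoint": spec.timepoint, "genotype": geno,
                     "replicate": i, "value": float(v)}
                )
    return pd.DataFrame(rows)


def generate_annotation(
    n_terms: int,
    term_size_range: tuple[int, int],
    n_genes: int,
    enriched_term: str | None = None,
    target_set: set | None = None,
    seed: int = 0,
    overlap_rate: float = 1.0,
) -> AnnotationMap:
    """Random GMT-style annotation over a synthetic gene universe.

    Terms draw genes uniformly from the universe ``g00000 .. g{n_genes-1}``;
    if ``enriched_term`` is given, that term is built to overlap
    ``target_set`` at ``overlap_rate`` (fraction of the target it contains),
    padded with background genes up to its drawn size.
    """
    if n_genes < 1:
        raise ValueError("empty gene universe")
    lo, hi = term_size_range
    if lo < 1 or hi > n_genes or lo > hi:
        raise ValueError("term sizes must lie within [1, n_genes]")
    rng = np.random.default_rng(seed)
    universe = [f"g{i:05d}" for i in range(n_genes)]
    gene_sets: dict[str, set] = {}
    desc: dict[str, str] = {}
    for t in range(n_terms):
        name = f"term{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        gene_sets[name] = set(rng.choice(universe, size=size, replace=False))
        desc[name] = "synthetic background term"
    if enriched_term is not None:
        target = sorted(set(target_set or ()) & set(universe))
        k = int(round(overlap_rate * len(target)))
        chosen = list(rng.choice(target, size=k, replace=False)) if k else []
        size = max(int(rng.integers(lo, hi + 1)), k)
        background = sorted(set(universe) - set(target))
        pad = list(rng.choice(background, size=size - k, replace=False)) if size > k else []
        gene_sets[enriched_term] = set(chosen) | set(pad)
        desc[enriched_term] = "synthetic planted enriched term"
    return AnnotationMap(gene_sets=gene_sets, descriptions=desc, universe=set(universe))
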