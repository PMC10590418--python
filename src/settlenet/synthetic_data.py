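"""Synthetic settlement-experiment generator with planted structure.

Emulates the tetrapod conditioning design: tanks of conditioned
tetrapods (plus an unconditioned control), three compartment samples per
tetrapod, per-tetrapod larval settlement counts whose within-tank
fractions respect drawn settlement categories, and an ASV count table
with planted statistical structure the downstream analysis is supposed
to recover:

* **modules** — groups of taxa sharing a latent log-scale factor, so
  their abundances co-vary across tetrapods;
* **bridging taxa** — loading equally on two modules;
* **category-exclusive taxa** — hard-gated to zero outside the samples
  of their settlement category (each category's exclusives also share a
  latent factor so they co-occur);
* **rare taxa** — base levels tuned so expected relative abundance stays
  below 0.1%;
* background taxa with independent noise.

Counts are drawn multinomially per compartment at a negative-binomial
sequencing depth, reproducing compositional closure and over-dispersion.
The generator is deterministic per seed, and returns a :class:`SimTruth`
for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RANKS, CountTable, SampleMetadata, TaxonomyTable, UNASSIGNED
from .settlement import SCHEMES, CategoryScheme


class ConfigError(ValueError):
    """Infeasible or invalid simulation configuration."""


CATEGORIES = ("low", "medium", "high")


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the conditioning design
    (12 tanks per conditioning type, three conditioned tetrapods plus one
    unconditioned control each, compartments sampled separately)."""

    n_tanks_per_conditioning: int = 12
    conditioned_per_tank: int = 3
    controls_per_tank: int = 1
    conditioning: str = "aquarium"
    n_taxa: int = 100
    n_modules: int = 5
    taxa_per_module: int = 12
    n_exclusive_per_category: int = 5
    n_rare: int = 10
    n_bridging: int = 4
    module_effect: float = 1.5           # latent-factor loading, log scale
    noise_sd: float = 0.5                # residual log-scale noise
    base_sd: float = 0.3                 # spread of per-taxon base levels
    rare_target_rel: float = 2e-4        # expected relative abundance of rare taxa
    depth_mean: float = 50_000.0         # reads per tetrapod
    depth_dispersion: float = 10.0       # negative-binomial shape
    compartment_alpha: float = 5.0       # symmetric Dirichlet over 3 compartments
    larvae_per_tank: int = 350
    settle_rate: float = 0.4             # fraction of larvae that settle at all
    category_probs: dict = field(default_factory=lambda: {c: 1 / 3 for c in CATEGORIES})
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_taxa <= 0:
            raise ConfigError("n_taxa must be positive")
        structured = (self.n_modules * self.taxa_per_module
                      + len(CATEGORIES) * self.n_exclusive_per_category
                      + self.n_rare + self.n_bridging)
        if structured > self.n_taxa:
            raise ConfigError(
                f"planted taxa ({structured}) exceed n_taxa ({self.n_taxa})")
        if self.n_bridging and self.n_modules < 2:
            raise ConfigError("bridging taxa need at least 2 modules")
        probs = [self.category_probs.get(c, 0.0) for c in CATEGORIES]
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(f"category_probs must be in [0,1] and sum to 1: {probs}")
        if self.conditioned_per_tank < 1 or self.n_tanks_per_conditioning < 1:
            raise ConfigError("need at least one tank with one conditioned tetrapod")


@dataclass
class SimTruth:
    """Planted labels: module per taxon, exclusive category per exclusive
    taxon, bridging taxa with their module pair, rare taxa, and the
    settlement category of every tetrapod."""

    module_of: dict
    exclusive_of: dict
    bridging: dict
    rare: list
    category_of_tetrapod: dict

    def to_dict(self) -> dict:
        return {"module_of": self.module_of, "exclusive_of": self.exclusive_of,
                "bridging": {k: list(v) for k, v in self.bridging.items()},
                "rare": list(self.rare),
                "category_of_tetrapod": self.category_of_tetrapod}


# ---------------------------------------------------------------------------
# Settlement counts
# ---------------------------------------------------------------------------


def settlement_from_category(categories: list[str], scheme: CategoryScheme,
                             rng: np.random.Generator, total: int,
                             max_attempts: int = 100) -> list[int]:
    """Settled-larvae counts for one tank whose within-tank fractions fall
    inside each tetrapod's category interval.

    Each tetrapod starts at the smallest count whose fraction reaches its
    interval's lower bound; the remaining larvae are assigned one at a time
    to tetrapods with spare capacity below their upper bound (intervals are
    half-open [lo, hi) except the terminal one). Raises when the category
    combination is infeasible at this total.
    """
    intervals = [scheme.interval(c) for c in categories]
    lows = np.array([lo for lo, _ in intervals])
    widths = np.array([hi - lo for lo, hi in intervals])
    if 1.0 - lows.sum() < 0 or widths.sum() < 1.0 - lows.sum():
        raise ConfigError(f"jointly infeasible category bounds for tank: {categories}")
    c_lo = np.array([math.ceil(lo * total - 1e-9) for lo, _ in intervals])
    c_hi = np.array([total if hi >= 1.0 else math.ceil(hi * total - 1e-9) - 1
                     for _, hi in intervals])
    if c_lo.sum() > total or c_hi.sum() < total:
        raise ConfigError(
            f"category bounds {categories} infeasible for a tank total of {total}")
    for _ in range(max_attempts):
        counts = c_lo.copy()
        ok = True
        for _ in range(total - int(c_lo.sum())):
            capacity = (c_hi - counts).astype(float)
            if capacity.sum() <= 0:
                ok = False
                break
            counts[rng.choice(len(counts), p=capacity / capacity.sum())] += 1
        if ok and counts.sum() == total:
            return [int(c) for c in counts]
    raise ConfigError(
        f"could not realise within-tank fractions for categories {categories} "
        f"after {max_attempts} attempts")


def _feasible_categories(k: int, scheme: CategoryScheme, probs: list[float],
                         rng: np.random.Generator, max_attempts: int = 100) -> list[str]:
    for _ in range(max_attempts):
        cats = list(rng.choice(CATEGORIES, size=k, p=probs))
        intervals = [scheme.interval(c) for c in cats]
        if (sum(lo for lo, _ in intervals) <= 1.0
                and sum(hi for _, hi in intervals) >= 1.0):
            return [str(c) for c in cats]
    raise ConfigError("could not draw a jointly feasible category assignment")


# ---------------------------------------------------------------------------
# Experiment generator
# ---------------------------------------------------------------------------


def generate_experiment(config: SimConfig
                        ) -> tuple[CountTable, SampleMetadata, TaxonomyTable,
                                   pd.DataFrame, SimTruth]:
    """Generate (counts, metadata, taxonomy, settlement counts, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    scheme = SCHEMES.get(config.conditioning, SCHEMES["aquarium"])
    probs = [config.category_probs[c] for c in CATEGORIES]

    # --- taxa layout -------------------------------------------------------
    n = config.n_taxa
    taxa = [f"asv{i:04d}" for i in range(n)]
    module_of: dict = {}
    bridging: dict = {}
    exclusive_of: dict = {}
    rare: list = []
    cursor = 0
    for m in range(config.n_modules):
        for _ in range(config.taxa_per_module):
            module_of[taxa[cursor]] = m
            cursor += 1
    for b in range(config.n_bridging):
        m1 = b % max(1, config.n_modules - 1)
        bridging[taxa[cursor]] = (m1, m1 + 1)
        cursor += 1
    for c in CATEGORIES:
        for _ in range(config.n_exclusive_per_category):
            exclusive_of[taxa[cursor]] = c
            cursor += 1
    for _ in range(config.n_rare):
        rare.append(taxa[cursor])
        cursor += 1
    background = taxa[cursor:]

    # --- per-taxon base log-abundance --------------------------------------
    base = rng.normal(0.0, config.base_sd, size=n)
    rare_idx = [taxa.index(t) for t in rare]
    # lognormal-mean correction keeps the expected relative abundance on target
    sigma2 = config.base_sd ** 2 + config.noise_sd ** 2
    base[rare_idx] += math.log(config.rare_target_rel * n) - sigma2 / 2

    # --- design: tanks, tetrapods, categories, settlement -------------------
    cond = config.conditioning
    meta_rows, settle_rows = [], []
    tet_ids, tet_cats, tet_times = [], [], []
    for tank in range(config.n_tanks_per_conditioning):
        tank_id = f"{cond}_tank{tank:02d}"
        k = config.conditioned_per_tank + config.controls_per_tank
        for _ in range(100):
            cats = _feasible_categories(k, scheme, probs, rng)
            total = int(rng.binomial(config.larvae_per_tank, config.settle_rate)) or 1
            try:
                counts = settlement_from_category(cats, scheme, rng, total)
                break
            except ConfigError:
                continue  # integer-infeasible at this total; redraw
        else:
            raise ConfigError(f"no realisable category assignment for tank {tank_id}")
        for j in range(k):
            is_control = j >= config.conditioned_per_tank
            time = 0 if is_control else (j % 3) + 1
            tet = f"{tank_id}_tet{j}"
            tet_ids.append(tet)
            tet_cats.append(cats[j])
            tet_times.append(time)
            settle_rows.append({"tetrapod_id": tet, "tank_id": tank_id,
                                "settled": counts[j]})
            for comp in ("surface", "crevice", "bottom"):
                meta_rows.append({"sample_id": f"{tet}_{comp}", "conditioning": cond,
                                  "time_months": time, "tank_id": tank_id,
                                  "tetrapod_id": tet, "compartment": comp})

    # --- abundances and counts ---------------------------------------------
    n_tet = len(tet_ids)
    factors = rng.normal(size=(config.n_modules + len(CATEGORIES), n_tet))
    loadings = np.zeros((n, config.n_modules + len(CATEGORIES)))
    for t, m in module_of.items():
        loadings[taxa.index(t), m] = config.module_effect
    for t, (m1, m2) in bridging.items():
        i = taxa.index(t)
        loadings[i, m1] = config.module_effect / math.sqrt(2)
        loadings[i, m2] = config.module_effect / math.sqrt(2)
    for t, c in exclusive_of.items():
        loadings[taxa.index(t), config.n_modules + CATEGORIES.index(c)] = config.module_effect

    eta = base[:, None] + loadings @ factors + rng.normal(
        0.0, config.noise_sd, size=(n, n_tet))
    gate = np.ones((n, n_tet), dtype=bool)
    for t, c in exclusive_of.items():
        i = taxa.index(t)
        gate[i] = np.array([tc == c for tc in tet_cats])

    counts_cols: dict = {}
    for j in range(n_tet):
        w = np.exp(eta[:, j]) * gate[:, j]
        p = w / w.sum()
        r = config.depth_dispersion
        depth = int(rng.negative_binomial(r, r / (r + config.depth_mean))) + 1000
        shares = rng.dirichlet([config.compartment_alpha] * 3)
        comp_depths = rng.multinomial(depth, shares)
        for comp, d in zip(("surface", "crevice", "bottom"), comp_depths):
            counts_cols[f"{tet_ids[j]}_{comp}"] = rng.multinomial(int(d), p)

    table = CountTable(pd.DataFrame(counts_cols, index=taxa))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    taxonomy = _make_taxonomy(taxa, module_of, exclusive_of, rare, bridging)
    settlement = pd.DataFrame(settle_rows)
    truth = SimTruth(module_of, exclusive_of, bridging, rare,
                     dict(zip(tet_ids, tet_cats)))
    return table, metadata, taxonomy, settlement, truth


def planted_ggm(n_taxa: int = 60, n_samples: int = 200, density: float = 0.05,
                partial_corr: float = 0.3, seed: int | None = 0
                ) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Data from a sparse Gaussian graphical model with known edges.

    Builds a precision matrix with ``density`` random off-diagonal entries of
    magnitude ``partial_corr`` (random sign), rescaled to diagonal dominance
    so it stays positive definite, and draws ``n_samples`` multivariate
    normal samples. Returns (taxa × samples matrix, set of true edges (i, j)
    with i < j) — the ground truth for network-recovery tests.
    """
    rng = np.random.default_rng(seed)
    edges = set()
    pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    n_edges = int(round(density * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    omega = np.eye(n_taxa)
    for k in chosen:
        i, j = pairs[k]
        edges.add((i, j))
        val = partial_corr * (1 if rng.random() < 0.5 else -1)
        omega[i, j] = omega[j, i] = val
    # enforce diagonal dominance, then renormalise to unit diagonal
    row = np.abs(omega).sum(axis=1) - 1.0
    scale = np.maximum(1.0, row / 0.9)
    omega = omega / np.sqrt(np.outer(scale, scale))
    np.fill_diagonal(omega, 1.0)
    cov = np.linalg.inv(omega)
    dstd = np.sqrt(np.diag(cov))
    cov = cov / np.outer(dstd, dstd)
    X = rng.multivariate_normal(np.zeros(n_taxa), cov, size=n_samples,
                                method="cholesky").T
    return X, edges


def _make_taxonomy(taxa, module_of, exclusive_of, rare, bridging) -> TaxonomyTable:
    """Plausible 7-rank lineages: taxa in the same planted group share
    higher ranks; families subdivide groups in threes."""
    rows = {}
    for i, t in enumerate(taxa):
        if t in module_of:
            group, gid = "Module", module_of[t]
        elif t in exclusive_of:
            group, gid = f"Excl{exclusive_of[t].capitalize()}", 0
        elif t in rare:
            group, gid = "Rare", 0
        elif t in bridging:
            group, gid = "Bridge", 0
        else:
            group, gid = "Background", 0
        fam = f"{group}{gid}Family{i % 3}"
        rows[t] = ("Bacteria", f"{group}Phylum", f"{group}Class",
                   f"{group}{gid}Order", fam, UNASSIGNED, UNASSIGNED)
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index",
                                                columns=list(RANKS)))
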