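"""Synthetic communities with known assembly regime for pipeline validation.

The generator emulates a small two-habitat survey design: 12 samples, a few
hundred OTUs whose metacommunity abundances follow a heavy-tailed log-normal
(most OTUs sit below the 0.01% abundant/rare threshold while a handful of
abundant OTUs carry most reads), a pure-birth phylogeny with depth normalized
to 1, and niche optima evolved by Brownian motion along the tree so that
close relatives prefer similar environments.

Three assembly regimes give ground truth for the null models:

* ``neutral`` — every sample is a multinomial draw from one shared
  metacommunity; pairs should look stochastic (|betaNTI| < 2).
* ``selection`` — samples sit at two contrasting ends of an environmental
  gradient and OTU abundances are filtered by a Gaussian niche kernel
  exp(-(trait - env)^2 / (2 sigma^2)); because traits are phylogenetically
  conserved, cross-environment pairs should show heterogeneous selection
  (betaNTI > 2).
* ``dispersal_limitation`` — OTUs are split into disjoint source pools and
  each sample draws only from its pool; between-pool pairs share no taxa,
  which Raup-Crick flags as dispersal limitation (RC_Bray > 0.95) while the
  pools are random with respect to the phylogeny so |betaNTI| stays small.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import random
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import EnvTable, OtuTable, Phylogeny

logger = logging.getLogger("ecoassembly")

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_tree_and_traits",
    "simulate_community",
    "simulate_env_table",
    "simulate_dataset",
]

REGIMES = ("neutral", "selection", "dispersal_limitation")


@dataclass
class SimConfig:
    """All knobs of the generator; serialized into output metadata.

    Defaults mirror the emulated survey: 12 samples, 300 OTUs, log-normal
    metacommunity (sd-log 4 gives a rare majority of OTUs holding a small
    minority of reads), depth-1 pure-birth tree, Brownian trait rate 1,
    two-level environmental contrast at +/-1 with Gaussian filter width
    sigma, and 50,000 reads per sample.
    """

    n_samples: int = 12
    n_otus: int = 300
    regime: str = "neutral"
    lognormal_mean: float = 0.0
    lognormal_sigma: float = 4.0
    birth_rate: float = 1.0
    trait_rate: float = 1.0
    env_contrast: float = 1.0  # selection regime: env = -c for one half, +c for other
    env_noise_sd: float = 0.05
    sigma: float = 0.35  # Gaussian niche-filter width (trait units)
    n_pools: int = 2
    depth: int = 50_000
    n_noise_variables: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticDataset:
    """A generated community with its tree, environment and ground truth."""

    table: OtuTable
    tree: Phylogeny
    env: EnvTable
    ground_truth: dict
    config: SimConfig

    def write(self, out_dir: str | Path) -> None:
        """Write table.tsv (OTUs as rows), tree.nwk, env.csv and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.counts.T.to_csv(out / "table.tsv", sep="\t")
        (out / "tree.nwk").write_text(self.tree.as_newick() + "\n")
        self.env.values.to_csv(out / "env.csv")
        truth = dict(self.ground_truth)
        truth["config"] = self.config.to_dict()
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _spawn_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_tree_and_traits(config: SimConfig) -> tuple[Phylogeny, pd.Series]:
    """Pure-birth tree (depth normalized to 1) with Brownian niche traits.

    Trait values accumulate independent Gaussian increments of variance
    rate * branch_length along each edge, so sibling tips end up more
    similar than random tips — the phylogenetic conservatism that betaNTI
    relies on.
    """
    if config.n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    tree_seed, trait_seed, hold_seed = _spawn_seeds(config.seed, 3)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_otus,
        rng=random.Random(tree_seed),
    )
    # the generator stops at the instant the n-th tip appears, leaving the
    # last cherry with zero-length edges; run the clock one more exponential
    # waiting time so every terminal branch is positive
    hold = np.random.default_rng(hold_seed).exponential(
        1.0 / (config.birth_rate * config.n_otus)
    )
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + hold
    tree.seed_node.edge.length = None  # a root edge has no meaning here
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / depth
    # relabel tips deterministically in newick traversal order
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{k + 1:04d}"
    rng = np.random.default_rng(trait_seed)
    traits: dict[str, float] = {}
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent_value = values.get(id(node.parent_node), 0.0)
        length = node.edge.length or 0.0
        value = parent_value + rng.normal(0.0, np.sqrt(config.trait_rate * length))
        values[id(node)] = value
        if node.is_leaf():
            traits[node.taxon.label] = value
    phylo = Phylogeny(tree)
    return phylo, pd.Series(traits, name="niche_optimum")[phylo.tip_labels]


def _sample_env_values(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    half = config.n_samples // 2
    if config.regime == "selection":
        levels = np.array(
            [-config.env_contrast] * half
            + [config.env_contrast] * (config.n_samples - half)
        )
    else:
        levels = np.zeros(config.n_samples)
    return levels + rng.normal(0.0, config.env_noise_sd, size=config.n_samples)


def simulate_community(
    config: SimConfig,
    tree: Phylogeny,
    traits: pd.Series,
) -> SyntheticDataset:
    """Draw the count table (and env/ground truth) for the configured regime.

    The metacommunity is log-normal; each sample's expected profile depends
    on the regime (shared pool, Gaussian niche filtering along the gradient,
    or disjoint source pools); observed counts are one multinomial draw of
    ``depth`` reads per sample. OTUs never observed in any sample are
    dropped from the table (they remain on the tree, which downstream
    analyses prune automatically).
    """
    meta_seed, env_seed, pool_seed, count_seed = _spawn_seeds(
        None if config.seed is None else config.seed + 1, 4
    )
    otus = tree.tip_labels
    n_otus = len(otus)
    rng_meta = np.random.default_rng(meta_seed)
    meta = rng_meta.lognormal(config.lognormal_mean, config.lognormal_sigma, n_otus)
    meta /= meta.sum()
    env_values = _sample_env_values(config, np.random.default_rng(env_seed))
    trait_arr = traits[otus].to_numpy()
    half = config.n_samples // 2
    pool_of_otu = np.random.default_rng(pool_seed).integers(0, config.n_pools, n_otus)
    pool_of_sample = np.array(
        [s * config.n_pools // config.n_samples for s in range(config.n_samples)]
    )
    expected = np.zeros((config.n_samples, n_otus))
    for s in range(config.n_samples):
        if config.regime == "neutral":
            w = meta.copy()
        elif config.regime == "selection":
            kernel = np.exp(
                -((trait_arr - env_values[s]) ** 2) / (2 * config.sigma**2)
            )
            w = meta * kernel
        else:  # dispersal_limitation
            w = np.where(pool_of_otu == pool_of_sample[s], meta, 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"sample {s}: expected total abundance is 0 "
                "(filter width sigma too small or empty pool)"
            )
        expected[s] = w / total
    rng_counts = np.random.default_rng(count_seed)
    counts = np.stack(
        [rng_counts.multinomial(config.depth, expected[s]) for s in range(config.n_samples)]
    )
    sample_ids = [f"S{k + 1:02d}" for k in range(config.n_samples)]
    if config.regime == "selection":
        habitat = {
            s: ("env_low" if k < half else "env_high")
            for k, s in enumerate(sample_ids)
        }
    elif config.regime == "dispersal_limitation":
        habitat = {
            s: f"pool_{pool_of_sample[k]}" for k, s in enumerate(sample_ids)
        }
    else:
        habitat = {s: "all" for s in sample_ids}
    df = pd.DataFrame(counts, index=sample_ids, columns=otus)
    observed = df.sum(axis=0) > 0
    table = OtuTable(df.loc[:, observed], habitat=habitat)
    env = simulate_env_table(config, env_values, sample_ids)
    ground_truth = {
        "regime": config.regime,
        "niche_optimum": {o: float(traits[o]) for o in otus},
        "env_values": {s: float(v) for s, v in zip(sample_ids, env_values)},
        "pool_of_sample": {s: int(p) for s, p in zip(sample_ids, pool_of_sample)},
        "metacommunity_abundance": {o: float(m) for o, m in zip(otus, meta)},
    }
    return SyntheticDataset(
        table=table, tree=tree, env=env, ground_truth=ground_truth, config=config
    )


def simulate_env_table(
    config: SimConfig,
    env_values: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> EnvTable:
    """Environmental table: the true gradient plus pure-noise variables.

    The noise columns exist so Mantel type-I behavior can be checked against
    variables with no real effect.
    """
    noise_seed, extra_seed = _spawn_seeds(
        None if config.seed is None else config.seed + 2, 2
    )
    if env_values is None:
        env_values = _sample_env_values(config, np.random.default_rng(extra_seed))
    if sample_ids is None:
        sample_ids = [f"S{k + 1:02d}" for k in range(config.n_samples)]
    rng = np.random.default_rng(noise_seed)
    data = {"gradient": np.asarray(env_values, dtype=float)}
    for k in range(config.n_noise_variables):
        data[f"noise_{k + 1}"] = rng.normal(0.0, 1.0, size=len(sample_ids))
    units = {"gradient": "trait units"}
    units.update({f"noise_{k + 1}": "arbitrary" for k in range(config.n_noise_variables)})
    return EnvTable(pd.DataFrame(data, index=sample_ids), units=units)


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Convenience wrapper: tree + traits + community in one call."""
    tree, traits = simulate_tree_and_traits(config)
    return simulate_community(config, tree, traits)
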