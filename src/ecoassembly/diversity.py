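"""Abundant/rare partitioning and alpha/beta diversity summaries.

Abundant taxa are OTUs whose relative abundance reaches 0.01% (1e-4) —
boundary inclusive — with everything below classed as rare; this follows the
convention used throughout the abundant/rare microbiome literature. Alpha
diversity covers observed richness, Shannon H (natural log), Pielou evenness,
and the Chao1 and ACE richness estimators; beta diversity is Bray-Curtis
principal-coordinates analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha

from .io import DegenerateInputError, OtuTable, RelAbundanceTable

logger = logging.getLogger("ecoassembly")

__all__ = [
    "AbundanceClassification",
    "OrdinationResult",
    "GroupComparison",
    "relative_abundance",
    "classify_abundance",
    "alpha_diversity",
    "compare_groups",
    "pcoa_bray",
    "bray_curtis_matrix",
]

ABUNDANT = "abundant"
RARE = "rare"


@dataclass
class AbundanceClassification:
    """Partition of the OTU set into abundant vs rare taxa.

    ``labels`` maps every OTU id to ``"abundant"`` or ``"rare"``;
    ``threshold`` and ``scope`` record how the call was made.
    """

    labels: pd.Series
    threshold: float
    scope: str

    def otus(self, which: str) -> list[str]:
        return list(self.labels.index[self.labels == which])

    def fractions(self, rel: RelAbundanceTable) -> dict:
        """Per-class OTU-count fraction and summed relative-abundance fraction.

        The abundance fraction is the mean (over samples) of each class's
        summed per-sample relative abundance; both fraction pairs sum to 1.
        """
        n = len(self.labels)
        otu_frac = {
            cls: float((self.labels == cls).sum()) / n for cls in (ABUNDANT, RARE)
        }
        props = rel.proportions[self.labels.index]
        ra_frac = {
            cls: float(props.loc[:, (self.labels == cls).to_numpy()].sum(axis=1).mean())
            for cls in (ABUNDANT, RARE)
        }
        return {"otu_fraction": otu_frac, "abundance_fraction": ra_frac}

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "scope": self.scope,
            "labels": {k: v for k, v in self.labels.items()},
        }


@dataclass
class OrdinationResult:
    """Bray-Curtis distance matrix with PCoA scores and explained variance."""

    distances: pd.DataFrame
    scores: pd.DataFrame
    proportion_explained: pd.Series

    def to_dict(self) -> dict:
        return {
            "distances": self.distances,
            "scores": self.scores,
            "proportion_explained": self.proportion_explained,
        }


@dataclass
class GroupComparison:
    """One-way group comparison: ANOVA (or t-test) plus Tukey letters."""

    method: str
    statistic: float
    pvalue: float
    letters: dict[str, str] = field(default_factory=dict)
    group_means: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "letters": self.letters,
            "group_means": self.group_means,
        }


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Row-normalize an OTU count table to proportions."""
    return table.relative_abundance()


def classify_abundance(
    rel: RelAbundanceTable,
    threshold: float = 1e-4,
    scope: str = "mean",
) -> AbundanceClassification:
    """Split OTUs into abundant (>= threshold) and rare (< threshold) taxa.

    ``scope='mean'`` (default) applies the threshold to each OTU's mean
    relative abundance across samples; ``scope='per_sample_max'`` calls an
    OTU abundant if it reaches the threshold in any single sample. The
    boundary value itself is abundant.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    props = rel.proportions
    if scope == "mean":
        stat = props.mean(axis=0)
    elif scope == "per_sample_max":
        stat = props.max(axis=0)
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    labels = pd.Series(
        np.where(stat >= threshold, ABUNDANT, RARE), index=props.columns, name="class"
    )
    return AbundanceClassification(labels=labels, threshold=threshold, scope=scope)


def _chao1(counts: np.ndarray) -> float:
    # Classic Chao1 with bias-corrected fallback when doubletons are absent;
    # skbio's bias_corrected=False implements exactly this rule.
    return float(skbio_alpha.chao1(counts, bias_corrected=False))


def alpha_diversity(table: OtuTable, ace_rare_threshold: int = 10) -> pd.DataFrame:
    """Per-sample richness, Shannon (natural log), Pielou J, Chao1 and ACE.

    Requires raw counts: Chao1 and ACE depend on singleton/doubleton counts
    that proportions destroy.
    """
    values = table.counts.to_numpy()
    if values.sum() == values.shape[0]:  # all rows sum to ~1: proportions slipped in
        raise ValueError("alpha_diversity requires counts, not proportions")
    rows = []
    for i, sample in enumerate(table.sample_ids):
        c = values[i]
        c = c[c > 0]
        richness = int(len(c))
        h = float(skbio_alpha.shannon(c, base=np.e))
        pielou = h / np.log(richness) if richness >= 2 else np.nan
        chao1 = _chao1(c)
        if richness >= 2:
            try:
                ace = float(skbio_alpha.ace(c, rare_threshold=ace_rare_threshold))
            except ValueError:
                # all rare taxa are singletons: ACE is undefined; EstimateS
                # recommends bias-corrected Chao1 in that case
                ace = float(skbio_alpha.chao1(c, bias_corrected=True))
        else:
            ace = float(richness)
        rows.append(
            {
                "sample": sample,
                "richness": richness,
                "shannon": h,
                "pielou": pielou,
                "chao1": chao1,
                "ace": ace,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def _tukey_letters(groups: list[str], sig: dict[tuple[str, str], bool],
                   means: dict[str, float]) -> dict[str, str]:
    """Compact letter display: letters are the maximal cliques of the
    non-significance graph, ordered by descending group mean."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    for (a, b), reject in sig.items():
        if not reject:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(means[m] for m in c), sorted(c)))
    letters: dict[str, str] = {grp: "" for grp in groups}
    for k, clique in enumerate(cliques):
        ch = chr(ord("a") + k)
        for grp in clique:
            letters[grp] += ch
    return {g_: "".join(sorted(v)) for g_, v in letters.items()}


def compare_groups(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> GroupComparison:
    """One-way comparison of a per-sample metric across groups.

    Three or more groups get one-way ANOVA with pairwise Tukey HSD letters
    (groups sharing a letter are not significantly different at ``alpha``);
    exactly two groups degrade to Welch's t-test.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in names}
    for g, v in by_group.items():
        if len(v) < 2:
            raise DegenerateInputError(f"group {g!r} has fewer than 2 samples")
    means = {g: float(v.mean()) for g, v in by_group.items()}
    if len(names) == 2:
        a, b = names
        if np.ptp(by_group[a]) == 0 and np.ptp(by_group[b]) == 0:
            same = by_group[a][0] == by_group[b][0]
            stat, p = 0.0, (1.0 if same else 0.0)
        else:
            stat, p = stats.ttest_ind(by_group[a], by_group[b], equal_var=False)
        letters = {a: "a", b: "a" if p > alpha else "b"}
        return GroupComparison("t-test", float(stat), float(p), letters, means)
    stat, p = stats.f_oneway(*[by_group[g] for g in names])
    if np.isnan(stat):  # zero within-group variance everywhere
        stat, p = 0.0, 1.0
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy(), alpha=alpha)
    sig: dict[tuple[str, str], bool] = {}
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        sig[(g1, g2)] = reject
    letters = _tukey_letters(names, sig, means)
    return GroupComparison("anova", float(stat), float(p), letters, means)


def bray_curtis_matrix(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), on counts."""
    mat = squareform(pdist(table.counts.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


def pcoa_bray(table: OtuTable, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric MDS (PCoA) on the Bray-Curtis distance matrix.

    Negative eigenvalues (Bray-Curtis is non-Euclidean) are clipped to zero
    with a logged note; axis signs are canonicalized so the coordinate with
    the largest magnitude on each axis is positive.
    """
    if table.n_samples < 3:
        raise ValueError("PCoA needs at least 3 samples")
    dist = bray_curtis_matrix(table)
    d2 = dist.to_numpy() ** 2
    n = d2.shape[0]
    centerer = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int((eigvals < -1e-10).sum())
    if n_neg:
        logger.info("pcoa_bray: clipped %d negative eigenvalue(s) to zero", n_neg)
    eigvals = np.clip(eigvals, 0.0, None)
    keep = eigvals > 1e-12
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    scores = eigvecs * np.sqrt(eigvals)
    # sign canonicalization: largest-|loading| coordinate positive per axis
    for k in range(scores.shape[1]):
        idx = np.argmax(np.abs(scores[:, k]))
        if scores[idx, k] < 0:
            scores[:, k] = -scores[:, k]
    explained = eigvals / eigvals.sum() if eigvals.sum() > 0 else eigvals
    if n_axes is not None:
        scores = scores[:, :n_axes]
        explained = explained[:n_axes]
    axes = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return OrdinationResult(
        distances=dist,
        scores=pd.DataFrame(scores, index=table.sample_ids, columns=axes),
        proportion_explained=pd.Series(explained, index=axes, name="proportion"),
    )
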