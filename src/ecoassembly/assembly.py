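"""Null-model attribution of community assembly processes.

Two complementary turnover metrics are computed per sample pair and compared
against randomized expectations:

* **betaMNTD / betaNTI** — the abundance-weighted between-sample mean
  nearest-taxon distance, standardized against a null built by shuffling tip
  labels across the whole phylogeny (999 randomizations by default).
  betaNTI = (obs - mean_null) / sd_null.
* **RC_Bray** — Raup-Crick on Bray-Curtis: null community pairs preserve each
  sample's observed richness and total abundance, drawing species with
  probability proportional to occurrence frequency and individuals
  proportional to metacommunity relative abundance; RC rescales the rank of
  the observed dissimilarity among the nulls to [-1, 1].

The two metrics feed the five-way process scheme: |betaNTI| >= 2 indicates
deterministic selection (heterogeneous when betaNTI > +2, homogeneous when
< -2); among stochastic pairs (|betaNTI| < 2), RC_Bray > +0.95 indicates
dispersal limitation, RC_Bray < -0.95 homogenizing dispersal, and
|RC_Bray| <= 0.95 the undominated fraction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignmentError, OtuTable, Phylogeny, RelAbundanceTable

logger = logging.getLogger("ecoassembly")

__all__ = [
    "AssemblyResult",
    "PROCESSES",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "rc_bray",
    "classify_processes",
]

HETEROGENEOUS_SELECTION = "heterogeneous_selection"
HOMOGENEOUS_SELECTION = "homogeneous_selection"
DISPERSAL_LIMITATION = "dispersal_limitation"
HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
UNDOMINATED = "undominated"
PROCESSES = (
    HETEROGENEOUS_SELECTION,
    HOMOGENEOUS_SELECTION,
    DISPERSAL_LIMITATION,
    HOMOGENIZING_DISPERSAL,
    UNDOMINATED,
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


@dataclass
class AssemblyResult:
    """Per-pair turnover metrics, process labels and process fractions."""

    pairs: pd.DataFrame  # columns: sample_a, sample_b, beta_mntd, null_mean,
    #          null_sd, beta_nti, rc_bray, process
    n_null: int
    seed: int | None
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def process_fractions(self) -> dict[str, float]:
        """Fraction of (defined) pairs per process; sums to 1."""
        labelled = self.pairs.dropna(subset=["process"])
        n = len(labelled)
        if n == 0:
            return {p: float("nan") for p in PROCESSES}
        counts = labelled["process"].value_counts()
        return {p: float(counts.get(p, 0)) / n for p in PROCESSES}

    def to_dict(self) -> dict:
        return {
            "n_null": self.n_null,
            "seed": self.seed,
            "excluded_pairs": [list(p) for p in self.excluded_pairs],
            "process_fractions": self.process_fractions(),
            "pairs": [
                {
                    k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in row.items()
                }
                for row in self.pairs.to_dict(orient="records")
            ],
        }


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def _beta_mntd_pair(pa: np.ndarray, pb: np.ndarray, dist: np.ndarray) -> float:
    """Abundance-weighted betaMNTD for one pair of proportion vectors.

    0.5 * [ sum_j p_jA * min_{k in B} d(j,k) + sum_j p_jB * min_{k in A} d(j,k) ]
    with the minimum over all OTUs present in the other sample (a shared OTU
    therefore contributes distance 0).
    """
    ia = np.flatnonzero(pa > 0)
    ib = np.flatnonzero(pb > 0)
    sub = dist[np.ix_(ia, ib)]
    term_a = pa[ia] @ sub.min(axis=1)
    term_b = pb[ib] @ sub.min(axis=0)
    return 0.5 * float(term_a + term_b)


def beta_mntd_matrix(props: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """All-pairs betaMNTD for a samples-x-OTUs proportion matrix."""
    n = props.shape[0]
    out = np.zeros((n, n))
    present = [np.flatnonzero(props[i] > 0) for i in range(n)]
    weights = [props[i][present[i]] for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            sub = dist[np.ix_(present[i], present[j])]
            val = 0.5 * (
                weights[i] @ sub.min(axis=1) + weights[j] @ sub.min(axis=0)
            )
            out[i, j] = out[j, i] = val
    return out


def _aligned_inputs(
    rel: RelAbundanceTable, tree: Phylogeny
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    otus = rel.otu_ids
    missing = [o for o in otus if o not in set(tree.tip_labels)]
    if missing:
        raise AlignmentError(f"OTUs missing from tree: {missing}")
    dist = tree.patristic_matrix(otus).to_numpy()
    props = rel.proportions.to_numpy(dtype=float)
    return props, dist, otus


def beta_mntd(rel: RelAbundanceTable, tree: Phylogeny, pair: tuple[str, str]) -> float:
    """betaMNTD for one sample pair (symmetric, zero for identical profiles)."""
    props, dist, _ = _aligned_inputs(rel, tree)
    idx = {s: k for k, s in enumerate(rel.sample_ids)}
    a, b = pair
    if a not in idx or b not in idx:
        raise AlignmentError(f"unknown sample id in pair {pair!r}")
    return _beta_mntd_pair(props[idx[a]], props[idx[b]], dist)


def beta_nti(
    rel: RelAbundanceTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """betaNTI for every sample pair, via tip-label shuffling.

    Each of the ``n_null`` replicates permutes the tip labels of the whole
    phylogeny (equivalently: applies one permutation to the rows and columns
    of the patristic matrix) and recomputes betaMNTD for all pairs.

    Returns four square DataFrames (samples x samples): betaNTI, observed
    betaMNTD, null mean and null sd. Pairs whose null sd is zero get NaN
    betaNTI (flagged downstream and excluded from process fractions).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    props, dist, _ = _aligned_inputs(rel, tree)
    samples = rel.sample_ids
    obs = beta_mntd_matrix(props, dist)
    rng = np.random.default_rng(seed)
    n_otus = dist.shape[0]
    nulls = np.empty((n_null, len(samples), len(samples)))
    for k in range(n_null):
        perm = rng.permutation(n_otus)
        nulls[k] = beta_mntd_matrix(props, dist[np.ix_(perm, perm)])
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    # an effectively constant null (e.g. equidistant star tree) makes the
    # standardization undefined; float accumulation keeps sd slightly above 0
    degenerate = null_sd <= 1e-10 * np.maximum(1.0, np.abs(null_mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = (obs - null_mean) / null_sd
    bnti[degenerate] = np.nan
    np.fill_diagonal(bnti, 0.0)
    wrap = lambda m: pd.DataFrame(m, index=samples, columns=samples)  # noqa: E731
    return wrap(bnti), wrap(obs), wrap(null_mean), wrap(null_sd)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)
# ---------------------------------------------------------------------------


def _bray(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom > 0 else 0.0


def _null_community(
    rng: np.random.Generator,
    richness: int,
    depth: int,
    occ_prob: np.ndarray,
    abun_prob: np.ndarray,
) -> np.ndarray:
    """Draw one null community preserving richness and total abundance."""
    n_otus = len(occ_prob)
    chosen = rng.choice(n_otus, size=richness, replace=False, p=occ_prob)
    community = np.zeros(n_otus, dtype=np.int64)
    community[chosen] = 1
    remaining = depth - richness
    if remaining > 0:
        p = abun_prob[chosen]
        p = p / p.sum()
        community[chosen] += rng.multinomial(remaining, p)
    return community


def rc_bray(
    table: OtuTable, n_null: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Raup-Crick Bray-Curtis for every sample pair, in [-1, 1].

    RC = 2 * [(#(null < obs) + 0.5 * #(null == obs)) / n_null] - 1: +1 means
    the two communities are far more dissimilar than the stochastic null
    expects, -1 far more similar.
    """
    if table.n_samples < 2:
        raise ValueError("rc_bray needs at least 2 samples")
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = table.counts.to_numpy()
    samples = table.sample_ids
    n = len(samples)
    occurrence = (counts > 0).sum(axis=0).astype(float)
    occ_prob = occurrence / occurrence.sum()
    meta = counts.sum(axis=0).astype(float)
    abun_prob = meta / meta.sum()
    richness = (counts > 0).sum(axis=1)
    depth = counts.sum(axis=1)
    rng = np.random.default_rng(seed)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        obs = _bray(counts[i], counts[j])
        below = ties = 0
        for _ in range(n_null):
            a = _null_community(rng, int(richness[i]), int(depth[i]), occ_prob, abun_prob)
            b = _null_community(rng, int(richness[j]), int(depth[j]), occ_prob, abun_prob)
            null = _bray(a, b)
            if null < obs - 1e-12:
                below += 1
            elif abs(null - obs) <= 1e-12:
                ties += 1
        rc = 2.0 * ((below + 0.5 * ties) / n_null) - 1.0
        out[i, j] = out[j, i] = rc
    return pd.DataFrame(out, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# Process classification
# ---------------------------------------------------------------------------


def _label(bnti: float, rc: float) -> str | None:
    if np.isnan(bnti):
        return None
    if bnti >= BNTI_THRESHOLD:
        return HETEROGENEOUS_SELECTION
    if bnti <= -BNTI_THRESHOLD:
        return HOMOGENEOUS_SELECTION
    if rc > RC_THRESHOLD:
        return DISPERSAL_LIMITATION
    if rc < -RC_THRESHOLD:
        return HOMOGENIZING_DISPERSAL
    return UNDOMINATED


def classify_processes(
    bnti: pd.DataFrame,
    rc: pd.DataFrame,
    obs: pd.DataFrame | None = None,
    null_mean: pd.DataFrame | None = None,
    null_sd: pd.DataFrame | None = None,
    n_null: int = 999,
    seed: int | None = None,
) -> AssemblyResult:
    """Attach the five-way process label to every unordered sample pair.

    Boundary conventions: |betaNTI| >= 2 is deterministic selection (the
    sign separates heterogeneous from homogeneous), while the RC boundary is
    strict — |RC| = 0.95 exactly falls to undominated. Pairs with undefined
    betaNTI (null sd of zero) are excluded from fractions and listed in the
    result.
    """
    if list(bnti.index) != list(rc.index) or list(bnti.columns) != list(rc.columns):
        raise AlignmentError("betaNTI and RC matrices must share sample sets")
    samples = list(bnti.index)
    rows = []
    excluded = []
    for a, b in itertools.combinations(samples, 2):
        v_bnti = float(bnti.loc[a, b])
        v_rc = float(rc.loc[a, b])
        process = _label(v_bnti, v_rc)
        if process is None:
            excluded.append((a, b))
        row = {
            "sample_a": a,
            "sample_b": b,
            "beta_nti": v_bnti,
            "rc_bray": v_rc,
            "process": process,
        }
        if obs is not None:
            row["beta_mntd"] = float(obs.loc[a, b])
        if null_mean is not None:
            row["null_mean"] = float(null_mean.loc[a, b])
        if null_sd is not None:
            row["null_sd"] = float(null_sd.loc[a, b])
        rows.append(row)
    return AssemblyResult(
        pairs=pd.DataFrame(rows), n_null=n_null, seed=seed, excluded_pairs=excluded
    )


def assembly_analysis(
    table: OtuTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int | None = None,
) -> AssemblyResult:
    """Full per-pair pipeline: betaNTI + RC_Bray + process labels.

    The tree is pruned (via the patristic matrix) to the table's OTUs; the
    two null models consume independent streams derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seed_bnti, seed_rc = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    rel = table.relative_abundance()
    bnti, obs, null_mean, null_sd = beta_nti(rel, tree, n_null=n_null, seed=seed_bnti)
    rc = rc_bray(table, n_null=n_null, seed=seed_rc)
    return classify_processes(
        bnti, rc, obs=obs, null_mean=null_mean, null_sd=null_sd,
        n_null=n_null, seed=seed,
    )
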