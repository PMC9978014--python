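"""Mantel association between assembly turnover and environmental distance.

The Mantel statistic here is the Spearman correlation between the
lower-triangle entries of two sample-pair matrices — typically a betaNTI
matrix against the single-variable Euclidean distance matrix |x_i - x_k| of
one environmental variable. Significance comes from simultaneously permuting
the rows and columns of the second matrix; the reported p-value is two-sided,
(1 + #(|r_null| >= |r_obs|)) / (n_perm + 1).

A betaNTI matrix is not a metric distance (entries can be negative and the
triangle inequality need not hold); the permutation machinery is rank-based
and does not require metricity, but the caveat stands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlignmentError, DegenerateInputError, EnvTable

logger = logging.getLogger("ecoassembly")

__all__ = ["MantelResult", "env_distance", "mantel_spearman", "mantel_all"]


@dataclass
class MantelResult:
    """Spearman Mantel statistic for one variable with its permutation p."""

    variable: str
    r: float
    pvalue: float
    n_permutations: int
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "r": self.r,
            "pvalue": self.pvalue,
            "n_permutations": self.n_permutations,
            "n_pairs": self.n_pairs,
        }


def env_distance(
    env: EnvTable, variable: str, standardize: bool = False
) -> pd.DataFrame:
    """Single-variable Euclidean distance matrix |x_i - x_k|.

    Samples with a missing value are dropped (pairwise-complete handling
    happens at matrix alignment); ``standardize`` z-scores the variable
    first, which simply divides all distances by the sample sd.
    """
    if variable not in env.values.columns:
        raise KeyError(f"unknown environmental variable: {variable!r}")
    x = env.values[variable].dropna()
    if len(x) < 3:
        raise DegenerateInputError(
            f"variable {variable!r} has fewer than 3 non-missing samples"
        )
    if x.nunique() == 1:
        raise DegenerateInputError(f"variable {variable!r} has zero variance")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
    arr = x.to_numpy()
    mat = np.abs(arr[:, None] - arr[None, :])
    return pd.DataFrame(mat, index=x.index, columns=x.index)


def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices(mat.shape[0], k=-1)]


def mantel_spearman(
    m1: pd.DataFrame,
    m2: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    variable: str = "",
) -> MantelResult:
    """Spearman Mantel test between two sample-pair matrices.

    The matrices are aligned on their shared samples (pairs involving a
    sample missing from either matrix are dropped from both). The null
    permutes sample labels of ``m2``; joint relabeling of both matrices
    leaves r unchanged, and any monotone transform of ``m2`` leaves the
    whole test unchanged.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    shared = [s for s in m1.index if s in set(m2.index)]
    if len(shared) < 3:
        raise AlignmentError("matrices share fewer than 3 samples")
    a = m1.loc[shared, shared].to_numpy(dtype=float)
    b = m2.loc[shared, shared].to_numpy(dtype=float)
    x = _lower_triangle(a)
    r_obs = float(stats.spearmanr(x, _lower_triangle(b)).statistic)
    rng = np.random.default_rng(seed)
    n = len(shared)
    # rank x once; each permutation only re-ranks the permuted m2 triangle
    rx = stats.rankdata(x)
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c**2).sum())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y = _lower_triangle(b[np.ix_(perm, perm)])
        ry = stats.rankdata(y)
        ry_c = ry - ry.mean()
        denom = denom_x * np.sqrt((ry_c**2).sum())
        r_null = float(rx_c @ ry_c / denom) if denom > 0 else 0.0
        if abs(r_null) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(
        variable=variable,
        r=r_obs,
        pvalue=p,
        n_permutations=n_perm,
        n_pairs=len(x),
    )


def mantel_all(
    bnti: pd.DataFrame,
    env: EnvTable,
    n_perm: int = 999,
    seed: int | None = None,
    standardize: bool = False,
    correction: str = "none",
) -> pd.DataFrame:
    """Mantel test of a betaNTI matrix against every environmental variable.

    Returns a table (variable, r, pvalue, n_pairs); no multiplicity
    correction by default, ``correction='bh'`` adds a ``pvalue_adj`` column.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for variable, child in zip(env.variables, ss.spawn(len(env.variables))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            dist = env_distance(env, variable, standardize=standardize)
        except DegenerateInputError as exc:
            logger.warning("mantel_all: skipping %r (%s)", variable, exc)
            continue
        res = mantel_spearman(
            bnti, dist, n_perm=n_perm, seed=sub_seed, variable=variable
        )
        rows.append(res.to_dict())
    out = pd.DataFrame(rows)
    if correction == "bh" and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["pvalue_adj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
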