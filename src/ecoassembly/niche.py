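"""Levins' niche breadth and generalist/specialist classification.

For OTU j observed in N communities with proportions P_ij, let
q_i = P_ij / sum_i P_ij be the OTU's distribution over communities. Levins'
niche breadth is B_j = 1 / sum_i q_i**2, the inverse Simpson concentration of
that distribution: B = 1 when the OTU sits in a single community and B = N
when it is spread uniformly. The across-community normalization of P is
essential — without it B is not bounded by N.

Generalists and specialists are called by comparing each observed B against a
null envelope of B values obtained from randomized community matrices. The
default null ("count_swap") preserves both row (sample) and column (OTU)
totals exactly by repeated 2x2 checkerboard moves on the integer count
matrix, the quantitative analogue of the quasiswap algorithm; a simpler
"row_proportion" null redistributes each sample's total multinomially over
OTUs and is used as a fallback when the matrix is too sparse for the swap
chain to mix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable, RelAbundanceTable

logger = logging.getLogger("ecoassembly")

__all__ = [
    "NicheBreadthResult",
    "levins_b",
    "community_bm",
    "classify_specialists",
    "count_swap_null",
]

GENERALIST = "generalist"
SPECIALIST = "specialist"
NEUTRAL = "neutral"


@dataclass
class NicheBreadthResult:
    """Per-OTU Levins B with permutation envelope and category labels."""

    per_otu: pd.DataFrame  # columns: B, null_lower, null_upper, category
    bm_mean: float
    bm_sd: float
    n_perm: int
    conf: float
    null_model: str
    seed: int | None

    def category_fractions(self, rel: RelAbundanceTable | None = None) -> dict:
        """OTU-count fractions per category and, when a relative-abundance
        table is given, summed relative-abundance fractions as well."""
        cats = self.per_otu["category"]
        n = len(cats)
        out = {
            "otu_fraction": {
                c: float((cats == c).sum()) / n
                for c in (GENERALIST, SPECIALIST, NEUTRAL)
            }
        }
        if rel is not None:
            mean_ra = rel.proportions[cats.index].mean(axis=0)
            total = float(mean_ra.sum())
            out["abundance_fraction"] = {
                c: float(mean_ra[(cats == c).to_numpy()].sum()) / total
                for c in (GENERALIST, SPECIALIST, NEUTRAL)
            }
        return out

    def to_dict(self) -> dict:
        return {
            "bm_mean": self.bm_mean,
            "bm_sd": self.bm_sd,
            "n_perm": self.n_perm,
            "conf": self.conf,
            "null_model": self.null_model,
            "seed": self.seed,
            "per_otu": {
                otu: {
                    "B": row["B"],
                    "null_lower": row["null_lower"],
                    "null_upper": row["null_upper"],
                    "category": row["category"],
                }
                for otu, row in self.per_otu.iterrows()
            },
        }


def _levins_from_props(props: np.ndarray) -> np.ndarray:
    """Vectorized B over OTU columns of a samples-x-OTUs proportion matrix.

    OTUs absent everywhere get NaN.
    """
    col_sums = props.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = props / col_sums
        b = 1.0 / (q**2).sum(axis=0)
    b[col_sums == 0] = np.nan
    return b


def levins_b(rel: RelAbundanceTable, otu: str | None = None):
    """Levins' niche breadth per OTU (or for one OTU if ``otu`` is given).

    Raises for an OTU with zero abundance everywhere (B is undefined).
    """
    props = rel.proportions.to_numpy(dtype=float)
    b = pd.Series(_levins_from_props(props), index=rel.otu_ids, name="B")
    if otu is not None:
        if otu not in b.index:
            raise KeyError(f"unknown OTU id: {otu!r}")
        val = b[otu]
        if np.isnan(val):
            raise ValueError(f"OTU {otu!r} is absent from every sample; B undefined")
        return float(val)
    return b


def community_bm(
    rel: RelAbundanceTable,
    otus: list[str] | None = None,
    n_boot: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Community mean niche breadth B_m with a bootstrap standard deviation.

    B_m is the unweighted mean of B over the OTU set; the spread comes from
    resampling OTUs with replacement ``n_boot`` times (100 by default).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    b = levins_b(rel)
    if otus is not None:
        if not otus:
            raise ValueError("empty OTU set")
        b = b[[o for o in otus]]
    b = b.dropna()
    if b.empty:
        raise ValueError("no OTUs with defined B")
    values = b.to_numpy()
    rng = np.random.default_rng(seed)
    boot_means = values[rng.integers(0, len(values), size=(n_boot, len(values)))].mean(
        axis=1
    )
    sd = float(boot_means.std(ddof=1)) if n_boot > 1 else 0.0
    if n_boot == 1:
        warnings.warn("n_boot=1: bootstrap sd reported as 0", stacklevel=2)
    return float(values.mean()), sd


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------


def _count_checkerboard_units(mat: np.ndarray, max_needed: int = 2) -> int:
    """Count 2x2 submatrices admitting a sum-preserving swap (early exit)."""
    n_rows, _ = mat.shape
    found = 0
    for i1 in range(n_rows):
        for i2 in range(i1 + 1, n_rows):
            pos = np.flatnonzero(mat[i1] > 0)
            neg = np.flatnonzero(mat[i2] > 0)
            if len(pos) == 0 or len(neg) == 0:
                continue
            # a move needs j1 != j2 with mat[i1,j1] > 0 and mat[i2,j2] > 0,
            # impossible only when both rows have a single shared support column
            if len(pos) == 1 and len(neg) == 1 and pos[0] == neg[0]:
                continue
            found += 1
            if found >= max_needed:
                return found
    return found


def count_swap_null(
    counts: np.ndarray, rng: np.random.Generator, n_swaps: int | None = None
) -> np.ndarray:
    """One randomized matrix with exactly preserved row and column sums.

    Performs ``n_swaps`` successful 2x2 checkerboard moves ([[a,b],[c,d]] ->
    [[a-1,b+1],[c+1,d-1]] when a,d > 0, or the mirror move) starting from the
    given matrix. Default chain length is 5x the number of non-zero cells.
    """
    mat = counts.copy()
    n_rows, n_cols = mat.shape
    if n_swaps is None:
        n_swaps = 5 * int((mat > 0).sum())
    done = 0
    batch = max(256, n_swaps)
    while done < n_swaps:
        rows = rng.integers(0, n_rows, size=(batch, 2))
        cols = rng.integers(0, n_cols, size=(batch, 2))
        dirs = rng.integers(0, 2, size=batch)
        for k in range(batch):
            i1, i2 = rows[k]
            j1, j2 = cols[k]
            if i1 == i2 or j1 == j2:
                continue
            a, b = mat[i1, j1], mat[i1, j2]
            c, d = mat[i2, j1], mat[i2, j2]
            if dirs[k] == 0:
                if a > 0 and d > 0:
                    mat[i1, j1] -= 1
                    mat[i1, j2] += 1
                    mat[i2, j1] += 1
                    mat[i2, j2] -= 1
                    done += 1
            else:
                if b > 0 and c > 0:
                    mat[i1, j1] += 1
                    mat[i1, j2] -= 1
                    mat[i2, j1] -= 1
                    mat[i2, j2] += 1
                    done += 1
            if done >= n_swaps:
                break
    return mat


def _row_proportion_null(
    counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Redistribute each sample's total multinomially over OTUs using the
    pooled metacommunity relative abundances (row sums preserved exactly,
    column sums in expectation)."""
    totals = counts.sum(axis=1)
    pool = counts.sum(axis=0).astype(float)
    p = pool / pool.sum()
    return np.stack([rng.multinomial(int(t), p) for t in totals])


def classify_specialists(
    table: OtuTable,
    n_perm: int = 1000,
    conf: float = 0.95,
    null_model: str = "count_swap",
    seed: int | None = None,
    n_boot: int = 100,
) -> NicheBreadthResult:
    """Classify OTUs as generalist / specialist / neutral from a null envelope.

    For each permutation the count matrix is randomized, B recomputed per
    OTU, and the (1-conf)/2 and 1-(1-conf)/2 quantiles of each OTU's null B
    distribution form the envelope: observed B above the upper bound is a
    generalist (broader habitat use than chance), below the lower bound a
    specialist, otherwise neutral.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    counts = table.counts.to_numpy()
    rng = np.random.default_rng(seed)
    if null_model == "count_swap":
        if _count_checkerboard_units(counts) < 2:
            warnings.warn(
                "matrix too sparse for the count-swap chain to mix; "
                "falling back to the row_proportion null",
                stacklevel=2,
            )
            null_model = "row_proportion"
    if null_model == "count_swap":
        draw = lambda: count_swap_null(counts, rng)  # noqa: E731
    elif null_model == "row_proportion":
        draw = lambda: _row_proportion_null(counts, rng)  # noqa: E731
    else:
        raise ValueError(f"unknown null model: {null_model!r}")

    totals = counts.sum(axis=1, keepdims=True).astype(float)
    b_obs = _levins_from_props(counts / totals)
    null_b = np.empty((n_perm, counts.shape[1]))
    for k in range(n_perm):
        null = draw()
        null_b[k] = _levins_from_props(null / null.sum(axis=1, keepdims=True))
    lo_q, hi_q = (1 - conf) / 2, 1 - (1 - conf) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN null columns
        lower = np.nanquantile(null_b, lo_q, axis=0)
        upper = np.nanquantile(null_b, hi_q, axis=0)
    category = np.where(
        np.isnan(b_obs),
        "undefined",
        np.where(b_obs > upper, GENERALIST, np.where(b_obs < lower, SPECIALIST, NEUTRAL)),
    )
    per_otu = pd.DataFrame(
        {
            "B": b_obs,
            "null_lower": lower,
            "null_upper": upper,
            "category": category,
        },
        index=table.otu_ids,
    )
    rel = table.relative_abundance()
    bm_mean, bm_sd = community_bm(rel, n_boot=n_boot, seed=seed)
    return NicheBreadthResult(
        per_otu=per_otu,
        bm_mean=bm_mean,
        bm_sd=bm_sd,
        n_perm=n_perm,
        conf=conf,
        null_model=null_model,
        seed=seed,
    )


def compare_bm(
    rel_a: RelAbundanceTable, rel_b: RelAbundanceTable
) -> tuple[float, float]:
    """Two-sample Welch t-test comparing per-OTU B between two communities
    (e.g. abundant vs rare within a habitat). Returns (statistic, p)."""
    a = levins_b(rel_a).dropna().to_numpy()
    b = levins_b(rel_b).dropna().to_numpy()
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)
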