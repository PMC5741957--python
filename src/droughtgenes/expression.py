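"""Consensus differential-expression calling.

Three independent tests are run per gene — an unpaired pooled-variance
t-test, a rank-product test with permutation (or exact) p-values, and a
per-gene Fisher's exact test against pooled library totals — plus a >=2-fold
change call.  Genes significant under all three tests form the consensus set.

The rank product of gene g over k replicate comparisons is
``RP_g = (prod_i r_{g,i})^(1/k)`` where ``r_{g,i}`` is g's fold-change rank in
comparison i (rank 1 = most up-regulated).  Under the null each rank is
uniform on {1..n}, which gives an exact p-value by enumerating rank tuples at
small n^k and a Monte-Carlo estimate with +1 smoothing otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import PipelineConfig

Grouping = Literal["treatment", "tissue"]

TREATMENTS = ("drought", "control")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix with per-sample treatment/tissue metadata."""

    values: pd.DataFrame  # index = gene_ids, columns = sample_ids
    sample_meta: pd.DataFrame  # index = sample_ids, columns: treatment, tissue

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample order of values and sample_meta differ")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        bad = set(self.sample_meta["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatments {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def groups(self, grouping: Grouping) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Columns of the two compared groups.

        treatment grouping: drought vs control, pooling tissues.
        tissue grouping: the two tissues compared within the drought arm.
        """
        meta = self.sample_meta
        if grouping == "treatment":
            a = self.values.loc[:, meta.index[meta["treatment"] == "drought"]]
            b = self.values.loc[:, meta.index[meta["treatment"] == "control"]]
        elif grouping == "tissue":
            drought = meta[meta["treatment"] == "drought"]
            tissues = sorted(drought["tissue"].unique())
            if len(tissues) != 2:
                raise ValueError(
                    f"tissue grouping needs exactly 2 tissues in the drought arm, "
                    f"got {tissues}"
                )
            a = self.values.loc[:, drought.index[drought["tissue"] == tissues[0]]]
            b = self.values.loc[:, drought.index[drought["tissue"] == tissues[1]]]
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        if a.shape[1] == 0 or b.shape[1] == 0:
            raise ValueError("a compared group has zero samples")
        return a, b


@dataclass(frozen=True)
class DeResult:
    gene_id: str
    log2_fold_change: float
    p_ttest: float
    p_rp: float
    p_fisher: float
    q_ttest: float
    q_rp: float
    q_fisher: float
    direction: str  # up | down | none
    supported_by: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# Fold change
# ---------------------------------------------------------------------------


def fold_change_call(
    m: ExpressionMatrix, grouping: Grouping, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-gene log2 fold change (group A over group B) and up/down call.

    A pseudocount stabilises ratios at zero expression: 1 for integer count
    matrices, 0.01 for abundance-scale data (configurable).
    """
    cfg = cfg or PipelineConfig()
    a, b = m.groups(grouping)
    is_counts = np.allclose(m.values.values, np.round(m.values.values))
    eps = cfg.pseudocount_counts if is_counts else cfg.pseudocount_abundance
    fc = (a.mean(axis=1) + eps) / (b.mean(axis=1) + eps)
    direction = np.where(
        fc >= cfg.fold_change_min, "up", np.where(fc <= 1.0 / cfg.fold_change_min, "down", "none")
    )
    return pd.DataFrame(
        {"log2_fold_change": np.log2(fc), "direction": direction}, index=m.values.index
    )


# ---------------------------------------------------------------------------
# Unpaired t-test
# ---------------------------------------------------------------------------


def ttest_unpaired(m: ExpressionMatrix, grouping: Grouping) -> pd.DataFrame:
    """Pooled-variance two-sample t with df = n1 + n2 - 2, two-sided p.

    Genes with zero pooled variance get p = 1 when the group means agree and
    p = 0 otherwise (a deterministic difference).
    """
    a, b = m.groups(grouping)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("t-test needs >= 2 samples per group")
    t, p = stats.ttest_ind(a.values, b.values, axis=1, equal_var=True)
    mean_diff = a.values.mean(axis=1) - b.values.mean(axis=1)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, np.where(np.isclose(mean_diff, 0.0), 1.0, 0.0), p)
    return pd.DataFrame({"t": t, "p_ttest": p}, index=m.values.index)


# ---------------------------------------------------------------------------
# Rank product
# ---------------------------------------------------------------------------


def _rank_matrix(a: pd.DataFrame, b: pd.DataFrame, eps: float) -> np.ndarray:
    """Fold-change ranks per replicate comparison, shape genes x k.

    Comparison i ranks genes by (a_i + eps)/(b_i + eps) with rank 1 = most
    up-regulated (ties averaged).  Comparisons pair disjoint replicates
    (k = min(n1, n2)), so under the null a gene's ranks are independent
    across comparisons — the assumption the permutation null relies on.
    """
    k = min(a.shape[1], b.shape[1])
    cols = []
    for i in range(k):
        fc = (a.values[:, i] + eps) / (b.values[:, i] + eps)
        cols.append(stats.rankdata(-fc, method="average"))
    return np.column_stack(cols)


def _null_rp_samples(
    n_genes: int, k: int, permutations: int, rng: np.random.Generator
) -> np.ndarray:
    ranks = rng.integers(1, n_genes + 1, size=(permutations, k))
    return np.exp(np.log(ranks).mean(axis=1))


def _exact_rp_p(rp_obs: np.ndarray, n_genes: int, k: int) -> np.ndarray:
    """Exact null P(RP <= observed) by enumerating all n^k rank tuples."""
    grids = np.meshgrid(*([np.arange(1, n_genes + 1)] * k), indexing="ij")
    rp_all = np.exp(np.log(np.stack([g.ravel() for g in grids])).mean(axis=0))
    rp_all.sort()
    counts = np.searchsorted(rp_all, rp_obs * (1 + 1e-12), side="right")
    return counts / len(rp_all)


def rank_product(
    m: ExpressionMatrix,
    grouping: Grouping,
    cfg: PipelineConfig | None = None,
    exact: bool | None = None,
) -> pd.DataFrame:
    """Rank-product statistics and p-values per gene (up and down).

    With ``exact=None`` the exact enumeration is used automatically whenever
    n_genes**k stays small; otherwise ``rp_permutations`` Monte-Carlo draws of
    independent uniform rank tuples estimate the null with +1 smoothing:
    p = (#{null RP <= observed} + 1) / (permutations + 1).
    """
    cfg = cfg or PipelineConfig()
    a, b = m.groups(grouping)
    k = min(a.shape[1], b.shape[1])
    if k < 1:
        raise ValueError("rank product needs at least one replicate comparison")
    is_counts = np.allclose(m.values.values, np.round(m.values.values))
    eps = cfg.pseudocount_counts if is_counts else cfg.pseudocount_abundance
    ranks_up = _rank_matrix(a, b, eps)
    n = ranks_up.shape[0]
    ranks_down = n + 1 - ranks_up
    rp_up = np.exp(np.log(ranks_up).mean(axis=1))
    rp_down = np.exp(np.log(ranks_down).mean(axis=1))
    if exact is None:
        exact = n**k <= 2_000_000
    if exact:
        p_up = _exact_rp_p(rp_up, n, k)
        p_down = _exact_rp_p(rp_down, n, k)
    else:
        rng = np.random.default_rng(cfg.rng_seed)
        null = np.sort(_null_rp_samples(n, k, cfg.rp_permutations, rng))
        hits_up = np.searchsorted(null, rp_up * (1 + 1e-12), side="right")
        hits_down = np.searchsorted(null, rp_down * (1 + 1e-12), side="right")
        p_up = (hits_up + 1) / (cfg.rp_permutations + 1)
        p_down = (hits_down + 1) / (cfg.rp_permutations + 1)
    return pd.DataFrame(
        {"rp_up": rp_up, "rp_down": rp_down, "p_up": p_up, "p_down": p_down},
        index=m.values.index,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test on pooled counts
# ---------------------------------------------------------------------------


def fisher_counts(m: ExpressionMatrix, grouping: Grouping) -> pd.Series:
    """Two-sided Fisher's exact p per gene on a 2x2 pooled-count table.

    Rows: this gene's summed counts vs all remaining counts; columns: group A
    vs group B.  Input must be integer counts.
    """
    if not np.allclose(m.values.values, np.round(m.values.values)):
        raise ValueError("fisher_counts requires integer counts")
    a, b = m.groups(grouping)
    ga = a.values.sum(axis=1).astype(np.int64)
    gb = b.values.sum(axis=1).astype(np.int64)
    ta, tb = int(ga.sum()), int(gb.sum())
    ps = np.empty(len(ga))
    for i, (x, y) in enumerate(zip(ga, gb)):
        table = [[int(x), ta - int(x)], [int(y), tb - int(y)]]
        ps[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    return pd.Series(ps, index=m.values.index, name="p_fisher")


# ---------------------------------------------------------------------------
# BH FDR and consensus
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, original order restored."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0,1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def consensus(
    significant: dict[str, set[str]], universe: Sequence[str]
) -> dict:
    """Cross-method agreement over identical gene universes.

    Returns the per-gene support sets, the all-methods intersection, the
    union, and Venn-style pairwise overlap counts.
    """
    universe_set = set(universe)
    for name, genes in significant.items():
        extra = genes - universe_set
        if extra:
            raise ValueError(f"{name}: genes outside the universe: {sorted(extra)[:5]}")
    names = sorted(significant)
    supported_by = {
        g: frozenset(n for n in names if g in significant[n]) for g in universe
    }
    sets = [significant[n] for n in names]
    inter = set.intersection(*sets) if sets else set()
    union = set.union(*sets) if sets else set()
    pairwise = {
        (x, y): len(significant[x] & significant[y])
        for i, x in enumerate(names)
        for y in names[i + 1 :]
    }
    return {
        "supported_by": supported_by,
        "intersection": inter,
        "union": union,
        "pairwise_overlap": pairwise,
    }


# ---------------------------------------------------------------------------
# One-call DE analysis
# ---------------------------------------------------------------------------


def de_analysis(
    m: ExpressionMatrix,
    grouping: Grouping = "treatment",
    cfg: PipelineConfig | None = None,
    tests: Sequence[str] = ("ttest", "rp", "fisher"),
) -> tuple[pd.DataFrame, dict]:
    """Run the selected tests, adjust with BH, and build the consensus call.

    A gene is significant for a test when its raw p beats the per-test
    threshold and its BH q-value beats ``fdr_alpha``.  The consensus set is
    the intersection over the selected tests.
    """
    cfg = cfg or PipelineConfig()
    fc = fold_change_call(m, grouping, cfg)
    out = fc.copy()
    significant: dict[str, set[str]] = {}
    if "ttest" in tests:
        tt = ttest_unpaired(m, grouping)
        out["p_ttest"] = tt["p_ttest"]
        out["q_ttest"] = bh_fdr(tt["p_ttest"].values)
        significant["ttest"] = set(
            out.index[(out["p_ttest"] < cfg.p_ttest) & (out["q_ttest"] < cfg.fdr_alpha)]
        )
    if "rp" in tests:
        rp = rank_product(m, grouping, cfg)
        p_rp = np.minimum(1.0, 2.0 * np.minimum(rp["p_up"], rp["p_down"]))
        out["p_rp"] = p_rp
        out["q_rp"] = bh_fdr(p_rp.values)
        significant["rp"] = set(
            out.index[(out["p_rp"] < cfg.p_rp) & (out["q_rp"] < cfg.fdr_alpha)]
        )
    if "fisher" in tests:
        counts_ok = np.allclose(m.values.values, np.round(m.values.values))
        fm = m if counts_ok else ExpressionMatrix(m.values.round(), m.sample_meta)
        pf = fisher_counts(fm, grouping)
        out["p_fisher"] = pf
        out["q_fisher"] = bh_fdr(pf.values)
        significant["fisher"] = set(
            out.index[(out["p_fisher"] < cfg.p_fisher) & (out["q_fisher"] < cfg.fdr_alpha)]
        )
    cons = consensus(significant, list(m.values.index))
    out["supported_by"] = [
        ",".join(sorted(cons["supported_by"][g])) for g in out.index
    ]
    out["in_consensus"] = [g in cons["intersection"] for g in out.index]
    return out, cons


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_expression(
    matrix_path: str | Path, meta_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta.loc[values.columns])


def write_expression(
    m: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path
) -> None:
    m.values.to_csv(matrix_path, sep="\t", float_format="%.6g")
    m.sample_meta.to_csv(meta_path, sep="\t")
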