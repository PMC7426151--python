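"""Transcriptional divergence (TD) between duplicate gene copies.

A duplicate pair is transcriptionally diverged when the ratio of the higher-
to the lower-expressed copy, in a reference background (a timepoint in YPD by
default), exceeds a threshold tau (default 1.25, i.e. a >25% difference). The
module computes TD per pair, labels responding copies as high- or low-TDC
(transcriptionally diverged copy), maps per-copy differential-expression calls
onto five pair categories, and provides the enrichment machinery used around
these quantities: Fisher and binomial enrichment, resampling nulls of means
and of category counts, the TD-threshold sensitivity sweep, rank-sum group
comparisons, and set-overlap summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dge import compute_size_factors
from .errors import InputError

__all__ = [
    "EnrichmentResult",
    "ResamplingNull",
    "pair_expression",
    "compute_td",
    "td_table",
    "classify_tdc",
    "classify_pair_category",
    "fisher_enrichment",
    "binomial_td_enrichment",
    "resampling_null_mean",
    "category_count_null",
    "plasticity_td_correlation",
    "td_threshold_sweep",
    "compare_groups_ranksum",
    "overlap_summary",
    "OverlapSummary",
]

CATEGORIES = (
    "BothUp",
    "BothDown",
    "Discordant",
    "OneUpOneUnchanged",
    "OneDownOneUnchanged",
    "BothUnchanged",
)


# ---------------------------------------------------------------------------
# TD computation
# ---------------------------------------------------------------------------


def pair_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pairs: pd.DataFrame,
    background: tuple[str, str] = ("t0", "YPD"),
    size_factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Mean normalized expression of each copy in one background.

    ``pairs`` needs columns pair_id, gene_a, gene_b (class carried through if
    present). Expression is the mean of normalized counts across the
    background's replicates plus a pseudocount; pairs whose two copies have
    zero raw counts throughout are flagged ``excluded``.
    """
    timepoint, medium = background
    if "sample" in design.columns:
        design = design.set_index("sample")
    design = design.loc[counts.columns]
    samples = design.index[(design["timepoint"] == timepoint) & (design["medium"] == medium)]
    if len(samples) == 0:
        raise InputError(f"no samples in background {background!r}")
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    norm = counts[samples] / size_factors[samples]
    mean = norm.mean(axis=1)

    out = pairs[[c for c in ("pair_id", "class", "gene_a", "gene_b") if c in pairs.columns]].copy()
    missing = (set(out["gene_a"]) | set(out["gene_b"])) - set(mean.index)
    if missing:
        raise InputError(f"pair genes absent from count matrix: {sorted(missing)[:5]}")
    raw_a = mean.reindex(out["gene_a"]).to_numpy()
    raw_b = mean.reindex(out["gene_b"]).to_numpy()
    out["mean_a"] = raw_a + pseudocount
    out["mean_b"] = raw_b + pseudocount
    out["excluded"] = (raw_a == 0) & (raw_b == 0)
    return out


def compute_td(mean_a: float, mean_b: float, tau: float = 1.25) -> tuple[float, bool]:
    """TD ratio (higher/lower copy mean) and the strict TD flag ratio > tau.

    Undefined (NaN, False) when both means are zero.
    """
    if tau < 1.0:
        raise InputError("tau must be >= 1")
    if mean_a == 0 and mean_b == 0:
        return float("nan"), False
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    ratio = math.inf if lo == 0 else hi / lo
    return ratio, ratio > tau


def td_table(pair_expr: pd.DataFrame, tau: float = 1.25) -> pd.DataFrame:
    """Vectorized TD ratios/flags and high/low copy ids for a pair table."""
    if tau < 1.0:
        raise InputError("tau must be >= 1")
    out = pair_expr.copy()
    a = out["mean_a"].to_numpy(dtype=float)
    b = out["mean_b"].to_numpy(dtype=float)
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((hi == 0) & (lo == 0), np.nan, hi / lo)
    if "excluded" in out.columns:
        ratio = np.where(out["excluded"].to_numpy(), np.nan, ratio)
    out["td_ratio"] = ratio
    out["is_td"] = ratio > tau  # NaN compares False
    a_high = a >= b
    out["high_copy"] = np.where(a_high, out["gene_a"], out["gene_b"])
    out["low_copy"] = np.where(a_high, out["gene_b"], out["gene_a"])
    tie = a == b
    out.loc[tie, ["high_copy", "low_copy"]] = None
    out["tau"] = tau
    return out


def classify_tdc(pair_row, de_calls) -> list[tuple[str, str, str]]:
    """Label each responding copy of a TD pair as high-TDC or low-TDC.

    ``pair_row`` is a row of :func:`td_table` (mapping-like with is_td,
    high_copy, low_copy); ``de_calls`` maps gene -> call. Returns
    (gene, call, label) for every copy called up or down; refuses non-TD
    pairs.
    """
    if not bool(pair_row["is_td"]):
        raise InputError("TDC labels are defined only for TD pairs")
    labels = []
    for gene, label in ((pair_row["high_copy"], "high-TDC"), (pair_row["low_copy"], "low-TDC")):
        call = de_calls.get(gene, "unchanged") if hasattr(de_calls, "get") else de_calls[gene]
        if call in ("up", "down"):
            labels.append((gene, call, label))
    return labels


_CATEGORY_OF = {
    frozenset(("up",)): "BothUp",
    frozenset(("down",)): "BothDown",
    frozenset(("up", "down")): "Discordant",
    frozenset(("up", "unchanged")): "OneUpOneUnchanged",
    frozenset(("down", "unchanged")): "OneDownOneUnchanged",
    frozenset(("unchanged",)): "BothUnchanged",
}


def classify_pair_category(call_a: str, call_b: str) -> str:
    """Map the two copies' calls onto the five response categories (plus
    BothUnchanged); symmetric in the copies."""
    for c in (call_a, call_b):
        if c not in ("up", "down", "unchanged"):
            raise InputError(f"unknown call {c!r}")
    return _CATEGORY_OF[frozenset((call_a, call_b))]


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment (Fisher) or proportion (binomial) test outcome."""

    p: float
    odds_ratio: float | None = None
    table: np.ndarray | None = None
    k: int | None = None
    n: int | None = None
    p0: float | None = None
    alternative: str | None = None


def fisher_enrichment(table) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The sample odds ratio is (ad)/(bc), with a Haldane 0.5 added to every
    cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise InputError("table cells must be non-negative integers")
    t = np.round(t).astype(np.int64)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(p=float(p), odds_ratio=float(odds), table=t)


def binomial_td_enrichment(
    k: int, n: int, p0: float, alternative: str = "greater"
) -> EnrichmentResult:
    """Exact binomial test that k successes out of n deviate from rate p0.

    ``greater``/``less`` are exact one-sided tails; ``two-sided`` sums the
    point probabilities no larger than that of the observed k (the R
    binom.test convention).
    """
    if not 0 < p0 < 1:
        raise InputError("p0 must lie strictly in (0, 1)")
    if not 0 <= k <= n:
        raise InputError("require 0 <= k <= n")
    res = sps.binomtest(int(k), int(n), p0, alternative=alternative)
    return EnrichmentResult(p=float(res.pvalue), k=int(k), n=int(n), p0=float(p0),
                            alternative=alternative)


# ---------------------------------------------------------------------------
# Resampling nulls
# ---------------------------------------------------------------------------


@dataclass
class ResamplingNull:
    """Observed statistic against a without-replacement resampling null."""

    observed: float
    subset_size: int
    null: np.ndarray = field(repr=False)
    p: float = 0.0
    direction: str = "greater"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null, ddof=1)) if len(self.null) > 1 else 0.0


def resampling_null_mean(
    pool: np.ndarray,
    subset_size: int,
    observed: float,
    n_iter: int = 10_000,
    seed: int = 0,
    statistic=np.mean,
    direction: str | None = None,
) -> ResamplingNull:
    """Empirical p of an observed subset statistic against random subsets.

    Each iterate draws ``subset_size`` values from ``pool`` without
    replacement and applies ``statistic``. The one-sided empirical p carries
    the +1 correction: (1 + #{null >= observed}) / (n_iter + 1) for
    direction "greater" (mirrored for "less"). If ``direction`` is None it
    follows the sign of observed - statistic(pool).
    """
    pool = np.asarray(pool, dtype=float)
    if subset_size > pool.size:
        raise InputError(f"subset_size {subset_size} exceeds pool size {pool.size}")
    if subset_size <= 0:
        raise InputError("subset_size must be positive")
    rng = np.random.default_rng(seed)
    if statistic is np.mean:
        # vectorized: random keys, take the first subset_size per row
        keys = rng.random((n_iter, pool.size))
        idx = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
        null = pool[idx].mean(axis=1)
    else:
        null = np.array(
            [statistic(rng.choice(pool, size=subset_size, replace=False)) for _ in range(n_iter)]
        )
    if direction is None:
        direction = "greater" if observed >= statistic(pool) else "less"
    if direction == "greater":
        p = (1.0 + np.sum(null >= observed)) / (n_iter + 1.0)
    elif direction == "less":
        p = (1.0 + np.sum(null <= observed)) / (n_iter + 1.0)
    else:
        raise InputError(f"unknown direction {direction!r}")
    return ResamplingNull(
        observed=float(observed), subset_size=int(subset_size), null=null,
        p=float(p), direction=direction,
    )


_CALL_CODE = {"up": 0, "down": 1, "unchanged": 2}
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
_CAT_TABLE = np.empty((3, 3), dtype=np.int64)
for _ca, _i in _CALL_CODE.items():
    for _cb, _j in _CALL_CODE.items():
        _CAT_TABLE[_i, _j] = _CAT_INDEX[classify_pair_category(_ca, _cb)]


def category_count_null(
    calls_a,
    calls_b,
    n_iter: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed pair-category counts against a call-permutation null.

    The null permutes the pooled vector of per-copy DE calls across all
    duplicate genes (preserving the genome-wide up/down/unchanged totals) and
    recomputes category counts. One-sided empirical p per category with the
    +1 correction, direction following the sign of observed - null mean.
    """
    a = np.array([_CALL_CODE[c] for c in calls_a])
    b = np.array([_CALL_CODE[c] for c in calls_b])
    if a.size != b.size or a.size == 0:
        raise InputError("need equal-length, non-empty call vectors")
    m = a.size
    observed = np.bincount(_CAT_TABLE[a, b], minlength=len(CATEGORIES))

    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, len(CATEGORIES)), dtype=np.int64)
    for it in range(n_iter):
        perm = rng.permutation(pooled)
        null[it] = np.bincount(_CAT_TABLE[perm[:m], perm[m:]], minlength=len(CATEGORIES))

    null_mean = null.mean(axis=0)
    direction = np.where(observed >= null_mean, "greater", "less")
    ge = (null >= observed[None, :]).sum(axis=0)
    le = (null <= observed[None, :]).sum(axis=0)
    p = np.where(direction == "greater", (1.0 + ge) / (n_iter + 1.0), (1.0 + le) / (n_iter + 1.0))
    return pd.DataFrame(
        {
            "category": CATEGORIES,
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null.std(axis=0, ddof=1),
            "p": p,
            "direction": direction,
        }
    ).set_index("category")


# ---------------------------------------------------------------------------
# Correlation, sweep, group comparison, overlaps
# ---------------------------------------------------------------------------


def plasticity_td_correlation(td_ratio, plasticity) -> tuple[float, float]:
    """Pearson correlation of log TD ratio against log plasticity (a gene's
    YPE/YPD fold change), with the two-sided t-transform p-value."""
    x = np.log(np.asarray(td_ratio, dtype=float))
    y = np.log(np.asarray(plasticity, dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InputError("need >= 3 pairs with defined TD and plasticity")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def td_threshold_sweep(
    pair_expr: pd.DataFrame,
    de_calls,
    taus=np.round(np.arange(1.0, 4.01, 0.25), 2),
) -> pd.DataFrame:
    """Sensitivity of the TD enrichment to the TD threshold tau.

    For each tau, duplicate class (all/WGD/SSD) and direction (up/down):
    the TD pool size among defined pairs, the pool TD fraction p0, the
    responding duplicate genes n, those from TD pairs k, and the upper-tail
    binomial p. Rows where the test is undefined (empty pool, p0 in {0,1},
    or no responders) are flagged.
    """
    taus = np.asarray(taus, dtype=float)
    if (taus < 1.0).any():
        raise InputError("every tau must be >= 1")
    get_call = de_calls.get if hasattr(de_calls, "get") else de_calls.__getitem__
    rows = []
    classes = ["all"] + sorted(pair_expr["class"].unique()) if "class" in pair_expr.columns else ["all"]
    base = td_table(pair_expr, tau=1.0)
    defined = base[np.isfinite(base["td_ratio"])]
    for tau in taus:
        for cls in classes:
            sub = defined if cls == "all" else defined[defined["class"] == cls]
            n_pairs = len(sub)
            is_td = sub["td_ratio"] > tau
            n_td = int(is_td.sum())
            p0 = n_td / n_pairs if n_pairs else float("nan")
            gene_td = {}
            for _, row in sub.iterrows():
                gene_td[row["gene_a"]] = gene_td[row["gene_b"]] = bool(row["td_ratio"] > tau)
            for direction in ("up", "down"):
                genes = [g for g in gene_td if get_call(g) == direction]
                n = len(genes)
                k = sum(gene_td[g] for g in genes)
                undefined = n_pairs == 0 or n == 0 or not (0 < p0 < 1)
                p = (
                    float("nan")
                    if undefined
                    else binomial_td_enrichment(k, n, p0, alternative="greater").p
                )
                rows.append(
                    {
                        "tau": tau,
                        "class": cls,
                        "direction": direction,
                        "n_pairs": n_pairs,
                        "n_td_pairs": n_td,
                        "p0": p0,
                        "n_responders": n,
                        "k_td_responders": k,
                        "p": p,
                        "undefined": undefined,
                    }
                )
    return pd.DataFrame(rows)


def compare_groups_ranksum(values_a, values_b) -> tuple[float, float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (p, median_a, median_b).

    Exact enumeration for combined sample sizes <= 12 without ties, otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0)), float(np.median(a)), float(np.median(b))


@dataclass
class OverlapSummary:
    """Pairwise and core overlaps between call sets (e.g. per-timepoint up-sets)."""

    sizes: dict
    pairwise: pd.DataFrame
    core: set
    core_size: int

    def percentage(self, of: str, with_: str) -> float:
        row = self.pairwise[(self.pairwise["of"] == of) & (self.pairwise["with"] == with_)]
        return float(row["pct_of"].iloc[0])


def overlap_summary(call_sets: dict) -> OverlapSummary:
    """Venn-style intersection counts between named gene sets.

    For every ordered pair (A, B): |A ∩ B| and the percentage of A it covers
    (one decimal). The core set is the intersection of all sets.
    """
    names = list(call_sets)
    sets = {k: set(v) for k, v in call_sets.items()}
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            inter = len(sets[a] & sets[b])
            pct = round(100.0 * inter / len(sets[a]), 1) if sets[a] else 0.0
            rows.append({"of": a, "with": b, "size_of": len(sets[a]),
                         "intersection": inter, "pct_of": pct})
    core = set.intersection(*sets.values()) if sets else set()
    return OverlapSummary(
        sizes={k: len(v) for k, v in sets.items()},
        pairwise=pd.DataFrame(rows),
        core=core,
        core_size=len(core),
    )
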