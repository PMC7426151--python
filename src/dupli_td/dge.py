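"""Negative-binomial differential expression between media (YPE vs YPD).

The contrast is a per-timepoint two-group comparison on a gene x sample count
matrix: median-of-ratios size factors, method-of-moments dispersion estimates
shrunk toward the genome-wide median, a Wald test on the log2 fold change with
a delta-method standard error, Benjamini-Yekutieli (default) FDR adjustment,
and a trinary call at fold change > 25% and FDR < 0.005.

The modelling surface is :class:`NBExpressionModel` (construct from counts +
design, ``fit`` a timepoint contrast) returning :class:`DEResults`; the module
functions underneath are usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, InputError, NormalizationError

__all__ = [
    "CountMatrix",
    "NBExpressionModel",
    "DEResults",
    "compute_size_factors",
    "estimate_dispersions",
    "nb_test",
    "adjust_pvalues",
    "call_de",
]

DESIGN_COLUMNS = ("sample", "line", "timepoint", "medium", "replicate")
VALID_TIMEPOINTS = ("t0", "t100", "t110")
VALID_MEDIA = ("YPD", "YPE")


@dataclass
class CountMatrix:
    """Integer counts (genes x samples) with a per-sample design table.

    The design covers every sample exactly once, with columns line, timepoint
    (t0/t100/t110), medium (YPD/YPE) and replicate.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        counts, design = self.counts, self.design
        if "sample" in design.columns:
            design = design.set_index("sample")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise InputError("counts must be integers")
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise InputError("counts must be non-negative")
        missing = set(counts.columns) - set(design.index)
        extra = set(design.index) - set(counts.columns)
        if missing or extra:
            raise DesignError(
                f"design/sample mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )
        if design.index.has_duplicates:
            raise DesignError("design lists a sample more than once")
        bad_m = set(design["medium"]) - set(VALID_MEDIA)
        if bad_m:
            raise DesignError(f"unknown media {sorted(bad_m)}")
        self.counts = counts
        self.design = design.loc[counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, timepoint: str, medium: str) -> list[str]:
        d = self.design
        return list(d.index[(d["timepoint"] == timepoint) & (d["medium"] == medium)])

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        return cls(counts, design)


def compute_size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, restricted to
    genes expressed in every sample; each sample's factor is the median ratio
    of its counts to the reference. Normalized expression is count / factor.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) <= 0).any():
        bad = counts.columns[arr.sum(axis=0) <= 0].tolist()
        raise NormalizationError(f"all-zero sample(s): {bad}")
    pos = (arr > 0).all(axis=1)
    if pos.sum() < 1:
        # no universally expressed gene: fall back to library-size factors
        factors = arr.sum(axis=0)
    else:
        logs = np.log(arr[pos])
        ref = logs.mean(axis=1)
        factors = np.exp(np.median(logs - ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series | None = None,
    n_genes_prior: float = 10.0,
) -> pd.Series:
    """Per-gene NB dispersion by pooled method of moments with shrinkage.

    Within each condition (timepoint x medium group with >= 2 replicates) the
    raw moment estimate is (s^2 - m) / m^2 on normalized counts; estimates are
    pooled across conditions weighted by residual degrees of freedom and
    floored at 0. Each gene is shrunk toward a genome-wide common dispersion
    with weight ``n_genes_prior / (n_genes_prior + df_g)``. The common value
    solves the Pearson chi-square equation: phi such that the sum over genes
    and samples of (x - m)^2 / (m + phi m^2) equals the pooled residual
    degrees of freedom. This standardizes every gene equally, so it is robust
    to the heavy right tail of expression means, unlike a moment regression
    or the median of the noisy per-gene estimates.
    """
    if "sample" in design.columns:
        design = design.set_index("sample")
    design = design.loc[counts.columns]
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]

    groups = design.groupby(["timepoint", "medium"], observed=True).groups
    num = np.zeros(counts.shape[0])
    df_total = 0.0
    resid_sq = []  # per-cell (x - m)^2 and matching means, for Pearson chi^2
    mean_rep = []
    df_cells = 0.0
    for _, samples in groups.items():
        idx = counts.columns.get_indexer(samples)
        n = len(idx)
        if n < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += raw * (n - 1)
        df_total += n - 1
        ok = m > 0
        resid_sq.append(((sub - m[:, None]) ** 2)[ok].ravel())
        mean_rep.append(np.repeat(m[ok], n))
        df_cells += ok.sum() * (n - 1)
    if df_total == 0:
        raise DesignError(
            "no condition has >= 2 replicates; per-gene dispersion cannot be "
            "estimated — supply a common dispersion instead"
        )
    phi_raw = np.maximum(num / df_total, 0.0)

    r2 = np.concatenate(resid_sq)
    mm = np.concatenate(mean_rep)
    # scale (n-1)/n: the within-group residuals sum to (n-1) var units per gene
    def pearson_gap(phi: float) -> float:
        return float(np.sum(r2 / (mm + phi * mm**2))) - df_cells

    if pearson_gap(0.0) <= 0:
        phi_common = 0.0
    else:
        from scipy.optimize import brentq

        hi = 1.0
        while pearson_gap(hi) > 0 and hi < 1e4:
            hi *= 10.0
        phi_common = float(brentq(pearson_gap, 0.0, hi)) if pearson_gap(hi) <= 0 else hi
    w = n_genes_prior / (n_genes_prior + df_total)
    phi = w * phi_common + (1.0 - w) * phi_raw
    return pd.Series(phi, index=counts.index, name="dispersion")


def nb_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersions: pd.Series | float,
    timepoint: str,
    size_factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of YPE vs YPD at one timepoint on NB counts.

    lfc = log2((mean normalized YPE + pseudo) / (mean normalized YPD +
    pseudo)); its standard error comes from the NB variance mu + phi mu^2 of
    each sample's normalized count, propagated through the log by the delta
    method. Two-sided normal p-values.
    """
    if "sample" in design.columns:
        design = design.set_index("sample")
    design = design.loc[counts.columns]
    if size_factors is None:
        size_factors = compute_size_factors(counts)

    groups = {}
    for medium in ("YPE", "YPD"):
        sel = (design["timepoint"] == timepoint) & (design["medium"] == medium)
        samples = list(design.index[sel])
        if not samples:
            raise DesignError(f"no {medium} samples at timepoint {timepoint!r}")
        groups[medium] = samples

    phi = (
        dispersions.reindex(counts.index).to_numpy()
        if isinstance(dispersions, pd.Series)
        else np.full(counts.shape[0], float(dispersions))
    )

    stats = {}
    for medium, samples in groups.items():
        idx = counts.columns.get_indexer(samples)
        sf = size_factors.to_numpy()[idx]
        sub = counts.to_numpy(dtype=float)[:, idx] / sf[None, :]
        m = sub.mean(axis=1)
        n = len(idx)
        # var of the group mean of normalized counts: mean over samples of
        # (mu/s_j + phi mu^2) / n^2 summed over samples
        var_mean = (m[:, None] / sf[None, :] + phi[:, None] * m[:, None] ** 2).sum(axis=1) / n**2
        stats[medium] = (m, var_mean)

    m_e, v_e = stats["YPE"]
    m_d, v_d = stats["YPD"]
    ln2sq = np.log(2.0) ** 2
    lfc = np.log2((m_e + pseudocount) / (m_d + pseudocount))
    var_lfc = v_e / ((m_e + pseudocount) ** 2 * ln2sq) + v_d / ((m_d + pseudocount) ** 2 * ln2sq)
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    from scipy import stats as sps

    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    # genes identical in both groups carry no evidence
    p[(lfc == 0.0)] = 1.0
    return pd.DataFrame(
        {"lfc": lfc, "se": se, "p": p, "mean_ype": m_e, "mean_ypd": m_d}, index=counts.index
    )


def adjust_pvalues(p, method: str = "BY") -> np.ndarray:
    """Step-up FDR adjustment: BH, or BY (BH inflated by c(m) = sum 1/i)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise InputError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def call_de(
    lfc: np.ndarray,
    fdr: np.ndarray,
    fc_threshold: float = 1.25,
    fdr_threshold: float = 0.005,
) -> np.ndarray:
    """Trinary call: up iff linear FC > fc_threshold and FDR < fdr_threshold
    (strict inequalities), down symmetric with 1/fc_threshold, else unchanged."""
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise InputError("thresholds must be positive")
    lfc = np.asarray(lfc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    fc = np.power(2.0, lfc)
    call = np.full(lfc.shape, "unchanged", dtype=object)
    sig = fdr < fdr_threshold
    call[sig & (fc > fc_threshold)] = "up"
    call[sig & (fc < 1.0 / fc_threshold)] = "down"
    return call


@dataclass
class DEResults:
    """Per-gene DE table (gene, lfc, p, fdr, call) plus the contrast metadata."""

    table: pd.DataFrame
    timepoint: str
    fc_threshold: float
    fdr_threshold: float
    method: str

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    def calls(self) -> pd.Series:
        return self.table["call"]

    def summary(self) -> str:
        t = self.table
        lines = [
            f"NB differential expression, YPE vs YPD at {self.timepoint}",
            f"genes tested:      {len(t)}",
            f"upregulated:       {(t['call'] == 'up').sum()}"
            f"  (FC > {self.fc_threshold}, {self.method} FDR < {self.fdr_threshold})",
            f"downregulated:     {(t['call'] == 'down').sum()}",
            f"median |lfc|:      {t['lfc'].abs().median():.3f}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.reset_index(names="gene")
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


class NBExpressionModel:
    """Two-group NB expression model for a count matrix with a design.

    Parameters
    ----------
    data : CountMatrix, or a (counts, design) pair of DataFrames.
    n_genes_prior : strength of dispersion shrinkage toward the median.
    """

    def __init__(self, data: CountMatrix, n_genes_prior: float = 10.0):
        self.data = data
        self.size_factors = compute_size_factors(data.counts)
        self.dispersions = estimate_dispersions(
            data.counts, data.design, self.size_factors, n_genes_prior=n_genes_prior
        )

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, design: pd.DataFrame, **kw) -> "NBExpressionModel":
        return cls(CountMatrix(counts, design), **kw)

    def normalized(self) -> pd.DataFrame:
        return self.data.counts / self.size_factors

    def fit(
        self,
        timepoint: str,
        fc_threshold: float = 1.25,
        fdr_threshold: float = 0.005,
        method: str = "BY",
    ) -> DEResults:
        res = nb_test(self.data.counts, self.data.design, self.dispersions, timepoint,
                      size_factors=self.size_factors)
        res["fdr"] = adjust_pvalues(res["p"].to_numpy(), method=method)
        res["call"] = call_de(res["lfc"].to_numpy(), res["fdr"].to_numpy(),
                              fc_threshold, fdr_threshold)
        cols = ["lfc", "se", "p", "fdr", "call", "mean_ype", "mean_ypd"]
        return DEResults(res[cols], timepoint, fc_threshold, fdr_threshold, method.upper())
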