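"""Synthetic data generator for the duplicate-divergence pipeline.

Emulates a yeast-like genome of singletons plus whole-genome duplicates (WGD)
and small-scale duplicates (SSD), with planted copy-wise expression divergence,
a condition effect (ethanol vs glucose medium), negative-binomial count noise,
codon pairs with tunable synonymous divergence, annotation maps for
over-representation tests, and logistic growth curves with observation noise.

Everything downstream of raw reads is generated here so the full analysis is
testable without any sequencing data. All functions are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, SaturationError
from .genetic_code import SENSE_CODONS, SYNONYMOUS_NEIGHBORS, translate_cds

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_catalog",
    "simulate_counts",
    "simulate_cds_pairs",
    "simulate_growth_curves",
    "simulate_annotation_map",
    "default_design",
    "logistic",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic genome and count model.

    Defaults mirror the study system: a ~6000-gene budding-yeast genome with
    555 WGD pairs and 560 SSD pairs, of which roughly 80% show copy-wise
    transcriptional divergence, profiled in 3 biological replicates per
    medium. Dispersion 0.1 is a typical biological-replicate value for bulk
    RNA-seq counts.
    """

    n_singletons: int = 4000
    n_wgd_pairs: int = 555
    n_ssd_pairs: int = 560
    frac_td_pairs: float = 0.8
    td_log_ratio_sd: float = 0.5
    frac_de: float = 0.2
    de_lfc_mean: float = 0.0
    de_lfc_sd: float = 1.0
    dispersion: float = 0.1
    lib_size_mean: float = 2_000_000.0
    lib_size_log_sd: float = 0.2
    n_replicates: int = 3
    de_td_coupling: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_singletons", "n_wgd_pairs", "n_ssd_pairs", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("frac_td_pairs", "frac_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.dispersion <= 0:
            raise ConfigurationError(f"dispersion must be > 0, got {self.dispersion!r}")
        if self.td_log_ratio_sd < 0:
            raise ConfigurationError("td_log_ratio_sd must be >= 0")
        if self.lib_size_mean <= 0:
            raise ConfigurationError("lib_size_mean must be > 0")

    @property
    def n_genes(self) -> int:
        return self.n_singletons + 2 * (self.n_wgd_pairs + self.n_ssd_pairs)


@dataclass
class SimTruth:
    """Ground truth of one simulated genome.

    genes: per-gene table (gene, class, pair_id, partner, baseline_mean,
        copy_factor, is_de, true_lfc).
    pairs: per-pair table (pair_id, class, gene_a, gene_b, log_copy_ratio,
        is_td).
    lib_factors: per-sample library scaling factors (filled by
        :func:`simulate_counts`).
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    lib_factors: pd.Series | None = field(default=None)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_catalog(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a gene catalog with planted copy-wise divergence.

    Returns (catalog, truth). The catalog has one row per gene with columns
    gene/class/pair_id/partner; classes are singleton, WGD, SSD. A fraction
    ``frac_td_pairs`` of pairs receives a copy log-ratio drawn N(0,
    td_log_ratio_sd), applied multiplicatively to one randomly chosen copy;
    the remaining pairs have copy ratio exactly 1.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes, classes, pair_ids, partners = [], [], [], []
    pair_rows = []

    for i in range(cfg.n_singletons):
        genes.append(f"SNG{i:05d}")
        classes.append("singleton")
        pair_ids.append(None)
        partners.append(None)

    def add_pairs(n: int, cls: str, prefix: str) -> None:
        for i in range(n):
            pid = f"{prefix}{i:04d}"
            a, b = f"{prefix}{i:04d}a", f"{prefix}{i:04d}b"
            genes.extend([a, b])
            classes.extend([cls, cls])
            pair_ids.extend([pid, pid])
            partners.extend([b, a])
            pair_rows.append({"pair_id": pid, "class": cls, "gene_a": a, "gene_b": b})

    add_pairs(cfg.n_wgd_pairs, "WGD", "WGD")
    add_pairs(cfg.n_ssd_pairs, "SSD", "SSD")

    catalog = pd.DataFrame(
        {"gene": genes, "class": classes, "pair_id": pair_ids, "partner": partners}
    )

    pairs = pd.DataFrame(pair_rows, columns=["pair_id", "class", "gene_a", "gene_b"])
    n_pairs = len(pairs)
    is_td = rng.random(n_pairs) < cfg.frac_td_pairs
    log_ratio = np.where(is_td, rng.normal(0.0, cfg.td_log_ratio_sd, n_pairs), 0.0)
    divergent_copy = rng.integers(0, 2, n_pairs)  # which copy carries the factor
    pairs["log_copy_ratio"] = log_ratio
    pairs["is_td"] = is_td
    pairs["divergent_copy"] = divergent_copy

    # per-gene truth; the two copies of a pair share one baseline so the
    # planted copy factor is the only systematic within-pair difference
    baseline = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(genes))
    copy_factor = np.ones(len(genes))
    gene_index = pd.Index(genes)
    if n_pairs:
        pair_base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_pairs)
        for side, col in ((0, "gene_a"), (1, "gene_b")):
            idx = gene_index.get_indexer(pairs[col])
            baseline[idx] = pair_base
            sel = (pairs["divergent_copy"] == side).to_numpy()
            copy_factor[idx[sel]] = np.exp(pairs.loc[sel, "log_copy_ratio"])

    # DE indicator with optional logistic tilt for genes in TD pairs
    in_td_pair = np.zeros(len(genes), dtype=bool)
    if n_pairs:
        td_pairs = pairs.loc[pairs["is_td"]]
        td_genes = pd.concat([td_pairs["gene_a"], td_pairs["gene_b"]])
        in_td_pair[gene_index.get_indexer(td_genes)] = True
    if cfg.frac_de <= 0.0:
        p_de = np.zeros(len(genes))
    elif cfg.frac_de >= 1.0:
        p_de = np.ones(len(genes))
    else:
        base_logit = np.log(cfg.frac_de / (1.0 - cfg.frac_de))
        p_de = _sigmoid(base_logit + cfg.de_td_coupling * in_td_pair)
    is_de = rng.random(len(genes)) < p_de
    true_lfc = np.where(is_de, rng.normal(cfg.de_lfc_mean, cfg.de_lfc_sd, len(genes)), 0.0)

    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "class": classes,
            "pair_id": pair_ids,
            "partner": partners,
            "baseline_mean": baseline,
            "copy_factor": copy_factor,
            "is_de": is_de,
            "true_lfc": true_lfc,
        }
    )
    return catalog, SimTruth(genes=truth_genes, pairs=pairs)


def default_design(
    n_replicates: int = 3,
    timepoints: tuple[str, ...] = ("t0", "t100", "t110"),
    media: tuple[str, ...] = ("YPD", "YPE"),
    line: str = "a1",
) -> pd.DataFrame:
    """Full-factorial design table: timepoint x medium x replicate."""
    rows = []
    for tp in timepoints:
        for medium in media:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{line}_{tp}_{medium}_r{rep}",
                        "line": line,
                        "timepoint": tp,
                        "medium": medium,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(
    catalog: pd.DataFrame,
    truth: SimTruth,
    cfg: SimConfig,
    design: pd.DataFrame | list[tuple[str, str, int]],
) -> pd.DataFrame:
    """Draw a genes x samples NB count matrix for the given design.

    Per-gene mean: baseline x copy factor x 2**(lfc * [medium == YPE]) x a
    lognormal per-sample library factor. Variance follows mu + dispersion *
    mu**2 (gamma-Poisson mixture). Library factors are recorded on
    ``truth.lib_factors``.
    """
    cfg.validate()
    if isinstance(design, list):
        design = pd.DataFrame(
            [
                {
                    "sample": f"{m}_{tp}_r{rep}",
                    "line": "sim",
                    "timepoint": tp,
                    "medium": m,
                    "replicate": rep,
                }
                for (m, tp, rep) in design
            ]
        )
    if design.empty:
        raise InputError("design must be non-empty")
    genes = truth.genes
    missing = set(catalog["gene"]) - set(genes["gene"])
    if missing:
        raise InputError(f"genes absent from truth table: {sorted(missing)[:5]}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_genes, n_samples = len(genes), len(design)

    # scale baselines so the expected column total matches lib_size_mean
    base = genes["baseline_mean"].to_numpy() * genes["copy_factor"].to_numpy()
    base = base * (cfg.lib_size_mean / base.sum())
    lfc = genes["true_lfc"].to_numpy()
    is_ype = (design["medium"] == "YPE").to_numpy()

    lib = rng.lognormal(mean=0.0, sigma=cfg.lib_size_log_sd, size=n_samples)
    lib /= np.exp(np.mean(np.log(lib)))  # geometric mean 1

    mu = base[:, None] * np.power(2.0, lfc[:, None] * is_ype[None, :]) * lib[None, :]
    phi = cfg.dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    counts = rng.poisson(lam)

    truth.lib_factors = pd.Series(lib, index=design["sample"].to_numpy(), name="lib_factor")
    return pd.DataFrame(counts, index=genes["gene"].to_numpy(), columns=design["sample"].to_numpy())


# ---------------------------------------------------------------------------
# CDS pairs with tunable synonymous divergence
# ---------------------------------------------------------------------------

_P_SATURATION = 0.75  # pS at which Jukes-Cantor diverges


def _implied_ps(ds: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * ds / 3.0))


def simulate_cds_pairs(
    n_pairs: int,
    target_ds: float,
    n_codons: int,
    seed: int,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate CDS pairs whose realized NG86 dS clusters around ``target_ds``.

    Each pair descends from a random stop-free ancestor; synonymous
    substitutions are applied as single-nucleotide events (a codon moves to a
    uniformly chosen synonymous single-step neighbor), with repeated hits
    allowed, so back-substitutions occur and the Jukes-Cantor correction is
    exercised. The amino-acid sequence is preserved by construction.

    Returns (records, truth): records are (pair_id, cds_a, cds_b) and truth
    has one row per pair with the requested target.
    """
    if n_codons < 30:
        raise InputError("n_codons must be >= 30")
    if target_ds < 0:
        raise InputError("target_ds must be >= 0")
    if _implied_ps(target_ds) >= 0.75 * _P_SATURATION:
        raise SaturationError(
            f"target_ds={target_ds} implies pS beyond the Jukes-Cantor usable range"
        )

    rng = np.random.default_rng(seed)
    # ancestors use only codons with a synonymous single-step neighbor so
    # every codon can host a synonymous event
    usable = [c for c in SENSE_CODONS if SYNONYMOUS_NEIGHBORS[c]]
    records = []
    rows = []
    for i in range(n_pairs):
        anc = [usable[j] for j in rng.integers(0, len(usable), n_codons)]
        # synonymous-site total of the ancestor, to convert dS to event count
        s_sites = sum(len(SYNONYMOUS_NEIGHBORS[c]) / 3.0 for c in anc)
        seqs = []
        for _ in range(2):
            # each lineage accumulates half the pair divergence
            n_events = rng.poisson(target_ds * s_sites / 2.0)
            seq = list(anc)
            for _ in range(n_events):
                pos = int(rng.integers(0, n_codons))
                alts = SYNONYMOUS_NEIGHBORS[seq[pos]]
                if not alts:
                    continue  # drifted to a codon without synonymous neighbors
                seq[pos] = alts[int(rng.integers(0, len(alts)))]
            seqs.append("".join(seq))
        pid = f"CDSPAIR{i:04d}"
        records.append((pid, seqs[0], seqs[1]))
        assert translate_cds(seqs[0]) == translate_cds(seqs[1])
        rows.append({"pair_id": pid, "target_ds": target_ds, "n_codons": n_codons})
    return records, pd.DataFrame(rows, columns=["pair_id", "target_ds", "n_codons"])


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def logistic(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """Logistic growth N(t) = K / (1 + ((K - N0)/N0) * exp(-r t))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def simulate_growth_curves(
    K: float,
    r: float,
    N0: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_wells: int = 1,
    well_prefix: str = "W",
) -> pd.DataFrame:
    """OD600 series on a time grid: logistic mean plus Gaussian noise, floored at 0.

    Returns a long table (well, time_h, od600) emulating plate-reader output
    sampled every few minutes over a multi-day incubation.
    """
    if not (K > N0 > 0):
        raise InputError(f"require K > N0 > 0, got K={K}, N0={N0}")
    if r <= 0:
        raise InputError(f"growth rate r must be > 0, got {r}")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    frames = []
    for w in range(n_wells):
        od = logistic(times, K, r, N0)
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=times.shape)
        od = np.maximum(od, 0.0)
        frames.append(pd.DataFrame({"well": f"{well_prefix}{w+1}", "time_h": times, "od600": od}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Annotation maps for over-representation tests
# ---------------------------------------------------------------------------


def simulate_annotation_map(
    catalog: pd.DataFrame,
    n_terms: int,
    genes_per_term: int,
    planted_term: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random term -> gene map, optionally with one planted enriched term.

    Background terms draw ``genes_per_term`` genes uniformly without
    replacement. If ``planted_term`` (a gene list) is given, a term named
    PLANTED containing exactly those genes is appended.
    """
    genes = catalog["gene"].to_numpy()
    if genes_per_term > len(genes):
        raise InputError("genes_per_term exceeds genome size")
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        members = rng.choice(genes, size=genes_per_term, replace=False)
        rows.extend({"term": f"TERM{t:04d}", "gene": g} for g in members)
    if planted_term is not None:
        unknown = set(planted_term) - set(genes)
        if unknown:
            raise InputError(f"planted genes not in catalog: {sorted(unknown)[:5]}")
        rows.extend({"term": "PLANTED", "gene": g} for g in planted_term)
    return pd.DataFrame(rows, columns=["term", "gene"])
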