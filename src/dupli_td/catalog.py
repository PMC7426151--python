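"""Duplicate-gene catalogs: WGD lists, reciprocal best hits, and dS filtering.

WGD (ohnolog) pairs are ingested from a two-column list in the style of the
Yeast Gene Order Browser. SSD (small-scale duplicate) candidates come from
reciprocal best hits in all-vs-all BLASTP tabular output (E <= 1e-5, >= 50
bits), then are filtered to a synonymous-divergence (dS) window matching the
WGD dS distribution, so both duplicate classes date to a comparable epoch.

dS uses Nei-Gojobori (1986) counting — fractional synonymous sites from the
standard genetic code, equal-weight averaging over mutational pathways at
multi-difference codons — with the Jukes-Cantor correction
dS = -(3/4) ln(1 - (4/3) pS).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CatalogError, InputError, ParseError, SaturationError
from .genetic_code import AMINO_ACID, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS

__all__ = [
    "DsEstimate",
    "read_wgd_pairs",
    "read_blast_tab",
    "reciprocal_best_hits",
    "ng86_ds",
    "filter_ssd_by_ds",
    "assemble_catalog",
]

logger = logging.getLogger(__name__)

BLAST_OUTFMT6 = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_wgd_pairs(path) -> list[tuple[str, str]]:
    """Read an unordered, deduplicated duplicate-pair list from two-column TSV."""
    pairs: dict[frozenset, tuple[str, str]] = {}
    seen_partner: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError("expected two tab-separated gene ids", line=lineno)
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                raise ParseError(f"self-pair {a!r}", line=lineno)
            key = frozenset((a, b))
            if key in pairs:
                continue
            for g, other in ((a, b), (b, a)):
                if g in seen_partner and seen_partner[g] != other:
                    raise CatalogError(
                        f"gene {g!r} paired with both {seen_partner[g]!r} and {other!r}"
                    )
            seen_partner[a], seen_partner[b] = b, a
            pairs[key] = tuple(sorted((a, b)))
    return list(pairs.values())


def read_blast_tab(path) -> pd.DataFrame:
    """Read BLAST tabular output (-outfmt 6) into a hits table."""
    try:
        hits = pd.read_csv(path, sep="\t", names=BLAST_OUTFMT6, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"unreadable BLAST table: {exc}") from exc
    if hits[["evalue", "bitscore"]].isna().any().any():
        raise ParseError("missing evalue/bitscore fields in BLAST table")
    return hits


def reciprocal_best_hits(
    hits: pd.DataFrame,
    e_max: float = 1e-5,
    bits_min: float = 50.0,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs from all-vs-all hits.

    Self-hits and hits failing E <= e_max or bitscore >= bits_min are dropped.
    A query's best hits are those with the maximal bit score (ties kept); a
    pair is a candidate when each member is among the other's best hits.
    Candidates are resolved to a matching greedily by descending pair score
    (min of the two bit scores, then min E, then lexicographic ids).
    """
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame(hits, columns=["qseqid", "sseqid", "evalue", "bitscore"])
    h = hits.loc[
        (hits["qseqid"] != hits["sseqid"])
        & (hits["evalue"] <= e_max)
        & (hits["bitscore"] >= bits_min),
        ["qseqid", "sseqid", "evalue", "bitscore"],
    ]
    if h.empty:
        return []
    # keep the best record per (query, subject): highest bits then lowest E
    h = h.sort_values(
        ["qseqid", "sseqid", "bitscore", "evalue"], ascending=[True, True, False, True]
    ).drop_duplicates(["qseqid", "sseqid"])

    best: dict[str, dict[str, tuple[float, float]]] = {}
    for q, grp in h.groupby("qseqid", sort=False):
        top = grp["bitscore"].max()
        sel = grp[grp["bitscore"] == top]
        best[q] = {s: (b, e) for s, b, e in zip(sel["sseqid"], sel["bitscore"], sel["evalue"])}

    candidates = []
    for q, targets in best.items():
        for s, (bits_qs, e_qs) in targets.items():
            if q < s and s in best and q in best[s]:
                bits_sq, e_sq = best[s][q]
                score = (min(bits_qs, bits_sq), -max(e_qs, e_sq))
                candidates.append((score, q, s))
    candidates.sort(key=lambda t: (-t[0][0], -t[0][1], t[1], t[2]))

    used: set[str] = set()
    pairs = []
    for _, q, s in candidates:
        if q in used or s in used:
            continue
        used.update((q, s))
        pairs.append((q, s))
    return pairs


# ---------------------------------------------------------------------------
# NG86 synonymous divergence
# ---------------------------------------------------------------------------


@dataclass
class DsEstimate:
    """NG86 synonymous-divergence summary for one aligned codon pair.

    S: synonymous sites (mean of the two sequences); Sd: synonymous
    differences, pathway-averaged; pS = Sd/S; dS: Jukes-Cantor corrected,
    NaN when pS >= 3/4 (saturated=True).
    """

    S: float
    Sd: float
    pS: float
    dS: float
    n_codons: int
    saturated: bool = False


def _syn_site_fraction(codon: str) -> float:
    """Fractional synonymous sites of a sense codon (changes to stops are
    counted as nonsynonymous)."""
    aa = AMINO_ACID[codon]
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and AMINO_ACID.get(alt) == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {c: _syn_site_fraction(c) for c in SENSE_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two sense
    codons over all orderings of single-nucleotide steps, equally weighted.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if (not (cur in STOP_CODONS or nxt in STOP_CODONS)
                    and AMINO_ACID[cur] == AMINO_ACID[nxt]):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        results.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in results if not b]
    pool = open_paths if open_paths else [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in pool) / len(pool)
    nd = sum(n for _, n in pool) / len(pool)
    return sd, nd


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _codon_pair_sd(c1: str, c2: str) -> float:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    if key not in _PAIR_CACHE:
        _PAIR_CACHE[key] = _pathway_counts(*key)
    return _PAIR_CACHE[key][0]


def _iter_codons(seq: str):
    for i in range(0, len(seq), 3):
        yield seq[i : i + 3].upper()


def ng86_ds(cds1: str, cds2: str) -> DsEstimate:
    """NG86 dS between two aligned, equal-length, in-frame CDS.

    Codons containing gaps or ambiguous characters in either sequence are
    skipped pairwise; internal stop codons among counted codons are an error.
    """
    if len(cds1) != len(cds2):
        raise InputError(f"sequence lengths differ ({len(cds1)} vs {len(cds2)})")
    if len(cds1) % 3 != 0:
        raise InputError("sequence length is not a multiple of 3")

    s1 = s2 = sd = 0.0
    n_used = 0
    for c1, c2 in zip(_iter_codons(cds1), _iter_codons(cds2)):
        if any(nt not in "ACGT" for nt in c1 + c2):
            continue  # gap or ambiguity: skip the codon pairwise
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise InputError(f"internal stop codon among counted codons: {c1}/{c2}")
        s1 += _SYN_SITES[c1]
        s2 += _SYN_SITES[c2]
        sd += _codon_pair_sd(c1, c2)
        n_used += 1
    if n_used == 0:
        raise InputError("no comparable codons")
    S = 0.5 * (s1 + s2)
    if S <= 0:
        raise InputError("no synonymous sites in the comparable codons")
    pS = sd / S
    if pS >= 0.75:
        return DsEstimate(S=S, Sd=sd, pS=pS, dS=float("nan"), n_codons=n_used, saturated=True)
    dS = -0.75 * np.log(1.0 - (4.0 / 3.0) * pS)
    return DsEstimate(S=S, Sd=sd, pS=pS, dS=float(dS), n_codons=n_used, saturated=False)


# ---------------------------------------------------------------------------
# dS filtering and catalog assembly
# ---------------------------------------------------------------------------


def filter_ssd_by_ds(
    ssd_ds: pd.DataFrame,
    wgd_ds: np.ndarray,
    q_low: float = 0.025,
    q_high: float = 0.975,
) -> tuple[pd.DataFrame, float]:
    """Retain SSD candidates whose dS lies inside central quantiles of the WGD
    dS distribution; also report a two-sample KS statistic (retained vs WGD)
    as a similarity diagnostic.

    ``ssd_ds`` needs columns pair_id (or gene_a/gene_b) and ds.
    """
    wgd_ds = np.asarray(wgd_ds, dtype=float)
    wgd_ds = wgd_ds[np.isfinite(wgd_ds)]
    if wgd_ds.size == 0:
        raise InputError("empty WGD dS reference")
    if ssd_ds.empty:
        raise InputError("empty SSD candidate set")
    lo, hi = np.quantile(wgd_ds, [q_low, q_high])
    ds = ssd_ds["ds"].to_numpy(dtype=float)
    keep = np.isfinite(ds) & (ds >= lo) & (ds <= hi)
    retained = ssd_ds.loc[keep].copy()
    if retained.empty:
        ks = float("nan")
    else:
        ks = float(sps.ks_2samp(retained["ds"].to_numpy(), wgd_ds).statistic)
    return retained, ks


def assemble_catalog(
    all_genes,
    wgd_pairs: list[tuple[str, str]],
    ssd_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Classify every gene as singleton/WGD/SSD with pair membership.

    WGD takes precedence: an SSD pair touching a WGD gene is dropped with a
    warning. A gene in a pair list but absent from the gene universe is an
    error.
    """
    universe = list(dict.fromkeys(all_genes))
    known = set(universe)
    cls = {g: "singleton" for g in universe}
    pair_id = {g: None for g in universe}
    partner = {g: None for g in universe}

    def place(pairs, label, prefix):
        kept = []
        for i, (a, b) in enumerate(pairs):
            for g in (a, b):
                if g not in known:
                    raise CatalogError(f"gene {g!r} in {label} pair list absent from gene universe")
            if cls[a] != "singleton" or cls[b] != "singleton":
                logger.warning("dropping %s pair (%s, %s): gene already classified", label, a, b)
                continue
            pid = f"{prefix}{i:05d}"
            cls[a] = cls[b] = label
            pair_id[a] = pair_id[b] = pid
            partner[a], partner[b] = b, a
            kept.append((a, b))
        return kept

    place(wgd_pairs, "WGD", "WGDP")
    place(ssd_pairs, "SSD", "SSDP")
    return pd.DataFrame(
        {
            "gene": universe,
            "class": [cls[g] for g in universe],
            "pair_id": [pair_id[g] for g in universe],
            "partner": [partner[g] for g in universe],
        }
    )
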