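"""Duplicate catalogs: WGD lists, reciprocal best hits, NG86 dS, filtering.

The NG86 oracle here is written independently of the package implementation:
it enumerates synonymous site fractions and mutational pathways directly with
exact fractions, without the package's precomputed codon tables.
"""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dupli_td.catalog import (
    assemble_catalog,
    filter_ssd_by_ds,
    ng86_ds,
    read_wgd_pairs,
    reciprocal_best_hits,
)
from dupli_td.errors import CatalogError, InputError, ParseError
from dupli_td.simulate import simulate_cds_pairs

# --- independent brute-force NG86 oracle -----------------------------------

_BASES = "ACGT"
_CODE = {}
_STOPS = {"TAA", "TAG", "TGA"}
# build the standard code from Biopython only (shared convention, not shared code)
from Bio.Seq import Seq  # noqa: E402

for _c in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
    aa = str(Seq(_c).translate())
    if aa != "*":
        _CODE[_c] = aa


def oracle_syn_sites(codon):
    total = Fraction(0)
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _CODE and _CODE[alt] == _CODE[codon]:
                syn += 1
        total += Fraction(syn, 3)
    return total


def oracle_pair_sd(c1, c2):
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return Fraction(0)
    paths = []
    for order in itertools.permutations(diffs):
        cur, sd, blocked = c1, Fraction(0), False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if cur in _CODE and nxt in _CODE and _CODE[cur] == _CODE[nxt]:
                sd += 1
            cur = nxt
        paths.append((sd, blocked))
    usable = [sd for sd, b in paths if not b] or [sd for sd, _ in paths]
    return sum(usable, Fraction(0)) / len(usable)


def oracle_ng86(seq1, seq2):
    s1 = s2 = Fraction(0)
    sd = Fraction(0)
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1 += oracle_syn_sites(c1)
        s2 += oracle_syn_sites(c2)
        sd += oracle_pair_sd(c1, c2)
    S = Fraction(s1 + s2, 2)
    ps = sd / S
    ds = -0.75 * np.log(1 - 4 / 3 * float(ps))
    return float(S), float(sd), float(ps), float(ds)


# --- tests ------------------------------------------------------------------


class TestWgdPairs:
    def test_unordered_dedup(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("A\tB\nB\tA\n")
        assert read_wgd_pairs(f) == [("A", "B")]

    def test_self_pair_rejected(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("A\tA\n")
        with pytest.raises(ParseError, match="line 1"):
            read_wgd_pairs(f)

    def test_malformed_line_reports_number(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("A\tB\nC\n")
        with pytest.raises(ParseError, match="line 2"):
            read_wgd_pairs(f)

    def test_conflicting_pairing_rejected(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("A\tB\nA\tC\n")
        with pytest.raises(CatalogError):
            read_wgd_pairs(f)

    def test_catalog_scale_list(self, tmp_path):
        # an ohnolog list of the catalog's size survives a round trip intact
        f = tmp_path / "pairs.tsv"
        f.write_text("".join(f"L{i}\tR{i}\n" for i in range(555)))
        assert len(read_wgd_pairs(f)) == 555


def hits_df(rows):
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])


class TestRbh:
    def test_mutual_best_pair(self):
        hits = hits_df([("A", "B", 1e-20, 200), ("B", "A", 1e-19, 190)])
        assert reciprocal_best_hits(hits) == [("A", "B")]

    def test_non_reciprocal_excluded(self):
        hits = hits_df([
            ("A", "B", 1e-20, 200),
            ("B", "C", 1e-30, 300), ("C", "B", 1e-30, 300),
        ])
        pairs = reciprocal_best_hits(hits)
        assert ("A", "B") not in pairs and ("B", "C") in pairs

    def test_bit_score_threshold(self):
        hits = hits_df([("A", "B", 1e-20, 49.9), ("B", "A", 1e-20, 49.9)])
        assert reciprocal_best_hits(hits) == []

    def test_evalue_threshold_and_self_hits(self):
        hits = hits_df([
            ("A", "A", 0.0, 900),
            ("A", "B", 1e-4, 200), ("B", "A", 1e-4, 200),
        ])
        assert reciprocal_best_hits(hits) == []

    def test_output_is_a_matching(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(40)]
        rows = []
        for q in genes:
            for s in rng.choice(genes, size=10, replace=False):
                if q != s:
                    rows.append((q, s, 10.0 ** -rng.integers(6, 40), rng.uniform(60, 400)))
        pairs = reciprocal_best_hits(hits_df(rows))
        seen = [g for p in pairs for g in p]
        assert len(seen) == len(set(seen))
        # determinism
        assert pairs == reciprocal_best_hits(hits_df(rows))


class TestNg86:
    def test_identical_sequences(self):
        est = ng86_ds("ATGGCT", "ATGGCT")
        assert est.Sd == 0 and est.dS == 0

    def test_single_synonymous_change_hand_value(self):
        # three Gly codons; one third-position synonymous difference; S = 3
        est = ng86_ds("GGTGGGGGA", "GGCGGGGGA")
        assert est.S == pytest.approx(3.0)
        assert est.pS == pytest.approx(1 / 3)
        assert est.dS == pytest.approx(-0.75 * np.log(5 / 9), abs=1e-12)

    def test_symmetry(self):
        recs, _ = simulate_cds_pairs(5, 0.3, 60, seed=4)
        for _, a, b in recs:
            assert ng86_ds(a, b).dS == pytest.approx(ng86_ds(b, a).dS, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(InputError):
            ng86_ds("ATG", "ATGGCT")
        with pytest.raises(InputError):
            ng86_ds("ATGG", "ATGG")
        with pytest.raises(InputError):
            ng86_ds("TAAGCT", "TAAGCT")  # internal stop

    def test_gapped_codons_skipped(self):
        full = ng86_ds("GGTGGG", "GGCGGG")
        gapped = ng86_ds("GGTGGG---", "GGCGGGGGA")
        assert gapped.dS == pytest.approx(full.dS)

    def test_matches_bruteforce_oracle(self):
        recs, _ = simulate_cds_pairs(20, 0.35, 100, seed=5)
        for _, a, b in recs:
            est = ng86_ds(a, b)
            S, Sd, pS, dS = oracle_ng86(a, b)
            assert est.S == pytest.approx(S, abs=1e-9)
            assert est.Sd == pytest.approx(Sd, abs=1e-9)
            assert est.dS == pytest.approx(dS, abs=1e-9)

    def test_ds_monotone_in_ps(self):
        ps = np.linspace(0.01, 0.7, 30)
        ds = -0.75 * np.log(1 - 4 / 3 * ps)
        assert np.all(np.diff(ds) > 0)


class TestDsFilter:
    def test_central_value_retained_outlier_removed(self):
        wgd = np.linspace(0.5, 1.5, 200)
        cand = pd.DataFrame({"pair_id": ["m", "o"], "ds": [np.median(wgd), 10 * wgd.max()]})
        kept, _ = filter_ssd_by_ds(cand, wgd)
        assert list(kept["pair_id"]) == ["m"]

    def test_planted_outliers_filtered(self):
        recs_like, _ = simulate_cds_pairs(60, 0.4, 120, seed=6)
        # outliers at 2.5x the reference divergence (the largest multiple the
        # generator can realize below Jukes-Cantor saturation)
        recs_out, _ = simulate_cds_pairs(15, 1.0, 120, seed=7)
        wgd_ref, _ = simulate_cds_pairs(120, 0.4, 120, seed=8)
        wgd = np.array([ng86_ds(a, b).dS for _, a, b in wgd_ref])
        rows = [{"pair_id": f"like{i}", "ds": ng86_ds(a, b).dS}
                for i, (_, a, b) in enumerate(recs_like)]
        rows += [{"pair_id": f"out{i}", "ds": ng86_ds(a, b).dS}
                 for i, (_, a, b) in enumerate(recs_out)]
        kept, ks = filter_ssd_by_ds(pd.DataFrame(rows), wgd)
        kept_ids = set(kept["pair_id"])
        assert not any(i.startswith("out") for i in kept_ids)
        assert sum(i.startswith("like") for i in kept_ids) >= 0.95 * 60 * 0.9
        assert ks < 0.3

    def test_empty_reference_rejected(self):
        with pytest.raises(InputError):
            filter_ssd_by_ds(pd.DataFrame({"pair_id": ["x"], "ds": [0.1]}), np.array([]))


class TestAssembleCatalog:
    def test_counts_and_partition(self):
        genes = [f"g{i}" for i in range(10)]
        cat = assemble_catalog(genes, [("g0", "g1"), ("g2", "g3")], [("g4", "g5")])
        counts = cat["class"].value_counts()
        assert counts["WGD"] == 4 and counts["SSD"] == 2 and counts["singleton"] == 4
        n_pairs = cat["pair_id"].nunique()
        assert counts["singleton"] + 2 * n_pairs == len(genes)

    def test_wgd_precedence_over_ssd(self, caplog):
        genes = ["a", "b", "c"]
        cat = assemble_catalog(genes, [("a", "b")], [("b", "c")]).set_index("gene")
        assert cat.loc["b", "class"] == "WGD"
        assert cat.loc["c", "class"] == "singleton"

    def test_empty_pair_lists(self):
        cat = assemble_catalog(["x", "y"], [], [])
        assert (cat["class"] == "singleton").all()

    def test_unknown_gene_rejected(self):
        with pytest.raises(CatalogError):
            assemble_catalog(["a"], [("a", "zz")], [])
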