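"""Significance selection, greedy LD clumping (against a brute-force
re-derivation), enrichment and SNP extraction."""

import numpy as np
import pytest
from pandas.testing import assert_frame_equal

from mrkit.errors import FormatError, ParameterError
from mrkit.instruments import (
    LDMatrix,
    clump,
    enrich_instruments,
    extract_snps,
    select_significant,
)

from conftest import make_table


def identity_ld(ids):
    return LDMatrix(list(ids), np.eye(len(ids)))


def brute_force_clump(table, ld, r2_threshold, window_kb):
    """Independent re-derivation of the greedy fixed point using explicit
    sorted lists (no shared code with the implementation)."""
    rows = list(table.df.itertuples(index=False))
    rows.sort(key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    kept = []
    removed = set()
    for r in rows:
        if r.snp_id in removed:
            continue
        kept.append(r.snp_id)
        for other in rows:
            if other.snp_id == r.snp_id or other.snp_id in removed:
                continue
            if other.snp_id in kept:
                continue
            same_chrom = other.chrom == r.chrom
            close = abs(other.pos - r.pos) <= window_kb * 1000
            if same_chrom and close and ld.lookup(r.snp_id, other.snp_id) >= r2_threshold:
                removed.add(other.snp_id)
    return set(kept)


class TestSelectSignificant:
    def test_threshold_is_strict(self):
        t = make_table(snp_ids=["a", "b"], pval=[1e-9, 1e-7])
        assert select_significant(t, 5e-8).snp_ids == ["a"]

    def test_threshold_one_keeps_all(self):
        t = make_table(pval=[0.2, 0.9, 1.0])
        assert len(select_significant(t, 1.0)) == 2  # pval == 1 not < 1

    @pytest.mark.parametrize("bad", [0.0, -1e-3, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ParameterError):
            select_significant(make_table(), bad)


class TestLDMatrix:
    def test_rejects_asymmetry_and_bad_diagonal(self):
        with pytest.raises(FormatError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(FormatError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 0.9]]))

    def test_round_trip(self, tmp_path):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.25], [0.25, 1.0]]))
        path = tmp_path / "ld.tsv"
        ld.write(path)
        back = LDMatrix.read(path)
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r2, ld.r2)


class TestClump:
    def test_hand_traceable_three_snp_example(self):
        t = make_table(snp_ids=["SNP1", "SNP2", "SNP3"],
                       pos=[1000, 2000, 3000], pval=[1e-10, 1e-9, 1e-8])
        r2 = np.array([[1.0, 0.5, 0.0001],
                       [0.5, 1.0, 0.0002],
                       [0.0001, 0.0002, 1.0]])
        ld = LDMatrix(["SNP1", "SNP2", "SNP3"], r2)
        kept = clump(t, ld, r2_threshold=0.001)
        assert kept.snp_ids == ["SNP1", "SNP3"]

    def test_identity_ld_keeps_everything(self):
        t = make_table(pval=[1e-9, 1e-8, 1e-7])
        assert_frame_equal(clump(t, identity_ld(t.snp_ids), 0.001).df, t.df)

    def test_empty_input_empty_output(self):
        t = make_table().subset([])
        assert len(clump(t, identity_ld([]), 0.001)) == 0

    def test_snp_absent_from_panel_dropped(self, caplog):
        t = make_table(pval=[1e-9, 1e-8, 1e-7])
        ld = identity_ld(["rs1", "rs2"])
        kept = clump(t, ld, 0.001)
        assert kept.snp_ids == ["rs1", "rs2"]

    def test_row_order_invariance(self, rng):
        k = 10
        ids = [f"s{i}" for i in range(k)]
        a = rng.uniform(0, 1, (k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
        pvals = rng.uniform(1e-12, 1e-4, k)
        t = make_table(snp_ids=ids, pos=list(range(1000, 1000 + k)),
                       pval=pvals)
        shuffled = t.with_df(t.df.sample(frac=1, random_state=0))
        assert set(clump(t, ld, 0.3).snp_ids) == set(clump(shuffled, ld, 0.3).snp_ids)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(7_000 + trial)
        k = int(rng.integers(2, 13))
        ids = [f"s{i}" for i in range(k)]
        a = rng.uniform(0, 1, (k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
        chrom = [str(c) for c in rng.integers(1, 3, k)]
        t = make_table(
            snp_ids=ids, chrom=chrom,
            pos=[int(p) for p in rng.integers(1, 5_000_000, k)],
            pval=rng.uniform(1e-12, 1e-4, k),
        )
        threshold = float(rng.choice([0.001, 0.1, 0.5]))
        window = int(rng.choice([100, 10_000]))
        got = set(clump(t, ld, threshold, window).snp_ids)
        assert got == brute_force_clump(t, ld, threshold, window)

    def test_retained_pairs_below_threshold_property(self, rng):
        k = 12
        ids = [f"s{i}" for i in range(k)]
        a = rng.uniform(0, 1, (k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
        t = make_table(snp_ids=ids, pos=list(range(1000, 1000 + k)),
                       pval=rng.uniform(1e-12, 1e-4, k))
        kept = clump(t, ld, 0.4).snp_ids
        for i, s1 in enumerate(kept):
            for s2 in kept[i + 1:]:
                assert ld.lookup(s1, s2) < 0.4


class TestEnrich:
    def test_bonferroni_admission(self):
        base = make_table(snp_ids=["b1"], pval=[1e-10], pos=[100])
        target = make_table(snp_ids=["b1", "c1"], pval=[1e-10, 1e-4],
                            pos=[100, 900_000_000])
        cand = make_table(snp_ids=["c1"], pval=[1e-20], pos=[900_000_000])
        ld = identity_ld(["b1", "c1"])
        out = enrich_instruments(base, cand, target, 48, ld)
        assert set(out.snp_ids) == {"b1", "c1"}  # 1e-4 < 0.05/48

    def test_candidate_in_ld_with_stronger_instrument_removed(self):
        base = make_table(snp_ids=["b1"], pval=[1e-10], pos=[100])
        target = make_table(snp_ids=["b1", "c1"], pval=[1e-10, 1e-6],
                            pos=[100, 200])
        cand = make_table(snp_ids=["c1"], pval=[1e-20], pos=[200])
        r2 = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = LDMatrix(["b1", "c1"], r2)
        out = enrich_instruments(base, cand, target, 48, ld)
        assert out.snp_ids == ["b1"]  # admitted then clumped away

    def test_no_candidate_passes(self):
        base = make_table(snp_ids=["b1"], pval=[1e-10])
        target = make_table(snp_ids=["b1", "c1"], pval=[1e-10, 0.01])
        cand = make_table(snp_ids=["c1"], pval=[1e-20])
        out = enrich_instruments(base, cand, target, 48, identity_ld(["b1", "c1"]))
        assert out.snp_ids == ["b1"]

    def test_n_tests_domain(self):
        t = make_table()
        with pytest.raises(ParameterError):
            enrich_instruments(t, t, t, 0, identity_ld(t.snp_ids))


class TestExtract:
    def test_subset_and_missing_reported(self):
        t = make_table()
        sub, missing = extract_snps(t, ["rs3", "rs1", "rs99"])
        assert sub.snp_ids == ["rs3", "rs1"]  # requested order
        assert missing == ["rs99"]

    def test_empty_request(self):
        sub, missing = extract_snps(make_table(), [])
        assert len(sub) == 0 and missing == []

    def test_matches_membership_oracle(self, rng):
        ids = [f"r{i}" for i in range(20)]
        t = make_table(snp_ids=ids, pos=list(range(20)),
                       pval=rng.uniform(0.0001, 1, 20))
        wanted = [ids[i] for i in rng.choice(20, 8, replace=False)]
        sub, missing = extract_snps(t, wanted)
        assert missing == []
        assert set(sub.snp_ids) == {s for s in ids if s in set(wanted)}
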