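"""Association scan plumbing, significance filtering and QTL windows."""

import logging
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import damageqtl as dq
from damageqtl.gwas import MTA, build_qtl_windows, default_trait_prefix, \
    intersect_genes, significant_mtas, windows_to_bed, windows_to_table
from damageqtl.popgen import GenotypeMatrix
from damageqtl.simulate import FamilyDesign, PhenoSimSpec, TrialLayout, \
    simulate_f1_families, simulate_phenotypes


def _hw_matrix(rng, n, m, chrom_size=None):
    d = rng.binomial(2, 0.3, (n, m)).astype(float)
    chrom_size = chrom_size or m
    chrom = np.repeat(
        [str(c + 1) for c in range(int(np.ceil(m / chrom_size)))], chrom_size
    )[:m]
    pos = np.tile((np.arange(chrom_size) + 1) * 100, int(np.ceil(m / chrom_size)))[:m]
    return GenotypeMatrix(dosages=d, chrom=chrom, pos=pos,
                          ids=[f"i{k}" for k in range(n)])


class TestScan:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        g = _hw_matrix(rng, 200, 10_000, chrom_size=5000)
        y = rng.normal(size=200)
        scan = dq.scan_association(g, y)
        ks = stats.kstest(scan["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_planted_qtl_ranked_first(self):
        hits = 0
        n_sim = 100
        for s in range(n_sim):
            gm, _ = simulate_f1_families(
                FamilyDesign(family_sizes=(300,), n_snps=200, recomb_rate=0.5,
                             seed=50 + s)
            )
            prog = gm.take_individuals(range(2, gm.n_individuals))
            qtl = int(np.nanvar(prog.dosages, axis=0).argmax())
            # effect of half a phenotypic standard deviation
            spec = PhenoSimSpec(n_trials=1, var_g=0.5, var_e=0.5,
                                qtl_effects={qtl: 0.5}, seed=s)
            df, _ = simulate_phenotypes(prog, spec, TrialLayout(1, 1))
            y = df.set_index("genotype")["value"]
            scan = dq.scan_association(prog, y)
            if int(scan["p_value"].idxmin()) == qtl:
                hits += 1
        assert hits >= 0.9 * n_sim

    def test_permuted_phenotype_rarely_crosses_threshold(self):
        rng = np.random.default_rng(6)
        g = _hw_matrix(rng, 300, 10_000, chrom_size=5000)
        y = rng.normal(size=300)
        clean = 0
        for _ in range(20):
            scan = dq.scan_association(g, rng.permutation(y))
            if (-np.log10(scan["p_value"]) > 6).sum() == 0:
                clean += 1
        assert clean >= 19  # >= 95% of permutations

    def test_zero_variance_snp_gets_p_one(self, caplog):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.5, (50, 3)).astype(float)
        d[:, 1] = 2.0
        g = GenotypeMatrix(dosages=d, chrom=np.full(3, "1"), pos=[1, 2, 3],
                           ids=[f"i{k}" for k in range(50)])
        with caplog.at_level(logging.WARNING):
            scan = dq.scan_association(g, rng.normal(size=50))
        assert scan.loc[1, "p_value"] == 1.0
        assert scan.loc[1, "effect"] == 0.0
        assert "zero-variance" in caplog.text

    def test_misaligned_ids_rejected(self):
        rng = np.random.default_rng(8)
        g = _hw_matrix(rng, 10, 5)
        y = pd.Series(rng.normal(size=10), index=[f"other{k}" for k in range(10)])
        with pytest.raises(ValueError, match="missing"):
            dq.scan_association(g, y)

    def test_covariates_absorb_structure(self):
        gm, _ = simulate_f1_families(
            FamilyDesign(family_sizes=(150, 150), n_snps=400, seed=9)
        )
        prog = gm.take_individuals(range(3, gm.n_individuals))
        prog, _ = dq.filter_snps(prog, maf_min=0.05)
        rng = np.random.default_rng(9)
        fam_mean = np.array([0.0 if i.startswith("F1") else 1.5 for i in prog.ids])
        y = fam_mean + rng.normal(0, 1, prog.n_individuals)
        scores, _ = dq.pc_covariates(prog, 3)
        lam_plain = np.median(
            stats.chi2.isf(dq.scan_association(prog, y)["p_value"], 1)
        ) / stats.chi2.isf(0.5, 1)
        lam_pc = np.median(
            stats.chi2.isf(dq.scan_association(prog, y, covariates=scores)["p_value"], 1)
        ) / stats.chi2.isf(0.5, 1)
        # phenotypic family structure inflates the uncorrected scan; the PC
        # covariates absorb it (over-conservatively in a two-family design)
        assert lam_plain > 1.2
        assert lam_pc < lam_plain


class TestSignificanceFiltering:
    def _results(self, pvals):
        m = len(pvals)
        return pd.DataFrame(
            {
                "snp_id": [f"s{k}" for k in range(m)],
                "chrom": "1",
                "pos": (np.arange(m) + 1) * 1000,
                "effect": 0.1,
                "se": 0.01,
                "t": 1.0,
                "p_value": pvals,
                "maf": 0.3,
            }
        )

    def test_threshold_is_strict_on_log10(self):
        mtas, _ = significant_mtas(self._results([1e-7, 1e-5]), threshold_log10p=6)
        assert [m.snp_id for m in mtas] == ["s0"]

    def test_bh_adjustment_matches_direct_formula(self):
        _, out = significant_mtas(self._results([0.01, 0.02, 0.03, 0.5]))
        assert out["q_value"].tolist() == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_bh_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        _, out = significant_mtas(self._results(p))
        s = out.sort_values("p_value")["q_value"].to_numpy()
        assert (np.diff(s) >= -1e-12).all()

    def test_all_null_gives_empty_list(self):
        mtas, _ = significant_mtas(self._results([1.0, 1.0, 1.0]))
        assert mtas == []


def _mta(chrom, pos, trait="Total plant damage (DQU)"):
    return MTA(snp_id=f"s_{chrom}_{pos}", chrom=str(chrom), pos=pos,
               p_value=1e-8, effect=0.01, maf=0.3, trait=trait)


class TestQTLWindows:
    def test_windows_from_lead_positions(self):
        mtas = [_mta(7, 28_519_388), _mta(1, 11_524_270)]
        wins = build_qtl_windows(mtas, half_widths=(10_000,))[10_000]
        by_name = {w.name: w for w in wins}
        assert (by_name["qTPD7"].start, by_name["qTPD7"].end) == (
            28_509_388, 28_529_388)
        assert (by_name["qTPD1"].start, by_name["qTPD1"].end) == (
            11_514_270, 11_534_270)

    def test_window_width_before_clipping(self):
        for w in (2000, 5000, 10_000):
            wins = build_qtl_windows([_mta(3, 50_000)], half_widths=(w,))[w]
            assert wins[0].end - wins[0].start + 1 == 2 * w + 1

    def test_clipped_at_one(self):
        wins = build_qtl_windows([_mta(1, 500)], half_widths=(2000,))[2000]
        assert wins[0].start == 1 and wins[0].end == 2500

    def test_overlapping_windows_merge(self):
        mtas = [_mta(2, 100_000), _mta(2, 105_000)]
        wins = build_qtl_windows(mtas, half_widths=(10_000,))[10_000]
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end) == (90_000, 115_000)
        assert len(wins[0].mtas) == 2

    def test_merge_is_order_invariant_and_idempotent(self):
        mtas = [_mta(2, 100_000), _mta(2, 105_000), _mta(2, 300_000),
                _mta(5, 100_000)]
        ref = windows_to_table(build_qtl_windows(mtas, (10_000,))[10_000])
        for seed in range(5):
            shuffled = mtas[:]
            random.Random(seed).shuffle(shuffled)
            got = windows_to_table(build_qtl_windows(shuffled, (10_000,))[10_000])
            pd.testing.assert_frame_equal(ref, got)

    def test_ordinal_naming_per_prefix_and_chromosome(self):
        mtas = [
            _mta(12, 1_000_000),
            _mta(12, 2_000_000),
            _mta(12, 3_000_000, trait="Necrotic tissue (DTR)"),
            _mta(36, 500_000),
        ]
        wins = build_qtl_windows(mtas, half_widths=(10_000,))[10_000]
        names = sorted(w.name for w in wins)
        assert names == ["qNT12", "qTPD12-1", "qTPD12-2", "qTPD36"]

    def test_damage_prefix_takes_precedence_in_merged_window(self):
        mtas = [
            _mta(6, 100_000, trait="Necrotic tissue (DTR)"),
            _mta(6, 104_000, trait="Total plant damage (DQU)"),
        ]
        wins = build_qtl_windows(mtas, half_widths=(10_000,))[10_000]
        assert len(wins) == 1
        assert wins[0].name == "qTPD6"
        assert set(wins[0].traits) == {
            "Necrotic tissue (DTR)", "Total plant damage (DQU)"}

    def test_trait_prefix_rules(self):
        assert default_trait_prefix("Total plant damage (DQU)") == "qTPD"
        assert default_trait_prefix("Necrotic tissue (DTR)") == "qNT"
        assert default_trait_prefix("Insect survival (NTS)") == "qNTS"

    def test_bed_export_convention(self):
        wins = build_qtl_windows([_mta(1, 11_524_270)], (10_000,))[10_000]
        bed = windows_to_bed(wins)
        assert bed.loc[0, "start"] == 11_514_269
        assert bed.loc[0, "end"] == 11_534_270


class TestGeneIntersection:
    def _genes(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "start": [900, 2500, 1000],
                "end": [1100, 2600, 1200],
                "id": ["gA", "gB", "gC"],
            }
        )

    def test_abutting_gene_included(self):
        win = dq.QTLWindow(name="w", chrom="1", start=500, end=900)
        hits = intersect_genes([win], self._genes())
        assert hits["gene_id"].tolist() == ["gA"]

    def test_other_chromosome_excluded(self):
        win = dq.QTLWindow(name="w", chrom="1", start=950, end=1250)
        hits = intersect_genes([win], self._genes())
        assert "gC" not in hits["gene_id"].tolist()

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(4)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], 10),
                "start": rng.integers(1, 5000, 10),
                "id": [f"g{k}" for k in range(10)],
            }
        )
        genes["end"] = genes["start"] + rng.integers(50, 800, 10)
        wins = [
            dq.QTLWindow(name=f"w{k}", chrom=str(c), start=int(s), end=int(s) + 1000)
            for k, (c, s) in enumerate(
                zip(rng.choice(["1", "2"], 5), rng.integers(1, 5000, 5))
            )
        ]
        hits = intersect_genes(wins, genes)
        got = set(zip(hits["window"], hits["gene_id"]))
        want = {
            (w.name, r.id)
            for w in wins
            for r in genes.itertuples()
            if str(r.chrom) == w.chrom and r.start <= w.end and r.end >= w.start
        }
        assert got == want
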