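"""Species summaries, ANOVA/Bonferroni, subsampling, and the
divergence-vs-proteome-size correlation."""

import numpy as np
import pandas as pd
import pytest

from tpdiverge import (
    LocalizationCall,
    TPWindow,
    anova_bonferroni,
    compute_features,
    divergence_size_correlation,
    subsample_robustness,
    summarize_species,
    violin_table,
    welch_t,
)
from tpdiverge.synthetic import sample_protein_table, sample_species_summaries


def _call(pid, species, label):
    return LocalizationCall(pid, species, label, (pid,))


def _feat(pid, residues):
    return compute_features(TPWindow(pid, residues))


class TestSummarizeSpecies:
    def test_single_protein_mean(self):
        feats = [_feat("p1", "KRKR" + "A" * 16)]
        calls = [_call("p1", "spA", "mito")]
        out = summarize_species(feats, calls, {"spA": 10}, {"spA": "cladeX"})
        assert len(out) == 1
        row = out.iloc[0]
        assert row.mean_charge == 4.0 and row.n_proteins == 1
        assert row.proteome_size == 10 and row.clade == "cladeX"

    def test_two_protein_arithmetic_mean(self):
        feats = [_feat("p1", "KR" + "A" * 18), _feat("p2", "KRKR" + "A" * 16)]
        calls = [_call("p1", "spA", "mito"), _call("p2", "spA", "mito")]
        out = summarize_species(feats, calls, {"spA": 2}, {"spA": "c"})
        assert out.iloc[0].mean_charge == pytest.approx(3.0)

    def test_feature_without_call_rejected(self):
        with pytest.raises(ValueError):
            summarize_species([_feat("p1", "AAAA")], [], {}, {})

    def test_matches_generator_ground_truth(self, make_clade):
        ds = make_clade(mutation_rate=0.0)
        feats, calls = [], []
        for rec in ds.proteomes:
            feats.append(_feat(rec.protein_id, rec.sequence[:20]))
            calls.append(_call(rec.protein_id, rec.species,
                               ds.true_localization[rec.protein_id]))
        sizes = {sp: len(ds.proteins_of(sp)) for sp in ds.species}
        out = summarize_species(feats, calls, sizes, {s: "toy" for s in ds.species})
        for row in out.itertuples():
            want_c, want_p = ds.true_species_traits[row.species][row.organelle]
            assert row.mean_charge == pytest.approx(want_c)
            assert row.mean_phospho == pytest.approx(want_p)


class TestAnovaBonferroni:
    def _summaries(self, delta, seed=0, n_species=8, n=40):
        rng = np.random.default_rng(seed)
        return pd.concat(
            [
                sample_species_summaries("eud", n_species, n, delta, rng),
                sample_species_summaries("alg", n_species, n, 0.0, rng),
            ],
            ignore_index=True,
        )

    def test_identical_groups_flagged_degenerate(self):
        rows = []
        for clade in ("c1", "c2"):
            for sp in ("s1", "s2", "s3"):
                for org in ("mito", "plastid"):
                    rows.append({"species": f"{clade}_{sp}", "clade": clade,
                                 "organelle": org, "mean_charge": 1.0,
                                 "mean_phospho": 2.0})
        comp = anova_bonferroni(pd.DataFrame(rows), "charge")
        assert comp.degenerate and np.isnan(comp.anova_F)
        assert not comp.pairwise.significant.any()

    def test_planted_separation_detected(self):
        comp = anova_bonferroni(self._summaries(3.0), "charge")
        pw = comp.pairwise
        row = pw[(pw.group1 == "eud/mito") & (pw.group2 == "eud/plastid")]
        assert bool(row.significant.iloc[0])
        assert comp.anova_p < 0.01

    def test_adjustment_never_below_raw(self):
        comp = anova_bonferroni(self._summaries(1.0, seed=3), "phospho")
        assert (comp.pairwise.p_adj >= comp.pairwise.p_raw - 1e-15).all()
        assert (comp.pairwise.p_adj <= 1.0).all()
        assert comp.n_comparisons == len(comp.pairwise)

    def test_too_few_groups_rejected(self):
        df = pd.DataFrame(
            {"species": ["a", "b"], "clade": "c", "organelle": "mito",
             "mean_charge": [1.0, 2.0], "mean_phospho": [0.0, 1.0]}
        )
        with pytest.raises(ValueError):
            anova_bonferroni(df, "charge")

    def test_violin_table_quantiles(self):
        s = self._summaries(2.0, seed=9)
        table = violin_table(s, "charge")
        row = table[(table.clade == "eud") & (table.organelle == "mito")].iloc[0]
        vals = s[(s.clade == "eud") & (s.organelle == "mito")].mean_charge
        assert row["median"] == pytest.approx(vals.median())
        assert row.q25 <= row["median"] <= row.q75
        assert row.low == vals.min() and row.high == vals.max()


class TestSubsampleRobustness:
    COMPS = [(("eud", "plastid"), ("eud", "mito"))]

    def _table(self, seed=1, n=30):
        rng = np.random.default_rng(seed)
        return pd.concat(
            [sample_protein_table("eud", 6, n, 3.0, rng),
             sample_protein_table("alg", 6, n, 0.0, rng)],
            ignore_index=True,
        )

    def test_zero_reps_empty(self):
        out = subsample_robustness(self._table(), self.COMPS, reps=0)
        assert out.empty and "significant" in out.columns

    def test_full_subsample_equals_direct_welch(self):
        table = self._table()
        out = subsample_robustness(
            table, self.COMPS, n_range=(30, 30), N_range=(6, 6), reps=1, seed=4
        )
        means = table.groupby(["species", "clade", "organelle"],
                              as_index=False).agg(
            mean_charge=("net_charge", "mean"),
            mean_phospho=("phospho_count", "mean"))
        v1 = means[(means.clade == "eud") & (means.organelle == "plastid")]
        v2 = means[(means.clade == "eud") & (means.organelle == "mito")]
        for trait, col in (("charge", "mean_charge"), ("phospho", "mean_phospho")):
            t_direct, p_direct = welch_t(v1[col], v2[col])
            row = out[out.trait == trait].iloc[0]
            assert row.t == pytest.approx(t_direct)
            assert row.p_raw == pytest.approx(p_direct)

    def test_deterministic_under_seed(self):
        table = self._table()
        a = subsample_robustness(table, self.COMPS, (10, 20), (4, 5), 5, seed=11)
        b = subsample_robustness(table, self.COMPS, (10, 20), (4, 5), 5, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_robustness(self._table(), self.COMPS,
                                 n_range=(500, 500), N_range=(6, 6), reps=1)
        with pytest.raises(ValueError):
            subsample_robustness(self._table(), self.COMPS,
                                 n_range=(10, 10), N_range=(20, 20), reps=1)


class TestDivergenceSizeCorrelation:
    def _summaries_from_divergence(self, div, sizes):
        rows = []
        for i, (d, size) in enumerate(zip(div, sizes)):
            sp = f"sp{i:02d}"
            rows.append({"species": sp, "clade": "c", "organelle": "mito",
                         "mean_charge": d, "mean_phospho": 1.0,
                         "n_proteins": 5, "proteome_size": size})
            rows.append({"species": sp, "clade": "c", "organelle": "plastid",
                         "mean_charge": 0.0, "mean_phospho": 1.0 + d,
                         "n_proteins": 5, "proteome_size": size})
        return pd.DataFrame(rows)

    def test_perfect_monotone_relation(self):
        sizes = [1000, 2000, 3000, 4000, 5000]
        div = [0.5, 1.0, 1.5, 2.0, 2.5]
        out = divergence_size_correlation(self._summaries_from_divergence(div, sizes))
        assert np.allclose(out.spearman_rho, 1.0)

    def test_constant_divergence_flagged(self):
        out = divergence_size_correlation(
            self._summaries_from_divergence([1.0] * 5, [10, 20, 30, 40, 50])
        )
        assert out.constant.all()
        assert (out.spearman_rho == 0.0).all()

    def test_noisy_positive_slope_detected(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(600 + rep)
            sizes = rng.integers(1000, 20000, size=30)
            div = 0.5 + 1e-4 * sizes + rng.normal(0, 0.3, size=30)
            out = divergence_size_correlation(
                self._summaries_from_divergence(div, sizes)
            )
            charge = out[out.trait == "charge"].iloc[0]
            hits += (charge.spearman_rho > 0) and (charge.spearman_p < 0.05)
        assert hits / 30 >= 0.9

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            divergence_size_correlation(
                self._summaries_from_divergence([1.0, 2.0], [10, 20])
            )
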