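"""Background-binned scoring, meta-signatures, assignment, state contrasts."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import crcprograms as c
from crcprograms.scoring import UNASSIGNED, expression_bins


def _expr(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(X.shape[1])]
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i:04d}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=genes),
    )


class TestScoreCells:
    def test_constant_matrix_corrected_exactly_zero(self):
        e = _expr(np.full((20, 100), 3.0))
        sig = c.Signature(name="s", genes=[f"g{i:03d}" for i in range(10)])
        out = c.score_cells(e, sig, seed=0)
        assert (out["corrected"] == 0.0).all()

    def test_random_signature_centers_at_zero(self):
        # Signature sampled from one expression bin of homogeneous cells:
        # corrected scores centered at 0 (|mean| < 0.05 at 1000 cells).
        rng = np.random.default_rng(0)
        X = rng.normal(4.0, 1.0, size=(1000, 500)).clip(0)
        e = _expr(X)
        bins = expression_bins(e, n_bins=25)
        pool = bins.index[bins == 13]
        sig = c.Signature(name="null", genes=list(rng.choice(pool, 15, replace=False)))
        out = c.score_cells(e, sig, seed=1)
        assert abs(out["corrected"].mean()) < 0.05

    def test_planted_shift_separates_cells(self):
        # +2 log2 in a planted subset: corrected score separates the subset
        # with AUROC >= 0.9.
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        X = rng.normal(4.0, 1.0, size=(400, 300)).clip(0)
        members = [f"g{i:03d}" for i in range(30)]
        X[:100, :30] += 2.0
        e = _expr(X)
        sig = c.Signature(name="prog", genes=members)
        out = c.score_cells(e, sig, seed=3)
        y = np.zeros(400)
        y[:100] = 1
        assert roc_auc_score(y, out["corrected"]) >= 0.9

    def test_bin_wide_constant_shift_cancels(self):
        # Adding a constant to every gene of a bin leaves corrected scores
        # unchanged when the bin structure is held fixed.
        rng = np.random.default_rng(4)
        X = rng.normal(4.0, 1.0, size=(50, 200)).clip(0)
        e = _expr(X)
        bins = expression_bins(e, n_bins=10)
        sig = c.Signature(name="s", genes=list(bins.index[bins == 5][:10]))
        base = c.score_cells(e, sig, seed=5, gene_bins=bins)
        shifted = X.copy()
        shifted[:, (bins == 5).to_numpy()] += 1.7
        out = c.score_cells(_expr(shifted), sig, seed=5, gene_bins=bins)
        assert np.allclose(base["corrected"], out["corrected"], atol=1e-10)

    def test_absent_signature_rejected(self):
        e = _expr(np.ones((5, 20)))
        with pytest.raises(ValueError, match="no gene"):
            c.score_cells(e, c.Signature(name="x", genes=["nope1", "nope2"]), seed=0)
        mixed = c.Signature(name="y", genes=["g000", "a", "b", "d"])
        with pytest.raises(ValueError, match="<50%"):
            c.score_cells(e, mixed, seed=0)


class TestMetaSignatures:
    def _scores(self, cols):
        raw = pd.DataFrame(cols)
        return c.CellScoreTable(raw=raw, corrected=raw)

    def test_duplicate_signature_merged(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=200)
        scores = self._scores({"a": v, "b": v.copy(), "c": rng.normal(size=200)})
        sigs = [c.Signature(name=n, genes=[f"{n}{i}" for i in range(5)]) for n in "abc"]
        metas = c.combine_meta_signatures(scores, sigs, r_threshold=0.6)
        names = {m.name for m in metas}
        assert "a+b" in names and len(metas) == 2

    def test_anticorrelated_never_merged(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=300)
        scores = self._scores({"a": v, "b": -v})
        sigs = [c.Signature(name=n, genes=[f"{n}{i}" for i in range(5)]) for n in "ab"]
        metas = c.combine_meta_signatures(scores, sigs, r_threshold=0.6)
        assert len(metas) == 2

    def test_coupled_state_programs_merge_depends_on_threshold(self):
        # Cell-cycle and OXPHOS co-activated almost exclusively in TA
        # cells: their corrected score vectors correlate at r ~ 0.8
        # (measured over seeds), so they merge at the default r = 0.6 cut
        # but stay distinct at a strict r = 0.95 cut.
        cfg = c.default_spheroid_config(
            seed=21, n_patients=2, cells_per_patient=250, n_genes=800, program_size=40
        )
        cfg.state_coupling = {
            t: {"cell_cycle": 0.95 if t == "TA" else 0.02,
                "OXPHOS": 0.95 if t == "TA" else 0.02,
                "hypoxia_glycolysis": 0.05}
            for t in c.simulate.CELL_TYPES
        }
        counts, truth = c.generate_spheroid_cohort(cfg)
        e = c.normalize_cpm_log(counts)
        sigs = [
            c.Signature(name=p, genes=truth.members(p))
            for p in ("cell_cycle", "OXPHOS", "hypoxia_glycolysis")
        ]
        table = c.score_table(e, sigs, seed=2)
        loose = c.combine_meta_signatures(table, sigs, r_threshold=0.6)
        strict = c.combine_meta_signatures(table, sigs, r_threshold=0.95)
        assert any(set(m.members) >= {"cell_cycle", "OXPHOS"} for m in loose)
        assert all(len(m.members) == 1 for m in strict)

    def test_union_gene_list_ordered_by_best_rank(self):
        scores = self._scores({"a": np.arange(10.0), "b": np.arange(10.0)})
        sigs = [
            c.Signature(name="a", genes=["x", "y", "z"]),
            c.Signature(name="b", genes=["w", "y", "q"]),
        ]
        (meta,) = c.combine_meta_signatures(scores, sigs, r_threshold=0.6)
        assert set(meta.genes) == {"x", "y", "z", "w", "q"}
        assert meta.genes.index("y") < meta.genes.index("z")


class TestAssignCellTypes:
    def test_population_sd_hand_example(self):
        scores = pd.DataFrame({"s1": [0.0, 0.0, 0.0, 0.0, 10.0]})
        out = c.assign_cell_types(scores)
        # mean 2, population SD 4 -> threshold 6: only the 10-score cell.
        assert out.thresholds["s1"] == pytest.approx(6.0)
        assert out.active["s1"].tolist() == [False] * 4 + [True]
        assert out.assigned.tolist() == [UNASSIGNED] * 4 + ["s1"]

    def test_constant_scores_all_unassigned(self):
        scores = pd.DataFrame({"s1": [2.0] * 6, "s2": [3.0] * 6})
        out = c.assign_cell_types(scores)
        assert (out.assigned == UNASSIGNED).all()

    def test_assigned_type_is_among_active(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        out = c.assign_cell_types(scores)
        for cell in scores.index:
            lab = out.assigned[cell]
            if lab != UNASSIGNED:
                assert out.active.loc[cell, lab]


class TestCompareStates:
    def test_identical_groups_p_one(self):
        assigned = pd.Series(["A"] * 3 + ["B"] * 3, index=[f"c{i}" for i in range(6)])
        scores = pd.DataFrame({"s": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, index=assigned.index)
        out = c.compare_states_across_types(assigned, scores)
        assert out.loc[0, "p_value"] == pytest.approx(1.0, abs=0.05)

    def test_exact_small_sample_p(self):
        # (1,2,3) vs (4,5,6): U = 0, exact two-tailed p = 2/20 = 0.1.
        assigned = pd.Series(["A"] * 3 + ["B"] * 3, index=[f"c{i}" for i in range(6)])
        scores = pd.DataFrame({"s": [1.0, 2, 3, 4, 5, 6]}, index=assigned.index)
        out = c.compare_states_across_types(assigned, scores)
        assert out.loc[0, "U"] == 0.0
        assert out.loc[0, "p_value"] == pytest.approx(0.1)
        assert out.loc[0, "median_a"] == 2.0 and out.loc[0, "median_b"] == 5.0

    def test_empty_group_rejected(self):
        assigned = pd.Series(["A", "A", "B"], index=["c0", "c1", "c2"])
        scores = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=assigned.index)
        with pytest.raises(ValueError, match="cells"):
            c.compare_states_across_types(assigned, scores)

    def test_planted_metabolic_contrast_detected(self):
        # OXPHOS-high TA vs glycolysis-high Tdiff at >= 100 cells/group:
        # p < 0.01 in nearly all replicates.
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            ox = np.concatenate([rng.normal(1.0, 1.0, 120), rng.normal(0.0, 1.0, 120)])
            assigned = pd.Series(
                ["TA"] * 120 + ["Tdiff"] * 120, index=[f"c{i}" for i in range(240)]
            )
            scores = pd.DataFrame({"OXPHOS": ox}, index=assigned.index)
            out = c.compare_states_across_types(assigned, scores)
            hits += out.loc[0, "p_value"] < 0.01
        assert hits >= 9
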