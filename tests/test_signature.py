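"""Signature derivation and scoring: co-culture contrast, FDR/FC ranking,
the rank-weighted running-sum score, and local-max-AUC size selection."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgfbsig import diffexp as de
from tgfbsig import evaluate as ev
from tgfbsig import signature as sg
from tgfbsig import synthdata as sd

from oracles import ssgsea_naive

RAW = sg.SsgseaParams(normalize_across_samples=False)


def quiet_ssgsea(expr, genes, params=RAW):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sg.ssgsea(expr, genes, params)


class TestContrast:
    def test_weights(self):
        c = sg.coculture_contrast()
        assert c["cocult_tgfb"] == 1.0
        assert c.sum() == pytest.approx(0.0)
        assert (c.drop("cocult_tgfb") == -0.2).all()

    def test_missing_condition_named(self):
        with pytest.raises(ValueError, match="stroma_vehicle"):
            sg.coculture_contrast(["cocult_tgfb", "cocult_vehicle"])

    def test_flat_gene_zero_planted_gene_recovered(self):
        cfg = sd.CoCultureConfig(n_genes=100, n_planted=4, planted_log2fc=2.0, seed=3)
        expr, cond, truth = sd.simulate_coculture(cfg)
        design = de.cell_means_design(cond)
        fit = de.fit_linear_contrast(expr, design, sg.coculture_contrast(design.columns))
        planted = list(truth.gene_effects)
        assert fit.table.loc[planted, "log2fc"].mean() == pytest.approx(2.0, abs=0.4)
        flat = pd.DataFrame(np.full((1, len(cond)), 7.0), index=["F"], columns=cond.index)
        flat_fit = de.fit_linear_contrast(flat, design, sg.coculture_contrast(design.columns))
        assert flat_fit.table.loc["F", "log2fc"] == pytest.approx(0.0)


class TestRankCandidates:
    def test_filter_and_order(self):
        tab = pd.DataFrame(
            {"log2fc": [3.0, 5.0, 2.0], "p_adj": [0.01, 0.2, 0.05],
             "p": [0.001, 0.05, 0.01], "t": 1.0, "df": 4.0, "s2": 1.0},
            index=["A", "B", "C"],
        )
        cand = sg.rank_candidates(de.DEResult(table=tab, contrast_variance=1.0))
        assert cand.genes == ["A", "C"]  # B fails the FDR filter

    def test_all_filtered_gives_empty(self):
        tab = pd.DataFrame(
            {"log2fc": [3.0], "p_adj": [0.5], "p": [0.2], "t": 1.0, "df": 4.0, "s2": 1.0},
            index=["A"],
        )
        assert sg.rank_candidates(de.DEResult(table=tab, contrast_variance=1.0)).genes == []

    def test_fc_ties_broken_by_gene_id(self):
        tab = pd.DataFrame(
            {"log2fc": [2.0, 2.0, 2.5], "p_adj": [0.01] * 3,
             "p": [0.001] * 3, "t": 1.0, "df": 4.0, "s2": 1.0},
            index=["ZZZ", "AAA", "MMM"],
        )
        cand = sg.rank_candidates(de.DEResult(table=tab, contrast_variance=1.0))
        assert cand.genes == ["MMM", "AAA", "ZZZ"]

    def test_planted_genes_top_ranked(self):
        hits = 0
        for seed in range(10):
            cfg = sd.CoCultureConfig(n_genes=200, n_planted=6, planted_log2fc=2.0, seed=seed)
            expr, cond, truth = sd.simulate_coculture(cfg)
            design = de.cell_means_design(cond)
            fit = de.moderate(
                de.fit_linear_contrast(expr, design, sg.coculture_contrast(design.columns))
            )
            cand = sg.rank_candidates(fit, fdr_threshold=0.1)
            if set(cand.genes[:6]) == set(truth.gene_effects):
                hits += 1
        assert hits >= 9


class TestSsgsea:
    def test_singleton_hand_values(self):
        expr = pd.DataFrame({"s": [3.0, 2.0, 1.0]}, index=["A", "B", "C"])
        for tau in (0.0, 0.25, 1.0):
            p = sg.SsgseaParams(tau=tau, normalize_across_samples=False)
            assert quiet_ssgsea(expr, ["A"], p).scores["s"] == pytest.approx(1.5)
            assert quiet_ssgsea(expr, ["C"], p).scores["s"] == pytest.approx(-1.5)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i:03d}" for i in range(50)]
        for rep in range(5):
            expr = pd.DataFrame(
                rng.normal(size=(50, 10)), index=genes,
                columns=[f"s{j}" for j in range(10)],
            )
            gene_set = list(rng.choice(genes, 5, replace=False))
            scores = quiet_ssgsea(expr, gene_set).scores
            for s in expr.columns:
                ref = ssgsea_naive(
                    expr[s].to_numpy(), np.array(genes, dtype=object),
                    set(gene_set), 0.25,
                )
                assert scores[s] == pytest.approx(ref, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(30, 4)),
                            index=[f"G{i}" for i in range(30)])
        gene_set = [f"G{i}" for i in range(4)]
        a = quiet_ssgsea(expr, gene_set).scores
        b = quiet_ssgsea(np.exp(expr / 3.0) + 5.0, gene_set).scores
        assert np.allclose(a, b)

    def test_tau_zero_complement_antisymmetry(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(20, 3)),
                            index=[f"G{i}" for i in range(20)])
        gset = [f"G{i}" for i in range(7)]
        comp = [g for g in expr.index if g not in gset]
        p0 = sg.SsgseaParams(tau=0.0, normalize_across_samples=False)
        a = quiet_ssgsea(expr, gset, p0).scores
        b = quiet_ssgsea(expr, comp, p0).scores
        assert np.allclose(a, -b)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=12),
        k=st.integers(min_value=1, max_value=11),
        seed=st.integers(min_value=0, max_value=10_000),
        tau=st.sampled_from([0.0, 0.25, 1.0]),
    )
    def test_score_bounded_by_n_minus_one(self, n, k, seed, tau):
        k = min(k, n - 1)
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(rng.normal(size=(n, 2)), index=[f"G{i}" for i in range(n)])
        p = sg.SsgseaParams(tau=tau, normalize_across_samples=False)
        scores = quiet_ssgsea(expr, [f"G{i}" for i in range(k)], p).scores
        assert (scores.abs() <= n - 1 + 1e-9).all()

    def test_gene_set_errors(self):
        expr = pd.DataFrame(np.eye(3), index=["A", "B", "C"])
        with pytest.raises(ValueError, match="strict subset"):
            quiet_ssgsea(expr, ["A", "B", "C"])
        with pytest.raises(ValueError, match="absent"):
            quiet_ssgsea(expr, ["A", "NOPE"])
        with pytest.warns(UserWarning, match="dropping"):
            sg.ssgsea(expr, ["A", "NOPE"],
                      sg.SsgseaParams(normalize_across_samples=False, allow_missing=True))

    def test_cohort_normalization_rescales_by_range(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(30, 6)),
                            index=[f"G{i}" for i in range(30)])
        gset = [f"G{i}" for i in range(5)]
        raw = quiet_ssgsea(expr, gset).scores
        norm = sg.ssgsea(expr, gset, sg.SsgseaParams()).scores
        assert np.allclose(norm, raw / (raw.max() - raw.min()))


class TestSelectSignature:
    @staticmethod
    def _candidates(genes):
        tab = pd.DataFrame(
            {"log2fc": np.linspace(5, 1, len(genes)), "p_adj": 0.01},
            index=genes,
        )
        return sg.RankedCandidates(table=tab, fdr_threshold=0.1)

    def test_local_max_definition(self, monkeypatch):
        trace = {3: 0.70, 4: 0.85, 5: 0.80, 6: 0.90}
        genes = [f"G{i}" for i in range(6)]
        cand = self._candidates(genes)
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 8)),
                            index=[f"G{i}" for i in range(10)])
        scores = iter(trace)

        def fake_auc(s, labels, positive_label):
            return ev.RocResult(trace[next(scores)], (0.0, 1.0), (0.0, 1.0), positive_label)

        monkeypatch.setattr(sg, "roc_auc", fake_auc)
        sig = sg.select_signature(cand, expr, ["BCR"] * 4 + ["NED"] * 4, n_max=6)
        assert sig.n == 4 and sig.genes == tuple(genes[:4])

    def test_monotone_trace_returns_n_max_with_warning(self, monkeypatch):
        trace = {3: 0.6, 4: 0.7, 5: 0.8}
        genes = [f"G{i}" for i in range(5)]
        cand = self._candidates(genes)
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 8)),
                            index=[f"G{i}" for i in range(10)])
        scores = iter(trace)
        monkeypatch.setattr(
            sg, "roc_auc",
            lambda s, l, positive_label: ev.RocResult(
                trace[next(scores)], (0.0,), (0.0,), positive_label),
        )
        with pytest.warns(UserWarning, match="still increasing"):
            sig = sg.select_signature(cand, expr, ["BCR"] * 4 + ["NED"] * 4, n_max=5)
        assert sig.n == 5

    def test_errors(self):
        cand = self._candidates(["A", "B"])
        expr = pd.DataFrame(np.eye(4), index=["A", "B", "C", "D"])
        with pytest.raises(ValueError, match="n_start"):
            sg.select_signature(cand, expr, ["BCR", "NED", "BCR", "NED"])
        cand3 = self._candidates(["A", "B", "C"])
        with pytest.raises(ValueError, match="classes"):
            sg.select_signature(cand3, expr, ["BCR"] * 4)

    def test_locked_signature_is_immutable(self):
        sig = sg.GeneSignature(genes=("A", "B", "C"), n=3, tau=0.25)
        with pytest.raises(dataclasses.FrozenInstanceError):
            sig.n = 4
        with pytest.raises(TypeError):
            sig.genes[0] = "Z"

    def test_recovers_planted_signature_end_to_end(self):
        hits = 0
        for seed in range(10):
            cc = sd.CoCultureConfig(n_genes=200, n_planted=6, planted_log2fc=2.0, seed=seed)
            expr_cc, cond, truth = sd.simulate_coculture(cc)
            design = de.cell_means_design(cond)
            fit = de.moderate(
                de.fit_linear_contrast(expr_cc, design, sg.coculture_contrast(design.columns))
            )
            cand = sg.rank_candidates(fit, fdr_threshold=0.1)
            cohort = sd.CohortConfig(
                n_genes=200, signature_genes=tuple(sorted(truth.gene_effects)),
                signature_effect=1.0, seed=seed + 100,
            )
            expr_co, ann, _ = sd.simulate_cohort(cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = sg.select_signature(cand, expr_co, list(ann["outcome"]))
            spurious = set(sig.genes) - set(truth.gene_effects)
            if len(spurious) <= 1:
                hits += 1
        assert hits >= 8

    def test_null_cohort_selection_auc_documents_optimism(self):
        aucs = []
        for seed in range(10):
            cc = sd.CoCultureConfig(n_genes=200, n_planted=6, planted_log2fc=2.0, seed=seed)
            expr_cc, cond, truth = sd.simulate_coculture(cc)
            design = de.cell_means_design(cond)
            fit = de.moderate(
                de.fit_linear_contrast(expr_cc, design, sg.coculture_contrast(design.columns))
            )
            cand = sg.rank_candidates(fit, fdr_threshold=0.1)
            cohort = sd.CohortConfig(
                n_genes=200, signature_genes=tuple(sorted(truth.gene_effects)),
                signature_effect=0.0, seed=seed + 200,
            )
            expr_co, ann, _ = sd.simulate_cohort(cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = sg.select_signature(cand, expr_co, list(ann["outcome"]))
            aucs.append(sig.provenance["discovery_auc"])
        assert 0.45 <= float(np.median(aucs)) <= 0.65
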