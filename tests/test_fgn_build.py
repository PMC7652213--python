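import numpy as np
import pandas as pd
import pytest

from netnc.fgn_build import (
    EvidencePairTable,
    OntologyDag,
    balance_training,
    bin_posteriors,
    deepest_coannotation,
    emit_network,
    fit_integration,
    fit_logistic,
    read_evidence_table,
    select_threshold,
)


def toy_dag():
    """Six-term DAG: a process branch and a component branch of equal depth.

        root_p              root_c        (depth 0)
          |                   |
        mid_p               mid_c         (depth 1)
          |                   |
        leaf_p              leaf_c        (depth 2)
    """
    dag = OntologyDag()
    dag.add_term("root_p", "process")
    dag.add_term("mid_p", "process", ["root_p"])
    dag.add_term("leaf_p", "process", ["mid_p"])
    dag.add_term("root_c", "component")
    dag.add_term("mid_c", "component", ["root_c"])
    dag.add_term("leaf_c", "component", ["mid_c"])
    return dag


class TestOntology:
    def test_shared_leaf_term(self):
        dag = toy_dag()
        dag.annotate("g1", "leaf_p")
        dag.annotate("g2", "leaf_p")
        assert deepest_coannotation(dag, "g1", "g2") == ("leaf_p", 2)

    def test_shared_root_only(self):
        dag = toy_dag()
        dag.annotate("g1", "mid_p")
        dag.annotate("g2", "root_p")
        # closure of g2 is just the root; intersection depth 0
        assert deepest_coannotation(dag, "g1", "g2") == ("root_p", 0)

    def test_process_precedence_on_depth_tie(self):
        dag = toy_dag()
        for g in ("g1", "g2"):
            dag.annotate(g, "leaf_p")
            dag.annotate(g, "leaf_c")
        term, depth = deepest_coannotation(dag, "g1", "g2")
        assert term == "leaf_p" and depth == 2

    def test_no_shared_term_returns_none(self):
        dag = toy_dag()
        dag.annotate("g1", "leaf_p")
        dag.annotate("g2", "leaf_c")
        assert deepest_coannotation(dag, "g1", "g2") is None

    def test_annotation_closure_reaches_ancestors(self):
        dag = toy_dag()
        dag.annotate("g1", "leaf_p")
        assert dag.gene_terms("g1") == {"leaf_p", "mid_p", "root_p"}

    def test_obo_round_trip(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: T:1\nname: root\nnamespace: biological_process\n\n"
            "[Term]\nid: T:2\nname: kid\nnamespace: biological_process\n"
            "is_a: T:1 ! root\n\n"
            "[Term]\nid: T:3\nname: cc\nnamespace: cellular_component\n"
        )
        dag = OntologyDag.from_obo(obo)
        assert dag.depth("T:2") == 1
        assert dag.namespace["T:3"] == "component"

    def test_cycle_detected(self):
        dag = OntologyDag()
        dag.add_term("a", "process", ["b"])
        dag.add_term("b", "process", ["a"])
        with pytest.raises(ValueError, match="cycle"):
            dag._check_acyclic()


def simulated_table(n, rng, beta=(-4.0, 4.0, 3.5)):
    """Pairs whose positive probability is logistic in two latent scores."""
    s1 = rng.random(n)
    s2 = rng.random(n)
    eta = beta[0] + beta[1] * s1 + beta[2] * s2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    frame = pd.DataFrame({
        "gene_a": [f"a{i}" for i in range(n)],
        "gene_b": [f"b{i}" for i in range(n)],
        "go": s1,
        "string": s2,
        "label": y,
    })
    return EvidencePairTable(frame=frame, sources=["go", "string"])


class TestBinPosteriors:
    def test_recovers_identity_generative_model(self, rng):
        # P(pos | score) = score: posteriors should track the bin midpoints
        n = 4000
        s = rng.random(n)
        y = (rng.random(n) < s).astype(float)
        frame = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(n)],
            "gene_b": [f"b{i}" for i in range(n)],
            "src": s,
            "label": y,
        })
        table = EvidencePairTable(frame=frame, sources=["src"])
        bp = bin_posteriors(table, "src", n_bins=10)
        mids = (bp.edges[:-1] + bp.edges[1:]) / 2
        # binomial CI at ~400 per bin is about +-0.075 at 3 sigma
        assert np.all(np.abs(bp.posterior - mids) < 0.1)

    def test_posterior_monotone_for_monotone_signal(self, rng):
        table = simulated_table(4000, rng)
        bp = bin_posteriors(table, "go", n_bins=8)
        diffs = np.diff(bp.posterior)
        assert (diffs >= -0.05).all()  # monotone up to binomial noise

    def test_no_labels_errors(self):
        frame = pd.DataFrame({
            "gene_a": ["a"], "gene_b": ["b"], "src": [0.5],
            "label": [np.nan],
        })
        with pytest.raises(ValueError):
            bin_posteriors(
                EvidencePairTable(frame=frame, sources=["src"]), "src"
            )

    def test_missing_score_gets_prior(self, rng):
        table = simulated_table(500, rng)
        bp = bin_posteriors(table, "go")
        assert bp.lookup(float("nan")) == bp.prior


class TestBalanceTraining:
    def test_downsamples_negatives(self, rng):
        table = simulated_table(2000, rng, beta=(-2.5, 2.0, 1.0))
        bal = balance_training(table, rng)
        lab = bal.labelled()
        assert (lab["label"] == 1).sum() == (lab["label"] == 0).sum()

    def test_already_balanced_unchanged_in_size(self, rng):
        frame = pd.DataFrame({
            "gene_a": list("abcd"),
            "gene_b": list("wxyz"),
            "src": [0.1, 0.9, 0.2, 0.8],
            "label": [0.0, 1.0, 0.0, 1.0],
        })
        table = EvidencePairTable(frame=frame, sources=["src"])
        assert len(balance_training(table, rng).frame) == 4

    def test_deterministic_given_seed(self, rng):
        table = simulated_table(1000, rng)
        a = balance_training(table, np.random.default_rng(7)).frame
        b = balance_training(table, np.random.default_rng(7)).frame
        pd.testing.assert_frame_equal(a, b)

    def test_fewer_negatives_than_positives_errors(self, rng):
        frame = pd.DataFrame({
            "gene_a": list("abc"), "gene_b": list("xyz"),
            "src": [0.5] * 3, "label": [1.0, 1.0, 0.0],
        })
        with pytest.raises(ValueError):
            balance_training(
                EvidencePairTable(frame=frame, sources=["src"]), rng
            )


class TestLogisticIntegration:
    def test_coefficient_recovery_on_simulated_data(self):
        rng = np.random.default_rng(2024)
        beta = (-3.0, 3.0, 2.0)
        n = 5000
        x = rng.random((n, 2))
        eta = beta[0] + x @ np.array(beta[1:])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        params, bse, ridge = fit_logistic(x, y)
        assert not ridge
        for est, se, true in zip(params, bse, beta):
            assert abs(est - true) < 2 * se + 1e-9

    def test_probability_monotone_in_each_posterior(self, rng):
        table = simulated_table(3000, rng)
        bal = balance_training(table, rng)
        model = fit_integration(bal)
        assert all(c > 0 for c in model.coefficients.values())

    def test_separation_falls_back_to_ridge(self, rng):
        n = 200
        s = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        frame = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(n)],
            "gene_b": [f"b{i}" for i in range(n)],
            "src": s,
            "label": s.astype(float),
        })
        table = EvidencePairTable(frame=frame, sources=["src"])
        model = fit_integration(table, n_bins=2)
        assert model.ridge_fallback
        probs = model.pair_probability(table.frame)
        assert probs[s == 1].min() > probs[s == 0].max()

    def test_intercept_only_on_constant_evidence(self, rng):
        n = 400
        frame = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(n)],
            "gene_b": [f"b{i}" for i in range(n)],
            "src": np.zeros(n),
            "label": (rng.random(n) < 0.3).astype(float),
        })
        table = EvidencePairTable(frame=frame, sources=["src"])
        model = fit_integration(table, n_bins=4)
        probs = model.pair_probability(table.frame)
        prior = frame["label"].mean()
        assert np.allclose(probs, probs[0])
        assert probs[0] == pytest.approx(prior, abs=0.1)


class TestSelectThreshold:
    def test_perfectly_separated(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        t, metrics = select_threshold(scores, labels)
        assert 0.2 < t <= 0.8
        assert metrics["f_measure"] == 1.0

    def test_noisy_scores_threshold_near_half(self, rng):
        n = 4000
        y = (rng.random(n) < 0.5).astype(float)
        scores = y + rng.normal(0, 0.35, n)
        t, metrics = select_threshold(scores, y)
        assert 0.25 < t < 0.75
        assert metrics["f_measure"] > 0.8

    def test_tie_prefers_higher_threshold(self):
        # two thresholds reach F=1; the higher one must win
        scores = np.array([0.1, 0.5, 0.9])
        labels = np.array([0, 1, 1])
        t, _ = select_threshold(scores, labels)
        assert t == 0.5

    def test_degenerate_constant_scores(self):
        t, metrics = select_threshold(
            np.array([0.4, 0.4, 0.4]), np.array([0, 1, 1])
        )
        assert t == 0.4

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestEmitNetwork:
    def test_thresholded_emission_matches_filter(self, rng):
        table = simulated_table(2000, rng)
        bal = balance_training(table, rng)
        model = fit_integration(bal)
        probs = model.pair_probability(table.frame)
        model.threshold = 0.7
        net = emit_network(table, model)
        expected = int((probs >= 0.7).sum())
        assert net.n_edges == expected

    def test_impossible_threshold_gives_empty_network(self, rng):
        table = simulated_table(500, rng)
        bal = balance_training(table, rng)
        model = fit_integration(bal)
        model.threshold = 1.0 + 1e-9
        assert emit_network(table, model).n_edges == 0

    def test_unthresholded_model_errors(self, rng):
        table = simulated_table(300, rng)
        model = fit_integration(balance_training(table, rng))
        with pytest.raises(ValueError):
            emit_network(table, model)

    def test_end_to_end_precision_beats_baseline(self, rng):
        # thresholding should enrich for positives over the raw pair list
        table = simulated_table(3000, rng)
        bal = balance_training(table, rng)
        model = fit_integration(bal)
        lab = table.labelled()
        probs = model.pair_probability(lab)
        model.threshold, _ = select_threshold(probs, lab["label"].to_numpy())
        keep = probs >= model.threshold
        precision = lab["label"][keep].mean()
        assert precision > lab["label"].mean()


class TestEvidenceIo:
    def test_read_round_trip(self, tmp_path):
        f = tmp_path / "ev.tsv"
        f.write_text(
            "gene_a\tgene_b\tgo\tstring\tlabel\n"
            "g1\tg2\t0.5\t0.7\tpositive\n"
            "g3\tg4\t0.1\t\tnegative\n"
            "g5\tg6\t0.9\t0.2\t\n"
        )
        table = read_evidence_table(f)
        assert table.sources == ["go", "string"]
        assert len(table.labelled()) == 2
        assert np.isnan(table.frame["string"].iloc[1])

    def test_duplicate_unordered_pairs_dropped(self):
        frame = pd.DataFrame({
            "gene_a": ["b", "a"], "gene_b": ["a", "b"],
            "src": [0.5, 0.6], "label": [1.0, 0.0],
        })
        table = EvidencePairTable(frame=frame, sources=["src"])
        assert len(table.frame) == 1
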