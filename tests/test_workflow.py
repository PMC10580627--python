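"""Workflow orchestration: scoring runs, summaries, fact-checking,
selection/extraction, data-informed revision, graph export, reports."""

import json

import networkx as nx
import pytest

from generank.aggregation import ThemeAssignment
from generank.backends import ScriptedBackend, SimulatedScorerConfig, SimulatedScoringBackend
from generank.errors import (
    ExtractionError,
    GeneRankError,
    ValidationError,
)
from generank.fixtures import SyntheticStudySettings, generate_synthetic_study
from generank.records import ReferenceCitation
from generank.repertoire import GeneModule, Repertoire
from generank.rubric import CRITERION_KEYS
from generank.workflow import (
    OfflineResolver,
    SelectionDecision,
    WorkflowConfig,
    data_informed_selection,
    export_convergence_graph,
    extract_choice,
    fact_check,
    run_pipeline,
    run_scoring,
    select_top_candidate,
    summarize_justifications,
    write_report,
)


@pytest.fixture
def gpx4_repertoire():
    rep = Repertoire()
    rep.add(GeneModule("MG.1", "AG", ("GPX4",)))
    return rep


class TestRunScoring:
    def test_simulated_m92_dimensions(self, bundle):
        module = bundle.repertoire.modules["M9.2"]
        latent = {(g, k): 5.0 for g in module.genes for k in CRITERION_KEYS}
        backends = {
            m: SimulatedScoringBackend(SimulatedScorerConfig(latent=latent, seed=i))
            for i, m in enumerate(("model_a", "model_b"))
        }
        cfg = WorkflowConfig(
            module_id="M9.2", model_ids=("model_a", "model_b"),
            rubric=bundle.rubric, replicates=3,
        )
        _records, tensor = run_scoring(cfg, backends, bundle.repertoire)
        assert tensor.values.shape == (30, 6, 2, 3)

    def test_scripted_gpx4_replay(self, bundle, gpx4_line, gpx4_repertoire):
        backend = ScriptedBackend({("3.3", "GPX4"): gpx4_line})
        cfg = WorkflowConfig(
            module_id="MG.1", model_ids=("replay",), rubric=bundle.rubric,
            replicates=1,
        )
        _records, tensor = run_scoring(cfg, {"replay": backend}, gpx4_repertoire)
        assert tensor.values[0, :, 0, 0].tolist() == [2, 4, 5, 4, 7, 6]

    def test_garbage_replicate_marked_missing(self, bundle, gpx4_line, gpx4_repertoire):
        class Mixed:
            context_budget = None

            def respond(self, request):
                if request.params["replicate"] == 1:
                    return "this is not a scoring record"
                return gpx4_line

        cfg = WorkflowConfig(
            module_id="MG.1", model_ids=("mixed",), rubric=bundle.rubric,
            replicates=3,
        )
        _records, tensor = run_scoring(cfg, {"mixed": Mixed()}, gpx4_repertoire)
        import numpy as np

        assert np.isnan(tensor.values[0, :, 0, 1]).all()
        assert not np.isnan(tensor.values[0, :, 0, 0]).any()

    def test_all_replicates_unusable_is_hard_error(self, bundle, gpx4_repertoire):
        backend = ScriptedBackend({("3.3", "GPX4"): "garbage | text"})
        cfg = WorkflowConfig(
            module_id="MG.1", model_ids=("bad",), rubric=bundle.rubric,
            replicates=2,
        )
        with pytest.raises(GeneRankError, match="GPX4"):
            run_scoring(cfg, {"bad": backend}, gpx4_repertoire)


class TestSummarize:
    def test_prompt_contains_only_topk_justifications(self, bundle, gpx4_line):
        from generank.records import parse_score_record

        rec = parse_score_record(gpx4_line, bundle.rubric)
        captured = {}

        class Capture:
            context_budget = None

            def respond(self, request):
                captured["prompt"] = request.prompt
                return "summary text"

        out = summarize_justifications(
            [("model_a", rec), ("model_b", rec)], "a", Capture()
        )
        assert out == "summary text"
        justification_lines = [
            l for l in captured["prompt"].splitlines() if l.startswith("GPX4 (")
        ]
        assert len(justification_lines) == 2  # one per contributing record

    def test_empty_justifications_error(self):
        with pytest.raises(ValidationError):
            summarize_justifications([], "a", ScriptedBackend({}))


class TestFactCheck:
    def _resolver(self):
        return OfflineResolver.from_rows(
            [
                {
                    "first_author": "Yang",
                    "year": "2014",
                    "title": "Regulation of ferroptotic cancer cell death by GPX4",
                    "journal": "Cell",
                    "pmid": "900000004",
                }
            ]
        )

    def test_resolvable_reference_verifies(self):
        backend = ScriptedBackend(
            {
                ("5.1", "statement one"): 'Supported. "Yang, Regulation of '
                'ferroptotic cancer cell death by GPX4, 2014, Cell"'
            }
        )
        results = fact_check(["statement one"], backend, self._resolver())
        assert results[0].status == "verified"
        assert results[0].references[0].pmid == "900000004"

    def test_unresolvable_reference_eliminates(self):
        backend = ScriptedBackend(
            {("5.1", "bogus claim"): 'See "Nobody, A made up paper, 2099, Nowhere"'}
        )
        results = fact_check(["bogus claim"], backend, self._resolver())
        assert results[0].status == "eliminated"
        assert results[0].references == ()

    def test_no_resolver_means_unverified(self):
        backend = ScriptedBackend(
            {("5.1", "claim"): '"Yang, Regulation of ferroptotic cancer cell '
                               'death by GPX4, 2014, Cell"'}
        )
        results = fact_check(["claim"], backend, None)
        assert results[0].status == "unverified"

    def test_empty_statement_list(self):
        assert fact_check([], ScriptedBackend({}), self._resolver()) == []


class TestExtractChoice:
    def test_unique_candidate_in_first_sentence(self, top5):
        text = "I would suggest ALAS2 as the top candidate. FECH is also fine."
        assert extract_choice(text, top5) == "ALAS2"

    def test_parenthetical_enumeration_ignored(self, top5):
        text = (
            "Weighing all criteria equally, BCL2L1 (B-cell lymphoma 2-like 1) "
            "appears to be the top candidate among the genes described "
            "(BCL2L1, ALAS2, SLC4A1, CA1, and FECH)."
        )
        assert extract_choice(text, top5) == "BCL2L1"

    def test_no_candidate_raises(self, top5):
        with pytest.raises(ExtractionError):
            extract_choice("No gene is named here at all.", top5)

    def test_conflicting_candidates_raise(self, top5):
        with pytest.raises(ExtractionError, match="multiple"):
            extract_choice("Either ALAS2 or FECH would do equally well.", top5)

    def test_substring_symbols_not_confused(self):
        # GYPE must not match inside GYPB-like tokens
        assert extract_choice("GYPE is the pick.", ("GYPE", "GYP")) == "GYPE"


class TestSelection:
    def test_stepwise_replay_claude(self, bundle, top5):
        text = bundle.selection_transcripts["step6"]["claude"]["stepwise"]
        backend = ScriptedBackend({("6.1", "stepwise"): text})
        decision = select_top_candidate("summary", backend, top5, mode="stepwise")
        assert decision.chosen_gene == "ALAS2"
        assert decision.mode == "stepwise"

    def test_stepwise_replay_gpt4(self, bundle, top5):
        text = bundle.selection_transcripts["step6"]["gpt-4"]["stepwise"]
        backend = ScriptedBackend({("6.1", "stepwise"): text})
        decision = select_top_candidate("summary", backend, top5, mode="stepwise")
        assert decision.chosen_gene == "BCL2L1"

    def test_direct_replay_selects_from_module(self, bundle, m92):
        for model, expected in (("claude", "ALAS2"), ("gpt-4", "ALAS2")):
            text = bundle.selection_transcripts["step6"][model]["direct"]
            backend = ScriptedBackend({("6.2", "direct"): text})
            decision = select_top_candidate(
                "", backend, m92.genes, mode="direct"
            )
            assert decision.chosen_gene == expected

    def test_unnamed_candidate_raises(self, top5):
        backend = ScriptedBackend({("6.1", "stepwise"): "I cannot decide."})
        with pytest.raises(ExtractionError):
            select_top_candidate("summary", backend, top5, mode="stepwise")


class TestDataInformedSelection:
    def _prior(self, gene="BCL2L1"):
        return SelectionDecision(
            chosen_gene=gene, mode="stepwise", stage="summary_only",
            rationale="initial", history=(),
        )

    def test_gpt4_session_revises_after_rnaseq(self, bundle, top5):
        t7 = bundle.selection_transcripts["step7"]["gpt-4"]
        backend = ScriptedBackend({("7.2", "plus_rnaseq"): t7["plus_rnaseq"]})
        corpora = {
            "plus_rnaseq": ["short sentence"] ,
            # microarray corpus exceeds the 8192-token single context
            "plus_microarray": ["x" * 40000],
        }
        decision = data_informed_selection(
            self._prior("BCL2L1"), corpora, backend, top5,
            budget=8192, run_final=False,
        )
        choices = decision.stage_choices()
        assert choices["summary_only"] == "BCL2L1"
        assert choices["plus_rnaseq"] == "ALAS2"
        # skipped stage carries the prior forward
        assert choices["plus_microarray"] == "ALAS2"
        assert "skipped" in decision.rationale

    def test_claude_session_reaffirms_everywhere(self, bundle, top5):
        t7 = bundle.selection_transcripts["step7"]["claude"]
        backend = ScriptedBackend(
            {
                ("7.2", "plus_rnaseq"): t7["plus_rnaseq"],
                ("7.3", "plus_microarray"): t7["plus_microarray"],
                ("7.4", "plus_cohorts"): t7["plus_cohorts"],
                ("7.5", "final"): t7["final"],
            }
        )
        prior = SelectionDecision(
            chosen_gene="ALAS2", mode="stepwise", stage="summary_only",
            rationale=t7["summary_only"], history=(),
        )
        corpora = {s: ["data sentence"] for s in
                   ("plus_rnaseq", "plus_microarray", "plus_cohorts")}
        decision = data_informed_selection(
            prior, corpora, backend, top5, budget=100_000, run_final=True,
        )
        assert set(decision.stage_choices().values()) == {"ALAS2"}
        assert decision.stage == "final"
        assert len(decision.history) == 4


class TestConvergenceGraph:
    def test_gpt4_erythroid_theme_has_eight_gene_edges(self, bundle):
        gpt4 = [
            a for a in bundle.theme_table
            if a.source == "GPT-4" and "Erythrocyte" in a.theme
        ]
        g = export_convergence_graph(gpt4)
        theme_node = "GPT-4: Erythrocyte development and function"
        assert g.nodes[theme_node]["kind"] == "theme"
        assert g.degree[theme_node] == 8

    def test_empty_input(self):
        g = export_convergence_graph([])
        assert g.number_of_nodes() == 0

    def test_edge_count_equals_membership_sum(self, bundle):
        g = export_convergence_graph(bundle.theme_table)
        expected = sum(len(a.genes) for a in bundle.theme_table)
        assert g.number_of_edges() == expected
        assert nx.is_bipartite(g)


@pytest.fixture(scope="module")
def synthetic_report(bundle):
    study = generate_synthetic_study(SyntheticStudySettings(), seed=3)
    cfg = WorkflowConfig(
        module_id=study.module.module_id,
        model_ids=study.settings.models,
        rubric=bundle.rubric, k=5, seed=3,
    )
    report = run_pipeline(
        cfg, study.backends(bundle.rubric), study.repertoire,
        resolver=bundle.resolver,
    )
    return report, study


class TestPipelineAndReport:
    @pytest.fixture
    def report(self, synthetic_report):
        return synthetic_report

    def test_shortlist_and_decision_present(self, report):
        rep, study = report
        assert len(rep.shortlist) == 5
        assert rep.decisions
        for d in rep.decisions.values():
            assert d.chosen_gene in {rg.symbol for rg in rep.shortlist}

    def test_surviving_statements_have_references(self, report):
        rep, _ = report
        for fc in rep.fact_checks:
            if fc.status == "verified":
                assert len(fc.references) >= 1
                assert all(r.pmid for r in fc.references)

    def test_report_files_deterministic(self, report, tmp_path, bundle):
        rep, study = report
        paths1 = write_report(rep, tmp_path / "r1")
        cfg = WorkflowConfig(
            module_id=study.module.module_id,
            model_ids=study.settings.models,
            rubric=bundle.rubric, k=5, seed=3,
        )
        rep2 = run_pipeline(
            cfg, study.backends(bundle.rubric), study.repertoire,
            resolver=bundle.resolver,
        )
        paths2 = write_report(rep2, tmp_path / "r2")
        assert paths1["json"].read_bytes() == paths2["json"].read_bytes()
        assert paths1["markdown"].read_bytes() == paths2["markdown"].read_bytes()
        payload = json.loads(paths1["json"].read_text())
        assert payload["module"]["module_id"] == study.module.module_id

    def test_run_without_resolver_marks_skip(self, bundle):
        study = generate_synthetic_study(SyntheticStudySettings(n_genes=4), seed=5)
        cfg = WorkflowConfig(
            module_id=study.module.module_id,
            model_ids=study.settings.models,
            rubric=bundle.rubric, k=3, seed=5,
        )
        rep = run_pipeline(
            cfg, study.backends(bundle.rubric), study.repertoire, resolver=None
        )
        assert any("fact_check" in s for s in rep.skipped_steps)
        assert rep.fact_checks == []
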