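"""End-to-end orchestration of the prioritization funnel.

The stages run in the order the analysis dictates — target fishing, network
construction and scale-free selection, MCC hub ranking with apoptosis
intersection, four-tool miRNA consensus, accessibility filtering, and final
candidate ranking — each writing its artifact before the next starts, so a
failure leaves the completed stages' outputs on disk and is reported with
the failing stage's name.

A packaged "fixture run" (:func:`prepare_fixture_inputs` +
:func:`run_pipeline`) reproduces the published funnel on the transcribed
tables: 25 fished targets → a 35-protein/110-interaction network → ATM as
the top hub among six apoptosis-annotated hubs → 14 accessible candidates →
hsa-miR-181b-5p selected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .accessibility import (
    call_accessible_regions,
    rank_candidates,
    read_candidates_csv,
    read_profile_tsv,
    site_accessible,
)
from .consensus import apply_tool_filters, consensus, normalize_mirna_id, venn_as_json
from .dialects import read_prediction_table
from .errors import StageError
from .fixtures import annotated_set, fixture_path, load_fixture
from .hubs import intersect_annotated, mcc_scores, top_k
from .network import expand_network, read_edge_list, select_network, write_edge_list
from .synthetic import (
    SyntheticSpec,
    gen_accessibility_profile,
    gen_prediction_tables,
    gen_target_library,
    merged_windows,
    write_library_csv,
    write_prediction_tables,
    write_profile_tsv,
)
from .targets import fingerprint, fish_targets, read_library_csv

#: 5-hydroxy-7-methoxyflavanone, the flavanone query compound
DEFAULT_QUERY_SMILES = "COc1cc(O)c2c(c1)OC(c1ccccc1)CC2=O"


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the study's selection rules: similarity strictly
    above 0.7, potency strictly below 150 µM, interaction confidence
    strictly above 0.4, consensus of at least 3 of 4 tools, accessibility
    probability strictly above 0.5 with at least 1 nt site overlap, and a
    top-10 hub list.
    """

    library: str
    interactome: str
    tool_tables: dict[str, str]
    candidates: str
    profile: str
    outdir: str
    annotation: str | None = None
    query_smiles: str = DEFAULT_QUERY_SMILES
    sim_min: float = 0.7
    potency_max_um: float = 150.0
    organism: str = "Homo sapiens"
    score_floor: float = 0.4
    first_grid: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    second_grid: tuple[int, ...] = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    min_tools: int = 3
    access_threshold: float = 0.5
    min_overlap: int = 1
    top_k: int = 10
    require_evidence: bool = True
    apoptosis_term: str = "apoptotic process"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.sim_min <= 1:
            raise ValueError("sim_min must lie in [0, 1]")
        if self.potency_max_um <= 0:
            raise ValueError("potency_max_um must be positive")
        if not 0 <= self.score_floor < 1:
            raise ValueError("score_floor must lie in [0, 1)")
        if not 1 <= self.min_tools <= 4:
            raise ValueError("min_tools must lie in 1..4")
        if not 0 <= self.access_threshold <= 1:
            raise ValueError("access_threshold must lie in [0, 1]")
        if self.min_overlap < 1 or self.top_k < 1:
            raise ValueError("min_overlap and top_k must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key in ("first_grid", "second_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def relative_expression_ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """RT-qPCR relative expression by the 2^-ddCT method.

    ddCT = (CT_target - CT_reference)_treated - (CT_target - CT_reference)_control;
    the fold change versus control is 2 to the minus ddCT.

    Raises
    ------
    ValueError
        On non-finite CT values.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("CT values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the machine-readable run report.

    Artifacts (selected network TSV, fit table JSON, hub CSV, consensus CSV,
    Venn JSON, ranked candidates CSV, report JSON) are written under
    ``config.outdir``.  Stage failures raise :class:`StageError` naming the
    stage; artifacts of completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config_hash(config),
        },
        "stages": {},
    }

    # --- stage 1: ligand-based target fishing -------------------------------
    @_stage("target_fishing")
    def stage_fishing():
        library = read_library_csv(config.library)
        query = fingerprint(config.query_smiles)
        fished = fish_targets(
            query,
            library,
            sim_min=config.sim_min,
            potency_max_um=config.potency_max_um,
            organism=config.organism,
        )
        with open(outdir / "fished_targets.csv", "w") as fh:
            fh.write("target_id,target_name,compound_ids\n")
            for t in fished:
                fh.write(f"{t.target_id},{t.target_name},{';'.join(t.compound_ids)}\n")
        report["stages"]["target_fishing"] = {
            "n_library_records": len(library),
            "n_targets": len(fished),
        }
        return [t.target_id for t in fished]

    seeds = stage_fishing()

    # --- stage 2: network construction and scale-free selection -------------
    @_stage("network_selection")
    def stage_network():
        interactome = read_edge_list(config.interactome, score_floor=config.score_floor)
        candidates = []
        for first in config.first_grid:
            for second in config.second_grid:
                graph = expand_network(interactome, seeds, first, second)
                candidates.append(((first, second), graph))
        settings, graph, fit, table = select_network(candidates)
        write_edge_list(graph, outdir / "selected_network.tsv")
        with open(outdir / "fit_table.json", "w") as fh:
            json.dump([{**row, "settings": list(row["settings"])} for row in table],
                      fh, indent=1)
        report["stages"]["network_selection"] = {
            "selected_settings": list(settings),
            "gamma": fit.gamma,
            "r_squared": fit.r_squared,
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
        }
        return graph

    network = stage_network()

    # --- stage 3: MCC hubs and apoptosis intersection -----------------------
    @_stage("hub_ranking")
    def stage_hubs():
        apoptosis = annotated_set(config.apoptosis_term, config.annotation)
        table = mcc_scores(network)
        hubs = top_k(table, config.top_k)
        hits = intersect_annotated(hubs, apoptosis)
        with open(outdir / "hubs.csv", "w") as fh:
            fh.write("node,mcc,degree,annotated\n")
            for node in table.ranked:
                fh.write(
                    f"{node},{table.scores[node]},{network.degree(node)},"
                    f"{str(node in apoptosis).lower()}\n"
                )
        report["stages"]["hub_ranking"] = {
            "top_hubs": hubs,
            "apoptosis_hubs": hits,
            "n_apoptosis_hubs": len(hits),
            "top_hub": hubs[0],
        }
        return hits

    stage_hubs()

    # --- stage 4: miRNA consensus -------------------------------------------
    @_stage("mirna_consensus")
    def stage_consensus():
        records = []
        for tool, path in config.tool_tables.items():
            records.extend(read_prediction_table(path, tool))
        pass_sets, skipped, _ = apply_tool_filters(records)
        result = consensus(pass_sets, min_tools=config.min_tools)
        with open(outdir / "venn.json", "w") as fh:
            json.dump(venn_as_json(result.venn), fh, indent=1)
        with open(outdir / "consensus.csv", "w") as fh:
            fh.write("mirna,n_tools,tools\n")
            for mirna in sorted(result.kept):
                tools = sorted(t for t, s in result.per_tool_pass.items() if mirna in s)
                fh.write(f"{mirna},{len(tools)},{';'.join(tools)}\n")
        report["stages"]["mirna_consensus"] = {
            "n_records": len(records),
            "n_skipped_records": skipped,
            "per_tool_pass": {t: len(s) for t, s in result.per_tool_pass.items()},
            "n_consensus": len(result.kept),
        }
        return result.kept

    kept = stage_consensus()

    # --- stage 5: site accessibility ----------------------------------------
    @_stage("site_accessibility")
    def stage_accessibility():
        profile = read_profile_tsv(config.profile)
        regions = call_accessible_regions(profile, config.access_threshold)
        candidates = read_candidates_csv(config.candidates)
        passing = [
            c
            for c in candidates
            if normalize_mirna_id(c.mirna) in kept
            and site_accessible(
                c, regions, config.min_overlap, profile_length=len(profile)
            )
        ]
        report["stages"]["site_accessibility"] = {
            "n_regions": len(regions),
            "n_candidates_in": len(candidates),
            "n_accessible": len(passing),
        }
        return passing

    accessible = stage_accessibility()

    # --- stage 6: candidate ranking -----------------------------------------
    @_stage("candidate_ranking")
    def stage_ranking():
        ranked = rank_candidates(accessible, require_evidence=config.require_evidence)
        with open(outdir / "candidates_ranked.csv", "w") as fh:
            fh.write("rank,mirna,site_start,site_end,logit_prob,dg_hybrid,evidence\n")
            for i, c in enumerate(ranked, start=1):
                fh.write(
                    f"{i},{c.mirna},{c.site_start},{c.site_end},"
                    f"{c.logit_prob},{c.dg_hybrid},{str(c.evidence).lower()}\n"
                )
        report["stages"]["candidate_ranking"] = {
            "n_ranked": len(ranked),
            "final_candidate": ranked[0].mirna,
            "final_logit_prob": ranked[0].logit_prob,
            "final_dg_hybrid": ranked[0].dg_hybrid,
        }

    stage_ranking()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def prepare_fixture_inputs(workdir: str | Path, seed: int = 0) -> PipelineConfig:
    """Materialize the packaged fixture bundle and return its run config.

    The bundle combines the transcribed tables with synthetic stand-ins for
    the parts never published: a compound library engineered so exactly the
    25 target genes pass the fishing filters, four prediction tables with
    the 14 candidate miRNAs planted, and an accessibility profile whose
    accessible windows cover the printed site positions.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    table1 = load_fixture("table1")
    table2 = load_fixture("table2")

    spec = SyntheticSpec(
        seed=seed,
        n_mirnas=100,
        n_planted=len(table2),
        noise_rate=0.2,
        profile_length=3600,
        accessible_windows=merged_windows(
            (c.site_start, c.site_end) for c in table2
        ),
    )

    library = gen_target_library(
        DEFAULT_QUERY_SMILES,
        [(rec.gene_symbol, rec.target_name) for rec in table1],
        spec,
    )
    write_library_csv(library, workdir / "library.csv")

    shutil.copy(fixture_path("interactome"), workdir / "interactome.tsv")

    tables, _ = gen_prediction_tables(
        spec, gene="ATM", planted_ids=[c.mirna for c in table2]
    )
    tool_paths = write_prediction_tables(tables, workdir / "predictions")

    write_profile_tsv(gen_accessibility_profile(spec), workdir / "profile.tsv")
    shutil.copy(fixture_path("table2"), workdir / "candidates.csv")

    return PipelineConfig(
        library=str(workdir / "library.csv"),
        interactome=str(workdir / "interactome.tsv"),
        tool_tables={t: str(p) for t, p in tool_paths.items()},
        candidates=str(workdir / "candidates.csv"),
        profile=str(workdir / "profile.tsv"),
        outdir=str(workdir / "out"),
        seed=seed,
    )
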