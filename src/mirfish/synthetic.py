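"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline consumes an export format from an external
service (interaction database, prediction servers, folding server,
bioactivity database).  None of those can be queried reproducibly at test
time, so this module generates each input with the property the stage is
supposed to detect — or deliberately without it:

* interactomes: preferential-attachment (heavy-tailed, scale-free-like)
  versus Erdős–Rényi (binomial degrees) graphs as positive/negative
  controls for the power-law fit;
* four-tool prediction tables with a planted consensus set, plus decoys
  engineered to fail (wrong scores, or too few tools);
* single-strandedness profiles with planted accessible windows;
* a compound library engineered so a chosen target list passes the
  similarity/potency/organism filters.

All generators are deterministic functions of a :class:`SyntheticSpec`
(including its seed): equal specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .accessibility import AccessibilityProfile
from .errors import ConfigError
from .targets import LibraryRecord

TOOL_ORDER = ("diana", "mirdb", "targetscan", "rna22")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic-data generators.

    Defaults emulate the study's scale: an interactome of a few hundred
    proteins with preferential-attachment topology, on the order of a
    hundred distinct miRNAs across the four predictors with a planted
    consensus of ten, and a 3.6 kb 3'UTR profile (the length of the ATM
    3'UTR that the printed site coordinates imply).
    """

    seed: int = 0
    n_nodes: int = 200
    attachment_m: int = 2
    er_p: float = 0.05
    n_mirnas: int = 100
    n_planted: int = 10
    noise_rate: float = 0.2
    profile_length: int = 3600
    accessible_windows: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if not 0 <= self.er_p <= 1 or not 0 <= self.noise_rate <= 1:
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.n_planted > self.n_mirnas:
            raise ConfigError("n_planted must not exceed n_mirnas")
        if self.profile_length < 1:
            raise ConfigError("profile_length must be >= 1")
        for start, end in self.accessible_windows:
            if not (1 <= start <= end <= self.profile_length):
                raise ConfigError(
                    f"window ({start}, {end}) outside [1, {self.profile_length}]"
                )
        spans = sorted(self.accessible_windows)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError("accessible windows must be disjoint")


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([spec.seed, sum(map(ord, stream))])


def gen_ppi_network(spec: SyntheticSpec, model: str = "barabasi_albert") -> nx.Graph:
    """A synthetic interactome under a chosen degree-distribution regime.

    ``barabasi_albert``: preferential attachment seeded with the complete
    graph K_{m+1}; each later node attaches to ``attachment_m`` distinct
    existing nodes with probability proportional to degree.  Connected by
    construction, heavy-tailed for large n, and exactly K_n when
    m = n - 1.  ``erdos_renyi``: G(n, p), the negative control whose
    binomial degree law should *fail* a power-law fit.

    Edge confidence scores are drawn uniformly in (0.4, 1.0], above the
    default read filter, so generated graphs are filter-invariant.
    """
    if model not in {"barabasi_albert", "erdos_renyi"}:
        raise ConfigError(f"unknown model {model!r}")
    rng = _rng(spec, "network-" + model)
    n = spec.n_nodes
    if model == "barabasi_albert":
        m = spec.attachment_m
        if n < m + 1:
            raise ConfigError("n_nodes must be >= attachment_m + 1")
        graph = nx.complete_graph(min(m + 1, n))
        repeated: list[int] = [v for e in graph.edges for v in e]
        for new in range(m + 1, n):
            targets: set[int] = set()
            while len(targets) < m:
                targets.add(int(repeated[rng.integers(len(repeated))]))
            for t in sorted(targets):
                graph.add_edge(new, t)
                repeated += [new, t]
    else:
        if n < 1:
            raise ConfigError("n_nodes must be >= 1")
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < spec.er_p:
                    graph.add_edge(i, j)
    relabel = {v: f"P{v:04d}" for v in graph.nodes}
    graph = nx.relabel_nodes(graph, relabel)
    for a, b in sorted(graph.edges):
        # uniform in (0.4, 1.0]
        graph[a][b]["score"] = round(1.0 - 0.6 * float(rng.random()), 6)
    return graph


# --- prediction tables ------------------------------------------------------

#: (passing-range, failing-range) per score field; failing values miss the
#: threshold by at least 0.01 of its scale, so boundary arithmetic is never
#: exercised by accident.
_PASS = {
    "mitg_score": (0.71, 0.99),
    "prediction_score": (81.0, 99.0),
    "p_value": (0.001, 0.04),
    "context_plus": (-0.5, -0.11),
    "pct": (0.51, 0.95),
}
_FAIL = {
    "mitg_score": (0.10, 0.69),
    "prediction_score": (40.0, 79.0),
    "p_value": (0.06, 0.5),
    "context_plus": (-0.09, -0.01),
    "pct": (0.01, 0.49),
}


def _draw(rng, table, fields) -> dict[str, float]:
    return {
        f: round(float(rng.uniform(*table[f])), 4 if f != "prediction_score" else 1)
        for f in fields
    }


def _tool_scores(rng, tool: str, passing: bool) -> dict[str, float]:
    table = _PASS if passing else _FAIL
    if tool == "diana":
        return _draw(rng, table, ["mitg_score"])
    if tool == "mirdb":
        return _draw(rng, table, ["prediction_score"])
    if tool == "rna22":
        return _draw(rng, table, ["p_value"])
    if tool == "targetscan":
        # a passing TargetScan record satisfies the context+ arm; the PCT
        # column is drawn failing so the disjunction is what rescues it
        return {
            **_draw(rng, _PASS if passing else _FAIL, ["context_plus"]),
            **_draw(rng, _FAIL, ["pct"]),
        }
    raise ConfigError(tool)


def gen_prediction_tables(
    spec: SyntheticSpec,
    gene: str = "ATM",
    planted_ids: Sequence[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], frozenset[str]]:
    """Four per-tool prediction tables with a planted consensus set.

    Planted miRNAs appear in at least three tools with passing scores.
    Decoys can never reach consensus: a fraction ``noise_rate`` of them are
    "confusable" (passing scores, but present in at most two tools); the
    rest carry failing scores wherever they appear.  Returns the tables in
    each tool's export dialect plus the planted ground truth (canonical
    ids), so recovery is checkable without re-deriving it.

    ``planted_ids`` substitutes real miRNA names for the first
    ``len(planted_ids)`` planted slots (and overrides ``n_planted``).
    """
    rng = _rng(spec, "predictions")
    if planted_ids is not None:
        if len(planted_ids) > spec.n_mirnas:
            raise ConfigError("more planted ids than n_mirnas")
        mirnas = list(planted_ids) + [
            f"hsa-miR-{7000 + i}-5p" for i in range(spec.n_mirnas - len(planted_ids))
        ]
        planted = frozenset(planted_ids)
    else:
        mirnas = [f"hsa-miR-{7000 + i}-5p" for i in range(spec.n_mirnas)]
        planted = frozenset(mirnas[: spec.n_planted])

    rows: dict[str, list[dict]] = {t: [] for t in TOOL_ORDER}
    for mirna in mirnas:
        is_planted = mirna in planted
        if is_planted:
            n_tools = int(rng.integers(3, 5))
            passing = True
        else:
            confusable = bool(rng.random() < spec.noise_rate)
            n_tools = int(rng.integers(1, 3)) if confusable else int(rng.integers(1, 5))
            passing = confusable
        tools = [TOOL_ORDER[i] for i in sorted(rng.choice(4, size=n_tools, replace=False))]
        start = int(rng.integers(1, max(2, spec.profile_length - 30)))
        end = min(start + 18 + int(rng.integers(0, 8)), spec.profile_length)
        for tool in tools:
            rows[tool].append(
                {
                    "mirna": mirna,
                    "gene": gene,
                    "site_start": start,
                    "site_end": end,
                    **_tool_scores(rng, tool, passing),
                }
            )

    tables = {
        "diana": pd.DataFrame(
            [
                {"mirna_name": r["mirna"], "ensembl_gene_id": r["gene"],
                 "mitg_score": r["mitg_score"]}
                for r in rows["diana"]
            ],
            columns=["mirna_name", "ensembl_gene_id", "mitg_score"],
        ),
        "mirdb": pd.DataFrame(
            [
                {"miRNA Name": r["mirna"], "Gene Symbol": r["gene"],
                 "Target Score": r["prediction_score"]}
                for r in rows["mirdb"]
            ],
            columns=["miRNA Name", "Gene Symbol", "Target Score"],
        ),
        "targetscan": pd.DataFrame(
            [
                {"miRNA": r["mirna"], "Gene Symbol": r["gene"],
                 "Context++ score": r["context_plus"], "PCT": r["pct"],
                 "UTR start": r["site_start"], "UTR end": r["site_end"]}
                for r in rows["targetscan"]
            ],
            columns=["miRNA", "Gene Symbol", "Context++ score", "PCT",
                     "UTR start", "UTR end"],
        ),
        "rna22": pd.DataFrame(
            [
                {"miRNA": r["mirna"], "gene": r["gene"], "p_value": r["p_value"],
                 "site_start": r["site_start"], "site_end": r["site_end"]}
                for r in rows["rna22"]
            ],
            columns=["miRNA", "gene", "p_value", "site_start", "site_end"],
        ),
    }
    return tables, frozenset(m.lower() for m in planted)


def gen_accessibility_profile(spec: SyntheticSpec) -> AccessibilityProfile:
    """A single-strandedness profile with planted accessible windows.

    Positions inside a window draw probabilities in [0.55, 0.95]; positions
    outside draw in [0.05, 0.45].  The 0.05 margin on either side of the 0.5
    accessibility threshold keeps region calling away from the boundary.
    """
    rng = _rng(spec, "profile")
    probs = 0.05 + 0.40 * rng.random(spec.profile_length)
    for start, end in spec.accessible_windows:
        probs[start - 1 : end] = 0.55 + 0.40 * rng.random(end - start + 1)
    return AccessibilityProfile(probabilities=tuple(round(float(p), 6) for p in probs))


def gen_utr_sequence(spec: SyntheticSpec) -> str:
    """A random 3'UTR (RNA alphabet) of ``profile_length`` nucleotides."""
    rng = _rng(spec, "utr")
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=spec.profile_length))


def gen_target_library(
    query_structure: str,
    targets: Sequence[tuple[str, str]],
    spec: SyntheticSpec,
    organism: str = "Homo sapiens",
) -> list[LibraryRecord]:
    """A compound library engineered so exactly ``targets`` pass the filters.

    For every (target_id, target_name) one highly similar compound is
    emitted (the query structure with a single-atom extension — Tanimoto
    far above 0.7 under the substring fingerprint) with potency below the
    150 µM cut-off.  Interleaved decoy records each violate exactly one
    filter: a dissimilar structure, an over-potency value, a non-matching
    organism, or a missing potency.
    """
    rng = _rng(spec, "library")
    decoy_structures = ["c1ccncc1NC(=O)N", "O=S(=O)(N)c1ccccc1", "C1CCOC1CNCC#N"]
    records: list[LibraryRecord] = []
    for i, (target_id, target_name) in enumerate(targets):
        records.append(
            LibraryRecord(
                compound_id=f"SYN{i:04d}",
                structure=query_structure + "C",
                target_id=target_id,
                target_name=target_name,
                organism=organism,
                potency_um=round(float(rng.uniform(0.5, 140.0)), 2),
            )
        )
        fault = i % 4
        decoy_target = (f"DECOY{i:04d}", f"decoy target {i}")
        if fault == 0:  # dissimilar structure
            rec = LibraryRecord(
                compound_id=f"DX{i:04d}",
                structure=decoy_structures[i % len(decoy_structures)],
                target_id=decoy_target[0], target_name=decoy_target[1],
                organism=organism, potency_um=10.0,
            )
        elif fault == 1:  # too weak
            rec = LibraryRecord(
                compound_id=f"DX{i:04d}", structure=query_structure + "C",
                target_id=decoy_target[0], target_name=decoy_target[1],
                organism=organism,
                potency_um=round(float(rng.uniform(150.0, 900.0)), 2),
            )
        elif fault == 2:  # wrong organism
            rec = LibraryRecord(
                compound_id=f"DX{i:04d}", structure=query_structure + "C",
                target_id=decoy_target[0], target_name=decoy_target[1],
                organism="Rattus norvegicus", potency_um=10.0,
            )
        else:  # unverifiable potency
            rec = LibraryRecord(
                compound_id=f"DX{i:04d}", structure=query_structure + "C",
                target_id=decoy_target[0], target_name=decoy_target[1],
                organism=organism, potency_um=None,
            )
        records.append(rec)
    return records


# --- writers (all deterministic byte-for-byte) ------------------------------

def write_profile_tsv(profile: AccessibilityProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pos, p in enumerate(profile.probabilities, start=1):
            fh.write(f"{pos}\t{p:.6f}\n")


def write_prediction_tables(
    tables: dict[str, pd.DataFrame], outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tool, frame in tables.items():
        path = outdir / f"{tool}.csv"
        frame.to_csv(path, index=False)
        paths[tool] = path
    return paths


def write_utr_fasta(sequence: str, path: str | Path, name: str = "synthetic_3utr") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def write_library_csv(records: Iterable[LibraryRecord], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["compound_id", "structure", "target_id", "target_name", "organism", "potency_um"]
        )
        for rec in records:
            writer.writerow(
                [rec.compound_id, rec.structure, rec.target_id, rec.target_name,
                 rec.organism, "" if rec.potency_um is None else rec.potency_um]
            )


def merged_windows(sites: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge overlapping/adjacent 1-based inclusive intervals (for planting)."""
    spans = sorted(sites)
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)
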