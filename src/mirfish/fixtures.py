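"""Packaged golden fixtures for the prioritization pipeline.

The published study prints its key intermediate results as tables — the 25
predicted protein targets, the 14 accessibility-passing miRNA candidates
(with site positions, binding likelihoods and hybrid free energies), the
top-10 MCC hub list and the 14-gene apoptosis annotation — but deposits no
machine-readable inputs.  Those tables are transcribed here verbatim as the
pipeline's golden inputs.

The packaged interactome edge list is a *synthetic* construction: no edge
list was published, only the summary that the chosen network comprised 110
interactions among 35 proteins.  The fixture is engineered so that sphere
expansion from the 25 seed targets (first sphere 10, no second sphere)
reproduces those counts and the printed hub ranking.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources

from .accessibility import CandidateSite

_FIXTURE_FILES = {
    "table1": "table1_targets.csv",
    "table2": "table2_candidates.csv",
    "hub_top10": "hub_top10.txt",
    "apoptosis_set": "apoptosis_genes.txt",
    "interactome": "interactome.tsv",
    "annotation": "annotation.tsv",
}


@dataclass(frozen=True)
class TargetRecord:
    """One predicted-target row: compound-database id, name, gene symbol."""

    chembl_id: str
    target_name: str
    gene_symbol: str


def _read_text(name: str) -> str:
    return resources.files("mirfish.data").joinpath(name).read_text()


def fixture_path(name: str):
    """Filesystem path of a packaged fixture (for CLI/pipeline file inputs)."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; one of {sorted(_FIXTURE_FILES)}")
    return resources.files("mirfish.data").joinpath(_FIXTURE_FILES[name])


def load_fixture(name: str):
    """Load a packaged fixture as an immutable in-memory object.

    ``table1`` -> tuple of 25 :class:`TargetRecord`;
    ``table2`` -> tuple of 14 :class:`CandidateSite`;
    ``hub_top10`` -> tuple of 10 gene symbols in rank order;
    ``apoptosis_set`` -> frozenset of 14 gene symbols.

    Raises
    ------
    KeyError
        For an unknown fixture name.
    """
    if name == "table1":
        reader = csv.DictReader(io.StringIO(_read_text("table1_targets.csv")))
        return tuple(
            TargetRecord(
                chembl_id=row["chembl_id"],
                target_name=row["target_name"],
                gene_symbol=row["gene_symbol"],
            )
            for row in reader
        )
    if name == "table2":
        reader = csv.DictReader(io.StringIO(_read_text("table2_candidates.csv")))
        return tuple(
            CandidateSite(
                mirna=row["mirna"],
                site_start=int(row["site_start"]),
                site_end=int(row["site_end"]),
                logit_prob=float(row["logit_prob"]),
                dg_hybrid=float(row["dg_hybrid"]),
                evidence=row["evidence"] == "true",
            )
            for row in reader
        )
    if name == "hub_top10":
        return tuple(_read_text("hub_top10.txt").split())
    if name == "apoptosis_set":
        return frozenset(_read_text("apoptosis_genes.txt").split())
    raise KeyError(f"unknown fixture {name!r}; one of "
                   f"['table1', 'table2', 'hub_top10', 'apoptosis_set']")


def seed_symbols() -> tuple[str, ...]:
    """The 25 seed gene symbols (table1 fixture), in table order."""
    return tuple(rec.gene_symbol for rec in load_fixture("table1"))


def load_annotation(path=None) -> dict[str, str]:
    """Symbol -> GO-term label from a two-column TSV (packaged by default)."""
    if path is None:
        text = _read_text("annotation.tsv")
    else:
        with open(path) as fh:
            text = fh.read()
    out: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        symbol, term = line.split("\t")
        out[symbol] = term
    return out


def annotated_set(term: str = "apoptotic process", path=None) -> frozenset[str]:
    """Symbols annotated with ``term`` in the annotation table."""
    return frozenset(s for s, t in load_annotation(path).items() if t == term)
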