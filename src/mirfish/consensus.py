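"""Four-tool miRNA target-prediction consensus.

Web predictors disagree wildly (a single 3'UTR can draw a few dozen to a few
thousand predicted miRNAs depending on the tool), so candidates are kept only
when at least ``min_tools`` of the four tools predict them *and* each tool's
own confidence rule passes:

* RNA22          — p-value < 0.05                 (strict)
* miRDB          — prediction score > 80          (strict)
* DIANA-microT   — miTG score >= 0.7
* TargetScan     — context+ score <= -0.1  OR  PCT >= 0.5  (disjunction)

A miRNA is judged on its best-scoring record per tool (tools emit multiple
sites per miRNA; the unit of selection is the miRNA).  Identifiers are
matched case-insensitively with the ``hsa-`` prefix normalized on, since the
tools' exports disagree on both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

TOOLS = ("diana", "mirdb", "targetscan", "rna22")

#: score fields each tool must provide
REQUIRED_FIELDS = {
    "diana": ("mitg_score",),
    "mirdb": ("prediction_score",),
    "targetscan": ("context_plus", "pct"),  # at least one of the two
    "rna22": ("p_value",),
}


@dataclass(frozen=True)
class PredictionRecord:
    """One predictor row: tool, miRNA, gene, optional site, tool scores."""

    tool: str
    mirna: str
    gene: str
    scores: Mapping[str, float]
    site_start: int | None = None
    site_end: int | None = None

    def __post_init__(self):
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if (
            self.site_start is not None
            and self.site_end is not None
            and self.site_start > self.site_end
        ):
            raise ValueError("site_start must be <= site_end")


@dataclass
class ConsensusResult:
    """Kept miRNAs plus the full Venn decomposition over the four tools."""

    kept: set[str]
    venn: dict[frozenset, int]
    per_tool_pass: dict[str, set[str]]
    skipped: int = 0
    display: dict[str, str] = field(default_factory=dict)


def normalize_mirna_id(mirna: str) -> str:
    """Canonical matching key: lowercase, ``hsa-`` prefix guaranteed."""
    key = mirna.strip().lower()
    if not key.startswith("hsa-"):
        key = "hsa-" + key
    return key


def _passes(tool: str, best: dict[str, float]) -> bool:
    if tool == "rna22":
        return best["p_value"] < 0.05
    if tool == "mirdb":
        return best["prediction_score"] > 80
    if tool == "diana":
        return best["mitg_score"] >= 0.7
    if tool == "targetscan":
        ctx = best.get("context_plus")
        pct = best.get("pct")
        return (ctx is not None and ctx <= -0.1) or (pct is not None and pct >= 0.5)
    raise ValueError(tool)


def apply_tool_filters(
    records: Iterable[PredictionRecord],
) -> tuple[dict[str, set[str]], int, dict[str, str]]:
    """Per-tool sets of miRNA ids whose best record passes that tool's rule.

    For each (tool, miRNA) the best record is used: maximum prediction
    score / miTG / PCT, minimum p-value / context+ score.  Records missing
    their tool's required score fields are skipped and counted, never fatal.

    Returns
    -------
    (pass_sets, n_skipped, display)
        ``pass_sets`` maps tool -> set of canonical ids; ``display`` maps
        canonical id -> a representative original spelling.
    """
    # best[tool][mirna][field] -> extremal value seen
    best: dict[str, dict[str, dict[str, float]]] = {t: {} for t in TOOLS}
    display: dict[str, str] = {}
    skipped = 0
    maximize = {"prediction_score", "mitg_score", "pct"}
    for rec in records:
        required = REQUIRED_FIELDS[rec.tool]
        present = [f for f in required if f in rec.scores]
        if not present:
            skipped += 1
            continue
        key = normalize_mirna_id(rec.mirna)
        display.setdefault(key, rec.mirna if rec.mirna.lower().startswith("hsa-") else "hsa-" + rec.mirna)
        slot = best[rec.tool].setdefault(key, {})
        for f in present:
            value = float(rec.scores[f])
            if f not in slot:
                slot[f] = value
            elif f in maximize:
                slot[f] = max(slot[f], value)
            else:
                slot[f] = min(slot[f], value)
    pass_sets = {
        tool: {m for m, scores in per_mirna.items() if _passes(tool, scores)}
        for tool, per_mirna in best.items()
    }
    return pass_sets, skipped, display


def consensus(
    pass_sets: Mapping[str, set[str]], min_tools: int = 3
) -> ConsensusResult:
    """Keep miRNAs present in >= ``min_tools`` of the four pass sets.

    The Venn decomposition counts every miRNA exactly once, in the cell of
    its exact tool-membership subset; all 15 non-empty subsets are reported
    (zero counts included) so any bookkeeping discrepancy is visible.
    """
    if set(pass_sets) != set(TOOLS):
        raise ValueError(f"expected exactly the tools {TOOLS}")
    venn: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, len(TOOLS) + 1)
        for c in combinations(TOOLS, r)
    }
    kept: set[str] = set()
    union = set().union(*pass_sets.values())
    for mirna in union:
        members = frozenset(t for t in TOOLS if mirna in pass_sets[t])
        venn[members] += 1
        if len(members) >= min_tools:
            kept.add(mirna)
    return ConsensusResult(kept=kept, venn=venn, per_tool_pass=dict(pass_sets))


def venn_as_json(venn: Mapping[frozenset, int]) -> dict[str, int]:
    """Venn cells keyed by '+'-joined sorted tool names, for serialization."""
    return {
        "+".join(sorted(cell)): count
        for cell, count in sorted(venn.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    }
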