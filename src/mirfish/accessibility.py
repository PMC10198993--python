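"""Target-site accessibility and candidate ranking.

A miRNA can only nucleate binding where the 3'UTR is single-stranded, so
candidate sites are screened against a per-nucleotide single-strandedness
probability profile (as produced by partition-function folding servers):
positions with probability strictly above 0.5 form "accessible regions", and
a site must overlap one to survive.

Surviving candidates carry two external scores — a binding likelihood
(``logit_prob``, higher is better) and a hybrid free energy (``dg_hybrid``,
kcal/mol, lower i.e. more negative is better) — and are ranked by rank-sum
over the two.  The two criteria usually agree on real shortlists; when they
conflict the rank-sum makes the trade-off explicit and deterministic.

A simplified nearest-neighbor duplex energy (Watson–Crick stacks only, no
loop or dangling-end terms) is provided for generating plausible synthetic
``dg_hybrid`` values and for property tests; externally supplied energies
are never recomputed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

DEFAULT_THRESHOLD = 0.5

_WOBBLE = {("G", "U"), ("U", "G")}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-nucleotide single-strandedness probabilities, 1-based positions."""

    probabilities: tuple[float, ...]

    def __post_init__(self):
        if not self.probabilities:
            raise ValueError("profile must be non-empty")
        if any(p < 0 or p > 1 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self):
        return len(self.probabilities)


@dataclass(frozen=True)
class CandidateSite:
    """A miRNA binding-site candidate on the 3'UTR."""

    mirna: str
    site_start: int
    site_end: int
    logit_prob: float
    dg_hybrid: float
    evidence: bool = False

    def __post_init__(self):
        if self.site_start > self.site_end:
            raise ValueError("site_start must be <= site_end")
        if not 0 <= self.logit_prob <= 1:
            raise ValueError("logit_prob must lie in [0, 1]")


def read_profile_tsv(path: str | Path) -> AccessibilityProfile:
    """Read a two-column (position TAB probability) profile, 1-based contiguous."""
    probs: list[float] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            pos, p = int(row[0]), float(row[1])
            if pos != len(probs) + 1:
                raise ValueError(f"positions must be contiguous from 1, got {pos}")
            probs.append(p)
    return AccessibilityProfile(probabilities=tuple(probs))


def call_accessible_regions(
    profile: AccessibilityProfile, threshold: float = DEFAULT_THRESHOLD
) -> list[tuple[int, int]]:
    """Maximal runs of positions with probability strictly above ``threshold``.

    Returns sorted, disjoint (start, end) pairs, 1-based inclusive.  A
    probability exactly at the threshold is *not* accessible.
    """
    regions: list[tuple[int, int]] = []
    start = None
    for pos, p in enumerate(profile.probabilities, start=1):
        if p > threshold:
            if start is None:
                start = pos
        elif start is not None:
            regions.append((start, pos - 1))
            start = None
    if start is not None:
        regions.append((start, len(profile)))
    return regions


def site_accessible(
    site: CandidateSite,
    regions: Sequence[tuple[int, int]],
    min_overlap: int = 1,
    profile_length: int | None = None,
) -> bool:
    """Whether the site overlaps any accessible region by >= ``min_overlap`` nt."""
    if profile_length is not None and (
        site.site_start < 1 or site.site_end > profile_length
    ):
        raise ValueError(
            f"site {site.site_start}-{site.site_end} outside profile of "
            f"length {profile_length}"
        )
    for start, end in regions:
        overlap = min(site.site_end, end) - max(site.site_start, start) + 1
        if overlap >= min_overlap:
            return True
    return False


def load_duplex_params(path: str | Path | None = None) -> dict:
    """Packaged nearest-neighbor stack table (or a caller-supplied JSON)."""
    if path is None:
        text = resources.files("mirfish.data").joinpath("nn_stacks.json").read_text()
    else:
        text = Path(path).read_text()
    return json.loads(text)


def _is_pair(x: str, y: str) -> bool:
    return (x, y) in _WC or (x, y) in _WOBBLE


def duplex_dG(
    mirna_seq: str,
    site_seq: str,
    pairing: Sequence[tuple[int, int]],
    params: dict | None = None,
) -> float:
    """Nearest-neighbor free energy of a miRNA:site duplex, kcal/mol.

    ``pairing`` lists 0-based (miRNA index, site index) base pairs of an
    antiparallel duplex; both sequences are given 5'->3'.  The energy is the
    initiation penalty plus the stack term for every pair of consecutive
    base pairs (i, j), (i+1, j-1).  Only Watson–Crick stacks are tabulated;
    stacks involving a GU wobble contribute 0 in this simplified model, as
    do unpaired interior positions.

    Raises
    ------
    ValueError
        On a non-complementary pair (neither Watson–Crick nor GU wobble),
        an out-of-range index, or a crossing (non-antiparallel) pairing.
    """
    if params is None:
        params = load_duplex_params()
    mirna = mirna_seq.upper().replace("T", "U")
    site = site_seq.upper().replace("T", "U")
    pairs = sorted(pairing)
    for i, j in pairs:
        if not (0 <= i < len(mirna) and 0 <= j < len(site)):
            raise ValueError(f"pair ({i}, {j}) out of range")
        if not _is_pair(mirna[i], site[j]):
            raise ValueError(
                f"non-complementary pair {mirna[i]}{i}:{site[j]}{j}"
            )
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i1 == i2 or j2 >= j1:
            raise ValueError("pairing must be non-crossing and antiparallel")
    dg = float(params["init_penalty"])
    stacks = params["stack_energies"]
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 == i1 + 1 and j2 == j1 - 1:
            key = f"{mirna[i1]}{mirna[i2]}/{site[j1]}{site[j2]}"
            dg += stacks.get(key, 0.0)
    return dg


def _competition_ranks(values: Sequence[float]) -> list[int]:
    """1-based competition ranks ("min" method) of already-oriented values."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0] * len(values)
    for pos, i in enumerate(order):
        if pos > 0 and values[i] == values[order[pos - 1]]:
            ranks[i] = ranks[order[pos - 1]]
        else:
            ranks[i] = pos + 1
    return ranks


def rank_candidates(
    candidates: Sequence[CandidateSite], require_evidence: bool = False
) -> list[CandidateSite]:
    """Order candidates by rank-sum of binding likelihood and hybrid energy.

    Each candidate receives a rank by descending ``logit_prob`` and a rank by
    ascending ``dg_hybrid`` (most stable first); the rank-sum orders the
    output, smallest first.  Rank-sum ties are broken by higher
    ``logit_prob``, then by miRNA id, so the ordering is a deterministic
    function of the candidate *set* (input order is irrelevant).

    With ``require_evidence`` only literature-supported candidates compete.

    Raises
    ------
    ValueError
        If no candidate remains after the evidence filter.
    """
    pool = [c for c in candidates if c.evidence or not require_evidence]
    if not pool:
        raise ValueError("no candidates remain after filtering")
    logit_ranks = _competition_ranks([-c.logit_prob for c in pool])
    dg_ranks = _competition_ranks([c.dg_hybrid for c in pool])
    keyed = [
        (logit_ranks[i] + dg_ranks[i], -c.logit_prob, c.mirna, c)
        for i, c in enumerate(pool)
    ]
    return [item[3] for item in sorted(keyed, key=lambda t: t[:3])]


def select_best(
    candidates: Sequence[CandidateSite], require_evidence: bool = False
) -> CandidateSite:
    """The top-ranked candidate (see :func:`rank_candidates`)."""
    return rank_candidates(candidates, require_evidence=require_evidence)[0]


def read_candidates_csv(path: str | Path) -> list[CandidateSite]:
    """Read a candidates CSV: mirna,site_start,site_end,logit_prob,dg_hybrid,evidence."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CandidateSite(
                    mirna=row["mirna"],
                    site_start=int(row["site_start"]),
                    site_end=int(row["site_end"]),
                    logit_prob=float(row["logit_prob"]),
                    dg_hybrid=float(row["dg_hybrid"]),
                    evidence=str(row.get("evidence", "")).strip().lower()
                    in {"1", "true", "yes"},
                )
            )
    return out
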