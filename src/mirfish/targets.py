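"""Ligand-based target fishing.

Structurally similar compounds tend to bind similar proteins, so the targets
of a query compound can be "fished" from a bioactivity library: find library
compounds whose structure is more than 70% similar to the query (Tanimoto
over fingerprints), keep those with potency below 150 µM in the organism of
interest, and collect their annotated targets.

The fingerprint here is a deterministic substring-hash scheme over the raw
structure string (SMILES or otherwise): every contiguous substring up to a
maximum length is hashed (CRC-32) onto a fixed-width bit set.  It is a
transparent, dependency-free substrate for Tanimoto comparison; callers with
a cheminformatics toolkit can pass in their own precomputed bit sets
(e.g. RDKit Morgan fingerprints) since similarity and filtering only ever
see the ``Fingerprint`` interface.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

DEFAULT_WIDTH = 2048
DEFAULT_MAX_SUBSTRING = 7
DEFAULT_SIM_MIN = 0.7
DEFAULT_POTENCY_MAX_UM = 150.0
DEFAULT_ORGANISM = "Homo sapiens"


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width bit set for Tanimoto comparison."""

    bits: frozenset[int]
    width: int = DEFAULT_WIDTH

    def __post_init__(self):
        if any(b < 0 or b >= self.width for b in self.bits):
            raise ValueError("fingerprint bit index out of range")


@dataclass(frozen=True)
class LibraryRecord:
    """One bioactivity row: a compound, its target and its potency."""

    compound_id: str
    structure: str
    target_id: str
    target_name: str
    organism: str
    potency_um: float | None = None


@dataclass(frozen=True)
class FishedTarget:
    """A target that passed the filters, with its contributing compounds."""

    target_id: str
    target_name: str
    compound_ids: tuple[str, ...] = field(default_factory=tuple)


def fingerprint(
    structure: str,
    width: int = DEFAULT_WIDTH,
    max_substring: int = DEFAULT_MAX_SUBSTRING,
) -> Fingerprint:
    """Hash every contiguous substring of length 1..max_substring onto bits.

    The hash is CRC-32 of the UTF-8 substring modulo ``width`` — stable
    across runs, platforms and Python versions.

    Raises
    ------
    ValueError
        If ``structure`` is empty.
    """
    if not structure:
        raise ValueError("structure must be non-empty")
    if width < 1 or max_substring < 1:
        raise ValueError("width and max_substring must be >= 1")
    bits = set()
    n = len(structure)
    for i in range(n):
        for j in range(i + 1, min(i + max_substring, n) + 1):
            bits.add(zlib.crc32(structure[i:j].encode()) % width)
    return Fingerprint(bits=frozenset(bits), width=width)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |A∩B| / |A∪B| of two bit sets.

    Two empty fingerprints are defined to be 0.0 similar: 0/0 is
    indeterminate and structureless inputs should never match anything.

    Raises
    ------
    ValueError
        On width mismatch.
    """
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} != {b.width}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def fish_targets(
    query: Fingerprint,
    library: Sequence[LibraryRecord],
    sim_min: float = DEFAULT_SIM_MIN,
    potency_max_um: float = DEFAULT_POTENCY_MAX_UM,
    organism: str = DEFAULT_ORGANISM,
    fingerprints: dict[str, Fingerprint] | None = None,
) -> list[FishedTarget]:
    """Collect targets of library compounds similar to the query.

    A record contributes its target iff

    * Tanimoto(query, record) > ``sim_min`` (strictly more similar),
    * ``potency_um`` is present and strictly below ``potency_max_um``,
    * its organism matches.

    Records with unknown potency are excluded — the potency criterion cannot
    be verified for them.  Returns one entry per distinct target id, sorted
    by target id, each with the contributing compound ids as provenance.

    Parameters
    ----------
    fingerprints : optional
        Precomputed fingerprint per compound_id (e.g. from an external
        cheminformatics backend); structures are hashed on the fly otherwise.
    """
    if not library:
        raise ValueError("library must be non-empty")
    by_target: dict[str, tuple[str, list[str]]] = {}
    for rec in library:
        if rec.organism != organism:
            continue
        if rec.potency_um is None or not rec.potency_um < potency_max_um:
            continue
        fp = (
            fingerprints.get(rec.compound_id)
            if fingerprints is not None
            else None
        )
        if fp is None:
            fp = fingerprint(rec.structure, width=query.width)
        if not tanimoto(query, fp) > sim_min:
            continue
        name, compounds = by_target.setdefault(rec.target_id, (rec.target_name, []))
        if rec.compound_id not in compounds:
            compounds.append(rec.compound_id)
    return [
        FishedTarget(target_id=tid, target_name=name, compound_ids=tuple(compounds))
        for tid, (name, compounds) in sorted(by_target.items())
    ]


def read_library_csv(path) -> list[LibraryRecord]:
    """Read a compound library CSV.

    Expected header: compound_id,structure,target_id,target_name,organism,potency_um
    (potency_um may be blank for unknown potency).
    """
    import csv

    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            potency = row.get("potency_um", "")
            records.append(
                LibraryRecord(
                    compound_id=row["compound_id"],
                    structure=row["structure"],
                    target_id=row["target_id"],
                    target_name=row["target_name"],
                    organism=row["organism"],
                    potency_um=float(potency) if potency else None,
                )
            )
    return records
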