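"""Classify metabolites by likely organismal origin via KO-set logic.

Given a map from KEGG compound identifiers to the KEGG Orthology groups
(KOs) whose reactions can produce them, plus KO inventories for the host
genome, the sparse-model-selected taxa, and the remaining (non-selected)
taxa, each compound is classified as host_only, microbe_only,
host_or_microbe, or other (no producing KO in any provided inventory).
Microbial evidence is sub-labelled by whether it comes from the selected
taxa, the non-selected taxa, or both.

All KEGG content is consumed from local flat files; there is no live
database access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

HOST_ONLY = "host_only"
MICROBE_ONLY = "microbe_only"
HOST_OR_MICROBE = "host_or_microbe"
OTHER = "other"
CATEGORIES = (HOST_ONLY, MICROBE_ONLY, HOST_OR_MICROBE, OTHER)

SELECTED = "selected_taxa"
NONSELECTED = "nonselected_taxa"
BOTH = "both"


@dataclass
class KoSet:
    """A labelled set of KEGG Orthology identifiers."""

    label: str
    kos: frozenset[str]

    def __post_init__(self) -> None:
        kos = {k.strip() for k in self.kos}
        if any(not k for k in kos):
            raise ValueError("empty KO identifier")
        self.kos = frozenset(kos)


def read_ko_set(path: str | Path, label: str) -> KoSet:
    """One KO identifier per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    kos = {
        ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")
    }
    return KoSet(label=label, kos=frozenset(kos))


def read_production_map(path: str | Path) -> dict[str, set[str]]:
    """TSV of ``compound_id<TAB>ko_id`` rows -> compound -> producing KOs."""
    out: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed production-map line: {ln!r}")
        compound, ko = parts[0].strip(), parts[1].strip()
        out.setdefault(compound, set()).add(ko)
    return out


def collapse_compounds(
    name_to_id: Mapping[str, Optional[str]],
) -> tuple[list[str], list[str]]:
    """De-duplicate selected metabolite names to unique compound identifiers.

    Names mapping to the same identifier collapse to one compound; names
    with no identifier (None or empty) are reported separately as unmapped.
    Returns (unique compound ids, unmapped names), both sorted.
    """
    ids = set()
    unmapped = []
    for name, cid in name_to_id.items():
        if cid:
            ids.add(cid)
        else:
            unmapped.append(name)
    return sorted(ids), sorted(unmapped)


@dataclass
class OriginClassification:
    """Per-compound origin category plus microbial-evidence sub-label."""

    categories: dict[str, str]
    microbe_evidence: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cat in self.categories.values():
            out[cat] += 1
        return out

    def compounds_in(self, category: str) -> list[str]:
        return sorted(c for c, cat in self.categories.items() if cat == category)


def classify_origins(
    compounds: Iterable[str],
    production_map: Mapping[str, set[str]],
    host: KoSet,
    selected: KoSet,
    nonselected: KoSet,
) -> OriginClassification:
    """Assign each compound an origin category from its producing-KO set.

    Let P be the compound's producing KOs (empty if absent from the map).
    Host evidence means P intersects the host KO set; microbial evidence
    means P intersects the union of selected and non-selected taxa KOs.
    Direction of the annotated reactions is not considered.
    """
    categories: dict[str, str] = {}
    evidence: dict[str, str] = {}
    for compound in compounds:
        producing = set(production_map.get(compound, set()))
        host_hit = bool(producing & host.kos)
        sel_hit = bool(producing & selected.kos)
        nonsel_hit = bool(producing & nonselected.kos)
        microbe_hit = sel_hit or nonsel_hit
        if host_hit and microbe_hit:
            categories[compound] = HOST_OR_MICROBE
        elif host_hit:
            categories[compound] = HOST_ONLY
        elif microbe_hit:
            categories[compound] = MICROBE_ONLY
        else:
            categories[compound] = OTHER
        if microbe_hit:
            if sel_hit and nonsel_hit:
                evidence[compound] = BOTH
            elif sel_hit:
                evidence[compound] = SELECTED
            else:
                evidence[compound] = NONSELECTED
    return OriginClassification(categories=categories, microbe_evidence=evidence)
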