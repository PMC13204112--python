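"""Curated gene modules and ligand–receptor configurations.

The registry houses the gene sets used for per-sample module scoring
(multiciliogenesis master regulators, core and ciliary planar cell
polarity) together with the epithelial-cytokine ligand→receptor-subunit
configurations (TSLP, IL-33, IL-25) used for interaction scoring. Sets
are plain ordered lists of HGNC symbols; matching is case-insensitive
after uppercasing and no alias expansion is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "GeneSet",
    "LigandReceptorConfig",
    "GeneSetRegistry",
    "builtin_registry",
    "resolve",
    "load_registry",
    "save_registry",
    "CATEGORIES",
]

CATEGORIES = frozenset(
    {"master", "pcp_core", "pcp_cilia", "ciliogenesis", "mucus", "cytokine_receptor"}
)


class RegistryError(ValueError):
    """Malformed registry document or invalid gene-set definition."""


class EmptyOverlapError(ValueError):
    """A gene set shares no symbols with the data's gene universe."""


def _upper_unique(genes: Iterable[str], context: str) -> list[str]:
    out = [str(g).strip().upper() for g in genes]
    if not out:
        raise RegistryError(f"{context}: gene list is empty")
    seen = set()
    for g in out:
        if g in seen:
            raise RegistryError(f"{context}: duplicate gene symbol {g!r}")
        seen.add(g)
    return out


@dataclass(frozen=True)
class GeneSet:
    """A named, categorized gene module (ordered HGNC symbols)."""

    name: str
    category: str
    genes: tuple[str, ...]
    subcategory: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RegistryError(
                f"gene set {self.name!r}: unknown category {self.category!r} "
                f"(expected one of {sorted(CATEGORIES)})"
            )
        object.__setattr__(self, "genes", tuple(_upper_unique(self.genes, f"gene set {self.name!r}")))


@dataclass(frozen=True)
class LigandReceptorConfig:
    """A cytokine ligand with its receptor subunits (for interaction scores)."""

    ligand: str
    receptor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand", str(self.ligand).strip().upper())
        subunits = tuple(_upper_unique(self.receptor_subunits, f"receptor subunits of {self.ligand}"))
        if self.ligand in subunits:
            raise RegistryError(f"ligand {self.ligand} cannot be one of its own receptor subunits")
        object.__setattr__(self, "receptor_subunits", subunits)


@dataclass
class GeneSetRegistry:
    """Mapping of gene-set name -> GeneSet plus cytokine -> ligand/receptor config."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    lr_configs: dict[str, LigandReceptorConfig] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise RegistryError(f"duplicate gene-set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetRegistry):
            return NotImplemented
        return self.sets == other.sets and self.lr_configs == other.lr_configs


# Score sets: the three module scores. The 12-gene master heatmap set keeps
# CDC20B, which is not part of the 11-gene Cilia Master score set.
_CILIA_MASTER = (
    "TP73", "MCIDAS", "E2F4", "E2F5", "CCNO", "DEUP1",
    "MYB", "FOXJ1", "FOXN4", "RFX2", "RFX3",
)
_CORE_PCP = (
    "CELSR1", "CELSR2", "CELSR3", "FZD3", "FZD6", "VANGL1", "VANGL2",
    "DVL1", "DVL2", "DVL3", "PRICKLE1", "PRICKLE2", "PRICKLE3", "PRICKLE4",
    "ANKRD6",
)
_CILIA_PCP = ("FUZ", "INTU", "WDPCP")

# Partial mucus module: genes named in the main-text DEG tables. The full
# curated 25-gene list is not shipped; extend via load_registry / add().
_MUCUS = (
    "CCL26", "SPDEF", "MUC5AC", "MUC5B", "POSTN", "ALOX15", "SLC26A4",
    "TFF3", "FCGBP", "GSTP1", "SERPINE1", "F13A1", "DNASE1L3", "BPIFA1",
    "BPIFB1", "PLAT",
)
_MUCUS_DEGRADATION = ("DNASE1L3", "BPIFA1", "BPIFB1", "PLAT")
_CYTOKINE_RECEPTOR = (
    "TSLP", "CRLF2", "IL7R", "IL33", "IL1RL1", "IL1RAP",
    "IL25", "IL17RA", "IL17RB", "IL4R", "IL13RA1",
)


def builtin_registry() -> GeneSetRegistry:
    """Built-in registry with the curated scoring modules.

    Contains the three score sets (``cilia_master`` 11 genes, ``core_pcp``
    15, ``cilia_pcp`` 3), the 12-gene master heatmap set, partial mucus
    modules, the cytokine/receptor panel, and ligand–receptor configs for
    TSLP, IL-33 and IL-25.
    """
    reg = GeneSetRegistry()
    reg.add(GeneSet("cilia_master", "master", _CILIA_MASTER, "Ciliogenesis Master Switch"))
    reg.add(GeneSet("core_pcp", "pcp_core", _CORE_PCP, "Core PCP components"))
    reg.add(GeneSet("cilia_pcp", "pcp_cilia", _CILIA_PCP, "CPLANE ciliary effectors"))
    reg.add(
        GeneSet(
            "master_regulators", "master", _CILIA_MASTER + ("CDC20B",),
            "Multiciliogenesis master regulators (heatmap set)",
        )
    )
    reg.add(GeneSet("mucus", "mucus", _MUCUS, "Mucus Pathophysiology & GCM (partial)"))
    reg.add(
        GeneSet(
            "mucus_degradation", "mucus", _MUCUS_DEGRADATION,
            "Mucus Degradation & Remodeling",
        )
    )
    reg.add(
        GeneSet(
            "epithelial_cytokines", "cytokine_receptor", _CYTOKINE_RECEPTOR,
            "Epithelial-derived cytokines & receptors",
        )
    )
    reg.lr_configs = {
        "TSLP": LigandReceptorConfig("TSLP", ("CRLF2", "IL7R")),
        "IL33": LigandReceptorConfig("IL33", ("IL1RL1", "IL1RAP")),
        "IL25": LigandReceptorConfig("IL25", ("IL17RA", "IL17RB")),
    }
    return reg


def resolve(
    registry: GeneSetRegistry, set_name: str, universe: Iterable[str]
) -> tuple[list[str], list[str]]:
    """Split a gene set into (present, missing) against a gene universe.

    ``present`` keeps the set's own order; the two lists partition the set.
    Raises ``KeyError`` for an unknown set and ``EmptyOverlapError`` when no
    gene is present (a score over zero genes is undefined).
    """
    if set_name not in registry.sets:
        raise KeyError(f"unknown gene set {set_name!r}")
    uni = {str(g).upper() for g in universe}
    genes = registry.sets[set_name].genes
    present = [g for g in genes if g in uni]
    missing = [g for g in genes if g not in uni]
    if not present:
        raise EmptyOverlapError(
            f"gene set {set_name!r} has no overlap with the provided gene universe"
        )
    return present, missing


def save_registry(registry: GeneSetRegistry, path: str | Path) -> None:
    """Serialize a registry to JSON (keys: "sets", "lr_configs")."""
    doc = {
        "sets": {
            name: {
                "category": gs.category,
                "subcategory": gs.subcategory,
                "genes": list(gs.genes),
            }
            for name, gs in registry.sets.items()
        },
        "lr_configs": {
            name: {"ligand": cfg.ligand, "receptor_subunits": list(cfg.receptor_subunits)}
            for name, cfg in registry.lr_configs.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_registry(path: str | Path) -> GeneSetRegistry:
    """Load a registry from JSON, or from 2-column TSV (set_name<TAB>gene).

    TSV rows carry no category, so TSV-loaded sets default to the broad
    "ciliogenesis" category; use JSON for full control over categories,
    subcategories and ligand–receptor configs.
    """
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in {".tsv", ".txt"}:
        return _load_tsv_registry(text)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RegistryError(f"not valid JSON: {exc}") from exc
    if "sets" not in doc:
        raise RegistryError('registry document is missing the "sets" key')
    reg = GeneSetRegistry()
    for name, spec in doc["sets"].items():
        if "genes" not in spec:
            raise RegistryError(f'set {name!r} is missing the "genes" key')
        reg.add(
            GeneSet(
                name,
                spec.get("category", "ciliogenesis"),
                tuple(spec["genes"]),
                spec.get("subcategory"),
            )
        )
    for name, spec in doc.get("lr_configs", {}).items():
        if "ligand" not in spec or "receptor_subunits" not in spec:
            raise RegistryError(
                f'lr_config {name!r} needs "ligand" and "receptor_subunits" keys'
            )
        reg.lr_configs[name] = LigandReceptorConfig(
            spec["ligand"], tuple(spec["receptor_subunits"])
        )
    return reg


def _load_tsv_registry(text: str) -> GeneSetRegistry:
    groups: dict[str, list[str]] = {}
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise RegistryError(f"line {i}: expected 2 tab-separated columns")
        groups.setdefault(parts[0].strip(), []).append(parts[1])
    reg = GeneSetRegistry()
    for name, genes in groups.items():
        reg.add(GeneSet(name, "ciliogenesis", tuple(genes)))
    return reg
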