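"""Per-sample gene-set module scores and cytokine interaction scores.

A gene-set score is the arithmetic mean of log2(CPM+1) expression over the
set's genes present in the matrix. A cytokine interaction score is the
ligand's expression times the mean expression of its receptor subunits,
a per-sample proxy for signaling potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genesets import GeneSetRegistry, LigandReceptorConfig, resolve
from .preprocess import ExpressionMatrix, SpaceError

__all__ = ["ScoreTable", "geneset_score", "interaction_score", "compute_all_scores"]

DEFAULT_SCORE_SETS = ("cilia_master", "core_pcp", "cilia_pcp")
DEFAULT_CYTOKINES = ("TSLP", "IL33", "IL25")

#: interaction-score column name per cytokine
IX_COLUMN = {"TSLP": "tslp_ix", "IL33": "il33_ix", "IL25": "il25_ix"}


class CoverageError(ValueError):
    """Too few of a score's genes are present in the expression matrix."""


def _check_space(expr: ExpressionMatrix, allow: tuple[str, ...]) -> None:
    if expr.space not in allow:
        raise SpaceError(f"scores expect space in {allow}, got {expr.space!r}")


def _upper_index(expr: ExpressionMatrix) -> dict[str, str]:
    """Uppercase symbol -> actual row label (case-insensitive matching)."""
    return {str(g).upper(): g for g in expr.data.index}


def geneset_score(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Mean expression over ``genes`` for each sample.

    ``genes`` must be non-empty and fully contained in the matrix (resolve
    missing symbols against the registry first). Symbols are matched
    case-insensitively.
    """
    _check_space(expr, ("log2cpm1", "cpm"))
    if not genes:
        raise ValueError("gene list is empty")
    lookup = _upper_index(expr)
    genes = [g.upper() for g in genes]
    absent = [g for g in genes if g not in lookup]
    if absent:
        raise KeyError(f"genes not in expression matrix: {absent}")
    return expr.data.loc[[lookup[g] for g in genes]].mean(axis=0)


def interaction_score(expr: ExpressionMatrix, config: LigandReceptorConfig) -> pd.Series:
    """Ligand expression x mean expression of present receptor subunits.

    Receptor subunits absent from the matrix are dropped (the caller can
    track coverage); an absent ligand or a fully absent receptor panel is
    an error.
    """
    _check_space(expr, ("log2cpm1", "cpm"))
    lookup = _upper_index(expr)
    if config.ligand not in lookup:
        raise KeyError(f"ligand {config.ligand!r} not in expression matrix")
    present = [lookup[r] for r in config.receptor_subunits if r in lookup]
    if not present:
        raise KeyError(
            f"no receptor subunit of {config.ligand} present "
            f"(looked for {list(config.receptor_subunits)})"
        )
    return expr.data.loc[lookup[config.ligand]] * expr.data.loc[present].mean(axis=0)


@dataclass
class ScoreTable:
    """Per-sample score matrix plus per-score gene coverage fractions."""

    values: pd.DataFrame  # index = sample_id, one column per score
    coverage: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, score: str) -> pd.Series:
        return self.values[score]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def compute_all_scores(
    expr: ExpressionMatrix,
    registry: GeneSetRegistry,
    score_names: tuple[str, ...] = DEFAULT_SCORE_SETS,
    lr_names: tuple[str, ...] = DEFAULT_CYTOKINES,
    min_coverage: float = 0.5,
) -> ScoreTable:
    """Compute all requested gene-set and interaction scores.

    Missing genes are tolerated down to ``min_coverage`` of each set (the
    score is then the mean over the present subset); below that the score
    is refused. Ligands with zero expression everywhere yield an all-zero
    interaction score and a zero-variance flag.
    """
    _check_space(expr, ("log2cpm1", "cpm"))
    cols: dict[str, pd.Series] = {}
    coverage: dict[str, float] = {}
    flags: dict[str, str] = {}
    for name in score_names:
        present, missing = resolve(registry, name, expr.genes)
        cov = len(present) / (len(present) + len(missing))
        if cov < min_coverage:
            raise CoverageError(
                f"gene set {name!r}: only {len(present)}/{len(present) + len(missing)} "
                f"genes present (coverage {cov:.2f} < {min_coverage})"
            )
        cols[name] = geneset_score(expr, present)
        coverage[name] = cov
    for cyt in lr_names:
        if cyt not in registry.lr_configs:
            raise KeyError(f"no ligand-receptor config for cytokine {cyt!r}")
        cfg = registry.lr_configs[cyt]
        col = IX_COLUMN.get(cyt, f"{cyt.lower()}_ix")
        cols[col] = interaction_score(expr, cfg)
        lookup = _upper_index(expr)
        n_rec = len(cfg.receptor_subunits)
        n_present = sum(r in lookup for r in cfg.receptor_subunits)
        coverage[col] = (1 + n_present) / (1 + n_rec)
        if cols[col].nunique() == 1:
            flags[col] = "zero-variance"
    table = pd.DataFrame(cols)
    table.index.name = "sample_id"
    return ScoreTable(table, coverage, flags)
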