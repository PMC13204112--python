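"""End-to-end orchestration: scores -> group LMM + Tukey -> DE -> recovery.

`run_pipeline` wires the stages together behind a single RunConfig and
writes a ReportBundle of plot-ready tables plus a reproducibility manifest
(config echo, seed, package version, SHA-256 of every output). All outputs
are deterministic functions of the inputs and the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genesets import GeneSetRegistry, builtin_registry, load_registry, resolve
from .preprocess import (
    CountMatrix,
    SampleMetadata,
    cpm,
    gene_zscores,
    log2p1,
    read_counts,
    read_metadata,
)
from .scoring import DEFAULT_CYTOKINES, DEFAULT_SCORE_SETS, IX_COLUMN, ScoreTable, compute_all_scores
from .diffexpr import categorize_degs, estimate_dispersions, nb_wald, size_factors
from .mixedmodels import (
    adjusted_recovery_lmm,
    association_lmm,
    fit_group_lmm,
    fit_recovery_lmm,
    tukey_contrasts,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "DEFAULT_CONTRASTS"]

logger = logging.getLogger("mucocilia")

#: the six reporting-grid comparisons (level_a vs level_b)
DEFAULT_CONTRASTS = (
    ("PostECRS", "PreECRS"),
    ("nonECRS", "Ctrl"),
    ("PreECRS", "Ctrl"),
    ("PostECRS", "Ctrl"),
    ("PreECRS", "nonECRS"),
    ("PostECRS", "nonECRS"),
)


@dataclass
class RunConfig:
    """Paths and options for a full pipeline run."""

    counts_path: str
    metadata_path: str
    out_dir: str
    counts_format: str = "tsv"
    genes_path: str | None = None
    samples_path: str | None = None
    registry_path: str | None = None
    space: str = "log2cpm1"  # expression space for scores: log2cpm1 or cpm
    score_sets: tuple[str, ...] = DEFAULT_SCORE_SETS
    cytokines: tuple[str, ...] = DEFAULT_CYTOKINES
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    recovery_baseline: str = "IL33"
    recovery_scores: tuple[str, ...] = DEFAULT_SCORE_SETS
    adjust_covariates: tuple[str, ...] = ()
    padj_cut: float = 0.05
    lfc_cut: float = 1.0
    min_coverage: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in doc:
            doc["contrasts"] = tuple(tuple(c) for c in doc["contrasts"])
        for key in ("score_sets", "cytokines", "recovery_scores", "adjust_covariates"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d


@dataclass
class ReportBundle:
    """In-memory handles on everything the pipeline wrote."""

    out_dir: Path
    score_table: ScoreTable
    zscore_files: dict[str, Path]
    contrast_tables: dict[str, pd.DataFrame]
    lmm_summaries: dict[str, dict]
    de_results: dict[str, pd.DataFrame]
    categorized_degs: pd.DataFrame
    associations: dict[str, dict]
    recovery: dict[str, dict]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(doc: dict, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(doc), indent=1, sort_keys=True))


def _lmm_summary(fit) -> dict:
    return {
        "formula": fit.formula,
        "fixed_effects": {
            name: {k: float(row[k]) for k in ("estimate", "se", "df", "t", "p")}
            for name, row in fit.fixed_effects.iterrows()
        },
        "sigma2_u": float(fit.sigma2_u),
        "sigma2_e": float(fit.sigma2_e),
        "method": fit.method,
        "n_obs": int(fit.n_obs),
        "n_groups": int(fit.n_groups),
        "singular": bool(fit.singular),
    }


def run_pipeline(
    config: RunConfig,
    counts: CountMatrix | None = None,
    meta: SampleMetadata | None = None,
    registry: GeneSetRegistry | None = None,
) -> ReportBundle:
    """Execute preprocess -> scoring -> diffexpr -> mixed models, write outputs.

    In-memory ``counts``/``meta``/``registry`` override the config paths
    (used by the `simulate` round trip and the tests). Stage failures abort
    with the stage name; a missing PostECRS arm skips the recovery stage
    with a warning rather than failing the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        if counts is None:
            counts = read_counts(
                config.counts_path, config.counts_format,
                genes_path=config.genes_path, samples_path=config.samples_path,
            )
        if meta is None:
            meta = read_metadata(config.metadata_path)
        if registry is None:
            registry = (
                load_registry(config.registry_path) if config.registry_path else builtin_registry()
            )
        missing_samples = set(counts.samples) ^ set(meta.sample_ids)
        if missing_samples:
            raise ValueError(f"counts/metadata sample mismatch: {sorted(missing_samples)}")
        logger.info("loaded %d genes x %d samples", *counts.shape)

        # --- preprocess ------------------------------------------------
        expr_cpm = cpm(counts)
        expr_log = log2p1(expr_cpm)
        expr_scores = expr_log if config.space == "log2cpm1" else expr_cpm
        zmat = gene_zscores(expr_log)
        zscore_files: dict[str, Path] = {}
        for name, gs in registry.sets.items():
            try:
                present, _ = resolve(registry, name, counts.genes)
            except Exception:
                continue
            p = out / f"zscore_{name}.tsv"
            zmat.data.loc[present].to_csv(p, sep="\t", float_format="%.10g")
            zscore_files[name] = p
            written.append(p)

        # --- scoring ----------------------------------------------------
        st = compute_all_scores(
            expr_scores, registry, config.score_sets, config.cytokines,
            min_coverage=config.min_coverage,
        )
        p = out / "scores.tsv"
        st.to_tsv(p)
        written.append(p)
        p = out / "scores_coverage.json"
        _write_json({"coverage": st.coverage, "flags": st.flags, "space": config.space}, p)
        written.append(p)

        # --- group LMM + Tukey -------------------------------------------
        groups = meta.group_of()
        contrast_tables: dict[str, pd.DataFrame] = {}
        lmm_summaries: dict[str, dict] = {}
        for name in config.score_sets:
            fit = fit_group_lmm(st[name], meta)
            ct = tukey_contrasts(fit)
            contrast_tables[name] = ct.table
            lmm_summaries[name] = _lmm_summary(fit)
            p = out / f"contrasts_{name}.tsv"
            ct.to_tsv(p)
            written.append(p)
            p = out / f"lmm_{name}.json"
            _write_json(lmm_summaries[name], p)
            written.append(p)

        # --- differential expression -------------------------------------
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, groups)
        de_results: dict[str, pd.DataFrame] = {}
        all_cat = []
        for (a, b) in config.contrasts:
            n_a, n_b = (groups == a).sum(), (groups == b).sum()
            if n_a < 2 or n_b < 2:
                logger.warning("skipping contrast %s vs %s (too few samples)", a, b)
                continue
            res = nb_wald(counts, sf, disp, groups, (a, b))
            key = f"{a}_vs_{b}"
            de_results[key] = res
            p = out / f"de_{key}.tsv"
            res.drop(columns=["tested"]).to_csv(p, sep="\t", index=False, float_format="%.10g")
            written.append(p)
            cat = categorize_degs(res, registry)
            cat.insert(0, "contrast", key)
            all_cat.append(cat)
        categorized = (
            pd.concat(all_cat, ignore_index=True)
            if all_cat
            else pd.DataFrame(columns=["contrast", "gene", "set", "category", "subcategory", "call", "glyph"])
        )
        p = out / "degs_categorized.tsv"
        categorized.to_csv(p, sep="\t", index=False)
        written.append(p)

        # --- associations (cross-sectional) ------------------------------
        associations: dict[str, dict] = {}
        for cyt in config.cytokines:
            col = IX_COLUMN.get(cyt, f"{cyt.lower()}_ix")
            for name in config.score_sets:
                key = f"{name}~{col}"
                try:
                    a = association_lmm(st[name], st[col], meta)
                except ValueError as exc:
                    logger.warning("association %s skipped: %s", key, exc)
                    continue
                associations[key] = {
                    "slope": a.slope, "se": a.se, "df": a.df, "p_lmm": a.p_lmm,
                    "r2_marginal": a.r2_marginal, "r2_conditional": a.r2_conditional,
                    "rm": a.rm, "n_obs": a.n_obs,
                }
        p = out / "associations.json"
        _write_json(associations, p)
        written.append(p)

        # --- recovery prediction ------------------------------------------
        recovery: dict[str, dict] = {}
        if (groups == "PostECRS").any():
            baseline = _baseline_ix(st, meta, config.recovery_baseline)
            for name in config.recovery_scores:
                res = fit_recovery_lmm(st[name], meta, baseline)
                entry = {
                    "baseline": config.recovery_baseline,
                    "beta_condition": res.beta_condition,
                    "beta_baseline": res.beta_baseline,
                    "beta_interaction": res.beta_interaction,
                    "se_interaction": res.se_interaction,
                    "df_interaction": res.df_interaction,
                    "p_interaction": res.p_interaction,
                    "rm": res.rm,
                    "r2_marginal": res.r2_marginal,
                    "n_patients": res.n_patients,
                }
                if config.adjust_covariates:
                    adj = adjusted_recovery_lmm(
                        st[name], meta, baseline, covariate_names=config.adjust_covariates
                    )
                    entry["adjusted"] = {
                        "p_interaction": adj.p_interaction,
                        "beta_interaction": adj.beta_interaction,
                        "dropped_covariates": list(adj.dropped_covariates),
                        "covariates": {
                            n: {k: float(r[k]) for k in ("estimate", "se", "df", "t", "p")}
                            for n, r in (
                                adj.covariate_estimates
                                if adj.covariate_estimates is not None
                                else pd.DataFrame()
                            ).iterrows()
                        },
                    }
                recovery[name] = entry
        else:
            logger.warning("no PostECRS samples; recovery stage skipped")
        p = out / "recovery.json"
        _write_json(recovery, p)
        written.append(p)

        # --- manifest ------------------------------------------------------
        manifest = {
            "package": "mucocilia",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": {f.name: _sha256(f) for f in sorted(written)},
        }
        p = out / "manifest.json"
        _write_json(manifest, p)

        return ReportBundle(
            out_dir=out,
            score_table=st,
            zscore_files=zscore_files,
            contrast_tables=contrast_tables,
            lmm_summaries=lmm_summaries,
            de_results=de_results,
            categorized_degs=categorized,
            associations=associations,
            recovery=recovery,
            manifest=manifest,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def _baseline_ix(st: ScoreTable, meta: SampleMetadata, cytokine: str) -> pd.Series:
    """Per-patient pre-treatment interaction score, indexed by patient_id."""
    col = IX_COLUMN.get(cytokine, f"{cytokine.lower()}_ix")
    tab = meta.table
    pre = tab[tab["group"] == "PreECRS"]
    return pd.Series(
        st[col].loc[pre["sample_id"]].to_numpy(), index=pre["patient_id"].to_numpy()
    )
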