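"""End-to-end orchestration: qc -> contrasts -> three-way -> venn ->
validation -> enrichment -> qpcr, from a single config with one seed.

Every stage writes plain TSV/JSON under the run directory and the run ends
with a manifest (inputs, parameters, per-stage seeds, package version) from
which the run is reproducible.  Per-stage randomness derives from the single
top-level seed through ``numpy.random.SeedSequence([seed, stage_index])``.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deg_selection import (
    min_replicate_correlation,
    replicate_correlation,
    three_way_select,
    two_group_contrast,
    venn_summary,
)
from .go_enrichment import enrich
from .io_formats import (
    CandidateSet,
    StudyDesign,
    design_from_dict,
    load_annotations,
    load_design,
    load_expression,
    write_candidate_table,
    write_expression,
)
from .phenotyping import write_phenotypes
from .qpcr import concordance, summarize_ct_table
from .set_validation import kw_set_validation, poisson_overlap_p
from .synthetic_data import SimulationParams, simulate_ct_table, simulate_expression, simulate_phenotypes, truth_frame

__all__ = ["RunConfig", "run_pipeline", "simulate_bundle", "stage_seed"]

log = logging.getLogger("olivearch")

_STAGES = ("qc", "contrast", "threeway", "venn", "validate", "enrich", "qpcr")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the top-level seed."""
    idx = _STAGES.index(stage) if stage in _STAGES else 97
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    expression: str
    design: str
    output_dir: str
    annotations: str | None = None
    phenotypes: str | None = None
    ct_table: str | None = None
    truth: str | None = None
    alpha: float = 0.05
    fc_threshold: float = 2.0
    test_scale: str = "log2"
    n_random: int = 1000
    universe: int | None = None  # default: genes on the array
    enrichment_cutoff: float = 0.05
    seed: int = 0
    stages: tuple[str, ...] = _STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.get("paths", {})
        params = raw.get("parameters", {})
        known = {
            "expression", "design", "output_dir", "annotations",
            "phenotypes", "ct_table", "truth",
        }
        bad = set(paths) - known
        if bad:
            raise ValueError(f"unknown path keys in config: {sorted(bad)}")
        kwargs = {k: v for k, v in paths.items()}
        for key in (
            "alpha", "fc_threshold", "test_scale", "n_random",
            "universe", "enrichment_cutoff", "seed",
        ):
            if key in params:
                kwargs[key] = params[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    matrix = load_expression(config.expression)
    design: StudyDesign = load_design(config.design)
    if config.alpha is None:
        config.alpha = design.alpha
    universe_n = config.universe or matrix.n_genes

    manifest: dict = {
        "version": __version__,
        "inputs": {
            "expression": str(config.expression),
            "design": str(config.design),
            "annotations": config.annotations,
            "phenotypes": config.phenotypes,
            "ct_table": config.ct_table,
            "truth": config.truth,
        },
        "parameters": {
            "alpha": config.alpha,
            "fc_threshold": config.fc_threshold,
            "test_scale": config.test_scale,
            "n_random": config.n_random,
            "universe": universe_n,
            "enrichment_cutoff": config.enrichment_cutoff,
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        },
        "stages": list(config.stages),
        "outputs": {},
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, []).append(str(path))

    candidate_sets: list[CandidateSet] = []
    contrasts: dict[str, dict] = {}

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "qc":
                rc = replicate_correlation(matrix)
                rc.to_csv(out / "replicate_correlation.tsv", sep="\t", index=False, float_format="%.6g")
                record(stage, "replicate_correlation", out / "replicate_correlation.tsv")
                mins = min_replicate_correlation(matrix)
                mins.to_csv(out / "replicate_correlation_min.tsv", sep="\t", float_format="%.6g")
                record(stage, "replicate_correlation_min", out / "replicate_correlation_min.tsv")

            elif stage == "contrast":
                for d in design.three_way:
                    for role, (ga, gb) in (("primary", d.primary), ("concordance", d.concordance)):
                        res = two_group_contrast(
                            matrix, ga, gb,
                            alpha=config.alpha,
                            fc_threshold=config.fc_threshold,
                            test_scale=config.test_scale,
                        )
                        contrasts.setdefault(d.trait, {})[role] = res
                        path = out / f"contrast_{d.trait}_{role}.tsv"
                        res.write(path)
                        record(stage, f"{d.trait}_{role}", path)

            elif stage == "threeway":
                if not contrasts:
                    raise RuntimeError("threeway requires the contrast stage")
                for d in design.three_way:
                    cs = three_way_select(
                        contrasts[d.trait]["primary"],
                        contrasts[d.trait]["concordance"],
                        alpha=config.alpha,
                        trait=d.trait,
                    )
                    candidate_sets.append(cs)
                write_candidate_table(candidate_sets, out / "candidates.tsv")
                record(stage, "candidates", out / "candidates.tsv")
                if config.truth:
                    rec = recovery_metrics(candidate_sets, pd.read_csv(config.truth, sep="\t"))
                    rec.to_csv(out / "recovery.tsv", sep="\t", index=False, float_format="%.6g")
                    record(stage, "recovery", out / "recovery.tsv")

            elif stage == "venn":
                if len(candidate_sets) == 3:
                    vs = venn_summary(candidate_sets)
                    _write_json(vs.to_dict(), out / "venn.json")
                    record(stage, "venn", out / "venn.json")
                    pd.DataFrame(
                        sorted(vs.union_members), columns=["gene_id"]
                    ).to_csv(out / "union_members.tsv", sep="\t", index=False)
                    record(stage, "union_members", out / "union_members.tsv")
                else:
                    log.warning("venn skipped: %d candidate sets (need 3)", len(candidate_sets))

            elif stage == "validate":
                reports = []
                kw_seed = stage_seed(config.seed, stage)
                for cs in candidate_sets:
                    if len(cs) < 2:
                        log.warning("validate: set %s too small (%d), skipped", cs.trait, len(cs))
                        continue
                    rep = kw_set_validation(
                        matrix, cs.as_set(), n_random=config.n_random,
                        seed=kw_seed, alpha=config.alpha,
                    )
                    reports.append({"trait": cs.trait, **rep.to_dict()})
                overlaps = []
                for i in range(len(candidate_sets)):
                    for j in range(i + 1, len(candidate_sets)):
                        a, b = candidate_sets[i], candidate_sets[j]
                        k = len(a.as_set() & b.as_set())
                        overlaps.append(
                            poisson_overlap_p(
                                len(a), len(b), universe_n, k,
                                label=f"{a.trait}&{b.trait}",
                            ).to_dict()
                        )
                _write_json({"kruskal_wallis": reports, "overlap": overlaps}, out / "validation.json")
                record(stage, "validation", out / "validation.json")

            elif stage == "enrich":
                if config.annotations is None:
                    log.warning("enrich skipped: no annotation file configured")
                    continue
                annotations = load_annotations(config.annotations)
                background = [g for g in matrix.gene_ids if g in annotations]
                for cs in candidate_sets:
                    cand = [g for g in cs.gene_ids if g in annotations]
                    if not cand:
                        continue
                    table = enrich(cand, annotations, background, cutoff=config.enrichment_cutoff)
                    path = out / f"enrichment_{cs.trait}.tsv"
                    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
                    record(stage, cs.trait, path)

            elif stage == "qpcr":
                if config.ct_table is None:
                    log.warning("qpcr skipped: no Ct table configured")
                    continue
                ct = pd.read_csv(config.ct_table, sep="\t")
                summary = summarize_ct_table(ct)
                summary.to_csv(out / "qpcr_summary.tsv", sep="\t", index=False, float_format="%.6g")
                record(stage, "summary", out / "qpcr_summary.tsv")
                report = qpcr_array_concordance(summary, matrix, "Chiquitita", "Arbosana")
                if report is not None:
                    _write_json(report, out / "qpcr_concordance.json")
                    record(stage, "concordance", out / "qpcr_concordance.json")
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"[stage {stage}] {exc}") from exc
        log.info("stage %-9s done in %.2fs", stage, time.time() - t0)

    manifest["runtime_s"] = round(time.time() - t_start, 3)
    _write_json(manifest, out / "manifest.json")
    return manifest


def qpcr_array_concordance(
    qpcr_summary: pd.DataFrame,
    matrix,
    sample_a: str,
    sample_b: str,
    alpha: float = 0.005,
    tails: int = 1,
) -> dict | None:
    """Pair per-gene qPCR log2 ratios (sample_a vs sample_b) with the array's
    log2 fold changes and test Pearson concordance."""
    piv = qpcr_summary.pivot(index="gene", columns="sample", values="mean_log2_rel")
    if sample_a not in piv.columns or sample_b not in piv.columns:
        return None
    genes = [g for g in piv.index if g in set(matrix.gene_ids)]
    if len(genes) < 3:
        return None
    qpcr_ratio = (piv.loc[genes, sample_a] - piv.loc[genes, sample_b]).to_numpy()
    gi = matrix.gene_index()
    a = matrix.group_values(sample_a)
    b = matrix.group_values(sample_b)
    idx = [gi[g] for g in genes]
    array_ratio = np.log2(a.mean(axis=1)[idx] / b.mean(axis=1)[idx])
    rep = concordance(qpcr_ratio, array_ratio, alpha=alpha, tails=tails)
    return {"genes": genes, "contrast": f"{sample_a} vs {sample_b}", **rep.to_dict()}


def recovery_metrics(candidate_sets: list[CandidateSet], truth: pd.DataFrame) -> pd.DataFrame:
    """Precision/recall of candidate sets against a planted-truth table
    (columns gene_id, trait, log2_effect, concordant)."""
    rows = []
    for cs in candidate_sets:
        tsub = truth[truth["trait"] == cs.trait]
        concordant = set(tsub.loc[tsub["concordant"], "gene_id"])
        discordant = set(tsub.loc[~tsub["concordant"], "gene_id"])
        selected = cs.as_set()
        tp = len(selected & concordant)
        rows.append(
            {
                "trait": cs.trait,
                "n_selected": len(selected),
                "n_concordant_planted": len(concordant),
                "n_discordant_planted": len(discordant),
                "recall_concordant": tp / len(concordant) if concordant else float("nan"),
                "precision_planted": tp / len(selected) if selected else float("nan"),
                "discordant_excluded": (
                    1.0 - len(selected & discordant) / len(discordant)
                    if discordant else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_bundle(
    params: SimulationParams,
    output_dir: str | Path,
    n_seedlings: int = 120,
    ct_genes: int = 12,
    ct_sd: float = 0.2,
) -> dict:
    """Write a complete synthetic input bundle: expression, design, truth,
    phenotypes and a Ct table for a 12-gene qPCR panel drawn from the planted
    growth-habit candidates (falling back to the first genes if none).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_expression(params)
    write_expression(matrix, out / "expression.tsv")
    tf = truth_frame(truth)
    tf.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")

    design = params.design
    design_doc = {
        "groups": dict(design.groups),
        "three_way": [
            {"trait": d.trait, "primary": list(d.primary), "concordance": list(d.concordance)}
            for d in design.three_way
        ],
        "alpha": design.alpha,
        "fc_threshold": design.fc_threshold,
    }
    (out / "design.yaml").write_text(yaml.safe_dump(design_doc, sort_keys=False), encoding="utf-8")

    pheno = simulate_phenotypes(n_seedlings=n_seedlings, seed=stage_seed(params.seed, "qc"))
    write_phenotypes(pheno, out / "phenotypes.tsv")

    habit = tf[(tf["trait"] == "growth_habit") & tf["concordant"]]
    panel = list(habit["gene_id"][:ct_genes])
    if len(panel) < ct_genes:
        panel += [g for g in matrix.gene_ids if g not in panel][: ct_genes - len(panel)]
    gi = matrix.gene_index()
    genes_spec = {}
    for g in panel:
        row = np.log2(matrix.values[gi[g]])
        chi = row[matrix.group_columns("Chiquitita")].mean()
        arb = row[matrix.group_columns("Arbosana")].mean()
        genes_spec[g] = {"Chiquitita": float(chi - arb), "Arbosana": 0.0}
    ct = simulate_ct_table(genes_spec, ct_sd=ct_sd, seed=stage_seed(params.seed, "qpcr"))
    ct.to_csv(out / "ct_table.tsv", sep="\t", index=False, float_format="%.6g")

    return {
        "expression": str(out / "expression.tsv"),
        "design": str(out / "design.yaml"),
        "truth": str(out / "truth.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "ct_table": str(out / "ct_table.tsv"),
    }
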