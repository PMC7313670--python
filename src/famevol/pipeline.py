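"""Orchestrate the full analysis from a single flat config file.

Stages: tree loading; birth-death copy-number analysis (rate fit, family
Monte Carlo tests, branch-shift tests); EVE expression-conservation tests;
resampling/correlation statistics; copy-number vs expression correlations.
Stages whose input table is absent are marked skipped.  The report is a pure
function of (inputs, config, seeds); every p-value is computed exactly once
by its owning module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bdp, eve, stats
from .tree import parse_newick

log = logging.getLogger("famevol")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Input schema violation; carries the offending file for context."""


@dataclass
class RunConfig:
    tree: str
    expr_tree: str | None = None  # defaults to `tree`
    cn_table: str | None = None
    expr_table: str | None = None
    outdir: str = "famevol_out"
    seed: int = 0
    n_perm: int = 1_000_000
    n_sim: int = 1000
    subsample_k: int = 0  # 0 disables the subsampling stage
    subsample_reps: int = 100
    branch_divisor: int = stats.BONFERRONI_DIVISORS["branches"]
    family_divisor: int = stats.BONFERRONI_DIVISORS["families"]
    sister_pairs: tuple = (("Bonobo", "Chimp"), ("Borangutan", "Sorangutan"))

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Flat key = value config; '#' starts a comment."""
        kw: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"{path}:{lineno}: expected key = value, got {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key in {"seed", "n_perm", "n_sim", "subsample_k", "subsample_reps",
                       "branch_divisor", "family_divisor"}:
                kw[key] = int(val)
            elif key in {"tree", "expr_tree", "cn_table", "expr_table", "outdir"}:
                kw[key] = val
            else:
                raise PipelineError(f"{path}:{lineno}: unknown config key {key!r}")
        if "tree" not in kw:
            raise PipelineError(f"{path}: missing required key 'tree'")
        return cls(**kw)


def _load_cn(path: str) -> stats.CopyNumberTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("individual_id", "species"):
        if col not in df.columns:
            raise PipelineError(f"{path}: missing required column {col!r}")
    return stats.CopyNumberTable.from_tidy(df)


def _load_expr(path: str) -> eve.ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "species"):
        if col not in df.columns:
            raise PipelineError(f"{path}: missing required column {col!r}")
    return eve.ExpressionMatrix.from_tidy(df)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage whose inputs exist; write TSVs plus a JSON summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: str(v) for k, v in vars(config).items()}, "stages": {}}

    tree = parse_newick(Path(config.tree).read_text())
    log.info("tree: %d tips, root age %.2f ky", tree.n_tips, tree.root_age)
    report["stages"]["tree"] = {
        "status": "ok",
        "n_tips": tree.n_tips,
        "root_age_ky": tree.root_age,
    }

    cn = expr = None
    if config.cn_table:
        cn = _load_cn(config.cn_table)
        log.info("copy-number table: %d individuals, %d families, seed %d",
                 len(cn.data), len(cn.families), config.seed)
        medians = cn.medians()
        profiles = [
            bdp.FamilyProfile(fam, medians[fam].to_dict())
            for fam in medians.columns
            if medians[fam].max() > 0 and set(medians.index) >= set(tree.tip_labels)
        ]
        results = bdp.CopyNumberEvolutionModel(profiles, tree).fit()
        fam_p = results.family_pvalues(n_sim=config.n_sim, seed=config.seed)
        branch_frames = [results.branch_tests(p.name) for p in profiles]
        branches = pd.concat(branch_frames, ignore_index=True)
        cutoff = 0.05 / config.branch_divisor
        branches["significant"] = branches["pvalue"] < cutoff
        fam_cut = 0.05 / config.family_divisor
        fam_df = fam_p.to_frame()
        fam_df["significant"] = fam_df["pvalue"] < fam_cut
        fam_df.to_csv(outdir / "family_tests.tsv", sep="\t")
        branches.to_csv(outdir / "branch_tests.tsv", sep="\t", index=False)
        medians.to_csv(outdir / "species_medians.tsv", sep="\t")
        report["stages"]["bdp"] = {
            "status": "ok",
            "lambda_per_my": results.lambda_,
            "n_families": len(profiles),
            "significant_families": sorted(fam_df.index[fam_df["significant"]]),
            "significant_branches": int(branches["significant"].sum()),
        }

        # permutation tests on sister pairs present in the table
        perm_rows = []
        rng = np.random.default_rng(config.seed)
        sizes = cn.species_sizes()
        for sp_a, sp_b in config.sister_pairs:
            if sp_a not in sizes or sp_b not in sizes:
                continue
            for fam in cn.families:
                va, vb = cn.values_of(sp_a, fam), cn.values_of(sp_b, fam)
                if va.max() == 0 and vb.max() == 0:
                    continue
                res = stats.permutation_species_test(
                    va, vb, n_perm=config.n_perm, seed=int(rng.integers(2**31))
                )
                perm_rows.append(
                    {"species_a": sp_a, "species_b": sp_b, "family": fam,
                     "pvalue": res.pvalue, "display": str(res), "n_perm": res.n_perm}
                )
        if perm_rows:
            pd.DataFrame(perm_rows).to_csv(outdir / "permutation_tests.tsv", sep="\t", index=False)
        report["stages"]["permutation"] = {"status": "ok", "n_tests": len(perm_rows)}

        # size-variance correlations and PCA
        sv_rows = []
        for sp in medians.index:
            try:
                _, corr = stats.size_variance_relation(cn, sp)
            except ValueError:
                continue
            sv_rows.append({"species": sp, "rho": corr.rho, "pvalue": corr.pvalue,
                            "n": corr.n, "method": corr.method})
        pd.DataFrame(sv_rows).to_csv(outdir / "size_variance.tsv", sep="\t", index=False)
        fractions = stats.pca_variance_explained(cn)
        report["stages"]["cn_statistics"] = {
            "status": "ok",
            "pca_variance_explained": [float(f) for f in fractions[:4]],
        }
    else:
        report["stages"]["bdp"] = {"status": "skipped", "reason": "no copy-number table"}
        report["stages"]["permutation"] = {"status": "skipped", "reason": "no copy-number table"}
        report["stages"]["cn_statistics"] = {"status": "skipped", "reason": "no copy-number table"}

    if config.expr_table:
        expr = _load_expr(config.expr_table)
        log.info("expression table: %d samples, %d families", len(expr.data), len(expr.families))
        etree = parse_newick(Path(config.expr_tree).read_text()) if config.expr_tree else tree
        testable = expr.testable_families(etree)
        if len(testable) >= 2:
            eve_res = eve.ExpressionConservationModel(expr, etree, families=testable).fit()
            tests = eve_res.lr_tests()
            out = eve_res.shared_fit.join(tests[["lr", "pvalue", "beta_family", "call"]])
            out.to_csv(outdir / "eve_tests.tsv", sep="\t")
            report["stages"]["eve"] = {
                "status": "ok",
                "beta_shared": eve_res.beta_shared,
                "families": testable,
                "calls": tests["call"].to_dict(),
            }
        else:
            report["stages"]["eve"] = {
                "status": "skipped",
                "reason": "fewer than two families observed in all species",
            }
    else:
        report["stages"]["eve"] = {"status": "skipped", "reason": "no expression table"}

    if cn is not None and expr is not None:
        rows = []
        for by in ("species", "family"):
            for group, corr in stats.cn_expression_relation(cn, expr, by=by).items():
                rows.append({"by": by, "group": group, "rho": corr.rho,
                             "pvalue": corr.pvalue, "n": corr.n, "method": corr.method})
        pd.DataFrame(rows).to_csv(outdir / "cn_expression_corr.tsv", sep="\t", index=False)
        report["stages"]["cn_expression"] = {"status": "ok", "n_groups": len(rows)}
    else:
        report["stages"]["cn_expression"] = {
            "status": "skipped",
            "reason": "needs both copy-number and expression tables",
        }

    (outdir / "summary.json").write_text(json.dumps(report, indent=2, default=str))
    return report
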