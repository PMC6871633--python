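"""End-to-end pipeline: validate → HWE → PCA → match stats → rank → tree.

`run_pipeline` wires every analysis stage over one frequency table (and,
optionally, genotypes and query profiles), writes each stage's output as
tab-separated text under an output directory, and finishes with a manifest
recording the configuration, seed, package versions, and a SHA-256 hash of
every input and output.  Re-running the same configuration reproduces every
output file bitwise, manifest included.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .hwe import hwe_scan
from .likelihood import compare_top, rank_populations
from .match import match_stats_table
from .panel import (
    AisnpPanel,
    default_panel,
    read_frequency_table,
    read_genotypes,
    read_panel,
    write_frequency_table,
)
from .pca import pca_plot_table, pca_populations
from .tree import neighbor_joining, search_topologies, tau_matrix, tree_report

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    Only ``freq_path`` and ``out_dir`` are required; genotype-dependent stages
    (HWE) and query-dependent stages (ranking) run when their inputs are
    given.  All thresholds and the seed are echoed into the manifest.
    """

    freq_path: str | Path = ""
    out_dir: str | Path = "popkit_out"
    panel_path: str | Path | None = None
    geno_path: str | Path | None = None
    query_individual: str | None = None  # rank this individual from geno_path
    region_labels: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    floor: str = "pseudo"
    alpha: float = 0.05
    min_n: int = 5
    n_components: int = 3
    max_structures: int = 200
    top_k: int = 30
    decimals: int = 6


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Run every applicable stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    skipped: list[str] = []

    @_stage("validate")
    def load_inputs():
        panel = (
            read_panel(config.panel_path)
            if config.panel_path
            else default_panel()
        )
        if not config.freq_path:
            raise FileNotFoundError("freq_path is required")
        table = read_frequency_table(config.freq_path, panel)
        path = out / "frequencies.tsv"
        write_frequency_table(table, path, decimals=config.decimals)
        outputs["frequencies"] = path
        return panel, table

    panel, table = load_inputs()

    genotypes = None
    if config.geno_path:

        @_stage("hwe")
        def run_hwe():
            import pandas as pd

            geno = read_genotypes(config.geno_path, panel)
            results, summary = hwe_scan(geno, alpha=config.alpha, min_n=config.min_n)
            path = out / "hwe_report.tsv"
            pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
            outputs["hwe_report"] = path
            spath = out / "hwe_summary.json"
            spath.write_text(
                json.dumps(
                    {
                        "n_tests": summary.n_tests,
                        "alpha": summary.alpha,
                        "n_significant": summary.n_significant,
                        "expected_significant": summary.expected_significant,
                        "bonferroni_flags": list(summary.bonferroni_flags),
                    },
                    indent=2,
                )
                + "\n"
            )
            outputs["hwe_summary"] = spath
            return geno

        genotypes = run_hwe()
    else:
        skipped.append("hwe")

    @_stage("pca")
    def run_pca():
        res = pca_populations(table, n_components=config.n_components)
        tab = pca_plot_table(res, table, config.region_labels)
        path = out / "pca_scores.tsv"
        tab.to_csv(path, sep="\t", index_label="pop_id")
        outputs["pca_scores"] = path
        vpath = out / "pca_variance.json"
        vpath.write_text(
            json.dumps({"var_explained_pct": [round(v, 6) for v in res.var_explained]})
            + "\n"
        )
        outputs["pca_variance"] = vpath

    run_pca()

    @_stage("match-stats")
    def run_match():
        path = out / "match_stats.tsv"
        match_stats_table(table).to_csv(path, sep="\t", index=False)
        outputs["match_stats"] = path

    run_match()

    if config.query_individual and genotypes is not None:

        @_stage("rank")
        def run_rank():
            profile = genotypes.profile(config.query_individual)
            ranking = rank_populations(
                profile, table, query_id=config.query_individual, floor=config.floor
            )
            path = out / f"ranking_{config.query_individual}.tsv"
            compare_top(ranking, k=min(config.top_k, len(ranking.entries))).to_csv(
                path, sep="\t", index=False
            )
            outputs["ranking"] = path

        run_rank()
    else:
        skipped.append("rank")

    @_stage("tree")
    def run_tree():
        dist = tau_matrix(table)
        nj = neighbor_joining(dist)
        (out / "nj_tree.nwk").write_text(nj.newick() + "\n")
        outputs["nj_tree"] = out / "nj_tree.nwk"
        result = search_topologies(dist, start=nj, max_structures=config.max_structures)
        (out / "best_tree.nwk").write_text(result.best.newick() + "\n")
        outputs["best_tree"] = out / "best_tree.nwk"
        rpath = out / "tree_diagnostics.tsv"
        rpath.write_text(tree_report(result, top=10))
        outputs["tree_diagnostics"] = rpath

    run_tree()

    manifest = {
        "popkit_version": __version__,
        "seed": config.seed,
        "config": {
            k: str(v) if isinstance(v, Path) else v for k, v in asdict(config).items()
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in (config.freq_path, config.panel_path, config.geno_path)
            if p
        },
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
        "skipped_stages": skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
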