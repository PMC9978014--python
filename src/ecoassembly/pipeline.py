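"""End-to-end orchestration: partition -> diversity -> niche breadth ->
assembly null models -> co-occurrence network -> Mantel, with one config and
a machine-readable report.

Each habitat group is analyzed separately and, within it, the abundant and
rare subcommunities are analyzed separately (the FAB/FRB-style subsets of
the two-habitat design). Stage outputs are written to disk as they are
produced; the Mantel stage re-reads the betaNTI matrices from the assembly
stage's files rather than holding them in memory, so deleting intermediates
and resuming reproduces identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import assembly as assembly_mod
from . import diversity as diversity_mod
from . import mantel as mantel_mod
from . import network as network_mod
from . import niche as niche_mod
from .io import (
    EnvTable,
    OtuTable,
    Phylogeny,
    read_env_table,
    read_matrix_tsv,
    read_otu_table,
    read_tree,
    write_results,
)

logger = logging.getLogger("ecoassembly")

__all__ = ["PipelineConfig", "run_all"]


class _StageFailure(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage
        self.original = exc


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run."""

    otu_table: str
    tree: str | None = None
    env_table: str | None = None
    habitat_table: str | None = None  # CSV: sample_id,habitat
    out_dir: str = "ecoassembly_out"
    min_count: int = 2
    abundance_threshold: float = 1e-4
    abundance_scope: str = "mean"
    prevalence: float = 2 / 3
    r_min: float = 0.8
    p_max: float = 0.01
    n_perm: int = 1000  # niche-breadth permutation null
    n_boot: int = 100
    n_null: int = 999  # betaNTI / RC_Bray randomizations
    mantel_perm: int = 999
    modularity_restarts: int = 20
    conf: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_null", "mantel_perm"):
            if getattr(self, name) < 99:
                raise ValueError(f"{name} must be >= 99")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the destination directory is
        excluded: it does not affect any computed number)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_habitat(config: PipelineConfig, table: OtuTable) -> dict[str, str]:
    if config.habitat_table is not None:
        df = pd.read_csv(config.habitat_table, index_col=0)
        return {str(k): str(v) for k, v in df.iloc[:, 0].items()}
    if table.habitat:
        return dict(table.habitat)
    return {s: "all" for s in table.sample_ids}


def _subset_seed(master: int, *labels: str) -> int:
    blob = ":".join(labels).encode()
    h = int(hashlib.sha256(blob).hexdigest(), 16)
    return int((master + h) % (2**31))


def run_all(
    config: PipelineConfig,
    table: OtuTable | None = None,
    tree: Phylogeny | None = None,
    env: EnvTable | None = None,
) -> dict:
    """Execute the whole pipeline and return (and write) the report.

    Inputs may be passed pre-loaded (the simulator produces them directly);
    otherwise they are read from the paths in the config. Any stage error
    aborts with the stage name after writing a partial-results manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(log_handler)
    completed: list[str] = []
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "groups": {},
    }
    stage = "load_inputs"
    try:
        if table is None:
            table = read_otu_table(config.otu_table, min_count=config.min_count)
        if tree is None and config.tree is not None:
            tree = read_tree(config.tree)
        if env is None and config.env_table is not None:
            env = read_env_table(config.env_table)
        habitat = _load_habitat(config, table)
        if env is not None:
            env = env.align_to(table.sample_ids)
        completed.append(stage)
        groups = sorted(set(habitat.values()))
        for group in groups:
            stage = f"group:{group}"
            report["groups"][group] = _run_group(
                config, table, tree, env, habitat, group, out, completed
            )
        stage = "group_comparison"
        report["diversity_comparison"] = _compare_alpha_across_subsets(
            report["groups"], out
        )
        completed.append(stage)
        stage = "write_report"
        write_results(report, out / "report.json", format="json")
        completed.append(stage)
    except _StageFailure as failure:
        manifest = {"failed_stage": failure.stage, "completed_stages": completed}
        write_results(manifest, out / "partial_manifest.json", format="json")
        raise
    except Exception as exc:
        manifest = {"failed_stage": stage, "completed_stages": completed}
        write_results(manifest, out / "partial_manifest.json", format="json")
        raise _StageFailure(stage, exc) from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return report


def _run_group(
    config: PipelineConfig,
    table: OtuTable,
    tree: Phylogeny | None,
    env: EnvTable | None,
    habitat: dict[str, str],
    group: str,
    out: Path,
    completed: list[str],
) -> dict:
    samples = [s for s in table.sample_ids if habitat.get(s) == group]
    sub = table.subset(sample_ids=samples)
    rel = sub.relative_abundance()
    result: dict = {"n_samples": len(samples)}

    stage = f"{group}:partition"
    classification = diversity_mod.classify_abundance(
        rel, threshold=config.abundance_threshold, scope=config.abundance_scope
    )
    result["partition"] = {
        **classification.fractions(rel),
        "threshold": config.abundance_threshold,
    }
    write_results(
        classification.labels.to_frame(), out / "partition" / f"{group}.tsv", "tsv"
    )
    completed.append(stage)

    class_tables: dict[str, OtuTable] = {}
    for cls in (diversity_mod.ABUNDANT, diversity_mod.RARE):
        otus = classification.otus(cls)
        if not otus:
            continue
        try:
            class_tables[cls] = sub.subset(otu_ids=otus)
        except Exception:
            logger.warning("skipping %s/%s subset (degenerate)", group, cls)

    stage = f"{group}:diversity"
    diversity_tables = {}
    for cls, ct in class_tables.items():
        alpha = diversity_mod.alpha_diversity(ct)
        diversity_tables[cls] = alpha
        write_results(alpha, out / "diversity" / f"{group}_{cls}_alpha.tsv", "tsv")
        if ct.n_samples >= 3:
            ord_res = diversity_mod.pcoa_bray(ct)
            write_results(
                ord_res.to_dict(), out / "diversity" / f"{group}_{cls}_pcoa.json"
            )
    result["alpha_diversity"] = {
        cls: alpha.mean(numeric_only=True).to_dict()
        for cls, alpha in diversity_tables.items()
    }
    completed.append(stage)

    stage = f"{group}:niche"
    niche_summary: dict = {}
    niche_results: dict = {}
    for cls, ct in class_tables.items():
        seed = _subset_seed(config.seed, group, cls, "niche")
        res = niche_mod.classify_specialists(
            ct, n_perm=config.n_perm, conf=config.conf, seed=seed, n_boot=config.n_boot
        )
        niche_results[cls] = res
        niche_summary[cls] = {
            "bm_mean": res.bm_mean,
            "bm_sd": res.bm_sd,
            **res.category_fractions(ct.relative_abundance()),
        }
        write_results(res.per_otu, out / "niche" / f"{group}_{cls}.tsv", "tsv")
    if len(class_tables) == 2:
        stat, p = niche_mod.compare_bm(
            class_tables[diversity_mod.ABUNDANT].relative_abundance(),
            class_tables[diversity_mod.RARE].relative_abundance(),
        )
        niche_summary["abundant_vs_rare_ttest"] = {"statistic": stat, "pvalue": p}
    result["niche_breadth"] = niche_summary
    completed.append(stage)

    stage = f"{group}:assembly"
    if tree is not None:
        assembly_summary = {}
        for cls, ct in class_tables.items():
            if ct.n_samples < 3:
                continue
            seed = _subset_seed(config.seed, group, cls, "assembly")
            res = assembly_mod.assembly_analysis(
                ct, tree, n_null=config.n_null, seed=seed
            )
            assembly_summary[cls] = {
                "process_fractions": res.process_fractions(),
                "n_pairs": len(res.pairs),
                "n_excluded": len(res.excluded_pairs),
            }
            write_results(res.pairs, out / "assembly" / f"{group}_{cls}_pairs.tsv", "tsv")
            full = _square_from_pairs(res.pairs, ct.sample_ids)
            write_results(full, out / "assembly" / f"{group}_{cls}_bnti.tsv", "tsv")
        result["assembly"] = assembly_summary
        completed.append(stage)

    stage = f"{group}:network"
    try:
        filtered = network_mod.prevalence_filter(sub, min_fraction=config.prevalence)
        net = network_mod.build_network(
            filtered, r_min=config.r_min, p_max=config.p_max
        )
        if net.n_edges > 0:
            topo = network_mod.topology(
                net,
                n_modularity_restarts=config.modularity_restarts,
                seed=_subset_seed(config.seed, group, "network"),
            )
            fractions = network_mod.annotate_nodes(
                net,
                classification=classification,
                niche=niche_results.get(diversity_mod.ABUNDANT),
                taxonomy=table.taxonomy,
            )
            result["network"] = {"topology": topo, "node_fractions": fractions}
            write_results(net.graph, out / "network" / f"{group}.graphml", "graphml")
        else:
            result["network"] = {"topology": None, "note": "no edges pass thresholds"}
    except Exception as exc:
        result["network"] = {"topology": None, "note": str(exc)}
    completed.append(stage)

    stage = f"{group}:mantel"
    if env is not None and tree is not None:
        mantel_summary = {}
        for cls in class_tables:
            bnti_path = out / "assembly" / f"{group}_{cls}_bnti.tsv"
            if not bnti_path.exists():
                continue
            bnti = read_matrix_tsv(bnti_path)  # re-read from disk: no hidden state
            mtab = mantel_mod.mantel_all(
                bnti,
                env,
                n_perm=config.mantel_perm,
                seed=_subset_seed(config.seed, group, cls, "mantel"),
            )
            mantel_summary[cls] = mtab.to_dict(orient="records")
            write_results(mtab, out / "mantel" / f"{group}_{cls}.tsv", "tsv")
        result["mantel"] = mantel_summary
        completed.append(stage)
    return result


def _square_from_pairs(pairs: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=samples, columns=samples)
    for _, row in pairs.iterrows():
        a, b = row["sample_a"], row["sample_b"]
        mat.loc[a, b] = mat.loc[b, a] = row["beta_nti"]
    return mat


def _compare_alpha_across_subsets(groups: dict, out: Path) -> dict:
    """One-way comparison of each alpha metric across habitat x class subsets."""
    comparisons: dict = {}
    diversity_dir = out / "diversity"
    if not diversity_dir.exists():
        return comparisons
    frames = []
    for path in sorted(diversity_dir.glob("*_alpha.tsv")):
        label = path.name.replace("_alpha.tsv", "")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df["subset"] = label
        frames.append(df)
    if not frames:
        return comparisons
    longtab = pd.concat(frames)
    if longtab["subset"].nunique() < 2:
        return comparisons
    for metric in ("richness", "shannon", "pielou", "chao1", "ace"):
        values = longtab[metric]
        ok = values.notna()
        per_group_n = longtab.loc[ok].groupby("subset")[metric].count()
        if (per_group_n < 2).any() or per_group_n.size < 2:
            continue
        cmp = diversity_mod.compare_groups(values[ok], longtab.loc[ok, "subset"])
        comparisons[metric] = cmp.to_dict()
    return comparisons
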