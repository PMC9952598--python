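"""End-to-end orchestration: gap exclusion, N_ST reports, mutation calling
and screening, candidate selection, bootstrap UPGMA trees, report writing.

The reference sample anchors mutation calls but is excluded from the
ingroup frequency computations; outgroup sequences enter only the ancestral
screen and the trees.  Outputs are plain TSV/Newick plus a JSON run
manifest, and reruns with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import mutscan, phylo, popdiff, seqio

logger = logging.getLogger("breeddiff")

__all__ = ["RunConfig", "GeneResult", "RunResult", "run_all", "load_config"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    gene_fastas: Mapping[str, str]  # gene -> FASTA path
    sample_sheet: str
    reference: str = "REF"
    topology_table: str | None = None
    bootstrap: int = 1000
    seed: int = 0
    outdir: str = "breeddiff_out"


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


@dataclasses.dataclass
class GeneResult:
    gene: str
    alignment: seqio.GeneAlignment  # gap-excluded, all roles
    nst: popdiff.NstReport
    mutations: list[mutscan.AaMutation]
    tree: phylo.TreeNode
    discarded_replicates: int


@dataclasses.dataclass
class RunResult:
    config: RunConfig
    genes: dict[str, GeneResult]
    partition: seqio.PopulationPartition

    @property
    def mutations(self) -> list[mutscan.AaMutation]:
        return [m for g in self.genes.values() for m in g.mutations]

    @property
    def selected(self) -> list[mutscan.AaMutation]:
        return [m for m in self.mutations if m.selected]

    def nst_table(self) -> pd.DataFrame:
        return popdiff.nst_report_frame(g.nst for g in self.genes.values())

    def mutation_table(self) -> pd.DataFrame:
        return mutscan.mutation_frame(self.mutations)

    def selected_table(self) -> pd.DataFrame:
        return mutscan.mutation_frame(self.selected)


def _analyze_gene(
    gene: str,
    aln: seqio.GeneAlignment,
    cfg: RunConfig,
    partition: seqio.PopulationPartition,
    topo: mutscan.TopologyAnnotation | None,
) -> GeneResult:
    t0 = time.perf_counter()
    aln = seqio.exclude_gap_columns(aln)
    ingroup_aln = seqio.GeneAlignment(
        gene, aln.ingroup, aln.retained_columns
    )
    nst = popdiff.gene_nst(ingroup_aln, partition)
    muts = mutscan.call_aa_mutations(aln, cfg.reference)
    outgroups = aln.with_roles("outgroup")
    for mut in muts:
        mutscan.classify_mutation(mut, partition)
        if outgroups:
            mutscan.screen_ancestral(mut, outgroups)
        mutscan.annotate_region(mut, topo)
    mutscan.select_candidates(muts)
    tree, discarded = phylo.bootstrap_upgma(aln, B=cfg.bootstrap, seed=cfg.seed)
    if discarded:
        logger.warning("%s: %d bootstrap replicates discarded", gene, discarded)
    logger.info("%s: analyzed in %.2fs (%d segregating sites, %d mutations)",
                gene, time.perf_counter() - t0, nst.segregating_sites, len(muts))
    return GeneResult(
        gene=gene,
        alignment=aln,
        nst=nst,
        mutations=muts,
        tree=tree,
        discarded_replicates=discarded,
    )


def run_all(cfg: RunConfig) -> RunResult:
    """Run every stage for every gene and write the report bundle."""
    sheet = seqio.read_sample_sheet(cfg.sample_sheet)
    ingroup = sheet[sheet.role == "ingroup"]
    pops = ingroup.population.unique()
    if len(pops) != 2:
        raise ValueError(
            f"differentiation stages need exactly two ingroup subpopulations, "
            f"got {list(pops)}"
        )
    partition = seqio.PopulationPartition(
        dict(zip(ingroup.sample_id, ingroup.population))
    )
    topo_by_gene: dict[str, mutscan.TopologyAnnotation] = {}
    if cfg.topology_table:
        topo_by_gene = mutscan.read_topology_table(cfg.topology_table)
    else:
        logger.warning("no topology annotation: regions unannotated, "
                       "selection ignores the region criterion")

    genes: dict[str, GeneResult] = {}
    for gene, path in cfg.gene_fastas.items():
        try:
            aln = seqio.read_gene_fasta(path, sheet, gene=gene)
            genes[gene] = _analyze_gene(
                gene, aln, cfg, partition, topo_by_gene.get(gene)
            )
        except Exception as exc:
            raise RuntimeError(f"stage failure in gene {gene}: {exc}") from exc

    result = RunResult(config=cfg, genes=genes, partition=partition)
    _write_reports(result)
    return result


def _write_reports(result: RunResult) -> None:
    cfg = result.config
    outdir = Path(cfg.outdir)
    tmp = outdir.with_name(outdir.name + ".partial")
    if tmp.exists():
        for p in sorted(tmp.rglob("*"), reverse=True):
            p.unlink() if p.is_file() else p.rmdir()
        tmp.rmdir()
    tmp.mkdir(parents=True)
    try:
        result.nst_table().to_csv(tmp / "nst_report.tsv", sep="\t", index=False)
        result.mutation_table().to_csv(tmp / "mutations.tsv", sep="\t", index=False)
        result.selected_table().to_csv(tmp / "selected.tsv", sep="\t", index=False)
        for gene, g in result.genes.items():
            (tmp / f"{gene}.nwk").write_text(phylo.to_newick(g.tree) + "\n")
        manifest = {
            "config": dataclasses.asdict(cfg),
            "seed": cfg.seed,
            "bootstrap": cfg.bootstrap,
            "genes": {
                gene: {
                    "length_bp": g.nst.length_bp,
                    "segregating_sites": g.nst.segregating_sites,
                    "mutations": len(g.mutations),
                    "discarded_replicates": g.discarded_replicates,
                }
                for gene, g in result.genes.items()
            },
        }
        manifest["config"]["gene_fastas"] = dict(cfg.gene_fastas)
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception:
        for p in sorted(tmp.rglob("*"), reverse=True):
            p.unlink() if p.is_file() else p.rmdir()
        tmp.rmdir()
        raise
    if outdir.exists():
        for p in sorted(outdir.rglob("*"), reverse=True):
            p.unlink() if p.is_file() else p.rmdir()
        outdir.rmdir()
    tmp.rename(outdir)
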