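"""End-to-end pipeline: filter -> sharing/network -> diversity -> taxa -> transfer.

Every stage reads and writes files under the output directory; a
manifest.json records the config hash, derived seeds, package version and
per-stage row counts so that a rerun with the same config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (CountTable, read_count_table, read_taxonomy, read_tree,
                         filter_low_depth, relative_abundance, aggregate_by_rank,
                         aggregate_composition, CHILD_COMPARTMENTS)
from .diversity import (alpha_diversity_table, distance_matrix, pcoa, permanova,
                        alpha_variance_decomposition)
from .sharing import compartment_partition, sparcc_correlation, cooccurrence_edges, birth_unique_otus
from .taxa_stats import genus_timepoint_tests, log_display_transform
from .transfer import (transfer_scan, weighted_ratio, wr_permutation_test,
                       abundance_odds_correlation, phylo_signal_of_transfer,
                       dyad_distance_test, truncate_or_for_display)

log = logging.getLogger(__name__)

STAGES = ("filter", "network", "diversity", "taxa", "transfer")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    counts: str
    metadata: str
    tree: str | None = None
    taxonomy: str | None = None
    out_dir: str = "vertiseq_out"
    min_reads: int = 2000
    metrics: tuple[str, ...] = ("unweighted_unifrac",)
    dyad_metric: str = "jsd"
    n_perm: int = 999
    seed: int = 0
    delivery_mode: str | None = "vaginal"
    top_n_genera: int = 15
    edge_threshold: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("counts", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("tree", "taxonomy"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        needs_tree = any(m.endswith("unifrac") for m in self.metrics) or self.dyad_metric.endswith("unifrac")
        if needs_tree and self.tree is None:
            raise ValueError("UniFrac metrics requested but no tree given")
        self.metrics = tuple(self.metrics)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Stage seeds derive as seed + stage index (documented in manifest)."""
        return self.seed + STAGES.index(stage)


def _write_tsv(df: pd.DataFrame, path: Path, index_name: str | None = None) -> None:
    out = df.copy()
    if index_name is not None:
        out.index.name = index_name
    out.to_csv(path, sep="\t", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write all outputs, return the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "version": __version__, "stages": {},
                "seed_derivation": {s: config.stage_seed(s) for s in STAGES}}

    table = read_count_table(config.counts, config.metadata)
    tree = read_tree(config.tree) if config.tree else None
    tax = read_taxonomy(config.taxonomy) if config.taxonomy else None

    # -- filter ----------------------------------------------------------
    table = filter_low_depth(table, config.min_reads)
    manifest["stages"]["filter"] = {"n_samples": table.n_samples, "n_otus": table.n_otus}

    # -- sharing partition + co-occurrence network -----------------------
    partition = compartment_partition(table)
    (out / "partition.json").write_text(json.dumps(partition.to_json_dict(), indent=1) + "\n")
    corr = {}
    net_seed = config.stage_seed("network")
    for comp in ("vaginal", "feces", "airway"):
        sub = table.select(compartment=comp)
        keep = sub.counts.index[(sub.counts > 0).any(axis=1)]
        sub = CountTable(sub.counts.loc[keep], sub.metadata)
        if sub.n_samples >= 4 and sub.n_otus >= 4:
            corr[comp] = sparcc_correlation(sub, seed=net_seed)
    edges = cooccurrence_edges(corr, threshold=config.edge_threshold)
    edges.edges.to_csv(out / "edges.tsv", sep="\t", index=False, lineterminator="\n")
    manifest["stages"]["network"] = {"n_edges": int(len(edges.edges)),
                                     "compartments": sorted(corr)}

    # -- diversity -------------------------------------------------------
    vaginal = table.select(compartment="vaginal")
    alpha = alpha_diversity_table(table, tree=tree) if tree is not None else \
        alpha_diversity_table(table, metrics=("richness", "shannon"))
    _write_tsv(alpha, out / "alpha.tsv", "sample_id")
    div_seed = config.stage_seed("diversity")
    for metric in config.metrics:
        dm = distance_matrix(vaginal, metric, tree=tree)
        _write_tsv(dm.data, out / f"distance_{metric}.tsv", "sample_id")
        ordn = pcoa(dm)
        _write_tsv(ordn.coordinates, out / f"pcoa_{metric}.tsv", "sample_id")
        vd = permanova(dm, {"timepoint": vaginal.metadata["timepoint"],
                            "individual": vaginal.metadata["subject_id"]},
                       n_perm=config.n_perm, seed=div_seed)
        _write_tsv(vd.table, out / f"permanova_{metric}.tsv")
    alpha_vd = {}
    for metric in alpha.columns:
        vals = alpha.loc[vaginal.sample_ids, metric]
        vd = alpha_variance_decomposition(vals, vaginal.metadata["subject_id"],
                                          vaginal.metadata["timepoint"])
        alpha_vd[metric] = vd.table
        _write_tsv(vd.table, out / f"alpha_anova_{metric}.tsv")
    manifest["stages"]["diversity"] = {"metrics": list(config.metrics),
                                       "n_vaginal_samples": vaginal.n_samples}

    # -- taxa ------------------------------------------------------------
    taxa_rows = 0
    if tax is not None:
        genus = aggregate_by_rank(vaginal, tax, "genus")
        comp = relative_abundance(genus)
        results = genus_timepoint_tests(comp, top_n=config.top_n_genera)
        rows = []
        for r in results:
            row = {"genus": r.taxon, "test": r.test, "p": r.p_value, "q": r.q_value,
                   "direction": r.direction}
            for tp, (med, q1, q3) in r.summaries.items():
                row[f"{tp}_median"] = med
                row[f"{tp}_iqr"] = f"{q1:.6g}-{q3:.6g}"
            row.update({k: v for k, v in r.pairwise.items()})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "genus_tests.tsv", sep="\t", index=False,
                                  lineterminator="\n")
        taxa_rows = len(rows)
    unique_set, combined, summary = birth_unique_otus(vaginal)
    (out / "birth_unique.json").write_text(json.dumps(summary, indent=1) + "\n")
    manifest["stages"]["taxa"] = {"n_genus_rows": taxa_rows,
                                  "n_birth_unique": summary["n_unique"]}

    # -- transfer --------------------------------------------------------
    tr_seed = config.stage_seed("transfer")
    transfer_summary = {}
    vb = table.select(compartment="vaginal", timepoint="birth")
    if config.delivery_mode is not None and "delivery_mode" in table.metadata.columns:
        keep = vb.metadata.index[vb.metadata["delivery_mode"] == config.delivery_mode]
        vb = vb.subset_samples(keep)
    vb_comp = relative_abundance(vb)
    for comp_name in CHILD_COMPARTMENTS:
        child = table.select(compartment=comp_name)
        shared = sorted(set(vb.metadata["subject_id"]) & set(child.metadata["subject_id"]))
        if len(shared) < 3:
            continue
        vb_sub = vb.subset_samples(vb.metadata.index[vb.metadata["subject_id"].isin(shared)])
        ch_sub = child.subset_samples(child.metadata.index[child.metadata["subject_id"].isin(shared)])
        scan = transfer_scan(vb_sub, ch_sub)
        _write_tsv(scan.results, out / f"scan_{comp_name}.tsv", "otu")
        volcano = scan.results[["odds_ratio", "p_value", "n_children"]].copy()
        volcano["odds_ratio"] = volcano["odds_ratio"].map(truncate_or_for_display)
        _write_tsv(volcano, out / f"volcano_{comp_name}.tsv", "otu")
        wr = wr_permutation_test(vb_sub, ch_sub, n_perm=config.n_perm, seed=tr_seed)
        dyad = dyad_distance_test(vb_sub, ch_sub, metric=config.dyad_metric,
                                  tree=tree, n_perm=config.n_perm, seed=tr_seed)
        entry = {"n_dyads": scan.n_dyads, "n_eligible_otus": int(len(scan.results)),
                 "wr": wr.observed, "wr_p": wr.p_value,
                 "dyad_metric": dyad.metric, "dyad_observed": dyad.observed,
                 "dyad_p": dyad.p_value}
        if len(scan.results) >= 4:
            rho, rho_p = abundance_odds_correlation(scan, vb_comp)
            entry["abundance_odds_rho"] = rho
            entry["abundance_odds_p"] = rho_p
            if tree is not None:
                r2, mp = phylo_signal_of_transfer(scan, tree, n_perm=config.n_perm,
                                                  seed=tr_seed)
                entry["phylo_r2"] = r2
                entry["phylo_p"] = mp
        else:
            log.warning("transfer %s: only %d eligible OTUs; descriptor "
                        "analyses skipped", comp_name, len(scan.results))
        transfer_summary[comp_name] = entry
        (out / f"wr_{comp_name}.json").write_text(json.dumps(
            {"wr": wr.observed, "p": wr.p_value, "B": wr.n_perm, "seed": wr.seed},
            indent=1) + "\n")
    (out / "transfer_summary.json").write_text(json.dumps(transfer_summary, indent=1) + "\n")
    manifest["stages"]["transfer"] = {c: {"n_eligible_otus": v["n_eligible_otus"]}
                                      for c, v in transfer_summary.items()}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def render_report(out_dir) -> str:
    """Plain-markdown summary of a finished run, in results order."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines = [f"# vertiseq run report", "",
             f"config hash: {manifest['config_hash']}  (version {manifest['version']})", ""]
    part = json.loads((out / "partition.json").read_text())
    lines += ["## OTU sharing between compartments",
              f"total OTUs observed: {part['total_otus']}"]
    for region, vals in part["regions"].items():
        lines.append(f"- {region}: {vals['n_otus']} OTUs, "
                     f"{100 * vals['read_fraction']:.1f}% of reads")
    lines += ["", "## Stages"]
    for stage, info in manifest["stages"].items():
        lines.append(f"- {stage}: {json.dumps(info)}")
    summary_path = out / "transfer_summary.json"
    if summary_path.exists():
        lines += ["", "## Vertical transfer"]
        for comp, vals in json.loads(summary_path.read_text()).items():
            lines.append(f"- {comp}: WR = {vals['wr']:.3g} (p = {vals['wr_p']:.3g}), "
                         f"{vals['n_eligible_otus']} eligible OTUs over "
                         f"{vals['n_dyads']} dyads; dyad {vals['dyad_metric']} "
                         f"p = {vals['dyad_p']:.3g}")
    report = "\n".join(lines) + "\n"
    (out / "report.md").write_text(report)
    return report
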