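"""End-to-end orchestration: simulate -> graph -> variants -> sex -> homology.

One configuration object carries every threshold of the analysis (all
defaulted to the conventions used throughout the package) plus the
simulation parameters, and one call runs the stages in dependency order,
writes every output file, and returns a run report whose counts are
internally consistent.  For reproducibility the report embeds the full
configuration; per-stage wall-clock goes to a separate ``timings.json`` so
that every analytic output file is byte-identical across runs with the same
seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import yaml

from . import graph as graph_mod
from . import homology as homology_mod
from . import io_formats
from . import sexdiff as sexdiff_mod
from . import variants as variants_mod
from .records import OrfRecord
from .simulate import SimulationParams, SyntheticDataset, simulate_dataset, write_dataset


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline plus the simulation parameters."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    allele_id: float = 0.95
    dup_id_low: float = 0.80
    min_overlap: int = 40
    min_edge_support: int = 1
    min_cov: int = 5
    max_cov: int = 100
    min_prob: float = 0.9
    homopolymer_len: int = 3
    percentile: float = 0.99
    strict_cutoff: float = 1e-50
    screen_cutoff: float = 1e-5
    orf_min_len: int = 30
    blast_db: str = "NR"
    component_blast_cutoff: float = 1e-20
    homology_cluster_cutoff: float = 1e-20
    venn_cutoff: float = 1e-5
    chimera_cutoff: float = 1e-20
    chimera_max_overlap: float = 0.2
    chimera_whitelist: tuple[tuple[str, str], ...] = ()
    seed: int = 0
    write_reads: bool = False

    def validate(self) -> None:
        if not (0 < self.dup_id_low < self.allele_id <= 1):
            raise ValueError("need 0 < dup_id_low < allele_id <= 1")
        for name in ("strict_cutoff", "screen_cutoff", "component_blast_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.strict_cutoff > self.screen_cutoff:
            raise ValueError("strict_cutoff must be at least as stringent as screen")
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if not isinstance(sim, SimulationParams):
            known = {f.name for f in dataclasses.fields(SimulationParams)}
            unknown = set(sim) - known
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
            for key in ("exon_length", "allele_divergence", "merged_divergence",
                        "duplicate_divergence", "databases"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimulationParams(**sim)
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "chimera_whitelist" in d:
            d["chimera_whitelist"] = tuple(tuple(p) for p in d["chimera_whitelist"])
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    config: dict
    reads: dict
    assembly: dict
    graph: dict
    variants: dict
    sex: dict
    homology: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    report: RunReport
    dataset: SyntheticDataset
    clusters: list
    analyses: list
    calls: list
    component_categories: dict[str, int]
    filtered_variants: list
    summaries: list
    orfs: dict[str, OrfRecord]
    regression: variants_mod.RegressionResult | None
    candidates: list
    contig_classes: dict[str, str]
    singleton_classes: dict[str, str]
    gene_calls: dict
    enrichment: list
    homolog_clusters: list
    multi_membership: dict
    unique_counts: object
    venn_regions: dict
    chimera_calls: list
    singleton_mappings: list
    timings: dict[str, float]


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> PipelineResult:
    """Run every stage on a fresh simulation and write all outputs."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    timings: dict[str, float] = {}

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    sim_params = dataclasses.replace(config.simulation, seed=config.seed)
    ds = simulate_dataset(sim_params)
    write_dataset(ds, outdir, write_reads=config.write_reads)
    timings["simulate"] = time.perf_counter() - t0

    contig_seqs = {c.id: c.residues for c in ds.contigs}

    # -- graph clustering --------------------------------------------------
    t0 = time.perf_counter()
    g = graph_mod.build_graph(ds.read_status, config.min_edge_support)
    clusters = graph_mod.find_clusters(g)
    nr_hits = [
        h
        for h in ds.blast_hits
        if h.db_name == config.blast_db and h.evalue <= config.component_blast_cutoff
    ]
    analyses = []
    calls = []
    component_categories: dict[str, int] = {}
    for cluster in clusters:
        analysis = graph_mod.call_components(
            cluster,
            contig_seqs,
            allele_id=config.allele_id,
            dup_id_low=config.dup_id_low,
            min_overlap=config.min_overlap,
        )
        analyses.append(analysis)
        for call in analysis.calls:
            calls.append(call)
            component_categories[call.component_id] = graph_mod.blast_category(
                call.members, nr_hits
            )
    _write_graph_outputs(outdir, clusters, calls, component_categories)
    timings["graph"] = time.perf_counter() - t0

    # -- variants ----------------------------------------------------------
    t0 = time.perf_counter()
    filtered = variants_mod.filter_variants(
        ds.variants,
        contig_seqs,
        min_cov=config.min_cov,
        max_cov=config.max_cov,
        min_prob=config.min_prob,
        homopolymer_len=config.homopolymer_len,
    )
    by_contig: dict[str, list] = {}
    for v in filtered:
        by_contig.setdefault(v.contig_id, []).append(v)
    summaries = []
    orfs: dict[str, OrfRecord] = {}
    for contig in ds.contigs:
        vs = by_contig.get(contig.id)
        if not vs:
            continue
        orf = variants_mod.find_longest_orf(contig.residues, config.orf_min_len)
        if orf is not None:
            orf = dataclasses.replace(orf, contig_id=contig.id)
            orfs[contig.id] = orf
        summaries.append(variants_mod.summarize_contig(contig, vs, orf))
    regression = None
    candidates = []
    if summaries:
        variants_mod.flag_highly_variable(summaries, config.percentile)
        lengths = {s.length for s in summaries}
        if len(summaries) >= 3 and len(lengths) > 1:
            regression = variants_mod.regress_variants_on_length(summaries)
        candidates = variants_mod.selection_candidates(summaries)
    _write_variant_outputs(outdir, contig_seqs, filtered, summaries, orfs, candidates)
    timings["variants"] = time.perf_counter() - t0

    # -- sex comparison ----------------------------------------------------
    t0 = time.perf_counter()
    contig_classes, singleton_classes = sexdiff_mod.classify_sequences(ds.read_status)
    classes = dict(contig_classes)
    classes.update(singleton_classes)
    db_hits = [h for h in ds.blast_hits if h.db_name == config.blast_db]
    gene_calls = sexdiff_mod.call_sex_specific(
        db_hits, classes, config.strict_cutoff, config.screen_cutoff
    )
    female_genes = {s for s, ev in gene_calls.items() if ev.call == "female_specific"}
    male_genes = {s for s, ev in gene_calls.items() if ev.call == "male_specific"}
    enrichment = []
    if female_genes and male_genes:
        enrichment = sexdiff_mod.go_enrichment(
            female_genes, male_genes, ds.go_annotations
        )
    _write_sex_outputs(outdir, contig_classes, singleton_classes, gene_calls, enrichment)
    timings["sex"] = time.perf_counter() - t0

    # -- homology ----------------------------------------------------------
    t0 = time.perf_counter()
    homolog_clusters, multi = homology_mod.cluster_by_homolog(
        ds.blast_hits, config.blast_db, config.homology_cluster_cutoff
    )
    unique_counts = homology_mod.unique_homolog_counts(ds.blast_hits)
    _, venn_regions = homology_mod.presence_venn(
        ds.blast_hits, list(config.simulation.databases), config.venn_cutoff
    )
    qlens = {c.id: len(c.residues) for c in ds.contigs}
    qlens.update({s.id: len(s.residues) for s in ds.singletons})
    whitelist = {frozenset(p) for p in config.chimera_whitelist}
    chimera_calls = homology_mod.detect_chimeras(
        [h for h in ds.blast_hits if h.db_name == config.blast_db],
        max_overlap_frac=config.chimera_max_overlap,
        evalue_cutoff=config.chimera_cutoff,
        query_lengths=qlens,
        whitelist=whitelist,
    )
    singleton_mappings = homology_mod.map_singletons(ds.singletons, ds.contigs)
    _write_homology_outputs(
        outdir, homolog_clusters, multi, unique_counts, venn_regions,
        chimera_calls, singleton_mappings,
    )
    timings["homology"] = time.perf_counter() - t0

    # -- report ------------------------------------------------------------
    status_counts: dict[str, int] = {}
    sex_counts: dict[str, int] = {"F": 0, "M": 0}
    for r in ds.read_status:
        status_counts[r.status] = status_counts.get(r.status, 0) + 1
        sex_counts[r.sex] += 1
    placed = status_counts.get("assembled", 0) + status_counts.get(
        "partially_assembled", 0
    )
    ctype_counts: dict[str, int] = {}
    for c in calls:
        ctype_counts[c.ctype] = ctype_counts.get(c.ctype, 0) + 1
    class_counts: dict[str, int] = {}
    for cls in contig_classes.values():
        class_counts[cls] = class_counts.get(cls, 0) + 1

    report = RunReport(
        config=config.to_dict(),
        reads={
            "total": len(ds.read_status),
            "by_status": dict(sorted(status_counts.items())),
            "by_sex": sex_counts,
            "placed": placed,
            "accounting_ok": placed
            + status_counts.get("singleton", 0)
            + status_counts.get("discarded", 0)
            == len(ds.read_status),
        },
        assembly={
            "n_contigs": len(ds.contigs),
            "n_singletons": len(ds.singletons),
        },
        graph={
            "n_clusters": len(clusters),
            "n_clustered_contigs": sum(len(c.members) for c in clusters),
            "components_by_type": dict(sorted(ctype_counts.items())),
            "blast_categories": {
                str(cat): sum(1 for v in component_categories.values() if v == cat)
                for cat in range(1, 6)
            },
        },
        variants={
            "called": len(ds.variants),
            "pass_filter": len(filtered),
            "snp": sum(1 for v in filtered if v.var_type == "SNP"),
            "indel": sum(1 for v in filtered if v.is_indel),
            "ts_total": sum(s.ts for s in summaries),
            "tv_total": sum(s.tv for s in summaries),
            "ka_total": sum(s.ka or 0 for s in summaries),
            "ks_total": sum(s.ks or 0 for s in summaries),
            "highly_variable": sum(1 for s in summaries if s.highly_variable),
            "selection_candidates": len(candidates),
            "regression": dataclasses.asdict(regression) if regression else None,
        },
        sex={
            "contig_classes": dict(sorted(class_counts.items())),
            "female_specific_genes": len(female_genes),
            "male_specific_genes": len(male_genes),
            "shared_genes": sum(1 for e in gene_calls.values() if e.call == "shared"),
            "insufficient": sum(
                1 for e in gene_calls.values() if e.call == "insufficient"
            ),
            "enriched_terms_q05": sum(1 for e in enrichment if e.q_value < 0.05),
        },
        homology={
            "n_homolog_clusters": len(homolog_clusters),
            "multi_membership_seqs": len(multi),
            "unique_counts": {
                db: {f"{c:.0e}": int(unique_counts.at[db, c]) for c in unique_counts.columns}
                for db in unique_counts.index
            },
            "chimeras": len(chimera_calls),
            "rescued_singletons": len(singleton_mappings),
        },
    )
    with open(os.path.join(outdir, "run_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    with open(os.path.join(outdir, "timings.json"), "w") as fh:
        json.dump(timings, fh, indent=2)
        fh.write("\n")
    _write_text_report(os.path.join(outdir, "run_report.txt"), report)

    return PipelineResult(
        report=report,
        dataset=ds,
        clusters=clusters,
        analyses=analyses,
        calls=calls,
        component_categories=component_categories,
        filtered_variants=filtered,
        summaries=summaries,
        orfs=orfs,
        regression=regression,
        candidates=candidates,
        contig_classes=contig_classes,
        singleton_classes=singleton_classes,
        gene_calls=gene_calls,
        enrichment=enrichment,
        homolog_clusters=homolog_clusters,
        multi_membership=multi,
        unique_counts=unique_counts,
        venn_regions=venn_regions,
        chimera_calls=chimera_calls,
        singleton_mappings=singleton_mappings,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# output writers


def _write_graph_outputs(outdir, clusters, calls, categories) -> None:
    with open(os.path.join(outdir, "clusters.tsv"), "w") as fh:
        fh.write("# clusters.tsv: cluster_id member degree\n")
        for cluster in clusters:
            degree = {m: 0 for m in cluster.members}
            for a, b, _w in cluster.edges:
                degree[a] += 1
                degree[b] += 1
            for m in cluster.members:
                fh.write(f"{cluster.cluster_id}\t{m}\t{degree[m]}\n")
    with open(os.path.join(outdir, "components.tsv"), "w") as fh:
        fh.write("# components.tsv: component_id ctype members identity blast_category\n")
        for c in calls:
            ident = f"{c.identity:.4f}" if c.identity is not None else "NA"
            fh.write(
                f"{c.component_id}\t{c.ctype}\t{','.join(c.members)}\t{ident}"
                f"\t{categories.get(c.component_id, 'NA')}\n"
            )
    io_formats.write_fasta(
        [c.consensus for c in calls if c.consensus is not None],
        os.path.join(outdir, "merged_consensus.fasta"),
    )


def _write_variant_outputs(outdir, contig_seqs, filtered, summaries, orfs, candidates):
    io_formats.write_variants(filtered, os.path.join(outdir, "variants_filtered.tsv"))
    io_formats.write_variants_vcf(
        filtered, contig_seqs, os.path.join(outdir, "variants_filtered.vcf")
    )
    io_formats.write_orfs(
        [orfs[k] for k in sorted(orfs)], os.path.join(outdir, "orfs.bed")
    )
    with open(os.path.join(outdir, "variant_summary.tsv"), "w") as fh:
        fh.write(
            "# variant_summary.tsv: contig_id length n_snp n_indel ts tv ka ks "
            "tstv_ratio kaks_ratio density density_per_200bp highly_variable\n"
        )
        for s in summaries:
            ka = s.ka if s.ka is not None else "NA"
            ks = s.ks if s.ks is not None else "NA"
            kk = f"{s.kaks_ratio:.4f}" if s.kaks_ratio is not None else "NA"
            fh.write(
                f"{s.contig_id}\t{s.length}\t{s.n_snp}\t{s.n_indel}\t{s.ts}\t{s.tv}"
                f"\t{ka}\t{ks}\t{s.tstv_ratio:.4f}\t{kk}\t{s.density:.6f}"
                f"\t{s.density_per_200bp:.4f}\t{int(s.highly_variable)}\n"
            )
    with open(os.path.join(outdir, "candidates.tsv"), "w") as fh:
        fh.write("# candidates.tsv: contigs with Ka/Ks>1, TS/TV<1, highly variable\n")
        for s in candidates:
            fh.write(f"{s.contig_id}\t{s.kaks_ratio:.4f}\t{s.tstv_ratio:.4f}\n")


def _write_sex_outputs(outdir, contig_classes, singleton_classes, gene_calls, enrichment):
    with open(os.path.join(outdir, "sex_classes.tsv"), "w") as fh:
        fh.write("# sex_classes.tsv: seq_id class\n")
        for sid in sorted(contig_classes):
            fh.write(f"{sid}\t{contig_classes[sid]}\n")
        for sid in sorted(singleton_classes):
            fh.write(f"{sid}\t{singleton_classes[sid]}\n")
    with open(os.path.join(outdir, "sex_specific_genes.tsv"), "w") as fh:
        fh.write(
            "# sex_specific_genes.tsv: gene call female_seqs male_seqs "
            "best_female_e best_male_e\n"
        )
        for subject in sorted(gene_calls):
            ev = gene_calls[subject]
            fh.write(
                f"{subject}\t{ev.call}\t{','.join(sorted(ev.female_seqs)) or '-'}"
                f"\t{','.join(sorted(ev.male_seqs)) or '-'}"
                f"\t{ev.best_female_evalue if ev.best_female_evalue is not None else 'NA'}"
                f"\t{ev.best_male_evalue if ev.best_male_evalue is not None else 'NA'}\n"
            )
    with open(os.path.join(outdir, "enrichment.tsv"), "w") as fh:
        fh.write("# enrichment.tsv: term a_with a_without b_with b_without p q\n")
        for e in enrichment:
            (at, ao), (bt, bo) = e.table
            fh.write(
                f"{e.term_id}\t{at}\t{ao}\t{bt}\t{bo}"
                f"\t{e.p_value:.6g}\t{e.q_value:.6g}\n"
            )


def _write_homology_outputs(
    outdir, clusters, multi, unique_counts, venn_regions, chimeras, mappings
):
    with open(os.path.join(outdir, "homolog_clusters.tsv"), "w") as fh:
        fh.write("# homolog_clusters.tsv: db subject cutoff n_members members\n")
        for c in clusters:
            fh.write(
                f"{c.db_name}\t{c.subject_id}\t{c.cutoff:.0e}\t{len(c.members)}"
                f"\t{','.join(sorted(c.members))}\n"
            )
    with open(os.path.join(outdir, "multi_membership.tsv"), "w") as fh:
        fh.write("# multi_membership.tsv: seq_id subjects\n")
        for seq, subjects in multi.items():
            fh.write(f"{seq}\t{','.join(subjects)}\n")
    unique_counts.to_csv(
        os.path.join(outdir, "unique_counts.tsv"), sep="\t", index_label="db"
    )
    with open(os.path.join(outdir, "venn_regions.tsv"), "w") as fh:
        fh.write("# venn_regions.tsv: databases count\n")
        for region in sorted(venn_regions, key=lambda r: (len(r), sorted(r))):
            fh.write(f"{'+'.join(sorted(region))}\t{venn_regions[region]}\n")
    with open(os.path.join(outdir, "chimeras.tsv"), "w") as fh:
        fh.write("# chimeras.tsv: seq_id subject_a subject_b gap reason\n")
        for c in chimeras:
            fh.write(
                f"{c.seq_id}\t{c.hit_a.subject_id}\t{c.hit_b.subject_id}"
                f"\t{c.query_gap}\t{c.reason}\n"
            )
    with open(os.path.join(outdir, "singleton_map.tsv"), "w") as fh:
        fh.write("# singleton_map.tsv: read contig identity unaligned_5p unaligned_3p\n")
        for m in mappings:
            fh.write(
                f"{m.read_id}\t{m.contig_id}\t{m.identity:.2f}"
                f"\t{m.unaligned_5p}\t{m.unaligned_3p}\n"
            )


def _write_text_report(path: str, report: RunReport) -> None:
    d = report.to_dict()
    lines = ["run report", "=========="]
    for section in ("reads", "assembly", "graph", "variants", "sex", "homology"):
        lines.append(f"\n[{section}]")
        for key, value in d[section].items():
            lines.append(f"  {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryMetrics:
    component: dict
    sex: dict
    chimera: dict
    variant_filter: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_recovery(result: PipelineResult, truth=None) -> RecoveryMetrics:
    """Score pipeline output against the simulation's ground-truth ledger."""
    truth = truth if truth is not None else result.dataset.truth
    if len(truth.genes) == 0 or len(truth.contigs) == 0:
        raise ValueError("empty ground truth")

    # component recovery: a truth component is recovered when a call of the
    # same ctype has exactly its member set
    call_index = {(c.ctype, frozenset(c.members)) for c in result.calls}
    per_type: dict[str, dict[str, int]] = {}
    for _, row in truth.components.iterrows():
        members = frozenset(row["members"].split(","))
        stats = per_type.setdefault(row["ctype"], {"total": 0, "recovered": 0})
        stats["total"] += 1
        if (row["ctype"], members) in call_index:
            stats["recovered"] += 1
    total = sum(s["total"] for s in per_type.values())
    recovered = sum(s["recovered"] for s in per_type.values())
    component = {
        "per_type": per_type,
        "total": total,
        "recovered": recovered,
        "accuracy": recovered / total if total else float("nan"),
    }

    # sex-specific calling vs gene ledger (genes with an accession only)
    bias_to_call = {"female_only": "female_specific", "male_only": "male_specific"}
    confusion: dict[str, dict[str, int]] = {}
    tp = fp = fn = 0
    false_specific = 0
    for _, row in truth.genes.iterrows():
        acc = row["accession"]
        if not isinstance(acc, str) or not acc:
            continue
        expected = bias_to_call.get(row["sex_bias"], "shared")
        ev = result.gene_calls.get(acc)
        observed = ev.call if ev is not None else "insufficient"
        confusion.setdefault(expected, {}).setdefault(observed, 0)
        confusion[expected][observed] += 1
        if expected in ("female_specific", "male_specific"):
            if observed == expected:
                tp += 1
            else:
                fn += 1
        elif observed in ("female_specific", "male_specific"):
            fp += 1
            false_specific += 1
    n_called_specific = tp + fp
    sex = {
        "confusion": confusion,
        "precision": tp / n_called_specific if n_called_specific else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
        "false_specific": false_specific,
    }

    # chimeras
    truth_chimeras = set(
        truth.contigs.loc[truth.contigs["role"] == "chimera", "contig_id"]
    )
    called = {c.seq_id for c in result.chimera_calls}
    chimera = {
        "planted": len(truth_chimeras),
        "recovered": len(called & truth_chimeras),
        "false_positives": len(called - truth_chimeras),
        "recall": (
            len(called & truth_chimeras) / len(truth_chimeras)
            if truth_chimeras
            else float("nan")
        ),
    }

    # variant filter confusion
    truth_vars = {
        (row["contig_id"], int(row["position"]), row["var_type"]): row["truth"]
        for _, row in truth.variants.iterrows()
    }
    retained = {
        (v.contig_id, v.position, v.var_type) for v in result.filtered_variants
    }
    all_vars = {
        (v.contig_id, v.position, v.var_type) for v in result.dataset.variants
    }
    missing = all_vars - set(truth_vars)
    if missing:
        raise ValueError(f"variants missing from ledger: {sorted(missing)[:3]}")
    vf = {"true_retained": 0, "true_removed": 0, "false_retained": 0, "false_removed": 0}
    for key in all_vars:
        label = truth_vars[key]
        kept = key in retained
        if label == "true":
            vf["true_retained" if kept else "true_removed"] += 1
        else:
            vf["false_retained" if kept else "false_removed"] += 1

    return RecoveryMetrics(
        component=component, sex=sex, chimera=chimera, variant_filter=vf
    )
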