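"""Synthetic gene families, sex-labelled reads and emulated assembler output.

The generator produces everything the downstream stages consume — contig and
singleton FASTA, a read-status table with split-read placements, variant
calls with coverage and posterior probability, tabular homology hits and a
GO map — together with a complete ground-truth ledger, so that every stage
can be scored against known answers without any external data.

The emulation mimics how an overlap assembler handles a pooled, normalized
transcriptome:

* segment pairs whose identity reaches ``assembler_merge_identity`` collapse
  into one contig and their differences surface as variant calls;
* pairs below that identity stay as separate contigs, and reads spanning the
  boundary between a shared segment and a variant segment are split between
  the two contigs (the edge evidence of the contig graph);
* alternatively spliced isoforms yield one contig per exon, with junction
  reads split between consecutive exons of each isoform;
* planted chimeras concatenate halves of two unrelated sequences;
* a configurable fraction of reads stay singletons or are discarded, and a
  small rate of false variant calls (low-probability SNPs and
  homopolymer-adjacent INDELs) is injected.

There is no per-base sequencing error model: read cleaning is upstream of
this pipeline, so noise enters only through injected false variants and the
singleton/discard rates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_formats
from .records import (
    BlastHit,
    GoAnnotation,
    ReadPlacement,
    ReadStatusRecord,
    SequenceRecord,
    VariantRecord,
)
from .variants import homopolymer_mask

_PURINE_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

BIOSYNTHESIS_TERM = "GO:0009058"


@dataclass(frozen=True)
class GeneModel:
    """One simulated gene (or gene pair, for the paired categories)."""

    gene_id: str
    category: str  # unique | allele_pair | duplicate_pair | alt_splice | chimera_source
    sex_bias: str  # none | female_only | male_only
    exons: tuple[str, ...]
    divergence: float = 0.0
    # diverged copy of each exon for the paired categories (None = identical)
    paired_exons: tuple[str | None, ...] = ()
    isoforms: tuple[tuple[int, ...], ...] = ()
    accession: str | None = None
    accession2: str | None = None
    weak_homolog: bool = False
    go_terms: tuple[str, ...] = ()


@dataclass
class SimulationParams:
    """Study conditions for the emulation.

    Defaults reproduce a 200-gene / roughly 20k-read pooled design: mean read
    length 366 bp, 7.5% singletons and 5.7% discarded reads, allele pairs
    diverged 3.2-4.3% (identity 0.957-0.968, i.e. above the 0.95 allele
    threshold yet below the 0.97 assembler merge identity), duplicate pairs
    diverged 7-18% (identity 0.82-0.93) and low-divergence pairs (0.5-2%)
    that the emulated assembler collapses into variant-bearing contigs.
    """

    n_unique: int = 90
    n_allele_pairs: int = 25
    n_merged_pairs: int = 15
    n_duplicate_pairs: int = 25
    n_alt_splice: int = 35
    n_chimera: int = 10
    n_female_only: int = 10
    n_male_only: int = 10

    exon_length: tuple[int, int] = (600, 1200)
    read_length_mean: float = 366.0
    read_length_sd: float = 40.0
    read_length_min: int = 80
    depth_mean: float = 20.0
    sex_ratio: float = 0.5
    sex_leakage: float = 0.0

    assembler_merge_identity: float = 0.97
    allele_divergence: tuple[float, float] = (0.032, 0.043)
    merged_divergence: tuple[float, float] = (0.005, 0.02)
    duplicate_divergence: tuple[float, float] = (0.07, 0.18)
    ts_tv_weight: float = 2.0

    singleton_rate: float = 0.075
    discard_rate: float = 0.057
    n_junk_singletons: int = 30
    min_split_part: int = 30

    no_hit_fraction: float = 0.3
    weak_hit_fraction: float = 0.25
    exon_hit_prob: float = 0.85
    singleton_hit_rate: float = 0.2
    extra_db_prob: float = 0.8
    databases: tuple[str, ...] = ("NR", "HomoloGene", "UniGeneChicken", "AnoCarEnsembl")

    false_snp_rate: float = 0.3
    homopolymer_indel_rate: float = 0.15
    true_indels_per_merged: int = 2

    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_unique,
            self.n_allele_pairs,
            self.n_merged_pairs,
            self.n_duplicate_pairs,
            self.n_alt_splice,
            self.n_chimera,
            self.n_female_only,
            self.n_male_only,
        )
        if any(c < 0 for c in counts):
            raise ValueError("gene counts must be non-negative")
        if not (0 < self.assembler_merge_identity <= 1):
            raise ValueError("assembler_merge_identity must be in (0,1]")
        if self.n_female_only + self.n_male_only > self.n_unique:
            raise ValueError("more sex-biased genes than unique genes")
        # a read must never span more than two segments
        if self.exon_length[0] < self.read_length_mean + 3 * self.read_length_sd:
            raise ValueError("infeasible: exons shorter than the longest reads")
        if self.exon_length[0] > self.exon_length[1]:
            raise ValueError("bad exon length range")
        for lo, hi in (
            self.allele_divergence,
            self.merged_divergence,
            self.duplicate_divergence,
        ):
            if not (0 <= lo <= hi < 1):
                raise ValueError("bad divergence range")


@dataclass
class GroundTruthTable:
    """The simulation ledger: every emitted object mapped to its origin."""

    genes: pd.DataFrame
    contigs: pd.DataFrame
    reads: pd.DataFrame
    variants: pd.DataFrame
    components: pd.DataFrame

    _FILES = ("genes", "contigs", "reads", "variants", "components")

    def write(self, outdir: str | os.PathLike) -> None:
        for name in self._FILES:
            getattr(self, name).to_csv(
                os.path.join(outdir, f"ground_truth_{name}.tsv"), sep="\t", index=False
            )

    @classmethod
    def read(cls, outdir: str | os.PathLike) -> "GroundTruthTable":
        frames = {
            name: pd.read_csv(
                os.path.join(outdir, f"ground_truth_{name}.tsv"), sep="\t"
            )
            for name in cls._FILES
        }
        return cls(**frames)


@dataclass(frozen=True)
class SimulatedRead:
    record: SequenceRecord
    sex: str
    gene_id: str
    tx_index: int
    start: int
    junction: bool


# ---------------------------------------------------------------------------
# sequence helpers


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _orf_bearing_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence carrying a long planted ORF (ATG..stop) in frame 0."""
    utr5 = _random_seq(rng, 30)
    utr3_len = 30
    n_codons = (length - len(utr5) - utr3_len - 6) // 3
    body = "".join(
        np.array(_CODONS)[rng.integers(0, len(_CODONS), size=max(n_codons, 20))]
    )
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    seq = utr5 + "ATG" + body + stop
    seq += _random_seq(rng, max(length - len(seq), utr3_len))
    return seq


def mutate_sequence(
    seq: str,
    divergence: float,
    ts_tv_weight: float = 2.0,
    seed: int | np.random.Generator = 0,
    indel_rate: float = 0.0,
) -> str:
    """Return a diverged copy of ``seq``.

    Exactly ``round(divergence * len(seq))`` distinct sites are substituted,
    so the realized per-site difference matches the target to within rounding.
    Each substitution is a transition with probability ``w / (w + 1)`` where
    ``w = ts_tv_weight``, giving an expected transition:transversion ratio of
    ``w:1``.  Indels are only introduced when ``indel_rate > 0``.
    """
    if not (0 <= divergence < 1):
        raise ValueError("divergence must be in [0,1)")
    if ts_tv_weight <= 0:
        raise ValueError("ts_tv_weight must be positive")
    rng = _rng(seed)
    bases = list(seq)
    k = int(round(divergence * len(seq)))
    if k:
        positions = rng.choice(len(seq), size=k, replace=False)
        p_ts = ts_tv_weight / (ts_tv_weight + 1.0)
        for pos in sorted(int(p) for p in positions):
            ref = bases[pos]
            if ref not in _PURINE_TRANSITION:
                continue
            if rng.random() < p_ts:
                bases[pos] = _PURINE_TRANSITION[ref]
            else:
                tv = _TRANSVERSIONS[ref]
                bases[pos] = tv[int(rng.integers(0, 2))]
    if indel_rate > 0:
        n_indels = rng.poisson(indel_rate * len(seq))
        for _ in range(n_indels):
            pos = int(rng.integers(0, len(bases)))
            if rng.random() < 0.5:
                bases.insert(pos, "ACGT"[rng.integers(0, 4)])
            else:
                del bases[pos]
    return "".join(bases)


# ---------------------------------------------------------------------------
# gene set


def generate_gene_set(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], GroundTruthTable]:
    """Generate gene models and the gene section of the ground-truth ledger."""
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    models: list[GeneModel] = []
    acc_counter = 0
    go_pool = [f"GO:{i:07d}" for i in range(1, 26)]

    def next_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"ACC{acc_counter:05d}"

    def exon_len() -> int:
        return int(rng.integers(params.exon_length[0], params.exon_length[1] + 1))

    def go_terms(sex_bias: str) -> tuple[str, ...]:
        n = int(rng.integers(2, 5))
        terms = set(rng.choice(go_pool, size=n, replace=False))
        p_bio = 0.8 if sex_bias == "female_only" else 0.15
        if rng.random() < p_bio:
            terms.add(BIOSYNTHESIS_TERM)
        else:
            terms.discard(BIOSYNTHESIS_TERM)
        return tuple(sorted(terms))

    gid = 0

    def next_gid(prefix: str) -> str:
        nonlocal gid
        gid += 1
        return f"{prefix}{gid:04d}"

    # sex bias goes to the first unique genes; the homology-based caller can
    # only see genes with an accession, so biased genes always get one
    biases = (
        ["female_only"] * params.n_female_only
        + ["male_only"] * params.n_male_only
        + ["none"] * (params.n_unique - params.n_female_only - params.n_male_only)
    )
    for bias in biases:
        has_hit = True if bias != "none" else rng.random() >= params.no_hit_fraction
        weak = bool(
            has_hit and bias == "none" and rng.random() < params.weak_hit_fraction
        )
        acc = next_acc() if has_hit else None
        models.append(
            GeneModel(
                gene_id=next_gid("g"),
                category="unique",
                sex_bias=bias,
                exons=(_orf_bearing_seq(rng, exon_len()),),
                paired_exons=(None,),
                isoforms=((0,),),
                accession=acc,
                weak_homolog=weak,
                go_terms=go_terms(bias) if acc else (),
            )
        )

    def diverged_pair(category: str, band: tuple[float, float]) -> GeneModel:
        shared = _random_seq(rng, exon_len())
        var = _orf_bearing_seq(rng, exon_len())
        d = float(rng.uniform(*band))
        var_b = mutate_sequence(var, d, params.ts_tv_weight, rng)
        acc = next_acc()
        acc2 = next_acc() if category == "duplicate_pair" else None
        return GeneModel(
            gene_id=next_gid("g"),
            category=category,
            sex_bias="none",
            exons=(shared, var),
            paired_exons=(None, var_b),
            divergence=d,
            accession=acc,
            accession2=acc2,
            go_terms=go_terms("none"),
        )

    for _ in range(params.n_allele_pairs):
        models.append(diverged_pair("allele_pair", params.allele_divergence))

    for _ in range(params.n_merged_pairs):
        # low-divergence alleles: single segment, collapsed by the assembler
        seq = _orf_bearing_seq(rng, exon_len())
        d = float(rng.uniform(*params.merged_divergence))
        seq_b = mutate_sequence(seq, d, params.ts_tv_weight, rng)
        models.append(
            GeneModel(
                gene_id=next_gid("g"),
                category="allele_pair",
                sex_bias="none",
                exons=(seq,),
                paired_exons=(seq_b,),
                divergence=d,
                accession=next_acc(),
                go_terms=go_terms("none"),
            )
        )

    for _ in range(params.n_duplicate_pairs):
        models.append(diverged_pair("duplicate_pair", params.duplicate_divergence))

    for _ in range(params.n_alt_splice):
        n_exons = int(rng.integers(3, 5))
        exons = tuple(_random_seq(rng, exon_len()) for _ in range(n_exons))
        if n_exons == 3:
            isoforms = ((0, 1, 2), (0, 2))
        else:
            isoforms = ((0, 1, 2, 3), (0, 2, 3), (0, 1, 3))
        has_hit = rng.random() >= params.no_hit_fraction
        acc = next_acc() if has_hit else None
        models.append(
            GeneModel(
                gene_id=next_gid("g"),
                category="alt_splice",
                sex_bias="none",
                exons=exons,
                paired_exons=tuple(None for _ in exons),
                isoforms=isoforms,
                accession=acc,
                go_terms=go_terms("none") if acc else (),
            )
        )

    for _ in range(params.n_chimera):
        half_a = _random_seq(rng, exon_len())
        half_b = _random_seq(rng, exon_len())
        models.append(
            GeneModel(
                gene_id=next_gid("g"),
                category="chimera_source",
                sex_bias="none",
                exons=(half_a, half_b),
                paired_exons=(None, None),
                isoforms=((0, 1),),
                accession=next_acc(),
                accession2=next_acc(),
                go_terms=go_terms("none"),
            )
        )

    genes_df = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "category": [m.category for m in models],
            "sex_bias": [m.sex_bias for m in models],
            "divergence": [m.divergence for m in models],
            "accession": [m.accession or "" for m in models],
            "accession2": [m.accession2 or "" for m in models],
            "weak_homolog": [m.weak_homolog for m in models],
            "go_terms": [",".join(m.go_terms) for m in models],
        }
    )
    empty = pd.DataFrame()
    return models, GroundTruthTable(
        genes=genes_df, contigs=empty, reads=empty, variants=empty, components=empty
    )


# ---------------------------------------------------------------------------
# transcripts and layouts


def _transcripts(model: GeneModel) -> list[tuple[str, str]]:
    """All transcript sequences of a gene as (label, sequence)."""
    if model.category in ("allele_pair", "duplicate_pair"):
        primary = "".join(model.exons)
        parts = [
            pe if pe is not None else ex
            for ex, pe in zip(model.exons, model.paired_exons)
        ]
        return [("A", primary), ("B", "".join(parts))]
    if model.category == "alt_splice":
        return [
            (f"iso{k}", "".join(model.exons[i] for i in path))
            for k, path in enumerate(model.isoforms)
        ]
    # unique and chimera_source: one transcript over all exons
    return [("t", "".join(model.exons))]


def simulate_reads(
    models: list[GeneModel],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Draw sex-labelled reads uniformly along each gene's transcripts.

    Genes biased to one sex receive only that sex's reads (up to the optional
    leakage rate); unbiased genes draw each read's sex from the sex ratio.
    """
    if not models:
        raise ValueError("no gene models")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    reads: list[SimulatedRead] = []
    counter = 0
    for model in models:
        txs = _transcripts(model)
        mean_len = sum(len(t) for _, t in txs) / len(txs)
        n_reads = rng.poisson(params.depth_mean * mean_len / params.read_length_mean)
        for _ in range(int(n_reads)):
            tx_index = int(rng.integers(0, len(txs)))
            tx = txs[tx_index][1]
            length = int(
                np.clip(
                    rng.normal(params.read_length_mean, params.read_length_sd),
                    params.read_length_min,
                    min(len(tx), params.exon_length[0]),
                )
            )
            start = int(rng.integers(0, len(tx) - length + 1))
            if model.sex_bias == "female_only":
                sex = "F" if rng.random() >= params.sex_leakage else "M"
            elif model.sex_bias == "male_only":
                sex = "M" if rng.random() >= params.sex_leakage else "F"
            else:
                sex = "F" if rng.random() < params.sex_ratio else "M"
            counter += 1
            junction = _spans_boundary(model, tx_index, start, length)
            reads.append(
                SimulatedRead(
                    record=SequenceRecord(
                        id=f"r{counter:07d}", residues=tx[start : start + length]
                    ),
                    sex=sex,
                    gene_id=model.gene_id,
                    tx_index=tx_index,
                    start=start,
                    junction=junction,
                )
            )
    return reads


def _segment_bounds(model: GeneModel, tx_index: int) -> list[tuple[int, int, int]]:
    """(exon_index, tx_start, tx_end) for each segment of the transcript."""
    if model.category == "alt_splice":
        path = model.isoforms[tx_index]
    elif model.category in ("unique", "chimera_source"):
        path = model.isoforms[0] if model.isoforms else tuple(range(len(model.exons)))
    else:
        path = tuple(range(len(model.exons)))
    bounds = []
    pos = 0
    for idx in path:
        ln = len(model.exons[idx])
        bounds.append((idx, pos, pos + ln))
        pos += ln
    return bounds


def _spans_boundary(model: GeneModel, tx_index: int, start: int, length: int) -> bool:
    if model.category in ("unique", "chimera_source"):
        return False
    if model.category == "allele_pair" and len(model.exons) == 1:
        return False
    for _, s, e in _segment_bounds(model, tx_index):
        if s < start < e and start + length > e:
            return True
        if start < s < start + length:
            return True
    return False


# ---------------------------------------------------------------------------
# assembly emulation


@dataclass
class AssemblyEmulation:
    contigs: list[SequenceRecord]
    singletons: list[SequenceRecord]
    read_status: list[ReadStatusRecord]
    variants: list[VariantRecord]
    truth: GroundTruthTable


def _contig_layouts(
    models: list[GeneModel], params: SimulationParams
) -> tuple[list[SequenceRecord], dict, list[dict]]:
    """Decide the contig decomposition of every gene.

    Returns the contig records, a map gene_id -> per-transcript layout
    (list of (contig_id, tx_start, tx_end)), and the contig truth rows.
    """
    contigs: list[SequenceRecord] = []
    layouts: dict[str, list[list[tuple[str, int, int]]]] = {}
    rows: list[dict] = []
    counter = 0

    def new_contig(seq: str, gene_id: str, role: str) -> str:
        nonlocal counter
        counter += 1
        cid = f"c{counter:05d}"
        contigs.append(SequenceRecord(id=cid, residues=seq))
        rows.append({"contig_id": cid, "gene_id": gene_id, "role": role})
        return cid

    for model in models:
        if model.category in ("unique", "chimera_source"):
            seq = "".join(model.exons)
            role = "chimera" if model.category == "chimera_source" else "full"
            cid = new_contig(seq, model.gene_id, role)
            layouts[model.gene_id] = [[(cid, 0, len(seq))]]
        elif model.category in ("allele_pair", "duplicate_pair"):
            var_idx = len(model.exons) - 1
            a = model.exons[var_idx]
            b = model.paired_exons[var_idx]
            realized = 1.0 - round(model.divergence * len(a)) / len(a)
            if realized >= params.assembler_merge_identity:
                # collapse: one contig (copy A as consensus), diffs -> variants
                seq = "".join(model.exons)
                cid = new_contig(seq, model.gene_id, "merged_pair")
                layout = [(cid, 0, len(seq))]
                layouts[model.gene_id] = [layout, layout]
            else:
                tag = "allele" if model.category == "allele_pair" else "dup"
                cid_s = new_contig(model.exons[0], model.gene_id, "shared")
                cid_a = new_contig(a, model.gene_id, f"{tag}_A")
                cid_b = new_contig(b, model.gene_id, f"{tag}_B")
                ls, lv = len(model.exons[0]), len(a)
                layouts[model.gene_id] = [
                    [(cid_s, 0, ls), (cid_a, ls, ls + lv)],
                    [(cid_s, 0, ls), (cid_b, ls, ls + len(b))],
                ]
        elif model.category == "alt_splice":
            used = sorted({i for path in model.isoforms for i in path})
            exon_cid = {
                i: new_contig(model.exons[i], model.gene_id, f"exon{i}") for i in used
            }
            per_iso = []
            for path in model.isoforms:
                pos = 0
                layout = []
                for i in path:
                    ln = len(model.exons[i])
                    layout.append((exon_cid[i], pos, pos + ln))
                    pos += ln
                per_iso.append(layout)
            layouts[model.gene_id] = per_iso
        else:  # pragma: no cover
            raise ValueError(f"unknown category {model.category}")
    return contigs, layouts, rows


def _expected_components(models, params, contig_rows) -> pd.DataFrame:
    by_gene: dict[str, dict[str, str]] = {}
    for row in contig_rows:
        by_gene.setdefault(row["gene_id"], {})[row["role"]] = row["contig_id"]
    rows = []
    for model in models:
        roles = by_gene.get(model.gene_id, {})
        if model.category == "allele_pair" and "allele_A" in roles:
            rows.append(
                {
                    "component_key": f"truth_{model.gene_id}",
                    "gene_id": model.gene_id,
                    "ctype": "merged_alleles",
                    "members": ",".join(sorted((roles["allele_A"], roles["allele_B"]))),
                }
            )
        elif model.category == "duplicate_pair" and "dup_A" in roles:
            rows.append(
                {
                    "component_key": f"truth_{model.gene_id}",
                    "gene_id": model.gene_id,
                    "ctype": "duplicate_pair",
                    "members": ",".join(sorted((roles["dup_A"], roles["dup_B"]))),
                }
            )
        elif model.category == "alt_splice":
            members = sorted(c for r, c in roles.items() if r.startswith("exon"))
            rows.append(
                {
                    "component_key": f"truth_{model.gene_id}",
                    "gene_id": model.gene_id,
                    "ctype": "alt_splice",
                    "members": ",".join(members),
                }
            )
    return pd.DataFrame(
        rows, columns=["component_key", "gene_id", "ctype", "members"]
    )


def emulate_assembly(
    models: list[GeneModel],
    reads: list[SimulatedRead],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    truth: GroundTruthTable | None = None,
) -> AssemblyEmulation:
    """Emulate the assembler: contigs, read placements, variant calls."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    contigs, layouts, contig_rows = _contig_layouts(models, params)
    model_by_id = {m.gene_id: m for m in models}

    status_records: list[ReadStatusRecord] = []
    singleton_records: list[SequenceRecord] = []
    read_rows: list[dict] = []

    for read in reads:
        u = rng.random()
        if u < params.discard_rate:
            status, placements = "discarded", ()
        elif u < params.discard_rate + params.singleton_rate:
            status, placements = "singleton", ()
            singleton_records.append(read.record)
        else:
            layout = layouts[read.gene_id][read.tx_index]
            rlen = len(read.record.residues)
            r_start, r_end = read.start, read.start + rlen  # half-open on tx
            parts = []
            for cid, seg_s, seg_e in layout:
                ov_s, ov_e = max(r_start, seg_s), min(r_end, seg_e)
                if ov_e > ov_s:
                    parts.append((cid, ov_s, ov_e, seg_s))
            if len(parts) == 2 and all(
                (p[2] - p[1]) >= params.min_split_part for p in parts
            ):
                status = "partially_assembled"
                placements = tuple(
                    ReadPlacement(
                        contig_id=cid,
                        read_start=ov_s - r_start + 1,
                        read_end=ov_e - r_start,
                        contig_start=ov_s - seg_s + 1,
                        strand="+",
                    )
                    for cid, ov_s, ov_e, seg_s in parts
                )
            else:
                cid, ov_s, ov_e, seg_s = max(parts, key=lambda p: p[2] - p[1])
                status = "assembled"
                placements = (
                    ReadPlacement(
                        contig_id=cid,
                        read_start=ov_s - r_start + 1,
                        read_end=ov_e - r_start,
                        contig_start=ov_s - seg_s + 1,
                        strand="+",
                    ),
                )
        status_records.append(
            ReadStatusRecord(
                read_id=read.record.id,
                sex=read.sex,
                status=status,
                placements=placements,
            )
        )
        read_rows.append(
            {
                "read_id": read.record.id,
                "gene_id": read.gene_id,
                "sex": read.sex,
                "status": status,
                "junction": read.junction,
            }
        )

    # off-target singletons with no generating gene
    for k in range(params.n_junk_singletons):
        rid = f"junk{k + 1:04d}"
        seq = _random_seq(rng, int(params.read_length_mean))
        sex = "F" if rng.random() < params.sex_ratio else "M"
        singleton_records.append(SequenceRecord(id=rid, residues=seq))
        status_records.append(
            ReadStatusRecord(read_id=rid, sex=sex, status="singleton")
        )
        read_rows.append(
            {
                "read_id": rid,
                "gene_id": "",
                "sex": sex,
                "status": "singleton",
                "junction": False,
            }
        )

    # ------------------------------------------------------------------
    # variants
    variant_records: list[VariantRecord] = []
    variant_rows: list[dict] = []
    contig_seq = {c.id: c.residues for c in contigs}
    contig_gene = {row["contig_id"]: row["gene_id"] for row in contig_rows}
    contig_role = {row["contig_id"]: row["role"] for row in contig_rows}
    used_positions: dict[str, set[int]] = {c.id: set() for c in contigs}

    def add_variant(v: VariantRecord, truth_label: str) -> None:
        variant_records.append(v)
        variant_rows.append(
            {
                "contig_id": v.contig_id,
                "position": v.position,
                "var_type": v.var_type,
                "truth": truth_label,
            }
        )
        used_positions[v.contig_id].add(v.position)

    def true_cov() -> int:
        return max(int(rng.poisson(params.depth_mean)), 1)

    def true_prob() -> float:
        return min(float(rng.beta(20, 1)), 1.0)

    for model in models:
        if model.category != "allele_pair" or len(model.exons) != 1:
            continue
        layout = layouts[model.gene_id][0]
        if len(layout) != 1:
            continue
        cid = layout[0][0]
        a, b = model.exons[0], model.paired_exons[0]
        for i, (ra, rb) in enumerate(zip(a, b)):
            if ra != rb:
                add_variant(
                    VariantRecord(
                        contig_id=cid,
                        position=i + 1,
                        ref_allele=ra,
                        alt_allele=rb,
                        var_type="SNP",
                        coverage=true_cov(),
                        probability=true_prob(),
                    ),
                    "true",
                )
        # true INDELs placed away from homopolymers so the filter keeps them
        mask = homopolymer_mask(a, 3)
        safe = [
            i + 1
            for i in range(1, len(a) - 1)
            if not mask[i] and (i + 1) not in used_positions[cid]
        ]
        n_ind = min(params.true_indels_per_merged, len(safe))
        if n_ind:
            for pos in sorted(
                int(p) for p in rng.choice(safe, size=n_ind, replace=False)
            ):
                if rng.random() < 0.5:
                    v = VariantRecord(
                        contig_id=cid,
                        position=pos,
                        ref_allele=a[pos - 1],
                        alt_allele="-",
                        var_type="DEL",
                        coverage=true_cov(),
                        probability=true_prob(),
                    )
                else:
                    v = VariantRecord(
                        contig_id=cid,
                        position=pos,
                        ref_allele="-",
                        alt_allele="ACGT"[rng.integers(0, 4)],
                        var_type="INS",
                        coverage=true_cov(),
                        probability=true_prob(),
                    )
                add_variant(v, "true")

    # injected false calls
    for c in contigs:
        seq = c.residues
        for _ in range(int(rng.poisson(params.false_snp_rate))):
            pos = int(rng.integers(1, len(seq) + 1))
            if pos in used_positions[c.id]:
                continue
            ref = seq[pos - 1]
            if ref not in "ACGT":
                continue
            alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            add_variant(
                VariantRecord(
                    contig_id=c.id,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    var_type="SNP",
                    coverage=int(rng.integers(1, 131)),
                    probability=float(rng.beta(2, 2)),
                ),
                "false",
            )
        if rng.random() < params.homopolymer_indel_rate:
            mask = homopolymer_mask(seq, 3)
            inside = [i + 1 for i in range(len(seq)) if mask[i]]
            inside = [p for p in inside if p not in used_positions[c.id]]
            if inside:
                pos = int(inside[int(rng.integers(0, len(inside)))])
                add_variant(
                    VariantRecord(
                        contig_id=c.id,
                        position=pos,
                        ref_allele=seq[pos - 1],
                        alt_allele="-",
                        var_type="DEL",
                        coverage=true_cov(),
                        probability=true_prob(),
                    ),
                    "false",
                )

    contigs_df = pd.DataFrame(contig_rows, columns=["contig_id", "gene_id", "role"])
    reads_df = pd.DataFrame(
        read_rows, columns=["read_id", "gene_id", "sex", "status", "junction"]
    )
    variants_df = pd.DataFrame(
        variant_rows, columns=["contig_id", "position", "var_type", "truth"]
    )
    components_df = _expected_components(models, params, contig_rows)

    if truth is None:
        genes_df = pd.DataFrame()
    else:
        genes_df = truth.genes
    new_truth = GroundTruthTable(
        genes=genes_df,
        contigs=contigs_df,
        reads=reads_df,
        variants=variants_df,
        components=components_df,
    )
    return AssemblyEmulation(
        contigs=contigs,
        singletons=singleton_records,
        read_status=status_records,
        variants=variant_records,
        truth=new_truth,
    )


# ---------------------------------------------------------------------------
# homology hits


def _log_uniform_evalue(
    rng: np.random.Generator, lo_exp: float, hi_exp: float
) -> float:
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def simulate_blast_hits(
    contigs: list[SequenceRecord],
    truth: GroundTruthTable,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    models: list[GeneModel] | None = None,
    singletons: list[SequenceRecord] | None = None,
    singleton_reads: pd.DataFrame | None = None,
) -> list[BlastHit]:
    """Emulate tabular homology evidence against the reference databases.

    Contigs of genes without a homologue get no hits; allele contigs of one
    gene hit the same accession; the two diverged contigs of a duplicate pair
    hit different paralog accessions (the shared contig hits both); chimera
    contigs get two strong hits on opposite query halves.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    model_by_id = {m.gene_id: m for m in models} if models else {}
    gene_info = truth.genes.set_index("gene_id") if len(truth.genes) else None
    role = truth.contigs.set_index("contig_id")["role"].to_dict()
    gene_of = truth.contigs.set_index("contig_id")["gene_id"].to_dict()
    hits: list[BlastHit] = []

    def gene_field(gid: str, col: str):
        if gene_info is None or gid not in gene_info.index:
            return None
        val = gene_info.at[gid, col]
        if isinstance(val, str) and not val:
            return None
        return val

    def add_hit(qid, db, subject, qs, qe, evalue):
        span = qe - qs + 1
        hits.append(
            BlastHit(
                query_id=qid,
                db_name=db,
                subject_id=subject,
                percent_identity=float(rng.uniform(55, 95)),
                align_length=span,
                mismatches=int(span * 0.1),
                gap_opens=0,
                query_start=qs,
                query_end=qe,
                subject_start=1,
                subject_end=max(span // 3, 1),
                evalue=evalue,
                bitscore=float(span * 1.2),
            )
        )

    def dbs_for(rng) -> list[str]:
        out = [params.databases[0]]
        for db in params.databases[1:]:
            if rng.random() < params.extra_db_prob:
                out.append(db)
        return out

    for c in contigs:
        gid = gene_of.get(c.id)
        if gid is None:
            continue
        acc = gene_field(gid, "accession")
        if acc is None:
            continue
        acc2 = gene_field(gid, "accession2")
        weak = bool(gene_field(gid, "weak_homolog"))
        r = role.get(c.id, "")
        L = len(c.residues)
        strong = lambda: _log_uniform_evalue(rng, -120, -55)
        weak_e = lambda: _log_uniform_evalue(rng, -18, -6)
        if r == "chimera":
            mid = L // 2
            add_hit(c.id, params.databases[0], acc, 1, mid - 10, strong())
            add_hit(c.id, params.databases[0], acc2, mid + 10, L, strong())
            continue
        if r.startswith("exon") and rng.random() > params.exon_hit_prob:
            continue
        ev = weak_e() if weak else strong()
        qs, qe = max(1, int(L * 0.03)), int(L * 0.97)
        if r == "dup_B":
            subjects = [acc2]
        elif r == "shared" and acc2 is not None:
            subjects = [acc, acc2]
        else:
            subjects = [acc]
        for db in dbs_for(rng):
            for subj in subjects:
                add_hit(c.id, db, subj, qs, qe, ev)

    if singletons is not None and singleton_reads is not None:
        gene_of_read = singleton_reads.set_index("read_id")["gene_id"].to_dict()
        for s in singletons:
            gid = gene_of_read.get(s.id) or None
            if not gid:
                continue
            acc = gene_field(gid, "accession")
            if acc is None:
                continue
            if rng.random() < params.singleton_hit_rate:
                ev = _log_uniform_evalue(rng, -45, -30)
                add_hit(s.id, params.databases[0], acc, 5, len(s.residues) - 5, ev)
    return hits


def go_annotations_from_truth(truth: GroundTruthTable) -> list[GoAnnotation]:
    """Gene-level GO map keyed by homology accession."""
    out: list[GoAnnotation] = []
    for _, row in truth.genes.iterrows():
        acc = row["accession"]
        terms = row["go_terms"]
        if not acc or not isinstance(terms, str) or not terms:
            continue
        for term in terms.split(","):
            out.append(GoAnnotation(seq_id=acc, term_id=term))
    return out


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SyntheticDataset:
    params: SimulationParams
    models: list[GeneModel]
    reads: list[SimulatedRead]
    contigs: list[SequenceRecord]
    singletons: list[SequenceRecord]
    read_status: list[ReadStatusRecord]
    variants: list[VariantRecord]
    blast_hits: list[BlastHit]
    go_annotations: list[GoAnnotation]
    truth: GroundTruthTable


def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Run the full generator deterministically from ``params.seed``."""
    master = np.random.SeedSequence(params.seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(4)]
    models, truth = generate_gene_set(params, rngs[0])
    reads = simulate_reads(models, params, rngs[1])
    emu = emulate_assembly(models, reads, params, rngs[2], truth=truth)
    singleton_reads = emu.truth.reads[emu.truth.reads["status"] == "singleton"]
    hits = simulate_blast_hits(
        emu.contigs,
        emu.truth,
        params,
        rngs[3],
        models=models,
        singletons=emu.singletons,
        singleton_reads=singleton_reads,
    )
    return SyntheticDataset(
        params=params,
        models=models,
        reads=reads,
        contigs=emu.contigs,
        singletons=emu.singletons,
        read_status=emu.read_status,
        variants=emu.variants,
        blast_hits=hits,
        go_annotations=go_annotations_from_truth(emu.truth),
        truth=emu.truth,
    )


def write_dataset(
    ds: SyntheticDataset, outdir: str | os.PathLike, write_reads: bool = False
) -> None:
    """Write the full on-disk file set plus the ground-truth ledger."""
    os.makedirs(outdir, exist_ok=True)
    io_formats.write_fasta(ds.contigs, os.path.join(outdir, "contigs.fasta"))
    io_formats.write_fasta(ds.singletons, os.path.join(outdir, "singletons.fasta"))
    if write_reads:
        io_formats.write_fasta(
            [r.record for r in ds.reads], os.path.join(outdir, "reads.fasta")
        )
    io_formats.write_read_status(
        ds.read_status, os.path.join(outdir, "read_status.tsv")
    )
    io_formats.write_variants(ds.variants, os.path.join(outdir, "variants.tsv"))
    io_formats.write_blast_hits(ds.blast_hits, os.path.join(outdir, "blast.tsv"))
    io_formats.write_go_map(ds.go_annotations, os.path.join(outdir, "go_map.tsv"))
    ds.truth.write(outdir)
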