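"""Seeded simulator of bacterial genomes, operon structure and coverage.

The generative model mirrors the biology the classifier exploits: genes on
one strand come in runs; consecutive genes within a run are partitioned
into transcription units (TUs); all genes of a TU — and the intergenic
regions between them — are transcribed as one mRNA and therefore share one
expression level, so coverage is continuous across within-operon IGRs.
Between TUs each gene draws an independent level and the boundary IGR's
coverage is suppressed by ``gap_depth_ratio``.  Per-base read counts are
drawn negative-binomially per sample to emulate RNA-seq overdispersion.

A configurable fraction of genes is withheld from the emitted operon table,
producing label-2 (unknown) pairs downstream, and a fraction of
within-operon pairs receives an antisense gene inserted into their IGR
(noncontiguous-operon fixtures) whose own expression is added on top of the
continuing sense coverage.

With a fixed seed every output is byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import PairDataset, build_dataset
from .genome_io import CoverageTrack, GeneModel, GenePair, enumerate_pairs, write_annotation
from .labeling import OperonTable, label_pairs, write_operon_table

CONTIG = "chr"


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and coverage generator.

    Defaults emulate a bacterial chromosome: ~735 bp genes (log-normal),
    short IGRs with occasional abutting genes, about six genes per
    same-strand run, 61% of within-run gene pairs co-operonic and roughly
    half of all genes lacking experimental operon evidence — proportions in
    line with curated training compendia.  Mean coverage 50x with
    negative-binomial dispersion 10; non-operon boundary IGRs keep 10% of
    the flanking coverage.
    """

    seed: int = 0
    n_genes: int = 300
    n_samples: int = 3
    gene_length_logmean: float = math.log(735.0)
    gene_length_logsd: float = 0.35
    igr_length_logmean: float = math.log(60.0)
    igr_length_logsd: float = 0.8
    igr_length_offset: int = 10
    run_length_mean: float = 6.0
    operon_fraction: float = 0.61
    unknown_fraction: float = 0.49
    expression_shape: float = 2.0
    expression_mean: float = 50.0
    nb_dispersion: float = 10.0
    gap_depth_ratio: float = 0.1
    antisense_fraction: float = 0.05
    background_depth: float = 0.2
    strand_mode: str = "alternating"  # "alternating" runs or "single" strand
    inter_run_gap_extra: int = 50
    constant_expression: bool = False  # every TU at expression_mean exactly

    def __post_init__(self) -> None:
        for name in ("operon_fraction", "unknown_fraction", "gap_depth_ratio",
                     "antisense_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {value}")
        for name in ("expression_shape", "expression_mean", "nb_dispersion",
                     "run_length_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (1 <= self.n_samples <= 6):
            raise ValueError("n_samples must be between 1 and 6")
        if self.strand_mode not in ("alternating", "single"):
            raise ValueError("strand_mode must be 'alternating' or 'single'")


@dataclass
class SimOutput:
    """Everything the simulator produced, in memory."""

    config: SimConfig
    genes: list[GeneModel]
    pairs: list[GenePair]
    operon_table: OperonTable
    tracks: list[CoverageTrack]
    truth: dict[str, int]  # pair_id -> 0/1 from the generative TU partition
    tu_of: dict[str, str]  # gene_id -> transcription-unit id
    contig_lengths: dict[str, int]
    withheld_genes: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        """Write GFF3 + operon TSV + per-base depth TSVs + truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation(self.genes, outdir / "annotation.gff3")
        write_operon_table(self.operon_table, outdir / "operons.tsv")
        with open(outdir / "truth.tsv", "wt") as handle:
            handle.write("pair_id\tlabel\n")
            for pair_id, label in self.truth.items():
                handle.write(f"{pair_id}\t{label}\n")
        (outdir / "contigs.json").write_text(json.dumps(self.contig_lengths))
        (outdir / "sim_config.json").write_text(
            json.dumps(asdict(self.config), indent=2)
        )
        for track in self.tracks:
            with open(outdir / f"coverage_{track.sample_id}.tsv", "wt") as handle:
                for seqid, arr in track.depths.items():
                    nonzero = np.flatnonzero(arr)
                    for pos in nonzero:  # 1-based per-base dialect
                        handle.write(f"{seqid}\t{pos + 1}\t{arr[pos]}\n")


def _draw_length(rng, logmean, logsd, minimum=1):
    return max(minimum, int(round(rng.lognormal(logmean, logsd))))


def simulate(config: SimConfig) -> SimOutput:
    """Generate one synthetic genome, its operon table and coverage tracks."""
    rng = np.random.default_rng(config.seed)

    # ---- gene geometry: same-strand runs along one contig
    genes: list[dict] = []
    cursor = 200
    strand = "+" if rng.random() < 0.5 else "-"
    n_placed = 0
    run_index = 0
    while n_placed < config.n_genes:
        run_len = min(
            config.n_genes - n_placed,
            int(rng.geometric(1.0 / config.run_length_mean)),
        )
        if run_len == 0:
            continue
        for i in range(run_len):
            length = _draw_length(
                rng, config.gene_length_logmean, config.gene_length_logsd,
                minimum=60,
            )
            genes.append({
                "gene_id": f"g{n_placed:05d}",
                "start": cursor,
                "end": cursor + length,
                "strand": strand,
                "run": run_index,
                "pos_in_run": i,
            })
            cursor += length
            n_placed += 1
            if i < run_len - 1:
                igr = max(
                    0,
                    _draw_length(rng, config.igr_length_logmean,
                                 config.igr_length_logsd, minimum=0)
                    - config.igr_length_offset,
                )
                cursor += igr
        cursor += config.inter_run_gap_extra + max(
            0,
            _draw_length(rng, config.igr_length_logmean,
                         config.igr_length_logsd, minimum=0)
            - config.igr_length_offset,
        )
        if config.strand_mode == "alternating":
            strand = "-" if strand == "+" else "+"
        run_index += 1

    # ---- partition each run into transcription units
    tu_of: dict[str, str] = {}
    tu_genes: dict[str, list[str]] = {}
    tu_counter = 0
    for g in genes:
        if g["pos_in_run"] == 0 or rng.random() >= config.operon_fraction:
            tu_counter += 1
        tu_id = f"TU{tu_counter:05d}"
        tu_of[g["gene_id"]] = tu_id
        tu_genes.setdefault(tu_id, []).append(g["gene_id"])
    gene_by_id = {g["gene_id"]: g for g in genes}

    # ---- antisense insertions into within-operon IGRs (NcO fixtures)
    antisense: list[dict] = []
    n_anti = 0
    for left, right in zip(genes, genes[1:]):
        if left["run"] != right["run"]:
            continue
        if tu_of[left["gene_id"]] != tu_of[right["gene_id"]]:
            continue
        gap = right["start"] - left["end"]
        if gap < 40:
            continue
        if rng.random() < config.antisense_fraction:
            a_len = min(gap - 10, _draw_length(
                rng, config.gene_length_logmean, config.gene_length_logsd,
                minimum=30,
            ))
            a_start = left["end"] + 5
            tu_counter += 1
            tu_id = f"TU{tu_counter:05d}"
            gid = f"as{n_anti:04d}"
            antisense.append({
                "gene_id": gid,
                "start": a_start,
                "end": a_start + a_len,
                "strand": "-" if left["strand"] == "+" else "+",
            })
            tu_of[gid] = tu_id
            tu_genes[tu_id] = [gid]
            n_anti += 1

    # ---- expression: one gamma level per TU; mean-coverage profile
    contig_length = cursor + 200
    scale = config.expression_mean / config.expression_shape
    tu_level = {
        tu_id: (config.expression_mean if config.constant_expression
                else float(rng.gamma(config.expression_shape, scale)))
        for tu_id in sorted(tu_genes)
    }
    mu = np.full(contig_length, config.background_depth, dtype=float)
    sense_spans = []  # (start, end, tu_id) of sense TUs, in genomic order
    for tu_id, members in tu_genes.items():
        coords = [gene_by_id[m] for m in members if m in gene_by_id]
        if coords:  # sense TU: continuous coverage across internal IGRs
            start = min(c["start"] for c in coords)
            end = max(c["end"] for c in coords)
            mu[start:end] += tu_level[tu_id]
            sense_spans.append((start, end, tu_id))
    for a in antisense:
        mu[a["start"]:a["end"]] += tu_level[tu_of[a["gene_id"]]]
    # every gap between consecutive transcription units keeps a
    # gap_depth_ratio fraction of the mean flanking coverage
    sense_spans.sort()
    for (s1, e1, t1), (s2, e2, t2) in zip(sense_spans, sense_spans[1:]):
        if s2 > e1:
            level = config.gap_depth_ratio * 0.5 * (tu_level[t1] + tu_level[t2])
            mu[e1:s2] += level

    # ---- per-base negative-binomial counts per sample
    r = config.nb_dispersion
    tracks = []
    for s in range(config.n_samples):
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
        tracks.append(CoverageTrack(
            sample_id=f"sample{s}",
            depths={CONTIG: counts.astype(np.int64)},
        ))

    # ---- assemble annotation and enumerate pairs
    all_genes = [
        GeneModel(gene_id=g["gene_id"], seqid=CONTIG, start=g["start"],
                  end=g["end"], strand=g["strand"])
        for g in genes + antisense
    ]
    all_genes.sort(key=lambda g: (g.seqid, g.start, g.end, g.gene_id))
    pairs = enumerate_pairs(all_genes)
    truth = {
        p.pair_id: int(tu_of[p.gene1.gene_id] == tu_of[p.gene2.gene_id])
        for p in pairs
    }

    # ---- operon table with per-gene withholding
    # A pair is unknown when either gene is absent; withholding each gene
    # with q = 1 - sqrt(1 - u) gives expected pair-level unknown fraction u.
    q = 1.0 - math.sqrt(1.0 - config.unknown_fraction)
    withheld = {
        gid for gid in tu_of if rng.random() < q
    } if q > 0 else set()
    table_entries: dict[str, list[str]] = {}
    for tu_id, members in tu_genes.items():
        visible = [m for m in members if m not in withheld]
        if visible:
            table_entries[tu_id] = visible
    operon_table = OperonTable(table_entries)

    return SimOutput(
        config=config,
        genes=all_genes,
        pairs=pairs,
        operon_table=operon_table,
        tracks=tracks,
        truth=truth,
        tu_of=tu_of,
        contig_lengths={CONTIG: contig_length},
        withheld_genes=sorted(withheld),
    )


def sim_to_dataset(sim: SimOutput, max_samples: int = 6) -> PairDataset:
    """Run the simulator output through labeling + feature building.

    The dataset's labels are the *observed* 0/1/2 labels derived from the
    (possibly censored) operon table; the generative truth stays in
    ``sim.truth``.
    """
    observed = {
        lab.pair_id: lab.label
        for lab in label_pairs(sim.pairs, sim.operon_table)
    }
    return build_dataset(sim.pairs, sim.tracks, labels=observed,
                         max_samples=max_samples)


def separable_config(seed: int = 0, n_genes: int = 650) -> SimConfig:
    """Strong-signal regime: no coverage in non-operon IGRs, low dispersion."""
    return SimConfig(seed=seed, n_genes=n_genes, gap_depth_ratio=0.0,
                     nb_dispersion=50.0, unknown_fraction=0.0)


def null_config(seed: int = 0, n_genes: int = 650) -> SimConfig:
    """No-signal regime: operon and non-operon pairs indistinguishable.

    Boundary IGRs keep full coverage (``gap_depth_ratio=1``); every TU is
    expressed at exactly the same level, because shared-versus-independent
    TU levels are themselves a discriminative signal (segment means are
    estimated from hundreds of bases, so even small level variation
    leaks); and the genome uses a single strand with inter-run gaps drawn
    from the ordinary IGR distribution so pair geometry is exchangeable
    between classes.
    """
    return SimConfig(seed=seed, n_genes=n_genes, gap_depth_ratio=1.0,
                     constant_expression=True, nb_dispersion=50.0,
                     unknown_fraction=0.0, antisense_fraction=0.0,
                     strand_mode="single", inter_run_gap_extra=0)
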