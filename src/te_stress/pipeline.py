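"""File-level orchestration: simulate a dataset bundle, run the full analysis.

``simulate_bundle`` writes everything the pipeline consumes (GFF3, BED,
counts/metadata TSVs, alignment records, FASTA, transcript starts) plus
truth tables; ``run_pipeline`` reads those files back through the package's
own readers, executes annotation -> expression -> enrichment -> follow-up
stages and writes one TSV per report plus a JSON run manifest.  Every
result table carries its thresholds, window mode and seed as ``#`` comment
header lines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotations import (
    assign_te_to_genes,
    associations_to_frame,
    parse_gene_annotation,
    parse_te_annotation,
    write_gene_gff3,
    write_te_bed,
)
from .enrichment import (
    attribute_response,
    build_contingency,
    call_enriched_families,
    family_enrichment_table,
)
from .expression import (
    SampleMeta,
    aggregate_te_family_counts,
    bh_adjust,
    compute_rpkm,
    make_contrast_summaries,
    standin_de_test_matrix,
)
from .synthetic import (
    SimulationConfig,
    generate_counts,
    generate_genome,
    generate_sequences_and_transcripts,
    generate_te_alignments,
)
from .te_features import (
    ExemplarAlignment,
    classify_start_sites,
    distance_decay,
    motif_family_summary,
    positional_enrichment,
    start_site_summary,
    strand_bias_all_families,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "simulate_bundle", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run (flag-overridable from the CLI)."""

    genes: str
    tes: str
    counts: str
    samples: str
    out_dir: str
    padj: str | None = None  # optional per-gene adjusted p-values TSV
    family_map: str | None = None  # TSV family -> superfamily
    alignments: str | None = None
    consensus: str | None = None
    exemplar_alignments: str | None = None
    transcripts_control: str | None = None
    transcripts_stress: str | None = None
    genotype: str = "B73"
    stress: str = "cold"
    window: int = 1000
    window_mode: str = "upstream_only"
    expr_threshold: float = 1.0
    fc_threshold: float = 2.0
    padj_threshold: float = 0.1
    min_genes: int = 10
    fe_threshold: float = 2.0
    p_threshold: float = 0.001
    background: str = "expressed_genes"
    n_mc: int = 100_000
    seed: int = 0
    de_mode: str = "replicated"
    decay_bins: list[int] = field(default_factory=lambda: [0, 250, 500, 1000, 2000, 5000])

    def validate(self) -> None:
        for name in ("expr_threshold", "fc_threshold", "padj_threshold", "fe_threshold",
                     "p_threshold", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        missing = [
            p for p in (self.genes, self.tes, self.counts, self.samples)
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, header: dict | None = None,
               index: bool = False) -> None:
    with open(path, "w") as out:
        for key, value in (header or {}).items():
            out.write(f"# {key}={value}\n")
        df.to_csv(out, sep="\t", index=index)


def read_samples_tsv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        SampleMeta(str(r.sample_id), str(r.genotype), str(r.condition),
                   int(r.replicate), int(r.library_size))
        for r in df.itertuples(index=False)
    ]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# ---------------------------------------------------------------------------
# Simulation bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic dataset on disk, plus truth tables."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    synthetic = generate_counts(genome)
    alignments = generate_te_alignments(genome)
    sequences = generate_sequences_and_transcripts(genome)

    paths = {name: out / fname for name, fname in [
        ("genes", "genes.gff3"), ("tes", "tes.bed"), ("counts", "counts.tsv"),
        ("samples", "samples.tsv"), ("truth", "truth_genes.tsv"),
        ("te_gene_truth", "truth_te_gene.tsv"), ("alignments", "te_alignments.tsv"),
        ("alignment_ledger", "truth_alignment_ledger.tsv"),
        ("consensus", "consensus.fasta"),
        ("exemplar_alignments", "exemplar_alignments.tsv"),
        ("exemplar_truth", "truth_exemplar_region.tsv"),
        ("transcripts_control", "transcripts_control.tsv"),
        ("transcripts_stress", "transcripts_stress.tsv"),
        ("start_site_truth", "truth_start_sites.tsv"),
        ("family_map", "family_superfamily.tsv"),
        ("config", "sim_config.yaml"),
    ]}

    write_gene_gff3(genome.genes, paths["genes"])
    write_te_bed(genome.tes, paths["tes"])
    synthetic.counts.to_csv(paths["counts"], sep="\t")
    pd.DataFrame([s.__dict__ for s in synthetic.samples]).to_csv(
        paths["samples"], sep="\t", index=False
    )
    synthetic.truth.to_csv(paths["truth"], sep="\t", index=False)
    genome.te_gene_truth.to_csv(paths["te_gene_truth"], sep="\t", index=False)
    alignments.records.to_csv(paths["alignments"], sep="\t", index=False)
    alignments.ledger.to_csv(paths["alignment_ledger"], sep="\t", index=False)
    pd.DataFrame(
        {"family": list(genome.family_superfamily),
         "superfamily": list(genome.family_superfamily.values())}
    ).to_csv(paths["family_map"], sep="\t", index=False)

    with open(paths["consensus"], "w") as fa:
        for fam, seq in sequences.consensus.items():
            fa.write(f">{fam}\n")
            for i in range(0, len(seq), 80):
                fa.write(seq[i:i + 80] + "\n")

    pd.DataFrame(
        [
            {
                "te_id": a.te_id,
                "family": a.family,
                "label": a.label,
                "intervals": ";".join(f"{lo}-{hi}" for lo, hi in a.intervals),
            }
            for a in sequences.exemplar_alignments
        ]
    ).to_csv(paths["exemplar_alignments"], sep="\t", index=False)
    pd.DataFrame(
        [{"family": sequences.exemplar_family,
          "exemplar_length": sequences.exemplar_length,
          "region_start": sequences.planted_region[0],
          "region_end": sequences.planted_region[1]}]
    ).to_csv(paths["exemplar_truth"], sep="\t", index=False)

    for name, starts in (("transcripts_control", sequences.control_starts),
                         ("transcripts_stress", sequences.stress_starts)):
        pd.DataFrame(
            {"gene_id": list(starts), "start": list(starts.values())}
        ).to_csv(paths[name], sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": sequences.promoter_gene_ids, "planted": "te_promoter"}
    ).to_csv(paths["start_site_truth"], sep="\t", index=False)

    with open(paths["config"], "w") as cfg:
        yaml.safe_dump(asdict(config), cfg, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Full pipeline over files
# ---------------------------------------------------------------------------

def read_exemplar_alignments(path: str | Path) -> list[ExemplarAlignment]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        intervals = []
        if isinstance(row.intervals, str) and row.intervals:
            for chunk in row.intervals.split(";"):
                lo, _, hi = chunk.partition("-")
                intervals.append((int(lo), int(hi)))
        out.append(ExemplarAlignment(row.te_id, row.family, intervals, row.label))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage over file inputs; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": [],
        "status": "running",
    }
    provenance = {
        "window": config.window, "window_mode": config.window_mode,
        "expr_threshold": config.expr_threshold, "fc_threshold": config.fc_threshold,
        "padj_threshold": config.padj_threshold, "min_genes": config.min_genes,
        "fe_threshold": config.fe_threshold, "p_threshold": config.p_threshold,
        "background": config.background, "seed": config.seed,
    }

    def finish(stage: str) -> None:
        manifest["stages"].append(stage)
        with open(out / "manifest.json", "w") as mh:
            json.dump(manifest, mh, indent=2, default=str)

    try:
        genes = parse_gene_annotation(config.genes)
        fam_map = None
        if config.family_map:
            fm = pd.read_csv(config.family_map, sep="\t", comment="#")
            fam_map = dict(zip(fm["family"], fm["superfamily"]))
        tes = parse_te_annotation(config.tes, family_map=fam_map)
        associations = associations_to_frame(
            assign_te_to_genes(genes, tes, window=config.window, mode=config.window_mode)
        )
        _write_tsv(associations, out / "associations.tsv", provenance)
        finish("annotations")

        counts = read_counts_tsv(config.counts)
        samples = read_samples_tsv(config.samples)
        rpkm = compute_rpkm(counts, genes, samples)
        if config.padj:
            padj_df = pd.read_csv(config.padj, sep="\t", comment="#", index_col=0)
            padj = padj_df.iloc[:, 0]
        elif config.de_mode == "replicated":
            ctrl = [s.sample_id for s in samples
                    if s.genotype == config.genotype and s.condition == "control"]
            strs = [s.sample_id for s in samples
                    if s.genotype == config.genotype and s.condition == config.stress]
            pvals = standin_de_test_matrix(counts[ctrl].values, counts[strs].values)
            padj = pd.Series(bh_adjust(pvals), index=counts.index)
        else:
            padj = None
        contrasts = make_contrast_summaries(
            rpkm, samples, config.genotype, config.stress, padj=padj,
            mode=config.de_mode, expr_threshold=config.expr_threshold,
            fc_threshold=config.fc_threshold, padj_threshold=config.padj_threshold,
        )
        _write_tsv(contrasts, out / "contrasts.tsv", provenance)

        if config.alignments:
            te_expr = aggregate_te_family_counts(
                config.alignments, tes, samples, stress=config.stress
            )
            _write_tsv(te_expr, out / "te_family_expression.tsv", provenance)
        finish("expression")

        contingency = build_contingency(associations, contrasts, background=config.background)
        enrichment = call_enriched_families(
            family_enrichment_table(contingency, n_mc=config.n_mc, seed=config.seed),
            min_genes=config.min_genes, fe_threshold=config.fe_threshold,
            p_threshold=config.p_threshold,
        )
        fam_superfam = {t.family: t.superfamily for t in tes}
        enrichment.insert(1, "type", enrichment["family"].map(fam_superfam))
        _write_tsv(enrichment, out / "family_enrichment.tsv", provenance)

        enriched_up = sorted(enrichment.loc[enrichment["enriched_up"], "family"])
        attribution = attribute_response(contrasts, associations, enriched_up)
        _write_tsv(pd.DataFrame([attribution]), out / "attribution.tsv", provenance)
        finish("enrichment")

        strand = strand_bias_all_families(
            associations, contrasts, enriched_up or sorted(associations["family"].unique())
        )
        _write_tsv(strand, out / "strand_bias.tsv", provenance)

        wide = associations_to_frame(
            assign_te_to_genes(genes, tes, window=max(config.decay_bins), mode="upstream_only")
        )
        decay = distance_decay(wide, contrasts, bin_edges=config.decay_bins,
                               families=enriched_up or None)
        _write_tsv(decay, out / "distance_decay.tsv", provenance)

        if config.consensus:
            consensus = read_fasta(config.consensus)
            focal = set(enriched_up) & set(consensus)
            groups = {}
            if focal:
                groups["enriched_families"] = [consensus[f] for f in sorted(focal)]
            rest = [s for f, s in sorted(consensus.items()) if f not in focal]
            if rest:
                groups["other_families"] = rest
            if groups:
                _write_tsv(motif_family_summary(groups).reset_index(),
                           out / "motif_summary.tsv", provenance)

        if config.exemplar_alignments:
            ex = read_exemplar_alignments(config.exemplar_alignments)
            length = max(hi for a in ex for _, hi in a.intervals) if ex else 0
            curves, regions = positional_enrichment(ex, exemplar_length=length)
            _write_tsv(regions, out / "positional_enrichment_regions.tsv", provenance)
            _write_tsv(curves, out / "positional_coverage.tsv", provenance)

        if config.transcripts_control and config.transcripts_stress:
            c_starts = pd.read_csv(config.transcripts_control, sep="\t", comment="#")
            s_starts = pd.read_csv(config.transcripts_stress, sep="\t", comment="#")
            tes_by_id = {t.te_id: t.interval for t in tes}
            calls = classify_start_sites(
                genes, associations,
                dict(zip(c_starts["gene_id"], c_starts["start"])),
                dict(zip(s_starts["gene_id"], s_starts["start"])),
                tes_by_id,
            )
            _write_tsv(
                pd.DataFrame(
                    [{"gene_id": c.gene_id, "control_start": c.control_start,
                      "stress_start": c.stress_start, "category": c.category}
                     for c in calls]
                ),
                out / "start_sites.tsv", provenance,
            )
            _write_tsv(start_site_summary(calls), out / "start_site_summary.tsv", provenance)
        finish("te_features")

        manifest["status"] = "ok"
        finish("done")
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        finish("error")
        raise
    return manifest
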