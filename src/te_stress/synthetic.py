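"""Synthetic maize-like genomes, counts, alignments and sequences with planted effects.

The generator emulates the statistical structure the TE-proximity analysis
assumes: genes with strand-aware TSSs and exon structures on several
chromosomes; named TE families whose insertions either sit in the 1 kb
upstream of randomly chosen TSSs or in intergenic space; negative-binomial
control/stress counts with a background differential-expression fraction
plus planted cis effects for a handful of "enhancer-like" TE families with
stated penetrance and effect size; TE-derived alignment records carrying
multi-mapping multiplicities and boundary-straddling reads to exercise the
quantification filters; and consensus sequences with planted DREB/CBF
sites, an exemplar-coverage set with one over-covered region, and
control/stress transcript starts with a few planted TE-promoter genes.

Every generator takes its stream from a per-component child of the single
global seed, so adding a generator never perturbs earlier streams, and a
truth table records every planted effect for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotations import GeneModel, GenomicInterval, TEInsertion, SUPERFAMILIES
from .expression import SampleMeta
from .te_features import DREB_CBF_PATTERN, ExemplarAlignment, reverse_complement, scan_motif

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "SyntheticCounts",
    "AlignmentBundle",
    "SequenceBundle",
    "generate_genome",
    "generate_counts",
    "generate_te_alignments",
    "generate_sequences_and_transcripts",
]

READ_LENGTH = 100


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and planted effects.

    Effect sizes, penetrance and the background-DE fraction follow the
    regimes the analysis is designed to detect: a few TE families whose
    nearby genes respond to stress with high (but incomplete) penetrance on
    top of a genome-wide background response.
    """

    seed: int = 0
    n_genes: int = 5000
    n_chromosomes: int = 5
    n_families: int = 40
    insertions_per_family: float = 40.0  # Poisson mean
    frac_te_near_genes: float = 0.5
    planted_families: int = 4
    effect_log2: float = 2.5
    penetrance: float = 0.6
    background_de_frac: float = 0.10
    background_effect_log2: float = 2.0
    baseline_log_mean: float = 3.0  # log2 RPKM-like scale
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.1  # variance = mu + dispersion * mu^2
    replicates: int = 3
    library_size: int = 5_000_000
    same_strand_frac: float = 0.5
    distance_decay_halflife: float | None = None  # bp; None = flat within window
    motif_plant_rate: float = 2.0  # Poisson sites per planted consensus
    # study frame
    genotype: str = "B73"
    stress: str = "cold"
    window: int = 1000
    # alignment-record generation
    reads_per_insertion: float = 8.0  # Poisson mean per insertion per condition
    frac_multimap: float = 0.10  # extra reads with > 5 locations
    frac_straddle: float = 0.10  # extra reads straddling a TE edge
    # start-site generation
    n_promoter_genes: int = 5
    n_upstream_both_genes: int = 5

    def validate(self) -> None:
        problems = []
        for name in ("frac_te_near_genes", "penetrance", "background_de_frac",
                     "same_strand_frac", "frac_multimap", "frac_straddle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if self.planted_families > self.n_families:
            problems.append("planted_families cannot exceed n_families")
        for name in ("n_genes", "n_chromosomes", "n_families", "replicates",
                     "library_size", "window"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.nb_dispersion < 0:
            problems.append("nb_dispersion must be non-negative")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    def seed_streams(self) -> dict[str, np.random.Generator]:
        names = ("genome", "counts", "alignments", "sequences", "transcripts")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {name: np.random.default_rng(child) for name, child in zip(names, children)}


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    tes: list[TEInsertion]
    chrom_lengths: dict[str, int]
    planted_families: list[str]
    family_superfamily: dict[str, str]
    # per near-gene insertion: which gene it targets and at what distance
    te_gene_truth: pd.DataFrame  # columns te_id, family, gene_id, distance
    config: SimulationConfig


@dataclass
class SyntheticCounts:
    counts: pd.DataFrame  # genes x samples
    samples: list[SampleMeta]
    truth: pd.DataFrame  # per-gene planted-effect table
    config: SimulationConfig


@dataclass
class AlignmentBundle:
    records: pd.DataFrame  # chrom, start, end, locations, sample_id
    ledger: pd.DataFrame  # family, condition, n_retained (generation tally)


@dataclass
class SequenceBundle:
    consensus: dict[str, str]  # family -> sequence
    exemplar_family: str
    exemplar_length: int
    exemplar_alignments: list[ExemplarAlignment]
    planted_region: tuple[int, int]
    control_starts: dict[str, int]
    stress_starts: dict[str, int]
    promoter_gene_ids: list[str]
    upstream_both_gene_ids: list[str]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, iv: GenomicInterval) -> list[GenomicInterval]:
    """1-4 non-overlapping exons spanning the gene's 5' and 3' ends."""
    n_exons = int(rng.integers(1, 5))
    length = len(iv)
    if n_exons == 1 or length < 40 * n_exons:
        return [GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand)]
    # split the gene into n_exons equal blocks; each exon occupies a
    # sub-interval of its block, anchored so exon space touches both ends
    bounds = np.linspace(iv.start, iv.end, n_exons + 1).astype(int)
    exons = []
    for i in range(n_exons):
        lo, hi = int(bounds[i]), int(bounds[i + 1])
        if i == 0:
            e_start = lo
            e_end = int(rng.integers(lo + 20, hi))
        elif i == n_exons - 1:
            e_start = int(rng.integers(lo, hi - 20))
            e_end = hi
        else:
            e_start = int(rng.integers(lo, hi - 20))
            e_end = int(rng.integers(e_start + 10, hi))
        exons.append(GenomicInterval(iv.chrom, e_start, e_end, iv.strand))
    return exons


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Place genes and TE insertions deterministically for the given seed.

    Genes never overlap; a fraction ``frac_te_near_genes`` of each family's
    insertions lands 1..window bp upstream of a randomly chosen TSS and the
    remainder in intergenic space well clear of any TSS window (so the
    near-gene truth table is exact).  TEs never overlap one another.
    """
    config.validate()
    rng = config.seed_streams()["genome"]

    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    gene_idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = 6000
        for _ in range(per_chrom):
            if gene_idx >= config.n_genes:
                break
            glen = int(rng.integers(800, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, cursor, cursor + glen, strand)
            gene = GeneModel(f"gene{gene_idx:05d}", iv, _make_exons(rng, iv))
            genes.append(gene)
            gene_idx += 1
            cursor += glen + int(rng.integers(4000, 9000))
        chrom_lengths[chrom] = cursor + 6000

    families = [f"fam{i:02d}" for i in range(config.n_families)]
    superfams = {f: str(rng.choice(SUPERFAMILIES)) for f in families}
    planted = list(rng.choice(families, size=config.planted_families, replace=False))

    tss_by_chrom: dict[str, np.ndarray] = {}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, gs in genes_by_chrom.items():
        tss_by_chrom[chrom] = np.sort(np.array([g.tss for g in gs]))

    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_lengths}

    def place_clear(chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > chrom_lengths[chrom]:
            return False
        if occupied[chrom].overlap(start - 150, end + 150):
            return False
        occupied[chrom].addi(start, end)
        return True

    tes: list[TEInsertion] = []
    truth_rows = []
    te_counter = 0
    chrom_names = list(chrom_lengths)
    for family in families:
        n_ins = max(1, int(rng.poisson(config.insertions_per_family)))
        for _ in range(n_ins):
            near = rng.random() < config.frac_te_near_genes
            placed = False
            for _attempt in range(300):
                # shorter elements on later attempts so dense genomes still place
                max_len = 3000 if _attempt < 30 else 800
                te_len = int(rng.integers(150, max_len))
                if near:
                    gene = genes[int(rng.integers(len(genes)))]
                    d = int(rng.integers(1, config.window + 1))
                    tss = gene.tss
                    if gene.interval.strand == "-":
                        start = tss + d
                        end = start + te_len
                    else:
                        end = tss - d + 1
                        start = end - te_len
                    if start < 0:
                        continue
                    if place_clear(gene.interval.chrom, start, end):
                        chrom = gene.interval.chrom
                        target, dist = gene.gene_id, d
                        placed = True
                        break
                else:
                    chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                    start = int(rng.integers(0, max(1, chrom_lengths[chrom] - te_len)))
                    end = start + te_len
                    tss_arr = tss_by_chrom.get(chrom, np.array([], dtype=int))
                    pad = config.window + 100
                    lo = np.searchsorted(tss_arr, start - pad)
                    hi = np.searchsorted(tss_arr, end + pad)
                    if hi > lo:  # too close to some TSS; keep truth exact
                        continue
                    if place_clear(chrom, start, end):
                        target, dist = None, np.nan
                        placed = True
                        break
            if not placed:
                raise ValueError(
                    "could not place a TE insertion; genome too dense — "
                    "increase chromosome spacing or reduce insertions"
                )
            te_id = f"{family}_{te_counter:05d}"
            te_counter += 1
            if target is not None:
                te_strand = (
                    gene.interval.strand
                    if rng.random() < config.same_strand_frac
                    else ("-" if gene.interval.strand == "+" else "+")
                )
            else:
                te_strand = "+" if rng.random() < 0.5 else "-"
            tes.append(
                TEInsertion(te_id, family, superfams[family],
                            GenomicInterval(chrom, start, end, te_strand))
            )
            truth_rows.append(
                {"te_id": te_id, "family": family, "gene_id": target, "distance": dist}
            )

    return SyntheticGenome(
        genes=genes,
        tes=tes,
        chrom_lengths=chrom_lengths,
        planted_families=sorted(planted),
        family_superfamily=superfams,
        te_gene_truth=pd.DataFrame(truth_rows),
        config=config,
    )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts(genome: SyntheticGenome) -> SyntheticCounts:
    """Control/stress replicate counts with background and planted cis effects.

    Per-gene baseline RPKM is log-normal; ``background_de_frac`` of genes
    get a random-sign stress effect of ``background_effect_log2``; genes
    with a planted-family insertion in the upstream window respond (up only)
    with probability ``penetrance``, optionally attenuated by an exponential
    distance decay.  Counts are negative binomial around means scaled to the
    configured library size and exon space.
    """
    config = genome.config
    rng = config.seed_streams()["counts"]
    genes = genome.genes
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]

    baseline_log2 = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    baseline_rpkm = np.exp2(baseline_log2)

    bg_de = rng.random(n) < config.background_de_frac
    bg_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)

    near = genome.te_gene_truth
    planted_hits = near[near["family"].isin(genome.planted_families) & near["gene_id"].notna()]
    nearest_planted = (
        planted_hits.sort_values(["gene_id", "distance"]).drop_duplicates("gene_id")
        .set_index("gene_id")
    )
    idx = pd.Index(gene_ids)
    planted_hit = idx.isin(nearest_planted.index)
    planted_dist = pd.Series(np.nan, index=idx)
    planted_dist.loc[nearest_planted.index] = nearest_planted["distance"].values
    planted_fam = pd.Series(None, index=idx, dtype=object)
    planted_fam.loc[nearest_planted.index] = nearest_planted["family"].values

    respond_prob = np.where(planted_hit, config.penetrance, 0.0)
    if config.distance_decay_halflife:
        decay = np.exp2(-planted_dist.values / config.distance_decay_halflife)
        respond_prob = respond_prob * np.where(planted_hit, decay, 1.0)
    te_influenced = rng.random(n) < respond_prob

    effect = np.zeros(n)
    effect += np.where(bg_de, bg_sign * config.background_effect_log2, 0.0)
    effect += np.where(te_influenced, config.effect_log2, 0.0)
    stress_rpkm = baseline_rpkm * np.exp2(effect)

    exon_kb = np.array([g.exon_length_total for g in genes]) / 1000.0
    per_million = config.library_size / 1e6
    mu_control = baseline_rpkm * exon_kb * per_million
    mu_stress = stress_rpkm * exon_kb * per_million

    samples: list[SampleMeta] = []
    data = {}
    for rep in range(1, config.replicates + 1):
        sid = f"ctrl_rep{rep}"
        samples.append(SampleMeta(sid, config.genotype, "control", rep, config.library_size))
        data[sid] = _nb_draw(rng, mu_control, config.nb_dispersion)
    for rep in range(1, config.replicates + 1):
        sid = f"{config.stress}_rep{rep}"
        samples.append(SampleMeta(sid, config.genotype, config.stress, rep, config.library_size))
        data[sid] = _nb_draw(rng, mu_stress, config.nb_dispersion)

    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_rpkm": baseline_rpkm,
            "planted_hit": planted_hit,
            "planted_family": planted_fam.values,
            "planted_distance": planted_dist.values,
            "te_influenced": te_influenced,
            "background_de": bg_de,
            "background_sign": np.where(bg_de, bg_sign, 0.0),
            "effect_log2": effect,
            "activated_by_design": te_influenced & (baseline_rpkm <= 1.0),
        }
    )
    return SyntheticCounts(counts=counts, samples=samples, truth=truth, config=config)


# ---------------------------------------------------------------------------
# TE-derived alignment records
# ---------------------------------------------------------------------------

def generate_te_alignments(genome: SyntheticGenome) -> AlignmentBundle:
    """Reads inside TE insertions, plus filter-targeted decoys.

    Retained reads lie fully inside their insertion with 1-5 genomic
    locations; decoys either carry > 5 locations or straddle a TE edge, so
    the quantification filters must remove exactly them.  The ledger
    records the generation tally of retained reads per family and
    condition.  Planted families are up-regulated in stress by the
    configured effect; other families fluctuate mildly around no change.
    """
    config = genome.config
    rng = config.seed_streams()["alignments"]
    conditions = ("control", config.stress)
    rep_ids = {
        "control": [f"ctrl_rep{r}" for r in range(1, config.replicates + 1)],
        config.stress: [f"{config.stress}_rep{r}" for r in range(1, config.replicates + 1)],
    }
    fam_stress_mult = {
        fam: (np.exp2(config.effect_log2) if fam in genome.planted_families
              else float(np.exp2(rng.normal(0.0, 0.25))))
        for fam in sorted({t.family for t in genome.tes})
    }

    rows = []
    ledger: dict[tuple[str, str], int] = {}
    for te in genome.tes:
        iv = te.interval
        usable = len(iv) - READ_LENGTH
        if usable <= 0:
            continue
        for cond in conditions:
            rate = config.reads_per_insertion
            if cond != "control":
                rate *= fam_stress_mult[te.family]
            n_good = int(rng.poisson(rate))
            n_multi = int(rng.poisson(rate * config.frac_multimap))
            n_straddle = int(rng.poisson(rate * config.frac_straddle))
            ledger[(te.family, cond)] = ledger.get((te.family, cond), 0) + n_good
            sids = rep_ids[cond]
            for _ in range(n_good):
                start = iv.start + int(rng.integers(0, usable + 1))
                rows.append((iv.chrom, start, start + READ_LENGTH,
                             int(rng.integers(1, 6)), sids[int(rng.integers(len(sids)))]))
            for _ in range(n_multi):
                start = iv.start + int(rng.integers(0, usable + 1))
                rows.append((iv.chrom, start, start + READ_LENGTH,
                             int(rng.integers(6, 21)), sids[int(rng.integers(len(sids)))]))
            for _ in range(n_straddle):
                if iv.start >= READ_LENGTH // 2 and rng.random() < 0.5:
                    start = iv.start - READ_LENGTH // 2
                else:
                    start = iv.end - READ_LENGTH // 2
                rows.append((iv.chrom, start, start + READ_LENGTH,
                             int(rng.integers(1, 6)), sids[int(rng.integers(len(sids)))]))

    records = pd.DataFrame(rows, columns=["chrom", "start", "end", "locations", "sample_id"])
    ledger_df = pd.DataFrame(
        [{"family": fam, "condition": cond, "n_retained": n}
         for (fam, cond), n in sorted(ledger.items())]
    )
    return AlignmentBundle(records=records, ledger=ledger_df)


# ---------------------------------------------------------------------------
# Sequences, exemplar coverage, transcript starts
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _scrub_motif(rng: np.random.Generator, seq: str, pattern: str) -> str:
    """Rewrite any pattern occurrence (either strand) with fresh random bases."""
    k = len(pattern)
    for _ in range(50):
        n_hits, hits = scan_motif(seq, pattern, both_strands=True)
        if n_hits == 0:
            return seq
        chars = list(seq)
        for pos, _strand in hits:
            chars[pos:pos + k] = list(_random_seq(rng, k))
        seq = "".join(chars)
    raise RuntimeError("motif scrub failed to converge")


def _realize_motif(rng: np.random.Generator, pattern: str) -> str:
    from .te_features import IUPAC

    return "".join(
        ch if ch in "ACGT" else str(rng.choice(list(IUPAC[ch].replace("N", "") or "ACGT")))
        for ch in pattern.upper()
    )


def generate_sequences_and_transcripts(genome: SyntheticGenome) -> SequenceBundle:
    """Consensus sequences, exemplar coverage and transcript starts.

    Planted-family consensus sequences receive Poisson(``motif_plant_rate``)
    DREB/CBF sites on random strands; all other consensus sequences are
    motif-scrubbed random sequence.  One planted family serves as the
    exemplar: insertions near responsive genes cover a fixed internal
    region (800..1100) far more often than the rest, planting a positional
    enrichment.  A handful of genes with an upstream TE emit a stress
    transcript starting inside the TE (the planted TE-promoter cases) while
    their control transcript starts at the annotated TSS.
    """
    config = genome.config
    streams = config.seed_streams()
    rng = streams["sequences"]

    consensus: dict[str, str] = {}
    for fam in sorted({t.family for t in genome.tes}):
        seq = _scrub_motif(rng, _random_seq(rng, int(rng.integers(2000, 4001))),
                           DREB_CBF_PATTERN)
        if fam in genome.planted_families:
            n_sites = int(rng.poisson(config.motif_plant_rate))
            chars = list(seq)
            for _ in range(n_sites):
                site = _realize_motif(rng, DREB_CBF_PATTERN)
                if rng.random() < 0.5:
                    site = reverse_complement(site)
                pos = int(rng.integers(0, len(chars) - len(site)))
                chars[pos:pos + len(site)] = list(site)
            seq = "".join(chars)
        consensus[fam] = seq

    # exemplar coverage with a planted enriched region
    exemplar_family = genome.planted_families[0] if genome.planted_families else "fam00"
    exemplar_length = 2000
    region = (800, 1100)
    alignments: list[ExemplarAlignment] = []
    for label, n_group, p_region in (("responsive", 100, 0.9), ("non_responsive", 100, 0.1)):
        for i in range(n_group):
            intervals: list[tuple[int, int]] = []
            if rng.random() < p_region:
                intervals.append(region)
            for lo_bound, hi_bound in ((0, region[0]), (region[1], exemplar_length)):
                if rng.random() < 0.8:
                    length = int(rng.integers(200, 600))
                    lo = int(rng.integers(lo_bound, max(lo_bound + 1, hi_bound - length)))
                    intervals.append((lo, min(lo + length, hi_bound)))
            alignments.append(
                ExemplarAlignment(f"{exemplar_family}_{label}_{i}", exemplar_family,
                                  intervals, label)
            )

    # transcript start sites
    trng = streams["transcripts"]
    gene_by_id = {g.gene_id: g for g in genome.genes}
    near = genome.te_gene_truth
    # genes with exactly one near-TSS insertion, at >= 150 bp: for these the
    # "nearest upstream TE" is unambiguous, so the planted-promoter truth is exact
    hits = near[near["gene_id"].notna()]
    singles = hits.groupby("gene_id").filter(lambda d: len(d) == 1)
    nearest = singles[singles["distance"] >= 150]
    candidate_ids = list(nearest["gene_id"])
    trng.shuffle(candidate_ids)
    promoter_ids = candidate_ids[: config.n_promoter_genes]
    upstream_ids = candidate_ids[
        config.n_promoter_genes: config.n_promoter_genes + config.n_upstream_both_genes
    ]
    te_by_id = {t.te_id: t for t in genome.tes}
    nearest_te = nearest.set_index("gene_id")["te_id"]

    control_starts: dict[str, int] = {}
    stress_starts: dict[str, int] = {}
    for gene_id in candidate_ids:
        gene = gene_by_id[gene_id]
        tss = gene.tss
        if gene_id in promoter_ids:
            te_iv = te_by_id[nearest_te[gene_id]].interval
            control_starts[gene_id] = tss
            stress_starts[gene_id] = (te_iv.start + te_iv.end) // 2
        elif gene_id in upstream_ids:
            off = config.window + 200
            pos = tss + off if gene.interval.strand == "-" else tss - off
            control_starts[gene_id] = pos
            stress_starts[gene_id] = pos
        else:
            r = trng.random()
            if r < 0.1:
                continue  # no transcript in either condition
            control_starts[gene_id] = tss
            if r < 0.2:
                continue  # stress transcript missing
            stress_starts[gene_id] = tss

    return SequenceBundle(
        consensus=consensus,
        exemplar_family=exemplar_family,
        exemplar_length=exemplar_length,
        exemplar_alignments=alignments,
        planted_region=region,
        control_starts=control_starts,
        stress_starts=stress_starts,
        promoter_gene_ids=sorted(promoter_ids),
        upstream_both_gene_ids=sorted(upstream_ids),
    )
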