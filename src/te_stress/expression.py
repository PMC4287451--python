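"""Expression normalization, response classification, and TE-family quantification.

Gene expression is normalized to RPKM (reads per kilobase of merged exon
space per million uniquely-mapped reads); TE families are quantified as RPM
(reads per million, no length normalization) from reads that lie fully
inside an annotated insertion and map to at most ``max_locations`` genomic
locations.

Response classes per gene and contrast (genotype x stress):

* ``not_expressed`` — RPKM <= 1 in both conditions;
* ``up`` / ``down`` — expressed, at least 2-fold change (log2 ratio with a
  0.5 pseudocount on both sides), and, when replicates are available, an
  adjusted p-value below 0.1;
* ``nonDE`` — expressed but failing the fold-change or significance rule.

A gene is *activated* when it is up-regulated and only expressed after the
stress treatment (control RPKM at or below the expression threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import GeneModel, TEInsertion

logger = logging.getLogger(__name__)

PSEUDOCOUNT_RPKM = 0.5

__all__ = [
    "SampleMeta",
    "compute_rpkm",
    "condition_mean_rpkm",
    "log2_ratio",
    "classify_response",
    "classify_activation",
    "make_contrast_summaries",
    "standin_de_test",
    "standin_de_test_matrix",
    "bh_adjust",
    "read_alignment_records",
    "aggregate_te_family_counts",
]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    condition: str
    replicate: int
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"sample {self.sample_id}: library_size must be positive")


def samples_to_frame(samples: Sequence[SampleMeta]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in samples])
    if df.duplicated(["genotype", "condition", "replicate"]).any():
        raise ValueError("(genotype, condition, replicate) must be unique across samples")
    return df


def compute_rpkm(
    counts: pd.DataFrame,
    genes: Sequence[GeneModel] | Mapping[str, int],
    samples: Sequence[SampleMeta],
) -> pd.DataFrame:
    """RPKM = count / (exon_kb) / (library_size / 1e6), per gene x sample.

    ``genes`` may be GeneModel objects or a mapping gene_id -> total merged
    exon length in bp.
    """
    if isinstance(genes, Mapping):
        exon_len = pd.Series(dict(genes), dtype=float)
    else:
        exon_len = pd.Series({g.gene_id: float(g.exon_length_total) for g in genes})
    missing = counts.index.difference(exon_len.index)
    if len(missing):
        raise ValueError(f"no exon length for {len(missing)} gene(s), e.g. {missing[0]!r}")
    zero = exon_len[exon_len <= 0]
    if len(zero):
        raise ValueError(f"gene {zero.index[0]!r} has non-positive exon length")
    lib = pd.Series({s.sample_id: float(s.library_size) for s in samples})
    missing_s = counts.columns.difference(lib.index)
    if len(missing_s):
        raise ValueError(f"no library size for sample(s) {list(missing_s)}")
    exon_kb = exon_len.reindex(counts.index) / 1_000.0
    per_million = lib.reindex(counts.columns) / 1e6
    return counts.div(exon_kb, axis=0).div(per_million, axis=1)


def condition_mean_rpkm(
    rpkm: pd.DataFrame, samples: Sequence[SampleMeta], genotype: str, condition: str
) -> pd.Series:
    """Mean RPKM across replicates of one (genotype, condition)."""
    ids = [s.sample_id for s in samples if s.genotype == genotype and s.condition == condition]
    if not ids:
        raise ValueError(f"no samples for ({genotype}, {condition})")
    return rpkm[ids].mean(axis=1)


def log2_ratio(rpkm_control: float, rpkm_stress: float, pseudocount: float = PSEUDOCOUNT_RPKM):
    """log2((stress + c) / (control + c)); vectorizes over array input."""
    return np.log2((np.asarray(rpkm_stress, dtype=float) + pseudocount)
                   / (np.asarray(rpkm_control, dtype=float) + pseudocount))


def classify_response(
    rpkm_control: float,
    rpkm_stress: float,
    padj: float | None = None,
    mode: str = "replicated",
    expr_threshold: float = 1.0,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.1,
) -> str:
    """Classify one gene's response to stress for one contrast.

    ``mode='replicated'`` requires an adjusted p-value; ``single_replicate``
    applies the fold-change and expression rules alone.
    """
    if mode not in ("replicated", "single_replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    if max(rpkm_control, rpkm_stress) <= expr_threshold:
        return "not_expressed"
    lr = float(log2_ratio(rpkm_control, rpkm_stress))
    if abs(lr) < np.log2(fc_threshold):
        return "nonDE"
    if mode == "replicated":
        if padj is None or np.isnan(padj):
            raise ValueError("replicated mode requires an adjusted p-value")
        if not padj < padj_threshold:
            return "nonDE"
    return "up" if lr > 0 else "down"


def classify_activation(
    rpkm_control: float,
    rpkm_stress: float,
    response_class: str,
    expr_threshold: float = 1.0,
) -> bool:
    """True for genes expressed only after stress: up-regulated with control
    RPKM at or below the expression threshold."""
    return (
        response_class == "up"
        and rpkm_control <= expr_threshold
        and rpkm_stress > expr_threshold
    )


def make_contrast_summaries(
    rpkm: pd.DataFrame,
    samples: Sequence[SampleMeta],
    genotype: str,
    stress: str,
    control: str = "control",
    padj: pd.Series | None = None,
    mode: str = "replicated",
    expr_threshold: float = 1.0,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene contrast table: RPKM pair, log2 ratio, class, activation."""
    rc = condition_mean_rpkm(rpkm, samples, genotype, control)
    rs = condition_mean_rpkm(rpkm, samples, genotype, stress)
    df = pd.DataFrame(
        {
            "gene_id": rpkm.index,
            "genotype": genotype,
            "stress": stress,
            "rpkm_control": rc.values,
            "rpkm_stress": rs.values,
        }
    )
    df["log2_ratio"] = log2_ratio(df["rpkm_control"], df["rpkm_stress"])
    df["padj"] = padj.reindex(rpkm.index).values if padj is not None else np.nan

    expressed = np.maximum(df["rpkm_control"], df["rpkm_stress"]) > expr_threshold
    big_change = np.abs(df["log2_ratio"]) >= np.log2(fc_threshold)
    if mode == "replicated":
        if padj is None:
            raise ValueError("replicated mode requires per-gene adjusted p-values")
        significant = df["padj"] < padj_threshold
    else:
        significant = pd.Series(True, index=df.index)
    cls = np.where(
        ~expressed,
        "not_expressed",
        np.where(
            big_change & significant,
            np.where(df["log2_ratio"] > 0, "up", "down"),
            "nonDE",
        ),
    )
    df["response_class"] = cls
    df["activated"] = (
        (df["response_class"] == "up")
        & (df["rpkm_control"] <= expr_threshold)
        & (df["rpkm_stress"] > expr_threshold)
    )
    return df


# ---------------------------------------------------------------------------
# Stand-in differential-expression test
# ---------------------------------------------------------------------------

def estimate_common_dispersion(counts: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion pooled across genes.

    Under var = mean + alpha * mean^2, excess variance is pooled over genes
    and groups: alpha = sum(v - m) / sum(m^2 - v/n), the denominator
    correcting the sample mean's square for its own sampling variance (a
    per-gene moment ratio with 2 df is far too noisy and median-biased).
    Floored at 0.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        sub = counts[:, idx]
        n = sub.shape[1]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 5
        num += float((v[ok] - m[ok]).sum())
        den += float((m[ok] ** 2 - v[ok] / n).sum())
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def standin_de_test(
    control_counts: Sequence[float],
    stress_counts: Sequence[float],
    size_factors: Sequence[float] | None = None,
    dispersion: float | None = None,
) -> float:
    """Two-group negative-binomial Wald test on one gene's counts.

    A stand-in for a dedicated count-model DE package, NOT its shrinkage
    machinery: group means are compared on the log scale with a
    delta-method standard error under var = mu + alpha * mu^2.  ``dispersion``
    (alpha) should normally be pooled across genes with
    :func:`estimate_common_dispersion`; when omitted it is estimated from
    this gene alone.  Benjamini-Hochberg across genes is the caller's job.
    """
    c = np.asarray(control_counts, dtype=float)
    s = np.asarray(stress_counts, dtype=float)
    if c.size < 2 or s.size < 2:
        raise ValueError(
            "standin_de_test needs >=2 replicates per condition; "
            "use single_replicate classification otherwise"
        )
    if size_factors is not None:
        sf = np.asarray(size_factors, dtype=float)
        c = c / sf[: c.size]
        s = s / sf[c.size:]
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            np.hstack([c, s])[None, :],
            [np.arange(c.size), np.arange(c.size, c.size + s.size)],
        )
    return float(
        _nb_wald_pvalues(c[None, :], s[None, :], dispersion)[0]
    )


def _nb_wald_pvalues(c: np.ndarray, s: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized NB Wald p-values for genes x replicates matrices."""
    eps = 0.5
    mc = c.mean(axis=1) + eps
    ms = s.mean(axis=1) + eps
    # Var(log mean) ~ (1/mu + alpha) / n by the delta method
    se2 = (1.0 / mc + alpha) / c.shape[1] + (1.0 / ms + alpha) / s.shape[1]
    z = np.log(ms / mc) / np.sqrt(se2)
    return 2.0 * stats.norm.sf(np.abs(z))


def standin_de_test_matrix(
    control: np.ndarray, stress: np.ndarray, size_factors_control=None, size_factors_stress=None
) -> np.ndarray:
    """Stand-in NB Wald test over a genes x replicates count matrix pair,
    with the dispersion pooled across all genes."""
    c = np.asarray(control, dtype=float)
    s = np.asarray(stress, dtype=float)
    if size_factors_control is not None:
        c = c / np.asarray(size_factors_control, dtype=float)[None, :]
    if size_factors_stress is not None:
        s = s / np.asarray(size_factors_stress, dtype=float)[None, :]
    both = np.hstack([c, s])
    alpha = estimate_common_dispersion(
        both, [np.arange(c.shape[1]), np.arange(c.shape[1], both.shape[1])]
    )
    return _nb_wald_pvalues(c, s, alpha)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# TE-family read aggregation
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = ["chrom", "start", "end", "locations", "sample_id"]


def read_alignment_records(path: str | Path) -> pd.DataFrame:
    """Read alignment records from SAM/BAM or the plain-text TSV dialect.

    The TSV dialect has columns chrom, start, end (0-based half-open),
    locations (number of genomic locations for the read) and sample_id.
    SAM/BAM records take locations from the NH tag (default 1) and
    sample_id from the read group (RG tag), falling back to 'sample1'.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        import pysam

        try:
            handle = pysam.AlignmentFile(str(path), check_sq=False)
        except (OSError, ValueError) as exc:
            raise ValueError(
                f"could not open {path}: {exc}. For BAM input, sort and index the file "
                "(samtools sort/index) or convert to the TSV alignment dialect."
            ) from exc
        rows = []
        with handle:
            for rec in handle.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                rows.append(
                    (
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        rec.get_tag("NH") if rec.has_tag("NH") else 1,
                        rec.get_tag("RG") if rec.has_tag("RG") else "sample1",
                    )
                )
        return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment TSV {path} missing column(s) {missing}")
    return df[ALIGNMENT_COLUMNS]


def aggregate_te_family_counts(
    alignments: pd.DataFrame | str | Path,
    tes: Sequence[TEInsertion],
    samples: Sequence[SampleMeta],
    stress: str,
    control: str = "control",
    max_locations: int = 5,
    require_full_overlap: bool = True,
    min_reads: int = 10,
    pseudocount_rpm: float = 0.5,
) -> pd.DataFrame:
    """Aggregate read counts per TE family for a control/stress contrast.

    A read counts toward an insertion iff its aligned span is fully
    contained in the insertion interval (or merely overlaps it when
    ``require_full_overlap`` is off) and it maps to at most
    ``max_locations`` genomic locations.  Insertion counts are summed per
    family; RPM uses the pooled library size of each condition's samples.
    The log2(stress/control) RPM ratio is only reported when both raw
    counts reach ``min_reads`` (otherwise NaN with ``log2_available``
    False).  A read inside two overlapping insertions of different
    families counts once toward each family.
    """
    if not isinstance(alignments, pd.DataFrame):
        alignments = read_alignment_records(alignments)
    alignments = alignments[ALIGNMENT_COLUMNS]

    sample_condition = {s.sample_id: s.condition for s in samples}
    lib_by_condition: dict[str, float] = {}
    for s in samples:
        lib_by_condition[s.condition] = lib_by_condition.get(s.condition, 0.0) + s.library_size
    for cond in (control, stress):
        if cond not in lib_by_condition:
            raise ValueError(f"no samples for condition {cond!r}")

    trees: dict[str, IntervalTree] = {}
    for idx, te in enumerate(tes):
        trees.setdefault(te.interval.chrom, IntervalTree()).addi(
            te.interval.start, te.interval.end, idx
        )

    families = sorted({te.family for te in tes})
    counts = {(fam, cond): 0 for fam in families for cond in (control, stress)}
    for chrom, start, end, locations, sample_id in alignments.itertuples(index=False):
        if locations > max_locations:
            continue
        cond = sample_condition.get(sample_id)
        if cond not in (control, stress):
            continue
        tree = trees.get(chrom)
        if tree is None:
            continue
        hit_families = set()
        for hit in tree.overlap(start, end):
            if require_full_overlap and not (hit.begin <= start and end <= hit.end):
                continue
            hit_families.add(tes[hit.data].family)
        for fam in hit_families:
            counts[(fam, cond)] += 1

    rows = []
    for fam in families:
        nc, ns = counts[(fam, control)], counts[(fam, stress)]
        rpm_c = nc / (lib_by_condition[control] / 1e6)
        rpm_s = ns / (lib_by_condition[stress] / 1e6)
        available = nc >= min_reads and ns >= min_reads
        lr = (
            float(np.log2((rpm_s + pseudocount_rpm) / (rpm_c + pseudocount_rpm)))
            if available
            else np.nan
        )
        rows.append(
            {
                "family": fam,
                "n_reads_control": nc,
                "n_reads_stress": ns,
                "rpm_control": rpm_c,
                "rpm_stress": rpm_s,
                "log2_ratio": lr,
                "log2_available": available,
            }
        )
    return pd.DataFrame(rows)
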