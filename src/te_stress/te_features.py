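"""Mechanistic follow-up analyses for TE-associated stress response.

Covers: strand-orientation bias of insertions near up-regulated vs non-DE
genes (Fisher exact, BH across families); decay of the responsive fraction
with TSS distance; scanning TE consensus sequences for the degenerate
DREB/CBF binding site (IUPAC RCCGACNT, i.e. A/GCCGACNT); positional
enrichment of covered exemplar regions among insertions near responsive
genes; and comparison of assembled transcript start sites between control
and stress to find TE-derived novel starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import GeneModel, GenomicInterval
from .expression import bh_adjust

__all__ = [
    "StrandBiasResult",
    "ExemplarAlignment",
    "StartSiteCall",
    "strand_bias_test",
    "strand_bias_all_families",
    "distance_decay",
    "scan_motif",
    "motif_family_summary",
    "positional_enrichment",
    "classify_start_sites",
    "reverse_complement",
]

DREB_CBF_PATTERN = "RCCGACNT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Strand bias
# ---------------------------------------------------------------------------

@dataclass
class StrandBiasResult:
    family: str
    up_same: int
    up_opp: int
    nde_same: int
    nde_opp: int
    odds_ratio: float
    p_value: float
    p_adjusted: float = float("nan")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.up_same, self.up_opp], [self.nde_same, self.nde_opp]])


def _gene_strand_table(
    associations: pd.DataFrame, contrasts: pd.DataFrame, family: str
) -> tuple[int, int, int, int]:
    """2x2 counts (up/nonDE x same/opposite strand) for one family.

    Gene-level: a gene with several insertions of the family takes the
    strand flag of its nearest insertion (smallest |signed distance|).
    """
    sub = associations[associations["family"] == family].copy()
    if sub.empty:
        return (0, 0, 0, 0)
    sub["absd"] = sub["signed_distance"].abs()
    nearest = sub.sort_values(["gene_id", "absd"]).drop_duplicates("gene_id", keep="first")
    cls = contrasts.set_index("gene_id")["response_class"]
    nearest = nearest[nearest["gene_id"].isin(cls.index)]
    nearest["response_class"] = cls.reindex(nearest["gene_id"]).values
    up = nearest[nearest["response_class"] == "up"]
    nde = nearest[nearest["response_class"] == "nonDE"]
    return (
        int(up["same_strand"].sum()),
        int((~up["same_strand"]).sum()),
        int(nde["same_strand"].sum()),
        int((~nde["same_strand"]).sum()),
    )


def strand_bias_test(
    associations: pd.DataFrame, contrasts: pd.DataFrame, family: str
) -> StrandBiasResult:
    """Two-sided Fisher exact test for same-strand excess among up-regulated
    vs non-DE genes near one family; degenerate tables give p = NaN."""
    up_same, up_opp, nde_same, nde_opp = _gene_strand_table(associations, contrasts, family)
    table = np.array([[up_same, up_opp], [nde_same, nde_opp]])
    if table.sum(axis=1).min() == 0:
        return StrandBiasResult(family, up_same, up_opp, nde_same, nde_opp,
                                float("nan"), float("nan"))
    if table.sum(axis=0).min() == 0:  # empty column margin: OR undefined, no association
        return StrandBiasResult(family, up_same, up_opp, nde_same, nde_opp, float("nan"), 1.0)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return StrandBiasResult(family, up_same, up_opp, nde_same, nde_opp, float(odds), float(p))


def strand_bias_all_families(
    associations: pd.DataFrame, contrasts: pd.DataFrame, families: Sequence[str]
) -> pd.DataFrame:
    """Strand-bias tests over ``families`` with BH adjustment across them."""
    results = [strand_bias_test(associations, contrasts, f) for f in families]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["p_adjusted"] = bh_adjust(df["p_value"])
    return df


# ---------------------------------------------------------------------------
# Distance decay
# ---------------------------------------------------------------------------

def distance_decay(
    associations: pd.DataFrame,
    contrasts: pd.DataFrame,
    bin_edges: Sequence[int] = (0, 250, 500, 1000, 2000, 5000),
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Responsive fraction of genes per upstream-distance bin, per family.

    Each expressed gene is assigned to the bin of its *nearest* insertion of
    the family (upstream distances only, d >= 0); bins are half-open
    [lo, hi).  Empty bins report n_genes = 0 with NaN proportion.
    """
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("bin edges must be strictly increasing with >= 2 edges")
    cls = contrasts.set_index("gene_id")["response_class"]
    sub = associations[associations["signed_distance"] >= 0].copy()
    sub = sub[sub["gene_id"].isin(cls.index)]
    sub["response_class"] = cls.reindex(sub["gene_id"]).values
    sub = sub[sub["response_class"] != "not_expressed"]
    if families is None:
        families = sorted(sub["family"].unique())

    rows = []
    for fam in families:
        fam_assoc = sub[sub["family"] == fam]
        nearest = (
            fam_assoc.sort_values(["gene_id", "signed_distance"])
            .drop_duplicates("gene_id", keep="first")
        )
        which = pd.cut(nearest["signed_distance"], bins=edges, right=False)
        for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
            in_bin = nearest[which.cat.codes == i]
            n = int(in_bin.shape[0])
            n_up = int((in_bin["response_class"] == "up").sum())
            rows.append(
                {
                    "family": fam,
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "n_genes": n,
                    "n_up": n_up,
                    "prop_up": (n_up / n) if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def _pattern_tables(pattern: str) -> list[np.ndarray]:
    """Per-position 256-entry boolean lookup tables for an IUPAC pattern."""
    tables = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        table = np.zeros(256, dtype=bool)
        for base in IUPAC[ch]:
            table[ord(base)] = True
        tables.append(table)
    return tables


def _scan_one_strand(seq_codes: np.ndarray, tables: list[np.ndarray]) -> np.ndarray:
    k = len(tables)
    n = seq_codes.size
    if n < k:
        return np.array([], dtype=int)
    ok = tables[0][seq_codes[: n - k + 1]]
    for offset in range(1, k):
        ok &= tables[offset][seq_codes[offset: n - k + 1 + offset]]
    return np.flatnonzero(ok)


def scan_motif(
    sequence: str,
    pattern: str = DREB_CBF_PATTERN,
    both_strands: bool = True,
) -> tuple[int, list[tuple[int, str]]]:
    """Count ungapped matches of a degenerate IUPAC pattern in a sequence.

    Overlapping matches all count.  An 'N' in the sequence matches only the
    pattern symbol 'N'.  With ``both_strands`` the reverse strand is scanned
    too; hits are reported as (forward-strand start position, strand).
    """
    seq = sequence.upper()
    tables = _pattern_tables(pattern)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits = [(int(pos), "+") for pos in _scan_one_strand(codes, tables)]
    if both_strands:
        rc_tables = _pattern_tables(reverse_complement(pattern))
        # scanning for the reverse-complement pattern on the forward strand
        # is equivalent to scanning the pattern on the reverse strand
        hits += [(int(pos), "-") for pos in _scan_one_strand(codes, rc_tables)]
    hits.sort()
    return len(hits), hits


def motif_family_summary(
    groups: Mapping[str, Sequence[str]],
    pattern: str = DREB_CBF_PATTERN,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Per group of sequences: fraction with >= 1 motif hit, mean hits/sequence."""
    rows = []
    for name, seqs in groups.items():
        seqs = list(seqs)
        if not seqs:
            raise ValueError(f"group {name!r} has no sequences")
        counts = [scan_motif(s, pattern, both_strands)[0] for s in seqs]
        rows.append(
            {
                "group": name,
                "n_sequences": len(seqs),
                "prop_with_site": float(np.mean([c > 0 for c in counts])),
                "mean_sites_per_element": float(np.mean(counts)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Positional enrichment along an exemplar element
# ---------------------------------------------------------------------------

@dataclass
class ExemplarAlignment:
    """Portions of a family exemplar covered by one insertion, with the
    response label of the insertion's nearest gene."""

    te_id: str
    family: str
    intervals: list[tuple[int, int]] = field(default_factory=list)
    label: str = "non_responsive"  # {responsive, non_responsive}


def _coverage_counts(alignments: Sequence[ExemplarAlignment], length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=int)
    for aln in alignments:
        seen = np.zeros(length, dtype=bool)
        for lo, hi in aln.intervals:
            if not (0 <= lo < hi <= length):
                raise ValueError(f"interval ({lo},{hi}) outside exemplar of length {length}")
            seen[lo:hi] = True
        cov += seen
    return cov


def positional_enrichment(
    alignments: Sequence[ExemplarAlignment],
    exemplar_length: int,
    ratio_threshold: float = 4.0,
    min_run: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exemplar positions over-covered by responsive-gene insertions.

    Returns (per-position coverage table, enriched-region table).  The
    per-position enrichment ratio compares the coverage proportions of the
    two label groups with a +1 pseudocount on counts; enriched regions are
    maximal runs of at least ``min_run`` bp with ratio >= ``ratio_threshold``,
    each with a Fisher exact p on full-region containment counts.
    """
    if exemplar_length <= 0:
        raise ValueError("exemplar length must be positive")
    resp = [a for a in alignments if a.label == "responsive"]
    nonresp = [a for a in alignments if a.label == "non_responsive"]
    if not resp or not nonresp:
        raise ValueError("need non-empty responsive and non_responsive groups")
    cov_r = _coverage_counts(resp, exemplar_length)
    cov_n = _coverage_counts(nonresp, exemplar_length)
    prop_r = cov_r / len(resp)
    prop_n = cov_n / len(nonresp)
    ratio = ((cov_r + 1) / (len(resp) + 1)) / ((cov_n + 1) / (len(nonresp) + 1))
    curves = pd.DataFrame(
        {
            "position": np.arange(exemplar_length),
            "prop_responsive": prop_r,
            "prop_non_responsive": prop_n,
            "ratio": ratio,
        }
    )

    mask = ratio >= ratio_threshold
    regions = []
    pos = 0
    while pos < exemplar_length:
        if not mask[pos]:
            pos += 1
            continue
        run_start = pos
        while pos < exemplar_length and mask[pos]:
            pos += 1
        if pos - run_start >= min_run:
            n_r = sum(1 for a in resp if _covers_region(a, run_start, pos))
            n_n = sum(1 for a in nonresp if _covers_region(a, run_start, pos))
            _, p = stats.fisher_exact(
                [[n_r, len(resp) - n_r], [n_n, len(nonresp) - n_n]], alternative="two-sided"
            )
            regions.append(
                {
                    "start": run_start,
                    "end": pos,
                    "length": pos - run_start,
                    "n_responsive_containing": n_r,
                    "n_non_responsive_containing": n_n,
                    "fisher_p": float(p),
                }
            )
    return curves, pd.DataFrame(
        regions,
        columns=["start", "end", "length", "n_responsive_containing",
                 "n_non_responsive_containing", "fisher_p"],
    )


def _covers_region(aln: ExemplarAlignment, start: int, end: int) -> bool:
    """True when the union of the alignment's intervals contains [start, end)."""
    need = start
    for lo, hi in sorted(aln.intervals):
        if lo > need:
            return False
        if hi >= end and lo <= need:
            return True
        if hi > need:
            need = hi
    return need >= end


# ---------------------------------------------------------------------------
# Start-site comparison
# ---------------------------------------------------------------------------

@dataclass
class StartSiteCall:
    gene_id: str
    control_start: int | None
    stress_start: int | None
    te_interval: GenomicInterval | None
    category: str  # {novel_te_start_stress_only, upstream_both, concordant, no_data}


def _upstream_offset(gene: GeneModel, pos: int) -> int:
    """bp from the TSS toward 5' (positive = upstream of the TSS)."""
    return gene.tss - pos if gene.interval.strand != "-" else pos - gene.tss


def classify_start_sites(
    genes: Sequence[GeneModel],
    associations: pd.DataFrame,
    control_starts: Mapping[str, int],
    stress_starts: Mapping[str, int],
    tes_by_id: Mapping[str, GenomicInterval],
    tss_window: int = 100,
    te_slack: int = 50,
    min_upstream_te: int = 100,
) -> list[StartSiteCall]:
    """Compare assembled-transcript start sites between control and stress.

    Only genes with a TE at least ``min_upstream_te`` bp 5' of the annotated
    TSS are considered (nearest such insertion taken).  Categories:

    * ``no_data`` — a transcript start is missing in either condition;
    * ``novel_te_start_stress_only`` — the control transcript starts within
      the gene model or the TSS window while the stress transcript starts
      within the TE interval expanded by ``te_slack``;
    * ``upstream_both`` — both starts lie 5' of the TSS window (likely
      incomplete annotation);
    * ``concordant`` — everything else.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    eligible = associations[associations["signed_distance"] >= min_upstream_te]
    nearest_te = (
        eligible.sort_values(["gene_id", "signed_distance"])
        .drop_duplicates("gene_id", keep="first")
        .set_index("gene_id")["te_id"]
    )
    calls: list[StartSiteCall] = []
    for gene_id, te_id in nearest_te.items():
        gene = gene_by_id.get(gene_id)
        if gene is None:
            continue
        te_iv = tes_by_id[te_id]
        c = control_starts.get(gene_id)
        s = stress_starts.get(gene_id)
        if c is None or s is None:
            calls.append(StartSiteCall(gene_id, c, s, te_iv, "no_data"))
            continue
        control_in_gene = gene.interval.contains(c) or 0 <= _upstream_offset(gene, c) <= tss_window
        stress_in_te = te_iv.start - te_slack <= s < te_iv.end + te_slack
        both_upstream = (
            _upstream_offset(gene, c) > tss_window and _upstream_offset(gene, s) > tss_window
        )
        if control_in_gene and stress_in_te:
            category = "novel_te_start_stress_only"
        elif both_upstream:
            category = "upstream_both"
        else:
            category = "concordant"
        calls.append(StartSiteCall(gene_id, c, s, te_iv, category))
    return calls


def start_site_summary(calls: Sequence[StartSiteCall]) -> pd.DataFrame:
    df = pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls], "category": [c.category for c in calls]}
    )
    return df.groupby("category").size().rename("n_genes").reset_index()
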