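"""End-to-end simulation experiments: parameter recovery and null calibration.

These drivers run the full synthetic pipeline in memory — genome, counts,
response classification with the stand-in DE test, TE-gene assignment, and
family enrichment — and score the result against the generator's truth
table.  They are what the acceptance checks and the parameter-recovery
tests execute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotations import assign_te_to_genes, associations_to_frame
from .enrichment import (
    attribute_response,
    build_contingency,
    call_enriched_families,
    family_enrichment_table,
    multinomial_gof_test,
)
from .expression import bh_adjust, compute_rpkm, make_contrast_summaries, standin_de_test_matrix
from .synthetic import SimulationConfig, SyntheticCounts, SyntheticGenome, generate_counts, generate_genome

__all__ = [
    "RecoveryResult",
    "run_enrichment_pipeline",
    "run_recovery_simulation",
    "recovery_suite",
    "null_calibration_suite",
    "null_family_pvalues",
]


@dataclass
class RecoveryResult:
    config: SimulationConfig
    genome: SyntheticGenome
    synthetic: SyntheticCounts
    contrasts: pd.DataFrame
    associations: pd.DataFrame
    enrichment: pd.DataFrame
    planted_families: list[str]
    detected_up: list[str]
    false_calls: list[str]
    attribution: dict

    @property
    def sensitivity(self) -> float:
        if not self.planted_families:
            return float("nan")
        hit = set(self.detected_up) & set(self.planted_families)
        return len(hit) / len(self.planted_families)

    @property
    def n_false_calls(self) -> int:
        return len(self.false_calls)


def run_enrichment_pipeline(
    genome: SyntheticGenome,
    synthetic: SyntheticCounts,
    window: int = 1000,
    mode: str = "upstream_only",
    background: str = "expressed_genes",
    n_mc: int = 100_000,
    enrichment_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts -> (contrasts, associations, enriched-family table) for one dataset."""
    config = genome.config
    rpkm = compute_rpkm(synthetic.counts, genome.genes, synthetic.samples)
    control_cols = [s.sample_id for s in synthetic.samples if s.condition == "control"]
    stress_cols = [s.sample_id for s in synthetic.samples if s.condition == config.stress]
    pvals = standin_de_test_matrix(
        synthetic.counts[control_cols].values, synthetic.counts[stress_cols].values
    )
    padj = pd.Series(bh_adjust(pvals), index=synthetic.counts.index)
    contrasts = make_contrast_summaries(
        rpkm, synthetic.samples, config.genotype, config.stress, padj=padj, mode="replicated"
    )
    associations = associations_to_frame(
        assign_te_to_genes(genome.genes, genome.tes, window=window, mode=mode)
    )
    contingency = build_contingency(associations, contrasts, background=background)
    seed = enrichment_seed if enrichment_seed is not None else (config.seed % 2**31)
    enrichment = call_enriched_families(
        family_enrichment_table(contingency, n_mc=n_mc, seed=seed)
    )
    return contrasts, associations, enrichment


def run_recovery_simulation(
    config: SimulationConfig,
    n_mc: int = 20_000,
) -> RecoveryResult:
    """One simulate -> analyse -> score cycle."""
    genome = generate_genome(config)
    synthetic = generate_counts(genome)
    contrasts, associations, enrichment = run_enrichment_pipeline(
        genome, synthetic, window=config.window, n_mc=n_mc
    )
    planted = set(genome.planted_families)
    detected_up = sorted(enrichment.loc[enrichment["enriched_up"], "family"])
    called_any = enrichment.loc[
        enrichment["enriched_up"] | enrichment["enriched_down"], "family"
    ]
    false_calls = sorted(set(called_any) - planted)
    attribution = attribute_response(contrasts, associations, detected_up)
    return RecoveryResult(
        config=config,
        genome=genome,
        synthetic=synthetic,
        contrasts=contrasts,
        associations=associations,
        enrichment=enrichment,
        planted_families=sorted(planted),
        detected_up=detected_up,
        false_calls=false_calls,
        attribution=attribution,
    )


def recovery_suite(
    base_config: SimulationConfig | None = None,
    n_simulations: int = 20,
    seed0: int = 0,
    n_mc: int = 20_000,
) -> pd.DataFrame:
    """Sensitivity and false-call count over seeded simulations."""
    base = base_config or SimulationConfig()
    rows = []
    for i in range(n_simulations):
        res = run_recovery_simulation(replace(base, seed=seed0 + i), n_mc=n_mc)
        rows.append(
            {
                "seed": seed0 + i,
                "sensitivity": res.sensitivity,
                "n_false_calls": res.n_false_calls,
                "n_detected_up": len(res.detected_up),
                "prop_up_attributed": res.attribution["prop_up_attributed"],
            }
        )
    return pd.DataFrame(rows)


def null_calibration_suite(
    base_config: SimulationConfig | None = None,
    n_simulations: int = 50,
    seed0: int = 10_000,
    n_mc: int = 20_000,
) -> pd.DataFrame:
    """Enriched-call counts with no planted families (pure null genomes)."""
    base = base_config or SimulationConfig()
    base = replace(base, planted_families=0)
    rows = []
    for i in range(n_simulations):
        res = run_recovery_simulation(replace(base, seed=seed0 + i), n_mc=n_mc)
        n_called = int(
            (res.enrichment["enriched_up"] | res.enrichment["enriched_down"]).sum()
        )
        rows.append({"seed": seed0 + i, "n_enriched_calls": n_called})
    return pd.DataFrame(rows)


def null_family_pvalues(
    n_families: int = 2000,
    expected_props: tuple[float, float, float] = (0.05, 0.05, 0.90),
    n_range: tuple[int, int] = (15, 80),
    n_mc: int = 4999,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo multinomial p-values for families drawn from their own null.

    Each family's class counts are a multinomial draw at the stated
    background proportions; the returned p-values should be uniform (up to
    MC resolution), so their sub-0.05 fraction checks test calibration.
    """
    rng = np.random.default_rng(seed)
    props = np.asarray(expected_props, dtype=float)
    sizes = rng.integers(n_range[0], n_range[1] + 1, size=n_families)
    observed = np.vstack([rng.multinomial(n, props) for n in sizes])
    return np.array(
        [
            multinomial_gof_test(obs, props, method="monte_carlo", n_mc=n_mc, rng=rng)
            for obs in observed
        ]
    )
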