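"""End-to-end orchestration of the simulated-array analysis.

``run_pipeline`` executes the stages in fixed order — preprocessing, splicing
index, event calling, RT-PCR-style PSI, expression — and returns a results
bundle; the CLI writes each table with the configuration hash and seed in its
header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import expression as expr_mod
from . import preprocess, psi as psi_mod, simdata, splicecall


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the screening pipeline (defaults are the study's printed values)."""

    alpha: float = 0.05
    psi_fold: float = 1.5
    expression_fold: float = 1.5
    max_fdr: float = 0.15
    motif_window: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "psi_fold", "expression_fold", "max_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.motif_window < 10:
            raise ValueError("motif_window must be at least 10")


@dataclass(frozen=True)
class PipelineResult:
    signals: preprocess.SignalTable
    inorm: pd.DataFrame
    records: pd.DataFrame
    calls: pd.DataFrame
    psi_calls: pd.DataFrame | None
    expression: pd.DataFrame
    changed_genes: dict
    metrics: dict | None


def run_pipeline(
    sim: simdata.SimulatedArray,
    config: PipelineConfig = PipelineConfig(),
    rtpcr_bands: pd.DataFrame | None = None,
) -> PipelineResult:
    config.validate()
    signals = preprocess.preprocess_pipeline(sim.intensities, sim.annotation)
    candidate_ann = splicecall.apply_filters(sim.annotation)
    inorm = splicecall.compute_inorm(signals.probe_set_signal, signals.gene_signal, sim.annotation)
    inorm_candidates = inorm.loc[inorm.index.intersection(candidate_ann["probe_set_id"])]
    records = splicecall.inorm_records(inorm_candidates, candidate_ann, sim.genotypes)
    calls = splicecall.call_events(records, sim.annotation, alpha=config.alpha)
    psi_calls = None
    if rtpcr_bands is not None:
        psi_calls = psi_mod.psi_table(rtpcr_bands, fold=config.psi_fold)
    de = expr_mod.differential_expression(signals.gene_signal, sim.genotypes)
    changed = expr_mod.select_changed_genes(de, min_fold=config.expression_fold, max_fdr=config.max_fdr)
    metrics = splicecall.score_calls(calls, sim.truth) if sim.truth is not None else None
    return PipelineResult(
        signals=signals,
        inorm=inorm,
        records=records,
        calls=calls,
        psi_calls=psi_calls,
        expression=de,
        changed_genes=changed,
        metrics=metrics,
    )
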