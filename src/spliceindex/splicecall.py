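"""Splicing-index computation and tiered event calling.

The splicing index ``I_norm`` of a probe set is its background-corrected
signal divided by the background-corrected gene-expression signal of the
corresponding gene; dividing out expression isolates splicing change from
expression change.  Per probe set a pooled two-sample Student t-test compares
``I_norm`` between genotypes; probe sets with P below the screening alpha
"vote" for the event with an implied inclusion direction (skipping-junction
votes are inverted, because probe sets targeting competing isoforms must show
opposite ``I_norm`` trends).  Events are called in tiers: tier 1 needs at
least two concordant votes; a single-vote event qualifies as a tier-2
candidate only if it is conserved and neuron-specifically spliced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import INCLUSION_ROLES, ROLE_CONSTITUTIVE, SKIPPING_ROLES

__all__ = [
    "compute_inorm",
    "ttest_two_tailed",
    "apply_filters",
    "call_events",
    "cross_tissue_concordance",
    "inorm_records",
    "score_calls",
]

KNOWN_ROLES = INCLUSION_ROLES | SKIPPING_ROLES | {ROLE_CONSTITUTIVE}

TIER1 = "tier1"
TIER2 = "tier2_candidate"
NO_TIER = "none"


def compute_inorm(probe_set_signal: pd.DataFrame, gene_signal: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Probe-set x sample splicing index: probe-set signal / gene signal.

    Probe sets whose gene signal is non-positive in any sample are excluded
    with a warning rather than propagated.
    """
    ann = annotation.set_index("probe_set_id")
    rows = {}
    skipped = 0
    for ps in probe_set_signal.index:
        gene = ann.at[ps, "gene_id"]
        if gene not in gene_signal.index:
            skipped += 1
            continue
        g = gene_signal.loc[gene]
        if (g <= 0).any():
            skipped += 1
            continue
        rows[ps] = (probe_set_signal.loc[ps] / g).to_numpy()
    if skipped:
        warnings.warn(f"{skipped} probe set(s) excluded: missing or non-positive gene signal")
    out = pd.DataFrame.from_dict(rows, orient="index", columns=probe_set_signal.columns)
    out.index.name = "probe_set_id"
    return out


def ttest_two_tailed(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample Student t with df = n_a + n_b - 2.

    Degenerate inputs: zero pooled variance with equal means gives (0, 1);
    zero pooled variance with unequal means gives an infinite t and the
    smallest positive float as P.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * np.inf, np.finfo(float).tiny
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def apply_filters(annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop probe sets that cannot report differential splicing.

    Constitutive probe sets, probe sets matching more than one gene, and
    probe sets measuring alternative promoter activity are removed from
    candidate consideration (constitutive sets remain in use upstream for the
    gene-expression estimate).
    """
    unknown = set(annotation["role"]) - KNOWN_ROLES
    if unknown:
        raise ValueError(f"unknown probe-set role(s): {sorted(unknown)}")
    mask = (
        (annotation["flag_constitutive"] == 0)
        & (annotation["flag_multi_gene"] == 0)
        & (annotation["flag_alt_promoter"] == 0)
    )
    return annotation[mask].copy()


def inorm_records(
    inorm: pd.DataFrame,
    annotation: pd.DataFrame,
    genotypes: pd.Series,
) -> pd.DataFrame:
    """Per-probe-set statistics: group means of I_norm, pooled t, two-tailed P."""
    ann = annotation.set_index("probe_set_id")
    ctrl = genotypes.index[genotypes == "control"]
    mut = genotypes.index[genotypes == "mutant"]
    rows = []
    for ps in inorm.index:
        if ps not in ann.index:
            continue
        a = inorm.loc[ps, ctrl].to_numpy(dtype=float)
        b = inorm.loc[ps, mut].to_numpy(dtype=float)
        t, p = ttest_two_tailed(a, b)
        rows.append(
            dict(
                probe_set_id=ps,
                event_id=ann.at[ps, "event_id"],
                role=ann.at[ps, "role"],
                mean_control=a.mean(),
                mean_mutant=b.mean(),
                t=t,
                p=p,
            )
        )
    return pd.DataFrame(rows)


def _implied_direction(role: str, mean_control: float, mean_mutant: float) -> int:
    """+1 = inclusion up in mutant, -1 = inclusion down; skipping-junction trends invert."""
    sign = 1 if mean_mutant > mean_control else -1
    if role in SKIPPING_ROLES:
        sign = -sign
    return sign


def call_events(records: pd.DataFrame, annotation: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tiered voting over the probe sets of each splicing event.

    A probe set votes when its P is below ``alpha``; the vote's inclusion
    direction is the sign of the mutant-minus-control mean I_norm, inverted
    for the skipping junction.  Tier 1 requires at least two votes, all
    implying the same inclusion direction; opposing votes void the event
    (direction ``ambiguous``).  Exactly one vote yields a tier-2 candidate
    only when the event carries both the conserved and the neuron-specific
    flag.  Direction consistency is judged on voting probe sets only.
    """
    flags = (
        annotation[annotation["event_id"] != ""]
        .groupby("event_id")[["flag_conserved", "flag_neuron_specific"]]
        .max()
    )
    calls = []
    for event_id, sub in records[records["event_id"] != ""].groupby("event_id"):
        voters = sub[sub["p"] < alpha]
        dirs = [
            _implied_direction(r.role, r.mean_control, r.mean_mutant) for r in voters.itertuples(index=False)
        ]
        n_votes = len(dirs)
        conserved = bool(event_id in flags.index and flags.at[event_id, "flag_conserved"])
        neuron = bool(event_id in flags.index and flags.at[event_id, "flag_neuron_specific"])
        if n_votes >= 2 and len(set(dirs)) > 1:
            tier, direction = NO_TIER, "ambiguous"
        elif n_votes >= 2:
            tier = TIER1
            direction = "inclusion_up" if dirs[0] > 0 else "inclusion_down"
        elif n_votes == 1 and conserved and neuron:
            tier = TIER2
            direction = "inclusion_up" if dirs[0] > 0 else "inclusion_down"
        else:
            tier, direction = NO_TIER, "ambiguous" if n_votes == 0 else (
                "inclusion_up" if dirs[0] > 0 else "inclusion_down"
            )
        calls.append(
            dict(
                event_id=event_id,
                tier=tier,
                direction=direction,
                n_significant_probe_sets=n_votes,
                contributing_probe_sets=",".join(voters["probe_set_id"]),
            )
        )
    return pd.DataFrame(calls).sort_values("event_id").reset_index(drop=True)


def cross_tissue_concordance(ratios_a, ratios_b) -> tuple[float, float]:
    """Pearson correlation of per-probe-set genotype I_norm ratios between tissues."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def score_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Tier-1 recall and precision against a simulation truth table."""
    called = set(calls.loc[calls["tier"] == TIER1, "event_id"])
    positive = set(truth.loc[truth["is_differential"], "event_id"])
    tp = len(called & positive)
    recall = tp / len(positive) if positive else float("nan")
    precision = tp / len(called) if called else float("nan")
    return {"recall": recall, "precision": precision, "n_called": len(called)}
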