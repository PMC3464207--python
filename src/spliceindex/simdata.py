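"""Synthetic data generation with known truth.

Emulates an exon-junction microarray experiment on cassette exons: each
cassette event is interrogated by four probe sets (the cassette exon itself,
the upstream and downstream inclusion junctions, and the skipping junction),
every gene additionally carries constitutive exon probe sets, and observed
probe intensities follow a multiplicative log-normal noise model on top of an
additive exponential background — the same convolution the preprocessing
module inverts.  Companion generators produce 3' splice-site intron windows
with a planted polypyrimidine tract and GC motif, RT-PCR band-intensity
tables, and WT/mutant sequence pairs differing by a single deletion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimulatedArray",
    "simulate_array",
    "simulate_sequences",
    "simulate_rtpcr",
    "simulate_deletion",
    "make_psi_map",
]

PYRIMIDINES = "CT"
PURINES = "AG"

# probe-set roles used throughout the package
ROLE_EXON = "exon"
ROLE_JUNC_UP = "inclusion_junction_up"
ROLE_JUNC_DOWN = "inclusion_junction_down"
ROLE_JUNC_SKIP = "skipping_junction"
ROLE_CONSTITUTIVE = "constitutive"

INCLUSION_ROLES = frozenset({ROLE_EXON, ROLE_JUNC_UP, ROLE_JUNC_DOWN})
SKIPPING_ROLES = frozenset({ROLE_JUNC_SKIP})


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the synthetic microarray experiment.

    Parameters
    ----------
    n_genes : int
        Number of genes on the simulated array.
    n_cassette_events : int
        Number of cassette-exon events; assigned one-per-gene to the first
        ``n_cassette_events`` genes (must not exceed ``n_genes``).
    replicates_per_genotype : int
        Biological replicates per genotype (control, mutant); at least 2.
    psi_by_genotype : mapping
        ``event_id -> (psi_control, psi_mutant)``, each inclusion rate in
        [0, 1].  Every simulated event must have an entry.
    noise_sd_log2 : float
        SD of the multiplicative log-normal probe noise, log2 scale.
    background_mean : float
        Mean of the additive exponential optical background.
    affinity_sd_log2 : float
        SD of fixed per-probe affinities, log2 scale (removable by median
        polish because affinities do not vary across samples).
    expression_log2_mean, expression_log2_sd : float
        Gene expression levels are log-normal: ``2**Normal(mean, sd)``.
    probes_per_set : int
        Probes per probe set; individual probes are summarized by median
        polish downstream.
    constitutive_per_gene : int
        Constitutive exon probe sets per gene (gene-expression anchor).
    seed : int
        Seed for the single numpy generator stream; identical config
        (including seed) gives bit-identical outputs.
    """

    n_genes: int
    n_cassette_events: int
    replicates_per_genotype: int
    psi_by_genotype: Mapping[str, tuple[float, float]]
    noise_sd_log2: float = 0.15
    background_mean: float = 20.0
    affinity_sd_log2: float = 0.25
    expression_log2_mean: float = 9.0
    expression_log2_sd: float = 1.0
    probes_per_set: int = 4
    constitutive_per_gene: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cassette_events <= 0:
            raise ConfigurationError("n_genes and n_cassette_events must be positive")
        if self.n_cassette_events > self.n_genes:
            raise ConfigurationError("n_cassette_events cannot exceed n_genes")
        if self.replicates_per_genotype < 2:
            raise ConfigurationError("need at least 2 replicates per genotype")
        if self.noise_sd_log2 < 0 or self.background_mean < 0 or self.affinity_sd_log2 < 0:
            raise ConfigurationError("noise/background parameters must be non-negative")
        if self.probes_per_set < 1 or self.constitutive_per_gene < 1:
            raise ConfigurationError("probes_per_set and constitutive_per_gene must be >= 1")
        for eid in self.event_ids():
            if eid not in self.psi_by_genotype:
                raise ConfigurationError(f"psi_by_genotype missing event {eid!r}")
        for eid, (pc, pm) in self.psi_by_genotype.items():
            if not (0.0 <= pc <= 1.0 and 0.0 <= pm <= 1.0):
                raise ConfigurationError(f"psi for event {eid!r} outside [0, 1]")

    def gene_ids(self) -> list[str]:
        return [f"gene_{i:04d}" for i in range(self.n_genes)]

    def event_ids(self) -> list[str]:
        return [f"event_{i:04d}" for i in range(self.n_cassette_events)]


def make_psi_map(
    n_events: int,
    n_differential: int,
    psi_differential: tuple[float, float] = (0.8, 0.5),
    psi_null: float = 0.65,
) -> dict[str, tuple[float, float]]:
    """Build a ``psi_by_genotype`` map: the first ``n_differential`` events get
    the differential (control, mutant) pair, the remainder are null events with
    equal inclusion in both genotypes."""
    if n_differential > n_events:
        raise ConfigurationError("n_differential cannot exceed n_events")
    out: dict[str, tuple[float, float]] = {}
    for i in range(n_events):
        eid = f"event_{i:04d}"
        out[eid] = tuple(psi_differential) if i < n_differential else (psi_null, psi_null)
    return out


@dataclass(frozen=True)
class SimulatedArray:
    """Bundle returned by :func:`simulate_array`."""

    intensities: pd.DataFrame  # probe x sample, positive
    annotation: pd.DataFrame  # one row per probe set
    truth: pd.DataFrame  # one row per event
    genotypes: pd.Series  # sample_id -> genotype


def _annotation_rows(config: SimConfig) -> list[dict]:
    rows = []
    events = config.event_ids()
    for gi, gene in enumerate(config.gene_ids()):
        if gi < config.n_cassette_events:
            eid = events[gi]
            for role in (ROLE_EXON, ROLE_JUNC_UP, ROLE_JUNC_DOWN, ROLE_JUNC_SKIP):
                rows.append(
                    dict(
                        probe_set_id=f"{gene}.{eid}.{role}",
                        gene_id=gene,
                        event_id=eid,
                        role=role,
                        flag_constitutive=0,
                        flag_multi_gene=0,
                        flag_alt_promoter=0,
                        flag_conserved=1,
                        flag_neuron_specific=1,
                    )
                )
        for k in range(config.constitutive_per_gene):
            rows.append(
                dict(
                    probe_set_id=f"{gene}.const_{k}",
                    gene_id=gene,
                    event_id="",
                    role=ROLE_CONSTITUTIVE,
                    flag_constitutive=1,
                    flag_multi_gene=0,
                    flag_alt_promoter=0,
                    flag_conserved=0,
                    flag_neuron_specific=0,
                )
            )
    return rows


def simulate_array(config: SimConfig) -> SimulatedArray:
    """Simulate a probe-level intensity matrix with probe-set annotation and truth.

    Each probe's expected signal is ``affinity * gene_expression * f`` where
    ``f`` is the inclusion rate psi for inclusion-reporting probe sets
    (cassette exon and the two inclusion junctions), ``1 - psi`` for the
    skipping junction, and 1 for constitutive probe sets.  Observed intensity
    is ``mean * 2**Normal(0, noise_sd_log2) + Exponential(background_mean)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    nrep = config.replicates_per_genotype
    samples = [f"ctrl_{i}" for i in range(nrep)] + [f"mut_{i}" for i in range(nrep)]
    genotypes = pd.Series(
        ["control"] * nrep + ["mutant"] * nrep, index=pd.Index(samples, name="sample_id"), name="genotype"
    )

    expr = {
        gene: 2.0 ** rng.normal(config.expression_log2_mean, config.expression_log2_sd)
        for gene in config.gene_ids()
    }

    ann = pd.DataFrame(_annotation_rows(config))

    probe_ids: list[str] = []
    means: list[np.ndarray] = []
    for row in ann.itertuples(index=False):
        role = row.role
        if role in INCLUSION_ROLES:
            pc, pm = config.psi_by_genotype[row.event_id]
            frac = np.array([pc] * nrep + [pm] * nrep)
        elif role in SKIPPING_ROLES:
            pc, pm = config.psi_by_genotype[row.event_id]
            frac = np.array([1.0 - pc] * nrep + [1.0 - pm] * nrep)
        else:
            frac = np.ones(2 * nrep)
        base = expr[row.gene_id] * frac
        for k in range(config.probes_per_set):
            affinity = 2.0 ** rng.normal(0.0, config.affinity_sd_log2)
            probe_ids.append(f"{row.probe_set_id}:{k}")
            means.append(affinity * base)

    mean_mat = np.vstack(means)
    noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, size=mean_mat.shape)
    if config.background_mean > 0:
        background = rng.exponential(config.background_mean, size=mean_mat.shape)
    else:
        background = np.zeros_like(mean_mat)
    observed = mean_mat * noise + background
    # exponential background can be exactly 0; keep intensities strictly positive
    observed = np.maximum(observed, np.finfo(float).tiny)

    intensities = pd.DataFrame(observed, index=pd.Index(probe_ids, name="probe_id"), columns=samples)

    truth = pd.DataFrame(
        {
            "event_id": config.event_ids(),
            "psi_control": [config.psi_by_genotype[e][0] for e in config.event_ids()],
            "psi_mutant": [config.psi_by_genotype[e][1] for e in config.event_ids()],
        }
    )
    truth["is_differential"] = truth["psi_control"] != truth["psi_mutant"]

    return SimulatedArray(intensities=intensities, annotation=ann, truth=truth, genotypes=genotypes)


def probe_set_of(probe_id: str) -> str:
    """Map a probe id back to its probe set (convention: ``set:probe_index``)."""
    return probe_id.rsplit(":", 1)[0]


# ---------------------------------------------------------------------------
# 3' splice-site window simulation
# ---------------------------------------------------------------------------


def simulate_sequences(
    n_fg: int,
    n_bg: int,
    window_len: int = 50,
    motif: str = "TGC",
    offset_from_ppt_end: int = -6,
    tract_len_range: tuple[int, int] = (15, 25),
    seed: int = 0,
):
    """Generate intron 3'-end windows with a polypyrimidine tract; foreground
    windows carry the motif planted at a fixed offset from the tract 3' end.

    The window emulates the last ``window_len`` nucleotides of an intron: it
    ends in the canonical AG dinucleotide, the polypyrimidine tract sits
    immediately upstream of it, and the remaining 5' bases are random.  In
    foreground windows the motif starts at ``tract_end + offset_from_ppt_end``
    (0 would be immediately after the tract); with the default -6 the motif
    lies inside the tract close to its 3' end, mirroring the position of the
    GC element relative to the tract.  DNA alphabet (T not U) in output.

    Returns ``(records, labels)``: Biopython ``SeqRecord`` list and a
    DataFrame with per-record truth (label, tract interval, motif start).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    motif = motif.upper().replace("U", "T")
    if len(motif) == 0:
        raise ConfigurationError("motif must be non-empty")
    if n_fg < 0 or n_bg < 0:
        raise ConfigurationError("record counts must be non-negative")
    lo, hi = tract_len_range
    if lo < 8 or hi < lo:
        raise ConfigurationError("tract length range must satisfy 8 <= lo <= hi")
    if window_len < hi + len(motif) + 2:
        raise ConfigurationError("window_len too small for tract + motif + AG")

    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    rows: list[dict] = []

    def draw(alphabet: str, n: int) -> list[str]:
        return list(rng.choice(list(alphabet), size=n))

    for i in range(n_fg + n_bg):
        is_fg = i < n_fg
        tract_len = int(rng.integers(lo, hi + 1))
        # layout: [filler][tract][A G]; tract ends 2 nt before the window end
        tract_end = window_len - 2
        tract_start = tract_end - tract_len
        seq = draw("ACGT", window_len)
        seq[tract_start:tract_end] = draw(PYRIMIDINES, tract_len)
        seq[tract_end:] = ["A", "G"]
        if tract_start > 0:
            # purine boundary so the planted tract is exactly the maximal segment
            seq[tract_start - 1] = str(rng.choice(list(PURINES)))
        motif_start = None
        if is_fg:
            motif_start = tract_end + offset_from_ppt_end
            if motif_start < 0 or motif_start + len(motif) > window_len:
                raise ConfigurationError("offset places motif outside the window")
            if motif_start < tract_start:
                raise ConfigurationError("offset places motif upstream of the tract")
            seq[motif_start : motif_start + len(motif)] = list(motif)
        name = ("fg" if is_fg else "bg") + f"_{i:04d}"
        records.append(SeqRecord(Seq("".join(seq)), id=name, description=""))
        rows.append(
            dict(
                record_id=name,
                label="foreground" if is_fg else "background",
                tract_start=tract_start,
                tract_end=tract_end,
                motif_start=-1 if motif_start is None else motif_start,
            )
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RT-PCR band intensities
# ---------------------------------------------------------------------------


def simulate_rtpcr(
    truth: pd.DataFrame,
    band_noise_cv: float = 0.1,
    replicates_per_genotype: int = 3,
    scale: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate inclusion/skipping band intensities for each event and sample.

    Expected ``inclusion_band`` is proportional to the event's inclusion rate
    psi and ``skipping_band`` to ``1 - psi``; multiplicative noise with the
    given coefficient of variation is applied per band (clipped at 0).
    """
    if truth.empty:
        raise ConfigurationError("truth table is empty")
    if band_noise_cv < 0:
        raise ConfigurationError("band_noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for row in truth.itertuples(index=False):
        for genotype, psi in (("control", row.psi_control), ("mutant", row.psi_mutant)):
            for r in range(replicates_per_genotype):
                inc = scale * psi
                skip = scale * (1.0 - psi)
                if band_noise_cv > 0:
                    inc *= max(0.0, 1.0 + rng.normal(0.0, band_noise_cv))
                    skip *= max(0.0, 1.0 + rng.normal(0.0, band_noise_cv))
                rows.append(
                    dict(
                        event_id=row.event_id,
                        sample_id=f"{genotype}_{r}",
                        genotype=genotype,
                        inclusion_band=inc,
                        skipping_band=skip,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deletion pairs
# ---------------------------------------------------------------------------


def simulate_deletion(seq: str, del_start: int, del_len: int) -> tuple[str, str]:
    """Return ``(wt, mutant)`` where the mutant lacks ``[del_start, del_start+del_len)``."""
    if del_start < 0 or del_len < 0 or del_start + del_len > len(seq):
        raise ConfigurationError("deletion coordinates out of range")
    return seq, seq[:del_start] + seq[del_start + del_len :]


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))
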