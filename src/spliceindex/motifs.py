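"""Polypyrimidine-tract scanning, k-mer enrichment, ZOOPS EM motif discovery,
motif placement relative to the tract, and the GC-element mutation rules.

Intron windows are the last 50 nt upstream of a 3' splice site.  The
polypyrimidine tract (PPT) is found as the maximal-scoring contiguous segment
under a +1 pyrimidine / -1.5 purine scoring, so that a single purine
interrupts only weakly — the GC element characteristically sits as a lone
purine-containing triplet near the tract's 3' end.  Motif discovery is a
zero-or-one-occurrence-per-sequence (ZOOPS) expectation-maximization over a
position-frequency matrix with a 0th-order background, with Fisher-exact
k-mer presence enrichment as the complementary, model-free route.  All motif
logic runs on the RNA alphabet internally (T and U are equivalent); FASTA
I/O stays DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PPTract",
    "find_ppt",
    "kmer_enrichment",
    "MotifModel",
    "discover_motif_zoops",
    "motif_offset",
    "predict_substitution_effect",
]

RNA = "ACGU"
_IDX = {c: i for i, c in enumerate(RNA)}
PY = frozenset("CU")

PY_SCORE = 1.0
PUR_SCORE = -1.5
MIN_TRACT_LEN = 8


def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if any(c not in _IDX for c in s):
        raise ValueError("sequence contains non-ACGT/U characters")
    return s


@dataclass(frozen=True)
class PPTract:
    """Polypyrimidine tract: 0-based half-open interval within its window."""

    start: int
    end: int
    score: float
    pyrimidine_fraction: float


def find_ppt(
    window: str,
    py_score: float = PY_SCORE,
    purine_score: float = PUR_SCORE,
    min_len: int = MIN_TRACT_LEN,
) -> PPTract | None:
    """Maximal-scoring segment scan for the polypyrimidine tract.

    Scores +1 per pyrimidine and -1.5 per purine by default, requires a
    minimum segment length of 8 and a strictly positive score, and resolves
    score ties leftmost-first, then longest.  Returns ``None`` when no
    qualifying segment exists (e.g. an all-purine window).

    The scan is a Kadane-style pass with a minimum-length constraint: for
    each segment end the best admissible start is tracked via the running
    minimum of the prefix sums at least ``min_len`` positions back.
    """
    seq = _to_rna(window)
    n = len(seq)
    if n < 10:
        raise ValueError("window must be at least 10 nt")
    w = np.where(np.isin(list(seq), list(PY)), py_score, purine_score)
    prefix = np.concatenate([[0.0], np.cumsum(w)])

    best: tuple[float, int, int] | None = None  # (score, start, end)
    min_prefix_val = np.inf
    min_prefix_pos = -1
    for end in range(min_len, n + 1):
        cand_start = end - min_len  # prefix index newly admissible for this end
        # leftmost tie-break: strict '<' keeps the earliest minimal prefix
        if prefix[cand_start] < min_prefix_val:
            min_prefix_val = prefix[cand_start]
            min_prefix_pos = cand_start
        score = prefix[end] - min_prefix_val
        if best is None or score > best[0] + 1e-12:
            best = (score, min_prefix_pos, end)
        elif abs(score - best[0]) <= 1e-12:
            # ties: prefer leftmost start, then longest segment
            if (min_prefix_pos, -(end - min_prefix_pos)) < (best[1], -(best[2] - best[1])):
                best = (score, min_prefix_pos, end)
    if best is None or best[0] <= 0:
        return None
    score, start, end = best
    frac = sum(1 for c in seq[start:end] if c in PY) / (end - start)
    return PPTract(start=start, end=end, score=score, pyrimidine_fraction=frac)


def kmer_enrichment(fg_windows, bg_windows, k: int) -> pd.DataFrame:
    """Per-k-mer presence/absence contrast between foreground and background.

    A window counts once per k-mer regardless of occurrence multiplicity; the
    2x2 presence table is tested with a two-sided Fisher exact test.  Returns
    a DataFrame sorted by P with columns kmer, fg_count, bg_count, fold, p.
    """
    fg = [_to_rna(s) for s in fg_windows]
    bg = [_to_rna(s) for s in bg_windows]
    if k < 2:
        raise ValueError("k must be at least 2")
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if any(len(s) < k for s in fg + bg):
        raise ValueError("k exceeds a window length")

    def present(seqs: list[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in seqs:
            for km in {s[i : i + k] for i in range(len(s) - k + 1)}:
                counts[km] = counts.get(km, 0) + 1
        return counts

    fg_counts = present(fg)
    bg_counts = present(bg)
    rows = []
    for km in sorted(set(fg_counts) | set(bg_counts)):
        a = fg_counts.get(km, 0)
        b = bg_counts.get(km, 0)
        table = [[a, len(fg) - a], [b, len(bg) - b]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        fg_frac = a / len(fg)
        bg_frac = b / len(bg)
        fold = np.inf if bg_frac == 0 and fg_frac > 0 else (fg_frac / bg_frac if bg_frac else np.nan)
        rows.append(dict(kmer=km, fg_count=a, bg_count=b, fold=fold, p=p))
    return pd.DataFrame(rows).sort_values(["p", "kmer"]).reset_index(drop=True)


@dataclass(frozen=True)
class MotifModel:
    """ZOOPS motif model: PFM over ACGU plus per-sequence best sites."""

    width: int
    pfm: np.ndarray  # width x 4, rows sum to 1
    consensus: str
    gamma: float  # prior probability a sequence contains a site
    log_likelihood: float
    best_sites: list[int]  # best-posterior site start per sequence, -1 = none
    site_posteriors: list[float]

    def information_content(self) -> float:
        p = np.clip(self.pfm, 1e-12, 1.0)
        return float(np.sum(2.0 + np.sum(p * np.log2(p), axis=1)))


def _site_log_odds(x: np.ndarray, log_pfm: np.ndarray, log_bg: np.ndarray, w: int) -> np.ndarray:
    """Log-odds of a motif site starting at each admissible position."""
    m = len(x) - w + 1
    lods = np.zeros(m)
    for offset in range(w):
        lods += log_pfm[offset, x[offset : offset + m]] - log_bg[x[offset : offset + m]]
    return lods


def _zoops_em_once(
    encoded: list[np.ndarray],
    w: int,
    bg: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    ll_trace: list[float] | None = None,
):
    # seed the PFM from a random w-mer of a random sequence (MEME-style start)
    si = int(rng.integers(len(encoded)))
    sj = int(rng.integers(len(encoded[si]) - w + 1))
    pfm = np.full((w, 4), 0.17)
    for offset, base in enumerate(encoded[si][sj : sj + w]):
        pfm[offset, base] = 0.49
    gamma = 0.5

    log_bg = np.log(bg)
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_pfm = np.log(np.clip(pfm, 1e-300, 1.0))
        ll = 0.0
        counts = np.zeros((w, 4))
        gamma_sum = 0.0
        for x in encoded:
            lods = _site_log_odds(x, log_pfm, log_bg, w)
            m = lods.size
            site_w = (gamma / m) * np.exp(lods)
            denom = (1.0 - gamma) + site_w.sum()
            z = site_w / denom
            gamma_sum += z.sum()
            ll += np.log(denom) + log_bg[x].sum()
            for offset in range(w):
                counts[offset] += np.bincount(x[offset : offset + m], weights=z, minlength=4)
        # background-proportional pseudocounts: with no site evidence a column
        # relaxes to the background, never to the uniform distribution
        beta = 0.1
        pfm = (counts + beta * bg) / (counts.sum(axis=1, keepdims=True) + beta)
        gamma = min(max(gamma_sum / len(encoded), 1e-6), 1.0 - 1e-6)
        if ll_trace is not None:
            ll_trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return pfm, gamma, ll


def discover_motif_zoops(
    sequences,
    w: int,
    seed: int = 0,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 200,
    ll_trace: list[float] | None = None,
) -> MotifModel:
    """ZOOPS EM motif discovery: best of ``n_restarts`` seeded runs.

    Each sequence is modelled as containing either zero or one motif
    occurrence; the background is a 0th-order model estimated from the input.
    Deterministic given the seed.  ``ll_trace``, when supplied, collects one
    list of per-iteration log-likelihoods per restart (non-decreasing within
    a restart, up to numerical tolerance).
    """
    seqs = [_to_rna(s) for s in sequences]
    if w < 2:
        raise ValueError("motif width must be at least 2")
    if any(len(s) < w for s in seqs):
        raise ValueError("all sequences must be at least as long as the motif width")
    encoded = [np.array([_IDX[c] for c in s]) for s in seqs]
    # lightly smoothed 0th-order background so no letter has probability 0
    counts = np.zeros(4)
    for x in encoded:
        counts += np.bincount(x, minlength=4)
    bg = (counts + 0.5) / (counts.sum() + 2.0)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        sub_trace: list[float] | None = None
        if ll_trace is not None:
            sub_trace = []
            ll_trace.append(sub_trace)
        pfm, gamma, ll = _zoops_em_once(encoded, w, bg, rng, tol, max_iter, sub_trace)
        if best is None or ll > best[2]:
            best = (pfm, gamma, ll)
    pfm, gamma, ll = best

    log_pfm = np.log(np.clip(pfm, 1e-300, 1.0))
    log_bg = np.log(bg)
    best_sites: list[int] = []
    posteriors: list[float] = []
    for x in encoded:
        lods = _site_log_odds(x, log_pfm, log_bg, w)
        m = lods.size
        site_w = (gamma / m) * np.exp(lods)
        denom = (1.0 - gamma) + site_w.sum()
        z = site_w / denom
        j = int(np.argmax(z))
        if z[j] > 1.0 - gamma and z[j] > z.sum() / (2 * m):
            best_sites.append(j)
            posteriors.append(float(z[j]))
        else:
            best_sites.append(-1)
            posteriors.append(float(z[j]))
    consensus = "".join(RNA[i] for i in pfm.argmax(axis=1))
    return MotifModel(
        width=w,
        pfm=pfm,
        consensus=consensus,
        gamma=float(gamma),
        log_likelihood=float(ll),
        best_sites=best_sites,
        site_posteriors=posteriors,
    )


def motif_offset(tract: PPTract, site_start: int) -> int:
    """Signed offset of the motif start from the tract 3' end (0 = right after)."""
    return site_start - tract.end


def predict_substitution_effect(
    window: str,
    element_start: int,
    substitution: tuple[int, str, str],
) -> str:
    """Classify a point substitution against the functional (U)GC element.

    ``element_start`` is the 0-based position of the U preceding the GC
    dinucleotide; the rule table reflects the mutagenesis outcomes for this
    element: G-to-A at the element's G and C-to-U at its C disrupt
    Srrm4-dependent inclusion, substitutions of the preceding U are neutral,
    and anything outside the element is unknown to the rule table.
    """
    seq = _to_rna(window)
    pos, ref, alt = substitution
    ref = _to_rna(ref)
    alt = _to_rna(alt)
    if not (0 <= pos < len(seq)):
        raise ValueError("substitution position outside window")
    if seq[pos] != ref:
        raise ValueError(f"reference base {ref} does not match sequence base {seq[pos]} at {pos}")
    u_pos, g_pos, c_pos = element_start, element_start + 1, element_start + 2
    if pos == g_pos and ref == "G" and alt == "A":
        return "disrupting"
    if pos == c_pos and ref == "C" and alt == "U":
        return "disrupting"
    if pos == u_pos and ref == "U" and alt in {"C", "G", "A"}:
        return "neutral"
    return "unknown"
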