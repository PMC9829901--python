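"""Synthetic inputs with known ground truth.

Two generators: (1) short reads drawn from a spliced/unspliced transcript
mixture at a known fraction with i.i.d. substitution errors, standing in for
tumour RNA-seq FASTQs; (2) an expression + survival cohort in which a planted
gene signature modulates the hazard through an exponential proportional-
hazards model, standing in for a TCGA-style cohort.  Both are pure functions
of (config, seed) and return truth tables sufficient to compute every
downstream oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .junction import SpliceTarget
from .signatures import GeneSignature

__all__ = [
    "ReadSimConfig",
    "CohortSimConfig",
    "SimulatedReads",
    "SimulatedCohort",
    "make_synthetic_target",
    "simulate_reads",
    "simulate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-mixture simulation settings.

    ``true_spliced_fraction`` is the probability a read originates from the
    spliced isoform.  When ``junction_spanning_only`` is set, start positions
    are restricted so every read overlaps the junction with at least
    ``anchor`` bases on each side — emulating the junction-informative subset
    that actually enters the splicing-percentage denominator.
    """

    true_spliced_fraction: float = 0.5
    n_reads: int = 2000
    read_length: int = 50
    error_rate: float = 0.005
    base_quality: int = 30
    seed: int = 0
    junction_spanning_only: bool = False
    anchor: int = 10  # matches the aligner's default gap barrier

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_spliced_fraction <= 1.0:
            raise ValueError("true_spliced_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")
        if self.n_reads < 1 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be positive")
        if self.base_quality < 0 or self.base_quality > 60:
            raise ValueError("base_quality must be a sane Phred value")


@dataclass(frozen=True)
class CohortSimConfig:
    """Expression + survival cohort settings.

    ``effect_size`` is the log-hazard per unit of the standardized planted
    signature score; ``baseline_hazard`` is the exponential event rate in
    1/month (default ~ln 2 / 40, i.e. a 40-month baseline median, a realistic
    scale for lung adenocarcinoma overall survival).
    """

    n_samples: int = 300
    n_genes: int = 2000
    signature_size: int = 50
    effect_size: float = 1.0
    baseline_hazard: float = 0.0173
    censoring_rate: float = 0.2
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.signature_size) < 1:
            raise ValueError("counts must be positive")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size must not exceed n_genes")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.expression_noise_sd <= 0:
            raise ValueError("expression_noise_sd must be positive")


class SimulatedReads(NamedTuple):
    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: pd.DataFrame  # read_id, origin, start, covers_junction


class SimulatedCohort(NamedTuple):
    expression: pd.DataFrame  # genes x samples, abundance scale
    clinical: pd.DataFrame  # sample_id, time, event, age, stage
    signature: GeneSignature
    truth: dict  # score (pd.Series), beta, censor_upper


def _count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def _junction_reads_unambiguous(target: SpliceTarget, read_length: int = 50,
                                anchor: int = 10) -> bool:
    """True when every error-free junction-spanning read classifies correctly.

    Exhaustively aligns all spliced and unspliced read starts with at least
    ``anchor`` bases on each side of the junction under the default alignment
    parameters — the generator's contract is that junction reads are
    unambiguous, and with near-free gap penalties no cheap sequence heuristic
    guarantees that.
    """
    from .junction import align_to_target, classify_read

    js = target.junction_start
    for origin, source in (("spliced", target.spliced_sequence),
                           ("unspliced", target.sequence)):
        L = min(read_length, len(source))
        lo = max(0, js + anchor - L)
        hi = min(js - anchor, len(source) - L)
        for start in range(lo, hi + 1):
            read = source[start:start + L]
            aln = align_to_target(read, None, target)
            if classify_read(aln, target) != origin:
                return False
    return True


def make_synthetic_target(seed: int, length: int = 300, junction_start: int = 150,
                          excision_length: int = 26, anchor: int = 6,
                          transcript_id: str = "SYN_XBP1",
                          max_tries: int = 1000) -> SpliceTarget:
    """Random ACGT target on which junction-spanning reads are unambiguous.

    Rejection sampling enforces (a) uniqueness of the ``anchor``-wide
    junction-flanking k-mers, (b) clear divergence between the excised
    region and the sequence replacing it, and (c) correct classification of
    every error-free junction-spanning read under the default aligner —
    without (c), chance similarity between the excised region and the
    junction flanks lets short-anchored spliced reads align without the
    excision gap.  Deterministic per seed.
    """
    if not (anchor <= junction_start and junction_start + excision_length + anchor <= length):
        raise ValueError("junction too close to the sequence ends for the anchor windows")
    rng = np.random.default_rng(seed)
    js, ex = junction_start, excision_length

    def _mismatches(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    for _ in range(max_tries):
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        left = seq[js - anchor: js]
        right = seq[js + ex: js + ex + anchor]
        spliced_kmer = left + right
        spliced_seq = seq[:js] + seq[js + ex:]
        # the excised region must be clearly distinguishable from the
        # sequence that replaces it, or a short-anchored junction read could
        # align gap-free across the junction at equal or better score: under
        # the de-penalised gap scoring a t-base anchor forces the gap only if
        # at least 6 of its first ~10 bases mismatch the excised continuation
        w = min(10, ex)
        distinct = (
            _mismatches(seq[js + ex: js + ex + w], seq[js: js + w]) >= 6
            and _mismatches(seq[js - w: js], seq[js + ex - w: js + ex]) >= 6
        )
        if (distinct
                and _count_overlapping(seq, left) == 1
                and _count_overlapping(seq, right) == 1
                and _count_overlapping(seq, spliced_kmer) == 0
                and _count_overlapping(spliced_seq, spliced_kmer) == 1):
            candidate = SpliceTarget(transcript_id=transcript_id, sequence=seq,
                                     junction_start=js,
                                     excision_length=ex,
                                     label=f"synthetic target (seed={seed})")
            if _junction_reads_unambiguous(candidate):
                return candidate
    raise RuntimeError(
        f"could not build a target with unique junction flanks in {max_tries} tries")


def simulate_reads(target: SpliceTarget, cfg: ReadSimConfig) -> SimulatedReads:
    """Draw reads from the spliced/unspliced mixture with substitution errors."""
    rng = np.random.default_rng(cfg.seed)
    unspliced = target.sequence
    spliced = target.spliced_sequence
    L = cfg.read_length
    if L > len(spliced):
        raise ValueError("read_length exceeds the spliced isoform length")
    a = cfg.anchor
    js = target.junction_start
    ex = target.excision_length

    qual = chr(33 + cfg.base_quality) * L
    origins = rng.random(cfg.n_reads) < cfg.true_spliced_fraction
    reads: list[tuple[str, str, str]] = []
    rows = []
    for i in range(cfg.n_reads):
        is_spliced = bool(origins[i])
        source = spliced if is_spliced else unspliced
        if cfg.junction_spanning_only:
            # read must hold >= anchor aligned bases on each side of the
            # junction point (at js in both isoform coordinate systems)
            lo = max(0, js + a - L)
            hi = min(js - a, len(source) - L)
            if hi < lo:
                raise ValueError("read_length too short for junction-spanning reads")
            start = int(rng.integers(lo, hi + 1))
        else:
            start = int(rng.integers(0, len(source) - L + 1))
        frag = np.frombuffer(source[start:start + L].encode(), dtype=np.uint8).copy()
        if cfg.error_rate > 0:
            err = rng.random(L) < cfg.error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                idx = np.searchsorted(_BASES, frag[err])
                frag[err] = _BASES[(idx + shift) % 4]
        seq = frag.tobytes().decode()
        # in both isoform coordinate systems the junction point sits at js and
        # a read is junction-informative when it holds >= anchor bases on each
        # side of it (for spliced reads these are the deletion anchors)
        covers = start <= js - a and start + L >= js + a
        read_id = f"read{i:06d}"
        reads.append((read_id, seq, qual))
        rows.append((read_id, "spliced" if is_spliced else "unspliced", start, bool(covers)))
    truth = pd.DataFrame(rows, columns=["read_id", "origin", "start", "covers_junction"])
    return SimulatedReads(reads=reads, truth=truth)


def _solve_censor_upper(rates: np.ndarray, censoring_rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target rate.

    For T ~ Exp(lambda) and C ~ U(0, c):
    P(C < T | lambda) = (1 - exp(-lambda c)) / (lambda c).
    """
    def expected_censored(c: float) -> float:
        x = rates * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1e9
    target = censoring_rate
    # expected_censored decreases from 1 (c -> 0) to 0 (c -> inf)
    return brentq(lambda c: expected_censored(c) - target, lo, hi, xtol=1e-10)


def simulate_cohort(cfg: CohortSimConfig) -> SimulatedCohort:
    """Expression + survival cohort with a planted prognostic signature.

    Gene abundance is log-normal: expr_gi = exp(N(mu_g, sd)).  The latent
    risk score s_i is the standardized mean abundance of the planted
    signature genes; event times are exponential with hazard
    baseline_hazard * exp(beta * s_i); censoring is Uniform(0, c) with c
    solved to achieve the requested expected censoring rate.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    mu = rng.normal(3.0, 1.0, size=cfg.n_genes)
    log_expr = mu[:, None] + rng.normal(0.0, cfg.expression_noise_sd,
                                        size=(cfg.n_genes, cfg.n_samples))
    expr = pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)

    sig_idx = rng.choice(cfg.n_genes, size=cfg.signature_size, replace=False)
    sig_genes = sorted(genes[i] for i in sig_idx)
    raw = expr.iloc[sorted(sig_idx)].mean(axis=0)
    score = (raw - raw.mean()) / raw.std(ddof=0)

    rates = cfg.baseline_hazard * np.exp(cfg.effect_size * score.to_numpy())
    event_times = rng.exponential(1.0 / rates)
    if cfg.censoring_rate > 0:
        c_upper = _solve_censor_upper(rates, cfg.censoring_rate)
        censor_times = rng.uniform(0.0, c_upper, size=cfg.n_samples)
        observed = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        c_upper = float("inf")
        observed = event_times
        event = np.ones(cfg.n_samples, dtype=int)
    observed = np.maximum(observed, 1e-6)  # times must be strictly positive

    age = rng.normal(65.0, 8.0, size=cfg.n_samples).round(1)
    stage = rng.choice(["I", "II", "III"], size=cfg.n_samples, p=[0.5, 0.3, 0.2])
    clinical = pd.DataFrame({
        "sample_id": samples,
        "time": observed,
        "event": event,
        "age": age,
        "stage": stage,
    })

    signature = GeneSignature(name="planted_signature", genes=list(sig_genes),
                              direction="up", provenance="planted")
    truth = {"score": score, "beta": cfg.effect_size, "censor_upper": c_upper}
    return SimulatedCohort(expression=expr, clinical=clinical,
                           signature=signature, truth=truth)
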