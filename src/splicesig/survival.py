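"""Tertile stratification, Kaplan-Meier / log-rank / Cox analysis, and the
random-signature specificity null.

Patients are ranked by a continuous score (splicing percentage or ssGSEA
enrichment) and the top and bottom thirds compared.  Model fitting is
delegated to ``lifelines`` (product-limit estimator, Mantel-Cox log-rank,
Cox partial likelihood with Efron tie handling) behind this module's
interface; the specificity null re-scores length-matched random gene sets
and reports the fraction that fail to reach significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .signatures import GeneSignature, SsgseaRanking, ssgsea_score

__all__ = [
    "StratifiedCohort",
    "KMResult",
    "CoxResult",
    "SpecificityResult",
    "validate_clinical",
    "stratify_by_score",
    "km_logrank",
    "cox_multivariate",
    "random_signature_specificity",
]


@dataclass
class StratifiedCohort:
    """Sample -> stratum assignment (high / mid / low / excluded)."""

    assignments: dict[str, str]
    ranking: str = "score"
    mode: str = "tertile"
    tied: bool = False

    def stratum(self, name: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == name]


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # stratum -> columns (time, survival)
    medians: dict[str, float]  # NaN when the curve never reaches 0.5
    statistic: float
    p_value: float
    n: dict[str, int]


@dataclass
class CoxResult:
    summary: pd.DataFrame | None  # term, coef, hr, ci_lower, ci_upper, p
    converged: bool
    messages: list[str] = field(default_factory=list)
    reference: str = "low"


@dataclass
class SpecificityResult:
    n_random: int
    signature_length: int
    n_nonsignificant: int
    specificity: float
    alpha: float
    seed: int
    p_values: list[float]
    method: str = "logrank"
    true_p: float | None = None


def validate_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical table contract: positive finite times, binary events."""
    for col in ("sample_id", "time", "event"):
        if col not in records.columns:
            raise ValueError(f"clinical table is missing required column {col!r}")
    if records["sample_id"].duplicated().any():
        raise ValueError("clinical table has duplicate sample ids")
    t = pd.to_numeric(records["time"], errors="coerce")
    if t.isna().any() or not np.isfinite(t).all() or (t <= 0).any():
        raise ValueError("survival times must be finite and strictly positive")
    ev = records["event"]
    if not ev.isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return records


def stratify_by_score(scores: Mapping[str, float] | pd.Series,
                      mode: str = "tertile",
                      ranking: str = "score") -> StratifiedCohort:
    """Rank descending and take the top/bottom floor(n/k) as high/low.

    k is 3 (tertile) or 4 (quartile); ties are broken by sample id
    (lexicographic) so the assignment is deterministic, with a flag raised
    when ties cross any boundary-relevant ordering.
    """
    if mode not in ("tertile", "quartile"):
        raise ValueError("mode must be 'tertile' or 'quartile'")
    s = pd.Series(scores, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    k = 3 if mode == "tertile" else 4
    n = len(s)
    if n < k:
        raise ValueError(f"need at least {k} samples for {mode} stratification")
    order = sorted(s.index, key=lambda sid: (-s[sid], str(sid)))
    cut = n // k
    assignments = {sid: "mid" for sid in order}
    for sid in order[:cut]:
        assignments[sid] = "high"
    for sid in order[n - cut:]:
        assignments[sid] = "low"
    tied = bool(s.duplicated().any())
    return StratifiedCohort(assignments=assignments, ranking=ranking,
                            mode=mode, tied=tied)


def _km_curve(times: np.ndarray, events: np.ndarray) -> tuple[pd.DataFrame, float]:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(),
                          "survival": sf.iloc[:, 0].to_numpy()})
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")  # the curve never reaches 0.5
    return curve, median


def km_logrank(records: pd.DataFrame, cohort: StratifiedCohort) -> KMResult:
    """Per-stratum KM curves and the high-vs-low Mantel-Cox log-rank test."""
    records = validate_clinical(records)
    rec = records.set_index("sample_id")
    groups: dict[str, pd.DataFrame] = {}
    for name in ("high", "mid", "low"):
        ids = [s for s in cohort.stratum(name) if s in rec.index]
        if ids:
            groups[name] = rec.loc[ids]
    for name in ("high", "low"):
        if name not in groups or len(groups[name]) == 0:
            raise ValueError(f"stratum {name!r} contains no subjects")
        if int(groups[name]["event"].sum()) == 0:
            raise ValueError(f"stratum {name!r} contains no events; log-rank undefined")

    curves, medians, n = {}, {}, {}
    for name, g in groups.items():
        curves[name], medians[name] = _km_curve(g["time"].to_numpy(),
                                                g["event"].to_numpy())
        n[name] = len(g)
    res = logrank_test(groups["high"]["time"], groups["low"]["time"],
                       event_observed_A=groups["high"]["event"],
                       event_observed_B=groups["low"]["event"])
    return KMResult(curves=curves, medians=medians,
                    statistic=float(res.test_statistic),
                    p_value=float(res.p_value), n=n)


def cox_multivariate(records: pd.DataFrame, cohort: StratifiedCohort,
                     covariates: Sequence[str] = (),
                     reference: str = "low") -> CoxResult:
    """Cox proportional-hazards fit of high vs low with optional covariates.

    The group term is coded 1 for the non-reference stratum (hazard ratio is
    other-vs-reference).  Categorical covariates are one-hot encoded against
    their lexicographically first level; a covariate constant across samples
    is rejected by name.  Efron tie handling; non-convergence or separation
    returns a flagged result instead of silent output.
    """
    if reference not in ("high", "low"):
        raise ValueError("reference must be 'high' or 'low'")
    records = validate_clinical(records)
    other = "high" if reference == "low" else "low"
    rec = records.set_index("sample_id")
    keep = [s for s in rec.index
            if cohort.assignments.get(s) in ("high", "low")]
    if not keep:
        raise ValueError("no samples fall in the high or low strata")
    df = rec.loc[keep].copy()
    group_col = f"{other}_vs_{reference}"
    df[group_col] = [1 if cohort.assignments[s] == other else 0 for s in keep]
    if df[group_col].nunique() < 2:
        raise ValueError("both strata must be represented for a Cox fit")

    design = df[["time", "event", group_col]].copy()
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not found in the clinical table")
        col = df[cov]
        if col.nunique(dropna=False) < 2:
            raise ValueError(f"covariate {cov!r} has zero variance")
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = pd.to_numeric(col)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True,
                                     dtype=float)
            design = pd.concat([design, dummies], axis=1)

    cph = CoxPHFitter()
    messages: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(design, duration_col="time", event_col="event")
        messages = [str(w.message) for w in caught]
    except ConvergenceError as err:
        return CoxResult(summary=None, converged=False,
                         messages=[str(err)], reference=reference)
    summ = cph.summary
    out = pd.DataFrame({
        "term": summ.index,
        "coef": summ["coef"].to_numpy(),
        "hr": summ["exp(coef)"].to_numpy(),
        "ci_lower": summ["exp(coef) lower 95%"].to_numpy(),
        "ci_upper": summ["exp(coef) upper 95%"].to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    return CoxResult(summary=out, converged=True, messages=messages,
                     reference=reference)


def random_signature_specificity(expr: pd.DataFrame, records: pd.DataFrame,
                                 true_sig: GeneSignature,
                                 universe: Sequence[str],
                                 n_random: int = 1000,
                                 alpha: float = 0.05,
                                 seed: int = 0,
                                 method: str = "logrank",
                                 compare_to_true: bool = False,
                                 ssgsea_alpha: float = 0.25,
                                 covariates: Sequence[str] = ()) -> SpecificityResult:
    """Specificity of a prognostic signature against length-matched random sets.

    For each of ``n_random`` seeded draws a signature of the same effective
    length (|true signature ∩ matrix genes|) is sampled without replacement
    from ``universe`` minus the true signature, scored by ssGSEA, tertile-
    stratified and tested high vs low.  Specificity is the fraction of random
    signatures with p >= alpha (or, with ``compare_to_true``, with p above
    the true signature's own p).  ``method`` selects the log-rank p (default)
    or the Cox group-term p.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if method not in ("logrank", "cox"):
        raise ValueError("method must be 'logrank' or 'cox'")
    records = validate_clinical(records)
    true_genes = set(true_sig.genes)
    sig_len = len(true_genes & set(expr.index))
    if sig_len == 0:
        raise ValueError("true signature shares no genes with the matrix")
    candidates = sorted((set(universe) & set(expr.index)) - true_genes)
    if len(candidates) < sig_len:
        raise ValueError(
            f"universe too small: {len(candidates)} candidate genes for "
            f"signatures of length {sig_len}")

    ranking = SsgseaRanking(expr, alpha=ssgsea_alpha)

    def _p_for(genes: Iterable[str], name: str) -> float:
        scores = pd.Series(ranking.score(genes, name=name), index=ranking.samples)
        cohort = stratify_by_score(scores, mode="tertile", ranking=name)
        if method == "logrank":
            return km_logrank(records, cohort).p_value
        res = cox_multivariate(records, cohort, covariates=covariates)
        if not res.converged or res.summary is None:
            return float("nan")
        return float(res.summary.loc[0, "p"])

    true_p = _p_for(true_genes & set(expr.index), true_sig.name) if compare_to_true else None

    rng = np.random.default_rng(seed)
    cand = np.asarray(candidates)
    p_values: list[float] = []
    for i in range(n_random):
        draw = rng.choice(cand, size=sig_len, replace=False)
        p_values.append(_p_for(draw, f"random_{i}"))
    pv = np.asarray(p_values)
    if compare_to_true:
        nonsig = int(np.sum(pv > true_p))
    else:
        nonsig = int(np.sum(pv >= alpha))
    return SpecificityResult(
        n_random=n_random, signature_length=sig_len, n_nonsignificant=nonsig,
        specificity=nonsig / n_random, alpha=alpha, seed=seed,
        p_values=p_values, method=method, true_p=true_p)
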