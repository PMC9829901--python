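"""Gene-signature construction and single-sample GSEA scoring.

A signature is selected from a differential-expression table by strict
cutoffs on log2 fold-change, FDR and p value (optionally scanned over a
cutoff grid), mapped to another species through an ortholog table, and scored
per sample with the ssGSEA rank statistic.  A curated immunomodulator
database (GMT) can be intersected with a DE gene list to rank pathways by
the fraction of their members that are differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSignature",
    "ImmunomodulatorSet",
    "SsgseaRanking",
    "select_signature",
    "signature_grid",
    "map_orthologs",
    "OrthologMapping",
    "ssgsea_score",
    "intersect_immunomodulators",
]

_DGE_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene set with a direction and provenance."""

    name: str
    genes: tuple[str, ...]
    direction: str = "up"
    provenance: str = "loaded"

    def __init__(self, name: str, genes: Iterable[str], direction: str = "up",
                 provenance: str = "loaded") -> None:
        genes = tuple(genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {name!r} contains duplicate gene symbols")
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ImmunomodulatorSet:
    """A curated tumour-intrinsic immunomodulatory pathway gene set."""

    name: str
    genes: tuple[str, ...]
    immune_effect: str = ""  # suppressive / activating
    species: str = ""
    organ: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))


def _validate_dge(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _DGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DGE table is missing required columns: {missing}")
    if table["gene"].duplicated().any():
        dups = table.loc[table["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"DGE table has duplicate gene symbols, e.g. {list(dups)}")
    return table


def select_signature(table: pd.DataFrame, log2fc_min: float = 1.0,
                     fdr_max: float = 0.01, p_max: float = 0.05,
                     direction: str = "up", name: str | None = None) -> GeneSignature:
    """Select genes passing strict cutoffs, ordered by |log2FC| descending.

    Up-regulated: log2fc > log2fc_min; down-regulated: log2fc < -log2fc_min.
    All inequalities are strict, so a gene sitting exactly on a cutoff is
    excluded.  Ties in |log2FC| break lexicographically by symbol.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(table) == 0:
        genes: list[str] = []
    else:
        table = _validate_dge(table)
        if direction == "up":
            fc_ok = table["log2fc"] > log2fc_min
        else:
            fc_ok = table["log2fc"] < -log2fc_min
        keep = table[fc_ok & (table["fdr"] < fdr_max) & (table["pvalue"] < p_max)]
        keep = keep.assign(_absfc=keep["log2fc"].abs())
        keep = keep.sort_values(["_absfc", "gene"], ascending=[False, True])
        genes = list(keep["gene"])
    name = name or f"{direction}_fc{log2fc_min:g}_fdr{fdr_max:g}_p{p_max:g}"
    return GeneSignature(name=name, genes=genes, direction=direction,
                         provenance=f"log2fc>{log2fc_min:g},fdr<{fdr_max:g},p<{p_max:g}")


def signature_grid(table: pd.DataFrame, log2fc_grid: Sequence[float],
                   fdr_grid: Sequence[float], p_max: float = 0.05,
                   direction: str = "up") -> dict[tuple[float, float], GeneSignature]:
    """Enumerate signatures over a (log2FC cutoff, FDR cutoff) grid."""
    return {
        (fc, fdr): select_signature(table, fc, fdr, p_max, direction)
        for fc in log2fc_grid for fdr in fdr_grid
    }


@dataclass(frozen=True)
class OrthologMapping:
    signature: GeneSignature
    n_mapped: int
    n_dropped: int


def map_orthologs(sig: GeneSignature, mapping: pd.DataFrame,
                  first_match: bool = False) -> OrthologMapping:
    """Translate signature symbols through a two-column ortholog table.

    Unmapped genes are dropped; duplicates created by many-to-one mappings are
    collapsed (first occurrence kept).  A source symbol with several targets
    is an error unless ``first_match`` is given, in which case the first row
    wins.
    """
    if mapping.shape[1] < 2:
        raise ValueError("ortholog mapping must have two columns (source, target)")
    src, dst = mapping.columns[:2]
    if mapping[src].duplicated().any():
        if not first_match:
            dup = mapping.loc[mapping[src].duplicated(), src].unique()[:5]
            raise ValueError(
                f"one-to-many ortholog mapping for {list(dup)}; pass first_match=True "
                "to keep the first target")
        mapping = mapping.drop_duplicates(subset=src, keep="first")
    lut = dict(zip(mapping[src], mapping[dst]))
    translated: list[str] = []
    dropped = 0
    for g in sig.genes:
        t = lut.get(g)
        if t is None:
            dropped += 1
        elif t not in translated:
            translated.append(t)
    new_sig = GeneSignature(name=sig.name, genes=translated, direction=sig.direction,
                            provenance=f"{sig.provenance};orthologs")
    return OrthologMapping(signature=new_sig, n_mapped=len(sig) - dropped,
                           n_dropped=dropped)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

class SsgseaRanking:
    """Precomputed per-sample gene ranking reused across many signatures.

    Genes are ranked by expression descending within each sample, ties broken
    lexicographically by symbol.  The gene at descending position k (1-based)
    carries rank value N - k + 1, weighted by ``value ** alpha``.
    """

    def __init__(self, expr: pd.DataFrame, alpha: float = 0.25) -> None:
        if expr.shape[0] < 2:
            raise ValueError("expression matrix must contain at least 2 genes")
        if expr.index.duplicated().any():
            raise ValueError("expression matrix has duplicate gene symbols")
        if expr.columns.duplicated().any():
            raise ValueError("expression matrix has duplicate sample ids")
        if expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        expr = expr.sort_index()  # lexicographic tie-break via stable argsort
        self.alpha = float(alpha)
        self.genes = expr.index.to_numpy()
        self.samples = expr.columns.to_numpy()
        vals = expr.to_numpy(dtype=float)
        n = vals.shape[0]
        # stable argsort of -values: descending, equal values in symbol order
        self.order = np.argsort(-vals, axis=0, kind="stable")
        rank_value = (n - np.arange(n, dtype=float))  # N at the top, 1 at the bottom
        self.weights = rank_value ** self.alpha
        self._gene_pos = {g: i for i, g in enumerate(self.genes)}

    def score(self, genes: Iterable[str], name: str = "signature") -> np.ndarray:
        """Raw (unnormalised) ssGSEA scores for one gene set, per sample."""
        idx = [self._gene_pos[g] for g in genes if g in self._gene_pos]
        if not idx:
            raise ValueError(f"signature {name!r} shares no genes with the matrix")
        n, s = self.order.shape
        member = np.zeros(n, dtype=bool)
        member[idx] = True
        in_set = member[self.order]  # n x s: membership in ranked order
        w = np.where(in_set, self.weights[:, None], 0.0)
        cum_in = np.cumsum(w, axis=0) / w.sum(axis=0)
        n_out = n - len(idx)
        if n_out == 0:
            raise ValueError("signature covers the whole matrix; scores undefined")
        cum_out = np.cumsum(~in_set, axis=0) / n_out
        return (cum_in - cum_out).sum(axis=0)


def ssgsea_score(expr: pd.DataFrame,
                 signatures: GeneSignature | Sequence[GeneSignature],
                 alpha: float = 0.25, normalize: bool = True,
                 ranking: SsgseaRanking | None = None) -> pd.DataFrame:
    """Per-sample ssGSEA enrichment scores (samples x signatures).

    With ``normalize`` the whole score matrix is divided by its (max - min),
    the conventional cross-sample normalisation.  Raw scores for one sample
    never depend on the other samples; normalised scores do (through the
    range).  Pass a prebuilt ``ranking`` to amortise the sort across many
    signatures.
    """
    if isinstance(signatures, GeneSignature):
        signatures = [signatures]
    if ranking is None:
        ranking = SsgseaRanking(expr, alpha=alpha)
    elif ranking.alpha != alpha:
        raise ValueError("prebuilt ranking was computed with a different alpha")
    out = pd.DataFrame(
        {sig.name: ranking.score(sig.genes, name=sig.name) for sig in signatures},
        index=pd.Index(ranking.samples, name="sample_id"),
    )
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = out / rng
    return out


# ---------------------------------------------------------------------------
# immunomodulator overlap
# ---------------------------------------------------------------------------

def intersect_immunomodulators(deg_genes: Iterable[str],
                               db: Sequence[ImmunomodulatorSet],
                               min_size: int = 5,
                               universe: Sequence[str] | None = None) -> pd.DataFrame:
    """Overlap a DE gene list with curated immunomodulator pathways.

    Pathways below ``min_size`` genes are excluded.  For each remaining
    pathway the overlap fraction |DE ∩ pathway| / |pathway| is reported,
    sorted descending.  When a gene ``universe`` is given a hypergeometric
    enrichment p value is added (informational; no filtering).
    """
    deg = set(deg_genes)
    rows = []
    for pset in db:
        genes = set(pset.genes)
        if len(genes) < min_size:
            continue
        overlap = sorted(genes & deg)
        row = {
            "pathway": pset.name,
            "immune_effect": pset.immune_effect,
            "n_genes": len(genes),
            "overlap_count": len(overlap),
            "fraction": len(overlap) / len(genes),
            "overlap_genes": ",".join(overlap),
        }
        if universe is not None:
            uni = set(universe)
            m = len(uni)
            row["p_hypergeom"] = float(
                hypergeom.sf(len(overlap) - 1, m, len(genes & uni), len(deg & uni)))
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["fraction", "pathway"],
                              ascending=[False, True]).reset_index(drop=True)
    return out
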