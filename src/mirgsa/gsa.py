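"""Set-level logistic-regression analysis of a gene ranking index.

For each gene set F the model

    log P(g in F) / P(g not in F) = kappa + alpha * t_g

is fitted by maximum likelihood over the *targeted-gene universe* (genes
reached by at least one miRNA).  A significantly positive slope alpha
means the set is enriched among genes with high differential-inhibition
scores — the set is more inhibited by miRNA action in cases; a negative
slope means enrichment among genes more inhibited in controls, i.e. the
function is deregulated in cases.  Wald p-values are corrected across
sets by a step-up false-discovery-rate procedure.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

logger = logging.getLogger(__name__)

# classification labels
INHIBITED_IN_CASES = "inhibited_in_cases"
DEREGULATED_IN_CASES = "deregulated_in_cases"
NOT_SIGNIFICANT = "not_significant"
CLASSIFICATIONS = (INHIBITED_IN_CASES, DEREGULATED_IN_CASES, NOT_SIGNIFICANT)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. one GO term)."""

    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("set_id must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} has no genes")


class GeneSetCollection(Mapping[str, GeneSet]):
    """An ordered collection of :class:`GeneSet`, keyed by ``set_id``."""

    def __init__(self, sets: Iterable[GeneSet]) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.set_id in self._sets:
                raise ValueError(f"duplicate set_id {gs.set_id!r}")
            self._sets[gs.set_id] = gs

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self._sets.values():
            out |= gs.genes
        return frozenset(out)


@dataclass(frozen=True)
class GsaParams:
    """Tunable parameters of the set-level analysis.

    min_set_size / max_set_size bound the number of annotated genes a set
    must have *within the universe* to be tested; fdr_method selects the
    step-up correction (``BH`` assumes independence/PRDS, ``BY`` is valid
    under arbitrary dependence); significance_level is applied to the
    adjusted p-values; normalize_index rank-transforms the gene scores to
    standard-normal quantiles before fitting, taming the heavy tails of
    summed log-p scores.
    """

    min_set_size: int = 10
    max_set_size: int = 500
    fdr_method: str = "BH"
    significance_level: float = 0.05
    normalize_index: bool = True

    def __post_init__(self) -> None:
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if self.max_set_size < self.min_set_size:
            raise ValueError("max_set_size must be >= min_set_size")
        if self.fdr_method not in ("BH", "BY"):
            raise ValueError("fdr_method must be 'BH' or 'BY'")
        if not 0.0 < self.significance_level < 1.0:
            raise ValueError("significance_level must lie in (0, 1)")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single per-set logistic fit."""

    kappa: float
    alpha: float
    stderr: float
    pvalue: float
    converged: bool


@dataclass
class GsaRecord:
    """Per-set result row of the set-level analysis."""

    set_id: str
    name: str
    n_in_universe: int
    kappa: float
    alpha: float
    stderr: float
    pvalue: float
    padj: float
    classification: str
    converged: bool


def normalize_index(gi: pd.DataFrame) -> pd.DataFrame:
    """Rank-based inverse-normal transform of the targeted genes' scores.

    Scores of targeted genes are replaced by standard-normal quantiles at
    rank/(n+1), using average ranks on ties; the transform is strictly
    monotone in the original scores.  Untargeted genes are untouched.
    """
    targeted = gi["targeted"].to_numpy(bool)
    n = int(targeted.sum())
    if n < 3:
        raise ValueError(f"need >= 3 targeted genes to normalise, got {n}")
    t = gi.loc[targeted, "t"].to_numpy(float)
    ranks = scipy.stats.rankdata(t, method="average")
    quantiles = scipy.stats.norm.ppf(ranks / (n + 1))
    out = gi.copy()
    out.loc[targeted, "t"] = quantiles
    return out


def _universe_series(index: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(index, pd.DataFrame):
        if "targeted" in index.columns:
            index = index.loc[index["targeted"].astype(bool), "t"]
        else:
            index = index["t"]
    return index.astype(float)


def fit_set_logistic(
    index: pd.DataFrame | pd.Series, members: Iterable[str]
) -> FitResult:
    """Maximum-likelihood logistic fit of set membership on the gene score.

    Parameters
    ----------
    index
        The gene universe: either a Series mapping gene_id -> score, or a
        gene-index frame whose targeted rows define the universe.
    members
        Gene ids belonging to the set; must be a strict, non-empty subset
        of the universe.

    Returns
    -------
    FitResult
        Intercept ``kappa``, slope ``alpha``, its standard error and the
        two-sided Wald p-value for alpha = 0.  Under perfect separation
        or non-convergence the estimates are NaN and ``converged`` is
        False; a universe lacking members or non-members raises instead.
    """
    t = _universe_series(index)
    members = set(members)
    y = t.index.isin(members).astype(float)
    n_members = int(y.sum())
    if n_members == 0 or n_members == len(y):
        raise ValueError(
            "universe must contain both members and non-members "
            f"(got {n_members} members of {len(y)} genes)"
        )

    x = t.to_numpy(float)
    # complete separation in one covariate == classes split by a threshold
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)

    exog = np.column_stack([np.ones_like(x), x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)

    converged = bool(res.mle_retvals.get("converged", False)) and bool(
        np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))
    )
    if not converged:
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)
    kappa, alpha = res.params
    stderr = float(res.bse[1])
    pvalue = float(res.pvalues[1])
    return FitResult(float(kappa), float(alpha), stderr, pvalue, True)


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Step-up FDR adjustment (Benjamini-Hochberg or Benjamini-Yekutieli).

    Missing values (NaN) are passed through untouched and do not count
    towards the number of tests.
    """
    if method not in ("BH", "BY"):
        raise ValueError("method must be 'BH' or 'BY'")
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        key = "fdr_bh" if method == "BH" else "fdr_by"
        out[mask] = multipletests(p[mask], method=key)[1]
    return out


def classify_term(alpha: float, padj: float, level: float) -> str:
    """Interpret a fitted slope: which condition the set is inhibited in.

    A significantly positive slope flags the set as inhibited/intercepted
    by miRNA action in cases; a significantly negative slope flags it as
    inhibited in controls, i.e. deregulated in cases.  Anything else —
    including a missing adjusted p-value — is not significant.
    """
    if not np.isfinite(padj) or padj >= level:
        return NOT_SIGNIFICANT
    if alpha > 0:
        return INHIBITED_IN_CASES
    if alpha < 0:
        return DEREGULATED_IN_CASES
    return NOT_SIGNIFICANT


def run_gsa(
    gi: pd.DataFrame,
    sets: GeneSetCollection,
    params: GsaParams | None = None,
) -> list[GsaRecord]:
    """Run the full set-level analysis over a gene index.

    The universe is the set of targeted genes.  Sets are filtered to
    ``min_set_size <= n_in_universe <= max_set_size`` (sets covering the
    whole universe carry no contrast and are skipped); the optional rank
    normalisation is applied once, globally; adjusted p-values are
    computed jointly across all surviving sets; output is ordered by
    ``set_id``.
    """
    params = params or GsaParams()
    targeted = gi.loc[gi["targeted"].astype(bool)]
    if len(targeted) < 3:
        raise ValueError("need >= 3 targeted genes for set-level analysis")
    if params.normalize_index:
        gi = normalize_index(gi)
        targeted = gi.loc[gi["targeted"].astype(bool)]
    t = targeted["t"].astype(float)
    universe = set(t.index)

    records: list[GsaRecord] = []
    for set_id in sorted(sets):
        gs = sets[set_id]
        members = gs.genes & universe
        n = len(members)
        if n < params.min_set_size or n > params.max_set_size:
            continue
        if n == len(universe):
            logger.warning("set %s covers the whole universe; skipped", set_id)
            continue
        fit = fit_set_logistic(t, members)
        records.append(
            GsaRecord(
                set_id=set_id,
                name=gs.name,
                n_in_universe=n,
                kappa=fit.kappa,
                alpha=fit.alpha,
                stderr=fit.stderr,
                pvalue=fit.pvalue,
                padj=np.nan,
                classification=NOT_SIGNIFICANT,
                converged=fit.converged,
            )
        )
    if not records:
        logger.warning("no gene set survived size filtering")
        return []

    padj = adjust_pvalues([rec.pvalue for rec in records], params.fdr_method)
    for rec, adj in zip(records, padj):
        rec.padj = float(adj)
        if rec.converged:
            rec.classification = classify_term(
                rec.alpha, rec.padj, params.significance_level
            )
    return records


RESULT_COLUMNS = (
    "set_id",
    "name",
    "n_in_universe",
    "kappa",
    "alpha",
    "stderr",
    "pvalue",
    "padj",
    "classification",
    "converged",
)


def records_to_frame(records: Sequence[GsaRecord]) -> pd.DataFrame:
    """Tabulate GSA records with one row per set, ordered as given."""
    return pd.DataFrame(
        [[getattr(rec, col) for col in RESULT_COLUMNS] for rec in records],
        columns=list(RESULT_COLUMNS),
    )
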