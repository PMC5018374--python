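"""miRNA ranking index and miRNA-to-gene evidence transfer.

A miRNA differential-expression result (signed test statistic + p-value)
is collapsed into a single signed *ranking index*

    r = -sign(statistic) * ln(p)

so that strongly overexpressed miRNAs (in cases vs controls) take large
positive values and strongly underexpressed ones large negative values.
Because a miRNA inhibits the genes it targets, summing the indexes of all
miRNAs targeting a gene yields a *differential inhibition* score for that
gene: positive means the gene is more inhibited by miRNA action in cases,
negative means more inhibited in controls.  Opposite-direction miRNA
changes on the same gene cancel; many weak same-direction changes add up.
"""

from __future__ import annotations

import logging
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd

from .gsa import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

#: Required columns of a miRNA statistics table.
STATS_COLUMNS = ("mirna_id", "statistic", "pvalue")

#: Required columns of a miRNA->gene target table.
TARGET_COLUMNS = ("mirna_id", "gene_id", "weight")

#: Smallest positive normal double; p-values of exactly 0 are clamped here
#: because the log transform is undefined at 0.
P_FLOOR = float(np.finfo(float).tiny)


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def compute_ranking_index(stats: pd.DataFrame) -> pd.Series:
    """Collapse signed statistics and p-values into the signed ranking index.

    Parameters
    ----------
    stats
        Table with columns ``mirna_id``, ``statistic`` (signed, finite;
        positive = overexpressed in cases) and ``pvalue`` in ``[0, 1]``.
        Zero p-values are clamped to the smallest positive normal double
        with a logged warning.

    Returns
    -------
    pandas.Series
        ``r = -sign(statistic) * ln(pvalue)`` indexed by ``mirna_id``.
        ``r`` is 0 whenever the statistic is 0 or the p-value is 1.

    Raises
    ------
    ValueError
        On non-finite statistics, p-values outside ``[0, 1]`` or duplicate
        miRNA identifiers; the offending rows are named in the message.
    """
    _require_columns(stats, STATS_COLUMNS, "stats table")
    ids = stats["mirna_id"].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate mirna_id entries: {', '.join(dups[:5])}")
    if (ids == "").any():
        raise ValueError("empty mirna_id encountered")

    stat = np.asarray(stats["statistic"], dtype=float)
    pval = np.asarray(stats["pvalue"], dtype=float)

    bad_stat = ~np.isfinite(stat)
    if bad_stat.any():
        raise ValueError(
            "non-finite statistic for miRNA(s): "
            + ", ".join(ids[bad_stat].head(5))
        )
    bad_p = ~np.isfinite(pval) | (pval < 0.0) | (pval > 1.0)
    if bad_p.any():
        raise ValueError(
            "pvalue outside [0, 1] for miRNA(s): " + ", ".join(ids[bad_p].head(5))
        )

    n_zero = int((pval == 0.0).sum())
    if n_zero:
        logger.warning("%d zero p-value(s) clamped to %.3e", n_zero, P_FLOOR)
        pval = np.where(pval == 0.0, P_FLOOR, pval)

    r = -np.sign(stat) * np.log(pval)
    r = r + 0.0  # normalise -0.0 to +0.0
    return pd.Series(r, index=pd.Index(ids, name="mirna_id"), name="r")


def invert_target_map(tm: pd.DataFrame) -> dict[str, set[tuple[str, float]]]:
    """Invert a miRNA->gene target table into gene -> {(mirna, weight)}.

    The returned mapping contains exactly the genes present in ``tm``;
    re-flattening it recovers the original pair set.
    """
    _require_columns(tm, ("mirna_id", "gene_id"), "target map")
    weights = tm["weight"] if "weight" in tm.columns else pd.Series(1.0, index=tm.index)
    out: dict[str, set[tuple[str, float]]] = {}
    for mirna, gene, w in zip(tm["mirna_id"], tm["gene_id"], weights):
        out.setdefault(str(gene), set()).add((str(mirna), float(w)))
    return out


def transfer_index(
    ranking: pd.Series,
    tm: pd.DataFrame,
    expressed: Collection[str] | None = None,
) -> pd.DataFrame:
    """Transfer miRNA ranking indexes to per-gene differential-inhibition scores.

    Each gene targeted by at least one miRNA receives

        t_i = sum over targeting miRNAs j of  w_ij * r_j

    summing only over miRNAs present in ``ranking``.  Genes absent from
    the target map are flagged untargeted and score 0; they are excluded
    from downstream set-level analysis.

    Parameters
    ----------
    ranking
        Signed ranking index per miRNA (see :func:`compute_ranking_index`).
    tm
        Target table with columns ``mirna_id``, ``gene_id`` and optionally
        ``weight`` (default 1.0).
    expressed
        Optional set of expressed gene ids.  When given, genes outside it
        have their score forced to 0 (they cannot mediate miRNA action if
        no transcript is present) but keep their targeted flag; expressed
        genes missing from the target map are added as untargeted rows.

    Returns
    -------
    pandas.DataFrame
        Indexed by ``gene_id`` (sorted), columns ``t`` (float) and
        ``targeted`` (bool).
    """
    if ranking.empty:
        raise ValueError("ranking index is empty")
    if tm.empty:
        raise ValueError("target map is empty")
    _require_columns(tm, ("mirna_id", "gene_id"), "target map")

    pairs = tm.copy()
    if "weight" not in pairs.columns:
        pairs["weight"] = 1.0
    pairs["mirna_id"] = pairs["mirna_id"].astype(str)
    pairs["gene_id"] = pairs["gene_id"].astype(str)

    known = pairs["mirna_id"].isin(ranking.index)
    n_unknown = pairs.loc[~known, "mirna_id"].nunique()
    if not known.any():
        raise ValueError("no miRNA of the target map appears in the ranking index")
    if n_unknown:
        logger.warning(
            "%d miRNA(s) of the target map have no ranking index and contribute nothing",
            n_unknown,
        )

    sub = pairs.loc[known, ["mirna_id", "gene_id", "weight"]]
    # fixed summation order: results do not depend on input row order
    sub = sub.sort_values(["gene_id", "mirna_id", "weight"], kind="mergesort")
    contrib = sub["weight"].to_numpy(float) * ranking.reindex(sub["mirna_id"]).to_numpy(float)
    sums = (
        pd.Series(contrib, index=sub["gene_id"].to_numpy())
        .groupby(level=0, sort=True)
        .sum()
    )

    targeted_genes = pd.Index(sorted(pairs["gene_id"].unique()), name="gene_id")
    t = sums.reindex(targeted_genes).fillna(0.0)
    frame = pd.DataFrame({"t": t, "targeted": True}, index=targeted_genes)

    if expressed is not None:
        expressed = {str(g) for g in expressed}
        extra = sorted(expressed - set(targeted_genes))
        if extra:
            frame = pd.concat(
                [
                    frame,
                    pd.DataFrame(
                        {"t": 0.0, "targeted": False},
                        index=pd.Index(extra, name="gene_id"),
                    ),
                ]
            ).sort_index()
        frame.loc[~frame.index.isin(expressed), "t"] = 0.0
    return frame


def transfer_annotation_to_mirna(
    sets: GeneSetCollection, tm: pd.DataFrame
) -> GeneSetCollection:
    """Extrapolate gene-level annotation to the miRNA level.

    A miRNA belongs to an extrapolated set iff at least one of its target
    genes belongs to the original set.  The result lets the set-level
    logistic model run directly on the miRNA ranking index, with no
    transfer step.  Sets with no annotated miRNA are dropped.
    """
    if len(sets) == 0:
        raise ValueError("gene set collection is empty")
    if tm.empty:
        raise ValueError("target map is empty")
    gene_to_mirnas: dict[str, set[str]] = {}
    for mirna, gene in zip(tm["mirna_id"].astype(str), tm["gene_id"].astype(str)):
        gene_to_mirnas.setdefault(gene, set()).add(mirna)

    out: list[GeneSet] = []
    n_empty = 0
    for gs in sets.values():
        mirnas: set[str] = set()
        for gene in gs.genes:
            mirnas |= gene_to_mirnas.get(gene, set())
        if mirnas:
            out.append(GeneSet(gs.set_id, gs.name, frozenset(mirnas)))
        else:
            n_empty += 1
    if n_empty:
        logger.warning("%d set(s) had no annotated miRNA and were dropped", n_empty)
    return GeneSetCollection(out)
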