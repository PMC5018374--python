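"""Readers and writers for the pipeline's external file formats.

All formats are tab-separated UTF-8 text.  Lines starting with ``#`` are
treated as comments on read; writers emit Unix line endings and can
prepend comment headers (used by the CLI to record version and seed).
Identifier matching is exact-string and case-sensitive throughout: id
aliasing (miRBase/Ensembl mapping) is an upstream responsibility, and
silent fuzzy matching would corrupt the target relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gsa import GeneSet, GeneSetCollection, GsaRecord, RESULT_COLUMNS
from .nulls import NullExperimentResult

NA = "NA"


@dataclass
class ParseReport:
    """What a reader did: records kept, lines skipped, warnings raised."""

    n_records: int = 0
    n_skipped: int = 0
    warnings: list[str] = field(default_factory=list)


def _data_lines(path: str | Path) -> tuple[list[tuple[int, str]], int]:
    """Non-comment, non-blank lines with 1-based line numbers."""
    kept: list[tuple[int, str]] = []
    n_skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                n_skipped += 1
                continue
            kept.append((lineno, line))
    return kept, n_skipped


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: cannot parse {what} {text!r}") from exc


def read_stats_table(path: str | Path) -> tuple[pd.DataFrame, ParseReport]:
    """Read a miRNA statistics table (mirna_id, statistic, pvalue; header).

    Statistics must be finite; p-values must lie in [0, 1], with exact
    zeros clamped to the smallest positive normal double (warned).
    Duplicate miRNA ids are an error.
    """
    lines, n_skipped = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty stats table")
    header_no, header = lines[0]
    columns = header.split("\t")
    for col in ("mirna_id", "statistic", "pvalue"):
        if col not in columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = {col: columns.index(col) for col in ("mirna_id", "statistic", "pvalue")}

    report = ParseReport(n_skipped=n_skipped)
    ids: list[str] = []
    stats: list[float] = []
    pvals: list[float] = []
    seen: set[str] = set()
    p_floor = float(np.finfo(float).tiny)
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < len(columns):
            raise ValueError(f"line {lineno}: expected {len(columns)} fields")
        mirna = fields[idx["mirna_id"]]
        if not mirna:
            raise ValueError(f"line {lineno}: empty mirna_id")
        if mirna in seen:
            raise ValueError(f"line {lineno}: duplicate mirna_id {mirna!r}")
        seen.add(mirna)
        stat = _parse_float(fields[idx["statistic"]], "statistic", lineno)
        if not math.isfinite(stat):
            raise ValueError(f"line {lineno}: non-finite statistic for {mirna!r}")
        p = _parse_float(fields[idx["pvalue"]], "pvalue", lineno)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"line {lineno}: pvalue {p} outside [0, 1]")
        if p == 0.0:
            report.warnings.append(
                f"line {lineno}: pvalue 0 clamped to {p_floor:.3e}"
            )
            p = p_floor
        ids.append(mirna)
        stats.append(stat)
        pvals.append(p)
    if not ids:
        raise ValueError(f"{path}: stats table has no data rows")
    report.n_records = len(ids)
    frame = pd.DataFrame({"mirna_id": ids, "statistic": stats, "pvalue": pvals})
    return frame, report


def read_target_table(path: str | Path) -> tuple[pd.DataFrame, ParseReport]:
    """Read a miRNA->gene target table (mirna_id, gene_id[, weight]).

    Two-column rows default to weight 1.0.  Duplicate pairs are collapsed
    keeping the maximum weight, with a warning counting them.  An
    optional header line repeating the column names is tolerated.
    """
    lines, n_skipped = _data_lines(path)
    report = ParseReport(n_skipped=n_skipped)
    rows: list[tuple[str, str, float]] = []
    for lineno, line in lines:
        fields = line.split("\t")
        if fields[0] == "mirna_id":  # optional header
            report.n_skipped += 1
            continue
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 columns")
        mirna, gene = fields[0], fields[1]
        if not mirna or not gene:
            raise ValueError(f"line {lineno}: empty identifier")
        weight = 1.0
        if len(fields) >= 3 and fields[2] != "":
            weight = _parse_float(fields[2], "weight", lineno)
            if not math.isfinite(weight) or weight < 0.0:
                raise ValueError(f"line {lineno}: weight must be finite and >= 0")
        rows.append((mirna, gene, weight))
    if not rows:
        raise ValueError(f"{path}: target table has no pairs")

    best: dict[tuple[str, str], float] = {}
    n_dup = 0
    for mirna, gene, weight in rows:
        key = (mirna, gene)
        if key in best:
            n_dup += 1
            best[key] = max(best[key], weight)
        else:
            best[key] = weight
    if n_dup:
        report.warnings.append(
            f"{n_dup} duplicate (miRNA, gene) pair(s) collapsed keeping max weight"
        )
    frame = pd.DataFrame(
        [(m, g, w) for (m, g), w in best.items()],
        columns=["mirna_id", "gene_id", "weight"],
    )
    report.n_records = len(frame)
    return frame, report


def read_gmt(path: str | Path) -> tuple[GeneSetCollection, ParseReport]:
    """Read a gene set collection in GMT format.

    Each line is ``set_id TAB description TAB gene TAB gene ...``.
    Duplicate genes within a set are collapsed (warned); duplicate set
    ids are an error.
    """
    lines, n_skipped = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty GMT file")
    report = ParseReport(n_skipped=n_skipped)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"line {lineno}: GMT line needs set_id, description and >= 1 gene"
            )
        set_id, name = fields[0], fields[1]
        genes = [g for g in fields[2:] if g]
        if set_id in seen:
            raise ValueError(f"line {lineno}: duplicate set_id {set_id!r}")
        seen.add(set_id)
        unique = frozenset(genes)
        if len(unique) < len(genes):
            report.warnings.append(
                f"line {lineno}: {len(genes) - len(unique)} duplicate gene id(s) "
                f"collapsed in set {set_id!r}"
            )
        if not unique:
            raise ValueError(f"line {lineno}: set {set_id!r} lists no genes")
        sets.append(GeneSet(set_id, name, unique))
    report.n_records = len(sets)
    return GeneSetCollection(sets), report


def read_gene_list(path: str | Path) -> tuple[set[str], ParseReport]:
    """Read a plain gene-id list, one id per line (may be empty)."""
    lines, n_skipped = _data_lines(path)
    out = {line.strip() for _, line in lines}
    return out, ParseReport(n_records=len(out), n_skipped=n_skipped)


def _fmt(value: float | int | bool | str) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return NA
        return f"{value:.6g}"
    return str(value)


def _write_tsv(
    path: str | Path,
    header: Sequence[str],
    rows: Iterable[Sequence[object]],
    header_comments: Sequence[str] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for comment in header_comments or ():
            fh.write(f"# {comment}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_results(
    records: Sequence[GsaRecord],
    path: str | Path,
    header_comments: Sequence[str] | None = None,
) -> None:
    """Write GSA records as TSV (numbers to 6 significant digits, NA for
    missing; non-converged fits get NA p-values)."""
    rows = []
    for rec in records:
        pvalue = rec.pvalue if rec.converged else float("nan")
        padj = rec.padj if rec.converged else float("nan")
        rows.append(
            (
                rec.set_id,
                rec.name,
                rec.n_in_universe,
                rec.kappa,
                rec.alpha,
                rec.stderr,
                pvalue,
                padj,
                rec.classification,
                rec.converged,
            )
        )
    _write_tsv(path, RESULT_COLUMNS, rows, header_comments)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    lines, _ = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty results file")
    columns = lines[0][1].split("\t")
    rows = [line.split("\t") for _, line in lines[1:]]
    frame = pd.DataFrame(rows, columns=columns)
    for col in ("kappa", "alpha", "stderr", "pvalue", "padj"):
        frame[col] = pd.to_numeric(frame[col].mask(frame[col] == NA))
    frame["n_in_universe"] = frame["n_in_universe"].astype(int)
    frame["converged"] = frame["converged"] == "true"
    return frame


def write_stats_table(
    stats: pd.DataFrame,
    path: str | Path,
    header_comments: Sequence[str] | None = None,
) -> None:
    """Write a miRNA statistics table at full float precision."""
    rows = (
        (m, f"{s:.17g}", f"{p:.17g}")
        for m, s, p in zip(stats["mirna_id"], stats["statistic"], stats["pvalue"])
    )
    _write_tsv(path, ("mirna_id", "statistic", "pvalue"), rows, header_comments)


def write_target_table(
    tm: pd.DataFrame,
    path: str | Path,
    header_comments: Sequence[str] | None = None,
) -> None:
    """Write a target table; the weight column is omitted if all 1.0."""
    if "weight" in tm.columns and not (tm["weight"] == 1.0).all():
        rows = (
            (m, g, f"{w:.17g}")
            for m, g, w in zip(tm["mirna_id"], tm["gene_id"], tm["weight"])
        )
        _write_tsv(path, ("mirna_id", "gene_id", "weight"), rows, header_comments)
    else:
        rows = ((m, g) for m, g in zip(tm["mirna_id"], tm["gene_id"]))
        _write_tsv(path, ("mirna_id", "gene_id"), rows, header_comments)


def write_gmt(
    sets: GeneSetCollection,
    path: str | Path,
    header_comments: Sequence[str] | None = None,
) -> None:
    """Write a gene set collection in GMT format (genes sorted)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for comment in header_comments or ():
            fh.write(f"# {comment}\n")
        for set_id in sets:
            gs = sets[set_id]
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


def write_gene_list(
    genes: Iterable[str],
    path: str | Path,
    header_comments: Sequence[str] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for comment in header_comments or ():
            fh.write(f"# {comment}\n")
        for gene in sorted(set(genes)):
            fh.write(f"{gene}\n")


def write_truth_table(
    truth: pd.DataFrame,
    path: str | Path,
    header_comments: Sequence[str] | None = None,
) -> None:
    """Write the synthetic generator's planted-set truth labels."""
    rows = (
        (s, bool(pl), float(d))
        for s, pl, d in zip(truth["set_id"], truth["planted"], truth["delta"])
    )
    _write_tsv(path, ("set_id", "planted", "delta"), rows, header_comments)


def write_null_report(
    result: NullExperimentResult,
    path: str | Path,
    header_comments: Sequence[str] | None = None,
) -> None:
    """Write a permutation-experiment report: one row per permutation plus
    a summary row with the mean significant fraction."""
    rows: list[tuple[object, object]] = [
        (i + 1, frac)
        for i, frac in enumerate(result.per_permutation_sig_fraction)
    ]
    rows.append(("mean", result.mean_sig_fraction))
    _write_tsv(path, ("permutation", "sig_fraction"), rows, header_comments)
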