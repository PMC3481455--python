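"""Readers and writers for FASTA sequence sets and matrix text dialects.

Supported matrix dialects:

``jaspar_pfm``
    Raw position frequency matrix: optional ``>name`` header, four rows
    of counts, optionally prefixed with the base letter and wrapped in
    square brackets (``A [ 25 0 61 ... ]``).
``transfac_like``
    Position-per-row table with a ``PO``/``P0`` header naming the base
    columns and numbered data rows; trailing consensus letters ignored.
``native_tsv``
    This package's self-describing TSV with ``#`` metadata lines
    (kind, order, motif_length, site_count, cutoff, provenance), a
    ``symbol`` header column and one column per motif position.  Count
    and weight matrices round-trip exactly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import BASES, validate_sequence
from .matrix import AlignedSites, CountMatrix, WeightMatrix, symbols_for
from .promoters import PromoterSet

Dialect = Literal["auto", "jaspar_pfm", "transfac_like", "native_tsv"]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> tuple[list[str], list[str]]:
    """Read a FASTA file into (ids, uppercased sequences).

    Duplicate record identifiers are rejected because downstream hit
    tables key on them.
    """
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"duplicate FASTA id {record.id!r} in {path}")
        seen.add(record.id)
        ids.append(record.id)
        seqs.append(validate_sequence(str(record.seq)))
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    return ids, seqs


def write_fasta(path, ids, seqs) -> None:
    records = [
        SeqRecord(Seq(s), id=str(i), description="") for i, s in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path, tss_offset: int | None = None) -> PromoterSet:
    ids, seqs = read_fasta(path)
    return PromoterSet(seqs, ids, tss_offset)


def write_promoters(path, promoters: PromoterSet) -> None:
    write_fasta(path, promoters.ids, promoters.sequences)


def read_sites(path) -> AlignedSites:
    _, seqs = read_fasta(path)
    return AlignedSites(seqs)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _sniff_dialect(lines: list[str]) -> Dialect:
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            return "native_tsv"
        if s.upper().startswith(("PO", "P0")) and len(s.split()) >= 5:
            return "transfac_like"
        if s.startswith(">") or s[0] in "ACGT" or s[0].isdigit():
            return "jaspar_pfm"
    raise FormatError("cannot determine matrix dialect")


def _parse_jaspar(lines: list[str]) -> CountMatrix:
    rows: dict[str, list[float]] = {}
    order = []
    for line in lines:
        s = line.strip()
        if not s or s.startswith(">"):
            continue
        label = None
        if s[0] in BASES and (len(s) == 1 or not s[1].isdigit()):
            label, s = s[0], s[1:]
        s = s.replace("[", " ").replace("]", " ")
        values = [float(tok) for tok in s.split()]
        if label is None:
            label = BASES[len(rows)]
        if label in rows:
            raise FormatError(f"duplicate row for base {label}")
        rows[label] = values
        order.append(label)
    if sorted(order) != sorted(BASES):
        raise FormatError(f"expected 4 base rows, got {order}")
    ncols = {len(v) for v in rows.values()}
    if len(ncols) != 1:
        raise FormatError("ragged rows in PFM")
    counts = np.array([rows[b] for b in BASES])
    if not np.allclose(counts, np.round(counts)):
        raise FormatError("non-integer counts in PFM")
    counts = counts.astype(int)
    sums = set(counts.sum(axis=0).tolist())
    if len(sums) != 1:
        raise FormatError(f"column sums differ: {sorted(sums)}")
    return CountMatrix("mono", counts, sums.pop(), counts.shape[1])


def _parse_transfac(lines: list[str]) -> CountMatrix:
    header: list[str] | None = None
    data: list[list[float]] = []
    for line in lines:
        s = line.strip()
        if not s or s.startswith(("//", "XX", "ID", "BF", "NA", "DE", ">")):
            continue
        toks = s.split()
        if toks[0].upper() in ("PO", "P0"):
            header = [t.upper() for t in toks[1:5]]
            continue
        if header is not None and toks[0].rstrip(":").isdigit():
            vals = []
            for tok in toks[1:]:
                try:
                    vals.append(float(tok))
                except ValueError:
                    break  # trailing consensus letter
            if len(vals) < 4:
                raise FormatError(f"short TRANSFAC row: {s!r}")
            data.append(vals[:4])
    if header is None or sorted(header) != sorted(BASES):
        raise FormatError("missing or malformed PO header")
    by_base = {b: [row[j] for row in data] for j, b in enumerate(header)}
    counts = np.array([by_base[b] for b in BASES])
    if not np.allclose(counts, np.round(counts)):
        raise FormatError("non-integer counts in TRANSFAC table")
    counts = counts.astype(int)
    sums = set(counts.sum(axis=0).tolist())
    if len(sums) != 1:
        raise FormatError(f"column sums differ: {sorted(sums)}")
    return CountMatrix("mono", counts, sums.pop(), counts.shape[1])


def _parse_native(lines: list[str]) -> CountMatrix | WeightMatrix:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in lines:
        s = line.rstrip("\n")
        if s.startswith("#"):
            key, _, value = s.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        elif s.strip():
            body.append(s)
    kind = meta.get("kind")
    if kind not in ("counts", "weights"):
        raise FormatError(f"native TSV kind must be counts|weights, got {kind!r}")
    if not body or not body[0].split("\t")[0] == "symbol":
        raise FormatError("native TSV must start with a 'symbol' header row")
    rows: dict[str, list[str]] = {}
    for line in body[1:]:
        toks = line.split("\t")
        rows[toks[0]] = toks[1:]
    nrows = len(rows)
    if nrows == 4:
        order, symbols = "mono", symbols_for("mono")
    elif nrows == 16:
        order, symbols = "di", symbols_for("di")
    else:
        raise FormatError(f"native TSV must have 4 or 16 symbol rows, got {nrows}")
    if set(rows) != set(symbols):
        raise FormatError("unexpected symbol labels in native TSV")
    grid = np.array([[float(v) for v in rows[s]] for s in symbols])
    declared_order = meta.get("order", order)
    if declared_order != order:
        raise FormatError(
            f"declared order {declared_order!r} inconsistent with {nrows} rows"
        )
    ncols = grid.shape[1]
    motif_length = int(meta.get("motif_length", ncols if order == "mono" else ncols + 1))
    if kind == "counts":
        site_count = meta.get("site_count")
        counts = grid.astype(int)
        n = int(site_count) if site_count else int(counts.sum(axis=0)[0])
        return CountMatrix(order, counts, n, motif_length)
    cutoff = meta.get("cutoff") or None
    cutoff = float(cutoff) if cutoff not in (None, "", "none") else None
    return WeightMatrix(order, grid, motif_length, cutoff, meta.get("provenance", ""))


def read_matrix(path, dialect: Dialect = "auto") -> CountMatrix | WeightMatrix:
    lines = Path(path).read_text().splitlines()
    if dialect == "auto":
        dialect = _sniff_dialect(lines)
    if dialect == "jaspar_pfm":
        return _parse_jaspar(lines)
    if dialect == "transfac_like":
        return _parse_transfac(lines)
    if dialect == "native_tsv":
        return _parse_native(lines)
    raise ValueError(f"unknown dialect {dialect!r}")


def _format_value(x: float) -> str:
    return repr(float(x)) if not math.isclose(x, round(x), abs_tol=0) else str(x)


def write_matrix(path, matrix: CountMatrix | WeightMatrix) -> None:
    """Write a matrix as a self-describing native TSV (exact round trip)."""
    lines = []
    if isinstance(matrix, CountMatrix):
        lines += [
            "# kind=counts",
            f"# order={matrix.order}",
            f"# motif_length={matrix.motif_length}",
            f"# site_count={matrix.site_count}",
        ]
        grid = matrix.counts
        fmt = lambda v: str(int(v))  # noqa: E731
    else:
        lines += [
            "# kind=weights",
            f"# order={matrix.order}",
            f"# motif_length={matrix.motif_length}",
            f"# cutoff={'' if matrix.cutoff is None else repr(matrix.cutoff)}",
            f"# provenance={matrix.provenance}",
        ]
        grid = matrix.weights
        fmt = lambda v: repr(float(v))  # noqa: E731
    ncols = grid.shape[1]
    lines.append("symbol\t" + "\t".join(str(i + 1) for i in range(ncols)))
    for sym, row in zip(symbols_for(matrix.order), grid):
        lines.append(sym + "\t" + "\t".join(fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# hit / profile exports
# ---------------------------------------------------------------------------


def write_hits_bed(path, scan_result, promoters: PromoterSet) -> None:
    """BED6 export: 0-based half-open sequence-local coordinates.

    Minus-strand hits keep the coordinates of the matched forward-strand
    window, with ``-`` in the strand column; the score field carries the
    better-strand PWM score.
    """
    lm = scan_result.motif_length
    with open(path, "w") as fh:
        for site in scan_result.scored_sites(promoters):
            start = site.start + promoters.tss_offset
            fh.write(
                f"{site.promoter_id}\t{start}\t{start + lm}\t{site.sequence}"
                f"\t{site.score:.4f}\t{site.strand}\n"
            )


def write_profile_tsv(path, profile) -> None:
    """Positional profile as TSV with TSS-relative positions."""
    with open(path, "w") as fh:
        fh.write("position\tn_obs\tn_exp\tof_obs\tof_exp\tz\n")
        for i, pos in enumerate(profile.positions):
            fh.write(
                f"{pos}\t{profile.n_obs[i]}\t{profile.n_exp[i]:.6g}"
                f"\t{profile.of_obs[i]:.6g}\t{profile.of_exp[i]:.6g}"
                f"\t{profile.z[i]:.6g}\n"
            )
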