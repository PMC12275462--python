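"""Readers and writers for the external formats the tool touches.

Coordinates are 0-based half-open everywhere (BED/MAF convention).
FASTA and MAF parsing goes through Biopython; newick through the tree
module (dendropy-backed).  The PHAST ``.mod`` dialect (ALPHABET, ORDER,
SUBST_MOD, BACKGROUND, RATE_MAT, TREE records) has no installed reader,
so it is parsed here directly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import AlignIO

from .likelihood import MISSING, Alignment
from .substitution import NeutralModel
from .tree import read_newick, write_newick

__all__ = [
    "Region",
    "ScoreRecord",
    "MafBlock",
    "read_phast_mod",
    "write_phast_mod",
    "read_fasta_alignment",
    "read_maf",
    "extract_region",
    "read_bed",
    "write_scores",
    "read_scores",
    "write_track",
    "SCORE_COLUMNS",
]

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "chrom", "start", "end", "name", "rho0", "rho1", "lambda",
    "lrt_p", "pcorr", "scorr", "robust", "n_perm",
]

_ACCEPTED_SUBST_MODS = {"JC69", "F81", "HKY85", "REV"}


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ScoreRecord:
    """One scored element; missing analysis stages leave fields None."""

    region: Region
    rho0: float | None = None
    rho1: float | None = None
    lambda_hat: float | None = None
    lrt_p: float | None = None
    pcorr: float | None = None
    scorr: float | None = None
    robust: bool | None = None
    n_permulations_used: int = 0
    reason: str | None = None  # reason code for NA records; not serialized


# ---------------------------------------------------------------------------
# PHAST .mod


def read_phast_mod(text: str) -> NeutralModel:
    """Parse a PHAST ``.mod`` file into a unit-normalized NeutralModel.

    Only order-0 reversible nucleotide models are supported.  If the
    rate matrix is not unit-normalized, Q is rescaled to one expected
    substitution per site per unit time and the tree's branch lengths
    are multiplied by the original rate, leaving all Q*t products (and
    hence the likelihood) unchanged.
    """
    records: dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"malformed .mod line: {line!r}")
        key, _, value = line.partition(":")
        key = key.strip().upper()
        value = value.strip()
        if key == "RATE_MAT":
            rows = []
            while i < len(lines) and len(rows) < 4:
                row = lines[i].strip()
                i += 1
                if row:
                    rows.append(row)
            if len(rows) != 4:
                raise ValueError("RATE_MAT must have 4 rows")
            value = "\n".join(rows)
        records[key] = value

    alphabet = records.get("ALPHABET", "A C G T").replace(",", " ").split()
    if [c.upper() for c in alphabet] != ["A", "C", "G", "T"]:
        raise ValueError(f"unsupported alphabet {alphabet}; need A C G T")
    order = int(records.get("ORDER", "0"))
    if order != 0:
        raise ValueError(f"ORDER {order} not supported; need 0")
    subst = records.get("SUBST_MOD", "REV").upper()
    if subst not in _ACCEPTED_SUBST_MODS:
        raise ValueError(
            f"SUBST_MOD {subst} not supported; accepted: {sorted(_ACCEPTED_SUBST_MODS)}"
        )
    if "BACKGROUND" not in records:
        raise ValueError("missing BACKGROUND record")
    pi = np.array([float(x) for x in records["BACKGROUND"].split()])
    if pi.shape != (4,):
        raise ValueError("BACKGROUND must have 4 frequencies")
    off = abs(pi.sum() - 1.0)
    if off > 1e-6 * (1 + 1e-6):
        raise ValueError(f"BACKGROUND frequencies sum to {pi.sum():.8f}, not 1")
    if off > 0:
        logger.warning("renormalizing BACKGROUND (sum off by %.2e)", off)
        pi = pi / pi.sum()

    if "RATE_MAT" not in records:
        raise ValueError("missing RATE_MAT record")
    try:
        Q = np.array(
            [[float(x) for x in row.split()] for row in records["RATE_MAT"].splitlines()]
        )
    except ValueError as exc:
        raise ValueError(f"malformed RATE_MAT: {exc}") from exc
    if Q.shape != (4, 4):
        raise ValueError("RATE_MAT must be 4x4")
    rowsum = Q.sum(axis=1)
    if np.max(np.abs(rowsum)) > 1e-6 * (1 + 1e-6):
        raise ValueError("RATE_MAT rows do not sum to 0")
    if np.max(np.abs(rowsum)) > 0:
        logger.warning("fixing RATE_MAT diagonal (rows off by <= 1e-6)")
        np.fill_diagonal(Q, np.diag(Q) - rowsum)
    db = pi[:, None] * Q
    if np.max(np.abs(db - db.T)) > 1e-4:
        raise ValueError("RATE_MAT violates detailed balance beyond 1e-4")

    if "TREE" not in records:
        raise ValueError("missing TREE record")
    tree = read_newick(records["TREE"])

    mu = float(-(pi * np.diag(Q)).sum())
    if mu <= 0:
        raise ValueError("rate matrix has non-positive total rate")
    if abs(mu - 1.0) > 1e-6:
        logger.warning("rescaling Q to unit rate (was %.6f); tree rescaled", mu)
        Q = Q / mu
        tree = tree.rescale(mu)
    return NeutralModel(Q, pi, tree)


def write_phast_mod(model: NeutralModel) -> str:
    rows = "\n".join(
        "  " + " ".join(f"{x:+.6f}" for x in row) for row in model.Q
    )
    bg = " ".join(f"{x:.6f}" for x in model.pi)
    tree = write_newick(model.tree) if model.tree is not None else ""
    return (
        "ALPHABET: A C G T\nORDER: 0\nSUBST_MOD: REV\n"
        f"BACKGROUND: {bg}\nRATE_MAT:\n{rows}\nTREE: {tree}\n"
    )


# ---------------------------------------------------------------------------
# Alignments


def read_fasta_alignment(source: str | Path | TextIO) -> Alignment:
    """Read an aligned FASTA file into an Alignment (uppercased)."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        msa = AlignIO.read(handle, "fasta")
    except ValueError as exc:
        raise ValueError(f"invalid FASTA alignment: {exc}") from exc
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return Alignment.from_strings({rec.id: str(rec.seq) for rec in msa})


@dataclass
class MafBlock:
    """One MAF alignment block; the first 's' line is the reference."""

    species: list[str]       # source name before the first '.'
    texts: list[str]         # aligned rows, uppercased
    ref_chrom: str
    ref_start: int           # 0-based on the reference
    ref_size: int            # ungapped reference length

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_size

    @property
    def width(self) -> int:
        return len(self.texts[0])


def read_maf(source: str | Path | TextIO) -> Iterator[MafBlock]:
    """Stream MAF blocks; reference species = first row of each block."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        for msa in AlignIO.parse(handle, "maf"):
            records = list(msa)
            if not records:
                continue
            widths = {len(rec.seq) for rec in records}
            if len(widths) != 1:
                raise ValueError("MAF block with inconsistent text lengths")
            ref = records[0]
            if ref.annotations.get("strand", 1) != 1:
                raise ValueError("reference row must be on the + strand")
            src = ref.id
            species = [rec.id.split(".", 1)[0] for rec in records]
            texts = [str(rec.seq).upper() for rec in records]
            chrom = src.split(".", 1)[1] if "." in src else src
            yield MafBlock(
                species=species,
                texts=texts,
                ref_chrom=chrom,
                ref_start=int(ref.annotations["start"]),
                ref_size=int(ref.annotations["size"]),
            )
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def _block_keep_mask(block: MafBlock, start: int, end: int) -> np.ndarray:
    """Columns of the block to keep for reference interval [start, end).

    Non-gap reference columns are kept when their coordinate falls in
    the interval; reference-gap columns (insertions) are kept only when
    strictly internal to the extracted interval.
    """
    ref = block.texts[0]
    width = len(ref)
    keep = np.zeros(width, dtype=bool)
    pos = block.ref_start
    prev_in = False  # last non-gap ref column was inside the interval
    pending_gaps: list[int] = []
    for j, c in enumerate(ref):
        if c == "-":
            if prev_in:
                pending_gaps.append(j)
            continue
        inside = start <= pos < end
        if inside:
            if prev_in:
                for g in pending_gaps:
                    keep[g] = True
            keep[j] = True
        pending_gaps = []
        prev_in = inside
        pos += 1
    return keep


def extract_region(
    maf_stream: Iterable[MafBlock], region: Region
) -> Alignment | None:
    """Slice and stitch MAF blocks over a reference region.

    Species absent from a block are filled with 'N'; reference-gap
    columns internal to the region are retained.  Returns None when the
    region is entirely uncovered (caller emits an NA record).
    """
    pieces: list[tuple[list[str], np.ndarray]] = []  # (species, coded cols)
    species_order: list[str] = []
    from .likelihood import _CODE  # shared nucleotide coding

    for block in maf_stream:
        if block.ref_chrom != region.chrom:
            continue
        if block.ref_end <= region.start:
            continue
        if block.ref_start >= region.end:
            break  # blocks are reference-sorted
        keep = _block_keep_mask(block, region.start, region.end)
        if not keep.any():
            continue
        coded = np.array(
            [[_CODE[c] for c in text] for text in block.texts], dtype=np.int8
        )[:, keep]
        pieces.append((block.species, coded))
        for sp in block.species:
            if sp not in species_order:
                species_order.append(sp)
    if not pieces:
        return None
    total = sum(cols.shape[1] for _, cols in pieces)
    data = np.full((len(species_order), total), MISSING, dtype=np.int8)
    row_of = {sp: i for i, sp in enumerate(species_order)}
    at = 0
    for species, cols in pieces:
        w = cols.shape[1]
        for i, sp in enumerate(species):
            data[row_of[sp], at : at + w] = cols[i]
        at += w
    return Alignment(species_order, data)


# ---------------------------------------------------------------------------
# BED / score tables / tracks


def read_bed(source: str | Path | TextIO) -> list[Region]:
    handle = open(source) if isinstance(source, (str, Path)) else source
    regions: list[Region] = []
    try:
        for ln, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"BED line {ln}: non-numeric coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                regions.append(Region(fields[0], start, end, name, strand))
            except ValueError as exc:
                raise ValueError(f"BED line {ln}: {exc}") from exc
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return regions


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.6g}"


def write_scores(
    records: Iterable[ScoreRecord],
    dest: str | Path | TextIO,
    *,
    header_comments: Iterable[str] = (),
) -> None:
    handle = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        handle.write("\t".join(SCORE_COLUMNS) + "\n")
        for rec in records:
            r = rec.region
            robust = "NA" if rec.robust is None else str(rec.robust).lower()
            handle.write(
                "\t".join(
                    [
                        r.chrom, str(r.start), str(r.end), r.name or ".",
                        _fmt(rec.rho0), _fmt(rec.rho1), _fmt(rec.lambda_hat),
                        _fmt(rec.lrt_p), _fmt(rec.pcorr), _fmt(rec.scorr),
                        robust, str(rec.n_permulations_used),
                    ]
                )
                + "\n"
            )
    finally:
        if isinstance(dest, (str, Path)):
            handle.close()


def read_scores(source: str | Path | TextIO) -> list[ScoreRecord]:
    handle = open(source) if isinstance(source, (str, Path)) else source

    def _num(x: str) -> float | None:
        return None if x == "NA" else float(x)

    records: list[ScoreRecord] = []
    try:
        header: list[str] | None = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != SCORE_COLUMNS:
                    raise ValueError(f"unexpected score table columns: {header}")
                continue
            f = dict(zip(SCORE_COLUMNS, line.split("\t")))
            records.append(
                ScoreRecord(
                    region=Region(
                        f["chrom"], int(f["start"]), int(f["end"]),
                        None if f["name"] == "." else f["name"],
                    ),
                    rho0=_num(f["rho0"]), rho1=_num(f["rho1"]),
                    lambda_hat=_num(f["lambda"]), lrt_p=_num(f["lrt_p"]),
                    pcorr=_num(f["pcorr"]), scorr=_num(f["scorr"]),
                    robust=None if f["robust"] == "NA" else f["robust"] == "true",
                    n_permulations_used=int(f["n_perm"]),
                )
            )
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return records


def write_track(
    records: Iterable[ScoreRecord], dest: str | Path | TextIO
) -> None:
    """bedGraph of scorr; records without a calibrated score are omitted."""
    handle = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        rows = [
            (r.region.chrom, r.region.start, r.region.end, r.scorr)
            for r in records
            if r.scorr is not None
        ]
        rows.sort(key=lambda x: (x[0], x[1]))
        for chrom, start, end, value in rows:
            handle.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")
    finally:
        if isinstance(dest, (str, Path)):
            handle.close()
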